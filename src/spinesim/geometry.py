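"""Triangle-mesh representation of the spine membrane and its operators.

The membrane Gamma is a closed (watertight) triangle mesh: a spheroidal head
on a cylindrical neck, closed by a disc in the x-y plane that stands in for
the dendrite surface.  Disc and rim vertices are "fixed": they anchor the
spine and are never displaced by the dynamics.

The bending energy is the discrete Helfrich functional

    E_mem = kappa/2 * sum_v A_v * H_v^2,      H_v = |K_v| / A_v,

where K_v is the integrated mean-curvature vector from the cotangent
Laplacian (equal to the gradient of total surface area) and A_v the
barycentric dual area.  With this convention H is the *sum* of principal
curvatures, so a sphere of any radius has energy 8*pi*kappa.  The bending
force returned by :func:`bending_force` is the exact analytic gradient of
this discrete energy (hand-derived reverse-mode differentiation), which a
finite-difference oracle can verify to high accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

from .params import MechanicsParams

__all__ = [
    "SpineMesh",
    "build_initial_spine",
    "mesh_volume",
    "mesh_area",
    "bending_energy",
    "bending_force",
    "cross_section_radius",
    "cross_section_loops",
]

_MIN_FACE_AREA = 1e-12  # um^2


@dataclass
class SpineMesh:
    """Watertight, outward-oriented triangle mesh with a fixed vertex set.

    vertices : (n_v, 3) float array, positions in um.
    faces    : (n_f, 3) int array, outward-oriented triangles.
    fixed_mask : (n_v,) bool array; True for dendrite-base vertices that are
        held immobile by every dynamics operation.
    """

    vertices: np.ndarray
    faces: np.ndarray
    fixed_mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.fixed_mask is None:
            self.fixed_mask = np.zeros(len(self.vertices), dtype=bool)
        self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
        if self.fixed_mask.shape != (len(self.vertices),):
            raise ValueError("fixed_mask must have one entry per vertex")

    @property
    def n_v(self) -> int:
        return len(self.vertices)

    @property
    def fixed_vertex_ids(self) -> np.ndarray:
        return np.flatnonzero(self.fixed_mask)

    def copy(self) -> "SpineMesh":
        return SpineMesh(
            self.vertices.copy(), self.faces.copy(), self.fixed_mask.copy()
        )

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    # -- validation ---------------------------------------------------------

    def open_edges(self) -> np.ndarray:
        """Edges not shared by exactly two faces; empty for watertight."""
        e = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq[counts != 2]

    def is_watertight(self) -> bool:
        return len(self.open_edges()) == 0

    def check_valid(self) -> None:
        bad = self.open_edges()
        if len(bad):
            raise ValueError(
                f"mesh is not watertight; {len(bad)} open/overshared edges, "
                f"e.g. {bad[:5].tolist()}"
            )
        areas = _face_areas(self.vertices, self.faces)
        if (areas <= _MIN_FACE_AREA).any():
            raise ValueError(
                f"{int((areas <= _MIN_FACE_AREA).sum())} degenerate faces "
                f"(area <= {_MIN_FACE_AREA} um^2)"
            )

    def edge_lengths(self) -> np.ndarray:
        e = np.sort(self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        e = np.unique(e, axis=0)
        return np.linalg.norm(
            self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1
        )

    def save(self, path: str) -> None:
        """Write PLY/OFF (by extension) via trimesh."""
        self.as_trimesh().export(path)


# ---------------------------------------------------------------------------
# basic measures
# ---------------------------------------------------------------------------


def _face_normals_raw(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    return np.cross(V[F[:, 1]] - V[F[:, 0]], V[F[:, 2]] - V[F[:, 0]])


def _face_areas(V: np.ndarray, F: np.ndarray) -> np.ndarray:
    return 0.5 * np.linalg.norm(_face_normals_raw(V, F), axis=1)


def mesh_volume(mesh: SpineMesh) -> float:
    """Signed enclosed volume (divergence theorem); positive when outward."""
    bad = mesh.open_edges()
    if len(bad):
        raise ValueError(
            f"volume undefined: mesh not watertight ({len(bad)} open edges, "
            f"e.g. {bad[:5].tolist()})"
        )
    V, F = mesh.vertices, mesh.faces
    return float(
        np.einsum("ij,ij->i", V[F[:, 0]], _face_normals_raw(V, F) / 2).sum()
        / 3.0
    )


def mesh_area(mesh: SpineMesh) -> float:
    """Total surface area (sum of triangle areas)."""
    return float(_face_areas(mesh.vertices, mesh.faces).sum())


# ---------------------------------------------------------------------------
# discrete Helfrich bending energy and its exact gradient
# ---------------------------------------------------------------------------


def _curvature_quantities(V: np.ndarray, F: np.ndarray):
    """Integrated mean-curvature vectors K_v, dual areas A_v and cotangents.

    K_v = 1/2 sum_j (cot a_ij + cot b_ij)(s_v - s_j) equals the gradient of
    total area at v; |K_v| / A_v is the (principal-curvature-sum) mean
    curvature.  Returns (K, A_dual, cot, face_areas) with cot[c, f] the
    cotangent at corner c of face f.
    """
    n_v = len(V)
    i, j, k = F[:, 0], F[:, 1], F[:, 2]
    raw_n = _face_normals_raw(V, F)
    double_area = np.linalg.norm(raw_n, axis=1)
    fa = 0.5 * double_area

    # cotangent at each corner: dot of adjacent edges / twice face area
    cot = np.empty((3, len(F)))
    cot[0] = np.einsum("ij,ij->i", V[j] - V[i], V[k] - V[i]) / double_area
    cot[1] = np.einsum("ij,ij->i", V[k] - V[j], V[i] - V[j]) / double_area
    cot[2] = np.einsum("ij,ij->i", V[i] - V[k], V[j] - V[k]) / double_area

    K = np.zeros((n_v, 3))
    # corner c is opposite edge (a, b); contributes 0.5*cot_c*(s_a - s_b)
    for c, (a, b) in ((0, (j, k)), (1, (k, i)), (2, (i, j))):
        t = 0.5 * cot[c][:, None] * (V[a] - V[b])
        np.add.at(K, a, t)
        np.add.at(K, b, -t)

    A_dual = np.zeros(n_v)
    third = fa / 3.0
    for col in (i, j, k):
        np.add.at(A_dual, col, third)
    return K, A_dual, cot, fa


def bending_energy(mesh: SpineMesh, params: MechanicsParams) -> float:
    """Discrete Helfrich energy kappa/2 * sum_v |K_v|^2 / A_v (pN um)."""
    K, A, _, fa = _curvature_quantities(mesh.vertices, mesh.faces)
    if (fa <= _MIN_FACE_AREA).any():
        raise ValueError("degenerate faces: bending energy undefined")
    return float(0.5 * params.kappa * ((K * K).sum(axis=1) / A).sum())


def bending_force(mesh: SpineMesh, params: MechanicsParams) -> np.ndarray:
    """Per-vertex bending force F_mem = -dE_mem/ds (pN), exact gradient.

    Forces at fixed vertices are computed like any other; callers of the
    dynamics zero them.
    """
    V, F = mesh.vertices, mesh.faces
    K, A, cot, fa = _curvature_quantities(V, F)
    if (fa <= _MIN_FACE_AREA).any():
        raise ValueError("degenerate faces: bending force undefined")
    kappa = params.kappa

    # reverse-mode sensitivities of E = kappa/2 sum |K|^2 / A
    P = kappa * K / A[:, None]                      # dE/dK_v
    q = -0.5 * kappa * (K * K).sum(axis=1) / A**2   # dE/dA_v

    grad = np.zeros_like(V)
    i, j, k = F[:, 0], F[:, 1], F[:, 2]

    # --- through the dual areas: A_v = 1/3 sum_{f ni v} area(f)
    w_f = (q[i] + q[j] + q[k]) / 3.0                # dE/darea(f)
    nhat = _face_normals_raw(V, F)
    nhat = nhat / (2.0 * fa)[:, None]
    # grad_i area = 0.5 * (s_j - s_k) x nhat, cyclically
    for a, b, c in ((i, j, k), (j, k, i), (k, i, j)):
        np.add.at(grad, a, 0.5 * w_f[:, None] * np.cross(V[b] - V[c], nhat))

    # --- through K: per face, corner c opposite edge (a, b) contributes
    #     T = 0.5 * cot_c * (s_a - s_b) to K_a and -T to K_b.
    g_cot = np.empty((3, len(F)))
    # corner index order in `cot`: cot[0] at vertex i (opposite j,k), etc.
    opp = {0: (j, k), 1: (k, i), 2: (i, j)}
    for c in range(3):
        a, b = opp[c]
        G = P[a] - P[b]                              # dE/dT
        g_cot[c] = 0.5 * np.einsum("ij,ij->i", V[a] - V[b], G)
        t = 0.5 * cot[c][:, None] * G
        np.add.at(grad, a, t)
        np.add.at(grad, b, -t)

    # --- through the cotangents.  cot at corner c of face (with vertices
    # ordered so corner vertex is vc and the other two va, vb):
    # u = s_a - s_c, v = s_b - s_c, m = u x v,
    # cot = (u.v)/|m|;  d cot/du = v/|m| - (u.v)(v x m)/|m|^3, sym. for v.
    for c in range(3):
        vc_idx = F[:, c]
        va_idx = F[:, (c + 1) % 3]
        vb_idx = F[:, (c + 2) % 3]
        u = V[va_idx] - V[vc_idx]
        v = V[vb_idx] - V[vc_idx]
        m = np.cross(u, v)
        nrm = np.linalg.norm(m, axis=1)
        cdot = np.einsum("ij,ij->i", u, v)
        inv = 1.0 / nrm
        du = v * inv[:, None] - (cdot * inv**3)[:, None] * np.cross(m, v) * -1.0
        dv = u * inv[:, None] - (cdot * inv**3)[:, None] * np.cross(m, u)
        # note: d|m|/du = (v x m)/|m| ; cross(m, v) = -cross(v, m)
        g = g_cot[c][:, None]
        np.add.at(grad, va_idx, g * du)
        np.add.at(grad, vb_idx, g * dv)
        np.add.at(grad, vc_idx, -g * (du + dv))

    return -grad


# ---------------------------------------------------------------------------
# initial shape: spheroid head + cylindrical neck + base disc
# ---------------------------------------------------------------------------


def _profile_stations(head_radius, head_center_z, neck_radius, spacing):
    """(z, r) ring stations along the neck+head profile, ~`spacing` apart.

    The cylinder runs from z = 0 to the junction height
    z_j = zc - sqrt(R^2 - r_n^2) where it meets the sphere surface; above
    that the profile follows the sphere.  Stations are placed at equal
    arclength along this polyline, so steep parts of the head get
    correspondingly more rings.
    """
    R, zc, rn = head_radius, head_center_z, neck_radius
    z_j = zc - np.sqrt(R**2 - rn**2)
    th_j = np.arcsin(np.clip((z_j - zc) / R, -1.0, 1.0))
    th = np.linspace(th_j, np.pi / 2, 2000)
    zs = np.concatenate([[0.0], zc + R * np.sin(th)])
    rs = np.concatenate([[rn], R * np.cos(th)])
    seg = np.hypot(np.diff(zs), np.diff(rs))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_st = max(4, int(round(s[-1] / spacing)))
    s_st = np.linspace(0.0, s[-1], n_st + 1)
    z_st = np.interp(s_st, s, zs)
    r_st = np.interp(s_st, s, rs)
    return z_st, r_st, z_j


def _ring(z, r, n, phase=0.0):
    th = 2 * np.pi * (np.arange(n) + phase) / n
    return np.column_stack([r * np.cos(th), r * np.sin(th), np.full(n, z)])


def _bridge_faces(idx_lo, idx_hi, flip=False):
    """Triangulate the annulus between two vertex rings (index arrays).

    Rings are ordered by increasing angle; the zigzag walk advances on the
    ring whose next vertex has the smaller angle, giving near-equilateral
    triangles for arbitrary ring sizes.
    """
    n1, n2 = len(idx_lo), len(idx_hi)
    if n1 == 1:  # fan from a single apex below
        f = np.column_stack(
            [np.full(n2, idx_lo[0]), np.roll(idx_hi, -1), idx_hi]
        ).astype(np.int64)
        return f[:, ::-1] if flip else f
    if n2 == 1:  # fan to a single apex above
        f = np.column_stack(
            [idx_lo, np.roll(idx_lo, -1), np.full(n1, idx_hi[0])]
        ).astype(np.int64)
        return f[:, ::-1] if flip else f
    faces = []
    i = jj = 0
    while i < n1 or jj < n2:
        adv_lo = jj >= n2 or (i < n1 and (i + 1) / n1 <= (jj + 1) / n2)
        if adv_lo:
            faces.append(
                (idx_lo[i % n1], idx_lo[(i + 1) % n1], idx_hi[jj % n2])
            )
            i += 1
        else:
            faces.append(
                (idx_lo[i % n1], idx_hi[(jj + 1) % n2], idx_hi[jj % n2])
            )
            jj += 1
    faces = np.array(faces, dtype=np.int64)
    if flip:
        faces = faces[:, ::-1]
    return faces


def build_initial_spine(
    head_radius: float = 0.25,
    head_center_z: float = 0.85,
    neck_radius: float = 0.1,
    neck_length: float = 0.6,
    target_edge: float = 0.05,
    remesh: bool = True,
) -> SpineMesh:
    """Construct the initial spine membrane as a surface of revolution.

    A spherical head (radius ``head_radius`` centred on the z axis at
    ``head_center_z``) sits on a cylindrical neck of radius ``neck_radius``;
    the cylinder runs from z = 0 up to its tangential junction with the head
    sphere at z_j = zc - sqrt(R^2 - r_n^2), so the two surfaces meet cleanly
    (``neck_length`` is validated against the head position but the junction
    height is geometric).  The shape is closed by a disc in the x-y plane;
    disc and rim vertices (z = 0) are marked fixed.  The surface is sampled
    in rings ~``target_edge`` apart and optionally passed through the
    isotropic remesher for uniform edge lengths.
    """
    for name, val in (
        ("head_radius", head_radius),
        ("neck_radius", neck_radius),
        ("neck_length", neck_length),
        ("target_edge", target_edge),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    if neck_radius >= head_radius:
        raise ValueError(
            "degenerate geometry: neck_radius must be smaller than "
            f"head_radius (got {neck_radius} >= {head_radius})"
        )
    if target_edge >= neck_radius:
        raise ValueError("target_edge must be smaller than neck_radius")
    if head_center_z - head_radius > neck_length + 1e-12:
        raise ValueError(
            "degenerate geometry: head does not touch the neck "
            f"(head bottom {head_center_z - head_radius:.4f} above "
            f"neck top {neck_length:.4f})"
        )

    dz_nominal = target_edge * np.sqrt(3) / 2
    z_st, r_st, _ = _profile_stations(
        head_radius, head_center_z, neck_radius, dz_nominal
    )
    z_top = head_center_z + head_radius

    verts = []
    ring_indices = []
    fixed = []

    def add_ring(z, r, phase):
        n = max(6, int(round(2 * np.pi * r / target_edge)))
        start = len(verts)
        verts.extend(_ring(z, r, n, phase))
        idx = np.arange(start, start + n)
        return idx

    # base disc (z = 0): center point, then rings out to neck_radius
    verts.append(np.array([0.0, 0.0, 0.0]))
    fixed_upto = None
    disc_radii = np.arange(target_edge, neck_radius - 0.3 * target_edge,
                           target_edge)
    disc_radii = np.append(disc_radii, neck_radius)
    prev = np.array([0], dtype=np.int64)
    faces = []
    for m, r in enumerate(disc_radii):
        idx = add_ring(0.0, r, 0.5 * (m % 2))
        faces.append(_bridge_faces(prev, idx))
        prev = idx
    fixed_upto = len(verts)  # all disc vertices incl. rim are fixed

    # side wall: one ring per profile station above z = 0 (rim is `prev`)
    pole_cut = 0.45 * target_edge
    for m in range(1, len(z_st)):
        z, r = z_st[m], r_st[m]
        if r < pole_cut or z >= z_top - 1e-12:
            break
        idx = add_ring(z, r, 0.5 * (m % 2))
        faces.append(_bridge_faces(prev, idx))
        prev = idx

    # close the head with a pole vertex
    pole = len(verts)
    verts.append(np.array([0.0, 0.0, z_top]))
    n = len(prev)
    fan = np.column_stack(
        [prev, np.roll(prev, -1), np.full(n, pole, dtype=np.int64)]
    )
    faces.append(fan)

    V = np.asarray(verts, dtype=float)
    F = np.vstack(faces)
    fixed_mask = np.zeros(len(V), dtype=bool)
    fixed_mask[:fixed_upto] = True

    mesh = SpineMesh(V, F, fixed_mask)
    if mesh_volume(mesh) < 0:
        mesh = SpineMesh(V, F[:, ::-1], fixed_mask)
    mesh.check_valid()

    if remesh:
        from .remesh import remesh_isotropic

        # construction rings are already close to the target; allow the
        # larger volume slack a coarse target needs on curved regions
        mesh = remesh_isotropic(mesh, target_edge, n_iter=8, vol_tol=0.05)
        mesh.check_valid()
    return mesh


# ---------------------------------------------------------------------------
# planar cross-sections
# ---------------------------------------------------------------------------


def cross_section_loops(mesh: SpineMesh, z: float):
    """Closed polygon loops of the intersection of the mesh with plane z."""
    tm = mesh.as_trimesh()
    lines = trimesh.intersections.mesh_plane(
        tm, plane_normal=[0.0, 0.0, 1.0], plane_origin=[0.0, 0.0, z]
    )
    if len(lines) == 0:
        raise ValueError(f"plane z={z} does not intersect the mesh")
    # chain segments into loops by matching endpoints
    def key(p):
        return tuple(np.round(p, 9))

    segs = [(key(a), key(b), a, b) for a, b in lines]
    adj = {}
    for ka, kb, a, b in segs:
        adj.setdefault(ka, []).append((kb, b))
        adj.setdefault(kb, []).append((ka, a))
    visited = set()
    loops = []
    for ka, kb, a, b in segs:
        if ka in visited:
            continue
        loop = [a]
        cur, prev = ka, None
        for _ in range(len(segs) + 1):
            visited.add(cur)
            nxts = [n for n in adj[cur] if n[0] != prev]
            if not nxts:
                break
            prev = cur
            cur = nxts[0][0]
            if cur == key(loop[0]):
                break
            loop.append(nxts[0][1])
        if len(loop) >= 3:
            loops.append(np.asarray(loop))
    if not loops:
        raise ValueError(f"no closed intersection loop at z={z}")
    return loops


def cross_section_radius(mesh: SpineMesh, z: float) -> float:
    """Equivalent-area radius sqrt(A/pi) of the single mesh/plane loop."""
    loops = cross_section_loops(mesh, z)
    if len(loops) != 1:
        raise ValueError(
            f"cross-section at z={z} has {len(loops)} loops; expected 1"
        )
    poly = loops[0][:, :2]
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(
        np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))
    )
    return float(np.sqrt(area / np.pi))
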