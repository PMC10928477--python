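"""Signed distance from lattice points to the membrane mesh.

The reaction-transport fields live on a fixed cubic lattice; the membrane is
a moving triangle mesh.  Coupling between the two goes through the signed
distance d_s(r, Gamma) (negative inside the enclosed domain), the unit
direction field d = grad d_s pointing toward increasing distance (outward),
the soft repulsive potential

    psi(r, Gamma) = alpha * tanh(beta * d_s) / 2,

and the confining force density f_u = -grad psi, which is antiparallel to d
and maximal in magnitude on the membrane itself.

Closest-element queries are exact: a KD-tree over face centroids only prunes
candidates (using the nearest-vertex distance as an upper bound), and the
per-triangle arithmetic is identical to the exhaustive scan, so accelerated
results are bitwise equal to brute force.  Inside/outside is decided with
angle-weighted pseudo-normals, which are sign-correct for watertight meshes
even when the closest feature is an edge or vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import SpineMesh
from .params import RepulsivePotentialParams

__all__ = [
    "LatticeGrid",
    "DistanceField",
    "MeshQuery",
    "compute_signed_distance",
    "signed_distance_brute_force",
    "repulsive_potential",
    "force_density",
    "divergence_of_direction",
]

SURFACE_EPS = 1e-9  # um; |ds| below this counts as "on the surface"


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LatticeGrid:
    """Regular cubic lattice: positions origin + spacing * (i, j, k).

    Point (i, j, k) maps to flat index i*ny*nz + j*nz + k (C order).  The
    lattice never changes during a run.
    """

    origin: tuple
    spacing: float
    shape: tuple

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @classmethod
    def from_bounds(
        cls, bounds: np.ndarray, spacing: float, margin_cells: int = 4
    ) -> "LatticeGrid":
        """Grid covering [lo, hi] bounds with a margin of whole cells."""
        lo = np.asarray(bounds[0], dtype=float) - margin_cells * spacing
        hi = np.asarray(bounds[1], dtype=float) + margin_cells * spacing
        shape = np.ceil((hi - lo) / spacing).astype(int) + 1
        return cls(tuple(lo), float(spacing), tuple(shape))

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def axes(self):
        return tuple(
            self.origin[a] + self.spacing * np.arange(self.shape[a])
            for a in range(3)
        )

    def positions(self) -> np.ndarray:
        ax = self.axes()
        g = np.meshgrid(*ax, indexing="ij")
        return np.stack([c.ravel() for c in g], axis=1)

    def bounds(self) -> np.ndarray:
        lo = np.asarray(self.origin)
        hi = lo + self.spacing * (np.asarray(self.shape) - 1)
        return np.stack([lo, hi])

    def reshape(self, flat: np.ndarray) -> np.ndarray:
        return flat.reshape(self.shape + flat.shape[1:])

    @property
    def cell_volume(self) -> float:
        return self.spacing**3

    def contains_mesh(self, mesh: SpineMesh, margin_cells: int = 2) -> bool:
        lo, hi = self.bounds()
        m = margin_cells * self.spacing
        vlo = mesh.vertices.min(axis=0)
        vhi = mesh.vertices.max(axis=0)
        return bool((vlo >= lo + m - 1e-12).all() and (vhi <= hi - m + 1e-12).all())


# ---------------------------------------------------------------------------
# closest point on triangle (vectorized, Ericson's method)
# ---------------------------------------------------------------------------


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray):
    """Closest point of each p[i] on its triangle tri[i]; returns (q, bary)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    n = len(p)
    bary = np.empty((n, 3))
    done = np.zeros(n, dtype=bool)

    def assign(mask, u, v, w):
        m = mask & ~done
        bary[m, 0] = u if np.isscalar(u) else u[m]
        bary[m, 1] = v if np.isscalar(v) else v[m]
        bary[m, 2] = w if np.isscalar(w) else w[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), 1.0, 0.0, 0.0)            # vertex a
    assign((d3 >= 0) & (d4 <= d3), 0.0, 1.0, 0.0)           # vertex b
    assign((d6 >= 0) & (d5 <= d6), 0.0, 0.0, 1.0)           # vertex c

    with np.errstate(divide="ignore", invalid="ignore"):
        vc = d1 * d4 - d3 * d2
        t_ab = d1 / (d1 - d3)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), 1.0 - t_ab, t_ab, 0.0)

        vb = d5 * d2 - d1 * d6
        t_ac = d2 / (d2 - d6)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), 1.0 - t_ac, 0.0, t_ac)

        va = d3 * d6 - d5 * d4
        t_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        assign(
            (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
            0.0, 1.0 - t_bc, t_bc,
        )

        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        assign(np.ones(n, dtype=bool), 1.0 - v - w, v, w)   # face interior

    q = (bary[:, :, None] * tri).sum(axis=1)
    return q, bary


# ---------------------------------------------------------------------------
# mesh query structure
# ---------------------------------------------------------------------------


class MeshQuery:
    """Exact nearest-element queries against one snapshot of the membrane."""

    def __init__(self, mesh: SpineMesh):
        self.mesh = mesh
        V, F = mesh.vertices, mesh.faces
        self.tri = V[F]
        raw = np.cross(
            self.tri[:, 1] - self.tri[:, 0], self.tri[:, 2] - self.tri[:, 0]
        )
        nrm = np.linalg.norm(raw, axis=1)
        if (nrm <= 2e-12).any():
            raise ValueError("degenerate faces in mesh query")
        self.face_normals = raw / nrm[:, None]
        self._vert_tree = cKDTree(V)
        centroids = self.tri.mean(axis=1)
        self._cent_tree = cKDTree(centroids)
        self._max_reach = float(
            np.linalg.norm(self.tri - centroids[:, None, :], axis=2).max()
        )
        self._pseudo_normals = self._build_pseudo_normals()

    def _build_pseudo_normals(self):
        """Angle-weighted vertex normals and per-(face, corner) edge normals.

        edge_normals[f, c] is the summed normal of the two faces sharing the
        edge *opposite* corner c of face f, matching how a single zero
        barycentric coordinate identifies the closest edge.
        """
        V, F = self.mesh.vertices, self.mesh.faces
        vn = np.zeros_like(V)
        for c in range(3):
            vc = F[:, c]
            e1 = V[F[:, (c + 1) % 3]] - V[vc]
            e2 = V[F[:, (c + 2) % 3]] - V[vc]
            cosang = np.einsum("ij,ij->i", e1, e2) / (
                np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
            )
            ang = np.arccos(np.clip(cosang, -1.0, 1.0))
            np.add.at(vn, vc, ang[:, None] * self.face_normals)
        # edge opposite corner 0 is (v1, v2), etc.
        pairs = np.stack(
            [F[:, [1, 2]], F[:, [2, 0]], F[:, [0, 1]]], axis=1
        ).reshape(-1, 2)
        pairs = np.sort(pairs, axis=1)
        uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
        acc = np.zeros((len(uniq), 3))
        np.add.at(acc, inverse, np.repeat(self.face_normals, 3, axis=0))
        edge_normals = acc[inverse].reshape(len(F), 3, 3)
        return vn, edge_normals

    def query(
        self,
        points: np.ndarray,
        brute_force: bool = False,
        ub: np.ndarray | None = None,
    ):
        """Unsigned closest-element query.

        Returns (distance, face_id, bary, closest_point).  The pruned path
        evaluates the identical per-triangle arithmetic as the exhaustive
        scan over faces in index order, so results agree bitwise.  An
        optional per-point upper bound ``ub`` on the surface distance (e.g.
        from a warm start) tightens the candidate search.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        n_f = len(self.tri)
        if brute_force:
            cand = [np.arange(n_f)] * n
        else:
            if ub is None:
                ub, _ = self._vert_tree.query(points)
            lists = self._cent_tree.query_ball_point(
                points, ub + self._max_reach + 1e-12
            )
            cand = [np.sort(np.asarray(c, dtype=np.int64)) for c in lists]
            short = [i for i, c in enumerate(cand) if len(c) == 0]
            if short:  # stale bound: fall back to the vertex-tree bound
                ub2, _ = self._vert_tree.query(points[short])
                lists2 = self._cent_tree.query_ball_point(
                    points[short], ub2 + self._max_reach + 1e-12
                )
                for i, c in zip(short, lists2):
                    cand[i] = np.sort(np.asarray(c, dtype=np.int64))

        counts = np.array([len(c) for c in cand])
        if (counts == 0).any():
            raise RuntimeError("empty candidate set in mesh query")
        flat_faces = np.concatenate(cand)
        flat_pts = np.repeat(points, counts, axis=0)
        q, bary = _closest_on_triangles(flat_pts, self.tri[flat_faces])
        d2 = ((flat_pts - q) ** 2).sum(axis=1)

        # segmented argmin; candidates are sorted by face index so ties
        # resolve to the lowest face id, exactly as the exhaustive scan does
        offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        dmin = np.minimum.reduceat(d2, offsets)
        is_min = d2 == np.repeat(dmin, counts)
        flat_hits = np.flatnonzero(is_min)
        seg = np.searchsorted(offsets, flat_hits, side="right") - 1
        _, first = np.unique(seg, return_index=True)
        best = flat_hits[first]
        return (
            np.sqrt(d2[best]),
            flat_faces[best],
            bary[best],
            q[best],
        )

    def signs(self, points, dist, face_id, bary, closest) -> np.ndarray:
        """-1 inside, +1 outside, via the pseudo-normal of the closest feature."""
        F = self.mesh.faces
        vn, en = self._pseudo_normals
        w = points - closest
        nonzero = bary > 1e-12
        n_nonzero = nonzero.sum(axis=1)
        normal = self.face_normals[face_id].copy()       # face-interior case
        on_edge = n_nonzero == 2                          # one zero bary
        if on_edge.any():
            zero_corner = np.argmin(bary[on_edge], axis=1)
            normal[on_edge] = en[face_id[on_edge], zero_corner]
        on_vert = n_nonzero == 1
        if on_vert.any():
            corner = np.argmax(bary[on_vert], axis=1)
            vids = F[face_id[on_vert], corner]
            normal[on_vert] = vn[vids]
        dots = np.einsum("ij,ij->i", w, normal)
        return np.where(dots > 0, 1.0, -1.0)


# ---------------------------------------------------------------------------
# distance field
# ---------------------------------------------------------------------------


@dataclass
class DistanceField:
    """Per-lattice-point signed distance and closest-element map.

    ds : signed distance (um), negative inside the spine.
    face_id : closest face index per point.
    bary : barycentric coordinates of the closest point on that face
        (one-hot when the closest feature is a vertex).
    direction : unit vector d = grad ds (outward); equals the outward face
        normal where |ds| <= SURFACE_EPS.
    w : offset r - closest_point.
    """

    grid: LatticeGrid
    ds: np.ndarray
    face_id: np.ndarray
    bary: np.ndarray
    direction: np.ndarray
    w: np.ndarray
    mesh_vertices: np.ndarray = field(repr=False, default=None)
    mesh_faces: np.ndarray = field(repr=False, default=None)

    def matches_mesh(self, mesh: SpineMesh) -> bool:
        return (
            self.mesh_vertices is not None
            and self.mesh_vertices.shape == mesh.vertices.shape
            and np.array_equal(self.mesh_vertices, mesh.vertices)
            and np.array_equal(self.mesh_faces, mesh.faces)
        )

    @property
    def inside(self) -> np.ndarray:
        return self.ds < 0


def compute_signed_distance(
    grid: LatticeGrid,
    mesh: SpineMesh,
    query: MeshQuery | None = None,
    brute_force: bool = False,
) -> DistanceField:
    """Signed distance, closest element and outward direction per point."""
    if not grid.contains_mesh(mesh, margin_cells=0):
        raise ValueError(
            "grid too small: mesh bounding box "
            f"{mesh.vertices.min(axis=0)}..{mesh.vertices.max(axis=0)} "
            f"exceeds grid bounds {grid.bounds().tolist()}"
        )
    if query is None:
        query = MeshQuery(mesh)
    pts = grid.positions()
    dist, face_id, bary, closest = query.query(pts, brute_force=brute_force)
    sign = query.signs(pts, dist, face_id, bary, closest)
    ds = sign * dist
    w = pts - closest

    direction = np.zeros_like(w)
    off = dist > SURFACE_EPS
    # d = grad ds = sign * w/|w| (outward for both interior and exterior pts)
    direction[off] = sign[off, None] * w[off] / dist[off, None]
    direction[~off] = query.face_normals[face_id[~off]]

    return DistanceField(
        grid=grid,
        ds=ds,
        face_id=face_id,
        bary=bary,
        direction=direction,
        w=w,
        mesh_vertices=mesh.vertices.copy(),
        mesh_faces=mesh.faces.copy(),
    )


def update_signed_distance(
    prev: DistanceField,
    mesh: SpineMesh,
    band: float,
    query: MeshQuery | None = None,
) -> DistanceField:
    """Recompute the field exactly inside a band around the membrane.

    Points with previous ds < band are re-queried against the new mesh;
    points far outside keep their cached values (they are frozen at zero
    field anyway, and the membrane moves a small fraction of the band per
    step).  A periodic full recompute (at remeshing) refreshes the cache.
    """
    if query is None:
        query = MeshQuery(mesh)
    sel = prev.ds < band
    pts = prev.grid.positions()[sel]
    # warm start: the previous closest face still exists (faces persist
    # between remeshes) and bounds the new distance tightly
    prev_faces = prev.face_id[sel]
    valid = prev_faces < len(query.tri)
    if valid.all():
        qw, _ = _closest_on_triangles(pts, query.tri[prev_faces])
        ub = np.linalg.norm(pts - qw, axis=1)
    else:
        ub = None
    dist, face_id, bary, closest = query.query(pts, ub=ub)
    sign = query.signs(pts, dist, face_id, bary, closest)

    ds = prev.ds.copy()
    fid = prev.face_id.copy()
    bar = prev.bary.copy()
    direction = prev.direction.copy()
    w = prev.w.copy()

    ds[sel] = sign * dist
    fid[sel] = face_id
    bar[sel] = bary
    w[sel] = pts - closest
    dir_sel = np.where(
        (dist > SURFACE_EPS)[:, None],
        sign[:, None] * (pts - closest) / np.maximum(dist, SURFACE_EPS)[:, None],
        query.face_normals[face_id],
    )
    direction[sel] = dir_sel
    return DistanceField(
        grid=prev.grid, ds=ds, face_id=fid, bary=bar, direction=direction,
        w=w, mesh_vertices=mesh.vertices.copy(), mesh_faces=mesh.faces.copy(),
    )


def signed_distance_brute_force(
    points: np.ndarray, mesh: SpineMesh
) -> np.ndarray:
    """Exhaustive-scan signed distance at arbitrary points (test oracle)."""
    q = MeshQuery(mesh)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    dist, face_id, bary, closest = q.query(points, brute_force=True)
    return q.signs(points, dist, face_id, bary, closest) * dist


# ---------------------------------------------------------------------------
# potential, force density, divergence
# ---------------------------------------------------------------------------


def repulsive_potential(
    dfield: DistanceField, params: RepulsivePotentialParams
) -> np.ndarray:
    """psi = alpha * tanh(beta * ds) / 2 per lattice point (pN)."""
    return 0.5 * params.alpha * np.tanh(params.beta * dfield.ds)


def force_density(
    dfield: DistanceField, params: RepulsivePotentialParams
) -> np.ndarray:
    """f_u = -grad psi = -(alpha*beta/2) sech^2(beta*ds) d  (pN/um).

    Antiparallel to the outward direction d everywhere: for interior points
    it pushes barbed ends away from the membrane into the spine.
    """
    mag = 0.5 * params.alpha * params.beta / np.cosh(params.beta * dfield.ds) ** 2
    return -mag[:, None] * dfield.direction


def divergence_of_direction(
    dfield: DistanceField, grid: LatticeGrid | None = None
) -> np.ndarray:
    """div d per lattice point (1/um), central differences (one-sided at
    the grid boundary)."""
    grid = grid or dfield.grid
    d = grid.reshape(dfield.direction)
    h = grid.spacing
    out = (
        np.gradient(d[..., 0], h, axis=0)
        + np.gradient(d[..., 1], h, axis=1)
        + np.gradient(d[..., 2], h, axis=2)
    )
    return out.ravel()
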