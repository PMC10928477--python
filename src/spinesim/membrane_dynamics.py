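"""Membrane motion under bending and actin-polymerization forces.

The overdamped force balance  F_actin + F_mem + F_drag = 0  with
F_drag = -omega * dGamma/dt gives the update

    dGamma/dt = (F_mem + F_actin) / omega .

F_actin derives from the overlap energy of barbed ends with the soft
membrane potential,

    E_B = sum_{r in Omega} psi(d_s(r)) B(r) dx^3 ,

differentiated exactly through the closest-element map: the derivative of
the point-to-mesh distance with respect to a vertex of the closest element
is -b_i * d (barycentric weight times outward direction; Danskin's theorem),
so each interior lattice point pushes the vertices of its closest element
outward with weight  B dx^3 * (alpha*beta/2) sech^2(beta d_s).  A
finite-difference oracle against the recomputed E_B validates the assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance_field import DistanceField, repulsive_potential
from .geometry import SpineMesh, bending_energy, bending_force
from .params import MechanicsParams, RepulsivePotentialParams

__all__ = [
    "VertexForceField",
    "ProtrusionTracker",
    "actin_force",
    "overlap_energy",
    "advance_membrane",
    "relax_membrane",
]


@dataclass
class VertexForceField:
    """Per-vertex 3D force vectors (pN) with a provenance tag."""

    vectors: np.ndarray
    tag: str = "total"

    def masked(self, fixed_mask: np.ndarray) -> np.ndarray:
        out = self.vectors.copy()
        out[fixed_mask] = 0.0
        return out


def overlap_energy(
    B: np.ndarray,
    dfield: DistanceField,
    pot: RepulsivePotentialParams,
    cell_volume: float,
) -> float:
    """Discretized E_B = sum over interior points of psi * B * dx^3 (pN um)."""
    inside = dfield.inside
    psi = repulsive_potential(dfield, pot)
    return float((psi[inside] * B[inside]).sum() * cell_volume)


def actin_force(
    B: np.ndarray,
    dfield: DistanceField,
    mesh: SpineMesh,
    pot: RepulsivePotentialParams,
    cell_volume: float,
) -> VertexForceField:
    """F_actin = -dE_B/ds, assembled through the closest-element map.

    Requires the distance field to have been computed against exactly this
    mesh (stale maps are rejected).  The net effect pushes the membrane
    outward where B is large close to it.
    """
    if not dfield.matches_mesh(mesh):
        raise ValueError(
            "stale closest-element map: distance field was computed against "
            "a different mesh; recompute the signed distance first"
        )
    F = np.zeros_like(mesh.vertices)
    inside = dfield.inside & (B != 0)
    if not inside.any():
        return VertexForceField(F, tag="actin")
    ds = dfield.ds[inside]
    # dpsi/d(ds) = (alpha*beta/2) sech^2(beta ds); d(ds)/ds_i = -b_i d
    dpsi = 0.5 * pot.alpha * pot.beta / np.cosh(pot.beta * ds) ** 2
    weight = (B[inside] * cell_volume * dpsi)[:, None] * dfield.direction[inside]
    faces = mesh.faces[dfield.face_id[inside]]
    bary = dfield.bary[inside]
    for c in range(3):
        np.add.at(F, faces[:, c], bary[:, c, None] * weight)
    return VertexForceField(F, tag="actin")


def advance_membrane(
    mesh: SpineMesh,
    F_mem: VertexForceField,
    F_actin: VertexForceField,
    mech: MechanicsParams,
    dt: float,
    max_step: float | None = None,
) -> SpineMesh:
    """Forward-Euler update s <- s + (dt/omega)(F_mem + F_actin).

    Fixed vertices never move.  If max_step is given (typically half the
    target edge length), a larger per-vertex displacement raises.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    disp = (dt / mech.omega) * (F_mem.vectors + F_actin.vectors)
    disp[mesh.fixed_mask] = 0.0
    if max_step is not None:
        dmax = float(np.linalg.norm(disp, axis=1).max())
        if dmax > max_step:
            raise RuntimeError(
                f"membrane step too large: max displacement {dmax:.3g} um "
                f"exceeds {max_step:.3g} um; reduce dt"
            )
    return SpineMesh(mesh.vertices + disp, mesh.faces, mesh.fixed_mask)


@dataclass
class ProtrusionTracker:
    """Tracks one mid-head vertex's displacement along a fixed axis.

    The protrusion speed nu_mp = max(0, dx/dt) feeds the bulk-flow terms;
    negative displacements count as zero.  Across remeshing the vertex is
    re-bound to the nearest vertex of the new mesh.
    """

    vertex_id: int
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    last_position: np.ndarray = None
    nu_mp: float = 0.0
    displacements: list = field(default_factory=list)

    @classmethod
    def at_mid_head(cls, mesh: SpineMesh, head_center_z: float = 0.85):
        """Pick the vertex closest to the head equator on the +x side."""
        V = mesh.vertices
        score = np.abs(V[:, 2] - head_center_z) - V[:, 0]
        vid = int(np.argmin(score))
        return cls(vertex_id=vid, last_position=V[vid].copy())

    def update(self, mesh: SpineMesh, dt: float) -> float:
        """Record displacement since last call; returns nu_mp (um/s, >= 0)."""
        pos = mesh.vertices[self.vertex_id]
        dx = float(np.dot(pos - self.last_position, self.axis))
        self.displacements.append(dx)
        self.last_position = pos.copy()
        self.nu_mp = max(0.0, dx / dt)
        return self.nu_mp

    def rebind(self, new_mesh: SpineMesh, max_dist: float) -> None:
        """After remeshing, re-attach to the nearest new vertex."""
        d = np.linalg.norm(new_mesh.vertices - self.last_position, axis=1)
        vid = int(np.argmin(d))
        if d[vid] > max_dist:
            raise RuntimeError(
                f"tracked vertex lost after remesh: nearest new vertex is "
                f"{d[vid]:.3g} um away (> {max_dist:.3g})"
            )
        self.vertex_id = vid
        self.last_position = new_mesh.vertices[vid].copy()


def relax_membrane(
    mesh: SpineMesh,
    mech: MechanicsParams,
    dt: float,
    max_steps: int = 500,
    tol: float = 1e-5,
    adaptive: bool = True,
) -> SpineMesh:
    """Bending-energy gradient flow with F_actin = 0 (shape equilibration).

    Iterates the overdamped update using only the membrane force until the
    maximum per-step vertex displacement falls below tol (um).  Steps that
    would increase the discrete bending energy are rejected and retried
    with a smaller dt (backtracking), so the energy is non-increasing along
    the accepted trajectory.  Warns on non-convergence.
    """
    import warnings

    cur = mesh.copy()
    E = bending_energy(cur, mech)
    step = dt
    zero = VertexForceField(np.zeros_like(cur.vertices), tag="actin")
    for _ in range(max_steps):
        F = VertexForceField(bending_force(cur, mech), tag="membrane")
        F.vectors[cur.fixed_mask] = 0.0
        disp = np.linalg.norm(F.vectors, axis=1).max() * step / mech.omega
        if disp < tol:
            return cur
        nxt = advance_membrane(cur, F, zero, mech, step)
        E_new = bending_energy(nxt, mech)
        if adaptive and E_new > E:
            step *= 0.5
            if step < 1e-12 * dt:
                warnings.warn("relaxation stalled: step size underflow")
                return cur
            continue
        cur, E = nxt, E_new
        if adaptive:
            step = min(step * 1.2, 10 * dt)
    warnings.warn(
        f"membrane relaxation did not converge in {max_steps} steps; "
        f"residual step {disp:.3g} um"
    )
    return cur
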