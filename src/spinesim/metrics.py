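"""Observables of a running simulation: shape, totals, forces, velocity.

One :class:`SpineObservables` record is collected per output step; a list of
records converts to a tidy DataFrame for CSV export.  Field totals are
reported both as raw sums over lattice points and as volume integrals
(raw * dx^3).  Radii are equivalent-area radii of horizontal cross-sections
at fixed heights (defaults: neck z = 0.63 um, head z = 0.84 um).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .distance_field import LatticeGrid
from .geometry import SpineMesh, cross_section_radius, mesh_area, mesh_volume
from .membrane_dynamics import ProtrusionTracker, VertexForceField
from .reaction_transport import SpeciesFields

__all__ = [
    "SpineObservables",
    "collect_observables",
    "observables_frame",
    "normalize_series",
    "force_velocity_curve",
    "affine_fit_residual_ratio",
]


@dataclass
class SpineObservables:
    time: float
    volume: float
    area: float
    neck_radius: float
    head_radius: float
    B_sum: float
    A_sum: float
    C_sum: float
    B_integral: float
    A_integral: float
    C_integral: float
    F_mem_total: float
    F_actin_total: float
    F_total: float
    nu_mp: float


def collect_observables(
    state: SpeciesFields,
    mesh: SpineMesh,
    F_mem: VertexForceField,
    F_actin: VertexForceField,
    tracker: ProtrusionTracker | None,
    grid: LatticeGrid,
    z_neck: float = 0.63,
    z_head: float = 0.84,
    log=None,
) -> SpineObservables:
    """One record of every reported observable at the current time."""

    def radius_at(z):
        try:
            return cross_section_radius(mesh, z)
        except ValueError as err:
            if log is not None:
                log(f"t={state.time:.2f}s: cross-section at z={z} failed: {err}")
            return float("nan")

    dv = grid.cell_volume
    fm = float(np.linalg.norm(F_mem.vectors, axis=1).sum())
    fa = float(np.linalg.norm(F_actin.vectors, axis=1).sum())
    ft = float(
        np.linalg.norm(F_mem.vectors + F_actin.vectors, axis=1).sum()
    )
    return SpineObservables(
        time=state.time,
        volume=mesh_volume(mesh),
        area=mesh_area(mesh),
        neck_radius=radius_at(z_neck),
        head_radius=radius_at(z_head),
        B_sum=float(state.B.sum()),
        A_sum=float(state.A.sum()),
        C_sum=float(state.C.sum()),
        B_integral=float(state.B.sum() * dv),
        A_integral=float(state.A.sum() * dv),
        C_integral=float(state.C.sum() * dv),
        F_mem_total=fm,
        F_actin_total=fa,
        F_total=ft,
        nu_mp=0.0 if tracker is None else tracker.nu_mp,
    )


def observables_frame(records: list) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def normalize_series(frame: pd.DataFrame, t_ref: float) -> pd.DataFrame:
    """Divide every quantity by its value at the reference time.

    Also emits per-volume ("concentration / volume") normalized species
    columns, using the instantaneous volume; idempotent and scale-invariant.
    """
    t = frame["time"].to_numpy()
    if not (t.min() - 1e-9 <= t_ref <= t.max() + 1e-9):
        raise ValueError(f"t_ref={t_ref} outside series [{t.min()}, {t.max()}]")
    i_ref = int(np.argmin(np.abs(t - t_ref)))
    out = pd.DataFrame({"time": frame["time"]})
    for col in frame.columns:
        if col == "time":
            continue
        ref = frame[col].iloc[i_ref]
        if ref == 0 or not np.isfinite(ref):
            if col.startswith(("F_", "nu_")):  # forces may legitimately be 0
                out[col] = np.nan
                continue
            raise ValueError(f"zero/invalid reference value for '{col}'")
        out[col] = frame[col] / ref
    for sp in ("B", "A", "C"):
        conc = frame[f"{sp}_integral"] / frame["volume"]
        out[f"{sp}_per_volume"] = conc / conc.iloc[i_ref]
    return out


def force_velocity_curve(forces, velocities) -> np.ndarray:
    """Paired (local force magnitude, protrusion velocity) samples."""
    forces = np.asarray(forces, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if forces.shape != velocities.shape:
        raise ValueError(
            f"length mismatch: {forces.shape} forces vs "
            f"{velocities.shape} velocities"
        )
    if (velocities < 0).any():
        raise ValueError("protrusion velocities must be nonnegative")
    return np.column_stack([forces, velocities])


def affine_fit_residual_ratio(pairs: np.ndarray) -> float:
    """Residual variance fraction of the best straight line v = a*F + b.

    Values near 0 mean the relation is well described by a line; a ratio
    above ~0.1 rejects an affine force-velocity relation.
    """
    F, v = pairs[:, 0], pairs[:, 1]
    if len(F) < 3 or np.allclose(v, v[0]):
        return 0.0
    A = np.column_stack([F, np.ones_like(F)])
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    ss_tot = float(((v - v.mean()) ** 2).sum())
    if ss_tot == 0:
        return 0.0
    return float((resid**2).sum() / ss_tot)
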