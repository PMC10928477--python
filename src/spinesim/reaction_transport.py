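"""Lattice reaction-transport dynamics of barbed ends, Arp2/3 and cofilin.

State per lattice point: B (barbed ends / um^3), A and C (uM).  Their
evolution couples

  * polymerization transport of B along the outward direction field d at
    speed nu (conservative form, first-order upwind),
  * the confining force density f_u acting on B through the effective
    filament mobility eta (central differences),
  * bulk flow of A and C toward the membrane at speed xi * nu_mp (upwind),
  * first-order decay/efflux (k_beta, k_A, k_C),
  * Arp2/3 side-branching nucleation  f_nuc = k_nuc * A * Psi1 * B,
  * cooperative cofilin severing      f_sev = k_sev * C^n/(k_n + C^n) * Psi1 * B,
  * basal and stimulus-triggered influx on fixed lattice-point masks, each
    divided by the number of basal locations so total protein delivery is
    independent of the discretization.

Nucleation and severing create barbed ends (+Psi0 * f) while consuming the
corresponding protein (-f): the stoichiometry is asserted term-by-term in
the test-suite.

Points far outside the membrane (ds > 3/beta, where the repulsive potential
has saturated) are frozen at zero, and an absorbing plane below z_abs mimics
the stable actin arrangement at the neck base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .distance_field import DistanceField, LatticeGrid, divergence_of_direction
from .geometry import SpineMesh
from .params import KineticParams, RepulsivePotentialParams

__all__ = [
    "SpeciesFields",
    "InfluxGeometry",
    "nucleation_rate",
    "severing_rate",
    "build_influx_masks",
    "species_rhs",
    "step_fields",
    "TransportContext",
]


@dataclass
class SpeciesFields:
    """Species values per lattice point plus the simulation clock."""

    B: np.ndarray
    A: np.ndarray
    C: np.ndarray
    time: float = 0.0

    def copy(self) -> "SpeciesFields":
        return SpeciesFields(self.B.copy(), self.A.copy(), self.C.copy(),
                             self.time)

    def totals(self) -> tuple:
        return float(self.B.sum()), float(self.A.sum()), float(self.C.sum())


@dataclass
class InfluxGeometry:
    """Fixed influx locations: basal (head interior) and stimulus (near-
    membrane shell inside a z window).  head_scale rescales the stimulus
    delivery to the initial head size."""

    basal_mask: np.ndarray
    stimulus_mask: np.ndarray
    n_basal: int
    head_scale: float = 1.0


def nucleation_rate(A_val, B_val, params: KineticParams):
    """Arp2/3 side-branching nucleation f_nuc = k_nuc * A * Psi1 * B (uM/s)."""
    return params.k_nuc * np.asarray(A_val) * params.Psi1 * np.asarray(B_val)


def severing_rate(C_val, B_val, params: KineticParams):
    """Cooperative cofilin severing, Hill kinetics in C (uM/s).

    C is clamped at zero before the fractional power: transient integrator
    undershoot below zero carries no severing activity.
    """
    Cn = np.maximum(np.asarray(C_val, dtype=float), 0.0) ** params.n
    return params.k_sev * Cn / (params.k_n + Cn) * params.Psi1 * np.asarray(B_val)


def head_volume(dfield: DistanceField, z_min: float) -> float:
    """Interior lattice volume above z_min (um^3)."""
    z = dfield.grid.positions()[:, 2]
    return float(
        ((dfield.ds < 0) & (z >= z_min)).sum() * dfield.grid.cell_volume
    )


def build_influx_masks(
    mesh: SpineMesh,
    grid: LatticeGrid,
    dfield: DistanceField,
    z_window: tuple = (0.7, 1.0),
    head_z_min: float = 0.6,
    V_head_ref: float | None = None,
) -> InfluxGeometry:
    """Basal and stimulus influx point sets.

    basal: interior points (ds < 0) with z >= head_z_min (the spine head).
    stimulus: interior points within one lattice spacing of the membrane
    (-dx - eps <= ds < 0) and z inside z_window; recomputed at each stimulus
    onset from the membrane of that moment.
    head_scale = V_head(now) / V_head_ref.
    """
    z_lo, z_hi = z_window
    z = grid.positions()[:, 2]
    inside = dfield.ds < 0
    basal = inside & (z >= head_z_min)
    if not basal.any():
        raise ValueError(
            f"empty basal mask: no interior lattice points above z={head_z_min}"
        )
    shell = inside & (dfield.ds >= -grid.spacing - 1e-12)
    stim = shell & (z >= z_lo) & (z <= z_hi)
    if not stim.any():
        raise ValueError(
            f"empty stimulus mask: no near-membrane interior points with "
            f"z in [{z_lo}, {z_hi}]"
        )
    vh = head_volume(dfield, head_z_min)
    scale = 1.0 if V_head_ref is None else vh / V_head_ref
    return InfluxGeometry(
        basal_mask=basal,
        stimulus_mask=stim,
        n_basal=int(basal.sum()),
        head_scale=float(scale),
    )


# ---------------------------------------------------------------------------
# spatial operators
# ---------------------------------------------------------------------------


def _upwind_grad_dot(u: np.ndarray, phi: np.ndarray, grid: LatticeGrid):
    """First-order upwind u . grad(phi) for velocity field u (N,3)."""
    h = grid.spacing
    p = grid.reshape(phi)
    uu = grid.reshape(u)
    out = np.zeros_like(p)
    fwd = np.empty_like(p)
    bwd = np.empty_like(p)
    full = slice(None)
    for ax in range(3):
        lo = tuple(slice(0, -1) if a == ax else full for a in range(3))
        hi = tuple(slice(1, None) if a == ax else full for a in range(3))
        first = tuple(0 if a == ax else full for a in range(3))
        last = tuple(-1 if a == ax else full for a in range(3))
        np.subtract(p[hi], p[lo], out=fwd[lo])
        fwd[lo] /= h
        bwd[hi] = fwd[lo]
        # one-sided at the boundary: reuse the interior difference
        bwd[first] = fwd[first]
        fwd[last] = bwd[last]
        ua = uu[..., ax]
        out += np.where(ua > 0, ua * bwd, ua * fwd)
    return out.ravel()


def _central_grad_dot(u: np.ndarray, phi: np.ndarray, grid: LatticeGrid):
    """Central-difference u . grad(phi)."""
    h = grid.spacing
    p = grid.reshape(phi)
    uu = grid.reshape(u)
    out = np.zeros_like(p)
    for ax in range(3):
        out += uu[..., ax] * np.gradient(p, h, axis=ax)
    return out.ravel()


def _divergence(vec: np.ndarray, grid: LatticeGrid):
    """Central-difference divergence of a vector field (N,3)."""
    h = grid.spacing
    v = grid.reshape(vec)
    out = (
        np.gradient(v[..., 0], h, axis=0)
        + np.gradient(v[..., 1], h, axis=1)
        + np.gradient(v[..., 2], h, axis=2)
    )
    return out.ravel()


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------


@dataclass
class TransportContext:
    """Geometry-dependent quantities frozen for one global time-step."""

    grid: LatticeGrid
    dfield: DistanceField
    geom: InfluxGeometry
    params: KineticParams
    pot: RepulsivePotentialParams
    nu_mp: float = 0.0
    stimulus_on: bool = False
    z_abs: float = 0.3
    div_d: np.ndarray = field(default=None)
    f_u: np.ndarray = field(default=None)
    div_fu: np.ndarray = field(default=None)
    active: np.ndarray = field(default=None)
    influx_B: np.ndarray = field(default=None)
    influx_A: np.ndarray = field(default=None)
    influx_C: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        from .distance_field import force_density

        if self.div_d is None:
            self.div_d = divergence_of_direction(self.dfield, self.grid)
        if self.f_u is None:
            self.f_u = force_density(self.dfield, self.pot)
        if self.div_fu is None:
            self.div_fu = _divergence(self.f_u, self.grid)
        if self.active is None:
            z = self.grid.positions()[:, 2]
            frozen = self.dfield.ds > 3.0 / self.pot.beta
            absorbed = z < self.z_abs
            self.active = ~(frozen | absorbed)
        if self.influx_B is None:
            p = self.params
            nb = self.geom.n_basal
            basal = self.geom.basal_mask
            self.influx_B = np.zeros(self.grid.n_points)
            self.influx_A = np.zeros(self.grid.n_points)
            self.influx_C = np.zeros(self.grid.n_points)
            self.influx_B[basal] = p.I_beta / nb
            self.influx_A[basal] = p.I_A / nb
            self.influx_C[basal] = p.I_C / nb
            if self.stimulus_on:
                stim = self.geom.stimulus_mask
                hs = self.geom.head_scale
                self.influx_B[stim] += p.IS_beta / nb * hs
                self.influx_A[stim] += p.IS_A / nb * hs
                self.influx_C[stim] += p.IS_C / nb * hs


def species_rhs(fields: SpeciesFields, ctx: TransportContext):
    """Time derivatives (dB/dt, dA/dt, dC/dt) per lattice point."""
    p = ctx.params
    grid = ctx.grid
    d = ctx.dfield.direction
    B, A, C = fields.B, fields.A, fields.C

    f_nuc = nucleation_rate(A, B, p)
    f_sev = severing_rate(C, B, p)

    # barbed ends: -v.grad B - B div v + eta(f_u.grad B) + eta B div f_u
    adv_B = 0.0
    if p.nu != 0:
        adv_B = _upwind_grad_dot(p.nu * d, B, grid) + B * (p.nu * ctx.div_d)
    dB = (
        -adv_B
        + p.eta * _central_grad_dot(ctx.f_u, B, grid)
        + p.eta * B * ctx.div_fu
        - p.k_beta * B
        + p.Psi0 * (f_nuc + f_sev + ctx.influx_B)
    )

    # Arp2/3 and cofilin: bulk flow at speed xi*nu_mp along d
    speed = p.xi * ctx.nu_mp
    if speed != 0:
        u = speed * d
        adv_div = speed * ctx.div_d
        adv_A = _upwind_grad_dot(u, A, grid) + A * adv_div
        adv_C = _upwind_grad_dot(u, C, grid) + C * adv_div
    else:
        adv_A = adv_C = 0.0
    dA = -adv_A - p.k_A * A - f_nuc + ctx.influx_A
    dC = -adv_C - p.k_C * C - f_sev + ctx.influx_C

    inactive = ~ctx.active
    dB[inactive] = 0.0
    dA[inactive] = 0.0
    dC[inactive] = 0.0

    for name, arr in (("dB/dt", dB), ("dA/dt", dA), ("dC/dt", dC)):
        if not np.isfinite(arr).all():
            raise FloatingPointError(
                f"non-finite values in {name}; offending term diagnostics: "
                + _diagnose_nonfinite(fields, ctx)
            )
    return dB, dA, dC


def _diagnose_nonfinite(fields, ctx) -> str:
    terms = {
        "B": fields.B, "A": fields.A, "C": fields.C,
        "div_d": ctx.div_d, "f_u": ctx.f_u, "div_fu": ctx.div_fu,
        "f_nuc": nucleation_rate(fields.A, fields.B, ctx.params),
        "f_sev": severing_rate(fields.C, fields.B, ctx.params),
    }
    bad = [k for k, v in terms.items() if not np.isfinite(v).all()]
    return ", ".join(bad) if bad else "all inputs finite (overflow in sum)"


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------


def cfl_limit(ctx: TransportContext) -> float:
    """Largest stable advective time-step for the current speeds."""
    speed = max(
        ctx.params.nu,
        ctx.params.xi * ctx.nu_mp,
        ctx.params.eta * float(np.abs(ctx.f_u).max()),
    )
    if speed <= 0:
        return np.inf
    return ctx.grid.spacing / speed


def step_fields(
    fields: SpeciesFields,
    ctx: TransportContext,
    dt: float,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    clip_log: dict | None = None,
) -> SpeciesFields:
    """Advance fields by dt with adaptive RK45 sub-stepping.

    Negative values (upwind undershoot) are clipped to zero after the step;
    the clipped amount (in field units summed over points) is accumulated in
    clip_log['clipped_B'/'clipped_A'/'clipped_C'] when a dict is given.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    limit = cfl_limit(ctx)
    if dt > limit:
        raise ValueError(
            f"advective CFL violation: dt={dt} exceeds stable limit "
            f"{limit:.3g}; reduce dt below this bound"
        )
    n = len(fields.B)
    y0 = np.concatenate([fields.B, fields.A, fields.C])

    def rhs(t, y):
        f = SpeciesFields(y[:n], y[n:2 * n], y[2 * n:], t)
        dB, dA, dC = species_rhs(f, ctx)
        return np.concatenate([dB, dA, dC])

    # fast path: nothing changes
    if not np.any(rhs(fields.time, y0)):
        out = fields.copy()
        out.time = fields.time + dt
        return out

    t0, t1 = fields.time, fields.time + dt
    sol = solve_ivp(
        rhs, (t0, t1), y0,
        method="RK45", rtol=rtol, atol=atol, dense_output=False,
        first_step=min(t1 - t0, limit),
    )
    if not sol.success:
        raise RuntimeError(f"field integration failed: {sol.message}")
    y = sol.y[:, -1]
    B, A, C = y[:n].copy(), y[n:2 * n].copy(), y[2 * n:].copy()
    for key, arr in (("clipped_B", B), ("clipped_A", A), ("clipped_C", C)):
        neg = arr < 0
        if neg.any():
            if clip_log is not None:
                clip_log[key] = clip_log.get(key, 0.0) - float(arr[neg].sum())
            arr[neg] = 0.0
    return SpeciesFields(B, A, C, fields.time + dt)


def initial_fields(
    grid: LatticeGrid, geom: InfluxGeometry, params: KineticParams
) -> SpeciesFields:
    """Reaction-only fixed point of the basal system, on the basal mask.

    Per basal point: B = Psi0*I_beta/(k_beta*n), A = I_A/(k_A*n),
    C = I_C/(k_C*n), so that domain totals match the non-spatial steady
    state (Psi0*beta*, A*, C*) up to parameter rounding.
    """
    n = geom.n_basal
    B = np.zeros(grid.n_points)
    A = np.zeros(grid.n_points)
    C = np.zeros(grid.n_points)
    B[geom.basal_mask] = params.Psi0 * params.I_beta / (params.k_beta * n)
    A[geom.basal_mask] = params.I_A / (params.k_A * n)
    C[geom.basal_mask] = params.I_C / (params.k_C * n)
    return SpeciesFields(B, A, C, 0.0)
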