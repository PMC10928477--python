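"""Parameter containers for the spine model.

All quantities use the micrometre / second / piconewton / micromolar unit
system.  Defaults are the calibrated values of the full model: kinetic rates
were fitted to normalized fluorescence time courses of beta-actin, Arp2/3 and
cofilin-1 in stimulated hippocampal spines; mechanical and numerical
parameters were set to physiological ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace


@dataclass(frozen=True)
class MechanicsParams:
    """Membrane mechanics: Helfrich bending modulus and effective drag.

    kappa : bending modulus (pN um).  0.18 pN um ~ 1.8e-19 J, the lower end
        of measured neuronal membrane stiffness.
    omega : effective drag coefficient (s pN / um) folding fluid drag and
        extracellular-matrix adhesion into a single dissipative term.
    """

    kappa: float = 0.18
    omega: float = 1.0e5

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.omega <= 0:
            raise ValueError("kappa and omega must be strictly positive")


@dataclass(frozen=True)
class RepulsivePotentialParams:
    """Soft membrane-confinement potential psi = alpha * tanh(beta * ds) / 2.

    alpha : amplitude (pN); beta : steepness (dimensionless, per um of signed
    distance).  In the limit alpha, beta -> inf the membrane becomes a hard
    reflective wall.
    """

    alpha: float = 3.0e4
    beta: float = 40.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be strictly positive")


@dataclass(frozen=True)
class KineticParams:
    """Kinetics of barbed ends (B), Arp2/3 (A) and cofilin (C).

    Rates are per second, influxes in uM/s, k_nuc in 1/(uM s), k_n in uM^n.
    Psi0 converts uM to barbed ends per um^3; Psi1 converts barbed ends per
    um^3 back to uM.  nu is the F-actin polymerization speed, xi the bulk-flow
    speed restriction (0 < xi < 1) and eta the effective filament mobility
    that couples the confining force density to barbed-end transport.
    """

    k_beta: float = 0.0081
    I_beta: float = 24.4284
    IS_beta: float = 25.6684
    k_A: float = 0.0013
    I_A: float = 0.0255
    IS_A: float = 0.0293
    k_C: float = 0.0006
    I_C: float = 0.0237
    IS_C: float = 0.4384
    k_nuc: float = 0.0153
    k_sev: float = 0.0120
    k_n: float = 0.6
    n: float = 3.5
    Psi0: float = 3.6
    Psi1: float = 0.02
    nu: float = 1.0e-5
    xi: float = 0.1
    eta: float = 1.0e-10

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"{f.name} must be nonnegative, got {v}")
        if not (0.0 < self.xi < 1.0):
            raise ValueError(f"xi must lie in (0, 1), got {self.xi}")

    def with_overrides(self, **kw: float) -> "KineticParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class MinimalParams:
    """Non-spatial kinetic sub-model for the normalized concentrations.

    The dimensional system  dX/dt = IS_X(t) + I_X - k_X X  is scaled by the
    steady states (beta_star, A_star, C_star) = (I/k) so that the
    pre-stimulus state is exactly (1, 1, 1).  Basal influxes are therefore
    defined as I = k * (steady state), which makes the normalization exact.
    """

    k_beta: float = 0.0081
    k_A: float = 0.0013
    k_C: float = 0.0006
    IS_beta: float = 25.6684
    IS_A: float = 0.0293
    IS_C: float = 0.4384
    beta_star: float = 3000.0
    A_star: float = 20.0
    C_star: float = 40.0

    def __post_init__(self) -> None:
        for name in ("k_beta", "k_A", "k_C", "beta_star", "A_star", "C_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("IS_beta", "IS_A", "IS_C"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def I_beta(self) -> float:
        return self.k_beta * self.beta_star

    @property
    def I_A(self) -> float:
        return self.k_A * self.A_star

    @property
    def I_C(self) -> float:
        return self.k_C * self.C_star


@dataclass(frozen=True)
class StimulusSchedule:
    """Disjoint, ordered stimulus windows [(t_on, t_off), ...] in seconds.

    The default is a single one-minute window starting at t = 0, matching
    one minute of glutamate uncaging.
    """

    windows: tuple = ((0.0, 60.0),)

    def __post_init__(self) -> None:
        prev_off = -float("inf")
        for t_on, t_off in self.windows:
            if t_off <= t_on:
                raise ValueError(f"window ({t_on}, {t_off}) has t_off <= t_on")
            if t_on < prev_off:
                raise ValueError("stimulus windows must be disjoint and ordered")
            prev_off = t_off

    def active(self, t: float) -> bool:
        return any(t_on <= t < t_off for t_on, t_off in self.windows)

    def shifted(self, dt: float) -> "StimulusSchedule":
        return StimulusSchedule(
            tuple((a + dt, b + dt) for a, b in self.windows)
        )
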