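"""Scenario configuration and the coupled simulation driver.

A run proceeds in phases: (1) the species fields evolve with the membrane
held fixed; (2) coupled field+membrane evolution to a pre-stimulus
mechanical equilibrium; (3) one or more one-minute stimulus windows;
(4) post-stimulus evolution.  Observables are collected on a fixed cadence;
the membrane is periodically remeshed.  Runs are deterministic for a fixed
configuration and seed.

The scenario catalog reproduces the perturbation experiments: knockout or
enhancement of individual stimulus influxes, a bending-stiffness sweep,
window-scoped mechanical perturbations standing in for molecular-clutch
engagement (nu, eta) and extracellular-matrix degradation (omega), and
repeated stimulation.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .distance_field import (
    LatticeGrid,
    compute_signed_distance,
    update_signed_distance,
)
from .geometry import SpineMesh, build_initial_spine
from .membrane_dynamics import (
    ProtrusionTracker,
    VertexForceField,
    actin_force,
    advance_membrane,
    relax_membrane,
)
from .metrics import (
    collect_observables,
    normalize_series,
    observables_frame,
)
from .params import (
    KineticParams,
    MechanicsParams,
    RepulsivePotentialParams,
    StimulusSchedule,
)
from .reaction_transport import (
    TransportContext,
    build_influx_masks,
    head_volume,
    initial_fields,
    step_fields,
)
from .remesh import remesh_isotropic
from .geometry import bending_force

__all__ = ["ScenarioConfig", "RunResult", "run_scenario", "scenario_catalog",
           "PRESETS"]


PRESETS = {
    # full-resolution settings
    "full": dict(
        dx=0.0315, dt=0.01, ds_edge=0.05,
        fixed_duration=60.0, relax_duration=180.0, post_duration=240.0,
        remesh_every=0.5, sdf_every=1,
    ),
    # coarse preset: same physics, ~2 simulated minutes, coarse lattice/mesh
    "reduced": dict(
        dx=0.06, dt=0.05, ds_edge=0.08,
        fixed_duration=10.0, relax_duration=20.0, post_duration=30.0,
        remesh_every=2.0, sdf_every=2,
    ),
}


@dataclass
class ScenarioConfig:
    name: str = "control"
    preset: str = "reduced"
    # numerics (None -> taken from preset)
    dx: float | None = None
    dt: float | None = None
    ds_edge: float | None = None
    fixed_duration: float | None = None
    relax_duration: float | None = None
    post_duration: float | None = None
    # stimulus windows relative to the end of the pre-stimulus phase
    windows: tuple = ((0.0, 60.0),)
    # parameter overrides
    kinetic_overrides: dict = field(default_factory=dict)
    mech_overrides: dict = field(default_factory=dict)
    pot_overrides: dict = field(default_factory=dict)
    # multiplicative factors applied only while a stimulus window is active
    window_factors: dict = field(default_factory=dict)  # keys: nu, eta, omega
    # geometry
    head_radius: float = 0.25
    head_center_z: float = 0.85
    neck_radius: float = 0.1
    neck_length: float = 0.6
    # masks / boundaries / measurement heights
    z_window: tuple = (0.7, 1.0)
    z_abs: float = 0.3
    head_z_min: float = 0.6
    z_neck: float = 0.63
    z_head: float = 0.84
    V_head_ref: float | None = None
    # cadences (s of simulated time; remesh/SDF cadence from the preset).
    # sdf_every: distance-field refresh interval in steps; between
    # refreshes forces use the last geometry snapshot (membrane motion per
    # step is a tiny fraction of the lattice spacing)
    output_every: float = 1.0
    remesh_every: float | None = None
    sdf_every: int | None = None
    mesh_every: float = 10.0
    seed: int = 0

    def resolve(self) -> "ScenarioConfig":
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset '{self.preset}'; choose from {list(PRESETS)}"
            )
        p = PRESETS[self.preset]
        kw = {
            k: (getattr(self, k) if getattr(self, k) is not None else v)
            for k, v in p.items()
        }
        out = replace(self, **kw)
        for val, nm in ((out.dt, "dt"), (out.dx, "dx"), (out.ds_edge, "ds_edge")):
            if val <= 0:
                raise ValueError(f"{nm} must be positive")
        return out

    def params(self):
        kin = KineticParams(**self.kinetic_overrides)
        mech = MechanicsParams(**self.mech_overrides)
        pot = RepulsivePotentialParams(**self.pot_overrides)
        return kin, mech, pot

    def schedule(self) -> StimulusSchedule:
        t0 = self.fixed_duration + self.relax_duration
        return StimulusSchedule(
            tuple((a + t0, b + t0) for a, b in self.windows)
        )

    def total_time(self) -> float:
        sched = self.schedule()
        return sched.windows[-1][1] + self.post_duration


@dataclass
class RunResult:
    config: ScenarioConfig
    observables: "object"          # DataFrame, one row per output step
    normalized: "object"           # DataFrame normalized to stimulus onset
    force_velocity: "object"       # DataFrame: local forces and nu_mp
    final_mesh: SpineMesh
    clip_log: dict
    timings: dict
    out_dir: str | None = None


def _ray_hit_face(mesh, origin, direction):
    """Nearest face hit by a ray (vectorized Moller-Trumbore); None if none."""
    V, F = mesh.vertices, mesh.faces
    v0, v1, v2 = V[F[:, 0]], V[F[:, 1]], V[F[:, 2]]
    e1, e2 = v1 - v0, v2 - v0
    h = np.cross(direction, e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-14
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ok, 1.0 / a, 0.0)
        s = origin - v0
        u = f * np.einsum("ij,ij->i", s, h)
        qv = np.cross(s, e1)
        v = f * (qv @ direction)
        t = f * np.einsum("ij,ij->i", e2, qv)
    hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1 + 1e-12) & (t > 1e-9)
    if not hit.any():
        return None
    return int(np.flatnonzero(hit)[np.argmin(t[hit])])


def _local_face_forces(mesh, tracker, F_mem, F_actin):
    """Average vertex forces of the face hit by the tracked displacement ray."""
    origin = tracker.last_position - 0.05 * tracker.axis
    fi = _ray_hit_face(mesh, origin, tracker.axis)
    if fi is not None:
        face = mesh.faces[fi]
    else:  # fall back: incident face whose centroid is most along the axis
        incident = np.flatnonzero((mesh.faces == tracker.vertex_id).any(axis=1))
        cent = mesh.vertices[mesh.faces[incident]].mean(axis=1)
        face = mesh.faces[incident[np.argmax(cent @ tracker.axis)]]
    fm = float(np.linalg.norm(F_mem.vectors[face].mean(axis=0)))
    fa = float(np.linalg.norm(F_actin.vectors[face].mean(axis=0)))
    ft = float(
        np.linalg.norm((F_mem.vectors[face] + F_actin.vectors[face]).mean(axis=0))
    )
    return fm, fa, ft


def run_scenario(config: ScenarioConfig, out_dir: str | None = None) -> RunResult:
    """Execute all phases of a scenario; see module docstring."""
    import pandas as pd

    cfg = config.resolve()
    kin_base, mech_base, pot = cfg.params()
    schedule = cfg.schedule()
    t_end = cfg.total_time()
    log_lines = []

    def log(msg):
        log_lines.append(msg)

    timings = {}
    tic = _time.perf_counter()

    # --- initial shape: build, bending-relax, remesh -----------------------
    mesh = build_initial_spine(
        cfg.head_radius, cfg.head_center_z, cfg.neck_radius,
        cfg.neck_length, cfg.ds_edge,
    )
    F0 = np.linalg.norm(bending_force(mesh, mech_base), axis=1).max()
    dt_relax = 0.05 * cfg.ds_edge * mech_base.omega / max(F0, 1e-12)
    mesh = relax_membrane(mesh, mech_base, dt_relax, max_steps=300, tol=5e-4)
    mesh = remesh_isotropic(mesh, cfg.ds_edge, vol_tol=0.05)
    timings["shape_init_s"] = _time.perf_counter() - tic

    # --- lattice, fields, masks -------------------------------------------
    # x/y/top margins leave room for growth; below the dendrite plane two
    # cells suffice (species are absorbed in the neck anyway)
    m = (int(np.ceil(0.25 / cfg.dx)) + 2) * cfg.dx
    lo = mesh.vertices.min(axis=0) - (m, m, 0.0)
    hi = mesh.vertices.max(axis=0) + (m, m, m)
    lo[2] = -2 * cfg.dx
    shape = np.ceil((hi - lo) / cfg.dx).astype(int) + 1
    grid = LatticeGrid(tuple(lo), cfg.dx, tuple(shape))
    dfield = compute_signed_distance(grid, mesh)
    geom = build_influx_masks(
        mesh, grid, dfield, cfg.z_window, cfg.head_z_min, V_head_ref=None
    )
    V_head0 = head_volume(dfield, cfg.head_z_min)
    head_scale = 1.0 if cfg.V_head_ref is None else V_head0 / cfg.V_head_ref
    geom.head_scale = head_scale
    state = initial_fields(grid, geom, kin_base)
    tracker = ProtrusionTracker.at_mid_head(mesh, cfg.head_center_z)
    field_mesh = mesh

    records = []
    fv_rows = []
    clip_log = {}
    zero_force = VertexForceField(np.zeros_like(mesh.vertices), "zero")

    n_steps = int(round(t_end / cfg.dt))
    next_output = 0.0
    next_remesh = cfg.remesh_every
    next_mesh_out = 0.0
    mesh_dir = None
    if out_dir is not None:
        mesh_dir = Path(out_dir) / "meshes"
        mesh_dir.mkdir(parents=True, exist_ok=True)
    was_on = False
    t_phase2 = cfg.fixed_duration
    t_stim0 = cfg.fixed_duration + cfg.relax_duration

    tic = _time.perf_counter()
    for step in range(n_steps + 1):
        t = step * cfg.dt
        stimulus_on = schedule.active(t)

        # window-scoped parameter factors (molecular clutch / ECM effects)
        if stimulus_on and cfg.window_factors:
            kin = kin_base.with_overrides(**{
                k: getattr(kin_base, k) * v
                for k, v in cfg.window_factors.items() if k in ("nu", "eta")
            })
            mech = MechanicsParams(
                kappa=mech_base.kappa,
                omega=mech_base.omega * cfg.window_factors.get("omega", 1.0),
            )
        else:
            kin, mech = kin_base, mech_base

        # recompute the stimulus mask at each window onset (held for window)
        if stimulus_on and not was_on:
            geom = build_influx_masks(
                mesh, grid, dfield, cfg.z_window, cfg.head_z_min, None
            )
            geom.head_scale = head_scale
            log(f"t={t:.2f}s stimulus onset: {int(geom.stimulus_mask.sum())} "
                f"influx points, head_scale={head_scale:.3f}")
        was_on = stimulus_on

        ctx = TransportContext(
            grid=grid, dfield=dfield, geom=geom, params=kin, pot=pot,
            nu_mp=tracker.nu_mp, stimulus_on=stimulus_on, z_abs=cfg.z_abs,
        )

        # forces on the current membrane (actin force against the geometry
        # snapshot the distance field was computed on)
        F_mem = VertexForceField(bending_force(mesh, mech), "membrane")
        F_mem.vectors[mesh.fixed_mask] = 0.0
        F_actin = actin_force(state.B, dfield, field_mesh, pot,
                              grid.cell_volume)
        F_actin.vectors[mesh.fixed_mask] = 0.0

        if t >= next_output - 1e-9:
            rec = collect_observables(
                state, mesh, F_mem, F_actin, tracker, grid,
                cfg.z_neck, cfg.z_head, log=log,
            )
            records.append(rec)
            next_output += cfg.output_every
        # force-velocity pairs at every step once the membrane moves
        if t >= t_phase2:
            fm, fa, ft = _local_face_forces(mesh, tracker, F_mem, F_actin)
            px, py, pz = tracker.last_position
            fv_rows.append(
                dict(time=t, F_mem_local=fm, F_actin_local=fa,
                     F_total_local=ft, nu_mp=tracker.nu_mp,
                     tracked_x=px, tracked_y=py, tracked_z=pz)
            )
        if mesh_dir is not None and t >= next_mesh_out - 1e-9:
            mesh.save(str(mesh_dir / f"mesh_t{t:07.2f}s.ply"))
            next_mesh_out += cfg.mesh_every
        if step == n_steps:
            break

        # advance fields
        state = step_fields(state, ctx, cfg.dt, clip_log=clip_log)

        # advance membrane (after the fixed phase)
        if t >= t_phase2:
            mesh = advance_membrane(
                mesh, F_mem, F_actin, mech, cfg.dt, max_step=cfg.ds_edge / 2
            )
            tracker.update(mesh, cfg.dt)
            if t >= next_remesh - 1e-9:
                try:
                    mesh = remesh_isotropic(
                        mesh, cfg.ds_edge, n_iter=2, vol_tol=0.02
                    )
                    tracker.rebind(mesh, max_dist=cfg.ds_edge)
                except RuntimeError as err:
                    log(f"t={t:.2f}s remesh skipped: {err}")
                next_remesh += cfg.remesh_every
                dfield = compute_signed_distance(grid, mesh)
                field_mesh = mesh
            elif (step + 1) % cfg.sdf_every == 0:
                dfield = update_signed_distance(
                    dfield, mesh, band=3.0 / pot.beta + 2 * cfg.dx
                )
                field_mesh = mesh

    timings["evolution_s"] = _time.perf_counter() - tic

    obs = observables_frame(records)
    normalized = normalize_series(obs, t_ref=t_stim0)
    fv = pd.DataFrame(fv_rows)

    result = RunResult(
        config=cfg, observables=obs, normalized=normalized,
        force_velocity=fv, final_mesh=mesh, clip_log=clip_log,
        timings=timings, out_dir=out_dir,
    )
    if out_dir is not None:
        p = Path(out_dir)
        p.mkdir(parents=True, exist_ok=True)
        obs.to_csv(p / "observables.csv", index=False)
        normalized.to_csv(p / "normalized.csv", index=False)
        fv.to_csv(p / "force_velocity.csv", index=False)
        mesh.save(str(p / "final_mesh.ply"))
        cfg_dict = asdict(cfg)
        cfg_dict["clip_log"] = clip_log
        cfg_dict["timings"] = timings
        (p / "config.json").write_text(json.dumps(cfg_dict, indent=2))
        (p / "log.txt").write_text("\n".join(log_lines) + "\n")
        result.out_dir = str(p)
    return result


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------


def scenario_catalog() -> dict:
    """Named scenario configurations for every reported experiment.

    Each entry differs from control in exactly the documented parameters.
    Mechanical perturbations standing in for perisynaptic interactions
    (nu, eta, omega factors) apply during the stimulation window only.
    """
    cat = {}

    def add(name, **kw):
        cat[name] = ScenarioConfig(name=name, **kw)

    add("control")
    add("no_actin_stimulus", kinetic_overrides={"IS_beta": 0.0})
    add("no_arp23_stimulus", kinetic_overrides={"IS_A": 0.0})
    add("no_cofilin_stimulus", kinetic_overrides={"IS_C": 0.0})
    add("enhanced_abp_stimulus",
        kinetic_overrides={
            "IS_A": KineticParams.IS_A * 1.5,
            "IS_C": KineticParams.IS_C * 1.5,
        })
    add("kappa_up", mech_overrides={"kappa": MechanicsParams.kappa * 1.25})
    add("kappa_down", mech_overrides={"kappa": MechanicsParams.kappa * 0.75})
    add("eta_down", window_factors={"eta": 0.6})
    add("nu_up", window_factors={"nu": 1.4})
    add("omega_down", window_factors={"omega": 0.6})
    add("nu_up_omega_down", window_factors={"nu": 1.4, "omega": 0.6})
    add("nu_up_eta_down", window_factors={"nu": 1.4, "eta": 0.6})
    add("repeated", windows=((0.0, 60.0), (120.0, 180.0), (240.0, 300.0)))
    return cat


def get_scenario(name: str) -> ScenarioConfig:
    cat = scenario_catalog()
    if name not in cat:
        raise KeyError(
            f"unknown scenario '{name}'; available: {sorted(cat)}"
        )
    return cat[name]
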