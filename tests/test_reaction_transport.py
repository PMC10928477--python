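"""Kinetic rate laws, influx geometry, and lattice time stepping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _helpers import uniform_ctx as _uniform_ctx
from spinesim.distance_field import LatticeGrid, compute_signed_distance
from spinesim.params import KineticParams, RepulsivePotentialParams
from spinesim.reaction_transport import (
    SpeciesFields,
    build_influx_masks,
    initial_fields,
    nucleation_rate,
    severing_rate,
    species_rhs,
    step_fields,
)

P = KineticParams()
POT = RepulsivePotentialParams()


class TestRateLaws:
    def test_nucleation_values(self):
        assert nucleation_rate(0.0, 123.0, P) == 0.0
        # k_nuc * A * Psi1 * B = 0.0153 * 20 * 0.02 * 100
        assert nucleation_rate(20.0, 100.0, P) == pytest.approx(0.612)
        assert nucleation_rate(20.0, 200.0, P) == pytest.approx(
            2 * nucleation_rate(20.0, 100.0, P)
        )

    def test_severing_values(self):
        assert severing_rate(0.0, 100.0, P) == 0.0
        # half-saturation at C = k_n^(1/n)
        c_half = P.k_n ** (1.0 / P.n)
        assert severing_rate(c_half, 100.0, P) == pytest.approx(
            0.5 * P.k_sev * P.Psi1 * 100.0
        )
        # saturated Hill at C = 40 uM: ~ k_sev * Psi1 * B
        assert severing_rate(40.0, 100.0, P) == pytest.approx(
            0.024, rel=1e-4
        )

    def test_severing_clamps_negative_cofilin(self):
        assert severing_rate(-0.5, 100.0, P) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        b=st.floats(0, 1e4), a=st.floats(0, 100), c=st.floats(0, 100)
    )
    def test_rates_nonnegative_and_linear_in_b(self, b, a, c):
        assert nucleation_rate(a, b, P) >= 0
        assert severing_rate(c, b, P) >= 0
        assert nucleation_rate(a, 2 * b, P) == pytest.approx(
            2 * nucleation_rate(a, b, P), rel=1e-12, abs=1e-300
        )


@pytest.fixture(scope="module")
def lattice_setup(spine_coarse):
    grid = LatticeGrid((-0.5, -0.5, -0.12), 0.06, (17, 17, 23))
    dfield = compute_signed_distance(grid, spine_coarse)
    geom = build_influx_masks(spine_coarse, grid, dfield)
    return grid, dfield, geom


class TestInfluxMasks:
    def test_stimulus_mask_predicates(self, lattice_setup):
        grid, dfield, geom = lattice_setup
        z = grid.positions()[:, 2]
        stim = geom.stimulus_mask
        assert stim.any()
        assert (z[stim] >= 0.7 - 1e-12).all()
        assert (z[stim] <= 1.0 + 1e-12).all()
        assert (dfield.ds[stim] < 0).all()
        assert (dfield.ds[stim] >= -grid.spacing - 1e-9).all()

    def test_basal_points_are_interior(self, lattice_setup):
        grid, dfield, geom = lattice_setup
        assert (dfield.ds[geom.basal_mask] < 0).all()
        assert geom.n_basal == int(geom.basal_mask.sum())

    def test_window_above_mesh_raises(self, lattice_setup, spine_coarse):
        grid, dfield, _ = lattice_setup
        with pytest.raises(ValueError, match="empty stimulus mask"):
            build_influx_masks(spine_coarse, grid, dfield, z_window=(5.0, 6.0))


class TestRhs:
    def test_pure_decay_matches_closed_form(self):
        grid = LatticeGrid((0, 0, 0), 0.1, (3, 3, 3))
        p = KineticParams(
            I_beta=0, IS_beta=0, I_A=0, IS_A=0, I_C=0, IS_C=0,
            k_nuc=0, k_sev=0, nu=0, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        f0 = SpeciesFields(
            B=np.full(grid.n_points, 7.0),
            A=np.full(grid.n_points, 3.0),
            C=np.full(grid.n_points, 5.0),
        )
        out = step_fields(f0, ctx, 60.0, rtol=1e-10, atol=1e-13)
        assert np.allclose(
            out.B, 7.0 * np.exp(-p.k_beta * 60.0), rtol=1e-6
        )
        assert np.allclose(out.A, 3.0 * np.exp(-p.k_A * 60.0), rtol=1e-6)
        assert np.allclose(out.C, 5.0 * np.exp(-p.k_C * 60.0), rtol=1e-6)

    def test_all_rates_zero_is_identity(self):
        grid = LatticeGrid((0, 0, 0), 0.1, (3, 3, 3))
        p = KineticParams(
            k_beta=0, I_beta=0, IS_beta=0, k_A=0, I_A=0, IS_A=0,
            k_C=0, I_C=0, IS_C=0, k_nuc=0, k_sev=0, nu=0, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        f0 = SpeciesFields(
            B=np.arange(grid.n_points, dtype=float),
            A=np.ones(grid.n_points),
            C=np.ones(grid.n_points),
        )
        out = step_fields(f0, ctx, 1.0)
        assert np.array_equal(out.B, f0.B)
        assert np.array_equal(out.A, f0.A)
        assert np.array_equal(out.C, f0.C)

    def test_conservation_without_sources_and_sinks(self):
        """Transport alone conserves total mass to integrator tolerance."""
        grid = LatticeGrid((0, 0, 0), 0.1, (8, 8, 8))
        p = KineticParams(
            k_beta=0, I_beta=0, IS_beta=0, k_A=0, I_A=0, IS_A=0,
            k_C=0, I_C=0, IS_C=0, k_nuc=0, k_sev=0, nu=0, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        rng = np.random.default_rng(3)
        f0 = SpeciesFields(
            B=rng.uniform(0, 10, grid.n_points),
            A=rng.uniform(0, 5, grid.n_points),
            C=rng.uniform(0, 5, grid.n_points),
        )
        out = step_fields(f0, ctx, 10.0, rtol=1e-10, atol=1e-12)
        for a, b in ((out.B, f0.B), (out.A, f0.A), (out.C, f0.C)):
            assert a.sum() == pytest.approx(b.sum(), rel=1e-9)

    def test_stoichiometric_consistency(self):
        """f_nuc adds Psi0*f_nuc to dB and subtracts f_nuc from dA;
        f_sev likewise couples dB and dC, term by term."""
        grid = LatticeGrid((0, 0, 0), 0.1, (3, 3, 3))
        p = KineticParams(
            k_beta=0, I_beta=0, IS_beta=0, k_A=0, I_A=0, IS_A=0,
            k_C=0, I_C=0, IS_C=0, nu=0, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        rng = np.random.default_rng(4)
        f = SpeciesFields(
            B=rng.uniform(0, 10, grid.n_points),
            A=rng.uniform(0, 5, grid.n_points),
            C=rng.uniform(0, 5, grid.n_points),
        )
        dB, dA, dC = species_rhs(f, ctx)
        fn = nucleation_rate(f.A, f.B, p)
        fs = severing_rate(f.C, f.B, p)
        assert np.allclose(dB, p.Psi0 * (fn + fs), rtol=1e-12)
        assert np.allclose(dA, -fn, rtol=1e-12)
        assert np.allclose(dC, -fs, rtol=1e-12)

    def test_reactions_accelerate_arp23_depletion(self):
        """With nucleation active, A falls faster than pure degradation."""
        grid = LatticeGrid((0, 0, 0), 0.1, (2, 2, 2))
        p = KineticParams(I_beta=0, IS_beta=0, I_A=0, IS_A=0, I_C=0,
                          IS_C=0, nu=0, eta=0)
        ctx = _uniform_ctx(grid, p)
        f0 = SpeciesFields(
            B=np.full(grid.n_points, 100.0),
            A=np.full(grid.n_points, 20.0),
            C=np.full(grid.n_points, 40.0),
        )
        out = step_fields(f0, ctx, 30.0, rtol=1e-10)
        assert (out.A < 20.0 * np.exp(-p.k_A * 30.0)).all()

    def test_zero_fields_only_influx_terms(self):
        grid = LatticeGrid((0, 0, 0), 0.1, (3, 3, 3))
        ctx = _uniform_ctx(grid, P, stimulus_on=True)
        f = SpeciesFields(
            B=np.zeros(grid.n_points), A=np.zeros(grid.n_points),
            C=np.zeros(grid.n_points),
        )
        dB, dA, dC = species_rhs(f, ctx)
        expect_B = np.zeros(grid.n_points)
        expect_B[ctx.geom.basal_mask] += P.Psi0 * P.I_beta
        expect_B[ctx.geom.stimulus_mask] += P.Psi0 * P.IS_beta
        assert np.allclose(dB, expect_B)
        assert (dA[~(ctx.geom.basal_mask | ctx.geom.stimulus_mask)] == 0).all()

    def test_upwind_advection_of_gaussian_bump(self):
        """A bump advected along +x moves at the right speed and conserves
        interior mass within first-order-upwind bounds."""
        grid = LatticeGrid((0, 0, 0), 0.05, (40, 7, 7))
        p = KineticParams(
            k_beta=0, I_beta=0, IS_beta=0, k_A=0, I_A=0, IS_A=0,
            k_C=0, I_C=0, IS_C=0, k_nuc=0, k_sev=0, nu=0.05, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        pts = grid.positions()
        B0 = np.exp(-((pts[:, 0] - 0.5) ** 2) / (2 * 0.1**2))
        f = SpeciesFields(B=B0.copy(), A=np.zeros_like(B0),
                          C=np.zeros_like(B0))
        dt = 0.5
        for _ in range(10):
            f = step_fields(f, ctx, dt, rtol=1e-8)
        # mass conserved in the interior (bump far from boundaries)
        assert f.B.sum() == pytest.approx(B0.sum(), rel=0.01)
        # center of mass moved by nu * t
        x = pts[:, 0]
        com0 = (x * B0).sum() / B0.sum()
        com1 = (x * f.B).sum() / f.B.sum()
        assert com1 - com0 == pytest.approx(p.nu * 10 * dt, rel=0.05)

    def test_cfl_violation_raises(self):
        grid = LatticeGrid((0, 0, 0), 0.05, (4, 4, 4))
        p = KineticParams(nu=1.0, I_beta=0, IS_beta=0, I_A=0, IS_A=0,
                          I_C=0, IS_C=0)
        ctx = _uniform_ctx(grid, p)
        f = SpeciesFields(B=np.ones(grid.n_points),
                          A=np.ones(grid.n_points), C=np.ones(grid.n_points))
        with pytest.raises(ValueError, match="CFL"):
            step_fields(f, ctx, 1.0)

    def test_negative_clip_is_logged(self):
        """A sharp front advected by upwinding can undershoot; clipping
        reports the removed mass."""
        grid = LatticeGrid((0, 0, 0), 0.05, (30, 3, 3))
        p = KineticParams(
            k_beta=0, I_beta=0, IS_beta=0, k_A=0, I_A=0, IS_A=0, k_C=0,
            I_C=0, IS_C=0, k_nuc=0, k_sev=0, nu=0.04, eta=0,
        )
        ctx = _uniform_ctx(grid, p)
        B0 = np.zeros(grid.n_points)
        B0[grid.n_points // 2] = 100.0
        f = SpeciesFields(B=B0, A=np.zeros_like(B0), C=np.zeros_like(B0))
        clip = {}
        for _ in range(5):
            f = step_fields(f, ctx, 1.0, clip_log=clip)
        assert (f.B >= 0).all()
        assert clip.get("clipped_B", 0.0) >= 0.0


def test_initial_fields_match_nonspatial_steady_state(lattice_setup):
    grid, dfield, geom = lattice_setup
    f = initial_fields(grid, geom, P)
    assert f.B.sum() == pytest.approx(P.Psi0 * P.I_beta / P.k_beta, rel=1e-9)
    assert f.A.sum() == pytest.approx(P.I_A / P.k_A, rel=1e-9)
    assert f.C.sum() == pytest.approx(P.I_C / P.k_C, rel=1e-9)
    assert (f.B[~geom.basal_mask] == 0).all()
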