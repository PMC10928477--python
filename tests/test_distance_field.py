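"""Signed distance field: oracle equivalence, potential, force density."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinesim.distance_field import (
    DistanceField,
    LatticeGrid,
    MeshQuery,
    compute_signed_distance,
    divergence_of_direction,
    force_density,
    repulsive_potential,
    signed_distance_brute_force,
)
from spinesim.geometry import SpineMesh
from spinesim.params import RepulsivePotentialParams

POT = RepulsivePotentialParams()  # alpha=3e4 pN, beta=40


class TestClosestElement:
    def test_pruned_query_equals_brute_force_bitwise(self, icosphere, rng):
        """Accelerated nearest-element queries must match exhaustive search
        exactly, including tie-breaking to the lowest face index."""
        pts = rng.uniform(-1.6, 1.6, (200, 3))
        q = MeshQuery(icosphere)
        d1, f1, b1, c1 = q.query(pts)
        d2, f2, b2, c2 = q.query(pts, brute_force=True)
        assert np.array_equal(d1, d2)
        assert np.array_equal(f1, f2)
        assert np.array_equal(b1, b2)
        assert np.array_equal(c1, c2)

    def test_signs_match_analytic_sphere(self, icosphere, rng):
        pts = rng.uniform(-1.5, 1.5, (300, 3))
        r = np.linalg.norm(pts, axis=1)
        keep = np.abs(r - 1.0) > 0.02  # away from the faceted surface
        ds = signed_distance_brute_force(pts[keep], icosphere)
        assert np.array_equal(np.sign(ds), np.sign(r[keep] - 1.0))

    def test_vertex_coincident_point(self, icosphere):
        v0 = icosphere.vertices[7]
        q = MeshQuery(icosphere)
        d, fid, bary, closest = q.query(v0[None, :])
        assert d[0] == 0.0
        # closest element is that vertex: one-hot barycentric coordinates
        corner = int(np.argmax(bary[0]))
        assert icosphere.faces[fid[0], corner] == 7
        assert bary[0, corner] == pytest.approx(1.0)


class TestDistanceField:
    def test_sphere_center_and_direction(self, icosphere):
        grid = LatticeGrid((-1.4, -1.4, -1.4), 0.2, (15, 15, 15))
        field = compute_signed_distance(grid, icosphere)
        pts = grid.positions()
        i0 = int(np.argmin(np.linalg.norm(pts, axis=1)))
        assert field.ds[i0] == pytest.approx(-1.0, rel=0.01)
        norms = np.linalg.norm(field.direction, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)
        # direction points outward: d . r > 0 away from the center
        r = np.linalg.norm(pts, axis=1)
        sel = r > 0.3
        dots = np.einsum("ij,ij->i", field.direction[sel], pts[sel] / r[sel, None])
        assert (dots > 0.7).all()

    def test_gradient_of_ds_has_unit_norm(self, icosphere):
        """|grad ds| = 1 where the field is smooth (eikonal property)."""
        grid = LatticeGrid((-1.3, -1.3, -1.3), 0.1, (27, 27, 27))
        field = compute_signed_distance(grid, icosphere)
        ds = grid.reshape(field.ds)
        g = np.stack(
            [np.gradient(ds, 0.1, axis=a) for a in range(3)], axis=-1
        )
        gn = np.linalg.norm(g, axis=-1).ravel()
        pts = grid.positions()
        r = np.linalg.norm(pts, axis=1)
        smooth = (r > 0.4) & (np.abs(r - 1.0) > 0.15)  # avoid axis & surface
        assert np.abs(gn[smooth] - 1.0).max() < 0.05

    def test_grid_must_contain_mesh(self, icosphere):
        grid = LatticeGrid((-0.5, -0.5, -0.5), 0.1, (5, 5, 5))
        with pytest.raises(ValueError, match="grid too small"):
            compute_signed_distance(grid, icosphere)

    def test_rigid_motion_equivariance(self, icosphere, rng):
        """ds is unchanged when mesh and evaluation points move together."""
        pts = rng.uniform(-1.4, 1.4, (50, 3))
        ds0 = signed_distance_brute_force(pts, icosphere)
        th = 0.7
        R = np.array(
            [[np.cos(th), -np.sin(th), 0],
             [np.sin(th), np.cos(th), 0],
             [0, 0, 1.0]]
        )
        shift = np.array([0.3, -1.1, 2.2])
        moved = SpineMesh(icosphere.vertices @ R.T + shift, icosphere.faces)
        ds1 = signed_distance_brute_force(pts @ R.T + shift, moved)
        assert np.allclose(ds0, ds1, atol=1e-12)


def _radial_field(grid):
    """Exact signed-distance field of a unit sphere (analytic oracle)."""
    pts = grid.positions()
    r = np.linalg.norm(pts, axis=1)
    d = np.zeros_like(pts)
    ok = r > 1e-12
    d[ok] = pts[ok] / r[ok, None]
    return DistanceField(
        grid=grid, ds=r - 1.0, face_id=np.zeros(len(pts), dtype=np.int64),
        bary=np.zeros((len(pts), 3)), direction=d, w=pts.copy(),
    )


class TestPotentialAndForce:
    def test_potential_values(self):
        grid = LatticeGrid((0, 0, 0), 1.0, (2, 1, 1))
        f = _radial_field(LatticeGrid((-2, -2, -2), 0.5, (9, 9, 9)))
        psi = repulsive_potential(f, POT)
        # psi(0) = 0; saturation at alpha/2; odd in ds
        i_surface = int(np.argmin(np.abs(f.ds)))
        assert abs(psi[np.argmin(np.abs(f.ds))]) <= 0.5 * POT.alpha * np.tanh(
            POT.beta * abs(f.ds[i_surface])
        ) + 1e-9
        assert np.abs(psi).max() <= 0.5 * POT.alpha
        far = f.ds > 0.2
        assert np.allclose(psi[far], 0.5 * POT.alpha, rtol=1e-4)
        np.testing.assert_allclose(
            psi, 0.5 * POT.alpha * np.tanh(POT.beta * f.ds), rtol=1e-12
        )

    def test_potential_at_inverse_beta(self):
        # ds = 1/beta: psi = alpha tanh(1)/2 = 0.3807970...*alpha
        f = _radial_field(LatticeGrid((-2, -2, -2), 0.5, (9, 9, 9)))
        f.ds[:] = 1.0 / POT.beta
        psi = repulsive_potential(f, POT)
        assert np.allclose(psi, 0.38079707797788244 * POT.alpha, rtol=1e-12)

    def test_force_density_magnitude_and_direction(self):
        f = _radial_field(LatticeGrid((-2, -2, -2), 0.25, (17, 17, 17)))
        fu = force_density(f, POT)
        # antiparallel to d everywhere
        dots = np.einsum("ij,ij->i", fu, f.direction)
        r = np.linalg.norm(f.grid.positions(), axis=1)
        assert (dots[r > 1e-6] < 0).all()
        # peak magnitude alpha*beta/2 at the surface
        mag = np.linalg.norm(fu, axis=1)
        i_surf = int(np.argmin(np.abs(f.ds)))
        expect = 0.5 * POT.alpha * POT.beta / np.cosh(
            POT.beta * f.ds[i_surf]
        ) ** 2
        assert mag[i_surf] == pytest.approx(expect, rel=1e-12)
        assert mag.max() <= 0.5 * POT.alpha * POT.beta + 1e-9

    def test_force_density_is_minus_grad_psi(self, icosphere):
        """Analytic f_u matches finite differences of the psi lattice.

        The potential width 1/beta must be resolved by the lattice for the
        finite-difference oracle to converge, so a gentle steepness is used
        here (the identity f_u = -grad psi holds for any beta).
        """
        pot = RepulsivePotentialParams(alpha=POT.alpha, beta=2.0)
        grid = LatticeGrid((-1.4, -1.4, -1.4), 0.07, (41, 41, 41))
        field = compute_signed_distance(grid, icosphere)
        psi = grid.reshape(repulsive_potential(field, pot))
        fu = force_density(field, pot)
        g = np.stack(
            [-np.gradient(psi, grid.spacing, axis=a) for a in range(3)],
            axis=-1,
        ).reshape(-1, 3)
        pts = grid.positions()
        r = np.linalg.norm(pts, axis=1)
        # compare where psi varies and the field is smooth
        sel = (np.abs(field.ds) < 0.05) & (r > 0.5)
        num = np.linalg.norm(g[sel] - fu[sel], axis=1)
        den = np.linalg.norm(fu[sel], axis=1)
        assert np.median(num / den) < 0.05


class TestDivergence:
    def test_radial_direction_divergence_is_2_over_r(self):
        grid = LatticeGrid((-2, -2, -2), 0.1, (41, 41, 41))
        f = _radial_field(grid)
        div = divergence_of_direction(f, grid)
        pts = grid.positions()
        r = np.linalg.norm(pts, axis=1)
        sel = (r > 0.5) & (r < 1.6)
        rel = np.abs(div[sel] - 2.0 / r[sel]) / (2.0 / r[sel])
        assert rel.max() < 0.05

    def test_planar_field_divergence_zero(self):
        grid = LatticeGrid((0, 0, 0), 0.1, (12, 12, 12))
        pts = grid.positions()
        d = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        f = DistanceField(
            grid=grid, ds=pts[:, 2] - 0.5,
            face_id=np.zeros(len(pts), dtype=np.int64),
            bary=np.zeros((len(pts), 3)), direction=d, w=pts,
        )
        assert np.abs(divergence_of_direction(f, grid)).max() < 1e-6


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    ds=st.floats(-10, 10),
    alpha=st.floats(1.0, 1e6),
    beta=st.floats(0.1, 100.0),
)
def test_potential_odd_and_bounded(ds, alpha, beta):
    """psi is odd in signed distance and bounded by alpha/2."""
    grid = LatticeGrid((0, 0, 0), 1.0, (1, 1, 2))
    pot = RepulsivePotentialParams(alpha=alpha, beta=beta)
    base = dict(
        grid=grid, face_id=np.zeros(2, dtype=np.int64),
        bary=np.zeros((2, 3)),
        direction=np.tile([0.0, 0.0, 1.0], (2, 1)),
        w=np.zeros((2, 3)),
    )
    f_pos = DistanceField(ds=np.array([ds, -ds]), **base)
    psi = repulsive_potential(f_pos, pot)
    assert psi[0] == pytest.approx(-psi[1], rel=1e-12, abs=1e-300)
    assert abs(psi[0]) <= alpha / 2 + 1e-9
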