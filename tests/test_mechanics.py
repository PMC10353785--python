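"""Mechanics: Morton keys, voxel sorting, force laws, integration, confinement."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from cellvox import mechanics as mech
from cellvox.grid import Grid
from cellvox.params import DuctGeometry, MechanicsParams, VolumeParams

from conftest import make_population


def morton_bitloop(i, j, k):
    """Independent bit-loop oracle for the Morton interleave."""
    v = 0
    for b in range(21):
        v |= ((i >> b) & 1) << (3 * b)
        v |= ((j >> b) & 1) << (3 * b + 1)
        v |= ((k >> b) & 1) << (3 * b + 2)
    return v


class TestMorton:
    @pytest.mark.parametrize("ijk,expected", [
        ((0, 0, 0), 0),
        ((1, 0, 0), 1),   # bit 0 of i -> key bit 0
        ((0, 1, 0), 2),   # bit 0 of j -> key bit 1
        ((0, 0, 1), 4),   # bit 0 of k -> key bit 2
        ((3, 5, 1), morton_bitloop(3, 5, 1)),  # = 143 under this convention
    ])
    def test_examples_match_bitloop_oracle(self, ijk, expected):
        assert int(mech.morton_encode(*ijk)) == expected == morton_bitloop(*ijk)

    @given(st.integers(0, 2 ** 21 - 1), st.integers(0, 2 ** 21 - 1),
           st.integers(0, 2 ** 21 - 1))
    def test_encode_matches_oracle_and_roundtrips(self, i, j, k):
        key = int(mech.morton_encode(i, j, k))
        assert key == morton_bitloop(i, j, k)
        ii, jj, kk = mech.morton_decode(key)
        assert (int(ii), int(jj), int(kk)) == (i, j, k)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            mech.morton_encode(-1, 0, 0)
        with pytest.raises(ValueError):
            mech.morton_encode(4, 0, 0, shape=(4, 4, 4))
        with pytest.raises(ValueError):
            mech.morton_encode(1 << 21, 0, 0)


class TestSortByVoxel:
    def test_ranges_match_brute_force_membership(self, rng):
        grid = Grid(5, 4, 3, 25.0, origin=(0, 0, 0))
        n = 1000
        pos = rng.uniform(0, 1, (n, 3)) * (np.array(grid.shape) * grid.dx - 1e-9)
        pop = make_population(pos)
        mech.sort_by_voxel(pop, grid)
        lin = grid.linear_index(grid.voxel_index(pop.position))
        for v in range(grid.n_voxels):
            in_range = set(range(grid.voxel_start[v], grid.voxel_end[v]))
            by_position = set(np.flatnonzero(lin == v))
            assert in_range == by_position

    def test_sort_is_a_permutation(self, rng):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pos = rng.uniform(0, 100, (200, 3))
        pop = make_population(pos)
        pop.phase_clock[:] = np.arange(200, dtype=float)
        mech.sort_by_voxel(pop, grid)
        # multiset of per-cell records is invariant
        assert sorted(pop.phase_clock) == sorted(range(200))
        np.testing.assert_allclose(np.sort(pop.position.ravel()),
                                   np.sort(pos.ravel()))

    def test_already_sorted_is_identity(self, rng):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pos = rng.uniform(0, 100, (50, 3))
        pop = make_population(pos)
        mech.sort_by_voxel(pop, grid)
        before = pop.position.copy()
        order = mech.sort_by_voxel(pop, grid)
        np.testing.assert_array_equal(order, np.arange(50))
        np.testing.assert_array_equal(pop.position, before)

    def test_single_voxel_single_range(self, rng):
        grid = Grid(3, 3, 3, 25.0, origin=(0, 0, 0))
        pop = make_population(rng.uniform(30, 45, (20, 3)))
        mech.sort_by_voxel(pop, grid)
        v = grid.linear_index(grid.voxel_index(pop.position))[0]
        assert grid.voxel_start[v] == 0 and grid.voxel_end[v] == 20
        others = np.delete(np.arange(grid.n_voxels), v)
        assert np.all(grid.voxel_start[others] == grid.voxel_end[others])


class TestPairwiseForce:
    def setup_method(self):
        self.p = MechanicsParams()  # C_cca=0.4, C_ccr=10, factor 1.25
        self.R = VolumeParams().R_std

    def test_repulsion_vanishes_at_contact_distance(self):
        RR = 2 * self.R
        f = mech.pairwise_force([0, 0, 0], [RR, 0, 0], self.R, self.R, self.p)
        # only adhesion remains at |r| = R_R
        RA = self.p.adhesion_distance_factor * RR
        expected = self.p.C_cca * (1 - RR / RA) ** 2
        assert f[0] == pytest.approx(expected)

    def test_total_force_vanishes_at_adhesion_range(self):
        RA = self.p.adhesion_distance_factor * 2 * self.R
        f = mech.pairwise_force([0, 0, 0], [RA, 0, 0], self.R, self.R, self.p)
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_half_overlap_magnitudes(self):
        # |r| = R_R / 2: repulsive magnitude C_ccr (1 - 1/2)^2 = 2.5
        RR = 2 * self.R
        d = 0.5 * RR
        RA = self.p.adhesion_distance_factor * RR
        f = mech.pairwise_force([0, 0, 0], [d, 0, 0], self.R, self.R, self.p)
        adhesive = self.p.C_cca * (1 - d / RA) ** 2
        assert f[0] == pytest.approx(adhesive - 2.5)

    def test_coincident_centers_fallback(self):
        f = mech.pairwise_force([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                self.R, self.R, self.p)
        np.testing.assert_allclose(f, [-self.p.C_ccr, 0.0, 0.0])
        # the aggregator keeps the pair antisymmetric via the cell ordering
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pop = make_population([[50.0, 50.0, 50.0], [50.0, 50.0, 50.0]])
        mech.sort_by_voxel(pop, grid)
        F = mech.aggregate_forces(pop, grid, self.p)
        np.testing.assert_array_equal(F[0], -F[1])
        assert abs(F[0, 0]) == self.p.C_ccr

    @given(st.floats(1.0, 40.0), st.floats(5.0, 12.0), st.floats(5.0, 12.0))
    def test_antisymmetry(self, d, Ri, Rj):
        xi, xj = np.zeros(3), np.array([d * 0.6, d * 0.64, -d * 0.48]) / 1.0
        fij = mech.pairwise_force(xi, xj, Ri, Rj, self.p)
        fji = mech.pairwise_force(xj, xi, Rj, Ri, self.p)
        np.testing.assert_allclose(fij, -fji, atol=1e-12)


def brute_force_all_pairs(pop, params):
    """Independent O(N^2) force oracle (vectorized, no neighbor lists)."""
    x = pop.position
    R = pop.radius
    r = x[None, :, :] - x[:, None, :]           # r[i, j] = x_j - x_i
    d = np.linalg.norm(r, axis=-1)
    np.fill_diagonal(d, np.inf)
    RR = R[:, None] + R[None, :]
    RA = params.adhesion_distance_factor * RR
    mag = np.where(d <= RA, params.C_cca * (1 - d / RA) ** 2, 0.0)
    mag -= np.where(d <= RR, params.C_ccr * (1 - d / RR) ** 2, 0.0)
    f = (mag / d)[:, :, None] * r
    return f.sum(axis=1) + np.asarray(params.F_mot)


class TestAggregateForces:
    def test_single_cell_feels_only_motility(self):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pop = make_population([[50.0, 50.0, 50.0]])
        mech.sort_by_voxel(pop, grid)
        p = MechanicsParams(F_mot=(0.5, -0.25, 0.0))
        F = mech.aggregate_forces(pop, grid, p)
        np.testing.assert_allclose(F, [[0.5, -0.25, 0.0]])

    def test_matches_all_pairs_oracle(self, rng, mech_params):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        for _ in range(5):
            n = int(rng.integers(50, 200))
            pos = rng.uniform(0, 100, (n, 3))
            V = rng.uniform(0.5, 2.0, n) * VolumeParams().V_std
            pop = make_population(pos, V=V)
            mech.sort_by_voxel(pop, grid)
            F = mech.aggregate_forces(pop, grid, mech_params)
            Fb = brute_force_all_pairs(pop, mech_params)
            assert np.abs(F - Fb).max() <= 1e-10

    def test_newtons_third_law_across_voxels(self, mech_params):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        # two cells in adjacent voxels, within interaction range
        pop = make_population([[20.0, 50.0, 50.0], [30.0, 50.0, 50.0]])
        mech.sort_by_voxel(pop, grid)
        F = mech.aggregate_forces(pop, grid, mech_params)
        np.testing.assert_array_equal(F[0], -F[1])

    def test_momentum_conservation(self, rng, mech_params):
        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pop = make_population(rng.uniform(0, 100, (150, 3)))
        mech.sort_by_voxel(pop, grid)
        F = mech.aggregate_forces(pop, grid, mech_params)
        assert np.abs(F.sum(axis=0)).max() <= 1e-10


class TestIntegration:
    def test_velocity_is_force_over_drag(self):
        F = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(mech.velocities(F, MechanicsParams(eta=1.0)), F)
        np.testing.assert_allclose(
            mech.velocities(np.array([[1.0, 0, 0]]), MechanicsParams(eta=2.0)),
            [[0.5, 0, 0]])

    def test_adams_bashforth_two_step(self):
        pop = make_population([[0.0, 0.0, 0.0]])
        v1 = np.array([[1.0, 0.0, 0.0]])
        mech.update_positions(pop, v1, 0.1)   # bootstrap: Euler
        np.testing.assert_allclose(pop.position, [[0.1, 0, 0]])
        v2 = np.array([[2.0, 0.0, 0.0]])
        # x += dt/2 (3 v2 - v1) = 0.05 * 5 = 0.25
        mech.update_positions(pop, v2, 0.1)
        np.testing.assert_allclose(pop.position, [[0.35, 0, 0]])
        np.testing.assert_allclose(pop.previous_velocity, v2)

    def test_stationary_under_zero_velocity(self):
        pop = make_population([[1.0, 2.0, 3.0]])
        mech.update_positions(pop, np.zeros((1, 3)), 0.1)
        np.testing.assert_allclose(pop.position, [[1.0, 2.0, 3.0]])


class TestConfinement:
    def setup_method(self):
        self.grid = Grid(40, 24, 24, 25.0,
                         origin=(-500.0, -300.0, -300.0))
        self.duct = DuctGeometry(axis=(1, 0, 0), radius=100.0, length=1000.0,
                                 closed_end_position=-400.0)

    def test_interior_cell_unchanged(self):
        pop = make_population([[0.0, 10.0, -20.0]])
        before = pop.position.copy()
        mech.apply_confinement(pop, self.grid, self.duct)
        np.testing.assert_array_equal(pop.position, before)

    def test_radial_projection(self):
        pop = make_population([[0.0, 105.0, 0.0]])  # 5 um outside the lumen wall
        R = pop.radius[0]
        mech.apply_confinement(pop, self.grid, self.duct)
        assert np.hypot(pop.position[0, 1], pop.position[0, 2]) == \
            pytest.approx(self.duct.radius - R)
        assert pop.position[0, 0] == 0.0

    def test_closed_end_clamp(self):
        pop = make_population([[-402.0, 0.0, 0.0]])  # 2 um behind the closed end
        R = pop.radius[0]
        mech.apply_confinement(pop, self.grid, self.duct)
        assert pop.position[0, 0] == pytest.approx(
            self.duct.closed_end_position + R)

    def test_domain_box_clamp(self):
        pop = make_population([[510.0, 0.0, 0.0]])  # outside the x face
        R = pop.radius[0]
        mech.apply_confinement(pop, self.grid, None)
        assert pop.position[0, 0] == pytest.approx(500.0 - R)


class TestTwoCellEquilibrium:
    def test_relaxes_to_force_balance_separation(self):
        # overlapping identical standard cells relax to the separation d*
        # solving sqrt(C_ccr) (1 - d/R_R) = sqrt(C_cca) (1 - d/R_A)
        from scipy.optimize import brentq
        p = MechanicsParams()
        R = VolumeParams().R_std
        RR, RA = 2 * R, p.adhesion_distance_factor * 2 * R

        d_star = brentq(lambda d: np.sqrt(p.C_ccr) * (1 - d / RR)
                        - np.sqrt(p.C_cca) * (1 - d / RA), 1e-6, RR)
        assert d_star == pytest.approx(16.02, abs=0.01)

        grid = Grid(4, 4, 4, 25.0, origin=(0, 0, 0))
        pop = make_population([[44.0, 50.0, 50.0], [56.0, 50.0, 50.0]])
        for _ in range(3000):
            mech.sort_by_voxel(pop, grid)
            F = mech.aggregate_forces(pop, grid, p)
            mech.update_positions(pop, mech.velocities(F, p), 0.1)
        d_sim = np.linalg.norm(pop.position[0] - pop.position[1])
        assert abs(d_sim - d_star) / d_star < 0.01
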