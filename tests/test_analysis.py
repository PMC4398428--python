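import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from schlogl.analysis import (classify_bistable, detect_switches, kl_divergence,
                              kymograph, pair_correlation,
                              random_control_snapshot, bistable_range)
from schlogl.containers import Histogram1D, Trajectory
from schlogl.geometry import Box, ParticleSnapshot, Sphere
from schlogl.params import standard_parameters


def _hist(weights, edges=None):
    weights = np.asarray(weights, dtype=float)
    if edges is None:
        edges = np.arange(len(weights) + 1, dtype=float)
    return Histogram1D(edges=edges, weights=weights)


class TestKLDivergence:
    def test_identical_distributions(self):
        h = _hist([0.3, 0.7])
        assert kl_divergence(h, h, pseudocount=0.0) == 0.0
        assert kl_divergence(h, h) == 0.0

    def test_two_term_reference_value(self):
        val = kl_divergence(_hist([0.5, 0.5]), _hist([0.9, 0.1]), pseudocount=0.0)
        assert val == pytest.approx(0.5108, abs=1e-4)

    def test_asymmetry(self):
        a, b = _hist([0.5, 0.5]), _hist([0.9, 0.1])
        assert kl_divergence(a, b, 0.0) != kl_divergence(b, a, 0.0)

    def test_mismatched_bins_rejected(self):
        with pytest.raises(ValueError):
            kl_divergence(_hist([1.0, 1.0]), _hist([1.0, 1.0, 1.0]))

    def test_zero_bin_policy(self):
        ref, test = _hist([1.0, 1.0]), _hist([2.0, 0.0])
        assert np.isfinite(kl_divergence(ref, test))  # pseudocount keeps it finite
        with pytest.raises(ValueError):
            kl_divergence(ref, test, pseudocount=0.0)

    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=8),
           st.lists(st.floats(0.0, 10.0), min_size=2, max_size=8))
    def test_nonnegative(self, w1, w2):
        n = min(len(w1), len(w2))
        assert kl_divergence(_hist(w1[:n]), _hist(w2[:n])) >= -1e-12


class TestPairCorrelation:
    def test_poisson_control_is_flat(self):
        box = Box.cube(10.0)
        snaps = [random_control_snapshot(1000, box, seed=i) for i in range(20)]
        pc = pair_correlation(snaps)
        sel = pc.r <= box.Lx / 4.0
        assert abs(pc.g[sel].mean() - 1.0) < 0.03  # ~3 SE at these counts

    def test_single_pair_occupies_one_shell(self):
        box = Box.cube(8.0)
        d = 0.51
        snap = ParticleSnapshot(time=0.0,
                                x_positions=np.array([[1.0, 1.0, 1.0],
                                                      [1.0 + d, 1.0, 1.0]]),
                                x2_positions=np.empty((0, 3)), geometry=box)
        pc = pair_correlation([snap], a=0.1)
        hit = pc.g > 0
        assert hit.sum() == 1
        k = int(np.flatnonzero(hit)[0])
        assert pc.r[k] - 0.1 < d <= pc.r[k]

    def test_small_snapshots_skipped_with_warning(self):
        box = Box.cube(8.0)
        good = random_control_snapshot(50, box, seed=0)
        lonely = random_control_snapshot(1, box, seed=1)
        with pytest.warns(UserWarning):
            pc = pair_correlation([good, lonely])
        assert pc.n_snapshots == 1

    def test_non_periodic_geometry_rejected(self):
        snap = random_control_snapshot(10, Sphere.from_volume(8.0), seed=0)
        with pytest.raises(ValueError):
            pair_correlation([snap])


class TestRandomControl:
    def test_empty_snapshot(self):
        snap = random_control_snapshot(0, Box.cube(1.0), seed=0)
        assert snap.n_X == 0

    def test_seeded_repeat_identical(self):
        a = random_control_snapshot(100, Box.cube(1.0), seed=7)
        b = random_control_snapshot(100, Box.cube(1.0), seed=7)
        np.testing.assert_array_equal(a.x_positions, b.x_positions)

    def test_nearest_neighbor_distance_matches_poisson_form(self):
        # mean NN distance of a unit-intensity Poisson process: 0.5539 N^(-1/3)
        box = Box.cube(1.0)
        dists = []
        for seed in range(5):
            pos = random_control_snapshot(1000, box, seed=seed).x_positions
            delta = pos[:, None, :] - pos[None, :, :]
            delta -= np.rint(delta)  # minimum image, L = 1
            d = np.sqrt((delta ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            dists.append(d.min(axis=1).mean())
        assert np.mean(dists) == pytest.approx(0.5539 * 1000 ** (-1 / 3), rel=0.03)


class TestKymograph:
    def test_uniform_particles_flat_columns(self):
        box = Box(10.0, 1.0, 1.0)
        snaps = [random_control_snapshot(2000, box, seed=i) for i in range(3)]
        km = kymograph(snaps, n_bins=20)
        assert km.counts.shape == (3, 20)
        assert np.all(km.counts.sum(axis=1) == 2000)  # column sums = totals
        assert km.counts.std() / km.counts.mean() < 0.35  # counting noise only

    def test_left_half_occupation(self):
        box = Box(10.0, 1.0, 1.0)
        pos = np.random.default_rng(0).uniform(0, 1, (100, 3)) * [5.0, 1.0, 1.0]
        snap = ParticleSnapshot(time=0.0, x_positions=pos,
                                x2_positions=np.empty((0, 3)), geometry=box)
        km = kymograph([snap], n_bins=20)
        assert km.counts[0, 10:].sum() == 0
        assert km.counts[0, :10].sum() == 100

    def test_non_box_rejected(self):
        snap = random_control_snapshot(10, Sphere.from_volume(8.0), seed=0)
        with pytest.raises(ValueError):
            kymograph([snap])


def _traj(x_values, V=10.0, dt=1.0):
    x = np.asarray(x_values, dtype=float)
    return Trajectory(times=np.arange(len(x)) * dt, X=(x * V).astype(int),
                      X2=np.zeros(len(x), dtype=int), scheme="conventional",
                      V=V, t_max=len(x) * dt)


class TestSwitchDetection:
    def test_monotone_crossing_is_one_switch(self, std):
        rec = detect_switches(_traj(np.linspace(0.2, 2.6, 30)), std)
        assert rec.n_switches == 1
        assert rec.directions == ("low->high",)

    def test_basin_oscillation_suppressed(self, std):
        x = 0.3 + 0.2 * np.sin(np.linspace(0, 20, 100))  # stays below upper band
        rec = detect_switches(_traj(x), std)
        assert rec.n_switches == 0

    def test_directions_alternate(self, std, rng):
        x = rng.uniform(0.0, 3.0, size=300)
        rec = detect_switches(_traj(x), std)
        for a, b in zip(rec.directions, rec.directions[1:]):
            assert a != b

    def test_monostable_rejected(self):
        with pytest.raises(ValueError):
            detect_switches(_traj([0.2, 0.3]), standard_parameters(1.0))

    def test_classification_symmetric_round_trip(self, std):
        up_down = _traj([0.2, 2.6, 0.2, 2.6])
        one_way = _traj([0.2, 2.6, 2.6])
        assert classify_bistable(up_down, up_down, std)
        assert not classify_bistable(one_way, up_down, std)


class TestBistableRange:
    def test_well_mixed_interval_contains_reference_point(self, std):
        rng = bistable_range(std, 10.0, np.arange(3.4, 5.0, 0.05),
                             mode="well-mixed")
        assert rng is not None
        assert rng[0] <= 3.7 <= rng[1]

    def test_spatial_classification_at_fast_diffusion(self, std):
        # small volume so dwell times (~30 time units) are far shorter than
        # the run; fast diffusion keeps the system well mixed, so reversible
        # switching must be observed from both starts
        out = bistable_range(std, 5.0, [3.6], mode="spatial", D=(30.0, 10.0),
                             t_max=400.0, seed=42, record_dt=0.25)
        assert out == (3.6, 3.6)

    def test_spatial_mode_monostable_grid_point(self, std):
        # outside the deterministic window no thresholds exist: classified
        # monostable without running any simulation
        out = bistable_range(std, 5.0, [3.0], mode="spatial", D=(30.0, 10.0),
                             t_max=10.0, seed=0)
        assert out is None
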