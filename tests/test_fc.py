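"""Seed geometry, correlation maps, Fisher averaging and thresholding."""

import numpy as np
import pytest

from fusikit.errors import DegenerateSignalError, GeometryError
from fusikit.fc import (
    SeedMap,
    SeedSpec,
    average_maps_fisher,
    seed_map,
    seed_signal,
    sphere_mask,
    threshold_top_fraction,
)


class TestSphere:
    def test_radius_three_voxels_in_3d_counts_123(self):
        mask = sphere_mask((9, 9, 9), 0.1, (0.4, 0.4, 0.4), 0.3)
        # brute-force voxel-center count
        count = sum(
            (0.1 * i - 0.4) ** 2 + (0.1 * j - 0.4) ** 2 + (0.1 * k - 0.4) ** 2
            <= 0.3**2 + 1e-12
            for i in range(9)
            for j in range(9)
            for k in range(9)
        )
        assert mask.sum() == count == 123

    def test_empty_sphere_raises(self):
        with pytest.raises(GeometryError):
            sphere_mask((5, 5), 1.0, (100.0, 100.0), 0.3)


class TestSeedSignal:
    def test_single_voxel_sphere_returns_that_series(self):
        rng = np.random.default_rng(0)
        clean = rng.standard_normal((20, 7, 7))
        spec = SeedSpec("s", (0.3, 0.3), radius_mm=0.05)
        assert np.allclose(seed_signal(clean, spec, 0.1), clean[:, 3, 3])

    def test_uniform_volume_equals_global_signal(self):
        vals = np.linspace(0, 1, 15)
        clean = np.repeat(vals[:, None, None], 25, axis=1).reshape(15, 5, 5)
        spec = SeedSpec("s", (0.2, 0.2), radius_mm=0.15)
        assert np.allclose(seed_signal(clean, spec, 0.1), vals)


class TestSeedMap:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.sig = rng.standard_normal(1000)
        self.clean = np.zeros((1000, 5, 5))
        self.clean[:, 2, 2] = self.sig
        self.clean[:, 0, 0] = self.sig * 3 + 2  # identical up to affine
        self.clean[:, 4, 4] = -self.sig
        self.clean[:, 1, 3] = rng.standard_normal(1000)  # independent
        self.spec = SeedSpec("s", (0.2, 0.2), radius_mm=0.05)

    def test_correlations(self):
        smap = seed_map(self.clean, self.spec, 0.1)
        assert smap.r[2, 2] == pytest.approx(1.0)
        assert smap.r[0, 0] == pytest.approx(1.0)
        assert smap.r[4, 4] == pytest.approx(-1.0)
        assert abs(smap.r[1, 3]) < 0.1
        assert smap.zero_variance[3, 3]
        assert smap.r[3, 3] == 0.0

    def test_affine_invariance(self):
        a = seed_map(self.clean, self.spec, 0.1)
        b = seed_map(self.clean * 2.5 + 7.0, self.spec, 0.1)
        assert np.allclose(a.r, b.r, atol=1e-12)

    def test_constant_seed_rejected(self):
        clean = np.ones((10, 3, 3))
        with pytest.raises(DegenerateSignalError):
            seed_map(clean, SeedSpec("s", (0.1, 0.1), radius_mm=0.05), 0.1)


class TestFisherAveraging:
    def spec_map(self, r):
        spec = SeedSpec("s", (0.0, 0.0))
        return SeedMap(r=np.asarray(r, float), seed=spec, n_frames=100)

    def test_single_map_identity(self):
        m = self.spec_map([[0.3, -0.8], [0.0, 1.0]])
        assert np.allclose(average_maps_fisher([m]).r, m.r, atol=1e-6)

    def test_odd_symmetry_cancels(self):
        out = average_maps_fisher([self.spec_map([[0.5]]), self.spec_map([[-0.5]])])
        assert out.r[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_pair(self):
        out = average_maps_fisher([self.spec_map([[0.2]]), self.spec_map([[0.6]])])
        expected = np.tanh((np.arctanh(0.2) + np.arctanh(0.6)) / 2)
        assert out.r[0, 0] == pytest.approx(expected)
        assert expected == pytest.approx(0.4202, abs=5e-4)


class TestThreshold:
    def test_fraction_one_returns_brain_mask(self):
        smap = SeedMap(np.random.default_rng(2).uniform(-1, 1, (10, 10)),
                       SeedSpec("s", (0, 0)), 100)
        brain = np.zeros((10, 10), bool)
        brain[2:8, 2:8] = True
        assert np.array_equal(threshold_top_fraction(smap, brain, 1.0), brain)

    def test_exact_count_and_separation(self):
        r = np.full(100, 0.1)
        top = np.random.default_rng(3).choice(100, 10, replace=False)
        r[top] = 0.9
        smap = SeedMap(r.reshape(10, 10), SeedSpec("s", (0, 0)), 100)
        mask = threshold_top_fraction(smap, np.ones((10, 10), bool), 0.10)
        assert mask.sum() == 10
        assert set(np.flatnonzero(mask.reshape(-1))) == set(top)

    def test_absolute_vs_signed_ranking(self):
        r = np.zeros((10, 10))
        r.reshape(-1)[:5] = -0.9
        r.reshape(-1)[5:10] = 0.5
        smap = SeedMap(r, SeedSpec("s", (0, 0)), 100)
        brain = np.ones((10, 10), bool)
        by_abs = threshold_top_fraction(smap, brain, 0.05, by_absolute=True)
        by_signed = threshold_top_fraction(smap, brain, 0.05, by_absolute=False)
        assert set(np.flatnonzero(by_abs.reshape(-1))) == {0, 1, 2, 3, 4}
        assert set(np.flatnonzero(by_signed.reshape(-1))) == {5, 6, 7, 8, 9}


def test_network_recovery_on_quiet_pd_sim(quiet_pd_sim):
    """Top-10 % of a seed map recovers the seeded bilateral network."""
    from fusikit.simulate import network_centers

    config, pd, gt = quiet_pd_sim
    center = network_centers(config.grid_shape)[0]
    spec = SeedSpec("seed0", tuple(np.array(center) * config.voxel_size_mm))
    smap = seed_map(pd.volumes, spec, config.voxel_size_mm, gt.brain_mask)
    top = threshold_top_fraction(smap, gt.brain_mask, 0.10)
    network = np.isin(gt.network_membership, [0, 1])
    assert (top & network).sum() >= 0.8 * network.sum()


def test_interhemispheric_correlation_margin(quiet_pd_sim):
    """Voxels sharing a latent correlate far above background pairs."""
    config, pd, gt = quiet_pd_sim
    X = pd.volumes.reshape(config.n_blocks, -1)
    Xc = X - X.mean(axis=0)
    Xn = Xc / np.linalg.norm(Xc, axis=0)
    left, right = config.network_rois[0], config.network_rois[1]
    background = np.flatnonzero(
        (gt.network_membership.reshape(-1) < 0) & gt.brain_mask.reshape(-1)
    )[:30]
    inter = (Xn[:, left].T @ Xn[:, right]).mean()
    to_bg = (Xn[:, left].T @ Xn[:, background]).mean()
    assert inter - to_bg >= 0.2
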