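"""Denoising pipeline: scrubbing, filtering, confound regression, and ordering."""

import numpy as np
import pytest

from fusikit.clutter import ClutterFilterSpec, PowerDopplerSeries
from fusikit.denoise import (
    ConfoundSet,
    DenoiseStrategy,
    ScrubMask,
    compute_confounds,
    detect_high_motion,
    drop_scrubbed,
    frequency_filter,
    gaussian_smooth,
    regress_confounds,
    run_denoise,
    scrub_replace,
)
from fusikit.errors import RejectedAcquisitionError, StrategyError
from fusikit.qc import TemporalQC, temporal_qc
from fusikit.simulate import MotionEvent, SimConfig, simulate_power_doppler, simulate_velocity


def make_tqc(n, rgs=None, rdv=None, gvs=None, rate=2.5):
    return TemporalQC(
        rgs_pct=np.zeros(n) if rgs is None else np.asarray(rgs, float),
        gv_mm_s=np.full(n, 0.02) if gvs is None else np.asarray(gvs, float),
        rdvars=np.concatenate([[np.nan], np.ones(n - 1)]) if rdv is None else np.asarray(rdv, float),
        frame_times_s=np.arange(n) / rate,
    )


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self):
        rng = np.random.default_rng(0)
        pd = PowerDopplerSeries(rng.uniform(1, 2, (5, 8, 8)), 2.5, voxel_size_mm=0.1)
        assert gaussian_smooth(pd, 0.0) is pd

    def test_constant_volume_unchanged(self):
        pd = PowerDopplerSeries(np.full((3, 10, 10), 4.0), 2.5, voxel_size_mm=0.1)
        assert np.allclose(gaussian_smooth(pd, 0.3).volumes, 4.0)

    def test_impulse_mass_conserved(self):
        vols = np.zeros((1, 21, 21))
        vols[0, 10, 10] = 1.0
        pd = PowerDopplerSeries(vols, 2.5, voxel_size_mm=0.1)
        out = gaussian_smooth(pd, 0.3).volumes
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert out[0, 10, 10] < 1.0


class TestDetectHighMotion:
    def test_gv_threshold_is_decile_plus_margin(self):
        gvs = np.full(100, 0.02)
        gvs[7] = 0.05
        mask = detect_high_motion(make_tqc(100, gvs=gvs), DenoiseStrategy(scrub_metric="gv"))
        assert np.flatnonzero(mask.flagged).tolist() == [7]

    def test_rdvars_below_threshold_flags_nothing(self):
        mask = detect_high_motion(make_tqc(50), DenoiseStrategy(scrub_metric="rdvars"))
        assert mask.n_flagged == 0

    def test_none_metric_flags_nothing(self):
        mask = detect_high_motion(make_tqc(10), DenoiseStrategy(scrub_metric="none"))
        assert mask.n_flagged == 0

    def test_constant_energy_with_rgs_is_forbidden(self):
        with pytest.raises(StrategyError):
            DenoiseStrategy(
                clutter=ClutterFilterSpec(method="constant_energy", T=40),
                scrub_metric="rgs",
            )


class TestScrubReplace:
    def test_flagged_frame_replaced_by_mean_of_others(self):
        series = np.array([1.0, 10.0, 2.0])[:, None]
        mask = ScrubMask(np.array([False, True, False]), 0.4)
        assert np.allclose(scrub_replace(series, mask).ravel(), [1.0, 1.5, 2.0])

    def test_empty_mask_is_identity(self):
        rng = np.random.default_rng(1)
        series = rng.standard_normal((10, 4))
        mask = ScrubMask(np.zeros(10, bool), 0.4)
        assert np.array_equal(scrub_replace(series, mask), series)

    def test_all_but_one_flagged_copies_survivor(self):
        series = np.arange(5.0)[:, None]
        mask = ScrubMask(np.array([True, True, False, True, True]), 0.4)
        assert np.allclose(scrub_replace(series, mask).ravel(), 2.0)


class TestFrequencyFilter:
    def test_highpass_removes_dc(self):
        out = frequency_filter(np.full((2000, 2), 5.0), 2.5, "highpass")
        assert np.abs(out).max() < 1e-6 * 5.0

    def test_bandpass_passes_slow_oscillation(self):
        t = np.arange(4000) / 2.5
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = frequency_filter(x, 2.5, "bandpass")
        mid = slice(1000, 3000)
        assert np.abs(out[mid]).max() == pytest.approx(1.0, rel=0.02)

    def test_bandpass_rejects_fast_oscillation(self):
        t = np.arange(4000) / 2.5
        x = np.sin(2 * np.pi * 0.5 * t)[:, None]
        out = frequency_filter(x, 2.5, "bandpass")
        assert np.abs(out[1000:3000]).max() < 0.01


class TestDropScrubbed:
    def test_empty_mask_identity_map(self):
        series = np.arange(10.0)[:, None]
        out, idx = drop_scrubbed(series, ScrubMask(np.zeros(10, bool), 60.0))
        assert np.array_equal(out, series) and np.array_equal(idx, np.arange(10))

    def test_counts(self):
        flags = np.zeros(100, bool)
        flags[:10] = True
        out, idx = drop_scrubbed(np.ones((100, 2)), ScrubMask(flags, 60.0))
        assert out.shape[0] == 90 and idx.size == 90

    def test_five_minute_rule_rejects(self):
        # 3000 frames at 2.5 Hz with 2260 flagged -> 296 s retained < 300 s
        flags = np.zeros(3000, bool)
        flags[:2260] = True
        with pytest.raises(RejectedAcquisitionError) as exc:
            drop_scrubbed(np.ones((3000, 1)), ScrubMask(flags, 0.4))
        assert exc.value.retained_seconds == pytest.approx(296.0)


class TestConfounds:
    def grid_pd(self, flat, shape=(6, 6)):
        return PowerDopplerSeries(flat.reshape(flat.shape[0], *shape), 2.5)

    def test_rank_one_data_first_component_recovers_latent(self):
        rng = np.random.default_rng(2)
        latent = rng.standard_normal(300)
        spatial = rng.uniform(0.5, 1.5, 36)
        flat = 10 + np.outer(latent, spatial) + 1e-4 * rng.standard_normal((300, 36))
        pd = self.grid_pd(flat)
        cs = compute_confounds(pd, "tcompcor", np.ones((6, 6), bool), n_components=2)
        r = np.corrcoef(cs.regressors[:, 0], latent)[0, 1]
        assert abs(r) > 0.999

    def test_none_method_empty(self):
        pd = self.grid_pd(np.random.default_rng(3).uniform(1, 2, (20, 36)))
        assert compute_confounds(pd, "none", np.ones((6, 6), bool)).k == 0

    def test_global_signal_on_uniform_volume(self):
        vals = np.linspace(1, 2, 20)
        pd = self.grid_pd(np.repeat(vals[:, None], 36, axis=1))
        cs = compute_confounds(pd, "global_signal", np.ones((6, 6), bool))
        assert np.allclose(cs.regressors[:, 0], vals)

    def test_random_mask_matches_wmcsf_cardinality_and_is_seeded(self):
        rng = np.random.default_rng(4)
        pd = self.grid_pd(rng.uniform(1, 2, (50, 36)))
        brain = np.ones((6, 6), bool)
        wmcsf = np.zeros((6, 6), bool)
        wmcsf[2:4, :] = True
        a = compute_confounds(pd, "random_compcor", brain, wmcsf, rng=7)
        b = compute_confounds(pd, "random_compcor", brain, wmcsf, rng=7)
        assert a.source_mask.sum() == wmcsf.sum()
        assert np.array_equal(a.regressors, b.regressors)

    def test_lowvar_mask_picks_lowest_variance_voxels(self):
        rng = np.random.default_rng(5)
        flat = 100.0 + rng.standard_normal((100, 36)) * np.linspace(0.1, 5, 36)
        pd = self.grid_pd(flat)
        wmcsf = np.zeros((6, 6), bool)
        wmcsf.reshape(-1)[:6] = True
        cs = compute_confounds(pd, "lowvar_compcor", np.ones((6, 6), bool), wmcsf)
        assert np.array_equal(np.flatnonzero(cs.source_mask.reshape(-1)), np.arange(6))


class TestRegression:
    def test_perfect_fit_gives_zero(self):
        rng = np.random.default_rng(6)
        C = rng.standard_normal((50, 3))
        beta = rng.standard_normal((3, 4))
        X = C @ beta
        out = regress_confounds(X, ConfoundSet(C, "test"))
        assert np.abs(out).max() < 1e-8 * np.abs(X).max()

    def test_no_confounds_is_identity(self):
        X = np.random.default_rng(7).standard_normal((30, 5))
        out = regress_confounds(X, ConfoundSet(np.empty((30, 0)), "none"))
        assert np.array_equal(out, X)

    def test_matches_normal_equations_oracle_and_orthogonality(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((60, 7))
        C = rng.standard_normal((60, 3))
        out = regress_confounds(X, ConfoundSet(C, "test"), add_intercept=False)
        beta = np.linalg.solve(C.T @ C, C.T @ X)
        assert np.allclose(out, X - C @ beta, atol=1e-8)
        assert np.abs(C.T @ out).max() < 1e-8 * np.abs(X).max() * 60

    def test_rank_deficient_confounds_warn_and_drop(self):
        rng = np.random.default_rng(9)
        c0 = rng.standard_normal(40)
        C = np.column_stack([c0, 2 * c0])
        X = rng.standard_normal((40, 3))
        with pytest.warns(UserWarning, match="rank deficient"):
            out = regress_confounds(X, ConfoundSet(C, "test"))
        assert np.abs(c0 @ out).max() < 1e-8 * np.abs(X).max() * 40


class TestPipeline:
    def test_reduces_to_smooth_plus_filter_without_motion_or_confounds(self):
        config = SimConfig(n_blocks=900, rng_seed=21)
        pd, gt = simulate_power_doppler(config)
        vel = simulate_velocity(config)
        tqc = temporal_qc(pd, vel, gt.brain_mask)
        strategy = DenoiseStrategy(scrub_metric="none", confound_method="none")
        clean, mask, kept = run_denoise(pd, strategy, tqc, gt.brain_mask)
        manual = frequency_filter(
            gaussian_smooth(pd, 0.3).volumes, pd.sampling_rate_hz, "highpass"
        )
        assert mask.n_flagged == 0
        assert np.allclose(clean, manual)

    def test_flags_exactly_injected_surges_and_order_matters(self):
        events = (MotionEvent(100, 0.05, 3.0), MotionEvent(500, 0.05, 4.0))
        config = SimConfig(n_blocks=900, rng_seed=22, motion_events=events)
        pd, gt = simulate_power_doppler(config)
        vel = simulate_velocity(config)
        tqc = temporal_qc(pd, vel, gt.brain_mask)
        strategy = DenoiseStrategy(scrub_metric="gv", confound_method="none")
        clean, mask, kept = run_denoise(pd, strategy, tqc, gt.brain_mask)
        assert np.array_equal(np.flatnonzero(mask.flagged), [100, 500])
        assert clean.shape[0] == 898
        # scrub-replace before filtering differs from filtering the raw surges
        filtered_first = frequency_filter(
            gaussian_smooth(pd, 0.3).volumes, pd.sampling_rate_hz, "highpass"
        )[~mask.flagged]
        assert not np.allclose(clean, filtered_first, atol=1e-3)
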