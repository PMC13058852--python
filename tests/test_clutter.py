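"""Eigen-subspace clutter filtering against SVD and brute-force oracles."""

import numpy as np
import pytest

from fusikit.clutter import (
    ClutterFilterSpec,
    apply_clutter_filter,
    compute_energy_threshold,
    doppler_from_blocks,
    gram_eigendecomposition,
    power_doppler_integrate,
    select_clutter_constant_energy,
    select_clutter_static,
    temporal_highpass_iq,
)
from fusikit.errors import ParameterError


def random_block(rng, n_t, n_v):
    return rng.standard_normal((n_t, n_v)) + 1j * rng.standard_normal((n_t, n_v))


class TestGramEigendecomposition:
    def test_diagonal_matrix(self):
        basis = gram_eigendecomposition(np.array([[1.0, 0.0], [0.0, 2.0]]))
        assert np.allclose(basis.energies, [4.0, 1.0])

    def test_trace_identity_and_orthonormality(self):
        rng = np.random.default_rng(0)
        M = random_block(rng, 10, 50)
        basis = gram_eigendecomposition(M)
        assert np.sum(basis.energies) == pytest.approx(basis.total_energy, rel=1e-8)
        gram = basis.vectors.conj().T @ basis.vectors
        assert np.allclose(gram, np.eye(10), atol=1e-8)

    def test_eigenvalues_match_squared_singular_values(self):
        rng = np.random.default_rng(1)
        M = random_block(rng, 10, 50)
        s = np.linalg.svd(M, compute_uv=False)
        basis = gram_eigendecomposition(M)
        assert np.allclose(basis.energies, s**2, rtol=1e-8)


class TestClutterSelection:
    def test_static_selection(self):
        rng = np.random.default_rng(2)
        basis = gram_eigendecomposition(random_block(rng, 8, 20))
        assert select_clutter_static(basis, 0).size == 0
        assert np.array_equal(select_clutter_static(basis, 2), [0, 1])
        with pytest.raises(ParameterError):
            select_clutter_static(basis, 9)

    def test_constant_energy_worked_example(self):
        # energies [10, 5, 2, 1], total 18, C=4: k=1 leaves 8 > 4, k=2 leaves 3
        M = np.diag(np.sqrt([10.0, 5.0, 2.0, 1.0]))
        basis = gram_eigendecomposition(M)
        assert select_clutter_constant_energy(basis, 4.0).size == 2
        assert select_clutter_constant_energy(basis, basis.total_energy).size == 0
        assert select_clutter_constant_energy(basis, 0.0).size == 4

    def test_constant_energy_matches_brute_force_over_k(self):
        rng = np.random.default_rng(3)
        M = random_block(rng, 12, 30)
        basis = gram_eigendecomposition(M)
        for C in np.linspace(0, basis.total_energy, 17):
            residuals = basis.total_energy - np.concatenate(
                [[0.0], np.cumsum(basis.energies)]
            )
            brute_k = min(k for k in range(len(residuals)) if residuals[k] <= C + 1e-9)
            assert select_clutter_constant_energy(basis, C).size == brute_k

    def test_constant_energy_residual_is_maximal_admissible(self):
        rng = np.random.default_rng(4)
        M = random_block(rng, 10, 25)
        basis = gram_eigendecomposition(M)
        C = 0.3 * basis.total_energy
        k = select_clutter_constant_energy(basis, C).size
        residual = basis.total_energy - basis.energies[:k].sum()
        assert residual <= C + 1e-6
        if k > 0:
            assert basis.total_energy - basis.energies[: k - 1].sum() > C


class TestEnergyThreshold:
    def test_minimum_across_blocks(self):
        rng = np.random.default_rng(5)
        blocks = [random_block(rng, 8, 20) * s for s in (1.0, 0.5, 2.0)]
        residuals = []
        for M in blocks:
            b = gram_eigendecomposition(M)
            residuals.append(b.total_energy - b.energies[:3].sum())
        assert compute_energy_threshold(blocks, 3) == pytest.approx(min(residuals))

    def test_identical_blocks_select_exactly_T(self):
        rng = np.random.default_rng(6)
        M = random_block(rng, 10, 30)
        C = compute_energy_threshold([M, M.copy()], T=4)
        basis = gram_eigendecomposition(M)
        assert select_clutter_constant_energy(basis, C).size == 4


class TestApplyFilter:
    def test_empty_set_is_identity(self):
        rng = np.random.default_rng(7)
        X = random_block(rng, 6, 10)
        assert np.array_equal(apply_clutter_filter(X, np.empty((6, 0))), X)

    def test_rank_one_fully_removed(self):
        u = np.exp(1j * np.linspace(0, 1, 8))[:, None]
        u /= np.linalg.norm(u)
        X = u @ (np.random.default_rng(8).standard_normal((1, 15)) + 0j)
        filtered = apply_clutter_filter(X, u)
        assert np.linalg.norm(filtered) < 1e-8 * np.linalg.norm(X)

    def test_matches_truncated_svd_residual(self):
        rng = np.random.default_rng(9)
        X = random_block(rng, 10, 40)
        basis = gram_eigendecomposition(X)
        filtered = apply_clutter_filter(X, basis.vectors[:, :2])
        U, s, Vh = np.linalg.svd(X, full_matrices=False)
        oracle = X - (U[:, :2] * s[:2]) @ Vh[:2]
        assert np.allclose(filtered, oracle, atol=1e-8 * s[0])

    def test_energy_conservation_and_idempotence(self):
        rng = np.random.default_rng(10)
        X = random_block(rng, 200, 500)
        basis = gram_eigendecomposition(X)
        k = 20
        filtered = apply_clutter_filter(X, basis.vectors[:, :k])
        residual = np.sum(np.abs(filtered) ** 2)
        expected = basis.total_energy - basis.energies[:k].sum()
        assert residual == pytest.approx(expected, rel=1e-6)
        twice = apply_clutter_filter(filtered, basis.vectors[:, :k])
        assert np.allclose(twice, filtered, atol=1e-10 * np.abs(X).max())
        # residuals orthogonal to every clutter vector
        inner = basis.vectors[:, :k].conj().T @ filtered
        assert np.max(np.abs(inner)) < 1e-8 * np.linalg.norm(X)


class TestTemporalHighpass:
    def test_dc_removed(self):
        X = np.full((200, 5), 3.0 + 4.0j)
        out = temporal_highpass_iq(X, f_iq_hz=500.0)
        assert np.sum(np.abs(out) ** 2) < 1e-6 * np.sum(np.abs(X) ** 2)

    def test_passband_tone_preserved(self):
        t = np.arange(400)
        X = np.exp(1j * 2 * np.pi * 100.0 * t / 500.0)[:, None]
        out = temporal_highpass_iq(X, f_iq_hz=500.0)
        mid = slice(100, 300)  # away from edge transients
        assert np.abs(out[mid]).mean() == pytest.approx(1.0, rel=0.01)

    def test_stopband_tone_attenuated_60db(self):
        t = np.arange(2000)
        X = np.exp(1j * 2 * np.pi * 5.0 * t / 500.0)[:, None]
        out = temporal_highpass_iq(X, f_iq_hz=500.0)
        assert np.abs(out[500:1500]).max() < 1e-3  # >= 60 dB down

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            temporal_highpass_iq(np.zeros((50, 2), complex), f_iq_hz=30.0)


class TestPowerDoppler:
    @pytest.mark.parametrize(
        "block, expected",
        [
            (np.full((7, 3), 1j), 1.0),  # unit modulus
            (np.zeros((4, 3), complex), 0.0),
            (np.array([[1.0 + 0j], [3.0 + 0j]]), 5.0),  # (1 + 9) / 2
        ],
    )
    def test_mean_squared_modulus(self, block, expected):
        assert np.allclose(power_doppler_integrate(block), expected)


def test_blood_recovery_on_quiet_phantom(quiet_iq_sim):
    """Static filtering with T >= clutter rank recovers regional CBV dynamics."""
    config, blocks, gt = quiet_iq_sim
    pd = doppler_from_blocks(blocks, ClutterFilterSpec(method="static", T=5))
    P = pd.volumes.reshape(config.n_blocks, -1)
    C = gt.true_cbv.reshape(config.n_blocks, -1)
    for roi in config.network_rois:
        r = np.corrcoef(P[:, roi].mean(axis=1), C[:, roi].mean(axis=1))[0, 1]
        assert r >= 0.9
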