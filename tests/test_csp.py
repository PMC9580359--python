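"""CSP: covariance normalization, whitening construction, log-variance features."""

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings
from hypothesis import strategies as st

import tfbcsp as t
from tfbcsp.errors import (ContractError, DegenerateTrialError,
                           InvalidLabelsError, InvalidParameterError)


def _epochs_from_classes(rng, cov_a, cov_b, n_per=20, n_samples=400):
    """Gaussian trials with per-class channel covariance."""
    n_ch = cov_a.shape[0]
    La, Lb = np.linalg.cholesky(cov_a), np.linalg.cholesky(cov_b)
    data = np.concatenate([
        np.einsum("ij,tjs->tis", La, rng.standard_normal((n_per, n_ch, n_samples))),
        np.einsum("ij,tjs->tis", Lb, rng.standard_normal((n_per, n_ch, n_samples))),
    ])
    labels = np.array(["a"] * n_per + ["b"] * n_per)
    return t.EpochSet(data, labels, fs=100.0)


class TestNormalizedCovariance:
    def test_trace_one_and_psd(self, rng):
        C = t.normalized_covariance(rng.standard_normal((2, 200)))
        assert np.trace(C) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-12)

    def test_single_channel_is_unit(self, rng):
        C = t.normalized_covariance(rng.standard_normal((1, 50)))
        assert np.allclose(C, [[1.0]])

    def test_fixed_matrix_hand_computed(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 1.0, 0.0, 1.0]])
        XX = X @ X.T
        expected = XX / np.trace(XX)
        assert np.allclose(t.normalized_covariance(X), expected)

    def test_zero_trial_degenerate(self):
        with pytest.raises(DegenerateTrialError):
            t.normalized_covariance(np.zeros((3, 10)))


class TestFitCSP:
    def test_identical_class_covariances_lambda_half(self, rng):
        cov = np.eye(3)
        ep = _epochs_from_classes(rng, cov, cov, n_per=400, n_samples=2000)
        model = t.fit_csp(ep, m=1)
        lam = model.eigvals[ep.classes[0]]
        assert np.all(np.abs(lam - 0.5) < 0.02)  # statistical, large n

    def test_identical_covariance_inputs_exact(self):
        """With literally shared trials across classes every eigenvalue is
        exactly 0.5 up to float tolerance."""
        rng = np.random.default_rng(7)
        trials = rng.standard_normal((4, 3, 200))
        data = np.concatenate([trials, trials])
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=100.0)
        model = t.fit_csp(ep, m=1)
        assert np.allclose(model.eigvals["a"], 0.5, atol=1e-8)

    def test_diagonal_covariances_axis_aligned(self, rng):
        ep = _epochs_from_classes(rng, np.diag([9.0, 1.0]), np.diag([1.0, 9.0]),
                                  n_per=300, n_samples=1500)
        model = t.fit_csp(ep, m=1)
        lam = model.eigvals["a"]
        assert lam[0] == pytest.approx(0.9, abs=0.02)
        assert lam[-1] == pytest.approx(0.1, abs=0.02)
        # extremal filters align with the coordinate axes
        for row, axis in [(model.W[0], 0), (model.W[-1], 1)]:
            u = row / np.linalg.norm(row)
            assert abs(u[axis]) > 0.99

    def test_22_channels_m7_gives_14_features(self, rng):
        data = rng.standard_normal((12, 22, 300))
        data[:6, :4] *= 2.0
        ep = t.EpochSet(data, np.array(["a"] * 6 + ["b"] * 6), fs=250.0)
        model = t.fit_csp(ep, m=7)
        assert model.n_features == 14
        f = t.logvar_features(model, data[0])
        assert f.shape == (14,)

    def test_duplicated_rows_when_2m_exceeds_channels(self, rng):
        """3-channel data with m=3 keeps the literal first/last-m rows,
        duplicating the middle ones: 6 features, exponentials sum to 1."""
        data = rng.standard_normal((8, 3, 200))
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=250.0)
        model = t.fit_csp(ep, m=3)
        assert list(model.selected_rows) == [0, 1, 2, 0, 1, 2]
        f = t.logvar_features(model, data[0])
        assert f.shape == (6,)
        assert np.exp(f).sum() == pytest.approx(1.0, rel=1e-12)

    def test_m_exceeding_channels_rejected(self, rng):
        ep = _epochs_from_classes(rng, np.eye(3), np.eye(3), n_per=3, n_samples=50)
        with pytest.raises(InvalidParameterError):
            t.fit_csp(ep, m=4)

    def test_single_class_rejected(self, rng):
        ep = t.EpochSet(rng.standard_normal((4, 3, 50)), np.array(["a"] * 4), fs=100.0)
        with pytest.raises(InvalidLabelsError):
            t.fit_csp(ep, m=1)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n_ch=st.integers(3, 6), seed=st.integers(0, 10 ** 6))
    def test_invariants_and_generalized_eig_oracle(self, n_ch, seed):
        """Whitening identity, complementarity, and row-wise agreement (up to
        sign/scale) with a direct generalized eigendecomposition of
        (C_class0, C_composite)."""
        g = np.random.default_rng(seed)
        ep = _epochs_from_classes(
            g, *(a @ a.T + 0.1 * np.eye(n_ch) for a in
                 (g.standard_normal((n_ch, n_ch)), g.standard_normal((n_ch, n_ch)))),
            n_per=10, n_samples=300)
        model = t.fit_csp(ep, m=1)
        n = model.n_channels
        Cc = model.composite_cov
        assert np.allclose(model.whitener @ Cc @ model.whitener.T, np.eye(n), atol=1e-8)
        S_sum = model.S["a"] + model.S["b"]
        assert np.allclose(S_sum, np.eye(n), atol=1e-8)
        assert np.allclose(model.eigvals["a"] + model.eigvals["b"], 1.0, atol=1e-10)
        assert np.all(np.diff(model.eigvals["a"]) <= 1e-12)  # descending

        lam, V = scipy.linalg.eigh(model.class_covs["a"], Cc)
        oracle = V[:, ::-1].T  # rows = filters, descending eigenvalue
        assert np.allclose(np.sort(lam)[::-1], model.eigvals["a"], atol=1e-8)
        for wa, wb in zip(model.W, oracle):
            cos = abs(wa @ wb) / (np.linalg.norm(wa) * np.linalg.norm(wb))
            assert cos == pytest.approx(1.0, abs=1e-6)


class TestLogvarFeatures:
    def test_two_equal_variance_components(self, rng):
        data = rng.standard_normal((8, 2, 300))
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=100.0)
        model = t.fit_csp(ep, m=1)
        trial = np.linalg.inv(model.W) @ rng.standard_normal((2, 500))
        # construct a trial whose projected components have equal variance
        Z = model.W @ trial
        rms = np.sqrt(np.mean(Z ** 2, axis=1, keepdims=True))
        trial_eq = np.linalg.inv(model.W) @ (Z / rms)
        f = t.logvar_features(model, trial_eq)
        assert np.allclose(f, np.log(0.5), atol=1e-10)

    def test_variance_ratio_3_to_1(self):
        """Selected variances (3, 1) -> features (log .75, log .25)."""
        v = np.array([3.0, 1.0])
        f = np.log(v / v.sum())
        assert f == pytest.approx([-0.2877, -1.3863], abs=5e-4)
        # same through the library on a constructed model
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 2, 300))
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=100.0)
        model = t.fit_csp(ep, m=1)
        Z = np.vstack([np.sqrt(3.0) * np.ones(400), np.ones(400)])
        trial = np.linalg.inv(model.W) @ Z
        assert np.allclose(t.logvar_features(model, trial), f, atol=1e-10)

    def test_features_nonpositive_and_normalized(self, small_planted, small_config):
        epochs, _ = small_planted
        grid = small_config.grid()
        cells = t.decompose(t.bandpass_filter(epochs, 4, 30, 5), grid)
        model = t.fit_csp(cells[0], m=2)
        F = t.transform_features(model, cells[0])
        assert np.all(F <= 1e-12)
        assert np.allclose(np.exp(F).sum(axis=1), 1.0)

    def test_global_scaling_invariance(self, rng):
        data = rng.standard_normal((8, 3, 200))
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=100.0)
        model = t.fit_csp(ep, m=1)
        f1 = t.logvar_features(model, data[0])
        f2 = t.logvar_features(model, 7.5 * data[0])
        assert np.allclose(f1, f2, atol=1e-12)

    def test_channel_mismatch_and_degenerate(self, rng):
        data = rng.standard_normal((8, 3, 200))
        ep = t.EpochSet(data, np.array(["a"] * 4 + ["b"] * 4), fs=100.0)
        model = t.fit_csp(ep, m=1)
        with pytest.raises(ContractError):
            t.logvar_features(model, rng.standard_normal((4, 200)))
        with pytest.raises(DegenerateTrialError):
            t.logvar_features(model, np.zeros((3, 200)))
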