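"""Linear decoders: construction, gradient training, closed-form ridge."""

import numpy as np
import pytest

from vlaai.baselines import (
    LinearDecoderConfig,
    LinearDecoderModel,
    build_linear_decoder,
    fit_ridge_decoder,
    laplacian_penalty,
    train_linear_si,
)
from vlaai.containers import WindowPairSet

from conftest import linear_window_set


class TestConstruction:
    def test_integration_window_to_lags(self):
        assert LinearDecoderConfig(integration_window_ms=500).n_lags(64.0) == 32
        assert LinearDecoderConfig(integration_window_ms=250).n_lags(64.0) == 16

    def test_parameter_count_500ms_64ch(self):
        model = build_linear_decoder(LinearDecoderConfig(), 64, 64.0)
        assert model.n_parameters == 64 * 32 + 1

    def test_single_lag_unit_weight_is_identity(self, rng):
        model = LinearDecoderModel(1, 1, 64.0)
        model.set_weights(np.array([[1.0]]), bias=0.0)
        x = rng.standard_normal((2, 50, 1))
        y, _ = model.forward(x)
        np.testing.assert_allclose(y, x[..., 0])

    def test_zero_weights_zero_output(self, rng):
        model = LinearDecoderModel(3, 8, 64.0)
        model.set_weights(np.zeros((8, 3)), bias=0.0)
        y, _ = model.forward(rng.standard_normal((1, 40, 3)))
        np.testing.assert_array_equal(y, 0.0)

    def test_scaling_equivariance_without_bias(self, rng):
        model = LinearDecoderModel(3, 8, 64.0, seed=1)
        model.set_weights(rng.standard_normal((8, 3)), bias=0.0)
        x = rng.standard_normal((2, 40, 3))
        y1, _ = model.forward(x)
        y2, _ = model.forward(3.0 * x)
        np.testing.assert_allclose(y2, 3.0 * y1, rtol=1e-12)

    def test_window_shorter_than_lags_rejected(self, rng):
        model = LinearDecoderModel(2, 32, 64.0)
        with pytest.raises(ValueError, match="integration window"):
            model.forward(rng.standard_normal((1, 16, 2)))

    def test_invalid_ridge_grid_rejected(self):
        with pytest.raises(ValueError):
            LinearDecoderConfig(ridge_grid=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            LinearDecoderConfig(ridge_grid=np.array([-1.0, 1.0]))


class TestRidge:
    def test_noiseless_weights_recovered_against_lstsq_oracle(self, rng):
        # backward-identifiable system: envelope generated from white EEG by
        # known weights; direct least squares is the oracle
        windows, w_true = linear_window_set(rng, n_windows=60, n_channels=3, n_lags=8)
        train = windows.subset(np.arange(40))
        val = windows.subset(np.arange(40, 60))
        cfg = LinearDecoderConfig(
            integration_window_ms=8 / 64 * 1000,
            ridge_grid=np.logspace(-7, 1, 9),
            laplacian_regularization=False,
        )
        model, report = fit_ridge_decoder(train, val, cfg)
        rms = np.sqrt(np.mean((model.weights - w_true) ** 2)) / np.sqrt(np.mean(w_true**2))
        assert rms < 1e-3
        # and the independent oracle agrees
        from vlaai.baselines import _design_rows

        X = np.concatenate([_design_rows(train.eeg[i], train.envelope[i], 8)[0] for i in range(40)])
        y = np.concatenate([_design_rows(train.eeg[i], train.envelope[i], 8)[1] for i in range(40)])
        w_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(
            w_ls.reshape(3, 8).T, w_true, atol=1e-6
        )

    def test_normal_equations_satisfied(self, rng):
        windows, _ = linear_window_set(rng, n_windows=30, n_channels=2, n_lags=6, noise=0.5)
        train = windows.subset(np.arange(20))
        val = windows.subset(np.arange(20, 30))
        cfg = LinearDecoderConfig(integration_window_ms=6 / 64 * 1000)
        model, report = fit_ridge_decoder(train, val, cfg)
        lam = model.ridge_lambda
        from vlaai.baselines import _design_rows

        X = np.concatenate([_design_rows(train.eeg[i], train.envelope[i], 6)[0] for i in range(20)])
        y = np.concatenate([_design_rows(train.eeg[i], train.envelope[i], 6)[1] for i in range(20)])
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        R = laplacian_penalty(6, 2) + 1e-6 * np.eye(12)
        w = model.weights.T.ravel()  # channel-major
        lhs = (Xc.T @ Xc + lam * R) @ w
        rhs = Xc.T @ yc
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_infinite_ridge_limit_shrinks_weights_to_zero(self, rng):
        windows, _ = linear_window_set(rng, n_windows=30, n_channels=2, n_lags=6, noise=0.5)
        train = windows.subset(np.arange(20))
        val = windows.subset(np.arange(20, 30))
        cfg = LinearDecoderConfig(
            integration_window_ms=6 / 64 * 1000,
            ridge_grid=np.array([1e10, 1e12]),
            laplacian_regularization=False,
        )
        model, _ = fit_ridge_decoder(train, val, cfg)
        assert np.abs(model.weights).max() < 1e-3
        y, _ = model.forward(train.eeg[:1])
        assert y.std() < 1e-3  # predictions collapse to a constant

    def test_selection_finds_interior_grid_optimum(self, rng):
        # heavy noise and a tiny training set put the optimal shrinkage
        # strictly inside the grid; brute force over the same grid is the
        # oracle for the selection
        windows, _ = linear_window_set(rng, n_windows=53, n_channels=8, n_lags=16, noise=20.0)
        train = windows.subset(np.arange(3))
        val = windows.subset(np.arange(3, 53))
        cfg = LinearDecoderConfig(integration_window_ms=16 / 64 * 1000)
        model, report = fit_ridge_decoder(train, val, cfg, selection_tolerance=0.0)
        losses = np.array(report["val_loss"])
        assert report["selected_lambda"] == report["lambdas"][int(np.argmin(losses))]
        assert 0 < int(np.argmin(losses)) < len(losses) - 1

    def test_agrees_with_mne_receptive_field(self, rng):
        # cross-check the closed form against the standard backward-model
        # implementation (identity regularization, one shared lambda)
        pytest.importorskip("mne")
        from mne.decoding import ReceptiveField

        n, C, L = 4000, 3, 8
        eeg = rng.standard_normal((n, C))
        w = rng.standard_normal((L, C))
        env = np.zeros(n)
        for j in range(L):
            env[: n - j] += eeg[j:, :] @ w[j]
        env += 2.0 * rng.standard_normal(n)
        lam = 10.0
        cfg = LinearDecoderConfig(
            integration_window_ms=L / 64 * 1000,
            ridge_grid=np.array([lam]),
            laplacian_regularization=False,
        )
        from vlaai.preprocessing import make_windows

        val = make_windows(eeg[:640].T, env[:640], 64.0)
        model, _ = fit_ridge_decoder((eeg, env), val, cfg)

        # backward model in mne's convention: env(t) = sum_tau eeg(t - tau)
        # with tau in [-(L-1)/fs, 0]; our lag j corresponds to tau = -j/fs
        rf = ReceptiveField(
            tmin=-(L - 1) / 64, tmax=0.0, sfreq=64.0, estimator=float(lam), patterns=False
        )
        rf.fit(eeg, env)
        # coef_ is (channels, delays) with delays -(L-1)..0; delay -j is lag j
        w_mne = rf.coef_[:, ::-1].T
        assert np.corrcoef(w_mne.ravel(), model.weights.ravel())[0, 1] > 0.99


class TestGradientTrained:
    def test_recovers_linear_system_and_matches_ridge(self, rng):
        # the Pearson loss is scale-free, so Adam needs enough steps to walk
        # the weights from their small initialization into the right
        # direction; small batches give it those steps on this tiny fixture
        windows, _ = linear_window_set(rng, n_windows=120, n_channels=3, n_lags=8, noise=0.05)
        train = windows.subset(np.arange(80))
        val = windows.subset(np.arange(80, 100))
        test = windows.subset(np.arange(100, 120))
        cfg = LinearDecoderConfig(integration_window_ms=8 / 64 * 1000)
        model = LinearDecoderModel(3, 8, 64.0, seed=0)
        model, history = train_linear_si(
            model, train, val, batch_size=8, seed=0, max_epochs=250
        )
        from vlaai.evaluation import window_correlations

        r_sgd = np.nanmean(window_correlations(model, test))
        assert r_sgd > 0.95
        ridge, _ = fit_ridge_decoder(train, val, cfg)
        r_ridge = np.nanmean(window_correlations(ridge, test))
        assert abs(r_sgd - r_ridge) < 0.02

    def test_uncorrelated_noise_yields_near_zero_validation_r(self, rng):
        eeg = rng.standard_normal((60, 320, 2))
        env = rng.standard_normal((60, 320))
        ws = WindowPairSet(eeg=eeg, envelope=env, fs=64.0)
        model = LinearDecoderModel(2, 8, 64.0, seed=0)
        model, history = train_linear_si(
            model, ws.subset(np.arange(40)), ws.subset(np.arange(40, 60)), seed=0, max_epochs=10
        )
        assert abs(history["best_val_loss"]) < 0.1

    def test_deterministic_given_seed(self, rng):
        windows, _ = linear_window_set(rng, n_windows=30, n_channels=2, n_lags=4, noise=0.5)
        train = windows.subset(np.arange(20))
        val = windows.subset(np.arange(20, 30))
        runs = []
        for _ in range(2):
            m = LinearDecoderModel(2, 4, 64.0, seed=5)
            m, _ = train_linear_si(m, train, val, seed=5, max_epochs=5)
            runs.append(m.weights.copy())
        np.testing.assert_allclose(runs[0], runs[1], atol=1e-6)

    def test_empty_training_set_rejected(self, rng):
        windows, _ = linear_window_set(rng, n_windows=10)
        model = LinearDecoderModel(4, 8, 64.0)
        with pytest.raises(ValueError, match="empty"):
            train_linear_si(model, windows.subset(np.array([], dtype=int)), windows)
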