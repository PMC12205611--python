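"""Lagged designs, banded ridge, block cross-validation, progressive search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fixenc.encoding import FeatureChannel
from fixenc.trf import (ProgressiveSearcher, SessionDesign,
                        build_lagged_design, delta_r_unique, extract_trf,
                        lag_axis, loo_block_cv_predict, pearson_per_column,
                        progressive_lambda_search, ridge_solve)

from conftest import random_session


def chan(values, band, fs=100.0):
    return FeatureChannel(name=band, band=band,
                          values=np.asarray(values, dtype=float), fs=fs)


class TestLagAxis:
    def test_default_has_121_lags(self):
        lags = lag_axis((-0.2, 1.0), 100.0)
        assert len(lags) == 121
        assert lags[0] == pytest.approx(-0.2)
        assert lags[-1] == pytest.approx(1.0)

    def test_invalid_order(self):
        with pytest.raises(ValueError):
            lag_axis((0.5, 0.1))


class TestLaggedDesign:
    def test_impulse_lands_on_lagged_rows(self):
        x = np.zeros(200)
        x[50] = 1.0
        design = build_lagged_design([chan(x, "a")], delays=(-0.2, 1.0), fs=100.0)
        assert design.matrix.shape == (200, 121)
        lags = design.lags
        col_zero = int(np.flatnonzero(np.isclose(lags, 0.0))[0])
        col_pos = int(np.flatnonzero(np.isclose(lags, 0.1))[0])
        col_neg = int(np.flatnonzero(np.isclose(lags, -0.1))[0])
        # column (band, tau) at row t equals x(t - tau)
        assert design.matrix[50, col_zero] == 1.0
        assert design.matrix[60, col_pos] == 1.0
        assert design.matrix[40, col_neg] == 1.0
        assert design.matrix.sum() == pytest.approx(121.0)  # zero-padded edges

    def test_band_slices_disjoint_exhaustive(self):
        rng = np.random.default_rng(0)
        design = build_lagged_design(
            [chan(rng.normal(size=80), "a"), chan(rng.normal(size=80), "b")],
            delays=(-0.1, 0.2), fs=100.0)
        sl_a, sl_b = design.band_slices["a"], design.band_slices["b"]
        assert sl_a == slice(0, 31) and sl_b == slice(31, 62)
        assert design.matrix.shape[1] == 62

    def test_duplicate_band_raises(self):
        x = np.zeros(10)
        with pytest.raises(ValueError, match="duplicate"):
            build_lagged_design([chan(x, "a"), chan(x, "a")])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            build_lagged_design([chan(np.zeros(10), "a"),
                                 chan(np.zeros(11), "b")])


class TestRidgeSolve:
    def _problem(self, seed, n=60, bands=("a", "b")):
        rng = np.random.default_rng(seed)
        channels = [chan(rng.normal(size=n), b) for b in bands]
        design = build_lagged_design(channels, delays=(-0.05, 0.1), fs=100.0)
        eeg = rng.normal(size=(n, 3))
        return design, eeg

    def test_matches_normal_equations(self):
        design, eeg = self._problem(1)
        lambdas = {"a": 3.0, "b": 40.0}
        model = ridge_solve(design, eeg, lambdas)
        Xc = design.matrix - design.matrix.mean(axis=0)
        Yc = eeg - eeg.mean(axis=0)
        pen = np.concatenate([np.full(design.n_lags, lambdas[b] ** 2)
                              for b in design.band_order])
        expected = np.linalg.solve(Xc.T @ Xc + np.diag(pen), Xc.T @ Yc)
        assert np.allclose(model.weights, expected, atol=1e-10)

    def test_lambda_division_equivalence(self):
        # scaling band columns by 1/lambda + unit ridge + rescale == lambda^2 penalty
        design, eeg = self._problem(2)
        lambdas = {"a": 2.0, "b": 150.0}
        model = ridge_solve(design, eeg, lambdas)
        Xc = design.matrix - design.matrix.mean(axis=0)
        Yc = eeg - eeg.mean(axis=0)
        scale = np.concatenate([np.full(design.n_lags, lambdas[b])
                                for b in design.band_order])
        Xs = Xc / scale
        Ws = np.linalg.solve(Xs.T @ Xs + np.eye(Xs.shape[1]), Xs.T @ Yc)
        assert np.allclose(model.weights, Ws / scale[:, None], atol=1e-10)

    def test_nonpositive_lambda_rejected(self):
        design, eeg = self._problem(3)
        with pytest.raises(ValueError, match="positive"):
            ridge_solve(design, eeg, {"a": 0.0, "b": 1.0})

    def test_recovers_planted_weights_noiseless(self):
        rng = np.random.default_rng(4)
        x = np.zeros(600)
        x[rng.choice(600, size=40, replace=False)] = rng.normal(size=40)
        design = build_lagged_design([chan(x, "a")], delays=(-0.05, 0.2))
        w_true = rng.normal(size=(design.matrix.shape[1], 1))
        eeg = design.matrix @ w_true
        model = ridge_solve(design, eeg, {"a": 1e-4})
        assert np.allclose(model.weights, w_true, atol=1e-3)
        trf = extract_trf(model, "a")
        assert trf.shape == (1, design.n_lags)
        assert np.allclose(trf[0], w_true[:, 0], atol=1e-3)


class TestPearson:
    def test_matches_corrcoef(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        r = pearson_per_column(a, b)
        for j in range(3):
            assert r[j] == pytest.approx(np.corrcoef(a[:, j], b[:, j])[0, 1])

    def test_constant_column_scores_zero(self):
        a = np.ones((10, 1))
        b = np.arange(10.0)[:, None]
        assert pearson_per_column(a, b)[0] == 0.0


class TestSessionDesign:
    def test_requires_three_blocks(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="3 blocks"):
            random_session(rng, n_blocks=2)

    def test_fit_block_matches_ridge_solve(self):
        rng = np.random.default_rng(7)
        session = random_session(rng, n_blocks=3, n_samples=300)
        # rebuild the same channels to compare against the full-matrix path
        rng2 = np.random.default_rng(7)
        lambdas = {"a": 5.0, "b": 17.0}
        block0 = None
        for b in range(3):
            channels = []
            for band in ("a", "b"):
                values = np.zeros(300)
                idx = rng2.choice(300, size=15, replace=False)
                values[idx] = rng2.normal(size=15)
                channels.append(chan(values, band))
            eeg = rng2.normal(size=(300, 2))
            if b == 0:
                design = build_lagged_design(channels, delays=(-0.1, 0.3))
                block0 = ridge_solve(design, eeg, lambdas)
        W = session.fit_block(0, ["a", "b"], lambdas)
        assert np.allclose(W, block0.weights, atol=1e-9)

    def test_column_subset(self):
        rng = np.random.default_rng(8)
        session = random_session(rng, bands=("a", "b", "c"))
        idx, slices = session.columns(["c", "a"])
        n_lags = len(session.lags)
        assert len(idx) == 2 * n_lags
        assert slices["c"] == slice(0, n_lags)
        assert slices["a"] == slice(n_lags, 2 * n_lags)


class TestLooCV:
    def test_gram_r_equals_explicit_prediction_r(self):
        rng = np.random.default_rng(9)
        n_blocks, n_samples = 3, 300
        block_channels, block_eeg = [], []
        for _ in range(n_blocks):
            channels = []
            for band in ("a", "b"):
                values = np.zeros(n_samples)
                idx = rng.choice(n_samples, size=15, replace=False)
                values[idx] = rng.normal(size=15)
                channels.append(chan(values, band))
            block_channels.append(channels)
            block_eeg.append(rng.normal(size=(n_samples, 2)))
        session = SessionDesign(block_channels, block_eeg, delays=(-0.1, 0.3))
        lambdas = {"a": 10.0, "b": 10.0}
        score = loo_block_cv_predict(session, ["a", "b"], lambdas)

        # brute force: rebuild full matrices, average the training models
        designs = [build_lagged_design(c, delays=(-0.1, 0.3))
                   for c in block_channels]
        weights = [ridge_solve(designs[b], block_eeg[b], lambdas).weights
                   for b in range(n_blocks)]
        for test in range(n_blocks):
            W = np.mean([weights[b] for b in range(n_blocks) if b != test],
                        axis=0)
            Xc = designs[test].matrix - designs[test].matrix.mean(axis=0)
            expected = pearson_per_column(Xc @ W, block_eeg[test])
            assert np.allclose(score.r[test], expected, atol=1e-9)

    def test_return_models(self):
        rng = np.random.default_rng(10)
        session = random_session(rng)
        score, models = loo_block_cv_predict(session, ["a", "b"],
                                             {"a": 1.0, "b": 1.0},
                                             return_models=True)
        assert len(models) == session.n_blocks
        assert models[0].fit_blocks == (0,)
        assert extract_trf(models[0], "a").shape == \
            (session.n_channels, len(session.lags))


class TestProgressiveSearch:
    def test_sweep_count_and_cache(self):
        rng = np.random.default_rng(11)
        session = random_session(rng, bands=("a", "b", "c"))
        grid = np.logspace(0, 4, 5)
        searcher = ProgressiveSearcher(session, grid)
        lambdas = searcher.search(["a", "b", "c"])
        assert set(lambdas) == {"a", "b", "c"}
        assert all(lam in grid for lam in lambdas.values())
        assert searcher.n_sweeps == 5 * 3
        searcher.search(["a", "b", "c"])       # fully cached
        assert searcher.n_sweeps == 5 * 3
        searcher.search(["a", "b"])            # prefix cached too
        assert searcher.n_sweeps == 5 * 3

    def test_wrapper_equals_searcher(self):
        rng = np.random.default_rng(12)
        session = random_session(rng)
        grid = np.logspace(0, 4, 4)
        assert progressive_lambda_search(session, ["a", "b"], grid) == \
            ProgressiveSearcher(session, grid).search(["a", "b"])

    def test_grid_validation(self):
        rng = np.random.default_rng(13)
        session = random_session(rng)
        with pytest.raises(ValueError):
            ProgressiveSearcher(session, np.array([1.0]))
        with pytest.raises(ValueError):
            ProgressiveSearcher(session, np.array([2.0, 1.0]))


class TestDeltaR:
    def _planted_session(self, seed, relevant=True):
        """EEG driven by band 'sig' (plus noise); band 'null' is unrelated."""
        rng = np.random.default_rng(seed)
        n_samples = 500
        delays = (-0.1, 0.3)
        lags = lag_axis(delays, 100.0)
        kernel = np.exp(-0.5 * ((lags - 0.1) / 0.05) ** 2)
        block_channels, block_eeg = [], []
        for _ in range(4):
            channels = {}
            for band in ("sig", "null"):
                values = np.zeros(n_samples)
                idx = rng.choice(n_samples, size=25, replace=False)
                values[idx] = rng.normal(size=25)
                channels[band] = chan(values, band)
            design = build_lagged_design([channels["sig"]], delays=delays)
            signal = design.matrix @ kernel[:, None]
            eeg = signal + 0.5 * rng.normal(size=(n_samples, 2)) * signal.std()
            block_channels.append([channels["sig"], channels["null"]])
            block_eeg.append(eeg)
        return SessionDesign(block_channels, block_eeg, delays=delays)

    def test_planted_band_has_positive_delta(self):
        session = self._planted_session(0)
        grid = np.logspace(0, 4, 5)
        res = delta_r_unique(session, ["sig", "null"], "sig", grid)
        assert res.delta.mean() > 0.1
        assert res.block_values.shape == (session.n_blocks,)

    def test_irrelevant_band_has_tiny_delta(self):
        session = self._planted_session(1)
        grid = np.logspace(0, 4, 5)
        res = delta_r_unique(session, ["sig", "null"], "null", grid)
        assert abs(res.delta.mean()) < 0.02

    def test_unknown_band(self):
        rng = np.random.default_rng(14)
        session = random_session(rng)
        with pytest.raises(KeyError):
            delta_r_unique(session, ["a", "b"], "zzz")

    @given(st.integers(0, 2 ** 31 - 1))
    def test_delta_equals_full_minus_reduced(self, seed):
        rng = np.random.default_rng(seed)
        session = random_session(rng, n_samples=250)
        res = delta_r_unique(session, ["a", "b"], "b", np.logspace(0, 4, 3))
        assert np.allclose(res.delta, res.r_full - res.r_without)
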