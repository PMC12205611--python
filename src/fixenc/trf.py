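"""Banded ridge temporal response functions with progressive regularization.

The encoding model predicts each EEG channel as a linear superposition of
lagged regressors (delays −0.2 to 1.0 s at 100 Hz, 121 lags).  Regularization
is banded: each regressor group ("band") has its own strength λ, applied by
dividing the band's columns by λ and solving a unit-penalty ridge — which is
the same as penalizing the original-scale weights with λ² (documented below).
λ values are selected by a progressive grid search: bands enter the model in
a fixed order, each band's λ is chosen to maximize leave-one-block-out
cross-validated prediction correlation with earlier λs frozen, so any shared
variance is attributed to the band added first.  Unique variance of one band
(Δr) is measured by adding that band last.

Cross-validation follows the session structure: one model per block, and the
average of all models except the test block predicts the held-out block.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .encoding import FeatureChannel

logger = logging.getLogger(__name__)

DEFAULT_DELAYS = (-0.2, 1.0)
DEFAULT_LAMBDA_GRID = np.logspace(0.0, 4.0, 15)


def lag_axis(delays: tuple[float, float] = DEFAULT_DELAYS, fs: float = 100.0
             ) -> np.ndarray:
    """Lag axis in seconds; positive lag = neural response after the event."""
    lo, hi = delays
    if hi <= lo:
        raise ValueError("delays must satisfy lo < hi")
    lo_s = int(round(lo * fs))
    hi_s = int(round(hi * fs))
    return np.arange(lo_s, hi_s + 1) / fs


@dataclass
class LaggedDesign:
    """Time-lagged design matrix with disjoint, exhaustive per-band column blocks."""

    matrix: np.ndarray            # samples × (bands × lags)
    band_slices: dict[str, slice]
    lags: np.ndarray              # seconds
    fs: float

    @property
    def band_order(self) -> tuple[str, ...]:
        return tuple(self.band_slices)

    @property
    def n_lags(self) -> int:
        return len(self.lags)


def _lag_matrix(x: np.ndarray, lag_samples: np.ndarray) -> np.ndarray:
    n = len(x)
    out = np.zeros((n, len(lag_samples)))
    for j, lag in enumerate(lag_samples):
        if abs(lag) >= n:
            continue
        if lag > 0:
            out[lag:, j] = x[:n - lag]
        elif lag < 0:
            out[:lag, j] = x[-lag:]
        else:
            out[:, j] = x
    return out


def build_lagged_design(channels: Sequence[FeatureChannel],
                        delays: tuple[float, float] = DEFAULT_DELAYS,
                        fs: float = 100.0) -> LaggedDesign:
    """Stack lagged copies of each regressor; column (band, τ) at row t is x(t−τ).

    Out-of-range samples are zero-padded (blocks are separate recording
    segments, so no signal crosses their edges).
    """
    lengths = {len(c.values) for c in channels}
    if len(lengths) != 1:
        raise ValueError(f"channels have mismatched lengths {sorted(lengths)}")
    lags = lag_axis(delays, fs)
    lag_samples = np.round(lags * fs).astype(int)
    blocks = []
    band_slices: dict[str, slice] = {}
    col = 0
    for ch in channels:
        if ch.band in band_slices:
            raise ValueError(f"duplicate band {ch.band!r}")
        blocks.append(_lag_matrix(np.asarray(ch.values, dtype=float), lag_samples))
        band_slices[ch.band] = slice(col, col + len(lags))
        col += len(lags)
    return LaggedDesign(matrix=np.hstack(blocks), band_slices=band_slices,
                        lags=lags, fs=fs)


@dataclass
class TRFModel:
    """Fitted banded model: per-band λ and weight matrices over lags.

    Weights are stored flat (columns × EEG channels) in original feature
    units; ``extract_trf`` reshapes one band to channels × lags.
    """

    weights: np.ndarray                  # (bands × lags) × n_channels
    band_slices: dict[str, slice]
    band_lambdas: dict[str, float]
    lags: np.ndarray
    fit_blocks: tuple[int, ...] = ()

    @property
    def band_order(self) -> tuple[str, ...]:
        return tuple(self.band_slices)


def extract_trf(model: TRFModel, band: str) -> np.ndarray:
    """TRF of one band as an n_channels × n_lags matrix in original units."""
    if band not in model.band_slices:
        raise KeyError(f"unknown band {band!r}")
    return model.weights[model.band_slices[band]].T


def _penalty_vector(band_slices: Mapping[str, slice], n_cols: int,
                    band_lambdas: Mapping[str, float]) -> np.ndarray:
    pen = np.empty(n_cols)
    for band, sl in band_slices.items():
        lam = band_lambdas[band]
        if not lam > 0:
            raise ValueError(f"lambda for band {band!r} must be positive")
        pen[sl] = lam ** 2
    return pen


def _solve_banded_ridge(G: np.ndarray, C: np.ndarray, pen: np.ndarray) -> np.ndarray:
    """Solve (XᵀX + diag(pen)) W = XᵀY.

    This is the λ-division trick in closed form: scaling band b's columns by
    1/λ_b, solving a unit-penalty ridge, and rescaling the weights by 1/λ_b
    yields W = (XᵀX + diag(λ_b²))⁻¹ XᵀY, i.e. an effective original-scale
    penalty of λ² per band.
    """
    A = G + np.diag(pen)
    return cho_solve(cho_factor(A, lower=True), C)


def ridge_solve(design: LaggedDesign, eeg: np.ndarray,
                band_lambdas: Mapping[str, float]) -> TRFModel:
    """Fit the banded ridge model on one segment of data.

    The design columns and EEG channels are mean-centered before the solve
    (no penalized intercept); weights come back in original feature units.
    """
    X = np.asarray(design.matrix, dtype=float)
    Y = np.atleast_2d(np.asarray(eeg, dtype=float))
    if Y.ndim == 2 and Y.shape[0] != X.shape[0]:
        Y = Y.T
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in design or EEG")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    pen = _penalty_vector(design.band_slices, X.shape[1], band_lambdas)
    W = _solve_banded_ridge(Xc.T @ Xc, Xc.T @ Yc, pen)
    return TRFModel(weights=W, band_slices=dict(design.band_slices),
                    band_lambdas=dict(band_lambdas), lags=design.lags)


def pearson_per_column(predicted: np.ndarray, actual: np.ndarray) -> np.ndarray:
    """Pearson r for each column; constant columns score 0 with a warning."""
    a = predicted - predicted.mean(axis=0)
    b = actual - actual.mean(axis=0)
    na = np.sqrt((a ** 2).sum(axis=0))
    nb = np.sqrt((b ** 2).sum(axis=0))
    denom = na * nb
    r = np.zeros(predicted.shape[1])
    ok = denom > 0
    if not ok.all():
        logger.warning("constant predicted or actual channel; r set to 0")
    r[ok] = (a * b).sum(axis=0)[ok] / denom[ok]
    return r


@dataclass
class PredictionScore:
    """Held-out prediction correlations per block and channel."""

    r: np.ndarray  # n_blocks × n_channels
    block_ids: tuple[int, ...]

    @property
    def block_mean(self) -> np.ndarray:
        """r per channel, averaged over blocks first (then channels if needed)."""
        return self.r.mean(axis=0)

    @property
    def grand_mean(self) -> float:
        return float(self.block_mean.mean())


@dataclass
class _Block:
    G: np.ndarray    # XᵀX of the centered lagged design
    C: np.ndarray    # XᵀY
    yss: np.ndarray  # per-channel sum of squares of centered EEG
    n: int


class SessionDesign:
    """Per-block lagged designs reduced to cached Gram matrices.

    Blocks are built independently (lagging never crosses block edges) and
    mean-centered per block.  Held-out Pearson r needs only XᵀX, XᵀY and the
    EEG sum of squares — cov(Xw, y) = wᵀXᵀy and var(Xw) = wᵀXᵀXw for centered
    data — so the full lagged matrices are never retained and a λ evaluation
    costs one Cholesky solve per block.
    """

    def __init__(self, block_channels: Sequence[Sequence[FeatureChannel]],
                 block_eeg: Sequence[np.ndarray],
                 delays: tuple[float, float] = DEFAULT_DELAYS,
                 fs: float = 100.0):
        if len(block_channels) != len(block_eeg):
            raise ValueError("block_channels and block_eeg length mismatch")
        if len(block_channels) < 3:
            raise ValueError("leave-one-block-out needs at least 3 blocks")
        self.blocks: list[_Block] = []
        self.band_slices: dict[str, slice] = {}
        self.lags = lag_axis(delays, fs)
        self.fs = fs
        for channels, eeg in zip(block_channels, block_eeg):
            design = build_lagged_design(channels, delays, fs)
            if not self.band_slices:
                self.band_slices = design.band_slices
            elif design.band_slices != self.band_slices:
                raise ValueError("blocks disagree on band layout")
            Y = np.asarray(eeg, dtype=float)
            if Y.shape[0] != design.matrix.shape[0]:
                raise ValueError("EEG length does not match design length")
            Xc = design.matrix - design.matrix.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            self.blocks.append(_Block(G=Xc.T @ Xc, C=Xc.T @ Yc,
                                      yss=(Yc ** 2).sum(axis=0), n=len(Yc)))

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def n_channels(self) -> int:
        return self.blocks[0].C.shape[1]

    @property
    def band_order(self) -> tuple[str, ...]:
        return tuple(self.band_slices)

    def columns(self, bands: Sequence[str]) -> tuple[np.ndarray, dict[str, slice]]:
        """Column indices of a band subset plus the subset's own band slices."""
        idx_parts = []
        sub_slices: dict[str, slice] = {}
        col = 0
        for band in bands:
            sl = self.band_slices[band]
            idx_parts.append(np.arange(sl.start, sl.stop))
            sub_slices[band] = slice(col, col + (sl.stop - sl.start))
            col += sl.stop - sl.start
        return np.concatenate(idx_parts), sub_slices

    def fit_block(self, block: int, bands: Sequence[str],
                  band_lambdas: Mapping[str, float]) -> np.ndarray:
        """Weights (subset columns × channels) for a model trained on one block."""
        idx, sub_slices = self.columns(bands)
        blk = self.blocks[block]
        pen = _penalty_vector(sub_slices, len(idx), band_lambdas)
        return _solve_banded_ridge(blk.G[np.ix_(idx, idx)], blk.C[idx], pen)


def loo_block_cv_predict(session: SessionDesign, bands: Sequence[str],
                         band_lambdas: Mapping[str, float],
                         return_models: bool = False,
                         ) -> PredictionScore | tuple[PredictionScore, list[TRFModel]]:
    """Leave-one-block-out prediction with model averaging.

    One model is trained per block; the held-out block is predicted by the
    average of the weight matrices of every other block's model.
    """
    idx, sub_slices = session.columns(bands)
    n_blocks = session.n_blocks
    per_block_w = [session.fit_block(b, bands, band_lambdas) for b in range(n_blocks)]
    r = np.zeros((n_blocks, session.n_channels))
    warned = False
    for test in range(n_blocks):
        train = [b for b in range(n_blocks) if b != test]
        assert test not in train  # never evaluate a model on its training block
        W = np.mean([per_block_w[b] for b in train], axis=0)
        blk = session.blocks[test]
        # Pearson r from Gram algebra: cov = wᵀC, var(pred) = wᵀGw (X centered)
        cov = (W * blk.C[idx]).sum(axis=0)
        pred_ss = (W * (blk.G[np.ix_(idx, idx)] @ W)).sum(axis=0)
        denom = np.sqrt(np.maximum(pred_ss, 0.0) * blk.yss)
        ok = denom > 0
        if not ok.all() and not warned:
            logger.warning("constant predicted or actual channel; r set to 0")
            warned = True
        r[test, ok] = cov[ok] / denom[ok]
    score = PredictionScore(r=r, block_ids=tuple(range(n_blocks)))
    if not return_models:
        return score
    models = [TRFModel(weights=w, band_slices=sub_slices,
                       band_lambdas={b: band_lambdas[b] for b in bands},
                       lags=session.lags, fit_blocks=(b,))
              for b, w in enumerate(per_block_w)]
    return score, models


class ProgressiveSearcher:
    """Ordered per-band λ grid search with memoization across band orders.

    At step k the candidate band's λ is swept over the grid with all earlier
    λs frozen; the λ maximizing the grand-mean cross-validated r wins, ties
    going to the smaller λ.  Results are cached by (frozen prefix, candidate
    band) so that the N_bands re-orderings of the unique-variance procedure
    share their common prefixes.
    """

    def __init__(self, session: SessionDesign,
                 grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                 use_cache: bool = True):
        grid = np.asarray(grid, dtype=float)
        if len(grid) < 2:
            raise ValueError("lambda grid needs at least 2 values")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("lambda grid must be strictly increasing")
        self.session = session
        self.grid = grid
        self.use_cache = use_cache
        self._step_cache: dict = {}
        self._score_cache: dict = {}
        self.n_sweeps = 0          # λ evaluations counted per (step, λ)

    def _cv_score(self, bands: tuple[str, ...], lambdas: tuple[float, ...]
                  ) -> PredictionScore:
        key = (bands, lambdas)
        if self.use_cache and key in self._score_cache:
            return self._score_cache[key]
        score = loo_block_cv_predict(self.session, bands,
                                     dict(zip(bands, lambdas)))
        if self.use_cache:
            self._score_cache[key] = score
        return score

    def sweep(self, frozen: dict[str, float], candidate: str
              ) -> tuple[float, PredictionScore]:
        """Best λ for ``candidate`` given frozen earlier bands, plus its CV score."""
        key = (tuple(frozen.items()), candidate)
        if self.use_cache and key in self._step_cache:
            return self._step_cache[key]
        bands = tuple(frozen) + (candidate,)
        best_lam, best_score, best_mean = None, None, -np.inf
        for lam in self.grid:
            self.n_sweeps += 1
            score = self._cv_score(bands, tuple(frozen.values()) + (float(lam),))
            mean = score.grand_mean
            if mean > best_mean:  # strict: first (smallest) λ wins ties
                best_lam, best_score, best_mean = float(lam), score, mean
        result = (best_lam, best_score)
        if self.use_cache:
            self._step_cache[key] = result
        return result

    def search(self, band_order: Sequence[str]) -> dict[str, float]:
        """Progressive search over a band order; returns the selected λ per band."""
        frozen: dict[str, float] = {}
        for band in band_order:
            lam, _ = self.sweep(frozen, band)
            frozen[band] = lam
        return frozen


def progressive_lambda_search(session: SessionDesign,
                              band_order: Sequence[str],
                              grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                              ) -> dict[str, float]:
    """Convenience wrapper: one ordered search (N_λ × N_bands sweeps)."""
    return ProgressiveSearcher(session, grid).search(band_order)


@dataclass
class DeltaRResult:
    """Unique-variance result for one band added last to the model."""

    band: str
    r_full: np.ndarray      # n_blocks × n_channels
    r_without: np.ndarray
    band_lambdas: dict[str, float]

    @property
    def delta(self) -> np.ndarray:
        return self.r_full - self.r_without

    @property
    def block_values(self) -> np.ndarray:
        """Δr averaged over electrodes, per block (the unit of the bootstrap)."""
        return self.delta.mean(axis=1)


def delta_r_unique(session: SessionDesign, band_order: Sequence[str],
                   band_of_interest: str,
                   grid: np.ndarray = DEFAULT_LAMBDA_GRID,
                   searcher: Optional[ProgressiveSearcher] = None,
                   ) -> DeltaRResult:
    """Change in held-out r when the band of interest is added last.

    All other bands keep their given order; their λs are selected
    progressively, then the band of interest enters last, so Δr reflects only
    its unique variance.
    """
    if band_of_interest not in band_order:
        raise KeyError(f"{band_of_interest!r} not among bands")
    if searcher is None:
        searcher = ProgressiveSearcher(session, grid)
    others = [b for b in band_order if b != band_of_interest]
    frozen = searcher.search(others)
    r_without = searcher._cv_score(tuple(others), tuple(frozen.values())).r
    lam, score_full = searcher.sweep(frozen, band_of_interest)
    lambdas = dict(frozen)
    lambdas[band_of_interest] = lam
    return DeltaRResult(band=band_of_interest, r_full=score_full.r,
                        r_without=r_without, band_lambdas=lambdas)
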