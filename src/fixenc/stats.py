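"""Nonparametric inference for encoding-model results.

* Hierarchical bootstrap: resampling with replacement at each level of the
  participants → sessions → blocks nesting, for a one-sided test that the
  grand-mean improvement in prediction correlation exceeds zero.
* One-sided Wilcoxon signed-rank summaries across reading sessions.
* Spatiotemporal cluster permutation on TRFs: one-sample t per (channel, lag),
  signed suprathreshold clusters joined by channel adjacency and temporal
  contiguity, whole-session sign flips for the null of maximal cluster mass.
* Spearman correlation with Bonferroni correction, and the Δr significance
  masks used to select features and word positions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

#: Δr threshold for displaying a (feature, position) cell as significant.
DR_DISPLAY_MIN = 2e-5
#: Stricter Δr threshold for selecting positions whose TRFs are averaged.
DR_TRF_MIN = 3e-5


# ---------------------------------------------------------------------------
# Hierarchical bootstrap

@dataclass
class NestedSample:
    """Block-level values nested as participants → sessions → blocks."""

    data: dict[Hashable, dict[Hashable, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("empty hierarchy")
        for p, sessions in self.data.items():
            if not sessions:
                raise ValueError(f"participant {p!r} has no sessions")
            for s, blocks in sessions.items():
                arr = np.asarray(blocks, dtype=float)
                if arr.size == 0:
                    raise ValueError(f"session {s!r} of {p!r} has no blocks")
                if not np.isfinite(arr).all():
                    raise ValueError(f"non-finite block value in session {s!r}")
                sessions[s] = arr

    @classmethod
    def from_records(cls, records: Iterable[tuple[Hashable, Hashable, float]]
                     ) -> "NestedSample":
        """Build from (participant, session, value) records, one per block."""
        data: dict = {}
        for participant, session, value in records:
            data.setdefault(participant, {}).setdefault(session, []).append(value)
        return cls(data)

    def rectangular(self) -> Optional[np.ndarray]:
        """(P, S, B) array when every level has equal size, else None."""
        sessions = [list(s.values()) for s in self.data.values()]
        n_sess = {len(s) for s in sessions}
        n_blk = {len(b) for s in sessions for b in s}
        if len(n_sess) == 1 and len(n_blk) == 1:
            return np.array([[b for b in s] for s in sessions])
        return None


def hierarchical_bootstrap_p(sample: NestedSample, n_boot: int = 10_000,
                             seed: Optional[int] = None,
                             rng: Optional[np.random.Generator] = None) -> float:
    """One-sided bootstrap p-value for "grand-mean improvement > 0".

    Each replicate resamples participants with replacement, then sessions
    within each drawn participant, then blocks within each drawn session; the
    statistic is the nested grand mean.  p = (1 + #{replicates ≤ 0}) /
    (n_boot + 1).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rect = sample.rectangular()
    if rect is not None:
        n_p, n_s, n_b = rect.shape
        pi = rng.integers(n_p, size=(n_boot, n_p))[:, :, None, None]
        si = rng.integers(n_s, size=(n_boot, n_p, n_s))[:, :, :, None]
        bi = rng.integers(n_b, size=(n_boot, n_p, n_s, n_b))
        reps = rect[pi, si, bi].mean(axis=(1, 2, 3))
    else:
        participants = list(sample.data.values())
        reps = np.empty(n_boot)
        for i in range(n_boot):
            p_idx = rng.integers(len(participants), size=len(participants))
            p_means = []
            for j in p_idx:
                sessions = list(participants[j].values())
                s_idx = rng.integers(len(sessions), size=len(sessions))
                s_means = []
                for k in s_idx:
                    blocks = sessions[k]
                    s_means.append(blocks[rng.integers(len(blocks),
                                                       size=len(blocks))].mean())
                p_means.append(np.mean(s_means))
            reps[i] = np.mean(p_means)
    return (1 + int(np.sum(reps <= 0))) / (n_boot + 1)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank

@dataclass(frozen=True)
class WilcoxonResult:
    """One-sided signed-rank test that ``after`` exceeds ``before``.

    ``W`` is the sum of ranks (by absolute difference, average ranks for
    ties) of the pairs with positive difference.  Two effect-size
    conventions are reported: rank-biserial r = (W⁺ − W⁻)/T and Z/√n.
    """

    W: float
    p: float
    n: int
    r_rank_biserial: float
    r_z: float


def _wilcoxon_exact_p(ranks: np.ndarray, W: float) -> float:
    """P(W⁺ ≥ W) by dynamic programming over all 2^m sign assignments.

    Average ranks are half-integers, so doubled ranks are integers and the
    distribution of 2·W⁺ is a polynomial convolution.
    """
    ranks2 = np.round(2 * ranks).astype(int)
    counts = np.zeros(ranks2.sum() + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:len(counts) - r]
        counts = counts + shifted
    target = int(np.ceil(2 * W - 1e-9))
    return counts[target:].sum() / 2 ** len(ranks2)


def wilcoxon_signed_rank(before: Sequence[float], after: Sequence[float],
                         one_sided: bool = True) -> WilcoxonResult:
    """Signed-rank test on paired values; zero differences are dropped.

    Exact p by enumeration (via the equivalent sum over all sign
    assignments) for n ≤ 12; normal approximation with tie and continuity
    corrections otherwise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("before and after must have equal length")
    d = after - before
    d = d[d != 0]
    m = len(d)
    if m == 0:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())
    W_neg = float(ranks[d < 0].sum())
    total = m * (m + 1) / 2
    if m <= 12:
        p = _wilcoxon_exact_p(ranks, W)
    else:
        mu = total / 2
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24 - (tie_counts ** 3 - tie_counts).sum() / 48
        z = (W - mu - 0.5) / np.sqrt(var)
        p = float(sps.norm.sf(z))
    if not one_sided:
        p = min(1.0, 2 * min(p, 1 - p + 1e-300))
    mu = total / 2
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24)
    return WilcoxonResult(W=W, p=float(p), n=m,
                          r_rank_biserial=(W - W_neg) / total,
                          r_z=float((W - mu) / sigma / np.sqrt(m)))


# ---------------------------------------------------------------------------
# Spatiotemporal cluster permutation

@dataclass(frozen=True)
class Cluster:
    members: frozenset[tuple[int, int]]  # (channel, lag) points
    mass: float                          # summed t over members (signed)
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_map: np.ndarray                    # channels × lags
    threshold: float
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def grid_adjacency(rows: int, cols: int) -> np.ndarray:
    """4-neighborhood adjacency of a rows × cols electrode grid (row-major)."""
    n = rows * cols
    adj = np.zeros((n, n), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                adj[i, i + 1] = adj[i + 1, i] = True
            if r + 1 < rows:
                adj[i, i + cols] = adj[i + cols, i] = True
    return adj


def _neighbor_lists(adjacency, n_channels: int) -> list[list[int]]:
    adj = np.asarray(adjacency)
    if adj.ndim == 2 and adj.shape == (n_channels, n_channels):
        mat = adj.astype(bool)
    else:  # edge list
        mat = np.zeros((n_channels, n_channels), dtype=bool)
        for i, j in adjacency:
            mat[i, j] = mat[j, i] = True
    np.fill_diagonal(mat, False)
    # connectivity check (warn only)
    seen = {0}
    stack = [0]
    while stack:
        for j in np.nonzero(mat[stack.pop()])[0]:
            if j not in seen:
                seen.add(j)
                stack.append(int(j))
    if len(seen) < n_channels:
        warnings.warn("channel adjacency graph is disconnected", stacklevel=3)
    return [list(np.nonzero(mat[i])[0]) for i in range(n_channels)]


def _find_signed_clusters(t: np.ndarray, threshold: float,
                          neighbors: list[list[int]]
                          ) -> list[tuple[frozenset, float]]:
    """Connected suprathreshold sets of one sign at a time."""
    n_ch, n_lags = t.shape
    out = []
    for sign in (1.0, -1.0):
        mask = sign * t >= threshold
        visited = np.zeros_like(mask)
        for c in range(n_ch):
            for l in np.nonzero(mask[c])[0]:
                if visited[c, l]:
                    continue
                stack = [(c, int(l))]
                visited[c, l] = True
                members = []
                while stack:
                    ci, li = stack.pop()
                    members.append((ci, li))
                    for lj in (li - 1, li + 1):
                        if 0 <= lj < n_lags and mask[ci, lj] and not visited[ci, lj]:
                            visited[ci, lj] = True
                            stack.append((ci, lj))
                    for cj in neighbors[ci]:
                        if mask[cj, li] and not visited[cj, li]:
                            visited[cj, li] = True
                            stack.append((cj, li))
                mass = float(sum(t[ci, li] for ci, li in members))
                out.append((frozenset(members), mass))
    return out


def _t_maps(data2d: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t for each sign-flip row; zero-variance points get t = 0."""
    n = data2d.shape[0]
    mean = flips @ data2d / n
    sumsq = (data2d ** 2).sum(axis=0)
    var = np.maximum(sumsq - n * mean ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def cluster_permutation(trfs: np.ndarray, adjacency,
                        t_threshold: float = 2.5, n_perm: int = 1000,
                        seed: Optional[int] = None,
                        rng: Optional[np.random.Generator] = None
                        ) -> ClusterResult:
    """Spatiotemporal cluster permutation test on per-session TRFs.

    ``trfs`` is sessions × channels × lags.  Points with |t| ≥ threshold and
    the same sign are joined by channel adjacency and temporal contiguity;
    the cluster statistic is the summed t (mass).  The null permutes the sign
    of each session's whole TRF and records the maximal |mass| over both
    signs; p = (1 + #{null ≥ |observed mass|}) / (n_perm + 1).
    """
    trfs = np.asarray(trfs, dtype=float)
    if trfs.ndim != 3 or trfs.shape[0] < 2:
        raise ValueError("need sessions × channels × lags with >= 2 sessions")
    n_sessions, n_ch, n_lags = trfs.shape
    neighbors = _neighbor_lists(adjacency, n_ch)
    data2d = trfs.reshape(n_sessions, -1)

    t_obs = _t_maps(data2d, np.ones((1, n_sessions)))[0].reshape(n_ch, n_lags)
    observed = _find_signed_clusters(t_obs, t_threshold, neighbors)

    if rng is None:
        rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_sessions))
    t_null = _t_maps(data2d, flips)
    null_max = np.zeros(n_perm)
    for i in range(n_perm):
        t_i = t_null[i].reshape(n_ch, n_lags)
        if np.any(np.abs(t_i) >= t_threshold):
            masses = [abs(m) for _, m in
                      _find_signed_clusters(t_i, t_threshold, neighbors)]
            if masses:
                null_max[i] = max(masses)

    clusters = [Cluster(members=members, mass=mass,
                        p=(1 + int(np.sum(null_max >= abs(mass)))) / (n_perm + 1))
                for members, mass in observed]
    clusters.sort(key=lambda c: -abs(c.mass))
    return ClusterResult(clusters=clusters, t_map=t_obs,
                         threshold=t_threshold, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Correlation with behavior, and masking

def spearman_with_bonferroni(x: Sequence[float], y: Sequence[float],
                             n_tests: int = 1) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with Bonferroni-corrected p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), min(1.0, float(p) * n_tests)


def mask_significant_features(delta_r, p_boot, dr_min: float = DR_DISPLAY_MIN,
                              alpha: float = 0.05):
    """True where p_boot < alpha AND Δr > dr_min (the display rule).

    With ``dr_min=DR_TRF_MIN`` the same rule selects positions for TRF
    averaging.  Accepts aligned arrays or pandas objects.
    """
    dr = np.asarray(delta_r, dtype=float)
    pb = np.asarray(p_boot, dtype=float)
    if dr.shape != pb.shape:
        raise ValueError("delta_r and p_boot tables are misaligned")
    if hasattr(delta_r, "index") and hasattr(p_boot, "index"):
        if not delta_r.index.equals(p_boot.index):
            raise ValueError("delta_r and p_boot tables are misaligned")
    mask = (pb < alpha) & (dr > dr_min)
    if hasattr(delta_r, "index"):
        import pandas as pd
        if dr.ndim == 1:
            return pd.Series(mask, index=delta_r.index)
        return pd.DataFrame(mask, index=delta_r.index, columns=delta_r.columns)
    return mask
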