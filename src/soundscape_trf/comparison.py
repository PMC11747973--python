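"""Nested model comparison and its statistics.

Feature sets of increasing information content (acoustic -> + sound identity
-> + condition split) are evaluated with identical folds so their prediction
scores can be compared pairwise (Wilcoxon signed-rank, Benjamini-Hochberg
FDR). The chance level is an onset-shuffle noise floor that preserves the
inter-onset-interval multiset, and TRF weight differences between conditions
are assessed with a cluster-based permutation test along the lag axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import FeatureSet
from .synth import EEGRecording
from .trf import DEFAULT_LAMBDA_GRID, DEFAULT_TMAX_MS, DEFAULT_TMIN_MS, fit_predict_cv


def nested_comparison(
    model_specs: dict,
    eeg: EEGRecording,
    n_segments: int = 10,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
    unit_id=0,
) -> pd.DataFrame:
    """Evaluate every model on identical folds.

    ``model_specs`` maps model_id -> FeatureSet. Returns a tidy score table
    with one row per (model_id, fold) holding the mean channel correlation on
    the held-out fold; fold boundaries and z-scoring are shared across models
    so paired statistics are valid.
    """
    rows = []
    for model_id, feats in model_specs.items():
        if feats.n_features == 0:
            raise ValueError(f"model {model_id!r} has zero features")
        scores = fit_predict_cv(
            feats, eeg, n_segments=n_segments, lambda_grid=lambda_grid,
            tmin_ms=tmin_ms, tmax_ms=tmax_ms,
        )
        for fold, s in enumerate(scores):
            rows.append(
                {"model_id": model_id, "unit_id": unit_id, "fold": fold,
                 "mean_channel_r": float(s)}
            )
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(x, y) -> tuple[float, float, float]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon convention). Returns
    (W, Z, p) where W is the smaller of the two signed rank sums, Z the
    tie-corrected normal approximation, and p exact (full enumeration) for
    fewer than 10 nonzero pairs without ties, normal-approximate otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D paired samples")
    if len(x) < 5:
        raise ValueError("at least 5 pairs are required")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    W = min(w_plus, w_minus)
    mu = n * (n + 1) / 4.0
    # tie correction on the rank variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    Z = 0.0 if sigma2 == 0 else (w_plus - mu) / np.sqrt(sigma2)
    has_ties = np.any(counts > 1)
    if n < 10 and not has_ties:
        res = stats.wilcoxon(d, zero_method="wilcox", method="exact")
        p = float(res.pvalue)
    else:
        p = float(2 * stats.norm.sf(abs(Z))) if sigma2 > 0 else 1.0
        p = min(p, 1.0)
    return W, float(Z), p


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (reject flags, monotone adjusted p-values).
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def shuffle_preserving_ioi(onset_vector: np.ndarray, seed: int = 0) -> np.ndarray:
    """Shuffle onset positions while preserving the inter-onset intervals.

    The interval multiset of the binary train is permuted and the whole train
    re-anchored at a uniform random start within the feasible slack, so the
    shuffled train never exceeds the recording.
    """
    v = np.asarray(onset_vector).ravel()
    idx = np.flatnonzero(v)
    if len(idx) < 2:
        raise ValueError("need at least 2 onsets to shuffle")
    rng = np.random.default_rng(seed)
    intervals = np.diff(idx)
    perm = rng.permutation(intervals)
    span = int(perm.sum())
    slack = len(v) - 1 - span
    start = int(rng.integers(0, slack + 1)) if slack > 0 else 0
    new_idx = start + np.concatenate(([0], np.cumsum(perm)))
    out = np.zeros_like(v, dtype=float)
    out[new_idx] = 1.0
    return out


@dataclass
class NoiseFloor:
    """Null distribution of prediction scores from onset-shuffled models."""

    null_scores: np.ndarray
    ci_low: float
    ci_high: float

    @property
    def n_perm(self) -> int:
        return len(self.null_scores)


def onset_noise_floor(
    onsets: FeatureSet,
    eeg: EEGRecording,
    n_perm: int = 100,
    n_segments: int = 6,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
    mask_scores: bool = False,
    seed: int = 0,
) -> NoiseFloor:
    """Chance-level prediction: re-run the full protocol on interval-preserving
    onset shuffles and report the 95% CI of the null fold-mean scores.

    With ``mask_scores`` the null models are scored only on their own
    explainable samples (matching the masked evaluation pipeline).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    from .masking import explainable_mask  # local import avoids a cycle

    col = onsets.data[:, 0]
    rng = np.random.default_rng(seed)
    null_scores = np.zeros(n_perm)
    for p in range(n_perm):
        shuffled = shuffle_preserving_ioi(col, seed=int(rng.integers(0, 2**31 - 1)))
        feats = FeatureSet(shuffled[:, None], list(onsets.names),
                           onsets.discrete, onsets.rate)
        mask = None
        if mask_scores:
            mask = explainable_mask(feats, tmin_ms, tmax_ms).mask
        try:
            scores = fit_predict_cv(
                feats, eeg, n_segments=n_segments, lambda_grid=lambda_grid,
                tmin_ms=tmin_ms, tmax_ms=tmax_ms, mask=mask,
            )
        except Exception as exc:
            raise RuntimeError(f"noise-floor permutation {p} failed: {exc}") from exc
        null_scores[p] = float(np.nanmean(scores))
    lo, hi = np.percentile(null_scores, [2.5, 97.5])
    return NoiseFloor(null_scores, float(lo), float(hi))


@dataclass
class Cluster:
    """A contiguous run of supra-threshold lags with its permutation p-value."""

    start: int
    stop: int  # half-open [start, stop)
    stat: float
    p_value: float


def cluster_permutation_time(
    weights_a: np.ndarray,
    weights_b: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int = 0,
) -> list:
    """Cluster-based permutation test on TRF weights along the lag axis.

    Inputs are unit x lag arrays (channel-aggregated weights per condition).
    A paired t-test runs per lag; contiguous supra-threshold lags of the same
    sign form clusters scored by their summed t. The null flips condition
    labels within unit at random; each cluster's p is the proportion of null
    maximum |cluster sums| that reach its observed |sum|.
    """
    a = np.asarray(weights_a, float)
    b = np.asarray(weights_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("weight arrays must be equal-shape (unit x lag)")
    n_units = a.shape[0]
    if n_units < 6:
        raise ValueError("at least 6 units are required")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution")
    diffs = a - b
    t_crit = stats.t.ppf(1 - alpha_cluster / 2, df=n_units - 1)

    def clusters_of(d):
        t = _paired_t(d)
        out = []
        lag = 0
        L = len(t)
        while lag < L:
            if abs(t[lag]) > t_crit:
                sign = np.sign(t[lag])
                start = lag
                while lag < L and abs(t[lag]) > t_crit and np.sign(t[lag]) == sign:
                    lag += 1
                out.append((start, lag, float(t[start:lag].sum())))
            else:
                lag += 1
        return out

    observed = clusters_of(diffs)
    if not observed:
        return []
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        flips = rng.choice([-1.0, 1.0], size=n_units)
        perm_clusters = clusters_of(diffs * flips[:, None])
        null_max[p] = max((abs(c[2]) for c in perm_clusters), default=0.0)
    return [
        Cluster(start, stop, stat, float(np.mean(null_max >= abs(stat))))
        for start, stop, stat in observed
    ]


def _paired_t(d: np.ndarray) -> np.ndarray:
    """t statistic of the mean against zero, per column."""
    n = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)
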