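"""Cross-prediction between single-feature encoding models.

Two models are trained per fold, one per feature; at test time each model's
weights predict the EEG from both its own feature and the other feature,
yielding four scores per fold (two within, two cross). The rank correlation
between matched within/cross score vectors measures how well one model's
weights generalize to the other feature; a latency-shift correction aligns
TRF peak trajectories before cross-predicting when the two features lead the
response by different delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .features import FeatureSet
from .synth import EEGRecording
from .trf import (
    DEFAULT_LAMBDA_GRID,
    DEFAULT_TMAX_MS,
    DEFAULT_TMIN_MS,
    TRF,
    _SegmentedRidge,
    _cv_lambda_cached,
    build_lagged_design,
    pearson_by_channel,
    segment_and_zscore,
)


@dataclass
class CrossPredictionResult:
    """Four fold-score vectors plus the within/cross rank correlations."""

    within_a: np.ndarray
    within_b: np.ndarray
    cross_ab: np.ndarray  # A's weights predicting from B's feature
    cross_ba: np.ndarray
    rho_a: float  # corr(within_a, cross_ba): A-feature scores, both models
    rho_b: float
    shift_samples: int = 0


def _shift_feature(feats: FeatureSet, shift: int) -> FeatureSet:
    data = np.zeros_like(feats.data)
    if shift > 0:
        data[shift:] = feats.data[:-shift]
    elif shift < 0:
        data[:shift] = feats.data[-shift:]
    else:
        data = feats.data.copy()
    return FeatureSet(data, list(feats.names), feats.discrete, feats.rate)


def cross_predict_pair(
    feat_a: FeatureSet,
    feat_b: FeatureSet,
    eeg: EEGRecording,
    n_segments: int = 6,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
    shift_samples: int = 0,
) -> CrossPredictionResult:
    """Train per-fold models on each feature and swap weights at test time.

    Both features must be single-column (feature dimensions have to be
    consistent for weights to transfer). ``shift_samples`` delays feature A
    by that many samples (advance if negative) wherever it stands in for B,
    implementing the latency-shift correction symmetrically.
    """
    for name, f in (("A", feat_a), ("B", feat_b)):
        if f.n_features != 1:
            raise ValueError(
                f"feature {name} has {f.n_features} columns; cross-prediction "
                "requires single-column features (dimensional consistency)"
            )
    if feat_a.n_samples != feat_b.n_samples:
        raise ValueError("features must have equal length")
    split, eeg_z, _ = segment_and_zscore(eeg, feat_a, n_segments)
    eng_a = _SegmentedRidge(feat_a, eeg_z, split, tmin_ms, tmax_ms)
    eng_b = _SegmentedRidge(feat_b, eeg_z, split, tmin_ms, tmax_ms)
    # Shifted copies used for the swapped predictions. With shift s > 0
    # (B's TRF trajectory peaks s samples later than A's, i.e. w_B(tau) ~
    # w_A(tau - s)), A's weights expect a feature delayed by s relative to B,
    # and B's weights expect A advanced by s.
    feat_a_sh = _shift_feature(feat_a, -shift_samples)
    feat_b_sh = _shift_feature(feat_b, shift_samples)
    eng_a_sh = _SegmentedRidge(feat_a_sh, eeg_z, split, tmin_ms, tmax_ms)
    eng_b_sh = _SegmentedRidge(feat_b_sh, eeg_z, split, tmin_ms, tmax_ms)

    wa = np.zeros(n_segments)
    wb = np.zeros(n_segments)
    xab = np.zeros(n_segments)
    xba = np.zeros(n_segments)
    for test in range(n_segments):
        train = [k for k in range(n_segments) if k != test]
        lam_a, _ = _cv_lambda_cached(eng_a, list(lambda_grid), exclude=(test,))
        lam_b, _ = _cv_lambda_cached(eng_b, list(lambda_grid), exclude=(test,))
        trf_a = eng_a.fit(train, lam_a)
        trf_b = eng_b.fit(train, lam_b)
        wa[test] = eng_a.score(trf_a, test)
        wb[test] = eng_b.score(trf_b, test)
        # A's weights applied to (shifted) B's feature, and vice versa
        xab[test] = eng_b_sh.score(trf_a, test)
        xba[test] = eng_a_sh.score(trf_b, test)
    if n_segments >= 5:
        rho_a = score_correlation(wa, xba)
        rho_b = score_correlation(wb, xab)
    else:  # too few folds for a meaningful rank correlation
        rho_a = rho_b = float("nan")
    return CrossPredictionResult(wa, wb, xab, xba, rho_a, rho_b, shift_samples)


def score_correlation(within, cross, method: str = "spearman") -> float:
    """Rank correlation between paired within/cross score vectors."""
    within = np.asarray(within, float)
    cross = np.asarray(cross, float)
    if within.shape != cross.shape or within.ndim != 1:
        raise ValueError("score vectors must be equal-length and 1-D")
    if len(within) < 5:
        raise ValueError("at least 5 paired scores are required")
    if np.ptp(within) == 0 or np.ptp(cross) == 0:
        warnings.warn("constant score vector; correlation undefined")
        return float("nan")
    if method == "spearman":
        rho, _ = stats.spearmanr(within, cross)
    elif method == "pearson":
        rho, _ = stats.pearsonr(within, cross)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(rho)


def estimate_latency_shift(trf_a: TRF, trf_b: TRF, max_shift_ms: float = 100.0) -> int:
    """Lag shift (samples) aligning B's TRF trajectory to A's.

    Cross-correlates the channel-RMS lag profiles and returns the shift in
    [-max_shift, +max_shift] samples maximizing it; positive means B's
    profile peaks later than A's. A warning flags solutions at the search
    boundary (the window may be too small).
    """
    if not np.array_equal(trf_a.lags, trf_b.lags) or trf_a.rate != trf_b.rate:
        raise ValueError("TRFs must share the lag grid and rate")
    pa = trf_a.lag_profile().mean(axis=0)
    pb = trf_b.lag_profile().mean(axis=0)
    pa = pa - pa.mean()
    pb = pb - pb.mean()
    max_shift = int(round(max_shift_ms * trf_a.rate / 1000.0))
    full = np.correlate(pb, pa, mode="full")  # index L-1 <-> zero shift
    center = len(pa) - 1
    lo = max(0, center - max_shift)
    hi = min(len(full), center + max_shift + 1)
    window = full[lo:hi]
    shift = int(np.argmax(window) + lo - center)
    if abs(shift) == max_shift:
        warnings.warn("optimal shift at the search boundary; widen max_shift_ms")
    return shift
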