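"""Lagged ridge regression: the temporal response function (TRF) estimator.

The forward model is r(t, c) = sum_tau w(tau, c) s(t - tau) + eps(t, c): the
neural time series is a lagged linear readout of the stimulus features. The
weights are estimated per channel by ridge regression on a lagged design
matrix, w = (S'S + lambda*I)^-1 S'r, with the regularization strength chosen
by segment-wise cross-validation over a log-spaced grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

from .features import FeatureSet
from .synth import EEGRecording

#: lambda search grid: 10^-4 ... 10^4 in multiplicative steps of 10
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-4, 5))

DEFAULT_TMIN_MS = -100.0
DEFAULT_TMAX_MS = 500.0


def lag_samples(tmin_ms: float, tmax_ms: float, rate: float) -> np.ndarray:
    """Integer sample lags from round(tmin*rate/1000) to round(tmax*rate/1000)."""
    if tmin_ms > tmax_ms:
        raise ValueError("tmin_ms must be <= tmax_ms")
    lo = int(round(tmin_ms * rate / 1000.0))
    hi = int(round(tmax_ms * rate / 1000.0))
    return np.arange(lo, hi + 1)


@dataclass
class LaggedDesign:
    """Design matrix S holding the stimulus at every time lag.

    Columns are feature-major, lags ascending; rows shifted beyond the data
    are zero-filled so the model stays causal with respect to the padding.
    """

    matrix: np.ndarray  # T x (N_ft * L)
    lags: np.ndarray
    tmin_ms: float
    tmax_ms: float
    rate: float
    feature_names: list


@dataclass
class TRF:
    """Fitted encoding model: weights w(feature, lag, channel) and lambda."""

    weights: np.ndarray  # N_ft x L x C
    lam: float
    tmin_ms: float
    tmax_ms: float
    rate: float
    feature_names: list
    residual_rms: np.ndarray | None = None

    @property
    def lags(self) -> np.ndarray:
        return lag_samples(self.tmin_ms, self.tmax_ms, self.rate)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.rate

    def lag_profile(self) -> np.ndarray:
        """Channel-RMS trajectory over lags per feature (N_ft x L)."""
        return np.sqrt(np.mean(self.weights**2, axis=2))


@dataclass
class SegmentSplit:
    """Contiguous near-equal segments partitioning [0, T)."""

    boundaries: list  # list of (start, stop)

    @property
    def n_segments(self) -> int:
        return len(self.boundaries)

    def indices(self, k: int) -> np.ndarray:
        start, stop = self.boundaries[k]
        return np.arange(start, stop)


def build_lagged_design(
    features: FeatureSet,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
) -> LaggedDesign:
    """Expand features into the lagged design: column (f, tau) holds s_f(t - tau)."""
    if features.n_features == 0 or features.n_samples == 0:
        raise ValueError("empty feature set")
    lags = lag_samples(tmin_ms, tmax_ms, features.rate)
    T, nft = features.data.shape
    L = len(lags)
    S = np.zeros((T, nft * L))
    for f in range(nft):
        x = features.data[:, f]
        for j, tau in enumerate(lags):
            col = f * L + j
            if tau >= 0:
                S[tau:, col] = x[: T - tau] if tau < T else 0.0
            else:
                S[:tau, col] = x[-tau:]
    return LaggedDesign(S, lags, tmin_ms, tmax_ms, features.rate, list(features.names))


def fit_ridge(design: LaggedDesign, eeg: EEGRecording | np.ndarray, lam: float) -> TRF:
    """Ridge solution w = (S'S + lambda I)^-1 S'r per channel.

    lambda = 0 reduces to the ordinary normal equation and fails with advice
    when S'S is singular.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    r = eeg.data if isinstance(eeg, EEGRecording) else np.atleast_2d(np.asarray(eeg, float))
    if r.ndim == 1:
        r = r[:, None]
    S = design.matrix
    if S.shape[0] != r.shape[0]:
        raise ValueError("design and EEG must have the same number of rows")
    gram = S.T @ S
    cross = S.T @ r
    return _solve_trf(gram, cross, lam, design, residual_data=(S, r))


def _solve_trf(gram, cross, lam, design: LaggedDesign, residual_data=None) -> TRF:
    A = gram + lam * np.eye(gram.shape[0])
    try:
        w = linalg.solve(A, cross, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "S'S (+ lambda I) is singular; use lambda > 0 to regularize"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise linalg.LinAlgError(
            "non-finite ridge solution; S'S is singular, use lambda > 0"
        )
    L = len(design.lags)
    nft = len(design.feature_names)
    C = cross.shape[1]
    residual_rms = None
    if residual_data is not None:
        S, r = residual_data
        residual_rms = np.sqrt(np.mean((r - S @ w) ** 2, axis=0))
    return TRF(
        weights=w.reshape(nft, L, C),
        lam=float(lam),
        tmin_ms=design.tmin_ms,
        tmax_ms=design.tmax_ms,
        rate=design.rate,
        feature_names=list(design.feature_names),
        residual_rms=residual_rms,
    )


def predict(trf: TRF, features: FeatureSet) -> np.ndarray:
    """Predicted EEG: the lagged design of ``features`` times the TRF weights."""
    if features.n_features != len(trf.feature_names):
        raise ValueError(
            f"feature count mismatch: TRF has {len(trf.feature_names)}, "
            f"got {features.n_features}"
        )
    if features.rate != trf.rate:
        raise ValueError("feature rate must match the TRF rate")
    design = build_lagged_design(features, trf.tmin_ms, trf.tmax_ms)
    C = trf.weights.shape[2]
    w = trf.weights.reshape(-1, C)
    return design.matrix @ w


def pearson_by_channel(
    pred: np.ndarray, actual: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Pearson r per channel over (optionally masked) samples.

    Channels with fewer than 3 usable samples or zero variance get NaN and
    are excluded from downstream averages (which use nanmean).
    """
    pred = np.atleast_2d(pred)
    actual = np.atleast_2d(actual)
    if pred.shape != actual.shape:
        raise ValueError("pred and actual must have identical shapes")
    if mask is not None:
        mask = np.asarray(mask, bool)
        if mask.shape[0] != pred.shape[0]:
            raise ValueError("mask length must equal the sample count")
        pred = pred[mask]
        actual = actual[mask]
    n = pred.shape[0]
    out = np.full(pred.shape[1], np.nan)
    if n < 3:
        return out
    p = pred - pred.mean(axis=0)
    a = actual - actual.mean(axis=0)
    denom = np.sqrt((p**2).sum(axis=0) * (a**2).sum(axis=0))
    ok = denom > 0
    out[ok] = (p * a).sum(axis=0)[ok] / denom[ok]
    return out


def segment_and_zscore(
    eeg: EEGRecording, features: FeatureSet, n_segments: int
) -> tuple[SegmentSplit, EEGRecording, FeatureSet]:
    """Split [0, T) into contiguous near-equal segments; z-score the EEG per
    channel within each segment so segments are comparable. Features pass
    through unchanged."""
    T = eeg.n_samples
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    if T < n_segments:
        raise ValueError("fewer samples than segments")
    if features.n_samples != T:
        raise ValueError("features and EEG must have equal length")
    edges = np.linspace(0, T, n_segments + 1).round().astype(int)
    boundaries = [(int(edges[i]), int(edges[i + 1])) for i in range(n_segments)]
    z = eeg.data.copy()
    for k, (a, b) in enumerate(boundaries):
        seg = z[a:b]
        sd = seg.std(axis=0)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"constant channel {eeg.channel_names[bad[0]]!r} in segment {k}"
            )
        z[a:b] = (seg - seg.mean(axis=0)) / sd
    return (
        SegmentSplit(boundaries),
        EEGRecording(z, eeg.rate, list(eeg.channel_names)),
        features,
    )


class _SegmentedRidge:
    """Per-segment designs with cached cross-products.

    Designs are built independently per segment (zero-padded at segment
    edges), so any train set's normal equations are sums of segment terms.
    """

    def __init__(self, features: FeatureSet, eeg: EEGRecording,
                 split: SegmentSplit, tmin_ms: float, tmax_ms: float):
        self.split = split
        self.tmin_ms = tmin_ms
        self.tmax_ms = tmax_ms
        self.designs = []
        self.eeg_segs = []
        self.grams = []
        self.crosses = []
        for a, b in split.boundaries:
            seg_feat = FeatureSet(
                features.data[a:b], list(features.names), features.discrete,
                features.rate,
            )
            d = build_lagged_design(seg_feat, tmin_ms, tmax_ms)
            r = eeg.data[a:b]
            self.designs.append(d)
            self.eeg_segs.append(r)
            self.grams.append(d.matrix.T @ d.matrix)
            self.crosses.append(d.matrix.T @ r)

    def fit(self, train_idx, lam: float) -> TRF:
        gram = sum(self.grams[i] for i in train_idx)
        cross = sum(self.crosses[i] for i in train_idx)
        return _solve_trf(gram, cross, lam, self.designs[train_idx[0]])

    def score(self, trf: TRF, test_idx: int, mask=None) -> float:
        pred = self.designs[test_idx].matrix @ trf.weights.reshape(
            -1, trf.weights.shape[2]
        )
        r = pearson_by_channel(pred, self.eeg_segs[test_idx], mask=mask)
        return float(np.nanmean(r))


def cv_lambda(
    features: FeatureSet,
    eeg: EEGRecording,
    split: SegmentSplit,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
    exclude=(),
) -> tuple[float, np.ndarray]:
    """Exhaustive lambda search by leave-one-segment-out validation.

    Segments listed in ``exclude`` (e.g. the outer test fold) take part in
    neither training nor validation. Returns the winning lambda (ties broken
    toward the smaller value) and the per-lambda fold-mean score table.
    """
    lambda_grid = list(lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda grid must be non-empty")
    engine = _SegmentedRidge(features, eeg, split, tmin_ms, tmax_ms)
    return _cv_lambda_cached(engine, lambda_grid, exclude)


def _cv_lambda_cached(engine: _SegmentedRidge, lambda_grid, exclude=()):
    segs = [k for k in range(engine.split.n_segments) if k not in set(exclude)]
    if len(segs) < 2:
        raise ValueError("need at least two usable segments for lambda selection")
    scores = np.zeros((len(lambda_grid), len(segs)))
    for j, val in enumerate(segs):
        train = [k for k in segs if k != val]
        for i, lam in enumerate(lambda_grid):
            trf = engine.fit(train, lam)
            scores[i, j] = engine.score(trf, val)
    mean_scores = scores.mean(axis=1)
    if np.all(np.isnan(mean_scores)):
        raise ValueError("all validation scores are undefined")
    best = int(np.nanargmax(mean_scores))  # argmax returns first = smallest lambda
    return float(lambda_grid[best]), mean_scores


def fit_predict_cv(
    features: FeatureSet,
    eeg: EEGRecording,
    n_segments: int = 6,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
    mask: np.ndarray | None = None,
    return_trfs: bool = False,
):
    """The full evaluation protocol: outer cross-validation over segments.

    Each segment serves as the held-out test set once; the ridge strength is
    selected on the remaining segments by inner leave-one-segment-out
    validation, the model refit on all training segments, and the mean
    channel correlation recorded on the test segment. An optional boolean
    ``mask`` restricts scoring to explainable samples.

    Returns per-fold mean-channel scores (and the per-fold TRFs on request).
    """
    split, eeg_z, feats = segment_and_zscore(eeg, features, n_segments)
    engine = _SegmentedRidge(feats, eeg_z, split, tmin_ms, tmax_ms)
    lambda_grid = list(lambda_grid)
    fold_scores = np.zeros(n_segments)
    trfs = []
    for test in range(n_segments):
        lam, _ = _cv_lambda_cached(engine, lambda_grid, exclude=(test,))
        train = [k for k in range(n_segments) if k != test]
        trf = engine.fit(train, lam)
        seg_mask = None
        if mask is not None:
            a, b = split.boundaries[test]
            seg_mask = np.asarray(mask, bool)[a:b]
        fold_scores[test] = engine.score(trf, test, mask=seg_mask)
        if return_trfs:
            trfs.append(trf)
    if return_trfs:
        return fold_scores, trfs
    return fold_scores
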