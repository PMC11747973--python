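"""Explainable-sample (masked) evaluation of discrete-feature models.

A model built from discrete event markers predicts exactly zero during
event-free periods: its lagged design has no support there. Scoring such a
model over the whole recording dilutes the correlation with stretches where
the prediction is uninformative. The explainable mask marks the samples
inside the lag window around at least one event; masked scores correlate
prediction and EEG only there and report the proportion of the recording
that is explainable at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureSet
from .trf import TRF, DEFAULT_TMAX_MS, DEFAULT_TMIN_MS, pearson_by_channel, predict


@dataclass
class ExplainableMask:
    """Boolean per-sample mask with its coverage proportion."""

    mask: np.ndarray
    proportion: float
    source_features: list
    tmin_ms: float
    tmax_ms: float

    def intervals_s(self, rate: float) -> list:
        """Mask as (start_s, end_s) intervals (BED-like, half-open)."""
        m = np.concatenate(([False], self.mask, [False]))
        starts = np.flatnonzero(~m[:-1] & m[1:])
        stops = np.flatnonzero(m[:-1] & ~m[1:])
        return [(s / rate, e / rate) for s, e in zip(starts, stops)]


def explainable_mask(
    feature_set: FeatureSet,
    tmin_ms: float = DEFAULT_TMIN_MS,
    tmax_ms: float = DEFAULT_TMAX_MS,
) -> ExplainableMask:
    """Samples a discrete-feature model can predict at all.

    Sample t is explainable iff some event at sample e (any discrete column)
    satisfies t in [e + lag_min, e + lag_max] — exactly the support of the
    lagged design. The full window is used, including any acausal portion.
    A set containing a continuous column predicts every sample: all-true mask.
    """
    if feature_set.n_features == 0:
        raise ValueError("feature set has no columns")
    T = feature_set.n_samples
    if not np.all(feature_set.discrete):
        mask = np.ones(T, dtype=bool)
        return ExplainableMask(mask, 1.0, list(feature_set.names), tmin_ms, tmax_ms)
    rate = feature_set.rate
    lag_min = int(round(tmin_ms * rate / 1000.0))
    lag_max = int(round(tmax_ms * rate / 1000.0))
    mask = np.zeros(T, dtype=bool)
    events = np.flatnonzero(feature_set.data.any(axis=1))
    for e in events:
        lo = max(0, e + lag_min)
        hi = min(T, e + lag_max + 1)
        mask[lo:hi] = True
    return ExplainableMask(
        mask, float(mask.mean()), list(feature_set.names), tmin_ms, tmax_ms
    )


def masked_scores(
    trf: TRF,
    features: FeatureSet,
    eeg,
    mask: np.ndarray | ExplainableMask,
) -> tuple[np.ndarray, float]:
    """Per-channel correlation over mask-true samples, plus the proportion.

    With an all-true mask this reproduces the unmasked evaluation exactly.
    Masks with fewer than 3 true samples yield NaN scores (flagged, excluded
    from averages).
    """
    if isinstance(mask, ExplainableMask):
        mask = mask.mask
    mask = np.asarray(mask, bool)
    data = eeg.data if hasattr(eeg, "data") else np.atleast_2d(eeg)
    if mask.shape[0] != data.shape[0]:
        raise ValueError("mask length must equal the EEG sample count")
    pred = predict(trf, features)
    r = pearson_by_channel(pred, data, mask=mask)
    return r, float(mask.mean())
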