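"""Stimulus feature extraction at the EEG sampling rate.

Three acoustic representations of increasing detail (binary acoustic onsets
from an energy novelty function, the broadband envelope in two variants, and
a 40-band mel-spectrogram) plus discrete sound-identity / condition markers
derived from event annotations. All features are delivered as time x feature
matrices sampled at the EEG rate, with per-column discreteness flags so that
downstream masking knows which models predict only around events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .synth import AudioTrack, EventTable


@dataclass
class FeatureConfig:
    """Tunable parameters of the feature extractors.

    ``novelty_window``/``novelty_hop`` are in audio samples (Hann smoothing of
    the squared waveform), ``gamma`` is the log-compression factor
    log(1 + gamma*x), and ``onset_threshold`` is in novelty units. The default
    threshold was calibrated once on the synthetic tone bank so that >= 95% of
    true event onsets are recovered within +/-50 ms.
    """

    novelty_window: int = 2048
    novelty_hop: int = 128
    gamma: float = 10.0
    onset_threshold: float = 0.05
    butter_order: int = 3
    butter_cutoff_hz: float = 30.0
    n_mels: int = 40
    eeg_rate_hz: float = 100.0
    power_compression_exponent: float = float(np.log10(2))
    mel_window_s: float = 0.025

    def __post_init__(self) -> None:
        if self.novelty_hop > self.novelty_window:
            raise ValueError("novelty_hop must be <= novelty_window")
        for name in ("novelty_window", "novelty_hop", "gamma", "butter_order",
                     "butter_cutoff_hz", "n_mels", "eeg_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FeatureSet:
    """Time x feature stimulus matrix s(t) at the EEG rate."""

    data: np.ndarray
    names: list
    discrete: np.ndarray  # bool per column
    rate: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("feature data must be 2-D (time x feature)")
        self.discrete = np.asarray(self.discrete, dtype=bool)
        if len(self.names) != self.data.shape[1] or len(self.discrete) != self.data.shape[1]:
            raise ValueError("names/discrete flags must match the column count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("feature values must be finite")
        for j in np.flatnonzero(self.discrete):
            col = self.data[:, j]
            if not np.all(np.isin(col, (0.0, 1.0))):
                raise ValueError(f"discrete column {self.names[j]!r} must be binary")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def select(self, names) -> "FeatureSet":
        idx = [self.names.index(n) for n in names]
        return FeatureSet(self.data[:, idx], [self.names[i] for i in idx],
                          self.discrete[idx], self.rate)


def _require_mono(audio: AudioTrack) -> np.ndarray:
    x = np.asarray(audio.samples, float)
    if x.ndim != 1:
        raise ValueError("stereo input: convert to mono first (average the channels)")
    return x


def _target_length(n_audio: int, audio_rate: float, eeg_rate: float) -> int:
    return int(round(n_audio / audio_rate * eeg_rate))


def _resample_to(x: np.ndarray, rate_in: float, rate_out: float, n_out: int) -> np.ndarray:
    """Polyphase resampling with trim/pad to an exact output length."""
    frac = Fraction(rate_out / rate_in).limit_denominator(10**6)
    y = signal.resample_poly(x, frac.numerator, frac.denominator)
    if len(y) >= n_out:
        return y[:n_out]
    return np.pad(y, (0, n_out - len(y)))


def energy_novelty(audio: AudioTrack, config: FeatureConfig | None = None) -> FeatureSet:
    """Energy novelty curve: the smoothed, half-rectified rate of change of
    log-compressed sound energy, resampled to the EEG rate.

    Pipeline: square -> Hann smooth (window/hop) -> log(1 + gamma*x) ->
    first difference -> Hann smooth (quarter-length kernel) -> half-wave
    rectify -> polyphase resample. Output is nonnegative and peaks at
    transient energy increases.
    """
    config = config or FeatureConfig()
    x = _require_mono(audio)
    if audio.rate < 2 * config.eeg_rate_hz:
        raise ValueError("audio rate must be at least twice the EEG rate")
    n_out = _target_length(len(x), audio.rate, config.eeg_rate_hz)

    win = signal.windows.hann(config.novelty_window, sym=False)
    win /= win.sum()
    energy = signal.fftconvolve(x**2, win, mode="same")[:: config.novelty_hop]
    energy = np.maximum(energy, 0.0)  # fft round-off can dip below zero
    frame_rate = audio.rate / config.novelty_hop

    compressed = np.log1p(config.gamma * energy)
    diff = np.diff(compressed, prepend=compressed[0])
    n_smooth = max(3, int(round(config.novelty_window / config.novelty_hop / 4)))
    smooth = signal.windows.hann(n_smooth, sym=True)
    smooth /= smooth.sum()
    diff = signal.fftconvolve(diff, smooth, mode="same")
    novelty = np.maximum(diff, 0.0)

    out = _resample_to(novelty, frame_rate, config.eeg_rate_hz, n_out)
    out = np.maximum(out, 0.0)  # resampling can ring slightly negative
    return FeatureSet(out[:, None], ["novelty"], [False], config.eeg_rate_hz)


def detect_onsets(novelty: FeatureSet, threshold: float) -> FeatureSet:
    """Binary acoustic onsets: local maxima of the novelty curve above threshold.

    Plateau ties resolve to the first sample of the plateau; every other
    sample is zero.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    x = novelty.data[:, 0]
    padded = np.concatenate(([-np.inf], x, [-np.inf]))
    rising = padded[1:-1] > padded[:-2]
    not_falling = padded[1:-1] >= padded[2:]
    peaks = rising & not_falling & (x > threshold)
    out = peaks.astype(float)
    return FeatureSet(out[:, None], ["onsets"], [True], novelty.rate)


def hilbert_envelope(audio: AudioTrack, config: FeatureConfig | None = None) -> FeatureSet:
    """Broadband amplitude envelope: |Hilbert transform|, zero-phase
    Butterworth low-pass (order 3, 30 Hz), downsampled to the EEG rate."""
    config = config or FeatureConfig()
    x = _require_mono(audio)
    # filtfilt needs a few filter lengths of signal to initialize
    if len(x) < 10 * (config.butter_order + 1):
        raise ValueError("audio too short for the low-pass filter warm-up")
    env = np.abs(signal.hilbert(x))
    sos = signal.butter(
        config.butter_order, config.butter_cutoff_hz, fs=audio.rate, output="sos"
    )
    env = signal.sosfiltfilt(sos, env)
    n_out = _target_length(len(x), audio.rate, config.eeg_rate_hz)
    out = _resample_to(env, audio.rate, config.eeg_rate_hz, n_out)
    return FeatureSet(out[:, None], ["envelope"], [False], config.eeg_rate_hz)


def power_envelope(audio: AudioTrack, config: FeatureConfig | None = None) -> FeatureSet:
    """Power-based envelope: x^2 -> moving-average resample (non-overlapping
    windows of rate_ratio samples) -> pointwise compression x^log10(2)."""
    config = config or FeatureConfig()
    x = _require_mono(audio)
    ratio = audio.rate / config.eeg_rate_hz
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("audio rate must be an integer multiple of the EEG rate")
    ratio = int(round(ratio))
    n_out = len(x) // ratio
    power = np.square(x[: n_out * ratio]).reshape(n_out, ratio).mean(axis=1)
    out = power ** config.power_compression_exponent
    return FeatureSet(out[:, None], ["power_envelope"], [False], config.eeg_rate_hz)


def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank (HTK mel scale) over the rFFT bins.

    Returns (filters: n_mels x n_bins, center_frequencies_hz).
    """
    n_bins = n_fft // 2 + 1
    if n_mels > n_bins - 2:
        raise ValueError("n_mels exceeds the number of usable FFT bins")
    mel_pts = np.linspace(hz_to_mel(0.0), hz_to_mel(rate / 2), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    bin_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
    return fb, hz_pts[1:-1]


def mel_spectrogram(audio: AudioTrack, config: FeatureConfig | None = None) -> FeatureSet:
    """40-band mel power spectrogram framed at the EEG rate (25 ms windows,
    hop = 1/eeg_rate), trimmed/padded to the EEG sample count."""
    config = config or FeatureConfig()
    x = _require_mono(audio)
    hop = int(round(audio.rate / config.eeg_rate_hz))
    n_fft = int(round(config.mel_window_s * audio.rate))
    f, t, sxx = signal.spectrogram(
        x,
        fs=audio.rate,
        window="hann",
        nperseg=n_fft,
        noverlap=n_fft - hop,
        mode="psd",
    )
    fb, centers = mel_filterbank(config.n_mels, n_fft, audio.rate)
    mel = fb @ sxx  # n_mels x frames
    n_out = _target_length(len(x), audio.rate, config.eeg_rate_hz)
    out = np.zeros((n_out, config.n_mels))
    n_copy = min(n_out, mel.shape[1])
    out[:n_copy] = mel[:, :n_copy].T
    names = [f"mel_{fc:.0f}Hz" for fc in centers]
    return FeatureSet(out, names, [False] * config.n_mels, config.eeg_rate_hz)


def events_to_markers(
    events: EventTable,
    n_samples: int,
    rate: float,
    categories=None,
    condition_split: bool = False,
) -> FeatureSet:
    """Binary sound-identity markers: one column per category (or per
    category x condition when ``condition_split`` is on) with a single 1 at
    round(onset * rate) for each event, zero elsewhere."""
    if len(events) and np.any(events.onsets_s >= n_samples / rate):
        raise ValueError("all event onsets must fall before the end of the recording")
    if categories is None:
        categories = sorted(set(events.categories))
    columns = []
    names = []
    for cat in categories:
        if condition_split:
            conds = sorted(
                {c for c in events.select(category=cat).conditions if c is not None}
            ) or [None]
        else:
            conds = [None]
        for cond in conds:
            sub = events.select(category=cat, condition=cond if condition_split else None)
            col = np.zeros(n_samples)
            for onset in sub.onsets_s:
                i = int(round(onset * rate))
                if col[i] == 1.0:
                    raise ValueError(
                        f"two events of column {cat!r}/{cond!r} collide at sample {i} "
                        f"(marker resolution limit at {rate} Hz)"
                    )
                col[i] = 1.0
            columns.append(col)
            names.append(cat if cond is None else f"{cat}_{cond}")
    if not columns:
        columns = [np.zeros(n_samples)]
        names = ["events"]
    data = np.stack(columns, axis=1)
    return FeatureSet(data, names, [True] * data.shape[1], rate)


def combine(*feature_sets: FeatureSet) -> FeatureSet:
    """Concatenate feature sets onto a common [0, 1] scale.

    Non-binary columns are min-max normalized (a constant column maps to all
    zeros); binary columns pass through untouched so markers and onsets keep
    their 0/1 coding.
    """
    if not feature_sets:
        raise ValueError("at least one feature set is required")
    rate = feature_sets[0].rate
    n = feature_sets[0].n_samples
    for fs in feature_sets[1:]:
        if fs.rate != rate:
            raise ValueError("feature sets must share the sampling rate")
        if fs.n_samples != n:
            raise ValueError(
                f"length mismatch: {fs.n_samples} vs {n} samples"
            )
    cols, names, flags = [], [], []
    for fs in feature_sets:
        for j in range(fs.n_features):
            col = fs.data[:, j].copy()
            if not fs.discrete[j]:
                lo, hi = col.min(), col.max()
                col = np.zeros_like(col) if hi == lo else (col - lo) / (hi - lo)
            cols.append(col)
            names.append(fs.names[j])
            flags.append(bool(fs.discrete[j]))
    return FeatureSet(np.stack(cols, axis=1), names, flags, rate)
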