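"""Synthetic soundscapes and EEG with known ground truth.

The generator emulates the kind of data the analysis pipeline targets: a
tone-sequence soundscape (RMS-matched sounds at annotated onsets, with
category and attentional-condition labels) and multichannel EEG formed by
convolving the event train with a triphasic P1-N1-P2 kernel and adding
1/f ("pink") noise at a controlled single-trial SNR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("narrow", "wide")

EVENT_COLUMNS = ["onset_s", "category", "condition", "duration_s"]


@dataclass
class EventTable:
    """Annotated sound events: onset (s), category, condition, duration (s)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")
        self.df = self.df[EVENT_COLUMNS].reset_index(drop=True)
        onsets = self.df["onset_s"].to_numpy(float)
        if len(onsets) and (np.any(onsets < 0) or np.any(np.diff(onsets) < 0)):
            raise ValueError("onsets must be sorted ascending and >= 0")
        if len(self.df) and np.any(self.df["duration_s"].to_numpy(float) <= 0):
            raise ValueError("durations must be > 0")

    @property
    def onsets_s(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy(float)

    @property
    def categories(self) -> np.ndarray:
        return self.df["category"].to_numpy(object)

    @property
    def conditions(self) -> np.ndarray:
        return self.df["condition"].to_numpy(object)

    def __len__(self) -> int:
        return len(self.df)

    def select(self, category=None, condition=None) -> "EventTable":
        sub = self.df
        if category is not None:
            sub = sub[sub["category"] == category]
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        return EventTable(sub.reset_index(drop=True))


@dataclass
class AudioTrack:
    """Mono waveform (dimensionless samples, nominally in [-1, 1]) + rate."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioTrack is mono: samples must be 1-D")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass
class ERPKernel:
    """Evoked-response kernel on a uniform lag grid starting at lag 0."""

    amplitude: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.ndim != 1:
            raise ValueError("kernel amplitude must be 1-D")

    @property
    def lag_axis(self) -> np.ndarray:
        return np.arange(len(self.amplitude)) / self.rate

    @property
    def span_s(self) -> float:
        return (len(self.amplitude) - 1) / self.rate


@dataclass
class EEGRecording:
    """Multichannel neural-like time series r(t, c)."""

    data: np.ndarray  # T x C
    rate: float
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] == 1 and self.data.shape[1] > 1 and not self.channel_names:
            pass  # caller's responsibility; keep T x C as given
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG values must be finite")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class SimulationConfig:
    """Conditions of the ERP-in-pink-noise simulation."""

    duration_s: float = 600.0
    n_events: int = 396
    snr_grid_db: tuple = (-30, -25, -20, -15, -10, -5, 0, 5, 10)
    n_channels: int = 22
    eeg_rate: float = 100.0
    min_gap_s: float = 0.6
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.eeg_rate <= 0 or self.n_events < 0:
            raise ValueError("invalid simulation configuration")


def generate_event_train(
    duration_s: float,
    n_events: int,
    min_gap_s: float = 0.6,
    categories=("tone",),
    category_probs=None,
    condition_split: float | None = None,
    duration_event_s: float = 0.2,
    seed: int = 0,
) -> EventTable:
    """Randomly place ``n_events`` onsets in [0, duration_s) with a minimum gap.

    Placement uses the stick-breaking construction: after reserving
    ``min_gap_s`` per event the remaining slack is distributed uniformly, so
    every admissible configuration has positive density and the inter-onset
    gaps are guaranteed >= ``min_gap_s`` by construction.

    ``condition_split`` in (0, 1] assigns each event to "narrow" with that
    probability and "wide" otherwise; ``None`` leaves the condition unset.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    if n_events == 0:
        return EventTable(pd.DataFrame(columns=EVENT_COLUMNS))
    slack = duration_s - n_events * min_gap_s
    if slack <= 0:
        raise ValueError(
            f"cannot place {n_events} events with min gap {min_gap_s} s "
            f"in {duration_s} s (needs > {n_events * min_gap_s} s)"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n_events))
    onsets = u + min_gap_s * np.arange(n_events)
    categories = list(categories)
    if category_probs is None:
        category_probs = [1.0 / len(categories)] * len(categories)
    cats = rng.choice(categories, size=n_events, p=category_probs)
    if condition_split is None:
        conds = np.array([None] * n_events, dtype=object)
    else:
        conds = np.where(
            rng.uniform(size=n_events) < condition_split, "narrow", "wide"
        ).astype(object)
    df = pd.DataFrame(
        {
            "onset_s": onsets,
            "category": cats,
            "condition": conds,
            "duration_s": duration_event_s,
        }
    )
    return EventTable(df)


def make_tone_bank(
    categories=("beep", "irrelevant", "alarm"),
    rate: float = 8000.0,
    seed: int = 0,
) -> dict:
    """Synthesize a small bank of distinct tones, one per category.

    Defaults mirror a surgical-soundscape palette: a short 800 Hz beep,
    a 200 ms two-tone monitor sound, and a 200 ms frequency-modulated alarm.
    Amplitudes are left un-normalized; ``render_soundscape`` RMS-matches them.
    """
    rng = np.random.default_rng(seed)
    bank = {}
    specs = {
        "beep": (0.06, lambda t: np.sin(2 * np.pi * 800 * t)),
        "irrelevant": (0.2, lambda t: 0.6 * np.sin(2 * np.pi * 520 * t)
                       + 0.4 * np.sin(2 * np.pi * 660 * t)),
        "alarm": (0.2, lambda t: np.sin(2 * np.pi * (950 + 150 * np.sin(2 * np.pi * 8 * t)) * t)),
    }
    for cat in categories:
        if cat in specs:
            dur, f = specs[cat]
        else:
            dur = 0.15
            f0 = rng.uniform(300, 1200)
            f = lambda t, f0=f0: np.sin(2 * np.pi * f0 * t)
        t = np.arange(int(round(dur * rate))) / rate
        tone = f(t)
        # 5 ms raised-cosine on/off ramps avoid clicks
        n_ramp = max(1, int(0.005 * rate))
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        tone[:n_ramp] *= ramp
        tone[-n_ramp:] *= ramp[::-1]
        bank[cat] = AudioTrack(tone, rate)
    return bank


def render_soundscape(
    events: EventTable,
    tone_bank: dict,
    rate: float,
    duration_s: float | None = None,
) -> AudioTrack:
    """Place RMS-matched tones at the event onsets; overlaps sum.

    Every tone is rescaled so its RMS equals the bank-average RMS before
    placement. Samples outside all event extents are exactly zero.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    for cat in set(events.categories):
        if cat not in tone_bank:
            raise KeyError(f"no tone in bank for category {cat!r}")
    rms = {
        cat: float(np.sqrt(np.mean(np.square(trk.samples))))
        for cat, trk in tone_bank.items()
    }
    target_rms = float(np.mean(list(rms.values()))) if rms else 0.0
    if duration_s is None:
        ext = [
            o + tone_bank[c].duration_s
            for o, c in zip(events.onsets_s, events.categories)
        ]
        duration_s = max(ext) if ext else 1.0
    n = int(round(duration_s * rate))
    out = np.zeros(n)
    for onset, cat in zip(events.onsets_s, events.categories):
        tone = tone_bank[cat].samples
        if rms[cat] > 0:
            tone = tone * (target_rms / rms[cat])
        i0 = int(round(onset * rate))
        i1 = min(i0 + len(tone), n)
        out[i0:i1] += tone[: i1 - i0]
    return AudioTrack(out, rate)


def make_triphasic_kernel(
    rate: float,
    peak_latencies_s=(0.05, 0.10, 0.20),
    peak_amplitudes=(1.0, -2.0, 1.0),
    span_s: float = 0.5,
    width_s: float = 0.015,
) -> ERPKernel:
    """Triphasic P1-N1-P2 kernel: sum of three Gaussian bumps.

    Local extrema sit at the requested latencies with the requested signed
    amplitudes; the kernel is forced to zero at lag 0 and at the end of its
    span so event-free EEG stays exactly zero outside response windows.
    """
    lat = np.asarray(peak_latencies_s, float)
    amp = np.asarray(peak_amplitudes, float)
    if len(lat) != 3 or len(amp) != 3:
        raise ValueError("three latencies and three amplitudes are required")
    if np.any(np.diff(lat) <= 0):
        raise ValueError("peak latencies must be strictly increasing")
    if np.any(lat < 0) or np.any(lat > 0.5):
        raise ValueError("peak latencies must lie within [0, 0.5] s")
    n = int(round(span_s * rate)) + 1
    t = np.arange(n) / rate
    k = np.zeros(n)
    for l, a in zip(lat, amp):
        k += a * np.exp(-0.5 * ((t - l) / width_s) ** 2)
    k[0] = 0.0
    k[-1] = 0.0
    return ERPKernel(k, rate)


def pink_noise(n_samples: int, n_channels: int = 1, seed: int = 0) -> np.ndarray:
    """Unit-variance 1/f noise, independently per channel.

    White Gaussian noise is shaped in the frequency domain with amplitude
    proportional to f^(-1/2) (power spectral density ~ 1/f); the DC bin is
    zeroed and each channel is normalized to zero mean, unit variance.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((n_samples, n_channels))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(n_samples)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** -0.5
    shaped = np.fft.irfft(spec * gain[:, None], n=n_samples, axis=0)
    shaped -= shaped.mean(axis=0)
    shaped /= shaped.std(axis=0)
    return shaped


def event_signal(
    events: EventTable,
    kernel: ERPKernel,
    n_samples: int,
    rate: float,
) -> np.ndarray:
    """Noiseless response: the kernel placed at every event onset (sums on overlap)."""
    sig = np.zeros(n_samples)
    k = kernel.amplitude
    for onset in events.onsets_s:
        i0 = int(round(onset * rate))
        if i0 >= n_samples:
            continue
        i1 = min(i0 + len(k), n_samples)
        sig[i0:i1] += k[: i1 - i0]
    return sig


def _solve_noise_sigma(kernel: ERPKernel, snr_db: float, response_s: float = 0.5) -> float:
    """Noise std realizing the target single-trial SNR as an amplitude ratio.

    The trial-SNR convention is 20*log10(mean|x_response| / sd(x_baseline)),
    so the noise gain is solved from the kernel's mean absolute amplitude
    over the response window: sigma = mean|kernel| * 10^(-snr/20). The gain
    is strictly monotone in the target, which keeps SNR sweeps ordered.
    Re-reading the realized SNR with the estimator on 1/f noise is biased a
    few dB upward (short baselines under-estimate the sd of pink noise, whose
    slow drift also inflates mean|x_response|); see the methods note.
    """
    n_resp = int(round(response_s * kernel.rate)) + 1
    k = np.zeros(n_resp)
    seg = kernel.amplitude[:n_resp]
    k[: len(seg)] = seg
    m = float(np.mean(np.abs(k)))
    if m == 0:
        raise ValueError("kernel is identically zero; SNR undefined")
    return m * 10 ** (-snr_db / 20)


def synthesize_eeg(
    events: EventTable,
    kernel: ERPKernel,
    snr_db: float,
    n_channels: int = 22,
    eeg_rate: float = 100.0,
    duration_s: float | None = None,
    seed: int = 0,
    amplitude_jitter_sd: float = 0.0,
) -> EEGRecording:
    """Clean event-kernel signal plus pink noise at a controlled trial SNR.

    The clean signal is identical on every channel and for every trial (the
    simulation assumes identical responses per trial); ``np.inf`` for
    ``snr_db`` disables the noise entirely. ``amplitude_jitter_sd`` > 0
    multiplies each event's response by N(1, sd^2) (off by default).
    """
    if kernel.rate != eeg_rate:
        raise ValueError("kernel rate must equal eeg_rate")
    if np.isnan(snr_db):
        raise ValueError("snr_db must not be NaN")
    if duration_s is None:
        duration_s = (
            float(events.onsets_s.max()) + kernel.span_s if len(events) else 1.0
        )
    n = int(round(duration_s * eeg_rate))
    if len(events) and np.any(events.onsets_s >= duration_s):
        raise ValueError("all event onsets must fall within duration_s")
    rng = np.random.default_rng(seed)
    if amplitude_jitter_sd > 0:
        sig = np.zeros(n)
        k = kernel.amplitude
        gains = 1.0 + amplitude_jitter_sd * rng.standard_normal(len(events))
        for onset, g in zip(events.onsets_s, gains):
            i0 = int(round(onset * eeg_rate))
            i1 = min(i0 + len(k), n)
            sig[i0:i1] += g * k[: i1 - i0]
    else:
        sig = event_signal(events, kernel, n, eeg_rate)
    data = np.tile(sig[:, None], (1, n_channels))
    if np.isfinite(snr_db):
        sigma = _solve_noise_sigma(kernel, snr_db)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        data = data + sigma * pink_noise(n, n_channels, seed=noise_seed)
    return EEGRecording(data, eeg_rate)
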