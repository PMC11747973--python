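"""File I/O: WAV audio, delimited-text event tables, EEG/features/TRFs as
binary array containers with structured-text sidecars."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .features import FeatureSet
from .synth import AudioTrack, EventTable, EVENT_COLUMNS
from .trf import TRF


def read_audio(path) -> AudioTrack:
    """Read a WAV file; stereo input is converted to mono by channel average."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    data = data.astype(float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return AudioTrack(data, float(rate))


def write_audio(path, audio: AudioTrack) -> None:
    wavfile.write(path, int(round(audio.rate)), audio.samples.astype(np.float32))


def read_events(path) -> EventTable:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed event table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} missing columns: {missing}")
    bad = df.index[pd.to_numeric(df["onset_s"], errors="coerce").isna()]
    if len(bad):
        raise ValueError(f"event table {path}: non-numeric onset at line {bad[0] + 2}")
    df["condition"] = df["condition"].astype(object).where(df["condition"].notna(), None)
    return EventTable(df)


def write_events(path, events: EventTable) -> None:
    events.df.to_csv(path, index=False)


def _sidecar(path) -> Path:
    return Path(str(path) + ".yaml")


def read_eeg(path):
    """Read EEG from a .npy container (or delimited text) + YAML sidecar.

    The sidecar must carry the sampling rate; a missing rate is an error, not
    a guessed default.
    """
    from .synth import EEGRecording

    path = Path(path)
    meta_path = _sidecar(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path} (carries the rate)")
    meta = yaml.safe_load(meta_path.read_text())
    if not isinstance(meta, dict) or "rate" not in meta:
        raise ValueError(f"sidecar {meta_path} does not state the sampling rate")
    data = np.load(path) if path.suffix == ".npy" else np.loadtxt(path, delimiter=",", ndmin=2)
    return EEGRecording(data, float(meta["rate"]), meta.get("channel_names") or [])


def write_eeg(path, eeg) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, eeg.data)
    else:
        np.savetxt(path, eeg.data, delimiter=",")
    _sidecar(path).write_text(
        yaml.safe_dump({"rate": float(eeg.rate), "channel_names": list(eeg.channel_names)})
    )


def read_features(path) -> FeatureSet:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    data = np.load(path) if path.suffix == ".npy" else np.loadtxt(path, delimiter=",", ndmin=2)
    return FeatureSet(data, meta["names"], np.asarray(meta["discrete"], bool), float(meta["rate"]))


def write_features(path, feats: FeatureSet) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, feats.data)
    else:
        np.savetxt(path, feats.data, delimiter=",")
    _sidecar(path).write_text(
        yaml.safe_dump(
            {
                "rate": float(feats.rate),
                "names": list(feats.names),
                "discrete": [bool(d) for d in feats.discrete],
            }
        )
    )


def read_trf(path) -> TRF:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    weights = np.load(path)
    return TRF(
        weights=weights,
        lam=float(meta["lambda"]),
        tmin_ms=float(meta["tmin_ms"]),
        tmax_ms=float(meta["tmax_ms"]),
        rate=float(meta["rate"]),
        feature_names=list(meta["feature_names"]),
    )


def write_trf(path, trf: TRF) -> None:
    path = Path(path)
    np.save(path, trf.weights)
    _sidecar(path).write_text(
        yaml.safe_dump(
            {
                "lambda": float(trf.lam),
                "tmin_ms": float(trf.tmin_ms),
                "tmax_ms": float(trf.tmax_ms),
                "rate": float(trf.rate),
                "feature_names": list(trf.feature_names),
            }
        )
    )
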