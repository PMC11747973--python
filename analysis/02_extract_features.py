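#!/usr/bin/env python
"""Extract the stimulus features from the simulated soundscape.

Produces the acoustic onsets (energy novelty + threshold peak picking), the
Hilbert and power envelopes, and the per-category sound-identity markers,
all sampled at the 100 Hz EEG rate. Writes feature_*.npy (+ sidecars).
"""

from pathlib import Path

from soundscape_trf.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    run_pipeline({"stages": ["features"], "seed": 1}, OUT)
    print(f"features written to {OUT}")
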