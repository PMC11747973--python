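#!/usr/bin/env python
"""Generate the synthetic study data: annotated soundscape + EEG.

Renders a 2-minute tone-sequence soundscape (beep / irrelevant / alarm
events with narrow/wide condition labels), and the matching 22-channel EEG
built from a triphasic P1-N1-P2 kernel plus pink noise at 5 dB. Writes
events.csv, soundscape.wav, eeg.npy (+ sidecar) to results/run/.
"""

from pathlib import Path

from soundscape_trf.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    run_pipeline({"stages": ["simulate"], "seed": 1}, OUT)
    print(f"synthetic soundscape + EEG written to {OUT}")
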