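#!/usr/bin/env python
"""Cross-prediction between the onset and envelope models.

Per fold, each model's weights predict the EEG from both its own feature
and the partner feature; within-model scores should dominate cross-model
scores, while a high rank correlation between them indicates the weights
generalize. Writes cross_prediction.csv.
"""

from pathlib import Path

import pandas as pd

from soundscape_trf.pipeline import run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

if __name__ == "__main__":
    run_pipeline({"stages": ["crosspred"], "seed": 1}, OUT)
    table = pd.read_csv(OUT / "cross_prediction.csv")
    print(table.to_string(index=False))
    print("\nfold means:")
    print(table[["within_A", "within_B", "cross_AB", "cross_BA"]].mean())
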