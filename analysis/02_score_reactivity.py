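#!/usr/bin/env python
"""Score local/global reactivity for every subject x target in the demo dataset.

Reads the TEP files written by 01_simulate_cohort.py, computes the three
scalar predictors (local z AUC, global GMFA AUC, rectified baseline
activity), and writes results/reactivity_scores.csv.
"""

import os

from tepkit.pipeline import score_directory

DATA = "scratch/analysis_data"
RESULTS = "results"


def main() -> None:
    os.makedirs(RESULTS, exist_ok=True)
    scores = score_directory(DATA)
    out = os.path.join(RESULTS, "reactivity_scores.csv")
    scores.to_csv(out, index=False)
    print(f"scored {len(scores)} subject x target pairs -> {out}")
    print(scores.groupby("target")[["local_auc", "global_auc"]].describe()
          .round(1).to_string())


if __name__ == "__main__":
    main()
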