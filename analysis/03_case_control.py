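#!/usr/bin/env python
"""Case-control comparison of the four scores.

For each score, a logistic model of diagnosis on age, sex and the first
two ancestry components (baseline) is compared with the same model plus
the score: reported are the score's beta (se), Wald statistic, the
Nagelkerke pseudo-R2 difference between the nested models, and BH-FDR
adjusted p-values across the four-score family.

Writes results/03_case_control.tsv.
"""

from pathlib import Path

import pandas as pd

from harscore.io import read_study_inputs
from harscore.pipeline import case_control_table

ROOT = Path(__file__).resolve().parents[1]


def main():
    cohort = read_study_inputs(ROOT / "scratch" / "sim")["cohort"]
    scores = pd.read_csv(ROOT / "results" / "02_prs_scores.tsv",
                         sep="\t", index_col="individual")
    table = case_control_table(scores, cohort)
    table.to_csv(ROOT / "results" / "03_case_control.tsv",
                 sep="\t", index=False)
    cols = ["prs", "beta", "se", "wald", "delta_r2", "fdr_p", "significant"]
    print(table[cols].round(4).to_string(index=False))
    sig = table[table["significant"]]["prs"].tolist()
    print(f"\nscores separating the groups at FDR q=0.05: {sig or 'none'}")


if __name__ == "__main__":
    main()
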