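#!/usr/bin/env python
"""Brain-region association scans.

For every score x measure (CT, SA) x mode (within controls, within
patients, score-by-diagnosis interaction on the whole sample), fits one
linear model per Desikan-Killiany region (68 regions) with sex, age,
premorbid IQ, intracranial volume and scanner as covariates
(antipsychotic dose added within patients) and applies BH-FDR across the
68 regions of each family.

Writes the full combined tidy table to scratch/region_scans_full.tsv,
a compact per-family summary plus all FDR-significant rows to
results/04_region_scans_significant.tsv, and prints the latter.
"""

from pathlib import Path

import pandas as pd

from harscore.io import read_study_inputs
from harscore.stats import region_scan

ROOT = Path(__file__).resolve().parents[1]


def main():
    inputs = read_study_inputs(ROOT / "scratch" / "sim")
    cohort, brain = inputs["cohort"], inputs["brain"]
    scores = pd.read_csv(ROOT / "results" / "02_prs_scores.tsv",
                         sep="\t", index_col="individual")
    tables = []
    for name in scores.columns:
        for measure in ("CT", "SA"):
            for group in ("HC", "SZ", "interaction"):
                tables.append(region_scan(scores[name], brain, cohort,
                                          measure=measure, group=group,
                                          prs_name=name))
    combined = pd.concat(tables, ignore_index=True)
    (ROOT / "scratch").mkdir(exist_ok=True)
    combined.to_csv(ROOT / "scratch" / "region_scans_full.tsv",
                    sep="\t", index=False)
    sig = combined[combined["significant"]]
    sig.to_csv(ROOT / "results" / "04_region_scans_significant.tsv",
               sep="\t", index=False)
    if sig.empty:
        print("no region reached FDR significance in any family")
    else:
        cols = ["prs", "measure", "group", "region", "beta", "std_beta",
                "se", "p", "fdr_p", "adj_r2"]
        print("FDR-significant regions:")
        print(sig[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
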