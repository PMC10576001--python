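#!/usr/bin/env python
"""Clinical-profile regressions and scatter data for significant regions.

Within patients: (a) each score is regressed against age at onset,
illness duration, PANSS scores and antipsychotic dose (sex-controlled,
BH-FDR per score family); (b) for every FDR-significant patient SA
region of the foetal-brain HAR score, the unstandardised SA residuals
(covariates regressed out) are paired with the score for plotting and
regressed on the clinical phenotypes (age, sex and dose controlled).

Writes results/05_clinical_prs.tsv, results/05_clinical_sa.tsv and
results/05_figure_<region>.tsv.
"""

from pathlib import Path

import pandas as pd

from harscore.io import read_study_inputs
from harscore.pipeline import CLINICAL_TARGETS, make_figures
from harscore.stats import clinical_regressions, region_scan

ROOT = Path(__file__).resolve().parents[1]


def main():
    inputs = read_study_inputs(ROOT / "scratch" / "sim")
    cohort, brain = inputs["cohort"], inputs["brain"]
    scores = pd.read_csv(ROOT / "results" / "02_prs_scores.tsv",
                         sep="\t", index_col="individual")
    resdir = ROOT / "results"

    prs_tabs = [clinical_regressions(cohort, scores[name], CLINICAL_TARGETS,
                                     covariates=("sex",), predictor_name=name)
                for name in scores.columns]
    clinical_prs = pd.concat(prs_tabs, ignore_index=True)
    clinical_prs.to_csv(resdir / "05_clinical_prs.tsv", sep="\t", index=False)
    n_sig = int(clinical_prs["significant"].sum())
    print(f"score -> clinical profile: {n_sig} FDR-significant associations")

    sa_scan = region_scan(scores["fb_hars"], brain, cohort,
                          measure="SA", group="SZ", prs_name="fb_hars")
    figures = make_figures(scores, sa_scan, brain, cohort, "fb_hars")
    clin_rows = []
    for region, pairs in figures.items():
        pairs.to_csv(resdir / f"05_figure_{region}.tsv", sep="\t", index=False)
        print(f"{region}: slope {pairs.attrs['slope']:.1f} "
              f"(se {pairs.attrs['slope_se']:.1f}), n={len(pairs)}")
        resid = pd.Series(pairs["sa_residual"].to_numpy(),
                          index=pairs["subject_id"])
        clin_rows.append(clinical_regressions(
            cohort, resid,
            ("age_at_onset", "illness_duration", "panss_total",
             "panss_positive", "panss_negative", "panss_general"),
            covariates=("age", "sex", "cpz"),
            predictor_name=f"sa_resid:{region}"))
    if clin_rows:
        clinical_sa = pd.concat(clin_rows, ignore_index=True)
        clinical_sa.to_csv(resdir / "05_clinical_sa.tsv", sep="\t", index=False)
        n_sig = int(clinical_sa["significant"].sum())
        print(f"SA residuals -> clinical profile: {n_sig} FDR-significant")
    else:
        print("no significant SA region; no residual analysis to run")


if __name__ == "__main__":
    main()
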