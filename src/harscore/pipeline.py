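"""End-to-end orchestration of the four-score analysis.

From one study bundle (real files read through :mod:`harscore.io`, or an
in-memory synthetic study) the pipeline:

1. pools the active chromatin states of the foetal (E081, E082) and adult
   (E067, E069, E072, E073) brain epigenomes and derives the
   tissue-exclusive regions;
2. intersects HAR SNPs with those regions to define the FB-HAR and AB-HAR
   SNP panels;
3. builds the four scores — genome-wide (threshold scanned over the
   thirteen candidates and fixed by covariate-adjusted Nagelkerke dR2),
   HAR-restricted, FB-HAR and AB-HAR (single threshold p < 1.0);
4. runs the case/control nested logistic comparisons, the per-region CT/SA
   scans in each diagnostic group and in interaction mode, and the
   clinical-profile regressions, each with BH-FDR within its family;
5. assembles scatter data (score vs unstandardised SA residuals) for every
   FDR-significant patient SA region.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import intervals as gi
from .prs import (
    GLOBAL_PROFILE,
    HAR_PROFILE,
    GenotypeMatrix,
    PrsProfile,
    build_prs,
    harmonise,
    pick_best_threshold,
)
from .simulate import ADULT_EPIGENOMES, FOETAL_EPIGENOMES, SimConfig, SyntheticStudy, gen_study
from .stats import (
    bh_fdr,
    fit_linear,
    fit_logistic,
    nagelkerke_delta,
    region_scan,
    residualise,
    clinical_regressions,
)

logger = logging.getLogger(__name__)

PRS_NAMES = ("global", "hars", "fb_hars", "ab_hars")
CLINICAL_TARGETS = ("age_at_onset", "illness_duration", "panss_total",
                    "panss_positive", "panss_negative", "panss_general", "cpz")
BASELINE_COVARIATES = ("age", "sex", "PC1", "PC2")


@dataclass
class RunReport:
    """Tidy result tables of a full run."""

    snp_panels: Dict[str, List[str]]
    chosen_threshold: float
    scores: pd.DataFrame                       # individual x 4 scores
    case_control: pd.DataFrame                 # 4 rows, Table-1-like columns
    region_tables: Dict[Tuple[str, str, str], pd.DataFrame]
    clinical_prs: pd.DataFrame
    clinical_sa: pd.DataFrame
    figure_data: Dict[str, pd.DataFrame]
    provenance: dict


def derive_snp_panels(geno: GenotypeMatrix, hars: gi.IntervalSet,
                      segments: Mapping[str, Sequence[gi.StateSegment]]
                      ) -> Dict[str, Set[str]]:
    """HAR / FB-HAR / AB-HAR SNP id sets from intervals + segmentations."""
    snp_tab = geno.variants[["id", "chrom", "pos"]]
    har_ids = gi.snps_in_intervals(snp_tab, hars)
    foetal = gi.select_active_states(
        [s for e in FOETAL_EPIGENOMES for s in segments.get(e, [])])
    adult = gi.select_active_states(
        [s for e in ADULT_EPIGENOMES for s in segments.get(e, [])])
    fb_excl, ab_excl = gi.tissue_exclusive_regions(foetal, adult)
    fb_ids = har_ids & gi.snps_in_intervals(snp_tab, fb_excl)
    ab_ids = har_ids & gi.snps_in_intervals(snp_tab, ab_excl)
    return {"hars": har_ids, "fb_hars": fb_ids, "ab_hars": ab_ids}


def build_all_scores(sumstats: pd.DataFrame, geno: GenotypeMatrix,
                     cohort: pd.DataFrame,
                     panels: Mapping[str, Set[str]],
                     global_profile: PrsProfile = GLOBAL_PROFILE,
                     har_profile: PrsProfile = HAR_PROFILE,
                     ) -> Tuple[pd.DataFrame, float, Dict[str, List[str]]]:
    """The four score vectors; the global threshold is scanned and fixed."""
    aligned = harmonise(sumstats, geno)
    res_global = build_prs(aligned, geno, global_profile)
    best = pick_best_threshold(res_global.scores, cohort,
                               covariates=BASELINE_COVARIATES)
    out = {"global": res_global.scores[best]}
    used = {"global": res_global.snp_sets[best]}
    for name in ("hars", "fb_hars", "ab_hars"):
        res = build_prs(aligned, geno, har_profile, restrict_to=panels[name])
        thr = har_profile.p_thresholds[-1]
        out[name] = res.scores[thr]
        used[name] = res.snp_sets[thr]
    scores = pd.DataFrame(out)
    scores.index.name = "individual"
    return scores, best, used


def case_control_table(scores: pd.DataFrame, cohort: pd.DataFrame,
                       q: float = 0.05) -> pd.DataFrame:
    """Nested logistic comparison per score, BH-FDR across the four."""
    y = cohort["diagnosis"].to_numpy(dtype=float)
    base_design = cohort[list(BASELINE_COVARIATES)].astype(float)
    baseline = fit_logistic(y, base_design)
    rows = []
    for name in scores.columns:
        design = base_design.copy()
        design["prs"] = scores[name].reindex(cohort["subject_id"]).to_numpy()
        full = fit_logistic(y, design)
        nk = nagelkerke_delta(baseline, full)
        from scipy.stats import chi2

        rows.append({
            "prs": name,
            "beta": full.params["prs"], "se": full.bse["prs"],
            "wald": full.wald["prs"],
            "p": float(chi2.sf(full.wald["prs"], df=1)),
            "delta_r2": nk.delta_r2,
            "r2_baseline": nk.r2_baseline, "r2_full": nk.r2_full,
            "n": full.n, "converged": full.converged,
        })
    out = pd.DataFrame(rows)
    fdr = bh_fdr(out["p"].to_numpy(), q=q, family="case_control")
    out["fdr_p"] = fdr.adjusted
    out["significant"] = fdr.significant
    return out


def make_figures(scores: pd.DataFrame, scan: pd.DataFrame,
                 brain: pd.DataFrame, cohort: pd.DataFrame,
                 prs_name: str = "fb_hars") -> Dict[str, pd.DataFrame]:
    """Scatter data for FDR-significant patient SA regions.

    For each significant region: per-patient (score, unstandardised SA
    residual) pairs — residuals from regressing the region SA on age, sex,
    ICV, scanner and antipsychotic dose — plus the fitted line and 95% CI
    band parameters. Empty dict when nothing is significant.
    """
    sig = scan[scan["significant"]] if "significant" in scan else scan.iloc[0:0]
    out: Dict[str, pd.DataFrame] = {}
    pats = cohort[cohort["diagnosis"] == 1].merge(brain, on="subject_id")
    pats = pats.assign(prs=scores[prs_name].reindex(pats["subject_id"]).to_numpy())
    covs = ["age", "sex", "icv", "scanner", "cpz"]
    for region in sig["region"]:
        sub = pats.dropna(subset=[region, "prs", *covs])
        resid = residualise(sub[region].to_numpy(), sub[covs].astype(float))
        pairs = pd.DataFrame({
            "subject_id": sub["subject_id"].to_numpy(),
            "prs": sub["prs"].to_numpy(),
            "sa_residual": resid,
        })
        line = fit_linear(resid, pairs[["prs"]])
        pairs.attrs["slope"] = float(line.params["prs"])
        pairs.attrs["intercept"] = float(line.params["const"])
        pairs.attrs["slope_se"] = float(line.bse["prs"])
        pairs.attrs["ci95_t"] = 1.96
        out[region] = pairs
    return out


def run_full(study: SyntheticStudy, q: float = 0.05) -> RunReport:
    """Execute the complete analysis on a study bundle.

    Deterministic given the study; a hard failure inside one analysis
    family is recorded and the remaining families still run.
    """
    t0 = time.time()
    panels = derive_snp_panels(study.geno, study.intervals.hars,
                               study.intervals.segments)
    scores, best_thr, used = build_all_scores(
        study.sumstats, study.geno, study.cohort, panels)
    errors: Dict[str, str] = {}

    cc = pd.DataFrame()
    try:
        cc = case_control_table(scores, study.cohort, q=q)
    except Exception as exc:
        errors["case_control"] = str(exc)
        logger.exception("case-control stage failed")

    region_tables: Dict[Tuple[str, str, str], pd.DataFrame] = {}
    for name in PRS_NAMES:
        for measure in ("CT", "SA"):
            for group in ("HC", "SZ", "interaction"):
                key = (name, measure, group)
                try:
                    region_tables[key] = region_scan(
                        scores[name], study.brain, study.cohort,
                        measure=measure, group=group, q=q, prs_name=name)
                except Exception as exc:
                    errors[f"scan:{key}"] = str(exc)
                    logger.exception("region scan %s failed", key)

    clin_prs = []
    for name in PRS_NAMES:
        try:
            tab = clinical_regressions(
                study.cohort, scores[name], CLINICAL_TARGETS,
                covariates=("sex",), q=q, predictor_name=name)
            clin_prs.append(tab)
        except Exception as exc:
            errors[f"clinical:{name}"] = str(exc)
    clinical_prs = pd.concat(clin_prs, ignore_index=True) if clin_prs else pd.DataFrame()

    # SA residuals of significant patient regions vs clinical profile
    sz_sa = region_tables.get(("fb_hars", "SA", "SZ"), pd.DataFrame())
    clinical_sa = pd.DataFrame()
    figure_data: Dict[str, pd.DataFrame] = {}
    if len(sz_sa):
        try:
            figure_data = make_figures(scores, sz_sa, study.brain,
                                       study.cohort, "fb_hars")
            clin_rows = []
            for region, pairs in figure_data.items():
                resid = pd.Series(pairs["sa_residual"].to_numpy(),
                                  index=pairs["subject_id"])
                tab = clinical_regressions(
                    study.cohort, resid,
                    ("age_at_onset", "illness_duration", "panss_total",
                     "panss_positive", "panss_negative", "panss_general"),
                    covariates=("age", "sex", "cpz"), q=q,
                    predictor_name=f"sa_resid:{region}")
                clin_rows.append(tab)
            if clin_rows:
                clinical_sa = pd.concat(clin_rows, ignore_index=True)
        except Exception as exc:
            errors["clinical_sa"] = str(exc)

    provenance = {
        "config": study.config.to_dict(),
        "seed": study.config.seed,
        "q": q,
        "chosen_threshold": best_thr,
        "panel_sizes": {k: len(v) for k, v in panels.items()},
        "errors": errors,
        "elapsed_s": round(time.time() - t0, 2),
    }
    provenance["config_hash"] = hashlib.sha256(
        json.dumps(provenance["config"], sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    return RunReport(
        snp_panels={k: sorted(v) for k, v in panels.items()},
        chosen_threshold=best_thr,
        scores=scores,
        case_control=cc,
        region_tables=region_tables,
        clinical_prs=clinical_prs,
        clinical_sa=clinical_sa,
        figure_data=figure_data,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# recovery harness (synthetic ground-truth checks)


@dataclass
class RecoveryResult:
    designated_flagged: int       # designated regions FDR-significant (of 4)
    designated_total: int
    flagged_signs: List[float]    # std betas of flagged designated regions
    ct_flagged: int               # CT regions FDR-significant (any)
    sa_other_flagged: int         # non-designated SA regions flagged
    fb_panel_matches_truth: bool


def run_recovery_replicate(config: SimConfig, q: float = 0.05) -> RecoveryResult:
    """One end-to-end replicate: intervals -> FB-restricted score -> scans.

    Generates a study, recomputes the FB-HAR SNP panel from the emitted
    interval data (not the ground truth), builds the FB-HAR score, scans
    patient SA and CT, and reports how many designated regions were
    flagged at FDR q, with their effect signs.
    """
    study = gen_study(config)
    panels = derive_snp_panels(study.geno, study.intervals.hars,
                               study.intervals.segments)
    aligned = harmonise(study.sumstats, study.geno)
    res = build_prs(aligned, study.geno, HAR_PROFILE,
                    restrict_to=panels["fb_hars"])
    score = res.scores[HAR_PROFILE.p_thresholds[-1]]
    sa = region_scan(score, study.brain, study.cohort,
                     measure="SA", group="SZ", q=q, prs_name="fb_hars")
    ct = region_scan(score, study.brain, study.cohort,
                     measure="CT", group="SZ", q=q, prs_name="fb_hars")
    designated = set(study.truth.designated_regions)
    des = sa[sa["region"].isin(designated)]
    flagged = des[des["significant"]]
    return RecoveryResult(
        designated_flagged=int(des["significant"].sum()),
        designated_total=len(designated),
        flagged_signs=[float(b) for b in flagged["std_beta"]],
        ct_flagged=int(ct["significant"].sum()),
        sa_other_flagged=int(
            sa.loc[~sa["region"].isin(designated), "significant"].sum()),
        fb_panel_matches_truth=panels["fb_hars"] == study.truth.fb_snps,
    )
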