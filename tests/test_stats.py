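"""Association statistics: logistic IRLS, Nagelkerke, OLS, FDR, Table tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from harscore import (
    bh_fdr,
    chi2_2x2,
    clinical_regressions,
    fit_linear,
    fit_logistic,
    nagelkerke_delta,
    nagelkerke_r2,
    region_scan,
    residualise,
    ttest_from_summary,
)
from harscore.simulate import SimConfig, gen_brain

from oracles import bh_adjust_brute, grid_logistic


# -- fit_logistic ----------------------------------------------------------


def test_logistic_intercept_only_balanced_gives_zero():
    y = np.array([0, 1] * 25, dtype=float)
    fit = fit_logistic(y, np.empty((50, 0)))
    assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
    assert fit.loglik == pytest.approx(50 * np.log(0.5))


def test_logistic_matches_grid_search_oracle():
    # classes overlap in x, so the MLE is finite
    y = np.array([0, 1, 1, 0, 0, 1], dtype=float)
    x = np.array([-1.2, -0.5, 0.3, 0.1, 0.8, 1.5])
    fit = fit_logistic(y, x[:, None])
    _, ll = grid_logistic(y, np.column_stack([np.ones(6), x]))
    assert fit.loglik == pytest.approx(ll, abs=1e-4)
    assert fit.converged


def test_logistic_matches_statsmodels(rng):
    n = 200
    X = rng.normal(size=(n, 3))
    eta = 0.3 + X @ np.array([0.5, -0.8, 0.0])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(y, X)
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    assert np.allclose(fit.params, ref.params, atol=1e-6)
    assert np.allclose(fit.bse, ref.bse, atol=1e-6)
    assert fit.llnull == pytest.approx(ref.llnull)
    assert np.allclose(fit.wald, (ref.params / ref.bse) ** 2, atol=1e-6)


def test_logistic_null_wald_calibration_and_chi2_distribution():
    """Under the null the Wald statistic is chi2(1): ~5% exceed 3.84 and
    the whole distribution passes a KS test."""
    walds = []
    for seed in range(1, 1001):
        r = np.random.default_rng(seed)
        n = 500
        x = r.normal(size=n)
        y = (r.uniform(size=n) < 0.5).astype(float)
        fit = fit_logistic(y, x[:, None])
        walds.append(fit.wald.iloc[1])
    walds = np.asarray(walds)
    assert np.mean(walds[:100] < 3.84) >= 0.93
    assert sps.kstest(walds, "chi2", args=(1,)).pvalue > 0.01


def test_logistic_separation_flagged_not_raised():
    # complete separation with a point near the boundary: coefficients
    # diverge past the standardised-scale flag threshold
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    x = np.array([-3.0, -2.0, -0.2, 0.2, 2.0, 3.0])
    fit = fit_logistic(y, x[:, None])
    assert not fit.converged
    assert fit.loglik > -1e-3   # perfectly predictive


def test_logistic_rank_deficiency_names_columns():
    y = np.array([0, 1] * 10, dtype=float)
    X = pd.DataFrame({"a": np.arange(20.0), "b": 2 * np.arange(20.0)})
    with pytest.raises(ValueError, match="collinear"):
        fit_logistic(y, X)


def test_logistic_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        fit_logistic(np.ones(10), np.zeros((10, 1)))


# -- Nagelkerke ------------------------------------------------------------


def test_nagelkerke_zero_when_full_equals_baseline(rng):
    n = 100
    X = rng.normal(size=(n, 2))
    y = (rng.uniform(size=n) < 0.5).astype(float)
    fit = fit_logistic(y, X)
    res = nagelkerke_delta(fit, fit)
    assert res.delta_r2 == pytest.approx(0.0)


def test_nagelkerke_perfect_prediction_limit():
    y = np.array([0] * 10 + [1] * 10, dtype=float)
    x = np.array([-1.0] * 10 + [1.0] * 10)
    base = fit_logistic(y, np.empty((20, 0)))
    full = fit_logistic(y, x[:, None])
    res = nagelkerke_delta(base, full)
    assert res.r2_full == pytest.approx(1.0, abs=1e-3)


def test_nagelkerke_matches_formula_with_grid_loglik(rng):
    """R2 recomputed from independently grid-maximised log-likelihoods."""
    for seed in range(3):
        r = np.random.default_rng(seed)
        n = 20
        x = r.normal(size=n)
        y = (r.uniform(size=n) < 1 / (1 + np.exp(-0.8 * x))).astype(float)
        if y.min() == y.max():
            continue
        base = fit_logistic(y, np.empty((n, 0)))
        full = fit_logistic(y, x[:, None])
        res = nagelkerke_delta(base, full)
        _, ll0 = grid_logistic(y, np.ones((n, 1)))
        _, ll1 = grid_logistic(y, np.column_stack([np.ones(n), x]))
        cs = lambda llm: 1 - np.exp((2 / n) * (ll0 - llm))
        expect_full = cs(ll1) / cs(-n * np.log(2)) if False else \
            cs(ll1) / (1 - np.exp((2 / n) * ll0))
        expect_base = cs(ll0) / (1 - np.exp((2 / n) * ll0))
        assert res.r2_full == pytest.approx(expect_full, abs=1e-4)
        assert res.delta_r2 == pytest.approx(expect_full - expect_base, abs=1e-4)


def test_nagelkerke_monotone_in_added_terms(rng):
    n = 150
    X = rng.normal(size=(n, 3))
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
    fits = [fit_logistic(y, X[:, :k]) for k in range(4)]
    r2 = [nagelkerke_r2(f.loglik, f.llnull, f.n) for f in fits]
    assert all(0 <= v <= 1 for v in r2)
    assert all(r2[k + 1] >= r2[k] - 1e-10 for k in range(3))


def test_nagelkerke_rejects_non_nested():
    y = np.array([0, 1] * 20, dtype=float)
    r = np.random.default_rng(0)
    good = fit_logistic(y, r.normal(size=(40, 1)))
    worse = fit_logistic(y, np.empty((40, 0)))
    if good.loglik > worse.loglik + 1e-6:
        with pytest.raises(ValueError, match="subset|nested"):
            nagelkerke_delta(good, worse)


# -- fit_linear / residualise ----------------------------------------------


def test_linear_exact_fit_and_standardised_beta(rng):
    x = rng.normal(size=30)
    y = 2.0 + 3.0 * x
    fit = fit_linear(y, x[:, None])
    assert fit.rsquared == pytest.approx(1.0)
    assert np.allclose(fit.resid, 0, atol=1e-10)
    # standardised x and y: standardised beta equals Pearson r
    x2 = rng.normal(size=50)
    y2 = 0.4 * x2 + rng.normal(size=50)
    xs = (x2 - x2.mean()) / x2.std()
    ys = (y2 - y2.mean()) / y2.std()
    fit2 = fit_linear(ys, xs[:, None])
    assert fit2.std_params.iloc[1] == pytest.approx(np.corrcoef(x2, y2)[0, 1])


def test_linear_matches_hand_normal_equations():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = np.array([1.0, 2.0, 2.0, 4.0])
    X = np.column_stack([np.ones(4), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (4 - 2)
    se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
    r2 = 1 - (resid @ resid) / ((y - y.mean()) @ (y - y.mean()))
    adj = 1 - (1 - r2) * (4 - 1) / (4 - 1 - 1)
    fit = fit_linear(y, x[:, None])
    assert np.allclose(fit.params, beta)
    assert np.allclose(fit.bse, se)
    assert fit.rsquared_adj == pytest.approx(adj)
    assert np.allclose(residualise(y, x[:, None]), resid)


def test_residualise_degenerate_cases(rng):
    x = rng.normal(size=40)
    X1 = np.column_stack([np.ones(40), x])
    # outcome orthogonal to intercept + covariate: residuals = outcome
    y = rng.normal(size=40)
    y_orth = y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]
    assert np.allclose(residualise(y_orth, x[:, None]), y_orth, atol=1e-10)
    # outcome in the span of covariates -> all-zero residuals
    y_span = 1.5 + 2.0 * x
    assert np.allclose(residualise(y_span, x[:, None]), 0, atol=1e-10)


def test_linear_and_residualise_agree(rng):
    X = rng.normal(size=(60, 3))
    y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(size=60)
    fit = fit_linear(y, X)
    Xc = np.column_stack([np.ones(60), X])
    assert np.allclose(y - Xc @ fit.params.to_numpy(), fit.resid, rtol=1e-10)


# -- BH-FDR ----------------------------------------------------------------


def test_bh_fdr_hand_cases():
    assert bh_fdr([0.03]).adjusted == pytest.approx([0.03])
    assert bh_fdr([0.2, 0.2, 0.2]).adjusted == pytest.approx([0.2] * 3)
    res = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert res.adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert res.significant.all()


def test_bh_fdr_matches_brute_force_and_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for _ in range(300):
        m = int(rng.integers(1, 9))
        p = np.round(rng.uniform(size=m), 3)
        res = bh_fdr(p)
        assert np.allclose(res.adjusted, bh_adjust_brute(p), atol=1e-12)
        _, adj_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(res.adjusted, adj_sm, atol=1e-12)
        assert (res.adjusted >= p - 1e-15).all()


def test_bh_fdr_monotone_in_rank_order(rng):
    p = rng.uniform(size=30)
    res = bh_fdr(p)
    order = np.argsort(p)
    assert (np.diff(res.adjusted[order]) >= -1e-15).all()


def test_bh_fdr_rejects_invalid_p():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_null_false_discovery_proportion():
    """Realised FDP under the complete null stays at or below q."""
    fdps = []
    for seed in range(400):
        r = np.random.default_rng(seed)
        p = r.uniform(size=68)
        res = bh_fdr(p, q=0.05)
        rejected = int(res.significant.sum())
        fdps.append(1.0 if rejected else 0.0)
    mean_fdp = np.mean(fdps)
    mc_se = np.std(fdps) / np.sqrt(len(fdps))
    assert mean_fdp <= 0.05 + 2 * mc_se


# -- summary-level tests ---------------------------------------------------


def test_pooled_t_reproduces_group_summaries():
    # age and premorbid IQ rows of the cohort description
    assert ttest_from_summary(38.44, 11.98, 115, 40.15, 10.96, 128) == \
        pytest.approx(-1.17, abs=0.011)
    assert round(ttest_from_summary(103.52, 8.43, 115, 101.05, 9.16, 128), 2) \
        == 2.18
    assert ttest_from_summary(5, 1, 10, 5, 2, 12) == 0.0


def test_chi2_2x2_reproduces_sex_table_and_matches_scipy():
    assert round(chi2_2x2(60, 55, 82, 46), 2) == 3.53
    assert chi2_2x2(10, 10, 20, 20) == pytest.approx(0.0)
    ref = sps.chi2_contingency([[1, 2], [3, 4]], correction=False)[0]
    assert chi2_2x2(1, 2, 3, 4) == pytest.approx(ref)
    with pytest.raises(ValueError):
        chi2_2x2(0, 0, 3, 4)
    with pytest.raises(ValueError):
        ttest_from_summary(1, 0, 10, 2, 1, 10)


# -- region scans ----------------------------------------------------------


def _cohort_brain(seed, gamma=0.0, score=None, both_groups=False):
    """Cohort + brain pair with an optional planted SA effect."""
    cfg = SimConfig(seed=seed, n_snps=2000, n_hars=100, gamma_sa=gamma)
    r = np.random.default_rng(seed + 999)
    n = cfg.n_hc + cfg.n_sz
    cohort = pd.DataFrame({
        "subject_id": [f"i{k}" for k in range(n)],
        "diagnosis": np.array([0] * cfg.n_hc + [1] * cfg.n_sz),
        "age": r.normal(39, 11, n),
        "sex": r.integers(0, 2, n),
        "PC1": r.normal(0, 0.01, n), "PC2": r.normal(0, 0.01, n),
        "premorbid_iq": r.normal(102, 9, n),
        "icv": r.normal(1.45e6, 1.4e5, n),
        "scanner": r.integers(0, 2, n),
        "cpz": np.where(np.arange(n) >= cfg.n_hc,
                        r.lognormal(6.0, 0.8, n), np.nan),
        "age_at_onset": np.nan, "illness_duration": np.nan,
        "panss_total": np.nan, "panss_positive": np.nan,
        "panss_negative": np.nan, "panss_general": np.nan,
    })
    if score is None:
        score = pd.Series(r.normal(size=n),
                          index=pd.Index(cohort["subject_id"], name="individual"))
    fb = score.copy()
    if both_groups:
        # same planted effect in HC and SZ via an all-cases trick
        cohort2 = cohort.assign(diagnosis=1)
        brain = gen_brain(cfg, cohort2, fb, np.random.default_rng(seed + 5))
    else:
        brain = gen_brain(cfg, cohort, fb, np.random.default_rng(seed + 5))
    return cfg, cohort, brain, score


def test_region_scan_null_family_false_discoveries():
    """Zero planted effects: FDR-significant regions are rare."""
    flags = []
    for seed in range(1, 101):
        cfg, cohort, brain, score = _cohort_brain(seed, gamma=0.0)
        scan = region_scan(score, brain, cohort, "SA", "SZ")
        flags.append(1.0 if scan["significant"].any() else 0.0)
    mean_fdp = np.mean(flags)
    mc_se = np.std(flags) / np.sqrt(len(flags))
    assert mean_fdp <= 0.05 + 2 * mc_se


def test_region_scan_planted_effect_tops_ranking():
    """Planted std beta -0.25 in the designated regions: the smallest raw
    p belongs to the designated set in most replicates."""
    tops, hits = 0, 0
    n_reps = 50
    for seed in range(1, n_reps + 1):
        cfg, cohort, brain, score = _cohort_brain(seed, gamma=-0.25)
        scan = region_scan(score, brain, cohort, "SA", "SZ")
        best = scan.loc[scan["p"].idxmin(), "region"]
        if best in cfg.designated_regions:
            tops += 1
        des = scan[scan["region"].isin(cfg.designated_regions)]
        hits += int((des["std_beta"] < 0).sum())
    assert tops / n_reps >= 0.8
    assert hits / (4 * n_reps) >= 0.9   # recovered effects are negative


def test_region_scan_interaction_null_when_effect_shared():
    """Identical effect in both groups: interaction term centred on zero."""
    vals = []
    for seed in range(1, 101):
        cfg, cohort, brain, score = _cohort_brain(seed, gamma=-0.25,
                                                  both_groups=True)
        scan = region_scan(score, brain, cohort, "SA", "interaction")
        des = scan[scan["region"].isin(cfg.designated_regions)]
        vals.extend(des["std_beta"].tolist())
    assert abs(np.mean(vals)) < 0.05


def test_region_scan_reports_68_regions_and_family_fdr(study):
    score = study.truth.fb_score
    scan = region_scan(score, study.brain, study.cohort, "SA", "SZ")
    assert len(scan) == 68
    ref = bh_fdr(scan["p"].to_numpy(), q=0.05)
    assert np.allclose(scan["fdr_p"], ref.adjusted)


def test_region_scan_ct_carries_no_planted_signal(study):
    scan = region_scan(study.truth.fb_score, study.brain, study.cohort,
                       "CT", "SZ")
    des = scan[scan["region"].isin(
        [r.replace("sa_", "ct_") for r in study.truth.designated_regions])]
    assert (des["fdr_p"] > 0.05).all()


# -- clinical regressions --------------------------------------------------


def test_clinical_self_regression_sanity(study):
    cohort = study.cohort
    pats = cohort[cohort["diagnosis"] == 1]
    target = pd.Series(pats["panss_total"].to_numpy(),
                       index=pats["subject_id"])
    out = clinical_regressions(cohort, target, ["panss_total"],
                               covariates=("sex",))
    row = out.iloc[0]
    assert row["std_beta"] == pytest.approx(1.0, abs=1e-6)
    assert row["p"] < 1e-20


def test_clinical_null_associations_rare():
    sig = []
    for seed in range(1, 41):
        cfg, cohort, brain, score = _cohort_brain(seed)
        r = np.random.default_rng(seed)
        pats = cohort[cohort["diagnosis"] == 1].copy()
        cohort.loc[pats.index, "panss_total"] = r.normal(66, 18, len(pats))
        cohort.loc[pats.index, "age_at_onset"] = r.normal(21, 7, len(pats))
        out = clinical_regressions(cohort, score,
                                   ["panss_total", "age_at_onset"],
                                   covariates=("sex",))
        sig.append(1.0 if out["significant"].any() else 0.0)
    assert np.mean(sig) <= 0.05 + 2 * np.std(sig) / np.sqrt(len(sig))


def test_clinical_recovers_planted_cpz_effect():
    """Planted std beta 0.4 of antipsychotic dose on total symptom score."""
    betas = []
    for seed in range(1, 51):
        r = np.random.default_rng(seed)
        n = 126
        cpz = r.lognormal(6.0, 0.8, n)
        z = (cpz - cpz.mean()) / cpz.std()
        target = 66 + 18 * (0.4 * z + np.sqrt(1 - 0.16) * r.normal(size=n))
        cohort = pd.DataFrame({
            "subject_id": [f"p{k}" for k in range(n)],
            "diagnosis": 1, "sex": r.integers(0, 2, n),
            "panss_total": target, "cpz": cpz,
        })
        pred = pd.Series(cpz, index=cohort["subject_id"])
        out = clinical_regressions(cohort, pred, ["panss_total"],
                                   covariates=("sex",))
        betas.append(out.iloc[0]["std_beta"])
    assert np.mean(betas) == pytest.approx(0.4, abs=0.1)
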