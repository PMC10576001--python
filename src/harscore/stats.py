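"""Association statistics for the case-control and brain-region analyses.

Covers nested logistic regression with Nagelkerke pseudo-R2 differences and
Wald statistics, per-region ordinary least squares with standardised betas,
score x diagnosis interactions, residualisation, clinical-profile
regressions, Benjamini-Hochberg FDR, and summary-level two-group tests
(pooled t, Pearson chi-square).

Logistic fits use iteratively reweighted least squares (Newton scoring)
with an explicit convergence contract (max |score| < 1e-8, at most 100
iterations) and a separation diagnostic: a fit whose coefficients on the
standardised design exceed 50 in absolute value is flagged non-converged
instead of raising, so pseudo-R2 limits remain computable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: Covariates of the brain-region scans (antipsychotic dose added within
#: patients); matches the covariate set used for CT/SA models.
SCAN_COVARIATES = ("sex", "age", "premorbid_iq", "icv", "scanner")


# ---------------------------------------------------------------------------
# fit containers


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    wald: pd.Series          # (beta / se)^2 per term
    loglik: float
    llnull: float            # intercept-only log-likelihood, same rows
    n: int
    converged: bool
    terms: Tuple[str, ...] = ()


@dataclass
class NagelkerkeResult:
    r2_baseline: float
    r2_full: float
    delta_r2: float


@dataclass
class LinearFit:
    params: pd.Series
    std_params: pd.Series    # beta * sd(x) / sd(y); NaN for the intercept
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    resid: np.ndarray
    n: int


@dataclass
class FdrResult:
    family: str
    pvalues: np.ndarray
    adjusted: np.ndarray
    significant: np.ndarray
    q: float


# ---------------------------------------------------------------------------
# design handling


def _as_design(design: pd.DataFrame | np.ndarray, add_const: bool = True
               ) -> Tuple[np.ndarray, List[str]]:
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{j}" for j in range(X.shape[1])]
    if add_const:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["const"] + names
    return X, names


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR exposes which trailing columns are dependent
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# logistic regression (IRLS)


def _intercept_only_loglik(y: np.ndarray) -> float:
    n = len(y)
    k = y.sum()
    if k == 0 or k == n:
        return 0.0
    p = k / n
    return float(k * np.log(p) + (n - k) * np.log(1 - p))


def fit_logistic(outcome: Sequence[float] | np.ndarray,
                 design: pd.DataFrame | np.ndarray,
                 add_const: bool = True,
                 max_iter: int = 100, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    ``design`` holds the covariates without an intercept column (one is
    added unless ``add_const=False``). Raises on a rank-deficient design
    or a single-class outcome; flags (rather than raises on) complete
    separation.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X, names = _as_design(design, add_const)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design/outcome contain missing values; drop them first")
    _check_full_rank(X, names)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    from scipy.special import expit

    for _ in range(max_iter):
        eta = np.clip(X @ beta, -300, 300)
        mu = expit(eta)
        score_vec = X.T @ (y - mu)
        if np.max(np.abs(score_vec)) < tol:
            converged = True
            break
        W = np.clip(mu * (1 - mu), 1e-10, None)
        XtWX = X.T @ (X * W[:, None])
        try:
            delta = np.linalg.solve(XtWX, score_vec)
        except np.linalg.LinAlgError:
            break
        # dampen absurd Newton steps near separation
        step = np.max(np.abs(delta))
        if step > 1e4:
            delta *= 1e4 / step
        beta = beta + delta
    eta = np.clip(X @ beta, -300, 300)
    mu = expit(eta)
    # stable Bernoulli log-likelihood: y*eta - log(1 + exp(eta))
    loglik = float(y @ eta - np.logaddexp(0.0, eta).sum())
    W = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = X.T @ (X * W[:, None])
    try:
        cov = np.linalg.inv(XtWX)
        bse = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        bse = np.full(p, np.nan)
    # separation diagnostic on the standardised design scale
    sds = X.std(axis=0)
    sds[sds == 0] = 1.0
    if np.max(np.abs(beta * sds)) > 50:
        converged = False
        logger.warning("fit_logistic: separation suspected (|beta_std| > 50)")
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (beta / bse) ** 2
    idx = pd.Index(names)
    return LogisticFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(bse, index=idx),
        wald=pd.Series(wald, index=idx),
        loglik=loglik,
        llnull=_intercept_only_loglik(y),
        n=n,
        converged=converged,
        terms=tuple(names),
    )


def nagelkerke_r2(loglik: float, llnull: float, n: int) -> float:
    """Nagelkerke pseudo-R2 from model and intercept-only log-likelihoods."""
    cs = 1.0 - np.exp((2.0 / n) * (llnull - loglik))
    denom = 1.0 - np.exp((2.0 / n) * llnull)
    if denom <= 0:
        return 0.0
    return float(min(1.0, max(0.0, cs / denom)))


def nagelkerke_delta(baseline: LogisticFit, full: LogisticFit,
                     tol: float = 1e-6) -> NagelkerkeResult:
    """Pseudo-R2 of two nested fits and their difference.

    Both models are referred to the intercept-only likelihood of the same
    observations; the baseline covariate model is NOT the null reference.
    """
    if baseline.n != full.n:
        raise ValueError("nested fits must use the same observations")
    if not set(baseline.terms) <= set(full.terms):
        raise ValueError("baseline terms must be a subset of full terms")
    if full.loglik < baseline.loglik - tol:
        raise ValueError(
            "full-model likelihood below baseline; models are not nested"
        )
    n = full.n
    llnull = full.llnull
    r2_base = nagelkerke_r2(baseline.loglik, llnull, n)
    r2_full = nagelkerke_r2(full.loglik, llnull, n)
    return NagelkerkeResult(r2_base, r2_full, r2_full - r2_base)


# ---------------------------------------------------------------------------
# linear models


def fit_linear(outcome: Sequence[float] | np.ndarray,
               design: pd.DataFrame | np.ndarray,
               add_const: bool = True) -> LinearFit:
    """Ordinary least squares with standardised coefficients.

    The standardised beta of term x is beta * sd(x) / sd(y) (population
    sd; the ratio is scale-free). Raises on rank deficiency, naming the
    collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(design, add_const)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("design/outcome contain missing values; drop them first")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than model terms")
    _check_full_rank(X, names)
    res = sm.OLS(y, X).fit()
    sd_y = y.std()
    sd_x = X.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        std = res.params * sd_x / sd_y if sd_y > 0 else np.full(X.shape[1], np.nan)
    std = np.where(sd_x == 0, np.nan, std)  # intercept column
    idx = pd.Index(names)
    return LinearFit(
        params=pd.Series(res.params, index=idx),
        std_params=pd.Series(std, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        resid=np.asarray(res.resid),
        n=len(y),
    )


def residualise(outcome: Sequence[float] | np.ndarray,
                covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unstandardised OLS residuals of outcome on covariates (+ intercept)."""
    return fit_linear(outcome, covariates).resid


# ---------------------------------------------------------------------------
# multiple testing


def bh_fdr(pvalues: Sequence[float] | np.ndarray, q: float = 0.05,
           family: str = "") -> FdrResult:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags.

    adj_(i) = min_{k >= i} m * p_(k) / k (capped at 1), mapped back to the
    input order; flags are adj < q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return FdrResult(family, p, p.copy(), np.zeros(0, dtype=bool), q)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return FdrResult(family, p, adj, adj < q, q)


# ---------------------------------------------------------------------------
# brain-region scans


def _region_columns(brain: pd.DataFrame, measure: str) -> List[str]:
    prefix = measure.lower() + "_"
    skip = {"mean_ct", "total_sa"}
    return [c for c in brain.columns if c.startswith(prefix) and c not in skip]


def region_scan(score: pd.Series, brain: pd.DataFrame, cohort: pd.DataFrame,
                measure: str = "SA", group: str = "SZ", q: float = 0.05,
                prs_name: str = "prs") -> pd.DataFrame:
    """Per-region linear models of a cortical measure on a PRS.

    ``group`` is 'HC' or 'SZ' (model fitted within that diagnostic group,
    antipsychotic dose added as covariate within patients) or
    'interaction' (whole sample; PRS, diagnosis and PRS x diagnosis terms,
    the interaction term reported). BH-FDR is applied across the regions
    of the scan — one family per (PRS, measure, group).

    Subjects with missing covariates are dropped with a logged count.
    Returns a tidy frame: region, term, beta, std_beta, se, t, p, fdr_p,
    significant, adj_r2, n.
    """
    if measure.upper() not in ("CT", "SA"):
        raise ValueError("measure must be 'CT' or 'SA'")
    if group not in ("HC", "SZ", "interaction"):
        raise ValueError("group must be 'HC', 'SZ' or 'interaction'")
    df = cohort.copy()
    df = df.merge(brain, on="subject_id", how="inner")
    df["prs"] = score.reindex(df["subject_id"]).to_numpy()
    covs = list(SCAN_COVARIATES)
    if group == "SZ":
        df = df[df["diagnosis"] == 1]
        covs = covs + ["cpz"]
        term = "prs"
    elif group == "HC":
        df = df[df["diagnosis"] == 0]
        term = "prs"
    else:
        term = "prs_x_dx"
    regions = _region_columns(df, measure)
    if not regions:
        raise ValueError(f"no {measure} region columns found")
    need = covs + ["prs"] + (["diagnosis"] if group == "interaction" else [])
    complete = df.dropna(subset=need)
    if len(complete) < len(df):
        logger.info("region_scan: dropped %d subjects with missing covariates",
                    len(df) - len(complete))
    rows = []
    for region in regions:
        sub = complete.dropna(subset=[region])
        design = sub[["prs"] + covs].astype(float)
        if group == "interaction":
            design = design.copy()
            design["diagnosis"] = sub["diagnosis"].astype(float)
            design["prs_x_dx"] = design["prs"] * design["diagnosis"]
        fit = fit_linear(sub[region].to_numpy(), design)
        rows.append({
            "prs": prs_name, "measure": measure.upper(), "group": group,
            "region": region, "term": term,
            "beta": fit.params[term], "std_beta": fit.std_params[term],
            "se": fit.bse[term], "t": fit.tvalues[term],
            "p": fit.pvalues[term], "adj_r2": fit.rsquared_adj, "n": fit.n,
        })
    out = pd.DataFrame(rows)
    fdr = bh_fdr(out["p"].to_numpy(), q=q,
                 family=f"{prs_name}:{measure}:{group}")
    out["fdr_p"] = fdr.adjusted
    out["significant"] = fdr.significant
    return out


def clinical_regressions(cohort: pd.DataFrame, predictor: pd.Series,
                         targets: Sequence[str],
                         covariates: Sequence[str] = ("sex",),
                         q: float = 0.05,
                         predictor_name: str = "prs") -> pd.DataFrame:
    """Linear models of clinical phenotypes on a predictor, patients only.

    One fit per target with the given covariate set; BH-FDR across the
    family of targets. All-missing targets are skipped with a warning.
    Returns a tidy frame like region_scan.
    """
    pats = cohort[cohort["diagnosis"] == 1].copy()
    pats["pred"] = predictor.reindex(pats["subject_id"]).to_numpy()
    rows = []
    for target in targets:
        sub = pats.dropna(subset=[target, "pred", *covariates])
        if sub.empty or sub[target].nunique() < 2:
            warnings.warn(f"clinical target {target!r}: no usable data; skipped")
            continue
        design = sub[["pred", *covariates]].astype(float)
        fit = fit_linear(sub[target].to_numpy(), design)
        rows.append({
            "predictor": predictor_name, "target": target,
            "beta": fit.params["pred"], "std_beta": fit.std_params["pred"],
            "se": fit.bse["pred"], "t": fit.tvalues["pred"],
            "p": fit.pvalues["pred"], "adj_r2": fit.rsquared_adj, "n": fit.n,
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        fdr = bh_fdr(out["p"].to_numpy(), q=q, family=f"clinical:{predictor_name}")
        out["fdr_p"] = fdr.adjusted
        out["significant"] = fdr.significant
    return out


# ---------------------------------------------------------------------------
# summary-level two-group tests


def ttest_from_summary(mean1: float, sd1: float, n1: int,
                       mean2: float, sd2: float, n2: int) -> float:
    """Pooled-variance two-sample t statistic from group summaries."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
    return float((mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2)))


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square (1 df, no continuity correction) of a 2x2 table.

    Table layout: rows are groups, columns are categories — [[a, b], [c, d]].
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("all margins must be positive")
    n = a + b + c + d
    return float(n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2))
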