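"""PRS-C+T engine: harmonisation, LD r2, greedy clumping, thresholding, scoring.

A polygenic risk score here is the weighted sum of counted-allele dosages,
weights being GWAS log-odds effect sizes, after two filters: LD clumping
(keep the most significant SNP of any pair in LD within a physical window)
and p-value thresholding. Two named parameter profiles are provided:

* ``GLOBAL_PROFILE`` — genome-wide score: 1000 kb windows, remove r2 > 0.015,
  thirteen candidate p-value thresholds scanned for the best predictor of
  case/control status.
* ``HAR_PROFILE`` — set-restricted scores (sparser SNP panels): 250 kb
  windows, remove r2 > 0.5, single threshold p < 1.0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The thirteen candidate thresholds of the genome-wide threshold scan.
THIRTEEN_THRESHOLDS: Tuple[float, ...] = (
    5e-8, 5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 1.0,
)

SUMSTAT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                   "beta", "se", "pvalue"]


@dataclass(frozen=True)
class PrsProfile:
    """Clumping + thresholding parameter set."""

    name: str
    clump_kb: float          # window half-width from the index SNP, kb
    clump_r2: float          # remove SNPs with r2 strictly above this
    p_thresholds: Tuple[float, ...]

    def __post_init__(self):
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be > 0")
        if not (0 < self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in (0, 1]")
        if not self.p_thresholds or any(not (0 < t <= 1) for t in self.p_thresholds):
            raise ValueError("p_thresholds must be in (0, 1]")


GLOBAL_PROFILE = PrsProfile("global", clump_kb=1000, clump_r2=0.015,
                            p_thresholds=THIRTEEN_THRESHOLDS)
HAR_PROFILE = PrsProfile("hars", clump_kb=250, clump_r2=0.5, p_thresholds=(1.0,))


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix.

    ``dosage[i, j]`` counts copies of ``variants.counted_allele[j]`` carried
    by individual i, in [0, 2], NaN for missing. ``variants`` has columns
    id, chrom, pos (1-based), counted_allele, other_allele.
    """

    individuals: List[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = self.dosage.shape
        if n != len(self.individuals):
            raise ValueError("dosage rows != number of individuals")
        if m != len(self.variants):
            raise ValueError("dosage columns != number of variants")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosage < 0) | (self.dosage > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2]")
        self.variants = self.variants.reset_index(drop=True)
        self._col_of = {v: j for j, v in enumerate(self.variants["id"])}

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosage[:, self._col_of[snp_id]]

    def col_index(self, snp_id: str) -> int:
        return self._col_of[snp_id]

    def allele_freq(self, snp_id: str) -> float:
        """Counted-allele frequency from non-missing dosages."""
        d = self.column(snp_id)
        d = d[~np.isnan(d)]
        if d.size == 0:
            raise ValueError(f"variant {snp_id} entirely missing")
        return float(d.mean() / 2.0)

    def subset_individuals(self, keep: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.individuals)}
        rows = [pos[s] for s in keep]
        return GenotypeMatrix(list(keep), self.variants.copy(), self.dosage[rows])

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self._col_of[v] for v in ids]
        return GenotypeMatrix(
            list(self.individuals),
            self.variants.iloc[cols].reset_index(drop=True),
            self.dosage[:, cols],
        )


@dataclass
class ClumpResult:
    """Greedy clumping output: ordered index SNPs and their absorbed members."""

    index_ids: List[str]
    members: Dict[str, List[str]]

    def all_assigned(self) -> Set[str]:
        out = set(self.index_ids)
        for v in self.members.values():
            out.update(v)
        return out


@dataclass
class PrsResult:
    """Per-threshold score vectors plus the SNP bookkeeping behind them."""

    profile: PrsProfile
    scores: Dict[float, pd.Series]           # threshold -> individual scores
    snp_sets: Dict[float, List[str]]         # threshold -> scored SNP ids
    clump: ClumpResult
    stats: pd.DataFrame                      # harmonised stats used


def validate_sumstats(stats: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SUMSTAT_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    p = stats["pvalue"]
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (stats["effect_allele"] == stats["other_allele"]).any():
        raise ValueError("effect and other allele must differ")
    return stats


def harmonise(stats: pd.DataFrame, geno: GenotypeMatrix,
              drop_ambiguous: bool = False) -> pd.DataFrame:
    """Align summary-statistic effect alleles to the genotype counted allele.

    If the counted allele is the stated effect allele the weight is kept;
    if it is the other allele the weight's sign is flipped and the alleles
    swapped; any other allele pair is dropped with a logged count. Strand
    flipping is never attempted; ``drop_ambiguous`` removes A/T and C/G
    SNPs up front for data not known to be pre-aligned.
    """
    validate_sumstats(stats)
    st = stats.copy()
    if drop_ambiguous:
        pairs = st["effect_allele"].str.upper() + st["other_allele"].str.upper()
        amb = pairs.isin(["AT", "TA", "CG", "GC"])
        if amb.any():
            logger.info("dropping %d strand-ambiguous SNPs", int(amb.sum()))
            st = st[~amb]
    gv = geno.variants.set_index("id")[["counted_allele", "other_allele"]]
    st = st[st["id"].isin(gv.index)].copy()
    if st.empty:
        raise ValueError("no SNPs shared between summary statistics and genotypes")
    counted = gv.loc[st["id"], "counted_allele"].to_numpy()
    g_other = gv.loc[st["id"], "other_allele"].to_numpy()
    same = (st["effect_allele"].to_numpy() == counted) & \
           (st["other_allele"].to_numpy() == g_other)
    flipped = (st["effect_allele"].to_numpy() == g_other) & \
              (st["other_allele"].to_numpy() == counted)
    mismatch = ~(same | flipped)
    if mismatch.any():
        logger.info("dropping %d SNPs with allele mismatch", int(mismatch.sum()))
    st = st[~mismatch].copy()
    flip = flipped[~mismatch]
    st.loc[flip, "beta"] = -st.loc[flip, "beta"]
    ea = st["effect_allele"].copy()
    st.loc[flip, "effect_allele"] = st.loc[flip, "other_allele"].to_numpy()
    st.loc[flip, "other_allele"] = ea[flip].to_numpy()
    if "eaf" in st.columns:
        st.loc[flip, "eaf"] = 1.0 - st.loc[flip, "eaf"]
    if st.empty:
        raise ValueError("no SNPs left after allele harmonisation")
    return st.reset_index(drop=True)


def ld_r2(geno: GenotypeMatrix, i: int | str, j: int | str) -> float:
    """Squared Pearson correlation of two dosage columns.

    Computed over pairwise-complete individuals. Returns NaN (the "not in
    LD" sentinel) when either variant is monomorphic over the complete
    pairs or fewer than two complete pairs exist.
    """
    a = geno.column(i) if isinstance(i, str) else geno.dosage[:, i]
    b = geno.column(j) if isinstance(j, str) else geno.dosage[:, j]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        logger.warning("ld_r2: fewer than two complete pairs; returning NaN")
        return float("nan")
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        logger.warning("ld_r2: monomorphic variant over complete pairs; NaN")
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2_vector(dos: np.ndarray, idx: int, cand: np.ndarray) -> np.ndarray:
    """r2 of column ``idx`` with each column in ``cand`` (NaN-aware)."""
    x = dos[:, idx]
    out = np.empty(len(cand))
    Y = dos[:, cand]
    nan_x = np.isnan(x)
    if not nan_x.any() and not np.isnan(Y).any():
        xc = x - x.mean()
        vx = xc @ xc
        Yc = Y - Y.mean(axis=0)
        vy = (Yc * Yc).sum(axis=0)
        cov = xc @ Yc
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (cov * cov) / (vx * vy)
        out[(vx == 0) | (vy == 0)] = np.nan
        return out
    for k, c in enumerate(cand):
        y = dos[:, c]
        ok = ~(nan_x | np.isnan(y))
        xa, ya = x[ok], y[ok]
        if xa.size < 2 or xa.var() == 0 or ya.var() == 0:
            out[k] = np.nan
            continue
        r = np.corrcoef(xa, ya)[0, 1]
        out[k] = r * r
    return out


def clump(stats: pd.DataFrame, geno: GenotypeMatrix,
          clump_kb: float, clump_r2: float) -> ClumpResult:
    """Greedy LD clumping.

    Repeatedly select the unassigned SNP with the smallest p-value as an
    index (ties broken by chrom, pos, id ascending) and absorb every
    unassigned SNP on the same chromosome within ``clump_kb`` kilobases
    whose r2 with the index strictly exceeds ``clump_r2``. Undefined r2
    (monomorphic) never removes a SNP.
    """
    validate_sumstats(stats)
    missing = set(stats["id"]) - set(geno.variants["id"])
    if missing:
        raise ValueError(
            f"{len(missing)} SNPs in stats absent from genotypes; harmonise first"
        )
    st = stats.reset_index(drop=True)
    chrom_key = st["chrom"].astype(str).to_numpy()
    pos = st["pos"].to_numpy(dtype=np.int64)
    ids = st["id"].to_numpy()
    order = st.sort_values(
        ["pvalue", "chrom", "pos", "id"],
        key=lambda s: s.astype(str) if s.name == "chrom" else s,
    ).index.to_numpy()
    geno_cols = np.array([geno.col_index(v) for v in ids])
    assigned = np.zeros(len(st), dtype=bool)
    window = clump_kb * 1000.0
    index_ids: List[str] = []
    members: Dict[str, List[str]] = {}
    ptr = 0
    while ptr < len(order):
        while ptr < len(order) and assigned[order[ptr]]:
            ptr += 1
        if ptr >= len(order):
            break
        i = order[ptr]
        assigned[i] = True
        index_ids.append(ids[i])
        members[ids[i]] = []
        near = np.flatnonzero(
            (~assigned)
            & (chrom_key == chrom_key[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if near.size:
            r2 = _pairwise_r2_vector(geno.dosage, geno_cols[i], geno_cols[near])
            hit = near[np.nan_to_num(r2, nan=-1.0) > clump_r2]
            if hit.size:
                assigned[hit] = True
                # members in (chrom, pos, id) order for determinism
                hit = hit[np.lexsort((ids[hit], pos[hit]))]
                members[ids[i]] = [str(v) for v in ids[hit]]
    return ClumpResult(index_ids, members)


def threshold_select(stats: pd.DataFrame, threshold: float) -> Set[str]:
    """Ids with p-value strictly below the threshold."""
    return set(stats.loc[stats["pvalue"] < threshold, "id"])


def score(stats: pd.DataFrame, geno: GenotypeMatrix,
          snp_ids: Iterable[str]) -> pd.Series:
    """Weighted allelic score: sum over SNPs of beta x dosage.

    Missing dosages are imputed as 2 x counted-allele frequency computed
    from the non-missing dosages of that variant. Returns a Series indexed
    by individual id. An empty SNP set yields an all-zero vector with a
    warning.
    """
    snp_ids = list(snp_ids)
    idx = pd.Index(geno.individuals, name="individual")
    if not snp_ids:
        warnings.warn("score() called with an empty SNP set; returning zeros")
        return pd.Series(np.zeros(geno.n_individuals), index=idx)
    w = stats.set_index("id")["beta"]
    unknown = set(snp_ids) - set(w.index)
    if unknown:
        raise KeyError(f"SNPs not in summary statistics: {sorted(unknown)[:5]}")
    total = np.zeros(geno.n_individuals)
    for sid in snp_ids:
        d = geno.column(sid).copy()
        nan = np.isnan(d)
        if nan.all():
            raise ValueError(f"variant {sid} entirely missing")
        if nan.any():
            d[nan] = 2.0 * geno.allele_freq(sid)
        total += w[sid] * d
    return pd.Series(total, index=idx)


def build_prs(stats: pd.DataFrame, geno: GenotypeMatrix, profile: PrsProfile,
              restrict_to: Optional[Iterable[str]] = None) -> PrsResult:
    """Full C+T run under a profile.

    Optional restriction (e.g. to SNPs inside HARs, or inside tissue-
    exclusive regulatory regions) is applied BEFORE clumping; scoring at
    each threshold uses the clump index SNPs passing that threshold.
    """
    st = stats
    if restrict_to is not None:
        keep = set(restrict_to)
        st = st[st["id"].isin(keep)].reset_index(drop=True)
        if st.empty:
            warnings.warn(f"profile {profile.name}: restriction leaves no SNPs")
    cl = (clump(st, geno, profile.clump_kb, profile.clump_r2)
          if len(st) else ClumpResult([], {}))
    index_set = st[st["id"].isin(cl.index_ids)]
    scores: Dict[float, pd.Series] = {}
    snp_sets: Dict[float, List[str]] = {}
    for thr in profile.p_thresholds:
        chosen = threshold_select(index_set, thr)
        # deterministic scoring order: clump selection order
        ordered = [v for v in cl.index_ids if v in chosen]
        snp_sets[thr] = ordered
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scores[thr] = score(st, geno, ordered) if ordered else pd.Series(
                np.zeros(geno.n_individuals),
                index=pd.Index(geno.individuals, name="individual"),
            )
    return PrsResult(profile, scores, snp_sets, cl, st)


def pick_best_threshold(scores: Mapping[float, pd.Series], cohort: pd.DataFrame,
                        covariates: Sequence[str] = ("age", "sex", "PC1", "PC2"),
                        outcome: str = "diagnosis") -> float:
    """Threshold whose score maximises the covariate-adjusted Nagelkerke dR2.

    For each candidate threshold the case/control logistic model with
    baseline covariates plus the score is compared to the baseline-only
    model; the threshold with the largest pseudo-R2 gain wins, ties going
    to the smaller threshold. Non-convergent fits are skipped with a
    warning.
    """
    from .stats import fit_logistic, nagelkerke_delta

    if not scores:
        raise ValueError("no thresholds supplied")
    y = cohort[outcome].to_numpy(dtype=float)
    base_design = cohort[list(covariates)].astype(float)
    baseline = fit_logistic(y, base_design)
    best_thr, best_delta = None, -np.inf
    for thr in sorted(scores):
        design = base_design.copy()
        if "subject_id" in cohort.columns:
            vals = scores[thr].reindex(cohort["subject_id"]).to_numpy()
        else:
            vals = scores[thr].to_numpy()
        design["prs"] = vals
        try:
            full = fit_logistic(y, design)
            if not full.converged:
                raise RuntimeError("did not converge")
            delta = nagelkerke_delta(baseline, full).delta_r2
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"threshold {thr}: fit skipped ({exc})")
            continue
        if delta > best_delta + 1e-12:
            best_thr, best_delta = thr, delta
    if best_thr is None:
        raise RuntimeError("no threshold produced a convergent fit")
    return best_thr
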