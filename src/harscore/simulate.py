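"""Synthetic study generator.

Emulates the full data footprint of a case-control neuroimaging-genetics
study of schizophrenia polygenic risk restricted to human accelerated
regions (HARs): LD-structured genotype dosages, an external discovery GWAS
(summary statistics independent of the target cohort), HAR intervals and
per-epigenome ChromHMM 15-state segmentations whose active states overlap
HARs in configurable tissue-exclusive patterns, a liability-threshold
case/control cohort with demographic and clinical covariates, and regional
cortical thickness / surface area tables with a planted negative
surface-area effect of the foetal-brain HAR score in four designated
right-hemisphere regions of patients only.

All generators are pure functions of (config, seed): independent
SeedSequence children drive each stage, so every emitted table is
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .intervals import (
    AUTOSOMES,
    GenomicInterval,
    IntervalSet,
    StateSegment,
)
from .prs import GenotypeMatrix

FOETAL_EPIGENOMES = ("E081", "E082")
ADULT_EPIGENOMES = ("E067", "E069", "E072", "E073")

#: Desikan-Killiany atlas: 34 cortical regions per hemisphere.
DK_REGIONS: Tuple[str, ...] = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal",
    "middletemporal", "paracentral", "parahippocampal", "parsopercularis",
    "parsorbitalis", "parstriangularis", "pericalcarine", "postcentral",
    "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal",
)

DESIGNATED_SA_REGIONS: Tuple[str, ...] = (
    "sa_rh_lateralorbitofrontal",
    "sa_rh_superiortemporal",
    "sa_rh_parstriangularis",
    "sa_rh_paracentral",
)

#: Non-active filler states cycled through when tiling chromosomes.
_FILLER_STATES = ("15_Quies", "5_TxWk", "9_Het", "14_ReprPCWk", "4_Tx",
                  "13_ReprPC")
_ACTIVE_PAINT_STATES = ("1_TssA", "2_TssAFlnk", "7_Enh", "6_EnhG")


@dataclass
class SimConfig:
    """All dials of the synthetic study; the defaults ARE the study design.

    Group sizes, the planted standardised surface-area effect and the four
    designated right-hemisphere regions mirror the study scale (115 HC /
    128 SZ, standardised beta ~= -0.234). Genotype scale (20,000 SNPs in
    200 exchangeable-correlation LD blocks over the 22 autosomes) is the
    desk-scale default; smaller scans pass a reduced ``n_snps``.
    """

    seed: int
    # cohort
    n_hc: int = 115
    n_sz: int = 128
    pool_size: int = 1600
    prevalence: float = 0.10
    # genotypes
    n_snps: int = 20000
    block_size: int = 100
    rho: float = 0.25
    maf_range: Tuple[float, float] = (0.05, 0.5)
    snp_spacing_bp: int = 800
    block_gap_bp: int = 2_000_000
    # intervals
    n_hars: int = 600
    har_length_bp: int = 1000
    p_har_foetal_only: float = 0.15
    p_har_adult_only: float = 0.15
    p_har_both: float = 0.20
    n_decoy_active: int = 120
    decoy_length_bp: int = 1500
    active_jitter_bp: int = 200
    # discovery GWAS
    causal_fraction: float = 0.5
    background_causal_fraction: float = 0.01
    tau: float = 0.15
    discovery_n: int = 50000
    # phenotype
    liability_h2: float = 0.3
    # brain (relative effect shares of each region's baseline size)
    gamma_sa: float = -0.234
    designated_regions: Tuple[str, ...] = DESIGNATED_SA_REGIONS
    c_age: float = 0.05
    c_sex: float = 0.06
    c_icv: float = 0.06
    c_scanner: float = 0.02
    c_iq: float = 0.02
    c_noise: float = 0.08
    # cohort distributions (Table-2-like means/sds)
    age_hc: Tuple[float, float] = (38.44, 11.98)
    age_sz: Tuple[float, float] = (40.15, 10.96)
    male_frac_hc: float = 0.522
    male_frac_sz: float = 0.641
    iq_hc: Tuple[float, float] = (103.52, 8.43)
    iq_sz: Tuple[float, float] = (101.05, 9.16)
    icv_mean: float = 1.45e6
    icv_sd: float = 1.4e5
    icv_sex_shift: float = 1.0e5
    scanner_frac: float = 0.42
    cpz_logmean: float = 6.02
    cpz_logsd: float = 0.825
    onset_mean: float = 21.0
    onset_sd: float = 7.3
    panss_pos: Tuple[float, float] = (15.66, 5.88)
    panss_neg: Tuple[float, float] = (19.34, 7.31)
    panss_gen: Tuple[float, float] = (31.48, 9.15)
    n_missing_onset: int = 6
    n_missing_panss: int = 4
    n_missing_cpz: int = 2

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.p_har_foetal_only + self.p_har_adult_only + self.p_har_both > 1:
            raise ValueError("HAR category probabilities exceed 1")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_snps % self.block_size:
            raise ValueError("n_snps must be a multiple of block_size")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("maf_range", "age_hc", "age_sz", "iq_hc", "iq_sz",
                    "panss_pos", "panss_neg", "panss_gen",
                    "designated_regions"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class GroundTruth:
    """Recovery-test bookkeeping: what the generator actually planted."""

    causal_ids: List[str]
    causal_betas: Dict[str, float]
    har_snps: Set[str]
    fb_snps: Set[str]
    ab_snps: Set[str]
    designated_regions: Tuple[str, ...]
    gamma_sa: float
    true_score: Optional[pd.Series] = None      # all-causal score, pool
    fb_score: Optional[pd.Series] = None        # FB-causal score, pool

    def to_json_dict(self) -> dict:
        return {
            "causal_ids": self.causal_ids,
            "causal_betas": self.causal_betas,
            "har_snps": sorted(self.har_snps),
            "fb_snps": sorted(self.fb_snps),
            "ab_snps": sorted(self.ab_snps),
            "designated_regions": list(self.designated_regions),
            "gamma_sa": self.gamma_sa,
        }


@dataclass
class IntervalData:
    hars: IntervalSet
    segments: Dict[str, List[StateSegment]]     # epigenome -> segments
    har_table: pd.DataFrame                     # chrom,start,end,category


@dataclass
class SyntheticStudy:
    config: SimConfig
    geno: GenotypeMatrix            # cohort individuals only
    sumstats: pd.DataFrame
    intervals: IntervalData
    cohort: pd.DataFrame
    brain: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# genome layout


def _snp_layout(config: SimConfig) -> pd.DataFrame:
    """Deterministic variant table: blocks round-robin over the autosomes."""
    n_blocks = config.n_snps // config.block_size
    span = config.block_size * config.snp_spacing_bp
    chroms, pos, block_ids = [], [], []
    per_chrom_count = {c: 0 for c in AUTOSOMES}
    for b in range(n_blocks):
        chrom = AUTOSOMES[b % len(AUTOSOMES)]
        k = per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        start = 1 + k * (span + config.block_gap_bp)
        for j in range(config.block_size):
            chroms.append(chrom)
            pos.append(start + j * config.snp_spacing_bp)
            block_ids.append(b)
    ids = [f"rs{i + 1}" for i in range(config.n_snps)]
    return pd.DataFrame({
        "id": ids, "chrom": chroms, "pos": pos, "block": block_ids,
        "counted_allele": "A", "other_allele": "G",
    })


# ---------------------------------------------------------------------------
# genotypes


def gen_genotypes(config: SimConfig, rng: Optional[np.random.Generator] = None,
                  n_individuals: Optional[int] = None) -> GenotypeMatrix:
    """LD-block genotypes via a Gaussian-copula haplotype model.

    Within each block the two haplotypes of every individual share a
    latent exchangeable-correlation (rho) multivariate normal; each
    coordinate is thresholded at the quantile of its SNP's MAF (drawn
    uniformly from ``maf_range``), and the dosage is the haplotype sum.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = n_individuals if n_individuals is not None else config.pool_size
    layout = _snp_layout(config)
    m = len(layout)
    maf = rng.uniform(*config.maf_range, size=m)
    thr = norm.ppf(maf)
    dosage = np.empty((n, m), dtype=np.float64)
    sr, se = np.sqrt(config.rho), np.sqrt(1 - config.rho)
    for b in range(m // config.block_size):
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        block_dosage = np.zeros((n, config.block_size))
        for _hap in range(2):
            f = rng.standard_normal((n, 1))
            e = rng.standard_normal((n, config.block_size))
            z = sr * f + se * e
            block_dosage += (z < thr[cols]).astype(np.float64)
        dosage[:, cols] = block_dosage
    individuals = [f"ind{i + 1:05d}" for i in range(n)]
    variants = layout.drop(columns="block")
    variants.attrs["block_size"] = config.block_size
    return GenotypeMatrix(individuals, variants, dosage)


# ---------------------------------------------------------------------------
# intervals


def gen_intervals(config: SimConfig, variants: pd.DataFrame,
                  rng: Optional[np.random.Generator] = None) -> Tuple[IntervalData, GroundTruth]:
    """HAR intervals plus per-epigenome 15-state segmentations.

    HARs are centred on randomly chosen SNPs (guaranteeing SNP content)
    with enforced edge separation, then assigned a tissue category:
    foetal-only, adult-only, both, or neither. The matching epigenomes
    receive active-state segments painted over the HAR (with a small
    independent boundary jitter per epigenome); decoy active segments are
    placed well away from every HAR, and the remainder of each chromosome
    is tiled with non-active filler states, so each file is a full
    segmentation.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    half = config.har_length_bp // 2
    buffer = config.har_length_bp + 2 * config.active_jitter_bp + 600
    # centre HARs on SNPs: oversample, keep non-conflicting
    cand = rng.choice(len(variants), size=min(len(variants), config.n_hars * 3),
                      replace=False)
    cand_tab = variants.iloc[np.sort(cand)][["chrom", "pos"]]
    hars: List[Tuple[str, int, int]] = []
    last_end: Dict[str, int] = {}
    for chrom, pos in cand_tab.itertuples(index=False):
        start = max(0, pos - 1 - half)
        end = pos - 1 + half
        if start <= last_end.get(chrom, -buffer) + buffer:
            continue
        hars.append((chrom, start, end))
        last_end[chrom] = end
        if len(hars) == config.n_hars:
            break
    if len(hars) < config.n_hars:
        raise ValueError(
            f"could only place {len(hars)} of {config.n_hars} HARs without "
            "overlap; lower n_hars or har_length_bp"
        )
    order = rng.permutation(len(hars))
    probs = (config.p_har_foetal_only, config.p_har_adult_only, config.p_har_both)
    cats = rng.choice(
        ["fb", "ab", "both", "none"], size=len(hars),
        p=[*probs, 1 - sum(probs)],
    )
    har_table = pd.DataFrame(
        [hars[i] for i in order], columns=["chrom", "start", "end"]
    )
    har_table["category"] = cats
    har_table = har_table.sort_values(["chrom", "start"]).reset_index(drop=True)

    chrom_end = {
        c: int(variants.loc[variants["chrom"] == c, "pos"].max()) + 10_000
        for c in variants["chrom"].unique()
    }

    def paint(epigenome: str, classes: Sequence[str]) -> List[StateSegment]:
        actives: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_end}
        for chrom, start, end, cat in har_table.itertuples(index=False):
            if cat not in classes:
                continue
            j1 = int(rng.integers(0, config.active_jitter_bp + 1))
            j2 = int(rng.integers(0, config.active_jitter_bp + 1))
            actives[chrom].append((max(0, start - j1), end + j2))
        # decoy active segments away from every HAR
        placed = 0
        attempts = 0
        har_set = IntervalSet.from_intervals(
            [(c, max(0, s - buffer), e + buffer)
             for c, s, e, _ in har_table.itertuples(index=False)]
        )
        chrom_list = list(chrom_end)
        while placed < config.n_decoy_active and attempts < config.n_decoy_active * 50:
            attempts += 1
            chrom = chrom_list[int(rng.integers(len(chrom_list)))]
            s = int(rng.integers(0, max(1, chrom_end[chrom] - config.decoy_length_bp)))
            e = s + config.decoy_length_bp
            if har_set.contains_positions(chrom, np.array([s, e - 1])).any():
                continue
            actives[chrom].append((s, e))
            placed += 1
        segments: List[StateSegment] = []
        fill_i = 0
        for chrom in sorted(chrom_end, key=lambda c: (len(c), c)):
            merged = IntervalSet({chrom: np.array(actives[chrom])}) \
                if actives[chrom] else IntervalSet()
            cursor = 0
            arr = merged.arrays().get(chrom, np.empty((0, 2), dtype=np.int64))
            for s, e in arr:
                if s > cursor:
                    segments.append(StateSegment(
                        GenomicInterval(chrom, cursor, int(s)),
                        _FILLER_STATES[fill_i % len(_FILLER_STATES)], epigenome))
                    fill_i += 1
                state = _ACTIVE_PAINT_STATES[int(rng.integers(len(_ACTIVE_PAINT_STATES)))]
                segments.append(StateSegment(
                    GenomicInterval(chrom, int(s), int(e)), state, epigenome))
                cursor = int(e)
            if cursor < chrom_end[chrom]:
                segments.append(StateSegment(
                    GenomicInterval(chrom, cursor, chrom_end[chrom]),
                    _FILLER_STATES[fill_i % len(_FILLER_STATES)], epigenome))
                fill_i += 1
        return segments

    segments = {epi: paint(epi, ("fb", "both")) for epi in FOETAL_EPIGENOMES}
    segments.update({epi: paint(epi, ("ab", "both")) for epi in ADULT_EPIGENOMES})

    har_set = IntervalSet.from_intervals(
        [(c, s, e) for c, s, e, _ in har_table.itertuples(index=False)]
    )
    interval_data = IntervalData(har_set, segments, har_table)

    def snps_in_category(cats_wanted: Sequence[str]) -> Set[str]:
        sub = har_table[har_table["category"].isin(cats_wanted)]
        if sub.empty:
            return set()
        iv = IntervalSet.from_intervals(
            [(c, s, e) for c, s, e, _ in sub.itertuples(index=False)]
        )
        from .intervals import snps_in_intervals

        return snps_in_intervals(variants[["id", "chrom", "pos"]], iv)

    truth = GroundTruth(
        causal_ids=[], causal_betas={},
        har_snps=snps_in_category(["fb", "ab", "both", "none"]),
        fb_snps=snps_in_category(["fb"]),
        ab_snps=snps_in_category(["ab"]),
        designated_regions=config.designated_regions,
        gamma_sa=config.gamma_sa,
    )
    return interval_data, truth


# ---------------------------------------------------------------------------
# discovery GWAS


def gen_summary_stats(config: SimConfig, geno: GenotypeMatrix,
                      truth: GroundTruth,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Noisy external-GWAS summary statistics.

    True effects: a ``causal_fraction`` of foetal-brain HAR SNPs plus a
    genome-wide background fraction receive beta ~ N(0, tau^2); every
    SNP's reported beta-hat is its LD-induced marginal effect (block
    covariance times the true betas) plus estimation noise at the standard
    error of a discovery sample of ``discovery_n``, so the table is a
    noisy estimate of truth, independent of the target cohort.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    variants = geno.variants
    m = len(variants)
    ids = variants["id"].to_numpy()
    beta_true = np.zeros(m)

    fb_idx = np.flatnonzero(np.isin(ids, sorted(truth.fb_snps)))
    n_fb_causal = int(round(config.causal_fraction * fb_idx.size))
    fb_causal = rng.choice(fb_idx, size=n_fb_causal, replace=False) \
        if n_fb_causal else np.array([], dtype=int)
    rest = np.setdiff1d(np.arange(m), fb_idx)
    n_bg = int(round(config.background_causal_fraction * rest.size))
    bg_causal = rng.choice(rest, size=n_bg, replace=False) \
        if n_bg else np.array([], dtype=int)
    causal = np.sort(np.concatenate([fb_causal, bg_causal]))
    beta_true[causal] = rng.normal(0.0, config.tau, size=causal.size)

    # LD-induced marginal effects within causal blocks
    block_size = variants.attrs.get("block_size", config.block_size)
    beta_marg = beta_true.copy()
    var_j = np.maximum(np.nanvar(geno.dosage, axis=0), 1e-4)
    for b in np.unique(causal // block_size):
        cols = slice(b * block_size, min((b + 1) * block_size, m))
        sub = geno.dosage[:, cols]
        C = np.cov(sub.T)
        beta_marg[cols] = C @ beta_true[cols] / np.maximum(np.diag(C), 1e-4)

    se = 1.0 / np.sqrt(config.discovery_n * var_j)
    beta_hat = beta_marg + rng.normal(0.0, 1.0, size=m) * se
    z = beta_hat / se
    pvalue = np.clip(2.0 * norm.sf(np.abs(z)), 1e-300, 1.0)
    eaf = np.nanmean(geno.dosage, axis=0) / 2.0

    truth.causal_ids = [str(v) for v in ids[causal]]
    truth.causal_betas = {str(ids[i]): float(beta_true[i]) for i in causal}

    return pd.DataFrame({
        "id": ids,
        "chrom": variants["chrom"].to_numpy(),
        "pos": variants["pos"].to_numpy(),
        "effect_allele": variants["counted_allele"].to_numpy(),
        "other_allele": variants["other_allele"].to_numpy(),
        "beta": beta_hat,
        "se": se,
        "pvalue": pvalue,
        "eaf": eaf,
    })


def true_scores(geno: GenotypeMatrix, truth: GroundTruth) -> Tuple[pd.Series, pd.Series]:
    """(all-causal score, FB-causal score) under the TRUE planted betas."""
    ids = geno.variants["id"].to_numpy()
    beta = np.array([truth.causal_betas.get(v, 0.0) for v in ids])
    total = pd.Series(geno.dosage @ beta, index=pd.Index(geno.individuals,
                                                         name="individual"))
    fb_mask = np.isin(ids, sorted(truth.fb_snps))
    fb = pd.Series(geno.dosage @ (beta * fb_mask),
                   index=pd.Index(geno.individuals, name="individual"))
    return total, fb


# ---------------------------------------------------------------------------
# phenotypes


def _truncnorm(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def gen_phenotypes(config: SimConfig, geno: GenotypeMatrix, truth: GroundTruth,
                   rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Liability-threshold case/control cohort with covariates.

    Liability = standardised true score * sqrt(h2) + N(0, sqrt(1-h2));
    the threshold is the (1 - prevalence) empirical liability quantile.
    Cases are drawn from above it, controls from below, to the configured
    group sizes; demographic and clinical fields follow the configured
    (Table-2-like) group distributions, with configured missingness.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    total, fb = true_scores(geno, truth)
    truth.true_score, truth.fb_score = total, fb
    g = total.to_numpy()
    sd = g.std()
    z = (g - g.mean()) / sd if sd > 0 else np.zeros_like(g)
    h2 = config.liability_h2
    liability = z * np.sqrt(h2) + rng.normal(0, np.sqrt(1 - h2), size=len(z))
    thr = np.quantile(liability, 1 - config.prevalence)
    above = np.flatnonzero(liability >= thr)
    below = np.flatnonzero(liability < thr)
    if above.size < config.n_sz or below.size < config.n_hc:
        raise ValueError(
            "pool too small for requested group sizes at this prevalence"
        )
    cases = rng.choice(above, size=config.n_sz, replace=False)
    controls = rng.choice(below, size=config.n_hc, replace=False)
    sel = np.concatenate([controls, cases])
    dx = np.concatenate([np.zeros(config.n_hc), np.ones(config.n_sz)]).astype(int)
    n = len(sel)
    is_sz = dx == 1

    age = np.where(
        is_sz,
        _truncnorm(rng, *config.age_sz, 18, 65, n),
        _truncnorm(rng, *config.age_hc, 18, 65, n),
    )
    sex = (rng.uniform(size=n) <
           np.where(is_sz, config.male_frac_sz, config.male_frac_hc)).astype(int)
    iq = np.where(
        is_sz,
        _truncnorm(rng, *config.iq_sz, 70, 140, n),
        _truncnorm(rng, *config.iq_hc, 70, 140, n),
    )
    icv = rng.normal(config.icv_mean, config.icv_sd, size=n) \
        + sex * config.icv_sex_shift
    scanner = (rng.uniform(size=n) < config.scanner_frac).astype(int)
    pc = rng.normal(0, 0.01, size=(n, 2))

    cpz = np.where(is_sz,
                   np.minimum(rng.lognormal(config.cpz_logmean,
                                            config.cpz_logsd, size=n), 4000.0),
                   np.nan)
    onset = np.where(is_sz,
                     np.clip(rng.normal(config.onset_mean, config.onset_sd,
                                        size=n), 10, None),
                     np.nan)
    onset = np.minimum(onset, age - 1)
    duration = age - onset
    shared = rng.normal(size=n)

    def panss(mean, sd_, floor):
        x = mean + sd_ * (np.sqrt(0.5) * shared + np.sqrt(0.5) * rng.normal(size=n))
        return np.where(is_sz, np.clip(x, floor, None), np.nan)

    p_pos = panss(*config.panss_pos, 7)
    p_neg = panss(*config.panss_neg, 7)
    p_gen = panss(*config.panss_gen, 16)
    p_tot = p_pos + p_neg + p_gen

    cohort = pd.DataFrame({
        "subject_id": [geno.individuals[i] for i in sel],
        "diagnosis": dx,
        "age": np.round(age, 1),
        "sex": sex,
        "PC1": pc[:, 0],
        "PC2": pc[:, 1],
        "premorbid_iq": np.round(iq, 1),
        "icv": np.round(icv, 0),
        "scanner": scanner,
        "cpz": np.round(cpz, 1),
        "age_at_onset": np.round(onset, 1),
        "illness_duration": np.round(duration, 1),
        "panss_total": np.round(p_tot, 0),
        "panss_positive": np.round(p_pos, 0),
        "panss_negative": np.round(p_neg, 0),
        "panss_general": np.round(p_gen, 0),
    })
    # configured clinical missingness among patients
    pat_rows = np.flatnonzero(is_sz)
    for cols, k in ((["age_at_onset", "illness_duration"], config.n_missing_onset),
                    (["panss_total", "panss_positive", "panss_negative",
                      "panss_general"], config.n_missing_panss),
                    (["cpz"], config.n_missing_cpz)):
        if k and pat_rows.size >= k:
            drop = rng.choice(pat_rows, size=k, replace=False)
            cohort.loc[drop, cols] = np.nan
    return cohort


# ---------------------------------------------------------------------------
# brain measures


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = np.nanstd(x)
    return (x - np.nanmean(x)) / sd if sd > 0 else np.zeros_like(x)


def gen_brain(config: SimConfig, cohort: pd.DataFrame,
              fb_score: Optional[pd.Series] = None,
              rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Regional CT/SA tables with the planted patient-only SA effect.

    Every region's measure is its baseline size times (1 + covariate
    contributions + noise); in the four designated regions the cases
    additionally receive gamma_units * standardised FB score, where
    gamma_units = gamma_sa * S0 / sqrt(1 - gamma_sa^2) and S0 is the
    no-effect standard deviation — so the planted within-patient
    standardised beta equals gamma_sa regardless of the noise share.
    CT receives no score effect anywhere (null CT contrast).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = len(cohort)
    is_case = (cohort["diagnosis"] == 1).to_numpy()
    z_age = _standardise(cohort["age"].to_numpy(dtype=float))
    z_icv = _standardise(cohort["icv"].to_numpy(dtype=float))
    z_iq = _standardise(cohort["premorbid_iq"].to_numpy(dtype=float))
    sex_c = cohort["sex"].to_numpy(dtype=float)
    sex_c = sex_c - sex_c.mean()
    scan_c = cohort["scanner"].to_numpy(dtype=float)
    scan_c = scan_c - scan_c.mean()

    cov_part = (config.c_age * z_age + config.c_sex * sex_c
                + config.c_icv * z_icv + config.c_scanner * scan_c
                + config.c_iq * z_iq)
    v_cov = float(np.var(cov_part))
    s0 = np.sqrt(v_cov + config.c_noise ** 2)
    gamma_units = config.gamma_sa * s0 / np.sqrt(1 - config.gamma_sa ** 2)

    if fb_score is not None:
        fb = fb_score.reindex(cohort["subject_id"]).to_numpy(dtype=float)
        case_vals = fb[is_case]
        fb_z = np.zeros(n)
        csd = case_vals.std()
        if csd > 0:
            fb_z[is_case] = (case_vals - case_vals.mean()) / csd
    else:
        fb_z = np.zeros(n)

    out = {"subject_id": cohort["subject_id"].to_numpy()}
    for measure in ("ct", "sa"):
        base_lo, base_hi = (2.0, 3.2) if measure == "ct" else (1200.0, 4200.0)
        for hemi in ("lh", "rh"):
            for region in DK_REGIONS:
                col = f"{measure}_{hemi}_{region}"
                base = float(rng.uniform(base_lo, base_hi))
                rel = cov_part + config.c_noise * rng.normal(size=n)
                if measure == "sa" and col in config.designated_regions:
                    rel = rel + gamma_units * fb_z * is_case
                vals = base * (1.0 + rel)
                if (vals <= 0).any():
                    raise ValueError(
                        f"non-positive {col}; reduce effect shares or noise"
                    )
                out[col] = np.round(vals, 4 if measure == "ct" else 2)
    brain = pd.DataFrame(out)
    ct_cols = [c for c in brain.columns if c.startswith("ct_")]
    sa_cols = [c for c in brain.columns if c.startswith("sa_")]
    brain["mean_ct"] = brain[ct_cols].mean(axis=1).round(4)
    brain["total_sa"] = brain[sa_cols].sum(axis=1).round(2)
    return brain


# ---------------------------------------------------------------------------
# whole-study driver


def gen_study(config: SimConfig) -> SyntheticStudy:
    """Generate the complete synthetic study from one seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_g, rng_i, rng_s, rng_p, rng_b = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    pool = gen_genotypes(config, rng_g)
    intervals, truth = gen_intervals(config, pool.variants, rng_i)
    sumstats = gen_summary_stats(config, pool, truth, rng_s)
    cohort = gen_phenotypes(config, pool, truth, rng_p)
    fb_pool = truth.fb_score
    brain = gen_brain(config, cohort, fb_pool, rng_b)
    geno = pool.subset_individuals(cohort["subject_id"].tolist())
    geno.variants.attrs["block_size"] = config.block_size
    # restrict stored truth scores to the cohort
    truth.true_score = truth.true_score.reindex(cohort["subject_id"])
    truth.fb_score = truth.fb_score.reindex(cohort["subject_id"])
    return SyntheticStudy(config, geno, sumstats, intervals, cohort, brain, truth)
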