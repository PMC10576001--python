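# Methods

This note documents the models, parameters and design choices behind
`harscore`: what is computed, what the synthetic cohort emulates, and
what passing tests do and do not establish about real data.

## 1. Interval algebra

Intervals are stored 0-based half-open per chromosome, normalised on
construction (sorted, overlapping *and abutting* intervals merged —
per-base semantics are the contract, matching what bedtools-style
intersection implies). `chr` prefixes are stripped so `chr1` and `1`
compare equal; only autosomes 1–22 are kept by default (HAR analyses are
autosomal), with non-autosomal input counted and dropped. SNP positions
are 1-based (VCF convention) and converted at the membership test, which
is half-open: a SNP at 1-based position `p` is inside `[start, end)` iff
`start <= p-1 < end`.

ChromHMM segments use the core 15-state vocabulary; state matching is on
the mnemonic suffix after the numeric prefix, case-insensitive
(`7_Enh` == `Enh`), because segmentation dialects differ. "Active
regulatory" defaults to {TssA, TssAFlnk, Enh, EnhG}. Tissue-exclusive
regions are plain set differences of the pooled foetal and pooled adult
active sets; the two outputs are disjoint by construction.

## 2. PRS C+T engine

*Harmonisation.* Weights are aligned to the genotype counted allele:
kept if the effect allele is counted, sign-flipped if the other allele
is counted, dropped (and counted in the log) otherwise. No strand
flipping is attempted; strand-ambiguous (A/T, C/G) SNPs are kept by
default under exact-allele matching — imputed panels are assumed
pre-aligned — with a `drop_ambiguous` flag for data that is not.

*LD.* `r^2` is the squared Pearson correlation of dosages over
pairwise-complete individuals, computed from the analysis genotypes
themselves (a separate reference panel can be supplied as a
`GenotypeMatrix`). Undefined `r^2` (monomorphic, < 2 complete pairs)
returns NaN and is treated as "not in LD": removal from a clump requires
positive evidence.

*Clumping.* Greedy: the unassigned SNP with the smallest p becomes an
index (ties broken by chromosome, position, id — determinism), and every
unassigned SNP on the same chromosome within `clump_kb` kilobases of the
index (PLINK-style distance from the index) with `r^2` strictly greater
than `clump_r2` joins its clump. Strict `>` follows the threshold's
definition as an exceedance. The suite checks exact agreement with an
exhaustive reference that re-scans eligibility after every selection.

*Thresholding and scoring.* Inclusion is strict (`p < t`); the score is
a weighted **sum** (not mean) of dosages, so its magnitude scales with
panel size. Missing dosages are mean-imputed as twice the sample
counted-allele frequency. Set restriction (HAR / FB / AB panels) is
applied **before** clumping, so index selection happens within the
restricted panel — the composition property
`build_prs(restrict) == snps_in_intervals ∘ clump ∘ threshold ∘ score`
is asserted in the tests.

*Threshold scan.* The genome-wide profile scans thirteen thresholds
(5e-8 … 1.0). For each, diagnosis is fit by logistic regression on
age, sex, PC1, PC2 (baseline) and baseline + score (full); the threshold
maximising the Nagelkerke ΔR² wins, ties to the smaller threshold, and
non-convergent fits are skipped with a warning. The scan is
covariate-adjusted because the downstream report is.

## 3. Statistics

*Logistic regression* is iteratively reweighted least squares (Newton
scoring), converged when the maximum absolute score is below 1e-8, at
most 100 iterations, linear predictor clipped at ±300 and the Bernoulli
log-likelihood evaluated stably via `log(1+exp)`. Complete separation is
flagged, not raised: a fit whose coefficients exceed 50 on the
standardised design is marked non-converged but still returns its
(boundary) log-likelihood, so pseudo-R² limits remain computable. Rank
deficiency raises, naming the collinear columns via pivoted QR. The
implementation is cross-checked against statsmodels `Logit` and a
grid-search likelihood oracle in the tests.

*Nagelkerke pseudo-R²* for a model with log-likelihood `LL_m` on `n`
observations is `[1 - exp((2/n)(LL0 - LL_m))] / [1 - exp((2/n) LL0)]`
where `LL0` is the **intercept-only** likelihood of the same
observations — the covariate baseline is not the null reference; it gets
its own R² against `LL0`, and the reported quantity is the difference
between full and baseline R². Values are clamped to [0, 1] (the formula
can stray below 0 by float dust when `LL_m ≈ LL0`). A full model whose
likelihood falls below the baseline's beyond 1e-6 indicates broken
nesting and raises.

*Linear models* go through statsmodels OLS. Standardised betas are
`beta * sd(x)/sd(y)` (population sd; the ratio is scale-free), NaN for
the intercept. Residualisation returns unstandardised residuals.

*Region scans.* One model per region (68 per measure): measure ~ PRS +
{sex, age, premorbid IQ, ICV, scanner}, plus antipsychotic dose within
patients; interaction mode uses the whole sample with PRS, diagnosis and
PRS × diagnosis and reports the interaction term. Subjects missing any
model variable are dropped with a logged count. BH-FDR is applied
within each (PRS, measure, group) family of 68 regions — the most
conservative family definition consistent with per-table reporting; the
four-score case-control comparison is its own family, as are the
clinical-target families per predictor.

*BH-FDR* is the step-up adjustment `adj_(i) = min_{k>=i} m p_(k)/k`,
capped at 1, flags `adj < q`, `q = 0.05` throughout. Checked against a
brute-force evaluation over all ranks for every `m <= 8` and against
statsmodels `multipletests`.

*Group-description tests* are the pooled-variance two-sample t from
summary statistics and the 1-df Pearson χ² without continuity
correction; pooled (not Welch) variance is used because it reproduces the
two-decimal premorbid-IQ comparison of the bundled cohort description
exactly.

## 4. Synthetic study generator

All generators are pure functions of `(config, seed)`; independent
SeedSequence children drive each stage, and every emitted table is
byte-identical across runs.

*Genotypes.* Gaussian-copula haplotypes: within each LD block of 100
SNPs, each haplotype draws a latent exchangeable-correlation
(`rho = 0.25`) normal vector, thresholded at the quantile of the SNP's
MAF ~ U(0.05, 0.5); dosage is the haplotype sum. Blocks are laid
round-robin over the 22 autosomes, 800 bp SNP spacing, 2 Mb inter-block
gaps (beyond every clumping window, so LD is purely intra-block).
Default scale: 20,000 SNPs in 200 blocks, a 1,600-individual pool —
large enough to exercise clumping and FDR behaviour while a full study
generates in ~15 s.

*Intervals.* HARs (default 600, 1 kb long — of the order of real HAR
lengths, typically containing one or two SNPs at this SNP density) are
centred on randomly chosen SNPs with enforced separation, then assigned
foetal-only / adult-only / both / neither categories
(0.15/0.15/0.20/0.50). Matching epigenomes get active-state segments
painted over their HARs with a small independent boundary jitter; decoy
active segments are placed away from every HAR; the rest of each
chromosome is tiled with non-active filler states so each file is a
complete segmentation. Ground-truth FB/AB/HAR SNP memberships are
recorded and must round-trip exactly through the interval module —
a test asserts this.

*Discovery GWAS.* Half of the FB-HAR SNPs plus a 1% genome-wide
background receive true effects β ~ N(0, 0.15²). Reported effects are
the LD-induced **marginal** effects (block covariance × true betas) plus
estimation noise at the standard error of an external sample of 50,000 —
so summary statistics are noisy, LD-convolved estimates of truth,
independent of the target cohort (mirroring the use of an external,
much larger discovery study). Noise is independent across SNPs; the
LD-correlation of estimation errors in real GWAS is not modelled.

*Phenotype.* Liability = standardised true score × √h² + N(0, √(1−h²)),
h² = 0.3; cases are sampled above the empirical (1 − prevalence)
liability quantile (prevalence 0.10 at pool scale), controls below, to
exactly 115 HC / 128 SZ. Covariates and clinical scores follow the
group-level means/sds of the cohort description (age ≈ 38/40, ~52%/64%
male, IQ ≈ 103/101, ICV 1.45e6 ± 1.4e5 mm³ with a male shift, two
scanners 58/42, CPZ log-normal around 580 mg/day, PANSS subscales with a
shared severity factor so the total's dispersion is realistic), with the
study's clinical missingness counts (onset 122/128, PANSS 124, CPZ 126).
Ancestry PCs are pure noise — no population structure is simulated.

*Brain measures.* Each region's measure is its baseline size times
(1 + covariate shares + noise): age, sex, ICV, scanner and IQ shares
chosen once (0.05/0.06/0.06/0.02/0.02 of baseline, noise 0.08) so that
covariates explain roughly half the variance, in the range of the
adjusted R² values such scans report on real data. In the four
designated right-hemisphere SA regions (lateral orbitofrontal, superior
temporal, pars triangularis, paracentral), cases additionally receive
`gamma_units × z`, where `z` is the within-case standardised **true**
foetal-brain score and
`gamma_units = gamma_sa × S0 / sqrt(1 − gamma_sa²)` with `S0` the
no-effect standard deviation — this self-consistent injection makes the
planted within-patient standardised beta equal `gamma_sa = −0.234`
regardless of the noise share (so the noiseless limit recovers −0.234
exactly). CT receives no score effect anywhere: the CT scans are a
built-in negative control.

*Score-fidelity calibration.* The planted SA effect is defined on the
true FB score, but the pipeline scans with its own estimated FB score;
the recovered effect is therefore attenuated by the correlation between
the two. The generator's LD design (latent rho 0.25, single-SNP-scale
HARs, causal fraction 0.5) keeps that correlation at ~0.95–0.98, so the
planted standardised effect remains identifiable at n = 128. Stronger
within-block LD or multi-SNP HARs mix random-sign causal effects into
neighbouring marginal weights and attenuate the recovered effect — a
real phenomenon, but one that would make the recovery study measure LD
attenuation rather than pipeline correctness.

*What passing does not show.* The generator has no recombination-map
realism, no population structure, no genotyping error, no cross-block
LD, Gaussian (not heavy-tailed) effect sizes, and region measures that
are conditionally independent given covariates (no spatial correlation
across the cortex). Recovery results therefore validate the pipeline's
logic and calibration, not its behaviour under real-data confounding.

## 5. Problem sizes

The full-scale study (20,000 SNPs, 1,600-individual pool) backs the
analysis scripts. The replicate-based checks (end-to-end recovery, null
calibrations) run at 4,000 SNPs / 40 blocks with 240 HARs — the same
cohort sizes, planted effects and profiles — which preserves every
qualitative property at about 1 s per replicate; 25 seeded replicates
are used for the recovery study, 50–1,000 for the scalar calibration
checks, sizes chosen so each suite run stays in the minutes range.

## 6. Known limitations

- The liability in the simulation is driven by a score concentrated in
  FB-HAR SNPs, so all four scores separate cases from controls; the
  generator does not attempt to reproduce a *null* HAR-risk contrast
  alongside a non-null genome-wide one.
- Clumping uses the analysis sample as its own LD reference by default;
  reference-panel mismatch effects are out of scope.
- The pipeline reads whole files (no tabix/indexed access) and assumes
  one genome build throughout (no liftover).
- Binary PLINK filesets and alternative PRS estimators (lassosum,
  PRS-CS, LDpred) are out of scope.
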