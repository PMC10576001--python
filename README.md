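# harscore

Set-restricted polygenic risk scoring over Human Accelerated Regions
(HARs), with brain-region association scans and a fully synthetic study
generator.

## The scientific problem

Schizophrenia is highly polygenic, and part of its genetic architecture
overlaps HARs — genomic segments conserved across mammals that changed
rapidly in the human lineage and act largely as neurodevelopmental
regulatory elements. This package implements a case-control
neuroimaging-genetics analysis that asks whether the schizophrenia risk
burden carried specifically by HARs — and, more narrowly, by HARs lying
in chromatin that is active only in the foetal brain or only in the
adult brain — (a) separates patients from controls and (b) modulates
regional cortical thickness (CT) and surface area (SA).

It is written for researchers who want to run or stress-test this style
of analysis without access to protected genotype and MRI data: every
input (LD-structured genotypes, discovery GWAS, HAR and chromatin-state
intervals, cohort covariates, regional brain measures with planted
effects) can be simulated from a single seed, with the ground truth
recorded for recovery checks.

## The method

Four scores per subject, all by clumping + thresholding (C+T):

`PRS_i = sum_j beta_j * d_ij`

where `d_ij` is subject *i*'s dosage of the effect allele of SNP *j* and
`beta_j` the discovery-GWAS log-odds ratio, after (1) greedy LD clumping
— keep the most significant SNP of any pair with `r^2` above a threshold
within a physical window — and (2) p-value thresholding:

| score      | SNP set                                   | clump           | thresholds |
|------------|-------------------------------------------|-----------------|------------|
| global     | genome-wide                               | 1000 kb, r² > 0.015 | 13-value scan, best by ΔR² |
| hars       | SNPs inside HARs                          | 250 kb, r² > 0.5 | p < 1.0 |
| fb_hars    | HAR SNPs in foetal-brain-specific active chromatin | 250 kb, r² > 0.5 | p < 1.0 |
| ab_hars    | HAR SNPs in adult-brain-specific active chromatin  | 250 kb, r² > 0.5 | p < 1.0 |

Tissue-specific chromatin is built from ChromHMM 15-state segmentations:
active states (TssA, TssAFlnk, Enh, EnhG) are pooled over the foetal
(E081, E082) and adult (E067, E069, E072, E073) brain epigenomes, and
the two set differences define foetal-specific and adult-specific
regions.

Statistics: nested logistic regression (diagnosis ~ covariates vs
covariates + PRS) reported as the Nagelkerke pseudo-R² difference and
the Wald statistic `(beta/se)^2`; per-region linear models of CT/SA on
each PRS within each diagnostic group and as PRS × diagnosis
interactions, with standardised betas; Benjamini–Hochberg FDR at
q = 0.05 within each analysis family.

## Worked example

```bash
python analysis/01_simulate_study.py   # writes raw study files to scratch/sim/
python analysis/02_build_scores.py
python analysis/03_case_control.py
python analysis/04_region_scans.py
python analysis/05_clinical_and_figures.py
```

On the default seed (2023) the case-control step prints:

```
    prs   beta     se    wald  delta_r2  fdr_p  significant
 global 0.9513 0.1360 48.9426    0.3489 0.0000         True
   hars 0.5487 0.1579 12.0802    0.0681 0.0010         True
fb_hars 0.6885 0.2260  9.2841    0.0516 0.0031         True
ab_hars 2.4614 0.8781  7.8574    0.0435 0.0051         True
```

— the genome-wide score separates the 128 patients from the 115
controls most strongly (ΔR² = 0.35), as expected since the simulated
liability is genetic. The region scan then prints, among others:

```
fb_hars  SA  SZ  sa_rh_lateralorbitofrontal  -72.13  std_beta -0.2123  fdr_p 0.0038
fb_hars  SA  SZ  sa_rh_paracentral          -117.61  std_beta -0.2908  fdr_p 0.0001
fb_hars  SA  SZ  sa_rh_parstriangularis      -93.98  std_beta -0.2348  fdr_p 0.0002
```

— the foetal-brain HAR score recovers negative surface-area effects
(standardised β ≈ −0.21…−0.29 against a planted −0.234) in the
designated right-hemisphere regions of patients, while CT stays
essentially null and the clinical-profile regressions find nothing, as
constructed.

The same machinery is scriptable:

```python
from harscore import SimConfig, gen_study, run_full
report = run_full(gen_study(SimConfig(seed=7)))
report.case_control          # 4-row table as above
report.region_tables         # 24 tidy per-region tables
```

and a thin CLI wraps it: `harscore simulate`, `harscore prs`,
`harscore all` (see `--help`).

## Layout

- `src/harscore/` — library: `intervals` (BED/ChromHMM interval
  algebra), `prs` (C+T engine), `stats` (regressions, FDR, group
  tests), `simulate` (synthetic study generator), `pipeline`
  (orchestration), `io`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — pytest suite with independent oracles in
  `tests/oracles.py`.
- `docs/methods.md` — model, parameter and design documentation.
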