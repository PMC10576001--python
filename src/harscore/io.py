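"""Readers and writers for the study's file formats.

Summary statistics are TSV with header (ID, CHR, POS, A1, A2, BETA, SE, P,
optional FRQ; an OR column is accepted and log-transformed). Genotypes are
VCF (GT parsed to ALT-allele dosage) or a TSV dosage matrix with a sidecar
variant table. Cohort and brain tables are CSV with header; region files
are BED / 4-column ChromHMM dialects handled by the intervals module.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .intervals import (
    IntervalSet,
    StateSegment,
    normalise_chrom,
    parse_bed,
    read_chromhmm,
)
from .prs import GenotypeMatrix
from .simulate import (
    ADULT_EPIGENOMES,
    FOETAL_EPIGENOMES,
    GroundTruth,
    SyntheticStudy,
)

_SUMSTAT_ALIASES = {
    "ID": "id", "SNP": "id", "CHR": "chrom", "POS": "pos", "BP": "pos",
    "A1": "effect_allele", "A2": "other_allele", "BETA": "beta", "SE": "se",
    "P": "pvalue", "PVAL": "pvalue", "FRQ": "eaf", "EAF": "eaf", "OR": "or_",
}


def read_sumstats(path) -> pd.DataFrame:
    """Read GWAS summary statistics TSV, mapping common header dialects."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _SUMSTAT_ALIASES.get(c.upper(), c.lower())
                            for c in df.columns})
    if "beta" not in df.columns and "or_" in df.columns:
        df["beta"] = np.log(df["or_"].astype(float))
    if "or_" in df.columns:
        df = df.drop(columns="or_")
    df["chrom"] = df["chrom"].astype(str).map(normalise_chrom)
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={
        "id": "ID", "chrom": "CHR", "pos": "POS", "effect_allele": "A1",
        "other_allele": "A2", "beta": "BETA", "se": "SE", "pvalue": "P",
        "eaf": "FRQ",
    })
    out.to_csv(path, sep="\t", index=False)


# -- genotypes -------------------------------------------------------------


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write integer dosages as GT records (ALT is the counted allele)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted({str(c) for c in geno.variants["chrom"]},
                        key=lambda c: (len(c), c)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.individuals) + "\n")
        for j, row in enumerate(geno.variants.itertuples(index=False)):
            d = geno.dosage[:, j]
            cells = [
                "./." if np.isnan(x) else gt_map[int(round(x))] for x in d
            ]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.other_allele}\t"
                     f"{row.counted_allele}\t.\t.\t.\tGT\t" + "\t".join(cells) + "\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into ALT-allele dosages (counted allele = ALT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, pos, ref, alt = [], [], [], [], []
    rows = []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(normalise_chrom(var.CHROM))
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else "N")
        g = np.array(var.genotypes, dtype=object)
        dos = np.array([
            np.nan if (a[0] < 0 or a[1] < 0) else float(a[0] + a[1]) for a in g
        ])
        rows.append(dos)
    variants = pd.DataFrame({
        "id": ids, "chrom": chroms, "pos": pos,
        "counted_allele": alt, "other_allele": ref,
    })
    return GenotypeMatrix(individuals, variants,
                          np.array(rows).T if rows else np.empty((len(individuals), 0)))


def write_dosage_tsv(geno: GenotypeMatrix, dosage_path, variants_path) -> None:
    df = pd.DataFrame(geno.dosage, columns=geno.variants["id"])
    df.insert(0, "individual", geno.individuals)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA")
    geno.variants.to_csv(variants_path, sep="\t", index=False)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t", na_values=["NA", "."])
    individuals = df["individual"].astype(str).tolist()
    variants = pd.read_csv(variants_path, sep="\t")
    variants["chrom"] = variants["chrom"].astype(str).map(normalise_chrom)
    dosage = df[variants["id"]].to_numpy(dtype=float)
    return GenotypeMatrix(individuals, variants, dosage)


# -- intervals -------------------------------------------------------------


def write_bed(intervals: IntervalSet, path, chr_prefix: bool = True) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom = f"chr{iv.chrom}" if chr_prefix else iv.chrom
            fh.write(f"{chrom}\t{iv.start}\t{iv.end}\n")


def write_chromhmm(segments: Sequence[StateSegment], path,
                   chr_prefix: bool = True) -> None:
    with open(path, "w") as fh:
        for seg in segments:
            chrom = f"chr{seg.interval.chrom}" if chr_prefix else seg.interval.chrom
            fh.write(f"{chrom}\t{seg.interval.start}\t{seg.interval.end}\t"
                     f"{seg.state}\n")


# -- cohort / brain --------------------------------------------------------


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA", ""])


def read_brain(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA", ""])


# -- whole study -----------------------------------------------------------


def write_study(study: SyntheticStudy, outdir) -> Dict[str, str]:
    """Write every emitted file of a synthetic study into ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "sumstats": out / "sumstats.tsv",
        "hars": out / "hars.bed",
        "cohort": out / "cohort.csv",
        "brain": out / "brain.csv",
        "truth": out / "truth.json",
    }
    write_vcf(study.geno, paths["vcf"])
    write_sumstats(study.sumstats, paths["sumstats"])
    write_bed(study.intervals.hars, paths["hars"])
    for epi, segs in study.intervals.segments.items():
        p = out / f"segmentation_{epi}.bed"
        write_chromhmm(segs, p)
        paths[f"segmentation_{epi}"] = p
    study.cohort.to_csv(paths["cohort"], index=False, na_rep="NA")
    study.brain.to_csv(paths["brain"], index=False, na_rep="NA")
    with open(paths["truth"], "w") as fh:
        json.dump(study.truth.to_json_dict(), fh, indent=1)
    return {k: str(v) for k, v in paths.items()}


def read_study_inputs(indir) -> dict:
    """Read back the files of a written study (no ground truth needed)."""
    indir = Path(indir)
    geno = read_vcf(indir / "genotypes.vcf")
    segments = {}
    for epi in FOETAL_EPIGENOMES + ADULT_EPIGENOMES:
        p = indir / f"segmentation_{epi}.bed"
        if p.exists():
            segments[epi] = read_chromhmm(p, epi)
    return {
        "geno": geno,
        "sumstats": read_sumstats(indir / "sumstats.tsv"),
        "hars": parse_bed(indir / "hars.bed"),
        "segments": segments,
        "cohort": read_cohort(indir / "cohort.csv"),
        "brain": read_brain(indir / "brain.csv"),
    }
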