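"""Genomic interval algebra for regulatory-region set restriction.

Intervals are held 0-based half-open per chromosome (BED convention),
normalised on construction: sorted by start, overlapping or abutting
intervals merged. SNP positions arrive 1-based (VCF convention) and are
converted at the membership test.

The module carries three kinds of region sets through the pipeline:
human accelerated regions (HARs), ChromHMM chromatin-state segments per
epigenome, and the tissue-exclusive active regions derived from them
(bases active in foetal brain but not adult brain, and vice versa).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOMES: Tuple[str, ...] = tuple(str(c) for c in range(1, 23))

#: ChromHMM core 15-state model vocabulary (numbered mnemonics).
CHROMHMM_15_STATES: Tuple[str, ...] = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk",
    "6_EnhG", "7_Enh", "8_ZNF/Rpts", "9_Het", "10_TssBiv",
    "11_BivFlnk", "12_EnhBiv", "13_ReprPC", "14_ReprPCWk", "15_Quies",
)

#: Default "active regulatory element" states: active TSS, its flank,
#: enhancers and genic enhancers.
ACTIVE_STATES: Tuple[str, ...] = ("TssA", "TssAFlnk", "Enh", "EnhG")

_STATE_SUFFIXES = {s.split("_", 1)[1].lower() for s in CHROMHMM_15_STATES}


class BedParseError(ValueError):
    """Raised on a malformed BED-like line, naming the offending line."""


def normalise_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so 'chr1' and '1' compare equal."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c


def _state_mnemonic(state: str) -> str:
    """Mnemonic suffix of a state label: '7_Enh' -> 'enh' (lowercased)."""
    m = re.match(r"^\d+_(.+)$", state)
    return (m.group(1) if m else state).lower()


@dataclass(frozen=True)
class GenomicInterval:
    """Single 0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )


@dataclass(frozen=True)
class StateSegment:
    """One ChromHMM segment: interval + state label + epigenome id."""

    interval: GenomicInterval
    state: str
    epigenome: str

    def __post_init__(self):
        if _state_mnemonic(self.state) not in _STATE_SUFFIXES:
            raise ValueError(f"unknown ChromHMM state label: {self.state!r}")


@dataclass(frozen=True)
class VariantLocus:
    """SNP identity and 1-based position."""

    id: str
    chrom: str
    pos: int
    effect_allele: str = "A"
    other_allele: str = "G"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")


class IntervalSet:
    """Normalised per-chromosome interval collection.

    Internally a dict chrom -> (n, 2) int64 array of [start, end) rows,
    sorted and with overlapping/abutting intervals merged, so per-base
    membership is well defined and searchsorted queries are valid.
    """

    def __init__(self, by_chrom: Dict[str, np.ndarray] | None = None,
                 _normalised: bool = False):
        self._by_chrom: Dict[str, np.ndarray] = {}
        if by_chrom:
            for chrom, arr in by_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if arr.size == 0:
                    continue
                if not _normalised:
                    arr = _merge_array(arr)
                self._by_chrom[normalise_chrom(chrom)] = arr

    # -- construction ------------------------------------------------------

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable[GenomicInterval | Tuple[str, int, int]],
        autosomes_only: bool = True,
    ) -> "IntervalSet":
        by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        dropped = 0
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                chrom, start, end = iv.chrom, iv.start, iv.end
            else:
                chrom, start, end = iv
            chrom = normalise_chrom(chrom)
            if start >= end or start < 0:
                raise ValueError(f"invalid interval [{start}, {end}) on {chrom}")
            if autosomes_only and chrom not in AUTOSOMES:
                dropped += 1
                continue
            by_chrom.setdefault(chrom, []).append((start, end))
        if dropped:
            logger.info("dropped %d non-autosomal intervals", dropped)
        return cls({c: np.array(v) for c, v in by_chrom.items()})

    # -- basic protocol ----------------------------------------------------

    @property
    def chroms(self) -> List[str]:
        return sorted(self._by_chrom, key=lambda c: (len(c), c))

    def arrays(self) -> Dict[str, np.ndarray]:
        return dict(self._by_chrom)

    def __len__(self) -> int:
        return sum(a.shape[0] for a in self._by_chrom.values())

    def __iter__(self):
        for chrom in self.chroms:
            for start, end in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, int(start), int(end))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(
            np.array_equal(self._by_chrom[c], other._by_chrom[c])
            for c in self._by_chrom
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_chrom)} chroms)"

    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._by_chrom.values()))

    def is_empty(self) -> bool:
        return not self._by_chrom

    # -- set algebra -------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Return a normalised copy (idempotent; sets are kept normalised)."""
        return IntervalSet(self._by_chrom, _normalised=True)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._by_chrom) | set(other._by_chrom):
            parts = [s._by_chrom[chrom] for s in (self, other) if chrom in s._by_chrom]
            out[chrom] = _merge_array(np.vstack(parts))
        return IntervalSet(out, _normalised=True)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom in set(self._by_chrom) & set(other._by_chrom):
            arr = _intersect_arrays(self._by_chrom[chrom], other._by_chrom[chrom])
            if arr.size:
                out[chrom] = arr
        return IntervalSet(out, _normalised=True)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom, arr in self._by_chrom.items():
            if chrom in other._by_chrom:
                res = _subtract_arrays(arr, other._by_chrom[chrom])
            else:
                res = arr
            if res.size:
                out[chrom] = res
        return IntervalSet(out, _normalised=True)

    def contains_positions(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorised membership of 0-based positions on one chromosome."""
        chrom = normalise_chrom(chrom)
        pos0 = np.asarray(pos0, dtype=np.int64)
        if chrom not in self._by_chrom:
            return np.zeros(pos0.shape, dtype=bool)
        flat = self._by_chrom[chrom].ravel()  # sorted: s0,e0,s1,e1,...
        idx = np.searchsorted(flat, pos0, side="right")
        return (idx % 2) == 1


# -- array kernels ---------------------------------------------------------


def _merge_array(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or abutting [start, end) rows."""
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    starts, ends = arr[:, 0], arr[:, 1]
    # a row starts a new run when its start exceeds the running max end
    # of all previous rows (abutting rows, start == end, are merged too)
    run_end = np.maximum.accumulate(ends)
    new_run = np.ones(len(arr), dtype=bool)
    new_run[1:] = starts[1:] > run_end[:-1]
    out_starts = starts[new_run]
    out_ends = np.maximum.reduceat(ends, np.flatnonzero(new_run))
    return np.column_stack([out_starts, out_ends])


def _intersect_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _subtract_arrays(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j, 1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k, 0] < e:
            if b[k, 0] > cur:
                out.append((cur, b[k, 0]))
            cur = max(cur, b[k, 1])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return np.array(out, dtype=np.int64).reshape(-1, 2)


# -- parsing ---------------------------------------------------------------


def parse_bed(path, zero_based: bool = True, autosomes_only: bool = True) -> IntervalSet:
    """Read a BED-like file (3+ columns) into a normalised IntervalSet.

    Lines starting with '#', 'track' or 'browser' are skipped. With
    ``zero_based=False`` the file is taken as 1-based inclusive and start
    is shifted down by one to the half-open convention.
    """
    intervals: List[Tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            if not zero_based:
                start -= 1
            if start < 0 or start >= end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            intervals.append((chrom, start, end))
    return IntervalSet.from_intervals(intervals, autosomes_only=autosomes_only)


def read_chromhmm(path, epigenome: str, autosomes_only: bool = True) -> List[StateSegment]:
    """Read a 4-column ChromHMM segmentation (chrom start end state)."""
    segments: List[StateSegment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: expected >= 4 columns")
            chrom = normalise_chrom(fields[0])
            if autosomes_only and chrom not in AUTOSOMES:
                continue
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-numeric coordinates"
                ) from exc
            segments.append(
                StateSegment(GenomicInterval(chrom, start, end), fields[3], epigenome)
            )
    return segments


# -- state selection and tissue exclusivity --------------------------------


def select_active_states(
    segments: Iterable[StateSegment],
    states: Sequence[str] = ACTIVE_STATES,
) -> IntervalSet:
    """Merged set of segments whose state mnemonic is in ``states``.

    Matching is on the mnemonic suffix after the numeric prefix,
    case-insensitive ('7_Enh' matches 'Enh'); segments of all epigenomes
    passed in are pooled.
    """
    if not states:
        raise ValueError("states must be non-empty")
    wanted = set()
    for s in states:
        mn = _state_mnemonic(s)
        if mn not in _STATE_SUFFIXES:
            raise ValueError(f"unknown ChromHMM state label: {s!r}")
        wanted.add(mn)
    picked = [
        seg.interval for seg in segments if _state_mnemonic(seg.state) in wanted
    ]
    return IntervalSet.from_intervals(picked)


def tissue_exclusive_regions(
    foetal: IntervalSet, adult: IntervalSet
) -> Tuple[IntervalSet, IntervalSet]:
    """(foetal-specific, adult-specific) = (foetal - adult, adult - foetal)."""
    return foetal.subtract(adult), adult.subtract(foetal)


# -- SNP membership --------------------------------------------------------


def snps_in_intervals(
    snps: pd.DataFrame | Iterable[VariantLocus],
    regions: IntervalSet,
) -> Set[str]:
    """Ids of SNPs whose 0-based position (pos - 1) falls in ``regions``.

    ``snps`` is a DataFrame with columns id/chrom/pos (pos 1-based) or an
    iterable of VariantLocus. Membership is half-open.
    """
    if not isinstance(snps, pd.DataFrame):
        snps = pd.DataFrame(
            [(v.id, v.chrom, v.pos) for v in snps], columns=["id", "chrom", "pos"]
        )
    if snps.empty:
        return set()
    out: Set[str] = set()
    for chrom, sub in snps.groupby(snps["chrom"].map(normalise_chrom)):
        mask = regions.contains_positions(chrom, sub["pos"].to_numpy() - 1)
        out.update(sub.loc[mask, "id"])
    return out
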