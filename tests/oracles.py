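"""Independent slow-but-obviously-correct reference implementations.

These stay deliberately naive (per-base sets, exhaustive re-scans, grid
searches) and share no code with the package paths they check.
"""

from __future__ import annotations

from typing import Dict, List, Set, Tuple

import numpy as np


# -- per-base interval oracle ----------------------------------------------


def bases_of(intervals) -> Dict[str, Set[int]]:
    """All covered bases of an IntervalSet (small instances only)."""
    out: Dict[str, Set[int]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    return {c: s for c, s in out.items() if s}


def bases_of_raw(triples) -> Dict[str, Set[int]]:
    out: Dict[str, Set[int]] = {}
    for chrom, start, end in triples:
        out.setdefault(str(chrom), set()).update(range(start, end))
    return {c: s for c, s in out.items() if s}


def random_triples(rng: np.random.Generator, n: int, span: int = 5000,
                   chroms=("1", "2")) -> List[Tuple[str, int, int]]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, 200))
        out.append((chrom, start, start + length))
    return out


# -- exhaustive clumping oracle --------------------------------------------


def pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def exhaustive_clump(stats, geno, clump_kb: float, clump_r2: float):
    """Reference clumping that re-scans every remaining SNP each round.

    Returns (index_ids, members dict) with members sorted by (pos, id).
    """
    remaining = {
        row.id: (str(row.chrom), int(row.pos), float(row.pvalue))
        for row in stats.itertuples(index=False)
    }
    index_ids, members = [], {}
    while remaining:
        best = min(
            remaining.items(),
            key=lambda kv: (kv[1][2], kv[1][0], kv[1][1], kv[0]),
        )[0]
        b_chrom, b_pos, _ = remaining.pop(best)
        index_ids.append(best)
        grabbed = []
        for sid, (chrom, pos, _p) in list(remaining.items()):
            if chrom != b_chrom or abs(pos - b_pos) > clump_kb * 1000:
                continue
            r2 = pair_r2(geno.column(best), geno.column(sid))
            if not np.isnan(r2) and r2 > clump_r2:
                grabbed.append((pos, sid))
                del remaining[sid]
        members[best] = [sid for _, sid in sorted(grabbed)]
    return index_ids, members


# -- logistic grid-search oracle -------------------------------------------


def logistic_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(X @ beta, -35, 35)
    mu = 1 / (1 + np.exp(-eta))
    return float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))


def grid_logistic(y: np.ndarray, X: np.ndarray,
                  lo: float = -10, hi: float = 10,
                  rounds: int = 7, points: int = 21):
    """Coarse-to-fine grid maximisation of a p-parameter logistic likelihood.

    Practical for p <= 2-3. Returns (best beta, best loglik).
    """
    p = X.shape[1]
    centers = np.zeros(p)
    width = hi - lo
    best_beta, best_ll = centers.copy(), -np.inf
    for _ in range(rounds):
        axes = [np.linspace(c - width / 2, c + width / 2, points)
                for c in centers]
        mesh = np.meshgrid(*axes, indexing="ij")
        grid = np.stack([m.ravel() for m in mesh], axis=1)
        lls = np.array([logistic_loglik(y, X, b) for b in grid])
        k = int(np.argmax(lls))
        if lls[k] > best_ll:
            best_ll = float(lls[k])
            best_beta = grid[k]
        centers = grid[k]
        width = width * 2.2 / (points - 1)  # shrink around the winner
    return best_beta, best_ll


# -- BH step-up brute force ------------------------------------------------


def bh_adjust_brute(p: np.ndarray) -> np.ndarray:
    """adj_(i) = min_{k >= i} m p_(k) / k via explicit loops."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = []
    for i in range(m):
        best = min(m * p[order[k]] / (k + 1) for k in range(i, m))
        adj_sorted.append(min(best, 1.0))
    adj = np.empty(m)
    for rank, idx in enumerate(order):
        adj[idx] = adj_sorted[rank]
    return adj
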