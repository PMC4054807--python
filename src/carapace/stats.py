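"""Selection-test statistics layer and gene-family utilities.

The branch-site likelihood-ratio test for positive selection tests a
parameter pinned to the boundary of its space under the null, so the
null distribution of the LRT statistic is not chi-square: it is a 50:50
mixture of a point mass at zero and a chi-square with one degree of
freedom.  p-values computed against that mixture are conservative.
This module provides the mixture p-value, Benjamini-Hochberg FDR
control, and a simulator of the canonical boundary test used to
validate the mixture null.  The likelihood machinery that produces the
statistics is upstream; statistics enter via TSV.

Gene-family side: the normalized bit-score distance used to weight
BLASTP alignments when clustering orthologous groups, and the
conservative collapse of family members more than 97% identical at the
amino-acid level.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# boundary-mixture null and FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionTestResult:
    gene_id: str
    lrt_statistic: float
    p_value: float
    q_value: float


def mixture_pvalue(t: float) -> float:
    """p-value of an LRT statistic under the 50:50 chi2_1 / point-mass null.

    P(T >= t) = 1 for t = 0 (the point mass is included), and
    0.5 x chi2_1 upper tail for t > 0, computed through the
    complementary error function identity sf(t) = erfc(sqrt(t/2)).
    """
    if t < 0:
        raise ValueError("LRT statistic must be non-negative")
    if t == 0:
        return 1.0
    return 0.5 * math.erfc(math.sqrt(t / 2.0))


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def simulate_boundary_lrt(n_reps: int, sample_size: int = 1,
                          seed: int = 0) -> np.ndarray:
    """Null LRT statistics for the canonical boundary test.

    H0: theta = 0 vs H1: theta >= 0 for a normal mean with known unit
    variance gives T = max(0, Z)^2 with Z = sqrt(n) x sample mean: zero
    with probability 1/2, chi2_1 otherwise.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_reps, sample_size)).mean(axis=1) * math.sqrt(sample_size)
    return np.maximum(z, 0.0) ** 2


def selection_results(gene_stats: Sequence[tuple[str, float]],
                      fdr: float = 0.1) -> list[SelectionTestResult]:
    """Mixture p-values plus BH q-values for a table of (gene_id, T)."""
    ps = [mixture_pvalue(t) for _g, t in gene_stats]
    qs = bh_fdr(ps)
    return [SelectionTestResult(g, t, p, q)
            for (g, t), p, q in zip(gene_stats, ps, qs)]


# ---------------------------------------------------------------------------
# gene-family utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BitScorePair:
    """Reciprocal BLASTP bit scores between sequences i and j."""

    s_ij: float
    s_ji: float

    def __post_init__(self) -> None:
        if self.s_ij <= 0 or self.s_ji <= 0:
            raise ValueError("bit scores must be positive")


def bitscore_distance(pair: BitScorePair) -> float:
    """Normalized bit-score distance 1 - min(s_ij, s_ji)/max(s_ij, s_ji).

    Symmetric in its arguments; 0 for identical scores, approaching 1 as
    the scores diverge.
    """
    lo, hi = sorted((pair.s_ij, pair.s_ji))
    return 1.0 - lo / hi


@dataclass
class FamilyIdentityMatrix:
    """Pairwise amino-acid identities within one gene family."""

    members: list[str]
    identities: np.ndarray  # fractions in [0, 1], symmetric, diagonal 1
    threshold: float = 0.97

    def __post_init__(self) -> None:
        m = np.asarray(self.identities, dtype=float)
        n = len(self.members)
        if m.shape != (n, n):
            raise ValueError("identity matrix shape must match member count")
        if not np.allclose(m, m.T):
            raise ValueError("identity matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("identity matrix diagonal must be 1.0")
        self.identities = m


class CollapseResult(NamedTuple):
    members: list[str]
    count: int
    exact: bool


EXACT_COLLAPSE_LIMIT = 15


def collapse_family(matrix: FamilyIdentityMatrix) -> CollapseResult:
    """Conservative family size after removing near-identical duplicates.

    Members whose pairwise identity strictly exceeds the threshold
    (default 97%) are considered redundant; the result is a
    maximum-cardinality subset with no such pair.  Exact subset search
    up to 15 members (deterministic: lexicographically smallest optimum);
    above that a greedy heuristic removes the member with the most
    over-threshold partners (tie-break lexicographic) and the result is
    flagged approximate.
    """
    n = len(matrix.members)
    if n == 0:
        return CollapseResult([], 0, True)
    order = sorted(range(n), key=lambda i: matrix.members[i])
    conflict = matrix.identities > matrix.threshold
    np.fill_diagonal(conflict, False)

    if n <= EXACT_COLLAPSE_LIMIT:
        best: tuple[int, ...] = ()
        for size in range(n, 0, -1):
            candidates = [
                subset for subset in combinations(order, size)
                if not any(conflict[i, j] for i, j in combinations(subset, 2))
            ]
            if candidates:
                best = min(candidates,
                           key=lambda s: [matrix.members[i] for i in s])
                break
        kept = sorted(matrix.members[i] for i in best)
        return CollapseResult(kept, len(kept), True)

    alive = set(range(n))
    while True:
        degrees = {i: sum(1 for j in alive if conflict[i, j]) for i in alive}
        worst = max(degrees.values(), default=0)
        if worst == 0:
            break
        victim = min((i for i in alive if degrees[i] == worst),
                     key=lambda i: matrix.members[i])
        alive.remove(victim)
    kept = sorted(matrix.members[i] for i in alive)
    return CollapseResult(kept, len(kept), False)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_lrt_tsv(path) -> list[tuple[str, float]]:
    """(gene_id, T) pairs from a two-column TSV with header."""
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        next(r)
        return [(row[0], float(row[1])) for row in r if row]


def write_results_tsv(results: Sequence[SelectionTestResult], path,
                      fdr: float = 0.1) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tT\tp\tq\tsignificant\n")
        for res in results:
            fh.write(f"{res.gene_id}\t{res.lrt_statistic:.6g}\t"
                     f"{res.p_value:.6g}\t{res.q_value:.6g}\t"
                     f"{int(res.q_value < fdr)}\n")


def read_identity_tsv(path, threshold: float = 0.97) -> FamilyIdentityMatrix:
    """Square identity-matrix TSV: header row/column of member ids."""
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh, delimiter="\t") if row]
    members = rows[0][1:]
    mat = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return FamilyIdentityMatrix(members, mat, threshold)
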