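"""Windowed GC and isochore statistics.

Isochore structure — long-range compositional heterogeneity — shows up
as excess variance of windowed GC relative to a compositionally
homogeneous genome.  For iid bases with GC proportion p, window GC has
standard deviation sqrt(p(1-p)/w), so quadrupling the window size
halves the SD; a slower decline flags heterogeneity.  The module also
computes GC at third codon positions (GC3), the high/low-GC3 split of
per-gene dN/dS with a rank-based two-sample test, pooled GC across
equal-count bins, and the gene-versus-flank GC correlation.

Window GC is computed over non-N bases, and windows with more than
``max_missing`` N are excluded — the 80%-complete-data convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

_GC_BYTES = frozenset(b"GCgc")


@dataclass
class GCWindowSpec:
    """Window size (bases), genome GC proportion, and the missing-data cap."""

    window_size: int
    gc: float = 0.41
    max_missing: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 <= self.gc <= 1):
            raise ValueError("gc must be in [0, 1]")


@dataclass
class GCProfile:
    """Per-window GC fractions plus the count of windows dropped for missing data."""

    spec: GCWindowSpec
    values: np.ndarray
    n_excluded: int = 0


@dataclass
class GeneComposition:
    gene_id: str
    gc3: float
    dnds: float
    gene_gc: float = float("nan")
    flank_gc: float | None = None


def _seq_to_arrays(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """(is_gc, is_n) boolean arrays from an A/C/G/T/N string."""
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    is_gc = (raw == ord("G")) | (raw == ord("C"))
    is_n = raw == ord("N")
    return is_gc, is_n


def window_gc(sequence: str, spec: GCWindowSpec) -> GCProfile:
    """Non-overlapping window GC, left to right.

    GC is computed over non-N bases; a window whose N fraction exceeds
    ``max_missing`` is excluded (and counted); the trailing partial
    window is discarded.
    """
    if not sequence:
        raise ValueError("cannot profile an empty sequence")
    w = spec.window_size
    is_gc, is_n = _seq_to_arrays(sequence)
    n_win = len(sequence) // w
    if n_win == 0:
        return GCProfile(spec, np.empty(0), 0)
    gc_counts = is_gc[:n_win * w].reshape(n_win, w).sum(axis=1)
    n_counts = is_n[:n_win * w].reshape(n_win, w).sum(axis=1)
    keep = n_counts <= spec.max_missing * w
    denom = w - n_counts[keep]
    values = np.where(denom > 0, gc_counts[keep] / np.maximum(denom, 1), 0.0)
    return GCProfile(spec, values, int((~keep).sum()))


def sd_profile(sequence: str,
               window_sizes: Sequence[int],
               gc: float = 0.41,
               max_missing: float = 0.2) -> list[tuple[int, float]]:
    """Population SD of window GC at each spatial scale.

    Scales with fewer than 2 usable windows are omitted with a warning.
    """
    out = []
    for w in window_sizes:
        profile = window_gc(sequence, GCWindowSpec(w, gc, max_missing))
        if len(profile.values) < 2:
            warnings.warn(f"fewer than 2 windows at size {w}; scale omitted")
            continue
        out.append((w, float(np.std(profile.values))))  # population SD
    return out


def expected_sd(spec: GCWindowSpec) -> float:
    """Homogeneous-genome (iid) expectation sqrt(p(1-p)/w).

    Quadrupling the window size halves this value exactly, the yardstick
    against which observed SD profiles are compared.
    """
    return float(np.sqrt(spec.gc * (1 - spec.gc) / spec.window_size))


def gc3(cds: str) -> float:
    """GC fraction at third codon positions of a coding sequence.

    The trailing partial codon is ignored; N at third positions is
    excluded from both numerator and denominator.
    """
    if len(cds) < 3:
        raise ValueError("CDS has no complete codon")
    thirds = cds.upper()[2:(len(cds) // 3) * 3:3]
    usable = [c for c in thirds if c != "N"]
    if not usable:
        raise ValueError("no usable third codon positions (all N)")
    return sum(c in "GC" for c in usable) / len(usable)


def partition_dnds(genes: Sequence[GeneComposition]
                   ) -> tuple[dict, dict, float, float]:
    """Split genes at the median GC3 and compare dN/dS between the halves.

    Ties at the median go to the low-GC3 group.  Returns (high summary,
    low summary, Mann-Whitney U, two-sided p); the exact null
    distribution is used when min(n, m) <= 8 and there are no ties in
    dN/dS, mid-rank asymptotics otherwise.
    """
    gc3s = np.array([g.gc3 for g in genes], dtype=float)
    med = float(np.median(gc3s))
    high = [g.dnds for g in genes if g.gc3 > med]
    low = [g.dnds for g in genes if g.gc3 <= med]
    if not high or np.all(gc3s == gc3s[0]):
        raise ValueError("degenerate GC3 split: no genes above the median")
    if len(high) < 2 or len(low) < 2:
        raise ValueError("need >= 2 genes per group after the median split")

    pooled = high + low
    if len(set(pooled)) == 1:
        u, p = len(high) * len(low) / 2, 1.0  # fully tied data
    else:
        method = ("exact" if min(len(high), len(low)) <= 8
                  and len(set(pooled)) == len(pooled) else "asymptotic")
        res = sps.mannwhitneyu(high, low, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(res.pvalue)
    summarize = lambda xs: {"n": len(xs), "median_dnds": float(np.median(xs))}
    return summarize(high), summarize(low), u, min(p, 1.0)


def gc_bins(items: Sequence[tuple[int, float]],
            n_bins: int,
            ordering: str = "by_length") -> list[tuple[tuple[int, int], float]]:
    """Pooled GC across equal-count bins of scaffolds or intergenic pieces.

    ``items`` are (length, gc) pairs; ``by_length`` sorts ascending by
    length, ``by_position`` keeps input order.  The remainder after
    equal division goes to the last bin.  Pooled GC is the
    length-weighted mean; the bin range reports (min, max) length.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(items) < n_bins:
        raise ValueError(f"{len(items)} items cannot fill {n_bins} bins")
    if ordering == "by_length":
        ordered = sorted(items, key=lambda it: it[0])
    elif ordering == "by_position":
        ordered = list(items)
    else:
        raise ValueError(f"unknown ordering {ordering!r}")
    per = len(ordered) // n_bins
    out = []
    for i in range(n_bins):
        chunk = ordered[i * per:] if i == n_bins - 1 else ordered[i * per:(i + 1) * per]
        total = sum(ln for ln, _gc in chunk)
        pooled = sum(g * ln for ln, g in chunk) / total
        out.append(((min(ln for ln, _ in chunk), max(ln for ln, _ in chunk)),
                    pooled))
    return out


def flank_gc_correlation(genes: Sequence[GeneComposition]
                         ) -> tuple[float, int]:
    """Pearson correlation between gene GC and 20-kb-flank GC.

    Genes with missing flank GC (flanks failing the 80%-complete rule)
    are excluded from n.
    """
    xs = [(g.gene_gc, g.flank_gc) for g in genes if g.flank_gc is not None]
    if len(xs) < 3:
        raise ValueError("need >= 3 genes with flank GC")
    gene = np.array([x for x, _ in xs])
    flank = np.array([y for _, y in xs])
    if np.std(gene) == 0 or np.std(flank) == 0:
        raise ValueError("zero variance in gene or flank GC")
    r = sps.pearsonr(gene, flank).statistic
    return float(r), len(xs)
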