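"""Pairwise alignment-block post-filters and assembly-QC statistics.

Homology-based scaffold ordering starts from pairwise whole-genome
alignment blocks (one scaffold segment aligned to one reference
chromosome).  Before any ordering is attempted the raw blocks are
post-filtered: short blocks and blocks with extreme expansion or
contraction between the two genomes are discarded, and isolated short
blocks that interrupt an otherwise consistent run of alignments to a
single chromosome are smoothed away as likely paralogous noise.

This module also carries two small assembly-quality statistics: the
fraction of ESTs covered above a threshold, and the Phred
quality-to-error-rate conversion.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

log = logging.getLogger("carapace")

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

BLOCK_TSV_COLUMNS = [
    "scaffold_id", "s_start", "s_end", "reference_id",
    "chrom", "r_start", "r_end", "strand", "aligned_bases",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment between a scaffold and a reference chromosome.

    Coordinates are 0-based, half-open on both sides.  ``aligned_bases``
    counts matched bases inside the block and can be smaller than either
    span when the alignment is gapped.
    """

    scaffold_id: str
    s_start: int
    s_end: int
    reference_id: str
    chrom: str
    r_start: int
    r_end: int
    strand: str
    aligned_bases: int

    def __post_init__(self) -> None:
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad scaffold span {self.s_start}..{self.s_end}")
        if not (0 <= self.r_start < self.r_end):
            raise ValueError(f"bad reference span {self.r_start}..{self.r_end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.aligned_bases > min(self.s_end - self.s_start,
                                    self.r_end - self.r_start):
            raise ValueError("aligned_bases exceeds both spans")

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start

    @property
    def r_span(self) -> int:
        return self.r_end - self.r_start


@dataclass
class FilterConfig:
    """Thresholds for block filtering and smoothing.

    min_span
        minimum scaffold-side span, inclusive (default 2000 bases).
    max_expansion
        symmetric span-ratio ceiling, exclusive (default 10x).
    smooth_max_span
        smoothing removes flanked singletons shorter than this
        (default 10000 bases).
    smooth_min_flank_blocks
        same-chromosome blocks required on each side of a removable
        singleton (default 1; the "large block" of flanking alignments is
        not quantified upstream, so this is a knob).
    """

    min_span: int = 2000
    max_expansion: float = 10.0
    smooth_max_span: int = 10000
    smooth_min_flank_blocks: int = 1

    def __post_init__(self) -> None:
        if self.min_span < 1:
            raise ValueError("min_span must be >= 1")
        if self.max_expansion <= 1:
            raise ValueError("max_expansion must be > 1")
        if self.smooth_max_span < 1:
            raise ValueError("smooth_max_span must be >= 1")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_blocks(blocks: Sequence[AlignmentBlock],
                  cfg: FilterConfig | None = None) -> list[AlignmentBlock]:
    """Keep blocks spanning >= min_span scaffold bases with span ratio < max_expansion.

    The expansion/contraction ratio is symmetric:
    max(ref_span/scaffold_span, scaffold_span/ref_span).  The span
    threshold is inclusive ("at least"), the ratio threshold strict
    ("<10X").  Input order is preserved; the input list is not modified.
    """
    cfg = cfg or FilterConfig()
    out = []
    for b in blocks:
        if b.s_span < cfg.min_span:
            continue
        ratio = max(b.r_span / b.s_span, b.s_span / b.r_span)
        if ratio >= cfg.max_expansion:
            continue
        out.append(b)
    return out


def _run_lengths(chroms: list[str]) -> list[int]:
    """Length of the consecutive same-chromosome run containing each index."""
    n = len(chroms)
    runs = [1] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and chroms[j + 1] == chroms[i]:
            j += 1
        for k in range(i, j + 1):
            runs[k] = j - i + 1
        i = j + 1
    return runs


def smooth_blocks(blocks: Sequence[AlignmentBlock],
                  cfg: FilterConfig | None = None) -> list[AlignmentBlock]:
    """Remove short single-block interruptions of a same-chromosome run.

    Within each (scaffold, reference) pair, ordered by scaffold start, a
    block is removed iff it spans fewer than ``smooth_max_span`` scaffold
    bases, it is the only consecutive block to its chromosome at that
    position, and it is flanked on both sides by blocks that agree on a
    single different chromosome.  Blocks at scaffold ends are never
    removed.  All removals are decided against the input neighbourhood,
    so the operation is idempotent.
    """
    cfg = cfg or FilterConfig()
    by_pair: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        by_pair.setdefault((b.scaffold_id, b.reference_id), []).append(b)

    removed: set[int] = set()
    for pair_blocks in by_pair.values():
        ordered = sorted(pair_blocks, key=lambda b: (b.s_start, b.s_end))
        chroms = [b.chrom for b in ordered]
        runs = _run_lengths(chroms)
        k = cfg.smooth_min_flank_blocks
        for i, b in enumerate(ordered):
            if b.s_span >= cfg.smooth_max_span or runs[i] != 1:
                continue
            left = chroms[:i]
            right = chroms[i + 1:]
            if len(left) < k or len(right) < k:
                continue
            flank = left[-1]
            if flank == b.chrom or right[0] != flank:
                continue
            if any(c != flank for c in left[-k:]) or any(c != flank for c in right[:k]):
                continue
            removed.add(id(b))
            log.debug("smoothing removed %s:%d-%d (%s, flanked by %s)",
                      b.scaffold_id, b.s_start, b.s_end, b.chrom, flank)
    return [b for b in blocks if id(b) not in removed]


# ---------------------------------------------------------------------------
# assembly QC statistics
# ---------------------------------------------------------------------------

def est_coverage_fraction(est_alignments: Iterable[tuple[str, int, int]],
                          min_fraction: float = 0.5) -> float:
    """Fraction of ESTs whose aligned portion reaches ``min_fraction``.

    ``est_alignments`` yields (est_id, est_length, aligned_bases) tuples.
    The per-EST threshold is inclusive ("at least 50% of the EST align").
    """
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    n = covered = 0
    for _est_id, est_length, aligned in est_alignments:
        if aligned > est_length:
            raise ValueError("aligned_bases exceeds est_length")
        n += 1
        if aligned / est_length >= min_fraction:
            covered += 1
    if n == 0:
        raise ValueError("coverage fraction undefined for empty input")
    return covered / n


def phred_error_rate(q: float) -> float:
    """Base-call error probability for a Phred quality score: 10^(-Q/10)."""
    if q < 0:
        raise ValueError("Phred quality must be non-negative")
    return 10.0 ** (-q / 10.0)


# ---------------------------------------------------------------------------
# I/O: alignment-block TSV dialect and PSL ingestion
# ---------------------------------------------------------------------------

def write_blocks_tsv(blocks: Iterable[AlignmentBlock], path) -> None:
    """Write blocks in the 9-column tab-separated dialect (with header)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(BLOCK_TSV_COLUMNS)
        for b in blocks:
            w.writerow([b.scaffold_id, b.s_start, b.s_end, b.reference_id,
                        b.chrom, b.r_start, b.r_end, b.strand, b.aligned_bases])


def read_blocks_tsv(path) -> list[AlignmentBlock]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != BLOCK_TSV_COLUMNS:
            raise ValueError(f"unexpected block TSV header: {header}")
        return [
            AlignmentBlock(row[0], int(row[1]), int(row[2]), row[3],
                           row[4], int(row[5]), int(row[6]), row[7], int(row[8]))
            for row in r if row
        ]


def read_psl(path, reference_id: str) -> list[AlignmentBlock]:
    """Map PSL records onto alignment blocks.

    The PSL query is taken as the scaffold and the target as the
    reference chromosome; ``aligned_bases`` comes from the matches column
    and strand from the strand column.  Header lines are skipped.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 17 or not fields[0].isdigit():
                continue  # psLayout header / separator lines
            matches = int(fields[0])
            strand = fields[8][0]
            q_name, q_start, q_end = fields[9], int(fields[11]), int(fields[12])
            t_name, t_start, t_end = fields[13], int(fields[15]), int(fields[16])
            out.append(AlignmentBlock(q_name, q_start, q_end, reference_id,
                                      t_name, t_start, t_end, strand, matches))
    return out
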