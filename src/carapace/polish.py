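"""Read-consensus indel polishing of a draft reference.

Deep short-read data mapped back onto a draft assembly exposes small
consensus errors.  The rule implemented here introduces 1-2 bp
insertions and deletions into the reference wherever the mapped reads
are unanimous: more than 3 and fewer than 200 reads cover the site, all
with mapping quality above 40, the indel lies more than 10 bases from
every read's alignment end, and every read disagrees with the reference
while agreeing with one another.  All thresholds are strict
(exclusive), exactly as stated.

Alignment and duplicate-read removal happen upstream; the input here is
a per-site pileup summary (the TSV dialect below is the contract
boundary).
"""

from __future__ import annotations

import csv
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

log = logging.getLogger("carapace")

PILEUP_TSV_COLUMNS = [
    "contig_id", "position", "kind", "length", "allele",
    "depth", "min_mapq", "min_dist_to_end", "unanimous",
]


@dataclass(frozen=True)
class PileupSite:
    """Summary of read evidence for one candidate indel site.

    ``position`` is 1-based.  ``min_mapq`` and ``min_dist_to_end`` are
    minima over the supporting reads, so the site-level thresholds are
    conservative.  ``unanimous`` means every read disagrees with the
    reference and all reads agree with one another.
    """

    contig_id: str
    position: int
    kind: str               # "ins" or "del"
    length: int
    allele: str             # inserted bases for "ins"; "" for "del"
    depth: int
    min_mapq: int
    min_dist_to_end: int
    unanimous: bool

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if self.kind not in ("ins", "del"):
            raise ValueError(f"kind must be 'ins' or 'del', got {self.kind!r}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.kind == "ins" and len(self.allele) != self.length:
            raise ValueError("insertion allele length must equal length")


@dataclass
class PolishConfig:
    """Evidence thresholds; all exclusive (>3, <200, >40, >10)."""

    min_reads: int = 3
    max_reads: int = 200
    min_mapq: int = 40
    min_dist: int = 10

    def __post_init__(self) -> None:
        if self.min_reads >= self.max_reads:
            raise ValueError("min_reads must be < max_reads")


def call_candidate_indels(sites: Sequence[PileupSite],
                          cfg: PolishConfig | None = None) -> list[PileupSite]:
    """Select sites meeting every evidence criterion.

    A site is called iff its length is 1 or 2, depth is strictly between
    min_reads and max_reads, minimum mapping quality and minimum
    distance-to-end strictly exceed their thresholds, and the reads are
    unanimous.  If more than one surviving site shares a (contig,
    position), all colliding sites are rejected with a warning.
    """
    cfg = cfg or PolishConfig()
    survivors = [
        s for s in sites
        if s.length in (1, 2)
        and cfg.min_reads < s.depth < cfg.max_reads
        and s.min_mapq > cfg.min_mapq
        and s.min_dist_to_end > cfg.min_dist
        and s.unanimous
    ]
    seen = Counter((s.contig_id, s.position) for s in survivors)
    colliding = {key for key, n in seen.items() if n > 1}
    for contig, pos in sorted(colliding):
        log.warning("rejecting colliding indel calls at %s:%d", contig, pos)
    return [s for s in survivors if (s.contig_id, s.position) not in colliding]


def apply_indels(sequence: str,
                 calls: Sequence[PileupSite]) -> tuple[str, int]:
    """Apply indel calls to a sequence; returns (edited sequence, edit count).

    Calls must be sorted by position and non-overlapping on the original
    coordinate system.  A deletion removes ``length`` bases starting at
    its (1-based) position; an insertion inserts ``allele`` after its
    position.  Edits are applied from the highest position down so
    lower coordinates stay valid.
    """
    n = len(sequence)
    prev_end = 0  # last original base consumed so far (1-based)
    for c in calls:
        if c.position <= prev_end:
            raise ValueError(
                f"calls out of order or overlapping at {c.contig_id}:{c.position} "
                f"(previous edit extends to {prev_end})")
        if c.kind == "del":
            if c.position + c.length - 1 > n:
                raise ValueError(f"deletion at {c.position} runs past sequence end")
            prev_end = c.position + c.length - 1
        else:
            if c.position > n:
                raise ValueError(f"insertion position {c.position} beyond sequence end")
            prev_end = c.position
    edited = sequence
    for c in reversed(calls):
        i = c.position - 1
        if c.kind == "del":
            edited = edited[:i] + edited[i + c.length:]
        else:
            edited = edited[:i + 1] + c.allele + edited[i + 1:]
    return edited, len(calls)


# ---------------------------------------------------------------------------
# I/O: pileup TSV dialect and edits TSV
# ---------------------------------------------------------------------------

def write_pileup_tsv(sites: Iterable[PileupSite], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PILEUP_TSV_COLUMNS)
        for s in sites:
            w.writerow([s.contig_id, s.position, s.kind, s.length, s.allele,
                        s.depth, s.min_mapq, s.min_dist_to_end,
                        int(s.unanimous)])


def read_pileup_tsv(path) -> list[PileupSite]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != PILEUP_TSV_COLUMNS:
            raise ValueError(f"unexpected pileup TSV header: {header}")
        return [
            PileupSite(row[0], int(row[1]), row[2], int(row[3]), row[4],
                       int(row[5]), int(row[6]), int(row[7]),
                       bool(int(row[8])))
            for row in r if row
        ]


def write_edits_tsv(calls: Iterable[PileupSite], path) -> None:
    """5-column record of the applied edits."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["contig_id", "position", "kind", "length", "allele"])
        for c in calls:
            w.writerow([c.contig_id, c.position, c.kind, c.length, c.allele])
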