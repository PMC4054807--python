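"""Truth-labeled synthetic data for every pipeline stage.

Each generator emulates the statistical structure one stage assumes —
an ancestral genome fragmented into scaffolds with known order and
orientation, derived reference genomes carrying segmental inversions
and translocations, noisy alignment blocks, read-consensus pileups with
implanted unanimous 1-2 bp indels, gene models with implanted defects,
and genomes of homogeneous or blockwise-varying GC — while carrying the
generating truth alongside, so recovery can be asserted exactly.  No
sequence-evolution or read-level simulation is attempted: divergence
between genomes is modelled only as rearrangement and span jitter,
which is what the ordering and screening rules are sensitive to.

All generators are pure functions of their arguments including the
seed: the same call returns byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .alignment import AlignmentBlock
from .orthologs import GeneModelAlignment, PRESERVED, LOST
from .polish import PileupSite

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rearranged segments are 1-100 kb, uniformly chosen
SEGMENT_MIN, SEGMENT_MAX = 1_000, 100_000


def _random_seq(rng: np.random.Generator, length: int,
                p: Sequence[float] | None = None) -> str:
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# truth sets: ancestral genome, derived references, fragmented scaffolds
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Free knobs of the alignment/pileup noise (not estimates of anything).

    drop_rate
        probability a true alignment block is lost.
    spurious_rate
        expected spurious (<10 kb, wrong-chromosome) blocks per scaffold.
    expansion_jitter
        multiplicative range around 1 applied to reference spans.
    indel_error_rate
        expected spurious pileup sites per contig base.
    """

    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    expansion_jitter: tuple[float, float] = (1.0, 1.0)
    indel_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.drop_rate <= 1):
            raise ValueError("drop_rate must be in [0, 1]")
        if self.spurious_rate < 0:
            raise ValueError("spurious_rate must be >= 0")
        lo, hi = self.expansion_jitter
        if not (0 < lo <= hi):
            raise ValueError("expansion_jitter must be a positive range")
        if not (0 <= self.indel_error_rate <= 1):
            raise ValueError("indel_error_rate must be in [0, 1]")


@dataclass
class _RefSegment:
    """One reference-chromosome segment and its ancestral source interval."""

    chrom: str
    r_start: int
    r_len: int
    a_start: int
    a_end: int
    strand: str


@dataclass
class TruthSet:
    """An ancestral genome, derived references, and its fragmentation truth."""

    ancestral_genome: str
    references: dict[str, list[tuple[str, str]]]
    scaffolds: list[tuple[str, str]]
    true_layout: list[list[tuple[str, str]]]
    seed: int
    scaffold_intervals: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    reference_maps: dict[str, list[_RefSegment]] = field(default_factory=dict)

    @property
    def scaffold_lengths(self) -> dict[str, int]:
        return {sid: len(seq) for sid, seq in self.scaffolds}

    def true_adjacencies(self) -> set[tuple[str, str, str, str]]:
        """Canonical (first, second, fo, so) tuples of the generating layout."""
        from .ordering import canonical_pair
        out = set()
        for group in self.true_layout:
            for (a, oa), (b, ob) in zip(group, group[1:]):
                out.add(canonical_pair(a, oa, b, ob))
        return out


def make_truth_set(seed: int, genome_length: int, n_references: int,
                   n_scaffolds: int, rearrangement_rate: float = 0.0
                   ) -> TruthSet:
    """Generate an ancestral genome, derived references, and scaffolds.

    The ancestral genome is fragmented at uniform random breakpoints
    into ``n_scaffolds`` scaffolds, each randomly oriented (sequences
    are stored as assembled, i.e. reverse-complemented when the layout
    orientation is '-') and shuffled.  Each reference is a copy of the
    ancestral genome with Poisson(rate x length in Mb) segmental
    inversions/translocations (segments 1-100 kb) and mild per-segment
    span jitter.
    """
    if genome_length < 1 or n_scaffolds < 1 or n_references < 1:
        raise ValueError("lengths and counts must be positive")
    if genome_length < n_scaffolds:
        raise ValueError("genome_length must be >= n_scaffolds")
    if rearrangement_rate < 0:
        raise ValueError("rearrangement_rate must be >= 0")
    rng = np.random.default_rng(seed)
    ancestral = _random_seq(rng, genome_length)

    # fragmentation at distinct uniform breakpoints
    if n_scaffolds > 1:
        cuts = np.sort(rng.choice(genome_length - 1, size=n_scaffolds - 1,
                                  replace=False) + 1)
    else:
        cuts = np.empty(0, dtype=int)
    bounds = [0, *cuts.tolist(), genome_length]
    width = len(str(n_scaffolds))
    layout: list[tuple[str, str]] = []
    intervals: dict[str, tuple[int, int, str]] = {}
    scaffolds: list[tuple[str, str]] = []
    for i in range(n_scaffolds):
        sid = f"scaf{i + 1:0{width}d}"
        a, b = bounds[i], bounds[i + 1]
        # a lone scaffold has no order signal; keep the identity orientation
        orient = "+" if n_scaffolds == 1 else ("+" if rng.random() < 0.5 else "-")
        piece = ancestral[a:b]
        scaffolds.append((sid, piece if orient == "+" else _revcomp(piece)))
        layout.append((sid, orient))
        intervals[sid] = (a, b, orient)
    perm = rng.permutation(n_scaffolds)
    scaffolds = [scaffolds[i] for i in perm]

    references: dict[str, list[tuple[str, str]]] = {}
    maps: dict[str, list[_RefSegment]] = {}
    for r in range(n_references):
        ref_id = f"ref{r + 1}"
        segments = _rearrange(rng, genome_length, rearrangement_rate)
        ref_segs: list[_RefSegment] = []
        parts: list[str] = []
        pos = 0
        for a_start, a_end, strand in segments:
            span = a_end - a_start
            factor = 1.0
            if rearrangement_rate > 0:
                factor = rng.uniform(0.95, 1.05)
            r_len = max(1, round(span * factor))
            piece = ancestral[a_start:a_end]
            if strand == "-":
                piece = _revcomp(piece)
            if r_len < span:
                piece = piece[:r_len]
            elif r_len > span:
                piece = piece + _random_seq(rng, r_len - span)
            ref_segs.append(_RefSegment("chr1", pos, r_len, a_start, a_end, strand))
            parts.append(piece)
            pos += r_len
        references[ref_id] = [("chr1", "".join(parts))]
        maps[ref_id] = ref_segs

    return TruthSet(ancestral, references, scaffolds, [layout], seed,
                    intervals, maps)


def _rearrange(rng: np.random.Generator, length: int,
               rate: float) -> list[tuple[int, int, str]]:
    """Segment list (ancestral start, end, strand), in reference order,
    after random inversions and translocations of 1-100 kb intervals.

    Events are drawn in reference coordinates of the current genome
    (cumulative segment spans), so repeated events compose correctly.
    """
    segments: list[tuple[int, int, str]] = [(0, length, "+")]
    n_events = rng.poisson(rate * length / 1e6) if rate > 0 else 0
    for _ in range(n_events):
        seg_len = int(rng.integers(SEGMENT_MIN, min(SEGMENT_MAX, length) + 1))
        start = int(rng.integers(0, max(1, length - seg_len)))
        segments = _cut_at_ref(segments, start)
        segments = _cut_at_ref(segments, start + seg_len)
        lo = hi = 0
        pos = 0
        for i, (a, b, _s) in enumerate(segments):
            if pos == start:
                lo = i
            pos += b - a
            if pos == start + seg_len:
                hi = i + 1
                break
        piece = segments[lo:hi]
        if rng.random() < 0.5:  # inversion in place
            piece = [(a, b, "-" if s == "+" else "+") for a, b, s in reversed(piece)]
            segments = segments[:lo] + piece + segments[hi:]
        else:  # translocation to a random junction of the remainder
            rest = segments[:lo] + segments[hi:]
            at = int(rng.integers(0, len(rest) + 1))
            segments = rest[:at] + piece + rest[at:]
    return segments


def _cut_at_ref(segments: list[tuple[int, int, str]], ref_pos: int
                ) -> list[tuple[int, int, str]]:
    """Split the segment containing reference position ``ref_pos``."""
    out: list[tuple[int, int, str]] = []
    pos = 0
    for a, b, s in segments:
        span = b - a
        if pos < ref_pos < pos + span:
            off = ref_pos - pos
            if s == "+":
                out.extend([(a, a + off, s), (a + off, b, s)])
            else:
                out.extend([(b - off, b, s), (a, b - off, s)])
        else:
            out.append((a, b, s))
        pos += span
    return out


# ---------------------------------------------------------------------------
# alignment-block simulation
# ---------------------------------------------------------------------------

def simulate_alignments(truth: TruthSet, noise: NoiseModel | None = None,
                        seed: int = 0) -> list[AlignmentBlock]:
    """True scaffold-to-reference blocks plus dropout/jitter/spurious noise.

    For every scaffold x reference the scaffold's image in the reference
    coordinate system is emitted as one block per rearrangement segment
    it overlaps, unless dropped with probability ``drop_rate``.
    Reference spans are scaled by a factor drawn from
    ``expansion_jitter``.  Poisson(``spurious_rate``) short (<10 kb)
    blocks per scaffold are added on decoy chromosomes absent from the
    true map.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    blocks: list[AlignmentBlock] = []
    lo_j, hi_j = noise.expansion_jitter

    for sid, seq in truth.scaffolds:
        a, b, orient = truth.scaffold_intervals[sid]
        for ref_id, segs in truth.reference_maps.items():
            for seg in segs:
                x, y = max(a, seg.a_start), min(b, seg.a_end)
                if x >= y:
                    continue
                if rng.random() < noise.drop_rate:
                    continue
                span = seg.a_end - seg.a_start
                # proportional image of [x, y) inside the (jittered) segment
                if seg.strand == "+":
                    r0 = seg.r_start + int(np.floor((x - seg.a_start) / span * seg.r_len))
                    r1 = seg.r_start + int(np.ceil((y - seg.a_start) / span * seg.r_len))
                else:
                    r0 = seg.r_start + int(np.floor((seg.a_end - y) / span * seg.r_len))
                    r1 = seg.r_start + int(np.ceil((seg.a_end - x) / span * seg.r_len))
                factor = rng.uniform(lo_j, hi_j) if (lo_j, hi_j) != (1.0, 1.0) else 1.0
                r1 = r0 + max(1, round((r1 - r0) * factor))
                s0, s1 = (x - a, y - a) if orient == "+" else (b - y, b - x)
                strand = "+" if orient == seg.strand else "-"
                blocks.append(AlignmentBlock(
                    sid, s0, s1, ref_id, seg.chrom, r0, r1, strand,
                    min(s1 - s0, r1 - r0)))
        for _ in range(rng.poisson(noise.spurious_rate)):
            span = int(rng.integers(500, 10_000))
            s_span = min(span, len(seq))
            s0 = int(rng.integers(0, len(seq) - s_span + 1))
            ref_id = f"ref{int(rng.integers(1, len(truth.references) + 1))}"
            chrom = f"chrU{int(rng.integers(1, 6))}"
            r0 = int(rng.integers(0, 10_000_000))
            strand = "+" if rng.random() < 0.5 else "-"
            blocks.append(AlignmentBlock(
                sid, s0, s0 + s_span, ref_id, chrom, r0, r0 + span, strand,
                min(s_span, span)))
    return blocks


# ---------------------------------------------------------------------------
# pileup simulation (single-factor violation fixtures)
# ---------------------------------------------------------------------------

TRUE_LABEL = "true"
VIOLATION_LABELS = ("depth", "mapq", "dist_to_end", "unanimous", "length")


def simulate_pileup(contig: str,
                    true_indels: Sequence[tuple[int, str, int, str]],
                    noise: NoiseModel | None = None,
                    seed: int = 0,
                    contig_id: str = "contig1"
                    ) -> list[tuple[PileupSite, str]]:
    """Pileup sites for implanted indels plus single-violation noise sites.

    Each true (position, kind, length, allele) indel yields a site
    passing all five calling criteria (4-199 unanimous reads, MAPQ > 40,
    > 10 bases from every read end).  Poisson(indel_error_rate x contig
    length) noise sites each violate exactly one criterion, labeled with
    the criterion violated; true sites are labeled "true".
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    sites: list[tuple[PileupSite, str]] = []
    used = set()
    for pos, kind, length, allele in true_indels:
        if not (1 <= pos <= len(contig)):
            raise ValueError(f"indel position {pos} outside contig")
        if length not in (1, 2):
            raise ValueError("indel length must be 1 or 2")
        sites.append((PileupSite(
            contig_id, pos, kind, length,
            allele if kind == "ins" else "",
            depth=int(rng.integers(4, 200)),
            min_mapq=int(rng.integers(41, 61)),
            min_dist_to_end=int(rng.integers(11, 61)),
            unanimous=True), TRUE_LABEL))
        used.add(pos)

    n_noise = rng.poisson(noise.indel_error_rate * len(contig))
    free = [p for p in range(1, len(contig) + 1) if p not in used]
    for _ in range(min(n_noise, len(free))):
        idx = int(rng.integers(0, len(free)))
        pos = free.pop(idx)
        kind = "ins" if rng.random() < 0.5 else "del"
        length = int(rng.integers(1, 3))
        depth = int(rng.integers(4, 200))
        mapq = int(rng.integers(41, 61))
        dist = int(rng.integers(11, 61))
        unanimous = True
        label = VIOLATION_LABELS[int(rng.integers(0, len(VIOLATION_LABELS)))]
        if label == "depth":
            depth = int(rng.integers(0, 4)) if rng.random() < 0.5 \
                else int(rng.integers(200, 300))
        elif label == "mapq":
            mapq = int(rng.integers(0, 41))
        elif label == "dist_to_end":
            dist = int(rng.integers(0, 11))
        elif label == "unanimous":
            unanimous = False
        elif label == "length":
            length = 3
        allele = _random_seq(rng, length) if kind == "ins" else ""
        sites.append((PileupSite(contig_id, pos, kind, length, allele,
                                 depth, mapq, dist, unanimous), label))
    sites.sort(key=lambda t: t[0].position)
    return sites


# ---------------------------------------------------------------------------
# gene-model simulation (one implanted defect per model at most)
# ---------------------------------------------------------------------------

DEFECT_KINDS = ("premature_stop", "lone_frameshift", "compensated_frameshift",
                "broken_splice", "large_gap", "split_chain")

# clean-model condition each defect must break ("clean" = breaks none)
DEFECT_CONDITION = {
    "premature_stop": "elements_preserved",
    "broken_splice": "elements_preserved",
    "lone_frameshift": "frameshifts_ok",
    "compensated_frameshift": "clean",
    "large_gap": "no_significant_gaps",
    "split_chain": "single_chain",
}

CLEAN_LABEL = "clean"


def simulate_gene_models(n_genes: int,
                         defect_rates: dict[str, float] | None = None,
                         seed: int = 0,
                         compensation_window: int = 30
                         ) -> list[tuple[GeneModelAlignment, str]]:
    """Remapped gene models, each with at most one implanted defect.

    The truth label is the clean-model condition the model must fail
    ("clean" when it must pass, including compensated frameshifts whose
    compensating indel lies within ``compensation_window`` bases).
    """
    defect_rates = defect_rates or {}
    for kind in defect_rates:
        if kind not in DEFECT_KINDS:
            raise ValueError(f"unknown defect kind {kind!r}")
    if any(not (0 <= v <= 1) for v in defect_rates.values()):
        raise ValueError("defect rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[tuple[GeneModelAlignment, str]] = []
    for i in range(n_genes):
        n_exons = int(rng.integers(1, 9))
        codons = rng.integers(20, 200, size=n_exons)
        exons: list[tuple[int, int]] = []
        pos = int(rng.integers(0, 10_000))
        for c in codons:
            exons.append((pos, pos + int(c) * 3))
            pos += int(c) * 3 + int(rng.integers(100, 2000))  # intron
        cds_length = sum(e - s for s, e in exons)
        model = GeneModelAlignment(
            gene_id=f"gene{i + 1:04d}", model_id=f"model{i + 1:04d}.1",
            species_id="target", exons=exons, chain_count=1,
            net_kind="reciprocal_best" if rng.random() < 0.5 else "syntenic",
            element_status={el: PRESERVED for el in
                            ("donor", "acceptor", "start_codon", "stop_codon")})

        u = rng.random()
        label = CLEAN_LABEL
        acc = 0.0
        for kind in DEFECT_KINDS:
            acc += defect_rates.get(kind, 0.0)
            if u < acc:
                label = _implant(model, kind, rng, compensation_window)
                break
        out.append((model, label))
    return out


def _implant(model: GeneModelAlignment, kind: str,
             rng: np.random.Generator, window: int) -> str:
    pos = int(rng.integers(3, max(4, model.cds_length - window - 3)))
    if kind == "premature_stop":
        model.element_status["stop_codon"] = LOST
    elif kind == "broken_splice":
        el = "donor" if rng.random() < 0.5 else "acceptor"
        model.element_status[el] = LOST
    elif kind == "lone_frameshift":
        model.indel_events.append((pos, int(rng.choice([-2, -1, 1, 2]))))
    elif kind == "compensated_frameshift":
        shift = int(rng.choice([-1, 1]))
        gap = int(rng.integers(3, window + 1))
        model.indel_events.extend([(pos, shift), (pos + gap, -shift)])
    elif kind == "large_gap":
        model.gap_events.append((pos, int(rng.integers(91, 201))))
    elif kind == "split_chain":
        model.chain_count = 2
    return DEFECT_CONDITION[kind]


# ---------------------------------------------------------------------------
# GC genome simulation
# ---------------------------------------------------------------------------

def simulate_gc_genome(length: int, mode: str = "homogeneous",
                       gc: float = 0.41, block_length: int = 100_000,
                       gc_spread: float = 0.1, seed: int = 0) -> str:
    """Genome with iid (homogeneous) or blockwise-varying GC composition.

    Homogeneous: every base iid with P(G or C) = gc.  Blockwise: each
    ``block_length`` block draws its own GC uniformly from
    gc +/- gc_spread, clipped to [0, 1] — a caricature of isochores.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not (0 <= gc <= 1):
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if mode == "homogeneous":
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return _random_seq(rng, length, p)
    if mode != "blockwise":
        raise ValueError(f"unknown mode {mode!r}")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    parts = []
    done = 0
    while done < length:
        n = min(block_length, length - done)
        g = float(np.clip(rng.uniform(gc - gc_spread, gc + gc_spread), 0, 1))
        parts.append(_random_seq(rng, n, [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]))
        done += n
    return "".join(parts)


# ---------------------------------------------------------------------------
# writers (FASTA 60-column wrap; truth TSV)
# ---------------------------------------------------------------------------

def write_fasta(records: Sequence[tuple[str, str]], path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=sid, description="")
                 for sid, seq in records], str(path), "fasta")


def write_truth_tsv(truth: TruthSet, path) -> None:
    """Generating layout: scaffold_id, group_id, rank, orientation."""
    with open(path, "w") as fh:
        fh.write("scaffold_id\tgroup_id\trank\torientation\n")
        for g, group in enumerate(truth.true_layout, start=1):
            for rank, (sid, orient) in enumerate(group, start=1):
                fh.write(f"{sid}\ttrue{g}\t{rank}\t{orient}\n")


def write_lengths_tsv(lengths: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tlength\n")
        for sid, ln in sorted(lengths.items()):
            fh.write(f"{sid}\t{ln}\n")
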