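"""Homology-consensus scaffold ordering and AGP emission.

Given filtered alignment blocks against several reference genomes, each
scaffold is first placed at a single position and orientation per
reference (majority-chromosome rule, midpoint of the union span).
Consecutive placements on a reference chromosome yield ordered,
oriented adjacency relations; relations are canonicalized so a relation
and its reverse-complement merge, and their per-reference support is
accumulated.  A relation survives the vote when at least ``k`` distinct
references support the same order and orientation (k=3 of 4 by
default).  Surviving relations are linked into ordered groups
(super-scaffolds) by a support-weighted greedy path cover, and the
groups are written as AGP objects whose inter-scaffold gaps are
annotated as 'contig' gaps with linkage 'no' — ordering by homology
carries no spanning-clone evidence.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import AlignmentBlock

log = logging.getLogger("carapace")

_FLIP = {"+": "-", "-": "+"}

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """A scaffold's single position on one reference.

    ``position`` is the midpoint (floor) of the union span of the
    scaffold's blocks on its majority chromosome; ``placed_fraction`` is
    the fraction of the scaffold's aligned bases on that chromosome;
    ``aligned_bases`` is the scaffold's total aligned bases on that
    reference (used downstream as a tie-break weight).
    """

    scaffold_id: str
    reference_id: str
    chrom: str
    position: int
    orientation: str
    placed_fraction: float
    aligned_bases: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.placed_fraction <= 1):
            raise ValueError("placed_fraction must be in (0, 1]")
        if self.orientation not in ("+", "-"):
            raise ValueError("orientation must be '+' or '-'")


@dataclass
class AdjacencyRelation:
    """A canonicalized ordered, oriented scaffold pair.

    Canonical form has ``first_id < second_id``; the reverse-complement
    reading (swap ids, flip both orientations, reverse order) maps to
    the same canonical relation.  ``weight`` accumulates aligned bases
    of the participating placements across supporting references.
    """

    first_id: str
    second_id: str
    first_orient: str
    second_orient: str
    supporting_refs: set[str] = field(default_factory=set)
    weight: int = 0

    @property
    def support(self) -> int:
        return len(self.supporting_refs)

    def key(self) -> tuple[str, str, str, str]:
        return (self.first_id, self.second_id, self.first_orient, self.second_orient)


def canonical_pair(first_id: str, first_orient: str,
                   second_id: str, second_orient: str
                   ) -> tuple[str, str, str, str]:
    """Canonical (first, second, fo, so) for an ordered, oriented pair."""
    if first_id <= second_id:
        return (first_id, second_id, first_orient, second_orient)
    return (second_id, first_id, _FLIP[second_orient], _FLIP[first_orient])


@dataclass
class ConsensusConfig:
    """Voting and output parameters.

    min_support
        distinct references that must agree on an adjacency (default 3,
        mirroring 3-of-4 references).
    min_place_fraction
        majority-chromosome fraction required to place a scaffold at all
        (default 0.6; must exceed 0.5 so the majority chromosome is
        unique).
    gap_length
        AGP gap size between linked scaffolds (default 100; homology
        ordering estimates no gap sizes).
    max_adjacency_gap
        optional cap on the reference distance between consecutive
        placements before an adjacency is recorded (None = no cap).
    """

    min_support: int = 3
    n_references: int = 4
    min_place_fraction: float = 0.6
    gap_length: int = 100
    max_adjacency_gap: int | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.min_support <= self.n_references):
            raise ValueError("min_support must be in [1, n_references]")
        if not (0.5 < self.min_place_fraction <= 1):
            raise ValueError("min_place_fraction must be in (0.5, 1]")


@dataclass
class OrderedGroup:
    """An ordered, oriented run of scaffolds (a super-scaffold)."""

    group_id: str
    members: list[tuple[str, str, int]]  # (scaffold_id, orientation, length)
    unplaced: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("group must have at least one member")


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def place_scaffolds(blocks: Sequence[AlignmentBlock],
                    cfg: ConsensusConfig | None = None) -> list[Placement]:
    """One placement per (scaffold, reference) with a clear majority chromosome.

    Aligned bases are summed per chromosome; if the top chromosome holds
    at least ``min_place_fraction`` of the scaffold's aligned bases on
    that reference, the scaffold is placed at the floor-midpoint of the
    union span of its blocks there, oriented by the strand carrying the
    majority of those aligned bases.  Ambiguous scaffolds are left
    unplaced on that reference.
    """
    cfg = cfg or ConsensusConfig()
    grouped: dict[tuple[str, str], list[AlignmentBlock]] = {}
    for b in blocks:
        grouped.setdefault((b.scaffold_id, b.reference_id), []).append(b)

    placements = []
    for (scaf, ref), bs in sorted(grouped.items()):
        per_chrom: dict[str, int] = {}
        for b in bs:
            per_chrom[b.chrom] = per_chrom.get(b.chrom, 0) + b.aligned_bases
        total = sum(per_chrom.values())
        if total == 0:
            continue
        top_chrom = max(per_chrom, key=lambda c: (per_chrom[c], c))
        frac = per_chrom[top_chrom] / total
        if frac < cfg.min_place_fraction:
            continue
        on_top = [b for b in bs if b.chrom == top_chrom]
        lo = min(b.r_start for b in on_top)
        hi = max(b.r_end for b in on_top)
        plus = sum(b.aligned_bases for b in on_top if b.strand == "+")
        minus = sum(b.aligned_bases for b in on_top if b.strand == "-")
        orient = "+" if plus >= minus else "-"
        placements.append(Placement(scaf, ref, top_chrom, (lo + hi) // 2,
                                    orient, frac, total))
    return placements


# ---------------------------------------------------------------------------
# adjacency derivation and voting
# ---------------------------------------------------------------------------

def derive_adjacencies(placements: Sequence[Placement],
                       cfg: ConsensusConfig | None = None
                       ) -> list[AdjacencyRelation]:
    """Adjacency relations from consecutive placements per (reference, chromosome)."""
    cfg = cfg or ConsensusConfig()
    lanes: dict[tuple[str, str], list[Placement]] = {}
    for p in placements:
        lanes.setdefault((p.reference_id, p.chrom), []).append(p)

    merged: dict[tuple[str, str, str, str], AdjacencyRelation] = {}
    for (ref, chrom), ps in sorted(lanes.items()):
        ps.sort(key=lambda p: (p.position, p.scaffold_id))
        for i in range(len(ps) - 1):
            a, b = ps[i], ps[i + 1]
            if a.position == b.position:
                log.warning("tie at %s:%s position %d between %s and %s; "
                            "ordering lexicographically",
                            ref, chrom, a.position, a.scaffold_id, b.scaffold_id)
            if (cfg.max_adjacency_gap is not None
                    and b.position - a.position > cfg.max_adjacency_gap):
                continue
            key = canonical_pair(a.scaffold_id, a.orientation,
                                 b.scaffold_id, b.orientation)
            rel = merged.get(key)
            if rel is None:
                rel = AdjacencyRelation(key[0], key[1], key[2], key[3])
                merged[key] = rel
            rel.supporting_refs.add(ref)
            rel.weight += a.aligned_bases + b.aligned_bases
    return [merged[k] for k in sorted(merged)]


def vote_adjacencies(relations: Sequence[AdjacencyRelation],
                     cfg: ConsensusConfig | None = None
                     ) -> list[AdjacencyRelation]:
    """Keep relations on which at least ``min_support`` references agree."""
    cfg = cfg or ConsensusConfig()
    kept = [r for r in relations if r.support >= cfg.min_support]
    kept.sort(key=lambda r: (r.first_id, r.second_id,
                             r.first_orient, r.second_orient))
    return kept


# ---------------------------------------------------------------------------
# group linking (support-weighted greedy path cover)
# ---------------------------------------------------------------------------

def _relation_ends(rel: AdjacencyRelation
                   ) -> tuple[tuple[str, str], tuple[str, str]]:
    """The two scaffold ends a relation joins.

    Reading "first then second": the link leaves the first scaffold's
    right end when it sits '+' (its left end when '-') and enters the
    second scaffold's left end when it sits '+' (right end when '-').
    """
    end_a = (rel.first_id, "R" if rel.first_orient == "+" else "L")
    end_b = (rel.second_id, "L" if rel.second_orient == "+" else "R")
    return end_a, end_b


def build_groups(relations: Sequence[AdjacencyRelation],
                 scaffold_lengths: Mapping[str, int],
                 cfg: ConsensusConfig | None = None) -> list[OrderedGroup]:
    """Link voted relations into ordered groups.

    Each scaffold is a segment with two ends; a relation joins one end
    of each scaffold.  Relations are admitted in decreasing
    (support, weight) order; a relation whose required end is already
    taken is dropped with a warning, so surviving links form simple
    paths and cycles.  Each cycle is broken at its weakest relation.
    Paths become groups in a canonical direction (first member id
    lexicographically <= last member id); scaffolds in no link are
    returned as singleton groups flagged unplaced.
    """
    cfg = cfg or ConsensusConfig()
    for r in relations:
        for sid in (r.first_id, r.second_id):
            if sid not in scaffold_lengths:
                raise KeyError(f"relation references unknown scaffold {sid!r}")

    order = sorted(relations,
                   key=lambda r: (-r.support, -r.weight,
                                  r.first_id, r.second_id,
                                  r.first_orient, r.second_orient))
    taken: dict[tuple[str, str], AdjacencyRelation] = {}
    accepted: list[AdjacencyRelation] = []
    for rel in order:
        end_a, end_b = _relation_ends(rel)
        if end_a in taken or end_b in taken:
            log.warning("dropping conflicting adjacency %s(%s)->%s(%s) "
                        "(support %d): end already linked",
                        rel.first_id, rel.first_orient,
                        rel.second_id, rel.second_orient, rel.support)
            continue
        taken[end_a] = rel
        taken[end_b] = rel
        accepted.append(rel)

    # components over scaffolds; a component with as many links as
    # scaffolds is a cycle and loses its weakest link
    adj: dict[str, list[AdjacencyRelation]] = {}
    for rel in accepted:
        adj.setdefault(rel.first_id, []).append(rel)
        adj.setdefault(rel.second_id, []).append(rel)

    visited: set[str] = set()
    final_links: list[AdjacencyRelation] = []
    for start in sorted(adj):
        if start in visited:
            continue
        comp_nodes, comp_rels, stack = {start}, set(), [start]
        while stack:
            node = stack.pop()
            visited.add(node)
            for rel in adj[node]:
                comp_rels.add(id(rel))
                for other in (rel.first_id, rel.second_id):
                    if other not in comp_nodes:
                        comp_nodes.add(other)
                        stack.append(other)
        rels = [r for r in accepted if id(r) in comp_rels]
        if len(rels) == len(comp_nodes):  # cycle
            weakest = min(rels, key=lambda r: (r.support, r.weight,
                                               r.first_id, r.second_id))
            log.warning("breaking cycle at %s->%s (support %d)",
                        weakest.first_id, weakest.second_id, weakest.support)
            rels.remove(weakest)
        final_links.extend(rels)

    joins: dict[tuple[str, str], tuple[str, str]] = {}
    for rel in final_links:
        end_a, end_b = _relation_ends(rel)
        joins[end_a] = end_b
        joins[end_b] = end_a

    linked = {r.first_id for r in final_links} | {r.second_id for r in final_links}
    paths: list[list[tuple[str, str]]] = []
    seen: set[str] = set()
    for sid in sorted(linked):
        if sid in seen:
            continue
        # walk to a free end, then traverse the whole path
        entry = (sid, "L")
        if entry in joins or (sid, "R") in joins:
            # find the free end of this path
            node, side = sid, "L"
            while (node, side) in joins:
                node, other_side = joins[(node, side)]
                side = "R" if other_side == "L" else "L"
            # (node, side) is free; enter the path through it
            members: list[tuple[str, str]] = []
            cur, enter = node, side
            while True:
                seen.add(cur)
                members.append((cur, "+" if enter == "L" else "-"))
                exit_end = (cur, "R" if enter == "L" else "L")
                if exit_end not in joins:
                    break
                cur, enter = joins[exit_end]
            if members[0][0] > members[-1][0]:
                members = [(s, _FLIP[o]) for s, o in reversed(members)]
            paths.append(members)

    paths.sort(key=lambda m: m[0][0])
    groups = [
        OrderedGroup(f"group{i}",
                     [(s, o, scaffold_lengths[s]) for s, o in members])
        for i, members in enumerate(paths, start=1)
    ]
    n = len(groups)
    for j, sid in enumerate(sorted(set(scaffold_lengths) - linked), start=1):
        groups.append(OrderedGroup(f"group{n + j}",
                                   [(sid, "+", scaffold_lengths[sid])],
                                   unplaced=True))
    return groups


# ---------------------------------------------------------------------------
# AGP I/O (v1.1 dialect: component 'W' lines, 'U' contig gaps, linkage 'no')
# ---------------------------------------------------------------------------

def write_agp(groups: Sequence[OrderedGroup],
              cfg: ConsensusConfig | None = None,
              out=None, include_singletons: bool = False) -> str | None:
    """Emit AGP for multi-member groups (singletons only on request).

    Coordinates are 1-based inclusive; part numbers run from 1; gap
    lines are 'U' gaps of ``cfg.gap_length`` typed 'contig' with linkage
    'no'.  ``out`` may be a path or a text handle; with ``out=None``
    the AGP text is returned.
    """
    cfg = cfg or ConsensusConfig()
    lines = ["##agp-version\t1.1"]
    for g in groups:
        if len(g.members) < 2 and not include_singletons:
            continue
        pos = 0
        part = 0
        for i, (sid, orient, length) in enumerate(g.members):
            if length <= 0:
                raise ValueError(f"zero-length component {sid!r}")
            if i > 0:
                part += 1
                lines.append("\t".join(map(str, [
                    g.group_id, pos + 1, pos + cfg.gap_length, part,
                    "U", cfg.gap_length, "contig", "no"])))
                pos += cfg.gap_length
            part += 1
            lines.append("\t".join(map(str, [
                g.group_id, pos + 1, pos + length, part,
                "W", sid, 1, length, orient])))
            pos += length
    text = "\n".join(lines) + "\n"
    if out is None:
        return text
    if hasattr(out, "write"):
        out.write(text)
    else:
        with open(out, "w") as fh:
            fh.write(text)
    return None


def read_agp(source) -> list[OrderedGroup]:
    """Parse an AGP file written by :func:`write_agp` (tolerant reader).

    Validates coordinate continuity and consecutive part numbers,
    naming the offending line on failure.  Gap lines with linkage 'yes'
    are accepted but flagged as non-conforming to this dialect.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and "\n" in source:
        text = source
    else:
        with open(source) as fh:
            text = fh.read()

    objects: dict[str, list[tuple[str, str, int]]] = {}
    state: dict[str, tuple[int, int]] = {}  # object -> (last_end, last_part)
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        obj, beg, end, part = f[0], int(f[1]), int(f[2]), int(f[3])
        last_end, last_part = state.get(obj, (0, 0))
        if beg != last_end + 1:
            raise ValueError(f"line {lineno}: object_beg {beg} != previous "
                             f"object_end {last_end} + 1")
        if part != last_part + 1:
            raise ValueError(f"line {lineno}: part_number {part} not consecutive")
        state[obj] = (end, part)
        if f[4] == "W":
            sid, comp_beg, comp_end, orient = f[5], int(f[6]), int(f[7]), f[8]
            length = comp_end - comp_beg + 1
            if end - beg + 1 != length:
                raise ValueError(f"line {lineno}: object span != component span")
            objects.setdefault(obj, []).append((sid, orient, length))
        elif f[4] in ("U", "N"):
            if f[7] != "no":
                log.warning("line %d: gap linkage %r does not conform to the "
                            "'no'-linkage dialect", lineno, f[7])
            objects.setdefault(obj, [])
        else:
            raise ValueError(f"line {lineno}: unknown component type {f[4]!r}")
    return [OrderedGroup(obj, members, unplaced=len(members) == 1)
            for obj, members in objects.items()]


def write_groups_tsv(groups: Sequence[OrderedGroup],
                     relations: Sequence[AdjacencyRelation], path) -> None:
    """Groups table: group_id, rank, scaffold_id, orientation, support.

    ``support`` is the vote count of the relation linking a member to
    its predecessor ('.' for the first member of a group).
    """
    by_pair = {canonical_pair(r.first_id, r.first_orient,
                              r.second_id, r.second_orient): r.support
               for r in relations}
    with open(path, "w") as fh:
        fh.write("group_id\trank\tscaffold_id\torientation\tsupport\n")
        for g in groups:
            prev = None
            for rank, (sid, orient, _length) in enumerate(g.members, start=1):
                if prev is None:
                    support = "."
                else:
                    key = canonical_pair(prev[0], prev[1], sid, orient)
                    support = str(by_pair.get(key, "."))
                fh.write(f"{g.group_id}\t{rank}\t{sid}\t{orient}\t{support}\n")
                prev = (sid, orient)
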