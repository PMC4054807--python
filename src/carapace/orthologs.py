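"""Clean-ortholog gene-model screening and per-gene model selection.

Gene models remapped from a well-annotated reference genome to a target
genome through whole-genome alignment accumulate artifacts.  A model is
considered *clean* in a genome when (1) it is covered by a single
alignment chain within the syntenic or reciprocal-best net, (2) the
alignment has no significant gaps, (3) any frameshift is compensated
within a short window of sequence, and (4) all structural elements
(donor sites, acceptor sites, translation start, stop codon) are
preserved.  For each gene a single model clean in the focal genome is
selected, preferring models clean in the most genomes and then the
longest.  Since translation start/stop positions are noisy, incomplete
variants with 10% of the coding sequence trimmed off each end are also
screened.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

ELEMENTS = ("donor", "acceptor", "start_codon", "stop_codon")
PRESERVED, LOST, NOT_APPLICABLE = "preserved", "lost", "na"


@dataclass
class GeneModelAlignment:
    """A remapped transcript model with its per-element alignment evidence.

    Exon coordinates are 0-based half-open on the target and must be
    sorted and non-overlapping.  ``gap_events`` are (position, length)
    alignment gaps within the CDS; ``indel_events`` are (position,
    signed length) with insertions positive and deletions negative,
    positions in CDS coordinates.
    """

    gene_id: str
    model_id: str
    species_id: str
    exons: list[tuple[int, int]]
    chain_count: int
    net_kind: str  # "syntenic" or "reciprocal_best"
    gap_events: list[tuple[int, int]] = field(default_factory=list)
    indel_events: list[tuple[int, int]] = field(default_factory=list)
    element_status: dict[str, str] = field(default_factory=dict)
    cds_length: int = 0

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.exons:
            if s >= e or s < prev_end:
                raise ValueError(f"exons must be sorted, non-overlapping: {self.exons}")
            prev_end = e
        if self.exons and self.cds_length == 0:
            self.cds_length = sum(e - s for s, e in self.exons)
        if self.exons and self.cds_length != sum(e - s for s, e in self.exons):
            raise ValueError("cds_length must equal the summed exon lengths")
        for _pos, ln in self.indel_events:
            if ln == 0:
                raise ValueError("indel event lengths must be non-zero")
        for el in self.element_status:
            if el not in ELEMENTS:
                raise ValueError(f"unknown element {el!r}")


@dataclass
class ScreenConfig:
    """Thresholds for the clean-model conditions.

    frameshift_window
        bases within which a frameshift must be compensated (default 30).
    max_gap_run / max_gap_fraction
        a gap run longer than ``max_gap_run`` bases (default 90), or
        total gaps above ``max_gap_fraction`` of the CDS (default 0.2),
        is a significant gap.
    trim_fraction
        coding fraction removed from each end for incomplete variants
        (default 0.10).
    """

    frameshift_window: int = 30
    max_gap_fraction: float = 0.2
    max_gap_run: int = 90
    trim_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.frameshift_window < 3:
            raise ValueError("frameshift_window must be >= 3")
        if not (0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")


@dataclass
class CleanVerdict:
    """Per-condition flags for one model; clean iff all four hold."""

    model_id: str
    single_chain: bool
    no_significant_gaps: bool
    frameshifts_ok: bool
    elements_preserved: bool
    clean_species_count: int = 0

    @property
    def clean(self) -> bool:
        return (self.single_chain and self.no_significant_gaps
                and self.frameshifts_ok and self.elements_preserved)

    @property
    def failed_conditions(self) -> list[str]:
        return [name for name, ok in [
            ("single_chain", self.single_chain),
            ("no_significant_gaps", self.no_significant_gaps),
            ("frameshifts_ok", self.frameshifts_ok),
            ("elements_preserved", self.elements_preserved),
        ] if not ok]


def detect_frameshift_correction(indel_events: Sequence[tuple[int, int]],
                                 window: int = 30) -> bool:
    """True iff every frameshift is compensated within ``window`` bases.

    The cumulative frame offset (mod 3) is tracked across events sorted
    by position; whenever it leaves zero it must return to zero within
    ``window`` bases of the event that displaced it.  Compensation may
    be distributed over several events.  A frame left open at the end of
    the list is an uncorrected frameshift.
    """
    offset = 0
    shift_pos: int | None = None  # position of the event that left frame 0
    for pos, ln in indel_events:
        prev = offset
        offset = (offset + ln) % 3
        if prev == 0 and offset != 0:
            shift_pos = pos
        elif prev != 0 and offset == 0:
            if pos - shift_pos > window:
                return False
            shift_pos = None
        elif prev != 0 and offset != 0:
            if pos - shift_pos > window:
                return False
    return offset == 0


def classify_model(model: GeneModelAlignment,
                   cfg: ScreenConfig | None = None) -> CleanVerdict:
    """Evaluate the four clean-model conditions on one model."""
    cfg = cfg or ScreenConfig()
    total_gap = sum(ln for _pos, ln in model.gap_events)
    longest_gap = max((ln for _pos, ln in model.gap_events), default=0)
    return CleanVerdict(
        model_id=model.model_id,
        single_chain=model.chain_count == 1,
        no_significant_gaps=(longest_gap <= cfg.max_gap_run
                             and total_gap <= cfg.max_gap_fraction * model.cds_length),
        frameshifts_ok=detect_frameshift_correction(model.indel_events,
                                                    cfg.frameshift_window),
        elements_preserved=all(status != LOST
                               for status in model.element_status.values()),
    )


def select_gene_model(models: Mapping[str, tuple[Mapping[str, CleanVerdict], int]],
                      focal_species: str) -> str | None:
    """Pick one model per gene, or None (gene excluded).

    ``models`` maps model_id to (per-species verdicts, CDS length).
    Among models clean in the focal species, the winner maximises
    (number of species in which it is clean, CDS length, model_id).
    """
    best: tuple[int, int, str] | None = None
    for model_id, (verdicts, length) in models.items():
        focal = verdicts.get(focal_species)
        if focal is None or not focal.clean:
            continue
        n_clean = sum(1 for v in verdicts.values() if v.clean)
        key = (n_clean, length, model_id)
        if best is None or key > best:
            best = key
    return best[2] if best else None


def trim_variants(model: GeneModelAlignment,
                  cfg: ScreenConfig | None = None) -> GeneModelAlignment:
    """Incomplete-model variant with ``trim_fraction`` cut from each end.

    The trim amount floor(trim_fraction x cds_length) is rounded down to
    a codon boundary so downstream frame logic stays valid; exons are
    adjusted, events outside the retained window are dropped (positions
    shifted), and the start/stop element statuses become not-applicable.
    """
    cfg = cfg or ScreenConfig()
    if model.cds_length < 30:
        raise ValueError(f"model {model.model_id} too short to trim "
                         f"({model.cds_length} < 30 coding bases)")
    t = (int(cfg.trim_fraction * model.cds_length) // 3) * 3
    lo, hi = t, model.cds_length - t  # retained CDS-coordinate window

    new_exons: list[tuple[int, int]] = []
    cds_pos = 0
    for s, e in model.exons:
        ln = e - s
        keep_lo = max(lo - cds_pos, 0)
        keep_hi = min(hi - cds_pos, ln)
        if keep_lo < keep_hi:
            new_exons.append((s + keep_lo, s + keep_hi))
        cds_pos += ln

    status = dict(model.element_status)
    for el in ("start_codon", "stop_codon"):
        if el in status:
            status[el] = NOT_APPLICABLE
    return replace(
        model,
        model_id=f"{model.model_id}.trim",
        exons=new_exons,
        gap_events=[(p - lo, ln) for p, ln in model.gap_events if lo <= p < hi],
        indel_events=[(p - lo, ln) for p, ln in model.indel_events if lo <= p < hi],
        element_status=status,
        cds_length=hi - lo,
    )


# ---------------------------------------------------------------------------
# I/O: model-evidence TSV, verdicts TSV, selected-models TSV
# ---------------------------------------------------------------------------

EVIDENCE_TSV_COLUMNS = [
    "gene_id", "model_id", "species_id", "exons", "chain_count", "net_kind",
    "gap_events", "indel_events", "element_status",
]


def _fmt_pairs(pairs: Sequence[tuple[int, int]], signed: bool = False) -> str:
    if not pairs:
        return "."
    fmt = "{}:{:+d}" if signed else "{}:{}"
    return ",".join(fmt.format(p, ln) for p, ln in pairs)


def _parse_pairs(text: str) -> list[tuple[int, int]]:
    if text == ".":
        return []
    return [(int(p), int(ln)) for p, ln in
            (item.split(":") for item in text.split(","))]


def write_evidence_tsv(models: Sequence[GeneModelAlignment], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(EVIDENCE_TSV_COLUMNS)
        for m in models:
            w.writerow([
                m.gene_id, m.model_id, m.species_id,
                _fmt_pairs(m.exons), m.chain_count, m.net_kind,
                _fmt_pairs(m.gap_events),
                _fmt_pairs(m.indel_events, signed=True),
                ";".join(f"{el}={st}" for el, st in sorted(m.element_status.items()))
                or ".",
            ])


def read_evidence_tsv(path) -> list[GeneModelAlignment]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header != EVIDENCE_TSV_COLUMNS:
            raise ValueError(f"unexpected evidence TSV header: {header}")
        out = []
        for row in r:
            if not row:
                continue
            status = {} if row[8] == "." else dict(
                item.split("=") for item in row[8].split(";"))
            out.append(GeneModelAlignment(
                gene_id=row[0], model_id=row[1], species_id=row[2],
                exons=_parse_pairs(row[3]), chain_count=int(row[4]),
                net_kind=row[5], gap_events=_parse_pairs(row[6]),
                indel_events=_parse_pairs(row[7]), element_status=status))
        return out


def read_exons_gff3(path) -> dict[str, list[tuple[int, int]]]:
    """CDS exon coordinates per transcript model from a GFF3 file.

    Returns 0-based half-open (start, end) lists keyed by the CDS
    features' Parent (falling back to ID).  The evidence TSV can carry
    exons directly; this reader is for workflows where the models live
    in a GFF3 annotation.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    exons: dict[str, list[tuple[int, int]]] = {}
    for cds in db.features_of_type("CDS", order_by=("seqid", "start")):
        parents = cds.attributes.get("Parent") or cds.attributes.get("ID") or ["?"]
        for model_id in parents:
            exons.setdefault(model_id, []).append((cds.start - 1, cds.end))
    for model_id in exons:
        exons[model_id].sort()
    return exons


def write_verdicts_tsv(verdicts: Sequence[CleanVerdict], path) -> None:
    with open(path, "w") as fh:
        fh.write("model_id\tsingle_chain\tno_significant_gaps\t"
                 "frameshifts_ok\telements_preserved\tclean\n")
        for v in verdicts:
            fh.write("\t".join([
                v.model_id,
                *[str(int(flag)) for flag in (v.single_chain,
                                              v.no_significant_gaps,
                                              v.frameshifts_ok,
                                              v.elements_preserved,
                                              v.clean)],
            ]) + "\n")


def write_selected_tsv(selected: Mapping[str, str | None], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmodel_id\n")
        for gene_id, model_id in sorted(selected.items()):
            fh.write(f"{gene_id}\t{model_id if model_id else '.'}\n")
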