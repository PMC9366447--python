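"""Strict orthology validation of perfect-pattern loci.

Codifies the manual curation rules for diagnostic retroelement markers:
identical SINE family inserted in the same orientation in all present
species, element starts shifted by strictly less than 3 nt, an 8–30 nt
target-site duplication at the element boundaries, no evidence of segmental
duplication of the locus, presence/absence consistent across the required
number of representatives per lineage, a clean empty site in the outgroup,
and no co-transferred flank sequence at absence alleles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from ._seq import KmerIndex, cluster_seed_hits, local_align
from .annotate import CandidateLocus
from .config import PipelineConfig
from .screen import ABSENT, AMBIGUOUS, PRESENT, PresenceCall

logger = logging.getLogger(__name__)

REJECT_AMBIGUOUS = "ambiguous"
REJECT_FAMILY = "family"
REJECT_ORIENTATION = "orientation"
REJECT_SHIFT = "shift"
REJECT_REPRESENTATIVES = "representatives"
REJECT_OUTGROUP = "outgroup"
REJECT_DUPLICATION = "duplication"
REJECT_FLANK_TRANSFER = "flank_transfer"


@dataclass
class TSD:
    """A detected target-site duplication."""

    sequence: str
    length: int
    mismatches: int = 0


@dataclass
class DiagnosticMarker:
    """A validated diagnostic insertion assigned to one grouping hypothesis."""

    locus_id: str
    hypothesis: str
    family: str
    orientation: str
    tsd: TSD | None
    shifts: dict[str, int]
    representative_support: dict[str, int]
    states: dict[str, str]
    genic_context: str = "unknown"
    coordinates: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)


@dataclass
class ValidationResult:
    """Accepted marker or a typed rejection; never an exception."""

    locus_id: str
    marker: DiagnosticMarker | None = None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.marker is not None


def detect_tsd(
    window: str, element_start: int, element_end: int,
    config: PipelineConfig | None = None,
) -> TSD | None:
    """Longest direct repeat framing the element within the TSD length range.

    One copy must end at the element 5' boundary and one begin at the 3'
    boundary. At most one mismatch is allowed for lengths >= 10; lengths of
    8–9 nt must match exactly.
    """
    cfg = config or PipelineConfig()
    if element_start < cfg.tsd_max or len(window) - element_end < cfg.tsd_max:
        raise ValueError(
            "window must extend >= tsd_max nt beyond both element boundaries"
        )
    for length in range(cfg.tsd_max, cfg.tsd_min - 1, -1):
        left = window[element_start - length : element_start].upper()
        right = window[element_end : element_end + length].upper()
        mism = sum(a != b for a, b in zip(left, right))
        allowed = 1 if length >= 10 else 0
        if mism <= allowed:
            return TSD(sequence=left, length=length, mismatches=mism)
    return None


def check_duplication(
    locus: CandidateLocus,
    index: KmerIndex,
    sequences: dict[str, str],
    config: PipelineConfig | None = None,
) -> bool:
    """True iff either flank recurs elsewhere in the genome.

    A second match counts when it reaches >= 90% identity over >= 80% of the
    flank length outside the locus's own span.
    """
    cfg = config or PipelineConfig()
    ann = locus.annotation
    own = (ann.contig, ann.start - cfg.flank_len, ann.end + cfg.flank_len)
    for flank in (locus.left_flank, locus.right_flank):
        if not flank:
            raise ValueError("empty flank")
        for contig, pairs in index.hits(flank).items():
            seq = sequences[contig]
            for diag, gmin, gmax in cluster_seed_hits(pairs, band=16,
                                                      max_gap=len(flank)):
                ws = max(0, min(diag, gmin) - 50)
                we = min(len(seq), max(diag + len(flank), gmax + index.k) + 50)
                if contig == own[0] and ws < own[2] and we > own[1]:
                    continue  # the locus itself
                aln = local_align(flank, seq[ws:we])
                if aln is None:
                    continue
                covered = aln.query_end - aln.query_start
                if (aln.identity >= cfg.dup_min_identity
                        and covered >= cfg.dup_min_coverage * len(flank)):
                    return True
    return False


def _junction_explained(gap_seq: str, tsd: TSD | None, cfg: PipelineConfig) -> bool:
    """Is an absence-allele junction free of co-transferred sequence?

    Up to ``flank_transfer_max`` nt is always tolerated; beyond that the gap
    must be one retained target-site copy (>= 80% identity to the TSD, at
    most 5 residual nt).
    """
    n = len(gap_seq or "")
    if n <= cfg.flank_transfer_max:
        return True
    if tsd is None or n > tsd.length + cfg.flank_transfer_max:
        return False
    res = edlib.align(tsd.sequence, gap_seq.upper(), mode="HW", task="distance")
    ed = res["editDistance"]
    return ed >= 0 and ed <= 0.2 * tsd.length


def verify_orthology(
    call: PresenceCall,
    hypothesis: str,
    lineage_map: dict[str, str],
    config: PipelineConfig | None = None,
    tsd: TSD | None = None,
    duplication: bool = False,
    min_lineage_representatives: int | None = None,
    outgroup_lineage: str = "outgroup",
) -> ValidationResult:
    """Apply the strict orthology criteria to one perfect-pattern call.

    All failures come back as typed rejections with a machine-readable
    reason code; the checks partition every input locus into accepted or
    exactly one rejection reason.
    """
    cfg = config or PipelineConfig()
    min_reps = (cfg.min_lineage_representatives
                if min_lineage_representatives is None
                else min_lineage_representatives)

    states = call.states
    if any(st == AMBIGUOUS for st in states.values()):
        return ValidationResult(call.locus_id, reason=REJECT_AMBIGUOUS)

    present = {sp: ev for sp, ev in call.evidence.items() if ev.state == PRESENT}
    families = {ev.family for ev in present.values() if ev.family is not None}
    if len(families) > 1:
        return ValidationResult(call.locus_id, reason=REJECT_FAMILY)
    orientations = {ev.element_strand for ev in present.values()
                    if ev.element_strand is not None}
    if len(orientations) > 1:
        return ValidationResult(call.locus_id, reason=REJECT_ORIENTATION)

    shifts = {sp: ev.shift for sp, ev in present.items() if ev.shift is not None}
    if shifts and max(shifts.values()) - min(shifts.values()) >= cfg.shift_tolerance:
        return ValidationResult(call.locus_id, reason=REJECT_SHIFT)

    # per-lineage representative consistency
    support: dict[str, int] = {}
    by_lineage: dict[str, list[str]] = {}
    for sp, st in states.items():
        by_lineage.setdefault(lineage_map[sp], []).append(st)
    for lineage, sts in by_lineage.items():
        if len(set(sts)) != 1:
            return ValidationResult(call.locus_id, reason=REJECT_REPRESENTATIVES)
        support[lineage] = len(sts)
    for lineage, count in support.items():
        if count < min_reps:
            return ValidationResult(call.locus_id, reason=REJECT_REPRESENTATIVES)

    # clear absent state in the outgroup
    out_species = [sp for sp in states if lineage_map[sp] == outgroup_lineage]
    for sp in out_species:
        ev = call.evidence[sp]
        if ev.state != ABSENT:
            return ValidationResult(call.locus_id, reason=REJECT_OUTGROUP)
        if ev.gap_seq is not None and len(ev.gap_seq) > cfg.empty_site_slack:
            return ValidationResult(call.locus_id, reason=REJECT_OUTGROUP)

    if duplication:
        return ValidationResult(call.locus_id, reason=REJECT_DUPLICATION)

    # absence alleles must align flank-to-flank with no co-transferred flanks
    for sp, ev in call.evidence.items():
        if ev.state == ABSENT and not _junction_explained(ev.gap_seq, tsd, cfg):
            return ValidationResult(call.locus_id, reason=REJECT_FLANK_TRANSFER)

    marker = DiagnosticMarker(
        locus_id=call.locus_id,
        hypothesis=hypothesis,
        family=next(iter(families)) if families else call.family,
        orientation=next(iter(orientations)) if orientations else "+",
        tsd=tsd,
        shifts=shifts,
        representative_support=support,
        states=dict(states),
        coordinates=dict(call.query_coordinates),
    )
    return ValidationResult(call.locus_id, marker=marker)


def load_gene_annotation(gff3_path):
    """Load a GFF3 file into an in-memory gffutils database."""
    import gffutils

    return gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def annotate_genic_context(
    contig: str, start: int, end: int, db
) -> str:
    """Classify a marker position against gene annotation.

    exonic if overlapping any exon, intron if inside a gene but outside all
    exons, intergenic otherwise; unknown when no annotation covers the
    contig at all.
    """
    contigs = {f.seqid for f in db.all_features()}
    if contig not in contigs:
        return "unknown"
    # gffutils regions are 1-based inclusive
    feats = list(db.region(region=(contig, start + 1, end), completely_within=False))
    types = {f.featuretype for f in feats}
    if "exon" in types or "CDS" in types:
        return "exonic"
    if "gene" in types or "mRNA" in types:
        return "intron"
    return "intergenic"


def validate_pattern_loci(
    assigned: dict[str, list[PresenceCall]],
    lineage_map: dict[str, str],
    genomes: dict[str, dict[str, str]],
    config: PipelineConfig | None = None,
    min_lineage_representatives: int | None = None,
    check_duplications: bool = False,
    candidate_index: dict[str, CandidateLocus] | None = None,
    indexes: dict[str, KmerIndex] | None = None,
    outgroup_lineage: str = "outgroup",
) -> tuple[list[DiagnosticMarker], list[ValidationResult]]:
    """Validate every perfect-pattern call; returns (markers, rejections).

    TSDs are detected in the reference genome window of each call; the
    duplication screen runs when ``check_duplications`` is set and the
    originating candidate loci are supplied.
    """
    cfg = config or PipelineConfig()
    markers: list[DiagnosticMarker] = []
    rejections: list[ValidationResult] = []
    for label in sorted(assigned):
        for call in assigned[label]:
            tsd = None
            ref_ev = call.evidence.get(call.reference_species)
            if (ref_ev is not None and ref_ev.state == PRESENT
                    and ref_ev.element_start is not None):
                seq = genomes[call.reference_species][ref_ev.contig]
                ws = max(0, ref_ev.element_start - cfg.tsd_max)
                we = min(len(seq), ref_ev.element_end + cfg.tsd_max)
                window = seq[ws:we]
                try:
                    tsd = detect_tsd(window, ref_ev.element_start - ws,
                                     ref_ev.element_end - ws, cfg)
                except ValueError:
                    tsd = None
            dup = False
            if check_duplications and candidate_index and indexes:
                locus = candidate_index.get(call.locus_id)
                if locus is not None:
                    dup = check_duplication(
                        locus, indexes[call.reference_species],
                        genomes[call.reference_species], cfg,
                    )
            res = verify_orthology(
                call, label, lineage_map, cfg, tsd=tsd, duplication=dup,
                min_lineage_representatives=min_lineage_representatives,
                outgroup_lineage=outgroup_lineage,
            )
            (markers.append(res.marker) if res.accepted else rejections.append(res))
    return markers, rejections


def write_marker_table(markers: list[DiagnosticMarker], path) -> None:
    """One row per validated marker, mirroring a curated supplementary table."""
    with open(path, "w") as fh:
        fh.write("locus_id\thypothesis\tfamily\torientation\ttsd_len\ttsd_seq\t"
                 "genic_context\tstates\tcoordinates\n")
        for m in markers:
            states = ";".join(f"{sp}:{st}" for sp, st in sorted(m.states.items()))
            coords = ";".join(
                f"{sp}:{c[0]}:{c[1]}-{c[2]}({c[3]})"
                for sp, c in sorted(m.coordinates.items())
            )
            tsd_len = m.tsd.length if m.tsd else 0
            tsd_seq = m.tsd.sequence if m.tsd else ""
            fh.write(f"{m.locus_id}\t{m.hypothesis}\t{m.family}\t{m.orientation}"
                     f"\t{tsd_len}\t{tsd_seq}\t{m.genic_context}\t{states}\t{coords}\n")
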