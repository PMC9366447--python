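"""End-to-end orchestration: simulated genomes through validated markers.

Wires the stages together for the four-taxon synthetic study design: genome
simulation, per-genome SINE annotation, candidate-locus filtering,
multidirectional presence/absence screening with alternating references,
perfect-pattern extraction, strict orthology validation, and the pattern
significance tests. Each stage remains usable on its own for real data
(RepeatMasker input, externally supplied genomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import KmerIndex, revcomp
from .annotate import CandidateLocus, scan_genome, select_candidate_loci
from .config import PipelineConfig
from .screen import (
    ABSENT,
    PRESENT,
    PresenceCall,
    compile_multidirectional,
    default_hypothesis_patterns,
    extract_perfect_patterns,
)
from .simulate import (
    GenomeSet,
    SpeciesTreeSpec,
    default_element_library,
    simulate_marker_patterns,
    synthesize_genomes,
)
from .stats import PatternCounts, SignificanceResult, evaluate_pattern_counts
from .validate import DiagnosticMarker, ValidationResult, validate_pattern_loci

OUTGROUP_LINEAGE = "outgroup"


@dataclass
class PipelineResult:
    """Everything the synthetic end-to-end run produces."""

    tree: SpeciesTreeSpec
    genome_set: GenomeSet
    genomes: dict[str, dict[str, str]]
    lineage_map: dict[str, str]
    candidates_by_reference: dict[str, list[CandidateLocus]]
    calls: list[PresenceCall]
    assigned: dict[str, list[PresenceCall]]
    discards: list[tuple[str, str]]
    markers: list[DiagnosticMarker]
    rejections: list[ValidationResult]
    counts: PatternCounts
    significance: SignificanceResult
    truth_counts: dict[str, int] = field(default_factory=dict)

    @property
    def recovered_counts(self) -> dict[str, int]:
        out = {"H1": 0, "H2": 0, "H3": 0}
        for m in self.markers:
            out[m.hypothesis] += 1
        return out


def default_lineage_map(tree: SpeciesTreeSpec) -> dict[str, str]:
    """One lineage per ingroup leaf; the outgroup leaf maps to 'outgroup'."""
    a, b, c, o = tree.leaves
    return {a: a, b: b, c: c, o: OUTGROUP_LINEAGE}


def run_synthetic_pipeline(
    tree: SpeciesTreeSpec,
    n_events: int,
    ancestral_length: int,
    seed: int,
    config: PipelineConfig | None = None,
    library: dict[str, str] | None = None,
    alpha: float = 0.05,
    check_duplications: bool = False,
) -> PipelineResult:
    """Simulate a four-genome study and run the full marker pipeline on it.

    The synthetic design has one genome per lineage, so validation runs with
    ``min_lineage_representatives=1`` (the representative-consistency check
    degenerates to state consistency).
    """
    cfg = config or PipelineConfig()
    lib = library or default_element_library()

    events = simulate_marker_patterns(tree, n_events, seed)
    genome_set = synthesize_genomes(events, tree, ancestral_length, lib, seed + 1)
    genomes = {sp: {genome_set.contig_name: seq}
               for sp, seq in genome_set.sequences.items()}
    lineage_map = default_lineage_map(tree)
    a, b, c, o = tree.leaves

    candidates_by_reference: dict[str, list[CandidateLocus]] = {}
    for ref in (a, b, c):
        anns = scan_genome(genomes[ref], lib, min_identity=cfg.scan_min_identity,
                           species=ref, k=cfg.scan_k)
        candidates_by_reference[ref] = select_candidate_loci(anns, genomes[ref], cfg)

    indexes = {sp: KmerIndex(seqs, cfg.anchor_k) for sp, seqs in genomes.items()}
    calls = compile_multidirectional(
        candidates_by_reference, genomes, outgroup=o, library=lib,
        config=cfg, indexes=indexes,
    )
    patterns = default_hypothesis_patterns(a, b, c, OUTGROUP_LINEAGE)
    assigned, discards = extract_perfect_patterns(calls, lineage_map, patterns)

    candidate_index = {
        loc.locus_id: loc
        for cands in candidates_by_reference.values() for loc in cands
    }
    markers, rejections = validate_pattern_loci(
        assigned, lineage_map, genomes, cfg,
        min_lineage_representatives=1,
        check_duplications=check_duplications,
        candidate_index=candidate_index, indexes=indexes,
        outgroup_lineage=OUTGROUP_LINEAGE,
    )
    rec = {"H1": 0, "H2": 0, "H3": 0}
    for m in markers:
        rec[m.hypothesis] += 1
    counts = PatternCounts(rec["H1"], rec["H2"], rec["H3"])
    significance = evaluate_pattern_counts(counts, alpha=alpha)
    return PipelineResult(
        tree=tree, genome_set=genome_set, genomes=genomes,
        lineage_map=lineage_map,
        candidates_by_reference=candidates_by_reference,
        calls=calls, assigned=assigned, discards=discards,
        markers=markers, rejections=rejections,
        counts=counts, significance=significance,
        truth_counts=genome_set.truth_pattern_counts(
            tree, filter_passing_only=True, max_truncation=cfg.max_truncation
        ),
    )


def screen_genome_files(
    genomes: dict[str, dict[str, str]],
    library: dict[str, str],
    outgroup: str,
    lineage_map: dict[str, str] | None = None,
    config: PipelineConfig | None = None,
    references: list[str] | None = None,
    min_lineage_representatives: int | None = None,
    check_duplications: bool = False,
    alpha: float = 0.05,
):
    """Annotate, screen and validate a set of genomes supplied as sequences.

    The file-driven counterpart of :func:`run_synthetic_pipeline`: references
    default to all non-outgroup species, the lineage map defaults to one
    lineage per species. Returns (calls, assigned, discards, markers,
    rejections, significance).
    """
    cfg = config or PipelineConfig()
    if outgroup not in genomes:
        raise ValueError(f"outgroup {outgroup!r} has no genome")
    refs = references or [sp for sp in genomes if sp != outgroup]
    if lineage_map is None:
        lineage_map = {sp: (OUTGROUP_LINEAGE if sp == outgroup else sp)
                       for sp in genomes}
    ingroup_lineages = sorted(
        {l for l in lineage_map.values() if l != OUTGROUP_LINEAGE}
    )
    if len(ingroup_lineages) != 3:
        raise ValueError("need exactly 3 ingroup lineages")

    candidates_by_reference: dict[str, list[CandidateLocus]] = {}
    for ref in refs:
        anns = scan_genome(genomes[ref], library,
                           min_identity=cfg.scan_min_identity,
                           species=ref, k=cfg.scan_k)
        candidates_by_reference[ref] = select_candidate_loci(anns, genomes[ref], cfg)

    indexes = {sp: KmerIndex(seqs, cfg.anchor_k) for sp, seqs in genomes.items()}
    calls = compile_multidirectional(
        candidates_by_reference, genomes, outgroup=outgroup, library=library,
        config=cfg, indexes=indexes,
    )
    patterns = default_hypothesis_patterns(*ingroup_lineages, OUTGROUP_LINEAGE)
    assigned, discards = extract_perfect_patterns(calls, lineage_map, patterns)
    candidate_index = {
        loc.locus_id: loc
        for cands in candidates_by_reference.values() for loc in cands
    }
    markers, rejections = validate_pattern_loci(
        assigned, lineage_map, genomes, cfg,
        min_lineage_representatives=min_lineage_representatives,
        check_duplications=check_duplications,
        candidate_index=candidate_index, indexes=indexes,
        outgroup_lineage=OUTGROUP_LINEAGE,
    )
    rec = {"H1": 0, "H2": 0, "H3": 0}
    for m in markers:
        rec[m.hypothesis] += 1
    counts = PatternCounts(rec["H1"], rec["H2"], rec["H3"])
    significance = evaluate_pattern_counts(counts, alpha=alpha) if counts.total else None
    return calls, assigned, discards, markers, rejections, significance


def extract_locus_flank_alignment(
    call: PresenceCall,
    genomes: dict[str, dict[str, str]],
    analysis_flank_len: int = 1000,
) -> dict[str, str]:
    """Per-species flanking sequence around the insertion point/empty site.

    Takes ``analysis_flank_len/2`` nt on each side of the element (present
    alleles) or of the empty-site junction (absent alleles), in the locus
    frame, and concatenates left+right. Under the indel-free synthetic model
    the rows are columnwise orthologous and need no realignment. Species
    without usable coordinates are skipped.
    """
    half = analysis_flank_len // 2
    out: dict[str, str] = {}
    for sp, ev in call.evidence.items():
        if ev.contig is None:
            continue
        seq = genomes[sp][ev.contig]
        if ev.state == PRESENT and ev.element_start is not None:
            lo, hi = ev.element_start, ev.element_end
        elif ev.state == ABSENT and ev.junction_start is not None:
            lo, hi = ev.junction_start, ev.junction_end
        else:
            continue
        if lo - half < 0 or hi + half > len(seq):
            continue
        left = seq[lo - half : lo]
        right = seq[hi : hi + half]
        if ev.orientation == "-":
            left, right = revcomp(right), revcomp(left)
        out[sp] = left + right
    return out
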