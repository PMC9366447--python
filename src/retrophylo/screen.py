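"""Flank-anchored orthologous presence/absence screening.

For each candidate SINE locus discovered in a reference genome, both 500-nt
flanks are anchored in every query genome by unique best local alignments
(exact 20-mer seeds refined with edlib). A locus is called *present* when an
element of some library family lies between the anchors in the expected
orientation, *absent* when the anchors are contiguous up to a small slack
(one retained target-site copy plus a few nt), and *ambiguous* otherwise —
anchors on different contigs, non-unique anchors, low anchor identity or an
oversized unexplained gap. Screens run multidirectionally with alternating
reference genomes and merge loci that anchor to the same orthologous span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import KmerIndex, cluster_seed_hits, local_align, revcomp, semiglobal_locate
from .annotate import CandidateLocus
from .config import PipelineConfig

PRESENT, ABSENT, AMBIGUOUS = "present", "absent", "ambiguous"


@dataclass
class SpeciesEvidence:
    """Per-species outcome of mapping one locus into one genome."""

    state: str
    contig: str | None = None
    window_start: int | None = None  # anchored span, 0-based half-open
    window_end: int | None = None
    orientation: str | None = None   # query strand carrying the locus frame
    family: str | None = None        # for present calls
    element_strand: str | None = None  # element orientation in the locus frame
    element_start: int | None = None   # forward genome coordinates
    element_end: int | None = None
    shift: int | None = None         # element start offset vs reference, locus frame
    gap_seq: str | None = None       # junction sequence for absent calls
    junction_start: int | None = None  # empty-site span, forward coordinates
    junction_end: int | None = None
    reason: str | None = None        # why ambiguous


@dataclass
class PresenceCall:
    """One orthologous locus with per-species presence/absence states."""

    locus_id: str
    reference_species: str
    family: str                       # reference element family
    evidence: dict[str, SpeciesEvidence] = field(default_factory=dict)
    source_loci: list[str] = field(default_factory=list)

    @property
    def states(self) -> dict[str, str]:
        return {sp: ev.state for sp, ev in self.evidence.items()}

    @property
    def query_coordinates(self) -> dict[str, tuple[str, int, int, str]]:
        return {
            sp: (ev.contig, ev.window_start, ev.window_end, ev.orientation or "+")
            for sp, ev in self.evidence.items()
            if ev.contig is not None
        }

    @property
    def element_shift(self) -> dict[str, int]:
        return {sp: ev.shift for sp, ev in self.evidence.items() if ev.shift is not None}


@dataclass
class HypothesisPattern:
    """Required presence/absence states per lineage for one grouping hypothesis."""

    label: str
    required_states: dict[str, str]

    def __post_init__(self):
        vals = set(self.required_states.values())
        if not vals <= {PRESENT, ABSENT}:
            raise ValueError("required states must be 'present' or 'absent'")


def default_hypothesis_patterns(
    lineage1: str, lineage2: str, lineage3: str, outgroup: str
) -> list[HypothesisPattern]:
    """The three competing two-lineage groupings, outgroup always absent.

    H1 groups lineage1+lineage2 (e.g. Phalangeroidea+Petauroidea), H2 groups
    lineage1+lineage3, H3 groups lineage2+lineage3.
    """
    return [
        HypothesisPattern("H1", {lineage1: PRESENT, lineage2: PRESENT,
                                 lineage3: ABSENT, outgroup: ABSENT}),
        HypothesisPattern("H2", {lineage1: PRESENT, lineage3: PRESENT,
                                 lineage2: ABSENT, outgroup: ABSENT}),
        HypothesisPattern("H3", {lineage2: PRESENT, lineage3: PRESENT,
                                 lineage1: ABSENT, outgroup: ABSENT}),
    ]


def _anchor_flank(
    flank: str, index: KmerIndex, sequences: dict[str, str], cfg: PipelineConfig
):
    """Unique best semiglobal placement of a flank in a genome.

    Returns (contig, start, end, score) or (None, reason).
    """
    hits = index.hits(flank)
    candidates: list[tuple[float, str, int, int]] = []
    max_ed = max(2, int(round((1 - cfg.anchor_min_identity) * len(flank) * 2)))
    for contig, pairs in hits.items():
        seq = sequences[contig]
        for diag, gmin, gmax in cluster_seed_hits(pairs, band=16, max_gap=len(flank)):
            ws = max(0, min(diag, gmin) - 50)
            we = min(len(seq), max(diag + len(flank), gmax + index.k) + 50)
            loc = semiglobal_locate(flank, seq[ws:we], max_ed=max_ed)
            if loc is None:
                continue
            s, e, ed = loc
            candidates.append((float(len(flank) - ed), contig, ws + s, ws + e))
    if not candidates:
        return None, "no_anchor"
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    best = candidates[0]
    identity = best[0] / len(flank)
    if identity < cfg.anchor_min_identity:
        return None, "low_anchor_identity"
    # uniqueness: discard near-duplicate placements of the same region
    second = None
    for c in candidates[1:]:
        if c[1] == best[1] and not (c[3] <= best[2] or c[2] >= best[3]):
            continue  # overlaps best placement
        second = c
        break
    if second is not None and best[0] < cfg.anchor_uniqueness_ratio * second[0]:
        return None, "non_unique_anchor"
    return (best[1], best[2], best[3], best[0]), None


def _find_element_in_gap(
    gap_seq: str, library: dict[str, str], cfg: PipelineConfig
):
    """Best library element hit inside an inter-anchor gap, or None."""
    best = None
    for family in sorted(library):
        cons = library[family].upper()
        for strand in "+-":
            query = cons if strand == "+" else revcomp(cons)
            aln = local_align(query, gap_seq)
            if aln is None or aln.length < cfg.min_element_len:
                continue
            if aln.identity < cfg.scan_min_identity:
                continue
            if best is None or aln.score > best[0].score:
                best = (aln, family, strand)
    return best


def map_locus_to_query(
    locus: CandidateLocus,
    index: KmerIndex,
    sequences: dict[str, str],
    library: dict[str, str],
    config: PipelineConfig | None = None,
) -> SpeciesEvidence:
    """Call presence/absence of one candidate locus in one query genome.

    Never raises on unanchorable input — every failure mode yields an
    ambiguous call with a reason code.
    """
    cfg = config or PipelineConfig()
    if not locus.left_flank or not locus.right_flank:
        return SpeciesEvidence(state=AMBIGUOUS, reason="empty_flank")

    # try both orientations of the locus frame in the query genome
    frames = {
        "+": (locus.left_flank, locus.right_flank),
        "-": (revcomp(locus.right_flank), revcomp(locus.left_flank)),
    }
    placements = {}
    for orient, (up, down) in frames.items():
        a_up, r_up = _anchor_flank(up, index, sequences, cfg)
        a_down, r_down = _anchor_flank(down, index, sequences, cfg)
        placements[orient] = (a_up, a_down, r_up or r_down)
    scored = {
        o: (p[0][3] + p[1][3]) for o, p in placements.items()
        if p[0] is not None and p[1] is not None
    }
    if not scored:
        # report the most informative failure across the two orientations
        priority = ("non_unique_anchor", "low_anchor_identity", "no_anchor")
        reasons = {placements["+"][2], placements["-"][2]} - {None}
        reason = next((r for r in priority if r in reasons), "no_anchor")
        return SpeciesEvidence(state=AMBIGUOUS, reason=reason)
    orient = max(scored, key=scored.get)
    (uc, us, ue, _), (dc, ds, de, _), _ = placements[orient]
    if uc != dc:
        return SpeciesEvidence(state=AMBIGUOUS, reason="anchors_split_contigs",
                               orientation=orient)
    gap = ds - ue
    # at a clean empty site the two anchors overlap by the target-site
    # length (both reference flanks carry one TSD copy), so contiguity is
    # judged within +/- empty_site_slack
    if gap < -cfg.empty_site_slack:
        return SpeciesEvidence(state=AMBIGUOUS, reason="anchor_overlap",
                               contig=uc, window_start=us, window_end=de,
                               orientation=orient)
    gap_seq = sequences[uc][ue:ds] if ds > ue else ""
    if gap <= cfg.empty_site_slack:
        return SpeciesEvidence(
            state=ABSENT, contig=uc, window_start=us, window_end=de,
            orientation=orient, gap_seq=gap_seq,
            junction_start=ue, junction_end=ds,
        )
    if gap >= cfg.min_element_len:
        found = _find_element_in_gap(gap_seq, library, cfg)
        if found is not None:
            aln, family, strand = found
            es = ue + aln.target_start
            ee = ue + aln.target_end
            # element start offset in the locus frame relative to the
            # reference layout (element immediately after the left flank)
            if orient == "+":
                shift = es - ue
                elem_strand_frame = strand
            else:
                # oriented frame reverses the window: the reference left
                # flank anchors at [ds, de) and the element start maps to ee
                shift = ds - ee
                elem_strand_frame = "+" if strand == "-" else "-"
            # correct frame-strand for the reference element orientation:
            # flanks are stored element-oriented, so frame '+' carries the
            # element on the reference element's strand
            return SpeciesEvidence(
                state=PRESENT, contig=uc, window_start=us, window_end=de,
                orientation=orient, family=family,
                element_strand=elem_strand_frame,
                element_start=es, element_end=ee, shift=shift,
            )
        return SpeciesEvidence(state=AMBIGUOUS, reason="gap_without_element",
                               contig=uc, window_start=us, window_end=de,
                               orientation=orient)
    return SpeciesEvidence(state=AMBIGUOUS, reason="oversized_gap",
                           contig=uc, window_start=us, window_end=de,
                           orientation=orient)


def _reference_evidence(locus: CandidateLocus, cfg: PipelineConfig) -> SpeciesEvidence:
    ann = locus.annotation
    return SpeciesEvidence(
        state=PRESENT, contig=ann.contig,
        window_start=ann.start - cfg.flank_len, window_end=ann.end + cfg.flank_len,
        orientation="+" if ann.strand == "+" else "-",
        family=ann.family, element_strand="+",  # locus frame is element-oriented
        element_start=ann.start, element_end=ann.end, shift=0,
    )


def screen_locus(
    locus: CandidateLocus,
    genomes: dict[str, dict[str, str]],
    indexes: dict[str, KmerIndex],
    library: dict[str, str],
    config: PipelineConfig | None = None,
) -> PresenceCall:
    """Screen one candidate locus across all genomes (reference included)."""
    cfg = config or PipelineConfig()
    call = PresenceCall(
        locus_id=locus.locus_id,
        reference_species=locus.reference_species,
        family=locus.annotation.family,
        source_loci=[locus.locus_id],
    )
    for sp in genomes:
        if sp == locus.reference_species:
            call.evidence[sp] = _reference_evidence(locus, cfg)
        else:
            call.evidence[sp] = map_locus_to_query(
                locus, indexes[sp], genomes[sp], library, cfg
            )
    return call


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int], frac: float) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def compile_multidirectional(
    candidates_by_reference: dict[str, list[CandidateLocus]],
    genomes: dict[str, dict[str, str]],
    outgroup: str,
    library: dict[str, str],
    config: PipelineConfig | None = None,
    indexes: dict[str, KmerIndex] | None = None,
) -> list[PresenceCall]:
    """Run the multidirectional screen and merge calls at orthologous spans.

    Loci discovered from different reference genomes whose anchored windows
    overlap reciprocally by >= 50% in any shared species are merged into one
    call; per-species state conflicts between merged calls are downgraded to
    ambiguous.
    """
    cfg = config or PipelineConfig()
    ingroup_refs = [r for r in candidates_by_reference if r != outgroup]
    if len(ingroup_refs) < 3:
        raise ValueError("need >= 3 ingroup reference species")
    if outgroup not in genomes:
        raise ValueError(f"outgroup {outgroup!r} has no genome")
    if indexes is None:
        indexes = {sp: KmerIndex(seqs, cfg.anchor_k) for sp, seqs in genomes.items()}

    calls: list[PresenceCall] = []
    for ref in sorted(candidates_by_reference):
        for locus in candidates_by_reference[ref]:
            calls.append(screen_locus(locus, genomes, indexes, library, cfg))

    # merge calls anchored at the same orthologous span
    uf = _UnionFind(len(calls))
    per_species: dict[str, list[tuple[int, int, int]]] = {}
    for i, call in enumerate(calls):
        for sp, ev in call.evidence.items():
            if ev.contig is not None and ev.window_start is not None:
                per_species.setdefault(f"{sp}\t{ev.contig}", []).append(
                    (ev.window_start, ev.window_end, i)
                )
    for spans in per_species.values():
        spans.sort()
        for j in range(len(spans)):
            s1, e1, i1 = spans[j]
            for k in range(j + 1, len(spans)):
                s2, e2, i2 = spans[k]
                if s2 >= e1:
                    break
                if _reciprocal_overlap((s1, e1), (s2, e2), 0.5):
                    uf.union(i1, i2)

    groups: dict[int, list[PresenceCall]] = {}
    for i, call in enumerate(calls):
        groups.setdefault(uf.find(i), []).append(call)

    merged: list[PresenceCall] = []
    for root in sorted(groups):
        group = groups[root]
        base = group[0]
        out = PresenceCall(
            locus_id=base.locus_id,
            reference_species=base.reference_species,
            family=base.family,
            source_loci=sorted(l for c in group for l in c.source_loci),
        )
        for sp in genomes:
            evs = [c.evidence[sp] for c in group if sp in c.evidence]
            definite = [e for e in evs if e.state != AMBIGUOUS]
            states = {e.state for e in definite}
            if states == {PRESENT, ABSENT}:
                first = definite[0]
                out.evidence[sp] = SpeciesEvidence(
                    state=AMBIGUOUS, reason="merge_conflict",
                    contig=first.contig, window_start=first.window_start,
                    window_end=first.window_end, orientation=first.orientation,
                )
            elif definite:
                out.evidence[sp] = definite[0]
            elif evs:
                out.evidence[sp] = evs[0]
        merged.append(out)
    return merged


def extract_perfect_patterns(
    calls: list[PresenceCall],
    lineage_map: dict[str, str],
    patterns: list[HypothesisPattern],
) -> tuple[dict[str, list[PresenceCall]], list[tuple[str, str]]]:
    """Assign calls with perfect presence/absence patterns to hypotheses.

    A call is assigned iff every screened species matches its lineage's
    required state with no ambiguous entries. Returns ({label: calls},
    discard ledger of (locus_id, reason)).
    """
    assigned: dict[str, list[PresenceCall]] = {p.label: [] for p in patterns}
    discards: list[tuple[str, str]] = []
    for call in calls:
        for sp in call.states:
            if sp not in lineage_map:
                raise KeyError(f"species {sp!r} missing from lineage map")
        if any(st == AMBIGUOUS for st in call.states.values()):
            discards.append((call.locus_id, "ambiguous"))
            continue
        hit = None
        for pat in patterns:
            ok = all(
                call.states[sp] == pat.required_states[lineage_map[sp]]
                for sp in call.states
                if lineage_map[sp] in pat.required_states
            )
            if ok:
                hit = pat.label
                break
        if hit is None:
            discards.append((call.locus_id, "no_matching_pattern"))
        else:
            assigned[hit].append(call)
    return assigned, discards


def write_call_table(calls: list[PresenceCall], path, species: list[str]) -> None:
    """Per-locus call table TSV preserving the multidirectional audit trail."""
    with open(path, "w") as fh:
        head = ["locus_id", "reference", "family"]
        for sp in species:
            head += [f"{sp}_state", f"{sp}_coords", f"{sp}_shift", f"{sp}_reason"]
        fh.write("\t".join(head) + "\n")
        for call in calls:
            row = [call.locus_id, call.reference_species, call.family]
            for sp in species:
                ev = call.evidence.get(sp)
                if ev is None:
                    row += ["", "", "", ""]
                    continue
                coords = (
                    f"{ev.contig}:{ev.window_start}-{ev.window_end}({ev.orientation})"
                    if ev.contig is not None else ""
                )
                row += [ev.state, coords,
                        "" if ev.shift is None else str(ev.shift),
                        ev.reason or ""]
            fh.write("\t".join(row) + "\n")
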