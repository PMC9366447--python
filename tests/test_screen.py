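"""Presence/absence calling, multidirectional merging, pattern extraction."""

from __future__ import annotations

import numpy as np
import pytest

from retrophylo import (
    PipelineConfig,
    default_hypothesis_patterns,
    extract_perfect_patterns,
    map_locus_to_query,
)
from retrophylo._seq import KmerIndex
from retrophylo.annotate import CandidateLocus, RepeatAnnotation
from retrophylo.screen import (
    ABSENT,
    AMBIGUOUS,
    PRESENT,
    PresenceCall,
    SpeciesEvidence,
)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def locus_fixture():
    """A reference locus with a planted element, plus carrier/empty genomes."""
    cfg = PipelineConfig()
    left = _random_seq(800, 21)
    right = _random_seq(800, 22)
    elem = _random_seq(180, 23)
    tsd = _random_seq(12, 24)
    lib = {"FAM1": elem}
    ref_seq = left + tsd + elem + tsd + right
    es = len(left) + 12
    ann = RepeatAnnotation(species="ref", contig="c1", start=es, end=es + 180,
                           strand="+", family="FAM1", divergence=0.0)
    locus = CandidateLocus(
        locus_id="ref|c1", reference_species="ref", annotation=ann,
        left_flank=ref_seq[es - 500 : es], right_flank=ref_seq[es + 180 : es + 680],
        flank_te_fraction=0.0,
    )
    present_genome = {"q1": _random_seq(300, 25) + ref_seq + _random_seq(300, 26)}
    absent_genome = {"q1": _random_seq(300, 27) + left + tsd + right + _random_seq(300, 28)}
    return cfg, lib, locus, present_genome, absent_genome


def test_absent_query_called_absent_with_contiguous_anchors(locus_fixture):
    cfg, lib, locus, _, absent_genome = locus_fixture
    ev = map_locus_to_query(locus, KmerIndex(absent_genome, cfg.anchor_k),
                            absent_genome, lib, cfg)
    assert ev.state == ABSENT
    assert ev.gap_seq == ""  # anchors share the single target-site copy


def test_present_query_recovers_element_coordinates(locus_fixture):
    cfg, lib, locus, present_genome, _ = locus_fixture
    ev = map_locus_to_query(locus, KmerIndex(present_genome, cfg.anchor_k),
                            present_genome, lib, cfg)
    assert ev.state == PRESENT
    assert ev.family == "FAM1"
    assert (ev.element_start, ev.element_end) == (300 + 800 + 12, 300 + 800 + 12 + 180)
    assert ev.shift == 0
    assert ev.element_strand == "+"


def test_inverted_query_locus_found_on_reverse_frame(locus_fixture):
    cfg, lib, locus, present_genome, _ = locus_fixture
    from retrophylo._seq import revcomp

    flipped = {"q1": revcomp(present_genome["q1"])}
    ev = map_locus_to_query(locus, KmerIndex(flipped, cfg.anchor_k), flipped, lib, cfg)
    assert ev.state == PRESENT
    assert ev.orientation == "-"
    assert ev.shift == 0
    assert ev.element_strand == "+"  # unchanged in the locus frame


def test_anchors_on_two_contigs_ambiguous(locus_fixture):
    cfg, lib, locus, present_genome, _ = locus_fixture
    seq = present_genome["q1"]
    es = 300 + 800 + 12
    split = {"cA": seq[: es - 20], "cB": seq[es + 200 :]}
    ev = map_locus_to_query(locus, KmerIndex(split, cfg.anchor_k), split, lib, cfg)
    assert ev.state == AMBIGUOUS
    assert ev.reason == "anchors_split_contigs"


def test_unanchorable_locus_ambiguous_never_raises(locus_fixture):
    cfg, lib, locus, _, _ = locus_fixture
    unrelated = {"q1": _random_seq(5000, 99)}
    ev = map_locus_to_query(locus, KmerIndex(unrelated, cfg.anchor_k),
                            unrelated, lib, cfg)
    assert ev.state == AMBIGUOUS
    assert ev.reason == "no_anchor"


def test_duplicated_flank_region_non_unique_anchor(locus_fixture):
    cfg, lib, locus, present_genome, _ = locus_fixture
    seq = present_genome["q1"]
    # plant a second full copy of the left-flank region elsewhere
    dup = {"q1": seq + _random_seq(50, 30) + locus.left_flank + _random_seq(50, 31)}
    ev = map_locus_to_query(locus, KmerIndex(dup, cfg.anchor_k), dup, lib, cfg)
    assert ev.state == AMBIGUOUS
    assert ev.reason == "non_unique_anchor"


def test_merged_locus_count_matches_truth(zero_mut_pipeline):
    """Mutation-free multidirectional screen: merged loci = filter-passing truth."""
    res = zero_mut_pipeline
    cfg = PipelineConfig()
    gs = res.genome_set
    expected = set()
    for ev in gs.truth:
        if ev.truncation_5p >= cfg.max_truncation or ev.truncation_3p >= cfg.max_truncation:
            continue
        # discoverable from at least one ingroup reference away from contig ends
        ok = False
        for ref in res.tree.ingroup:
            if ref in ev.coordinates:
                _, s, e, _ = ev.coordinates[ref]
                if s >= cfg.flank_len and e + cfg.flank_len <= len(gs.sequences[ref]):
                    ok = True
        if ok:
            expected.add(ev.event_id)
    assert len(res.calls) == len(expected)


def test_merge_produces_single_call_per_event(zero_mut_pipeline):
    """Loci discovered from several references collapse into one call."""
    res = zero_mut_pipeline
    multi_ref = [c for c in res.calls if len(c.source_loci) > 1]
    assert multi_ref, "expected at least one locus discovered from two references"
    ids = [c.locus_id for c in res.calls]
    assert len(ids) == len(set(ids))


def _call(states, locus_id="L0"):
    call = PresenceCall(locus_id=locus_id, reference_species="L1", family="F")
    for sp, st in states.items():
        call.evidence[sp] = SpeciesEvidence(state=st)
    return call


@pytest.fixture()
def patterns():
    return default_hypothesis_patterns("L1", "L2", "L3", "outgroup")


@pytest.fixture()
def lineage_map():
    return {"L1": "L1", "L2": "L2", "L3": "L3", "O": "outgroup"}


class TestPerfectPatterns:
    def test_cherry_pattern_assigned_h1(self, patterns, lineage_map):
        call = _call({"L1": PRESENT, "L2": PRESENT, "L3": ABSENT, "O": ABSENT})
        assigned, discards = extract_perfect_patterns([call], lineage_map, patterns)
        assert [c.locus_id for c in assigned["H1"]] == ["L0"]
        assert discards == []

    def test_all_present_uninformative(self, patterns, lineage_map):
        call = _call({"L1": PRESENT, "L2": PRESENT, "L3": PRESENT, "O": ABSENT})
        assigned, discards = extract_perfect_patterns([call], lineage_map, patterns)
        assert all(not v for v in assigned.values())
        assert discards == [("L0", "no_matching_pattern")]

    def test_ambiguous_state_discarded(self, patterns, lineage_map):
        call = _call({"L1": PRESENT, "L2": PRESENT, "L3": AMBIGUOUS, "O": ABSENT})
        _, discards = extract_perfect_patterns([call], lineage_map, patterns)
        assert discards == [("L0", "ambiguous")]

    def test_outgroup_presence_never_matches(self, patterns, lineage_map):
        call = _call({"L1": PRESENT, "L2": PRESENT, "L3": ABSENT, "O": PRESENT})
        assigned, discards = extract_perfect_patterns([call], lineage_map, patterns)
        assert all(not v for v in assigned.values())

    def test_unknown_lineage_raises(self, patterns):
        call = _call({"X": PRESENT})
        with pytest.raises(KeyError):
            extract_perfect_patterns([call], {"L1": "L1"}, patterns)

    def test_relabeling_cherry_swaps_conflicting_counts(self, patterns, lineage_map):
        """Swapping L1 and L2 exchanges H2 and H3; H1 is invariant."""
        calls = [
            _call({"L1": PRESENT, "L2": PRESENT, "L3": ABSENT, "O": ABSENT}, "a"),
            _call({"L1": PRESENT, "L2": ABSENT, "L3": PRESENT, "O": ABSENT}, "b"),
            _call({"L1": PRESENT, "L2": ABSENT, "L3": PRESENT, "O": ABSENT}, "c"),
            _call({"L1": ABSENT, "L2": PRESENT, "L3": PRESENT, "O": ABSENT}, "d"),
        ]
        assigned, _ = extract_perfect_patterns(calls, lineage_map, patterns)
        swapped_map = {"L1": "L2", "L2": "L1", "L3": "L3", "O": "outgroup"}
        swapped, _ = extract_perfect_patterns(calls, swapped_map, patterns)
        assert len(assigned["H1"]) == len(swapped["H1"]) == 1
        assert len(assigned["H2"]) == len(swapped["H3"]) == 2
        assert len(assigned["H3"]) == len(swapped["H2"]) == 1
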