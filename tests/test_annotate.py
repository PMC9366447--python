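"""Annotator and locus-filter contracts against constructed fixtures."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from retrophylo import (
    PipelineConfig,
    RepeatAnnotation,
    read_repeatmasker_out,
    scan_genome,
    select_candidate_loci,
)
from retrophylo._seq import revcomp
from retrophylo.annotate import read_annotations, write_annotations


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="module")
def consensus():
    return {"FAM1": _random_seq(180, 1), "FAM2": _random_seq(150, 2)}


def test_exact_copy_recovered_at_truth_coordinates(consensus):
    left, right = _random_seq(700, 3), _random_seq(700, 4)
    genome = {"c1": left + consensus["FAM1"] + right}
    anns = scan_genome(genome, consensus, species="s")
    assert len(anns) == 1
    a = anns[0]
    assert (a.start, a.end, a.strand, a.family) == (700, 880, "+", "FAM1")
    assert a.divergence == 0.0
    assert a.truncation_5p == 0 and a.truncation_3p == 0


def test_reverse_complement_copy_gets_minus_strand(consensus):
    genome = {"c1": _random_seq(600, 5) + revcomp(consensus["FAM2"]) + _random_seq(600, 6)}
    anns = scan_genome(genome, consensus, species="s")
    assert len(anns) == 1
    assert anns[0].strand == "-"
    assert anns[0].family == "FAM2"
    assert (anns[0].start, anns[0].end) == (600, 750)


def test_five_prime_truncation_measured_on_consensus(consensus):
    genome = {"c1": _random_seq(650, 7) + consensus["FAM1"][15:] + _random_seq(650, 8)}
    anns = scan_genome(genome, consensus, species="s")
    assert len(anns) == 1
    assert anns[0].truncation_5p == 15
    assert anns[0].truncation_3p == 0
    # same truncation planted on the minus strand stays 5' in consensus terms
    genome2 = {"c1": _random_seq(650, 9) + revcomp(consensus["FAM1"][15:]) + _random_seq(650, 10)}
    anns2 = scan_genome(genome2, consensus, species="s")
    assert anns2[0].strand == "-" and anns2[0].truncation_5p == 15


def test_scan_recovers_all_planted_copies(zero_mut_pipeline):
    """100% recovery at exact coordinates on mutation-free genomes."""
    gs = zero_mut_pipeline.genome_set
    lib_events = [
        ev for ev in gs.truth
        if ev.truncation_5p == 0 and ev.truncation_3p == 0
    ]
    from retrophylo import default_element_library

    lib = default_element_library()
    for sp, seq in gs.sequences.items():
        anns = scan_genome({"chr1": seq}, lib, species=sp)
        found = {(a.start, a.end, a.strand, a.family) for a in anns}
        for ev in lib_events:
            if sp in ev.coordinates:
                contig, s, e, strand = ev.coordinates[sp]
                assert (s, e, strand, ev.family) in found


def test_scan_input_validation(consensus):
    with pytest.raises(ValueError, match="empty"):
        scan_genome({"c": "ACGT" * 100}, {})
    with pytest.raises(ValueError, match="empty"):
        scan_genome({}, consensus)
    with pytest.raises(ValueError, match="min_identity"):
        scan_genome({"c": "ACGT" * 100}, consensus, min_identity=0.4)


RM_OUT = """\
   SW   perc perc perc  query     position in query        matching repeat       position in repeat
score   div. del. ins.  sequence  begin end (left)  repeat class/family  begin  end (left)   ID

 1234    2.1  0.0  0.0  c1        101   200 (799)   +  FAM1  SINE/tRNA     1    100   (80)    1
  987    5.0  0.1  0.0  c1        501   640 (359)   C  FAM2  SINE/tRNA   (10)   140     1     2
  555    1.0  0.0  0.0  c1        oops  200 (799)   +  FAM1  SINE/tRNA     1    100   (80)    3
"""


def test_repeatmasker_reader_coordinates_and_strand(tmp_path, caplog):
    fp = tmp_path / "test.out"
    fp.write_text(RM_OUT)
    with caplog.at_level(logging.WARNING):
        anns = read_repeatmasker_out(fp, species="q")
    assert len(anns) == 2  # malformed row skipped
    assert any("malformed" in r.getMessage() for r in caplog.records)
    plus, minus = anns
    # 1-based inclusive -> 0-based half-open
    assert (plus.start, plus.end, plus.strand) == (100, 200, "+")
    assert plus.truncation_5p == 0 and plus.truncation_3p == 80
    assert plus.divergence == pytest.approx(0.021)
    # C row read right-to-left: (left)=10, end=140, begin=1
    assert (minus.start, minus.end, minus.strand) == (500, 640, "-")
    assert minus.truncation_5p == 0 and minus.truncation_3p == 10


def test_annotation_tsv_roundtrip(tmp_path, consensus):
    genome = {"c1": _random_seq(700, 3) + consensus["FAM1"] + _random_seq(700, 4)}
    anns = scan_genome(genome, consensus, species="s")
    fp = tmp_path / "anns.tsv"
    write_annotations(anns, fp)
    assert read_annotations(fp) == anns


class TestCandidateSelection:
    def _annotation(self, **kw):
        base = dict(species="s", contig="c1", start=600, end=780, strand="+",
                    family="FAM1", divergence=0.0)
        base.update(kw)
        return RepeatAnnotation(**base)

    def test_truncated_element_rejected(self):
        genome = {"c1": _random_seq(1400, 11)}
        ann = self._annotation(truncation_5p=15)
        assert select_candidate_loci([ann], genome) == []
        # boundary: exactly 10 nt truncation is also rejected (strict < 10)
        ann10 = self._annotation(truncation_5p=10)
        assert select_candidate_loci([ann10], genome) == []
        ann9 = self._annotation(truncation_5p=9)
        assert len(select_candidate_loci([ann9], genome)) == 1

    def test_te_dense_flank_rejected(self):
        genome = {"c1": _random_seq(1400, 12)}
        ann = self._annotation()
        # cover 60% of the left flank [100, 600) with other repeats
        cover = RepeatAnnotation(species="s", contig="c1", start=150, end=450,
                                 strand="+", family="FAM2", divergence=0.1)
        assert select_candidate_loci([ann, cover], genome) == []
        # 40% coverage passes
        cover2 = RepeatAnnotation(species="s", contig="c1", start=200, end=400,
                                  strand="+", family="FAM2", divergence=0.1)
        kept = select_candidate_loci([ann, cover2], genome)
        assert [c.annotation.start for c in kept] == [600]

    def test_clean_locus_gets_strand_normalized_flanks(self):
        seq = _random_seq(1400, 13)
        genome = {"c1": seq}
        plus = select_candidate_loci([self._annotation()], genome)[0]
        assert plus.left_flank == seq[100:600]
        assert plus.right_flank == seq[780:1280]
        minus = select_candidate_loci([self._annotation(strand="-")], genome)[0]
        assert minus.left_flank == revcomp(seq[780:1280])
        assert minus.right_flank == revcomp(seq[100:600])

    def test_contig_end_proximity_rejected(self):
        genome = {"c1": _random_seq(1000, 14)}
        ann = self._annotation(start=100, end=280)  # < 500 nt from contig start
        assert select_candidate_loci([ann], genome) == []

    def test_unknown_contig_raises(self):
        with pytest.raises(KeyError, match="contig"):
            select_candidate_loci([self._annotation(contig="nope")],
                                  {"c1": _random_seq(1400, 15)})

    def test_counts_match_truth_table_filter(self, zero_mut_pipeline):
        """Selected candidate counts equal a brute-force truth-table filter."""
        res = zero_mut_pipeline
        cfg = PipelineConfig()
        gs = res.genome_set
        for ref in res.tree.ingroup:
            expected = 0
            for ev in gs.truth:
                if ref not in ev.coordinates:
                    continue
                if ev.truncation_5p >= cfg.max_truncation:
                    continue
                if ev.truncation_3p >= cfg.max_truncation:
                    continue
                _, s, e, _ = ev.coordinates[ref]
                if s < cfg.flank_len or e + cfg.flank_len > len(gs.sequences[ref]):
                    continue
                expected += 1
            assert len(res.candidates_by_reference[ref]) == expected
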