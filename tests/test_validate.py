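"""Strict orthology criteria: TSDs, duplication screen, rejection taxonomy."""

from __future__ import annotations

import numpy as np
import pytest

from retrophylo import PipelineConfig, check_duplication, detect_tsd, verify_orthology
from retrophylo._seq import KmerIndex
from retrophylo.annotate import CandidateLocus, RepeatAnnotation
from retrophylo.screen import ABSENT, AMBIGUOUS, PRESENT, PresenceCall, SpeciesEvidence
from retrophylo.validate import (
    REJECT_AMBIGUOUS,
    REJECT_DUPLICATION,
    REJECT_FLANK_TRANSFER,
    REJECT_ORIENTATION,
    REJECT_OUTGROUP,
    REJECT_REPRESENTATIVES,
    REJECT_SHIFT,
    TSD,
    annotate_genic_context,
    load_gene_annotation,
)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestTsdDetection:
    def _window(self, tsd, elem, pad=40, seed=50):
        left = _random_seq(pad, seed)
        right = _random_seq(pad, seed + 1)
        window = left + tsd + elem + tsd + right
        es = pad + len(tsd)
        return window, es, es + len(elem)

    def test_exact_direct_repeat_detected(self):
        tsd = "ACGTTGCAACGT"  # 12 nt
        window, es, ee = self._window(tsd, _random_seq(150, 52))
        hit = detect_tsd(window, es, ee)
        assert hit is not None
        assert (hit.length, hit.sequence, hit.mismatches) == (12, tsd, 0)

    def test_repeat_below_minimum_length_ignored(self):
        # only a 6-mer repeats at the boundaries: below the 8 nt minimum
        tsd = "ACGTGA"
        window, es, ee = self._window(tsd, _random_seq(150, 53), seed=54)
        assert detect_tsd(window, es, ee) is None

    def test_one_mismatch_allowed_for_long_repeats(self):
        left = "ACGTACGTACGTAC"  # 14 nt
        right = "ACGTACCTACGTAC"  # one internal mismatch
        pad = 40
        window = (_random_seq(pad, 55) + left + _random_seq(150, 56)
                  + right + _random_seq(pad, 57))
        es, ee = pad + 14, pad + 14 + 150
        hit = detect_tsd(window, es, ee)
        assert hit is not None and hit.length == 14 and hit.mismatches == 1

    def test_no_mismatch_allowed_for_short_repeats(self):
        left = "ACGTACGTT"  # 9 nt
        right = "ACGTACGTA"  # one mismatch: must not qualify at length 9
        pad = 40
        window = (_random_seq(pad, 58) + left + _random_seq(150, 59)
                  + right + _random_seq(pad, 60))
        hit = detect_tsd(window, pad + 9, pad + 9 + 150)
        assert hit is None or hit.mismatches == 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            detect_tsd("ACGT" * 10, 5, 20)

    def test_planted_tsds_recovered_exactly(self, zero_mut_pipeline):
        """Mutation-free study: detected TSD length equals the planted one."""
        res = zero_mut_pipeline
        truth = {ev.event_id: ev for ev in res.genome_set.truth}
        cfg = PipelineConfig()
        checked = 0
        for ev in res.genome_set.truth:
            for sp, (contig, s, e, strand) in ev.coordinates.items():
                seq = res.genome_set.sequences[sp]
                ws = s - cfg.tsd_max
                hit = detect_tsd(seq[ws : e + cfg.tsd_max], s - ws, e - ws, cfg)
                assert hit is not None
                assert hit.length == ev.tsd_length
                checked += 1
        assert checked > 0


class TestDuplicationScreen:
    def _locus(self, genome_seq, start, end, left, right):
        ann = RepeatAnnotation(species="s", contig="c1", start=start, end=end,
                               strand="+", family="F", divergence=0.0)
        return CandidateLocus("s|c1", "s", ann, left, right, 0.0)

    def test_unique_locus_not_flagged(self):
        seq = _random_seq(4000, 61)
        locus = self._locus(seq, 1000, 1180, seq[500:1000], seq[1180:1680])
        idx = KmerIndex({"c1": seq}, 20)
        assert check_duplication(locus, idx, {"c1": seq}) is False

    def test_segmental_duplication_flagged(self):
        seq = _random_seq(4000, 62)
        dup = seq + seq[400:1800]  # locus region duplicated at the end
        locus = self._locus(dup, 1000, 1180, dup[500:1000], dup[1180:1680])
        idx = KmerIndex({"c1": dup}, 20)
        assert check_duplication(locus, idx, {"c1": dup}) is True

    def test_diverged_copy_below_identity_not_flagged(self):
        rng = np.random.default_rng(63)
        seq = _random_seq(4000, 64)
        flank = seq[500:1000]
        # second copy at ~85% identity: below the 90% duplication threshold
        copy = list(flank)
        for i in rng.choice(len(copy), size=75, replace=False):
            copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        full = seq + "".join(copy) + _random_seq(200, 65)
        locus = self._locus(full, 1000, 1180, flank, full[1180:1680])
        idx = KmerIndex({"c1": full}, 20)
        assert check_duplication(locus, idx, {"c1": full}) is False


def _evidence(state, family="F", strand="+", shift=0, gap=""):
    if state == PRESENT:
        return SpeciesEvidence(state=state, contig="c", window_start=0,
                               window_end=10, orientation="+", family=family,
                               element_strand=strand, element_start=1,
                               element_end=2, shift=shift)
    if state == ABSENT:
        return SpeciesEvidence(state=state, contig="c", window_start=0,
                               window_end=10, orientation="+", gap_seq=gap,
                               junction_start=5, junction_end=5 + len(gap))
    return SpeciesEvidence(state=state, reason="x")


def _call(evidence):
    call = PresenceCall(locus_id="L", reference_species="L1", family="F")
    call.evidence = evidence
    return call


LMAP = {"L1": "L1", "L2": "L2", "L3": "L3", "O": "outgroup"}


class TestVerifyOrthology:
    def _h1_call(self, **overrides):
        ev = {
            "L1": _evidence(PRESENT, shift=0),
            "L2": _evidence(PRESENT, shift=0),
            "L3": _evidence(ABSENT),
            "O": _evidence(ABSENT),
        }
        ev.update(overrides)
        return _call(ev)

    def _verify(self, call, **kw):
        kw.setdefault("min_lineage_representatives", 1)
        return verify_orthology(call, "H1", LMAP, PipelineConfig(), **kw)

    def test_two_nt_shift_accepted(self):
        res = self._verify(self._h1_call(L2=_evidence(PRESENT, shift=2)))
        assert res.accepted
        assert res.marker.hypothesis == "H1"

    def test_three_nt_shift_rejected(self):
        res = self._verify(self._h1_call(L2=_evidence(PRESENT, shift=3)))
        assert not res.accepted and res.reason == REJECT_SHIFT

    def test_opposite_orientation_rejected(self):
        res = self._verify(self._h1_call(L2=_evidence(PRESENT, strand="-")))
        assert not res.accepted and res.reason == REJECT_ORIENTATION

    def test_family_mismatch_rejected(self):
        res = self._verify(self._h1_call(L2=_evidence(PRESENT, family="G")))
        assert res.reason == "family"

    def test_ambiguous_state_rejected(self):
        res = self._verify(self._h1_call(L3=_evidence(AMBIGUOUS)))
        assert res.reason == REJECT_AMBIGUOUS

    def test_outgroup_presence_rejected(self):
        res = self._verify(self._h1_call(O=_evidence(PRESENT)))
        assert res.reason == REJECT_OUTGROUP

    def test_duplication_flag_rejected(self):
        res = self._verify(self._h1_call(), duplication=True)
        assert res.reason == REJECT_DUPLICATION

    def test_representative_minimum_enforced(self):
        res = verify_orthology(self._h1_call(), "H1", LMAP, PipelineConfig(),
                               min_lineage_representatives=2)
        assert res.reason == REJECT_REPRESENTATIVES

    def test_cotransferred_flank_rejected(self):
        # 20 unexplained nt at an absence junction, unlike the 12-nt TSD
        res = self._verify(
            self._h1_call(L3=_evidence(ABSENT, gap="ACGTACGTACGTACGTACGT")),
            tsd=TSD("GGGTTTCCCAAA", 12),
        )
        assert res.reason == REJECT_FLANK_TRANSFER

    def test_retained_target_site_copy_tolerated(self):
        res = self._verify(
            self._h1_call(L3=_evidence(ABSENT, gap="GGGTTTCCCAAA")),
            tsd=TSD("GGGTTTCCCAAA", 12),
        )
        assert res.accepted

    def test_rejection_reasons_partition_inputs(self):
        calls = [
            self._h1_call(),
            self._h1_call(L2=_evidence(PRESENT, shift=5)),
            self._h1_call(L3=_evidence(AMBIGUOUS)),
            self._h1_call(O=_evidence(PRESENT)),
        ]
        results = [self._verify(c) for c in calls]
        accepted = sum(r.accepted for r in results)
        rejected = sum(not r.accepted for r in results)
        assert accepted + rejected == len(calls)
        assert all(r.reason is not None for r in results if not r.accepted)


GFF3 = """\
##gff-version 3
c1\tsrc\tgene\t1001\t5000\t.\t+\t.\tID=gene1
c1\tsrc\texon\t1001\t1500\t.\t+\t.\tID=exon1;Parent=gene1
c1\tsrc\texon\t4001\t5000\t.\t+\t.\tID=exon2;Parent=gene1
"""


@pytest.fixture(scope="module")
def db(tmp_path_factory):
    fp = tmp_path_factory.mktemp("gff") / "genes.gff3"
    fp.write_text(GFF3)
    return load_gene_annotation(fp)


class TestGenicContext:
    def test_between_exons_is_intron(self, db):
        assert annotate_genic_context("c1", 2000, 2180, db) == "intron"

    def test_inside_exon_is_exonic(self, db):
        assert annotate_genic_context("c1", 1100, 1200, db) == "exonic"

    def test_outside_genes_is_intergenic(self, db):
        assert annotate_genic_context("c1", 8000, 8180, db) == "intergenic"

    def test_unannotated_contig_is_unknown(self, db):
        assert annotate_genic_context("c99", 10, 20, db) == "unknown"
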