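"""Tests for clone classification, TSS mapping, donors and ATG scanning."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

import riftscan as rs
from riftscan.coords import genomic_to_l1, l1_to_genomic
from riftscan.features import (OTHER, PREMATURE_SENSE_POLYA, SPLICED_AS_RIFT,
                               UNSPLICED_AS_RIFT, CLASS_LABELS, class_counts,
                               classify_clone, find_splice_donors, map_tss,
                               scan_atg, summarize_donor_usage)
from riftscan.models import L1Integrant, L1Reference, TranscriptClone


def _l1(strand="-", start=10_000, end=17_000, l1_id="L1_ref"):
    return L1Integrant(l1_id=l1_id, chrom="chr1", start=start, end=end,
                       strand=strand, subfamily="L1Md_T", full_length=True,
                       present_in=frozenset({"B6"}))


def _clone(blocks, strand="+", five_prime=None, polya=False,
           clone_id="c1", tissue="testis"):
    blocks = tuple(("chr1", s, e) for s, e in blocks)
    if five_prime is None:
        five_prime = blocks[0][1] if strand == "+" else blocks[-1][2] - 1
    return TranscriptClone(clone_id=clone_id, tissue=tissue, strain="B6",
                           blocks=blocks, strand=strand,
                           five_prime_genomic=five_prime, has_polyA=polya)


class TestClassifyClone:
    def test_two_block_antisense_clone_is_spliced_rift(self):
        # block 1 antisense inside the minus-strand L1, block 2 in a
        # downstream gene exon
        clone = _clone([(14_800, 15_200), (30_000, 30_200)], strand="+")
        assert classify_clone(clone, [_l1()]) == SPLICED_AS_RIFT

    def test_single_block_through_l1_5prime_is_unspliced_rift(self):
        # minus-strand L1: its 5' end is at the genomic right edge
        clone = _clone([(14_800, 17_500)], strand="+")
        assert classify_clone(clone, [_l1()]) == UNSPLICED_AS_RIFT

    def test_sense_polya_clone_within_l1_is_premature(self):
        clone = _clone([(10_100, 10_700)], strand="-", polya=True)
        assert classify_clone(clone, [_l1()]) == PREMATURE_SENSE_POLYA

    def test_clone_outside_any_l1_is_other(self):
        clone = _clone([(500_000, 500_600)])
        assert classify_clone(clone, [_l1()]) == OTHER

    def test_sense_clone_without_polya_is_other(self):
        clone = _clone([(10_100, 10_700)], strand="-", polya=False)
        assert classify_clone(clone, [_l1()]) == OTHER

    def test_every_generated_clone_gets_exactly_one_label(self, default_run):
        labels = [classify_clone(c, default_run["annotation"].l1s)
                  for c in default_run["clones"]]
        assert set(labels) <= set(CLASS_LABELS)

    def test_decoys_classify_as_premature_sense(self, default_run):
        ann = default_run["annotation"]
        for clone in default_run["clones"]:
            if clone.clone_id.startswith("decoy"):
                assert classify_clone(clone, ann.l1s) == PREMATURE_SENSE_POLYA

    def test_class_count_table_percentages(self):
        l1 = _l1()
        clones = (
            [_clone([(14_800, 15_200), (30_000, 30_200)], clone_id=f"s{i}")
             for i in range(21)]
            + [_clone([(14_800, 17_500)], clone_id=f"u{i}") for i in range(4)]
            + [_clone([(10_100, 10_700)], strand="-", polya=True,
                      clone_id=f"p{i}") for i in range(2)])
        table = class_counts(clones, [l1]).set_index("clone_class")
        assert table.loc[SPLICED_AS_RIFT, "count"] == 21
        assert table.loc[SPLICED_AS_RIFT, "percent"] == 78  # 21/27
        assert table.loc[UNSPLICED_AS_RIFT, "percent"] == 15  # 4/27
        assert table.loc[PREMATURE_SENSE_POLYA, "percent"] == 7


class TestCoordinates:
    def test_plus_strand_l1_start_maps_to_coordinate_one(self):
        l1 = _l1(strand="+", start=1000, end=8000)
        assert genomic_to_l1(1000, l1) == 1

    def test_minus_strand_mapping_matches_hand_computation(self):
        l1 = _l1(strand="-", start=1000, end=8000)
        assert genomic_to_l1(5799, l1) == 8000 - 5799  # 2201

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(strand=st.sampled_from("+-"),
           start=st.integers(min_value=0, max_value=10**8),
           length=st.integers(min_value=1, max_value=8000),
           data=st.data())
    def test_round_trip_is_identity_on_both_strands(self, strand, start,
                                                    length, data):
        l1 = L1Integrant(l1_id="x", chrom="chr1", start=start,
                         end=start + length, strand=strand,
                         subfamily="L1Md_T", full_length=length > 5000,
                         present_in=frozenset({"B6"}))
        coord = data.draw(st.integers(min_value=1, max_value=length))
        pos = l1_to_genomic(coord, l1)
        assert genomic_to_l1(pos, l1) == coord
        gpos = data.draw(st.integers(min_value=start,
                                     max_value=start + length - 1))
        assert l1_to_genomic(genomic_to_l1(gpos, l1), l1) == gpos

    def test_positions_outside_the_element_are_rejected(self):
        l1 = _l1(strand="+", start=1000, end=8000)
        with pytest.raises(ValueError):
            genomic_to_l1(999, l1)
        with pytest.raises(ValueError):
            l1_to_genomic(0, l1)


class TestMapTss:
    def test_planted_testis_clones_map_into_the_race_window(self, default_run):
        ann = default_run["annotation"]
        as_clones = [c for c in default_run["clones"]
                     if classify_clone(c, ann.l1s).endswith("AS_RIFT")]
        dist = map_tss(as_clones, ann.l1s, default_run["ref"])
        for tissue, counter in dist.items():
            lo, hi = default_run["config"].tss_window_for(tissue)
            assert min(counter) >= lo and max(counter) <= hi

    def test_counts_are_conserved(self, default_run):
        ann = default_run["annotation"]
        clones = default_run["clones"]
        mappable = [c for c in clones
                    if any(l1.start <= c.five_prime_genomic < l1.end
                           for l1 in ann.l1s)]
        dist = map_tss(clones, ann.l1s)
        assert sum(sum(c.values()) for c in dist.values()) == len(mappable)

    def test_unmappable_clone_is_skipped(self):
        clone = _clone([(500_000, 500_600)])
        assert map_tss([clone], [_l1()]) == {}


class TestSpliceDonors:
    @pytest.fixture(scope="class")
    @staticmethod
    def ref():
        return rs.make_l1_reference(seed=0)

    def _spliced_clone(self, l1, donor_coord, tss=2230):
        if l1.strand == "-":
            blocks = [(l1.end - tss, l1.end - donor_coord + 1),
                      (l1.end + 5_000, l1.end + 5_200)]
            strand = "+"
        else:
            blocks = [(l1.start - 5_200, l1.start - 5_000),
                      (l1.start + donor_coord - 1, l1.start + tss)]
            strand = "-"
        return _clone(blocks, strand=strand)

    @pytest.mark.parametrize("strand", ["-", "+"])
    @pytest.mark.parametrize("donor,exonic,intronic", [
        (1838, "GATG", "gtgag"), (1892, "TCAG", "gtgtg")])
    def test_canonical_donors_reproduce_their_motifs(self, ref, strand,
                                                     donor, exonic, intronic):
        l1 = _l1(strand=strand, start=100_000, end=107_000)
        call = find_splice_donors(self._spliced_clone(l1, donor), [l1], ref)
        assert call is not None and call.valid
        assert call.exonic4 == exonic
        assert call.intronic5 == intronic
        assert call.l1_sense_coord == donor
        assert call.donor_9mer == exonic + intronic

    def test_unspliced_clone_has_no_donor(self, ref):
        l1 = _l1()
        clone = _clone([(14_800, 17_500)], strand="+")
        assert find_splice_donors(clone, [l1], ref) is None

    def test_noncanonical_junction_flagged_invalid(self):
        # reference with no gt at the junction's intron side
        ref = L1Reference(name="flat", length=7000,
                          sense_sequence="A" * 7000)
        l1 = _l1(strand="-", start=100_000, end=107_000)
        call = find_splice_donors(self._spliced_clone(l1, 1838), [l1], ref)
        assert call is not None and not call.valid
        assert not call.intronic5.startswith("gt")

    def test_generated_clone_donors_match_truth(self, default_run):
        ann, ref = default_run["annotation"], default_run["ref"]
        truth = {r.l1_id: r for r in default_run["planted"]}
        n_canonical = 0
        for clone in default_run["clones"]:
            call = find_splice_donors(clone, ann.l1s, ref)
            if call is None:
                continue
            l1 = next(l1 for l1 in ann.l1s
                      if l1.start <= clone.five_prime_genomic < l1.end)
            rift = truth[l1.l1_id]
            assert call.l1_sense_coord == rift.donor_l1_coord
            if rift.donor_motif is not None:
                assert call.donor_9mer == rift.donor_motif
                assert call.valid
                n_canonical += 1
            if call.valid:
                assert call.intronic5.startswith("gt")
        assert n_canonical > 0


class TestScanAtg:
    def test_window_without_purines_has_no_starts(self):
        ref = L1Reference(name="g", length=60, sense_sequence="G" * 60)
        assert scan_atg(ref, (1, 60)) == []  # antisense is all C

    def test_single_atg_offset_and_frame(self):
        # antisense of the window reads CATGG -> one ATG at offset 1, frame 1
        ref = L1Reference(name="t", length=5,
                          sense_sequence=rs.revcomp("CATGG"))
        hits = scan_atg(ref, (1, 5))
        assert hits == [(1, 1, 4)]

    def test_eight_planted_antisense_starts_in_two_frames(self):
        offsets = [0, 6, 12, 18, 25, 31, 37, 43]  # frames 0 and 1
        as_seq = ["C"] * 60
        for off in offsets:
            as_seq[off:off + 3] = "ATG"
        ref = L1Reference(name="orf1", length=60,
                          sense_sequence=rs.revcomp("".join(as_seq)))
        hits = scan_atg(ref, (1, 60))
        assert [h[0] for h in hits] == offsets
        assert {h[1] for h in hits} == {0, 1}
        assert len(hits) == 8

    def test_window_outside_reference_raises(self):
        ref = L1Reference(name="g", length=10, sense_sequence="G" * 10)
        with pytest.raises(ValueError):
            scan_atg(ref, (5, 11))


class TestDonorUsage:
    def test_published_style_usage_table(self):
        calls = (
            [rs.SpliceDonorCall(f"a{i}", "GATG", "gtgag", 1838, True)
             for i in range(44)]
            + [rs.SpliceDonorCall(f"b{i}", "TCAG", "gtgtg", 1892, True)
               for i in range(13)]
            + [rs.SpliceDonorCall(f"c{i}", "CCCC", "gtaaa", 2000, True)
               for i in range(8)])
        table = summarize_donor_usage(calls).set_index("donor")
        assert table.loc["GATGgtgag", "count"] == 44
        assert table.loc["GATGgtgag", "percent"] == 68
        assert table.loc["TCAGgtgtg", "percent"] == 20

    def test_single_donor_is_100_percent(self):
        calls = [rs.SpliceDonorCall("a", "GATG", "gtgag", 1838, True)]
        assert summarize_donor_usage(calls)["percent"].iloc[0] == 100

    def test_empty_input_gives_empty_table(self):
        assert summarize_donor_usage([]).empty
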