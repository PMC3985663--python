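"""Unit and property tests for the probe-run caller and the L1 join."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import riftscan as rs
from riftscan.caller import (interval_gap, l1_passes_static_filters,
                             normalize_subfamily)
from riftscan.models import CallerParams, GeneModel, GenomeAnnotation, \
    L1Integrant, RunCall

from conftest import tiny_matrix


def brute_force_runs(flags: list[bool], min_run: int) -> list[tuple[int, int]]:
    """All maximal windows of consecutive True of length >= min_run."""
    out = []
    n = len(flags)
    for i in range(n):
        for j in range(i + min_run, n + 1):
            if all(flags[i:j]) \
                    and (i == 0 or not flags[i - 1]) \
                    and (j == n or not flags[j]):
                out.append((i, j))
    # windows nested in a maximal one are excluded by the edge conditions;
    # keep only the longest per start (maximality)
    return [(i, j) for i, j in out
            if not any(a <= i and j <= b and (a, b) != (i, j) for a, b in out)]


class TestThreshold:
    def test_constant_intensities_give_zero_sd(self):
        m = tiny_matrix([6.0] * 10)
        assert rs.compute_threshold(m, "s1") == pytest.approx(6.0)

    def test_mean_plus_sample_sd(self):
        m = tiny_matrix([5, 6, 7, 8, 9])
        expected = 7.0 + math.sqrt(2.5)  # n-1 denominator
        assert rs.compute_threshold(m, "s1") == pytest.approx(expected)

    def test_single_probe_is_insufficient(self):
        m = tiny_matrix([6.0])
        with pytest.raises(ValueError, match="2 probes"):
            rs.compute_threshold(m, "s1")

    def test_sd_multiplier_scales(self):
        m = tiny_matrix([5, 6, 7, 8, 9])
        t2 = rs.compute_threshold(m, "s1", CallerParams(sd_multiplier=2))
        assert t2 == pytest.approx(7.0 + 2 * math.sqrt(2.5))


class TestHighProbes:
    def test_strictly_above_threshold(self):
        m = tiny_matrix([5, 6, 7, 8, 9])
        flags = rs.call_high_probes(m, "s1", 7.0)
        assert flags.tolist() == [False, False, False, True, True]

    def test_probe_at_threshold_is_not_high(self):
        m = tiny_matrix([7.0, 7.0001])
        assert rs.call_high_probes(m, "s1", 7.0).tolist() == [False, True]

    def test_minus_infinity_flags_everything(self):
        m = tiny_matrix([1, 2, 3])
        assert rs.call_high_probes(m, "s1", -np.inf).all()

    def test_computed_threshold_flags_exactly_one(self):
        m = tiny_matrix([5, 6, 7, 8, 9])
        thr = rs.compute_threshold(m, "s1")
        assert rs.call_high_probes(m, "s1", thr).sum() == 1  # only the 9


class TestFindRuns:
    def test_five_consecutive_then_low(self):
        m = tiny_matrix([0] * 6)
        flags = [True] * 5 + [False]
        runs = rs.find_runs(m, "s1", np.array(flags))
        assert len(runs) == 1 and runs[0].run_length == 5

    def test_all_low_yields_nothing(self):
        m = tiny_matrix([0] * 8)
        assert rs.find_runs(m, "s1", np.zeros(8, dtype=bool)) == []

    def test_maximal_run_of_six(self):
        flags = [True, True, False, True, True, True, True, True, True]
        m = tiny_matrix([0] * 9)
        runs = rs.find_runs(m, "s1", np.array(flags))
        assert len(runs) == 1
        assert runs[0].probe_indices == tuple(range(3, 9))

    def test_runs_do_not_cross_gene_boundaries(self):
        genes = ["g1"] * 4 + ["g2"] * 4
        m = tiny_matrix([0] * 8, gene_ids=genes)
        runs = rs.find_runs(m, "s1", np.ones(8, dtype=bool),
                            CallerParams(min_run=5))
        assert runs == []  # 8 high probes, but max 4 per gene

    def test_unassigned_probes_are_ignored(self):
        m = tiny_matrix([0] * 6, gene_ids=[""] * 6)
        assert rs.find_runs(m, "s1", np.ones(6, dtype=bool)) == []

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(flags=st.lists(st.booleans(), min_size=1, max_size=50),
           min_run=st.integers(min_value=1, max_value=6))
    def test_matches_brute_force_window_scan(self, flags, min_run):
        m = tiny_matrix([0] * len(flags))
        runs = rs.find_runs(m, "s1", np.array(flags),
                            CallerParams(min_run=min_run))
        got = [(r.probe_indices[0], r.probe_indices[-1] + 1) for r in runs]
        assert got == brute_force_runs(flags, min_run)


def _gene(gene_id="geneA", start=100_000, end=200_000, strand="+",
          chrom="chr1", n_exons=5):
    width = (end - start) // n_exons
    exons = tuple((start + i * width, start + i * width + 200)
                  for i in range(n_exons))
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, exons=exons)


def _l1(l1_id="L1_x", start=150_000, end=157_000, strand="-",
        subfamily="L1Md_T", chrom="chr1", present=("B6",), full_length=True):
    return L1Integrant(l1_id=l1_id, chrom=chrom, start=start, end=end,
                       strand=strand, subfamily=subfamily,
                       full_length=full_length,
                       present_in=frozenset(present))


def _run_for(gene, matrix):
    idx = tuple(int(i) for i in
                matrix.probes.index[matrix.probes["gene_id"] == gene.gene_id])
    return RunCall(gene_id=gene.gene_id, sample_id="s1", probe_indices=idx)


class TestFindInitiatingL1:
    def setup_method(self):
        self.gene = _gene()
        self.matrix = tiny_matrix([9] * 5, gene_ids=["geneA"] * 5,
                                  start0=100_000, step=20_000)
        self.run = _run_for(self.gene, self.matrix)

    def _ann(self, *l1s):
        return GenomeAnnotation(genes=(self.gene,), l1s=tuple(l1s))

    def test_intronic_antisense_l1_matches_at_distance_zero(self):
        hit = rs.find_initiating_l1(self.run, self.matrix.probes,
                                    self._ann(_l1()))
        assert hit is not None
        l1, dist_gene, dist_probe = hit
        assert l1.l1_id == "L1_x" and dist_gene == 0

    def test_short_l1_is_rejected(self):
        short = _l1(end=154_000)  # 4 kb
        assert rs.find_initiating_l1(self.run, self.matrix.probes,
                                     self._ann(short)) is None

    def test_both_distance_clauses_fail(self):
        # > 100 kb from every run probe and > 30 kb from the gene span
        far = _l1(start=310_026, end=317_026)
        gap_probe = min(interval_gap(far.start, far.end, s, e)
                        for s, e in zip(self.matrix.probes["start"],
                                        self.matrix.probes["end"]))
        assert gap_probe > 100_000
        assert interval_gap(far.start, far.end, *self.gene.span) > 30_000
        assert rs.find_initiating_l1(self.run, self.matrix.probes,
                                     self._ann(far)) is None

    def test_sense_l1_rejected_unless_antisense_not_required(self):
        sense = _l1(strand="+")
        assert rs.find_initiating_l1(self.run, self.matrix.probes,
                                     self._ann(sense)) is None
        hit = rs.find_initiating_l1(
            self.run, self.matrix.probes, self._ann(sense),
            CallerParams(require_antisense=False))
        assert hit is not None

    def test_inactive_subfamily_rejected(self):
        assert rs.find_initiating_l1(
            self.run, self.matrix.probes,
            self._ann(_l1(subfamily="Lx5"))) is None

    def test_tie_breaks_on_probe_distance_then_id(self):
        near = _l1(l1_id="L1_b", start=150_000, end=157_000)
        far = _l1(l1_id="L1_a", start=60_000, end=67_000)
        hit = rs.find_initiating_l1(self.run, self.matrix.probes,
                                    self._ann(near, far))
        assert hit[0].l1_id == "L1_b"  # smaller probe distance wins
        twin = _l1(l1_id="L1_a", start=150_000, end=157_000)
        hit = rs.find_initiating_l1(self.run, self.matrix.probes,
                                    self._ann(near, twin))
        assert hit[0].l1_id == "L1_a"  # equal distance: lexicographic id


class TestSubfamilyTable:
    @pytest.mark.parametrize("name,expected", [
        ("L1Md_T", "T_F"), ("L1Md_Tf_I", "T_F"), ("L1Md_Gf", "G_F"),
        ("L1Md_A", "A"), ("L1Md_F2", "F"), ("L1_Mus3", "F"),
        ("l1md_t", "T_F"), ("T_F", "T_F"), ("Lx5", None), ("B2_Mm1a", None),
    ])
    def test_repeatmasker_names_normalize(self, name, expected):
        assert normalize_subfamily(name) == expected


class TestCallRifts:
    def test_planted_truth_fully_recovered(self, default_run):
        calls = rs.call_rifts(default_run["matrix"],
                              default_run["annotation"])
        ev = rs.evaluate_against_truth(calls, default_run["planted"],
                                       default_run["matrix"])
        assert ev["precision"] == 1.0 and ev["recall"] == 1.0
        assert ev["n_expected"] > 0

    def test_polymorphic_l1_only_called_in_carrier_strains(self, default_run):
        ann, planted = default_run["annotation"], default_run["planted"]
        poly = [r for r in planted
                if r.strains < frozenset(default_run["config"].strains)]
        assert poly, "study conditions should include polymorphic RIFTs"
        calls = rs.call_rifts(default_run["matrix"], ann)
        strains = default_run["matrix"].samples.set_index("sample_id")["strain"]
        for rift in poly:
            called_strains = {strains[c.sample_id] for c in calls
                              if c.l1_id == rift.l1_id}
            assert called_strains <= rift.strains

    def test_removing_a_strain_removes_only_its_calls(self, default_run):
        ann = default_run["annotation"]
        matrix = default_run["matrix"]
        calls = rs.call_rifts(matrix, ann)
        target = calls[0]
        strains = matrix.samples.set_index("sample_id")["strain"]
        drop = strains[target.sample_id]
        l1s = tuple(
            dataclasses.replace(l1, present_in=l1.present_in - {drop})
            if l1.l1_id == target.l1_id else l1 for l1 in ann.l1s)
        calls2 = rs.call_rifts(matrix, dataclasses.replace(ann, l1s=l1s))
        removed = {(c.gene_id, c.l1_id, c.sample_id) for c in calls} \
            - {(c.gene_id, c.l1_id, c.sample_id) for c in calls2}
        assert removed == {(c.gene_id, c.l1_id, c.sample_id) for c in calls
                           if c.l1_id == target.l1_id
                           and strains[c.sample_id] == drop}

    def test_chromosome_mismatch_is_an_input_error(self):
        m = tiny_matrix([6, 6, 6], chrom="chrX")
        ann = GenomeAnnotation(genes=(_gene(),), l1s=(_l1(),))
        with pytest.raises(ValueError, match="chrX"):
            rs.call_rifts(m, ann)

    def test_tightening_thresholds_never_adds_calls(self, default_run):
        # monotonicity holds for the set of called (gene, sample) pairs: a
        # stricter threshold can split one long run into two, so the raw
        # call count is not the monotone quantity
        matrix, ann = default_run["matrix"], default_run["annotation"]

        def pairs(params=CallerParams()):
            return {(c.gene_id, c.sample_id)
                    for c in rs.call_rifts(matrix, ann, params)}

        base = pairs()
        assert pairs(CallerParams(min_run=8)) <= base
        assert pairs(CallerParams(sd_multiplier=3.0)) <= base
        wide = CallerParams(gene_distance_kb=300, probe_distance_kb=1000)
        assert pairs(wide) >= base

    def test_strain_aware_candidates(self):
        # Arhgap15-like scenario: polymorphic intronic L1 present only in B6
        gene = _gene(n_exons=10)
        l1 = _l1(start=130_000, end=137_000, present=("B6",))
        ann = GenomeAnnotation(genes=(gene,), l1s=(l1,))
        starts = [s for s, _ in gene.exons] \
            + [500_000 + 1000 * i for i in range(20)]  # background gene
        n = len(starts)
        probe_df = pd.DataFrame({
            "probe_id": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": starts,
            "end": [s + 25 for s in starts],
            "gene_id": ["geneA"] * 10 + [""] * 20,
        })
        samples = pd.DataFrame({
            "sample_id": ["B6_t", "DBA_t"], "strain": ["B6", "DBA2J"],
            "tissue": ["testis", "testis"]})
        intens = np.full((n, 2), 6.0)
        intens[5:10, :] = 18.0  # elevated 3' signal in both strains
        matrix = rs.ProbeMatrix(probe_df, samples, intens)
        calls = rs.call_rifts(matrix, ann)
        assert {c.sample_id for c in calls} == {"B6_t"}
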