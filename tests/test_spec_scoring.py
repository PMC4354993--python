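import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellici import ReferenceCompendium
from cellici.spec_scoring import (
    GeneRejected,
    build_spec_table,
    cutoff_candidates,
    filter_genes,
    find_transition_bin,
    refine_cutoff,
    spec_scores,
)

from _oracle import brute_spec


def _ref(rows: dict, labels: dict) -> ReferenceCompendium:
    return ReferenceCompendium(
        expression=pd.DataFrame(rows).T.astype(float),
        tissue_of=pd.Series(labels),
    )


class TestGeneFilters:
    def test_median_cap_is_strict(self):
        # median 251 is constitutively high; median exactly 250 is retained
        ref = _ref(
            {"hi": [251, 251, 251, 251], "edge": [250, 250, 250, 250], "zero": [0, 0, 0, 0]},
            {0: "A", 1: "A", 2: "B", 3: "B"},
        )
        kept = filter_genes(ref, median_cap=250)
        assert kept == {"edge", "zero"}

    def test_exclusion_list_beats_median(self):
        ref = _ref(
            {"wound": [1, 2, 1, 2], "ok": [1, 2, 1, 2]},
            {0: "A", 1: "A", 2: "B", 3: "B"},
        )
        assert filter_genes(ref, exclude={"wound"}) == {"ok"}


class TestTransitionBin:
    def test_hand_enumerated_occupancy(self):
        # 14 background values near zero and 6 spread high: o_1=14, o_2=0, e=2
        values = np.array([0.1 * k for k in range(14)] + [50, 60, 70, 80, 90, 100.0])
        occ = find_transition_bin(values, l=10, u=3)
        assert occ.e == 2.0
        assert occ.counts[0] == 14
        assert occ.m == 2

    def test_late_transition_rejected(self):
        # background mass pushed up so the first sub-expected bin is past u
        values = np.array(
            [1, 2, 3, 4, 11, 12, 13, 14, 21, 22, 23, 24, 31, 32, 33, 34, 41, 60, 70, 100.0]
        )  # o_1..o_4 = 4 >= e, first sub-expected bin is b=5
        counts, _ = np.histogram(values, bins=10, range=(0, 100))
        assert all(counts[:4] >= 2) and counts[4] < 2  # setup check
        with pytest.raises(GeneRejected, match="m_gt_u"):
            find_transition_bin(values, l=10, u=3)

    def test_constant_gene_rejected(self):
        with pytest.raises(GeneRejected, match="constant"):
            find_transition_bin(np.full(20, 7.0), l=10, u=3)

    def test_highest_rule_takes_topmost_sparse_bin(self):
        values = np.array([0.1 * k for k in range(14)] + [50, 60, 70, 80, 90, 100.0])
        occ = find_transition_bin(values, l=10, u=10, rule="highest")
        assert occ.m > find_transition_bin(values, l=10, u=10, rule="first").m


class TestCutoffRefinement:
    labels = np.array(["A", "A", "A", "A", "B", "B", "B", "B"] + ["C"] * 4)

    def test_separating_candidate_found(self):
        # tissue A's samples are cleanly high; the best cutoff separates them
        values = np.array([90, 95, 100, 105, 1, 2, 3, 4, 2, 3, 1, 2.0])
        occ = find_transition_bin(values, l=4, u=3)
        c = refine_cutoff(values, occ, self.labels)
        s = spec_scores(values, c, self.labels)
        assert s["A"] == pytest.approx(1.0, abs=1e-12)

    def test_tie_breaks_to_smallest_candidate(self):
        values = np.array([90, 95, 100, 105, 1, 2, 3, 4, 2, 3, 1, 2.0])
        occ = find_transition_bin(values, l=4, u=3)
        cands = cutoff_candidates(values, occ)
        best = refine_cutoff(values, occ, self.labels)
        ties = [
            c
            for c in cands
            if max(spec_scores(values, c, self.labels).values())
            == max(spec_scores(values, best, self.labels).values())
        ]
        assert best == min(ties)

    def test_single_candidate_returned(self):
        values = np.array([0.0, 0, 0, 0, 0, 0, 0, 0, 50, 60, 70, 80])
        occ = find_transition_bin(values, l=4, u=3)
        cands = cutoff_candidates(values, occ)
        if len(cands) == 1:
            assert refine_cutoff(values, occ, self.labels) == cands[0]


class TestSpecScores:
    def test_perfect_marker_and_absence_clipping(self):
        values = np.array([10.0, 12.0, 0.0, 0.0])
        labels = np.array(["A", "A", "B", "B"])
        signed = spec_scores(values, 1.0, labels, clip=False)
        assert signed["A"] == pytest.approx(1.0, abs=1e-12)
        assert signed["B"] == pytest.approx(-1.0, abs=1e-12)
        clipped = spec_scores(values, 1.0, labels)
        assert clipped["B"] == 0.0

    def test_uniform_gene_scores_zero(self):
        # identical bin membership proportions in every tissue → I(b) = 0
        values = np.array([10.0, 0.0] * 4)
        labels = np.repeat(["A", "B", "C", "D"], 2)
        s = spec_scores(values, 1.0, labels, clip=False)
        assert all(abs(v) < 1e-12 for v in s.values())

    def test_two_of_ten_tissues_closed_form(self):
        # gene high in all replicates of exactly 2 of 10 tissues
        labels = np.repeat([f"t{i}" for i in range(10)], 2)
        values = np.where(np.isin(labels, ["t0", "t1"]), 50.0, 0.0)
        s = spec_scores(values, 1.0, labels)
        expect = 1.0 - math.log(2) / math.log(10)
        assert s["t0"] == pytest.approx(expect, abs=1e-12)
        assert s["t1"] == pytest.approx(expect, abs=1e-12)
        assert all(s[f"t{i}"] == 0.0 for i in range(2, 10))

    def test_empty_high_bin_scores_zero(self):
        values = np.array([1.0, 2, 1, 2])
        s = spec_scores(values, 10.0, np.array(["A", "A", "B", "B"]))
        assert set(s.values()) == {0.0}

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        n_tissues = data.draw(st.integers(2, 4))
        reps = data.draw(st.lists(st.integers(2, 4), min_size=n_tissues, max_size=n_tissues))
        labels = np.repeat([f"t{i}" for i in range(n_tissues)], reps)
        m = labels.size
        values = np.array(
            data.draw(
                st.lists(
                    st.floats(0, 100, allow_nan=False, width=32), min_size=m, max_size=m
                )
            )
        )
        cutoff = data.draw(st.floats(-1, 101, allow_nan=False))
        ours = spec_scores(values, cutoff, labels, clip=False)
        ref = brute_spec(values.tolist(), cutoff, labels.tolist())
        for t in ref:
            assert ours[t] == pytest.approx(ref[t], abs=1e-12)
            assert -1 - 1e-12 <= ours[t] <= 1 + 1e-12

    def test_tissue_relabeling_permutes_scores(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 50, 12)
        labels = np.repeat(["A", "B", "C"], 4)
        swapped = np.where(labels == "A", "B", np.where(labels == "B", "A", "C"))
        s1 = spec_scores(values, 10.0, labels)
        s2 = spec_scores(values, 10.0, swapped)
        assert s1["A"] == s2["B"] and s1["B"] == s2["A"] and s1["C"] == s2["C"]

    def test_sample_order_irrelevant(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 50, 12)
        labels = np.repeat(["A", "B", "C"], 4)
        perm = rng.permutation(12)
        assert spec_scores(values, 10.0, labels) == spec_scores(
            values[perm], 10.0, labels[perm]
        )


class TestBuildSpecTable:
    def test_gene_scaling_invariance(self):
        # equal-width bins span each gene's own range, so a positive rescale
        # of one gene changes neither its transition bin nor its Spec scores
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.uniform(0, 3, 14), rng.uniform(60, 100, 6)])
        labels = np.repeat(["A", "B", "C", "D", "E"], 4)
        occ1 = find_transition_bin(values, l=10, u=3)
        c1 = refine_cutoff(values, occ1, labels)
        occ2 = find_transition_bin(values * 7.5, l=10, u=3)
        c2 = refine_cutoff(values * 7.5, occ2, labels)
        assert occ1.m == occ2.m
        assert c2 == pytest.approx(7.5 * c1, rel=1e-12)
        s1 = spec_scores(values, c1, labels)
        s2 = spec_scores(values * 7.5, c2, labels)
        for t in s1:
            assert s1[t] == pytest.approx(s2[t], abs=1e-12)

    def test_planted_markers_score_high(self, bench_reference, bench_spec_table):
        _, truth = bench_reference
        st_ = bench_spec_table
        for tissue, genes in truth.items():
            for g in genes:
                assert g in st_.eligible
                assert st_.spec.loc[g, tissue] >= 0.9

    def test_lower_u_is_stricter(self, bench_reference):
        ref, _ = bench_reference
        sub = ReferenceCompendium(
            expression=ref.expression.iloc[:300], tissue_of=ref.tissue_of
        )
        n_u3 = len(build_spec_table(sub, u=3).eligible)
        n_u1 = len(build_spec_table(sub, u=1).eligible)
        assert n_u1 <= n_u3

    def test_exclude_everything_empties_table(self, toy_reference):
        table = build_spec_table(toy_reference, exclude=set(toy_reference.gene_ids), l=2)
        assert len(table.eligible) == 0
        assert all(reason == "excluded" for _, reason in table.rejections)

    def test_scores_lie_in_unit_interval(self, bench_spec_table):
        vals = bench_spec_table.spec.to_numpy()
        assert vals.min() >= 0.0 and vals.max() <= 1.0
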