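"""Concordance, overlap significance, term enrichment, BH adjustment."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpscreen.errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    ParameterError,
)
from rbpscreen.stats_enrich import (
    AnnotationMap,
    benjamini_hochberg,
    hypergeom_upper_tail,
    overlap_significance,
    replicate_concordance,
    term_enrichment,
)


def exact_upper_tail(k, N, K, n):
    """Independent oracle: exact hypergeometric P(X >= k) by enumeration."""
    num = sum(math.comb(K, j) * math.comb(N - K, n - j)
              for j in range(max(k, 0, K + n - N), min(K, n) + 1))
    return num / math.comb(N, n)


class TestReplicateConcordance:
    def test_identical_scans_perfectly_concordant(self, ratio_scan):
        scan = ratio_scan({"A": 1.0, "B": 2.0, "C": 3.0, "D": 1.5})
        r, r2 = replicate_concordance(scan, scan)
        assert r2 == pytest.approx(1.0)

    def test_exact_linearity(self, ratio_scan):
        a = ratio_scan({"A": 1.0, "B": 2.0, "C": 3.0})
        b = ratio_scan({"A": 2.0, "B": 4.0, "C": 6.0})
        r, r2 = replicate_concordance(a, b)
        assert r == pytest.approx(1.0)

    def test_zero_correlation_example(self, ratio_scan):
        a = ratio_scan({"P1": 1.0, "P2": 0.0, "P3": 1.0, "P4": 0.0})
        b = ratio_scan({"P1": 1.0, "P2": 0.0, "P3": 0.0, "P4": 1.0})
        r, r2 = replicate_concordance(a, b)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_affine_invariance(self, ratio_scan):
        a = ratio_scan({"A": 1.0, "B": 2.5, "C": 3.0, "D": 0.5})
        b = ratio_scan({"A": 1.2, "B": 2.0, "C": 3.5, "D": 0.9})
        b_scaled = ratio_scan({"A": 1.2 * 3 + 1, "B": 2.0 * 3 + 1,
                               "C": 3.5 * 3 + 1, "D": 0.9 * 3 + 1})
        assert replicate_concordance(a, b)[0] == pytest.approx(
            replicate_concordance(a, b_scaled)[0])

    def test_too_few_shared_proteins(self, ratio_scan):
        a = ratio_scan({"A": 1.0, "B": 2.0})
        with pytest.raises(InsufficientDataError):
            replicate_concordance(a, a)

    def test_zero_variance_rejected(self, ratio_scan):
        flat = ratio_scan({"A": 2.0, "B": 2.0, "C": 2.0})
        other = ratio_scan({"A": 1.0, "B": 2.0, "C": 3.0})
        with pytest.raises(DegenerateDistributionError):
            replicate_concordance(flat, other)


class TestOverlapSignificance:
    def test_complete_overlap_small_universe(self):
        # both sets are the same 5 of 10: p = 1/C(10,5) = 1/252
        hits = {f"p{i}" for i in range(5)}
        assert overlap_significance(hits, hits, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert overlap_significance({"a"}, {"b"}, 100) == pytest.approx(1.0)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ParameterError):
            overlap_significance({"a", "b"}, {"c"}, 2)

    @given(st.integers(2, 40), st.data())
    @settings(max_examples=80)
    def test_matches_enumeration_oracle(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
            exact_upper_tail(k, N, K, n), abs=1e-12)


class TestTermEnrichment:
    universe = {f"p{i}" for i in range(20)}

    def ann(self, members):
        return AnnotationMap(namespace="test", terms={"T": frozenset(members)})

    def test_enumerated_example(self):
        # N=20, K=5, n=4, k=3: p = (C(5,3)C(15,1) + C(5,4)) / C(20,4) = 155/4845
        members = {f"p{i}" for i in range(5)}
        hits = {"p0", "p1", "p2", "p19"}
        (res,) = term_enrichment(hits, self.universe, self.ann(members))
        assert (res.k, res.K, res.n, res.N) == (3, 5, 4, 20)
        assert res.p == pytest.approx(155 / 4845, abs=1e-12)

    def test_ease_variant_is_larger(self):
        members = {f"p{i}" for i in range(5)}
        hits = {"p0", "p1", "p2", "p19"}
        (std,) = term_enrichment(hits, self.universe, self.ann(members))
        (eased,) = term_enrichment(hits, self.universe, self.ann(members), ease=True)
        assert eased.p == pytest.approx(exact_upper_tail(2, 20, 5, 4), abs=1e-12)
        assert eased.p > std.p

    def test_extreme_enrichment_is_minimal_p(self):
        members = {f"p{i}" for i in range(4)}
        (res,) = term_enrichment(members, self.universe, self.ann(members))
        assert res.p == pytest.approx(1 / math.comb(20, 4), abs=1e-15)

    def test_empty_hits_gives_p_one(self):
        (res,) = term_enrichment(set(), self.universe,
                                 self.ann({f"p{i}" for i in range(5)}))
        assert res.p == 1.0

    def test_term_without_universe_members_skipped(self):
        ann = AnnotationMap(namespace="t", terms={"T": frozenset({"q1", "q2"})})
        assert term_enrichment({"p0"}, self.universe, ann) == []

    def test_hits_outside_universe_rejected(self):
        with pytest.raises(ParameterError):
            term_enrichment({"zzz"}, self.universe, self.ann({"p0"}))

    def test_agrees_with_overlap_significance(self):
        # enrichment of "term = hits_b" is the same hypergeometric
        hits_a = {"p0", "p1", "p2", "p3"}
        hits_b = {"p2", "p3", "p4", "p5", "p6"}
        (res,) = term_enrichment(hits_a, self.universe, self.ann(hits_b))
        assert res.p == pytest.approx(
            overlap_significance(hits_a, hits_b, 20), abs=1e-15)

    def test_results_sorted_by_p(self):
        ann = AnnotationMap(namespace="t", terms={
            "weak": frozenset({"p10", "p11", "p12", "p13", "p14", "p0"}),
            "strong": frozenset({"p0", "p1", "p2"}),
        })
        res = term_enrichment({"p0", "p1", "p2"}, self.universe, ann)
        assert [r.term_id for r in res] == ["strong", "weak"]
        assert res[0].p_adj >= res[0].p

    def test_annotation_tsv_round_trip(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("T1\tp0\nT1\tp1\nT2\tp2\n")
        ann = AnnotationMap.from_tsv(path, namespace="pfam")
        assert ann.terms == {"T1": frozenset({"p0", "p1"}),
                             "T2": frozenset({"p2"})}


class TestBenjaminiHochberg:
    def test_hand_step_up(self):
        # p*(m/i) = (.04, .04, .04, .04) after monotonicity enforcement
        assert benjamini_hochberg([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_distinct_adjustments(self):
        out = benjamini_hochberg([0.01, 0.04, 0.9])
        assert out == pytest.approx([0.03, 0.06, 0.9])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]) == [0.2]

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=60)
    def test_bh_properties(self, pvals):
        adj = benjamini_hochberg(pvals)
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        assert all(p <= a <= 1 + 1e-12 for p, a in zip(pvals, adj))
        ranked = [adj[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(ranked, ranked[1:]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=40)
    def test_matches_hand_rolled_step_up(self, pvals):
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        adj = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, pvals[i] * m / rank)
            adj[i] = running
        assert benjamini_hochberg(pvals) == pytest.approx(adj, abs=1e-12)
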