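"""Fisher one-sided enrichment, BH adjustment, and the enrich pipeline."""

from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

from keynet.datatypes import AnalysisConfig
from keynet.enrichment import bh_adjust, enrich, fisher_term_p, top_terms
from keynet.simulate import default_universe, generate_annotations


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Direct combinatorial sum P(X >= k) for X ~ Hypergeom(N, K, n)."""
    denom = comb(N, n)
    return sum(
        comb(K, i) * comb(N - K, n - i) / denom
        for i in range(k, min(K, n) + 1)
    )


class TestFisherTermP:
    def test_zero_hits_gives_one(self):
        assert fisher_term_p(0, 5, 10, 100) == pytest.approx(1.0)

    def test_saturated_counts_give_one(self):
        assert fisher_term_p(10, 10, 10, 10) == pytest.approx(1.0)

    def test_matches_combinatorial_oracle(self):
        assert fisher_term_p(3, 5, 10, 100) == pytest.approx(
            hypergeom_tail_oracle(3, 5, 10, 100)
        )

    @given(st.data())
    def test_random_tuples_match_oracle(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert fisher_term_p(k, K, n, N) == pytest.approx(
            hypergeom_tail_oracle(k, K, n, N), rel=1e-9
        )

    def test_monotone_decreasing_in_k(self):
        ps = [fisher_term_p(k, 20, 30, 200) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_term_p(6, 5, 10, 100)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.04, 0.04, 0.04]) == pytest.approx([0.04] * 3)

    def test_hand_step_up_oracle(self):
        p = [0.005, 0.049, 0.05, 0.2, 0.9]
        m = len(p)
        # step-up: q_(i) = min_{j>=i} (m/j) p_(j), on sorted p
        sorted_q = [
            min((m / j) * p[j - 1] for j in range(i, m + 1)) for i in range(1, m + 1)
        ]
        assert bh_adjust(p) == pytest.approx(sorted_q)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=12))
    def test_stable_under_permutation(self, pvals):
        perm = list(reversed(pvals))
        direct = dict(zip(pvals, bh_adjust(pvals)))
        permuted = dict(zip(perm, bh_adjust(perm)))
        for p in pvals:
            assert direct[p] == pytest.approx(permuted[p])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


@pytest.fixture(scope="module")
def planted():
    universe = default_universe(1000)
    query = universe[:20]
    anno = generate_annotations(
        universe, query, planted_terms=[(50, 0.5)], n_decoy_terms=30, seed=5
    )
    return universe, query, anno


class TestEnrich:
    def test_planted_term_ranks_first_with_oracle_p(self, planted):
        universe, query, anno = planted
        rows = enrich(query, anno, AnalysisConfig())
        assert rows[0].term_id == "PLANT:0000"
        assert rows[0].p == pytest.approx(
            hypergeom_tail_oracle(rows[0].k, rows[0].K, rows[0].n, rows[0].N)
        )
        assert rows[0].k == 10  # half of the 20-symbol query planted in the term

    def test_query_missing_from_background_rejected(self, planted):
        _, _, anno = planted
        with pytest.raises(ValueError, match="background"):
            enrich({"NOT_A_SYMBOL"}, anno)

    def test_query_hitting_no_term_gives_no_rows(self):
        universe = default_universe(200)
        # one term over the tail of the universe; query the head
        from keynet.datatypes import AnnotationSet, Term

        term = Term("T", "tail only", "BP", frozenset(universe[100:150]))
        anno = AnnotationSet(terms=(term,), background=frozenset(universe))
        assert enrich(universe[:10], anno) == []

    def test_bh_never_reports_more_than_raw_threshold(self, planted):
        universe, query, anno = planted
        cfg = AnalysisConfig(enrichment_p_threshold=0.05, enrichment_q_threshold=0.05)
        rows = enrich(query, anno, cfg)
        raw = [
            t for t in anno.terms
            if fisher_term_p(
                len(frozenset(query) & t.members), len(t.members), 20, 1000
            ) < 0.05
        ]
        assert len(rows) <= len(raw)

    def test_term_order_invariance(self, planted):
        universe, query, anno = planted
        from keynet.datatypes import AnnotationSet

        shuffled = AnnotationSet(
            terms=tuple(reversed(anno.terms)), background=anno.background
        )
        a = {(r.term_id, r.p, r.q) for r in enrich(query, anno)}
        b = {(r.term_id, r.p, r.q) for r in enrich(query, shuffled)}
        assert a == b

    def test_bh_within_category(self):
        # identical member sets in different categories must get identical q
        universe = default_universe(100)
        query = universe[:10]
        from keynet.datatypes import AnnotationSet, Term

        members = frozenset(universe[:30])
        anno = AnnotationSet(
            terms=(
                Term("c1", "x", "CC", members),
                Term("b1", "x", "BP", members),
                Term("b2", "decoy", "BP", frozenset(universe[50:90])),
            ),
            background=frozenset(universe),
        )
        rows = enrich(query, anno, AnalysisConfig(
            enrichment_p_threshold=0.999999, enrichment_q_threshold=0.999999
        ))
        by_id = {r.term_id: r for r in rows}
        assert by_id["c1"].p == pytest.approx(by_id["b1"].p)
        # BP category carries an extra (non-significant) term in its family
        assert by_id["b1"].q >= by_id["c1"].q

    def test_top_terms_per_category(self, planted):
        universe, query, anno = planted
        cfg = AnalysisConfig(enrichment_p_threshold=0.999999, enrichment_q_threshold=0.999999)
        rows = enrich(query, anno, cfg)
        top = top_terms(rows, 5)
        assert len(top) <= 10
        bp = [r for r in top if r.category == "BP"]
        assert bp == sorted(bp, key=lambda r: r.p)[:5]
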