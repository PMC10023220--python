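"""The three scoring metrics, BH adjustment, stable ranking, and the
end-to-end query pipeline."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

import netquery as nq
from netquery.ranking import ScoredResult

from .conftest import approved_only
from .oracles import exact_hypergeom_ccdf


class TestOverlapCount:
    @pytest.mark.parametrize(
        "query, network, expected",
        [
            ({"A", "B", "C"}, {"B", "C", "D"}, 2),
            ({"A", "B"}, {"C", "D"}, 0),
            ({"A", "B"}, {"A", "B", "C", "D"}, 2),
        ],
    )
    def test_examples(self, query, network, expected):
        assert nq.overlap_count(query, network) == expected


class TestIDF:
    def test_ubiquitous_gene_weighs_zero(self):
        idx = nq.build_index(
            [
                nq.GeneSet("a", "a", frozenset("XY"), "gmt"),
                nq.GeneSet("b", "b", frozenset("XZ"), "gmt"),
            ]
        )
        assert nq.idf(idx, "X") == 0.0  # df = m
        assert nq.idf(idx, "Y") == pytest.approx(math.log(2))

    def test_closed_form(self, three_network_index):
        assert nq.idf(three_network_index, "A") == pytest.approx(math.log(3))
        assert nq.idf(three_network_index, "B") == pytest.approx(math.log(1.5))

    def test_strictly_decreasing_in_df(self):
        rng = random.Random(0)
        for _ in range(20):
            m = rng.randint(2, 500)
            df1, df2 = sorted(rng.sample(range(1, m + 1), 2))
            assert math.log(m / df1) > math.log(m / df2)

    def test_outside_universe_is_contract_violation(self, three_network_index):
        with pytest.raises(KeyError):
            nq.idf(three_network_index, "NOPE")


class TestCosineSimilarity:
    def test_self_similarity_is_one(self, three_network_index):
        assert nq.cosine_similarity({"A", "B"}, frozenset("AB"), three_network_index) == 1.0

    def test_disjoint_is_zero(self, three_network_index):
        assert nq.cosine_similarity({"A", "B"}, frozenset("CD"), three_network_index) == 0.0

    def test_three_network_closed_form(self, three_network_index):
        """Hand vector algebra: D1={A,B}, D2={B,C}, D3={C,D}, query {A,B};
        idf(A)=idf(D)=ln 3, idf(B)=idf(C)=ln(3/2)."""
        ia, ib = math.log(3.0), math.log(1.5)
        expected_d2 = ib * ib / (
            math.sqrt(ia * ia + ib * ib) * math.sqrt(ib * ib + ib * ib)
        )
        got = nq.cosine_similarity({"A", "B"}, frozenset("BC"), three_network_index)
        assert got == pytest.approx(expected_d2, abs=1e-12)
        assert nq.cosine_similarity({"A", "B"}, frozenset("AB"), three_network_index) == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_returns_zero(self):
        # the only query gene appears in every network: weight 0 everywhere
        idx = nq.build_index(
            [
                nq.GeneSet("a", "a", frozenset("BX"), "gmt"),
                nq.GeneSet("b", "b", frozenset("BY"), "gmt"),
            ]
        )
        assert nq.cosine_similarity({"B"}, frozenset("BX"), idx) == 0.0

    def test_symmetry_and_range(self, three_network_index):
        rng = random.Random(1)
        genes = ["A", "B", "C", "D"]
        for _ in range(50):
            s1 = set(rng.sample(genes, rng.randint(0, 4)))
            s2 = set(rng.sample(genes, rng.randint(0, 4)))
            a = nq.cosine_similarity(s1, s2, three_network_index)
            b = nq.cosine_similarity(s2, s1, three_network_index)
            assert a == b
            assert 0.0 <= a <= 1.0

    def test_rare_gene_contributes_more_than_common(self):
        """Swapping a common query gene for a rare gene the network also
        contains never decreases similarity to that network."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            m = int(rng.integers(4, 30))
            genes = [f"G{i}" for i in range(40)]
            sets = []
            for i in range(m):
                members = set(rng.choice(genes[2:], size=8, replace=False))
                members |= {"COMMON"}  # df = m
                sets.append(nq.GeneSet(f"s{i}", f"s{i}", frozenset(members), "gmt"))
            # one network additionally holds the rare gene (df = 1)
            target = nq.GeneSet(
                "target", "target", sets[0].genes | {"RARE"}, "gmt"
            )
            idx = nq.build_index(sets[1:] + [target])
            base = set(rng.choice(sorted(target.genes - {"RARE", "COMMON"}), size=3, replace=False))
            with_common = nq.cosine_similarity(base | {"COMMON"}, target.genes, idx)
            with_rare = nq.cosine_similarity(base | {"RARE"}, target.genes, idx)
            assert with_rare >= with_common


class TestHypergeomCCDF:
    def test_ccdf_at_zero_is_one(self):
        for N, K, n in [(10, 3, 4), (5, 0, 5), (1, 1, 0)]:
            assert nq.hypergeom_ccdf(N, K, n, 0) == 1.0

    def test_all_success_urn(self):
        assert nq.hypergeom_ccdf(7, 7, 3, 3) == 1.0
        assert nq.hypergeom_ccdf(7, 7, 3, 2) == 1.0

    def test_exact_value_small_urn(self):
        # sum_{i=3}^{5} C(5,i) C(15,5-i) / C(20,5) = 1126/15504
        assert nq.hypergeom_ccdf(20, 5, 5, 3) == pytest.approx(
            1126 / 15504, rel=1e-12
        )

    @pytest.mark.parametrize(
        "N, K, n, k",
        [(5, 6, 2, 1), (5, 3, 6, 1), (10, 3, 3, 4), (10, 3, 3, -1), (-1, 0, 0, 0)],
    )
    def test_invalid_arguments_rejected(self, N, K, n, k):
        with pytest.raises(ValueError):
            nq.hypergeom_ccdf(N, K, n, k)

    def test_non_increasing_in_k(self):
        rng = random.Random(3)
        for _ in range(20):
            N = rng.randint(2, 40)
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            values = [nq.hypergeom_ccdf(N, K, n, k) for k in range(min(K, n) + 1)]
            assert values[0] == 1.0
            assert all(a >= b for a, b in zip(values, values[1:]))
            assert all(v > 0 for v in values)

    def test_matches_exact_oracle_on_spot_checks(self):
        rng = random.Random(4)
        for _ in range(200):
            N = rng.randint(1, 60)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k = rng.randint(0, min(K, n))
            exact = float(exact_hypergeom_ccdf(N, K, n, k))
            assert nq.hypergeom_ccdf(N, K, n, k) == pytest.approx(exact, rel=1e-12)

    def test_underflow_falls_back_to_positive_value(self):
        # the double-precision tail underflows; the result must stay > 0
        p = nq.hypergeom_ccdf(100_000, 500, 500, 500)
        assert 0.0 < p < 1e-300


class TestBHAdjust:
    def test_single_pvalue_identity(self):
        assert nq.bh_adjust([0.04], 1) == [0.04]

    def test_textbook_example(self):
        assert nq.bh_adjust([0.01, 0.02, 0.06], 3) == pytest.approx(
            [0.03, 0.03, 0.06]
        )

    def test_bounded_by_one(self):
        # 0.9 * 2 / 1 = 1.8 would escape [0, 1]; the step-up minimum
        # (or, failing that, the cap) keeps every adjusted value <= 1
        adj = nq.bh_adjust([0.9, 0.95], 2)
        assert all(a <= 1.0 for a in adj)
        assert adj == pytest.approx([0.95, 0.95])
        assert nq.bh_adjust([0.99], 1) == [0.99]
        assert nq.bh_adjust([0.6, 0.99], 2) == pytest.approx([0.99, 0.99])

    def test_m_may_exceed_pvalue_count(self):
        # zero-overlap networks inflate the multiplicity but yield no p
        assert nq.bh_adjust([0.01], 100) == [1.0]
        assert nq.bh_adjust([0.001, 0.002], 10) == pytest.approx([0.01, 0.01])

    def test_m_below_count_rejected(self):
        with pytest.raises(ValueError):
            nq.bh_adjust([0.1, 0.2], 1)

    def test_ties_get_equal_adjusted_values(self):
        adj = nq.bh_adjust([0.05, 0.05, 0.05], 3)
        assert adj == pytest.approx([0.05, 0.05, 0.05])

    @given(
        st.lists(
            st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60
        ),
        st.integers(0, 500),
    )
    def test_contract_properties(self, p, extra):
        """Adjusted values dominate raw, stay in (0,1], are monotone in
        raw order, and match p*m/rank when that sequence is monotone."""
        m = len(p) + extra
        adj = nq.bh_adjust(p, m)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1.0 for a in adj)
        order = sorted(range(len(p)), key=lambda i: p[i])
        along = [adj[i] for i in order]
        assert all(x <= y for x, y in zip(along, along[1:]))
        plain = [p[i] * m / (r + 1) for r, i in enumerate(order)]
        if all(x <= y for x, y in zip(plain, plain[1:])):
            assert along == pytest.approx([min(1.0, v) for v in plain])

    def test_cross_check_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 40))).tolist()
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            assert nq.bh_adjust(p, len(p)) == pytest.approx(expected.tolist())


def _result(set_id, k=1, sim=0.5, p_adj=0.5):
    return ScoredResult(
        set_id=set_id,
        name=set_id,
        K=k,
        k=k,
        similarity=sim,
        p_raw=p_adj,
        pvalue_rank=1,
        p_adj=p_adj,
        overlapping_genes=[],
    )


class TestRankResults:
    def test_chained_sort_composes(self):
        """Sorting by p-value and then by overlap gives an overlap-major
        list whose overlap-ties are ordered by p-value."""
        rows = [
            _result("a", k=2, p_adj=0.30),
            _result("b", k=3, p_adj=0.20),
            _result("c", k=2, p_adj=0.10),
            _result("d", k=3, p_adj=0.40),
            _result("e", k=1, p_adj=0.05),
        ]
        chained = nq.rank_results(nq.rank_results(rows, "pvalue"), "overlap")
        assert [r.set_id for r in chained] == ["b", "d", "c", "a", "e"]

    def test_all_ties_preserve_input_order(self):
        rows = [_result(s) for s in "abcd"]
        for key in nq.SORT_KEYS:
            assert [r.set_id for r in nq.rank_results(rows, key)] == list("abcd")

    def test_single_result(self):
        rows = [_result("only")]
        assert nq.rank_results(rows, "similarity") == rows

    def test_unknown_sort_key_rejected(self):
        with pytest.raises(ValueError, match="sort key"):
            nq.rank_results([], "alphabetical")

    def test_stability_against_decorated_oracle(self):
        from .oracles import decorated_sort

        rng = random.Random(6)
        for _ in range(30):
            rows = [
                (rng.randint(0, 3), rng.choice([0.1, 0.2, 0.3]), i)
                for i in range(rng.randint(1, 40))
            ]
            results = [
                _result(f"r{i}", k=k, sim=s, p_adj=s) for k, s, i in rows
            ]
            for key, idx, desc in [
                ("overlap", 0, True),
                ("similarity", 1, True),
                ("pvalue", 1, False),
            ]:
                got = [r.set_id for r in nq.rank_results(results, key)]
                expected = [
                    f"r{t[2]}" for t in decorated_sort(rows, idx, desc)
                ]
                assert got == expected


class TestRunQuery:
    def test_planted_network_ranks_first_under_all_keys(self):
        spec = nq.FixtureSpec(n_networks=50, universe_size=300, seed=11)
        sets, planted_id, query = nq.generate_collection(spec)
        idx = nq.build_index(sets)
        table = approved_only(idx.universe)
        raw = " ".join(sorted(query))
        for key in nq.SORT_KEYS:
            qr = nq.run_query(raw, idx, table, sort_key=key)
            assert qr.results[0].set_id == planted_id

    def test_query_disjoint_from_universe(self, three_network_index):
        table = approved_only({"A", "B", "C", "D", "ZZ"})
        qr = nq.run_query("ZZ unknown", three_network_index, table)
        assert qr.results == []
        assert qr.n == 0
        assert qr.normalization.matched == ["ZZ"]
        assert qr.normalization.invalid == ["UNKNOWN"]

    def test_n_is_effective_query_restricted_to_universe(self, three_network_index):
        table = approved_only({"A", "B", "OUTSIDE"})
        qr = nq.run_query("A B OUTSIDE", three_network_index, table)
        assert qr.n == 2

    def test_reported_counts_match_brute_force(self):
        """k and K per result equal a direct index-free set scan."""
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(40)]
        for trial in range(20):
            sets = [
                nq.GeneSet(
                    f"s{i}",
                    f"s{i}",
                    frozenset(
                        rng.choice(genes, size=int(rng.integers(1, 12)), replace=False)
                    ),
                    "gmt",
                )
                for i in range(int(rng.integers(2, 12)))
            ]
            idx = nq.build_index(sets)
            query = set(rng.choice(genes, size=6, replace=False))
            table = approved_only(set(genes))
            qr = nq.run_query(" ".join(sorted(query)), idx, table)
            effective = query & set(idx.universe)
            by_id = {gs.set_id: gs for gs in sets}
            expected_ids = sorted(
                gs.set_id for gs in sets if gs.genes & effective
            )
            assert sorted(r.set_id for r in qr.results) == expected_ids
            for r in qr.results:
                gs = by_id[r.set_id]
                assert r.k == len(gs.genes & effective)
                assert r.K == len(gs.genes)
                assert r.overlapping_genes == sorted(gs.genes & effective)
                assert r.k == len(r.overlapping_genes)

    def test_adjusted_pvalues_use_collection_multiplicity(self):
        # a single candidate among m=3 networks: p_adj = p_raw * 3 / 1
        idx = nq.build_index(
            [
                nq.GeneSet("a", "a", frozenset("AB"), "gmt"),
                nq.GeneSet("b", "b", frozenset("CD"), "gmt"),
                nq.GeneSet("c", "c", frozenset("EF"), "gmt"),
            ]
        )
        table = approved_only(idx.universe)
        qr = nq.run_query("A", idx, table)
        assert len(qr.results) == 1
        r = qr.results[0]
        assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 3))

    def test_max_results_truncates_after_ranking(self):
        spec = nq.FixtureSpec(n_networks=30, universe_size=200, seed=12)
        sets, _, query = nq.generate_collection(spec)
        idx = nq.build_index(sets)
        table = approved_only(idx.universe)
        raw = " ".join(sorted(query))
        full = nq.run_query(raw, idx, table, sort_key="pvalue")
        short = nq.run_query(raw, idx, table, sort_key="pvalue", max_results=3)
        assert [r.set_id for r in short.results] == [
            r.set_id for r in full.results[:3]
        ]

    def test_unknown_sort_key_rejected(self, three_network_index):
        with pytest.raises(ValueError):
            nq.run_query("A", three_network_index, approved_only({"A"}), sort_key="zeta")
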