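import math

import numpy as np
import pandas as pd
import pytest

from ferretmeth.enrich import (
    GeneSetCollection,
    bh_adjust,
    build_network,
    enrichment_with_fdr,
    hypergeometric_enrichment,
    read_edge_list,
    read_gmt,
    term_overlap,
)
from ferretmeth.errors import FormatError


def _collection(terms, universe=None):
    return GeneSetCollection(
        {tid: (tid, frozenset(genes)) for tid, genes in terms.items()},
        frozenset(universe or []),
    )


def brute_force_hypergeom_p(N, K, n, k):
    """Upper tail by direct enumeration of the hypergeometric mass."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


class TestHypergeometric:
    def test_exact_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        term = {f"g{i}" for i in range(5)}
        coll = _collection({"T": term}, universe)
        table = hypergeometric_enrichment(term, coll)
        assert table.loc[0, "p"] == pytest.approx(1.0 / 15504.0)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        coll = _collection({"T": {"g0", "g1"}}, universe)
        table = hypergeometric_enrichment({"g5", "g6"}, coll)
        assert table.loc[0, "p"] == pytest.approx(1.0)
        assert table.loc[0, "fold"] == 0.0

    def test_term_covering_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        coll = _collection({"ALL": universe}, universe)
        table = hypergeometric_enrichment({"g0", "g3"}, coll)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 30))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            term = set(rng.choice(universe, size=K, replace=False))
            query = set(rng.choice(universe, size=n, replace=False))
            coll = _collection({"T": term}, universe)
            table = hypergeometric_enrichment(query, coll)
            k = len(term & query)
            assert table.loc[0, "k"] == k
            assert table.loc[0, "p"] == pytest.approx(
                brute_force_hypergeom_p(N, K, n, k), rel=1e-10
            )

    def test_empty_harmonized_query_rejected(self):
        coll = _collection({"T": {"g0"}}, {"g0", "g1"})
        with pytest.raises(ValueError, match="empty"):
            hypergeometric_enrichment({"zz"}, coll)


class TestBhAdjust:
    def test_step_up_hand_computation(self):
        adjusted, sig = bh_adjust([0.001, 0.01, 0.02, 0.05])
        assert np.allclose(adjusted, [0.004, 0.02, 0.02666667, 0.05])
        assert sig.all()

    def test_single_p_unchanged(self):
        adjusted, sig = bh_adjust([0.04])
        assert adjusted[0] == pytest.approx(0.04) and sig[0]

    def test_all_ones_nothing_significant(self):
        _, sig = bh_adjust(np.ones(10))
        assert not sig.any()

    def test_monotone_and_stable_under_reapplication(self, rng):
        p = rng.random(50)
        once, _ = bh_adjust(p)
        # step-up adjustment preserves the input ordering ...
        order = np.argsort(p)
        assert (np.diff(once[order]) >= -1e-12).all()
        # ... and re-adjusting already-adjusted values can only raise them
        # (no spurious new discoveries), while the ranking is unchanged
        twice, _ = bh_adjust(once)
        assert (twice >= once - 1e-12).all()
        assert (np.diff(twice[order]) >= -1e-12).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestNetwork:
    def _edges(self, rows):
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])

    def test_confidence_threshold_is_inclusive_at_cutoff(self):
        edges = self._edges([("A", "B", 0.9), ("B", "C", 0.69), ("C", "D", 0.7)])
        net = build_network(edges, seed_genes={"A"})
        assert net.interactors == {"A", "B"}
        assert not net.graph.has_edge("B", "C")
        assert net.graph.has_edge("C", "D")

    def test_triangle_fully_reachable(self):
        edges = self._edges([("A", "B", 0.8), ("B", "C", 0.8), ("A", "C", 0.8)])
        net = build_network(edges, seed_genes={"A"})
        assert net.interactors == {"A", "B", "C"}

    def test_absent_seed_kept_isolated(self):
        edges = self._edges([("A", "B", 0.9)])
        net = build_network(edges, seed_genes={"Z"})
        assert net.n_isolated_seeds == 1
        assert "Z" in net.graph

    def test_components_match_union_find_oracle(self, rng):
        for _ in range(25):
            genes = [f"g{i}" for i in range(15)]
            rows = []
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    if rng.random() < 0.15:
                        rows.append((genes[i], genes[j], float(rng.random())))
            if not rows:
                continue
            edges = self._edges(rows)
            net = build_network(edges, seed_genes=set())
            # union-find over edges >= 0.7
            parent = {}

            def find(a):
                parent.setdefault(a, a)
                while parent[a] != a:
                    parent[a] = parent[parent[a]]
                    a = parent[a]
                return a

            for a, b, c in rows:
                if c >= 0.7 and a != b:
                    parent[find(a)] = find(b)
            groups = {}
            for node in parent:
                groups.setdefault(find(node), set()).add(node)
            assert {frozenset(g) for g in groups.values()} == set(net.components)

    def test_raising_cutoff_never_grows_components(self, rng):
        rows = [
            (f"g{i}", f"g{j}", float(rng.random()))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.3
        ]
        edges = self._edges(rows)
        lo = build_network(edges, seed_genes=set(), min_confidence=0.5)
        hi = build_network(edges, seed_genes=set(), min_confidence=0.8)
        assert hi.graph.number_of_edges() <= lo.graph.number_of_edges()
        biggest = lambda net: max((len(c) for c in net.components), default=0)
        assert biggest(hi) <= biggest(lo)


class TestTermOverlapAndIo:
    def _results(self, sig_terms):
        return pd.DataFrame(
            {"term": sorted(sig_terms | {"PAD"}),
             "significant": [t in sig_terms for t in sorted(sig_terms | {"PAD"})]}
        )

    def test_identical_sets_full_overlap(self):
        res = {lab: self._results({"T1", "T2"}) for lab in ("a", "b", "c")}
        counts = term_overlap(res)
        assert counts["a&b&c"] == 2

    def test_disjoint_sets_no_overlap(self):
        res = {
            "a": self._results({"T1"}),
            "b": self._results({"T2"}),
        }
        counts = term_overlap(res)
        assert counts["a&b"] == 0

    def test_gmt_reader(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("T1\tdesc one\tg1\tg2\nT2\tdesc two\tg2\tg3\tg4\n")
        coll = read_gmt(path)
        assert coll.terms["T2"][1] == frozenset({"g2", "g3", "g4"})
        assert coll.universe == frozenset({"g1", "g2", "g3", "g4"})

    def test_gmt_short_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("T1\tonly-description\n")
        with pytest.raises(FormatError, match="line 1"):
            read_gmt(path)

    def test_edge_list_confidence_bounds(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("gene_a\tgene_b\tconfidence\nA\tB\t1.4\n")
        with pytest.raises(FormatError, match="confidence"):
            read_edge_list(path)

    def test_enrichment_with_fdr_flags(self, rng):
        universe = [f"g{i}" for i in range(40)]
        target = set(universe[:8])
        coll = _collection({"HIT": target, "MISS": set(universe[20:30])}, universe)
        table = enrichment_with_fdr(target, coll, fdr=0.05)
        hit = table.set_index("term")
        assert bool(hit.loc["HIT", "significant"])
        assert not bool(hit.loc["MISS", "significant"])
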