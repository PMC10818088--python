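import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferretmeth.dms import call_dmclusters, overlap_sets, select_outliers


def _table(betas, ps, chrom="scaf1", positions=None):
    n = len(betas)
    positions = positions if positions is not None else np.arange(1, n + 1) * 100
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "context": "CG",
            "beta": betas,
            "p": ps,
            "skip_reason": "none",
        }
    )


def brute_force_select(table, beta_q=(0.01, 0.99), p_q=0.01):
    """Independent dual-threshold filter via sorted-array quantiles."""
    fitted = table[table["skip_reason"] == "none"]
    beta = np.sort(fitted["beta"].to_numpy())
    p = np.sort(fitted["p"].to_numpy())

    def interp_quantile(sorted_vals, q):
        h = (len(sorted_vals) - 1) * q
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])

    b_lo = interp_quantile(beta, beta_q[0])
    b_hi = interp_quantile(beta, beta_q[1])
    p_thr = interp_quantile(p, p_q)
    keep = fitted[
        ((fitted["beta"] <= b_lo) | (fitted["beta"] >= b_hi))
        & (fitted["p"] <= p_thr)
    ]
    return set(zip(keep["chrom"], keep["pos"], keep["context"]))


def brute_force_clusters(positions_by_chrom, max_gap=40):
    """O(n^2) pairwise chaining: union sites whose gap < max_gap, per chrom."""
    clusters = []
    for chrom, positions in positions_by_chrom.items():
        positions = sorted(positions)
        n = len(positions)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if abs(positions[i] - positions[j]) < max_gap:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(positions[i])
        clusters.extend((chrom, tuple(sorted(g))) for g in groups.values())
    return set(clusters)


class TestSelectOutliers:
    def test_extreme_corners_selected(self):
        betas = np.arange(1.0, 101.0)
        ps = np.where((betas == 1) | (betas == 100), 0.001, 0.5)
        dms = select_outliers(_table(betas, ps))
        assert set(dms.sites["beta"]) == {1.0, 100.0}

    def test_degenerate_equal_betas_collapse_tails(self):
        betas = np.full(100, 2.0)
        ps = np.linspace(0.001, 1.0, 100)
        dms = select_outliers(_table(betas, ps))
        # both beta tails coincide at 2.0, so selection is driven by p alone
        assert len(dms) == (ps <= np.quantile(ps, 0.01)).sum()
        assert (dms.sites["beta"] == 2.0).all()

    def test_matches_brute_force_on_random_tables(self, rng):
        for _ in range(25):
            n = int(rng.integers(50, 400))
            table = _table(rng.normal(size=n), rng.random(size=n))
            got = select_outliers(table).site_keys()
            assert got == brute_force_select(table)

    def test_row_permutation_invariance(self, rng):
        table = _table(rng.normal(size=200), rng.random(size=200))
        shuffled = table.sample(frac=1, random_state=5)
        assert (
            select_outliers(table).site_keys()
            == select_outliers(shuffled).site_keys()
        )

    def test_skipped_sites_excluded_from_quantiles(self, rng):
        table = _table(rng.normal(size=100), rng.random(size=100))
        table.loc[:49, "skip_reason"] = "monomorphic"
        got = select_outliers(table).site_keys()
        assert got == brute_force_select(table)

    def test_all_skipped_rejected(self):
        table = _table([1.0, 2.0], [0.1, 0.2])
        table["skip_reason"] = "monomorphic"
        with pytest.raises(ValueError):
            select_outliers(table)


class TestDmClusters:
    def _dms_frame(self, by_chrom):
        rows = [
            {"chrom": c, "pos": p, "context": "CG", "beta": 1.0, "p": 0.001}
            for c, ps in by_chrom.items()
            for p in ps
        ]
        return pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)

    def test_definition_forced_example(self):
        frame = self._dms_frame({"scaf1": [100, 130, 165, 300], "scaf2": [50, 80, 119]})
        cs = call_dmclusters(frame, max_gap=40, min_sites=3)
        got = {(c.chrom, c.positions) for c in cs.clusters}
        assert got == {
            ("scaf1", (100, 130, 165)),
            ("scaf1", (300,)),
            ("scaf2", (50, 80, 119)),
        }
        assert {(c.chrom, c.positions) for c in cs.network_subset} == {
            ("scaf1", (100, 130, 165)),
            ("scaf2", (50, 80, 119)),
        }

    def test_gap_of_exactly_forty_splits(self):
        cs = call_dmclusters(self._dms_frame({"scaf1": [100, 140]}), max_gap=40)
        assert len(cs.clusters) == 2

    def test_matches_pairwise_chaining_oracle(self, rng):
        for _ in range(25):
            by_chrom = {
                f"scaf{c}": sorted(
                    rng.choice(2000, size=int(rng.integers(2, 40)), replace=False)
                )
                for c in range(1, 4)
            }
            cs = call_dmclusters(self._dms_frame(by_chrom))
            got = {(c.chrom, c.positions) for c in cs.clusters}
            assert got == brute_force_clusters(by_chrom)

    def test_clusters_partition_the_dms(self, rng):
        positions = sorted(rng.choice(5000, size=60, replace=False))
        cs = call_dmclusters(self._dms_frame({"scaf1": positions}))
        flattened = [p for c in cs.clusters for p in c.positions]
        assert sorted(flattened) == positions

    @given(st.integers(min_value=1, max_value=200))
    @settings(max_examples=20, deadline=None)
    def test_wider_gap_only_merges(self, extra):
        rng = np.random.default_rng(extra)
        positions = sorted(rng.choice(3000, size=30, replace=False))
        frame = self._dms_frame({"scaf1": positions})
        narrow = call_dmclusters(frame, max_gap=40).clusters
        wide = call_dmclusters(frame, max_gap=40 + extra).clusters
        assert len(wide) <= len(narrow)
        # each narrow cluster is contained in exactly one wide cluster
        for c in narrow:
            containing = [
                w for w in wide if set(c.positions) <= set(w.positions)
            ]
            assert len(containing) == 1


class TestOverlapSets:
    def test_triple_intersection_singleton(self):
        counts = overlap_sets({"x": {"A", "B"}, "y": {"B", "C"}, "z": {"B", "D"}})
        assert counts["x&y&z"] == 1
        assert counts["x"] == 1 and counts["y"] == 1 and counts["z"] == 1

    def test_identical_sets_all_in_center(self):
        s = {"A", "B", "C"}
        counts = overlap_sets({"x": set(s), "y": set(s), "z": set(s)})
        assert counts["x&y&z"] == 3
        assert sum(v for k, v in counts.items() if k != "x&y&z") == 0

    def test_regions_sum_to_union(self, rng):
        for _ in range(25):
            sets = {
                lab: set(rng.choice(30, size=int(rng.integers(0, 20)), replace=False))
                for lab in ("a", "b", "c")
            }
            if not any(sets.values()):
                continue
            counts = overlap_sets(sets)
            assert sum(counts.values()) == len(set().union(*sets.values()))
            # inclusion-exclusion oracle per region
            universe = set().union(*sets.values())
            for elem in universe:
                member = [lab for lab in sets if elem in sets[lab]]
                key = "&".join(member)
                assert counts[key] >= 1
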