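from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from reductomir import network
from reductomir.core_io import GeneSetCollection


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Independent exact tail sum P(X >= k) in rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        total += Fraction(comb(K, x) * comb(N - K, n - x), comb(N, n))
    return float(total)


def de_frame(rows):
    """rows: (feature_id, pvalue, log2FC)."""
    frame = pd.DataFrame(rows, columns=["feature_id", "pvalue", "log2FC"])
    frame["qvalue_bonferroni"] = np.minimum(frame["pvalue"] * len(frame), 1.0)
    return frame


class TestReductomirCalls:
    def _inputs(self, mirnas):
        """mirnas: dict id -> (p_pooled, lfc, p_dose, n_are, n_targets)."""
        pooled = de_frame([(m, v[0], v[1]) for m, v in mirnas.items()])
        dose = de_frame([(m, v[2], 1.0) for m, v in mirnas.items()])
        ares = {m: v[3] for m, v in mirnas.items()}
        rows = []
        for m, v in mirnas.items():
            for i in range(v[4]):
                rows.append({"mirna_id": m, "target_id": f"t_{m}_{i}", "n_sources": 3})
        inter = pd.DataFrame(rows, columns=["mirna_id", "target_id", "n_sources"])
        suppressed = list(inter["target_id"]) if len(inter) else []
        return pooled, dose, ares, inter, suppressed

    def test_tier_definitions(self):
        pooled, dose, ares, inter, supp = self._inputs(
            {
                "eff": (0.01, 1.5, 0.01, 2, 3),  # everything -> effector
                "no_are": (0.01, 1.5, 0.01, 0, 3),  # induced but no ARE -> none
                "are_only": (0.01, 1.5, 0.50, 1, 0),  # not dose-responsive
                "down": (0.01, -1.5, 0.01, 2, 3),  # suppressed, not induced
            }
        )
        calls, _ = network.call_reductomirs(pooled, dose, ares, inter, supp)
        tiers = calls.set_index("mirna_id")["tier"]
        assert tiers["eff"] == "effector_reductomir"
        assert tiers["no_are"] == "none"
        assert tiers["are_only"] == "are_demir"
        assert tiers["down"] == "none"

    def test_coverage_percentage_on_nested_fixture(self):
        # 22 dose-responsive ARE-bearing miRNAs, 19 of which have targets
        mirnas = {}
        for i in range(22):
            n_targets = 2 if i < 19 else 0
            mirnas[f"mir{i:02d}"] = (0.001, 2.0, 0.001, 1, n_targets)
        pooled, dose, ares, inter, supp = self._inputs(mirnas)
        calls, summary = network.call_reductomirs(pooled, dose, ares, inter, supp)
        assert summary["n_dose_reductomir"] == 22
        assert summary["n_effector_reductomir"] == 19
        assert summary["effector_coverage_pct"] == 86

    def test_tiers_are_nested(self):
        rng = np.random.default_rng(1)
        mirnas = {
            f"m{i}": (
                float(rng.random()),
                float(rng.normal()),
                float(rng.random()),
                int(rng.integers(0, 3)),
                int(rng.integers(0, 3)),
            )
            for i in range(100)
        }
        pooled, dose, ares, inter, supp = self._inputs(mirnas)
        calls, summary = network.call_reductomirs(pooled, dose, ares, inter, supp)
        sub = calls.set_index("mirna_id")
        eff = set(sub.index[sub["tier"] == "effector_reductomir"])
        dos = eff | set(sub.index[sub["tier"] == "dose_reductomir"])
        are = dos | set(sub.index[sub["tier"] == "are_demir"])
        ind = set(sub.index[sub["induced"]])
        assert eff <= dos <= are <= ind
        assert summary["n_are_demir"] == len(are)


class TestBipartiteNetwork:
    def test_complete_two_by_two(self):
        inter = pd.DataFrame(
            {
                "mirna_id": ["m1", "m1", "m2", "m2"],
                "target_id": ["t1", "t2", "t1", "t2"],
                "n_sources": [3, 4, 5, 6],
            }
        )
        g = network.build_network(inter)
        assert g.number_of_edges() == 4
        assert all(d == 2 for _, d in g.degree)
        assert g.edges["m1", "t2"]["weight"] == 4
        # strictly bipartite
        for u, v in g.edges:
            assert g.nodes[u]["bipartite"] != g.nodes[v]["bipartite"]

    def test_empty_network_is_valid(self, tmp_path):
        g = network.build_network(
            pd.DataFrame(columns=["mirna_id", "target_id", "n_sources"])
        )
        assert g.number_of_nodes() == 0
        network.write_network(g, tmp_path / "n.graphml", tmp_path / "n.tsv")
        assert (tmp_path / "n.graphml").exists()

    def test_degrees_match_brute_force_on_random_fixture(self, rng):
        pairs = {
            (f"m{rng.integers(20)}", f"t{rng.integers(30)}") for _ in range(100)
        }
        inter = pd.DataFrame(
            [{"mirna_id": m, "target_id": t, "n_sources": 3} for m, t in sorted(pairs)]
        )
        g = network.build_network(inter)
        for node in g.nodes:
            expected = sum(1 for m, t in pairs if node in (m, t))
            assert g.degree(node) == expected
            assert g.nodes[node]["degree"] == expected

    def test_namespace_collision_rejected(self):
        inter = pd.DataFrame(
            {"mirna_id": ["x", "m"], "target_id": ["t", "x"], "n_sources": [3, 3]}
        )
        with pytest.raises(ValueError, match="both miRNA and target"):
            network.build_network(inter)


class TestORA:
    def _collection(self, sets):
        return GeneSetCollection(sets=sets)

    def test_saturated_set_has_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        coll = self._collection({"all": universe})
        res = network.ora(universe[:4], coll, universe)
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)
        assert res.loc[0, "overlap"] == 4

    def test_exact_tail_example(self):
        # N=20, K=5, n=5, k=4
        universe = [f"g{i}" for i in range(20)]
        coll = self._collection({"s": universe[:5]})
        query = universe[:4] + [universe[10]]
        res = network.ora(query, coll, universe)
        expected = exact_hypergeom_tail(4, 20, 5, 5)
        assert expected == pytest.approx(76 / 15504)
        assert res.loc[0, "pvalue"] == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_exact_oracle_on_small_cases(self, rng):
        for _ in range(30):
            N = int(rng.integers(5, 51))
            universe = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            members = list(rng.choice(universe, K, replace=False))
            query = list(rng.choice(universe, n, replace=False))
            res = network.ora(query, self._collection({"s": members}), universe)
            k = len(set(members) & set(query))
            assert res.loc[0, "overlap"] == k
            assert res.loc[0, "pvalue"] == pytest.approx(
                exact_hypergeom_tail(k, N, K, n), abs=1e-10
            )

    def test_enrichment_ratio_definition(self):
        universe = [f"g{i}" for i in range(100)]
        coll = self._collection({"s": universe[:60]})
        res = network.ora(universe[:3], coll, universe)
        assert res.loc[0, "enrichment_ratio"] == pytest.approx(5.0)

    def test_bh_is_monotone_in_p_rank(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = {
            f"s{j}": list(rng.choice(universe, int(rng.integers(3, 20)), replace=False))
            for j in range(12)
        }
        res = network.ora(list(rng.choice(universe, 15, replace=False)),
                          self._collection(sets), universe)
        assert (res["qvalue_bh"].diff().dropna() >= -1e-12).all()
        assert (res["qvalue_bh"] >= res["pvalue"] - 1e-12).all()

    def test_query_outside_universe_warns_and_drops(self):
        universe = ["a", "b", "c", "d"]
        coll = self._collection({"s": ["a", "b"]})
        with pytest.warns(UserWarning, match="outside the universe"):
            res = network.ora(["a", "zzz"], coll, universe)
        assert res.loc[0, "query_size"] == 1

    def test_empty_universe_is_an_error(self):
        with pytest.raises(ValueError, match="empty universe"):
            network.ora(["a"], self._collection({"s": ["a"]}), [])
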