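import numpy as np
import pandas as pd
import pytest

from lncnet import build_network, find_master_regulators, phenotype_unique
from lncnet.network import (
    NetworkComponent,
    greedy_set_cover,
    overall_concordance,
    unique_phenotype_gene_sets,
)


def _pairs(edges):
    return pd.DataFrame(
        [(l, m, 0.95, 10, True) for l, m in edges],
        columns=["lnc_id", "mrna_id", "r", "n_samples", "sign_concordant"],
    )


def _relevance(rows):
    """rows: (feature_id, de_direction, cls, groups-string)."""
    return pd.DataFrame(
        rows, columns=["feature_id", "de_direction", "cls", "groups"]
    )


class TestBuildNetwork:
    def test_components_match_expected_partition(self):
        pairs = _pairs([("L1", "M1"), ("L1", "M2"), ("L2", "M2"), ("L3", "M3")])
        rel = _relevance(
            [
                ("L1", "up", "oncogenic", "grade"),
                ("L2", "up", "oncogenic", "grade"),
                ("L3", "up", "oncogenic", "grade"),
                ("M1", "up", "oncogenic", "grade"),
                ("M2", "up", "oncogenic", "grade"),
                ("M3", "up", "none", ""),
            ]
        )
        comps = build_network(pairs, rel)
        assert [(c.lnc_ids, c.mrna_ids) for c in comps] == [
            (["L1", "L2"], ["M1", "M2"]),
            (["L3"], ["M3"]),
        ]
        assert comps[0].cls == "oncogenic"

    def test_irrelevant_lncRNAs_drop_with_their_edges(self):
        pairs = _pairs([("L1", "M1"), ("L2", "M2")])
        rel = _relevance(
            [("L1", "up", "oncogenic", "grade"), ("L2", "up", "none", ""),
             ("M1", "up", "oncogenic", "grade"), ("M2", "up", "none", "")]
        )
        comps = build_network(pairs, rel)
        assert len(comps) == 1 and comps[0].lnc_ids == ["L1"]

    def test_single_edge_concordance_is_zero_or_one(self):
        pairs = _pairs([("L1", "M1")])
        rel = _relevance(
            [("L1", "up", "oncogenic", "grade"), ("M1", "up", "oncogenic", "capsule")]
        )
        comps = build_network(pairs, rel)
        assert comps[0].concordance == 0.0  # no shared group
        rel2 = _relevance(
            [("L1", "up", "oncogenic", "grade"), ("M1", "up", "oncogenic", "grade")]
        )
        assert build_network(pairs, rel2)[0].concordance == 1.0

    def test_half_concordant_component(self):
        # M1 shares the grade association with L, M2 has none -> 0.5
        pairs = _pairs([("L1", "M1"), ("L1", "M2")])
        rel = _relevance(
            [
                ("L1", "up", "oncogenic", "grade"),
                ("M1", "up", "oncogenic", "grade"),
                ("M2", "up", "none", ""),
            ]
        )
        comps = build_network(pairs, rel)
        assert comps[0].concordance == pytest.approx(0.5)
        assert overall_concordance(comps) == pytest.approx(0.5)

    def test_mixed_direction_component_reported_not_dropped(self):
        pairs = _pairs([("L1", "M1"), ("L2", "M1")])
        rel = _relevance(
            [
                ("L1", "up", "oncogenic", "grade"),
                ("L2", "down", "suppressor", "invasion"),
                ("M1", "up", "oncogenic", "grade"),
            ]
        )
        comps = build_network(pairs, rel)
        assert len(comps) == 1 and comps[0].cls == "mixed"

    def test_matches_union_find_oracle_on_random_bipartite_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n_l, n_m = rng.integers(1, 26), rng.integers(1, 26)
            lncs = [f"L{i}" for i in range(n_l)]
            mrnas = [f"M{i}" for i in range(n_m)]
            n_edges = int(rng.integers(1, n_l * n_m + 1))
            edges = {
                (lncs[rng.integers(n_l)], mrnas[rng.integers(n_m)])
                for _ in range(n_edges)
            }
            rel = _relevance(
                [(l, "up", "oncogenic", "grade") for l in lncs]
                + [(m, "up", "none", "") for m in mrnas]
            )
            comps = build_network(_pairs(sorted(edges)), rel)
            got = sorted(tuple(sorted(c.lnc_ids + c.mrna_ids)) for c in comps)
            assert got == _union_find_components(edges)


def _union_find_components(edges):
    parent = {}

    def find(a):
        parent.setdefault(a, a)
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in edges:
        union(a, b)
    groups = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestMasterRegulators:
    def _component(self, covers, concordance=1.0):
        edges = [(l, m) for l, ms in covers.items() for m in ms]
        mrnas = sorted({m for _, m in edges})
        return NetworkComponent(
            lnc_ids=sorted(covers),
            mrna_ids=mrnas,
            edges=_pairs(edges),
            cls="oncogenic",
            concordance=concordance,
            edge_concordance=concordance,
        )

    def test_greedy_cover_trace(self):
        covers = {
            "L1": frozenset({"a", "b", "c"}),
            "L2": frozenset({"c", "d"}),
            "L3": frozenset({"a"}),
        }
        assert greedy_set_cover(covers, {"a", "b", "c", "d"}) == ["L1", "L2"]

    def test_small_component_gated_out(self):
        comp = self._component({"L1": ["M1", "M2", "M3", "M4", "M5"]})
        assert find_master_regulators(comp, min_mrna=20) == []

    def test_low_concordance_gated_out(self):
        covers = {f"L{i}": [f"M{j}" for j in range(25)] for i in range(2)}
        comp = self._component(covers, concordance=0.5)
        assert find_master_regulators(comp, min_mrna=20, concordance_min=0.8) == []

    def test_enrichment_gate(self):
        covers = {"L1": [f"M{j}" for j in range(25)]}
        comp = self._component(covers)
        no_hit = pd.DataFrame({"set_name": ["S"], "significant": [False]})
        hit = pd.DataFrame({"set_name": ["S"], "significant": [True]})
        assert find_master_regulators(comp, enrichment=no_hit) == []
        assert find_master_regulators(comp, enrichment=hit) == ["L1"]

    def test_cover_is_minimal_wrt_feasibility_and_never_exceeds_lnc_count(self):
        rng = np.random.default_rng(32)
        for _ in range(30):
            n_l, n_m = int(rng.integers(2, 8)), int(rng.integers(5, 30))
            mrnas = [f"M{j}" for j in range(n_m)]
            covers = {}
            for i in range(n_l):
                size = int(rng.integers(1, n_m + 1))
                covers[f"L{i}"] = frozenset(
                    rng.choice(mrnas, size=size, replace=False).tolist()
                )
            targets = set().union(*covers.values())
            chosen = greedy_set_cover(covers, targets)
            assert len(chosen) <= n_l
            assert set().union(*(covers[c] for c in chosen)) == targets


class TestPhenotypeUnique:
    def test_unique_single_group_lncRNAs_listed(self):
        rel = _relevance(
            [
                ("L1", "up", "oncogenic", "grade"),
                ("L2", "up", "oncogenic", "grade,capsule"),
                ("L3", "down", "suppressor", ""),
            ]
        )
        unique = phenotype_unique(rel)
        assert unique == {"grade": ["L1"]}

    def test_unique_gene_sets_deduplicate_partners(self):
        unique = {"grade": ["L1", "L2"]}
        pairs = _pairs([("L1", "M1"), ("L2", "M1"), ("L1", "M2")])
        de = pd.DataFrame(
            {"feature_id": ["M1", "M2"], "direction": ["up", "down"]}
        )
        out = unique_phenotype_gene_sets(unique, pairs, de)
        assert out == {"grade": {"up": ["M1"], "down": ["M2"]}}

    def test_empty_map_gives_empty_lists(self):
        out = unique_phenotype_gene_sets({}, _pairs([]), pd.DataFrame(columns=["feature_id", "direction"]))
        assert out == {}
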