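"""Bipartite lncRNA-mRNA network construction and master-regulator search.

Edges are the called co-expression pairs whose lncRNA is clinically
relevant (classified oncogenic or suppressor).  Connected components of
the bipartite graph are the reported networks; each is classified by the
tumor direction of its member lncRNAs and scored for clinical
concordance: the fraction of member mRNAs that share at least one
direction-concordant significant clinical group with at least one of
their correlated lncRNAs.

A master-regulator set is the minimal lncRNA subset of a large,
concordant, pathway-enriched component whose correlated mRNAs cover the
component's mRNAs (greedy set cover; an exact search is available for
small components).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .clinical import parse_groups


@dataclass
class NetworkComponent:
    lnc_ids: list[str]
    mrna_ids: list[str]
    edges: pd.DataFrame
    cls: str  # oncogenic | suppressive | mixed
    concordance: float
    edge_concordance: float
    master_set: list[str] = field(default_factory=list)
    enriched_sets: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.lnc_ids) + len(self.mrna_ids)


def _claims(relevance: pd.DataFrame) -> dict[str, frozenset]:
    """Per feature, the set of (clinical group, DE direction) claims.

    ``groups`` already contains only direction-concordant significant
    groups, so pairing them with the feature's own DE direction encodes
    the clinical direction unambiguously.
    """
    out = {}
    for rec in relevance.itertuples(index=False):
        out[rec.feature_id] = frozenset(
            (g, rec.de_direction) for g in parse_groups(rec.groups)
        )
    return out


def build_network(pairs: pd.DataFrame, relevance: pd.DataFrame) -> list[NetworkComponent]:
    """Connected components of the clinically-relevant bipartite graph.

    ``pairs`` is a called-pairs table; ``relevance`` must cover the pair
    members (lncRNAs with cls == 'none' or absent are dropped along with
    their edges).  Components are ordered by decreasing size, then
    lexicographically by their sorted node list.
    """
    rel = relevance.set_index("feature_id")
    relevant_lnc = set(rel.index[rel["cls"] != "none"])
    kept = pairs[pairs["lnc_id"].isin(relevant_lnc)]
    if kept.empty:
        return []
    graph = nx.Graph()
    lnc_nodes = set(kept["lnc_id"])
    for rec in kept.itertuples(index=False):
        graph.add_edge(rec.lnc_id, rec.mrna_id)
    claims = _claims(relevance)
    direction = dict(zip(relevance["feature_id"], relevance["de_direction"]))

    components = []
    for nodes in nx.connected_components(graph):
        lncs = sorted(n for n in nodes if n in lnc_nodes)
        mrnas = sorted(n for n in nodes if n not in lnc_nodes)
        edges = kept[kept["lnc_id"].isin(lncs) & kept["mrna_id"].isin(mrnas)]
        edges = edges.sort_values(["lnc_id", "mrna_id"], kind="stable").reset_index(drop=True)
        dirs = {direction.get(l) for l in lncs}
        if dirs == {"up"}:
            cls = "oncogenic"
        elif dirs == {"down"}:
            cls = "suppressive"
        else:
            cls = "mixed"
        conc = _mrna_concordance(edges, mrnas, claims)
        econc = _edge_concordance(edges, claims)
        components.append(
            NetworkComponent(lncs, mrnas, edges, cls, conc, econc)
        )
    components.sort(key=lambda c: (-c.n_nodes, c.lnc_ids + c.mrna_ids))
    return components


def _mrna_concordance(edges: pd.DataFrame, mrnas: list[str], claims: dict) -> float:
    if not mrnas:
        return float("nan")
    partners: dict[str, set[str]] = {m: set() for m in mrnas}
    for rec in edges.itertuples(index=False):
        partners[rec.mrna_id].add(rec.lnc_id)
    n_shared = sum(
        1
        for m in mrnas
        if any(claims.get(m, frozenset()) & claims.get(l, frozenset()) for l in partners[m])
    )
    return n_shared / len(mrnas)


def _edge_concordance(edges: pd.DataFrame, claims: dict) -> float:
    if edges.empty:
        return float("nan")
    n_shared = sum(
        1
        for rec in edges.itertuples(index=False)
        if claims.get(rec.mrna_id, frozenset()) & claims.get(rec.lnc_id, frozenset())
    )
    return n_shared / len(edges)


def overall_concordance(components: list[NetworkComponent]) -> float:
    """mRNA-level concordance pooled over all components."""
    total = sum(len(c.mrna_ids) for c in components)
    if total == 0:
        return float("nan")
    shared = sum(c.concordance * len(c.mrna_ids) for c in components)
    return shared / total


# ---------------------------------------------------------------------------
# master regulators


def _coverage(component: NetworkComponent) -> dict[str, frozenset]:
    cov: dict[str, set[str]] = {l: set() for l in component.lnc_ids}
    for rec in component.edges.itertuples(index=False):
        cov[rec.lnc_id].add(rec.mrna_id)
    return {l: frozenset(s) for l, s in cov.items()}


def greedy_set_cover(covers: dict[str, frozenset], targets: set, cover_fraction: float = 1.0) -> list[str]:
    """Greedy cover of ``targets`` by the ``covers`` sets.

    Picks the set with the largest marginal coverage first; ties break on
    larger total degree, then lexicographic name.  Stops once the covered
    fraction reaches ``cover_fraction`` or no candidate adds coverage.
    """
    need = max(0, int(-(-cover_fraction * len(targets) // 1)))  # ceil
    covered: set = set()
    chosen: list[str] = []
    remaining = dict(covers)
    while len(covered) < need and remaining:
        best = min(
            remaining,
            key=lambda l: (-len(remaining[l] - covered), -len(remaining[l]), l),
        )
        gain = remaining[best] - covered
        if not gain:
            break
        chosen.append(best)
        covered |= gain
        del remaining[best]
    return chosen


def exact_set_cover(covers: dict[str, frozenset], targets: set) -> list[str]:
    """Smallest covering subset by exhaustive search (small inputs only)."""
    names = sorted(covers)
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            if set().union(*(covers[n] for n in combo)) >= targets:
                return list(combo)
    return []


def find_master_regulators(
    component: NetworkComponent,
    min_mrna: int = 20,
    concordance_min: float = 0.8,
    cover_fraction: float = 1.0,
    enrichment: pd.DataFrame | None = None,
    exact_max: int = 0,
) -> list[str]:
    """Minimal lncRNA subset that covers the component's mRNAs.

    Returns empty unless the component is large (>= ``min_mrna`` member
    mRNAs), clinically concordant (concordance strictly above
    ``concordance_min``) and -- when an enrichment table is supplied --
    has at least one significantly enriched gene set.  Cover search is
    greedy; components with at most ``exact_max`` lncRNAs use exhaustive
    search instead.
    """
    if len(component.mrna_ids) < min_mrna:
        return []
    if not component.concordance > concordance_min:
        return []
    if enrichment is not None and not enrichment["significant"].any():
        return []
    covers = _coverage(component)
    targets = set(component.mrna_ids)
    if 0 < len(covers) <= exact_max and cover_fraction >= 1.0:
        return exact_set_cover(covers, targets)
    return greedy_set_cover(covers, targets, cover_fraction)


# ---------------------------------------------------------------------------
# phenotype-unique lncRNAs


def phenotype_unique(relevance: pd.DataFrame, lnc_ids=None) -> dict[str, list[str]]:
    """lncRNAs associated with exactly one clinical group, keyed by group."""
    out: dict[str, list[str]] = {}
    sub = relevance
    if lnc_ids is not None:
        keep = set(lnc_ids)
        sub = relevance[relevance["feature_id"].isin(keep)]
    for rec in sub.itertuples(index=False):
        if rec.cls == "none":
            continue
        groups = parse_groups(rec.groups)
        if len(groups) == 1:
            (g,) = groups
            out.setdefault(g, []).append(rec.feature_id)
    return {g: sorted(v) for g, v in sorted(out.items())}


def unique_phenotype_gene_sets(
    unique_map: dict[str, list[str]], pairs: pd.DataFrame, de: pd.DataFrame
) -> dict[str, dict[str, list[str]]]:
    """Per group and DE direction, the mRNAs correlated with that group's
    unique lncRNAs (set union, duplicates removed)."""
    direction = dict(zip(de["feature_id"], de["direction"]))
    out: dict[str, dict[str, list[str]]] = {}
    for group, lncs in unique_map.items():
        partners = pairs[pairs["lnc_id"].isin(set(lncs))]["mrna_id"].unique()
        buckets: dict[str, set[str]] = {"up": set(), "down": set()}
        for m in partners:
            d = direction.get(m)
            if d in buckets:
                buckets[d].add(m)
        out[group] = {d: sorted(v) for d, v in buckets.items()}
    return out
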