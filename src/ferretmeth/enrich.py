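"""Gene-set over-representation and confidence-filtered interaction networks.

Enrichment is the one-sided upper-tail hypergeometric test: with a universe
of N genes, a term covering K of them, and a query of n genes overlapping
the term in k, p = P(X >= k); fold enrichment is (k/n)/(K/N).  Benjamini-
Hochberg step-up adjustment flags significant terms at an FDR cutoff
(default 0.05).  Interaction networks keep user-supplied undirected edges
with confidence >= 0.7 and report seed genes together with their direct
neighbours, standing in for database-backed network tools run offline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """term ID -> (name, member genes), with a background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.universe:
            members: set[str] = set()
            for _, genes in self.terms.values():
                members |= genes
            self.universe = frozenset(members)
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid} is empty")
            if not genes <= self.universe:
                raise ValueError(f"term {tid} has members outside the universe")


def read_gmt(path, universe=None) -> GeneSetCollection:
    """Read a GMT file (term, description, then member genes, tab-separated)."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            terms[fields[0]] = (fields[1], frozenset(g for g in fields[2:] if g))
    return GeneSetCollection(terms, frozenset(universe) if universe else frozenset())


def hypergeometric_enrichment(
    query, collection: GeneSetCollection
) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric p and fold enrichment.

    Query genes outside the universe are dropped (counted in the log); an
    empty harmonized query is an error.
    """
    query = set(query)
    outside = query - collection.universe
    if outside:
        logger.info(
            "enrichment: dropped %d query genes outside the universe", len(outside)
        )
    query &= collection.universe
    if not query:
        raise ValueError("query empty after harmonization against the universe")

    N = len(collection.universe)
    n = len(query)
    rows = []
    for tid, (name, genes) in collection.terms.items():
        K = len(genes)
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if k else 0.0
        rows.append(
            {"term": tid, "name": name, "k": k, "K": K, "n": n, "N": N,
             "p": p, "fold": fold}
        )
    return pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)


def bh_adjust(p_values, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and the significant mask."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adjusted, adjusted <= fdr


def enrichment_with_fdr(
    query, collection: GeneSetCollection, fdr: float = 0.05
) -> pd.DataFrame:
    """Enrichment table with BH-adjusted p and significance flags."""
    table = hypergeometric_enrichment(query, collection)
    adjusted, significant = bh_adjust(table["p"].to_numpy(), fdr=fdr)
    table["p_adj"] = adjusted
    table["significant"] = significant
    return table


def read_edge_list(path) -> pd.DataFrame:
    """Read an interaction edge TSV: gene_a, gene_b, confidence in [0, 1]."""
    edges = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if edges.shape[1] < 3:
        raise FormatError("edge list needs gene_a, gene_b, confidence columns")
    edges = edges.iloc[:, :3]
    edges.columns = ["gene_a", "gene_b", "confidence"]
    edges["confidence"] = edges["confidence"].astype(float)
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise FormatError("edge confidences must lie in [0, 1]")
    return edges


@dataclass
class InteractionGraph:
    """Confidence-filtered undirected interaction graph around seed genes."""

    graph: nx.Graph
    seed_genes: frozenset[str]
    interactors: frozenset[str]
    components: list[frozenset[str]]
    n_isolated_seeds: int
    min_confidence: float

    def to_json(self, path) -> None:
        payload = {
            "min_confidence": self.min_confidence,
            "nodes": sorted(self.graph.nodes),
            "edges": sorted(
                [a, b, d["confidence"]] for a, b, d in self.graph.edges(data=True)
            ),
            "seed_genes": sorted(self.seed_genes),
            "interactors": sorted(self.interactors),
            "components": [sorted(c) for c in self.components],
            "n_isolated_seeds": self.n_isolated_seeds,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def build_network(
    edges: pd.DataFrame, seed_genes, min_confidence: float = 0.7
) -> InteractionGraph:
    """Assemble the interaction graph at a confidence cutoff.

    Edges below ``min_confidence`` are removed (>= keeps); self-loops are
    dropped.  The interactor set is the seeds plus their direct neighbours;
    seeds absent from the filtered graph stay as isolated nodes (counted).
    """
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        raise ValueError("edge confidences must lie in [0, 1]")
    g = nx.Graph()
    kept = edges[edges["confidence"] >= min_confidence]
    for a, b, c in zip(kept["gene_a"], kept["gene_b"], kept["confidence"]):
        if a == b:
            continue
        g.add_edge(a, b, confidence=float(c))

    seeds = frozenset(seed_genes)
    isolated = 0
    for s in seeds:
        if s not in g:
            g.add_node(s)
            isolated += 1
    if isolated:
        logger.info("build_network: %d seed genes isolated at cutoff", isolated)

    interactors: set[str] = set(seeds)
    for s in seeds:
        interactors.update(g.neighbors(s))
    components = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), sorted(c)[0]),
    )
    return InteractionGraph(
        graph=g,
        seed_genes=seeds,
        interactors=frozenset(interactors),
        components=components,
        n_isolated_seeds=isolated,
        min_confidence=min_confidence,
    )


def term_overlap(results: dict[str, pd.DataFrame]) -> dict[str, int]:
    """Venn partition of significant term IDs across 2-3 enrichment runs."""
    from .dms import overlap_sets

    sets = {
        label: set(table.loc[table["significant"], "term"])
        for label, table in results.items()
    }
    return overlap_sets(sets)
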