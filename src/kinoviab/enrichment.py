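"""Interaction enrichment of selected genes against the inhibition panel.

Given a high-confidence protein-interaction network, the selected
expression genes are scored by (a) how many of them interact with at least
one protein in the inhibition panel and (b) the mean number of panel
interactors per gene.  Significance comes from a resampling null: random
gene sets of the same size drawn uniformly without replacement from the
expression universe, with the observed statistic's percentile reported
against the null draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Undirected graph from an edge list (node_a, node_b, confidence)."""
    g = nx.Graph()
    for a, b, c in edges[["node_a", "node_b", "confidence"]].itertuples(
            index=False):
        g.add_edge(a, b, confidence=float(c))
    return g


def filter_network(network: nx.Graph, min_confidence: float = 0.7) -> nx.Graph:
    """High-confidence subgraph: keep edges with confidence strictly above
    the cutoff; self-edges are dropped."""
    out = nx.Graph()
    out.add_nodes_from(network.nodes)
    for a, b, data in network.edges(data=True):
        if a != b and data.get("confidence", 0.0) > min_confidence:
            out.add_edge(a, b, **data)
    return out


def count_interactors(query_genes, target_proteins,
                      network: nx.Graph) -> tuple[int, float]:
    """(# query genes touching the target set, mean target interactors).

    Per query gene, distinct target proteins adjacent to it are counted;
    genes with zero interactors are included in the mean.
    """
    query = list(query_genes)
    if not query:
        raise ValueError("empty query gene set")
    targets = set(target_proteins)
    counts = []
    for g in query:
        if network.has_node(g):
            counts.append(len(targets.intersection(network.neighbors(g))))
        else:
            counts.append(0)
    counts = np.asarray(counts)
    return int(np.sum(counts >= 1)), float(np.mean(counts))


@dataclass
class EnrichmentResult:
    """Observed interactor statistics with their resampling null.

    Percentiles use the half-tie convention: (#draws strictly below + half
    the ties) / n_draws * 100.
    """

    observed_n_interacting: int
    observed_mean_interactors: float
    null_n_interacting: list[int]
    null_mean_interactors: list[float]
    percentile_n: float
    percentile_mean: float
    n_draws: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _percentile(null: np.ndarray, observed: float) -> float:
    less = np.sum(null < observed)
    ties = np.sum(null == observed)
    return float((less + 0.5 * ties) / null.size * 100.0)


def resample_null(
    gene_universe,
    target_proteins,
    network: nx.Graph,
    query_genes,
    n_draws: int = 10000,
    seed: int = 0,
) -> EnrichmentResult:
    """Score a query gene set against random same-size sets.

    ``n_draws`` uniform without-replacement samples of ``len(query_genes)``
    genes are drawn from ``gene_universe``; both statistics are computed per
    draw and the observed set's percentile within each null is reported.
    Deterministic given seed.
    """
    universe = list(gene_universe)
    query = list(query_genes)
    if len(query) > len(universe):
        raise ValueError("query set larger than gene universe")
    if n_draws < 100:
        warnings.warn("n_draws < 100 gives unstable percentiles",
                      stacklevel=2)
    targets = set(target_proteins)
    # per-universe-gene count of adjacent target proteins (computed once)
    counts = np.array([
        len(targets.intersection(network.neighbors(g)))
        if network.has_node(g) else 0
        for g in universe
    ])
    obs_n, obs_mean = count_interactors(query, targets, network)

    rng = np.random.default_rng(seed)
    set_size = len(query)
    u = len(universe)
    if n_draws * u <= 20_000_000:
        # vectorized without-replacement sampling via random-key argpartition
        keys = rng.random((n_draws, u))
        picks = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        sampled = counts[picks]
        null_n = np.sum(sampled >= 1, axis=1)
        null_mean = sampled.mean(axis=1)
    else:
        null_n = np.empty(n_draws, dtype=int)
        null_mean = np.empty(n_draws)
        for i in range(n_draws):
            sampled = counts[rng.choice(u, size=set_size, replace=False)]
            null_n[i] = np.sum(sampled >= 1)
            null_mean[i] = sampled.mean()

    return EnrichmentResult(
        observed_n_interacting=obs_n,
        observed_mean_interactors=obs_mean,
        null_n_interacting=null_n.tolist(),
        null_mean_interactors=null_mean.tolist(),
        percentile_n=_percentile(null_n, obs_n),
        percentile_mean=_percentile(null_mean, obs_mean),
        n_draws=n_draws,
        seed=seed,
    )
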