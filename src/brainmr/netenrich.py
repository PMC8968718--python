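"""Connectivity enrichment of a gene set on a background interaction network.

Observed edges among the query genes' induced subgraph are compared with
the expectation under a uniform edge-density null: with background density
``D = |E| / C(|V|, 2)`` and ``k`` query nodes, ``E_exp = C(k, 2) * D`` and
the tail probability of observing at least ``E_obs`` edges is binomial.
A uniform node-set permutation gives the empirical alternative.  Edge
confidence is ignored for counting (unweighted degrees); a confidence
cutoff can filter edges beforehand.  This density null is deliberately
simple and degree-homogeneous — it does not reproduce degree-corrected
nulls used by curated interaction databases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb

import networkx as nx
import numpy as np
from scipy import stats as sps

from ._seeds import substream

logger = logging.getLogger(__name__)

__all__ = ["ConnectivityResult", "induced_stats", "expected_edges", "connectivity_pvalue"]


@dataclass
class ConnectivityResult:
    n_nodes: int
    e_obs: int
    e_exp: float
    mean_degree: float
    p: float
    method: str


def _present(network: nx.Graph, genes, include_missing: bool) -> list[str]:
    genes = list(dict.fromkeys(genes))
    present = [g for g in genes if g in network]
    absent = [g for g in genes if g not in network]
    if absent and not include_missing:
        logger.info("dropping %d query genes absent from the network", len(absent))
    if include_missing:
        present = genes  # absent genes count as isolated nodes
    if not [g for g in present if g in network]:
        raise ValueError("query gene set does not intersect the network")
    return present


def induced_stats(
    network: nx.Graph, genes: list[str] | set[str], include_missing: bool = False
) -> tuple[int, int, float]:
    """(n_nodes, observed induced edges, mean unweighted degree) for a gene set."""
    nodes = _present(network, genes, include_missing)
    in_net = [g for g in nodes if g in network]
    e_obs = network.subgraph(in_net).number_of_edges()
    n = len(nodes)
    return n, e_obs, 2 * e_obs / n


def expected_edges(network: nx.Graph, k: int) -> float:
    """Expected induced edges for k uniform nodes: C(k,2) * background density."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = network.number_of_nodes()
    if n < 2:
        raise ValueError("network needs at least 2 nodes")
    density = network.number_of_edges() / comb(n, 2)
    return comb(k, 2) * density


def connectivity_pvalue(
    network: nx.Graph,
    genes: list[str] | set[str],
    method: str = "binomial",
    n_perm: int = 10_000,
    seed: int = 0,
    include_missing: bool = False,
    min_confidence: float | None = None,
) -> ConnectivityResult:
    """Upper-tail p-value for the connectivity of a gene set.

    ``binomial``: P(Binomial(C(k,2), D) >= E_obs).  ``permutation``: draw
    ``n_perm`` uniform k-node sets and use the add-one estimator
    ``(1 + #{draws with >= E_obs edges}) / (1 + n_perm)`` (never exactly 0).
    """
    if method not in ("binomial", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    if min_confidence is not None:
        keep = [
            (u, v) for u, v, c in network.edges(data="confidence", default=1.0)
            if c >= min_confidence
        ]
        filtered = nx.Graph()
        filtered.add_nodes_from(network.nodes)
        filtered.add_edges_from(keep)
        network = filtered
    n_nodes, e_obs, mean_deg = induced_stats(network, genes, include_missing)
    k = n_nodes
    if k < 2:
        raise ValueError("need at least 2 query nodes in the network")
    e_exp = expected_edges(network, k)
    density = network.number_of_edges() / comb(network.number_of_nodes(), 2)

    if method == "binomial":
        p = float(sps.binom.sf(e_obs - 1, comb(k, 2), density))
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = substream(seed, "connectivity_permutation")
        nodes = np.array(sorted(network.nodes))
        adj = nx.to_numpy_array(network, nodelist=nodes, dtype=bool)
        hits = 0
        for _ in range(n_perm):
            idx = rng.choice(len(nodes), size=k, replace=False)
            if adj[np.ix_(idx, idx)].sum() // 2 >= e_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return ConnectivityResult(k, e_obs, e_exp, mean_deg, min(1.0, p), method)
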