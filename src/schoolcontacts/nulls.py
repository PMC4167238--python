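"""Randomization schemes benchmarking day-to-day neighborhood similarity.

Six null models destroy different aspects of the daily contact networks
while conserving others; comparing the empirical day-pair neighborhood
cosine similarities to each scheme's distribution shows how much of the
observed stability survives randomization:

======================  ====================================================
scheme                  conserves
======================  ====================================================
random_edges_global     N, E, weight multiset (edges placed uniformly)
random_edges_classpair  ... plus the number of edges E_XY per class pair
rewire_global           the degree of every node (double-edge swaps,
                        weights carried with the edges)
rewire_classpair        per-node degrees within every class-pair subgraph
weight_shuffle_global   the full topology; weights permuted over all edges
weight_shuffle_classpair topology; weights permuted within each class pair
======================  ====================================================

Each edge's (weight, count) attribute pair travels together, so every
scheme conserves the global weight multiset, and the class-pair variants
conserve it per class pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .longitudinal import SimilaritySummary, pooled_daypair_similarities
from .network import AggregatedNetwork

logger = logging.getLogger("schoolcontacts")

SCHEMES: tuple[str, ...] = (
    "random_edges_global",
    "random_edges_classpair",
    "rewire_global",
    "rewire_classpair",
    "weight_shuffle_global",
    "weight_shuffle_classpair",
)

SWAP_MULTIPLIER = 10  # target successful double-edge swaps per edge


class NullModelError(ValueError):
    pass


def _edge_attrs(g: nx.Graph) -> list[dict]:
    return [d.copy() for _, _, d in g.edges(data=True)]


def _empty_copy(network: AggregatedNetwork) -> nx.Graph:
    g = nx.Graph()
    for node, d in network.graph.nodes(data=True):
        g.add_node(node, **d)
    return g


def _place_random_edges(
    g: nx.Graph, nodes_a: Sequence, nodes_b: Sequence, attrs: list[dict], rng, same_pool: bool
) -> None:
    """Place len(attrs) distinct edges uniformly between two node pools."""
    if same_pool:
        pairs = list(combinations(nodes_a, 2))
    else:
        pairs = [(a, b) for a in nodes_a for b in nodes_b]
    if len(attrs) > len(pairs):
        raise NullModelError("more edges than available pairs")
    sel = rng.choice(len(pairs), size=len(attrs), replace=False)
    order = rng.permutation(len(attrs))
    for k, s in zip(order, sel):
        a, b = pairs[s]
        g.add_edge(a, b, **attrs[k])


def _double_edge_swaps(g: nx.Graph, edges: list[tuple], rng, bipartite: bool) -> None:
    """In-place degree-preserving swaps on a subset of edges.

    ``edges`` lists [u, v] pairs (for bipartite class pairs, oriented as
    (class-X end, class-Y end) so swaps stay within the pair subgraph).
    Weights travel with their edge.  Rejected proposals (self-loop or
    duplicate edge anywhere in g) do not count toward the swap target.
    """
    m = len(edges)
    if m < 2:
        return  # degenerate subgraph: left unchanged
    edges = [list(e) for e in edges]
    target = SWAP_MULTIPLIER * m
    max_attempts = 20 * target
    done = attempts = 0
    while done < target and attempts < max_attempts:
        attempts += 1
        e1, e2 = rng.choice(m, size=2, replace=False)
        a, b = edges[e1]
        c, d = edges[e2]
        if not bipartite and rng.random() < 0.5:
            c, d = d, c
        # propose (a, d), (c, b)
        if a == d or c == b:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        attr1 = g.edges[a, b].copy()
        attr2 = g.edges[c, d].copy()
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d, **attr1)
        g.add_edge(c, b, **attr2)
        edges[e1] = [a, d]
        edges[e2] = [c, b]
        done += 1
    if done < target:
        logger.debug("double-edge swaps: %d/%d achieved", done, target)


def _class_pair_edges(network: AggregatedNetwork) -> dict[tuple[str, str], list[tuple]]:
    cls = network.roster["class"]
    out: dict[tuple[str, str], list[tuple]] = {}
    for i, j in network.graph.edges():
        ci, cj = cls[i], cls[j]
        if (ci, cj) <= (cj, ci):
            key, edge = (ci, cj), (i, j)
        else:
            key, edge = (cj, ci), (j, i)
        out.setdefault(key, []).append(edge)
    return out


def randomize(
    network: AggregatedNetwork, scheme: str, seed: int | np.random.Generator = 0
) -> AggregatedNetwork:
    """One randomized realization of ``network`` under the given scheme."""
    if scheme not in SCHEMES:
        raise NullModelError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    roster = network.roster
    cls = roster["class"]

    if scheme == "random_edges_global":
        g = _empty_copy(network)
        _place_random_edges(g, list(roster.index), list(roster.index), _edge_attrs(network.graph), rng, same_pool=True)
        return AggregatedNetwork(graph=g, roster=roster, window=network.window)

    if scheme == "random_edges_classpair":
        g = _empty_copy(network)
        by_class: dict[str, list] = {}
        for node in roster.index:
            by_class.setdefault(cls[node], []).append(node)
        for (cx, cy), edges in _class_pair_edges(network).items():
            attrs = [network.graph.edges[e].copy() for e in edges]
            _place_random_edges(g, by_class[cx], by_class[cy], attrs, rng, same_pool=(cx == cy))
        return AggregatedNetwork(graph=g, roster=roster, window=network.window)

    if scheme == "rewire_global":
        g = network.graph.copy()
        _double_edge_swaps(g, list(g.edges()), rng, bipartite=False)
        return AggregatedNetwork(graph=g, roster=roster, window=network.window)

    if scheme == "rewire_classpair":
        g = network.graph.copy()
        for (cx, cy), edges in _class_pair_edges(network).items():
            _double_edge_swaps(g, edges, rng, bipartite=(cx != cy))
        return AggregatedNetwork(graph=g, roster=roster, window=network.window)

    if scheme == "weight_shuffle_global":
        g = network.graph.copy()
        _shuffle_weights(g, list(g.edges()), rng)
        return AggregatedNetwork(graph=g, roster=roster, window=network.window)

    # weight_shuffle_classpair
    g = network.graph.copy()
    for _, edges in _class_pair_edges(network).items():
        _shuffle_weights(g, edges, rng)
    return AggregatedNetwork(graph=g, roster=roster, window=network.window)


def _shuffle_weights(g: nx.Graph, edges: list[tuple], rng) -> None:
    attrs = [g.edges[e].copy() for e in edges]
    for e, k in zip(edges, rng.permutation(len(attrs))):
        g.edges[e].update(attrs[k])


# ---------------------------------------------------------------------------
# similarity benchmark
# ---------------------------------------------------------------------------


@dataclass
class NullEnsemble:
    """Pooled day-pair similarity distribution under one null scheme."""

    scheme: str
    n_real: int
    seed: int
    values: np.ndarray = field(repr=False)  # all sigma, pooled across realizations
    per_real_mean: np.ndarray = field(repr=False)

    def summary(self) -> SimilaritySummary:
        return SimilaritySummary.from_values(self.values)


def null_similarity_benchmark(
    day_networks: Sequence[AggregatedNetwork],
    scheme: str,
    n_real: int = 1000,
    seed: int = 0,
    scope: str = "all",
) -> NullEnsemble:
    """Distribution of day-pair neighborhood similarities under a null model.

    Each realization independently randomizes every daily network with the
    scheme, then pools the per-node cosine similarities over all unordered
    day pairs.
    """
    if len(day_networks) < 2:
        raise NullModelError("need at least 2 daily networks")
    rng = np.random.default_rng(seed)
    values: list[np.ndarray] = []
    means = np.empty(n_real)
    for r in range(n_real):
        randomized = [randomize(net, scheme, seed=rng) for net in day_networks]
        pooled = pooled_daypair_similarities(randomized, scope=scope)
        sig = pooled["sigma"].to_numpy()
        values.append(sig)
        means[r] = np.mean(sig) if sig.size else np.nan
    return NullEnsemble(
        scheme=scheme,
        n_real=n_real,
        seed=seed,
        values=np.concatenate(values) if values else np.array([]),
        per_real_mean=means,
    )


def benchmark_all_schemes(
    day_networks: Sequence[AggregatedNetwork],
    n_real: int = 1000,
    seed: int = 0,
    scope: str = "all",
    schemes: Sequence[str] = SCHEMES,
) -> pd.DataFrame:
    """Summary table (scheme, n, median, q25, q75, mean), plus the empirical row."""
    rows = []
    emp = SimilaritySummary.from_values(
        pooled_daypair_similarities(day_networks, scope=scope)["sigma"].to_numpy()
    )
    rows.append(("empirical", emp.n, emp.median, emp.q25, emp.q75, emp.mean))
    for k, scheme in enumerate(schemes):
        ens = null_similarity_benchmark(
            day_networks, scheme, n_real=n_real, seed=seed + k, scope=scope
        )
        s = ens.summary()
        rows.append((scheme, s.n, s.median, s.q25, s.q75, s.mean))
    return pd.DataFrame(rows, columns=["scheme", "n", "median", "q25", "q75", "mean"])
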