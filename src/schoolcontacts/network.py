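"""Aggregated weighted contact networks and their statistics.

Over any aggregation window the contact stream defines an undirected graph:
nodes are all roster individuals (contact-free students remain as isolates),
an edge joins a pair that was in contact at least once, the edge *count*
n_ij is its number of contact events and the edge *weight* w_ij its
cumulative contact duration in seconds.  A node's degree k_i counts its
distinct partners, its strength s_i its total contact seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import zeta

from .stream_io import (
    RESOLUTION,
    DAY_SECONDS,
    StreamValidationError,
    TimeWindow,
    check_roster_covers,
    records_to_events,
)


class UndefinedStatisticError(ValueError):
    """A statistic is not defined for the given input (e.g. N < 2)."""


@dataclass
class AggregatedNetwork:
    """Weighted contact graph over one window, plus roster provenance."""

    graph: nx.Graph
    roster: pd.DataFrame
    window: TimeWindow | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> pd.Series:
        return pd.Series(dict(self.graph.degree()), name="degree").reindex(self.roster.index)

    def strengths(self) -> pd.Series:
        return pd.Series(
            dict(self.graph.degree(weight="weight")), name="strength"
        ).reindex(self.roster.index)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            (i, j, d["weight"], d["count"]) for i, j, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["i", "j", "weight", "count"]).sort_values(
            ["i", "j"], ignore_index=True
        )

    def total_weight(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


def aggregate(
    stream: pd.DataFrame,
    roster: pd.DataFrame,
    window: TimeWindow | None = None,
) -> AggregatedNetwork:
    """Build the aggregated network of a stream (optionally window-restricted)."""
    check_roster_covers(stream, roster)
    if window is not None:
        stream = stream[(stream["t"] >= window.start) & (stream["t"] < window.end)]
    g = nx.Graph()
    for node, row in roster.iterrows():
        g.add_node(node, **{"class": row["class"], "gender": row["gender"]})
    events = records_to_events(stream)
    if not events.empty:
        agg = events.groupby(["i", "j"], sort=False).agg(
            weight=("duration", "sum"), count=("duration", "size")
        )
        for (i, j), row in agg.iterrows():
            g.add_edge(i, j, weight=int(row["weight"]), count=int(row["count"]))
    return AggregatedNetwork(graph=g, roster=roster, window=window)


# ---------------------------------------------------------------------------
# distribution summaries
# ---------------------------------------------------------------------------


@dataclass
class DistributionSummary:
    """Empirical distribution with mean, CV^2 and a survival-function table.

    CV^2 (squared coefficient of variation) is the population variance over
    the squared mean; values well above 1 indicate a heavy-tailed,
    heterogeneous distribution.
    """

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.n else math.nan

    @property
    def cv2(self) -> float:
        if self.n == 0:
            return math.nan
        m = self.mean
        if m == 0:
            return math.nan
        return float(np.var(self.values) / m**2)

    def survival(self) -> pd.DataFrame:
        """Table of P(X >= x) at each distinct value x."""
        xs, counts = np.unique(self.values, return_counts=True)
        surv = 1.0 - np.concatenate(([0.0], np.cumsum(counts[:-1]))) / self.n
        return pd.DataFrame({"value": xs, "survival": surv})

    def to_frame(self) -> pd.DataFrame:
        return self.survival().assign(label=self.label)


def contact_duration_distribution(stream: pd.DataFrame) -> DistributionSummary:
    """Durations of contact events (seconds)."""
    events = records_to_events(stream)
    return DistributionSummary(events["duration"].to_numpy(float), label="contact_duration")


def inter_contact_distribution(
    stream: pd.DataFrame, day_seconds: int = DAY_SECONDS
) -> DistributionSummary:
    """Per-node gaps between successive contact activity, within each day.

    A node's contact intervals (from any partner) are merged into busy
    periods first, so simultaneous contacts with different partners do not
    produce spurious zero or negative gaps.  Overnight gaps are excluded:
    contacts outside school hours were never observable, so cross-day gaps
    would be censoring artifacts rather than genuine inter-contact times.
    """
    events = records_to_events(stream)
    gaps: list[float] = []
    if events.empty:
        return DistributionSummary(np.array([]), label="inter_contact")
    ev = events.assign(day=events["start"] // day_seconds, end=events["start"] + events["duration"])
    long = pd.concat(
        [
            ev[["i", "day", "start", "end"]].rename(columns={"i": "node"}),
            ev[["j", "day", "start", "end"]].rename(columns={"j": "node"}),
        ]
    )
    for (_, _), sub in long.groupby(["node", "day"], sort=False):
        sub = sub.sort_values("start")
        busy_end = None
        for start, end in zip(sub["start"], sub["end"]):
            if busy_end is None:
                busy_end = end
            elif start > busy_end:
                gaps.append(start - busy_end)
                busy_end = end
            else:
                busy_end = max(busy_end, end)
    return DistributionSummary(np.array(gaps, dtype=float), label="inter_contact")


def degree_distribution(network: AggregatedNetwork, rescaled: bool = False) -> DistributionSummary:
    """Distribution of node degrees, optionally rescaled by the mean degree."""
    if network.n_edges == 0:
        raise UndefinedStatisticError("degree distribution of an edgeless network")
    k = network.degrees().to_numpy(float)
    label = "degree"
    if rescaled:
        k = k / k.mean()
        label = "degree_rescaled"
    return DistributionSummary(k, label=label)


def weight_distribution(network: AggregatedNetwork) -> DistributionSummary:
    if network.n_edges == 0:
        raise UndefinedStatisticError("weight distribution of an edgeless network")
    w = np.array([d["weight"] for _, _, d in network.graph.edges(data=True)], float)
    return DistributionSummary(w, label="edge_weight")


# ---------------------------------------------------------------------------
# graph-level statistics
# ---------------------------------------------------------------------------


def density(n_nodes: int, n_edges: int) -> float:
    """Edge density 2E / (N(N-1)) over the full roster."""
    if n_nodes < 2:
        raise UndefinedStatisticError("density needs at least 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def graph_statistics(network: AggregatedNetwork) -> dict[str, float]:
    """Density, clustering and average shortest path length.

    Clustering is the average local clustering coefficient over nodes with
    degree >= 2 (degree-0/1 nodes have no defined triangle fraction and are
    excluded); transitivity is reported alongside.  The shortest path length
    is averaged over the largest connected component, edges unweighted.
    """
    g = network.graph
    n = g.number_of_nodes()
    if n < 2:
        raise UndefinedStatisticError("graph statistics need at least 2 nodes")
    out = {"n_nodes": n, "n_edges": g.number_of_edges()}
    out["density"] = density(n, g.number_of_edges())
    eligible = [v for v, k in g.degree() if k >= 2]
    out["clustering"] = (
        float(np.mean(list(nx.clustering(g, eligible).values()))) if eligible else math.nan
    )
    out["transitivity"] = nx.transitivity(g)
    comps = list(nx.connected_components(g))
    giant = g.subgraph(max(comps, key=len))
    out["avg_shortest_path"] = (
        nx.average_shortest_path_length(giant) if giant.number_of_nodes() > 1 else math.nan
    )
    return out


# ---------------------------------------------------------------------------
# discrete power-law tail fit (Clauset-style MLE with KS xmin selection)
# ---------------------------------------------------------------------------


class PowerLawFitError(ValueError):
    pass


@dataclass
class PowerLawFit:
    exponent: float
    xmin: float
    ks_distance: float
    n_tail: int


def _discrete_mle(tail: np.ndarray, xmin: float) -> float:
    # Standard discrete approximation: alpha = 1 + n / sum(ln(x / (xmin - 1/2)))
    return 1.0 + tail.size / np.sum(np.log(tail / (xmin - 0.5)))


def _ks_discrete(tail: np.ndarray, xmin: float, alpha: float) -> float:
    xs, counts = np.unique(tail, return_counts=True)
    emp_cdf = np.cumsum(counts) / tail.size
    # model CDF via Hurwitz zeta: P(X <= x) = 1 - zeta(alpha, x+1)/zeta(alpha, xmin)
    denom = zeta(alpha, xmin)
    model_cdf = 1.0 - zeta(alpha, xs + 1.0) / denom
    return float(np.max(np.abs(emp_cdf - model_cdf)))


def fit_powerlaw_tail(
    values: Sequence[float], min_tail: int = 50, max_xmin_candidates: int = 100
) -> PowerLawFit:
    """Fit a discrete power-law tail P(x) ~ x^-alpha, selecting xmin by KS.

    Values are expected on an integer-like grid (rescale durations by the
    20-s resolution before fitting).  Requires at least ``min_tail`` values
    above the selected cutoff and at least two distinct values.
    """
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if x.size < min_tail:
        raise PowerLawFitError(f"need at least {min_tail} positive values, got {x.size}")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise PowerLawFitError("degenerate sample: single distinct value")
    candidates = uniq[:-1]
    if candidates.size > max_xmin_candidates:
        idx = np.linspace(0, candidates.size - 1, max_xmin_candidates).astype(int)
        candidates = candidates[np.unique(idx)]
    best: PowerLawFit | None = None
    for xmin in candidates:
        tail = x[x >= xmin]
        if tail.size < min_tail or np.unique(tail).size < 2:
            continue
        alpha = _discrete_mle(tail, xmin)
        if not np.isfinite(alpha) or alpha <= 1.0:
            continue
        ks = _ks_discrete(tail, xmin, alpha)
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(float(alpha), float(xmin), ks, int(tail.size))
    if best is None:
        raise PowerLawFitError("no admissible xmin with a sufficient tail")
    return best
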