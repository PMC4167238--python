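"""Time-resolved activity, contact growth curves and neighborhood stability.

The day-to-day stability of an individual's contacts is measured with the
cosine similarity between the node's weighted neighbor vectors in two
aggregated networks (e.g. two daily networks):

    sigma_i = sum_j w_ij^(1) w_ij^(2) / sqrt(sum_j (w_ij^(1))^2 * sum_j (w_ij^(2))^2)

sigma_i = 1 when i met the same partners with proportional cumulative
durations in both windows; sigma_i = 0 when the partner sets are disjoint.
A *scope* restricts the neighbor sum to same-class or other-class partners
(weights to out-of-scope neighbors are zeroed before normalization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .network import AggregatedNetwork
from .stream_io import RESOLUTION, ConfigurationError, records_to_events

logger = logging.getLogger("schoolcontacts")

Scope = Literal["all", "intra", "inter"]


def activity_series(
    stream: pd.DataFrame, window_len: int, count: Literal["records", "events"] = "records"
) -> pd.Series:
    """Contact activity per aligned time window of length ``window_len`` s.

    By default counts 20-s proximity records; ``count="events"`` counts
    contact-event starts instead (the two readings of "number of contacts").
    The series index is the window start time; windows tile [0, max t].
    """
    if window_len <= 0 or window_len % RESOLUTION:
        raise ConfigurationError("window_len must be a positive multiple of 20 s")
    if count == "events":
        ts = records_to_events(stream)["start"]
    else:
        ts = stream["t"]
    if len(ts) == 0:
        return pd.Series(dtype=int, name="n_contacts")
    n_win = int(ts.max() // window_len) + 1
    counts = np.bincount((ts // window_len).astype(int), minlength=n_win)
    index = pd.Index(np.arange(n_win) * window_len, name="t")
    return pd.Series(counts, index=index, name="n_contacts")


def growth_curves(
    stream: pd.DataFrame, roster: pd.DataFrame, grid: Sequence[int] | None = None
) -> pd.DataFrame:
    """Average cumulated contact time and distinct-partner count per student.

    At each grid time t the curves give, averaged over the *full roster*
    (students with no contacts yet contribute zeros):

    * ``time_total`` / ``time_same_class`` / ``time_other_class``: average
      seconds spent in contact since the study start;
    * ``distinct_total`` / ``distinct_same_class`` / ``distinct_other_class``:
      average number of distinct partners met since the study start.

    Time accrues at record (20 s) granularity; a partner is counted from the
    pair's first record on.  Same-class and other-class components sum to
    the totals exactly.
    """
    n_roster = len(roster)
    cls = roster["class"]
    rec = stream.copy()
    same = (cls.loc[rec["i"]].to_numpy() == cls.loc[rec["j"]].to_numpy()) if len(rec) else np.array([], bool)
    rec["same_class"] = same
    if grid is None:
        grid = np.unique(rec["t"]) + RESOLUTION if len(rec) else np.array([0])
    grid = np.asarray(sorted(grid))

    out = pd.DataFrame(index=pd.Index(grid, name="t"))
    # contact seconds: each record adds 20 s to each of its two participants
    for label, mask in (("same_class", same), ("other_class", ~same)):
        ts = np.sort(rec.loc[mask, "t"].to_numpy()) if len(rec) else np.array([])
        cum = np.searchsorted(ts, grid, side="left")  # records starting before t
        out[f"time_{label}"] = cum * 2.0 * RESOLUTION / n_roster
    # distinct partners: first record time of each pair
    if len(rec):
        firsts = rec.groupby(["i", "j"], sort=False).agg(t=("t", "min"), same=("same_class", "first"))
    else:
        firsts = pd.DataFrame(columns=["t", "same"])
    for label, want_same in (("same_class", True), ("other_class", False)):
        ts = np.sort(firsts.loc[firsts["same"] == want_same, "t"].to_numpy()) if len(firsts) else np.array([])
        cum = np.searchsorted(ts, grid, side="left")
        out[f"distinct_{label}"] = cum * 2.0 / n_roster
    out["time_total"] = out["time_same_class"] + out["time_other_class"]
    out["distinct_total"] = out["distinct_same_class"] + out["distinct_other_class"]
    return out


# ---------------------------------------------------------------------------
# neighborhood cosine similarity
# ---------------------------------------------------------------------------


def _weight_vectors(net: AggregatedNetwork) -> dict[str, dict[str, float]]:
    vec: dict[str, dict[str, float]] = {}
    for i, j, d in net.graph.edges(data=True):
        vec.setdefault(i, {})[j] = float(d["weight"])
        vec.setdefault(j, {})[i] = float(d["weight"])
    return vec


def _scoped(vec: dict[str, float], node: str, cls: pd.Series, scope: Scope) -> dict[str, float]:
    if scope == "all":
        return vec
    own = cls[node]
    if scope == "intra":
        return {j: w for j, w in vec.items() if cls[j] == own}
    return {j: w for j, w in vec.items() if cls[j] != own}


def neighborhood_similarity(
    net1: AggregatedNetwork,
    net2: AggregatedNetwork,
    scope: Scope = "all",
) -> pd.DataFrame:
    """Per-node cosine similarity of weighted neighborhoods in two windows.

    Nodes with zero scoped strength in either window have undefined sigma
    and are excluded (their count is logged and available from the result's
    ``attrs["n_excluded"]``).
    """
    cls = net1.roster["class"]
    v1 = _weight_vectors(net1)
    v2 = _weight_vectors(net2)
    rows = []
    excluded = 0
    for node in net1.roster.index:
        a = _scoped(v1.get(node, {}), node, cls, scope)
        b = _scoped(v2.get(node, {}), node, cls, scope)
        if not a or not b:
            excluded += 1
            continue
        dot = sum(w * b[j] for j, w in a.items() if j in b)
        na = np.sqrt(sum(w * w for w in a.values()))
        nb = np.sqrt(sum(w * w for w in b.values()))
        rows.append((node, dot / (na * nb)))
    if excluded:
        logger.debug("neighborhood_similarity: %d nodes with undefined sigma", excluded)
    out = pd.DataFrame(rows, columns=["node", "sigma"])
    out.attrs["n_excluded"] = excluded
    out.attrs["scope"] = scope
    return out


@dataclass
class SimilaritySummary:
    """Boxplot-ready summary of a pooled similarity distribution."""

    n: int
    median: float
    q25: float
    q75: float
    mean: float

    @classmethod
    def from_values(cls, values: np.ndarray) -> "SimilaritySummary":
        v = np.asarray(values, float)
        if v.size == 0:
            return cls(0, np.nan, np.nan, np.nan, np.nan)
        return cls(
            int(v.size),
            float(np.median(v)),
            float(np.percentile(v, 25)),
            float(np.percentile(v, 75)),
            float(np.mean(v)),
        )


def pooled_daypair_similarities(
    day_networks: Sequence[AggregatedNetwork], scope: Scope = "all"
) -> pd.DataFrame:
    """All node similarities over all unordered day pairs, as a tidy frame."""
    if len(day_networks) < 2:
        raise ConfigurationError("need at least 2 daily networks")
    frames = []
    for a, b in combinations(range(len(day_networks)), 2):
        sim = neighborhood_similarity(day_networks[a], day_networks[b], scope=scope)
        sim = sim.assign(day_a=a, day_b=b)
        frames.append(sim)
    return pd.concat(frames, ignore_index=True)


def daypair_similarity_summary(
    day_networks: Sequence[AggregatedNetwork],
    scopes: Sequence[Scope] = ("intra", "inter"),
) -> pd.DataFrame:
    """Per-class pooled day-pair similarity distributions (boxplot summary).

    For each class and scope, pools sigma over all unordered day pairs and
    all class members with defined sigma, mirroring the accounting
    "(number of day pairs) x (class members)" of per-class boxplots.
    """
    roster = day_networks[0].roster
    rows = []
    for scope in scopes:
        pooled = pooled_daypair_similarities(day_networks, scope=scope)
        pooled["class"] = roster["class"].reindex(pooled["node"]).to_numpy()
        for cname, sub in pooled.groupby("class", sort=True):
            s = SimilaritySummary.from_values(sub["sigma"].to_numpy())
            rows.append((cname, scope, s.n, s.median, s.q25, s.q75, s.mean))
    return pd.DataFrame(
        rows, columns=["class", "scope", "n", "median", "q25", "q75", "mean"]
    )
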