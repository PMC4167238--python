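"""Gender homophily: preference index, edge-type shares, and the ER null.

Because the study population is strongly gender-imbalanced, raw same-gender
edge shares cannot be read as homophily.  The comparison baseline is an
Erdos-Renyi-style null: graphs with the same numbers of nodes (with their
gender labels) and edges, but edges placed uniformly at random.  Under this
null the expected male-male edge share is C(n_M, 2)/C(N, 2) and a male
node's expected same-gender neighbor fraction is (n_M - 1)/(N - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from .network import AggregatedNetwork
from .stream_io import StreamValidationError


class HomophilyError(ValueError):
    pass


@dataclass
class PreferenceIndexResult:
    """Per-node same-gender edge fractions h_i, with per-gender summaries."""

    per_node: pd.DataFrame  # columns: gender, degree, h
    n_zero_degree: int

    def summary(self) -> pd.DataFrame:
        """median / quartiles / mean of h per gender (boxplot-ready)."""
        rows = []
        for gender, sub in self.per_node.groupby("gender", sort=True):
            h = sub["h"].to_numpy()
            rows.append(
                (
                    gender,
                    len(h),
                    float(np.median(h)),
                    float(np.percentile(h, 25)),
                    float(np.percentile(h, 75)),
                    float(np.mean(h)),
                )
            )
        return pd.DataFrame(rows, columns=["gender", "n", "median", "q25", "q75", "mean"])

    def mean(self, gender: str) -> float:
        sub = self.per_node[self.per_node["gender"] == gender]
        return float(sub["h"].mean())


@dataclass(frozen=True)
class GenderEdgeFractions:
    mm: float
    ff: float
    mf: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mm, self.ff, self.mf)


def same_gender_preference(network: AggregatedNetwork) -> PreferenceIndexResult:
    """h_i = fraction of node i's edges joining a same-gender partner.

    Edge-based (unweighted); nodes with no edges have undefined h and are
    excluded, with their count reported.
    """
    roster = network.roster
    if roster["gender"].isna().any():
        raise StreamValidationError("missing gender label in roster")
    g = network.graph
    rows = []
    n_zero = 0
    gender = roster["gender"]
    for node in roster.index:
        k = g.degree(node)
        if k == 0:
            n_zero += 1
            continue
        same = sum(1 for nb in g.neighbors(node) if gender[nb] == gender[node])
        rows.append((node, gender[node], k, same / k))
    per_node = pd.DataFrame(rows, columns=["node", "gender", "degree", "h"]).set_index("node")
    return PreferenceIndexResult(per_node=per_node, n_zero_degree=n_zero)


def gender_edge_fractions(network: AggregatedNetwork) -> GenderEdgeFractions:
    """Shares of M-M, F-F and mixed edges (sum to 1)."""
    g = network.graph
    if g.number_of_edges() == 0:
        raise HomophilyError("edge fractions undefined for an edgeless network")
    gender = network.roster["gender"]
    mm = ff = mf = 0
    for i, j in g.edges():
        gi, gj = gender[i], gender[j]
        if gi == gj == "M":
            mm += 1
        elif gi == gj == "F":
            ff += 1
        else:
            mf += 1
    e = g.number_of_edges()
    return GenderEdgeFractions(mm / e, ff / e, mf / e)


def threshold_network(network: AggregatedNetwork, min_weight: int) -> AggregatedNetwork:
    """Keep only edges with cumulative duration >= ``min_weight`` seconds.

    ("larger than a given threshold" is read inclusively on the 20-s grid.)
    The node set is unchanged.
    """
    g = network.graph.copy()
    drop = [(i, j) for i, j, d in g.edges(data=True) if d["weight"] < min_weight]
    g.remove_edges_from(drop)
    return AggregatedNetwork(graph=g, roster=network.roster, window=network.window)


# ---------------------------------------------------------------------------
# Erdos-Renyi null ensemble
# ---------------------------------------------------------------------------


@dataclass
class ERNullEnsemble:
    """Summary of gender statistics over uniform G(N, E) realizations."""

    n_nodes: int
    n_edges: int
    n_male: int
    n_female: int
    n_real: int
    seed: int
    # per-realization arrays
    mm: np.ndarray = field(repr=False)
    ff: np.ndarray = field(repr=False)
    mf: np.ndarray = field(repr=False)
    male_pref: np.ndarray = field(repr=False)
    female_pref: np.ndarray = field(repr=False)

    def mean(self, stat: str) -> float:
        return float(np.mean(getattr(self, stat)))

    def mc_se(self, stat: str) -> float:
        """Monte-Carlo standard error of the ensemble mean."""
        v = getattr(self, stat)
        return float(np.std(v, ddof=1) / np.sqrt(len(v)))

    def expected_mm(self) -> float:
        return comb(self.n_male, 2) / comb(self.n_nodes, 2)

    def expected_ff(self) -> float:
        return comb(self.n_female, 2) / comb(self.n_nodes, 2)

    def expected_male_pref(self) -> float:
        return (self.n_male - 1) / (self.n_nodes - 1)

    def summary(self) -> pd.DataFrame:
        rows = [
            (stat, self.mean(stat), self.mc_se(stat))
            for stat in ("mm", "ff", "mf", "male_pref", "female_pref")
        ]
        return pd.DataFrame(rows, columns=["stat", "mean", "mc_se"])


def er_null_ensemble(
    n_male: int,
    n_female: int,
    n_edges: int,
    n_real: int = 1000,
    seed: int = 0,
) -> ERNullEnsemble:
    """Uniform random graphs with fixed N, E and gender labels.

    For each realization, edges are a uniform sample (without replacement)
    of the C(N, 2) possible pairs; the ensemble records gendered edge shares
    and the per-gender mean same-gender preference index (nodes with no
    edges excluded, as in the empirical index).
    """
    n = n_male + n_female
    n_pairs = comb(n, 2)
    if n_edges > n_pairs:
        raise HomophilyError(f"cannot place {n_edges} edges among {n_pairs} pairs")
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    is_male = np.zeros(n, dtype=bool)
    is_male[:n_male] = True  # labels are exchangeable under the null
    mm = np.empty(n_real)
    ff = np.empty(n_real)
    mf = np.empty(n_real)
    male_pref = np.empty(n_real)
    female_pref = np.empty(n_real)
    for r in range(n_real):
        sel = rng.choice(n_pairs, size=n_edges, replace=False)
        a, b = iu[sel], ju[sel]
        am, bm = is_male[a], is_male[b]
        mm[r] = np.mean(am & bm)
        ff[r] = np.mean(~am & ~bm)
        mf[r] = np.mean(am ^ bm)
        deg = np.bincount(a, minlength=n) + np.bincount(b, minlength=n)
        same = np.bincount(a[am & bm], minlength=n) + np.bincount(b[am & bm], minlength=n)
        same += np.bincount(a[~am & ~bm], minlength=n) + np.bincount(b[~am & ~bm], minlength=n)
        with np.errstate(invalid="ignore"):
            h = same / deg
        male_pref[r] = np.nanmean(np.where(is_male & (deg > 0), h, np.nan))
        female_pref[r] = np.nanmean(np.where(~is_male & (deg > 0), h, np.nan))
    return ERNullEnsemble(
        n_nodes=n,
        n_edges=n_edges,
        n_male=n_male,
        n_female=n_female,
        n_real=n_real,
        seed=seed,
        mm=mm,
        ff=ff,
        mf=mf,
        male_pref=male_pref,
        female_pref=female_pref,
    )
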