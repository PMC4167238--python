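"""Susceptible-Infected spreading on temporal contacts and mixing surrogates.

The question addressed here: is a class-level description of the contact
patterns sufficient to model spreading in this population, or must classes
be further split by gender?  Three population representations are compared
under matched transmission parameters:

* ``temporal`` — SI on the full 20-s-resolved contact stream: each record
  between an infected and a susceptible transmits with probability beta.
  Updates are synchronous per 20-s slot (a node infected in slot t starts
  transmitting in later slots), so at beta = 1 the infected set is exactly
  the set reachable by time-respecting paths with strictly increasing
  record times.
* ``class_mixing`` — discrete-time stochastic SI over class compartments:
  a susceptible of group X is infected per 20-s step with probability
  1 - exp(-beta * sum_Y c_XY I_Y / n_Y), where c_XY is the per-capita
  contact-rate matrix (expected contact events per individual of X with
  group Y per step) estimated from the stream.
* ``class_gender_mixing`` — the same dynamics over class x gender groups.

Nights and other out-of-school periods carry no contacts in the stream and
are treated as contact-free gaps; the surrogate's step count covers the
in-school slots only, so time axes are comparable across representations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .matrices import contact_matrix, gender_block_matrix
from .network import aggregate
from .stream_io import RESOLUTION, DAY_SECONDS, ConfigurationError

Representation = Literal["temporal", "class_mixing", "class_gender_mixing"]


@dataclass(frozen=True)
class SIConfig:
    beta: float = 0.01  # per-20-s-record transmission probability
    n_runs: int = 100
    seed: int = 0
    seed_node: str | None = None  # None: uniform random seed node per run

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ConfigurationError("beta must be in [0, 1]")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")


@dataclass
class SITrajectories:
    """Ensemble of SI runs: per-run infection times (seconds; NaN = never)."""

    infection_times: pd.DataFrame  # rows: nodes, columns: runs
    groups: pd.Series  # node -> group label
    representation: str

    @property
    def n_nodes(self) -> int:
        return len(self.infection_times)

    def final_sizes(self) -> np.ndarray:
        return self.infection_times.notna().sum(axis=0).to_numpy()

    def prevalence(self, grid: Sequence[float]) -> pd.DataFrame:
        """Mean fraction infected at each grid time, with MC quantile band."""
        grid = np.asarray(grid, float)
        times = self.infection_times.to_numpy(float)
        frac = np.array(
            [(np.nan_to_num(times, nan=np.inf) <= t).mean(axis=0) for t in grid]
        )  # shape (len(grid), n_runs)
        return pd.DataFrame(
            {
                "t": grid,
                "mean": frac.mean(axis=1),
                "q05": np.quantile(frac, 0.05, axis=1),
                "q95": np.quantile(frac, 0.95, axis=1),
            }
        )

    def group_prevalence(self, grid: Sequence[float]) -> pd.DataFrame:
        frames = []
        for gname in sorted(self.groups.unique()):
            nodes = self.groups[self.groups == gname].index
            sub = SITrajectories(
                self.infection_times.loc[nodes], self.groups[nodes], self.representation
            )
            frames.append(sub.prevalence(grid).assign(group=gname))
        return pd.concat(frames, ignore_index=True)

    def time_to_half(self) -> float:
        """Median over runs of the first time prevalence reaches 1/2 (NaN if never)."""
        times = self.infection_times.to_numpy(float)
        half = (self.n_nodes + 1) // 2
        out = []
        for r in range(times.shape[1]):
            col = np.sort(times[:, r])
            out.append(col[half - 1] if np.isfinite(col[: half]).all() else np.nan)
        return float(np.nanmedian(out)) if np.isfinite(out).any() else float("nan")


# ---------------------------------------------------------------------------
# temporal SI
# ---------------------------------------------------------------------------


def run_si_temporal(
    stream: pd.DataFrame, roster: pd.DataFrame, config: SIConfig
) -> SITrajectories:
    """SI on the raw contact stream, synchronous per 20-s slot."""
    rng = np.random.default_rng(config.seed)
    nodes = list(roster.index)
    node_pos = {n: k for k, n in enumerate(nodes)}
    ts = stream["t"].to_numpy() if len(stream) else np.array([], int)
    ia = stream["i"].map(node_pos).to_numpy() if len(stream) else np.array([], int)
    ja = stream["j"].map(node_pos).to_numpy() if len(stream) else np.array([], int)
    slot_bounds = np.flatnonzero(np.diff(ts, prepend=-1))  # start index of each slot

    times = np.full((len(nodes), config.n_runs), np.nan)
    for run in range(config.n_runs):
        if config.seed_node is None:
            seed_idx = int(rng.integers(len(nodes)))
        else:
            seed_idx = node_pos[config.seed_node]
        t_inf = np.full(len(nodes), np.inf)
        t_inf[seed_idx] = -np.inf  # infectious from the very first slot
        for b, start in enumerate(slot_bounds):
            end = slot_bounds[b + 1] if b + 1 < len(slot_bounds) else len(ts)
            t = ts[start]
            ii, jj = ia[start:end], ja[start:end]
            inf_i = t_inf[ii] < t  # infected strictly before this slot
            inf_j = t_inf[jj] < t
            risky_i = jj[inf_i & ~inf_j]  # susceptible endpoints at risk
            risky_j = ii[inf_j & ~inf_i]
            at_risk = np.concatenate([risky_i, risky_j])
            if at_risk.size == 0:
                continue
            hit = at_risk[rng.random(at_risk.size) < config.beta]
            t_inf[hit] = np.minimum(t_inf[hit], float(t))
        t_inf[seed_idx] = 0.0
        times[:, run] = np.where(np.isfinite(t_inf), t_inf, np.nan)
    return SITrajectories(
        infection_times=pd.DataFrame(times, index=nodes),
        groups=roster["class"].copy(),
        representation="temporal",
    )


# ---------------------------------------------------------------------------
# mixing-matrix surrogate
# ---------------------------------------------------------------------------


def contact_rate_matrix(
    stream: pd.DataFrame,
    roster: pd.DataFrame,
    by_gender: bool = False,
) -> tuple[pd.DataFrame, dict[str, int], int]:
    """Per-capita contact events per 20-s in-school slot, between groups.

    Returns (rate matrix c_XY, group sizes, number of in-school slots).
    The slot count covers, per study day, the span from the day's first to
    last record; days without records contribute nothing.
    """
    net = aggregate(stream, roster)
    if by_gender:
        m = gender_block_matrix(net, mode="nbar")
    else:
        m = contact_matrix(net, mode="nbar")
    n_slots = 0
    if len(stream):
        for _, sub in stream.groupby(stream["t"] // DAY_SECONDS):
            n_slots += int((sub["t"].max() - sub["t"].min()) // RESOLUTION) + 1
    n_slots = max(n_slots, 1)
    return m.data / n_slots, m.group_sizes, n_slots


def run_si_mixing(
    rates: pd.DataFrame,
    group_sizes: dict[str, int],
    config: SIConfig,
    n_steps: int,
    seed_group: str | None = None,
    representation: str = "class_mixing",
) -> SITrajectories:
    """Discrete-time stochastic SI over group compartments.

    Per 20-s step, a susceptible in group X is infected with probability
    1 - exp(-beta * sum_Y c_XY I_Y / n_Y).  Compartment members are
    interchangeable; pseudo-node ids ``<group>#<k>`` are used so that the
    trajectory container matches the temporal representation's.
    """
    labels = list(rates.index)
    if set(labels) != set(group_sizes):
        raise ConfigurationError("rate matrix labels do not match group sizes")
    sizes = np.array([group_sizes[g] for g in labels], float)
    c = np.nan_to_num(rates.loc[labels, labels].to_numpy(float))
    rng = np.random.default_rng(config.seed)
    n_groups = len(labels)
    nodes = [f"{g}#{k}" for gi, g in enumerate(labels) for k in range(int(sizes[gi]))]
    groups = pd.Series(
        [g for gi, g in enumerate(labels) for _ in range(int(sizes[gi]))], index=nodes
    )
    times = np.full((len(nodes), config.n_runs), np.nan)
    offsets = np.concatenate(([0], np.cumsum(sizes))).astype(int)
    for run in range(config.n_runs):
        infected = np.zeros(n_groups)
        if seed_group is None:
            # uniform over individuals
            gi = int(np.searchsorted(np.cumsum(sizes), rng.integers(int(sizes.sum())) + 1))
        else:
            gi = labels.index(seed_group)
        infected[gi] = 1
        inf_counts = [(0.0, infected.copy())]
        for step in range(1, n_steps + 1):
            force = config.beta * (c @ (infected / sizes))
            p = 1.0 - np.exp(-force)
            susceptible = sizes - infected
            new = rng.binomial(susceptible.astype(int), p)
            if new.any():
                infected = infected + new
                inf_counts.append((step * RESOLUTION, infected.copy()))
            if infected.sum() >= sizes.sum():
                break
        # convert compartment counts to pseudo-node infection times
        prev = np.zeros(n_groups, int)
        for t, counts in inf_counts:
            for g in range(n_groups):
                k_new = int(counts[g]) - prev[g]
                if k_new > 0:
                    lo = offsets[g] + prev[g]
                    times[lo : lo + k_new, run] = t
                    prev[g] = int(counts[g])
    return SITrajectories(
        infection_times=pd.DataFrame(times, index=nodes),
        groups=groups,
        representation=representation,
    )


# ---------------------------------------------------------------------------
# representation comparison
# ---------------------------------------------------------------------------


def compare_representations(
    stream: pd.DataFrame,
    roster: pd.DataFrame,
    config: SIConfig,
    grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Prevalence curves of the three representations at matched beta.

    Returns a tidy frame (representation, t, mean, q05, q95) plus summary
    attrs ``final_size`` and ``time_to_half`` per representation.
    """
    if grid is None:
        t_max = float(stream["t"].max() + RESOLUTION) if len(stream) else RESOLUTION
        grid = np.linspace(0, t_max, 60)
    results = {}
    results["temporal"] = run_si_temporal(stream, roster, config)
    for by_gender, name in ((False, "class_mixing"), (True, "class_gender_mixing")):
        rates, sizes, n_slots = contact_rate_matrix(stream, roster, by_gender=by_gender)
        results[name] = run_si_mixing(
            rates, sizes, config, n_steps=n_slots, representation=name
        )
    frames = []
    summaries = {}
    for name, traj in results.items():
        frames.append(traj.prevalence(grid).assign(representation=name))
        summaries[name] = {
            "final_size_mean": float(traj.final_sizes().mean()),
            "n_nodes": traj.n_nodes,
            "time_to_half": traj.time_to_half(),
        }
    out = pd.concat(frames, ignore_index=True)
    out.attrs["summaries"] = summaries
    return out
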