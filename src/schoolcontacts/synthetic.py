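"""Synthetic multi-day school contact streams with realistic structure.

The generator emulates the statistical features of high-resolution contact
data collected in a high school with wearable proximity sensors, so that
every downstream analysis stage can be exercised without the real data:

* five classes with the deployment's class sizes and gender counts, and a
  two-group class substructure (two "MP" classes; three "PC"/"PSI" classes);
* strongly assortative mixing — the default weights imply ~91.5% of contacts
  within classes, with same-group class pairs mixing more than cross-group;
* heavy-tailed contact durations on the 20-s grid (bounded discrete power
  law, default exponent 2.5) and heavy-tailed within-day inter-event gaps
  (default exponent 1.8 — the empirical inter-contact tail is reported only
  qualitatively, so this exponent is an explicit assumption);
* a school-day activity profile with morning-break, lunch and
  afternoon-break peaks;
* tunable day-to-day pair persistence pi: each day a pair keeps its
  previous-day activity state with probability pi and is re-drawn at its
  stationary activation rate otherwise (pi = 0 gives independent days,
  pi = 1 a frozen contact set); cross-class pairs use a reduced pi so that
  intra-class neighborhoods are the more stable ones, and pi directly
  controls the day-to-day neighborhood cosine similarity.

The model is deliberately minimal: each pair has a daily activation
probability proportional to its mixing weight, active pairs draw a bursty
number of events with independent durations, and event start times follow
the activity profile.  No latent friendship or spatial mechanism is posited
beyond what the emulated statistics require.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .stream_io import RESOLUTION, DAY_SECONDS, STREAM_COLUMNS, ConfigurationError

# Default day schedule (seconds from midnight) and activity multipliers.
SCHOOL_START = 8 * 3600
SCHOOL_END = 18 * 3600
DEFAULT_ACTIVITY_PROFILE: tuple[tuple[int, int, float], ...] = (
    (10 * 3600, 10 * 3600 + 1800, 3.0),  # morning break
    (12 * 3600, 14 * 3600, 2.5),  # lunch
    (15 * 3600 + 2400, 16 * 3600, 3.0),  # afternoon break
)

# Mixing weights calibrated so the implied intra-class contact share is
# 91.5% for the default five-class roster (see implied_intraclass_fraction).
DEFAULT_W_SAME = 1.0
DEFAULT_W_GROUP = 0.04
DEFAULT_W_CROSS = 0.010487


@dataclass(frozen=True)
class SchoolConfig:
    """Parameters of the synthetic school; defaults emulate the 2012 study."""

    classes: tuple[tuple[str, int, int], ...] = reference.CLASSES_2012
    class_groups: tuple[tuple[str, ...], ...] = reference.CLASS_GROUPS_2012
    n_days: int = 7
    school_start: int = SCHOOL_START
    school_end: int = SCHOOL_END
    activity_profile: tuple[tuple[int, int, float], ...] = DEFAULT_ACTIVITY_PROFILE
    w_same: float = DEFAULT_W_SAME
    w_group: float = DEFAULT_W_GROUP
    w_cross: float = DEFAULT_W_CROSS
    mean_active_pairs_per_day: float = 650.0
    mean_events_per_pair: float = 2.0
    duration_exponent: float = 2.5
    duration_cap_slots: int = 180  # 1 hour
    intercontact_exponent: float = 1.8
    intercontact_cap_slots: int = 360  # 2 hours
    persistence: float = 0.75  # pi: day-to-day state-copy probability per pair
    cross_class_persistence_factor: float = 0.3  # cross-class pairs are less stable
    pair_affinity_sigma: float = 0.75  # lognormal sd of static per-pair intensity
    gender_homophily: float = 0.0  # 0 = gender-blind mixing
    exam_day: int | None = None  # 0-based day with a quiet afternoon
    exam_afternoon_multiplier: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence <= 1.0):
            raise ConfigurationError("persistence must be in [0, 1]")
        if min(self.w_same, self.w_group, self.w_cross) < 0:
            raise ConfigurationError("mixing weights must be >= 0")
        if any(m + f <= 0 for _, m, f in self.classes):
            raise ConfigurationError("class sizes must be positive")
        if not (-1.0 <= self.gender_homophily <= 1.0):
            raise ConfigurationError("gender_homophily must be in [-1, 1]")
        if self.duration_exponent <= 1.0 or self.intercontact_exponent <= 0.0:
            raise ConfigurationError("invalid tail exponents")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchoolConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("classes", "class_groups", "activity_profile"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(entry) for entry in raw[key])
        return cls(**raw)


@dataclass
class SyntheticDataset:
    """Generated stream + roster, with the generating config as provenance."""

    stream: pd.DataFrame
    roster: pd.DataFrame
    config: SchoolConfig


# ---------------------------------------------------------------------------
# roster and pair-type machinery
# ---------------------------------------------------------------------------


def build_roster(classes: Sequence[tuple[str, int, int]]) -> pd.DataFrame:
    """Roster with zero-padded ids (lexicographic == enrollment order)."""
    rows = []
    k = 0
    for name, n_male, n_female in classes:
        for _ in range(n_male):
            rows.append((f"s{k:04d}", name, "M"))
            k += 1
        for _ in range(n_female):
            rows.append((f"s{k:04d}", name, "F"))
            k += 1
    return pd.DataFrame(rows, columns=["id", "class", "gender"]).set_index("id")


def _pair_weights(config: SchoolConfig, roster: pd.DataFrame) -> tuple[np.ndarray, ...]:
    """Per-pair mixing weights and the upper-triangle pair index arrays."""
    n = len(roster)
    iu, ju = np.triu_indices(n, k=1)
    cls = roster["class"].to_numpy()
    group_of = {}
    for g, members in enumerate(config.class_groups):
        for name in members:
            group_of[name] = g
    # classes outside any declared group fall in the cross-group tier
    grp_per_node = np.array([group_of.get(c, -1) for c in cls])
    same_class = cls[iu] == cls[ju]
    same_group = (grp_per_node[iu] == grp_per_node[ju]) & (grp_per_node[iu] >= 0)
    w = np.where(same_class, config.w_same, np.where(same_group, config.w_group, config.w_cross))
    if config.gender_homophily:
        gen = roster["gender"].to_numpy()
        same_gender = gen[iu] == gen[ju]
        h = config.gender_homophily
        w = w * np.where(same_gender, 1.0 + h, 1.0 - h)
    return w.astype(float), iu, ju, same_class


def implied_intraclass_fraction(config: SchoolConfig) -> float:
    """Expected share of contacts within classes implied by the mixing weights.

    Exact expectation over pair types: sum of weights of intra-class pairs
    over the sum of all pair weights (each pair's expected contact count is
    proportional to its weight under the activation model).
    """
    roster = build_roster(config.classes)
    w, _, _, same_class = _pair_weights(config, roster)
    total = w.sum()
    if total == 0:
        raise ConfigurationError("all mixing weights are zero")
    return float(w[same_class].sum() / total)


def _bounded_zipf_pmf(exponent: float, cap: int) -> np.ndarray:
    k = np.arange(1, cap + 1, dtype=float)
    p = k**-exponent
    return p / p.sum()


def _slot_weights(config: SchoolConfig, day: int) -> np.ndarray:
    """Activity multiplier per 20-s slot of the school day."""
    n_slots = (config.school_end - config.school_start) // RESOLUTION
    starts = config.school_start + np.arange(n_slots) * RESOLUTION
    w = np.ones(n_slots)
    for lo, hi, mult in config.activity_profile:
        w[(starts >= lo) & (starts < hi)] = mult
    if config.exam_day is not None and day == config.exam_day:
        w[starts >= 13 * 3600] *= config.exam_afternoon_multiplier
    return w / w.sum()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate(config: SchoolConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate a multi-day contact stream; identical (config, seed) inputs
    produce identical output."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roster = build_roster(config.classes)
    w, iu, ju, _ = _pair_weights(config, roster)
    total_w = w.sum()
    if total_w <= 0:
        raise ConfigurationError("total mixing weight is zero; nothing to generate")
    activation = np.clip(config.mean_active_pairs_per_day * w / total_w, 0.0, 0.95)

    ids = roster.index.to_numpy()
    n_slots = (config.school_end - config.school_start) // RESOLUTION
    dur_pmf = _bounded_zipf_pmf(config.duration_exponent, config.duration_cap_slots)
    gap_pmf = _bounded_zipf_pmf(config.intercontact_exponent, config.intercontact_cap_slots)
    extra_events = max(config.mean_events_per_pair - 1.0, 0.0)

    times: list[np.ndarray] = []
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    active = rng.random(w.size) < activation
    # static pair affinity: stable relationship intensity, mean 1, drives the
    # number of events of an active pair and hence day-to-day weight
    # correlation on persistent edges (durations themselves stay iid)
    sig = config.pair_affinity_sigma
    affinity = np.exp(rng.normal(-0.5 * sig**2, sig, size=w.size)) if sig > 0 else np.ones(w.size)
    _, _, _, same_class = _pair_weights(config, roster)
    # per-pair state-copy probability: with prob pi_p a pair keeps yesterday's
    # activity state, otherwise it is re-drawn at its stationary rate — exactly
    # stationary marginals, and memoryless across days when pi_p = 0
    pi_p = np.where(
        same_class,
        config.persistence,
        config.persistence * config.cross_class_persistence_factor,
    )
    for day in range(config.n_days):
        if day > 0:
            keep = rng.random(w.size) < pi_p
            redraw = rng.random(w.size) < activation
            active = np.where(keep, active, redraw)
        pair_idx = np.flatnonzero(active)
        if pair_idx.size == 0:
            continue
        slot_p = _slot_weights(config, day)
        n_events = 1 + rng.poisson(extra_events * affinity[pair_idx])
        day_base = day * DAY_SECONDS + config.school_start
        for p, m in zip(pair_idx, n_events):
            durs = 1 + rng.choice(config.duration_cap_slots, size=m, p=dur_pmf)
            start = int(rng.choice(n_slots, p=slot_p))
            for e in range(m):
                d = int(durs[e])
                if start >= n_slots:
                    break
                d = min(d, n_slots - start)
                slots = day_base + (start + np.arange(d)) * RESOLUTION
                times.append(slots)
                ii.append(np.repeat(iu[p], d))
                jj.append(np.repeat(ju[p], d))
                gap = 1 + int(rng.choice(config.intercontact_cap_slots, p=gap_pmf))
                start = start + d + 1 + gap
    if not times:
        stream = pd.DataFrame(columns=STREAM_COLUMNS)
    else:
        stream = pd.DataFrame(
            {
                "t": np.concatenate(times),
                "i": ids[np.concatenate(ii)],
                "j": ids[np.concatenate(jj)],
            }
        )
        stream = stream.sort_values(STREAM_COLUMNS, kind="mergesort").reset_index(drop=True)
    return SyntheticDataset(stream=stream, roster=roster, config=config)


def calibrate_cross_weight(
    config: SchoolConfig, target_intraclass: float = 0.915
) -> SchoolConfig:
    """Return a config whose cross-group weight is solved so that the implied
    intra-class contact share equals ``target_intraclass`` (w_same and
    w_group held fixed)."""
    roster = build_roster(config.classes)
    base = replace(config, gender_homophily=0.0)
    # tier masses (number of pairs in each mixing tier), via unit weights
    mass_same = _pair_weights(replace(base, w_same=1, w_group=0, w_cross=0), roster)[0].sum()
    mass_group = _pair_weights(replace(base, w_same=0, w_group=1, w_cross=0), roster)[0].sum()
    mass_cross = _pair_weights(replace(base, w_same=0, w_group=0, w_cross=1), roster)[0].sum()
    intra_mass = config.w_same * mass_same
    needed_off = intra_mass * (1.0 - target_intraclass) / target_intraclass
    w_cross = (needed_off - config.w_group * mass_group) / mass_cross
    if w_cross < 0:
        raise ConfigurationError(
            "w_group alone already exceeds the off-diagonal budget for this target"
        )
    return replace(config, w_cross=float(w_cross))
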