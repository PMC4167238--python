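"""Reading, validating and windowing 20-second-resolved contact streams.

The canonical exchange format is the SocioPatterns "tij" list: one row per
20-second window in which a pair of badges was in face-to-face proximity,
``t<TAB>i<TAB>j`` with ``t`` in seconds.  A *contact event* is a maximal run
of consecutive 20-s records for a pair; it is considered interrupted as soon
as the pair misses a 20-s window (gap between successive record times
> 20 s).  A single isolated record therefore counts as one contact of
duration 20 s, and the total event duration of a pair always equals
20 s x (number of its records).

Streams are plain pandas DataFrames with columns ``t`` (int seconds),
``i``, ``j`` (string node ids, canonically ordered ``i < j``), sorted by
``(t, i, j)``.  Rosters are DataFrames indexed by node id with columns
``class`` and ``gender`` (``"M"``/``"F"``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger("schoolcontacts")

RESOLUTION = 20  # seconds per proximity-detection window
DAY_SECONDS = 86400

STREAM_COLUMNS = ["t", "i", "j"]
EVENT_COLUMNS = ["i", "j", "start", "duration"]


class StreamParseError(ValueError):
    """A tij or roster file could not be parsed (reported with line number)."""


class StreamValidationError(ValueError):
    """A stream violates the 20-s grid, pair or uniqueness invariants."""


class ConfigurationError(ValueError):
    """Invalid run configuration (e.g. overlapping windows)."""


@dataclass(frozen=True)
class TimeWindow:
    """Half-open aggregation window ``[start, end)`` in study seconds."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError(
                f"window {self.label!r}: start {self.start} >= end {self.end}"
            )

    def contains(self, t: int) -> bool:
        return self.start <= t < self.end


# ---------------------------------------------------------------------------
# parsing and validation
# ---------------------------------------------------------------------------


def canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with each pair ordered lexicographically (i < j)."""
    out = df.copy()
    i = out["i"].astype(str)
    j = out["j"].astype(str)
    swap = i > j
    out["i"] = i.where(~swap, j)
    out["j"] = j.where(~swap, i)
    return out


def validate_stream(df: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize, sort and check invariants of a raw record table."""
    if list(df.columns) != STREAM_COLUMNS:
        df = df.rename(columns=dict(zip(df.columns, STREAM_COLUMNS)))
    if (df["t"] < 0).any():
        bad = int(df.loc[df["t"] < 0, "t"].iloc[0])
        raise StreamValidationError(f"negative timestamp {bad}")
    off_grid = df["t"] % RESOLUTION != 0
    if off_grid.any():
        bad = int(df.loc[off_grid, "t"].iloc[0])
        raise StreamValidationError(f"timestamp {bad} is not a multiple of {RESOLUTION}")
    df = canonical_pairs(df)
    if (df["i"] == df["j"]).any():
        node = df.loc[df["i"] == df["j"], "i"].iloc[0]
        raise StreamValidationError(f"self-contact record for node {node!r}")
    dup = df.duplicated(subset=STREAM_COLUMNS)
    if dup.any():
        t, i, j = df.loc[dup, STREAM_COLUMNS].iloc[0]
        raise StreamValidationError(f"duplicate record (t={t}, {i!r}, {j!r})")
    return df.sort_values(STREAM_COLUMNS, kind="mergesort").reset_index(drop=True)


def read_tij(path: str | Path) -> pd.DataFrame:
    """Read a (possibly gzipped) tab/space-separated ``t i j`` contact list."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    rows: list[tuple[int, str, str]] = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise StreamParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                t = int(parts[0])
            except ValueError as exc:
                raise StreamParseError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from exc
            rows.append((t, parts[1], parts[2]))
    df = pd.DataFrame(rows, columns=STREAM_COLUMNS)
    return validate_stream(df)


def write_tij(stream: pd.DataFrame, path: str | Path) -> None:
    stream.to_csv(path, sep="\t", header=False, index=False)


def read_roster(path: str | Path) -> pd.DataFrame:
    """Read a ``id class gender`` TSV into a roster indexed by node id."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["id", "class", "gender"], dtype=str)
    return validate_roster(df.set_index("id"))


def validate_roster(roster: pd.DataFrame) -> pd.DataFrame:
    bad = ~roster["gender"].isin(["M", "F"])
    if bad.any():
        raise StreamValidationError(
            f"node {roster.index[bad][0]!r}: gender must be 'M' or 'F'"
        )
    if roster.index.duplicated().any():
        raise StreamValidationError("duplicate node id in roster")
    return roster


def write_roster(roster: pd.DataFrame, path: str | Path) -> None:
    roster.reset_index().to_csv(path, sep="\t", header=False, index=False)


def check_roster_covers(stream: pd.DataFrame, roster: pd.DataFrame) -> None:
    ids = set(roster.index)
    seen = set(stream["i"]).union(stream["j"])
    missing = seen - ids
    if missing:
        raise StreamValidationError(f"stream nodes absent from roster: {sorted(missing)[:5]}")


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


def records_to_events(stream: pd.DataFrame) -> pd.DataFrame:
    """Merge consecutive records of a pair into contact events.

    Successive record times for a pair separated by more than 20 s terminate
    the event; the duration of an event spanning records ``t_first..t_last``
    is ``t_last - t_first + 20``.

    Returns a DataFrame ``(i, j, start, duration)`` sorted by (start, i, j).
    """
    if stream.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    df = stream.sort_values(["i", "j", "t"], kind="mergesort")
    same_pair = (df["i"] == df["i"].shift()) & (df["j"] == df["j"].shift())
    gap = df["t"].diff()
    new_event = ~(same_pair & (gap <= RESOLUTION))
    event_id = new_event.cumsum()
    grouped = df.groupby(event_id, sort=False)
    events = grouped.agg(
        i=("i", "first"), j=("j", "first"), start=("t", "first"), last=("t", "last")
    )
    events["duration"] = events["last"] - events["start"] + RESOLUTION
    events = events.drop(columns="last")
    return (
        events.sort_values(["start", "i", "j"], kind="mergesort").reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# windows and calendar
# ---------------------------------------------------------------------------


def check_windows(windows: Iterable[TimeWindow]) -> list[TimeWindow]:
    ws = sorted(windows, key=lambda w: w.start)
    for a, b in zip(ws, ws[1:]):
        if b.start < a.end:
            raise ConfigurationError(f"windows {a.label!r} and {b.label!r} overlap")
    return ws


def split_by_window(
    stream: pd.DataFrame, windows: Iterable[TimeWindow]
) -> dict[str, pd.DataFrame]:
    """Assign records to the unique window containing their timestamp.

    Records outside every window are dropped (count logged).  Because the
    assignment operates on 20-s records, a contact event spanning a boundary
    is split between the adjacent windows at slot granularity, keeping
    per-window duration totals additive.
    """
    ws = check_windows(windows)
    out: dict[str, pd.DataFrame] = {}
    assigned = pd.Series(False, index=stream.index)
    for w in ws:
        mask = (stream["t"] >= w.start) & (stream["t"] < w.end)
        out[w.label] = stream.loc[mask].reset_index(drop=True)
        assigned |= mask
    dropped = int((~assigned).sum())
    if dropped:
        logger.info("split_by_window: dropped %d records outside all windows", dropped)
    return out


def day_windows(n_days: int, day_seconds: int = DAY_SECONDS) -> list[TimeWindow]:
    """One window per study day: ``[d*day_seconds, (d+1)*day_seconds)``."""
    return [
        TimeWindow(f"day{d + 1}", d * day_seconds, (d + 1) * day_seconds)
        for d in range(n_days)
    ]


def halfday_windows(
    n_days: int, cut_hour: float = 13.0, day_seconds: int = DAY_SECONDS
) -> list[TimeWindow]:
    """Morning/afternoon windows per day, split at ``cut_hour`` (default 1 PM)."""
    cut = int(cut_hour * 3600)
    out = []
    for d in range(n_days):
        base = d * day_seconds
        out.append(TimeWindow(f"day{d + 1}_am", base, base + cut))
        out.append(TimeWindow(f"day{d + 1}_pm", base + cut, base + day_seconds))
    return out


# ---------------------------------------------------------------------------
# writers for computed artifacts
# ---------------------------------------------------------------------------


def write_edge_list(network, path: str | Path) -> None:
    """Write an aggregated network as an ``i j weight count`` TSV."""
    rows = [
        (i, j, int(d["weight"]), int(d["count"]))
        for i, j, d in network.graph.edges(data=True)
    ]
    rows.sort()
    pd.DataFrame(rows, columns=["i", "j", "weight", "count"]).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_csv(matrix, path: str | Path) -> None:
    """Write a contact matrix as labeled CSV (group labels as header row/col)."""
    matrix.data.to_csv(path)


def read_matrix_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_graphml(network, path: str | Path) -> None:
    nx.write_graphml(network.graph, path)
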