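"""Published summary statistics of the two school deployments.

These constants describe the composition of the participating classes and the
headline counts of the aggregated contact networks, as released with the
deployments.  They parameterize the synthetic generator defaults and the
matched null-model ensembles; the raw contact streams themselves are not
bundled here.

Class composition tuples are ``(class_name, n_male, n_female)``.
"""

from __future__ import annotations

# 2012 collection: five second-year classes, 7 school days.
CLASSES_2012: tuple[tuple[str, int, int], ...] = (
    ("MP*1", 27, 4),
    ("MP*2", 27, 8),
    ("PC", 24, 14),
    ("PC*", 26, 9),
    ("PSI*", 29, 12),
)

# 2011 collection: three classes, 4 school days.
CLASSES_2011: tuple[tuple[str, int, int], ...] = (
    ("PC", 16, 15),
    ("PC*", 32, 13),
    ("PSI*", 32, 10),
)

# The two-group substructure of the 2012 classes (shared topics / adjacent
# classrooms): more contacts occur between classes of the same group.
CLASS_GROUPS_2012: tuple[tuple[str, ...], ...] = (
    ("MP*1", "MP*2"),
    ("PC", "PC*", "PSI*"),
)

# Aggregated-network headline numbers (whole-study aggregation).
NETWORK_2012 = {"nodes": 180, "edges": 2220, "contacts": 19774, "duration_s": 900940}
NETWORK_2011 = {"nodes": 126, "edges": 1710, "contacts": 10432, "duration_s": 561010}

# Number of intra-class contact events in the 2012 collection.
INTRACLASS_CONTACTS_2012 = 18101

# Per-day contact counts and cumulative durations (seconds), 2012 collection,
# in chronological order (Mon, Tue, Wed, Thu, Fri, Mon, Tue).
DAILY_CONTACTS_2012: tuple[int, ...] = (4191, 3170, 1547, 2641, 3184, 2988, 2053)
DAILY_DURATION_S_2012: tuple[int, ...] = (
    199140,
    132720,
    64540,
    106920,
    154360,
    156360,
    93540,
)


def class_sizes(classes: tuple[tuple[str, int, int], ...]) -> dict[str, int]:
    """Total size of each class (males + females)."""
    return {name: m + f for name, m, f in classes}


def gender_totals(classes: tuple[tuple[str, int, int], ...]) -> tuple[int, int]:
    """Return ``(n_male, n_female)`` summed over classes."""
    return sum(m for _, m, _ in classes), sum(f for _, _, f in classes)
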