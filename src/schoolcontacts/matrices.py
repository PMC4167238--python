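"""Class x class contact matrices and the matrix cosine similarity.

Six normalization modes describe the mixing between groups X, Y over a
window:

====  ======================================================================
mode  entry at (X, Y)
====  ======================================================================
T     total contact seconds between members of X and members of Y
N     total number of contact events between X and Y
E     number of pairs (one in X, one in Y) in contact at least once
rho   E normalized by its maximum (n_X n_Y off-diagonal, n_X(n_X-1)/2 on it)
tau   average contact seconds of an individual of X with members of Y
nbar  average number of contacts of an individual of X with members of Y
====  ======================================================================

T, N and E are symmetric; tau and nbar are per-capita (divide row X by n_X)
and hence generally asymmetric.  A contact between two members of the same
class X counts once in T_XX/N_XX/E_XX but contributes to *both* members'
personal tallies, so tau_XX = 2 T_XX / n_X (and likewise nbar_XX).
The optional ``n_days`` divisor yields average-daily per-capita matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .network import AggregatedNetwork

Mode = Literal["T", "N", "E", "rho", "tau", "nbar"]
MODES: tuple[str, ...] = ("T", "N", "E", "rho", "tau", "nbar")

SYMMETRIC_MODES = {"T", "N", "E", "rho"}


class MatrixError(ValueError):
    pass


@dataclass
class ContactMatrix:
    """Group x group mixing matrix with labeled pandas storage."""

    data: pd.DataFrame
    mode: str
    group_sizes: dict[str, int]
    window_label: str | None = None
    n_days: float | None = None

    @property
    def labels(self) -> list[str]:
        return list(self.data.index)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(float)

    def restrict(self, labels: Sequence[str]) -> "ContactMatrix":
        """Submatrix over a subset of group labels (e.g. shared classes)."""
        labels = list(labels)
        missing = set(labels) - set(self.labels)
        if missing:
            raise MatrixError(f"unknown group labels {sorted(missing)}")
        return ContactMatrix(
            data=self.data.loc[labels, labels].copy(),
            mode=self.mode,
            group_sizes={g: self.group_sizes[g] for g in labels},
            window_label=self.window_label,
            n_days=self.n_days,
        )


def pair_capacity(n_x: int, n_y: int, same_group: bool) -> int:
    """Maximum possible number of edges between two groups."""
    return n_x * (n_x - 1) // 2 if same_group else n_x * n_y


def _group_totals(
    network: AggregatedNetwork, node_group: pd.Series, labels: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    idx = {g: k for k, g in enumerate(labels)}
    m = len(labels)
    T = np.zeros((m, m))
    N = np.zeros((m, m))
    E = np.zeros((m, m))
    for i, j, d in network.graph.edges(data=True):
        try:
            gi, gj = node_group[i], node_group[j]
        except KeyError as exc:
            raise MatrixError(f"node {exc.args[0]!r} has no group label") from exc
        a, b = idx[gi], idx[gj]
        T[a, b] += d["weight"]
        N[a, b] += d["count"]
        E[a, b] += 1
        if a != b:
            T[b, a] += d["weight"]
            N[b, a] += d["count"]
            E[b, a] += 1
    wrap = lambda arr: pd.DataFrame(arr, index=labels, columns=labels)
    return wrap(T), wrap(N), wrap(E)


def _build(
    network: AggregatedNetwork,
    node_group: pd.Series,
    sizes: dict[str, int],
    mode: str,
    window_label: str | None,
    n_days: float | None,
) -> ContactMatrix:
    if mode not in MODES:
        raise MatrixError(f"unknown mode {mode!r}; expected one of {MODES}")
    labels = list(sizes)
    T, N, E = _group_totals(network, node_group, labels)
    if mode == "T":
        data = T
    elif mode == "N":
        data = N
    elif mode == "E":
        data = E
    elif mode == "rho":
        cap = pd.DataFrame(
            [
                [pair_capacity(sizes[x], sizes[y], x == y) for y in labels]
                for x in labels
            ],
            index=labels,
            columns=labels,
            dtype=float,
        )
        data = E / cap.where(cap > 0)  # capacity 0 (group of size <= 1) -> NaN
    else:  # per-capita tau / nbar
        base = T if mode == "tau" else N
        data = base.copy().astype(float)
        for x in labels:
            data.loc[x, x] *= 2.0
            data.loc[x] /= sizes[x] if sizes[x] else np.nan
        if n_days:
            data /= n_days
    return ContactMatrix(
        data=data,
        mode=mode,
        group_sizes=sizes,
        window_label=window_label,
        n_days=n_days,
    )


def contact_matrix(
    network: AggregatedNetwork, mode: Mode, n_days: float | None = None
) -> ContactMatrix:
    """Class x class matrix in one of the six modes (see module docstring)."""
    roster = network.roster
    sizes = roster["class"].value_counts().sort_index().to_dict()
    label = network.window.label if network.window else None
    return _build(network, roster["class"], sizes, mode, label, n_days)


def gender_block_matrix(
    network: AggregatedNetwork, mode: Mode, n_days: float | None = None
) -> ContactMatrix:
    """(class, gender) x (class, gender) matrix — 2C groups like ``PC/F``.

    Groups of size 0 have no rows of their own; diagonal density of a
    size-1 group is undefined (capacity 0) and reported as NaN.
    """
    roster = network.roster
    groups = roster["class"].str.cat(roster["gender"], sep="/")
    sizes = groups.value_counts().sort_index().to_dict()
    label = network.window.label if network.window else None
    return _build(network, groups, sizes, mode, label, n_days)


def matrix_similarity(
    a: ContactMatrix | pd.DataFrame | np.ndarray,
    b: ContactMatrix | pd.DataFrame | np.ndarray,
    scope: Literal["all", "offdiag"] = "all",
) -> float:
    """Cosine similarity between two mixing matrices.

    Equals 1 iff the in-scope entries are proportional, 0 iff their supports
    are disjoint.  ``scope="offdiag"`` restricts to off-diagonal entries, the
    robustness variant that discounts the dominant diagonal.
    """
    va = _entry_vector(a, scope)
    vb = _entry_vector(b, scope)
    if va.shape != vb.shape:
        raise MatrixError(f"shape mismatch {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise MatrixError("all-zero matrix in similarity scope")
    return float(np.dot(va, vb) / (na * nb))


def _entry_vector(m, scope: str) -> np.ndarray:
    if isinstance(m, ContactMatrix):
        arr = m.values()
    else:
        arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise MatrixError(f"expected a square matrix, got shape {arr.shape}")
    arr = np.nan_to_num(arr)
    if scope == "offdiag":
        mask = ~np.eye(arr.shape[0], dtype=bool)
        return arr[mask]
    if scope != "all":
        raise MatrixError(f"unknown scope {scope!r}")
    return arr.ravel()
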