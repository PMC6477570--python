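"""Self-report normalization and binary stress labeling strategies.

Perceived-stress self-reports on a 10-cm visual analog scale (VAS) vary
strongly between people, so scores are first min-max normalized per
participant, then pooled and clustered with an *exact* 1-D k-means (dynamic
programming over contiguous partitions of the sorted values — deterministic,
no random initialization, globally optimal within-cluster SSE).  Four
strategies map clusters to binary Stress / No-Stress labels:

* L1 — k=3; lowest cluster is No-Stress, the upper two are Stress.
* L2 — k=3; the two lowest clusters are No-Stress.
* L3 — k=2; lower cluster is No-Stress.
* L4 — raw VAS threshold at 10/3 cm (the border between the lowest and the
  middle of three equal sections of the scale); no normalization.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "KMeans1DResult",
    "normalize_scores",
    "kmeans_1d",
    "assign_labels",
    "L4_THRESHOLD",
    "STRATEGIES",
]

#: L4 decision boundary: the 10-cm VAS divided into three equal sections.
L4_THRESHOLD = 10.0 / 3.0

STRATEGIES = ("L1", "L2", "L3", "L4")

NO_STRESS, STRESS = "NoStress", "Stress"


def _check_table(table: pd.DataFrame) -> None:
    required = {"participant_id", "session_id", "vas"}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"score table needs columns {sorted(required)}")
    vas = table["vas"].to_numpy(dtype=float)
    if np.any(vas < 0) or np.any(vas > 10):
        raise InvalidInputError("VAS scores must lie in [0, 10]")
    counts = table.groupby("participant_id").size()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise InvalidInputError(
            f"participants with fewer than 2 sessions: {bad}"
        )


def normalize_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each participant's VAS scores to [0, 1].

    Adds a ``normalized`` column; raises if any participant's scores have
    zero range (their min and max coincide, leaving the scale undefined).
    """
    _check_table(table)
    out = table.copy()
    normalized = np.empty(len(out), dtype=float)
    for pid, group in out.groupby("participant_id"):
        vas = group["vas"].to_numpy(dtype=float)
        lo, hi = vas.min(), vas.max()
        if hi - lo <= 0:
            raise InvalidInputError(
                f"participant {pid!r} has zero score range; cannot normalize"
            )
        normalized[out.index.get_indexer(group.index)] = (vas - lo) / (hi - lo)
    out["normalized"] = normalized
    return out


@dataclass(frozen=True)
class KMeans1DResult:
    """Exact 1-D k-means partition; clusters indexed by ascending centroid."""

    assignment: np.ndarray  # cluster index per input value, in input order
    centroids: np.ndarray   # ascending
    sse: float


def kmeans_1d(values, k: int) -> KMeans1DResult:
    """Globally optimal 1-D k-means by dynamic programming.

    The optimal partition of scalars is contiguous in sorted order, so the
    exact solution is a choice of k-1 breakpoints minimizing within-cluster
    SSE; found here by O(k n^2) DP with prefix sums.  Deterministic — no
    random initialization, no seed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise InvalidInputError("values must be a non-empty 1-D sequence")
    if k < 2:
        raise InvalidInputError("k must be at least 2")
    if len(np.unique(x)) < k:
        raise InvalidInputError(
            f"need at least {k} distinct values, got {len(np.unique(x))}"
        )
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = len(xs)
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs**2)))

    def seg_cost(i: int, j: int) -> float:
        # SSE of xs[i:j]
        m = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / m

    inf = float("inf")
    cost = np.full((k + 1, n + 1), inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = inf, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + seg_cost(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j], back[c, j] = best, arg
    # recover breakpoints
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = back[c, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centroids = np.empty(k)
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        labels_sorted[i:j] = c
        centroids[c] = xs[i:j].mean()
    assignment = np.empty(n, dtype=int)
    assignment[order] = labels_sorted
    return KMeans1DResult(assignment, centroids, float(cost[k, n]))


def assign_labels(table: pd.DataFrame, strategy: str) -> pd.DataFrame:
    """Binary Stress / No-Stress labels under strategy L1-L4.

    Returns a copy of the table with ``normalized`` (NaN for L4, which uses
    raw scores), ``cluster`` (-1 for L4) and ``label`` columns.
    """
    if strategy not in STRATEGIES:
        raise InvalidInputError(f"unknown strategy {strategy!r}; use L1-L4")
    _check_table(table)
    if strategy == "L4":
        out = table.copy()
        out["normalized"] = np.nan
        out["cluster"] = -1
        vas = out["vas"].to_numpy(dtype=float)
        out["label"] = np.where(vas < L4_THRESHOLD, NO_STRESS, STRESS)
        out["strategy"] = strategy
        return out
    out = normalize_scores(table)
    k = 2 if strategy == "L3" else 3
    result = kmeans_1d(out["normalized"].to_numpy(), k)
    out["cluster"] = result.assignment
    if strategy == "L1":
        stress = result.assignment >= 1
    elif strategy == "L2":
        stress = result.assignment >= 2
    else:  # L3
        stress = result.assignment >= 1
    out["label"] = np.where(stress, STRESS, NO_STRESS)
    out["strategy"] = strategy
    return out
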