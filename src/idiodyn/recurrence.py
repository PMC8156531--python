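"""Multidimensional recurrence quantification and the recurrence network.

Each measurement occasion is treated as a point in V-dimensional profile
space (no delay embedding: the observed items *are* the state vector).  Two
occasions recur when their profiles lie within radius epsilon of each other;
the resulting T x T recurrence matrix supports classical RQA measures (RR,
DET, LAM), and doubles as a weighted undirected network over occasions whose
hubs define the person's recurrent "profiles".

The radius is calibrated to a target recurrence rate (standard RQA practice
when no physical radius is known), and a Theiler band around the main
diagonal excludes trivial self-matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import LongitudinalSeries

logger = logging.getLogger("idiodyn")

__all__ = [
    "RecurrenceStructure",
    "RQAMeasures",
    "StateLabeling",
    "RadiusResult",
    "profile_series",
    "distance_matrix",
    "radius_for_rate",
    "recurrence_structure",
    "rqa_measures",
    "build_network",
    "strength_centrality",
    "categorize_profiles",
    "profile_summary",
    "UNCATEGORISED",
    "UNIQUE",
]

UNCATEGORISED = "uncategorised"
UNIQUE = "unique"


@dataclass
class RecurrenceStructure:
    """Distance matrix, radius, recurrence matrix and edge similarities.

    ``weights[i, j] = 1 - dist[i, j] / radius`` where recurrent, else 0
    ("number of connections weighted by the similarity of the connected
    nodes"); an exponential similarity ``exp(-d / eps)`` is selectable.
    Entries inside the Theiler band ``|i - j| <= theiler`` are never
    recurrent.
    """

    dist: np.ndarray
    radius: float
    rec: np.ndarray
    weights: np.ndarray
    theiler: int

    @property
    def n_occasions(self) -> int:
        return self.dist.shape[0]

    def eligible_mask(self) -> np.ndarray:
        T = self.n_occasions
        off = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
        return off > self.theiler


@dataclass
class RQAMeasures:
    recurrence_rate: float
    determinism: float        # NaN when no recurrent points
    laminarity: float         # NaN when no recurrent points
    mean_line: float          # mean diagonal line length (>= l_min); NaN if none
    l_min: int = 2


@dataclass
class StateLabeling:
    """Per-occasion categorical profile labels.

    ``labels[i]`` is one of ``class_1..class_k`` (hub classes in decreasing
    hub strength), ``uncategorised`` (recurs but joins no hub class) or
    ``unique`` (no recurrence-network neighbours at all).  ``occasions``
    maps label positions back to occasion indices of the original series
    when incomplete occasions were excluded upstream.
    """

    labels: list[str]
    hub_ids: list[int]
    strengths: np.ndarray
    occasions: np.ndarray | None = None

    @property
    def categories(self) -> list[str]:
        cats = [f"class_{m + 1}" for m in range(len(self.hub_ids))]
        return cats + [UNCATEGORISED, UNIQUE]


class RadiusResult(NamedTuple):
    epsilon: float
    achieved_rr: float
    n_eligible: int


# ---------------------------------------------------------------------------


def profile_series(
    series: LongitudinalSeries,
    mode: str = "raw",
    standardise: str = "none",
) -> tuple[np.ndarray, np.ndarray]:
    """Occasion-by-variable profile matrix for distance computation.

    Occasions with any masked variable are excluded (the exclusion count is
    logged; no imputation).  ``mode='first_difference'`` analyses change
    profiles between consecutive retained occasions instead of raw scores —
    useful when scale usage drifts.  Returns ``(profiles, occasion_indices)``.
    """
    if mode not in ("raw", "first_difference"):
        raise ValueError("mode must be 'raw' or 'first_difference'")
    if standardise not in ("none", "per_variable"):
        raise ValueError("standardise must be 'none' or 'per_variable'")
    keep = series.complete_occasions
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("profile_series: excluded %d incomplete occasions", n_dropped)
    idx = np.flatnonzero(keep)
    X = series.values[idx]
    if mode == "first_difference":
        X = np.diff(X, axis=0)
        idx = idx[1:]
    if X.shape[0] < 1:
        raise ValueError("no complete profiles")
    if standardise == "per_variable":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.argmax(sd == 0))
            raise ValueError(
                f"variable index {j} is constant; cannot z-standardise"
            )
        X = (X - X.mean(axis=0)) / sd
    return X, idx


def distance_matrix(profiles: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Symmetric pairwise profile distances with zero diagonal."""
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    name = {"euclidean": "euclidean", "manhattan": "cityblock",
            "chebyshev": "chebyshev"}.get(metric)
    if name is None:
        raise ValueError(f"unknown metric {metric!r}")
    return squareform(pdist(X, metric=name))


def _eligible_upper(dist: np.ndarray, theiler: int) -> np.ndarray:
    T = dist.shape[0]
    i, j = np.triu_indices(T, k=theiler + 1)
    return dist[i, j]


def radius_for_rate(dist: np.ndarray, target_rr: float, theiler: int = 1) -> RadiusResult:
    """Smallest radius whose achieved recurrence rate reaches ``target_rr``.

    Epsilon is the ceil(target * n)-th smallest eligible (outside the
    Theiler band) pairwise distance, so with distinct distances
    ``|achieved - target| <= 1/n_eligible``.
    """
    if not (0.0 < target_rr < 1.0):
        raise ValueError("target_rr must lie strictly between 0 and 1")
    d = np.sort(_eligible_upper(dist, theiler))
    if d.size == 0:
        raise ValueError("Theiler window leaves no eligible pairs")
    if d[-1] - d[0] <= 1e-12 * max(d[-1], 1.0):
        raise ValueError(
            "all eligible distances are identical; choose the radius manually"
        )
    m = int(np.ceil(target_rr * d.size))
    eps = float(d[max(m, 1) - 1])
    achieved = float(np.mean(d <= eps))
    logger.info("radius_for_rate: eps=%.6g achieved RR=%.4f (target %.4f)",
                eps, achieved, target_rr)
    return RadiusResult(epsilon=eps, achieved_rr=achieved, n_eligible=int(d.size))


def recurrence_structure(
    dist: np.ndarray,
    epsilon: float,
    theiler: int = 1,
    weight_kind: str = "linear",
) -> RecurrenceStructure:
    """Threshold distances at ``epsilon`` into a recurrence matrix + weights."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    T = dist.shape[0]
    if theiler >= T:
        raise ValueError(f"theiler ({theiler}) must be smaller than T ({T})")
    off = np.abs(np.subtract.outer(np.arange(T), np.arange(T)))
    rec = (dist <= epsilon) & (off > theiler)
    if weight_kind == "linear":
        w = 1.0 - dist / epsilon
    elif weight_kind == "exponential":
        w = np.exp(-dist / epsilon)
    else:
        raise ValueError("weight_kind must be 'linear' or 'exponential'")
    weights = np.where(rec, np.clip(w, 0.0, 1.0), 0.0)
    return RecurrenceStructure(dist=dist, radius=float(epsilon), rec=rec,
                               weights=weights, theiler=theiler)


def _diagonal_line_lengths(rec: np.ndarray, theiler: int) -> np.ndarray:
    """Lengths of all diagonal runs of recurrent points (upper triangle)."""
    T = rec.shape[0]
    lengths = []
    for off in range(theiler + 1, T):
        diag = np.diagonal(rec, offset=off)
        if not diag.any():
            continue
        padded = np.concatenate(([0], diag.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        lengths.extend((edges[1::2] - edges[0::2]).tolist())
    return np.asarray(lengths, dtype=int)


def _vertical_line_lengths(rec: np.ndarray) -> np.ndarray:
    """Lengths of vertical runs per column (Theiler band already zeroed)."""
    lengths = []
    for col in rec.T:
        if not col.any():
            continue
        padded = np.concatenate(([0], col.view(np.int8), [0]))
        edges = np.flatnonzero(np.diff(padded))
        lengths.extend((edges[1::2] - edges[0::2]).tolist())
    return np.asarray(lengths, dtype=int)


def rqa_measures(rs: RecurrenceStructure, l_min: int = 2) -> RQAMeasures:
    """RR plus line-based measures from the classical RQA definitions.

    RR is the fraction of eligible pairs that recur.  DET is the fraction of
    recurrent points lying on diagonal lines of length >= ``l_min`` (counted
    in the upper triangle; the matrix is symmetric), LAM the analogue for
    vertical lines over the full matrix.  DET/LAM/mean_line are NaN when
    there are no recurrent points.
    """
    elig = rs.eligible_mask()
    n_elig = int(elig.sum())
    n_rec = int(rs.rec[elig].sum())
    rr = n_rec / n_elig if n_elig else np.nan
    if n_rec == 0:
        return RQAMeasures(rr, np.nan, np.nan, np.nan, l_min)

    dlines = _diagonal_line_lengths(rs.rec, rs.theiler)
    long_d = dlines[dlines >= l_min]
    det = float(long_d.sum() / dlines.sum()) if dlines.size else np.nan
    mean_line = float(long_d.mean()) if long_d.size else np.nan

    vlines = _vertical_line_lengths(rs.rec)
    long_v = vlines[vlines >= l_min]
    lam = float(long_v.sum() / vlines.sum()) if vlines.size else np.nan
    return RQAMeasures(float(rr), det, lam, mean_line, l_min)


# ---------------------------------------------------------------------------
# Network view and profile categorisation
# ---------------------------------------------------------------------------


def build_network(rs: RecurrenceStructure) -> nx.Graph:
    """Weighted undirected recurrence network over measurement occasions."""
    G = nx.Graph()
    T = rs.n_occasions
    G.add_nodes_from(range(T))
    ii, jj = np.nonzero(np.triu(rs.rec, k=1))
    G.add_weighted_edges_from(
        (int(i), int(j), float(rs.weights[i, j])) for i, j in zip(ii, jj)
    )
    strengths = rs.weights.sum(axis=1)
    nx.set_node_attributes(G, {i: float(strengths[i]) for i in range(T)}, "strength")
    return G


def strength_centrality(graph: nx.Graph) -> dict[int, float]:
    """Per-node strength: sum of incident edge weights (0 for isolates)."""
    return {n: float(s) for n, s in graph.degree(weight="weight")}


def _adjacency_from_graph(graph: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    nodes = sorted(graph.nodes())
    if nodes != list(range(len(nodes))):
        raise ValueError("graph nodes must be occasion indices 0..T-1")
    W = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return W > 0, W


def categorize_profiles(
    graph: nx.Graph | RecurrenceStructure,
    k: int = 4,
) -> StateLabeling:
    """Hub-based categorisation of occasions into recurrent profile classes.

    Algorithm: (1) the strongest node (strength centrality, ties broken by
    earlier occasion) is hub 1; it and its neighbours form class 1.
    (2) Hub m is the strongest yet-unlabelled node *not adjacent to any
    earlier hub*; class m adds its unlabelled neighbours.  Earlier classes
    take precedence.  (3) Remaining nodes with at least one neighbour are
    ``uncategorised`` (they recur, but outside the main attractors); isolated
    nodes are ``unique`` — configurations observed only once.

    If fewer than ``k`` mutually non-adjacent hubs exist, fewer classes are
    returned (logged).
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if isinstance(graph, RecurrenceStructure):
        adj, W = graph.rec, graph.weights
    else:
        adj, W = _adjacency_from_graph(graph)
    T = adj.shape[0]
    strengths = W.sum(axis=1)
    degree = adj.sum(axis=1)
    # order: strength descending, then earlier occasion index
    order = np.lexsort((np.arange(T), -strengths))
    labels = np.full(T, "", dtype=object)
    hub_ids: list[int] = []
    hub_blocked = np.zeros(T, dtype=bool)   # adjacent to some earlier hub
    for m in range(k):
        hub = next(
            (int(i) for i in order
             if labels[i] == "" and not hub_blocked[i] and degree[i] > 0),
            None,
        )
        if hub is None:
            logger.info("categorize_profiles: only %d hub classes available "
                        "(%d requested)", m, k)
            break
        name = f"class_{m + 1}"
        hub_ids.append(hub)
        members = np.flatnonzero(adj[hub])
        labels[hub] = name
        for i in members:
            if labels[i] == "":
                labels[i] = name
        hub_blocked |= adj[hub]
    for i in range(T):
        if labels[i] == "":
            labels[i] = UNCATEGORISED if degree[i] > 0 else UNIQUE
    return StateLabeling(labels=list(labels), hub_ids=hub_ids, strengths=strengths)


def profile_summary(
    profiles: np.ndarray,
    labeling: StateLabeling,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-class mean profile and occupancy fraction.

    ``profiles`` must be the same matrix the labelling was computed from
    (one row per labelled occasion).
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] != len(labeling.labels):
        raise ValueError("profiles and labels are misaligned")
    variables = variables or [f"v{j + 1}" for j in range(X.shape[1])]
    rows = []
    labs = np.asarray(labeling.labels, dtype=object)
    for cat in labeling.categories:
        sel = labs == cat
        if not sel.any():
            continue
        row = {"class": cat, "occupancy": float(sel.mean())}
        row.update(dict(zip(variables, X[sel].mean(axis=0))))
        rows.append(row)
    return pd.DataFrame(rows)
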