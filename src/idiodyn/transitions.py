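"""State-transition matrix and network from a categorical labelling.

Columns are the source ("from") state and rows the destination, so
``counts[r, c]`` counts occasions in category ``c`` followed by category
``r`` and each non-empty percent column sums to 100.  A zero cell means the
transition never appeared during data collection, not that it is
impossible.  Flow asymmetry between states is itself a nonlinearity
indicator: a linear-stochastic system produces roughly symmetric flows.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "TransitionModel",
    "transition_counts",
    "transition_percents",
    "asymmetry_index",
    "export_transition_network",
]


@dataclass
class TransitionModel:
    categories: list[str]
    counts: np.ndarray          # counts[dest, source]
    n_transitions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.categories,
                            columns=self.categories)


def transition_counts(
    labels,
    categories: list[str] | None = None,
    occasions=None,
) -> TransitionModel:
    """Count consecutive-pair transitions in a label sequence.

    If ``occasions`` (original occasion indices) is given, only pairs of
    *temporally adjacent* occasions are counted, so gaps left by excluded
    incomplete occasions never produce spurious transitions.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labelled occasions")
    if categories is None:
        categories = list(dict.fromkeys(labels))
    index = {c: i for i, c in enumerate(categories)}
    unknown = set(labels) - set(index)
    if unknown:
        raise ValueError(f"labels contain unknown categories: {sorted(unknown)}")
    C = len(categories)
    counts = np.zeros((C, C), dtype=int)
    n = 0
    for t in range(len(labels) - 1):
        if occasions is not None and occasions[t + 1] - occasions[t] != 1:
            continue
        counts[index[labels[t + 1]], index[labels[t]]] += 1
        n += 1
    return TransitionModel(categories=list(categories), counts=counts,
                           n_transitions=n)


def transition_percents(model: TransitionModel) -> np.ndarray:
    """Column-normalised percentages; empty source columns become NaN.

    Percentages are carried at full precision — any rounding ("columns may
    not sum to 100") happens only at report time.
    """
    totals = model.counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * model.counts / totals, np.nan)
    return pct


def asymmetry_index(model: TransitionModel) -> float:
    """Normalised asymmetry of off-diagonal flows, in [0, 1].

    ``sum |C - C^T| / (2 * sum off-diagonal counts)``: 0 for perfectly
    reciprocated flows (consistent with linear dynamics), 1 when every flow
    is one-way.  NaN when there are no off-diagonal transitions.
    """
    C = model.counts.astype(float)
    off = C.sum() - np.trace(C)
    if off == 0:
        return float("nan")
    return float(np.abs(C - C.T).sum() / (2.0 * off))


def export_transition_network(
    model: TransitionModel,
    path=None,
    edgelist_path=None,
) -> nx.DiGraph:
    """Directed transition network; edge weight = percent, self-loops kept.

    Zero-count transitions are omitted.  Optionally writes GraphML and/or an
    edge-list CSV (source,target,percent,count).
    """
    pct = transition_percents(model)
    G = nx.DiGraph()
    G.add_nodes_from(model.categories)
    rows = []
    for c, src in enumerate(model.categories):
        for r, dst in enumerate(model.categories):
            if model.counts[r, c] > 0:
                G.add_edge(src, dst, weight=float(pct[r, c]),
                           count=int(model.counts[r, c]))
                rows.append((src, dst, float(pct[r, c]), int(model.counts[r, c])))
    if path is not None:
        nx.write_graphml(G, path)
    if edgelist_path is not None:
        pd.DataFrame(rows, columns=["source", "target", "percent", "count"]).to_csv(
            edgelist_path, index=False
        )
    return G
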