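"""Label co-occurrence graph and label-correlation statistics.

Two labels are joined by an edge when at least one sample carries both;
the edge weight counts such samples.  Pairwise association between labels
is measured with the bias-corrected Cramér's V statistic, the
small-sample correction that shrinks the classical V toward zero
(chi-square is the Pearson statistic without continuity correction).
"""

from __future__ import annotations

import os
import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .datasets import MultiLabelDataset


@dataclass
class LabelGraph:
    """Weighted undirected graph on labels.

    ``labels`` keeps the vertex order of the source dataset (isolated
    labels included); ``graph`` is the underlying :class:`networkx.Graph`
    whose edges carry an integer ``weight`` attribute >= 1.
    """

    labels: tuple[str, ...]
    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        missing = [l for l in self.labels if l not in self.graph]
        if missing:
            raise ValueError(f"vertices missing from graph: {missing}")

    @property
    def n_vertices(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, li: str, lj: str) -> int:
        """Edge weight w(li, lj); 0 when the labels never co-occur."""
        data = self.graph.get_edge_data(li, lj)
        return 0 if data is None else data["weight"]

    def edges(self) -> list[tuple[str, str, int]]:
        order = {l: i for i, l in enumerate(self.labels)}
        out = []
        for u, v, w in self.graph.edges(data="weight"):
            if order[u] > order[v]:
                u, v = v, u
            out.append((u, v, w))
        return sorted(out, key=lambda e: (order[e[0]], order[e[1]]))

    def to_edgelist_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            self.edges(), columns=["label_i", "label_j", "weight"]
        ).to_csv(path, sep="\t", index=False)

    def to_graphml(self, path: str | os.PathLike) -> None:
        nx.write_graphml(self.graph, path)


def build_graph(labels, weighted_edges) -> LabelGraph:
    """Assemble a LabelGraph from a vertex order and (u, v, w) triples."""
    g = nx.Graph()
    g.add_nodes_from(labels)
    for u, v, w in weighted_edges:
        if u == v:
            raise ValueError(f"self-loop on {u!r}")
        g.add_edge(u, v, weight=w)
    return LabelGraph(labels=tuple(labels), graph=g)


def build_cooccurrence_graph(
    dataset: MultiLabelDataset, weighted: bool = True
) -> LabelGraph:
    """Build the label co-occurrence graph from a dataset's label matrix.

    An edge {li, lj} exists iff >= 1 sample carries both labels; when
    ``weighted``, its weight is the number of such samples, otherwise 1.
    """
    Y = dataset.labels.astype(np.int64)
    co = Y.T @ Y  # co[i, j] = number of samples with both labels
    names = dataset.label_names
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if co[i, j] >= 1:
                edges.append((names[i], names[j], int(co[i, j]) if weighted else 1))
    return build_graph(names, edges)


def cramers_v_corrected(table) -> float:
    """Bias-corrected Cramér's V of an r x c contingency table.

    Computes phi2 = chi2/n (Pearson chi-square, no continuity
    correction), subtracts the (r-1)(c-1)/(n-1) bias term (floored at 0),
    shrinks the margins to r~ and c~, and returns
    sqrt(phi2~ / min(r~ - 1, c~ - 1)).

    Degenerate inputs: a zero row/column margin makes chi-square
    undefined and yields 0.0 with a warning (association with a constant
    is undefined; 0 is the conservative report), as does min(r~-1, c~-1)
    <= 0.  n < 2 raises, since the correction divides by n - 1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    n = t.sum()
    if n < 2:
        raise ValueError(f"need n >= 2 observations, got n={n:g}")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        warnings.warn(
            "zero margin in contingency table; Cramér's V reported as 0",
            stacklevel=2,
        )
        return 0.0
    r, c = t.shape
    chi2 = chi2_contingency(t, correction=False).statistic
    phi2 = chi2 / n
    phi2_tilde = max(0.0, phi2 - (r - 1) * (c - 1) / (n - 1))
    r_tilde = r - (r - 1) ** 2 / (n - 1)
    c_tilde = c - (c - 1) ** 2 / (n - 1)
    m_tilde = min(r_tilde - 1, c_tilde - 1)
    if m_tilde <= 0:
        warnings.warn(
            "degenerate corrected dimension (m~ <= 0); Cramér's V reported as 0",
            stacklevel=2,
        )
        return 0.0
    return float(min(1.0, np.sqrt(phi2_tilde / m_tilde)))


def _pair_table(yi: np.ndarray, yj: np.ndarray) -> np.ndarray:
    """2x2 cross-tabulation of two binary membership vectors."""
    both = int(np.sum((yi == 1) & (yj == 1)))
    only_i = int(np.sum((yi == 1) & (yj == 0)))
    only_j = int(np.sum((yi == 0) & (yj == 1)))
    neither = int(np.sum((yi == 0) & (yj == 0)))
    return np.array([[both, only_i], [only_j, neither]])


def pairwise_cramers_v(dataset: MultiLabelDataset) -> pd.DataFrame:
    """M x M symmetric matrix of bias-corrected Cramér's V between labels.

    The diagonal is defined as 1.0 (self-association).  Returned as a
    labelled DataFrame for direct CSV export.
    """
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Y = dataset.labels
    m = dataset.n_labels
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            out[i, j] = out[j, i] = cramers_v_corrected(_pair_table(Y[:, i], Y[:, j]))
    return pd.DataFrame(out, index=dataset.label_names, columns=dataset.label_names)


def label_intersection_counts(
    dataset: MultiLabelDataset,
) -> tuple[dict[frozenset, int], dict[str, int]]:
    """Counts of observed label combinations plus per-label totals.

    The first mapping keys exactly the distinct label sets occurring in
    the data (values sum to N); the second gives per-label column sums.
    These are the counts underlying UpSet-style intersection summaries.
    """
    combos = Counter(dataset.label_sets())
    totals = {
        name: int(dataset.labels[:, i].sum())
        for i, name in enumerate(dataset.label_names)
    }
    return dict(combos), totals
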