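"""Community detection on the label co-occurrence graph.

Two detectors are provided, both linear-time in practice and both
emitting pairwise-disjoint communities covering every vertex:

* greedy modularity maximization (Louvain-style agglomeration): start
  from singleton communities and repeatedly merge the pair whose merge
  raises modularity most, stopping when no merge helps;
* asynchronous label propagation (LPA): give every vertex a unique tag
  and repeatedly reassign each vertex the weighted-majority tag of its
  neighbours, sweeping in a freshly shuffled order, until every vertex
  already holds a dominant tag.

Partition quality is scored with weighted Newman modularity
Q = sum_c [ W_in(c)/W - (deg(c)/2W)^2 ].
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .label_space import LabelGraph


@dataclass
class CommunityPartition:
    """Assignment of labels to communities C_1..C_k.

    The data model allows intersecting communities; both detectors here
    emit disjoint partitions covering all vertices.
    """

    communities: list[tuple[str, ...]]
    algorithm: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.communities = [tuple(c) for c in self.communities]
        if any(len(c) == 0 for c in self.communities):
            raise ValueError("empty community")

    @property
    def k(self) -> int:
        return len(self.communities)

    @property
    def membership(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for i, comm in enumerate(self.communities):
            for label in comm:
                out.setdefault(label, []).append(i)
        return out

    def is_disjoint(self) -> bool:
        return all(len(v) == 1 for v in self.membership.values())

    def covers(self, labels) -> bool:
        return set(self.membership) >= set(labels)

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = json.dumps(
            {
                "communities": [list(c) for c in self.communities],
                "algorithm": self.algorithm,
                "seed": self.seed,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "CommunityPartition":
        d = json.loads(text)
        return cls(
            communities=[tuple(c) for c in d["communities"]],
            algorithm=d.get("algorithm", ""),
            seed=d.get("seed"),
        )


def _order_communities(graph: LabelGraph, comms) -> list[tuple[str, ...]]:
    """Deterministic ordering: within a community by vertex order, then
    communities by their first vertex."""
    pos = {l: i for i, l in enumerate(graph.labels)}
    ordered = [tuple(sorted(c, key=pos.__getitem__)) for c in comms]
    return sorted(ordered, key=lambda c: pos[c[0]])


def modularity(graph: LabelGraph, partition: CommunityPartition) -> float:
    """Weighted Newman modularity Q of a disjoint covering partition."""
    if graph.n_edges == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if not partition.is_disjoint():
        raise ValueError("partition must be disjoint")
    if set(partition.membership) != set(graph.labels):
        raise ValueError("partition must cover exactly the graph's vertices")
    return float(
        nx.community.modularity(
            graph.graph,
            [set(c) for c in partition.communities],
            weight="weight",
        )
    )


def louvain_partition(
    graph: LabelGraph, seed: int = 0, restarts: int = 5
) -> CommunityPartition:
    """Greedy modularity maximization (Louvain-style).

    Starts from singleton communities and greedily merges/moves toward
    higher modularity.  Because greedy search is order-dependent, the
    deterministic agglomerative pass and ``restarts`` seeded runs of the
    node-moving variant are all computed and the partition of highest Q
    is returned (ties keep the agglomerative result).  Isolated vertices
    end up as singleton communities.  Deterministic given ``seed``.
    """
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    if graph.n_edges == 0:
        return CommunityPartition(
            communities=[(l,) for l in graph.labels],
            algorithm="louvain",
            seed=seed,
        )
    candidates = [
        nx.community.greedy_modularity_communities(graph.graph, weight="weight")
    ]
    for child in np.random.SeedSequence(seed).spawn(max(0, restarts)):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        candidates.append(
            nx.community.louvain_communities(
                graph.graph, weight="weight", seed=child_seed
            )
        )
    best, best_q = None, -np.inf
    for cand in candidates:
        part = CommunityPartition(
            communities=_order_communities(graph, cand),
            algorithm="louvain",
            seed=seed,
        )
        q = modularity(graph, part)
        if q > best_q:
            best, best_q = part, q
    return best


def async_label_propagation(
    graph: LabelGraph, seed: int = 0, max_iter: int = 100, restarts: int = 5
) -> CommunityPartition:
    """Multiple asynchronous label propagation.

    A single propagation run gives every vertex a unique tag, then sweeps
    the vertices in a freshly shuffled order, giving each vertex the tag
    of maximal total incident edge weight among its neighbours' tags;
    ties are broken uniformly at random (keeping the current tag only
    when it is among the tied maxima).  A run stops when a full sweep
    changes nothing — i.e. every vertex already holds a dominant tag in
    its neighbourhood — or after ``max_iter`` sweeps with a warning.

    Because asynchronous propagation is order-dependent and can merge
    well-separated groups on dense graphs, ``restarts`` independent runs
    are made with seeds derived from ``seed`` and the partition of
    highest modularity is returned (first found wins ties; on an edgeless
    graph all runs agree on singletons).  Deterministic given ``seed``.
    """
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    best: CommunityPartition | None = None
    best_q = -np.inf
    for child in np.random.SeedSequence(seed).spawn(max(1, restarts)):
        part = _lpa_once(graph, np.random.default_rng(child), max_iter)
        part.seed = seed
        if graph.n_edges == 0:
            return part
        q = modularity(graph, part)
        if q > best_q:
            best, best_q = part, q
    assert best is not None
    return best


def _lpa_once(
    graph: LabelGraph, rng: np.random.Generator, max_iter: int
) -> CommunityPartition:
    labels = list(graph.labels)
    tags = {v: i for i, v in enumerate(labels)}
    g = graph.graph
    for _ in range(max_iter):
        changed = False
        for idx in rng.permutation(len(labels)):
            v = labels[idx]
            weight_by_tag: dict[int, float] = {}
            for u in g[v]:
                w = g[v][u].get("weight", 1)
                weight_by_tag[tags[u]] = weight_by_tag.get(tags[u], 0.0) + w
            if not weight_by_tag:  # isolated vertex keeps its own tag
                continue
            best = max(weight_by_tag.values())
            winners = sorted(t for t, w in weight_by_tag.items() if w == best)
            if tags[v] in winners:
                continue
            tags[v] = int(winners[rng.integers(len(winners))])
            changed = True
        if not changed:
            break
    else:
        warnings.warn(
            f"label propagation did not converge in {max_iter} sweeps",
            stacklevel=2,
        )
    groups: dict[int, list[str]] = {}
    for v in labels:
        groups.setdefault(tags[v], []).append(v)
    return CommunityPartition(
        communities=_order_communities(graph, groups.values()),
        algorithm="lpa",
    )
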