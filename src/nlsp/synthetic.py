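"""Synthetic multilabel data with planted label-community structure.

The generator emulates the statistical shape of the drug-classification
benchmark without any chemistry: a binary label matrix whose labels
co-activate in planted blocks, and features laid out as three
concatenated M-wide blocks of per-class maximum-similarity scores in
[0, 1], elevated for the classes a sample actually carries.

Label model (block-factor Bernoulli mixture): per sample, a global
factor g0 ~ Bern(pi); each block's factor g_b copies g0 with probability
rho_out and is otherwise a fresh Bern(pi); each label copies its block
factor with probability rho_in and is otherwise an independent
Bern(pi).  Marginal prevalence stays pi for every label while pairwise
co-occurrence is strong within blocks (driven by rho_in) and weak across
(driven by rho_out).  All-zero label rows are rejected and redrawn.

Feature model: column (block, label l) ~ Normal(mu_pos if the sample
carries l else mu_neg, sigma), truncated to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import truncnorm

from .datasets import MultiLabelDataset, default_label_names
from .label_space import LabelGraph, build_graph

FEATURE_BLOCKS = ("int", "strsim", "fpsim")


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    Defaults are the standard strong-signal scenario used throughout the
    test suite: 600 samples, 14 labels in two planted blocks of 7,
    within-block coupling 0.9, cross-block coupling 0.05, prevalence 0.2,
    feature means 0.8 (carried class) vs 0.3 (other classes), spread 0.1.
    """

    n_samples: int = 600
    n_labels: int = 14
    planted_communities: list[tuple[str, ...]] | None = None
    rho_in: float = 0.9
    rho_out: float = 0.05
    prevalence: float = 0.2
    mu_pos: float = 0.8
    mu_neg: float = 0.3
    sigma: float = 0.1
    seed: int = 0
    label_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label_names:
            self.label_names = default_label_names(self.n_labels)
        if len(self.label_names) != self.n_labels:
            raise ValueError("label_names length must equal n_labels")
        if self.planted_communities is None:
            half = self.n_labels // 2
            self.planted_communities = [
                tuple(self.label_names[:half]),
                tuple(self.label_names[half:]),
            ]
        self.planted_communities = [tuple(b) for b in self.planted_communities]
        flat = [l for b in self.planted_communities for l in b]
        if sorted(flat) != sorted(self.label_names):
            raise ValueError("planted_communities must partition the labels")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("rho_in", "rho_out"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rho_out > self.rho_in:
            raise ValueError("rho_out must not exceed rho_in")
        if not 0 <= self.mu_neg < self.mu_pos <= 1:
            raise ValueError("need 0 <= mu_neg < mu_pos <= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def _draw_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample the label matrix; every row gets >= 1 label."""
    n, m, pi = spec.n_samples, spec.n_labels, spec.prevalence
    block_of = np.empty(m, dtype=int)
    pos = {l: j for j, l in enumerate(spec.label_names)}
    for b, block in enumerate(spec.planted_communities):
        for l in block:
            block_of[pos[l]] = b
    n_blocks = len(spec.planted_communities)
    Y = np.empty((n, m), dtype=np.int8)
    filled = 0
    draws = 0
    while filled < n:
        batch = max(n - filled, 64)
        draws += batch
        if draws > 10**6:
            raise RuntimeError(
                "zero-label rejection exceeded 1e6 draws; spec infeasible"
            )
        g0 = rng.random(batch) < pi
        copy0 = rng.random((batch, n_blocks)) < spec.rho_out
        fresh_b = rng.random((batch, n_blocks)) < pi
        g = np.where(copy0, g0[:, None], fresh_b)
        copy_l = rng.random((batch, m)) < spec.rho_in
        fresh_l = rng.random((batch, m)) < pi
        y = np.where(copy_l, g[:, block_of], fresh_l).astype(np.int8)
        keep = y.sum(axis=1) > 0
        take = min(int(keep.sum()), n - filled)
        Y[filled:filled + take] = y[keep][:take]
        filled += take
    return Y


def generate_dataset(spec: SyntheticSpec) -> MultiLabelDataset:
    """Generate a dataset under the given conditions; byte-identical per seed.

    Features come in the canonical three-block column order: columns
    1..M, M+1..2M and 2M+1..3M correspond to the interaction-like,
    structural-similarity-like and fingerprint-similarity-like blocks.
    """
    rng = np.random.default_rng(spec.seed)
    Y = _draw_labels(spec, rng)
    n, m = Y.shape
    X = np.empty((n, 3 * m))
    for b in range(3):
        mean = np.where(Y == 1, spec.mu_pos, spec.mu_neg)
        if spec.sigma == 0:
            X[:, b * m:(b + 1) * m] = mean
        else:
            a = (0.0 - mean) / spec.sigma
            bnd = (1.0 - mean) / spec.sigma
            X[:, b * m:(b + 1) * m] = truncnorm.rvs(
                a, bnd, loc=mean, scale=spec.sigma, random_state=rng
            )
    feature_names = [
        f"{blk}:{l}" for blk in FEATURE_BLOCKS for l in spec.label_names
    ]
    width = len(str(n))
    return MultiLabelDataset(
        features=X,
        labels=Y,
        label_names=list(spec.label_names),
        sample_ids=[f"S{i:0{width}d}" for i in range(n)],
        feature_names=feature_names,
    )


def planted_partition_graph(
    block_sizes: list[int],
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> LabelGraph:
    """Random graph with planted blocks and unit-weight edges.

    Each within-block pair is joined with probability ``p_in``, each
    cross-block pair with ``p_out``; all vertices are present even when
    isolated.  Vertex names are v0, v1, ... in block order.
    """
    if p_out > p_in:
        raise ValueError("p_out must not exceed p_in")
    g = nx.random_partition_graph(list(block_sizes), p_in, p_out, seed=seed)
    names = [f"v{i}" for i in range(sum(block_sizes))]
    edges = [(names[u], names[v], 1) for u, v in g.edges()]
    return build_graph(names, edges)


def planted_blocks_for_graph(block_sizes: list[int]) -> list[tuple[str, ...]]:
    """Ground-truth vertex blocks matching planted_partition_graph naming."""
    blocks, start = [], 0
    for size in block_sizes:
        blocks.append(tuple(f"v{i}" for i in range(start, start + size)))
        start += size
    return blocks
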