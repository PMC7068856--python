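"""Label-aware (0-1) centrality features on a labeled network.

Given a binary prior labeling x of a network's genes (1 = known
disease gene), every classical centrality used here is split into the
contribution coming from label-0 nodes and from label-1 nodes:

* 0-1 degree: counts of neighbors with each label;
* 0-1 closeness: inverse shortest-path sums to nodes of each label,
  normalized by (n0 - 1) resp. (n1 - 1);
* 0-1 truncated Katz: damped walk counts ``sum_{k=1..K} alpha^k
  (A^k)_{ji}`` split by the label of the walk's starting node j.

The Katz series is truncated at maximum walk length K; with a finite K
the sum is always finite, so no convergence condition is imposed on
alpha.  :func:`katz_trunc` and :func:`katz_01` count every walk ending
at the node, as the plain centrality definition does.  The *feature
vector* built by :func:`feature_table` / :class:`FeatureEngine`
additionally drops walks that start at the node itself (the k=0
identity term and the closed-walk diagonal ``(A^k)_{ii}``): those
terms would feed a gene's own prior label into its own feature, which
both leaks the training label and systematically separates a
relabeled held-out gene from the genes it was trained against.

The per-gene feature vector is
``phi_i = (1, C_d0, C_d1, C_c0, C_c1, C_k0, C_k1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneNetwork

FEATURE_COLUMNS = ["dummy", "degree0", "degree1", "closeness0", "closeness1", "katz0", "katz1"]


@dataclass(frozen=True)
class KatzParams:
    """Damping factor and maximum walk length of the truncated series."""

    alpha: float
    k: int

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class LabelConfiguration:
    """Binary prior labels over (at least) a network's node set."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, got {sorted(bad)}")

    @classmethod
    def from_positives(cls, nodes, positives) -> "LabelConfiguration":
        positives = set(positives)
        return cls({n: (1 if n in positives else 0) for n in nodes})

    def require_cover(self, net: GeneNetwork) -> None:
        missing = net.nodes - self.labels.keys()
        if missing:
            raise ValueError(f"configuration misses {len(missing)} nodes, e.g. {sorted(missing)[0]!r}")


def _check_node(net: GeneNetwork, i: str) -> None:
    if i not in net.graph:
        raise ValueError(f"node {i!r} not in network")


def degree_01(net: GeneNetwork, cfg: LabelConfiguration, i: str) -> tuple[float, float]:
    """(# neighbors labeled 0, # neighbors labeled 1)."""
    _check_node(net, i)
    d1 = sum(cfg.labels[j] for j in net.graph.neighbors(i))
    d0 = net.graph.degree(i) - d1
    return float(d0), float(d1)


def closeness_01(net: GeneNetwork, cfg: LabelConfiguration, i: str) -> tuple[float, float]:
    """Label-split closeness; unreachable nodes contribute 0 and a class
    with fewer than 2 members in the network yields a 0 component."""
    _check_node(net, i)
    n1 = sum(cfg.labels[j] for j in net.graph.nodes)
    n0 = net.graph.number_of_nodes() - n1
    lengths = nx.single_source_shortest_path_length(net.graph, i)
    acc0 = acc1 = 0.0
    for j, d in lengths.items():
        if j == i or d == 0:
            continue
        w = 1.0 / d
        if cfg.labels[j]:
            acc1 += w
        else:
            acc0 += w
    c0 = acc0 / (n0 - 1) if n0 > 1 else 0.0
    c1 = acc1 / (n1 - 1) if n1 > 1 else 0.0
    return c0, c1


def _adjacency(net: GeneNetwork, nodelist: list[str]):
    return nx.to_scipy_sparse_array(net.graph, nodelist=nodelist, format="csr", dtype=float)


def katz_trunc(net: GeneNetwork, p: KatzParams, i: str) -> float:
    """Truncated Katz: sum over walk lengths 1..K of alpha^k times the
    number of walks of length k ending at i."""
    _check_node(net, i)
    nodes = sorted(net.graph.nodes)
    a = _adjacency(net, nodes)
    col = np.zeros(len(nodes))
    col[nodes.index(i)] = 1.0
    total = 0.0
    damp = 1.0
    for _ in range(p.k):
        col = a @ col
        damp *= p.alpha
        total += damp * col.sum()
    return float(total)


def katz_01(net: GeneNetwork, cfg: LabelConfiguration, p: KatzParams, i: str) -> tuple[float, float]:
    """Truncated Katz split by the label of the walk's starting node."""
    _check_node(net, i)
    nodes = sorted(net.graph.nodes)
    a = _adjacency(net, nodes)
    x = np.array([cfg.labels[n] for n in nodes], dtype=float)
    col = np.zeros(len(nodes))
    col[nodes.index(i)] = 1.0
    k0 = k1 = 0.0
    damp = 1.0
    for _ in range(p.k):
        col = a @ col
        damp *= p.alpha
        k1 += damp * float(x @ col)
        k0 += damp * float((1.0 - x) @ col)
    return k0, k1


class FeatureEngine:
    """Vectorized feature computation for one network.

    Shortest-path structure is precomputed once (it is independent of
    the labeling), so features under many different configurations --
    as needed by leave-one-out relabeling -- cost only a handful of
    sparse matrix-vector products each.
    """

    def __init__(self, net: GeneNetwork, katz: KatzParams, nodes_of_interest=None):
        self.net = net
        self.katz = katz
        self.nodes = sorted(net.graph.nodes)
        self.index = {g: idx for idx, g in enumerate(self.nodes)}
        self.adj = _adjacency(net, self.nodes)
        self.degree = np.asarray(self.adj.sum(axis=1)).ravel()
        self.interest = sorted(nodes_of_interest) if nodes_of_interest is not None else list(self.nodes)
        missing = set(self.interest) - set(self.nodes)
        if missing:
            raise ValueError(f"nodes of interest not in network: {sorted(missing)[:3]}")
        self.rows = np.array([self.index[g] for g in self.interest], dtype=int)
        n = len(self.nodes)
        # diagonals of A^k (closed-walk counts), used to exclude walks
        # a node sends to itself from its own Katz feature
        self.diags = []
        power = self.adj.copy()
        for k in range(katz.k):
            if k > 0:
                power = power @ self.adj
            self.diags.append(np.asarray(power.diagonal()).ravel())
        invd = np.zeros((len(self.interest), n))
        for r, g in enumerate(self.interest):
            for j, d in nx.single_source_shortest_path_length(net.graph, g).items():
                if d > 0:
                    invd[r, self.index[j]] = 1.0 / d
        self.invd = invd

    def label_vector(self, positives) -> np.ndarray:
        positives = set(positives)
        return np.array([1.0 if g in positives else 0.0 for g in self.nodes])

    def features(self, x: np.ndarray) -> pd.DataFrame:
        """Feature table for the nodes of interest under labeling x."""
        x = np.asarray(x, dtype=float)
        n = len(self.nodes)
        n1 = x.sum()
        n0 = n - n1
        d1_all = self.adj @ x
        d0_all = self.degree - d1_all
        k1_all = np.zeros(n)
        ktot_all = np.zeros(n)
        tx = x.copy()
        tones = np.ones(n)
        damp = 1.0
        for k in range(self.katz.k):
            tx = self.adj @ tx
            tones = self.adj @ tones
            damp *= self.katz.alpha
            # closed walks (j = i) excluded: a gene's own label must not
            # enter its own feature
            k1_all += damp * (tx - self.diags[k] * x)
            ktot_all += damp * (tones - self.diags[k])
        k0_all = ktot_all - k1_all
        c1 = (self.invd @ x) / (n1 - 1) if n1 > 1 else np.zeros(len(self.interest))
        c0 = (self.invd @ (1.0 - x)) / (n0 - 1) if n0 > 1 else np.zeros(len(self.interest))
        r = self.rows
        table = np.column_stack([
            np.ones(len(r)), d0_all[r], d1_all[r], c0, c1, k0_all[r], k1_all[r],
        ])
        return pd.DataFrame(table, index=self.interest, columns=FEATURE_COLUMNS)


def feature_table(net: GeneNetwork, cfg: LabelConfiguration, p: KatzParams) -> pd.DataFrame:
    """Per-gene 7-dimensional feature vectors for every node of ``net``."""
    cfg.require_cover(net)
    engine = FeatureEngine(net, p)
    x = engine.label_vector({g for g, v in cfg.labels.items() if v == 1})
    return engine.features(x)
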