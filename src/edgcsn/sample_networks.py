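"""Patient-specific network construction and cluster-wise fusion.

A gene is *activated* in a case sample when its expression reaches
``lam`` times its mean control expression.  A single sample-based
network keeps exactly those static-PPI edges whose two endpoints are
both activated in the sample.  The single-sample networks of a patient
cluster are fused by an edge-frequency threshold: an edge survives iff
it appears in at least ``epsilon`` member networks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ActivationProfile:
    """Which genes exceeded the activation threshold in one case sample."""

    sample_id: str
    active_genes: frozenset
    lambda_used: float


@dataclass
class FusionResult:
    """A cluster's fused network plus the membership that produced it."""

    cluster_id: int
    member_samples: list[str]
    network: GeneNetwork
    epsilon_used: int


def control_means(control: ExpressionMatrix) -> pd.Series:
    """Per-gene arithmetic mean over all control samples."""
    if control.n_samples < 1:
        raise ValueError("need at least one control sample")
    return control.data.mean(axis=1)


def activate(case: ExpressionMatrix, ctrl_mean: pd.Series | dict, lam: float) -> list[ActivationProfile]:
    """One activation profile per case sample.

    Gene i is active in sample s iff expr[i, s] >= lam * ctrl_mean[i]
    (non-strict inequality; a gene with zero control mean is therefore
    always active, which preprocessing makes rare in practice).
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    mean = pd.Series(ctrl_mean)
    missing = [g for g in case.gene_ids if g not in mean.index]
    if missing:
        raise ValueError(f"ctrl_mean missing {len(missing)} case genes, e.g. {missing[0]!r}")
    thresh = lam * mean.loc[case.gene_ids].to_numpy()
    genes = np.asarray(case.gene_ids, dtype=object)
    profiles = []
    for j, sid in enumerate(case.sample_ids):
        active = genes[case.values[:, j] >= thresh]
        profiles.append(ActivationProfile(sid, frozenset(active), float(lam)))
    return profiles


def single_sample_network(static: GeneNetwork, prof: ActivationProfile) -> GeneNetwork:
    """Subgraph of the static network on the sample's activated genes.

    Only edges with both endpoints activated are kept, and the node set
    consists of the retained edges' endpoints (no isolated nodes).
    """
    active = prof.active_genes
    g = nx.Graph()
    g.add_edges_from(
        (u, v) for u, v in static.graph.edges if u in active and v in active
    )
    return GeneNetwork(g, kind="single_sample")


def fuse(
    networks: list[GeneNetwork],
    epsilon: int,
    cluster_id: int = 1,
    member_samples: list[str] | None = None,
) -> FusionResult:
    """Fuse single-sample networks by the edge-frequency rule.

    Each member network contributes at most one count per edge; edges
    with count >= epsilon survive, with their counts stored on the
    fused network.
    """
    if epsilon < 1:
        raise ValueError("epsilon must be >= 1")
    if not networks:
        raise ValueError("no networks to fuse")
    if epsilon > len(networks):
        logger.warning(
            "epsilon=%d exceeds the number of networks (%d); fused network will be empty",
            epsilon, len(networks),
        )
    tally: Counter = Counter()
    for net in networks:
        tally.update(net.edges)
    g = nx.Graph()
    for edge, count in tally.items():
        if count >= epsilon:
            u, v = sorted(edge)
            g.add_edge(u, v, count=count)
    return FusionResult(
        cluster_id=cluster_id,
        member_samples=list(member_samples or []),
        network=GeneNetwork(g, kind="fused"),
        epsilon_used=int(epsilon),
    )


def coverage_check(fused_nets: list[FusionResult], disease_genes: set[str]) -> tuple[float, bool]:
    """Fraction of known disease genes present in the union of fused
    networks; a parameter setting is invalid when more than 10% are
    missing."""
    if not disease_genes:
        raise ValueError("disease gene set is empty")
    union: set[str] = set()
    for fr in fused_nets:
        union |= fr.network.nodes
    frac = len(disease_genes & union) / len(disease_genes)
    return frac, (1.0 - frac) <= 0.10


def build_fused_networks(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    static: GeneNetwork,
    cluster_of: dict[str, int],
    lam: float,
    epsilon: int,
) -> list[FusionResult]:
    """Run activation -> single-sample networks -> per-cluster fusion."""
    mean = control_means(control)
    profiles = {p.sample_id: p for p in activate(case, mean, lam)}
    results = []
    for cid in sorted(set(cluster_of.values())):
        members = [s for s in case.sample_ids if cluster_of[s] == cid]
        nets = [single_sample_network(static, profiles[s]) for s in members]
        results.append(fuse(nets, epsilon, cluster_id=cid, member_samples=members))
    return results
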