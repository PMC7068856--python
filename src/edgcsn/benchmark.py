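"""Benchmark construction: negative selection and gold-standard sets.

Because no database records *non*-disease genes, negatives are chosen
through a disease-gene network (DGN) built from a disease--gene
association catalog: diseases link to their genes, and two diseases
link directly when they share at least one gene.  Genes of diseases
more than ``eta`` hops away from the disease under study (or
unreachable from it) are considered safe negatives, provided they
appear in every fused network.  Pairing the m known disease genes with
m sampled negatives, repeated with independent seeded draws, yields the
gold-standard benchmark sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .io_formats import DiseaseAssociationCatalog
from .sample_networks import FusionResult

logger = logging.getLogger(__name__)

# node namespaces inside the mixed DGN graph
_D = "disease"
_G = "gene"


@dataclass
class DiseaseGeneNetwork:
    """Mixed graph of disease nodes and gene nodes.

    Nodes are (namespace, name) tuples so that a disease id can never
    collide with a gene symbol.
    """

    graph: nx.Graph

    @property
    def disease_ids(self) -> set[str]:
        return {n for kind, n in self.graph.nodes if kind == _D}

    @property
    def gene_symbols(self) -> set[str]:
        return {n for kind, n in self.graph.nodes if kind == _G}

    def genes_of(self, disease: str) -> set[str]:
        node = (_D, disease)
        return {n for kind, n in self.graph.neighbors(node) if kind == _G}


@dataclass(frozen=True)
class GoldStandardSet:
    """m known disease genes paired with m sampled non-disease genes."""

    disease_genes: frozenset
    non_disease_genes: frozenset
    draw_index: int
    seed: int

    def __post_init__(self) -> None:
        if self.disease_genes & self.non_disease_genes:
            raise ValueError("disease and non-disease gene sets overlap")
        if len(self.disease_genes) != len(self.non_disease_genes):
            raise ValueError("gold set must be balanced")

    @property
    def genes(self) -> set[str]:
        return set(self.disease_genes) | set(self.non_disease_genes)

    def label_of(self, gene: str) -> int:
        return 1 if gene in self.disease_genes else 0


def build_dgn(cat: DiseaseAssociationCatalog) -> DiseaseGeneNetwork:
    """Disease--gene edges per association; disease--disease edges for
    every pair of diseases sharing at least one gene."""
    g = nx.Graph()
    for d, gene in cat.records:
        g.add_edge((_D, d), (_G, gene))
    by_disease = {d: cat.genes_of(d) for d in cat.diseases}
    for d1, d2 in combinations(sorted(by_disease), 2):
        if by_disease[d1] & by_disease[d2]:
            g.add_edge((_D, d1), (_D, d2))
    return DiseaseGeneNetwork(g)


def non_disease_pool(
    dgn: DiseaseGeneNetwork,
    target: str,
    fused_nets: list[FusionResult],
    known: set[str],
    eta: int = 5,
) -> set[str]:
    """Candidate negatives for ``target``.

    Union of the gene sets of diseases whose unweighted hop distance
    from the target in the DGN exceeds ``eta`` (unreachable counts as
    infinitely far), minus the known disease genes, restricted to genes
    present in *every* fused network.
    """
    if target not in dgn.disease_ids:
        raise ValueError(f"disease {target!r} not in DGN")
    dist = nx.single_source_shortest_path_length(dgn.graph, (_D, target))
    pool: set[str] = set()
    for d in dgn.disease_ids:
        if d == target:
            continue
        if dist.get((_D, d), np.inf) > eta:
            pool |= dgn.genes_of(d)
    pool -= set(known)
    for fr in fused_nets:
        pool &= fr.network.nodes
    return pool


def draw_gold_sets(
    disease_genes: set[str],
    pool: set[str],
    n_sets: int = 50,
    seed: int = 0,
) -> list[GoldStandardSet]:
    """Sample ``n_sets`` balanced gold-standard sets.

    Negatives are drawn uniformly without replacement from ``pool``;
    each draw uses an independent substream derived from (seed, draw
    index) so sets are reproducible and order-independent.
    """
    m = len(disease_genes)
    if m < 2:
        raise ValueError("need at least 2 known disease genes")
    if len(pool) < m:
        raise ValueError(
            f"negative pool too small: need {m}, have {len(pool)} (deficit {m - len(pool)})"
        )
    pool_list = sorted(pool)
    positives = frozenset(disease_genes)
    sets = []
    for i in range(1, n_sets + 1):
        rng = np.random.default_rng([int(seed), i])
        negatives = rng.choice(pool_list, size=m, replace=False)
        sets.append(GoldStandardSet(positives, frozenset(negatives.tolist()), i, int(seed)))
    return sets
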