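"""Self-contained synthetic data with the structure the pipeline assumes.

The generator emulates, at desk scale, the statistical shape of a
tumor-vs-normal RNA-seq study joined with a static PPI network:

* a sparse scale-free gene network (preferential attachment), with the
  planted disease modules wired into connected subgraphs;
* per-gene baseline abundances spanning several orders of magnitude on
  the raw (FPKM-like) scale, so that after TPM conversion the log2
  working values cover the realistic 0-15 range and low-abundance
  genes show background activation while high-abundance genes do not;
* case samples split into ``n_clusters`` patient subgroups, each
  over-expressing its own planted disease module by ``effect``-fold and
  additionally shifting a broader subtype signature of background
  genes (up or down, scaled with the module effect), the way tumor
  subtypes differ in whole expression programs rather than in a
  handful of genes;
* a latent per-sample expression-program factor with per-gene loadings
  (cases and controls alike), giving genes the correlated
  sample-to-sample fluctuations real co-regulated transcriptomes show;
  at ``effect = 1`` case and control are therefore generated
  identically and the planted labels carry no information;
* a disease--gene association catalog containing the target disease
  (genes = the planted modules), a chain of intermediate diseases
  linked by shared genes, and decoy diseases placed more than 5 hops
  away whose genes supply the negative pool.  Decoy genes are sampled
  from non-planted genes in the same abundance band as the planted
  genes, mirroring the standard practice of expression-matching
  negative controls.

Raw values are written on an arbitrary FPKM-like scale (``2**log2``
of the simulated signal); the pipeline's own TPM conversion and
preprocessing produce the working matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import DiseaseAssociationCatalog, ExpressionMatrix, GeneNetwork

TARGET_DISEASE = "D_TARGET"

# log2 abundance span of background genes on the raw scale; wide enough
# that post-TPM values cover ~0..15 like real log2(TPM+1) data
_BG_SPAN = (0.0, 17.0)
# planted and decoy genes sit in a moderate-abundance band (about 2-6
# on the post-TPM log2 scale) where the activation rule is informative
_MODULE_HALF_SPAN = 1.5
_DECOY_BAND = (2.5, 7.5)
_CHAIN_LENGTH = 5  # intermediate diseases between target and decoys


@dataclass
class SyntheticSpec:
    """Study-design parameters of the generator.

    ``effect`` is the fold-activation of a cluster's module genes in
    that cluster's case samples (1.0 = null, no signal); ``base_mean``
    is the center of the planted genes' log2 baseline; ``noise_sd`` is
    the per-gene log2 measurement noise.
    """

    n_genes: int = 300
    n_case: int = 60
    n_control: int = 20
    n_clusters: int = 2
    module_size: int = 10
    attachment: int = 3
    base_mean: float = 8.0
    effect: float = 4.0
    noise_sd: float = 0.3
    seed: int = 0
    factor_sd: float = 0.6
    signature_size: int = 50
    n_decoy_diseases: int = 3
    genes_per_decoy: int = 20

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.module_size * self.n_clusters > self.n_genes:
            raise ValueError("planted modules cannot overlap: modules exceed gene count")
        if self.effect < 1:
            raise ValueError("effect must be >= 1")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside the generated data."""

    planted_disease_genes: dict[int, frozenset]
    sample_cluster: dict[str, int]
    catalog: DiseaseAssociationCatalog
    target_disease: str = TARGET_DISEASE

    @property
    def all_planted(self) -> set[str]:
        return set().union(*self.planted_disease_genes.values())


def generate(spec: SyntheticSpec):
    """Produce (static network, case matrix, control matrix, truth).

    Fully deterministic for a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]

    # --- static scale-free network with wired-in modules
    ba = nx.barabasi_albert_graph(spec.n_genes, spec.attachment, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(ba, {i: genes[i] for i in range(spec.n_genes)})
    n_planted = spec.n_clusters * spec.module_size
    planted_idx = rng.choice(spec.n_genes, size=n_planted, replace=False)
    modules: dict[int, frozenset] = {}
    for c in range(spec.n_clusters):
        members = [genes[i] for i in planted_idx[c * spec.module_size:(c + 1) * spec.module_size]]
        # connect as a path plus random chords; the chords bring the
        # internal density toward that of a protein complex rather
        # than a bare chain
        for a, b in zip(members, members[1:]):
            g.add_edge(a, b)
        for _ in range(max(1, spec.module_size)):
            a, b = rng.choice(members, size=2, replace=False)
            if a != b:
                g.add_edge(a, b)
        modules[c + 1] = frozenset(members)
    static = GeneNetwork(g, kind="static")

    planted_set = set().union(*modules.values())
    module_mask = np.zeros((spec.n_clusters, spec.n_genes), dtype=bool)
    for cid, mem in modules.items():
        for i, gene in enumerate(genes):
            if gene in mem:
                module_mask[cid - 1, i] = True

    # --- baseline log2 abundances
    baseline = rng.uniform(*_BG_SPAN, size=spec.n_genes)
    for i in planted_idx:
        baseline[i] = spec.base_mean + rng.uniform(-_MODULE_HALF_SPAN, _MODULE_HALF_SPAN)

    # --- co-expression programs aligned with network communities:
    # interacting genes tend to be co-regulated, so each community of
    # the static network forms one expression program whose per-sample
    # activity its members share.  Because the programs partition the
    # transcriptome, their activities average out across samples and do
    # not create a dominant global axis of variation.
    idx = {gene: i for i, gene in enumerate(genes)}
    communities = list(nx.community.greedy_modularity_communities(g))
    program = np.zeros(spec.n_genes, dtype=int)
    for ci, comm in enumerate(communities):
        for gene in comm:
            program[idx[gene]] = ci
    n_programs = len(communities)
    # planted genes are re-assigned to a program of one of their
    # *background* neighbors, avoiding the programs of their module
    # partners: absent the disease effect, adjacent module genes then
    # do not co-activate, so null-model co-membership of labeled genes
    # in a fused network reflects only background co-expression
    for cid, mem in modules.items():
        for gene in sorted(mem):
            partners = set(g.neighbors(gene)) & mem
            partner_progs = {program[idx[p]] for p in partners}
            bg_progs = sorted({int(program[idx[n]]) for n in g.neighbors(gene) if n not in planted_set})
            free = [p for p in bg_progs if p not in partner_progs]
            if free:
                program[idx[gene]] = free[0]
            elif bg_progs:
                program[idx[gene]] = bg_progs[0]

    # --- catalog gene picks (linker chain + decoys) from the abundance band
    band = sorted(
        genes[i] for i in range(spec.n_genes)
        if _DECOY_BAND[0] <= baseline[i] <= _DECOY_BAND[1] and genes[i] not in planted_set
    )
    n_linkers = _CHAIN_LENGTH
    n_decoy_genes = spec.n_decoy_diseases * spec.genes_per_decoy
    if len(band) < n_linkers + n_decoy_genes:
        raise ValueError(
            f"infeasible spec: need {n_linkers + n_decoy_genes} non-planted genes in the "
            f"decoy abundance band, found {len(band)}"
        )
    picks = rng.choice(band, size=n_linkers + n_decoy_genes, replace=False).tolist()
    linkers = picks[:n_linkers]
    decoy_genes = picks[n_linkers:]

    # --- per-cluster subtype signatures over background genes outside
    # the band (hence disjoint from planted, linker and decoy genes);
    # signed shifts scale with the module effect and vanish in the null
    # signature genes sit outside the decoy band (so they stay
    # disjoint from planted, linker and decoy genes) and below the
    # extreme-abundance tail: shifting a very high-abundance gene would
    # noticeably move its cluster's library total and so perturb every
    # gene's TPM
    sig_candidates = [i for i in range(spec.n_genes)
                      if genes[i] not in planted_set
                      and baseline[i] <= 12.0
                      and not (_DECOY_BAND[0] <= baseline[i] <= _DECOY_BAND[1])]
    boost = np.log2(spec.effect)
    signature = np.zeros((spec.n_clusters, spec.n_genes))
    n_sig = min(spec.signature_size, len(sig_candidates) // max(1, spec.n_clusters))
    sig_pool = rng.permutation(sig_candidates)
    for c in range(spec.n_clusters):
        chosen = sig_pool[c * n_sig:(c + 1) * n_sig]
        signature[c, chosen] = boost * rng.choice([-1.0, 1.0], size=len(chosen))

    # --- samples
    case_ids = [f"case{j:03d}" for j in range(spec.n_case)]
    ctrl_ids = [f"ctrl{j:03d}" for j in range(spec.n_control)]
    sample_cluster = {sid: (j % spec.n_clusters) + 1 for j, sid in enumerate(case_ids)}

    def _expr(sample_ids, clusters):
        vals = np.empty((spec.n_genes, len(sample_ids)))
        for j, sid in enumerate(sample_ids):
            activity = rng.normal(0.0, spec.factor_sd, size=n_programs)
            log2 = (baseline + activity[program]
                    + rng.normal(0.0, spec.noise_sd, size=spec.n_genes))
            if clusters is not None:
                c = clusters[sid] - 1
                log2 = log2 + boost * module_mask[c] + signature[c]
            vals[:, j] = 2.0 ** log2
        return vals

    case_vals = _expr(case_ids, sample_cluster)
    ctrl_vals = _expr(ctrl_ids, None)
    case = ExpressionMatrix(pd.DataFrame(case_vals, index=genes, columns=case_ids), "case", "raw")
    control = ExpressionMatrix(pd.DataFrame(ctrl_vals, index=genes, columns=ctrl_ids), "control", "raw")

    records = {(TARGET_DISEASE, gene) for gene in sorted(planted_set)}
    # chain D_CHAIN1..k: consecutive diseases share a gene, so hop
    # distance from the target grows by one per link
    anchor = sorted(planted_set)[0]
    prev_link = anchor
    for k in range(1, _CHAIN_LENGTH + 1):
        d = f"D_CHAIN{k}"
        records.add((d, prev_link))
        records.add((d, linkers[k - 1]))
        prev_link = linkers[k - 1]
    for di in range(spec.n_decoy_diseases):
        d = f"D_DECOY{di + 1}"
        records.add((d, prev_link))  # shares a gene with the chain end only
        for gene in decoy_genes[di * spec.genes_per_decoy:(di + 1) * spec.genes_per_decoy]:
            records.add((d, gene))
    catalog = DiseaseAssociationCatalog(frozenset(records))

    truth = SyntheticTruth(
        planted_disease_genes=modules,
        sample_cluster=sample_cluster,
        catalog=catalog,
    )
    return static, case, control, truth


# ---------------------------------------------------------------------------
# worked example: a fully hand-computed 8-gene instance


@dataclass
class WorkedExample:
    """Tiny fixture whose expected outputs were computed by hand.

    Two control samples put every gene's control mean at 2.0, so with
    lam = 1.1 the activation threshold is 2.2: case values of 3.0 are
    active, values of 1.0 are not.  Expected activation sets, fused
    edge lists (epsilon = 2), feature vectors (alpha = 0.1, K = 2) and
    the composition of one leave-one-out fold are recorded below.
    """

    static: GeneNetwork
    case: ExpressionMatrix
    control: ExpressionMatrix
    lam: float
    epsilon: int
    katz: object = None  # KatzParams; set in worked_example()
    disease_genes: frozenset = frozenset()
    non_disease_genes: frozenset = frozenset()
    expected_active: dict = field(default_factory=dict)
    expected_cluster_of: dict = field(default_factory=dict)
    expected_fused_edges: dict = field(default_factory=dict)
    expected_features: dict = field(default_factory=dict)
    expected_fold: dict = field(default_factory=dict)


def worked_example() -> WorkedExample:
    """8 genes, 4 case + 2 control samples, everything hand-checkable."""
    from .features import KatzParams

    genes = list("ABCDEFGH")
    edges = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D"),
             ("D", "E"), ("E", "F"), ("F", "G"), ("G", "H")]
    static = GeneNetwork.from_edges(edges, kind="static")

    active_sets = {
        "s1": {"A", "B", "C", "D"},
        "s2": {"A", "B", "C"},
        "s3": {"E", "F", "G", "H"},
        "s4": {"E", "F", "G"},
    }
    case_cols = {}
    for sid, act in active_sets.items():
        case_cols[sid] = [3.0 if g in act else 1.0 for g in genes]
    case = ExpressionMatrix(
        pd.DataFrame(case_cols, index=genes), condition="case", stage="log2tpm"
    )
    control = ExpressionMatrix(
        pd.DataFrame({"c1": [2.0] * 8, "c2": [2.0] * 8}, index=genes),
        condition="control", stage="log2tpm",
    )

    # hand-computed expectations (triangle A-B-C fused for cluster 1,
    # path E-F-G for cluster 2; disease genes {A, B, F})
    expected_fused = {
        1: {frozenset({"A", "B"}), frozenset({"A", "C"}), frozenset({"B", "C"})},
        2: {frozenset({"E", "F"}), frozenset({"F", "G"})},
    }
    # feature vectors (1, d0, d1, c0, c1, k0, k1); Katz entries count
    # damped walks of length 1..2 ending at the node, walks from the
    # node to itself excluded
    expected_features = {
        # fused network 1, labels A=1 B=1 C=0 (n1=2, n0=1)
        1: {
            "A": (1.0, 1.0, 1.0, 0.0, 1.0, 0.11, 0.11),
            "B": (1.0, 1.0, 1.0, 0.0, 1.0, 0.11, 0.11),
            "C": (1.0, 0.0, 2.0, 0.0, 2.0, 0.00, 0.22),
        },
        # fused network 2, labels F=1, E=G=0 (n1=1, n0=2)
        2: {
            "E": (1.0, 0.0, 1.0, 0.5, 0.0, 0.01, 0.10),
            "F": (1.0, 2.0, 0.0, 2.0, 0.0, 0.20, 0.00),
            "G": (1.0, 0.0, 1.0, 0.5, 0.0, 0.01, 0.10),
        },
    }
    # leave-one-out fold holding out gene A with its label forced to 0:
    # network 1 then has labels A=0, B=1, C=0 (n1=1, n0=2)
    expected_fold = {
        "held_out": "A",
        "trained_networks": [1],          # A is absent from network 2
        "train_genes": {1: ["B", "C"]},
        "train_features": {
            "B": (1.0, 2.0, 0.0, 2.0, 0.0, 0.22, 0.00),
            "C": (1.0, 1.0, 1.0, 1.0, 0.0, 0.11, 0.11),
        },
        "heldout_features": (1.0, 1.0, 1.0, 1.0, 0.0, 0.11, 0.11),
    }
    return WorkedExample(
        static=static,
        case=case,
        control=control,
        lam=1.1,
        epsilon=2,
        katz=KatzParams(alpha=0.1, k=2),
        disease_genes=frozenset({"A", "B", "F"}),
        non_disease_genes=frozenset({"C", "E", "G"}),
        expected_active={k: frozenset(v) for k, v in active_sets.items()},
        expected_cluster_of={"s1": 1, "s2": 1, "s3": 2, "s4": 2},
        expected_fused_edges=expected_fused,
        expected_features=expected_features,
        expected_fold=expected_fold,
    )
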