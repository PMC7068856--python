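"""Per-cluster logistic models, ensemble-max prediction and evaluation.

One logistic model is fitted per fused network on the 0-1 centrality
features of the gold-standard genes present in that network; a gene's
final score is the maximum of its per-network probabilities, so a gene
only needs to look disease-like in *one* patient cluster to rank high.
Evaluation is leave-one-out cross validation over the 2m gold genes
with trapezoidal ROC/AUC, averaged over the gold-set draws.

The maximum-likelihood fit of the logistic model is ill-posed under
separable data (likely with a few dozen training genes), so a weak L2
ridge (default 1e-2, not applied to the intercept) guarantees a finite
optimum and keeps the weights off the max-margin blow-up that
separable fits otherwise drift into; relative to the log-likelihood of
a few dozen training genes it is far too weak to reorder clearly
separated classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve

from .benchmark import GoldStandardSet
from .features import FeatureEngine, KatzParams
from .sample_networks import FusionResult

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-2


@dataclass
class LogisticModel:
    """Weight vector aligned to the 7-dim feature order; theta[0] is the
    intercept multiplying the dummy feature."""

    theta: np.ndarray
    network_id: int = 0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (7,):
            raise ValueError("theta must have 7 entries")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")


@dataclass
class RocResult:
    """ROC points over the threshold sweep plus trapezoidal AUC."""

    points: list[tuple[float, float]]  # (FPR, TPR)
    auc: float


@dataclass
class EvaluationResult:
    mean_auc: float
    per_set_auc: list[float] = field(default_factory=list)


def fit_logistic(
    features: np.ndarray,
    labels: np.ndarray,
    network_id: int = 0,
    ridge: float = DEFAULT_RIDGE,
) -> LogisticModel:
    """Penalized maximum-likelihood fit of the logistic model.

    ``features`` is n x 7 with the leading dummy column; the dummy is
    handled as an unpenalized intercept.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[1] != 7:
        raise ValueError("features must be n x 7")
    if x.shape[0] != y.shape[0]:
        raise ValueError("features and labels misaligned")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    lr = LogisticRegression(
        C=1.0 / ridge, fit_intercept=True, solver="lbfgs",
        max_iter=5000, tol=1e-10,
    )
    lr.fit(x[:, 1:], y)
    theta = np.concatenate([lr.intercept_, lr.coef_.ravel()])
    return LogisticModel(theta, network_id=network_id)


def predict_prob(model: LogisticModel, phi: np.ndarray) -> float:
    """sigma(theta . phi), numerically stable for large |theta . phi|."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != (7,):
        raise ValueError("phi must have 7 entries")
    return float(expit(model.theta @ phi))


def ensemble_max(per_network_probs: dict[int, float]) -> float:
    """Final probability: the maximum over the networks covering the gene."""
    if not per_network_probs:
        raise ValueError("gene appears in no fused network")
    return max(per_network_probs.values())


def confusion_at(scores: dict[str, float], truth: dict[str, int], gamma: float):
    """TP/FP/TN/FN and TPR/FPR at a single threshold (score >= gamma is
    called positive)."""
    tp = fp = tn = fn = 0
    for g, s in scores.items():
        pred = s >= gamma
        if truth[g] == 1:
            tp += pred
            fn += not pred
        else:
            fp += pred
            tn += not pred
    tpr = tp / (tp + fn) if (tp + fn) else 0.0
    fpr = fp / (tn + fp) if (tn + fp) else 0.0
    return {"TP": tp, "FP": fp, "TN": tn, "FN": fn, "TPR": tpr, "FPR": fpr}


def roc_auc(scores: dict[str, float], truth: dict[str, int]) -> RocResult:
    """Threshold sweep over all distinct scores (non-strict >=) with
    trapezoidal area under the resulting curve."""
    genes = sorted(scores)
    y = np.array([truth[g] for g in genes], dtype=int)
    s = np.array([scores[g] for g in genes], dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("truth contains a single class")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


# ---------------------------------------------------------------------------
# LOOCV over gold-standard genes


def _engines(fused_nets, katz, interest_by_net):
    engines = {}
    for fr in fused_nets:
        interest = interest_by_net[fr.cluster_id]
        if interest:
            engines[fr.cluster_id] = FeatureEngine(fr.network, katz, nodes_of_interest=interest)
    return engines


def loocv(
    gold: GoldStandardSet,
    fused_nets: list[FusionResult],
    katz: KatzParams,
    ridge: float = DEFAULT_RIDGE,
    relabel: bool = True,
) -> dict[str, float]:
    """Leave-one-out probabilities for the 2m gold genes.

    For each held-out gene g, every fused network is labeled with the
    known disease genes as 1; when ``relabel`` is on, g's own label is
    forced to 0 for its fold and the features are recomputed under that
    configuration, so g's positive status can never leak into the fold
    through its neighbors' features.  Per network, a model is fitted on
    the remaining gold genes present there; g's probability is the
    maximum over the networks containing it.  Gold genes absent from
    every fused network are dropped with a warning.
    """
    known = set(gold.disease_genes)
    present: dict[int, list[str]] = {}
    for fr in fused_nets:
        present[fr.cluster_id] = sorted(gold.genes & fr.network.nodes)
    engines = _engines(fused_nets, katz, present)

    covered = sorted({g for genes in present.values() for g in genes})
    dropped = sorted(gold.genes - set(covered))
    if dropped:
        logger.warning("loocv: %d gold genes in no fused network, e.g. %r", len(dropped), dropped[0])

    base_x = {cid: eng.label_vector(known) for cid, eng in engines.items()}
    out: dict[str, float] = {}
    for g in covered:
        per_net: dict[int, float] = {}
        for cid, eng in engines.items():
            rows = present[cid]
            if g not in eng.index:
                continue
            x = base_x[cid]
            if relabel and g in known:
                x = x.copy()
                x[eng.index[g]] = 0.0
            feats = eng.features(x)
            train = [r for r in rows if r != g]
            y = np.array([gold.label_of(r) for r in train], dtype=int)
            if len(train) < 2 or len(np.unique(y)) < 2:
                logger.debug("loocv: network %d skipped for fold %r (single-class)", cid, g)
                continue
            model = fit_logistic(feats.loc[train].to_numpy(), y, network_id=cid, ridge=ridge)
            per_net[cid] = predict_prob(model, feats.loc[g].to_numpy())
        if per_net:
            out[g] = ensemble_max(per_net)
    return out


def evaluate_benchmark(
    gold_sets: list[GoldStandardSet],
    fused_nets: list[FusionResult],
    katz: KatzParams,
    ridge: float = DEFAULT_RIDGE,
    relabel: bool = True,
) -> EvaluationResult:
    """Mean LOOCV ROC-AUC over the gold-standard sets."""
    if not gold_sets:
        raise ValueError("no gold sets")
    aucs = []
    for gs in gold_sets:
        try:
            probs = loocv(gs, fused_nets, katz, ridge=ridge, relabel=relabel)
            truth = {g: gs.label_of(g) for g in probs}
            aucs.append(roc_auc(probs, truth).auc)
        except ValueError as exc:
            raise ValueError(f"gold set {gs.draw_index}: {exc}") from exc
    return EvaluationResult(mean_auc=float(np.mean(aucs)), per_set_auc=aucs)


def de_novo_rank(
    gold_sets: list[GoldStandardSet],
    fused_nets: list[FusionResult],
    katz: KatzParams,
    known: set[str] | None = None,
    top_n: int = 10,
    ridge: float = DEFAULT_RIDGE,
) -> list[tuple[str, float]]:
    """Rank unknown genes by their average ensemble probability.

    Unknown genes are all genes of any fused network minus the known
    disease genes.  For each gold set, per-network models are trained on
    the full 2m genes and the ensemble-max probability of every unknown
    gene is computed; probabilities are averaged over the sets
    (max-then-average), sorted descending with alphabetical tie-break.
    """
    if known is None:
        known = set(gold_sets[0].disease_genes)
    engines = {fr.cluster_id: FeatureEngine(fr.network, katz) for fr in fused_nets}
    feats = {}
    for cid, eng in engines.items():
        feats[cid] = eng.features(eng.label_vector(known))

    all_nodes = sorted(set().union(*(fr.network.nodes for fr in fused_nets)))
    unknown = [g for g in all_nodes if g not in known]

    sums: dict[str, float] = {g: 0.0 for g in unknown}
    counts: dict[str, int] = {g: 0 for g in unknown}
    for gs in gold_sets:
        per_gene: dict[str, dict[int, float]] = {g: {} for g in unknown}
        for cid, eng in engines.items():
            table = feats[cid]
            train = sorted(gs.genes & set(table.index))
            y = np.array([gs.label_of(r) for r in train], dtype=int)
            if len(train) < 2 or len(np.unique(y)) < 2:
                logger.debug("de_novo_rank: network %d skipped for set %d", cid, gs.draw_index)
                continue
            model = fit_logistic(table.loc[train].to_numpy(), y, network_id=cid, ridge=ridge)
            probs = expit(table.to_numpy() @ model.theta)
            for g, p in zip(table.index, probs):
                if g in per_gene:
                    per_gene[g][cid] = float(p)
        for g, pn in per_gene.items():
            if pn:
                sums[g] += ensemble_max(pn)
                counts[g] += 1
    avg = {g: sums[g] / counts[g] for g in unknown if counts[g]}
    ranked = sorted(avg.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_n]


def grid_search(
    case,
    control,
    static,
    cluster_of: dict[str, int],
    dgn,
    target_disease: str,
    known: set[str],
    lambdas: list[float],
    alphas: list[float],
    ks: list[int],
    epsilon: int = 3,
    eta: int = 5,
    n_sets: int = 50,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    relabel: bool = True,
) -> pd.DataFrame:
    """Full Cartesian sweep over (lambda, alpha, k).

    Fusion epsilon is held fixed.  A cell is flagged invalid (AUC NaN)
    when more than 10% of the known disease genes are missing from the
    fused networks at that lambda, or when the negative pool cannot
    supply m genes.
    """
    from .benchmark import draw_gold_sets, non_disease_pool
    from .sample_networks import build_fused_networks, coverage_check

    if not (lambdas and alphas and ks):
        raise ValueError("grids must be nonempty")
    rows = []
    for lam in lambdas:
        fused = build_fused_networks(case, control, static, cluster_of, lam, epsilon)
        frac, valid = coverage_check(fused, known)
        gold_sets = None
        note = ""
        if valid:
            pool = non_disease_pool(dgn, target_disease, fused, known, eta=eta)
            if len(pool) >= len(known):
                gold_sets = draw_gold_sets(known, pool, n_sets=n_sets, seed=seed)
            else:
                note = f"pool too small ({len(pool)} < {len(known)})"
        else:
            note = f"coverage {frac:.2f} below 0.90"
        for alpha in alphas:
            for k in ks:
                if gold_sets is None:
                    rows.append((lam, alpha, k, np.nan, False, note))
                    continue
                res = evaluate_benchmark(gold_sets, fused, KatzParams(alpha, k), ridge=ridge, relabel=relabel)
                rows.append((lam, alpha, k, res.mean_auc, True, ""))
    return pd.DataFrame(rows, columns=["lam", "alpha", "k", "mean_auc", "valid", "note"])
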