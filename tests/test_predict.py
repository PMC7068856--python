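import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import rankdata

from edgcsn.clustering import cluster_samples
from edgcsn.features import FeatureEngine, KatzParams
from edgcsn.io_formats import GeneNetwork
from edgcsn.predict import (
    LogisticModel,
    confusion_at,
    ensemble_max,
    fit_logistic,
    loocv,
    predict_prob,
    roc_auc,
)
from edgcsn.sample_networks import build_fused_networks, fuse


def mann_whitney_auc(scores, truth):
    """AUC as the normalized Mann-Whitney U statistic (rank oracle)."""
    genes = sorted(scores)
    s = np.array([scores[g] for g in genes])
    y = np.array([truth[g] for g in genes])
    ranks = rankdata(s)
    n1 = y.sum()
    n0 = len(y) - n1
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return u / (n1 * n0)


def oracle_penalized_fit(features, labels, ridge):
    """Direct minimization of the penalized binomial deviance; the
    independent route against sklearn's solver."""
    x = np.asarray(features, float)
    y = np.asarray(labels, float)

    def loss(theta):
        z = x @ theta
        return np.sum(np.logaddexp(0.0, -z * (2 * y - 1))) + 0.5 * ridge * np.sum(theta[1:] ** 2)

    res = minimize(loss, np.zeros(7), method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
    return res.x


class TestPredictProb:
    def test_zero_logit_is_half(self):
        model = LogisticModel(np.zeros(7))
        assert predict_prob(model, np.ones(7)) == 0.5

    def test_unit_intercept(self):
        theta = np.zeros(7)
        theta[0] = 1.0
        assert predict_prob(LogisticModel(theta), np.array([1, 0, 0, 0, 0, 0, 0.0])) == pytest.approx(
            np.exp(1) / (1 + np.exp(1))
        )

    def test_extreme_logits_stable(self):
        theta = np.zeros(7)
        theta[0] = 700.0
        p = predict_prob(LogisticModel(theta), np.array([1, 0, 0, 0, 0, 0, 0.0]))
        assert p == pytest.approx(1.0)
        theta[0] = -700.0
        assert predict_prob(LogisticModel(theta), np.array([1, 0, 0, 0, 0, 0, 0.0])) == pytest.approx(0.0)


class TestEnsembleMax:
    @pytest.mark.parametrize("probs, expected", [
        ({1: 0.3, 2: 0.9}, 0.9),
        ({1: 0.4}, 0.4),
        ({1: 0.5, 2: 0.5, 3: 0.5}, 0.5),
    ])
    def test_maximum(self, probs, expected):
        assert ensemble_max(probs) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no fused network"):
            ensemble_max({})


class TestFitLogistic:
    def test_separable_ordering(self):
        phi = np.ones((8, 7))
        phi[:, 2] = [3, 3.5, 4, 5, 0, 0.5, 1, 1.5]
        y = [1, 1, 1, 1, 0, 0, 0, 0]
        model = fit_logistic(phi, y)
        probs = [predict_prob(model, row) for row in phi]
        assert min(probs[:4]) > max(probs[4:])

    def test_uninformative_features_give_prevalence(self):
        phi = np.ones((10, 7))
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        model = fit_logistic(phi, y)
        assert predict_prob(model, phi[0]) == pytest.approx(0.3, abs=0.02)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.ones((4, 7)), [1, 1, 1, 1])

    def test_parameter_recovery_direction(self, rng):
        theta_true = np.array([0.5, 1.5, -2.0, 0.8, 0.0, -1.0, 2.5])
        phi = np.column_stack([np.ones(2000), rng.normal(size=(2000, 6))])
        p = 1 / (1 + np.exp(-phi @ theta_true))
        y = (rng.uniform(size=2000) < p).astype(int)
        model = fit_logistic(phi, y)
        a, b = model.theta[1:], theta_true[1:]
        cos = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        assert np.degrees(np.arccos(cos)) < 15.0

    def test_matches_direct_likelihood_optimization(self, rng):
        phi = np.column_stack([np.ones(30), rng.normal(size=(30, 6))])
        y = (rng.uniform(size=30) < 0.5).astype(int)
        y[:2] = [0, 1]
        ridge = 1e-2
        model = fit_logistic(phi, y, ridge=ridge)
        theta_oracle = oracle_penalized_fit(phi, y, ridge)
        probe = np.column_stack([np.ones(5), rng.normal(size=(5, 6))])
        for row in probe:
            assert predict_prob(model, row) == pytest.approx(
                1 / (1 + np.exp(-row @ theta_oracle)), abs=1e-4
            )


class TestRocAuc:
    def test_perfect_separation(self):
        scores = {"a": 0.9, "b": 0.8, "c": 0.2, "d": 0.1}
        truth = {"a": 1, "b": 1, "c": 0, "d": 0}
        assert roc_auc(scores, truth).auc == 1.0

    def test_eq10_confusion_arithmetic(self):
        # 4 positives, 6 negatives; at gamma=0.7: TP=3 FN=1 FP=2 TN=4
        scores = {"p1": 0.9, "p2": 0.8, "p3": 0.7, "p4": 0.3,
                  "n1": 0.75, "n2": 0.72, "n3": 0.2, "n4": 0.15, "n5": 0.1, "n6": 0.05}
        truth = {g: int(g.startswith("p")) for g in scores}
        c = confusion_at(scores, truth, 0.7)
        assert (c["TP"], c["FN"], c["FP"], c["TN"]) == (3, 1, 2, 4)
        assert c["TPR"] == pytest.approx(0.75)
        assert c["FPR"] == pytest.approx(1 / 3)
        # the ROC sweep passes through that point
        points = roc_auc(scores, truth).points
        assert any(f == pytest.approx(1 / 3) and t == pytest.approx(0.75) for f, t in points)

    def test_matches_mann_whitney_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 40))
            scores = {f"g{i}": float(rng.choice([0.1, 0.3, 0.5, 0.7, 0.9])) for i in range(n)}
            truth = {g: int(rng.integers(0, 2)) for g in scores}
            if len(set(truth.values())) < 2:
                truth["g0"] = 1 - truth["g1"] if "g1" in truth else 0
                truth["g1"] = 1 - truth["g0"]
            assert roc_auc(scores, truth).auc == pytest.approx(mann_whitney_auc(scores, truth))

    def test_invariant_under_monotone_transform(self, rng):
        scores = {f"g{i}": float(rng.uniform()) for i in range(30)}
        truth = {g: int(rng.integers(0, 2)) for g in scores}
        truth["g0"], truth["g1"] = 0, 1
        transformed = {g: float(np.exp(3 * s)) for g, s in scores.items()}
        assert roc_auc(scores, truth).auc == pytest.approx(roc_auc(transformed, truth).auc)

    def test_random_scores_near_half(self, rng):
        scores = {f"g{i}": float(rng.uniform()) for i in range(2000)}
        truth = {g: int(rng.integers(0, 2)) for g in scores}
        assert roc_auc(scores, truth).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            roc_auc({"a": 0.4, "b": 0.6}, {"a": 1, "b": 1})


class TestLoocv:
    def _square_gold(self):
        """One fused network (square A-B-C-D), gold = all four nodes."""
        from edgcsn.benchmark import GoldStandardSet

        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")],
                                     kind="single_sample")
        fused = [fuse([net], 1)]
        gold = GoldStandardSet(frozenset({"A", "B"}), frozenset({"C", "D"}), 1, 0)
        return gold, fused

    def test_every_gold_gene_gets_a_probability(self):
        gold, fused = self._square_gold()
        probs = loocv(gold, fused, KatzParams(0.1, 2))
        assert set(probs) == {"A", "B", "C", "D"}
        assert all(0.0 < p < 1.0 for p in probs.values())

    def test_gene_in_one_network_uses_it_alone(self, bundle):
        a = cluster_samples(bundle.case)
        fused = build_fused_networks(bundle.case, bundle.control, bundle.static,
                                     a.labels, bundle.lam, bundle.epsilon)
        probs = loocv(_gold(bundle), fused, bundle.katz)
        # A appears only in the cluster-1 network; its probability must
        # equal a fit/predict on that network alone (checked structurally
        # in the acceptance suite); here: a probability exists for A
        assert "A" in probs

    def test_relabel_off_reproduces_naive_variant(self):
        gold, fused = self._square_gold()
        on = loocv(gold, fused, KatzParams(0.1, 2), relabel=True)
        off = loocv(gold, fused, KatzParams(0.1, 2), relabel=False)
        assert set(on) == set(off)
        assert on != off  # relabeling changes neighbor features here


def _gold(bundle):
    from edgcsn.benchmark import GoldStandardSet

    return GoldStandardSet(bundle.disease_genes, bundle.non_disease_genes, 1, 0)


class TestGridSearch:
    @pytest.fixture(scope="class")
    def study(self):
        from edgcsn.benchmark import build_dgn
        from edgcsn.io_formats import preprocess, to_tpm
        from edgcsn.synthetic import SyntheticSpec, generate

        static, case_raw, ctrl_raw, truth = generate(SyntheticSpec(seed=0))
        case, control = preprocess(to_tpm(case_raw), to_tpm(ctrl_raw), static)
        assignment = cluster_samples(case)
        dgn = build_dgn(truth.catalog)
        return case, control, static, assignment.labels, dgn, truth

    def test_single_cell_matches_direct_evaluation(self, study):
        from edgcsn.benchmark import draw_gold_sets, non_disease_pool
        from edgcsn.predict import evaluate_benchmark, grid_search

        case, control, static, labels, dgn, truth = study
        known = truth.all_planted
        table = grid_search(case, control, static, labels, dgn, truth.target_disease,
                            known, lambdas=[1.1], alphas=[0.2], ks=[2],
                            n_sets=2, seed=0)
        assert len(table) == 1 and bool(table.loc[0, "valid"])
        fused = build_fused_networks(case, control, static, labels, 1.1, 3)
        pool = non_disease_pool(dgn, truth.target_disease, fused, known, eta=5)
        gold = draw_gold_sets(known, pool, n_sets=2, seed=0)
        direct = evaluate_benchmark(gold, fused, KatzParams(0.2, 2))
        assert table.loc[0, "mean_auc"] == pytest.approx(direct.mean_auc)

    def test_extreme_lambda_flagged_invalid(self, study):
        from edgcsn.predict import grid_search

        case, control, static, labels, dgn, truth = study
        table = grid_search(case, control, static, labels, dgn, truth.target_disease,
                            truth.all_planted, lambdas=[9.0], alphas=[0.2], ks=[1],
                            n_sets=2, seed=0)
        assert not bool(table.loc[0, "valid"])
        assert np.isnan(table.loc[0, "mean_auc"])


class TestDeNovoRank:
    def test_symmetric_unknowns_tie_break_alphabetically(self):
        from edgcsn.benchmark import GoldStandardSet
        from edgcsn.predict import de_novo_rank

        # square A-B-C-D: the automorphism swapping (A,B) and (C,D)
        # preserves labels, so C and D get identical probabilities
        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")],
                                     kind="single_sample")
        fused = [fuse([net], 1)]
        gold = GoldStandardSet(frozenset({"A", "B"}), frozenset({"C", "D"}), 1, 0)
        ranked = de_novo_rank([gold], fused, KatzParams(0.1, 2), known={"A", "B"})
        assert [g for g, _ in ranked] == ["C", "D"]
        assert ranked[0][1] == pytest.approx(ranked[1][1])

    def test_single_set_average_is_the_set_probability(self):
        from edgcsn.benchmark import GoldStandardSet
        from edgcsn.predict import de_novo_rank

        net = GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"),
                                      ("D", "E")], kind="single_sample")
        fused = [fuse([net], 1)]
        gold = GoldStandardSet(frozenset({"A", "B"}), frozenset({"C", "D"}), 1, 0)
        once = de_novo_rank([gold], fused, KatzParams(0.1, 2), known={"A", "B"})
        twice = de_novo_rank([gold, gold], fused, KatzParams(0.1, 2), known={"A", "B"})
        assert once == twice
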