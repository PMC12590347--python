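import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mastsig.de import DEGPartition, partition_degs
from mastsig.io import ValidationError
from mastsig.selection import (
    SelectionParams,
    clopper_pearson,
    cohen_kappa,
    derive_signatures,
    evaluate_classification,
    exact_binomial_ge,
    extract_signatures,
    fit_multinomial_elastic_net,
    fit_validation_network,
    multiclass_auc,
    standardize,
    stratified_split,
)


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "fraction,n_train,n_test", [(0.7, 15, 5), (0.5, 10, 10)]
    )
    def test_balanced_five_class_design(self, fraction, n_train, n_test):
        labels = np.repeat(list("abcde"), 4)
        tr, te = stratified_split(labels, fraction, seed=1)
        assert len(tr) == n_train and len(te) == n_test
        per_class = pd.Series(labels[te]).value_counts()
        assert (per_class == n_test // 5).all()
        assert not set(tr) & set(te)

    def test_full_fraction_rejected(self):
        with pytest.raises(ValidationError, match="no test"):
            stratified_split(np.repeat(list("ab"), 4), 1.0)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            stratified_split(np.array(["a", "a", "b"]), 0.5)

    def test_deterministic_under_seed(self):
        labels = np.repeat(list("abc"), 6)
        assert np.array_equal(
            stratified_split(labels, 0.7, seed=3)[0],
            stratified_split(labels, 0.7, seed=3)[0],
        )


class TestElasticNet:
    def _toy(self, seed=0, n_per=6, n_informative=3, n_noise=12):
        rng = np.random.default_rng(seed)
        classes = ["c1", "c2", "c3"]
        rows, labels = [], []
        for ci, c in enumerate(classes):
            for _ in range(n_per):
                x = rng.normal(0, 1, n_informative * len(classes) + n_noise)
                x[ci * n_informative : (ci + 1) * n_informative] += 4.0
                rows.append(x)
                labels.append(c)
        X = np.array(rows)
        names = [
            f"{c}_m{i}" for c in classes for i in range(n_informative)
        ] + [f"noise{i}" for i in range(n_noise)]
        return X, np.array(labels), names

    def test_huge_lambda_gives_intercept_only(self):
        X, y, names = self._toy()
        Xs, _, _ = standardize(X)
        coef = fit_multinomial_elastic_net(
            Xs, y, SelectionParams(lam=1e6), feature_names=names
        )
        assert (coef.abs() < 1e-8).all().all()

    def test_nonzero_coefficients_concentrate_on_markers(self):
        X, y, names = self._toy(seed=1)
        Xs, _, _ = standardize(X)
        coef = fit_multinomial_elastic_net(
            Xs, y, SelectionParams(lam=0.05), feature_names=names
        )
        selected = [g for g in names if coef[g].abs().max() > 1e-8]
        markers = [g for g in names if not g.startswith("noise")]
        precision = len(set(selected) & set(markers)) / len(selected)
        assert precision >= 0.8

    def test_zero_variance_gene_dropped_with_warning(self):
        X, y, names = self._toy()
        X[:, 5] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            coef = fit_multinomial_elastic_net(
                X, y, SelectionParams(lam=0.05), feature_names=names
            )
        assert (coef[names[5]] == 0).all()


class TestExtractSignatures:
    def _partition(self):
        return DEGPartition(
            unique={"IFNG": ["g1", "g2"], "IL33": ["g3"]},
            shared=[], core=[], shared_fraction=0.0,
        )

    def test_gene_class_from_exclusivity(self):
        coef = pd.DataFrame(
            [[0.5, 0.0, 0.2], [0.0, 0.0, -0.3]],
            index=["IFNG", "IL33"], columns=["g1", "g2", "g3"],
        )
        sigs = extract_signatures(coef, self._partition())
        assert sigs.sets == {"IFNG": ["g1"], "IL33": ["g3"]}

    def test_all_zero_coefficients_give_empty(self):
        coef = pd.DataFrame(0.0, index=["IFNG"], columns=["g1", "g3"])
        sigs = extract_signatures(coef, self._partition())
        assert len(sigs.sets) == 0

    def test_drop_classes_removed(self):
        coef = pd.DataFrame(
            [[0.5, 0.1, 0.2]], index=["x"], columns=["g1", "g2", "g3"]
        )
        sigs = extract_signatures(coef, self._partition(), drop_classes={"IFNG"})
        assert list(sigs.sets) == ["IL33"]

    def test_ambiguous_class_rejected(self):
        part = DEGPartition(
            unique={"A": ["g1"], "B": ["g1"]}, shared=[], core=[],
            shared_fraction=0.0,
        )
        coef = pd.DataFrame([[1.0]], index=["A"], columns=["g1"])
        with pytest.raises(ValidationError):
            extract_signatures(coef, part)


class TestExactStatistics:
    def test_clopper_pearson_beta_quantile_oracle(self):
        lo, hi = clopper_pearson(9, 10, 0.95)
        assert lo == pytest.approx(stats.beta.ppf(0.025, 9, 2))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 10, 1))

    def test_boundaries(self):
        assert clopper_pearson(0, 7, 0.95)[0] == 0.0
        assert clopper_pearson(7, 7, 0.95)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(0, 5), (3, 9), (10, 10), (7, 20)])
    def test_interval_contains_point_estimate(self, k, n):
        lo, hi = clopper_pearson(k, n, 0.95)
        assert lo <= k / n <= hi

    def test_width_shrinks_with_n(self):
        widths = [np.diff(clopper_pearson(k, n, 0.95))[0]
                  for k, n in [(4, 5), (40, 50), (400, 500)]]
        assert widths[0] > widths[1] > widths[2]

    def test_binomial_tail_matches_direct_summation(self):
        for n in [5, 12, 30]:
            for k in [0, 1, n // 2, n]:
                direct = sum(
                    stats.binom.pmf(i, n, 0.2) for i in range(k, n + 1)
                )
                assert exact_binomial_ge(k, n, 0.2) == pytest.approx(direct)

    def test_zero_successes_tail_is_one(self):
        assert exact_binomial_ge(0, 13, 0.37) == pytest.approx(1.0)


class TestKappa:
    def test_identity_confusion_is_one(self):
        assert cohen_kappa(np.eye(4) * 3) == pytest.approx(1.0)

    def test_single_predicted_class_on_balanced_truth_is_zero(self):
        m = np.zeros((5, 5))
        m[:, 0] = 2
        assert cohen_kappa(m) == pytest.approx(0.0)

    def test_invariant_under_class_permutation(self):
        rng = np.random.default_rng(0)
        m = rng.integers(0, 10, (4, 4))
        perm = rng.permutation(4)
        assert cohen_kappa(m[np.ix_(perm, perm)]) == pytest.approx(cohen_kappa(m))

    def test_degenerate_margins_reported_nan(self):
        m = np.zeros((2, 2))
        m[0, 0] = 5  # pe = 1
        assert np.isnan(cohen_kappa(m))


class TestMulticlassAUC:
    def test_perfect_ordering_gives_one(self):
        truth = ["a"] * 3 + ["b"] * 3
        scores = pd.DataFrame(
            {"a": [0.9, 0.8, 0.7, 0.2, 0.1, 0.0],
             "b": [0.1, 0.2, 0.3, 0.8, 0.9, 1.0]}
        )
        pair, m, ova = multiclass_auc(scores, truth)
        assert m == pytest.approx(1.0)
        assert (ova == 1.0).all()

    def test_constant_scores_give_half(self):
        truth = ["a", "a", "b", "b", "c", "c"]
        scores = pd.DataFrame(0.5, index=range(6), columns=["a", "b", "c"])
        _, m, ova = multiclass_auc(scores, truth)
        assert m == pytest.approx(0.5)
        assert np.allclose(ova, 0.5)

    def test_two_class_equals_standard_auc(self):
        rng = np.random.default_rng(2)
        truth = np.array(["a"] * 6 + ["b"] * 6)
        pa = rng.random(12)
        scores = pd.DataFrame({"a": pa, "b": 1 - pa})
        _, m, ova = multiclass_auc(scores, truth)
        # brute-force two-class AUC with half-ties
        pos, neg = pa[:6], pa[6:]
        brute = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos for q in neg
        ])
        assert m == pytest.approx(brute)
        assert ova["a"] == pytest.approx(brute)

    def test_matches_pairwise_rank_enumeration(self):
        """Random 3-class instance agrees with explicit pair enumeration."""
        rng = np.random.default_rng(7)
        truth = np.array(["a", "b", "c"] * 4)
        scores = pd.DataFrame(
            rng.random((12, 3)), columns=["a", "b", "c"]
        )
        pair, m, _ = multiclass_auc(scores, truth)

        def a_given_b(ci, cj):
            si = scores.loc[truth == ci, ci].to_numpy()
            sj = scores.loc[truth == cj, ci].to_numpy()
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in si for q in sj
            )
            return wins / (len(si) * len(sj))

        expected = []
        for ci, cj in itertools.combinations(["a", "b", "c"], 2):
            expected.append(0.5 * (a_given_b(ci, cj) + a_given_b(cj, ci)))
        assert m == pytest.approx(np.mean(expected))

    def test_absent_class_gets_nan(self):
        truth = ["a", "a", "b", "b"]
        scores = pd.DataFrame(
            np.random.default_rng(0).random((4, 3)), columns=["a", "b", "c"]
        )
        _, _, ova = multiclass_auc(scores, truth)
        assert np.isnan(ova["c"])


class TestEvaluateClassification:
    def test_all_wrong(self):
        ev = evaluate_classification(["b"] * 4, ["a"] * 2 + ["c"] * 2)
        assert ev.accuracy == 0.0
        assert (ev.sensitivity[["a", "c"]] == 0).all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            evaluate_classification([], [])

    def test_nir_is_max_class_share(self):
        ev = evaluate_classification(
            ["a", "a", "a", "b"], ["a", "a", "a", "b"]
        )
        assert ev.nir == pytest.approx(0.75)


class TestValidationNetwork:
    def _separable(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (5, 2)), rng.normal(3, 0.3, (5, 2))])
        y = np.array(["lo"] * 5 + ["hi"] * 5)
        return X, y

    def test_linearly_separable_toy_perfect(self):
        X, y = self._separable()
        proba = fit_validation_network(X, y, X, seed=0)
        preds = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
        assert (preds == y).all()

    def test_seed_determinism(self):
        X, y = self._separable()
        a = fit_validation_network(X, y, X, seed=5)
        b = fit_validation_network(X, y, X, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_shuffled_labels_near_nir(self):
        """Permutation control: accuracy close to chance on shuffled labels."""
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (40, 4))
        accs = []
        for seed in range(5):
            y = rng.permutation(np.array(["a", "b"] * 20))
            proba = fit_validation_network(X[:30], y[:30], X[30:], seed=seed)
            preds = proba.columns[np.argmax(proba.to_numpy(), axis=1)]
            accs.append((preds == y[30:]).mean())
        assert abs(np.mean(accs) - 0.5) < 0.25


def test_signature_subset_of_truth_on_planted_bulk(small_bulk):
    """Selected per-class signatures are nearly all planted truth genes."""
    from mastsig.de import de_all_contrasts, significant_genes

    cm, truth = small_bulk
    part = partition_degs(significant_genes(de_all_contrasts(cm)))
    sigs, ev, _ = derive_signatures(cm, part, SelectionParams(seed=0))
    for cond, genes in sigs.sets.items():
        ts = set(truth.unique_degs[cond])
        assert len(set(genes) & ts) / len(genes) >= 0.7
    assert ev.accuracy >= 0.6  # 5 balanced classes, NIR 0.2
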