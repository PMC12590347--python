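"""Minimal-signature selection and classifier evaluation.

Condition-unique DEGs are fed to a multinomial elastic net (mixing alpha,
penalty lambda, the glmnet parameterization); a gene enters the minimal
signature of its exclusivity class when any of its class coefficients is
nonzero.  The resulting signatures are evaluated with the standard
multi-class statistics: accuracy with an exact Clopper-Pearson interval,
Cohen's kappa, the exact binomial test of accuracy against the
no-information rate, per-class sensitivity/specificity, and multiclass
AUC (Hand-Till M plus one-vs-all).  A small feed-forward network provides
an independent validation classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier

from .de import DEGPartition, bh_adjust  # noqa: F401  (bh re-exported for CLI-style use)
from .io import SignatureSet, ValidationError

_NONZERO = 1e-8


@dataclass
class SelectionParams:
    """Elastic-net selection settings (glmnet parameterization).

    ``alpha`` mixes L1 and L2 (1 = lasso); ``lam`` is the penalty strength
    in the glmnet objective (1/n) * NLL + lam * [(1-alpha)/2 ||b||_2^2 +
    alpha ||b||_1].  The default lam is the optimized value used to derive
    the published minimal signatures.
    """

    alpha: float = 0.5
    lam: float = 0.007976564
    train_fraction: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValidationError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction must be in (0, 1)")


def stratified_split(
    labels, train_fraction: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split: ceil(fraction * n_c) samples to train, rest to test."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise ValidationError(f"class {cls!r} has fewer than 2 members")
        n_train = int(np.ceil(train_fraction * idx.size))
        if n_train >= idx.size:
            raise ValidationError(
                f"train_fraction {train_fraction} leaves no test samples for {cls!r}"
            )
        perm = rng.permutation(idx)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def standardize(
    X: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature standardization; statistics from the training split only.

    Zero-variance features get sd 1 (their standardized values are 0).
    """
    X = np.asarray(X, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mean) / sd, mean, sd


def fit_multinomial_elastic_net(
    X: np.ndarray, labels, params: SelectionParams, feature_names=None
) -> pd.DataFrame:
    """Multinomial elastic net; returns a classes x genes coefficient frame.

    ``X`` must already be standardized per gene on the training split.
    The glmnet penalty (lam, alpha) maps onto scikit-learn's saga solver
    via C = 1 / (n_samples * lam).
    """
    params.validate()
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("need >= 2 classes")
    zero_var = X.std(axis=0) < 1e-12
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance genes dropped")
    n = X.shape[0]
    if params.lam == 0:
        model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    else:
        model = LogisticRegression(
            solver="saga",
            l1_ratio=params.alpha,
            C=1.0 / (n * params.lam),
            max_iter=20000,
            tol=1e-7,
            random_state=params.seed,
        )
    keep = ~zero_var
    model.fit(X[:, keep], labels)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    coef = pd.DataFrame(0.0, index=model.classes_, columns=feature_names)
    coef.loc[:, np.asarray(feature_names)[keep]] = model.coef_
    coef.attrs["intercept"] = dict(zip(model.classes_, model.intercept_))
    return coef


def extract_signatures(
    coef: pd.DataFrame,
    partition: DEGPartition,
    drop_classes: set[str] | None = None,
    threshold: float = _NONZERO,
) -> SignatureSet:
    """Build per-class minimal signatures from elastic-net coefficients.

    Class membership of a gene comes from DEG exclusivity (the partition's
    unique lists), not from which class's coefficient survived: the
    elastic net only decides whether a gene is kept (any |coefficient|
    above ``threshold``).  ``drop_classes`` removes classes (e.g. the
    unstimulated reference) after selection.
    """
    gene_class: dict[str, str] = {}
    for cls, genes in partition.unique.items():
        for g in genes:
            if g in gene_class:
                raise ValidationError(f"gene {g!r} in multiple unique lists")
            gene_class[g] = cls
    missing = [g for g in coef.columns if g not in gene_class]
    if missing:
        raise ValidationError(
            f"{len(missing)} genes lack an exclusivity class (e.g. {missing[:3]})"
        )
    sets: dict[str, list[str]] = {}
    prov: dict[str, dict[str, float]] = {}
    for g in coef.columns:
        mag = float(coef[g].abs().max())
        if mag > threshold:
            cls = gene_class[g]
            sets.setdefault(cls, []).append(g)
            prov.setdefault(cls, {})[g] = mag
    if drop_classes:
        for cls in drop_classes:
            sets.pop(cls, None)
            prov.pop(cls, None)
    return SignatureSet(
        sets, {c: "elastic-net minimal signature" for c in sets}, prov
    )


def derive_signatures(
    cm,
    partition: DEGPartition,
    params: SelectionParams | None = None,
    condition_col: str = "condition",
    drop_classes: set[str] | None = None,
):
    """End-to-end minimal-signature derivation from counts and a DEG partition.

    Restricts the matrix to condition-unique DEGs, log2-transforms
    median-of-ratios normalized counts, splits samples stratified by
    condition, standardizes with training statistics, fits the
    multinomial elastic net on the training split and extracts per-class
    signatures.  Returns (SignatureSet, ClassifierEval on the test split,
    coefficient frame).
    """
    from .de import median_of_ratios

    params = params or SelectionParams()
    genes = [g for lst in partition.unique.values() for g in lst]
    sub = cm.subset_genes(genes)
    sf = median_of_ratios(cm)
    norm = np.log2(sub.counts / sf[None, :] + 1.0)
    X = norm.T  # samples x genes
    labels = cm.meta[condition_col].astype(str).to_numpy()
    train, test = stratified_split(labels, params.train_fraction, params.seed)
    Xtr, mean, sd = standardize(X[train])
    Xte, _, _ = standardize(X[test], mean, sd)
    coef = fit_multinomial_elastic_net(
        Xtr, labels[train], params, feature_names=sub.gene_ids
    )
    signatures = extract_signatures(coef, partition, drop_classes=drop_classes)
    model_classes = list(coef.index)
    # linear predictor on the test split for evaluation
    intercepts = np.array([coef.attrs["intercept"][c] for c in model_classes])
    logits = Xte @ coef.to_numpy().T + intercepts
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    preds = np.asarray(model_classes)[np.argmax(probs, axis=1)]
    evaluation = evaluate_classification(
        preds, labels[test], scores=pd.DataFrame(probs, columns=model_classes)
    )
    return signatures, evaluation, coef


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval via beta quantiles."""
    if n <= 0:
        raise ValidationError("n must be positive")
    if not (0 <= k <= n):
        raise ValidationError("need 0 <= k <= n")
    if not (0.0 < conf < 1.0):
        raise ValidationError("conf must be in (0, 1)")
    tail = (1.0 - conf) / 2.0
    lo = 0.0 if k == 0 else float(stats.beta.ppf(tail, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - tail, k + 1, n - k))
    return lo, hi


def exact_binomial_ge(k: int, n: int, p0: float) -> float:
    """Exact upper-tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValidationError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValidationError("p0 must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p0))


def cohen_kappa(confusion: np.ndarray | pd.DataFrame) -> float:
    """Cohen's kappa from a square confusion matrix (rows true, cols predicted)."""
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("confusion matrix must be square")
    total = m.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    po = np.trace(m) / total
    pe = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / total**2
    if abs(1.0 - pe) < 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def _rank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC of pos vs neg scores; ties count one half."""
    scores = np.concatenate([pos, neg])
    ranks = stats.rankdata(scores)
    r_pos = ranks[: len(pos)].sum()
    n1, n2 = len(pos), len(neg)
    return (r_pos - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def multiclass_auc(
    scores: pd.DataFrame, truth
) -> tuple[pd.DataFrame, float, pd.Series]:
    """Hand-Till multiclass AUC from per-class probability scores.

    Returns (pairwise matrix A(i,j), Hand-Till M, one-vs-all AUC per
    class).  A(i,j) = [A(i|j) + A(j|i)] / 2 where A(i|j) is the
    probability that a class-i sample outranks a class-j sample on the
    class-i score; M averages A(i,j) over unordered pairs.  One-vs-all is
    the ordinary AUC of the class score against all other samples; a class
    absent from the truth gets NaN.
    """
    truth = np.asarray(truth)
    classes = list(scores.columns)
    present = [c for c in classes if (truth == c).any()]
    if len(present) < 2:
        raise ValidationError("need >= 2 classes present in truth")
    pair = pd.DataFrame(np.nan, index=classes, columns=classes)
    vals = []
    for a_i in range(len(present)):
        for b_i in range(a_i + 1, len(present)):
            a, b = present[a_i], present[b_i]
            sa = scores.loc[truth == a]
            sb = scores.loc[truth == b]
            a_given_b = _rank_auc(sa[a].to_numpy(), sb[a].to_numpy())
            b_given_a = _rank_auc(sb[b].to_numpy(), sa[b].to_numpy())
            m = 0.5 * (a_given_b + b_given_a)
            pair.loc[a, b] = pair.loc[b, a] = m
            vals.append(m)
    hand_till = float(np.mean(vals))
    ova = {}
    for c in classes:
        mask = truth == c
        if not mask.any():
            ova[c] = np.nan
            continue
        ova[c] = _rank_auc(scores.loc[mask, c].to_numpy(), scores.loc[~mask, c].to_numpy())
    return pair, hand_till, pd.Series(ova, name="auc_one_vs_all")


@dataclass
class ClassifierEval:
    """Multi-class evaluation summary."""

    confusion: pd.DataFrame
    accuracy: float
    kappa: float
    ci: tuple[float, float]
    nir: float
    p_acc_gt_nir: float
    sensitivity: pd.Series = field(default_factory=pd.Series)
    specificity: pd.Series = field(default_factory=pd.Series)
    pairwise_auc: pd.DataFrame | None = None
    multiclass_auc: float | None = None
    one_vs_all_auc: pd.Series | None = None


def evaluate_classification(
    predictions, truth, conf: float = 0.95, scores: pd.DataFrame | None = None
) -> ClassifierEval:
    """Confusion matrix, accuracy/kappa/CI, NIR binomial p, per-class rates.

    ``scores`` (samples x classes probabilities) additionally fills the
    AUC fields.  The no-information rate is the largest class frequency in
    the truth of the evaluation set; p_acc_gt_nir is the exact binomial
    upper tail of the correct count at that rate.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValidationError("predictions and truth must be equal-length, non-empty")
    classes = sorted(set(truth) | set(predictions))
    conf_mat = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(truth, predictions):
        conf_mat.loc[t, p] += 1
    n = len(truth)
    correct = int((predictions == truth).sum())
    acc = correct / n
    nir = max((truth == c).mean() for c in classes)
    sens, spec = {}, {}
    for c in classes:
        tp = conf_mat.loc[c, c]
        fn = conf_mat.loc[c].sum() - tp
        fp = conf_mat[c].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = tp / (tp + fn) if (tp + fn) > 0 else np.nan
        spec[c] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    ev = ClassifierEval(
        confusion=conf_mat,
        accuracy=acc,
        kappa=cohen_kappa(conf_mat),
        ci=clopper_pearson(correct, n, conf),
        nir=float(nir),
        p_acc_gt_nir=exact_binomial_ge(correct, n, float(nir)),
        sensitivity=pd.Series(sens, name="sensitivity"),
        specificity=pd.Series(spec, name="specificity"),
    )
    if scores is not None:
        pair, m, ova = multiclass_auc(scores, truth)
        ev.pairwise_auc, ev.multiclass_auc, ev.one_vs_all_auc = pair, m, ova
    return ev


def fit_validation_network(
    X_train: np.ndarray,
    labels_train,
    X_test: np.ndarray,
    hidden: tuple[int, ...] = (8,),
    seed: int = 0,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Small feed-forward softmax classifier used as an independent check.

    One hidden layer of 8 logistic units by default; both matrices must be
    standardized with training-split statistics.  Returns test-set class
    probabilities (samples x classes); warns on non-convergence with the
    final loss.
    """
    net = MLPClassifier(
        hidden_layer_sizes=hidden,
        activation="logistic",
        solver="lbfgs",
        max_iter=max_iter,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(np.asarray(X_train, float), np.asarray(labels_train))
    if net.n_iter_ >= max_iter:
        warnings.warn(f"network did not converge; final loss {net.loss_:.4g}")
    proba = net.predict_proba(np.asarray(X_test, float))
    return pd.DataFrame(proba, columns=net.classes_)
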