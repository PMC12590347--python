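"""Negative-binomial differential expression and DEG partitioning.

The model follows the standard bulk RNA-seq workflow: median-of-ratios
size factors, per-gene NB generalized linear models with a log link and
log-size-factor offsets, gene-wise dispersions shrunk toward a fitted
mean-dispersion trend, Wald tests on the condition coefficient and
Benjamini-Hochberg adjustment.  Dispersion estimation is a simplified
analogue of the DESeq2 machinery: Cox-Reid-adjusted gene-wise maximum
likelihood, a log-linear trend versus mean expression, and
precision-weighted shrinkage of log-dispersion toward that trend.  Wald
statistics are referred to a t distribution with the design's residual
degrees of freedom, a small-sample correction for the estimated
dispersion.

Significant genes per cytokine contrast are then partitioned into
condition-unique and shared sets (the Venn partition feeding signature
selection downstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .io import CountMatrix, ValidationError

_MIN_DISP = 1e-8
_MAX_DISP = 10.0


def median_of_ratios(cm: CountMatrix | np.ndarray | pd.DataFrame) -> np.ndarray:
    """Median-of-ratios size factors.

    The per-gene reference is the geometric mean of that gene across
    samples, restricted to genes positive in every sample; a sample's size
    factor is the median over those genes of count / reference.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else np.asarray(cm)
    if counts.shape[1] < 2:
        raise ValidationError("median-of-ratios needs >= 2 samples")
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError(
            "no gene has positive counts in every sample; consider a "
            "pseudo-reference (e.g. positive-mean genes) before normalization"
        )
    sub = counts[all_pos].astype(float)
    log_ref = np.mean(np.log(sub), axis=1)
    ratios = np.log(sub) - log_ref[:, None]
    return np.exp(np.median(ratios, axis=0))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    NaN entries are excluded from the family (returned as NaN) and do not
    count toward the number of tests.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if ((pv < 0) | (pv > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


@dataclass
class DispersionFit:
    """Gene-wise, trend and shrunken NB dispersions."""

    raw: np.ndarray
    trend: np.ndarray
    shrunken: np.ndarray
    trend_coef: tuple[float, float]  # (a0, a1): log alpha = a0 + a1 log mu
    prior_var: float


def _design_matrix(meta: pd.DataFrame, condition_col: str, reference: str,
                   donor_col: str | None) -> tuple[np.ndarray, list[str]]:
    cond = meta[condition_col].astype(str)
    levels = [reference] + sorted(set(cond) - {reference})
    cols = [np.ones(len(meta))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append((cond == lv).to_numpy(float))
        names.append(f"{condition_col}_{lv}")
    if donor_col is not None:
        donors = sorted(meta[donor_col].astype(str).unique())
        for d in donors[1:]:
            cols.append((meta[donor_col].astype(str) == d).to_numpy(float))
            names.append(f"{donor_col}_{d}")
    return np.column_stack(cols), names


def _cr_mle_dispersion(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha_init: float = 0.1
) -> float:
    """Cox-Reid-adjusted profile MLE of the NB dispersion for one gene.

    Alternates a mean fit at the current dispersion with a bounded 1-D
    maximization of the CR-penalized log-likelihood over log-dispersion;
    the CR term -0.5 log det(X'WX) corrects the downward bias of the
    plain profile MLE at small sample sizes.
    """
    alpha = alpha_init
    for _ in range(2):
        beta, _, _ = _fit_nb_glm(y, X, offset, alpha)
        mu = np.maximum(np.exp(np.clip(X @ beta + offset, -30, 30)), 1e-8)

        def neg_apl(log_a: float) -> float:
            a = np.exp(log_a)
            r = 1.0 / a
            ll = float(
                (
                    special.gammaln(y + r)
                    - special.gammaln(r)
                    + y * np.log(a * mu / (1.0 + a * mu))
                    - r * np.log1p(a * mu)
                ).sum()
            )
            w = mu / (1.0 + a * mu)
            _, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            return -(ll - 0.5 * logdet)

        res = optimize.minimize_scalar(
            neg_apl,
            bounds=(np.log(_MIN_DISP), np.log(_MAX_DISP)),
            method="bounded",
            options={"xatol": 1e-4},
        )
        alpha = float(np.exp(res.x))
    return alpha


def estimate_dispersions(
    counts: np.ndarray,
    size_factors: np.ndarray,
    design: np.ndarray | pd.Series,
) -> DispersionFit:
    """Gene-wise CR-adjusted MLE dispersions with trend fitting and shrinkage.

    Per gene, the dispersion is the Cox-Reid-adjusted profile maximum
    likelihood estimate under the full design matrix (so covariate
    structure such as paired donors does not inflate it).  The trend is a
    least-squares line in log-log space versus mean normalized
    expression; per-gene log-dispersions are then shrunk toward the trend
    with weight prior_var / (prior_var + sampling_var), where
    sampling_var ~ trigamma(df/2) approximates the spread of a log
    variance-type estimate at df residual degrees of freedom and
    prior_var is the excess spread of residuals around the trend.

    ``design`` may also be a per-sample factor, which is expanded into a
    one-way design matrix.
    """
    if not isinstance(design, np.ndarray) or design.ndim == 1:
        groups = np.asarray(design)
        levels = list(np.unique(groups))
        design = np.column_stack(
            [np.ones(len(groups))] + [(groups == lv).astype(float) for lv in levels[1:]]
        )
    n, p = design.shape
    df = n - p
    if df < 1:
        raise ValidationError("no residual degrees of freedom for dispersion")

    q = counts / size_factors[None, :]
    mu = q.mean(axis=1)
    offset = np.log(size_factors)
    raw = np.full(counts.shape[0], _MIN_DISP)
    for g in range(counts.shape[0]):
        if counts[g].sum() == 0:
            continue
        raw[g] = _cr_mle_dispersion(counts[g], design, offset)
    raw = np.where(np.isfinite(raw), raw, _MIN_DISP)
    raw = np.clip(raw, _MIN_DISP, _MAX_DISP)

    # trend on informative genes (expressed, estimate above the floor)
    ok = (mu > 1.0) & (raw > 10 * _MIN_DISP)
    if ok.sum() >= 10:
        x = np.log(mu[ok])
        y = np.log(raw[ok])
        a1, a0 = np.polyfit(x, y, 1)
    else:  # pragma: no cover - degenerate tiny inputs
        a0, a1 = np.log(max(np.median(raw), _MIN_DISP)), 0.0
    with np.errstate(divide="ignore"):
        log_trend = a0 + a1 * np.log(np.maximum(mu, 1e-8))
    trend = np.clip(np.exp(log_trend), _MIN_DISP, _MAX_DISP)

    samp_var = float(special.polygamma(1, df / 2.0))
    resid = np.log(raw[ok]) - np.log(trend[ok]) if ok.any() else np.zeros(1)
    prior_var = max(float(np.var(resid)) - samp_var, 0.05)
    w = prior_var / (prior_var + samp_var)
    log_shrunk = np.log(trend) + w * (np.log(np.maximum(raw, _MIN_DISP)) - np.log(trend))
    shrunken = np.clip(np.exp(log_shrunk), _MIN_DISP, _MAX_DISP)
    return DispersionFit(raw, trend, shrunken, (float(a0), float(a1)), prior_var)


def _fit_nb_glm(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
    max_iter: int = 50, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS fit of an NB GLM with log link and fixed dispersion.

    Returns (beta, covariance, converged).  Weights are mu/(1+alpha*mu),
    the inverse variance of the working response.
    """
    n, p = X.shape
    beta = np.zeros(p)
    mean_rate = max(np.mean(y / np.exp(offset)), 1e-8)
    beta[0] = np.log(mean_rate)
    ridge = 1e-6
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        WX = X * w[:, None]
        A = X.T @ WX + ridge * np.eye(p)
        b = WX.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:  # pragma: no cover
            return beta, np.full((p, p), np.nan), False
        if np.max(np.abs(beta_new - beta)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = X.T @ (X * w[:, None]) + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:  # pragma: no cover
        cov = np.full((p, p), np.nan)
    return beta, cov, converged


def nb_wald_test(
    cm: CountMatrix,
    contrast: tuple[str, str],
    condition_col: str = "condition",
    donor_col: str | None = "donor",
    size_factors: np.ndarray | None = None,
    dispersions: DispersionFit | None = None,
) -> pd.DataFrame:
    """Wald test of ``contrast = (condition, reference)`` per gene.

    The GLM is fit on all samples with the full condition factor (plus the
    donor covariate when ``donor_col`` is given and present, the paired
    design default); dispersions are estimated from the full design.
    Returns a frame indexed by gene with columns baseMean, log2FC, lfcSE,
    stat, pvalue, padj; all-zero and non-converged genes carry NaN
    statistics and are excluded from the BH family.
    """
    cond, ref = contrast
    levels = set(cm.meta[condition_col].astype(str))
    for lv in (cond, ref):
        if lv not in levels:
            raise ValidationError(f"condition {lv!r} not present in metadata")
    counts_per_level = cm.meta[condition_col].value_counts()
    if (counts_per_level.loc[[cond, ref]] < 2).any():
        raise ValidationError("need >= 2 samples per contrast level")
    if donor_col is not None and donor_col not in cm.meta.columns:
        donor_col = None

    counts = cm.counts.astype(float)
    if size_factors is None:
        size_factors = median_of_ratios(cm)
    X, names = _design_matrix(cm.meta, condition_col, ref, donor_col)
    if dispersions is None:
        dispersions = estimate_dispersions(counts, size_factors, X)
    coef_idx = names.index(f"{condition_col}_{cond}")
    offset = np.log(size_factors)
    df_resid = X.shape[0] - X.shape[1]

    n_genes = cm.n_genes
    base_mean = (counts / size_factors[None, :]).mean(axis=1)
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    stat = np.full(n_genes, np.nan)
    pval = np.full(n_genes, np.nan)
    ln2 = np.log(2.0)
    for g in range(n_genes):
        y = counts[g]
        if y.sum() == 0:
            continue
        beta, cov, ok = _fit_nb_glm(y, X, offset, float(dispersions.shrunken[g]))
        if not ok or not np.isfinite(cov[coef_idx, coef_idx]) or cov[coef_idx, coef_idx] <= 0:
            continue
        b = beta[coef_idx]
        s = np.sqrt(cov[coef_idx, coef_idx])
        log2fc[g] = b / ln2
        se[g] = s / ln2
        stat[g] = b / s
        pval[g] = 2.0 * stats.t.sf(np.abs(stat[g]), df_resid)
    padj = bh_adjust(pval)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
        },
        index=pd.Index(cm.gene_ids, name="gene"),
    )


def de_all_contrasts(
    cm: CountMatrix,
    reference: str = "unstim",
    condition_col: str = "condition",
    donor_col: str | None = "donor",
) -> dict[str, pd.DataFrame]:
    """Run nb_wald_test of every non-reference condition against the reference."""
    size_factors = median_of_ratios(cm)
    X, _ = _design_matrix(cm.meta, condition_col, reference, donor_col)
    disp = estimate_dispersions(cm.counts.astype(float), size_factors, X)
    out = {}
    for cond in sorted(set(cm.meta[condition_col].astype(str)) - {reference}):
        out[cond] = nb_wald_test(
            cm, (cond, reference), condition_col, donor_col, size_factors, disp
        )
    return out


@dataclass
class DEGPartition:
    """Venn partition of per-condition DEG lists.

    ``unique`` holds genes significant in exactly one condition, ``shared``
    in at least two, ``core`` in all; ``shared_fraction`` is
    |shared| / |union of all DEGs|.
    """

    unique: dict[str, list[str]]
    shared: list[str]
    core: list[str]
    shared_fraction: float
    multiplicity: dict[str, int] = field(default_factory=dict)

    @property
    def all_genes(self) -> list[str]:
        out = set(self.shared)
        for lst in self.unique.values():
            out.update(lst)
        return sorted(out)


def partition_degs(deg_lists: dict[str, list[str]]) -> DEGPartition:
    """Partition per-condition significant gene lists into unique/shared/core."""
    if len(deg_lists) < 2:
        raise ValidationError("need DEG lists for >= 2 conditions")
    count: dict[str, int] = {}
    for genes in deg_lists.values():
        for g in set(genes):
            count[g] = count.get(g, 0) + 1
    if not count:
        warnings.warn("all DEG lists empty; returning an empty partition")
        return DEGPartition({c: [] for c in deg_lists}, [], [], 0.0, {})
    unique = {
        c: sorted(g for g in set(genes) if count[g] == 1)
        for c, genes in deg_lists.items()
    }
    shared = sorted(g for g, k in count.items() if k >= 2)
    core = sorted(g for g, k in count.items() if k == len(deg_lists))
    frac = len(shared) / len(count)
    return DEGPartition(unique, shared, core, frac, count)


def significant_genes(
    results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Extract per-condition FDR-significant gene lists from DE tables."""
    return {
        c: sorted(tab.index[tab["padj"] < alpha].tolist())
        for c, tab in results.items()
    }
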