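"""Per-cell signature scoring, cluster summaries and marker/contrast tests.

Cells are log-normalized with the single-cell convention
``ln(1 + count / total * scale)`` (natural log, scale 10^4); a cell's
signature score is the mean log-normalized expression of the signature's
genes.  Cluster markers use the Wilcoxon rank-sum test (one cluster vs
the rest), and disease-vs-healthy score differences use Welch t-tests
with BH correction across the whole signature x disease grid.  Because
scores are means of logged expression, the reported "logFC" of a score
contrast is the difference of group means.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust
from .io import CountMatrix, SignatureSet, ValidationError


def lognormalize_cells(cm: CountMatrix, scale: float = 1e4) -> pd.DataFrame:
    """ln(1 + count / cell_total * scale); zero-total cells are dropped."""
    df = cm.to_frame()
    totals = df.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        warnings.warn(f"dropping {len(zero)} zero-total cells: {zero[:5]}")
        df = df.drop(columns=zero)
        totals = totals.drop(zero)
    return np.log1p(df / totals * scale)


def score_cells(norm: pd.DataFrame, signatures: SignatureSet) -> pd.DataFrame:
    """Mean log-normalized expression per signature: cells x signatures.

    Signatures with no gene mapped to the matrix give an NA column with a
    warning.
    """
    out = pd.DataFrame(np.nan, index=norm.columns, columns=signatures.names)
    gene_set = set(norm.index)
    for name in signatures.names:
        mapped = [g for g in signatures[name] if g in gene_set]
        if not mapped:
            warnings.warn(f"signature {name!r}: no genes mapped; scores are NA")
            continue
        out[name] = norm.loc[mapped].mean(axis=0).to_numpy()
    out.index.name = "cell_id"
    return out


def cluster_signature_matrix(
    cells: pd.DataFrame,
    score_cols: list[str] | None = None,
    cluster_col: str = "cluster",
    z_scale: bool = False,
) -> pd.DataFrame:
    """Cluster x signature mean-score matrix, optionally z-scaled per signature.

    z-scaling standardizes each signature column across clusters; with a
    single cluster it is undefined and reported as NA with a warning.
    """
    if score_cols is None:
        score_cols = [c for c in cells.columns if c.startswith("score_")]
    mat = cells.groupby(cluster_col, sort=True)[score_cols].mean()
    if z_scale:
        if mat.shape[0] < 2:
            warnings.warn("z-scaling undefined with a single cluster; returning NA")
            return mat * np.nan
        mat = (mat - mat.mean(axis=0)) / mat.std(axis=0, ddof=1)
    return mat


def wilcoxon_markers(
    norm: pd.DataFrame,
    clusters: pd.Series,
    cluster: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Wilcoxon rank-sum markers of one cluster against all other cells.

    Exact p-values for small tie-free comparisons (both sides <= 8
    cells), otherwise the normal approximation with tie correction.  The
    log2FC column compares mean de-logged (expm1) normalized expression
    with a pseudocount.  Constant genes get p = 1.
    """
    clusters = clusters.loc[norm.columns].astype(str)
    in_c = (clusters == str(cluster)).to_numpy()
    if in_c.sum() < 3 or (~in_c).sum() < 3:
        raise ValidationError("cluster and complement each need >= 3 cells")
    X = norm.to_numpy(dtype=float)
    a = X[:, in_c]
    b = X[:, ~in_c]
    n1, n2 = a.shape[1], b.shape[1]
    small = n1 <= 8 and n2 <= 8
    stat = np.empty(X.shape[0])
    pval = np.empty(X.shape[0])
    for g in range(X.shape[0]):
        if np.ptp(X[g]) == 0.0:
            stat[g], pval[g] = n1 * n2 / 2.0, 1.0
            continue
        has_ties = len(np.unique(X[g])) < X.shape[1]
        method = "exact" if (small and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(
            a[g], b[g], alternative="two-sided", method=method, use_continuity=False
        )
        stat[g], pval[g] = res.statistic, min(float(res.pvalue), 1.0)
    mean_a = np.expm1(a).mean(axis=1)
    mean_b = np.expm1(b).mean(axis=1)
    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {
            "statistic": stat,
            "pvalue": pval,
            "qvalue": bh_adjust(pval),
            "log2FC": log2fc,
        },
        index=pd.Index(norm.index, name="gene"),
    )


def disease_contrast(
    cells: pd.DataFrame,
    score_cols: list[str],
    diseases: list[str],
    reference: str = "healthy",
    disease_col: str = "disease",
    trajectory: str | None = None,
    phase: str | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Welch t-tests of per-cell signature scores, disease vs reference.

    One row per (signature, disease); optional trajectory/phase filters
    restrict the cells first.  All tests are BH-adjusted in one family
    (the full signature x disease grid).  Groups smaller than
    ``min_cells`` after filtering give NA with a reason.  logFC is the
    difference of group mean scores (scores are on the log scale).
    """
    sub = cells
    if trajectory is not None:
        sub = sub[sub["trajectory_id"] == trajectory]
    if phase is not None:
        sub = sub[sub["phase"] == phase]
    ref_cells = sub[sub[disease_col].astype(str) == reference]
    rows = []
    for disease in diseases:
        d_cells = sub[sub[disease_col].astype(str) == str(disease)]
        for sig in score_cols:
            x = d_cells[sig].dropna().to_numpy(float)
            y = ref_cells[sig].dropna().to_numpy(float)
            row = {"signature": sig, "disease": disease, "n_disease": len(x),
                   "n_reference": len(y)}
            if len(x) < min_cells or len(y) < min_cells:
                row.update(logFC=np.nan, t=np.nan, pvalue=np.nan,
                           reason="group below min_cells")
            else:
                t, p = stats.ttest_ind(x, y, equal_var=False)
                row.update(logFC=float(x.mean() - y.mean()), t=float(t),
                           pvalue=float(p), reason="")
            rows.append(row)
    out = pd.DataFrame(rows)
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out
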