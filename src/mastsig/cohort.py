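"""Manual cohort signature scores: per-gene z-scores averaged per subject.

For a bulk cohort, each signature gene's log-normalized expression is
standardized across subjects (sample standard deviation); a subject's
signature score is the mean z-score over the signature's genes.  Group
differences use two-sided Welch t-tests; signature relationships use
Spearman correlation and ordinary least-squares regression.  By
construction the scores are invariant to per-gene location shifts and
positive rescaling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import SignatureSet, ValidationError


def gene_zscores(norm: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene across subjects: (x - mean) / sample sd.

    ``norm`` is genes x subjects log-normalized expression.  Genes
    constant across subjects get z = 0 with a warning.
    """
    if norm.shape[1] < 3:
        raise ValidationError("z-scores need >= 3 subjects")
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    constant = sd < 1e-12
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant genes set to z = 0")
    sd = sd.where(~constant, 1.0)
    z = norm.sub(mean, axis=0).div(sd, axis=0)
    z.loc[constant] = 0.0
    return z


def subject_signature_scores(
    z: pd.DataFrame, signatures: SignatureSet
) -> pd.DataFrame:
    """Subjects x signatures mean z-score table.

    Signatures with no genes mapped to the matrix give an NA column with
    a warning.
    """
    out = pd.DataFrame(np.nan, index=z.columns, columns=signatures.names)
    gene_set = set(z.index)
    for name in signatures.names:
        mapped = [g for g in signatures[name] if g in gene_set]
        if not mapped:
            warnings.warn(f"signature {name!r}: no genes mapped; scores are NA")
            continue
        out[name] = z.loc[mapped].mean(axis=0).to_numpy()
    out.index.name = "subject"
    return out


def group_compare(
    scores: pd.DataFrame, groups: pd.Series, test: str, reference: str
) -> pd.DataFrame:
    """Per-signature two-sided Welch t-test of ``test`` vs ``reference``.

    Returns mean difference (test - reference), t and p per signature;
    degenerate groups (fewer than 2 subjects or zero variance in both)
    give NA.
    """
    groups = groups.loc[scores.index].astype(str)
    a_idx = groups == str(test)
    b_idx = groups == str(reference)
    if a_idx.sum() < 2 or b_idx.sum() < 2:
        raise ValidationError("both groups need >= 2 subjects")
    rows = []
    for sig in scores.columns:
        x = scores.loc[a_idx, sig].dropna().to_numpy(float)
        y = scores.loc[b_idx, sig].dropna().to_numpy(float)
        if len(x) < 2 or len(y) < 2 or (np.ptp(x) == 0 and np.ptp(y) == 0):
            rows.append({"signature": sig, "diff": np.nan, "t": np.nan,
                         "pvalue": np.nan})
            continue
        t, p = stats.ttest_ind(x, y, equal_var=False)
        rows.append({"signature": sig, "diff": float(x.mean() - y.mean()),
                     "t": float(t), "pvalue": float(p)})
    return pd.DataFrame(rows).set_index("signature")


def signature_correlation(
    scores: pd.DataFrame, sig_a: str, sig_b: str
) -> dict[str, float]:
    """Spearman rho plus OLS regression of signature B on signature A.

    Returns rho, slope, intercept and R^2 over subjects with both scores;
    a constant score vector gives rho = NaN.
    """
    sub = scores[[sig_a, sig_b]].dropna()
    if len(sub) < 3:
        raise ValidationError("need >= 3 subjects with both scores")
    x = sub[sig_a].to_numpy(float)
    y = sub[sig_b].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    if np.ptp(x) == 0:
        slope, intercept, r2 = float("nan"), float("nan"), float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return {"rho": rho, "slope": slope, "intercept": intercept, "r2": r2}
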