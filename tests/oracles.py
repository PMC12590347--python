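"""Independent brute-force oracles, written separately from the package
implementations they check (plain loops, closed forms, enumeration)."""

import numpy as np
import pandas as pd
from scipy import stats


def gsva_brute_force(expr, gene_sets, kernel="gaussian", tau=1.0,
                     mode="max_diff"):
    """Independent plain-loop implementation of the published GSVA score.

    Per gene the kernel-smoothed CDF across samples (Gaussian bandwidth
    sd/4, or Poisson with lambda = x + 0.5); per sample a walk over genes
    ordered by decreasing density, in-set steps |p/2 - position|^tau
    (normalized over the set), out-of-set steps 1/(p - |S|); score =
    largest positive minus largest negative walk deviation.
    """
    genes = list(expr.index)
    p = len(genes)
    dens = {}
    for g in genes:
        x = expr.loc[g].to_numpy(float)
        if kernel == "gaussian":
            h = np.std(x, ddof=1) / 4.0
            vals = [sum(stats.norm.cdf((xi - xk) / h) for xk in x) for xi in x]
        elif kernel == "poisson":
            vals = [
                sum(stats.poisson.cdf(xi, xk + 0.5) for xk in x) for xi in x
            ]
        else:
            vals = stats.rankdata(x)
        dens[g] = np.asarray(vals, float)
    out = {}
    for name, members in gene_sets.items():
        in_set = set(members) & set(genes)
        scores = []
        for j in range(expr.shape[1]):
            col = np.array([dens[g][j] for g in genes])
            order = sorted(range(p), key=lambda i: -col[i])
            weights = [abs(p / 2.0 - (t + 1)) for t in range(p)]
            denom_in = sum(
                weights[t] ** tau
                for t in range(p)
                if genes[order[t]] in in_set
            )
            walk, v = [], 0.0
            for t in range(p):
                if genes[order[t]] in in_set:
                    v += weights[t] ** tau / denom_in
                else:
                    v -= 1.0 / (p - len(in_set))
                walk.append(v)
            if mode == "max_diff":
                scores.append(max(max(walk), 0.0) + min(min(walk), 0.0))
            else:
                scores.append(max(walk, key=abs))
        out[name] = scores
    return pd.DataFrame(out, index=expr.columns).T
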