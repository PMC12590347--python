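"""Pseudobulk GSVA enrichment of the minimal signatures and moderated
disease-vs-healthy comparison.

Simulates tissue single-cell data for 8 subjects (4 healthy, 4 disease)
with the IL33 signature shifted in disease cells, aggregates cells to
per-subject pseudobulk counts, normalizes (CPM/log2), scores each
signature per subject with the GSVA engine and compares groups with
empirical-Bayes moderated t-statistics."""

import warnings

import pandas as pd

from mastsig.gsva import (
    cpm_log2,
    fit_linear_model_ebayes,
    gsva_score,
    pseudobulk_aggregate,
)
from mastsig.io import SignatureSet
from mastsig.simulate import CellSimParams, simulate_tissue_cells

signatures = SignatureSet(
    {s: [f"{s.lower()}_{i}" for i in range(15)]
     for s in ["IFNG", "IL33", "IL4IL13", "TGFB"]}
)
params = CellSimParams(
    n_cells=2400, n_genes=400,
    utilization={"healthy": (0.5, 0.5), "disease": (0.5, 0.5)},
    signature_shift={"disease": {"IL33": 0.6}},
    seed=1,
)
cm, cells, _ = simulate_tissue_cells(params, signatures)

# assign cells round-robin to 4 subjects per condition
subject = cells.groupby("disease").cumcount() % 4
subject = cells["disease"] + "_" + subject.astype(str)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    pb = pseudobulk_aggregate(cm, subject)
print(f"pseudobulk: {pb.n_genes} genes x {pb.n_samples} subjects, "
      f"{pb.meta['n_cells'].min()}-{pb.meta['n_cells'].max()} cells each")

expr = cpm_log2(pb)
scores = gsva_score(expr, signatures)
print("GSVA scores (signatures x subjects), disease means vs healthy means:")
group = pd.Series(["disease" if s.startswith("disease") else "healthy"
                   for s in scores.columns], index=scores.columns)
print(scores.T.groupby(group).mean().T.round(3))

meta = pd.DataFrame({"group": group})
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # few signatures: weak variance prior
    fit = fit_linear_model_ebayes(scores, meta, "group",
                                  ("disease", "healthy"))
print("moderated contrast (disease - healthy):")
print(fit.table.round(4))
# The planted IL33 signature carries by far the largest positive moderated
# t.  The mild negative shifts of the other signatures are a property of
# rank-based enrichment: pushing one gene block up necessarily pushes the
# relative ranks of every other set down.
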