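"""Per-cell signature scores, pseudotime tertile phases, trajectory
utilization tests and phase-level score summaries.

Simulates tissue mast cells on two trajectories where disease cells
use trajectory T1 at 3:1 odds and carry an elevated IL33 signature,
then runs the single-cell analytics: mean log-normalized signature
scores, early/mid/late tertile phases, FDR-adjusted Fisher utilization
tests and the masked phase-score table."""

from mastsig.cells import disease_contrast, lognormalize_cells, score_cells
from mastsig.io import SignatureSet
from mastsig.phases import (
    assign_phases,
    phase_score_summary,
    utilization_fisher,
)
from mastsig.simulate import CellSimParams, simulate_tissue_cells

signatures = SignatureSet(
    {s: [f"{s.lower()}_{i}" for i in range(10)]
     for s in ["IFNG", "IL33", "IL4IL13", "TGFB"]}
)
params = CellSimParams(
    n_cells=1500, n_genes=300,
    utilization={"healthy": (0.5, 0.5), "copd": (0.75, 0.25)},
    signature_shift={"copd": {"IL33": 0.5}},
    seed=3,
)
cm, cells, _ = simulate_tissue_cells(params, signatures)
norm = lognormalize_cells(cm)
scores = score_cells(norm, signatures).add_prefix("score_")
cells = cells.join(scores)

phases = assign_phases(cells)
cells["phase"] = phases.phase
print("cells per phase:", cells["phase"].value_counts().to_dict())

util = utilization_fisher(cells, ["copd"], reference="healthy")
print("\ntrajectory utilization (copd vs healthy):")
print(util[["trajectory_id", "odds_ratio", "pvalue", "qvalue"]].round(4))

contrast = disease_contrast(cells, ["score_IFNG", "score_IL33"], ["copd"])
print("\nper-cell score contrasts (copd - healthy):")
print(contrast[["signature", "logFC", "t", "qvalue"]].round(4))

summary = phase_score_summary(cells, ["score_IL33"], min_cells=5)
print("\nIL33 score by trajectory/phase/disease (groups < 5 cells masked):")
print(summary.round(3).to_string(index=False))
# The planted 3:1 utilization shows as OR ~3.6 on T1 (and its reciprocal
# on T2); the IL33 contrast logFC ~0.5 matches the planted shift.
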