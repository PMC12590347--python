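"""Synthetic datasets with the statistical structure the pipeline assumes.

Three generators mirror the three kinds of input the analysis consumes:

* :func:`simulate_bulk_priming` — a paired bulk RNA-seq priming experiment:
  four donors, five conditions (unstimulated plus four cytokine primings),
  negative-binomial counts with planted condition-unique and shared
  differentially expressed genes.
* :func:`simulate_tissue_cells` — tissue single-cell data with clusters,
  disease labels, trajectories, pseudotime and planted per-disease
  signature shifts and trajectory-utilization odds.
* :func:`simulate_cohort` — a two-group bulk cohort (default 20 vs 17
  subjects) with planted elevation of selected signatures in one group.

Counts are negative binomial with mean mu and dispersion alpha so that
Var = mu + alpha*mu^2, matching the differential-expression model; every
generator is bit-reproducible under a fixed seed and returns a
:class:`SimTruth` ground-truth object for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix, SignatureSet, ValidationError

#: The five priming conditions of the bulk experiment; the first is the
#: unstimulated reference.
DEFAULT_CONDITIONS = ("unstim", "IFNG", "IL33", "IL4IL13", "TGFB")


@dataclass
class BulkSimParams:
    """Parameters of the paired bulk priming simulation.

    Defaults emulate the study design: 4 donors x 5 conditions, moderate
    library-size variation, log2 fold changes of planted DEGs drawn from
    [1, 3], NB dispersions log-uniform in [0.01, 0.3] (typical bulk range)
    and a donor effect of 0.2 on the natural-log scale.
    """

    n_genes: int = 2000
    n_donors: int = 4
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    n_unique_deg_per_condition: int = 50
    n_shared_deg: int = 100
    lfc_range: tuple[float, float] = (1.0, 3.0)
    dispersion_range: tuple[float, float] = (0.01, 0.3)
    donor_sd: float = 0.2
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if len(self.conditions) < 2:
            raise ValidationError("need at least 2 conditions")
        if self.lfc_range[0] < 0 or self.lfc_range[1] < self.lfc_range[0]:
            raise ValidationError("lfc_range must be non-negative and ordered")
        n_planted = (
            self.n_unique_deg_per_condition * (len(self.conditions) - 1)
            + self.n_shared_deg
        )
        if n_planted > self.n_genes:
            raise ValidationError(
                f"{n_planted} planted DEGs exceed {self.n_genes} genes"
            )


@dataclass
class CellSimParams:
    """Parameters of the tissue single-cell simulation.

    ``utilization`` maps each disease label to per-trajectory sampling
    probabilities (must sum to 1): disease cells oversample trajectories
    according to these odds.  ``signature_shift`` maps disease ->
    signature name -> additive shift of the signature genes' log-mean.
    """

    n_cells: int = 2000
    n_genes: int = 1000
    n_trajectories: int = 2
    utilization: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"healthy": (0.5, 0.5), "disease": (0.75, 0.25)}
    )
    signature_shift: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dropout: float = 0.1
    mean_counts_per_cell: float = 2000.0
    dispersion: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.utilization:
            raise ValidationError("at least one disease label required")
        if not (0 <= self.dropout < 1):
            raise ValidationError("dropout must be in [0, 1)")
        for disease, probs in self.utilization.items():
            if len(probs) != self.n_trajectories:
                raise ValidationError(
                    f"{disease}: {len(probs)} utilization probs for "
                    f"{self.n_trajectories} trajectories"
                )
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ValidationError(f"{disease}: utilization probs must sum to 1")


@dataclass
class CohortSimParams:
    """Two-group bulk cohort with planted signature elevation.

    Defaults follow the validation cohort design: 20 "high" vs 17 "low"
    subjects, IL-33 and TGF-beta signatures elevated in the high group by
    1 log2 unit.
    """

    n_high: int = 20
    n_low: int = 17
    shifted_signatures: Sequence[str] = ("IL33", "TGFB")
    effect_size: float = 1.0
    n_background_genes: int = 500
    dispersion_range: tuple[float, float] = (0.01, 0.3)
    lib_size_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_high < 2 or self.n_low < 2:
            raise ValidationError("both cohort groups need >= 2 subjects")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators, for recovery tests."""

    unique_degs: dict[str, list[str]] = field(default_factory=dict)
    shared_degs: list[str] = field(default_factory=list)
    lfc: pd.DataFrame | None = None  # genes x conditions true log2FC
    trajectory: pd.Series | None = None
    pseudotime: pd.Series | None = None
    utilization: dict[str, list[float]] = field(default_factory=dict)
    signature_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    group_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lists = list(self.unique_degs.values())
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                if set(lists[i]) & set(lists[j]):
                    raise ValidationError("unique DEG lists must be disjoint")
        shared = set(self.shared_degs)
        for lst in lists:
            if shared & set(lst):
                raise ValidationError("shared DEGs must be disjoint from unique lists")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, dispersion alpha): Var = mu + alpha mu^2; alpha->0 is Poisson."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mu[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_bulk_priming(params: BulkSimParams) -> tuple[CountMatrix, SimTruth]:
    """Paired multi-condition bulk experiment with planted DEGs.

    Counts for gene g, donor d, condition c are NB with mean

        lib_{d,c} * base_g * exp(donor_{d,g}) * 2^{lfc_{g,c}}

    where lfc is nonzero exactly on the planted DEGs: condition-unique
    genes carry an effect in a single cytokine condition, shared genes in a
    random subset of >= 2 conditions.  Signs of effects are random.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    conds = list(params.conditions)
    ref = conds[0]
    cyto = conds[1:]
    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    donors = [f"D{d + 1}" for d in range(params.n_donors)]

    base = np.exp(rng.normal(np.log(100.0), 1.2, size=params.n_genes))
    log_a_lo, log_a_hi = np.log(params.dispersion_range)
    alpha = np.exp(rng.uniform(log_a_lo, log_a_hi, size=params.n_genes))

    # planted effects
    lfc = pd.DataFrame(0.0, index=genes, columns=conds)
    order = rng.permutation(params.n_genes)
    pos = 0
    unique: dict[str, list[str]] = {}
    for c in cyto:
        idx = order[pos : pos + params.n_unique_deg_per_condition]
        pos += params.n_unique_deg_per_condition
        chosen = sorted(genes[i] for i in idx)
        unique[c] = chosen
        mag = rng.uniform(*params.lfc_range, size=len(idx))
        sign = rng.choice([-1.0, 1.0], size=len(idx))
        lfc.loc[chosen, c] = mag * sign
    shared_idx = order[pos : pos + params.n_shared_deg]
    shared = sorted(genes[i] for i in shared_idx)
    for g in shared:
        k = rng.integers(2, len(cyto) + 1)
        affected = rng.choice(cyto, size=k, replace=False)
        mag = rng.uniform(*params.lfc_range)
        sign = rng.choice([-1.0, 1.0])
        lfc.loc[g, list(affected)] = mag * sign

    donor_eff = rng.normal(0.0, params.donor_sd, size=(params.n_donors, params.n_genes))
    lib = rng.uniform(*params.lib_size_range, size=(params.n_donors, len(conds)))

    sample_ids, meta_rows, cols = [], [], []
    for ci, c in enumerate(conds):
        for di, d in enumerate(donors):
            mu = (
                lib[di, ci]
                * base
                * np.exp(donor_eff[di])
                * np.power(2.0, lfc[c].to_numpy())
            )
            cols.append(_nb_draw(rng, mu, alpha))
            sample_ids.append(f"{d}_{c}")
            meta_rows.append({"condition": c, "donor": d})
    counts = np.column_stack(cols)
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    cm = CountMatrix(counts, genes, sample_ids, meta)
    truth = SimTruth(unique_degs=unique, shared_degs=shared, lfc=lfc)
    return cm, truth


def simulate_tissue_cells(
    params: CellSimParams, signatures: SignatureSet
) -> tuple[CountMatrix, pd.DataFrame, SimTruth]:
    """Tissue single-cell counts with trajectories, pseudotime and shifts.

    Cells are split evenly among the disease labels; each cell samples its
    trajectory from its disease's utilization probabilities and a uniform
    pseudotime in [0, 1].  Cluster labels are trajectory x pseudotime
    tertile (e.g. ``T1_mid``) so that phase analytics are exactly
    checkable.  Genes of signature S in cells of disease D have log-mean
    shifted by ``signature_shift[D][S]``.  Independent Bernoulli dropout is
    applied on top of NB counts.

    Returns the cell count matrix, a per-cell annotation table (cluster,
    disease, trajectory_id, pseudotime) and the ground truth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    sig_genes = sorted({g for genes in signatures.sets.values() for g in genes})
    n_bg = params.n_genes - len(sig_genes)
    if n_bg < 0:
        raise ValidationError("n_genes smaller than the number of signature genes")
    genes = sig_genes + [f"bg{i:05d}" for i in range(n_bg)]
    gene_index = {g: i for i, g in enumerate(genes)}

    diseases = list(params.utilization)
    n = params.n_cells
    disease = np.array([diseases[i % len(diseases)] for i in range(n)])
    traj = np.empty(n, dtype=int)
    for d in diseases:
        mask = disease == d
        traj[mask] = rng.choice(
            params.n_trajectories, size=mask.sum(), p=list(params.utilization[d])
        )
    pseudotime = rng.uniform(0.0, 1.0, size=n)
    tertile = np.minimum((pseudotime * 3).astype(int), 2)
    phase_names = np.array(["early", "mid", "late"])
    cluster = np.array(
        [f"T{t + 1}_{phase_names[k]}" for t, k in zip(traj, tertile)]
    )

    # relative expression: signature genes moderately expressed, shifted per disease
    base_logmean = rng.normal(0.0, 1.0, size=params.n_genes)
    shift = np.zeros((n, params.n_genes))
    for d, per_sig in params.signature_shift.items():
        rows = disease == d
        for sig_name, delta in per_sig.items():
            cols = [gene_index[g] for g in signatures.sets.get(sig_name, []) if g in gene_index]
            shift[np.ix_(rows, cols)] += delta

    rel = np.exp(base_logmean[None, :] + shift)
    rel /= rel.sum(axis=1, keepdims=True)
    lib = rng.lognormal(np.log(params.mean_counts_per_cell), 0.3, size=n)
    mu = rel * lib[:, None]
    counts = _nb_draw(rng, mu, params.dispersion)
    if params.dropout > 0:
        keep = rng.random(counts.shape) >= params.dropout
        counts = counts * keep

    cell_ids = [f"cell{i:05d}" for i in range(n)]
    cells = pd.DataFrame(
        {
            "cluster": cluster,
            "disease": disease,
            "trajectory_id": [f"T{t + 1}" for t in traj],
            "pseudotime": pseudotime,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(counts.T, genes, cell_ids, cells.copy())
    truth = SimTruth(
        trajectory=cells["trajectory_id"].copy(),
        pseudotime=cells["pseudotime"].copy(),
        utilization={d: list(p) for d, p in params.utilization.items()},
        signature_shift={d: dict(s) for d, s in params.signature_shift.items()},
    )
    return cm, cells, truth


def simulate_cohort(
    params: CohortSimParams, signatures: SignatureSet
) -> tuple[CountMatrix, SimTruth]:
    """Two-group bulk cohort with signatures elevated in the "high" group.

    Genes of every signature named in ``shifted_signatures`` have their
    NB mean multiplied by ``2**effect_size`` in high-group subjects; all
    other genes are exchangeable between groups.  Group labels are stored
    in the metadata column ``group`` (values ``high`` / ``low``).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    sig_genes = sorted({g for genes in signatures.sets.values() for g in genes})
    genes = sig_genes + [f"bg{i:05d}" for i in range(params.n_background_genes)]
    shifted = set()
    for s in params.shifted_signatures:
        if s not in signatures.sets:
            raise ValidationError(f"unknown signature {s!r}")
        shifted.update(signatures.sets[s])

    n_genes = len(genes)
    base = np.exp(rng.normal(np.log(100.0), 1.2, size=n_genes))
    log_a_lo, log_a_hi = np.log(params.dispersion_range)
    alpha = np.exp(rng.uniform(log_a_lo, log_a_hi, size=n_genes))
    effect = np.array([params.effect_size if g in shifted else 0.0 for g in genes])

    groups = ["high"] * params.n_high + ["low"] * params.n_low
    sample_ids = [f"S{i + 1:02d}_{g}" for i, g in enumerate(groups)]
    cols = []
    for g in groups:
        lib = rng.uniform(*params.lib_size_range)
        mu = lib * base * np.power(2.0, effect if g == "high" else 0.0)
        cols.append(_nb_draw(rng, mu, alpha))
    counts = np.column_stack(cols)
    meta = pd.DataFrame({"group": groups}, index=sample_ids)
    cm = CountMatrix(counts, genes, sample_ids, meta)
    truth = SimTruth(
        group_effects={
            s: (params.effect_size if s in params.shifted_signatures else 0.0)
            for s in signatures.sets
        }
    )
    return cm, truth
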