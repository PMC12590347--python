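"""Pseudotime binning, tertile phases, utilization tests and phase tables.

Trajectory pseudotime is binned either by 1-D natural breaks (the
Fisher-Jenks optimal partition minimizing within-bin variance, solved
exactly by dynamic programming), equal-width intervals or equal-count
quantiles.  Phases are pseudotime tertiles (early/mid/late) per
trajectory, split at the 1/3 and 2/3 quantiles with ties toward the
earlier phase.  Disease-specific trajectory utilization is tested per
(trajectory, disease) pair with two-sided Fisher exact tests against the
healthy reference, BH-adjusted across all pairs.  Phase-level mean
signature scores mask groups below a minimum cell count (default 5), and
a complete (disease, trajectory, phase, cluster) contingency table
supports alluvial-style flow plots.

A simplified centroid-MST pseudotime convenience is included for when no
trajectory inference output is available: a minimum spanning tree over
cluster centroids, one trajectory per root-to-leaf path, with cell
pseudotime the normalized projected arc position along its cluster's
path segment.  It is not a principal-curve method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .de import bh_adjust
from .io import ValidationError

PHASES = ("early", "mid", "late")


@dataclass
class PhaseAssignment:
    """Per-cell bins/phases plus the breakpoints that produced them."""

    bins: pd.Series  # per-cell integer bin index (within trajectory)
    phase: pd.Series | None  # per-cell early/mid/late (tertile assignment)
    breakpoints: dict[str, list[float]] = field(default_factory=dict)
    method: str = ""


def _jenks_breaks(values: np.ndarray, k: int) -> list[float]:
    """Exact 1-D Fisher-Jenks optimal breaks (min within-bin sum of squares).

    Dynamic program over the sorted values using prefix sums; returns the
    k-1 interior breakpoints (midpoints between adjacent values across a
    split).
    """
    x = np.sort(values)
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(a: int, b: int) -> np.ndarray:
        """Vectorized SSE of x[a:b] for array-valued a (exclusive b)."""
        cnt = b - a
        s = pref[b] - pref[a]
        s2 = pref2[b] - pref2[a]
        return s2 - s**2 / np.maximum(cnt, 1)

    idx = np.arange(n + 1)
    cost = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[1] = sse(np.zeros(n + 1, dtype=int), idx)
    for kk in range(2, k + 1):
        for i in range(kk, n + 1):
            j = np.arange(kk - 1, i)
            cand = cost[kk - 1, j] + sse(j, i)
            best = int(np.argmin(cand))
            cost[kk, i] = cand[best]
            split[kk, i] = j[best]
    cuts = []
    i = n
    for kk in range(k, 1, -1):
        j = split[kk, i]
        cuts.append(0.5 * (x[j - 1] + x[j]))
        i = j
    return sorted(cuts)


def bin_pseudotime(
    cells: pd.DataFrame,
    method: str = "natural_breaks",
    k: int = 3,
    pseudotime_col: str = "pseudotime",
    trajectory_col: str = "trajectory_id",
) -> PhaseAssignment:
    """Bin pseudotime per trajectory into k ordered bins.

    ``natural_breaks`` uses the exact Fisher-Jenks partition;
    ``equal_width`` splits the trajectory's pseudotime range evenly;
    ``equal_count`` uses quantiles.  Trajectories with fewer distinct
    values than k fall back to fewer bins with a warning.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    if method not in ("natural_breaks", "equal_width", "equal_count"):
        raise ValidationError(f"unknown binning method {method!r}")
    if cells[pseudotime_col].isna().any():
        raise ValidationError("pseudotime missing for some cells")
    bins = pd.Series(0, index=cells.index, dtype=int)
    breakpoints: dict[str, list[float]] = {}
    for traj, grp in cells.groupby(trajectory_col):
        pt = grp[pseudotime_col].to_numpy(dtype=float)
        k_eff = min(k, len(np.unique(pt)))
        if k_eff < k:
            warnings.warn(
                f"trajectory {traj}: only {k_eff} distinct pseudotime values; "
                f"using {k_eff} bin(s)"
            )
        if k_eff <= 1:
            breakpoints[str(traj)] = []
            continue
        if method == "natural_breaks":
            cuts = _jenks_breaks(pt, k_eff)
        elif method == "equal_width":
            lo, hi = pt.min(), pt.max()
            cuts = list(lo + (hi - lo) * np.arange(1, k_eff) / k_eff)
        else:
            cuts = list(np.quantile(pt, np.arange(1, k_eff) / k_eff))
        breakpoints[str(traj)] = cuts
        bins.loc[grp.index] = np.searchsorted(cuts, pt, side="left")
    return PhaseAssignment(bins=bins, phase=None, breakpoints=breakpoints, method=method)


def assign_phases(
    cells: pd.DataFrame,
    pseudotime_col: str = "pseudotime",
    trajectory_col: str = "trajectory_id",
) -> PhaseAssignment:
    """Tertile phases per trajectory: early/mid/late at the 1/3, 2/3 quantiles.

    Cells exactly on a boundary go to the earlier phase.  Trajectories
    with fewer than 3 cells are all "early" with a warning.
    """
    if cells[pseudotime_col].isna().any():
        raise ValidationError("pseudotime missing for some cells")
    phase = pd.Series("early", index=cells.index, dtype=object)
    bins = pd.Series(0, index=cells.index, dtype=int)
    breakpoints: dict[str, list[float]] = {}
    for traj, grp in cells.groupby(trajectory_col):
        pt = grp[pseudotime_col].to_numpy(dtype=float)
        if len(pt) < 3 or np.ptp(pt) == 0.0:
            warnings.warn(f"trajectory {traj}: <3 cells or constant pseudotime; all early")
            breakpoints[str(traj)] = []
            continue
        q1, q2 = np.quantile(pt, [1.0 / 3.0, 2.0 / 3.0])
        breakpoints[str(traj)] = [float(q1), float(q2)]
        lab = np.where(pt <= q1, "early", np.where(pt <= q2, "mid", "late"))
        phase.loc[grp.index] = lab
        bins.loc[grp.index] = np.where(pt <= q1, 0, np.where(pt <= q2, 1, 2))
    return PhaseAssignment(bins=bins, phase=phase, breakpoints=breakpoints,
                           method="tertile")


def utilization_fisher(
    cells: pd.DataFrame,
    diseases: list[str],
    reference: str = "healthy",
    disease_col: str = "disease",
    trajectory_col: str = "trajectory_id",
) -> pd.DataFrame:
    """Fisher exact tests of trajectory utilization, disease vs reference.

    For trajectory T and disease D the 2x2 table is
    [[D on T, D off T], [ref on T, ref off T]]; two-sided p-values (all
    tables with probability <= the observed), BH across all (T, D) pairs.
    Diseases with no cells are skipped with a warning.
    """
    ref_cells = cells[cells[disease_col].astype(str) == reference]
    if len(ref_cells) == 0:
        raise ValidationError(f"no reference ({reference!r}) cells present")
    trajectories = sorted(cells[trajectory_col].astype(str).unique())
    rows = []
    for disease in diseases:
        d_cells = cells[cells[disease_col].astype(str) == str(disease)]
        if len(d_cells) == 0:
            warnings.warn(f"disease {disease!r} has no cells; skipped")
            continue
        for traj in trajectories:
            d_on = int((d_cells[trajectory_col].astype(str) == traj).sum())
            r_on = int((ref_cells[trajectory_col].astype(str) == traj).sum())
            table = [[d_on, len(d_cells) - d_on], [r_on, len(ref_cells) - r_on]]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            rows.append(
                {
                    "trajectory_id": traj,
                    "disease": disease,
                    "disease_on": d_on,
                    "disease_off": len(d_cells) - d_on,
                    "reference_on": r_on,
                    "reference_off": len(ref_cells) - r_on,
                    "odds_ratio": float(odds),
                    "pvalue": float(p),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def phase_score_summary(
    cells: pd.DataFrame,
    score_cols: list[str],
    min_cells: int = 5,
    disease_col: str = "disease",
    trajectory_col: str = "trajectory_id",
    phase_col: str = "phase",
) -> pd.DataFrame:
    """Mean signature score per (trajectory, phase, disease); small groups masked.

    Groups with fewer than ``min_cells`` cells have their score columns
    set to NA; the cell count is always reported, and masking never
    alters the values of unmasked groups.
    """
    grouped = cells.groupby([trajectory_col, phase_col, disease_col], observed=True)
    means = grouped[score_cols].mean()
    counts = grouped.size().rename("n_cells")
    out = means.join(counts)
    masked = out["n_cells"] < min_cells
    out.loc[masked, score_cols] = np.nan
    out["masked"] = masked
    return out.reset_index()


def phase_flow_table(
    cells: pd.DataFrame,
    disease_col: str = "disease",
    trajectory_col: str = "trajectory_id",
    phase_col: str = "phase",
    cluster_col: str = "cluster",
) -> pd.DataFrame:
    """Complete (disease, trajectory, phase, cluster) cell-count table.

    Zero-count strata are included so alluvial plots see every category
    combination; the count column totals the number of cells.
    """
    counts = (
        cells.groupby([disease_col, trajectory_col, phase_col, cluster_col],
                      observed=True)
        .size()
        .rename("n_cells")
    )
    levels = [
        sorted(cells[c].astype(str).unique())
        for c in (disease_col, trajectory_col, phase_col, cluster_col)
    ]
    full = pd.MultiIndex.from_product(
        levels, names=[disease_col, trajectory_col, phase_col, cluster_col]
    )
    return counts.reindex(full, fill_value=0).reset_index()


def centroid_mst_pseudotime(
    embedding: pd.DataFrame,
    clusters: pd.Series,
    root_cluster: str,
) -> pd.DataFrame:
    """Simplified trajectory inference: MST over cluster centroids.

    Each root-to-leaf path of the tree is one trajectory; a cell is
    assigned to every trajectory whose path contains its cluster, with
    pseudotime the arc position of its projection onto the path segments
    adjacent to its cluster centroid, normalized by total path length.
    Returns a frame with (cell_id, trajectory_id, pseudotime).
    """
    clusters = clusters.loc[embedding.index].astype(str)
    names = sorted(clusters.unique())
    if len(names) < 2:
        raise ValidationError("need >= 2 clusters")
    if str(root_cluster) not in names:
        raise ValidationError(f"root cluster {root_cluster!r} not found")
    cent = np.vstack(
        [embedding.loc[clusters == c].mean(axis=0).to_numpy() for c in names]
    )
    dist = cdist(cent, cent)
    mst = minimum_spanning_tree(dist).toarray()
    adj = (mst > 0) | (mst.T > 0)
    n_comp = _count_components(adj)
    if n_comp > 1:  # pragma: no cover - complete distance graphs are connected
        warnings.warn(f"embedding splits into {n_comp} disconnected groups")

    root = names.index(str(root_cluster))
    # depth-first paths from root to each leaf
    paths: list[list[int]] = []

    def walk(node: int, path: list[int], visited: set[int]) -> None:
        nbrs = [j for j in range(len(names)) if adj[node, j] and j not in visited]
        if not nbrs:
            if len(path) > 1:
                paths.append(list(path))
            return
        for j in nbrs:
            walk(j, path + [j], visited | {j})

    walk(root, [root], {root})
    rows = []
    for t_i, path in enumerate(sorted(paths)):
        pts = cent[path]
        seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc_at = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = arc_at[-1]
        for pos, node in enumerate(path):
            members = embedding.index[clusters == names[node]]
            segs = []
            if pos > 0:
                segs.append((pos - 1, pos))
            if pos < len(path) - 1:
                segs.append((pos, pos + 1))
            for cell in members:
                x = embedding.loc[cell].to_numpy(dtype=float)
                best = None
                for a, b in segs:
                    pa, pb = pts[a], pts[b]
                    v = pb - pa
                    denom = float(v @ v)
                    frac = 0.0 if denom == 0 else float(np.clip((x - pa) @ v / denom, 0, 1))
                    arc = arc_at[a] + frac * seg_len[a]
                    d = float(np.linalg.norm(x - (pa + frac * v)))
                    if best is None or d < best[0]:
                        best = (d, arc)
                rows.append(
                    {
                        "cell_id": cell,
                        "trajectory_id": f"T{t_i + 1}",
                        "pseudotime": best[1] / total if total > 0 else 0.0,
                    }
                )
    return pd.DataFrame(rows)


def _count_components(adj: np.ndarray) -> int:
    n = adj.shape[0]
    seen: set[int] = set()
    comps = 0
    for start in range(n):
        if start in seen:
            continue
        comps += 1
        stack = [start]
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            stack.extend(j for j in range(n) if adj[node, j] and j not in seen)
    return comps
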