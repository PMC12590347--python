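from itertools import product
from math import comb

import numpy as np
import pandas as pd
import pytest

from mastsig.io import ValidationError
from mastsig.phases import (
    PhaseAssignment,
    assign_phases,
    bin_pseudotime,
    centroid_mst_pseudotime,
    phase_flow_table,
    phase_score_summary,
    utilization_fisher,
)


def fisher_enumeration_p(table):
    """Two-sided Fisher p by hypergeometric enumeration over all tables
    with the observed margins (probability <= observed convention)."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def two_split_partitions_sse(values, cut_idx):
    left, right = values[:cut_idx], values[cut_idx:]
    return (np.var(left) * len(left) if len(left) else 0.0) + (
        np.var(right) * len(right) if len(right) else 0.0
    )


class TestBinPseudotime:
    def _cells(self, pt, traj="T1"):
        return pd.DataFrame(
            {"trajectory_id": [traj] * len(pt), "pseudotime": pt},
            index=[f"c{i}" for i in range(len(pt))],
        )

    def test_natural_breaks_finds_gap(self):
        """Two tight clumps: the optimal 2-bin split falls in the gap —
        verified against enumeration of every single-split partition."""
        values = np.array([0.0, 0.1, 0.2, 5.0, 5.1, 5.2])
        pa = bin_pseudotime(self._cells(values), "natural_breaks", k=2)
        assert 0.2 < pa.breakpoints["T1"][0] < 5.0
        best_cut = min(
            range(1, len(values)),
            key=lambda i: two_split_partitions_sse(values, i),
        )
        assert best_cut == 3  # enumeration agrees: split after the clump
        np.testing.assert_array_equal(pa.bins, [0, 0, 0, 1, 1, 1])

    def test_equal_width_breaks(self):
        pa = bin_pseudotime(
            self._cells(np.linspace(0, 1, 21)), "equal_width", k=4
        )
        np.testing.assert_allclose(pa.breakpoints["T1"], [0.25, 0.5, 0.75])

    def test_equal_count_quantiles(self):
        pa = bin_pseudotime(
            self._cells(np.arange(12) / 11), "equal_count", k=3
        )
        sizes = pa.bins.value_counts()
        assert (sizes == 4).all()

    def test_identical_values_single_bin_warns(self):
        with pytest.warns(UserWarning, match="distinct"):
            pa = bin_pseudotime(self._cells(np.zeros(5)), k=3)
        assert (pa.bins == 0).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValidationError):
            bin_pseudotime(self._cells(np.arange(4.0)), k=1)

    def test_natural_breaks_deterministic_and_monotone(self):
        rng = np.random.default_rng(0)
        pt = rng.random(60)
        cells = self._cells(pt)
        a = bin_pseudotime(cells, "natural_breaks", k=5)
        b = bin_pseudotime(cells, "natural_breaks", k=5)
        pd.testing.assert_series_equal(a.bins, b.bins)
        order = np.argsort(pt)
        assert (np.diff(a.bins.to_numpy()[order]) >= 0).all()


class TestAssignPhases:
    def _cells(self, pt, traj=None):
        traj = traj or ["T1"] * len(pt)
        return pd.DataFrame(
            {"trajectory_id": traj, "pseudotime": pt},
            index=[f"c{i}" for i in range(len(pt))],
        )

    def test_nine_cells_exact_tertiles(self):
        pa = assign_phases(self._cells(np.arange(9) / 8))
        assert pa.phase.value_counts().to_dict() == {
            "early": 3, "mid": 3, "late": 3
        }

    def test_ten_cells_tie_toward_early(self):
        pa = assign_phases(self._cells(np.arange(10) / 9))
        counts = pa.phase.value_counts()
        assert (counts["early"], counts["mid"], counts["late"]) == (4, 3, 3)

    def test_constant_pseudotime_all_early_warns(self):
        with pytest.warns(UserWarning):
            pa = assign_phases(self._cells(np.full(6, 0.4)))
        assert (pa.phase == "early").all()

    def test_monotone_in_pseudotime(self):
        rng = np.random.default_rng(1)
        pt = rng.random(50)
        pa = assign_phases(self._cells(pt))
        rank = pa.phase.map({"early": 0, "mid": 1, "late": 2}).to_numpy()
        assert (np.diff(rank[np.argsort(pt)]) >= 0).all()

    def test_per_trajectory_quantiles_independent(self):
        pt = np.concatenate([np.arange(9) / 8, np.arange(9) / 80])
        traj = ["T1"] * 9 + ["T2"] * 9
        pa = assign_phases(self._cells(pt, traj))
        t2 = pa.phase[9:]
        assert (t2.value_counts() == 3).all()


class TestUtilizationFisher:
    def _cells(self, d_on, d_off, h_on, h_off):
        rows = (
            [("d", "T1")] * d_on + [("d", "T2")] * d_off
            + [("healthy", "T1")] * h_on + [("healthy", "T2")] * h_off
        )
        return pd.DataFrame(rows, columns=["disease", "trajectory_id"])

    def test_proportional_table_null(self):
        res = utilization_fisher(self._cells(10, 30, 20, 60), ["d"])
        row = res[res["trajectory_id"] == "T1"].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["pvalue"] == pytest.approx(1.0)

    def test_complete_separation_five_v_five(self):
        res = utilization_fisher(self._cells(5, 0, 0, 5), ["d"])
        row = res[res["trajectory_id"] == "T1"].iloc[0]
        assert row["pvalue"] == pytest.approx(0.00794, abs=1e-5)
        assert row["pvalue"] == pytest.approx(
            fisher_enumeration_p([[5, 0], [0, 5]])
        )

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b, c, d = rng.integers(0, 40, 4)
            if (a + b) == 0 or (c + d) == 0:
                continue
            cells = self._cells(a, b, c, d)
            res = utilization_fisher(cells, ["d"])
            row = res[res["trajectory_id"] == "T1"].iloc[0]
            assert row["pvalue"] == pytest.approx(
                fisher_enumeration_p([[a, b], [c, d]]), rel=1e-9
            )

    def test_single_pair_q_equals_p(self):
        cells = self._cells(5, 0, 0, 5)
        cells = cells[cells["trajectory_id"] == "T1"].copy()
        cells.loc[len(cells)] = ["healthy", "T1"]
        res = utilization_fisher(cells, ["d"])
        assert (res["qvalue"] == res["pvalue"]).all()

    def test_planted_utilization_detected(self, tissue_cells):
        """3:1 vs 1:1 planted odds flagged at q < 0.05."""
        _, cells, _ = tissue_cells
        res = utilization_fisher(cells, ["copd"])
        assert (res["qvalue"] < 0.05).all()

    def test_missing_reference_rejected(self):
        cells = self._cells(3, 3, 0, 0)
        with pytest.raises(ValidationError, match="reference"):
            utilization_fisher(cells[cells.disease == "d"], ["d"])


class TestPhaseSummary:
    def _cells(self, n_late=4):
        rows = []
        for phase, n in [("early", 6), ("mid", 5), ("late", n_late)]:
            for i in range(n):
                rows.append(("T1", phase, "d", float(i)))
        return pd.DataFrame(
            rows, columns=["trajectory_id", "phase", "disease", "score_S"]
        )

    def test_group_below_threshold_masked(self):
        out = phase_score_summary(self._cells(n_late=4), ["score_S"])
        late = out[out["phase"] == "late"].iloc[0]
        assert np.isnan(late["score_S"]) and late["masked"]
        assert late["n_cells"] == 4

    def test_boundary_group_of_five_reported(self):
        out = phase_score_summary(self._cells(n_late=5), ["score_S"])
        late = out[out["phase"] == "late"].iloc[0]
        assert late["score_S"] == pytest.approx(2.0)
        assert not late["masked"]

    def test_masking_leaves_unmasked_values_untouched(self):
        masked = phase_score_summary(self._cells(4), ["score_S"])
        unmasked = phase_score_summary(self._cells(4), ["score_S"],
                                       min_cells=1)
        for phase in ["early", "mid"]:
            a = masked[masked["phase"] == phase]["score_S"].iloc[0]
            b = unmasked[unmasked["phase"] == phase]["score_S"].iloc[0]
            assert a == b


class TestFlowTable:
    def test_totals_and_zero_strata(self, tissue_cells):
        _, cells, _ = tissue_cells
        pa = assign_phases(cells)
        cells = cells.assign(phase=pa.phase)
        flow = phase_flow_table(cells)
        assert flow["n_cells"].sum() == len(cells)
        combos = (
            cells["disease"].nunique() * cells["trajectory_id"].nunique()
            * cells["phase"].nunique() * cells["cluster"].nunique()
        )
        assert len(flow) == combos  # zero-count strata included

    def test_invariant_to_cell_order(self, tissue_cells):
        _, cells, _ = tissue_cells
        pa = assign_phases(cells)
        cells = cells.assign(phase=pa.phase)
        a = phase_flow_table(cells)
        b = phase_flow_table(cells.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a, b)


class TestCentroidMST:
    def _embedding(self, centers, n=8, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        pts, labels = [], []
        for name, (x, y) in centers.items():
            pts.append(rng.normal([x, y], spread, (n, 2)))
            labels += [name] * n
        emb = pd.DataFrame(
            np.vstack(pts), columns=["x", "y"],
            index=[f"c{i}" for i in range(len(labels))],
        )
        return emb, pd.Series(labels, index=emb.index)

    def test_collinear_clusters_single_ordered_path(self):
        emb, cl = self._embedding({"a": (0, 0), "b": (1, 0), "c": (2, 0)})
        out = centroid_mst_pseudotime(emb, cl, "a")
        assert out["trajectory_id"].nunique() == 1
        merged = out.merge(
            cl.rename("cluster"), left_on="cell_id", right_index=True
        )
        means = merged.groupby("cluster")["pseudotime"].mean()
        assert means["a"] < means["b"] < means["c"]

    def test_y_shape_gives_two_trajectories_sharing_root(self):
        emb, cl = self._embedding(
            {"root": (0, 0), "mid": (1, 0), "up": (2, 1), "down": (2, -1)}
        )
        out = centroid_mst_pseudotime(emb, cl, "root")
        assert out["trajectory_id"].nunique() == 2
        root_cells = cl.index[cl == "root"]
        per_traj = out[out["cell_id"].isin(root_cells)]
        assert per_traj.groupby("trajectory_id").size().nunique() == 1

    def test_root_choice_reverses_ordering(self):
        emb, cl = self._embedding({"a": (0, 0), "b": (1, 0), "c": (2, 0)})
        fwd = centroid_mst_pseudotime(emb, cl, "a").set_index("cell_id")
        rev = centroid_mst_pseudotime(emb, cl, "c").set_index("cell_id")
        rho = np.corrcoef(
            fwd["pseudotime"], rev.loc[fwd.index, "pseudotime"]
        )[0, 1]
        assert rho < -0.9

    def test_unknown_root_rejected(self):
        emb, cl = self._embedding({"a": (0, 0), "b": (1, 0)})
        with pytest.raises(ValidationError, match="root"):
            centroid_mst_pseudotime(emb, cl, "zz")
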