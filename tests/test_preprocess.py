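"""Normalization and QC chain."""

import numpy as np
import pandas as pd
import pytest

import scmskit as sk
from scmskit.preprocess import cramers_v, qc_factor_diagnostics


def _dataset(raw, files, channels, rows=None, populations=None):
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    obs = pd.DataFrame(
        {
            "file_id": files,
            "channel": channels,
            "well_row": rows if rows is not None else ["A"] * n,
            "population": populations if populations is not None else ["x"] * n,
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )
    var = pd.DataFrame(
        index=pd.Index([f"p{j}" for j in range(raw.shape[1])], name="protein_id")
    )
    return sk.ScmsDataset.from_matrix(raw, obs, var)


class TestNormalizeMedians:
    def test_already_equalized_matrix_is_fixed_point(self):
        # per-file and per-channel medians already equal -> unchanged
        raw = np.array([[10.0, 10.0, 10.0, 10.0], [4.0, 4.0, 4.0, 4.0]]).T
        ds = _dataset(raw, ["f1", "f1", "f2", "f2"], ["126", "127N", "126", "127N"])
        out, factors = sk.normalize_medians(ds)
        np.testing.assert_allclose(out.layer("normalized"), raw)
        assert factors.iterations_used == 1
        assert factors.converged

    def test_injected_factors_removed_closed_form(self):
        # constant truth 10 with file2 x2 and channel2 x0.5
        true = 10.0
        file_f = {"f1": 1.0, "f2": 2.0}
        chan_f = {"126": 1.0, "127N": 0.5}
        files = ["f1", "f1", "f2", "f2"]
        chans = ["126", "127N", "126", "127N"]
        raw = np.array(
            [[true * file_f[f] * chan_f[c]] * 2 for f, c in zip(files, chans)]
        )
        ds = _dataset(raw, files, chans)
        out, _ = sk.normalize_medians(ds, convergence_threshold=1e-9, max_iter=200)
        x = out.layer("normalized")
        # all entries equal up to a global scale
        assert np.ptp(x / x.flat[0]) < 1e-6

    def test_stops_when_change_below_threshold(self):
        # an injected imbalance whose first-sweep correction is < 1.1 s/n
        raw = np.array([[10.0, 10.0, 11.0, 11.0], [10.0, 10.0, 11.0, 11.0]]).T
        ds = _dataset(raw, ["f1", "f1", "f2", "f2"], ["126", "127N", "126", "127N"])
        out, factors = sk.normalize_medians(ds, convergence_threshold=1.1)
        assert factors.converged
        assert factors.final_max_change < 1.1

    def test_idempotent_on_own_output(self, default_sim):
        ds, _ = default_sim
        out, _ = sk.normalize_medians(ds)
        # re-run on the normalized layer by promoting it to raw
        ds2 = out.copy()
        ds2.set_layer("raw_sn", out.layer("normalized"))
        _, factors2 = sk.normalize_medians(ds2)
        assert factors2.iterations_used == 1
        assert factors2.final_max_change < 1.1

    def test_scale_equivariance(self, default_sim):
        # factors are relative, so a global rescaling passes straight
        # through (the absolute stopping rule is rescaled alongside)
        ds, _ = default_sim
        scaled = ds.copy()
        scaled.set_layer("raw_sn", ds.layer("raw_sn") * 7.0)
        a, _ = sk.normalize_medians(ds, convergence_threshold=1.1)
        b, _ = sk.normalize_medians(scaled, convergence_threshold=1.1 * 7.0)
        np.testing.assert_allclose(
            b.layer("normalized"), a.layer("normalized") * 7.0, rtol=1e-9
        )

    def test_nonconvergence_warns_and_flags(self, default_sim):
        ds, _ = default_sim
        with pytest.warns(UserWarning, match="did not converge"):
            _, factors = sk.normalize_medians(ds, convergence_threshold=1e-12, max_iter=2)
        assert not factors.converged

    def test_factor_recovery_on_simulated_batches(self, processed):
        from scmskit.simulate import injected_level_effects

        ds_raw, gt, factors, _ = processed
        eff = injected_level_effects(
            gt, gt.tau.index.map(lambda c: c.rsplit("_", 1)[0]).to_series(), gt.file_factors
        )
        est = 1.0 / factors.file_factors.median(axis=1)
        est = est / np.exp(np.log(est).mean())
        eff = eff / np.exp(np.log(eff).mean())
        rel = np.abs(est / eff.reindex(est.index) - 1)
        assert rel.median() < 0.05


class TestNoiseFloor:
    def test_strictly_below_floor_masked_boundary_kept(self):
        raw = np.array([[1.0, 1.1, 1.2, 5.0]]).T
        ds = _dataset(raw, ["f1"] * 4, ["126", "127N", "128N", "128C"])
        ds.set_layer("normalized", raw.copy())
        out = sk.mask_noise_floor(ds, floor=1.1)
        x = out.layer("normalized")
        assert np.isnan(x[0, 0])
        assert x[1, 0] == 1.1  # strict inequality convention
        assert x[2, 0] == 1.2

    def test_all_above_floor_unchanged(self):
        raw = np.full((3, 2), 5.0)
        ds = _dataset(raw, ["f1"] * 3, ["126", "127N", "128N"])
        ds.set_layer("normalized", raw.copy())
        out = sk.mask_noise_floor(ds)
        np.testing.assert_array_equal(out.layer("normalized"), raw)


class TestFilterCells:
    def test_mad_outlier_removed(self):
        # log2 sums {10, 10.2, 9.8, 10.1, 3}: only the 3 is outside 3 MAD
        log2_sums = np.array([10.0, 10.2, 9.8, 10.1, 3.0])
        raw = (2.0**log2_sums)[:, None]
        ds = _dataset(raw, ["f1"] * 5, ["126", "127N", "128N", "128C", "129N"])
        ds.set_layer("normalized", raw.copy())
        out, report = sk.filter_cells(ds, mad_multiplier=3)
        assert out.n_cells == 4
        assert list(report.removed.index) == ["c4"]
        assert report.removed["reason"].iloc[0] == "sum_outlier"

    def test_min_proteins_reason_reported(self):
        raw = np.full((4, 20), 8.0)
        raw[3, 2:] = np.nan  # 2 proteins only
        ds = _dataset(raw, ["f1"] * 4, ["126", "127N", "128N", "128C"])
        ds.set_layer("normalized", raw.copy())
        out, report = sk.filter_cells(ds, mad_multiplier=50, min_proteins_per_cell=10)
        assert "min_proteins" in report.removed.loc["c3", "reason"]

    def test_empty_well_detection_on_simulation(self):
        # >= 95% of planted empty wells removed, <= 2% of true cells lost
        for seed in (0, 1, 2):
            cfg = sk.SimulationConfig(n_proteins=300, empty_well_rate=0.05, seed=seed)
            ds, gt = sk.simulate_dataset(cfg)
            ds, _ = sk.normalize_medians(ds)
            ds = sk.mask_noise_floor(ds)
            _, report = sk.filter_cells(ds, min_proteins_per_cell=30)
            removed = set(report.removed.index)
            empties = set(gt.is_empty[gt.is_empty].index)
            real = set(gt.is_empty[~gt.is_empty].index)
            assert len(empties & removed) / len(empties) >= 0.95
            assert len(real & removed) / len(real) <= 0.02

    def test_all_cells_removed_is_an_error(self):
        raw = np.full((3, 5), 4.0)
        ds = _dataset(raw, ["f1"] * 3, ["126", "127N", "128N"])
        ds.set_layer("normalized", raw.copy())
        with pytest.raises(ValueError, match="every cell"):
            sk.filter_cells(ds, mad_multiplier=50, min_proteins_per_cell=10)


class TestFilterProteins:
    def test_less_than_min_cells_dropped_boundary_kept(self):
        raw = np.full((4, 3), 5.0)
        raw[2:, 0] = np.nan  # p0 in 2 cells -> dropped
        raw[3, 1] = np.nan   # p1 in 3 cells -> kept
        ds = _dataset(raw, ["f1"] * 4, ["126", "127N", "128N", "128C"])
        ds.set_layer("normalized", raw.copy())
        out = sk.filter_proteins_min_cells(ds, min_cells=3)
        assert list(out.proteins.index) == ["p1", "p2"]

    def test_fully_observed_matrix_unchanged(self):
        raw = np.full((4, 3), 5.0)
        ds = _dataset(raw, ["f1"] * 4, ["126", "127N", "128N", "128C"])
        ds.set_layer("normalized", raw.copy())
        assert sk.filter_proteins_min_cells(ds).n_proteins == 3

    def test_filters_never_alter_surviving_values(self, processed):
        ds = processed[0]
        # values surviving the whole chain appear unchanged in raw->normalized
        # up to the accumulated multiplicative factors; here: masking and
        # protein/cell filters leave the normalized values bit-identical
        before = ds.copy()
        out = sk.filter_proteins_min_cells(before, min_cells=3)
        kept = out.proteins.index
        sub = before.layer("normalized")[:, before.proteins.index.get_indexer(kept)]
        np.testing.assert_array_equal(out.layer("normalized"), sub)


class TestMedianShift:
    def test_totals_equalized_to_median(self):
        raw = np.array([[50.0, 50.0], [100.0, 100.0], [200.0, 200.0]])
        ds = _dataset(raw, ["f1"] * 3, ["126", "127N", "128N"])
        ds.set_layer("normalized", raw.copy())
        out = sk.median_shift_and_log2(ds)
        totals = np.nansum(out.layer("normalized"), axis=1)
        np.testing.assert_allclose(totals, 200.0)

    def test_log2_layer_is_log2_of_shifted(self):
        raw = np.array([[8.0, 8.0]])
        ds = _dataset(raw, ["f1"], ["126"])
        ds.set_layer("normalized", raw.copy())
        out = sk.median_shift_and_log2(ds)
        np.testing.assert_allclose(out.layer("log2"), 3.0)

    def test_per_cell_totals_equal_to_machine_precision(self, processed):
        ds = processed[0]
        totals = np.nansum(ds.layer("normalized"), axis=1)
        np.testing.assert_allclose(totals, np.median(totals), rtol=1e-12)

    def test_zero_total_cell_rejected(self):
        raw = np.array([[5.0, 5.0], [np.nan, np.nan]])
        ds = _dataset(np.nan_to_num(raw, nan=0.0) + 0.0, ["f1", "f1"], ["126", "127N"])
        ds.set_layer("normalized", np.where(np.isnan(raw), np.nan, raw))
        ds.adata.layers["normalized"][1] = np.nan
        with pytest.raises(ValueError, match="total"):
            sk.median_shift_and_log2(ds)


class TestQcDiagnostics:
    def test_row_intensity_depression_flagged(self):
        cfg = sk.SimulationConfig(n_proteins=200, seed=21)
        ds, _ = sk.simulate_dataset(cfg)
        raw = ds.layer("raw_sn").copy()
        hit = (ds.cells["well_row"] == "C").to_numpy()
        raw[hit] /= 3.0
        ds.set_layer("raw_sn", raw)
        ds.set_layer("normalized", raw)
        diag = qc_factor_diagnostics(ds, factors=("well_row",), alpha=0.01)
        tab = diag["well_row"]
        assert bool(tab.loc["C", "flagged"])

    def test_batch_free_simulation_unflagged(self):
        cfg = sk.SimulationConfig(
            n_proteins=200, sigma_file=0.0, sigma_channel=0.0,
            booster_bleed_lambda=0.0, seed=22,
        )
        ds, _ = sk.simulate_dataset(cfg)
        ds.set_layer("normalized", ds.layer("raw_sn"))
        diag = qc_factor_diagnostics(ds, factors=("channel",), alpha=0.001)
        assert not diag["channel"]["flagged"].any()

    def test_perfect_confounding_scores_cramers_v_one(self):
        a = pd.Series(["r1"] * 10 + ["r2"] * 10)
        b = pd.Series(["LSC"] * 10 + ["Blast"] * 10)
        assert cramers_v(a, b) == pytest.approx(1.0)

    def test_single_level_factor_skipped_with_note(self, default_sim):
        ds, _ = default_sim
        diag = qc_factor_diagnostics(ds, factors=("plate_id",))
        assert "note" in diag["plate_id"].columns


class TestContaminantsAndRuns:
    def test_flagged_contaminants_dropped(self, default_sim):
        ds, _ = default_sim
        ds = ds.copy()
        flags = np.zeros(ds.n_proteins, bool)
        flags[:2] = True
        ds.adata.var["Contaminant"] = flags
        out = sk.remove_contaminants_and_failed_runs(ds)
        assert out.n_proteins == ds.n_proteins - 2

    def test_file_without_quantifications_removed(self, default_sim):
        ds, _ = default_sim
        ds = ds.copy()
        raw = ds.layer("raw_sn").copy()
        dead = (ds.cells["file_id"] == ds.cells["file_id"].iloc[0]).to_numpy()
        raw[dead] = np.nan
        ds.set_layer("raw_sn", raw)
        out = sk.remove_contaminants_and_failed_runs(ds)
        assert ds.cells["file_id"].iloc[0] not in set(out.cells["file_id"])

    def test_row_exclusion_removes_expected_wells(self, default_sim):
        # rows I and J of a full 384-well layout carry 2 x 24 wells; only
        # their single-cell wells appear as cells
        ds, _ = default_sim
        in_rows = int(ds.cells["well_row"].isin(["I", "J"]).sum())
        out = sk.remove_contaminants_and_failed_runs(ds, exclude_rows=["I", "J"])
        assert out.n_cells == ds.n_cells - in_rows
        # 2 rows x 24 columns = 48 wells, of which the sorted single-cell
        # wells (14 of 16 per column on average) appear as cells
        assert 30 <= in_rows <= 48
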