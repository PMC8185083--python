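"""Differential expression, multiple testing, enrichment and trajectory tools."""

import math

import numpy as np
import pandas as pd
import pytest

import scmskit as sk
from scmskit.stats import (
    hypergeom_pvalue,
    minmax_01,
    moving_average,
    protein_cluster_signatures,
)
from conftest import toy_dataset


def welch_by_hand(a, b):
    """Independent textbook computation of Welch's t and two-sided p."""
    from scipy.stats import t as tdist

    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def _de_dataset(a_vals, b_vals):
    x = np.array(a_vals + b_vals, dtype=float)[:, None]
    ds = toy_dataset(x)
    ds.set_layer("normalized", 2.0 ** x)
    mask_a = np.array([True] * len(a_vals) + [False] * len(b_vals))
    return ds, mask_a, ~mask_a


class TestWelchDE:
    def test_identical_groups_give_t0_p1(self):
        ds, a, b = _de_dataset([1.0, 2, 3], [1.0, 2, 3])
        res = sk.welch_de(ds, a, b)
        row = res.table.iloc[0]
        assert row["t"] == 0.0 and row["p"] == 1.0

    def test_matches_textbook_formula(self):
        ds, a, b = _de_dataset([1.0, 2, 3, 4], [2.0, 3, 4, 5])
        res = sk.welch_de(ds, a, b)
        t_ref, p_ref = welch_by_hand([1, 2, 3, 4], [2, 3, 4, 5])
        assert res.table["t"].iloc[0] == pytest.approx(t_ref)
        assert res.table["p"].iloc[0] == pytest.approx(p_ref)

    def test_protein_below_min_values_untested(self):
        ds, a, b = _de_dataset([1.0, 2, np.nan, np.nan], [2.0, 3, 4, 5])
        res = sk.welch_de(ds, a, b, min_per_group=3)
        assert not res.table["tested"].iloc[0]
        assert np.isnan(res.table["p"].iloc[0])

    def test_overlapping_groups_rejected(self):
        ds, a, b = _de_dataset([1.0, 2, 3], [4.0, 5, 6])
        with pytest.raises(ValueError, match="overlap"):
            sk.welch_de(ds, a, a)

    def test_global_null_type_one_error_calibrated(self):
        # pooled over 3 seeds: raw p < 0.05 within 1.5 binomial SD of 5%
        fracs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, (60, 1000))
            ds = toy_dataset(x)
            ds.set_layer("normalized", 2.0 ** x)
            ga = np.zeros(60, bool)
            ga[:30] = True
            res = sk.welch_de(ds, ga, ~ga)
            fracs.append(float((res.table["p"] < 0.05).mean()))
        pooled = np.mean(fracs)
        band = 1.5 * math.sqrt(0.05 * 0.95 / 3000)
        assert abs(pooled - 0.05) < band

    def test_q_monotone_in_rank_order(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (40, 200))
        x[:20, :50] += 1.0
        ds = toy_dataset(x)
        ds.set_layer("normalized", 2.0 ** x)
        ga = np.array([True] * 20 + [False] * 20)
        res = sk.welch_de(ds, ga, ~ga)
        tab = res.table.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(tab["q"]) >= -1e-12).all()
        assert tab["q"].iloc[0] >= tab["p"].iloc[0]


class TestBHAdjust:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            sk.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sk.bh_adjust([0.3]), [0.3])

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(sk.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_input_empty_output(self):
        assert sk.bh_adjust([]).size == 0

    def test_nan_entries_do_not_count_toward_m(self):
        q = sk.bh_adjust([0.01, np.nan, 0.04])
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])
        assert np.isnan(q[1])


class TestFoldChange:
    def test_simple_ratios(self):
        ds, a, b = _de_dataset([0.0], [0.0])
        ds.set_layer("normalized", np.array([[20.0], [10.0]]))
        fc = sk.log2_fold_change(ds, [True, False], [False, True])
        assert fc.iloc[0] == pytest.approx(1.0)
        fc = sk.log2_fold_change(ds, [False, True], [True, False])
        assert fc.iloc[0] == pytest.approx(-1.0)

    def test_group_swap_negates_all_values(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(2, 1, (20, 30))
        ds = toy_dataset(np.log2(x))
        ds.set_layer("normalized", x)
        ga = np.array([True] * 10 + [False] * 10)
        ab = sk.log2_fold_change(ds, ga, ~ga)
        ba = sk.log2_fold_change(ds, ~ga, ga)
        np.testing.assert_allclose(ab, -ba)

    def test_invariant_to_global_scaling(self):
        rng = np.random.default_rng(6)
        x = rng.lognormal(2, 1, (20, 30))
        ga = np.array([True] * 10 + [False] * 10)
        ds = toy_dataset(np.log2(x))
        ds.set_layer("normalized", x)
        ds2 = toy_dataset(np.log2(x))
        ds2.set_layer("normalized", x * 11.0)
        np.testing.assert_allclose(
            sk.log2_fold_change(ds, ga, ~ga), sk.log2_fold_change(ds2, ga, ~ga)
        )


class TestHypergeomEnrichment:
    def test_fully_enriched_closed_form(self):
        # N=10, K=5, n=5, k=5 -> C(5,5)C(5,0)/C(10,5) = 1/252
        assert hypergeom_pvalue(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_empty_term_gets_p_one(self):
        assert hypergeom_pvalue(0, 5, 0, 10) == 1.0

    def test_matches_exact_combinatorial_sum_small_universes(self):
        # every (N, K, n, k) with N <= 12 against the exact tail sum
        for N in range(2, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        exact = sum(
                            math.comb(K, i) * math.comb(N - K, n - i)
                            for i in range(k, min(n, K) + 1)
                        ) / math.comb(N, n)
                        assert hypergeom_pvalue(k, n, K, N) == pytest.approx(
                            exact, rel=1e-9
                        ), (N, K, n, k)

    def test_foreground_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            sk.hypergeom_enrichment(["x"], ["a", "b"], {"t": {"a"}})

    def test_enrichment_table_flags_overrepresented_term(self):
        bg = [f"p{i}" for i in range(40)]
        fg = bg[:10]
        terms = {"hit": set(bg[:10]), "flat": set(bg[::2])}
        res = sk.hypergeom_enrichment(fg, bg, terms)
        assert res.table.loc["hit", "p"] < res.table.loc["flat", "p"]
        assert res.table.loc["hit", "k"] == 10


class TestTrajectorySelection:
    def _planted_dataset(self, seed=0):
        # 30 trajectory proteins among 300 flat ones, three populations
        cfg = sk.SimulationConfig(
            n_proteins=330, n_plates=2, plate_cols=18, seed=seed,
            frac_trajectory=30 / 330,
        )
        ds, gt = sk.simulate_dataset(cfg)
        ds, _ = sk.normalize_medians(ds)
        ds = sk.mask_noise_floor(ds)
        ds, _ = sk.filter_cells(ds, min_proteins_per_cell=30)
        ds = sk.filter_proteins_min_cells(ds)
        ds = sk.median_shift_and_log2(ds)
        return ds, gt

    def test_planted_proteins_recovered_with_oracle_clusters(self):
        ds, gt = self._planted_dataset()
        clusters = ds.cells["population"].astype(str)
        sel = set(
            sk.trajectory_protein_selection(
                ds, clusters, min_cells=200, min_lfc=0.15, alpha=0.05
            )
        )
        truth = set(gt.trajectory_proteins) & set(ds.proteins.index)
        precision = len(sel & truth) / max(len(sel), 1)
        recall = len(sel & truth) / len(truth)
        assert precision >= 0.8 and recall >= 0.8

    def test_low_coverage_protein_excluded_regardless_of_effect(self):
        ds, _ = self._planted_dataset()
        detected = np.isfinite(ds.layer("normalized")).sum(axis=0)
        thin = detected < 200
        assert thin.any()
        sel = sk.trajectory_protein_selection(
            ds, ds.cells["population"].astype(str), min_cells=200
        )
        assert not set(ds.proteins.index[thin]) & set(sel)

    def test_small_fold_changes_excluded(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 0.005, (300, 20))
        x[:150] += 0.08  # |lfc| ~ 0.08 < 0.15 everywhere
        ds = toy_dataset(x)
        ds.set_layer("normalized", 2.0 ** x)
        clusters = pd.Series(["a"] * 150 + ["b"] * 150)
        sel = sk.trajectory_protein_selection(
            ds, clusters, min_cells=100, min_lfc=0.15, alpha=0.05
        )
        assert len(sel) == 0

    def test_single_cluster_falls_back_with_warning(self):
        ds, _ = self._planted_dataset()
        with pytest.warns(UserWarning, match="single"):
            sel = sk.trajectory_protein_selection(
                ds, pd.Series(["only"] * ds.n_cells), min_cells=200
            )
        assert len(sel) > 0


class TestHeatmapMachinery:
    def test_window_one_is_identity(self):
        x = np.random.default_rng(8).normal(size=(30, 4))
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_moving_average_edges_use_truncated_windows(self):
        x = np.arange(5.0)[:, None]
        out = moving_average(x, 3).reshape(-1)
        np.testing.assert_allclose(out, [0.5, 1.0, 2.0, 3.0, 3.5])

    def test_minmax_constant_maps_to_zero(self):
        np.testing.assert_array_equal(minmax_01(np.full((4, 1), 3.0)), 0.0)

    def test_identical_proteins_collapse_to_one_profile(self):
        rng = np.random.default_rng(9)
        n_cells = 60
        base = np.sin(np.linspace(0, 3, n_cells))
        x = np.tile(base[:, None], (1, 6)) + rng.normal(0, 1e-9, (n_cells, 6))
        ds = toy_dataset(x)
        ds.set_layer("imputed", x)
        pt = pd.Series(np.linspace(0, 1, n_cells), index=ds.cells.index)
        hm = protein_cluster_signatures(
            ds, ds.proteins.index, pt, n_clusters=2, window=5
        )
        # all proteins end up in effectively identical profiles
        profiles = hm.matrix.to_numpy()
        assert np.ptp(profiles, axis=0).max() < 1e-6
        sig = hm.signatures.to_numpy()
        np.testing.assert_allclose(sig[0], profiles[0], atol=1e-9)

    def test_more_clusters_than_proteins_rejected(self):
        x = np.random.default_rng(10).normal(size=(20, 3))
        ds = toy_dataset(x)
        ds.set_layer("imputed", x)
        pt = pd.Series(np.linspace(0, 1, 20), index=ds.cells.index)
        with pytest.raises(ValueError, match="n_clusters"):
            protein_cluster_signatures(ds, ds.proteins.index, pt, n_clusters=5)

    def test_cluster_count_and_signature_range(self, trajectory_run):
        ds, emb_ds, emb, gt = trajectory_run
        root = sk.choose_root_cell(emb, emb_ds.cells["population"], "LSC")
        pt = sk.diffusion_pseudotime(emb, root, n_dcs=2)
        sel = emb_ds.proteins.index[:40]
        hm = protein_cluster_signatures(emb_ds, sel, pt, n_clusters=5, window=50)
        assert hm.protein_clusters.nunique() <= 5
        assert hm.signatures.to_numpy().min() >= 0.0
        assert hm.signatures.to_numpy().max() <= 1.0
        assert list(hm.matrix.columns) == list(hm.cell_order)
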