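import numpy as np
import pandas as pd
import pytest

import scmskit as sk


@pytest.fixture(scope="session")
def default_sim():
    """One simulated plate at default study conditions."""
    cfg = sk.SimulationConfig(n_proteins=400, seed=3)
    return sk.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def processed(default_sim):
    """The default plate run through the normalization/QC chain."""
    ds, gt = default_sim
    ds, factors = sk.normalize_medians(ds)
    ds = sk.mask_noise_floor(ds)
    ds, report = sk.filter_cells(ds, min_proteins_per_cell=30)
    ds = sk.filter_proteins_min_cells(ds)
    ds = sk.median_shift_and_log2(ds)
    return ds, gt, factors, report


@pytest.fixture(scope="session")
def trajectory_run():
    """A ~500-cell differentiation continuum through the full pipeline."""
    cfg = sk.SimulationConfig(
        n_proteins=500, n_plates=2, plate_cols=18, tau_uniform=True, seed=0
    )
    ds, gt = sk.simulate_dataset(cfg)
    ds, _ = sk.normalize_medians(ds)
    ds = sk.mask_noise_floor(ds)
    ds, _ = sk.filter_cells(ds, min_proteins_per_cell=30)
    ds = sk.filter_proteins_min_cells(ds)
    ds = sk.median_shift_and_log2(ds)
    emb_ds = sk.prepare_embedding_layers(ds, 0.4, knn_k=5)
    emb = sk.embed_cells(
        emb_ds.layer("scaled"),
        n_pcs=30,
        n_neighbors=15,
        methods=("umap", "diffusion_map"),
        seed=0,
        cell_ids=emb_ds.cells.index,
    )
    return ds, emb_ds, emb, gt


def toy_dataset(x, populations=None, layer="log2"):
    """Small dataset wrapper around an explicit matrix (cells x proteins)."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"))
    if populations is not None:
        obs["population"] = list(populations)
    obs["file_id"] = "f1"
    obs["channel"] = [str(126 + i) for i in range(n)]
    var = pd.DataFrame(index=pd.Index([f"p{j}" for j in range(p)], name="protein_id"))
    ds = sk.ScmsDataset.from_matrix(np.abs(np.nan_to_num(x, nan=1.0)) + 1.0, obs, var)
    ds.set_layer(layer, x)
    return ds


def brute_force_knn_impute(x, k):
    """Independent exhaustive-search reference for kNN imputation."""
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    out = x.copy()
    for c in range(n):
        dists = []
        for o in range(n):
            if o == c:
                dists.append(np.inf)
                continue
            shared = np.isfinite(x[c]) & np.isfinite(x[o])
            if shared.any():
                dists.append(np.sqrt(((x[c][shared] - x[o][shared]) ** 2).mean()))
            else:
                dists.append(np.inf)
        nbrs = np.argsort(dists, kind="stable")[:k]
        for j in range(p):
            if not np.isfinite(x[c, j]):
                vals = x[nbrs, j]
                vals = vals[np.isfinite(vals)]
                out[c, j] = vals.mean() if len(vals) else np.nanmean(x[:, j])
    return out
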