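"""Imputation, scaling, dimensionality reduction and pseudotime.

Missing values must be imputed before embedding, but low-coverage
proteins tend to be of low abundance and imputing them mostly injects
noise. The coverage cutoff is therefore chosen per dataset: candidate
thresholds from "drop anything with a missing value" down to "keep all"
are scored by the separation of known cell labels (mean silhouette in
2-D UMAP space after imputation) and the best one wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
from sklearn.metrics import silhouette_samples

from .dataset import ScmsDataset


# ---------------------------------------------------------------------------
# kNN imputation


def _pairwise_missing_aware_distances(x: np.ndarray) -> np.ndarray:
    """Euclidean distance over mutually observed features, rescaled by the
    shared-feature count (root mean squared difference). Pairs with no
    shared feature get infinite distance."""
    m = np.isfinite(x).astype(float)
    z = np.where(np.isfinite(x), x, 0.0)
    sq = z * z
    d2 = sq @ m.T + m @ sq.T - 2.0 * (z @ z.T)
    counts = m @ m.T
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 / counts
    d2[counts == 0] = np.inf
    np.clip(d2, 0.0, None, out=d2)  # numerical negatives
    d = np.sqrt(d2)
    np.fill_diagonal(d, np.inf)
    return d


def impute_knn(matrix: np.ndarray, k: int = 5) -> np.ndarray:
    """Fill missing entries from the k nearest cells.

    Distance between cells is the root mean squared difference over
    mutually observed proteins. A missing entry (cell c, protein p)
    becomes the mean of p's observed values among c's k nearest cells;
    if none of those neighbours observes p the protein's global observed
    mean is used. Observed entries are never changed.
    """
    x = np.asarray(matrix, dtype=float)
    n_cells = x.shape[0]
    if k >= n_cells:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n_cells})")
    if not np.isfinite(x).any(axis=1).all():
        raise ValueError("every cell needs at least one observed value")
    if np.isfinite(x).all():
        return x.copy()
    d = _pairwise_missing_aware_distances(x)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        global_mean = np.nanmean(x, axis=0)
        neighbour_means = np.stack([np.nanmean(x[order[i]], axis=0) for i in range(n_cells)])
    fill = np.where(np.isfinite(neighbour_means), neighbour_means, global_mean[None, :])
    return np.where(np.isfinite(x), x, fill)


def scale_features(matrix: np.ndarray) -> np.ndarray:
    """Scale each protein to zero mean and unit (sample) variance.

    Constant proteins become all zeros, with a warning.
    """
    x = np.asarray(matrix, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance proteins scaled to zeros")
    safe = np.where(zero_var, 1.0, sd)
    out = (x - mean) / safe
    out[:, zero_var] = 0.0
    return out


# ---------------------------------------------------------------------------
# embedding

@dataclass
class EmbeddingResult:
    """PC coordinates, neighbour graph and 2-D embeddings for one dataset."""

    pc_coordinates: np.ndarray
    coords: dict[str, np.ndarray]
    diffusion_components: np.ndarray | None
    cell_ids: pd.Index
    pseudotime: pd.Series | None = None
    _adata: ad.AnnData = field(default=None, repr=False)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def embed_cells(
    scaled: np.ndarray,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    methods: tuple[str, ...] = ("umap", "diffusion_map"),
    seed: int = 0,
    min_dist: float = 0.5,
    cell_ids: pd.Index | None = None,
) -> EmbeddingResult:
    """PCA -> neighbour graph -> requested 2-D embeddings.

    ``methods`` may include ``umap``, ``diffusion_map`` and
    ``force_directed``. Deterministic for a fixed seed.
    """
    x = np.asarray(scaled, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("embedding input must be complete (impute first)")
    n_cells, n_proteins = x.shape
    if n_pcs >= min(n_cells, n_proteins):
        raise ValueError(f"n_pcs={n_pcs} must be < min(cells, proteins)={min(n_cells, n_proteins)}")
    adata = ad.AnnData(X=x.astype(np.float32))
    if cell_ids is not None:
        adata.obs_names = cell_ids.astype(str)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, n_pcs=n_pcs, random_state=seed)
    coords: dict[str, np.ndarray] = {}
    diffusion = None
    if "umap" in methods:
        sc.tl.umap(adata, random_state=seed, min_dist=min_dist)
        coords["umap"] = adata.obsm["X_umap"][:, :2].copy()
    if "diffusion_map" in methods or "force_directed" in methods:
        sc.tl.diffmap(adata)
        diffusion = adata.obsm["X_diffmap"].copy()
        if "diffusion_map" in methods:
            # component 0 is the trivial steady state
            coords["diffusion_map"] = diffusion[:, 1:3].copy()
    if "force_directed" in methods:
        sc.tl.draw_graph(adata, layout="fr", random_state=seed)
        coords["force_directed"] = adata.obsm["X_draw_graph_fr"][:, :2].copy()
    return EmbeddingResult(
        pc_coordinates=adata.obsm["X_pca"].copy(),
        coords=coords,
        diffusion_components=diffusion,
        cell_ids=adata.obs_names,
        _adata=adata,
    )


def diffusion_pseudotime(
    emb: EmbeddingResult,
    root_cell: str | int,
    n_dcs: int = 10,
) -> pd.Series:
    """Diffusion pseudotime from a root cell, scaled to [0, 1].

    The root gets pseudotime 0; cells unreachable from the root in the
    neighbour graph get missing values rather than a sentinel.
    """
    adata = emb._adata
    if adata is None:
        raise ValueError("EmbeddingResult does not carry its graph; re-run embed_cells")
    if isinstance(root_cell, str):
        if root_cell not in adata.obs_names:
            raise KeyError(f"root cell {root_cell!r} not in dataset")
        iroot = int(np.where(adata.obs_names == root_cell)[0][0])
    else:
        iroot = int(root_cell)
        if not 0 <= iroot < adata.n_obs:
            raise KeyError(f"root cell index {iroot} out of range")
    adata.uns["iroot"] = iroot
    n_dcs = min(n_dcs, adata.obsm["X_diffmap"].shape[1] if "X_diffmap" in adata.obsm else n_dcs)
    sc.tl.dpt(adata, n_dcs=n_dcs)
    pt = adata.obs["dpt_pseudotime"].to_numpy(float).copy()
    pt[~np.isfinite(pt)] = np.nan
    finite = np.isfinite(pt)
    if finite.any() and np.nanmax(pt) > 0:
        pt = pt / np.nanmax(pt)
    series = pd.Series(pt, index=adata.obs_names, name="pseudotime")
    emb.pseudotime = series
    return series


def choose_root_cell(
    emb: EmbeddingResult, labels: pd.Series, root_population: str
) -> str:
    """Pick the root as the extremal cell of a population.

    Within ``root_population``, the cell with the extremal first (non-
    trivial) diffusion component is chosen -- the tip of the trajectory
    on the root side.
    """
    if emb.diffusion_components is None:
        raise ValueError("embedding has no diffusion components")
    dc1 = emb.diffusion_components[:, 1]
    mask = (labels.reindex(emb.cell_ids) == root_population).to_numpy()
    if not mask.any():
        raise ValueError(f"no cells labelled {root_population!r}")
    # the population cell farthest from the bulk of cells along DC1
    center = np.median(dc1)
    idx = int(np.argmax(np.where(mask, np.abs(dc1 - center), -np.inf)))
    return str(emb.cell_ids[idx])


# ---------------------------------------------------------------------------
# silhouettes and coverage-threshold selection


def silhouette_scores(
    coordinates: np.ndarray,
    labels,
    restrict_to: tuple[str, ...] | None = None,
) -> tuple[pd.Series, float]:
    """Per-sample silhouette coefficients s(i) = (b - a) / max(a, b).

    ``restrict_to`` limits the computation to a label subset (cells with
    other labels are excluded entirely), e.g. scoring only the two
    populations whose separation is of interest.
    """
    labels = pd.Series(np.asarray(labels), index=None).astype(str)
    coords = np.asarray(coordinates, dtype=float)
    if restrict_to is not None:
        keep = labels.isin([str(r) for r in restrict_to]).to_numpy()
        coords, labels = coords[keep], labels[keep].reset_index(drop=True)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("silhouette needs at least two labels")
    if (counts < 2).any():
        singles = counts[counts < 2].index.tolist()
        raise ValueError(f"singleton cluster(s): {singles}")
    vals = silhouette_samples(coords, labels.to_numpy())
    return pd.Series(vals, name="silhouette"), float(vals.mean())


def protein_coverage(matrix: np.ndarray) -> np.ndarray:
    """Fraction of cells in which each protein is observed."""
    return np.isfinite(matrix).mean(axis=0)


def select_coverage_threshold(
    ds: ScmsDataset,
    labels,
    grid=None,
    knn_k: int = 5,
    n_pcs: int = 20,
    n_neighbors: int = 15,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Choose the low-coverage protein cutoff by label separation.

    For every candidate coverage fraction: drop proteins observed in a
    smaller fraction of cells, impute (kNN), scale, embed to 2-D UMAP
    with a fixed seed and compute the mean silhouette of the given
    labels. Returns the argmax threshold (ties broken toward the lowest
    value, which keeps the most proteins) and the full score table.
    """
    labels = pd.Series(np.asarray(labels)).astype(str)
    if labels.nunique() < 2:
        raise ValueError("need at least two labelled groups")
    if grid is None:
        grid = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    x = ds.layer("log2")
    cov = protein_coverage(x)
    rows = []
    for t in grid:
        keep = cov >= t
        if keep.sum() < 2:
            rows.append({"threshold": t, "n_proteins": int(keep.sum()), "silhouette": np.nan})
            continue
        sub = x[:, keep]
        imputed = impute_knn(sub, k=knn_k)
        scaled = scale_features(imputed)
        emb = embed_cells(
            scaled,
            n_pcs=min(n_pcs, min(scaled.shape) - 1),
            n_neighbors=n_neighbors,
            methods=("umap",),
            seed=seed,
        )
        _, mean_sil = silhouette_scores(emb.coords["umap"], labels)
        rows.append({"threshold": t, "n_proteins": int(keep.sum()), "silhouette": mean_sil})
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["silhouette"])
    if valid.empty:
        raise ValueError("no threshold left enough proteins to embed")
    best = valid.loc[valid["silhouette"].idxmax()]
    # ties -> lowest threshold
    tied = valid[np.isclose(valid["silhouette"], best["silhouette"])]
    chosen = float(tied["threshold"].min())
    return chosen, table


def prepare_embedding_layers(
    ds: ScmsDataset, coverage_threshold: float, knn_k: int = 5
) -> ScmsDataset:
    """Apply the chosen coverage cutoff, impute and scale.

    Subsets the dataset to proteins at or above the cutoff and adds the
    ``imputed`` and ``scaled`` layers.
    """
    x = ds.layer("log2")
    keep = protein_coverage(x) >= coverage_threshold
    out = ds.subset(protein_mask=keep)
    imputed = impute_knn(out.layer("log2"), k=knn_k)
    out.set_layer("imputed", imputed)
    out.set_layer("scaled", scale_features(imputed))
    out.log_op(
        "prepare_embedding_layers",
        coverage_threshold=coverage_threshold,
        knn_k=knn_k,
        n_proteins=int(keep.sum()),
    )
    return out
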