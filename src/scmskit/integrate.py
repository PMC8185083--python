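"""Integration of unbalanced datasets.

The median-equalization normalization assumes every sample contains
comparable numbers of each population, which fails when a pre-enriched
experiment is combined with an unbiased bulk-sorted one. Such designs
are integrated after a per-protein coverage filter by aligning datasets
in PC space: the default backend detects mutual nearest neighbours
(MNN) between datasets -- cells of shared populations -- and applies a
locally weighted translation to each cell. An external panorama-style
tool can be plugged in through the same contract.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .dataset import ScmsDataset
from .embedding import impute_knn, scale_features


def coverage_filter(ds: ScmsDataset, min_fraction: float = 0.40, layer: str = "normalized") -> ScmsDataset:
    """Keep proteins with at least ``min_fraction`` valid values (inclusive)."""
    x = ds.layer(layer)
    frac = np.isfinite(x).mean(axis=0)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError(f"no protein reaches {min_fraction:.0%} coverage")
    out = ds.subset(protein_mask=keep)
    out.log_op("coverage_filter", min_fraction=min_fraction, n_kept=int(keep.sum()))
    return out


def _mnn_pairs(a: np.ndarray, b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mutual k-nearest-neighbour pairs (i in a, j in b) and their distances."""
    k_ab = min(k, len(b))
    k_ba = min(k, len(a))
    d_ab, nn_ab = NearestNeighbors(n_neighbors=k_ab).fit(b).kneighbors(a)
    nn_ba = NearestNeighbors(n_neighbors=k_ba).fit(a).kneighbors(b, return_distance=False)
    ba_sets = [set(row) for row in nn_ba]
    pairs, dists = [], []
    for i, (drow, row) in enumerate(zip(d_ab, nn_ab)):
        for d, j in zip(drow, row):
            if i in ba_sets[j]:
                pairs.append((i, j))
                dists.append(d)
    return np.asarray(pairs, dtype=int).reshape(-1, 2), np.asarray(dists)


def mnn_correct(
    reference: np.ndarray,
    target: np.ndarray,
    k: int = 20,
    sigma_quantile: float = 0.5,
    max_pair_dist_factor: float = 5.0,
) -> tuple[np.ndarray, int]:
    """Shift ``target`` onto ``reference`` via MNN-anchored translations.

    Mutual pairs farther apart than ``max_pair_dist_factor`` times the
    reference's own nearest-neighbour scale are discarded -- without
    overlapping populations no credible anchors remain and an error is
    raised. Pair vectors (reference - target) are averaged per target
    cell with Gaussian weights in the distance to the paired target
    cells; sigma is the given quantile of those distances. Returns the
    corrected target and the number of pairs used.
    """
    pairs, pair_d = _mnn_pairs(reference, target, k)
    if len(pairs):
        within = NearestNeighbors(n_neighbors=2).fit(reference)
        ref_scale = np.median(within.kneighbors(reference)[0][:, 1])
        keep = pair_d <= max_pair_dist_factor * max(ref_scale, 1e-12)
        pairs, pair_d = pairs[keep], pair_d[keep]
    if len(pairs):
        # one anchor per target cell: its closest mutual partner. This
        # keeps the anchor set unbiased (two identical datasets anchor
        # every cell to its own copy with a zero vector).
        best: dict[int, int] = {}
        for idx in np.argsort(pair_d, kind="stable"):
            tgt = int(pairs[idx, 1])
            if tgt not in best:
                best[tgt] = idx
        pairs = pairs[sorted(best.values())]
    if len(pairs) == 0:
        raise ValueError(
            "no mutual nearest neighbours within range between datasets -- "
            "no shared populations detectable"
        )
    # pair columns are (index into reference, index into target)
    vectors = reference[pairs[:, 0]] - target[pairs[:, 1]]
    anchors = target[pairs[:, 1]]
    d2 = ((target[:, None, :] - anchors[None, :, :]) ** 2).sum(axis=2)
    sigma2 = np.quantile(d2, sigma_quantile) + 1e-12
    w = np.exp(-d2 / (2.0 * sigma2))
    w_sum = w.sum(axis=1, keepdims=True)
    w = np.where(w_sum > 0, w / w_sum, 1.0 / w.shape[1])
    corrected = target + w @ vectors
    return corrected, len(pairs)


def integrate_unbalanced(
    datasets: list[ScmsDataset],
    backend: str = "mnn_simple",
    min_coverage: float = 0.40,
    n_pcs: int = 20,
    knn_k: int = 5,
    mnn_k: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Joint PC-space embedding of unbalanced datasets.

    Each dataset is coverage-filtered, restricted to the shared protein
    space, imputed and scaled; a joint PCA is computed and every non-
    reference dataset is aligned to the first by the chosen backend.
    Returns ``(corrected_pcs, cell_table)`` where ``cell_table`` carries
    cell_id, dataset index and population.

    Backends: ``mnn_simple`` (built-in mutual-nearest-neighbour
    translation) or ``panorama`` (delegates to the external ``scanorama``
    package if installed).
    """
    if not datasets:
        raise ValueError("no datasets given")
    layer = "log2" if datasets[0].has_layer("log2") else "normalized"
    filtered = [coverage_filter(ds, min_coverage, layer=layer) for ds in datasets]
    shared = filtered[0].proteins.index
    for ds in filtered[1:]:
        shared = shared.intersection(ds.proteins.index)
    if len(shared) == 0:
        raise ValueError("no shared proteins after coverage filtering")
    blocks = []
    meta = []
    for di, ds in enumerate(filtered):
        sub = ds.subset(protein_mask=ds.proteins.index.isin(shared))
        # align column order
        order = sub.proteins.index.get_indexer(shared)
        x = sub.layer(layer)[:, order]
        x = impute_knn(x, k=min(knn_k, x.shape[0] - 1))
        blocks.append(scale_features(x))
        meta.append(
            pd.DataFrame(
                {
                    "cell_id": sub.cells.index,
                    "dataset": di,
                    "population": sub.cells.get("population", pd.Series(index=sub.cells.index)),
                }
            )
        )
    joint = np.vstack(blocks)
    cell_table = pd.concat(meta, ignore_index=True)
    n_comp = min(n_pcs, min(joint.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(joint)

    if len(datasets) == 1:
        return pcs, cell_table

    if backend == "panorama":
        try:
            import scanorama  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "panorama backend requires the optional 'scanorama' package; "
                "use backend='mnn_simple' instead"
            ) from exc
        corrected, _ = scanorama.correct(
            [b for b in blocks], [list(shared)] * len(blocks), return_dimred=True
        )
        return np.vstack(corrected), cell_table
    if backend != "mnn_simple":
        raise ValueError(f"unknown backend {backend!r}")

    offsets = np.cumsum([0] + [b.shape[0] for b in blocks])
    ref = pcs[offsets[0] : offsets[1]]
    corrected = [ref]
    for di in range(1, len(blocks)):
        tgt = pcs[offsets[di] : offsets[di + 1]]
        fixed, n_pairs = mnn_correct(np.vstack(corrected), tgt, k=mnn_k)
        corrected.append(fixed)
    return np.vstack(corrected), cell_table
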