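"""Differential expression, enrichment and trajectory analysis.

Group comparisons use a two-sided Welch's t-test on the log2 layer with
missing values excluded (never imputed), Benjamini-Hochberg FDR control,
and log2 fold changes computed from the pre-log normalized s/n layer --
two deliberately different layers: the test statistic benefits from the
variance-stabilized scale while ratios of group means are only
meaningful on the original intensity scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .dataset import ScmsDataset


# ---------------------------------------------------------------------------
# Welch DE


@dataclass
class DEResult:
    """Per-protein two-group comparison results.

    ``table`` columns: mean_a, mean_b (pre-log normalized scale), n_a,
    n_b, t, p, q, log2_fc, tested, significant.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str
    fdr_alpha: float
    effect_floor: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def welch_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and two-sided p with Satterthwaite df."""
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1).

    NaN entries (untested) propagate as NaN and do not count toward m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def log2_fold_change(ds: ScmsDataset, group_a, group_b, layer: str = "normalized") -> pd.Series:
    """Per-protein log2 of the ratio of group means on the pre-log layer.

    Missing where either group mean is unavailable.
    """
    x = ds.layer(layer)
    a_mask = np.asarray(group_a, dtype=bool)
    b_mask = np.asarray(group_b, dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_a = np.nanmean(x[a_mask], axis=0)
        mean_b = np.nanmean(x[b_mask], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(mean_a / mean_b)
    fc[~np.isfinite(fc)] = np.nan
    return pd.Series(fc, index=ds.proteins.index, name="log2_fc")


def welch_de(
    ds: ScmsDataset,
    group_a,
    group_b,
    min_per_group: int = 3,
    fdr_alpha: float = 0.05,
    effect_floor: float = 0.0,
    label_a: str = "A",
    label_b: str = "B",
) -> DEResult:
    """Two-sided Welch's t-test per protein between two cell groups.

    ``group_a``/``group_b`` are disjoint boolean cell masks. A protein is
    tested only with at least ``min_per_group`` observed values in each
    group; others are reported untested. Tests run on the log2 layer;
    fold changes come from the pre-log normalized layer. BH-adjusted q
    and a significance flag (q < alpha and |log2FC| >= effect_floor) are
    attached.
    """
    a_mask = np.asarray(group_a, dtype=bool)
    b_mask = np.asarray(group_b, dtype=bool)
    if (a_mask & b_mask).any():
        raise ValueError("groups overlap")
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both groups must be non-empty")
    x = ds.layer("log2")
    xa, xb = x[a_mask], x[b_mask]
    n_a = np.isfinite(xa).sum(axis=0)
    n_b = np.isfinite(xb).sum(axis=0)
    tested = (n_a >= min_per_group) & (n_b >= min_per_group)
    t = np.full(ds.n_proteins, np.nan)
    p = np.full(ds.n_proteins, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(xa, xb, equal_var=False, nan_policy="omit", axis=0)
    t[tested] = np.asarray(res.statistic)[tested]
    p[tested] = np.asarray(res.pvalue)[tested]
    # identical groups yield zero variance -> t=0/0; define t=0, p=1
    degenerate = tested & ~np.isfinite(t)
    t[degenerate], p[degenerate] = 0.0, 1.0
    q = bh_adjust(p)
    fc = log2_fold_change(ds, a_mask, b_mask).to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        norm = ds.layer("normalized")
        mean_a = np.nanmean(norm[a_mask], axis=0)
        mean_b = np.nanmean(norm[b_mask], axis=0)
    sig = tested & (q < fdr_alpha) & (np.abs(np.nan_to_num(fc)) >= effect_floor)
    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "n_a": n_a,
            "n_b": n_b,
            "t": t,
            "p": p,
            "q": q,
            "log2_fc": fc,
            "tested": tested,
            "significant": sig,
        },
        index=ds.proteins.index,
    )
    return DEResult(table=table, group_a=label_a, group_b=label_b,
                    fdr_alpha=fdr_alpha, effect_floor=effect_floor)


# ---------------------------------------------------------------------------
# hypergeometric enrichment


@dataclass
class EnrichmentResult:
    """Per-term over-representation results (upper-tail hypergeometric)."""

    table: pd.DataFrame
    fdr_alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.fdr_alpha]


def hypergeom_pvalue(k: int, n_fg: int, k_bg: int, n_bg: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n_bg, K=k_bg, n=n_fg)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, n_bg, k_bg, n_fg))


def hypergeom_enrichment(
    foreground,
    background,
    term_annotations: dict[str, set] | pd.Series,
    fdr_alpha: float = 0.05,
) -> EnrichmentResult:
    """Term over-representation in a protein set.

    ``foreground`` must be a subset of ``background``;
    ``term_annotations`` maps term -> set of member proteins. For each
    term the upper-tail hypergeometric p of seeing at least the observed
    number of foreground hits is computed and BH-adjusted across terms;
    terms without foreground hits are reported with p = 1.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    if isinstance(term_annotations, pd.Series):
        term_annotations = {t: set(m) for t, m in term_annotations.items()}
    rows = []
    for term, members in sorted(term_annotations.items()):
        members_bg = set(members) & bg
        k = len(fg & members_bg)
        rows.append(
            {
                "term": term,
                "k": k,
                "n": len(fg),
                "K": len(members_bg),
                "N": len(bg),
                "p": hypergeom_pvalue(k, len(fg), len(members_bg), len(bg)),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    table["q"] = bh_adjust(table["p"].to_numpy())
    return EnrichmentResult(table=table, fdr_alpha=fdr_alpha)


# ---------------------------------------------------------------------------
# trajectory-variable proteins and heatmap machinery


def leiden_clusters(emb, resolution: float = 1.0, seed: int = 0) -> pd.Series:
    """Leiden community detection on the cell-neighbourhood graph."""
    import scanpy as sc

    adata = emb._adata
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="leiden",
        flavor="leidenalg",
    )
    return adata.obs["leiden"].astype(str)


def trajectory_protein_selection(
    ds: ScmsDataset,
    clusters: pd.Series,
    min_cells: int = 200,
    min_lfc: float = 0.15,
    alpha: float = 0.05,
    min_per_group: int = 3,
    use_adjusted: bool = True,
) -> pd.Index:
    """Select proteins that change along the trajectory.

    Each cell cluster is tested one-vs-rest (Welch on log2, fold change
    on the normalized non-imputed layer). A protein is selected if it is
    detected in at least ``min_cells`` cells, and in some cluster shows
    |log2FC| >= ``min_lfc`` at significance below ``alpha`` (BH-adjusted
    within each cluster comparison by default). Falls back to a variance
    ranking with a warning if only one cluster is present.
    """
    clusters = pd.Series(np.asarray(clusters)).astype(str)
    detected = np.isfinite(ds.layer("normalized")).sum(axis=0)
    coverage_ok = detected >= min_cells
    levels = clusters.unique()
    if len(levels) < 2:
        warnings.warn("single cell cluster found; falling back to variance ranking")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            var = np.nanvar(ds.layer("log2"), axis=0)
        order = np.argsort(var)[::-1]
        keep = order[: max(1, int(0.1 * ds.n_proteins))]
        mask = np.zeros(ds.n_proteins, bool)
        mask[keep] = True
        return ds.proteins.index[mask & coverage_ok]
    selected = np.zeros(ds.n_proteins, dtype=bool)
    for lv in levels:
        in_c = (clusters == lv).to_numpy()
        res = welch_de(ds, in_c, ~in_c, min_per_group=min_per_group, fdr_alpha=alpha)
        tab = res.table
        crit = tab["q"] if use_adjusted else tab["p"]
        hits = (
            tab["tested"]
            & (crit < alpha)
            & (tab["log2_fc"].abs() >= min_lfc)
        ).to_numpy()
        selected |= hits
    return ds.proteins.index[selected & coverage_ok]


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 with truncated edge windows."""
    if window <= 1:
        return np.asarray(values, dtype=float)
    df = pd.DataFrame(np.asarray(values, dtype=float))
    return df.rolling(window, min_periods=1, center=True).mean().to_numpy().squeeze()


def minmax_01(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Min-max normalize to [0, 1] along an axis; constants map to 0."""
    v = np.asarray(values, dtype=float)
    lo = np.nanmin(v, axis=axis, keepdims=True)
    hi = np.nanmax(v, axis=axis, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (v - lo) / np.where(span > 0, span, 1.0), 0.0)
    return out


@dataclass
class TrajectoryHeatmap:
    """Smoothed, 0-1 normalized expression along pseudotime ordering."""

    matrix: pd.DataFrame          # proteins x ordered cells, smoothed, [0,1]
    protein_clusters: pd.Series   # protein -> cluster id (1..n)
    signatures: pd.DataFrame      # cluster x ordered cells, [0,1]
    cell_order: pd.Index


def protein_cluster_signatures(
    ds: ScmsDataset,
    selected: pd.Index,
    pseudotime: pd.Series,
    n_clusters: int = 5,
    window: int = 50,
    layer: str = "imputed",
    metric: str = "correlation",
    linkage_method: str = "average",
) -> TrajectoryHeatmap:
    """Cluster trajectory proteins and build smoothed signatures.

    Cells are ordered by pseudotime; the selected proteins' (imputed)
    expression is smoothed with a moving average across the ordering
    (window truncated at the edges), min-max normalized to [0, 1] per
    protein, and clustered hierarchically (correlation distance, average
    linkage) into ``n_clusters``. Each cluster's signature is the mean of
    its members, again min-max normalized.
    """
    sel_idx = ds.proteins.index.get_indexer(selected)
    if (sel_idx < 0).any():
        raise KeyError("selected proteins not all present in dataset")
    if n_clusters > len(selected):
        raise ValueError(f"n_clusters={n_clusters} > {len(selected)} selected proteins")
    pt = pseudotime.reindex(ds.cells.index)
    order = np.argsort(pt.to_numpy(), kind="stable")
    x = ds.layer(layer)[order][:, sel_idx]  # ordered cells x proteins
    smoothed = moving_average(x, window).reshape(x.shape)
    normed = minmax_01(smoothed, axis=0)  # per protein over cells

    prof = normed.T  # proteins x cells
    if len(selected) == 1:
        cluster_ids = np.array([1])
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = pdist(prof, metric=metric)
        dist = np.nan_to_num(dist, nan=1.0)
        z = hierarchy.linkage(dist, method=linkage_method)
        cluster_ids = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    clusters = pd.Series(cluster_ids, index=selected, name="protein_cluster")

    sig_rows = {}
    for cid in sorted(set(cluster_ids)):
        members = prof[cluster_ids == cid]
        sig_rows[cid] = minmax_01(members.mean(axis=0), axis=0)
    signatures = pd.DataFrame(sig_rows).T
    cell_order = ds.cells.index[order]
    signatures.columns = cell_order
    matrix = pd.DataFrame(prof, index=selected, columns=cell_order)
    return TrajectoryHeatmap(
        matrix=matrix,
        protein_clusters=clusters,
        signatures=signatures,
        cell_order=cell_order,
    )
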