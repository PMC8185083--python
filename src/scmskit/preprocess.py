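"""Normalization and quality control of multiplexed single-cell MS data.

The chain: remove contaminants and failed runs -> iterative median
equalization across files and channels -> noise-floor masking -> summed
intensity based cell QC -> minimum-cells-per-protein filter -> per-cell
median shift and log2 transform. All operations work on NaN-masked
(cells x proteins) layers of a :class:`~scmskit.dataset.ScmsDataset` and
append to its provenance log.

Batch effects in compiled TMT experiments arise per LC-MS file (loading,
spray performance, peptide selection) and per reporter channel (labeling
efficiency, booster impurity bleed). With an actively balanced, channel-
randomized layout the true median of every protein is constant across
files and across channels, so both effects can be removed without a
bridge channel by equalizing medians: one correction factor per protein
per file and one per protein per channel, iterated until the matrix
stops changing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import NormalizationFactors, ScmsDataset

#: Consistency constant making the MAD estimate sigma-consistent for
#: normal data.
MAD_SCALE = 1.4826


# ---------------------------------------------------------------------------
# contaminants / failed runs


def remove_contaminants_and_failed_runs(
    ds: ScmsDataset,
    contaminant_column: str = "Contaminant",
    run_min_proteins: int = 1,
    exclude_rows: list[str] | None = None,
) -> ScmsDataset:
    """Drop flagged contaminant proteins, failed files and excluded rows.

    A file "fails" when fewer than ``run_min_proteins`` proteins carry any
    value in its cells. ``exclude_rows`` removes whole plate rows (e.g.
    rows hit by a preparation batch effect confounded with biology).
    """
    out = ds
    if contaminant_column in ds.proteins.columns:
        flags = _as_bool(ds.proteins[contaminant_column])
        if flags.any():
            out = out.subset(protein_mask=~flags)
            out.log_op("remove_contaminants", n_removed=int(flags.sum()))
    raw = out.layer("raw_sn")
    counts = (
        pd.Series(np.isfinite(raw).sum(axis=1), index=out.cells.index)
        .groupby(out.cells["file_id"], observed=True)
        .sum()
    )
    failed = counts[counts < run_min_proteins].index.tolist()
    if failed:
        keep = ~out.cells["file_id"].isin(failed).to_numpy()
        out = out.subset(cell_mask=keep)
        out.log_op("remove_failed_runs", files=failed)
    if exclude_rows:
        keep = ~out.cells["well_row"].isin(exclude_rows).to_numpy()
        if not keep.any():
            raise ValueError("row exclusion would remove every cell")
        out = out.subset(cell_mask=keep)
        out.log_op("exclude_rows", rows=list(exclude_rows))
    if out.n_cells == 0:
        raise ValueError("all cells removed by contaminant/run filtering")
    return out


def _as_bool(col: pd.Series) -> np.ndarray:
    if col.dtype == bool:
        return col.to_numpy()
    return col.astype(str).str.lower().isin({"true", "yes", "1", "+"}).to_numpy()


# ---------------------------------------------------------------------------
# iterative median equalization


def _level_medians(x: np.ndarray, codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Per-level nanmedian of a cells x proteins matrix -> levels x proteins."""
    med = np.full((n_levels, x.shape[1]), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        for lv in range(n_levels):
            rows = x[codes == lv]
            if len(rows):
                med[lv] = np.nanmedian(rows, axis=0)
    return med


def _equalize(x, codes, n_levels):
    """One sweep: scale each level so its per-protein median hits the
    grand median (median of the per-level medians). Returns the factor
    matrix (levels x proteins) actually applied."""
    med = _level_medians(x, codes, n_levels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        grand = np.nanmedian(med, axis=0)
    factors = grand[None, :] / med
    # undefined (protein absent from a level) or degenerate -> leave alone
    factors[~np.isfinite(factors)] = 1.0
    factors[factors <= 0] = 1.0
    x *= factors[codes, :]
    return factors


def normalize_medians(
    ds: ScmsDataset,
    convergence_threshold: float = 1.1,
    max_iter: int = 100,
) -> tuple[ScmsDataset, NormalizationFactors]:
    """Equalize per-protein medians across files and channels iteratively.

    Each iteration applies two sweeps -- per protein per file, then per
    protein per channel -- multiplying each level so its per-protein
    median matches that protein's grand median (median of level medians,
    missing values ignored). Iteration stops when the largest absolute
    elementwise change of the matrix relative to the previous iteration,
    in s/n units, falls below ``convergence_threshold``.

    Returns the dataset with a ``normalized`` layer plus the accumulated
    per-protein-per-file and per-protein-per-channel factors.
    """
    out = ds.copy()
    x = out.layer("raw_sn").astype(float).copy()
    files = out.cells["file_id"].astype(str)
    chans = out.cells["channel"].astype(str)
    file_levels = pd.Index(files.unique())
    chan_levels = pd.Index(chans.unique())
    fcodes = file_levels.get_indexer(files)
    ccodes = chan_levels.get_indexer(chans)

    acc_file = np.ones((len(file_levels), x.shape[1]))
    acc_chan = np.ones((len(chan_levels), x.shape[1]))

    converged = False
    max_change = np.inf
    iterations = 0
    for iterations in range(1, max_iter + 1):
        prev = x.copy()
        acc_file *= _equalize(x, fcodes, len(file_levels))
        acc_chan *= _equalize(x, ccodes, len(chan_levels))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            max_change = np.nanmax(np.abs(x - prev))
        if not np.isfinite(max_change):
            max_change = 0.0
        if max_change < convergence_threshold:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"median normalization did not converge in {max_iter} iterations "
            f"(last max change {max_change:.3g} s/n)"
        )
    out.set_layer("normalized", x)
    out.log_op(
        "normalize_medians",
        convergence_threshold=convergence_threshold,
        iterations=iterations,
        final_max_change=float(max_change),
        converged=converged,
    )
    factors = NormalizationFactors(
        file_factors=pd.DataFrame(acc_file, index=file_levels, columns=out.proteins.index),
        channel_factors=pd.DataFrame(acc_chan, index=chan_levels, columns=out.proteins.index),
        iterations_used=iterations,
        final_max_change=float(max_change),
        converged=converged,
    )
    return out, factors


def mask_noise_floor(ds: ScmsDataset, floor: float = 1.1) -> ScmsDataset:
    """Set normalized values strictly below the noise floor to missing."""
    out = ds.copy()
    x = out.layer("normalized").copy()
    mask = np.isfinite(x) & (x < floor)
    x[mask] = np.nan
    out.set_layer("normalized", x)
    out.log_op("mask_noise_floor", floor=floor, n_masked=int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# cell / protein filtering


@dataclass
class CellFilterReport:
    removed: pd.DataFrame  # cell_id, reason, log2_sum, n_proteins
    bounds: tuple[float, float]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def filter_cells(
    ds: ScmsDataset,
    mad_multiplier: float = 3.0,
    min_proteins_per_cell: int = 0,
) -> tuple[ScmsDataset, CellFilterReport]:
    """Remove outlier cells by summed intensity and protein count.

    The log2 of each cell's total summed s/n separates intact single
    cells from empty wells, doublets and preparation losses. Cells
    outside ``median +/- mad_multiplier * 1.4826 * MAD`` of that quantity,
    or with fewer than ``min_proteins_per_cell`` observed proteins, are
    removed; the report lists every removal with its reason.
    """
    x = ds.layer("normalized")
    with np.errstate(divide="ignore"):
        log2_sum = np.log2(np.nansum(x, axis=1))
    n_prot = np.isfinite(x).sum(axis=1)
    med = np.median(log2_sum[np.isfinite(log2_sum)])
    mad = np.median(np.abs(log2_sum[np.isfinite(log2_sum)] - med))
    half = mad_multiplier * MAD_SCALE * mad
    lo, hi = med - half, med + half
    bad_sum = ~np.isfinite(log2_sum) | (log2_sum < lo) | (log2_sum > hi)
    bad_count = n_prot < min_proteins_per_cell
    removed = bad_sum | bad_count
    if removed.all():
        raise ValueError("cell QC would remove every cell")
    reasons = np.where(bad_sum & bad_count, "sum_outlier+min_proteins",
                       np.where(bad_sum, "sum_outlier", "min_proteins"))
    report = CellFilterReport(
        removed=pd.DataFrame(
            {
                "cell_id": ds.cells.index[removed],
                "reason": reasons[removed],
                "log2_sum": log2_sum[removed],
                "n_proteins": n_prot[removed],
            }
        ).set_index("cell_id"),
        bounds=(float(lo), float(hi)),
    )
    out = ds.subset(cell_mask=~removed)
    out.log_op(
        "filter_cells",
        mad_multiplier=mad_multiplier,
        min_proteins_per_cell=min_proteins_per_cell,
        bounds=[float(lo), float(hi)],
        n_removed=int(removed.sum()),
    )
    return out, report


def filter_proteins_min_cells(ds: ScmsDataset, min_cells: int = 3) -> ScmsDataset:
    """Drop proteins quantified in fewer than ``min_cells`` cells.

    "Fewer than" is exclusive: a protein observed in exactly ``min_cells``
    cells is kept.
    """
    x = ds.layer("normalized")
    counts = np.isfinite(x).sum(axis=0)
    keep = counts >= min_cells
    out = ds.subset(protein_mask=keep)
    out.log_op("filter_proteins_min_cells", min_cells=min_cells, n_removed=int((~keep).sum()))
    return out


def median_shift_and_log2(ds: ScmsDataset) -> ScmsDataset:
    """Equalize per-cell totals to the median total, then log2 transform.

    The shift normalizes for cell size and sampling depth. The shifted
    pre-log matrix replaces the ``normalized`` layer (fold changes are
    computed there, never on imputed values); its elementwise log2 becomes
    the ``log2`` layer.
    """
    out = ds.copy()
    x = out.layer("normalized").copy()
    totals = np.nansum(x, axis=1)
    if np.any(totals <= 0):
        raise ValueError("cell with non-positive total s/n; run cell QC first")
    target = np.median(totals)
    x *= (target / totals)[:, None]
    out.set_layer("normalized", x)
    with np.errstate(divide="ignore"):
        out.set_layer("log2", np.log2(x))
    out.log_op("median_shift_and_log2", target_total=float(target))
    return out


# ---------------------------------------------------------------------------
# post-hoc QC diagnostics


def cramers_v(a: pd.Series, b: pd.Series) -> float:
    """Cramer's V association between two categorical variables."""
    tab = pd.crosstab(a, b)
    if tab.size == 0 or min(tab.shape) < 2:
        return 0.0
    chi2 = stats.chi2_contingency(tab, correction=False)[0]
    n = tab.to_numpy().sum()
    return float(np.sqrt(chi2 / (n * (min(tab.shape) - 1))))


def qc_factor_diagnostics(
    ds: ScmsDataset,
    factors: tuple[str, ...] = ("file_id", "channel", "well_row"),
    alpha: float = 0.01,
    population_column: str = "population",
) -> dict[str, pd.DataFrame]:
    """Check cell-level QC metrics for residual technical structure.

    For every technical factor (sample file, TMT channel, plate row) the
    per-level medians of summed intensity and protein count are reported
    with a Kruskal-Wallis heterogeneity p-value per metric; individual
    levels are flagged by a Mann-Whitney test of that level against all
    other cells at ``alpha``. The confounding of each factor with the
    population label is reported as Cramer's V -- a factor confounded
    with biology cannot be normalized away and the affected cells may
    need exclusion instead.
    """
    x = ds.layer("normalized") if ds.has_layer("normalized") else ds.layer("raw_sn")
    metrics = pd.DataFrame(
        {
            "summed_intensity": np.nansum(x, axis=1),
            "n_proteins": np.isfinite(x).sum(axis=1),
        },
        index=ds.cells.index,
    )
    out: dict[str, pd.DataFrame] = {}
    for factor in factors:
        if factor not in ds.cells.columns:
            continue
        lv = ds.cells[factor].astype(str)
        if lv.nunique() < 2:
            out[factor] = pd.DataFrame({"note": [f"single level: {lv.unique()[0]}"]})
            continue
        rows = []
        kw = {}
        for metric in metrics.columns:
            groups = [metrics[metric][lv == g].to_numpy() for g in lv.unique()]
            kw[metric] = stats.kruskal(*groups).pvalue if len(groups) > 1 else np.nan
        for g in lv.unique():
            in_g = (lv == g).to_numpy()
            row = {"level": g, "n_cells": int(in_g.sum())}
            flagged = False
            for metric in metrics.columns:
                vals = metrics[metric].to_numpy()
                row[f"median_{metric}"] = float(np.median(vals[in_g]))
                if in_g.sum() >= 2 and (~in_g).sum() >= 2:
                    p = stats.mannwhitneyu(vals[in_g], vals[~in_g]).pvalue
                    row[f"p_{metric}"] = p
                    flagged = flagged or p < alpha
            row["flagged"] = flagged
            rows.append(row)
        tab = pd.DataFrame(rows).set_index("level")
        for metric, p in kw.items():
            tab.attrs[f"kruskal_p_{metric}"] = p
        if population_column in ds.cells.columns:
            tab.attrs["cramers_v_population"] = cramers_v(
                lv, ds.cells[population_column].astype(str)
            )
        out[factor] = tab
    return out
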