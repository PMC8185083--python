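"""Quantitative-performance evaluation on technical replicates.

Benchmarks an acquisition method (e.g. an injection-time setting) from
replicate injections of one pooled sample: per-protein per-channel
coefficients of variation after a per-protein replicate equalization,
the fraction of precise proteins (CV below a threshold), agreement of
population fold changes with a bulk reference, and the separation of
labelled populations in PC space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .embedding import silhouette_scores


# ---------------------------------------------------------------------------
# replicate normalization and CVs


def replicate_normalize(
    replicates: list[pd.DataFrame],
) -> tuple[list[pd.DataFrame], pd.DataFrame]:
    """Equalize the per-protein median across replicate injections.

    Each replicate is a proteins x channels frame of raw s/n. For every
    protein, each replicate is scaled so its median over the single-cell
    channels equals the median of those per-replicate medians (one
    correction factor per protein per replicate). Returns the scaled
    replicates and the factor table (proteins x replicates).
    """
    if len(replicates) < 2:
        raise ValueError("need at least two replicates")
    idx = replicates[0].index
    for rep in replicates[1:]:
        if not rep.index.equals(idx):
            raise ValueError("replicates must share the same protein index")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.stack(
            [np.nanmedian(rep.to_numpy(float), axis=1) for rep in replicates], axis=1
        )  # proteins x replicates
        target = np.nanmedian(medians, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = target[:, None] / medians
    factors[~np.isfinite(factors)] = np.nan
    out = []
    for r, rep in enumerate(replicates):
        f = factors[:, r]
        scaled = rep.to_numpy(float) * np.where(np.isfinite(f), f, 1.0)[:, None]
        out.append(pd.DataFrame(scaled, index=idx, columns=rep.columns))
    factor_table = pd.DataFrame(
        factors, index=idx, columns=[f"rep{r + 1}" for r in range(len(replicates))]
    )
    return out, factor_table


def protein_cv_profile(
    normalized: list[pd.DataFrame],
    raw: list[pd.DataFrame],
    threshold: float = 0.20,
) -> "ReplicateEvalReport":
    """Per-protein per-channel CVs across replicate injections.

    CV(protein, channel) = sample SD (ddof 1) of the *normalized* s/n
    across replicates divided by the mean of the *raw* s/n across
    replicates. Channels observed in fewer than two replicates are
    skipped. Only proteins quantified in every replicate enter the
    report. The per-protein mean CV (over up to n_channels values) and
    the fraction of proteins with mean CV below ``threshold`` are
    summarized.
    """
    idx = normalized[0].index
    channels = normalized[0].columns
    norm = np.stack([r.to_numpy(float) for r in normalized])  # reps x prot x chan
    rawm = np.stack([r.to_numpy(float) for r in raw])
    present = np.isfinite(rawm).any(axis=2).all(axis=0)  # quantified in all reps
    n_obs = np.isfinite(norm).sum(axis=0)  # prot x chan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.nanstd(norm, axis=0, ddof=1)
        mean_raw = np.nanmean(rawm, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = sd / mean_raw
        cv[n_obs < 2] = np.nan
        cv[~present, :] = np.nan
        mean_cv = np.nanmean(cv, axis=1)
        mean_log2_sn = np.log2(np.nanmean(np.nanmean(rawm, axis=0), axis=1))
    cv_table = pd.DataFrame(cv, index=idx, columns=channels)
    per_protein = pd.DataFrame(
        {"mean_cv": mean_cv, "mean_log2_sn": mean_log2_sn}, index=idx
    )
    valid = per_protein["mean_cv"].dropna()
    pct_below = float((valid < threshold).mean()) if len(valid) else np.nan
    return ReplicateEvalReport(
        channel_cvs=cv_table,
        per_protein=per_protein,
        cv_threshold=threshold,
        pct_cv_below=pct_below,
        n_proteins_considered=int(valid.size),
    )


@dataclass
class ReplicateEvalReport:
    """Precision summary of one acquisition method."""

    channel_cvs: pd.DataFrame       # proteins x channels
    per_protein: pd.DataFrame       # mean_cv, mean_log2_sn
    cv_threshold: float
    pct_cv_below: float
    n_proteins_considered: int


# ---------------------------------------------------------------------------
# fold-change agreement with a bulk reference


def fold_change_agreement(
    sc_fc: pd.Series,
    bulk_fc: pd.Series,
    selection: str = "shared",
    n: int | None = None,
    coverage: pd.Series | None = None,
    complete_mask: pd.Series | None = None,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of single-cell vs bulk log2 fold changes.

    Selection of the protein subset:

    ``shared``
        proteins with a finite fold change in both inputs,
    ``complete_case``
        additionally restricted by ``complete_mask`` (proteins without
        any missing value across channels/replicates),
    ``top_n_coverage``
        the ``n`` highest-coverage proteins (requires ``coverage``).
    """
    joined = pd.DataFrame({"sc": sc_fc, "bulk": bulk_fc}).dropna()
    if selection == "complete_case":
        if complete_mask is None:
            raise ValueError("complete_case selection needs complete_mask")
        joined = joined[complete_mask.reindex(joined.index).fillna(False).astype(bool)]
    elif selection == "top_n_coverage":
        if coverage is None or n is None:
            raise ValueError("top_n_coverage selection needs coverage and n")
        ranked = coverage.reindex(joined.index).sort_values(ascending=False)
        joined = joined.loc[ranked.index[:n]]
    elif selection != "shared":
        raise ValueError(f"unknown selection {selection!r}")
    if len(joined) < 3:
        raise ValueError(f"only {len(joined)} overlapping proteins; need >= 3")
    r = float(sps.pearsonr(joined["sc"], joined["bulk"]).statistic)
    return r, joined


def binned_fc_difference(
    sc_fc: pd.Series,
    bulk_fc: pd.Series,
    mean_log2_sn: pd.Series,
    n_bins: int = 12,
    bulk_q: pd.Series | None = None,
    bulk_fdr: float = 0.05,
    bulk_min_abs_fc: float = 0.5,
) -> pd.DataFrame:
    """Absolute fold-change error vs the bulk reference across s/n bins.

    Optionally restricted to proteins significantly changed in bulk
    (FDR below ``bulk_fdr`` and |log2FC| above ``bulk_min_abs_fc``).
    Proteins are split into ``n_bins`` equal-count bins of mean log2 s/n
    and the per-bin median and quartiles of |sc - bulk| are reported.
    """
    df = pd.DataFrame({"sc": sc_fc, "bulk": bulk_fc, "sn": mean_log2_sn}).dropna()
    if bulk_q is not None:
        sig = (bulk_q.reindex(df.index) < bulk_fdr) & (df["bulk"].abs() > bulk_min_abs_fc)
        df = df[sig.fillna(False)]
    if len(df) < n_bins:
        raise ValueError(f"{len(df)} proteins cannot fill {n_bins} bins")
    df["abs_diff"] = (df["sc"] - df["bulk"]).abs()
    df["bin"] = pd.qcut(df["sn"].rank(method="first"), n_bins, labels=False)
    rows = []
    for b, grp in df.groupby("bin"):
        rows.append(
            {
                "bin": int(b),
                "n": len(grp),
                "mean_log2_sn": grp["sn"].mean(),
                "median_abs_diff": grp["abs_diff"].median(),
                "q25": grp["abs_diff"].quantile(0.25),
                "q75": grp["abs_diff"].quantile(0.75),
            }
        )
    return pd.DataFrame(rows).set_index("bin")


# ---------------------------------------------------------------------------
# PC-space silhouettes


def pc_space_silhouette(
    matrix: pd.DataFrame,
    labels: pd.Series,
    n_pcs: int = 20,
    restrict_to: tuple[str, str] | None = None,
    seed: int = 0,
) -> tuple[pd.Series, float]:
    """Label separation in PC space for one method's cell matrix.

    ``matrix`` is cells x proteins (NaN = missing). Complete-case
    proteins are selected, a per-cell median shift and log2 transform
    applied, the first ``n_pcs`` principal components computed, and
    silhouette coefficients of the requested labels returned.
    """
    x = matrix.to_numpy(float)
    complete = np.isfinite(x).all(axis=0)
    if not complete.any():
        raise ValueError("no complete-case proteins")
    x = x[:, complete]
    totals = x.sum(axis=1)
    x = x * (np.median(totals) / totals)[:, None]
    x = np.log2(x)
    n_comp = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_comp, random_state=seed).fit_transform(
        (x - x.mean(axis=0))
    )
    coeffs, mean = silhouette_scores(pcs, labels.to_numpy(), restrict_to=restrict_to)
    coeffs.index = matrix.index[: len(coeffs)] if restrict_to is None else coeffs.index
    return coeffs, mean
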