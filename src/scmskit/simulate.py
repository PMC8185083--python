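"""Synthetic multiplexed single-cell MS datasets with ground truth.

The generator emulates the statistical structure of booster-channel TMT
single-cell proteomics so every pipeline stage can be exercised and
validated against known truth:

* three cell populations placed on a one-dimensional differentiation
  axis tau in [0, 1] (stem -> progenitor -> blast),
* per-protein log-normal abundance programs, a subset of proteins
  changing linearly (in log2) along tau,
* multiplicative per-file and per-TMT-channel batch factors,
* additive isotopic-impurity bleed from the heavily loaded booster
  channel into its mass-adjacent channels,
* multiplicative log-normal measurement noise whose spread shrinks with
  nominal ion injection time (longer sampling, better counting
  statistics),
* abundance-dependent missingness (logistic detection in log2 signal),
* empty wells and doublets at configurable rates,
* index-FACS marker fluorescence tied monotonically to tau.

Reporter signal scales are chosen to resemble published single-cell TMT
runs: median s/n of a few units per protein per channel, roughly half of
the matrix missing at default detection parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ScmsDataset
from .layout import (
    BOOSTER_ADJACENT_CHANNELS,
    TMTPRO_16,
    PlateLayout,
    build_plate_layout,
)

LN2 = np.log(2.0)


@dataclass
class PopulationSpec:
    """One cell population: mixing weight and its centre on the tau axis."""

    name: str
    weight: float
    tau_center: float


DEFAULT_POPULATIONS = (
    PopulationSpec("LSC", 5 / 14, 0.10),
    PopulationSpec("Progenitor", 5 / 14, 0.50),
    PopulationSpec("Blast", 4 / 14, 0.85),
)


@dataclass
class SimulationConfig:
    """Generative parameters for a synthetic scMS experiment.

    Defaults describe one 384-well plate (24 samples x 14 single cells)
    of a three-population hierarchy measured at a 500 ms reference
    injection time.
    """

    n_proteins: int = 1000
    n_plates: int = 1
    plate_rows: int = 16
    plate_cols: int = 24
    channels: Sequence[str] = TMTPRO_16
    populations: Sequence[PopulationSpec] = DEFAULT_POPULATIONS
    tau_sd: float = 0.08
    tau_uniform: bool = False  # continuum mode: tau ~ U(0,1), label by nearest centre
    baseline_log2_mean: float = 2.5
    baseline_log2_sd: float = 1.5
    frac_trajectory: float = 0.20
    traj_effect_range: tuple[float, float] = (0.8, 2.0)
    cell_size_log2_sd: float = 0.25
    sigma_file: float = 0.30
    sigma_channel: float = 0.15
    booster_cells: float = 200.0
    booster_bleed_lambda: float = 0.002
    bleed_channels: Sequence[str] = BOOSTER_ADJACENT_CHANNELS
    sigma_noise: float = 0.10
    noise_ref_sn: float = 8.0
    noise_abundance_exp: float = 0.5
    noise_max_sigma: float = 2.0
    it_ref_ms: float = 500.0
    detection_a: float = -1.0
    detection_b: float = 0.8
    ambient_frac: float = 0.005
    empty_well_rate: float = 0.0
    doublet_rate: float = 0.0
    facs_noise_sd: float = 0.15
    facs_markers: tuple[str, str] = ("CD34", "CD38")
    seed: int = 0

    def __post_init__(self) -> None:
        weights = np.array([p.weight for p in self.populations], dtype=float)
        if np.any(weights <= 0):
            zero = [p.name for p, w in zip(self.populations, weights) if w <= 0]
            raise ValueError(f"populations with non-positive weight: {zero}")
        if not np.isclose(weights.sum(), 1.0):
            raise ValueError("population weights must sum to 1")
        if not 0 <= self.booster_bleed_lambda < 1:
            raise ValueError("booster bleed fraction must lie in [0, 1)")
        if self.detection_b <= 0:
            raise ValueError("detection slope b must be > 0")
        for name in ("tau_sd", "sigma_file", "sigma_channel", "sigma_noise",
                     "cell_size_log2_sd", "facs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.empty_well_rate < 1 or not 0 <= self.doublet_rate < 1:
            raise ValueError("empty_well_rate and doublet_rate must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Latent truths behind a simulated dataset, for recovery tests."""

    tau: pd.Series                    # per cell
    population: pd.Series
    is_empty: pd.Series
    is_doublet: pd.Series
    file_factors: pd.Series           # per file, strictly positive
    channel_factors: pd.Series        # per channel, strictly positive
    true_abundance: pd.DataFrame      # cells x proteins, pre-batch pre-noise s/n
    protein_params: pd.DataFrame      # baseline_log2, traj_slope, is_trajectory
    marker_proteins: dict[str, str]   # FACS marker -> protein id

    def __post_init__(self) -> None:
        n = len(self.tau)
        if n == 0:
            raise ValueError("GroundTruth must describe at least one cell")
        if self.true_abundance.shape[0] != n:
            raise ValueError("true_abundance rows must match the number of cells")
        for f in (self.file_factors, self.channel_factors):
            if (f <= 0).any():
                raise ValueError("batch factors must be strictly positive")

    @property
    def trajectory_proteins(self) -> pd.Index:
        return self.protein_params.index[self.protein_params["is_trajectory"]]


def _protein_programs(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    ids = [f"P{i + 1:05d}" for i in range(cfg.n_proteins)]
    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, cfg.n_proteins)
    slopes = np.zeros(cfg.n_proteins)
    n_traj = int(round(cfg.frac_trajectory * cfg.n_proteins))
    n_traj = max(n_traj, 2)  # the two FACS marker proteins always vary
    traj_idx = rng.choice(cfg.n_proteins, size=n_traj, replace=False)
    lo, hi = cfg.traj_effect_range
    mag = rng.uniform(lo, hi, n_traj)
    sign = rng.choice([-1.0, 1.0], n_traj)
    slopes[traj_idx] = mag * sign
    # marker proteins: one falling (stem marker), one rising along tau;
    # surface markers are abundant, hence precisely measured
    m_dec, m_inc = traj_idx[0], traj_idx[1]
    slopes[m_dec] = -abs(slopes[m_dec])
    slopes[m_inc] = abs(slopes[m_inc])
    for m in (m_dec, m_inc):
        baseline[m] = cfg.baseline_log2_mean + 1.5 * cfg.baseline_log2_sd
    params = pd.DataFrame(
        {
            "baseline_log2": baseline,
            "traj_slope": slopes,
            "is_trajectory": np.zeros(cfg.n_proteins, bool),
        },
        index=pd.Index(ids, name="protein_id"),
    )
    params.iloc[traj_idx, params.columns.get_loc("is_trajectory")] = True
    params.attrs["marker_rows"] = (int(m_dec), int(m_inc))
    return params


def _apply_noise(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    signal: np.ndarray,
    it_ms: float | None = None,
) -> np.ndarray:
    """Multiplicative log-normal measurement noise, counting-statistics style.

    The reporter ion population grows with both the channel's signal and
    the injection time, so the log-normal sigma for an entry of true
    signal s at injection time IT is

        sigma(s, IT) = sigma_noise * sqrt(it_ref / IT)
                       * (noise_ref_sn / s) ** noise_abundance_exp

    i.e. ``sigma_noise`` is the relative precision at the reference
    abundance (s/n = ``noise_ref_sn``) and reference injection time.
    Sigma is capped at ``noise_max_sigma`` for near-zero signals.
    """
    if cfg.sigma_noise == 0:
        return signal
    it_factor = 1.0 if it_ms is None else float(np.sqrt(cfg.it_ref_ms / it_ms))
    with np.errstate(divide="ignore"):
        rel = np.where(signal > 0, cfg.noise_ref_sn / signal, np.inf)
    sigma = cfg.sigma_noise * it_factor * rel ** cfg.noise_abundance_exp
    sigma = np.minimum(sigma, cfg.noise_max_sigma)
    return signal * np.exp(rng.normal(0.0, 1.0, signal.shape) * sigma)


def _draw_tau(cfg: SimulationConfig, populations: pd.Series, rng) -> np.ndarray:
    centers = {p.name: p.tau_center for p in cfg.populations}
    if cfg.tau_uniform:
        return rng.uniform(0.0, 1.0, len(populations))
    mu = populations.map(centers).to_numpy(float)
    return np.clip(mu + rng.normal(0.0, cfg.tau_sd, len(populations)), 0.0, 1.0)


def _true_log2(params: pd.DataFrame, tau: np.ndarray, size: np.ndarray) -> np.ndarray:
    b = params["baseline_log2"].to_numpy()
    s = params["traj_slope"].to_numpy()
    return b[None, :] + s[None, :] * (tau[:, None] - 0.5) + size[:, None]


def simulate_dataset(cfg: SimulationConfig) -> tuple[ScmsDataset, GroundTruth]:
    """Generate one synthetic experiment (dataset + ground truth).

    Deterministic for a fixed ``cfg.seed``. Doublets are sums of two
    cells' true abundances before measurement; empty wells carry only
    ambient background plus booster bleed.
    """
    rng = np.random.default_rng(cfg.seed)
    params = _protein_programs(cfg, rng)
    m_dec, m_inc = params.attrs["marker_rows"]

    # layout: one block per sample, balanced populations, seeded per plate
    layouts: list[PlateLayout] = []
    for p in range(cfg.n_plates):
        layouts.append(
            build_plate_layout(
                rows=cfg.plate_rows,
                cols=cfg.plate_cols,
                channels=cfg.channels,
                populations=[pop.name for pop in cfg.populations],
                balanced=True,
                seed=int(rng.integers(2**31 - 1)),
                plate_id=f"plate{p + 1}",
            )
        )
    wells = pd.concat([lay.single_cell_wells for lay in layouts], ignore_index=True)
    n_cells = len(wells)
    cell_ids = wells["file_id"] + "_" + wells["channel"]

    populations = wells["population"].astype(str)
    tau = _draw_tau(cfg, populations, rng)
    if cfg.tau_uniform:
        centers = np.array([p.tau_center for p in cfg.populations])
        names = [p.name for p in cfg.populations]
        populations = pd.Series(
            [names[i] for i in np.argmin(np.abs(tau[:, None] - centers[None, :]), axis=1)],
            index=populations.index,
        )

    is_empty = rng.random(n_cells) < cfg.empty_well_rate
    is_doublet = (~is_empty) & (rng.random(n_cells) < cfg.doublet_rate)

    size = rng.normal(0.0, cfg.cell_size_log2_sd, n_cells)
    true_sn = np.exp2(_true_log2(params, tau, size))
    if is_doublet.any():
        # second cell of the doublet: fresh tau from a random population
        pops2 = rng.choice([p.name for p in cfg.populations], size=n_cells)
        tau2 = _draw_tau(cfg, pd.Series(pops2), rng)
        size2 = rng.normal(0.0, cfg.cell_size_log2_sd, n_cells)
        other = np.exp2(_true_log2(params, tau2, size2))
        true_sn[is_doublet] += other[is_doublet]
    true_sn[is_empty] = 0.0

    baseline_sn = np.exp2(params["baseline_log2"].to_numpy())
    background = cfg.ambient_frac * baseline_sn[None, :]
    bleed = cfg.booster_bleed_lambda * cfg.booster_cells * baseline_sn
    in_bleed = wells["channel"].isin(cfg.bleed_channels).to_numpy()
    signal = true_sn + background
    signal[in_bleed] += bleed[None, :]

    file_levels = wells["file_id"].unique()
    chan_levels = pd.unique(wells["channel"])
    file_factors = pd.Series(
        rng.lognormal(0.0, cfg.sigma_file, len(file_levels)), index=file_levels
    )
    channel_factors = pd.Series(
        rng.lognormal(0.0, cfg.sigma_channel, len(chan_levels)), index=chan_levels
    )
    batch = (
        file_factors[wells["file_id"]].to_numpy()[:, None]
        * channel_factors[wells["channel"]].to_numpy()[:, None]
    )
    measured = _apply_noise(cfg, rng, signal * batch)

    # abundance-dependent detection on the true (pre-batch) signal
    if np.isfinite(cfg.detection_b):
        with np.errstate(divide="ignore"):
            logit = cfg.detection_a + cfg.detection_b * np.log2(
                np.where(signal > 0, signal, np.finfo(float).tiny)
            )
        p_obs = 1.0 / (1.0 + np.exp(-logit))
        observed = rng.random(measured.shape) < p_obs
        # keep the imputation precondition: every cell observes >= 1 protein
        none_seen = ~observed.any(axis=1)
        if none_seen.any():
            top = np.argmax(signal[none_seen], axis=1)
            observed[np.where(none_seen)[0], top] = True
    else:
        observed = np.ones(measured.shape, bool)
    raw = np.where(observed, measured, np.nan)

    # index-FACS markers: monotone transforms of tau + log-scale noise
    facs_dec = 10 ** ((1.0 - tau) * 2.0 + rng.normal(0.0, cfg.facs_noise_sd, n_cells))
    facs_inc = 10 ** (tau * 2.0 + rng.normal(0.0, cfg.facs_noise_sd, n_cells))
    facs_dec[is_empty] = np.nan
    facs_inc[is_empty] = np.nan

    name_dec, name_inc = cfg.facs_markers
    obs = pd.DataFrame(
        {
            "file_id": wells["file_id"].to_numpy(),
            "channel": wells["channel"].to_numpy(),
            "plate_id": wells["plate_id"].to_numpy(),
            "well": wells["well"].to_numpy(),
            "well_row": wells["well_row"].to_numpy(),
            "well_col": wells["well_col"].to_numpy(),
            "population": populations.to_numpy(),
            "is_empty_well": np.zeros(n_cells, bool),  # not known at sort time
            f"facs_{name_dec}": facs_dec,
            f"facs_{name_inc}": facs_inc,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    from .io import normalize_facs_unit

    for m in (name_dec, name_inc):
        col = obs[f"facs_{m}"]
        if np.isfinite(col).any():
            obs[f"facs_{m}_norm"] = normalize_facs_unit(col.to_numpy())

    var = pd.DataFrame(
        {
            "gene": params.index,
            "Contaminant": np.zeros(cfg.n_proteins, bool),
        },
        index=params.index,
    )
    ds = ScmsDataset.from_matrix(raw, obs, var)
    ds.log_op("simulate_dataset", seed=cfg.seed, n_proteins=cfg.n_proteins, n_cells=n_cells)

    gt = GroundTruth(
        tau=pd.Series(tau, index=obs.index, name="tau"),
        population=pd.Series(populations.to_numpy(), index=obs.index, name="population"),
        is_empty=pd.Series(is_empty, index=obs.index, name="is_empty"),
        is_doublet=pd.Series(is_doublet, index=obs.index, name="is_doublet"),
        file_factors=file_factors,
        channel_factors=channel_factors,
        true_abundance=pd.DataFrame(signal, index=obs.index, columns=params.index),
        protein_params=params,
        marker_proteins={
            name_dec: params.index[m_dec],
            name_inc: params.index[m_inc],
        },
    )
    return ds, gt


def injected_level_effects(
    gt: GroundTruth, labels: pd.Series, injected: pd.Series
) -> pd.Series:
    """Total multiplicative offset each file/channel carries in the data.

    The batch factor written into the matrix for a file or channel is
    the injected factor composed with that level's sampling-composition
    offset (its cells happen to be larger/smaller or drawn from slightly
    different positions on the differentiation axis). Median
    equalization removes the composite, so recovery tests should compare
    against it: per protein, the level's median true signal relative to
    the grand median, aggregated over proteins by the median, times the
    injected factor.
    """
    true = gt.true_abundance.to_numpy()
    labels = np.asarray(labels)
    grand = np.median(true, axis=0)
    grand = np.where(grand > 0, grand, np.nan)
    eff = {}
    for lv in injected.index:
        med = np.median(true[labels == lv], axis=0)
        eff[lv] = float(np.nanmedian(med / grand)) * injected[lv]
    return pd.Series(eff, name="effective_factor")


# ---------------------------------------------------------------------------
# technical replicates at different injection times


def sigma_noise_for_it(cfg: SimulationConfig, it_ms: float) -> float:
    """Measurement noise at a nominal injection time.

    Counting statistics improve with the accumulated ion population, so
    the log-normal sigma shrinks as 1/sqrt(IT) relative to the reference
    injection time.
    """
    if it_ms <= 0:
        raise ValueError("injection time must be positive")
    return cfg.sigma_noise * float(np.sqrt(cfg.it_ref_ms / it_ms))


def simulate_technical_replicates(
    cfg: SimulationConfig,
    n_replicates: int = 3,
    it_levels: Sequence[float] = (150.0, 300.0, 500.0, 1000.0),
    n_pool_cells: int = 12,
) -> tuple[dict[float, list[ScmsDataset]], dict]:
    """Replicate injections of one pooled sample at several IT settings.

    One 14-channel sample is pooled from ``n_pool_cells`` cells per
    channel (channels keep fixed populations, e.g. 5 stem / 5 progenitor
    / 4 blast), mimicking the pooling of many identically laid out
    single-cell samples into a single aliquot. All replicate injections
    at every IT level share the same true channel values; only the
    measurement-noise sigma and the measured signal scale (both set by
    the injection time) differ, so longer IT yields stochastically lower
    CVs and deeper detection.

    Returns ``(datasets, truth)`` where ``datasets[it]`` is the list of
    replicate datasets and ``truth`` carries the shared true channel
    matrix, the channel populations, and true population fold changes.
    """
    if n_replicates < 2:
        raise ValueError("need at least two replicates (CV undefined otherwise)")
    if any(it <= 0 for it in it_levels):
        raise ValueError("injection times must be positive")
    rng = np.random.default_rng(cfg.seed)
    params = _protein_programs(cfg, rng)

    from .layout import _balanced_counts, default_channel_roles, ChannelRole

    roles = default_channel_roles(cfg.channels)
    sc_channels = [c for c in cfg.channels if roles[c] == ChannelRole.SINGLE_CELL]
    counts = _balanced_counts(len(sc_channels), [p.name for p in cfg.populations])
    chan_pop = []
    for pop, k in zip(cfg.populations, counts):
        chan_pop.extend([pop.name] * k)
    chan_pop = pd.Series(chan_pop, index=pd.Index(sc_channels, name="channel"))

    # pooled true channel values, shared by every injection
    true_sn = np.zeros((len(sc_channels), cfg.n_proteins))
    for i, ch in enumerate(sc_channels):
        pops = pd.Series([chan_pop[ch]] * n_pool_cells)
        tau = _draw_tau(cfg, pops, rng)
        size = rng.normal(0.0, cfg.cell_size_log2_sd, n_pool_cells)
        true_sn[i] = np.exp2(_true_log2(params, tau, size)).sum(axis=0)
    baseline_sn = np.exp2(params["baseline_log2"].to_numpy())
    bleed = cfg.booster_bleed_lambda * cfg.booster_cells * baseline_sn
    in_bleed = chan_pop.index.isin(cfg.bleed_channels)
    signal = true_sn + cfg.ambient_frac * baseline_sn[None, :]
    signal[in_bleed] += bleed[None, :]

    datasets: dict[float, list[ScmsDataset]] = {}
    for it in it_levels:
        scale = it / cfg.it_ref_ms  # ion counts, hence s/n, grow with IT
        reps = []
        for r in range(n_replicates):
            measured = _apply_noise(cfg, rng, signal * scale, it_ms=it)
            if np.isfinite(cfg.detection_b):
                logit = cfg.detection_a + cfg.detection_b * np.log2(measured)
                observed = rng.random(measured.shape) < 1.0 / (1.0 + np.exp(-logit))
            else:
                observed = np.ones(measured.shape, bool)
            raw = np.where(observed, measured, np.nan)
            file_id = f"rep{r + 1}_it{int(it)}"
            obs = pd.DataFrame(
                {
                    "file_id": file_id,
                    "channel": list(sc_channels),
                    "plate_id": "pooled",
                    "well": [f"A{i + 1}" for i in range(len(sc_channels))],
                    "well_row": "A",
                    "well_col": np.arange(1, len(sc_channels) + 1),
                    "population": chan_pop.to_numpy(),
                    "is_empty_well": False,
                },
                index=pd.Index([f"{file_id}_{c}" for c in sc_channels], name="cell_id"),
            )
            var = pd.DataFrame(index=params.index.copy())
            var["gene"] = params.index
            rep_ds = ScmsDataset.from_matrix(raw, obs, var)
            rep_ds.log_op(
                "simulate_technical_replicate",
                it_ms=it,
                replicate=r + 1,
                sigma_ref=sigma_noise_for_it(cfg, it),
            )
            reps.append(rep_ds)
        datasets[it] = reps

    pop_means = {
        pop.name: true_sn[(chan_pop == pop.name).to_numpy()].mean(axis=0)
        for pop in cfg.populations
    }
    truth = {
        "true_sn": pd.DataFrame(true_sn, index=chan_pop.index, columns=params.index),
        "channel_populations": chan_pop,
        "population_means": pd.DataFrame(pop_means, index=params.index),
        "protein_params": params,
    }
    return datasets, truth


def replicate_to_frame(ds: ScmsDataset) -> pd.DataFrame:
    """Proteins x channels frame of one replicate injection."""
    return pd.DataFrame(
        ds.layer("raw_sn").T, index=ds.proteins.index, columns=ds.cells["channel"].to_numpy()
    )


# ---------------------------------------------------------------------------
# ground-truth persistence


def write_ground_truth(gt: GroundTruth, path) -> None:
    """Write the ground truth as TSV tables into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cells = pd.DataFrame(
        {
            "tau": gt.tau,
            "population": gt.population,
            "is_empty": gt.is_empty,
            "is_doublet": gt.is_doublet,
        }
    )
    cells.index.name = "cell_id"
    cells.to_csv(path / "cells.tsv", sep="\t")
    factors = pd.concat(
        [
            pd.DataFrame({"kind": "file", "level": gt.file_factors.index,
                          "factor": gt.file_factors.to_numpy()}),
            pd.DataFrame({"kind": "channel", "level": gt.channel_factors.index,
                          "factor": gt.channel_factors.to_numpy()}),
        ],
        ignore_index=True,
    )
    factors.to_csv(path / "factors.tsv", sep="\t", index=False)
    gt.true_abundance.to_csv(path / "true_abundance.tsv", sep="\t")
    params = gt.protein_params.copy()
    params["facs_marker"] = ""
    for marker, pid in gt.marker_proteins.items():
        params.loc[pid, "facs_marker"] = marker
    params.to_csv(path / "proteins.tsv", sep="\t")


def read_ground_truth(path) -> GroundTruth:
    """Inverse of :func:`write_ground_truth`."""
    path = Path(path)
    cells = pd.read_csv(path / "cells.tsv", sep="\t", index_col="cell_id")
    factors = pd.read_csv(path / "factors.tsv", sep="\t", dtype={"level": str})
    true_ab = pd.read_csv(path / "true_abundance.tsv", sep="\t", index_col=0)
    params = pd.read_csv(path / "proteins.tsv", sep="\t", index_col="protein_id",
                         keep_default_na=False, na_values=[""])
    markers = {
        str(row["facs_marker"]): pid
        for pid, row in params.iterrows()
        if isinstance(row["facs_marker"], str) and row["facs_marker"]
    }
    file_f = factors[factors["kind"] == "file"].set_index("level")["factor"]
    chan_f = factors[factors["kind"] == "channel"].set_index("level")["factor"]
    return GroundTruth(
        tau=cells["tau"],
        population=cells["population"].astype(str),
        is_empty=cells["is_empty"].astype(bool),
        is_doublet=cells["is_doublet"].astype(bool),
        file_factors=file_f,
        channel_factors=chan_f,
        true_abundance=true_ab,
        protein_params=params.drop(columns=["facs_marker"]).assign(
            is_trajectory=params["is_trajectory"].astype(bool)
        ),
        marker_proteins=markers,
    )
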