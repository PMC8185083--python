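"""Pipeline configuration.

All scalar thresholds of the processing chain live in one place so that a
run can be reproduced from a single config file. Units: signal-to-noise
(s/n) is the dimensionless reporter-ion quantity exported per protein per
channel; fold changes are log2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass
class PipelineConfig:
    """Scalar parameters of the processing and analysis chain.

    Parameters
    ----------
    convergence_threshold
        Iterative median normalization stops when the largest elementwise
        change between successive matrices falls below this value, in s/n
        units. The default 1.1 sits slightly above the reporter noise level.
    noise_floor
        Normalized s/n values strictly below this are set to missing.
    mad_multiplier
        Half-width of the cell QC window on log2 summed s/n, in units of
        the sigma-consistent MAD (scaled by 1.4826).
    min_proteins_per_cell
        Cells with fewer observed proteins are removed during QC.
    min_cells_per_protein
        Proteins observed in fewer cells are removed ("less than" is
        exclusive: a protein seen in exactly this many cells is kept).
    knn_k
        Number of nearest neighbour cells used for imputation.
    n_pcs_eval, n_pcs_embed
        Principal components used for replicate evaluation (silhouettes in
        PC space) and for the embedding neighbour graph, respectively.
    n_neighbors
        Size of the cell neighbourhood graph.
    coverage_grid
        Candidate per-protein coverage fractions tested when choosing the
        low-coverage cutoff before imputation; must be sorted ascending.
    de_min_per_group
        Minimum observed values per group for a protein to be tested.
    fdr_alpha
        Benjamini-Hochberg FDR cutoff.
    traj_min_cells, traj_min_lfc, traj_alpha
        Filters for trajectory-variable protein selection: detected in at
        least this many cells, absolute log2 fold change at least this, at
        a significance level below alpha in some cell cluster.
    smooth_window
        Moving-average window (cells) for trajectory heatmaps.
    n_protein_clusters
        Number of hierarchical protein clusters for the trajectory heatmap.
    integrate_min_coverage
        Minimum fraction of valid values per protein before integration of
        unbalanced datasets.
    """

    convergence_threshold: float = 1.1
    noise_floor: float = 1.1
    mad_multiplier: float = 3.0
    min_proteins_per_cell: int = 100
    min_cells_per_protein: int = 3
    knn_k: int = 5
    n_pcs_eval: int = 20
    n_pcs_embed: int = 50
    n_neighbors: int = 15
    umap_min_dist: float = 0.5
    coverage_grid: Sequence[float] = field(
        default_factory=lambda: (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    )
    de_min_per_group: int = 3
    fdr_alpha: float = 0.05
    traj_min_cells: int = 200
    traj_min_lfc: float = 0.15
    traj_alpha: float = 0.05
    leiden_resolution: float = 1.0
    smooth_window: int = 50
    n_protein_clusters: int = 5
    integrate_min_coverage: float = 0.40
    max_norm_iter: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "convergence_threshold",
            "noise_floor",
            "mad_multiplier",
            "traj_min_lfc",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        grid = tuple(float(t) for t in self.coverage_grid)
        if list(grid) != sorted(grid):
            raise ValueError("coverage_grid must be sorted ascending")
        self.coverage_grid = grid

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)
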