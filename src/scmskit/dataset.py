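"""The core dataset container.

``ScmsDataset`` wraps an :class:`anndata.AnnData` (cells as observations,
proteins as variables, matching the single-cell ecosystem convention) and
adds named layers with missing-value support plus an append-only
provenance log. Layers:

``raw_sn``
    reporter signal-to-noise as exported by the search engine (>= 0 where
    present, NaN where missing),
``normalized``
    after iterative median equalization (and later the per-cell median
    shift), still on the s/n scale -- fold changes are computed here,
``log2``
    log2 of the shifted normalized matrix,
``imputed`` / ``scaled``
    complete matrices produced before embedding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

LAYER_NAMES = ("raw_sn", "normalized", "log2", "imputed", "scaled")


@dataclass
class CellRecord:
    """Metadata of one sorted well (a single cell or a deliberate empty)."""

    cell_id: str
    file_id: str
    channel: str
    plate_id: str
    well_row: str
    well_col: int
    population: str | None = None
    facs: Mapping[str, float] = field(default_factory=dict)
    facs_norm: Mapping[str, float] = field(default_factory=dict)
    is_empty_well: bool = False

    @property
    def well(self) -> str:
        return f"{self.well_row}{self.well_col}"


@dataclass
class NormalizationFactors:
    """Accumulated correction factors from iterative median equalization.

    ``file_factors`` and ``channel_factors`` are (level x protein) frames
    of strictly positive multipliers applied to the raw matrix.
    """

    file_factors: pd.DataFrame
    channel_factors: pd.DataFrame
    iterations_used: int
    final_max_change: float
    converged: bool

    def __post_init__(self) -> None:
        for f in (self.file_factors, self.channel_factors):
            vals = f.to_numpy(float)
            if np.any(vals[np.isfinite(vals)] <= 0):
                raise ValueError("normalization factors must be positive")


class ScmsDataset:
    """Protein x cell signal matrix with layers, metadata and provenance."""

    def __init__(self, adata: ad.AnnData):
        if "provenance" not in adata.uns:
            adata.uns["provenance"] = json.dumps([])
        adata.uns.setdefault("scmskit_schema", SCHEMA_VERSION)
        self.adata = adata

    # -- construction ---------------------------------------------------
    @classmethod
    def from_matrix(
        cls,
        raw_sn: np.ndarray,
        cells: pd.DataFrame,
        proteins: pd.DataFrame,
    ) -> "ScmsDataset":
        """Build from a cells x proteins raw s/n matrix (NaN = missing)."""
        raw_sn = np.asarray(raw_sn, dtype=float)
        if np.nanmin(raw_sn, initial=0.0) < 0:
            raise ValueError("raw s/n values must be >= 0 where present")
        adata = ad.AnnData(
            X=raw_sn.copy(), obs=cells.copy(), var=proteins.copy()
        )
        adata.layers["raw_sn"] = raw_sn.copy()
        return cls(adata)

    # -- basic access ---------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.adata.n_obs

    @property
    def n_proteins(self) -> int:
        return self.adata.n_vars

    @property
    def cells(self) -> pd.DataFrame:
        return self.adata.obs

    @property
    def proteins(self) -> pd.DataFrame:
        return self.adata.var

    def layer(self, name: str) -> np.ndarray:
        if name not in self.adata.layers:
            raise KeyError(f"layer {name!r} not present; have {list(self.adata.layers)}")
        return self.adata.layers[name]

    def set_layer(self, name: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (self.n_cells, self.n_proteins):
            raise ValueError(
                f"layer shape {matrix.shape} != dataset shape {(self.n_cells, self.n_proteins)}"
            )
        self.adata.layers[name] = matrix

    def has_layer(self, name: str) -> bool:
        return name in self.adata.layers

    # -- provenance ------------------------------------------------------
    @property
    def provenance(self) -> list[dict]:
        return json.loads(self.adata.uns["provenance"])

    def log_op(self, operation: str, **params) -> None:
        entries = self.provenance
        entries.append(
            {
                "operation": operation,
                "params": {k: _jsonable(v) for k, v in params.items()},
                "timestamp": datetime.now(timezone.utc).isoformat(),
            }
        )
        self.adata.uns["provenance"] = json.dumps(entries)

    # -- subsetting ------------------------------------------------------
    def subset(self, cell_mask=None, protein_mask=None) -> "ScmsDataset":
        """Return a copied subset; provenance is carried over."""
        a = self.adata
        if cell_mask is not None:
            a = a[np.asarray(cell_mask)]
        if protein_mask is not None:
            a = a[:, np.asarray(protein_mask)]
        return ScmsDataset(a.copy())

    def copy(self) -> "ScmsDataset":
        return ScmsDataset(self.adata.copy())

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        self.adata.uns["scmskit_schema"] = SCHEMA_VERSION
        self.adata.write_h5ad(path)

    @classmethod
    def load(cls, path) -> "ScmsDataset":
        try:
            adata = ad.read_h5ad(path)
        except Exception as exc:  # corrupt / truncated container
            raise SchemaError(f"cannot read dataset container {path}: {exc}") from exc
        version = adata.uns.get("scmskit_schema")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"container schema version {version!r} != supported {SCHEMA_VERSION}"
            )
        return cls(adata)

    def export_layer_tsv(self, name: str, path) -> None:
        pd.DataFrame(
            self.layer(name), index=self.adata.obs_names, columns=self.adata.var_names
        ).to_csv(path, sep="\t")

    def __repr__(self) -> str:
        return (
            f"ScmsDataset({self.n_cells} cells x {self.n_proteins} proteins, "
            f"layers={list(self.adata.layers)})"
        )


class SchemaError(RuntimeError):
    """Raised when an on-disk container does not match the supported schema."""


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.ndarray, list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def records_to_obs(records: list[CellRecord]) -> pd.DataFrame:
    """Convert CellRecords to a cell metadata frame indexed by cell_id."""
    rows = []
    for r in records:
        row = {
            "file_id": r.file_id,
            "channel": r.channel,
            "plate_id": r.plate_id,
            "well": r.well,
            "well_row": r.well_row,
            "well_col": r.well_col,
            "population": r.population,
            "is_empty_well": r.is_empty_well,
        }
        for m, v in r.facs.items():
            row[f"facs_{m}"] = v
        for m, v in r.facs_norm.items():
            row[f"facs_{m}_norm"] = v
        rows.append(row)
    obs = pd.DataFrame(rows, index=[r.cell_id for r in records])
    obs.index.name = "cell_id"
    if obs.index.duplicated().any():
        dupes = obs.index[obs.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate (file, channel) cell ids: {dupes}")
    return obs
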