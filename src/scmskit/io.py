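"""Readers and writers for quant tables, layouts and index-FACS exports.

The protein table dialect follows search-engine wide exports: one row per
protein, annotation columns (accession, gene symbol, contaminant flag,
term annotations), and one abundance column per LC-MS file x TMT channel
named ``Abundance: <file>: <channel>`` (the ``Abundance:`` prefix is
optional). Blank and zero-coded abundances are treated as missing: a
reporter s/n of 0 is indistinguishable from non-detection in exports.
"""

from __future__ import annotations

import re
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import CellRecord, ScmsDataset, records_to_obs
from .layout import ChannelRole, PlateLayout

_ABUNDANCE_RE = re.compile(
    r"^(?:abundances?\s*:\s*)?(?P<file>.+?)\s*:\s*(?P<channel>\d{3}[NC]?)\s*$",
    re.IGNORECASE,
)

_DELIMS = {"tab": "\t", "comma": ","}


class TableFormatError(ValueError):
    """Raised when a quant table cannot be parsed in the stated dialect."""


def parse_abundance_column(name: str) -> tuple[str, str] | None:
    """Return (file_id, channel) if *name* is an abundance column."""
    m = _ABUNDANCE_RE.match(name.strip())
    if m is None:
        return None
    return m.group("file").strip(), m.group("channel").strip()


def read_protein_table(
    path, dialect: str = "tab", id_column: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Read a wide protein quantification table.

    Returns ``(proteins, raw_sn, columns)`` where ``proteins`` is the
    annotation frame indexed by protein identifier, ``raw_sn`` is a
    proteins x (file, channel) frame of s/n values with NaN for missing,
    and ``columns`` lists the (file_id, channel) pair of each abundance
    column in original order. Row order is preserved.
    """
    if dialect not in _DELIMS:
        raise ValueError(f"dialect must be one of {sorted(_DELIMS)}")
    sep = _DELIMS[dialect]
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] <= 1:
        other = "comma" if dialect == "tab" else "tab"
        with open(path) as fh:
            head = fh.readline()
        if _DELIMS[other] in head:
            raise TableFormatError(
                f"no columns parsed with dialect={dialect!r}; header contains "
                f"{other!r} delimiters -- delimiter mismatch"
            )
    abundance_cols: list[str] = []
    mapping: list[tuple[str, str]] = []
    for col in df.columns:
        parsed = parse_abundance_column(col)
        if parsed is not None:
            abundance_cols.append(col)
            mapping.append(parsed)
        elif col.lower().startswith("abundance"):
            raise TableFormatError(
                f"column {col!r} looks like an abundance column but its "
                "file/channel could not be parsed"
            )
    if not abundance_cols:
        raise TableFormatError("no abundance columns (file:channel) found in header")

    if id_column is None:
        id_column = "Accession" if "Accession" in df.columns else df.columns[0]
    ids = df[id_column].astype(str)
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate protein identifiers: {dupes}")

    annot_cols = [c for c in df.columns if c not in abundance_cols and c != id_column]
    proteins = df[annot_cols].copy()
    proteins.index = pd.Index(ids, name="protein_id")

    def _exact_float(col: pd.Series) -> pd.Series:
        # python's float() is shortest-round-trip exact, unlike to_numeric
        def parse(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        return col.map(parse, na_action="ignore").astype(float)

    raw = df[abundance_cols].apply(_exact_float)
    raw = raw.mask(raw == 0)  # zero-coded = not detected
    raw.index = proteins.index
    raw.columns = pd.MultiIndex.from_tuples(mapping, names=["file_id", "channel"])
    return proteins, raw, mapping


def write_protein_table(
    proteins: pd.DataFrame,
    raw_sn: pd.DataFrame,
    path,
    dialect: str = "tab",
) -> None:
    """Inverse of :func:`read_protein_table` (full float precision)."""
    sep = _DELIMS[dialect]
    out = proteins.reset_index()
    out = out.rename(columns={proteins.index.name or "index": "Accession"})
    for (file_id, channel) in raw_sn.columns:
        vals = raw_sn[(file_id, channel)].to_numpy(float)
        # repr round-trips float64 exactly; blanks encode missing
        out[f"Abundance: {file_id}: {channel}"] = [
            repr(float(v)) if np.isfinite(v) else "" for v in vals
        ]
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# FACS metadata


def normalize_facs_unit(values) -> np.ndarray:
    """Min-max normalize a fluorescence vector to [0, 1].

    Missing values stay missing; a constant vector maps to all zeros (the
    documented degenerate convention). Idempotent.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("cannot unit-normalize an all-missing vector")
    lo = values[finite].min()
    hi = values[finite].max()
    out = np.full_like(values, np.nan)
    if hi == lo:
        out[finite] = 0.0
    else:
        out[finite] = (values[finite] - lo) / (hi - lo)
    return out


def read_facs_table(path) -> pd.DataFrame:
    """Read an index-FACS CSV export (well column + marker columns)."""
    df = pd.read_csv(path)
    well_col = next((c for c in df.columns if c.lower() == "well"), None)
    if well_col is None:
        raise TableFormatError("FACS table needs a 'well' column")
    df = df.rename(columns={well_col: "well"})
    df["well"] = df["well"].astype(str).str.upper()
    if df["well"].duplicated().any():
        dupes = df["well"][df["well"].duplicated()].unique().tolist()
        raise TableFormatError(f"duplicate wells in FACS table: {dupes}")
    return df.set_index("well")


def assemble_cell_metadata(
    layout: PlateLayout,
    facs_table: pd.DataFrame | None = None,
    markers: Sequence[str] | None = None,
) -> tuple[list[CellRecord], list[str]]:
    """Join a plate layout with per-well index-FACS values.

    Every single-cell well of the layout yields one :class:`CellRecord`;
    wells absent from the FACS table get missing marker values and a
    warning. Extra (unsorted) wells in the FACS table are ignored. FACS
    values are additionally unit-normalized per marker across the plate.
    Returns ``(records, warnings)``.
    """
    msgs: list[str] = []
    sc_wells = layout.single_cell_wells
    if facs_table is not None:
        max_col = facs_table.index.str[1:].astype(int).max()
        max_row = facs_table.index.str[0].max()
        if int(max_col) > layout.n_cols or (ord(max_row) - 64) > layout.n_rows:
            raise ValueError(
                f"FACS table well {max_row}{max_col} outside the "
                f"{layout.n_rows}x{layout.n_cols} plate layout"
            )
        if markers is None:
            markers = [c for c in facs_table.columns if c.lower() != "population"]
        extras = set(facs_table.index) - set(sc_wells["well"])
        if extras:
            msgs.append(f"ignored {len(extras)} FACS wells not sorted in layout")
    else:
        markers = list(markers or [])

    raw_per_marker: dict[str, list[float]] = {m: [] for m in markers}
    records: list[CellRecord] = []
    for _, w in sc_wells.iterrows():
        facs_vals: dict[str, float] = {}
        if facs_table is not None and w["well"] in facs_table.index:
            for m in markers:
                facs_vals[m] = float(facs_table.loc[w["well"], m])
        elif facs_table is not None:
            facs_vals = {m: np.nan for m in markers}
            msg = f"well {w['well']} missing from FACS table"
            msgs.append(msg)
            warnings.warn(msg)
        for m in markers:
            raw_per_marker[m].append(facs_vals.get(m, np.nan))
        records.append(
            CellRecord(
                cell_id=f"{w['file_id']}_{w['channel']}",
                file_id=w["file_id"],
                channel=w["channel"],
                plate_id=w["plate_id"],
                well_row=w["well_row"],
                well_col=int(w["well_col"]),
                population=w["population"],
                facs=facs_vals,
                is_empty_well=not w.get("sorted", True),
            )
        )
    # unit-normalize each marker across the plate
    for m in markers:
        vec = np.asarray(raw_per_marker[m], dtype=float)
        if np.isfinite(vec).any():
            norm = normalize_facs_unit(vec)
            for rec, v in zip(records, norm):
                if m in rec.facs:
                    rec.facs_norm = {**rec.facs_norm, m: float(v)}
    return records, msgs


def dataset_from_tables(
    proteins: pd.DataFrame,
    raw_sn: pd.DataFrame,
    records: list[CellRecord],
) -> ScmsDataset:
    """Assemble a dataset from a parsed quant table and cell metadata.

    Only (file, channel) columns matching a CellRecord enter the matrix;
    booster/empty-channel columns are dropped here, before normalization.
    """
    obs = records_to_obs(records)
    keys = list(zip(obs["file_id"], obs["channel"]))
    missing = [k for k in keys if k not in raw_sn.columns]
    if missing:
        raise ValueError(f"cells without matching abundance column: {missing[:5]}")
    mat = raw_sn.loc[:, keys].to_numpy(float).T  # cells x proteins
    ds = ScmsDataset.from_matrix(mat, obs, proteins)
    ds.log_op("dataset_from_tables", n_cells=len(records), n_proteins=len(proteins))
    return ds
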