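"""Plate layouts for multiplexed single-cell MS experiments.

A 384-well sort plate is partitioned into contiguous blocks of wells, one
block per multiplexed LC-MS sample. Each block carries one well per TMT
channel; the booster (carrier) channel and the channel left empty because
of booster isotopic impurity bleed are not sorted, the remaining channels
each receive one cell. With the 16-plex TMTpro set (126 = booster, 127C =
empty) a 16x24 plate yields 24 samples of 14 single cells: 336 cells per
plate.
"""

from __future__ import annotations

import enum
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The 16 TMTpro reporter channels in mass order.
TMTPRO_16 = (
    "126",
    "127N",
    "127C",
    "128N",
    "128C",
    "129N",
    "129C",
    "130N",
    "130C",
    "131N",
    "131C",
    "132N",
    "132C",
    "133N",
    "133C",
    "134N",
)

DEFAULT_BOOSTER_CHANNEL = "126"
DEFAULT_EMPTY_CHANNEL = "127C"

#: Channels adjacent in reporter mass to the booster, which can receive
#: isotopic-impurity bleed from a heavily loaded 126 carrier.
BOOSTER_ADJACENT_CHANNELS = ("127N", "127C", "128C")


class ChannelRole(str, enum.Enum):
    BOOSTER = "booster"
    REFERENCE = "reference"
    EMPTY = "empty"
    SINGLE_CELL = "single_cell"


def default_channel_roles(
    channels: Sequence[str] = TMTPRO_16,
    booster: str = DEFAULT_BOOSTER_CHANNEL,
    empty: str = DEFAULT_EMPTY_CHANNEL,
) -> dict[str, ChannelRole]:
    """Role map with one booster, one empty and the rest single-cell."""
    roles = {}
    for ch in channels:
        if ch == booster:
            roles[ch] = ChannelRole.BOOSTER
        elif ch == empty:
            roles[ch] = ChannelRole.EMPTY
        else:
            roles[ch] = ChannelRole.SINGLE_CELL
    if list(roles.values()).count(ChannelRole.BOOSTER) != 1:
        raise ValueError("exactly one booster channel is required")
    return roles


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> 'A1'-style well name (1-based column)."""
    return f"{string.ascii_uppercase[row]}{col + 1}"


@dataclass
class PlateLayout:
    """Well-to-(sample, channel, population) assignment for one plate.

    ``table`` has one row per well of every block with columns: well,
    well_row (letter), well_col (1-based), block (sample index), file_id,
    channel, role, population, sorted. Booster/empty-channel wells are
    unsorted and carry no population.
    """

    n_rows: int
    n_cols: int
    table: pd.DataFrame
    seed: int | None = None
    plate_id: str = "plate1"
    channel_roles: Mapping[str, ChannelRole] = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return self.table["block"].nunique()

    @property
    def single_cell_wells(self) -> pd.DataFrame:
        return self.table[self.table["role"] == ChannelRole.SINGLE_CELL.value]

    @property
    def n_single_cell_wells(self) -> int:
        return len(self.single_cell_wells)

    def population_counts_per_block(self) -> pd.DataFrame:
        sc = self.single_cell_wells
        return sc.groupby(["block", "population"], observed=True).size().unstack(fill_value=0)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_rows: int = 16, n_cols: int = 24) -> "PlateLayout":
        table = pd.read_csv(path, sep="\t", dtype={"channel": str})
        plate_id = table["plate_id"].iloc[0] if "plate_id" in table else "plate1"
        return cls(n_rows=n_rows, n_cols=n_cols, table=table, plate_id=plate_id)


def _balanced_counts(n_slots: int, populations: Sequence[str]) -> list[int]:
    """Split n_slots across populations as evenly as possible.

    Remainder slots go to the earlier populations, e.g. 14 slots over
    three populations -> 5, 5, 4.
    """
    base, extra = divmod(n_slots, len(populations))
    return [base + (1 if i < extra else 0) for i in range(len(populations))]


def build_plate_layout(
    rows: int = 16,
    cols: int = 24,
    channels: Sequence[str] = TMTPRO_16,
    channel_roles: Mapping[str, ChannelRole] | None = None,
    populations: Sequence[str] = ("LSC", "Progenitor", "Blast"),
    balanced: bool = True,
    seed: int | None = 0,
    plate_id: str = "plate1",
) -> PlateLayout:
    """Partition a sort plate into per-sample blocks of labelled wells.

    The plate is cut into contiguous blocks of ``len(channels)`` wells
    (column-major: with 16 channels on a 16-row plate each column is one
    block/sample). Within every block the channels are assigned to wells
    in a seeded random order; booster and empty channels yield unsorted
    wells. In balanced mode the single-cell channels of each block are
    distributed across populations as evenly as possible, so every sample
    contains comparable numbers of each population -- the premise of the
    median-equalization normalization downstream.
    """
    n_channels = len(channels)
    if len(set(channels)) != n_channels:
        raise ValueError("duplicate channel labels")
    n_wells = rows * cols
    if n_wells % n_channels:
        raise ValueError(
            f"plate of {n_wells} wells cannot be partitioned into blocks of {n_channels}"
        )
    roles = dict(channel_roles) if channel_roles is not None else default_channel_roles(channels)
    single_cell_channels = [c for c in channels if roles[c] == ChannelRole.SINGLE_CELL]
    if populations and len(populations) > len(single_cell_channels):
        raise ValueError(
            f"{len(populations)} populations cannot be assigned to "
            f"{len(single_cell_channels)} single-cell channels"
        )
    rng = np.random.default_rng(seed)
    n_blocks = n_wells // n_channels
    counts = _balanced_counts(len(single_cell_channels), populations) if populations else []

    records = []
    wells = [(r, c) for c in range(cols) for r in range(rows)]  # column-major blocks
    for b in range(n_blocks):
        block_wells = wells[b * n_channels : (b + 1) * n_channels]
        chan_order = list(channels)
        if balanced:
            chan_order = list(rng.permutation(chan_order))
        # population labels for the single-cell channels of this block
        pop_labels = []
        for pop, k in zip(populations, counts):
            pop_labels.extend([pop] * k)
        if balanced:
            pop_labels = list(rng.permutation(pop_labels))
        it_pop = iter(pop_labels)
        for (r, c), ch in zip(block_wells, chan_order):
            role = roles[ch]
            is_sc = role == ChannelRole.SINGLE_CELL
            records.append(
                {
                    "plate_id": plate_id,
                    "well": well_name(r, c),
                    "well_row": string.ascii_uppercase[r],
                    "well_col": c + 1,
                    "block": b,
                    "file_id": f"{plate_id}_s{b + 1:02d}",
                    "channel": ch,
                    "role": role.value,
                    "population": next(it_pop) if (is_sc and pop_labels) else None,
                    "sorted": is_sc,
                }
            )
    table = pd.DataFrame.from_records(records)
    return PlateLayout(
        n_rows=rows, n_cols=cols, table=table, seed=seed, plate_id=plate_id, channel_roles=roles
    )
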