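"""Occurrence records: reading, cleaning, spatial rarefaction, status split.

An :class:`OccurrenceSet` is a thin wrapper over a pandas DataFrame with the
columns ``species, longitude, latitude, status, uncertainty_km``. Presence
records are cleaned (coordinate validity, coordinate-uncertainty filter),
thinned to one record per ~5 x 5 km grid cell to blunt sampling bias, and
split into native and introduced populations for separate modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import KM_PER_DEG

logger = logging.getLogger(__name__)

VALID_STATUS = ("native", "introduced")

REQUIRED_COLUMNS = ["species", "longitude", "latitude", "status"]


class FormatError(ValueError):
    """Malformed occurrence input (missing column, unknown status label)."""


@dataclass
class OccurrenceSet:
    """Status-labelled presence points for one species."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required columns: {missing}")
        if "uncertainty_km" not in self.df.columns:
            self.df = self.df.assign(uncertainty_km=np.nan)
        self.df = self.df.reset_index(drop=True)
        bad = ~self.df["status"].isin(VALID_STATUS)
        if bad.any():
            labels = sorted(self.df.loc[bad, "status"].unique())
            raise FormatError(f"unknown status labels: {labels}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> str:
        return str(self.df["species"].iloc[0]) if len(self.df) else ""

    @property
    def lon(self) -> np.ndarray:
        return self.df["longitude"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.df["latitude"].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "OccurrenceSet":
        return OccurrenceSet(self.df.loc[np.asarray(mask, dtype=bool)])

    def to_csv(self, path: str | Path) -> None:
        cols = REQUIRED_COLUMNS + ["uncertainty_km"]
        self.df[cols].to_csv(path, index=False)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read an occurrence CSV, dropping rows with unparseable or out-of-range
    coordinates (count logged)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    n0 = len(df)
    for col in ("longitude", "latitude", "uncertainty_km"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["longitude"].between(-180.0, 180.0)
        & df["latitude"].between(-90.0, 90.0)
    )
    dropped = int(n0 - ok.sum())
    if dropped:
        logger.warning("%s: dropped %d rows with invalid coordinates", path, dropped)
    return OccurrenceSet(df.loc[ok])


def filter_uncertainty(occ: OccurrenceSet, max_km: float = 5.0) -> OccurrenceSet:
    """Keep records whose coordinate uncertainty is <= ``max_km`` or missing.

    Literature records typically lack an uncertainty field; they are retained.
    """
    if max_km <= 0:
        raise ValueError("max_km must be positive")
    u = occ.df["uncertainty_km"]
    keep = u.isna() | (u <= max_km)
    return occ.subset(keep.to_numpy())


def _thin_cells(lon: np.ndarray, lat: np.ndarray, cell_km: float) -> np.ndarray:
    """Equal-area-approximate cell index per point.

    Latitude bands of height cell_km; within a band the longitudinal cell
    width is widened by 1/cos(band-centre latitude) so cells stay ~square in
    km. Returns an (n, 2) integer array of (band, column) indices.
    """
    cell_deg = cell_km / KM_PER_DEG
    band = np.floor((lat + 90.0) / cell_deg).astype(int)
    band_center = -90.0 + (band + 0.5) * cell_deg
    cosphi = np.maximum(np.cos(np.deg2rad(band_center)), 1e-6)
    width = cell_deg / cosphi
    col = np.floor((lon + 180.0) / width).astype(int)
    return np.column_stack([band, col])


def spatial_rarefy(occ: OccurrenceSet, cell_km: float = 5.0, seed: int = 0) -> OccurrenceSet:
    """Retain one record per occupied cell_km x cell_km cell.

    Native and introduced subsets are rarefied independently (they are
    modelled separately, so a native record must not displace an introduced
    one). The grid origin is fixed at (-180, -90); the survivor within a cell
    is drawn uniformly at random under ``seed`` to remove input-order
    dependence while staying reproducible.
    """
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    if len(occ) == 0:
        return occ
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    for status in VALID_STATUS:
        part = occ.df.index[occ.df["status"] == status].to_numpy()
        if part.size == 0:
            continue
        cells = _thin_cells(
            occ.df.loc[part, "longitude"].to_numpy(dtype=float),
            occ.df.loc[part, "latitude"].to_numpy(dtype=float),
            cell_km,
        )
        order = rng.permutation(part.size)
        _, first = np.unique(cells[order], axis=0, return_index=True)
        keep_idx.extend(part[order[first]])
    keep = np.zeros(len(occ), dtype=bool)
    keep[np.asarray(keep_idx, dtype=int)] = True
    logger.info("rarefied %d -> %d records (cell %.1f km)", len(occ), keep.sum(), cell_km)
    return occ.subset(keep)


def split_by_status(occ: OccurrenceSet) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Partition into (native, introduced); exhaustive and disjoint."""
    native = occ.subset((occ.df["status"] == "native").to_numpy())
    introduced = occ.subset((occ.df["status"] == "introduced").to_numpy())
    return native, introduced


def minimum_count_gate(
    native: OccurrenceSet, introduced: OccurrenceSet, n_min: int = 30
) -> bool:
    """True iff both populations retain at least ``n_min`` records.

    Species failing the gate are excluded from the analysis (record scarcity
    makes the downstream models unreliable); the reason is logged.
    """
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    ok = len(native) >= n_min and len(introduced) >= n_min
    if not ok:
        logger.warning(
            "species excluded: native=%d, introduced=%d records after "
            "rarefaction (minimum %d each)",
            len(native), len(introduced), n_min,
        )
    return ok
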