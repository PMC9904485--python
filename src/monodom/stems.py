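"""Reading, validation, and geolocation of stem census records.

Stem tables are plain :class:`pandas.DataFrame` objects with the canonical
columns ``tag, species, census, quadrat_col, quadrat_row, x, y, dbh, ba,
status, date``.  Coordinates ``x``/``y`` are metres from the plot origin
(south-west corner, x increasing east, y increasing north, half-open
intervals ``[0, width)`` and ``[0, height)``).  DBH is in cm, basal area in
m².  A missing value is ``NaN``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlotGeometry",
    "CensusTable",
    "STEM_COLUMNS",
    "basal_area_from_dbh",
    "impute_missing_coordinates",
    "to_projected",
    "select_target_stems",
    "read_stem_table",
    "write_stem_table",
]

STEM_COLUMNS = [
    "tag", "species", "census", "quadrat_col", "quadrat_row",
    "x", "y", "dbh", "ba", "status", "date",
]


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular census plot anchored at a projected origin.

    The origin is the south-west corner in projected metres (e.g. UTM).
    Default dimensions follow the 200 m x 500 m layout of large forest
    dynamics plots.
    """

    origin_easting: float = 0.0
    origin_northing: float = 0.0
    width: float = 200.0
    height: float = 500.0
    crs_label: str = "local"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("plot width and height must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask of local coordinates inside the plot rectangle."""
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return (x >= 0) & (x < self.width) & (y >= 0) & (y < self.height)


@dataclass
class CensusTable:
    """All stem records of one census, plus the nominal decimal year.

    The nominal year (e.g. 1995.0 for a census spanning 1994-1996) is the
    time coordinate used by the movement regressions.
    """

    records: pd.DataFrame
    census_year: float

    def __post_init__(self) -> None:
        labels = self.records["census"].dropna().unique()
        if len(labels) > 1:
            raise ValueError(f"records mix census labels {sorted(labels)}")


def basal_area_from_dbh(dbh):
    """Basal area (m²) of a stem of diameter ``dbh`` (cm): pi*(dbh/200)**2."""
    dbh = np.asarray(dbh, float)
    if np.any(dbh[~np.isnan(dbh)] < 0):
        raise ValueError("negative DBH")
    out = math.pi * (dbh / 200.0) ** 2
    return float(out) if out.ndim == 0 else out


def impute_missing_coordinates(
    records: pd.DataFrame,
    quadrat_size: float = 20.0,
    seed: int | np.random.Generator | None = None,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Place coordinate-deficient stems uniformly at random in their quadrat.

    Both x and y are randomised.  Records that already carry coordinates are
    returned unchanged.  Imputed points are resampled (bounded retries) until
    no two stems in the table share identical coordinates at full float
    precision.

    Raises
    ------
    ValueError
        If a coordinate-deficient record has no usable quadrat index.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = records.copy()
    missing = out["x"].isna() | out["y"].isna()
    if not missing.any():
        return out
    bad = missing & (out["quadrat_col"].isna() | out["quadrat_row"].isna())
    if bad.any():
        tags = out.loc[bad, "tag"].tolist()[:5]
        raise ValueError(f"records lacking both coordinates and quadrat: tags {tags}")

    taken = set(zip(out.loc[~missing, "x"], out.loc[~missing, "y"]))
    idx = out.index[missing]
    cols = out.loc[idx, "quadrat_col"].to_numpy(float)
    rows = out.loc[idx, "quadrat_row"].to_numpy(float)
    xs = np.empty(len(idx))
    ys = np.empty(len(idx))
    for k in range(len(idx)):
        for _ in range(max_retries):
            x = (cols[k] + rng.random()) * quadrat_size
            y = (rows[k] + rng.random()) * quadrat_size
            if (x, y) not in taken:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not find a distinct imputed location")
        taken.add((x, y))
        xs[k], ys[k] = x, y
    out.loc[idx, "x"] = xs
    out.loc[idx, "y"] = ys
    return out


def to_projected(records: pd.DataFrame, plot: PlotGeometry) -> pd.DataFrame:
    """Add projected ``easting``/``northing`` columns by offsetting from the
    plot origin."""
    if records["x"].isna().any() or records["y"].isna().any():
        raise ValueError("cannot project records with missing local coordinates")
    out = records.copy()
    out["easting"] = plot.origin_easting + out["x"]
    out["northing"] = plot.origin_northing + out["y"]
    return out


def select_target_stems(
    records: pd.DataFrame,
    species_code: str,
    require_alive: bool = True,
) -> pd.DataFrame:
    """Restrict a stem table to the focal species with usable size data.

    Keeps records of ``species_code`` that are alive (any status other than
    ``"alive"`` counts as dead) and that carry a valid DBH or BA.  If ``ba``
    is missing but ``dbh`` is present, BA is filled in from DBH.
    """
    out = records[records["species"] == species_code].copy()
    if require_alive:
        out = out[out["status"] == "alive"]
    fill = out["ba"].isna() & out["dbh"].notna()
    if fill.any():
        out.loc[fill, "ba"] = basal_area_from_dbh(out.loc[fill, "dbh"].to_numpy())
    out = out[out["ba"].notna() & (out["ba"] > 0)]
    return out


def read_stem_table(
    path,
    column_map: dict[str, str] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited stem export, renaming columns via ``column_map``
    (source name -> canonical name).  Missing canonical columns are added
    as NaN."""
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=column_map)
    for col in STEM_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[STEM_COLUMNS + [c for c in df.columns if c not in STEM_COLUMNS]]


def write_stem_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
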