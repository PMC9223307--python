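"""Land-use area accounting on categorical rasters.

Tallies class areas per zone and per year from a categorical land-use grid
(cell-count × nominal cell area; a cell belongs wholly to the zone of its
center) and computes period change statistics (Δ km² and Δ%) in the layout
of standard land-use change tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The six primary land-use classes of the accounting scheme.
PRIMARY_CLASSES = (
    "cultivated land",
    "woodland",
    "grassland",
    "water",
    "construction land",
    "unused land",
)

#: Zone label used for whole-region aggregates.
ALL_ZONES = "ALL"


class AlignmentError(ValueError):
    """Raised when grids that must share a shape do not."""


@dataclass
class LandUseGrid:
    """A categorical land-use raster.

    Parameters
    ----------
    values
        2-D integer array of class codes.
    class_codes
        Mapping from integer code to class name. Every non-nodata cell must
        carry a known code.
    cell_area
        Area of one cell in km² (default 1, the nominal resolution of
        kilometre-grid land-use products).
    nodata
        Code marking cells outside the study area.
    """

    values: np.ndarray
    class_codes: dict[int, str] = field(
        default_factory=lambda: dict(enumerate(PRIMARY_CLASSES))
    )
    cell_area: float = 1.0
    nodata: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("land-use grid must be 2-D")
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be positive, got {self.cell_area}")
        known = set(self.class_codes) | {self.nodata}
        present = set(np.unique(self.values).tolist())
        unknown = present - known
        if unknown:
            raise ValueError(f"unknown class codes in grid: {sorted(unknown)}")


def read_class_map(path) -> dict[int, str]:
    """Read a ``code,name`` CSV mapping raw raster codes to class names."""
    df = pd.read_csv(path)
    if not {"code", "name"} <= set(df.columns):
        raise ValueError("class map CSV needs 'code' and 'name' columns")
    return dict(zip(df["code"].astype(int), df["name"].astype(str)))


def reclassify(values: np.ndarray, code_map: dict[int, int], nodata: int = -1) -> np.ndarray:
    """Map raw source codes onto accounting codes; unmapped cells become nodata."""
    out = np.full_like(values, nodata)
    for src, dst in code_map.items():
        out[values == src] = dst
    return out


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-style rounding, not banker's)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def tabulate_areas(
    grid: LandUseGrid,
    zones: np.ndarray | None = None,
    year: int | str | None = None,
    include_total: bool = True,
) -> pd.DataFrame:
    """Tally class areas (km²) per zone for one land-use grid.

    Returns a tidy frame with columns ``zone, year, land_class, area_km2``.
    Nodata cells are excluded. When ``zones`` is given, per-zone rows are
    emitted and, if ``include_total``, an ``ALL`` aggregate as well.
    """
    values = grid.values
    if zones is not None:
        zones = np.asarray(zones)
        if zones.shape != values.shape:
            raise AlignmentError(
                f"zone grid shape {zones.shape} != land-use grid shape {values.shape}"
            )
    rows: list[tuple] = []
    valid = values != grid.nodata

    def _tally(mask: np.ndarray, label) -> None:
        sub = values[mask]
        for code, name in grid.class_codes.items():
            rows.append((label, year, name, float(np.count_nonzero(sub == code)) * grid.cell_area))

    if zones is None:
        _tally(valid, ALL_ZONES)
    else:
        for z in np.unique(zones):
            _tally(valid & (zones == z), z)
        if include_total:
            _tally(valid, ALL_ZONES)
    return pd.DataFrame(rows, columns=["zone", "year", "land_class", "area_km2"])


def tabulate_stack(
    grids: dict, zones: np.ndarray | None = None, **kwargs
) -> pd.DataFrame:
    """Tally a ``{year: LandUseGrid}`` stack into one area table."""
    return pd.concat(
        [tabulate_areas(g, zones=zones, year=y, **kwargs) for y, g in grids.items()],
        ignore_index=True,
    )


def area_change(
    areas: pd.DataFrame,
    period: tuple,
    zone=ALL_ZONES,
    value_col: str = "area_km2",
) -> pd.DataFrame:
    """Net change per class over ``period = (year_from, year_to)``.

    Returns columns ``land_class, start, end, delta, delta_pct,
    percent_defined``. ``delta_pct`` is Δ/start × 100 rounded half away from
    zero to 2 decimals; a zero start with a zero end gives 0, a zero start
    with a nonzero end is flagged undefined (NaN percent, Δ still reported).
    """
    year_from, year_to = period
    sub = areas[areas["zone"] == zone]
    for y in (year_from, year_to):
        if y not in set(sub["year"]):
            raise ValueError(f"year {y!r} not present in area table for zone {zone!r}")
    start = sub[sub["year"] == year_from].set_index("land_class")[value_col]
    end = sub[sub["year"] == year_to].set_index("land_class")[value_col]
    classes = start.index
    out = []
    for cls in classes:
        a0, a1 = float(start[cls]), float(end.get(cls, 0.0))
        delta = a1 - a0
        if a0 == 0.0:
            pct, defined = (0.0, True) if a1 == 0.0 else (float("nan"), False)
        else:
            pct, defined = round_half_away(delta / a0 * 100.0, 2), True
        out.append((cls, a0, a1, delta, pct, defined))
    return pd.DataFrame(
        out,
        columns=["land_class", "start", "end", "delta", "delta_pct", "percent_defined"],
    )
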