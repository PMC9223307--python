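"""Ecosystem-service supply valuation by the equivalent-factor method.

Each land-use class carries a fixed per-hectare value coefficient for each
of nine services (gas regulation, climate regulation, water conservation,
waste disposal, soil formation and protection, biodiversity conservation,
food production, raw material, entertainment), in yuan/(hm²·a). Supply is

    ESV = Σₖ Aₖ × VCₖ

with Aₖ the class-k area in hectares and VCₖ its coefficient. Areas arrive
in km² (×100 to hm²) and values are reported in 10⁸ yuan ("100 million
yuan"), the unit chain that reproduces published provincial-scale tables.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .accounting import ALL_ZONES, round_half_away

#: The nine valued services, in conventional table order.
SERVICES = (
    "gas regulation",
    "climate regulation",
    "water conservation",
    "waste disposal",
    "soil formation and protection",
    "biodiversity conservation",
    "food production",
    "raw material",
    "entertainment",
)

KM2_TO_HM2 = 100.0
YUAN_TO_1E8 = 1e-8


class CoefficientLookupError(KeyError):
    """A land class in the area table has no value-coefficient row."""


def load_value_coefficients(path=None) -> pd.DataFrame:
    """Load a value-coefficient table (class × service, yuan/(hm²·a)).

    Without ``path`` the packaged coefficient set (the published equivalent
    factors for the six primary classes) is returned. A user CSV must have
    columns ``land_class, service, coefficient``.
    """
    if path is None:
        src = resources.files("esbalance.data") / "value_coefficients.csv"
        with resources.as_file(src) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if not {"land_class", "service", "coefficient"} <= set(df.columns):
        raise ValueError("coefficient CSV needs land_class, service, coefficient columns")
    table = df.pivot(index="land_class", columns="service", values="coefficient")
    if (table < 0).any().any():
        raise ValueError("value coefficients must be non-negative")
    order = [s for s in SERVICES if s in table.columns]
    order += [s for s in table.columns if s not in order]
    return table[order]


def load_reference_areas() -> pd.DataFrame:
    """Packaged whole-region land-use areas (km²) for 2000–2020."""
    src = resources.files("esbalance.data") / "landuse_areas.csv"
    with resources.as_file(src) as p:
        return pd.read_csv(p)


def esv_compute(areas: pd.DataFrame, coeffs: pd.DataFrame) -> pd.DataFrame:
    """Value every (zone, year, class, service) cell of an area table.

    Returns a tidy frame ``zone, year, land_class, service, esv`` with esv
    in 10⁸ yuan at full precision (round only for reporting).
    """
    missing = sorted(set(areas["land_class"]) - set(coeffs.index))
    if missing:
        raise CoefficientLookupError(
            f"no value coefficients for land class(es): {missing}"
        )
    vc = coeffs.stack().rename("coefficient").reset_index()
    out = areas.merge(vc, on="land_class")
    out["esv"] = out["area_km2"] * KM2_TO_HM2 * out["coefficient"] * YUAN_TO_1E8
    return out[["zone", "year", "land_class", "service", "esv"]]


def esv_by_class(esv: pd.DataFrame, zone=ALL_ZONES) -> pd.DataFrame:
    """Pivot to year × land-class totals (10⁸ yuan), with a Total column."""
    sub = esv[esv["zone"] == zone]
    table = sub.pivot_table(index="year", columns="land_class", values="esv", aggfunc="sum")
    table["Total"] = table.sum(axis=1)
    return table


def esv_by_service(esv: pd.DataFrame, zone=ALL_ZONES) -> pd.DataFrame:
    """Pivot to year × service totals (10⁸ yuan), with a Total column."""
    sub = esv[esv["zone"] == zone]
    table = sub.pivot_table(index="year", columns="service", values="esv", aggfunc="sum")
    table = table[[s for s in SERVICES if s in table.columns]]
    table["Total"] = table.sum(axis=1)
    return table


def esv_total(esv: pd.DataFrame, zone=ALL_ZONES) -> pd.Series:
    """Grand-total ESV per year (10⁸ yuan) for one zone."""
    sub = esv[esv["zone"] == zone]
    return sub.groupby("year")["esv"].sum()


def esv_zone_totals(esv: pd.DataFrame) -> pd.DataFrame:
    """Per-zone, per-year total ESV (10⁸ yuan); excludes the ALL aggregate."""
    sub = esv[esv["zone"] != ALL_ZONES]
    return sub.groupby(["zone", "year"], as_index=False)["esv"].sum()


def esv_change(
    esv: pd.DataFrame, period: tuple, by: str = "land_class", zone=ALL_ZONES
) -> pd.DataFrame:
    """Period change of ESV per class or per service (Δ 10⁸ yuan and Δ%).

    Same contract as :func:`esbalance.accounting.area_change` applied to
    values: Δ% = Δ/start × 100 (2 decimals); zero start with zero end → 0%,
    zero start with nonzero end → undefined percent, Δ still reported.
    """
    year_from, year_to = period
    sub = esv[esv["zone"] == zone]
    for y in (year_from, year_to):
        if y not in set(sub["year"]):
            raise ValueError(f"year {y!r} not present in ESV table for zone {zone!r}")
    start = sub[sub["year"] == year_from].groupby(by)["esv"].sum()
    end = sub[sub["year"] == year_to].groupby(by)["esv"].sum()
    out = []
    for key in start.index:
        v0, v1 = float(start[key]), float(end.get(key, 0.0))
        delta = v1 - v0
        if v0 == 0.0:
            pct, defined = (0.0, True) if v1 == 0.0 else (float("nan"), False)
        else:
            pct, defined = round_half_away(delta / v0 * 100.0, 2), True
        out.append((key, v0, v1, delta, pct, defined))
    return pd.DataFrame(
        out, columns=[by, "start", "end", "delta", "delta_pct", "percent_defined"]
    )


def service_composition(esv: pd.DataFrame, year, zone=ALL_ZONES) -> pd.Series:
    """Service shares of total ESV (%) for one year, in descending order."""
    sub = esv[(esv["zone"] == zone) & (esv["year"] == year)]
    if sub.empty:
        raise ValueError(f"year {year!r} not present for zone {zone!r}")
    by_service = sub.groupby("service")["esv"].sum()
    shares = by_service / by_service.sum() * 100.0
    return shares.sort_values(ascending=False)
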