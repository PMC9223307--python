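"""Ecosystem-service demand indexing from land use, population and nightlights.

Per zone i the demand index is

    X_i = D_i × log(P_i) × log(NLCI_i · c)

where D is the land-use degree (built-up share of zone area, %), P the
population density (persons/km²) and NLCI the nightlight composite index

    NLCI = P₁·I + P₂·S,   P₁ = 0.8, P₂ = 0.2,

with I the mean intensity of lit pixels relative to the DN-63 saturation
level and S the lit-pixel area share. DN values are DMSP-OLS style integers
in [0, 63]; a pixel is lit when 1 ≤ DN ≤ 63.

Logs are base 10 by default. Because NLCI ∈ [0, 1] would make its log
negative, the index term uses NLCI rescaled by c = 100 (a "percent" index),
and both the population and light terms are floored at 1 before the log so
that unlit / unpopulated zones contribute zero demand rather than negative
demand. The base, scale and floors are explicit arguments so a run's
configuration is fully recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .accounting import ALL_ZONES

#: Weights of mean intensity I and lit-area share S in the composite index.
NLCI_WEIGHT_I = 0.8
NLCI_WEIGHT_S = 0.2

#: Saturation gray level of the DN scale.
DN_MAX = 63


class DNRangeError(ValueError):
    """DN raster holds values outside [0, 63] (e.g. un-rescaled VIIRS radiance)."""


@dataclass(frozen=True)
class NightlightIndex:
    """Zonal nightlight statistics: intensity I, lit share S, composite NLCI."""

    intensity: float  # I ∈ [0, 1]
    lit_share: float  # S ∈ [0, 1]
    nlci: float  # 0.8·I + 0.2·S
    n_lit: int
    n_total: int


def light_stats(dn_grid: np.ndarray, mask: np.ndarray | None = None) -> NightlightIndex:
    """Compute (I, S, NLCI) over a DN grid, optionally restricted to a mask.

    I = Σⱼ DNⱼ·Nⱼ / (N_t·63) over lit pixels (1 ≤ DN ≤ 63), S = N_t/N.
    With no lit pixels I is defined as 0 (the ratio is 0/0), giving NLCI 0.
    """
    dn = np.asarray(dn_grid)
    if not np.issubdtype(dn.dtype, np.integer):
        if not np.allclose(dn, np.round(dn)):
            raise DNRangeError("DN grid must hold integers (rescale continuous radiance first)")
        dn = np.round(dn).astype(np.int64)
    if dn.size and (dn.min() < 0 or dn.max() > DN_MAX):
        raise DNRangeError(
            f"DN values must lie in [0, {DN_MAX}]; got range "
            f"[{dn.min()}, {dn.max()}] — un-rescaled VIIRS input?"
        )
    if mask is not None:
        dn = dn[np.asarray(mask)]
    n_total = int(dn.size)
    if n_total == 0:
        raise ValueError("empty pixel set")
    lit = dn[dn >= 1]
    n_lit = int(lit.size)
    s = n_lit / n_total
    i = float(lit.sum()) / (n_lit * DN_MAX) if n_lit else 0.0
    return NightlightIndex(i, s, NLCI_WEIGHT_I * i + NLCI_WEIGHT_S * s, n_lit, n_total)


def rescale_to_dn(
    raster: np.ndarray, saturation_percentile: float = 99.0
) -> np.ndarray:
    """Clip a continuous radiance raster at a saturation percentile and
    rescale linearly onto the integer DN range [0, 63]."""
    r = np.asarray(raster, dtype=float)
    if np.any(r < 0):
        r = np.clip(r, 0, None)
    top = np.percentile(r, saturation_percentile)
    if top <= 0:
        return np.zeros_like(r, dtype=np.int64)
    scaled = np.clip(r / top, 0.0, 1.0) * DN_MAX
    return np.round(scaled).astype(np.int64)


def landuse_degree(
    areas: pd.DataFrame, zone, year, builtup_class: str = "construction land"
) -> float:
    """Land-use degree D (%): built-up share of the zone's total area."""
    sub = areas[(areas["zone"] == zone) & (areas["year"] == year)]
    if sub.empty:
        raise ValueError(f"zone {zone!r} / year {year!r} not in area table")
    total = float(sub["area_km2"].sum())
    if total == 0.0:
        raise ValueError(f"zone {zone!r} has zero area in year {year!r}")
    built = float(sub.loc[sub["land_class"] == builtup_class, "area_km2"].sum())
    return built / total * 100.0


def demand_index(
    d: float,
    pop_density: float,
    nlci: float,
    log_base: float = 10.0,
    nlci_scale: float = 100.0,
    pop_floor: float = 1.0,
    nlci_floor: float = 1.0,
):
    """Demand index X = D × log(max(P, pop_floor)) × log(max(NLCI·c, nlci_floor)).

    Accepts scalars or arrays; monotone non-decreasing in each argument and
    identically zero where D = 0.
    """
    d = np.asarray(d, dtype=float)
    p = np.asarray(pop_density, dtype=float)
    n = np.asarray(nlci, dtype=float)
    if np.any(d < 0) or np.any(p < 0) or np.any(n < 0):
        raise ValueError("demand inputs must be non-negative")
    logb = np.log(log_base)
    x = (
        d
        * (np.log(np.maximum(p, pop_floor)) / logb)
        * (np.log(np.maximum(n * nlci_scale, nlci_floor)) / logb)
    )
    return float(x) if x.ndim == 0 else x


def demand_table(
    areas: pd.DataFrame,
    population: np.ndarray,
    nightlight: dict,
    zones: np.ndarray,
    **index_options,
) -> pd.DataFrame:
    """Assemble the per-zone demand decomposition (D, P, I, S, NLCI, X).

    ``nightlight`` maps year → DN grid; population is a density grid in
    persons/km². P is zone population total divided by zone area, which for
    equal-area cells equals the zone mean density.
    """
    zones = np.asarray(zones)
    pop = np.asarray(population, dtype=float)
    if pop.shape != zones.shape:
        raise ValueError(f"population shape {pop.shape} != zones shape {zones.shape}")
    rows = []
    for year, dn in nightlight.items():
        dn = np.asarray(dn)
        if dn.shape != zones.shape:
            raise ValueError(f"nightlight[{year!r}] shape {dn.shape} != zones shape")
        for z in np.unique(zones):
            mask = zones == z
            p = float(pop[mask].mean())  # total persons / zone area, equal cells
            d = landuse_degree(areas, z, year)
            ls = light_stats(dn, mask)
            x = demand_index(d, p, ls.nlci, **index_options)
            rows.append((z, year, d, p, ls.intensity, ls.lit_share, ls.nlci, x))
    return pd.DataFrame(
        rows, columns=["zone", "year", "D", "P", "I", "S", "NLCI", "X"]
    )
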