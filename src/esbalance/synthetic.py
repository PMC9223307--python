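"""Synthetic multi-year landscapes with known ground truth.

Emulates the data model of a kilometre-grid regional study: a categorical
land-use raster over the six primary classes evolving by per-interval Markov
transition rates (cultivated→construction conversion dominant, as in rapid
urbanisation), a static population-density surface co-located with built-up
land, per-year DN nightlight rasters (integers 0–63) that brighten with
population, and a partition of the grid into contiguous county-like zones.

Everything is reproducible from (config, seed); class-share trajectories
follow the transition chain in expectation, so downstream accounting can be
checked against closed-form Markov expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .accounting import PRIMARY_CLASSES, LandUseGrid

_DEFAULT_PROPORTIONS = {
    # first-year class shares, patterned on a large mixed river-basin region
    "cultivated land": 0.31,
    "woodland": 0.46,
    "grassland": 0.17,
    "water": 0.03,
    "construction land": 0.02,
    "unused land": 0.01,
}

_DEFAULT_TRANSITIONS = {
    # per-interval conversion probabilities; construction expands at the
    # expense of cultivated land and grassland, water grows slightly
    ("cultivated land", "construction land"): 0.02,
    ("cultivated land", "water"): 0.003,
    ("grassland", "construction land"): 0.005,
    ("grassland", "woodland"): 0.004,
    ("unused land", "construction land"): 0.002,
}

_DEFAULT_POP_MULTIPLIERS = {
    "cultivated land": 3.0,
    "woodland": 0.3,
    "grassland": 0.5,
    "water": 0.1,
    "construction land": 40.0,  # demand hot-spots co-locate with built-up land
    "unused land": 0.1,
}

_DEFAULT_DN_MEANS = {
    "cultivated land": 6.0,
    "woodland": 1.0,
    "grassland": 1.5,
    "water": 0.5,
    "construction land": 45.0,
    "unused land": 0.5,
}


class ConfigurationError(ValueError):
    """A landscape configuration violates its invariants."""


@dataclass
class PopulationParams:
    """Population model: density = base × class multiplier × lognormal noise."""

    base_density: float = 50.0  # persons/km²
    class_multipliers: dict = field(default_factory=lambda: dict(_DEFAULT_POP_MULTIPLIERS))
    noise_sd: float = 0.5  # sd of the log-normal noise on the log scale


@dataclass
class LightParams:
    """Nightlight model: DN ~ Normal(mean(class) + gain·log10(1+pop), sd),
    rounded and clipped to the integer DN range [0, 63]."""

    dn_means: dict = field(default_factory=lambda: dict(_DEFAULT_DN_MEANS))
    dn_sd: float = 3.0
    pop_gain: float = 4.0


@dataclass
class LandscapeConfig:
    """Full specification of a synthetic scene; see module docstring."""

    grid_shape: tuple[int, int] = (100, 100)
    cell_area: float = 1.0  # km² per cell
    years: tuple = (2000, 2005, 2010, 2015, 2020)
    class_proportions: dict = field(default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    transition_rates: dict = field(default_factory=lambda: dict(_DEFAULT_TRANSITIONS))
    pop_params: PopulationParams = field(default_factory=PopulationParams)
    light_params: LightParams = field(default_factory=LightParams)
    n_zones: int = 12
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions sum to {total!r}, expected 1"
            )
        for cls in self.class_proportions:
            if cls not in PRIMARY_CLASSES:
                raise ConfigurationError(f"unknown land class {cls!r} in class_proportions")
        outflow: dict[str, float] = {}
        for (src, dst), rate in self.transition_rates.items():
            for cls in (src, dst):
                if cls not in PRIMARY_CLASSES:
                    raise ConfigurationError(
                        f"unknown land class {cls!r} in transition ({src!r} -> {dst!r})"
                    )
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(
                    f"transition rate for ({src!r} -> {dst!r}) is {rate}, not in [0, 1]"
                )
            outflow[src] = outflow.get(src, 0.0) + rate
        for src, total_out in outflow.items():
            if total_out > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"transition row for {src!r} sums to {total_out} > 1"
                )
        rows, cols = self.grid_shape
        if not 1 <= self.n_zones <= rows * cols:
            raise ConfigurationError(
                f"n_zones must lie in [1, {rows * cols}], got {self.n_zones}"
            )
        if self.cell_area <= 0:
            raise ConfigurationError("cell_area must be positive")
        if not self.years:
            raise ConfigurationError("years must be non-empty")

    def transition_matrix(self) -> np.ndarray:
        """Row-stochastic per-interval transition matrix over PRIMARY_CLASSES;
        retained mass on the diagonal is 1 − Σ outflow."""
        k = len(PRIMARY_CLASSES)
        idx = {c: i for i, c in enumerate(PRIMARY_CLASSES)}
        T = np.zeros((k, k))
        for (src, dst), rate in self.transition_rates.items():
            T[idx[src], idx[dst]] += rate
        np.fill_diagonal(T, 1.0 - T.sum(axis=1))
        return T


@dataclass
class SyntheticScene:
    """Generated scene: per-year grids plus the generating config as truth."""

    landuse: dict  # year -> int grid (codes index PRIMARY_CLASSES)
    population: np.ndarray  # persons/km²
    nightlight: dict  # year -> int grid in [0, 63]
    zones: np.ndarray  # int labels 0..n_zones-1
    truth: LandscapeConfig

    def landuse_grid(self, year) -> LandUseGrid:
        return LandUseGrid(
            values=self.landuse[year], cell_area=self.truth.cell_area
        )

    def landuse_grids(self) -> dict:
        return {y: self.landuse_grid(y) for y in self.truth.years}


def expected_shares(config: LandscapeConfig, n_intervals: int) -> dict:
    """Closed-form Markov class shares after ``n_intervals`` transitions."""
    p0 = np.array([config.class_proportions.get(c, 0.0) for c in PRIMARY_CLASSES])
    p = p0 @ np.linalg.matrix_power(config.transition_matrix(), n_intervals)
    return dict(zip(PRIMARY_CLASSES, p))


def _generate_zones(shape: tuple[int, int], n_zones: int, rng: np.random.Generator) -> np.ndarray:
    """Contiguous county-like zones: nearest-centroid cells of seeded k-means
    on cell coordinates (Voronoi cells of the centroids, hence connected)."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    if n_zones == 1:
        return np.zeros(shape, dtype=np.int64)
    km = KMeans(
        n_clusters=n_zones,
        n_init=5,
        random_state=int(rng.integers(0, 2**31 - 1)),
    ).fit(coords)
    # relabel deterministically by centroid position (row-major)
    order = np.lexsort((km.cluster_centers_[:, 1], km.cluster_centers_[:, 0]))
    relabel = np.empty(n_zones, dtype=np.int64)
    relabel[order] = np.arange(n_zones)
    return relabel[km.labels_].reshape(shape)


def generate_scene(config: LandscapeConfig) -> SyntheticScene:
    """Generate a full scene from a validated configuration (deterministic
    given ``config.seed``)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols = config.grid_shape
    n_cells = rows * cols
    class_idx = {c: i for i, c in enumerate(PRIMARY_CLASSES)}

    zones = _generate_zones(config.grid_shape, config.n_zones, rng)

    # first-year land use: multinomial draw at the configured proportions
    p0 = np.array([config.class_proportions.get(c, 0.0) for c in PRIMARY_CLASSES])
    first = rng.choice(len(PRIMARY_CLASSES), size=n_cells, p=p0).reshape(config.grid_shape)
    T = config.transition_matrix()
    cum = np.cumsum(T, axis=1)
    landuse = {config.years[0]: first}
    current = first
    for year in config.years[1:]:
        u = rng.random(current.shape)
        nxt = (u[..., None] > cum[current]).sum(axis=-1)
        landuse[year] = nxt.astype(np.int64)
        current = landuse[year]

    # static population surface tied to first-year land cover
    pp = config.pop_params
    mult = np.array([pp.class_multipliers.get(c, 1.0) for c in PRIMARY_CLASSES])
    noise = rng.lognormal(mean=0.0, sigma=pp.noise_sd, size=config.grid_shape)
    population = pp.base_density * mult[first] * noise

    # per-year nightlights from that year's land cover + population coupling
    lp = config.light_params
    dn_mean = np.array([lp.dn_means.get(c, 0.0) for c in PRIMARY_CLASSES])
    nightlight = {}
    for year in config.years:
        loc = dn_mean[landuse[year]] + lp.pop_gain * np.log10(1.0 + population)
        dn = rng.normal(loc=loc, scale=lp.dn_sd)
        nightlight[year] = np.clip(np.round(dn), 0, 63).astype(np.int64)

    return SyntheticScene(
        landuse=landuse,
        population=population,
        nightlight=nightlight,
        zones=zones,
        truth=config,
    )


def generate_regression_dataset(
    n_zones: int,
    beta: np.ndarray,
    noise_sd: float,
    seed: int,
    covariates: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Zone-level dataset (balance index, 10 land-use proportions) with known β.

    ``beta`` has 11 entries (intercept first, then one slope per covariate).
    Proportions are a Dirichlet sub-composition: 11 categories (the ten
    detailed classes plus an unnamed remainder) are drawn on the simplex and
    the named ten kept, so rows sum to < 1 and the design stays full rank
    alongside an intercept. The response is X′β plus symmetric Gaussian
    noise; the true β is stored in ``df.attrs["beta"]``.
    """
    from .quantreg import DETAILED_COVARIATES

    if covariates is None:
        covariates = DETAILED_COVARIATES
    beta = np.asarray(beta, dtype=float).ravel()
    if len(beta) != len(covariates) + 1:
        raise ValueError(
            f"beta needs {len(covariates) + 1} entries (intercept + slopes), got {len(beta)}"
        )
    if n_zones < 30:
        raise ValueError(f"n_zones must be >= 30, got {n_zones}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    alpha = np.ones(len(covariates) + 1)
    props = rng.dirichlet(alpha, size=n_zones)[:, :-1]
    y = beta[0] + props @ beta[1:]
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n_zones)
    df = pd.DataFrame(props, columns=list(covariates))
    df.insert(0, "balance_index", y)
    df.attrs["beta"] = beta.copy()
    return df


def write_scene(scene: SyntheticScene, outdir) -> None:
    """Write the scene as multi-band TIFF rasters plus the config as YAML."""
    from pathlib import Path

    import tifffile
    import yaml

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    years = list(scene.truth.years)
    tifffile.imwrite(
        out / "landuse.tif",
        np.stack([scene.landuse[y] for y in years]).astype(np.int32),
    )
    tifffile.imwrite(
        out / "nightlight.tif",
        np.stack([scene.nightlight[y] for y in years]).astype(np.int32),
    )
    tifffile.imwrite(out / "population.tif", scene.population.astype(np.float32))
    tifffile.imwrite(out / "zones.tif", scene.zones.astype(np.int32))
    cfg = asdict(scene.truth)
    cfg["transition_rates"] = {
        f"{src} -> {dst}": rate for (src, dst), rate in scene.truth.transition_rates.items()
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
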