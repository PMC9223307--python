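"""Quantile and least-squares regression of the balance index on land use.

The response is the per-zone supply–demand balance index; covariates are
land-use composition proportions (canonically the ten detailed classes:
urban land, rural settlements, other construction land, paddy field, dry
land, other forest land, natural grassland, canal, lake, forest land) plus
an intercept. For quantile θ the coefficient vector β(θ) minimises the
check loss

    Σᵢ ρ_θ(yᵢ − xᵢ′β),   ρ_θ(u) = u·(θ − 1{u < 0}),

solved exactly as a linear programme (positive/negative residual split)
with the HiGHS solver — deterministic and optimal to solver tolerance.
Standard errors are x-y pair bootstrap (seeded), distribution-free and
identical across reruns; significance stars follow the 10%/5%/1% two-sided
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

#: Canonical detailed land-use covariates, in table order.
DETAILED_COVARIATES = (
    "urban land",
    "rural settlements",
    "other construction land",
    "paddy field",
    "dry land",
    "other forest land",
    "natural grassland",
    "canal",
    "lake",
    "forest land",
)

DEFAULT_THETAS = (0.1, 0.3, 0.5, 0.7, 0.9)


class RankDeficiencyError(ValueError):
    """Covariate matrix is not full column rank."""


@dataclass
class RegressionDesign:
    """Response vector and covariate matrix (intercept in first column)."""

    y: np.ndarray
    X: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if len(self.y) != n:
            raise ValueError("y and X row counts differ")
        if n <= p:
            raise ValueError(f"need n > p, got n={n}, p={p}")
        rank = np.linalg.matrix_rank(self.X)
        if rank < p:
            raise RankDeficiencyError(
                "covariate matrix is rank deficient "
                f"(rank {rank} < {p} columns); collinear columns: "
                f"{_collinear_columns(self.X, self.names)}"
            )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str = "balance_index",
        covariates: tuple[str, ...] | None = None,
        add_intercept: bool = True,
    ) -> "RegressionDesign":
        if covariates is None:
            covariates = tuple(c for c in df.columns if c != response)
        X = df[list(covariates)].to_numpy(dtype=float)
        names = tuple(covariates)
        if add_intercept:
            X = np.column_stack([np.ones(len(df)), X])
            names = ("intercept",) + names
        return cls(df[response].to_numpy(dtype=float), X, names)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Columns whose removal restores full rank (best-effort diagnosis)."""
    full = np.linalg.matrix_rank(X)
    out = []
    for j in range(X.shape[1]):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(rest) == full:
            out.append(names[j] if names else str(j))
    return out


def check_loss(theta: float, residuals: np.ndarray) -> float:
    """Asymmetric absolute-deviation loss Σ ρ_θ(u)."""
    u = np.asarray(residuals, dtype=float)
    return float(np.sum(u * (theta - (u < 0))))


@dataclass
class FitResult:
    """Coefficients with (optionally bootstrapped) standard errors."""

    beta: np.ndarray
    names: tuple[str, ...]
    se: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    objective: float | None = None
    theta: float | None = None
    method: str = ""

    @property
    def stars(self) -> tuple[str, ...]:
        if self.pvalues is None:
            return ("",) * len(self.beta)
        return tuple(significance_stars(p) for p in self.pvalues)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "se": self.se if self.se is not None else np.nan,
                "p": self.pvalues if self.pvalues is not None else np.nan,
                "stars": self.stars,
            },
            index=list(self.names),
        )


def significance_stars(p: float) -> str:
    """Two-sided significance stars: * 10%, ** 5%, *** 1%."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.10:
        return "*"
    return ""


def fit_ols(design: RegressionDesign) -> FitResult:
    """Ordinary least squares with classical standard errors."""
    model = sm.OLS(design.y, design.X).fit()
    return FitResult(
        beta=np.asarray(model.params),
        names=design.names,
        se=np.asarray(model.bse),
        pvalues=np.asarray(model.pvalues),
        objective=float(np.sum(model.resid**2)),
        method="ols",
    )


def _solve_quantile(y: np.ndarray, X: np.ndarray, theta: float) -> np.ndarray:
    """Exact LP solution of the check-loss programme via HiGHS.

    Variables (β, u⁺, u⁻) with Xβ + u⁺ − u⁻ = y, u± ≥ 0, minimise
    θ·1′u⁺ + (1−θ)·1′u⁻.
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, theta), np.full(n, 1.0 - theta)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = optimize.linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p]


def fit_quantile(design: RegressionDesign, theta: float) -> FitResult:
    """Quantile regression at θ ∈ (0, 1); no SEs (see :func:`bootstrap_se`)."""
    if not 0.0 < theta < 1.0:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    beta = _solve_quantile(design.y, design.X, theta)
    obj = check_loss(theta, design.y - design.X @ beta)
    return FitResult(
        beta=beta, names=design.names, objective=obj, theta=theta, method="quantile-lp"
    )


def bootstrap_se(
    design: RegressionDesign,
    theta: float | None,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """x-y pair bootstrap standard errors (θ = None bootstraps OLS)."""
    rng = np.random.default_rng(seed)
    n = design.n
    betas = np.empty((n_boot, design.p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb, yb = design.X[idx], design.y[idx]
        if theta is None:
            betas[b], *_ = np.linalg.lstsq(Xb, yb, rcond=None)
        else:
            betas[b] = _solve_quantile(yb, Xb, theta)
    return betas.std(axis=0, ddof=1)


def with_bootstrap_se(
    fit: FitResult, design: RegressionDesign, n_boot: int = 1000, seed: int = 0
) -> FitResult:
    """Attach bootstrap SEs and normal-approximation p-values to a fit."""
    se = bootstrap_se(design, fit.theta if fit.method != "ols" else None, n_boot, seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, fit.beta / se, np.inf * np.sign(fit.beta))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return FitResult(fit.beta, fit.names, se, p, fit.objective, fit.theta, fit.method)


@dataclass
class QuantilePath:
    """OLS column plus one quantile fit per θ, Table-style."""

    ols: FitResult
    fits: dict[float, FitResult] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Wide table: coefficient rows with SE rows beneath, stars attached."""
        cols = {"OLS": self.ols} | {f"q{t:g}": f for t, f in sorted(self.fits.items())}
        rows: dict[str, list[str]] = {}
        index = []
        names = self.ols.names
        for i, name in enumerate(names):
            index += [name, f"{name} (se)"]
        for label, fit in cols.items():
            col = []
            for i in range(len(names)):
                col.append(f"{fit.beta[i]:.3f}{fit.stars[i]}")
                col.append(f"({fit.se[i]:.3f})" if fit.se is not None else "")
            rows[label] = col
        return pd.DataFrame(rows, index=index)

    def crossing_count(self, X: np.ndarray) -> int:
        """Number of sample points whose fitted quantiles are non-monotone in θ."""
        thetas = sorted(self.fits)
        preds = np.stack([X @ self.fits[t].beta for t in thetas])
        return int(np.sum(np.any(np.diff(preds, axis=0) < -1e-9, axis=0)))


def quantile_path(
    design: RegressionDesign,
    thetas=DEFAULT_THETAS,
    n_boot: int = 1000,
    seed: int = 0,
) -> QuantilePath:
    """Fit OLS plus β(θ) over a θ grid with bootstrap SEs throughout."""
    ols = with_bootstrap_se(fit_ols(design), design, n_boot=n_boot, seed=seed)
    fits = {}
    for t in thetas:
        fits[float(t)] = with_bootstrap_se(
            fit_quantile(design, float(t)), design, n_boot=n_boot, seed=seed
        )
    return QuantilePath(ols=ols, fits=fits)
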