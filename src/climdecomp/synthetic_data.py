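"""Synthetic gridded climate, survey routes, and counts with known truth.

Emulates the structure of the real inputs — a national gridded climate
product, unbalanced multi-country breeding-bird route panels, and per-route
annual counts — so every downstream stage (decomposition, design assembly,
mixed-model fitting, effect assessment) can be exercised against known
generative parameters.

The climate generator produces, per variable, a cube that is exactly the sum
the decomposition assumes: a fixed spatial surface (a north-south gradient
plus smooth low-frequency structure), a year-specific anomaly shared by all
cells, and cell-by-year residual noise.  Temperature and precipitation
anomalies are drawn jointly with a configurable correlation (warm breeding
seasons tend to be drier).  Counts are drawn from the same model class that
is later fitted: a log-link Poisson/NB2 count process with a route random
intercept, log-effort offset, and an optional logit-linear structural-zero
mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .decomposition import ClimateCube, DecomposedClimate
from .covariates import (
    POOLED_CATEGORIES,
    DesignSpec,
    DesignMatrices,
    assemble_design,
)

__all__ = [
    "SyntheticConfig",
    "TrueParameters",
    "generate_climate",
    "generate_routes",
    "generate_habitat_covariates",
    "generate_counts",
    "simulate_counts_from_design",
    "write_dataset",
]

COUNTRIES = ("NO", "SE", "FI")


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for the synthetic study region.

    Defaults mirror the study conditions: a 48-year centering period
    (1971-2018) containing a 23-year study period (1996-2018); three
    "countries" with scheme start years 1996 (SE) and 2006 (NO, FI); paired
    Point/Line surveys for NO; counts recorded as individuals in SE and as
    pairs elsewhere.  Amplitudes are in the variable's units (deg C / mm).
    """

    n_cells_x: int = 20
    n_cells_y: int = 20
    centering_years: tuple[int, int] = (1971, 2018)
    study_years: tuple[int, int] = (1996, 2018)
    base_value: dict = field(
        default_factory=lambda: {"temperature": 10.7, "precipitation": 193.0}
    )
    spatial_gradient_amplitude: dict = field(
        default_factory=lambda: {"temperature": -6.0, "precipitation": 120.0}
    )
    spatial_noise_amplitude: dict = field(
        default_factory=lambda: {"temperature": 1.0, "precipitation": 30.0}
    )
    annual_anomaly_sd: dict = field(
        default_factory=lambda: {"temperature": 0.8, "precipitation": 25.0}
    )
    residual_sd: dict = field(
        default_factory=lambda: {"temperature": 0.5, "precipitation": 15.0}
    )
    temp_precip_correlation: float = -0.3
    residual_smoothing: float = 0.0   # spatial kernel length in cells; 0 = iid
    n_routes: int = 150
    country_shares: tuple[float, float, float] = (0.27, 0.41, 0.32)
    scheme_start_year: dict = field(
        default_factory=lambda: {"NO": 2006, "SE": 1996, "FI": 2006}
    )
    effort_range: tuple[int, int] = (4, 12)
    coverage: float = 0.85            # per route-year probability of a survey
    seed: int = 20180531

    def __post_init__(self) -> None:
        # YAML 1.1 parses a bare NO as boolean false (the "Norway problem")
        if False in self.scheme_start_year:
            self.scheme_start_year = {
                ("NO" if k is False else k): v
                for k, v in self.scheme_start_year.items()
            }
        if self.n_cells_x < 2 or self.n_cells_y < 2:
            raise SyntheticConfigError("grid dimensions must be >= 2")
        c0, c1 = self.centering_years
        s0, s1 = self.study_years
        if not (c0 <= s0 <= s1 <= c1):
            raise SyntheticConfigError("study_years must lie within centering_years")
        if abs(sum(self.country_shares) - 1.0) > 1e-12:
            raise SyntheticConfigError("country_shares must sum to 1")
        for d in (self.annual_anomaly_sd, self.residual_sd):
            if any(v < 0 for v in d.values()):
                raise SyntheticConfigError("standard deviations must be >= 0")
        if not -1.0 <= self.temp_precip_correlation <= 1.0:
            raise SyntheticConfigError("temp_precip_correlation must be in [-1, 1]")
        if self.effort_range[0] < 1 or self.effort_range[1] < self.effort_range[0]:
            raise SyntheticConfigError("effort_range must be positive and ordered")

    @property
    def n_cells(self) -> int:
        return self.n_cells_x * self.n_cells_y

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.centering_years[0], self.centering_years[1] + 1)

    def rng(self, stage: int) -> np.random.Generator:
        """Per-stage stream derived from the master seed (0=climate, 1=routes,
        2=habitat, 3=counts)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stage,))
        )


@dataclass
class TrueParameters:
    """Generative coefficients for the count process (named by design column).

    ``beta_count`` applies to the count-part linear predictor, ``gamma_zi``
    to the structural-zero logit.  ``theta`` is the NB2 dispersion
    (Var = mu + mu^2/theta); ``sigma_u`` the route random-intercept SD.
    """

    beta_count: dict = field(default_factory=dict)
    gamma_zi: dict = field(default_factory=dict)
    theta: float = 1.5
    sigma_u: float = 0.5
    family: str = "nb"
    habitat: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "nb", "zip", "zinb"):
            raise SyntheticConfigError(f"unknown family {self.family!r}")
        if self.family in ("nb", "zinb") and not self.theta > 0:
            raise SyntheticConfigError("theta must be > 0 for nb/zinb")
        if self.sigma_u < 0:
            raise SyntheticConfigError("sigma_u must be >= 0")
        if self.family in ("poisson", "nb") and self.gamma_zi:
            raise SyntheticConfigError("gamma_zi only valid for zip/zinb")

    @classmethod
    def default(cls, family: str = "nb") -> "TrueParameters":
        """A mountain-bird-like species: commoner at cold sites and in cold
        years, mildly wetter-is-better, moderately overdispersed."""
        beta = {
            "intercept": 0.3,
            "spatial_temp": -0.45, "spatial_prec": 0.20,
            "temporal_temp": -0.30, "temporal_prec": 0.15,
            "residual_temp": -0.20, "residual_prec": 0.10,
            "spatial_temp:spatial_prec": 0.05,
            "temporal_temp:temporal_prec": -0.05,
            "residual_temp:residual_prec": 0.05,
            "year1": 0.05, "year2": -0.03,
            "survey_point": 0.25, "unit_individual": 0.35,
            "mountain_vegetation": 0.30, "other_forest": -0.15,
            "wetlands": 0.20, "slope": 0.10,
        }
        gamma = {}
        if family in ("zip", "zinb"):
            gamma = {"intercept": -1.5, "spatial_temp": 0.3}
        return cls(
            beta_count=beta,
            gamma_zi=gamma,
            theta=1.5,
            sigma_u=0.5,
            family=family,
            habitat=("mountain_vegetation", "other_forest", "wetlands", "slope"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "beta_count": self.beta_count, "gamma_zi": self.gamma_zi,
                "theta": self.theta, "sigma_u": self.sigma_u,
                "family": self.family, "habitat": list(self.habitat),
            }, indent=2,
        ))


# ---------------------------------------------------------------------------
# climate
# ---------------------------------------------------------------------------

def _grid_cells(config: SyntheticConfig) -> pd.DataFrame:
    ys, xs = np.mgrid[0:config.n_cells_y, 0:config.n_cells_x]
    return pd.DataFrame({
        "cell_id": np.arange(config.n_cells),
        "x": xs.ravel().astype(float),
        "y": ys.ravel().astype(float),
    })


def _smooth_field(rng: np.random.Generator, nx: int, ny: int) -> np.ndarray:
    """Zero-mean low-frequency surface from a few random cosine modes."""
    ys, xs = np.mgrid[0:ny, 0:nx]
    fx, fy = xs / max(nx - 1, 1), ys / max(ny - 1, 1)
    out = np.zeros((ny, nx))
    for _ in range(4):
        kx, ky = rng.uniform(0.5, 2.0, size=2)
        px, py = rng.uniform(0, 2 * np.pi, size=2)
        out += rng.normal(0, 1) * np.cos(2 * np.pi * kx * fx + px) * np.cos(
            2 * np.pi * ky * fy + py
        )
    out -= out.mean()
    scale = out.std()
    return out / scale if scale > 0 else out


def _gaussian_smooth(field: np.ndarray, length: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    return gaussian_filter(field, sigma=length, mode="nearest")


def generate_climate(config: SyntheticConfig, variable: str) -> ClimateCube:
    """Cube = spatial surface + shared annual anomaly + cell-year residual.

    Temperature and precipitation anomalies are drawn from one joint stream,
    so calling this twice (once per variable) yields fields correlated at
    ``config.temp_precip_correlation``.  Precipitation is truncated at 0.
    """
    if variable not in ("temperature", "precipitation"):
        raise SyntheticConfigError(f"unknown variable {variable!r}")
    rng = config.rng(0)
    ny, nx = config.n_cells_y, config.n_cells_x
    years = config.years
    T = len(years)
    col = 0 if variable == "temperature" else 1

    # fixed spatial surface: latitudinal gradient + smooth structure
    ys = np.mgrid[0:ny, 0:nx][0] / max(ny - 1, 1)
    surfaces = {}
    for v in ("temperature", "precipitation"):
        grad = config.spatial_gradient_amplitude[v] * ys
        noise = config.spatial_noise_amplitude[v] * _smooth_field(rng, nx, ny)
        surfaces[v] = config.base_value[v] + grad + noise

    rho = config.temp_precip_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov)

    anom = (L @ rng.standard_normal((2, T)))  # (2, T), unit variance
    anom_sd = np.array([
        config.annual_anomaly_sd["temperature"],
        config.annual_anomaly_sd["precipitation"],
    ])
    anomalies = anom * anom_sd[:, None]

    resid = np.einsum("ab,btij->atij", L, rng.standard_normal((2, T, ny, nx)))
    if config.residual_smoothing > 0:
        for a in range(2):
            for t in range(T):
                sm = _gaussian_smooth(resid[a, t], config.residual_smoothing)
                s = sm.std()
                resid[a, t] = sm / s if s > 0 else sm
    resid_sd = np.array([
        config.residual_sd["temperature"],
        config.residual_sd["precipitation"],
    ])
    residuals = resid * resid_sd[:, None, None, None]

    field2d = (
        surfaces[variable][None, :, :]
        + anomalies[col][:, None, None]
        + residuals[col]
    )  # (T, ny, nx)
    if variable == "precipitation":
        field2d = np.clip(field2d, 0.0, None)

    values = field2d.reshape(T, -1).T  # (cells, years), row-major like _grid_cells
    return ClimateCube(
        variable=variable,
        values=values,
        cells=_grid_cells(config),
        years=years,
        centering_years=config.centering_years,
    )


# ---------------------------------------------------------------------------
# routes and habitat
# ---------------------------------------------------------------------------

def generate_routes(config: SyntheticConfig) -> pd.DataFrame:
    """Long route-year table with unbalanced multi-country panels.

    Routes sit on distinct grid cells.  Country NO emits paired Point and
    Line survey rows sharing one route id (spatially dependent surveys);
    SE and FI are Line-transect schemes.  Route-years before a country's
    scheme start year are absent, and each eligible route-year is surveyed
    with probability ``config.coverage``.
    """
    if config.n_routes > config.n_cells:
        raise SyntheticConfigError("n_routes exceeds the number of grid cells")
    rng = config.rng(1)
    cells = rng.choice(config.n_cells, size=config.n_routes, replace=False)

    n = config.n_routes
    n_no = int(round(config.country_shares[0] * n))
    n_se = int(round(config.country_shares[1] * n))
    country = np.array(
        ["NO"] * n_no + ["SE"] * n_se + ["FI"] * (n - n_no - n_se)
    )
    rng.shuffle(country)

    unit = {"NO": "Pair", "SE": "Individual", "FI": "Pair"}
    s0, s1 = config.study_years
    lo, hi = config.effort_range
    rows = []
    for r in range(n):
        ctry = country[r]
        surveys = ("Point", "Line") if ctry == "NO" else ("Line",)
        base_effort = int(rng.integers(lo, hi + 1))
        start = max(int(config.scheme_start_year[ctry]), s0)
        for year in range(start, s1 + 1):
            if rng.random() > config.coverage:
                continue
            effort = int(np.clip(base_effort + rng.integers(-1, 2), lo, hi))
            for survey in surveys:
                rows.append((
                    f"R{r:04d}", ctry, survey, unit[ctry],
                    int(cells[r]), year, effort,
                ))
    return pd.DataFrame(
        rows,
        columns=["route_id", "country", "survey", "unit", "cell_id", "year", "effort"],
    )


def generate_habitat_covariates(
    config: SyntheticConfig, routes: pd.DataFrame
) -> pd.DataFrame:
    """Static per-route habitat proportions and terrain covariates.

    Land-cover composition follows a latitude-tilted Dirichlet (more sparse
    mountain / mountain vegetation northward, more forest and agriculture
    southward); slope and solar radiation are synthetic stand-ins for the
    DEM-derived covariates.
    """
    rng = config.rng(2)
    base = routes[["route_id", "cell_id"]].drop_duplicates("route_id")
    lat = (base["cell_id"].to_numpy() // config.n_cells_x) / max(config.n_cells_y - 1, 1)
    n = len(base)
    conc = np.empty((n, len(POOLED_CATEGORIES)))
    # concentration per category: [sparse, mountain_veg, decid, other_forest,
    #                              wetlands, water, agriculture]
    for i, f in enumerate(lat):
        conc[i] = [
            0.5 + 2.5 * f, 1.0 + 3.0 * f, 0.8, 1.0 + 3.0 * (1 - f),
            1.0, 0.6, 0.3 + 2.0 * (1 - f),
        ]
    # Dirichlet with row-specific concentration via normalized gamma draws
    g = rng.gamma(shape=conc)
    props = g / g.sum(axis=1, keepdims=True)
    out = pd.DataFrame(props, columns=POOLED_CATEGORIES)
    out.insert(0, "route_id", base["route_id"].to_numpy())
    out["slope"] = rng.gamma(shape=2.0, scale=2.0, size=n)          # degrees
    out["solar_radiation"] = rng.normal(100.0, 15.0, size=n)        # synthetic units
    return out


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def simulate_counts_from_design(
    design: DesignMatrices,
    params: TrueParameters,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw counts for every design row under the generative model.

    eta = x'beta + u_route + log(effort); counts from the configured family
    with mean exp(eta); zip/zinb add structural zeros with
    pi = logistic(x_zi' gamma).
    """
    beta = pd.Series(params.beta_count)
    unknown = set(beta.index) - set(design.X.columns)
    if unknown:
        raise SyntheticConfigError(
            f"beta_count names not in the design: {sorted(unknown)}"
        )
    eta = design.X[beta.index].to_numpy() @ beta.to_numpy() + design.offset
    u = rng.normal(0.0, params.sigma_u, size=design.n_routes)
    eta = eta + u[design.route]
    mu = np.exp(eta)

    if params.family in ("poisson", "zip"):
        y = rng.poisson(mu).astype(float)
    else:
        lam = rng.gamma(shape=params.theta, scale=mu / params.theta)
        y = rng.poisson(lam).astype(float)

    if params.family in ("zip", "zinb"):
        gamma = pd.Series(params.gamma_zi)
        unknown = set(gamma.index) - set(design.X_zi.columns)
        if unknown:
            raise SyntheticConfigError(
                f"gamma_zi names not in the zi design: {sorted(unknown)}"
            )
        zi_eta = design.X_zi[gamma.index].to_numpy() @ gamma.to_numpy()
        pi = 1.0 / (1.0 + np.exp(-zi_eta))
        y[rng.random(len(y)) < pi] = 0.0
    return y


def generate_counts(
    routes: pd.DataFrame,
    temperature: DecomposedClimate,
    precipitation: DecomposedClimate,
    params: TrueParameters,
    covariates: pd.DataFrame | None = None,
    lag: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, DesignMatrices]:
    """Counts for every route-year row, plus the design they were drawn from."""
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    )
    spec = DesignSpec(habitat=params.habitat)
    design = assemble_design(
        routes, covariates, temperature, precipitation, lag=lag, spec=spec
    )
    y = simulate_counts_from_design(design, params, rng)
    design.y = y
    counts = design.frame[["route_id", "survey", "year"]].copy()
    counts["count"] = y.astype(int)
    return counts, design


def write_dataset(
    outdir: str | Path,
    config: SyntheticConfig,
    params: TrueParameters | None = None,
    lag: int = 0,
) -> dict:
    """Generate and write a complete synthetic dataset as CSV/JSON files."""
    from .decomposition import decompose

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = params or TrueParameters.default()
    manifest = {"seed": config.seed, "files": {}}
    cubes = {}
    for var in ("temperature", "precipitation"):
        cube = generate_climate(config, var)
        cube.to_csv(outdir / f"climate_{var}.csv")
        cubes[var] = cube
        manifest["files"][f"climate_{var}"] = f"climate_{var}.csv"
    routes = generate_routes(config)
    routes.to_csv(outdir / "routes.csv", index=False)
    habitat = generate_habitat_covariates(config, routes)
    habitat.to_csv(outdir / "habitat.csv", index=False)
    dec_t = decompose(cubes["temperature"], config.study_years)
    dec_p = decompose(cubes["precipitation"], config.study_years)
    counts, _ = generate_counts(
        routes, dec_t, dec_p, params, covariates=habitat, lag=lag, seed=config.seed
    )
    counts.to_csv(outdir / "counts.csv", index=False)
    params.to_json(outdir / "true_parameters.json")
    manifest["files"].update({
        "routes": "routes.csv", "habitat": "habitat.csv",
        "counts": "counts.csv", "true_parameters": "true_parameters.json",
    })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
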