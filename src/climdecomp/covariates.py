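"""Design inputs for the abundance models.

Covers the habitat/terrain side of the analysis: pooling the 44 CORINE land
cover classes into the seven categories relevant for mountain birds, matching
survey years to land-cover map epochs, summarising rasters within circular
buffers around survey geometry, variance-inflation-factor screening, and
assembling the model-ready design matrices (climate components, interactions,
year polynomial, survey-protocol factors, habitat covariates, log-effort
offset, z-standardisation).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decomposition import DecomposedClimate, lag_covariates

__all__ = [
    "POOLED_CATEGORIES",
    "LandCoverMap",
    "CollinearityReport",
    "DesignSpec",
    "DesignMatrices",
    "load_pooling_table",
    "pool_landcover",
    "match_epoch",
    "summarize_buffer",
    "compute_vif",
    "assemble_design",
]

#: the seven pooled land-cover categories (plus implicit "other")
POOLED_CATEGORIES = (
    "sparse_mountain",
    "mountain_vegetation",
    "deciduous_forest",
    "other_forest",
    "wetlands",
    "inland_waters",
    "agriculture",
)

#: land-cover epochs and the survey-year periods matched to each
EPOCH_PERIODS = {2000: (1996, 2003), 2006: (2004, 2009), 2012: (2010, 2015), 2018: (2016, 2018)}


class CovariateError(ValueError):
    pass


def load_pooling_table() -> pd.DataFrame:
    """Editable class_code -> pooled_category mapping shipped with the package."""
    src = importlib.resources.files("climdecomp") / "data" / "corine_pooling.csv"
    with importlib.resources.as_file(src) as path:
        return pd.read_csv(path)


@dataclass
class LandCoverMap:
    """Categorical raster of land-cover class codes.

    ``raster`` holds integer class codes; cell (row, col) has its center at
    ``((col + 0.5) * cell_size, (row + 0.5) * cell_size)``.
    """

    raster: np.ndarray
    epoch: int
    cell_size: float = 100.0
    pooled: bool = False

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.epoch not in EPOCH_PERIODS:
            raise CovariateError(f"unknown land-cover epoch {self.epoch}")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.raster.shape
        xs = (np.arange(nx) + 0.5) * self.cell_size
        ys = (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


def pool_landcover(lc: LandCoverMap, table: pd.DataFrame | None = None) -> LandCoverMap:
    """Map the 44-class raster onto the seven pooled categories (+ "other").

    Returns a new map whose raster holds indices into ``POOLED_CATEGORIES``
    (7 = other/sea).  Codes absent from the mapping table raise.
    """
    table = load_pooling_table() if table is None else table
    cat_index = {c: i for i, c in enumerate(POOLED_CATEGORIES)}
    cat_index["other"] = len(POOLED_CATEGORIES)
    mapping = dict(
        zip(table["class_code"].astype(int), table["pooled_category"].map(cat_index))
    )
    if table["pooled_category"].isna().any() or any(
        v is None or (isinstance(v, float) and np.isnan(v)) for v in mapping.values()
    ):
        raise CovariateError("pooling table contains unknown pooled categories")
    codes = np.unique(lc.raster)
    unmapped = [int(c) for c in codes if int(c) not in mapping]
    if unmapped:
        raise CovariateError(f"unmapped land-cover code(s): {unmapped}")
    lut = np.full(int(codes.max()) + 1, -1, dtype=int)
    for code, cat in mapping.items():
        if code < len(lut):
            lut[code] = cat
    return LandCoverMap(
        raster=lut[lc.raster], epoch=lc.epoch, cell_size=lc.cell_size, pooled=True
    )


def match_epoch(year: int) -> int:
    """Land-cover map epoch whose survey-year period contains ``year``."""
    for epoch, (lo, hi) in EPOCH_PERIODS.items():
        if lo <= year <= hi:
            return epoch
    raise CovariateError(f"survey year {year} outside supported range 1996-2018")


def summarize_buffer(
    values: np.ndarray,
    geometry: np.ndarray,
    radius: float,
    cell_size: float = 100.0,
    categorical: bool = False,
    n_categories: int | None = None,
) -> dict[str, float] | float:
    """Summarise a raster within circular buffers around survey geometry.

    ``geometry`` is an ``(n, 2)`` array of x/y points (point-count stations or
    densely sampled transect vertices).  A raster cell belongs to the buffer
    when its center lies within ``radius`` of any geometry point — no
    partial-cell weighting.  Categorical rasters return the proportion of each
    category among member cells; continuous rasters return the mean.
    """
    values = np.asarray(values)
    geometry = np.atleast_2d(np.asarray(geometry, dtype=float))
    ny, nx = values.shape
    xs = (np.arange(nx) + 0.5) * cell_size
    ys = (np.arange(ny) + 0.5) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((centers[:, None, :] - geometry[None, :, :]) ** 2).sum(axis=2)
    member = (d2.min(axis=1) <= radius**2)
    if not member.any():
        raise CovariateError("buffer does not intersect the raster")
    sel = values.ravel()[member]
    if categorical:
        ncat = int(n_categories if n_categories is not None else sel.max() + 1)
        counts = np.bincount(sel.astype(int), minlength=ncat)
        return {f"cat_{k}": counts[k] / member.sum() for k in range(ncat)}
    return float(sel.mean())


@dataclass
class CollinearityReport:
    vif: pd.Series
    threshold: float = 4.0

    @property
    def flags(self) -> pd.Series:
        return ~(self.vif < self.threshold)  # non-finite VIFs flag too

    @property
    def ok(self) -> bool:
        return not bool(self.flags.any())


def compute_vif(design: pd.DataFrame, threshold: float = 4.0) -> CollinearityReport:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on the others.

    Exactly collinear columns are reported with ``inf`` (flagged), not raised.
    An intercept column is implicit: columns are centered before regression.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise CovariateError("need at least two covariates for VIF")
    if n <= p:
        raise CovariateError("need more rows than covariates for VIF")
    Xc = X - X.mean(axis=0)
    vifs = {}
    for j, col in enumerate(design.columns):
        yj = Xc[:, j]
        Zj = np.delete(Xc, j, axis=1)
        tss = float(yj @ yj)
        if tss == 0.0:
            vifs[col] = np.inf
            continue
        coef, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
        rss = float(((yj - Zj @ coef) ** 2).sum())
        r2 = 1.0 - rss / tss
        vifs[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return CollinearityReport(vif=pd.Series(vifs), threshold=threshold)


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

#: column names of the six climate mains and their within-component interactions
CLIMATE_MAINS = (
    "spatial_temp", "spatial_prec",
    "temporal_temp", "temporal_prec",
    "residual_temp", "residual_prec",
)
CLIMATE_INTERACTIONS = (
    "spatial_temp:spatial_prec",
    "temporal_temp:temporal_prec",
    "residual_temp:residual_prec",
)


@dataclass
class DesignSpec:
    """What goes into the count-part (and zero-inflation-part) design."""

    habitat: tuple[str, ...] = ()
    interactions: bool = True
    year_poly: bool = True
    protocol_factors: bool = True     # Survey / Unit, count part only
    standardize: bool = True
    climate_blocks: tuple[str, ...] = CLIMATE_MAINS


@dataclass
class DesignMatrices:
    """Model-ready inputs: count design, zi design, offset, grouping, response."""

    X: pd.DataFrame
    X_zi: pd.DataFrame
    offset: np.ndarray
    route: np.ndarray               # integer route codes
    route_ids: np.ndarray           # original ids, aligned with codes
    frame: pd.DataFrame             # the merged route-year table
    scalers: dict[str, tuple[float, float]] = field(default_factory=dict)
    y: np.ndarray | None = None
    n_dropped_lag: int = 0

    @property
    def n_routes(self) -> int:
        return len(self.route_ids)

    def standardize_value(self, col: str, raw: np.ndarray) -> np.ndarray:
        """Apply the stored z-scaling of ``col`` to new raw values."""
        mu, sd = self.scalers.get(col, (0.0, 1.0))
        return (np.asarray(raw, dtype=float) - mu) / sd


def assemble_design(
    routes: pd.DataFrame,
    covariates: pd.DataFrame | None,
    temperature: DecomposedClimate,
    precipitation: DecomposedClimate,
    lag: int = 0,
    spec: DesignSpec | None = None,
    counts: pd.DataFrame | None = None,
) -> DesignMatrices:
    """Merge routes, habitat covariates and decomposed climate into designs.

    ``routes`` is a long route-year table with columns ``route_id, survey,
    unit, country, cell_id, year, effort``.  The zero-inflation design equals
    the count design minus the Survey/Unit protocol factors.  Continuous
    columns are z-standardised; the constants are stored for prediction.
    """
    spec = spec or DesignSpec()
    df = routes.copy()
    required = {"route_id", "survey", "unit", "cell_id", "year", "effort"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise CovariateError(f"route table missing columns: {sorted(missing_cols)}")

    if lag > 0:
        temperature = lag_covariates(temperature, lag)
        precipitation = lag_covariates(precipitation, lag)
    avail_years = set(int(y) for y in temperature.study_years)
    keep = df["year"].astype(int).isin(avail_years)
    n_dropped = int((~keep).sum())
    df = df[keep].reset_index(drop=True)

    if covariates is not None:
        on = ["route_id", "year"] if "year" in covariates.columns else ["route_id"]
        df = df.merge(covariates, on=on, how="left", validate="many_to_one")
    for name in spec.habitat:
        if name not in df.columns:
            raise CovariateError(f"habitat covariate {name!r} not available")
        if df[name].isna().any():
            bad = df.loc[df[name].isna(), ["route_id", "year"]].iloc[0]
            raise CovariateError(
                f"missing covariate {name!r} for route-year "
                f"{bad['route_id']}@{bad['year']}"
            )

    t_sp, t_tm, t_rs = temperature.lookup(df["cell_id"], df["year"])
    p_sp, p_tm, p_rs = precipitation.lookup(df["cell_id"], df["year"])
    clim = {
        "spatial_temp": t_sp, "spatial_prec": p_sp,
        "temporal_temp": t_tm, "temporal_prec": p_tm,
        "residual_temp": t_rs, "residual_prec": p_rs,
    }
    for name in spec.climate_blocks:
        df[name] = clim[name]

    effort = df["effort"].to_numpy(dtype=float)
    if np.any(effort <= 0):
        raise CovariateError("non-positive survey effort")
    offset = np.log(effort)

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    scalers: dict[str, tuple[float, float]] = {}

    def _z(name: str, raw: np.ndarray) -> np.ndarray:
        raw = np.asarray(raw, dtype=float)
        if not np.all(np.isfinite(raw)):
            raise CovariateError(f"non-finite values in covariate {name!r}")
        if spec.standardize:
            mu, sd = float(raw.mean()), float(raw.std())
            sd = sd if sd > 0 else 1.0
            scalers[name] = (mu, sd)
            return (raw - mu) / sd
        scalers[name] = (0.0, 1.0)
        return raw

    for name in spec.climate_blocks:
        cols[name] = _z(name, df[name].to_numpy())
    if spec.interactions:
        for inter in CLIMATE_INTERACTIONS:
            a, b = inter.split(":")
            if a in cols and b in cols:
                cols[inter] = cols[a] * cols[b]
    if spec.year_poly:
        z = _z("year1", df["year"].to_numpy(dtype=float))
        cols["year1"] = z
        cols["year2"] = _z("year2", z**2)
    zi_excluded = []
    if spec.protocol_factors:
        cols["survey_point"] = (df["survey"].astype(str) == "Point").astype(float).to_numpy()
        cols["unit_individual"] = (df["unit"].astype(str) == "Individual").astype(float).to_numpy()
        zi_excluded = ["survey_point", "unit_individual"]
    for name in spec.habitat:
        cols[name] = _z(name, df[name].to_numpy())

    X = pd.DataFrame(cols)
    X_zi = X.drop(columns=zi_excluded)

    route_ids, route_codes = np.unique(df["route_id"].to_numpy(), return_inverse=True)
    y = None
    if counts is not None:
        merged = df.merge(
            counts, on=[c for c in ("route_id", "survey", "year") if c in counts.columns],
            how="left",
        )
        if merged["count"].isna().any():
            bad = merged.loc[merged["count"].isna(), ["route_id", "year"]].iloc[0]
            raise CovariateError(
                f"missing count for route-year {bad['route_id']}@{bad['year']}"
            )
        y = merged["count"].to_numpy(dtype=float)

    return DesignMatrices(
        X=X, X_zi=X_zi, offset=offset, route=route_codes, route_ids=route_ids,
        frame=df, scalers=scalers, y=y, n_dropped_lag=n_dropped,
    )
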