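"""Breeding-season aggregation and spatial/temporal/residual climate decomposition.

A gridded climate variable :math:`C_{i,t}` (cell *i*, year *t*) is split into
additive components relative to its *global mean* over a long centering period:

.. math::

    CC_{i,t} &= C_{i,t} - \\bar{C} \\\\
    CCSpace_i &= \\frac{1}{T}\\sum_t CC_{i,t} \\\\
    CCTime_t &= \\frac{1}{N}\\sum_i CC_{i,t} \\\\
    CCResidual_{i,t} &= CC_{i,t} - CCSpace_i - CCTime_t

The spatial component is each cell's long-term anomaly (the "static" climate
surface), the temporal component is the shared annual anomaly, and the
residual is the spatiotemporal variation left over.  The centering period
(default 1971-2018 semantics) may be longer than the study period over which
temporal/residual components are used (default 1996-2018 semantics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ClimateCube",
    "DecomposedClimate",
    "seasonal_aggregate",
    "decompose",
    "reconstruct",
    "lag_covariates",
]

#: month-number spans for the supported breeding-season windows (inclusive)
SEASON_WINDOWS = {"may-jul": (5, 7), "may-jun": (5, 6)}


class DecompositionError(ValueError):
    """Raised for invalid cubes or year ranges."""


@dataclass
class ClimateCube:
    """Cell x year seasonal climate values.

    Parameters
    ----------
    variable
        ``"temperature"`` (deg C, seasonal mean) or ``"precipitation"``
        (mm, seasonal cumulative sum).
    values
        ``(n_cells, n_years)`` array.
    cells
        DataFrame with columns ``cell_id``, ``x``, ``y`` (one row per cell,
        aligned with the rows of ``values``).
    years
        Strictly increasing array of calendar years (columns of ``values``).
    centering_years
        Inclusive ``(first, last)`` range used for the global mean.
    season_window
        ``"may-jul"`` or ``"may-jun"`` label (metadata only).
    """

    variable: str
    values: np.ndarray
    cells: pd.DataFrame
    years: np.ndarray
    centering_years: tuple[int, int]
    season_window: str = "may-jul"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.values.ndim != 2:
            raise DecompositionError("values must be a cell x year matrix")
        if self.values.shape != (len(self.cells), len(self.years)):
            raise DecompositionError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {len(self.years)} years"
            )
        if np.any(np.diff(self.years) <= 0):
            raise DecompositionError("years must be strictly increasing")
        lo, hi = self.centering_years
        if lo > hi or lo < self.years[0] or hi > self.years[-1]:
            raise DecompositionError(
                f"centering_years {self.centering_years} not within "
                f"available years {self.years[0]}-{self.years[-1]}"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def year_index(self, years: np.ndarray) -> np.ndarray:
        pos = {int(y): j for j, y in enumerate(self.years)}
        try:
            return np.array([pos[int(y)] for y in years])
        except KeyError as err:
            raise DecompositionError(f"year {err} not in cube") from None

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        """Long format: cell_id, x, y, year, value."""
        idx = pd.MultiIndex.from_product(
            [self.cells["cell_id"], self.years], names=["cell_id", "year"]
        )
        df = pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()
        return df.merge(self.cells, on="cell_id")[["cell_id", "x", "y", "year", "value"]]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_xarray(self):
        import xarray as xr

        nx = self.cells["x"].nunique()
        ny = self.cells["y"].nunique()
        if nx * ny == self.n_cells:
            order = np.lexsort((self.cells["x"], self.cells["y"]))
            vals = self.values[order].reshape(ny, nx, len(self.years))
            return xr.DataArray(
                vals,
                dims=("y", "x", "year"),
                coords={
                    "y": np.sort(self.cells["y"].unique()),
                    "x": np.sort(self.cells["x"].unique()),
                    "year": self.years,
                },
                name=self.variable,
                attrs={
                    "centering_years": list(self.centering_years),
                    "season_window": self.season_window,
                },
            )
        raise DecompositionError("cube cells do not form a complete rectangle")

    def to_netcdf(self, path: str | Path) -> None:
        # scipy engine -> classic netCDF3, no extra dependency
        self.to_xarray().to_netcdf(path, engine="scipy")

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        variable: str,
        centering_years: tuple[int, int],
        season_window: str = "may-jul",
    ) -> "ClimateCube":
        piv = df.pivot_table(index="cell_id", columns="year", values="value")
        if piv.isna().any().any():
            raise DecompositionError("incomplete cell x year table")
        cells = df[["cell_id", "x", "y"]].drop_duplicates().set_index("cell_id")
        cells = cells.loc[piv.index].reset_index()
        return cls(
            variable=variable,
            values=piv.to_numpy(),
            cells=cells,
            years=piv.columns.to_numpy(int),
            centering_years=centering_years,
            season_window=season_window,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "ClimateCube":
        return cls.from_frame(pd.read_csv(path), **kw)


@dataclass
class DecomposedClimate:
    """Output of :func:`decompose` for one climate variable.

    ``spatial`` is indexed like the cube's cells; ``temporal`` and the
    columns of ``residual`` are indexed by ``study_years``.
    """

    variable: str
    global_mean: float
    spatial: np.ndarray            # (n_cells,)
    temporal: np.ndarray           # (n_study_years,)
    residual: np.ndarray           # (n_cells, n_study_years)
    cells: pd.DataFrame
    study_years: np.ndarray
    season_window: str = "may-jul"
    centering_years: tuple[int, int] = (0, 0)
    lag: int = 0
    dropped_years: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_cells(self) -> int:
        return len(self.spatial)

    def cell_index(self, cell_ids) -> np.ndarray:
        pos = pd.Series(np.arange(self.n_cells), index=self.cells["cell_id"])
        return pos.loc[np.asarray(cell_ids)].to_numpy()

    def year_pos(self, years) -> np.ndarray:
        pos = {int(y): j for j, y in enumerate(self.study_years)}
        try:
            return np.array([pos[int(y)] for y in np.atleast_1d(years)])
        except KeyError as err:
            raise DecompositionError(
                f"study year {err} not available (lag={self.lag})"
            ) from None

    def lookup(self, cell_ids, years) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spatial, temporal, residual values for aligned (cell, year) vectors."""
        ci = self.cell_index(cell_ids)
        yj = self.year_pos(years)
        return self.spatial[ci], self.temporal[yj], self.residual[ci, yj]

    # ------------------------------------------------------------------ I/O
    def write(self, outdir: str | Path, prefix: str | None = None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.variable
        pd.DataFrame(
            {"cell_id": self.cells["cell_id"], "value": self.spatial}
        ).to_csv(outdir / f"{prefix}_spatial.csv", index=False)
        pd.DataFrame(
            {"year": self.study_years, "value": self.temporal}
        ).to_csv(outdir / f"{prefix}_temporal.csv", index=False)
        long = pd.DataFrame(
            self.residual, columns=self.study_years
        ).assign(cell_id=self.cells["cell_id"].to_numpy()).melt(
            id_vars="cell_id", var_name="year", value_name="value"
        )
        long.to_csv(outdir / f"{prefix}_residual.csv", index=False)
        header = {
            "variable": self.variable,
            "global_mean": self.global_mean,
            "season_window": self.season_window,
            "centering_years": list(self.centering_years),
            "study_years": [int(self.study_years[0]), int(self.study_years[-1])],
            "lag": self.lag,
        }
        (outdir / f"{prefix}_decomposition.json").write_text(
            json.dumps(header, indent=2)
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def seasonal_aggregate(
    daily: pd.DataFrame,
    window: str = "may-jul",
    variable: str = "temperature",
    centering_years: tuple[int, int] | None = None,
) -> ClimateCube:
    """Aggregate per-cell daily series to one breeding-season value per year.

    ``daily`` needs columns ``cell_id, x, y, date, value`` (``date`` parseable
    by pandas).  Temperature aggregates by the seasonal mean, precipitation by
    the seasonal sum.  Every cell must cover the full window in every year it
    reports; incomplete coverage raises listing the offending cell-years.
    """
    if window not in SEASON_WINDOWS:
        raise DecompositionError(f"unknown season window {window!r}")
    m0, m1 = SEASON_WINDOWS[window]
    df = daily.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df[(df["date"].dt.month >= m0) & (df["date"].dt.month <= m1)]
    df["year"] = df["date"].dt.year

    # expected number of days in the window per year (handles leap years)
    def _ndays(year: int) -> int:
        start = pd.Timestamp(year=year, month=m0, day=1)
        end = pd.Timestamp(year=year, month=m1 + 1, day=1) if m1 < 12 else pd.Timestamp(
            year=year + 1, month=1, day=1
        )
        return int((end - start).days)

    counts = df.groupby(["cell_id", "year"])["value"].count()
    expected = counts.index.get_level_values("year").map(_ndays)
    bad = counts[counts.to_numpy() < expected.to_numpy()]
    if len(bad):
        missing = ", ".join(f"{c}@{y}" for c, y in bad.index[:20])
        raise DecompositionError(f"incomplete season coverage for: {missing}")

    stat = "mean" if variable == "temperature" else "sum"
    agg = df.groupby(["cell_id", "year"])["value"].agg(stat).reset_index()
    agg = agg.merge(df[["cell_id", "x", "y"]].drop_duplicates(), on="cell_id")
    years = np.sort(agg["year"].unique())
    if centering_years is None:
        centering_years = (int(years[0]), int(years[-1]))
    return ClimateCube.from_frame(
        agg, variable=variable, centering_years=centering_years,
        season_window=window,
    )


def decompose(
    cube: ClimateCube, study_years: tuple[int, int] | None = None
) -> DecomposedClimate:
    """Split a cube into global mean + spatial + temporal + residual parts.

    Centering (global mean and per-cell long-term means) uses the cube's
    ``centering_years``; the temporal and residual components are exposed for
    ``study_years`` only.  Missing values inside the centering window are a
    hard error — the additive identities assume a complete grid.
    """
    if study_years is None:
        study_years = cube.centering_years
    s0, s1 = int(study_years[0]), int(study_years[1])
    c0, c1 = cube.centering_years
    if s0 < c0 or s1 > c1:
        raise DecompositionError(
            f"study years {s0}-{s1} outside centering years {c0}-{c1}"
        )
    cmask = (cube.years >= c0) & (cube.years <= c1)
    cvals = cube.values[:, cmask]
    if not np.all(np.isfinite(cvals)):
        raise DecompositionError("missing values inside the centering window")

    global_mean = float(np.mean(cvals))
    centered = cvals - global_mean
    spatial = centered.mean(axis=1)          # per-cell long-term anomaly
    temporal_all = centered.mean(axis=0)     # per-year shared anomaly

    cyears = cube.years[cmask]
    smask = (cyears >= s0) & (cyears <= s1)
    study = cyears[smask]
    temporal = temporal_all[smask]
    residual = centered[:, smask] - spatial[:, None] - temporal[None, :]

    return DecomposedClimate(
        variable=cube.variable,
        global_mean=global_mean,
        spatial=spatial,
        temporal=temporal,
        residual=residual,
        cells=cube.cells.reset_index(drop=True),
        study_years=study,
        season_window=cube.season_window,
        centering_years=cube.centering_years,
    )


def reconstruct(d: DecomposedClimate) -> np.ndarray:
    """Raw cell x study-year values implied by the components (round trip)."""
    return (
        d.global_mean
        + d.spatial[:, None]
        + d.temporal[None, :]
        + d.residual
    )


def lag_covariates(d: DecomposedClimate, lag: int = 1) -> DecomposedClimate:
    """View of ``d`` where year *t* reads the anomalies of year ``t - lag``.

    The spatial component is time-invariant and unchanged.  Study years whose
    lagged source year is unavailable are dropped and recorded in
    ``dropped_years``.
    """
    if lag < 0:
        raise DecompositionError("lag must be >= 0")
    if lag == 0:
        return d
    have = set(int(y) for y in d.study_years)
    keep = np.array([int(y) - lag in have for y in d.study_years])
    dropped = tuple(int(y) for y in d.study_years[~keep])
    src = d.year_pos(d.study_years[keep] - lag)
    return replace(
        d,
        temporal=d.temporal[src],
        residual=d.residual[:, src],
        study_years=d.study_years[keep],
        lag=d.lag + lag,
        dropped_years=d.dropped_years + dropped,
    )
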