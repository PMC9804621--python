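"""Isolating and comparing the effect of each climate component.

For a fitted model, each climate component's effect is visualised by a 10x10
temperature x precipitation prediction grid: the target component is swept
over 10 evenly spaced values between its observed minimum and maximum while
the other components are held at zero (spatial sweep) or at the routes'
observed values (temporal/residual sweeps); all other covariates sit at
typical values, random effects are excluded, and predictions are summed over
routes.  Spearman rank correlations between grids quantify whether two
components drive abundance in the same direction; species are classified by
the spatial-vs-temporal correlation along the temperature gradient
(|r_s| > 0.5).  Model adequacy is checked by within-sample Pearson
correlations per country, leave-one-year-out cross-validation, and Moran's I
on residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import DesignMatrices, CLIMATE_INTERACTIONS
from .decomposition import DecomposedClimate
from .abundance import FittedModel, ModelSpec, fit, predict_mean

__all__ = [
    "EffectGrid",
    "CorrelationSummary",
    "ResponseClass",
    "PerformanceReport",
    "build_component_grid",
    "spearman",
    "correlate_components",
    "classify_species",
    "performance_pearson",
    "subset_design",
    "loyo_cv",
    "morans_i",
]

COMPONENTS = ("spatial", "temporal", "residual")
PAIRS = (("spatial", "temporal"), ("spatial", "residual"), ("temporal", "residual"))
GRADIENTS = ("joint", "temperature", "precipitation")


class AssessmentError(ValueError):
    pass


@dataclass
class EffectGrid:
    """Summed predicted abundance over routes for one climate component."""

    component: str
    temp_levels: np.ndarray          # raw component units (deg C)
    prec_levels: np.ndarray          # raw component units (mm)
    abundance: np.ndarray            # (n_levels, n_levels), [temp, prec]
    retained_temp: bool = True
    retained_prec: bool = True

    @property
    def retained(self) -> bool:
        return self.retained_temp or self.retained_prec

    def profile(self, gradient: str) -> np.ndarray:
        """Single-variable profile with the other variable fixed.

        The non-varied variable is fixed at the grid level nearest zero for
        anomaly components and nearest the mean level for the spatial
        component (its levels are centred anomalies too, but need not span 0).
        """
        if gradient == "joint":
            return self.abundance.ravel()
        if gradient == "temperature":
            other = self.prec_levels
            target = 0.0 if self.component != "spatial" else float(other.mean())
            j = int(np.argmin(np.abs(other - target)))
            return self.abundance[:, j]
        if gradient == "precipitation":
            other = self.temp_levels
            target = 0.0 if self.component != "spatial" else float(other.mean())
            i = int(np.argmin(np.abs(other - target)))
            return self.abundance[i, :]
        raise AssessmentError(f"unknown gradient {gradient!r}")

    def to_frame(self) -> pd.DataFrame:
        t, p = np.meshgrid(self.temp_levels, self.prec_levels, indexing="ij")
        return pd.DataFrame({
            "component": self.component,
            "temperature": t.ravel(),
            "precipitation": p.ravel(),
            "abundance": self.abundance.ravel(),
        })


def _typical_row(design: DesignMatrices, fitted: FittedModel) -> dict[str, float]:
    """Typical values on the standardized scale: median for continuous
    columns, reference (0) for the protocol dummies, intercept 1."""
    row = {}
    for col in design.X.columns:
        if col == "intercept":
            row[col] = 1.0
        elif col in ("survey_point", "unit_individual"):
            row[col] = 0.0
        else:
            row[col] = float(design.X[col].median())
    return row


def _component_cols(component: str) -> tuple[str, str, str]:
    return (
        f"{component}_temp",
        f"{component}_prec",
        f"{component}_temp:{component}_prec",
    )


def build_component_grid(
    fitted: FittedModel,
    design: DesignMatrices,
    temperature: DecomposedClimate,
    precipitation: DecomposedClimate,
    component: str,
    n_levels: int = 10,
    retained: dict[str, bool] | None = None,
) -> EffectGrid:
    """10 x 10 temperature x precipitation effect grid for one component.

    Sweep ranges are the observed minima/maxima of the component over the
    study region (all cells for spatial/residual, all study years for
    temporal).  For the spatial sweep the anomaly components are set to zero;
    for the temporal/residual sweeps the spatial component keeps each route's
    observed value.  Random effects are excluded; a component entirely
    dropped from the model yields a constant grid flagged as not retained.
    """
    if component not in COMPONENTS:
        raise AssessmentError(f"unknown component {component!r}")
    if not fitted.converged:
        raise AssessmentError("refusing to build grids from a non-converged fit")

    def _range(d: DecomposedClimate) -> tuple[float, float]:
        if component == "spatial":
            v = d.spatial
        elif component == "temporal":
            v = d.temporal
        else:
            v = d.residual
        return float(np.min(v)), float(np.max(v))

    t_lo, t_hi = _range(temperature)
    p_lo, p_hi = _range(precipitation)
    temp_levels = np.linspace(t_lo, t_hi, n_levels)
    prec_levels = np.linspace(p_lo, p_hi, n_levels)

    terms = set(fitted.beta.index)
    if retained is not None:
        ret_t = bool(retained.get(f"{component}_temp", f"{component}_temp" in terms))
        ret_p = bool(retained.get(f"{component}_prec", f"{component}_prec" in terms))
    else:
        ret_t = f"{component}_temp" in terms
        ret_p = f"{component}_prec" in terms

    # one row per route, all covariates typical, factors at reference
    frame = design.frame.drop_duplicates("route_id").reset_index(drop=True)
    n_routes = len(frame)
    typical = _typical_row(design, fitted)
    base = pd.DataFrame({c: np.full(n_routes, v) for c, v in typical.items()})

    # climate columns, raw scale per sweep rule, then standardized
    raw = {c: np.zeros(n_routes) for c in (
        "spatial_temp", "spatial_prec", "temporal_temp", "temporal_prec",
        "residual_temp", "residual_prec",
    )}
    if component != "spatial":
        raw["spatial_temp"] = frame["spatial_temp"].to_numpy(dtype=float)
        raw["spatial_prec"] = frame["spatial_prec"].to_numpy(dtype=float)

    tcol, pcol, icol = _component_cols(component)
    offset = float(np.mean(design.offset))
    abundance = np.empty((n_levels, n_levels))
    for i, tv in enumerate(temp_levels):
        for j, pv in enumerate(prec_levels):
            vals = dict(raw)
            vals[tcol] = np.full(n_routes, tv)
            vals[pcol] = np.full(n_routes, pv)
            row = base.copy()
            for name, rv in vals.items():
                if name in row.columns:
                    row[name] = design.standardize_value(name, rv)
            for inter in CLIMATE_INTERACTIONS:
                a, b = inter.split(":")
                if inter in row.columns:
                    row[inter] = row[a] * row[b]
            mu = predict_mean(
                fitted, row[list(fitted.beta.index)], offset=offset,
                X_zi=row, include_random=False,
            )
            abundance[i, j] = float(mu.sum())

    return EffectGrid(
        component=component,
        temp_levels=temp_levels,
        prec_levels=prec_levels,
        abundance=abundance,
        retained_temp=ret_t,
        retained_prec=ret_p,
    )


# ---------------------------------------------------------------------------
# rank correlations and classification
# ---------------------------------------------------------------------------

def spearman(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if undefined."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise AssessmentError("need two equal-length vectors of length >= 3")
    if np.ptp(stats.rankdata(a)) == 0 or np.ptp(stats.rankdata(b)) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.spearmanr(a, b).statistic
    return float(r)


@dataclass
class CorrelationSummary:
    """r_s for the three component pairs along the three gradient sets.

    ``table`` rows: pair, gradient, r_s, status.  Status follows the
    reporting convention for dropped components: ``one-absent`` pairs get
    r_s = 0, ``both-absent`` pairs r_s = 1 (agreement that neither matters).
    """

    table: pd.DataFrame
    retained: dict = field(default_factory=dict)

    def r(self, pair: tuple[str, str], gradient: str = "joint") -> float:
        m = self.table[
            (self.table["pair"] == f"{pair[0]}-{pair[1]}")
            & (self.table["gradient"] == gradient)
        ]
        return float(m["r_s"].iloc[0])

    def status(self, pair: tuple[str, str], gradient: str = "joint") -> str:
        m = self.table[
            (self.table["pair"] == f"{pair[0]}-{pair[1]}")
            & (self.table["gradient"] == gradient)
        ]
        return str(m["status"].iloc[0])


def correlate_components(grids: dict[str, EffectGrid]) -> CorrelationSummary:
    """Spearman correlations between component effect grids.

    For each pair and each gradient set (joint 100-cell surface,
    temperature-only 10-point profile, precipitation-only profile): if one
    component has no association along that gradient the pair reports
    r_s = 0 (``one-absent``); if neither does, r_s = 1 (``both-absent``).
    """
    missing = set(COMPONENTS) - set(grids)
    if missing:
        raise AssessmentError(f"missing grids for: {sorted(missing)}")

    def _present(g: EffectGrid, gradient: str) -> bool:
        if gradient == "temperature":
            return g.retained_temp
        if gradient == "precipitation":
            return g.retained_prec
        return g.retained

    rows = []
    retained = {
        c: {"temperature": g.retained_temp, "precipitation": g.retained_prec}
        for c, g in grids.items()
    }
    for a, b in PAIRS:
        for gradient in GRADIENTS:
            pa, pb = _present(grids[a], gradient), _present(grids[b], gradient)
            if pa and pb:
                r = spearman(grids[a].profile(gradient), grids[b].profile(gradient))
                status = "both-retained" if np.isfinite(r) else "undefined"
                if not np.isfinite(r):
                    r = float("nan")
            elif pa or pb:
                r, status = 0.0, "one-absent"
            else:
                r, status = 1.0, "both-absent"
            rows.append({
                "pair": f"{a}-{b}", "gradient": gradient, "r_s": r, "status": status,
            })
    return CorrelationSummary(table=pd.DataFrame(rows), retained=retained)


@dataclass
class ResponseClass:
    """Species response label from the spatial-temporal temperature r_s."""

    label: str                       # consistent | opposite | complex_or_none |
                                     # one_absent | both_absent | indeterminate
    baseline: str                    # cold | warm
    r_spatial_temporal_temp: float

    @property
    def combined(self) -> str:
        return f"{self.label}-{self.baseline}"


def classify_species(
    summary: CorrelationSummary,
    spatial_grid: EffectGrid,
    threshold: float = 0.5,
) -> ResponseClass:
    """Label the species by the spatial-vs-temporal temperature correlation.

    ``consistent`` (r_s > 0.5): the same climate direction raises abundance
    in space and time — with a cold spatial baseline these species are
    immediately vulnerable to warming.  ``opposite`` (r_s < -0.5): initially
    resilient.  Otherwise complex/none.  The cold/warm baseline is the
    temperature half of the spatial grid's abundance maximum.
    """
    i_max, _ = np.unravel_index(
        np.argmax(spatial_grid.abundance), spatial_grid.abundance.shape
    )
    baseline = "cold" if i_max < len(spatial_grid.temp_levels) / 2 else "warm"

    status = summary.status(("spatial", "temporal"), "temperature")
    r = summary.r(("spatial", "temporal"), "temperature")
    if status == "undefined":
        label = "indeterminate"
    elif status == "one-absent":
        label = "one_absent"
    elif status == "both-absent":
        label = "both_absent"
    elif r > threshold:
        label = "consistent"
    elif r < -threshold:
        label = "opposite"
    else:
        label = "complex_or_none"
    return ResponseClass(label=label, baseline=baseline, r_spatial_temporal_temp=r)


# ---------------------------------------------------------------------------
# performance
# ---------------------------------------------------------------------------

@dataclass
class PerformanceReport:
    per_group: pd.DataFrame          # group, r, n, passed
    pooled_r: float
    country_threshold: float = 0.4
    pooled_threshold: float = 0.5

    @property
    def passed(self) -> bool:
        country_ok = bool(self.per_group["passed"].all())
        return country_ok and self.pooled_r >= self.pooled_threshold


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def performance_pearson(
    fitted: FittedModel,
    design: DesignMatrices,
    country_threshold: float = 0.4,
    pooled_threshold: float = 0.5,
) -> PerformanceReport:
    """Pearson r between fitted local abundances and observed counts,
    per country and pooled (random effects at their conditional modes)."""
    if design.y is None:
        raise AssessmentError("design has no observed counts")
    pred = predict_mean(
        fitted, design.X, offset=design.offset, X_zi=design.X_zi,
        route=design.route, include_random=True,
    )
    obs = design.y
    rows = []
    groups = (
        design.frame["country"] if "country" in design.frame.columns
        else pd.Series(["all"] * len(obs))
    )
    for g, idx in pd.Series(np.arange(len(obs))).groupby(groups.to_numpy()):
        r = _pearson(obs[idx.to_numpy()], pred[idx.to_numpy()])
        rows.append({
            "group": g, "r": r, "n": len(idx),
            "passed": bool(np.isfinite(r) and r >= country_threshold),
        })
    pooled = _pearson(obs, pred)
    return PerformanceReport(
        per_group=pd.DataFrame(rows), pooled_r=pooled,
        country_threshold=country_threshold, pooled_threshold=pooled_threshold,
    )


def subset_design(design: DesignMatrices, mask: np.ndarray) -> DesignMatrices:
    """Row-subset of a design with routes re-coded (scalers kept as fitted)."""
    mask = np.asarray(mask, dtype=bool)
    old_routes = design.route[mask]
    kept_ids, new_codes = np.unique(old_routes, return_inverse=True)
    return DesignMatrices(
        X=design.X.loc[mask].reset_index(drop=True),
        X_zi=design.X_zi.loc[mask].reset_index(drop=True),
        offset=design.offset[mask],
        route=new_codes,
        route_ids=design.route_ids[kept_ids],
        frame=design.frame.loc[mask].reset_index(drop=True),
        scalers=dict(design.scalers),
        y=None if design.y is None else design.y[mask],
    )


def loyo_cv(
    design: DesignMatrices,
    spec: ModelSpec | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Leave-one-year-out cross-validation.

    For every survey year the model is refitted without it and the held-out
    counts are predicted (random effects at the training conditional modes
    for known routes, 0 for routes unseen in training).  Returns one row per
    year with the held-out Pearson r.
    """
    spec = spec or ModelSpec()
    years = np.sort(design.frame["year"].unique())
    if len(years) < 3:
        raise AssessmentError("need at least 3 years for leave-one-year-out CV")
    rows = []
    for year in years:
        test = (design.frame["year"] == year).to_numpy()
        train_design = subset_design(design, ~test)
        try:
            fm = fit(train_design, spec, compute_cov=False, **fit_kw)
        except Exception as err:  # noqa: BLE001 - any failed refit skips the year
            warnings.warn(f"refit without {year} failed: {err}", stacklevel=2)
            continue
        if not fm.converged:
            warnings.warn(f"refit without {year} did not converge", stacklevel=2)
            continue
        test_design = subset_design(design, test)
        # map held-out routes onto training random-effect modes (0 if unseen)
        train_pos = {rid: i for i, rid in enumerate(train_design.route_ids)}
        u = np.array([
            fm.u_modes[train_pos[rid]] if rid in train_pos else 0.0
            for rid in test_design.route_ids
        ])
        pred = predict_mean(
            fm, test_design.X, offset=test_design.offset + u[test_design.route],
            X_zi=test_design.X_zi, include_random=False,
        )
        rows.append({"year": int(year), "r": _pearson(test_design.y, pred)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# spatial autocorrelation
# ---------------------------------------------------------------------------

def morans_i(
    values: np.ndarray,
    coords: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    method: str = "inverse_distance",
    k: int = 5,
    cutoff: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Moran's I with a permutation p-value (two-sided around E[I] = -1/(n-1)).

    Weights come from an explicit matrix, inverse distance (optionally
    truncated at ``cutoff``), or k-nearest neighbours.  Constant values are
    undefined and flagged rather than raised.
    """
    z = np.asarray(values, dtype=float)
    n = len(z)
    if n < 2:
        raise AssessmentError("need at least 2 locations")
    if np.ptp(z) == 0:
        return {"I": float("nan"), "p": float("nan"), "defined": False}
    if weights is None:
        if coords is None:
            raise AssessmentError("need coords or an explicit weight matrix")
        coords = np.asarray(coords, dtype=float)
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        if method == "inverse_distance":
            with np.errstate(divide="ignore"):
                W = 1.0 / d
            np.fill_diagonal(W, 0.0)
            if cutoff is not None:
                W[d > cutoff] = 0.0
        elif method == "k_nearest":
            W = np.zeros((n, n))
            order = np.argsort(d, axis=1)
            for i in range(n):
                W[i, order[i, 1:k + 1]] = 1.0
        else:
            raise AssessmentError(f"unknown weight method {method!r}")
    else:
        W = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(W, 0.0)
    s0 = W.sum()
    if s0 == 0:
        raise AssessmentError("all spatial weights are zero")

    def _I(v: np.ndarray) -> float:
        zc = v - v.mean()
        return float(n / s0 * (zc @ W @ zc) / (zc @ zc))

    i_obs = _I(z)
    expect = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if abs(_I(rng.permutation(z)) - expect) >= abs(i_obs - expect) - 1e-15:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return {"I": i_obs, "p": p, "expected": expect, "defined": True}
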