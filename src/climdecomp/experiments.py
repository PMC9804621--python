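"""Reproducible simulation studies of the full method.

Each study generates data from the model class with known truth, runs the
estimation/assessment machinery, and summarises how well the truth is
recovered: coefficient bias and Wald coverage, AIC family-selection rates,
effect-grid classification recovery, and leave-one-year-out predictive skill.
Problem sizes are chosen so a study completes in minutes on one core while
keeping Monte-Carlo error well below the effect sizes of interest.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .synthetic_data import (
    SyntheticConfig,
    TrueParameters,
    generate_climate,
    generate_routes,
    simulate_counts_from_design,
)
from .decomposition import decompose
from .covariates import DesignSpec, assemble_design
from .abundance import ModelSpec, fit, select_family, select_covariates
from .assessment import (
    build_component_grid,
    classify_species,
    correlate_components,
    loyo_cv,
)

__all__ = [
    "recovery_study",
    "family_selection_study",
    "classification_study",
    "loyo_study",
]

#: the six decomposed-climate coefficients every study tracks
CLIMATE_COEFS = (
    "spatial_temp", "spatial_prec",
    "temporal_temp", "temporal_prec",
    "residual_temp", "residual_prec",
)


def _study_design(config: SyntheticConfig, spec: DesignSpec):
    """Climate cubes -> decomposition -> route panel -> empty design."""
    dec_t = decompose(generate_climate(config, "temperature"), config.study_years)
    dec_p = decompose(generate_climate(config, "precipitation"), config.study_years)
    routes = generate_routes(config)
    design = assemble_design(routes, None, dec_t, dec_p, spec=spec)
    return design, dec_t, dec_p


def recovery_study(
    n_replicates: int = 20,
    n_routes: int = 300,
    n_years: int = 15,
    theta: float = 1.5,
    sigma_u: float = 0.5,
    seed: int = 0,
) -> dict:
    """Parameter recovery for NB mixed fits at the reference study size.

    One route panel (n_routes x n_years, all schemes aligned) is reused;
    each replicate redraws counts under known coefficients, refits, and
    records the error and 95% Wald interval of each climate coefficient.
    """
    y1 = 2015 - n_years + 1
    config = SyntheticConfig(
        centering_years=(y1 - 15, 2015), study_years=(y1, 2015),
        scheme_start_year={"NO": y1, "SE": y1, "FI": y1},
        n_routes=n_routes, seed=int(seed),
    )
    beta = {
        "intercept": 0.4,
        "spatial_temp": -0.45, "spatial_prec": 0.2,
        "temporal_temp": -0.3, "temporal_prec": 0.15,
        "residual_temp": -0.2, "residual_prec": 0.1,
        "spatial_temp:spatial_prec": 0.05,
        "temporal_temp:temporal_prec": -0.05,
        "residual_temp:residual_prec": 0.05,
        "survey_point": 0.25, "unit_individual": 0.3,
    }
    params = TrueParameters(
        beta_count=beta, theta=theta, sigma_u=sigma_u, family="nb",
    )
    design, _, _ = _study_design(
        config, DesignSpec(habitat=(), year_poly=False),
    )
    truth = np.array([beta[c] for c in CLIMATE_COEFS])
    errors, covered = [], []
    n_converged = 0
    for rep in range(n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(10, rep))
        )
        design.y = simulate_counts_from_design(design, params, rng)
        fm = fit(design, ModelSpec(family="nb"), compute_cov=True)
        if not (fm.converged and fm.cov is not None):
            continue
        n_converged += 1
        est = fm.beta[list(CLIMATE_COEFS)].to_numpy()
        se = fm.se()[list(CLIMATE_COEFS)].to_numpy()
        errors.append(est - truth)
        covered.append(np.abs(est - truth) <= 1.96 * se)
    errors = np.array(errors)
    covered = np.array(covered)
    bias = errors.mean(axis=0)
    return {
        "n_replicates": n_converged,
        "bias": dict(zip(CLIMATE_COEFS, bias)),
        "max_abs_bias": float(np.abs(bias).max()),
        "coverage": float(covered.mean()),
        "rmse": float(np.sqrt((errors**2).mean())),
    }


def family_selection_study(
    n_replicates: int = 50,
    n_routes: int = 40,
    n_years: int = 6,
    seed: int = 0,
) -> dict:
    """How often AIC picks the generating family (Poisson vs NB theta=1).

    Small panels and a minimal design (intercept + the two spatial climate
    mains) keep 4 x n_replicates x 2 mixed fits cheap; the NB outcome counts
    nb or zinb as correct, mirroring how overdispersion is confounded with
    zero inflation at moderate sample size.
    """
    y1 = 2015 - n_years + 1
    config = SyntheticConfig(
        n_cells_x=8, n_cells_y=8,
        centering_years=(y1 - 6, 2015), study_years=(y1, 2015),
        scheme_start_year={"NO": y1, "SE": y1, "FI": y1},
        n_routes=n_routes, seed=int(seed),
    )
    design, _, _ = _study_design(config, DesignSpec(
        habitat=(), year_poly=False, protocol_factors=False,
        interactions=False, climate_blocks=("spatial_temp", "spatial_prec"),
    ))
    beta = {"intercept": 0.8, "spatial_temp": -0.4, "spatial_prec": 0.2}
    gens = {
        "poisson": TrueParameters(beta_count=beta, sigma_u=0.4, family="poisson"),
        "nb": TrueParameters(beta_count=beta, theta=1.0, sigma_u=0.4, family="nb"),
    }
    picks = {g: [] for g in gens}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            for gen, params in gens.items():
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=int(seed), spawn_key=(20, rep))
                )
                design.y = simulate_counts_from_design(design, params, rng)
                sel = select_family(design)
                picks[gen].append(sel.best.spec.family)
    po = np.mean([p == "poisson" for p in picks["poisson"]])
    nb = np.mean([p in ("nb", "zinb") for p in picks["nb"]])
    return {
        "poisson_rate": float(po),
        "nb_rate": float(nb),
        "picks": {g: pd.Series(v).value_counts().to_dict() for g, v in picks.items()},
    }


ARCHETYPES = {
    "consistent": {"temporal_temp": -0.5, "temporal_prec": 0.3},
    "opposite": {"temporal_temp": 0.5, "temporal_prec": -0.3},
    "temporal_null": {},
}
EXPECTED_CLASS = {
    "consistent": ("consistent",),
    "opposite": ("opposite",),
    "temporal_null": ("one_absent", "complex_or_none", "both_absent"),
}


def classification_study(
    n_replicates: int = 20,
    n_routes: int = 70,
    n_years: int = 8,
    seed: int = 0,
) -> dict:
    """End-to-end recovery of the species response classes.

    Species are constructed with equal, negated, or zero temporal
    coefficients relative to the spatial ones; each replicate refits,
    selects climate blocks for the null archetype (the other two keep the
    full model — with strong effects nothing drops), builds the effect
    grids and applies the |r_s| > 0.5 rule along the temperature gradient.
    """
    y1 = 2013 - n_years + 1
    config = SyntheticConfig(
        centering_years=(y1 - 8, 2013), study_years=(y1, 2013),
        scheme_start_year={"NO": y1, "SE": y1, "FI": y1},
        n_routes=n_routes, seed=int(seed),
    )
    design, dec_t, dec_p = _study_design(config, DesignSpec(
        habitat=(), year_poly=False, interactions=False,
    ))
    results = {name: [] for name in ARCHETYPES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rep in range(n_replicates):
            for name, tcoef in ARCHETYPES.items():
                beta = {
                    "intercept": 0.6,
                    "spatial_temp": -0.5, "spatial_prec": 0.3,
                    "residual_temp": -0.3, "residual_prec": 0.2,
                    "survey_point": 0.2, "unit_individual": 0.2,
                    **tcoef,
                }
                params = TrueParameters(
                    beta_count=beta, sigma_u=0.3, family="poisson",
                )
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=int(seed), spawn_key=(30, rep, hash(name) % 2**16)
                ))
                design.y = simulate_counts_from_design(design, params, rng)
                if name == "temporal_null":
                    sel = select_covariates(design, family="poisson")
                    fm, retained = sel.best, sel.retained
                else:
                    fm = fit(design, ModelSpec(family="poisson"),
                             compute_cov=False)
                    retained = None
                grids = {
                    c: build_component_grid(
                        fm, design, dec_t, dec_p, c, retained=retained,
                    )
                    for c in ("spatial", "temporal", "residual")
                }
                cls = classify_species(
                    correlate_components(grids), grids["spatial"],
                )
                results[name].append(cls.label)
    rates = {
        name: float(np.mean([lab in EXPECTED_CLASS[name] for lab in labs]))
        for name, labs in results.items()
    }
    n_total = sum(len(v) for v in results.values())
    n_ok = sum(
        lab in EXPECTED_CLASS[name]
        for name, labs in results.items() for lab in labs
    )
    return {
        "rates": rates,
        "overall_rate": float(n_ok / n_total),
        "labels": results,
    }


def loyo_study(
    n_routes: int = 60,
    n_years: int = 8,
    seed: int = 0,
) -> dict:
    """Leave-one-year-out predictive skill for a strong-signal and a null
    species.

    The strong species has deterministic counts (rounded means, no noise);
    the null species is pure overdispersed noise (all slopes zero, NB
    theta = 1).
    """
    y1 = 2013 - n_years + 1
    config = SyntheticConfig(
        centering_years=(y1 - 8, 2013), study_years=(y1, 2013),
        scheme_start_year={"NO": y1, "SE": y1, "FI": y1},
        n_routes=n_routes, seed=int(seed),
        effort_range=(8, 8),   # constant effort so the null species is
                               # genuinely unpredictable, not effort-driven
    )
    design, _, _ = _study_design(config, DesignSpec(
        habitat=(), year_poly=False, interactions=False,
    ))
    beta = pd.Series({
        "intercept": 0.6,
        "spatial_temp": -0.6, "spatial_prec": 0.4,
        "temporal_temp": -0.5, "temporal_prec": 0.3,
        "residual_temp": -0.4, "residual_prec": 0.25,
        "survey_point": 0.2, "unit_individual": 0.2,
    })
    eta = design.X[beta.index].to_numpy() @ beta.to_numpy() + design.offset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design.y = np.round(np.exp(eta))          # noiseless strong signal
        strong = loyo_cv(design, ModelSpec(family="poisson"))
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(40,))
        )
        null_params = TrueParameters(
            beta_count={"intercept": 1.0}, theta=1.0, sigma_u=0.0, family="nb",
        )
        design.y = simulate_counts_from_design(design, null_params, rng)
        null = loyo_cv(design, ModelSpec(family="nb"))
    return {
        "strong_min_r": float(strong["r"].min()),
        "strong_median_r": float(strong["r"].median()),
        "null_median_r": float(null["r"].median()),
        "n_years": int(len(strong)),
    }
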