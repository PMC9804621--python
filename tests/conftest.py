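import numpy as np
import pandas as pd
import pytest

import climdecomp as cd


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete synthetic study region."""
    return cd.SyntheticConfig(
        n_cells_x=10, n_cells_y=10,
        centering_years=(1996, 2015), study_years=(2004, 2015),
        scheme_start_year={"NO": 2008, "SE": 2004, "FI": 2008},
        n_routes=50, seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Cubes, decomposition, routes, habitat, NB counts and design."""
    cfg = small_config
    cube_t = cd.generate_climate(cfg, "temperature")
    cube_p = cd.generate_climate(cfg, "precipitation")
    dec_t = cd.decompose(cube_t, cfg.study_years)
    dec_p = cd.decompose(cube_p, cfg.study_years)
    routes = cd.generate_routes(cfg)
    habitat = cd.generate_habitat_covariates(cfg, routes)
    params = cd.TrueParameters.default("nb")
    counts, design = cd.generate_counts(
        routes, dec_t, dec_p, params, covariates=habitat, seed=cfg.seed,
    )
    return {
        "config": cfg, "cube_t": cube_t, "cube_p": cube_p,
        "dec_t": dec_t, "dec_p": dec_p, "routes": routes,
        "habitat": habitat, "params": params, "counts": counts,
        "design": design,
    }


@pytest.fixture(scope="session")
def nb_fit(small_dataset):
    """One converged NB mixed fit on the small dataset, reused across tests."""
    fm = cd.fit(small_dataset["design"], cd.ModelSpec(family="nb"),
                compute_cov=False)
    assert fm.converged
    return fm


def random_cube(rng, n_cells=6, n_years=8, year0=2000):
    """Helper: a random complete ClimateCube."""
    cells = pd.DataFrame({
        "cell_id": np.arange(n_cells),
        "x": rng.uniform(0, 10, n_cells),
        "y": rng.uniform(0, 10, n_cells),
    })
    years = np.arange(year0, year0 + n_years)
    values = rng.normal(10, 3, size=(n_cells, n_years))
    return cd.ClimateCube(
        "temperature", values, cells, years, (year0, year0 + n_years - 1)
    )
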