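"""Count mixed models for route-level abundance.

Four candidate error structures share one linear predictor: Poisson, NB2
(Var = mu + mu^2/theta), and their zero-inflated mixtures (ZIP, ZINB) with a
logit-linear structural-zero probability.  All use a log link, a log-effort
offset, and a Gaussian random intercept per survey route.  The marginal
likelihood integrates the route intercept out numerically with adaptive
Gauss-Hermite quadrature centered at each route's conditional mode (order 1
is the Laplace approximation); parameters are maximized by quasi-Newton on
unconstrained transforms (log theta, log sigma_u).  Families and climate
covariate blocks are compared by AIC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, log_expit, logsumexp
from numpy.polynomial.hermite import hermgauss

from .covariates import DesignMatrices, CLIMATE_MAINS, CLIMATE_INTERACTIONS

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "FittedModel",
    "SelectionResult",
    "conditional_loglik",
    "marginal_loglik",
    "fit",
    "select_family",
    "select_covariates",
    "predict_mean",
]

FAMILIES = ("poisson", "nb", "zip", "zinb")

_LOG_THETA_BOUNDS = (-8.0, 15.0)
_LOG_SIGMA_BOUNDS = (-8.0, 3.0)


class ModelError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class ModelSpec:
    """Which family and which design columns enter the two model parts.

    ``count_terms`` / ``zi_terms`` name columns of the assembled design
    (``None`` means every available column).  The zero-inflation part exists
    only for zip/zinb.
    """

    family: str = "nb"
    count_terms: tuple[str, ...] | None = None
    zi_terms: tuple[str, ...] | None = None
    quad_order: int = 7
    estimate_random: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")

    @property
    def has_theta(self) -> bool:
        return self.family in ("nb", "zinb")

    @property
    def has_zi(self) -> bool:
        return self.family in ("zip", "zinb")


@dataclass
class FittedModel:
    spec: ModelSpec
    beta: pd.Series
    gamma: pd.Series
    theta: float | None
    sigma_u: float
    u_modes: np.ndarray
    route_ids: np.ndarray
    loglik: float
    k: int
    n_obs: int
    converged: bool
    scalers: dict = field(default_factory=dict)
    cov: pd.DataFrame | None = None
    n_restarts: int = 0
    message: str = ""

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def se(self) -> pd.Series | None:
        if self.cov is None:
            return None
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.cov.index)

    def to_dict(self) -> dict:
        se = self.se()
        return {
            "family": self.spec.family,
            "count_terms": list(self.beta.index),
            "zi_terms": list(self.gamma.index),
            "quad_order": self.spec.quad_order,
            "beta": self.beta.to_dict(),
            "gamma": self.gamma.to_dict(),
            "se": None if se is None else se.to_dict(),
            "theta": self.theta,
            "sigma_u": self.sigma_u,
            "u_modes": self.u_modes.tolist(),
            "route_ids": [str(r) for r in self.route_ids],
            "loglik": self.loglik,
            "aic": self.aic,
            "k": self.k,
            "n_obs": self.n_obs,
            "converged": bool(self.converged),
            "scalers": {k: list(v) for k, v in self.scalers.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        spec = ModelSpec(
            family=d["family"],
            count_terms=tuple(d["count_terms"]),
            zi_terms=tuple(d["zi_terms"]) or None,
            quad_order=d.get("quad_order", 7),
        )
        return cls(
            spec=spec,
            beta=pd.Series(d["beta"]).reindex(d["count_terms"]),
            gamma=pd.Series(d["gamma"]).reindex(d["zi_terms"]).astype(float),
            theta=d["theta"],
            sigma_u=d["sigma_u"],
            u_modes=np.asarray(d["u_modes"], dtype=float),
            route_ids=np.asarray(d["route_ids"]),
            loglik=d["loglik"],
            k=d["k"],
            n_obs=d["n_obs"],
            converged=d["converged"],
            scalers={k: tuple(v) for k, v in d.get("scalers", {}).items()},
        )


# ---------------------------------------------------------------------------
# conditional (given u) log-likelihood and its eta-derivatives
# ---------------------------------------------------------------------------

def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ModelError("counts must be non-negative integers")
    return y


def conditional_loglik(
    y: np.ndarray,
    eta: np.ndarray,
    family: str = "poisson",
    theta: float | None = None,
    zi_eta: np.ndarray | None = None,
) -> np.ndarray:
    """Per-observation log density given the linear predictor.

    ``eta`` already includes offset and any random-intercept value.  For
    zip/zinb the mixture is ``pi * 1{y=0} + (1 - pi) * f(y)`` with
    ``pi = logistic(zi_eta)``.
    """
    y = _check_counts(y)
    eta = np.asarray(eta, dtype=float)
    if family in ("nb", "zinb") and not (theta is not None and theta > 0):
        raise ModelError("theta must be > 0 for nb/zinb")

    base = "poisson" if family in ("poisson", "zip") else "nb"
    if base == "poisson":
        ll = y * eta - np.exp(eta) - gammaln(y + 1.0)
    else:
        mu = np.exp(eta)
        ll = (
            gammaln(y + theta) - gammaln(theta) - gammaln(y + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + y * (eta - np.log(theta + mu))
        )
    if family in ("poisson", "nb"):
        return ll
    if zi_eta is None:
        raise ModelError("zi_eta required for zip/zinb")
    zi_eta = np.broadcast_to(np.asarray(zi_eta, dtype=float), ll.shape)
    log_pi = log_expit(zi_eta)
    log_1mpi = log_expit(-zi_eta)
    out = log_1mpi + ll
    zero = y == 0
    out = np.where(zero, np.logaddexp(log_pi, log_1mpi + ll), out)
    return out


def _eta_derivs(
    y: np.ndarray,
    eta: np.ndarray,
    family: str,
    theta: float | None,
    zi_eta: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivative of the per-obs log density w.r.t. eta."""
    mu = np.exp(eta)
    base = "poisson" if family in ("poisson", "zip") else "nb"
    if base == "poisson":
        g0 = -mu                     # dlogf(0)/deta
        h0 = -mu
        g = y - mu
        h = -mu
    else:
        g0 = -theta * mu / (theta + mu)
        h0 = -(theta**2) * mu / (theta + mu) ** 2
        g = y - (y + theta) * mu / (theta + mu)
        h = -(y + theta) * theta * mu / (theta + mu) ** 2
    if family in ("poisson", "nb"):
        return g, h
    zi_eta = np.broadcast_to(np.asarray(zi_eta, dtype=float), eta.shape)
    log_pi = log_expit(zi_eta)
    log_1mpi = log_expit(-zi_eta)
    if base == "poisson":
        logf0 = -mu
    else:
        logf0 = theta * (np.log(theta) - np.log(theta + mu))
    denom = np.logaddexp(log_pi, log_1mpi + logf0)
    w = np.exp(log_1mpi + logf0 - denom)     # weight of the count branch
    zero = y == 0
    g = np.where(zero, w * g0, g)
    h = np.where(zero, w * h0 + w * (1.0 - w) * g0**2, h)
    return g, h


# ---------------------------------------------------------------------------
# marginal likelihood (adaptive Gauss-Hermite over the route intercept)
# ---------------------------------------------------------------------------

def _route_obj(
    u: np.ndarray,
    y: np.ndarray,
    eta0: np.ndarray,
    route: np.ndarray,
    n_routes: int,
    sigma: float,
    family: str,
    theta: float | None,
    zi_eta: np.ndarray | None,
) -> np.ndarray:
    """Per-route joint log density f_r(u_r) + log phi(u_r; 0, sigma^2)."""
    ll = conditional_loglik(y, eta0 + u[route], family, theta, zi_eta)
    f = np.bincount(route, weights=ll, minlength=n_routes)
    return f - 0.5 * np.log(2 * np.pi * sigma**2) - u**2 / (2 * sigma**2)


def _find_modes(
    y: np.ndarray,
    eta0: np.ndarray,
    route: np.ndarray,
    n_routes: int,
    sigma: float,
    family: str,
    theta: float | None,
    zi_eta: np.ndarray | None,
    u0: np.ndarray | None = None,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized damped Newton for all route conditional modes at once.

    Returns the modes and the (negative) curvature H_r of the joint log
    density at the mode.
    """
    u = np.zeros(n_routes) if u0 is None else u0.copy()
    obj = _route_obj(u, y, eta0, route, n_routes, sigma, family, theta, zi_eta)
    H = np.full(n_routes, -1.0 / sigma**2)
    for _ in range(max_iter):
        g, h = _eta_derivs(y, eta0 + u[route], family, theta, zi_eta)
        G = np.bincount(route, weights=g, minlength=n_routes) - u / sigma**2
        H = np.bincount(route, weights=h, minlength=n_routes) - 1.0 / sigma**2
        H = np.minimum(H, -1e-10)
        step = -G / H
        # backtracking: halve steps on routes whose objective worsened
        for _ in range(8):
            new = _route_obj(
                u + step, y, eta0, route, n_routes, sigma, family, theta, zi_eta
            )
            bad = new < obj - 1e-12
            if not bad.any():
                break
            step = np.where(bad, step * 0.5, step)
        u = u + step
        obj = np.maximum(new, obj)
        if np.max(np.abs(G * step)) < tol:
            break
    g, h = _eta_derivs(y, eta0 + u[route], family, theta, zi_eta)
    H = np.bincount(route, weights=h, minlength=n_routes) - 1.0 / sigma**2
    H = np.minimum(H, -1e-10)
    return u, H


def marginal_loglik(
    y: np.ndarray,
    eta_fixed: np.ndarray,
    route: np.ndarray,
    sigma_u: float,
    family: str = "poisson",
    theta: float | None = None,
    zi_eta: np.ndarray | None = None,
    order: int = 7,
    u0: np.ndarray | None = None,
    return_modes: bool = False,
):
    """Log marginal likelihood, integrating each route's intercept.

    ``eta_fixed`` is the fixed-effect linear predictor including the offset.
    ``sigma_u = 0`` degenerates to the conditional log-likelihood at u = 0.
    Order 1 equals the Laplace approximation.
    """
    y = _check_counts(y)
    route = np.asarray(route)
    n_routes = int(route.max()) + 1 if len(route) else 0
    if order < 1:
        raise ModelError("quadrature order must be >= 1")
    if sigma_u == 0.0:
        total = float(np.sum(conditional_loglik(y, eta_fixed, family, theta, zi_eta)))
        if return_modes:
            return total, np.zeros(n_routes)
        return total

    u_hat, H = _find_modes(
        y, eta_fixed, route, n_routes, sigma_u, family, theta, zi_eta, u0=u0
    )
    s = 1.0 / np.sqrt(-H)
    z, w = hermgauss(order)
    logw = np.log(w)
    # joint log density evaluated at the shifted/scaled nodes, (R, K)
    vals = np.empty((n_routes, order))
    for k in range(order):
        uk = u_hat + np.sqrt(2.0) * s * z[k]
        vals[:, k] = (
            _route_obj(uk, y, eta_fixed, route, n_routes, sigma_u, family, theta, zi_eta)
            + z[k] ** 2
            + logw[k]
        )
    per_route = np.log(np.sqrt(2.0) * s) + logsumexp(vals, axis=1)
    total = float(per_route.sum())
    if return_modes:
        return total, u_hat
    return total


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _poisson_irls_start(
    X: np.ndarray, y: np.ndarray, offset: np.ndarray, n_iter: int = 25
) -> np.ndarray:
    """Plain fixed-effect Poisson IRLS for starting values (ridge-damped)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 0.05)) - offset.mean()
    for _ in range(n_iter):
        eta = np.clip(X @ beta + offset, -30, 30)
        mu = np.exp(eta)
        z = eta - offset + (y - mu) / np.maximum(mu, 1e-8)
        W = mu
        XtW = X.T * W
        A = XtW @ X + 1e-8 * np.eye(p)
        b = XtW @ z
        new = np.linalg.solve(A, b)
        if not np.all(np.isfinite(new)):
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new
    return beta


def _resolve_terms(design: DesignMatrices, spec: ModelSpec) -> tuple[list, list]:
    count_terms = list(spec.count_terms or design.X.columns)
    missing = set(count_terms) - set(design.X.columns)
    if missing:
        raise ModelError(f"count terms not in design: {sorted(missing)}")
    if spec.has_zi:
        if spec.zi_terms is None:
            zi_terms = [t for t in count_terms if t in design.X_zi.columns]
        else:
            zi_terms = list(spec.zi_terms)
            missing = set(zi_terms) - set(design.X_zi.columns)
            if missing:
                raise ModelError(f"zi terms not in design: {sorted(missing)}")
    else:
        if spec.zi_terms:
            raise ModelError("zi terms given for a family without zero inflation")
        zi_terms = []
    return count_terms, zi_terms


def fit(
    design: DesignMatrices,
    spec: ModelSpec | None = None,
    start: dict | None = None,
    compute_cov: bool = True,
    max_restarts: int = 5,
    maxiter: int = 400,
) -> FittedModel:
    """Maximize the marginal likelihood over (beta, gamma, log theta, log sigma_u).

    Raises on a rank-deficient count design.  Non-convergence after jittered
    restarts returns a ``FittedModel`` with ``converged=False``.
    """
    spec = spec or ModelSpec()
    if design.y is None:
        raise ModelError("design has no response counts")
    y = _check_counts(design.y)
    count_terms, zi_terms = _resolve_terms(design, spec)
    X = design.X[count_terms].to_numpy(dtype=float)
    Xzi = design.X_zi[zi_terms].to_numpy(dtype=float) if zi_terms else None
    offset = design.offset
    route = design.route
    n, p = X.shape
    q = 0 if Xzi is None else Xzi.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ModelError("count design is rank deficient")
    if design.n_routes < 2 and spec.estimate_random:
        raise ModelError("need >= 2 routes to estimate the random intercept")

    has_theta = spec.has_theta
    est_sigma = spec.estimate_random
    n_par = p + q + int(has_theta) + int(est_sigma)

    def unpack(v: np.ndarray):
        beta = v[:p]
        gamma = v[p:p + q]
        i = p + q
        theta = np.exp(v[i]) if has_theta else None
        i += int(has_theta)
        sigma = np.exp(v[i]) if est_sigma else 0.0
        return beta, gamma, theta, sigma

    u_cache = {"u": None}

    def nll(v: np.ndarray) -> float:
        beta, gamma, theta, sigma = unpack(v)
        eta = X @ beta + offset
        zi_eta = Xzi @ gamma if q else None
        if np.any(eta > 40):
            return 1e10
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            try:
                ll, u = marginal_loglik(
                    y, eta, route, sigma, spec.family, theta, zi_eta,
                    order=spec.quad_order, u0=u_cache["u"], return_modes=True,
                )
            except FloatingPointError:
                return 1e10
        if not np.isfinite(ll):
            return 1e10
        u_cache["u"] = u
        return -ll

    # starting values
    v0 = np.zeros(n_par)
    v0[:p] = _poisson_irls_start(X, y, offset)
    if q:
        frac0 = max(float(np.mean(y == 0)), 0.02)
        v0[p] = np.log(frac0 / (1 - frac0)) - 1.0 if zi_terms[0] == "intercept" else 0.0
    i = p + q
    if has_theta:
        mu_hat = np.exp(np.clip(X @ v0[:p] + offset, -30, 30))
        resid_var = float(np.var(y - mu_hat))
        mu2 = float(np.mean(mu_hat**2))
        excess = max(resid_var - float(np.mean(mu_hat)), 1e-3)
        v0[i] = np.log(np.clip(mu2 / excess, 0.1, 20.0))
        i += 1
    if est_sigma:
        v0[i] = np.log(0.3)

    bounds = [(None, None)] * (p + q)
    if has_theta:
        bounds.append(_LOG_THETA_BOUNDS)
    if est_sigma:
        bounds.append(_LOG_SIGMA_BOUNDS)

    if start:
        for name, val in start.get("beta", {}).items():
            if name in count_terms:
                v0[count_terms.index(name)] = val
        for name, val in start.get("gamma", {}).items():
            if name in zi_terms:
                v0[p + zi_terms.index(name)] = val
        if has_theta and start.get("theta"):
            v0[p + q] = np.log(start["theta"])
        if est_sigma and start.get("sigma_u"):
            v0[p + q + int(has_theta)] = np.log(max(start["sigma_u"], 1e-4))

    rng = np.random.default_rng(0)
    best = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        vstart = v0 if attempt == 0 else v0 + rng.normal(0, 0.2, size=n_par)
        u_cache["u"] = None
        res = minimize(
            nll, vstart, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-6},
        )
        ok = res.success and np.isfinite(res.fun) and res.fun < 1e9
        if best is None or res.fun < best.fun:
            best = res
        if ok:
            break
        n_restarts += 1

    converged = bool(best.success and np.isfinite(best.fun) and best.fun < 1e9)
    beta_v, gamma_v, theta_v, sigma_v = unpack(best.x)
    eta = X @ beta_v + offset
    zi_eta = Xzi @ gamma_v if q else None
    ll, u_modes = marginal_loglik(
        y, eta, route, sigma_v, spec.family, theta_v, zi_eta,
        order=spec.quad_order, return_modes=True,
    )

    cov = None
    if compute_cov and converged:
        cov = _fd_covariance(nll, best.x, count_terms, zi_terms, has_theta, est_sigma)

    return FittedModel(
        spec=spec,
        beta=pd.Series(beta_v, index=count_terms),
        gamma=pd.Series(gamma_v, index=zi_terms),
        theta=theta_v,
        sigma_u=sigma_v,
        u_modes=u_modes,
        route_ids=design.route_ids,
        loglik=float(ll),
        k=n_par,
        n_obs=n,
        converged=converged,
        scalers=dict(design.scalers),
        cov=cov,
        n_restarts=n_restarts,
        message=str(best.message),
    )


def _fd_covariance(nll, x, count_terms, zi_terms, has_theta, est_sigma):
    """Wald covariance from a central finite-difference Hessian of the
    negative log-likelihood at the optimum."""
    k = len(x)
    hstep = 1e-4 * np.maximum(1.0, np.abs(x))
    f0 = nll(x)
    fp = np.empty(k)
    fm = np.empty(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = hstep[i]
        fp[i] = nll(x + e)
        fm[i] = nll(x - e)
    H = np.empty((k, k))
    for i in range(k):
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hstep[i] ** 2
        for j in range(i + 1, k):
            ei = np.zeros(k); ei[i] = hstep[i]
            ej = np.zeros(k); ej[j] = hstep[j]
            fij = nll(x + ei + ej)
            H[i, j] = H[j, i] = (
                fij - fp[i] - fp[j] + f0
            ) / (hstep[i] * hstep[j])
    names = (
        list(count_terms)
        + [f"zi_{t}" for t in zi_terms]
        + (["log_theta"] if has_theta else [])
        + (["log_sigma_u"] if est_sigma else [])
    )
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
        return None
    return pd.DataFrame(cov, index=names, columns=names)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    table: pd.DataFrame
    best: FittedModel
    retained: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def select_family(
    design: DesignMatrices,
    base_spec: ModelSpec | None = None,
    families: tuple[str, ...] = FAMILIES,
    **fit_kw,
) -> SelectionResult:
    """Fit every candidate family with identical covariates; rank by AIC.

    Ties (delta AIC < 1e-6) break toward fewer parameters.  Non-convergent
    families are excluded with a warning; all failing is an error.
    """
    base_spec = base_spec or ModelSpec()
    rows, fits, warns = [], {}, []
    for fam in families:
        spec = replace(
            base_spec, family=fam,
            zi_terms=base_spec.zi_terms if fam in ("zip", "zinb") else None,
        )
        try:
            fm = fit(design, spec, compute_cov=False, **fit_kw)
        except (ModelError, np.linalg.LinAlgError) as err:
            warns.append(f"{fam}: {err}")
            continue
        if not fm.converged:
            warns.append(f"{fam}: did not converge ({fm.message})")
            continue
        fits[fam] = fm
        rows.append({"family": fam, "loglik": fm.loglik, "k": fm.k, "aic": fm.aic})
    if not fits:
        raise ConvergenceError("no candidate family converged: " + "; ".join(warns))
    for w in warns:
        warnings.warn(w, stacklevel=2)
    table = pd.DataFrame(rows).sort_values(["aic", "k"]).reset_index(drop=True)
    best_aic = table["aic"].min()
    contenders = table[table["aic"] - best_aic < 1e-6].sort_values("k")
    best = fits[contenders.iloc[0]["family"]]
    return SelectionResult(table=table, best=best, warnings=warns)


def _block_members(block: str, terms: list[str]) -> list[str]:
    """The main effect plus every interaction involving it."""
    members = [block]
    for inter in CLIMATE_INTERACTIONS:
        if block in inter.split(":") and inter in terms:
            members.append(inter)
    return members


def select_covariates(
    design: DesignMatrices,
    family: str | None = None,
    base_spec: ModelSpec | None = None,
    blocks: tuple[str, ...] = CLIMATE_MAINS,
    **fit_kw,
) -> SelectionResult:
    """Backward AIC elimination over whole climate component x variable blocks.

    A candidate drop removes the block's main effect together with any
    interaction that involves it (interactions are never retained without
    both mains).  Stops when no single drop lowers the AIC.  Habitat, year,
    and protocol terms are never candidates.
    """
    base_spec = base_spec or ModelSpec()
    if family is not None:
        base_spec = replace(base_spec, family=family)
    count_terms = list(base_spec.count_terms or design.X.columns)
    zi_terms = None
    if base_spec.has_zi:
        zi_terms = list(
            base_spec.zi_terms
            or [t for t in count_terms if t in design.X_zi.columns]
        )

    current = fit(
        design, replace(base_spec, count_terms=tuple(count_terms),
                        zi_terms=tuple(zi_terms) if zi_terms else None),
        compute_cov=False, **fit_kw,
    )
    active = [b for b in blocks if b in count_terms]
    rows = [{"step": 0, "dropped": None, "aic": current.aic}]
    step = 0
    while active:
        candidates = []
        for block in active:
            drop = set(_block_members(block, count_terms))
            ct = tuple(t for t in count_terms if t not in drop)
            zt = (
                tuple(t for t in zi_terms if t not in drop)
                if zi_terms is not None else None
            )
            spec = replace(base_spec, count_terms=ct, zi_terms=zt)
            try:
                fm = fit(
                    design, spec, compute_cov=False,
                    start={"beta": current.beta.to_dict(),
                           "gamma": current.gamma.to_dict(),
                           "theta": current.theta, "sigma_u": current.sigma_u},
                    **fit_kw,
                )
            except (ModelError, np.linalg.LinAlgError):
                continue
            if fm.converged:
                candidates.append((block, fm))
        if not candidates:
            break
        block, fm = min(candidates, key=lambda c: c[1].aic)
        if fm.aic < current.aic:
            step += 1
            rows.append({"step": step, "dropped": block, "aic": fm.aic})
            drop = set(_block_members(block, count_terms))
            count_terms = [t for t in count_terms if t not in drop]
            if zi_terms is not None:
                zi_terms = [t for t in zi_terms if t not in drop]
            active.remove(block)
            current = fm
        else:
            break
    retained = {b: (b in count_terms) for b in blocks}
    return SelectionResult(
        table=pd.DataFrame(rows), best=current, retained=retained
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_mean(
    fitted: FittedModel,
    X: pd.DataFrame,
    offset: np.ndarray | float = 0.0,
    X_zi: pd.DataFrame | None = None,
    route: np.ndarray | None = None,
    include_random: bool = False,
) -> np.ndarray:
    """Expected count mu = exp(x'beta [+ u_r] + offset), times (1 - pi) for
    zero-inflated families.

    ``X`` must contain every count-part column of the fit (already on the
    standardized scale used at fit time).  ``route`` gives integer codes into
    the training routes; required when ``include_random``.
    """
    missing = set(fitted.beta.index) - set(X.columns)
    if missing:
        raise ModelError(f"prediction design missing columns: {sorted(missing)}")
    eta = X[list(fitted.beta.index)].to_numpy(dtype=float) @ fitted.beta.to_numpy()
    eta = eta + np.asarray(offset, dtype=float)
    if include_random:
        if route is None:
            raise ModelError("route codes required for include_random")
        route = np.asarray(route)
        if route.max() >= len(fitted.u_modes):
            raise ModelError("unseen route code in prediction")
        eta = eta + fitted.u_modes[route]
    mu = np.exp(eta)
    if fitted.spec.has_zi and len(fitted.gamma):
        src = X_zi if X_zi is not None else X
        missing = set(fitted.gamma.index) - set(src.columns)
        if missing:
            raise ModelError(f"zi prediction design missing: {sorted(missing)}")
        zi_eta = src[list(fitted.gamma.index)].to_numpy(dtype=float) @ fitted.gamma.to_numpy()
        mu = mu / (1.0 + np.exp(zi_eta))     # (1 - pi) * mu
    return mu
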