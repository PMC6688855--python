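"""Beta GLMMs for per-cell cover proportions.

Proportions y in [0,1] are first pulled off the boundary with the
Smithson-Verkuilen transform y' = (y (n - 1) + 0.5) / n, where n is the
number of points or pixels behind the proportion (so exact 0s and 1s move
by half the detection limit).  The model is then

    y'_ij ~ Beta(mu_ij, phi)        (mean-precision parameterization)
    logit(mu_ij) = x_ij' beta + b_i,   b_i ~ N(0, sigma2_cell)

with one categorical fixed factor (flight altitude or sampling method,
treatment-coded) and a random intercept per 50 x 50 m cell.  The marginal
likelihood integrates b_i out by adaptive Gauss-Hermite quadrature
(integrand re-centred at each cell's conditional mode and rescaled by its
curvature); the outer optimizer is quasi-Newton (L-BFGS-B) on
(beta, log sigma2, log phi) from the fixed start beta = 0, sigma2 = 0.5,
phi = 10.  Wald F tests for the fixed factor use the containment-style
denominator df N - n_cells - (p - 1), which is 182 for the default design
(276 observations, 92 cells, 3 factor levels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, polygamma, psi

from .raster import CLASS_IDS, CLASS_NAMES

_GH_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gh_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GH_CACHE:
        x, w = np.polynomial.hermite.hermgauss(n)
        _GH_CACHE[n] = (x, np.log(w))
    return _GH_CACHE[n]


# ---------------------------------------------------------------- transform

def sv_transform(y, n):
    """Smithson-Verkuilen boundary transform y' = (y (n-1) + 0.5) / n."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y must be in [0, 1]")
    return (y * (n - 1.0) + 0.5) / n


def sv_inverse(y_prime, n):
    """Exact inverse of :func:`sv_transform`."""
    y_prime = np.asarray(y_prime, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    return (y_prime * n - 0.5) / (n - 1.0)


# ---------------------------------------------------------------- model fit

@dataclass
class BetaGLMMFit:
    """Estimates and tests from one beta GLMM."""

    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    sigma2_cell: float
    sigma2_cell_se: float
    phi: float
    phi_se: float
    loglik: float
    loglik_start: float
    wald_F: float
    wald_df: tuple[int, int]
    p_value: float
    dispersion: float
    converged: bool
    sigma2_boundary: bool
    n_obs: int
    n_cells: int
    b_modes: np.ndarray = field(repr=False)
    pearson_residuals: np.ndarray = field(repr=False)
    studentized_residuals: np.ndarray = field(repr=False)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": name, "estimate": est, "se": se}
            for name, est, se in zip(self.beta_names, self.beta, self.beta_se)
        ]
        rows.append({"term": "var(cell)", "estimate": self.sigma2_cell, "se": self.sigma2_cell_se})
        rows.append({"term": "phi", "estimate": self.phi, "se": self.phi_se})
        return pd.DataFrame(rows)


class _MarginalLikelihood:
    """Adaptive-GH marginal negative log-likelihood, vectorized over cells."""

    def __init__(self, y: np.ndarray, X: np.ndarray, cell: np.ndarray, nodes: int = 15):
        self.y = y
        self.X = X
        self.cell = cell
        self.n_cells = int(cell.max()) + 1
        self.log_y = np.log(y)
        self.log_1my = np.log1p(-y)
        self.logit_y = self.log_y - self.log_1my
        self.gh_x, self.gh_logw = _gh_nodes(nodes)
        self._warm_modes = np.zeros(self.n_cells)

    def _log_beta_pdf_sums(self, eta: np.ndarray, phi: float) -> np.ndarray:
        """Sum over each cell's observations of log Beta(y | mu(eta), phi)."""
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        logf = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * self.log_y + (b - 1.0) * self.log_1my
        return np.bincount(self.cell, weights=logf, minlength=self.n_cells)

    def _score_hess_b(self, xb: np.ndarray, b: np.ndarray, phi: float, sigma2: float):
        eta = xb + b[self.cell]
        mu = expit(eta)
        mup = mu * (1.0 - mu)
        A = self.logit_y - psi(mu * phi) + psi((1.0 - mu) * phi)
        score_obs = phi * mup * A
        trig = polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi)
        hess_obs = phi * (mup * (1.0 - 2.0 * mu) * A - phi * mup**2 * trig)
        score = np.bincount(self.cell, weights=score_obs, minlength=self.n_cells) - b / sigma2
        hess = np.bincount(self.cell, weights=hess_obs, minlength=self.n_cells) - 1.0 / sigma2
        return score, hess

    def modes(self, beta: np.ndarray, phi: float, sigma2: float, tol: float = 1e-9, max_iter: int = 60) -> tuple[np.ndarray, np.ndarray]:
        """Conditional modes b_i and curvatures h_i = -g'' at the mode."""
        xb = self.X @ beta
        b = self._warm_modes.copy()
        for _ in range(max_iter):
            score, hess = self._score_hess_b(xb, b, phi, sigma2)
            hess = np.minimum(hess, -1e-8)  # safeguard: keep Newton downhill
            step = -score / hess
            np.clip(step, -2.0, 2.0, out=step)
            b = np.clip(b + step, -15.0, 15.0)
            if np.max(np.abs(step)) < tol:
                break
        _, hess = self._score_hess_b(xb, b, phi, sigma2)
        self._warm_modes = b
        return b, -np.minimum(hess, -1e-8)

    def nll(self, theta: np.ndarray) -> float:
        beta = theta[:-2]
        sigma2 = np.exp(theta[-2])
        phi = np.exp(theta[-1])
        b_hat, h = self.modes(beta, phi, sigma2)
        s = np.sqrt(2.0 / h)
        xb = self.X @ beta
        log_prior_const = -0.5 * np.log(2.0 * np.pi * sigma2)
        terms = np.empty((len(self.gh_x), self.n_cells))
        for k, (x_k, logw_k) in enumerate(zip(self.gh_x, self.gh_logw)):
            b_k = b_hat + s * x_k
            g = self._log_beta_pdf_sums(xb + b_k[self.cell], phi)
            g += log_prior_const - b_k**2 / (2.0 * sigma2)
            terms[k] = logw_k + x_k**2 + g
        m = terms.max(axis=0)
        cell_ll = np.log(s) + m + np.log(np.exp(terms - m).sum(axis=0))
        out = -float(cell_ll.sum())
        if not np.isfinite(out):
            return 1e10  # steer the line search back into the finite region
        return out


def _fd_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_beta_glmm(
    y: np.ndarray,
    X: np.ndarray,
    cell: np.ndarray,
    beta_names: list[str] | None = None,
    quadrature_nodes: int = 15,
    max_iter: int = 500,
) -> BetaGLMMFit:
    """Fit the beta GLMM by maximum marginal likelihood.

    ``y`` must lie strictly in (0,1) (SV-transformed); ``X`` is the fixed
    design matrix with intercept first; ``cell`` holds 0-based consecutive
    cell indices.  Deterministic: fixed start beta=0, sigma2=0.5, phi=10.
    Raises on non-convergence; a sigma2 estimate at the lower bound is
    flagged (``sigma2_boundary``) but the fit is still returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    cell = np.asarray(cell)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("responses must be strictly inside (0,1); apply sv_transform")
    _, cell_idx = np.unique(cell, return_inverse=True)
    ml = _MarginalLikelihood(y, X, cell_idx, nodes=quadrature_nodes)
    p = X.shape[1]
    theta0 = np.concatenate([np.zeros(p), [np.log(0.5)], [np.log(10.0)]])
    nll0 = ml.nll(theta0)
    bounds = [(None, None)] * p + [(-12.0, 5.0), (-2.0, 12.0)]
    res = optimize.minimize(
        ml.nll, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and res.status != 1:  # 1 = maxiter of inner lnsrch, still usable
        raise RuntimeError(f"beta GLMM did not converge: {res.message}; trace nll={res.fun:.4f}")
    theta = res.x
    beta = theta[:-2]
    sigma2 = float(np.exp(theta[-2]))
    phi = float(np.exp(theta[-1]))
    sigma2_boundary = theta[-2] <= bounds[p][0] + 1e-6

    H = _fd_hessian(ml.nll, theta)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        cov = np.full((p + 2, p + 2), np.nan)
        se_all = np.full(p + 2, np.nan)
    beta_se = se_all[:p]
    sigma2_se = sigma2 * se_all[p]       # delta method from log scale
    phi_se = phi * se_all[p + 1]

    # Wald F for the non-intercept fixed effects
    q = p - 1
    n_obs, n_cells = len(y), ml.n_cells
    ddf = n_obs - n_cells - q
    if q > 0:
        Vb = cov[1:p, 1:p]
        bq = beta[1:p]
        F = float(bq @ np.linalg.solve(Vb, bq) / q)
        p_value = float(stats.f.sf(F, q, ddf))
    else:
        F, p_value = np.nan, np.nan

    # conditional residuals and dispersion at the optimum
    b_hat, _ = ml.modes(beta, phi, sigma2)
    mu = expit(X @ beta + b_hat[cell_idx])
    var = mu * (1.0 - mu) / (1.0 + phi)
    resid = (y - mu) / np.sqrt(var)
    chi2 = float(np.sum(resid**2))
    # conditional residuals consume ~one df per cell on top of the fixed
    # effects, so normalise by N - p - n_cells (≈ the containment df)
    resid_df = max(n_obs - p - n_cells, 1)
    dispersion = chi2 / resid_df
    student = resid / max(np.sqrt(chi2 / resid_df), 1e-12)

    names = beta_names if beta_names is not None else [f"beta{i}" for i in range(p)]
    return BetaGLMMFit(
        beta=beta, beta_se=beta_se, beta_names=list(names),
        sigma2_cell=sigma2, sigma2_cell_se=float(sigma2_se),
        phi=phi, phi_se=float(phi_se),
        loglik=-res.fun, loglik_start=-nll0,
        wald_F=F, wald_df=(q, ddf), p_value=p_value,
        dispersion=dispersion, converged=bool(res.success),
        sigma2_boundary=bool(sigma2_boundary),
        n_obs=n_obs, n_cells=n_cells, b_modes=b_hat,
        pearson_residuals=resid, studentized_residuals=student,
    )


def simulate_beta_glmm(
    beta: np.ndarray,
    sigma2: float,
    phi: float,
    n_cells: int,
    n_levels: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw one balanced dataset from the model (one obs per cell x level).

    Returns (y, X, cell) with treatment-coded X.  Used by the
    parameter-recovery and type-I-error simulations.
    """
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, np.sqrt(sigma2), n_cells)
    cell = np.repeat(np.arange(n_cells), n_levels)
    level = np.tile(np.arange(n_levels), n_cells)
    X = np.zeros((n_cells * n_levels, n_levels))
    X[:, 0] = 1.0
    for l in range(1, n_levels):
        X[level == l, l] = 1.0
    mu = expit(X @ np.asarray(beta, dtype=float) + b[cell])
    y = rng.beta(mu * phi, (1.0 - mu) * phi)
    y = np.clip(y, 1e-9, 1.0 - 1e-9)
    return y, X, cell


# ---------------------------------------------------------------- reporting

def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of per-cell proportions (paired by cell)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant method: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def _design_for_factor(sub: pd.DataFrame, factor: str, baseline) -> tuple[np.ndarray, list[str]]:
    levels = [baseline] + sorted(set(sub[factor]) - {baseline})
    X = np.zeros((len(sub), len(levels)))
    X[:, 0] = 1.0
    vals = sub[factor].to_numpy()
    names = ["intercept"]
    for j, lev in enumerate(levels[1:], start=1):
        X[vals == lev, j] = 1.0
        names.append(f"{factor}={lev}")
    return X, names


def fit_factor_model(
    table: pd.DataFrame, class_id: int, factor: str, baseline, quadrature_nodes: int = 15
) -> BetaGLMMFit:
    """Fit one beta GLMM of a cover class's transformed proportion on a
    single categorical factor ('altitude_m' or 'method'), random cell."""
    sub = table[table["class"] == class_id].copy()
    if sub.empty:
        raise ValueError(f"no rows for class {class_id}")
    y = sv_transform(sub["proportion"].to_numpy(), sub["n"].to_numpy())
    X, names = _design_for_factor(sub, factor, baseline)
    return fit_beta_glmm(y, X, sub["cell_id"].to_numpy(), beta_names=names, quadrature_nodes=quadrature_nodes)


def method_comparison_report(
    table: pd.DataFrame,
    altitudes: tuple[float, ...] = (75.0, 100.0, 120.0),
    reference_altitude: float = 75.0,
    quadrature_nodes: int = 15,
) -> dict[str, pd.DataFrame]:
    """The full mixed-model comparison.

    Altitude models: per drone method, per cover class, fixed factor
    altitude (baseline 75 m).  Method models: at the reference altitude,
    per cover class, fixed factor method (baseline ground).  Also
    back-transforms fixed-effect estimates through the inverse logit to
    the proportion scale for the estimate summary.

    Returns {'coefficients', 'tests', 'estimates'} DataFrames.
    """
    methods = set(table["method"])
    need = {"ground", "drone_pixels", "drone_transects"}
    if not need <= methods:
        raise ValueError(f"missing methods: {sorted(need - methods)}")
    coef_rows, test_rows, est_rows = [], [], []

    def record(fit: BetaGLMMFit, family: str, label: str, class_id: int):
        for name, est, se in zip(fit.beta_names, fit.beta, fit.beta_se):
            coef_rows.append(
                {"family": family, "model": label, "class": CLASS_NAMES[class_id],
                 "term": name, "estimate": est, "se": se}
            )
        coef_rows.append(
            {"family": family, "model": label, "class": CLASS_NAMES[class_id],
             "term": "var(cell)", "estimate": fit.sigma2_cell, "se": fit.sigma2_cell_se}
        )
        test_rows.append(
            {"family": family, "model": label, "class": CLASS_NAMES[class_id],
             "F": fit.wald_F, "df1": fit.wald_df[0], "df2": fit.wald_df[1],
             "p_value": fit.p_value, "dispersion": fit.dispersion}
        )
        # inverse-logit estimates per factor level for the estimate plot table
        intercept = fit.beta[0]
        est_rows.append({"family": family, "model": label, "class": CLASS_NAMES[class_id],
                         "level": "baseline", "proportion": float(expit(intercept))})
        for name, b in zip(fit.beta_names[1:], fit.beta[1:]):
            est_rows.append({"family": family, "model": label, "class": CLASS_NAMES[class_id],
                             "level": name, "proportion": float(expit(intercept + b))})

    for method in ("drone_pixels", "drone_transects"):
        sub = table[(table["method"] == method) & table["altitude_m"].isin(altitudes)]
        if len(set(sub["altitude_m"])) >= 2:
            for c in CLASS_IDS:
                fit = fit_factor_model(sub, c, "altitude_m", reference_altitude, quadrature_nodes)
                record(fit, "altitude", method, c)

    at_ref = table[
        (table["method"] == "ground")
        | ((table["method"].isin(["drone_pixels", "drone_transects"])) & (table["altitude_m"] == reference_altitude))
    ]
    for c in CLASS_IDS:
        fit = fit_factor_model(at_ref, c, "method", "ground", quadrature_nodes)
        record(fit, "method", f"methods@{reference_altitude:g}m", c)

    return {
        "coefficients": pd.DataFrame(coef_rows),
        "tests": pd.DataFrame(test_rows),
        "estimates": pd.DataFrame(est_rows),
    }
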