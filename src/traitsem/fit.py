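"""Maximum-likelihood covariance-structure estimation and fit assessment.

The estimator minimises the ML discrepancy

    F(S, Sigma) = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

between the sample moment matrix ``S`` and the model-implied covariance
``Sigma(theta) = F (I-A)^-1 S_shock (I-A)^-T F^T`` over the free parameters
of a :class:`~traitsem.model.RamSystem`.  ``(n-1) * F_min`` is the model
chi-square.  Variance parameters are log-transformed during optimisation to
keep them positive; the gradient of F is computed analytically from the RAM
derivatives, and several seeded restarts guard against local minima.

Reported solutions are standardized: every variable (including latents) is
rescaled to unit implied variance, and each latent's sign is normalised so
that its anchor indicator's loading is positive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import ModelSpec, RamSystem, build_ram, count_df
from .trait_io import CorrMatrix

__all__ = [
    "FitResult",
    "implied_covariance",
    "ml_discrepancy",
    "fit_ml",
    "baseline_fit",
    "standard_errors",
]

_VAR_FLOOR = 1e-6


class FitError(RuntimeError):
    pass


@dataclass
class FitResult:
    """A fitted covariance-structure model.

    ``a``/``s`` are the unstandardized RAM matrices at the optimum;
    ``a_std``/``s_std`` the standardized ones (all variables unit variance,
    latent signs anchored).  ``estimates`` and ``std_estimates`` map the
    parameter labels of the RAM slot layout to values.  ``r2`` maps each
    endogenous variable to 1 minus its standardized disturbance variance.
    """

    ram: RamSystem
    moments: CorrMatrix
    theta: np.ndarray
    converged: bool
    f_min: float
    grad_norm: float
    n_iter: int
    a: np.ndarray
    s: np.ndarray
    implied: np.ndarray
    sd: np.ndarray              # implied SDs of all variables (obs + latent)
    a_std: np.ndarray
    s_std: np.ndarray
    chi2: float
    df: int
    pvalue: float
    indices: dict[str, float] = field(default_factory=dict)
    se: np.ndarray | None = None
    z: np.ndarray | None = None
    p_params: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def spec(self) -> ModelSpec:
        return self.ram.spec

    @property
    def n(self) -> int:
        return self.moments.n

    @property
    def n_free(self) -> int:
        return self.ram.n_free

    @property
    def aic(self) -> float:
        return self.chi2 + 2.0 * self.n_free

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.ram.labels, self.theta))

    @property
    def std_estimates(self) -> dict[str, float]:
        out = {}
        for k, (mat, i, j) in enumerate(self.ram.slots):
            m = self.a_std if mat == "A" else self.s_std
            out[self.ram.labels[k]] = float(m[i, j])
        # anchor loadings are fixed at 1 unstandardized but informative here
        for (i, j), _ in self.ram.fixed_a.items():
            out[f"load({self.ram.variables[i]})"] = float(self.a_std[i, j])
        return out

    @property
    def r2(self) -> dict[str, float]:
        vars_ = self.ram.variables
        idx = {v: i for i, v in enumerate(vars_)}
        return {
            v: float(1.0 - self.s_std[idx[v], idx[v]])
            for v in self.spec.endogenous()
        }

    def std_path(self, source: str, target: str) -> float:
        idx = {v: i for i, v in enumerate(self.ram.variables)}
        return float(self.a_std[idx[target], idx[source]])

    def to_json(self) -> str:
        payload = {
            "model": {
                "observed": list(self.spec.observed),
                "latents": {k: list(v) for k, v in self.spec.latents.items()},
                "paths": [list(p) for p in self.spec.paths],
                "covariances": [list(c) for c in self.spec.covariances],
            },
            "n": self.n,
            "converged": self.converged,
            "f_min": self.f_min,
            "chi2": self.chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "indices": self.indices,
            "estimates": self.estimates,
            "std_estimates": self.std_estimates,
            "r2": self.r2,
            "se": None if self.se is None else dict(zip(self.ram.labels, self.se)),
            "param_pvalues": None
            if self.p_params is None
            else dict(zip(self.ram.labels, self.p_params)),
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2, default=float)

    def report(self) -> str:
        """Human-readable text report (fit indices, paths, R^2)."""
        lines = [
            f"Model: {len(self.spec.observed)} observed, "
            f"{len(self.spec.latents)} latent, n = {self.n}",
            f"chi2 = {self.chi2:.3f}  df = {self.df}  p = {self.pvalue:.3f}",
        ]
        for key in ("rmsea", "agfi", "cfi", "aic"):
            if key in self.indices:
                val = self.indices[key]
                lines.append(f"{key.upper()} = {val:.3f}" if val == val else
                             f"{key.upper()} = undefined")
        lines.append("standardized estimates:")
        ses = self.se
        for k, label in enumerate(self.ram.labels):
            extra = ""
            if ses is not None and np.isfinite(ses[k]) and self.p_params is not None:
                extra = f"  (p = {self.p_params[k]:.4f})"
            lines.append(f"  {label} = {self.std_estimates[label]:.3f}{extra}")
        for v, r in self.r2.items():
            lines.append(f"R2({v}) = {r:.3f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# implied moments and discrepancy


def implied_covariance(ram: RamSystem, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance matrix of the observed variables."""
    a, s = ram.matrices(np.asarray(theta, dtype=float))
    b = np.linalg.inv(np.eye(ram.n_vars) - a)
    full = b @ s @ b.T
    return full[: ram.n_observed, : ram.n_observed]


def ml_discrepancy(sample: np.ndarray | CorrMatrix, sigma: np.ndarray) -> float:
    """ML fit function F >= 0, zero iff the matrices coincide."""
    s = sample.values if isinstance(sample, CorrMatrix) else np.asarray(sample)
    sigma = np.asarray(sigma)
    p = s.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(s)
    sign_m, logdet_m = np.linalg.slogdet(sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise FitError(
            "moment matrix not positive definite; consider nearest_psd()"
        )
    return float(logdet_m - logdet_s + np.trace(s @ np.linalg.inv(sigma)) - p)


# ---------------------------------------------------------------------------
# optimisation internals


def _objective(ram: RamSystem, s_samp: np.ndarray, logdet_s: float):
    """Return f(x) -> (F, grad) on the working scale (log variances)."""
    nv = ram.n_vars
    po = ram.n_observed
    eye = np.eye(nv)
    var_mask = ram.is_variance()
    slots = ram.slots

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        theta = x.copy()
        theta[var_mask] = np.exp(x[var_mask])
        a, s = ram.matrices(theta)
        b = np.linalg.inv(eye - a)
        full = b @ s @ b.T
        sigma = full[:po, :po]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0 or not np.isfinite(logdet):
            return 1e10, np.zeros_like(x)
        sig_inv = np.linalg.inv(sigma)
        f = logdet - logdet_s + float(np.trace(s_samp @ sig_inv)) - po
        # W = dF/dSigma (symmetric); chain through the RAM structure
        w = sig_inv - sig_inv @ s_samp @ sig_inv
        wf = np.zeros((nv, nv))
        wf[:po, :po] = w
        bw = b.T @ wf @ b               # B' F' W F B
        x_a = b @ s @ bw                # B S B' F' W F B
        grad = np.empty_like(x)
        for k, (mat, i, j) in enumerate(slots):
            if mat == "A":
                # dF = 2 * (B S B' F' W F B)[j, i]
                grad[k] = 2.0 * x_a[j, i]
            elif i == j:
                grad[k] = bw[i, i] * theta[k]  # log-scale chain rule
            else:
                grad[k] = 2.0 * bw[i, j]
        return f, grad

    return fun


def _start_vector(ram: RamSystem) -> np.ndarray:
    """Paths/covariances 0, loadings 1, variances 0.5 (working scale)."""
    x0 = np.zeros(ram.n_free)
    for k, label in enumerate(ram.labels):
        if label.startswith("load("):
            x0[k] = 1.0
    x0[ram.is_variance()] = np.log(0.5)
    return x0


def fit_ml(
    spec: ModelSpec,
    moments: CorrMatrix,
    n_restarts: int = 5,
    seed: int = 0,
    gtol: float = 1e-6,
    compute_se: bool = True,
) -> FitResult:
    """Fit a model to a moment matrix by maximum likelihood.

    ``moments`` may contain more variables than the model uses; the observed
    submatrix is selected (and reordered) automatically.  A correlation
    matrix is treated as the covariance matrix of standardized data.  The fit
    is restarted ``n_restarts`` times from perturbed start values (seeded)
    and the best optimum kept.
    """
    sub = moments.submatrix(list(spec.observed))
    s_samp = sub.values
    po = len(spec.observed)
    if sub.n <= po:
        raise FitError(f"n = {sub.n} must exceed the {po} observed variables")
    sign, logdet_s = np.linalg.slogdet(s_samp)
    if sign <= 0:
        raise FitError("sample moment matrix not positive definite; "
                       "consider nearest_psd()")
    ram = build_ram(spec)
    df = count_df(spec)
    if df < 0:
        raise FitError(f"model under-identified (df = {df})")

    fun = _objective(ram, s_samp, logdet_s)
    var_mask = ram.is_variance()
    bounds = [
        (np.log(_VAR_FLOOR), None) if var_mask[k] else (None, None)
        for k in range(ram.n_free)
    ]
    rng = np.random.default_rng(seed)
    x0 = _start_vector(ram)
    best = None
    for r in range(max(1, n_restarts)):
        xr = x0 if r == 0 else x0 + rng.normal(scale=0.1, size=x0.shape)
        res = optimize.minimize(
            fun, xr, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        # polish: the bounded phase can stop on ftol short of the gradient
        # tolerance; an unbounded BFGS restart from its solution finishes the
        # job (positivity is already guaranteed by the log transform)
        polish = optimize.minimize(
            fun, res.x, jac=True, method="BFGS",
            options={"maxiter": 500, "gtol": 1e-9},
        )
        if polish.fun <= res.fun and np.all(
            polish.x[var_mask] >= np.log(_VAR_FLOOR) - 1e-9
        ):
            polish.nit += res.nit
            res = polish
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    x_opt = best.x
    f_min, grad = fun(x_opt)
    # projected gradient norm: ignore components pushing into the bound
    proj = grad.copy()
    at_floor = var_mask & (x_opt <= np.log(_VAR_FLOOR) + 1e-9)
    proj[at_floor & (proj > 0)] = 0.0
    grad_norm = float(np.linalg.norm(proj, ord=np.inf))
    converged = bool(np.isfinite(f_min) and grad_norm < gtol)

    theta = x_opt.copy()
    theta[var_mask] = np.exp(x_opt[var_mask])
    a, s = ram.matrices(theta)
    b = np.linalg.inv(np.eye(ram.n_vars) - a)
    full = b @ s @ b.T
    implied = full[:po, :po]

    notes: list[str] = []
    if at_floor.any():
        bad = [ram.labels[k] for k in np.flatnonzero(at_floor)]
        notes.append(f"Heywood case: variance at lower bound for {bad}")
    if not converged:
        notes.append(
            f"optimizer did not reach gradient tolerance "
            f"(|grad| = {grad_norm:.2e})"
        )

    a_std, s_std, sd = _standardize(ram, a, s, full)
    chi2 = (sub.n - 1) * f_min
    pvalue = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    fit = FitResult(
        ram=ram, moments=sub, theta=theta, converged=converged, f_min=f_min,
        grad_norm=grad_norm, n_iter=int(best.nit), a=a, s=s, implied=implied,
        sd=sd, a_std=a_std, s_std=s_std, chi2=chi2, df=df, pvalue=pvalue,
        notes=notes,
    )
    if converged:
        fit_indices(fit)
        if compute_se:
            standard_errors(fit)
    else:
        warnings.warn("fit did not converge; fit indices suppressed",
                      stacklevel=2)
    return fit


def _standardize(
    ram: RamSystem, a: np.ndarray, s: np.ndarray, full: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardized solution with latent signs anchored to the first indicator."""
    sd = np.sqrt(np.diag(full))
    if np.any(sd <= 0):
        raise FitError("zero implied variance; cannot standardize")
    a_std = a * sd[None, :] / sd[:, None]
    s_std = s / np.outer(sd, sd)
    idx = {v: i for i, v in enumerate(ram.variables)}
    flip = np.ones(ram.n_vars)
    for lat, inds in ram.spec.latents.items():
        if a_std[idx[inds[0]], idx[lat]] < 0:
            flip[idx[lat]] = -1.0
    if np.any(flip < 0):
        d = np.diag(flip)
        a_std = d @ a_std @ d
        s_std = d @ s_std @ d
    return a_std, s_std, sd


def baseline_fit(moments: CorrMatrix) -> tuple[float, int]:
    """Independence-model chi-square and df (all covariances fixed to zero).

    The ML optimum of the independence model is closed-form (fitted variances
    equal the sample variances), so no optimisation is needed:
    F_b = sum(ln s_ii) - ln|S|; for a correlation matrix, -ln|R|.
    """
    s = moments.values
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0:
        raise FitError("moment matrix not positive definite")
    f_b = float(np.sum(np.log(np.diag(s))) - logdet)
    p = moments.p
    return (moments.n - 1) * f_b, p * (p - 1) // 2


def fit_indices(fit: FitResult) -> FitResult:
    """Augment a converged fit with RMSEA, GFI/AGFI, CFI and AIC.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (n-1))); GFI is the weighted
    proportion of sample moments reproduced; AGFI adjusts GFI for df; CFI
    compares excess chi-square with the independence baseline; AIC uses the
    chi2 + 2t convention.  With df = 0, RMSEA and AGFI are undefined (NaN).
    """
    n = fit.n
    chi2, df = fit.chi2, fit.df
    sig_inv = np.linalg.inv(fit.implied)
    m = sig_inv @ fit.moments.values
    p = fit.moments.p
    eye = np.eye(p)
    gfi = 1.0 - np.trace((m - eye) @ (m - eye)) / np.trace(m @ m)
    if df > 0:
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    else:
        agfi = float("nan")
        rmsea = float("nan")
    chi2_b, df_b = baseline_fit(fit.moments)
    denom = max(chi2_b - df_b, chi2 - df, 0.0)
    cfi = 1.0 - max(chi2 - df, 0.0) / denom if denom > 0 else 1.0
    fit.indices.update(
        {
            "gfi": float(gfi),
            "agfi": float(agfi),
            "rmsea": rmsea,
            "cfi": float(cfi),
            "aic": float(chi2 + 2 * fit.n_free),
            "baseline_chi2": float(chi2_b),
            "baseline_df": int(df_b),
        }
    )
    return fit


def standard_errors(fit: FitResult, step: float = 1e-5) -> FitResult:
    """Asymptotic SEs from the numerical Hessian of F_ML at the optimum.

    Parameter covariance = (2/(n-1)) H^-1 with H the central-difference
    Hessian with respect to the untransformed parameters.  A singular or
    non-PD Hessian leaves SEs unavailable (NaN) with a note.
    """
    ram = fit.ram
    s_samp = fit.moments.values
    _, logdet_s = np.linalg.slogdet(s_samp)
    po = ram.n_observed

    def f_raw(theta: np.ndarray) -> float:
        a, s = ram.matrices(theta)
        b = np.linalg.inv(np.eye(ram.n_vars) - a)
        sigma = (b @ s @ b.T)[:po, :po]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf
        return logdet - logdet_s + float(
            np.trace(s_samp @ np.linalg.inv(sigma))
        ) - po

    t = fit.theta
    k = t.size
    h = np.empty((k, k))
    steps = step * np.maximum(1.0, np.abs(t))
    f0 = f_raw(t)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                val = (f_raw(t + ei) - 2 * f0 + f_raw(t - ei)) / steps[i] ** 2
            else:
                val = (
                    f_raw(t + ei + ej) - f_raw(t + ei - ej)
                    - f_raw(t - ei + ej) + f_raw(t - ei - ej)
                ) / (4 * steps[i] * steps[j])
            h[i, j] = h[j, i] = val
    try:
        cov = (2.0 / (fit.n - 1)) * np.linalg.inv(h)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance estimates")
        se = np.sqrt(diag)
    except np.linalg.LinAlgError:
        fit.se = np.full(k, np.nan)
        fit.z = np.full(k, np.nan)
        fit.p_params = np.full(k, np.nan)
        fit.notes.append("standard errors unavailable (singular Hessian)")
        return fit
    with np.errstate(divide="ignore", invalid="ignore"):
        z = fit.theta / se
    fit.se = se
    fit.z = z
    fit.p_params = 2.0 * stats.norm.sf(np.abs(z))
    return fit
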