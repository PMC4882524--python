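"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover every stage of the pipeline without any field data:

* :func:`simulate_model` — Gaussian draws from a causal model at chosen
  (standardized) parameter values, for parameter-recovery experiments;
* :func:`exact_moment_sample` — a table whose *in-sample* correlation matrix
  equals a target exactly, bridging raw-data operations and a printed
  correlation matrix (the moments are sufficient for the ML fit);
* :func:`study_correlations` / :func:`study_trait_summary` — the packaged
  oak foliar-nitrogen study fixtures: the published 10-variable Pearson
  correlation matrix (n = 90 trees) and the published per-variable summary
  (mean, SE, min, max, CV%) used as rescaling targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .model import ModelSpec, build_ram
from .trait_io import CorrMatrix, TraitTable

__all__ = [
    "SimSpec",
    "values_from_fit",
    "simulate_model",
    "exact_moment_sample",
    "study_correlations",
    "study_trait_summary",
    "reconstructed_sd",
]

STUDY_N = 90
DEFAULT_SEED = 26845


@dataclass(frozen=True)
class SimSpec:
    """A generative model: structure, true parameter values, sample size.

    ``values`` maps RAM parameter labels (``"MAP→TSK"``, ``"load(LS)"``,
    ``"cov(TSK,TSP)"``, ``"var(eTSP)"``) to true values; omitted variances
    default so that structural variables have unit total variance when paths
    are standardized.  ``rescale`` optionally maps observed variables to
    (mean, sd) targets applied after simulation.
    """

    spec: ModelSpec
    values: dict[str, float]
    n: int
    seed: int = DEFAULT_SEED
    rescale: dict[str, tuple[float, float]] = field(default_factory=dict)

    def system(self) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
        """True (A, S) matrices and the variable order.

        Values for anchor loadings (fixed to 1 during *fitting*) may be
        supplied too — a fully standardized solution has a non-unit anchor
        loading.  Unspecified variances are filled in topological order so
        every variable ends up with unit total variance.
        """
        ram = build_ram(self.spec)
        anchor_labels = {
            f"load({ram.variables[i]})": (i, j) for (i, j) in ram.fixed_a
        }
        unknown = set(self.values) - set(ram.labels) - set(anchor_labels)
        if unknown:
            raise KeyError(f"labels not in model: {sorted(unknown)}")
        theta = np.zeros(ram.n_free)
        var_slot: dict[str, int] = {}
        for k, label in enumerate(ram.labels):
            if label in self.values:
                theta[k] = self.values[label]
            elif label.startswith("load("):
                theta[k] = 0.7  # default standardized loading
            mat, i, j = ram.slots[k]
            if mat == "S" and i == j:
                var_slot[ram.variables[i]] = k
        a, s = ram.matrices(theta)
        for label, (i, j) in anchor_labels.items():
            # the fixed-to-1 anchor is a fitting identification device; in
            # the standardized generative metric it defaults like any loading
            a[i, j] = self.values.get(label, 0.7)
        idx = {v: i for i, v in enumerate(ram.variables)}
        nv = ram.n_vars
        b = np.linalg.inv(np.eye(nv) - a)
        for v in self.spec.topological_order():
            if ram.labels[var_slot[v]] in self.values:
                continue
            i = idx[v]
            systematic = (b @ s @ b.T)[i, i]
            resid = 1.0 - systematic
            if resid <= 0:
                raise ValueError(
                    f"values leave non-positive residual variance for "
                    f"{v!r} ({resid:.4f})"
                )
            s[i, i] = resid
        return a, s, ram.variables


def values_from_fit(fit) -> dict[str, float]:
    """Slot label -> standardized estimate, usable as SimSpec true values."""
    ram = fit.ram
    out = {}
    for k, (mat, i, j) in enumerate(ram.slots):
        m = fit.a_std if mat == "A" else fit.s_std
        out[ram.labels[k]] = float(m[i, j])
    for (i, j) in ram.fixed_a:  # standardized anchor loadings are not 1
        out[f"load({ram.variables[i]})"] = float(fit.a_std[i, j])
    return out


def simulate_model(sim: SimSpec) -> TraitTable:
    """Draw a trait table from a causal model.

    Independent-shock vectors are drawn from N(0, S) (S carries the free
    residual covariances), propagated through (I - A)^-1, latent columns
    discarded, and observed columns optionally rescaled to target mean/SD.
    """
    a, s, variables = sim.system()
    nv = len(variables)
    w, v = np.linalg.eigh((s + s.T) / 2.0)
    if w.min() < -1e-10:
        raise ValueError("shock covariance matrix is not positive semidefinite")
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(sim.seed)
    shocks = rng.standard_normal((sim.n, nv)) @ factor.T
    b = np.linalg.inv(np.eye(nv) - a)
    x = shocks @ b.T
    n_obs = len(sim.spec.observed)
    data = pd.DataFrame(x[:, :n_obs], columns=list(sim.spec.observed))
    for var, (mean, sd) in sim.rescale.items():
        data[var] = data[var] * sd + mean
    return TraitTable(data)


def exact_moment_sample(target: CorrMatrix, n: int, seed: int = 0) -> TraitTable:
    """An n x p table whose sample correlation matrix equals ``target``.

    Draw Gaussian columns, centre them, whiten with the sample Cholesky
    factor and recolour with the target's: the resulting columns have mean
    0, variance 1 and pairwise sample correlations equal to the target to
    numerical precision.
    """
    p = target.p
    if n <= p:
        raise ValueError(f"need n > p ({n} <= {p}): whitening impossible")
    l_t = np.linalg.cholesky(target.values)
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, p))
    x -= x.mean(axis=0)
    c = x.T @ x / (n - 1)
    l_s = np.linalg.cholesky(c)
    z = np.linalg.solve(l_s, x.T).T @ l_t.T
    return TraitTable(pd.DataFrame(z, columns=list(target.names)))


def _data_path(name: str):
    return resources.files("traitsem").joinpath(f"data/{name}")


def study_correlations(psd_check: bool = True) -> CorrMatrix:
    """The published 10-variable Pearson correlation matrix (n = 90 trees).

    Values exactly as printed (two decimals; the Nmass–Narea entry to
    three).  The matrix is positive definite as printed (smallest eigenvalue
    about 0.006), so no repair is applied; ``psd_check`` only verifies this.
    """
    df = pd.read_csv(_data_path("oak_corr.csv"), index_col=0)
    m = CorrMatrix(
        names=tuple(df.columns),
        values=df.to_numpy(dtype=float),
        n=STUDY_N,
        is_correlation=True,
    )
    if psd_check and m.min_eigenvalue() <= 0:
        warnings.warn(
            "printed correlation matrix is indefinite; apply nearest_psd()",
            stacklevel=2,
        )
    return m


def study_trait_summary() -> pd.DataFrame:
    """Published per-variable summary: mean, SE, min, max, CV (percent).

    Stored exactly as printed.  Note the leaf-dry-weight row is internally
    inconsistent as published (minimum equals the mean with a larger
    maximum and CV 30%); it is kept verbatim and flagged here rather than
    silently repaired.
    """
    df = pd.read_csv(_data_path("oak_summary.csv"), index_col=0)
    bad = df[(df["min"] >= df["mean"]) & (df["max"] > df["mean"])]
    df.attrs["inconsistent_rows"] = list(bad.index)
    return df


def reconstructed_sd(summary: pd.DataFrame) -> pd.Series:
    """Per-variable SD reconstructed as mean * CV / 100."""
    return summary["mean"] * summary["cv"] / 100.0
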