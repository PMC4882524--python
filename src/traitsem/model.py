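"""Declarative causal model specification and its RAM matrix form.

A model is a recursive (acyclic) system of directed paths among observed and
latent variables.  Latents are measured by >= 2 observed indicators; the first
indicator's loading is fixed to 1 to set the latent's scale.  Each variable
carries one free variance parameter (exogenous variance or disturbance
variance) and residual covariances may be freed pairwise.

The matrix form follows the reticular (RAM) convention: an asymmetric
coefficient matrix ``A`` (``A[i, j]`` is the coefficient of the path
``j -> i``), a symmetric matrix ``S`` of variances and free covariances of
the independent shocks, and a filter ``F`` selecting observed rows.  The
model-implied covariance of the observed variables is
``F (I-A)^-1 S (I-A)^-T F^T``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ModelSpec",
    "RamSystem",
    "ModelSpecError",
    "parse_model_spec",
    "format_model_spec",
    "build_ram",
    "count_df",
    "model_library",
]


class ModelSpecError(ValueError):
    """Invalid model description."""


@dataclass(frozen=True)
class ModelSpec:
    """Paths, latents and free covariances of a recursive model.

    ``latents`` maps latent name -> ordered indicator tuple (first indicator
    anchors the latent's scale).  ``paths`` are (source, target) pairs among
    structural variables; ``covariances`` are unordered residual pairs.
    """

    observed: tuple[str, ...]
    latents: dict[str, tuple[str, ...]] = field(default_factory=dict)
    paths: tuple[tuple[str, str], ...] = ()
    covariances: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        obs = self.observed
        if len(set(obs)) != len(obs):
            raise ModelSpecError("duplicate observed variable names")
        for lat, inds in self.latents.items():
            if lat in obs:
                raise ModelSpecError(f"latent {lat!r} clashes with an observed name")
            if len(inds) < 2:
                raise ModelSpecError(f"latent {lat!r} needs >= 2 indicators")
            if len(inds) == 2:
                warnings.warn(
                    f"latent {lat!r} has exactly 2 indicators; it is identified "
                    "only through its structural neighbours",
                    stacklevel=3,
                )
            unknown = [i for i in inds if i not in obs]
            if unknown:
                raise ModelSpecError(f"latent {lat!r}: unknown indicators {unknown}")
        known = set(obs) | set(self.latents)
        if len(set(self.paths)) != len(self.paths):
            raise ModelSpecError("duplicate paths")
        for s, t in self.paths:
            for v in (s, t):
                if v not in known:
                    raise ModelSpecError(f"path {s} -> {t}: unknown variable {v!r}")
            if s == t:
                raise ModelSpecError(f"self-loop {s} -> {t}")
        seen_pairs = set()
        for a, b in self.covariances:
            if a == b:
                raise ModelSpecError(f"covariance pair must be distinct: {a}")
            for v in (a, b):
                if v not in known:
                    raise ModelSpecError(f"covariance {a} ~~ {b}: unknown {v!r}")
            key = frozenset((a, b))
            if key in seen_pairs:
                raise ModelSpecError(f"duplicate covariance {a} ~~ {b}")
            seen_pairs.add(key)
        self.topological_order()  # raises on cycles

    @property
    def variables(self) -> tuple[str, ...]:
        """All variables, observed first then latents."""
        return self.observed + tuple(self.latents)

    def parents(self, v: str) -> list[str]:
        return [s for s, t in self.paths if t == v]

    def children(self, v: str) -> list[str]:
        return [t for s, t in self.paths if s == v]

    def indicator_of(self, v: str) -> str | None:
        for lat, inds in self.latents.items():
            if v in inds:
                return lat
        return None

    def endogenous(self) -> list[str]:
        """Variables receiving at least one path or loading."""
        targets = {t for _, t in self.paths}
        for inds in self.latents.values():
            targets.update(inds)
        return [v for v in self.variables if v in targets]

    def topological_order(self) -> list[str]:
        """Topological order over the directed graph (paths + loadings)."""
        edges = list(self.paths)
        for lat, inds in self.latents.items():
            edges.extend((lat, i) for i in inds)
        order: list[str] = []
        remaining = set(self.variables)
        incoming = {v: {s for s, t in edges if t == v} for v in remaining}
        while remaining:
            free = sorted(v for v in remaining if not (incoming[v] & remaining))
            if not free:
                raise ModelSpecError(
                    f"cycle detected among {sorted(remaining)}"
                )
            order.extend(free)
            remaining -= set(free)
        return order

    def drop_path(self, source: str, target: str) -> "ModelSpec":
        paths = tuple(p for p in self.paths if p != (source, target))
        if len(paths) == len(self.paths):
            raise KeyError(f"no path {source} -> {target}")
        return ModelSpec(self.observed, dict(self.latents), paths, self.covariances)

    def drop_covariance(self, a: str, b: str) -> "ModelSpec":
        covs = tuple(
            c for c in self.covariances if frozenset(c) != frozenset((a, b))
        )
        if len(covs) == len(self.covariances):
            raise KeyError(f"no covariance {a} ~~ {b}")
        return ModelSpec(self.observed, dict(self.latents), self.paths, covs)

    def drop_variable(self, v: str) -> "ModelSpec":
        """Remove an observed structural variable with no incident paths."""
        if v not in self.observed:
            raise KeyError(f"{v!r} is not observed")
        if self.indicator_of(v) is not None:
            raise ModelSpecError(f"{v!r} is a latent indicator; cannot drop")
        if self.parents(v) or self.children(v):
            raise ModelSpecError(f"{v!r} still has incident paths")
        covs = tuple(c for c in self.covariances if v not in c)
        observed = tuple(o for o in self.observed if o != v)
        return ModelSpec(observed, dict(self.latents), self.paths, covs)


@dataclass(frozen=True)
class RamSystem:
    """RAM matrices with a free-parameter slot map.

    ``slots[k]`` names the matrix ("A" or "S") and (row, col) written by free
    parameter k; symmetric S slots also write the mirror element.  ``labels``
    are human-readable parameter names ("TSK→Nmass", "load(LS)", "var(MAP)").
    Diagonal S slots are variance parameters (kept positive during fitting).
    """

    spec: ModelSpec
    variables: tuple[str, ...]
    fixed_a: dict[tuple[int, int], float]
    slots: tuple[tuple[str, int, int], ...]
    labels: tuple[str, ...]
    n_observed: int

    @property
    def n_free(self) -> int:
        return len(self.slots)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    def filter_matrix(self) -> np.ndarray:
        f = np.zeros((self.n_observed, self.n_vars))
        f[np.arange(self.n_observed), np.arange(self.n_observed)] = 1.0
        return f

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Assemble (A, S) from a free-parameter vector."""
        nv = self.n_vars
        a = np.zeros((nv, nv))
        s = np.zeros((nv, nv))
        for (i, j), v in self.fixed_a.items():
            a[i, j] = v
        for k, (mat, i, j) in enumerate(self.slots):
            if mat == "A":
                a[i, j] = theta[k]
            else:
                s[i, j] = theta[k]
                s[j, i] = theta[k]
        return a, s

    def is_variance(self) -> np.ndarray:
        """Boolean mask of diagonal-S (variance) slots."""
        return np.array(
            [mat == "S" and i == j for mat, i, j in self.slots], dtype=bool
        )

    def extract(self, a: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Read the free-parameter vector back out of (A, S) — round trip."""
        out = np.empty(self.n_free)
        for k, (mat, i, j) in enumerate(self.slots):
            out[k] = a[i, j] if mat == "A" else s[i, j]
        return out


def build_ram(spec: ModelSpec) -> RamSystem:
    """Lay out free-parameter slots for a model.

    One A slot per path and per non-anchor loading; one diagonal S slot per
    variable; one off-diagonal S slot per free covariance.
    """
    variables = spec.variables
    idx = {v: i for i, v in enumerate(variables)}
    fixed_a: dict[tuple[int, int], float] = {}
    slots: list[tuple[str, int, int]] = []
    labels: list[str] = []
    for lat, inds in spec.latents.items():
        fixed_a[(idx[inds[0]], idx[lat])] = 1.0
        for ind in inds[1:]:
            slots.append(("A", idx[ind], idx[lat]))
            labels.append(f"load({ind})")
    for s, t in spec.paths:
        slots.append(("A", idx[t], idx[s]))
        labels.append(f"{s}→{t}")
    for a, b in spec.covariances:
        slots.append(("S", idx[a], idx[b]))
        labels.append(f"cov({a},{b})")
    endo = set(spec.endogenous())
    for v in variables:
        slots.append(("S", idx[v], idx[v]))
        labels.append(f"var(e{v})" if v in endo else f"var({v})")
    return RamSystem(
        spec=spec,
        variables=variables,
        fixed_a=fixed_a,
        slots=tuple(slots),
        labels=tuple(labels),
        n_observed=len(spec.observed),
    )


def count_df(spec: ModelSpec) -> int:
    """Model degrees of freedom: p(p+1)/2 distinct moments minus free params."""
    p = len(spec.observed)
    t = build_ram(spec).n_free
    df = p * (p + 1) // 2 - t
    if df < 0:
        warnings.warn(
            f"model is under-identified: {t} free parameters for "
            f"{p * (p + 1) // 2} moments (df={df})",
            stacklevel=2,
        )
    return df


# ---------------------------------------------------------------------------
# model-text grammar


def parse_model_spec(text: str) -> ModelSpec:
    """Parse the line-oriented model grammar.

    Lines (``#`` starts a comment)::

        latent <L>: <ind1> <ind2> ...
        path <X> -> <Y>
        cov <X> ~~ <Y>

    Observed variables are every name that is not declared latent.
    """
    latents: dict[str, tuple[str, ...]] = {}
    paths: list[tuple[str, str]] = []
    covs: list[tuple[str, str]] = []
    mentioned: list[str] = []

    def note(*names: str) -> None:
        for nm in names:
            if nm not in mentioned:
                mentioned.append(nm)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        kw = tokens[0]
        try:
            if kw == "latent":
                rest = line[len("latent"):].strip()
                if ":" not in rest:
                    raise ModelSpecError("expected 'latent <name>: <indicators>'")
                name, inds_s = rest.split(":", 1)
                name = name.strip()
                inds = tuple(inds_s.split())
                if not name or not inds:
                    raise ModelSpecError("latent needs a name and indicators")
                if name in latents:
                    raise ModelSpecError(f"latent {name!r} declared twice")
                latents[name] = inds
                note(*inds)
            elif kw == "path":
                if len(tokens) != 4 or tokens[2] != "->":
                    raise ModelSpecError("expected 'path <X> -> <Y>'")
                paths.append((tokens[1], tokens[3]))
                note(tokens[1], tokens[3])
            elif kw == "cov":
                if len(tokens) != 4 or tokens[2] != "~~":
                    raise ModelSpecError("expected 'cov <X> ~~ <Y>'")
                covs.append((tokens[1], tokens[3]))
                note(tokens[1], tokens[3])
            else:
                raise ModelSpecError(f"unknown directive {kw!r}")
        except ModelSpecError as err:
            raise ModelSpecError(f"line {lineno}: {err}") from None
    observed = tuple(v for v in mentioned if v not in latents)
    return ModelSpec(observed, latents, tuple(paths), tuple(covs))


def format_model_spec(spec: ModelSpec) -> str:
    """Serialise a ModelSpec back to the model-text grammar."""
    lines = []
    for lat, inds in spec.latents.items():
        lines.append(f"latent {lat}: {' '.join(inds)}")
    for s, t in spec.paths:
        lines.append(f"path {s} -> {t}")
    for a, b in spec.covariances:
        lines.append(f"cov {a} ~~ {b}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# built-in model fixtures for the oak foliar-nitrogen study


def _load_model_text(name: str) -> ModelSpec:
    text = (
        resources.files("traitsem").joinpath(f"data/models/{name}.txt").read_text()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # two-indicator latents are deliberate
        return parse_model_spec(text)


def model_library() -> dict[str, ModelSpec]:
    """Named model fixtures of the oak foliar-nitrogen study.

    ``nmass_final``/``narea_final`` are the selected structures for mass- and
    area-based leaf N; ``prior_nmass``/``prior_narea`` are the reconstructed
    full starting models (all hypothesised climate/soil/morphology pathways,
    latent measured by SLA, LS and LDW, correlated climate and correlated
    soil-nutrient residuals) used as the stepwise-search starting point.
    """
    return {
        name: _load_model_text(name)
        for name in ("nmass_final", "narea_final", "prior_nmass", "prior_narea")
    }
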