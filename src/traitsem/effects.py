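"""Direct, indirect and total standardized effect decomposition.

For a recursive system with standardized coefficient matrix ``A*``
(``A*[i, j]`` the path ``j -> i``), the total-effect matrix is
``T = (I - A*)^-1 - I``: entry ``T[i, j]`` sums the products of coefficients
over every directed chain from ``j`` to ``i``.  Direct effects are the
entries of ``A*`` itself and indirect effects the difference, so
``total = direct + indirect`` holds identically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import FitResult
from .model import ModelSpec

__all__ = ["total_effects", "enumerate_paths", "chain_sum", "effect_table"]


def total_effects(fit: FitResult) -> pd.DataFrame:
    """Total standardized effects over all variables (observed + latent)."""
    nv = fit.ram.n_vars
    t = np.linalg.inv(np.eye(nv) - fit.a_std) - np.eye(nv)
    names = fit.ram.variables
    return pd.DataFrame(t, index=names, columns=names)


def enumerate_paths(
    spec: ModelSpec, source: str, target: str
) -> list[list[str]]:
    """All simple directed chains source -> ... -> target.

    Edges are structural paths plus latent -> indicator loadings, mirroring
    the coefficient matrix the total-effect identity operates on.
    """
    edges: dict[str, list[str]] = {v: [] for v in spec.variables}
    for s, t in spec.paths:
        edges[s].append(t)
    for lat, inds in spec.latents.items():
        edges[lat].extend(inds)
    for v in (source, target):
        if v not in edges:
            raise KeyError(f"unknown variable {v!r}")
    chains: list[list[str]] = []

    def walk(node: str, trail: list[str]) -> None:
        if node == target:
            chains.append(trail.copy())
            return
        for nxt in edges[node]:
            if nxt not in trail:
                trail.append(nxt)
                walk(nxt, trail)
                trail.pop()

    walk(source, [source])
    return sorted(chains)


def chain_sum(fit: FitResult, source: str, target: str) -> float:
    """Brute-force total effect: sum over chains of coefficient products."""
    idx = {v: i for i, v in enumerate(fit.ram.variables)}
    total = 0.0
    for chain in enumerate_paths(fit.spec, source, target):
        prod = 1.0
        for a, b in zip(chain, chain[1:]):
            prod *= fit.a_std[idx[b], idx[a]]
        total += prod
    return total


def effect_table(
    fit: FitResult,
    sources: list[str] | None = None,
    targets: list[str] | None = None,
) -> pd.DataFrame:
    """Direct/indirect/total standardized effects for requested pairs.

    Defaults to every ordered pair with a directed route.  Significance is
    attached only to direct effects (from the fitted path's p-value); the
    sampling distribution of composite effects is not computed.
    """
    names = list(fit.ram.variables)
    explicit = sources is not None and targets is not None
    sources = names if sources is None else list(sources)
    targets = names if targets is None else list(targets)
    for v in sources + targets:
        if v not in names:
            raise KeyError(f"unknown variable {v!r}")
    if explicit:
        overlap = sorted(set(sources) & set(targets))
        if overlap:
            raise ValueError(f"source equals target for {overlap}")
    idx = {v: i for i, v in enumerate(names)}
    t_mat = total_effects(fit).to_numpy()
    p_direct = _direct_pvalues(fit)
    rows = []
    for s in sources:
        for t in targets:
            if s == t:
                continue
            tot = t_mat[idx[t], idx[s]]
            direct = fit.a_std[idx[t], idx[s]]
            if tot == 0.0 and direct == 0.0:
                continue
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "direct": direct,
                    "indirect": tot - direct,
                    "total": tot,
                    "direct_p": p_direct.get((s, t), np.nan),
                }
            )
    return pd.DataFrame(
        rows, columns=["source", "target", "direct", "indirect", "total",
                       "direct_p"]
    )


def _direct_pvalues(fit: FitResult) -> dict[tuple[str, str], float]:
    if fit.p_params is None:
        return {}
    out = {}
    for k, label in enumerate(fit.ram.labels):
        if "→" in label:
            s, t = label.split("→")
            out[(s, t)] = float(fit.p_params[k])
    return out
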