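"""Partition each endogenous variable's explained variance among shock groups.

In the standardized system every variable is a linear combination of
independent shocks (exogenous variables and disturbances):
``x = (I - A*)^-1 u`` with ``cov(u) = S*``.  The variance of a target ``v``
therefore splits exactly into quadratic forms of its row of
``(I - A*)^-1`` over groups of shocks, provided shocks in different groups
are uncorrelated.  Within-group covariances (here the residual covariance of
the two soil nutrients) stay inside their group's share.  Shares are
reported in percent; together with the target's own disturbance they sum to
100, and the grouped (non-self) shares sum to 100 * R^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fit import FitResult

__all__ = ["SourceGroups", "default_groups", "partition_r2", "partition_all"]

_ZERO = 1e-12


class SourceGroups(dict):
    """Ordered mapping group label -> tuple of variable names.

    A variable's name stands for its shock: its exogenous variance if it has
    no parents, its disturbance otherwise.
    """

    def __init__(self, groups: dict[str, tuple[str, ...]]):
        super().__init__({k: tuple(v) for k, v in groups.items()})
        seen: set[str] = set()
        for label, members in self.items():
            dup = seen & set(members)
            if dup:
                raise ValueError(f"group {label!r} overlaps others: {sorted(dup)}")
            seen.update(members)


def default_groups(fit: FitResult) -> SourceGroups:
    """Study grouping: precipitation, pooled soil nutrients, latent morphology.

    Falls back to one singleton group per non-indicator variable for models
    without the study's variable names.
    """
    names = fit.ram.variables
    groups: dict[str, tuple[str, ...]] = {}
    if "MAP" in names:
        groups["MAP"] = ("MAP",)
    soil = tuple(v for v in ("TSN", "TSK", "TSP") if v in names)
    if soil:
        groups[" and ".join(soil)] = soil
    for lat in fit.spec.latents:
        groups[lat] = (lat,)
    covered = {v for g in groups.values() for v in g}
    for v in names:
        if v in covered or fit.spec.indicator_of(v) is not None:
            continue
        if v in ("Nmass", "Narea"):
            continue  # outcomes partition over the others
        groups.setdefault(v, (v,))
    return SourceGroups(groups)


def _sources_of(fit: FitResult, target: str) -> set[str]:
    """Shocks with a nonzero route into ``target`` (excluding its own)."""
    nv = fit.ram.n_vars
    b = np.linalg.inv(np.eye(nv) - fit.a_std)
    idx = {v: i for i, v in enumerate(fit.ram.variables)}
    row = b[idx[target]]
    return {
        v for v, i in idx.items() if v != target and abs(row[i]) > 1e-10
    }


def partition_r2(
    fit: FitResult, groups: SourceGroups, target: str
) -> dict[str, float]:
    """Percent of ``target``'s variance contributed by each shock group.

    Raises if the groups fail to cover every shock feeding the target, or if
    shocks from different groups are correlated (the decomposition would no
    longer be additive).
    """
    names = fit.ram.variables
    if target not in names:
        raise KeyError(f"unknown variable {target!r}")
    idx = {v: i for i, v in enumerate(names)}
    sources = _sources_of(fit, target)
    covered = {v for g in groups.values() for v in g}
    orphans = sorted(sources - covered)
    if orphans:
        raise ValueError(
            f"groups do not cover all variance sources of {target!r}: {orphans}"
        )
    nv = len(names)
    b = np.linalg.inv(np.eye(nv) - fit.a_std)
    row = b[idx[target]]
    s_std = fit.s_std
    # additivity requires cross-group shock covariances to vanish
    labels = list(groups)
    for a in range(len(labels)):
        for c in range(a + 1, len(labels)):
            ga = [idx[v] for v in groups[labels[a]] if v in sources]
            gc = [idx[v] for v in groups[labels[c]] if v in sources]
            if ga and gc and np.abs(s_std[np.ix_(ga, gc)]).max() > 1e-10:
                raise ValueError(
                    f"shock covariance across groups {labels[a]!r} and "
                    f"{labels[c]!r} breaks additivity"
                )
    out: dict[str, float] = {}
    for label, members in groups.items():
        g = [idx[v] for v in members if v != target]
        if not g or not (set(members) & sources):
            out[label] = float("nan")  # group not a source of this target
            continue
        contrib = row[g] @ s_std[np.ix_(g, g)] @ row[g]
        out[label] = 100.0 * float(contrib)
    return out


def partition_all(
    fit: FitResult, groups: SourceGroups | None = None
) -> pd.DataFrame:
    """Variance-partition table over all endogenous structural variables.

    Rows are endogenous variables that are not pure latent indicators;
    columns the groups plus the total explained percentage (= 100 R^2).
    """
    if groups is None:
        groups = default_groups(fit)
    targets = [
        v for v in fit.spec.endogenous() if fit.spec.indicator_of(v) is None
    ]
    rows = {}
    r2 = fit.r2
    for v in targets:
        shares = partition_r2(fit, groups, v)
        shares["total"] = 100.0 * r2[v]
        rows[v] = shares
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "variable"
    return table
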