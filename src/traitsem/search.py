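"""AIC-guided backward simplification from a full prior model.

Starting from the full hypothesised structure, each step tentatively drops
one structural path or one free residual covariance (never a loading), fits
every candidate, and accepts the drop with the lowest AIC (chi2 + 2t) if it
improves on the current model; ties break lexicographically by action label
so the search is deterministic.  After an accepted drop, observed structural
variables that no longer carry any outgoing path (and are not the outcome or
an indicator) are marginalised out of the model and the moment matrix — a
variable that neither sends paths anywhere relevant nor receives attention
from the outcome contributes nothing to the outcome's structure, which is
how "not included in the model" is operationalised here.  Variable removal
changes the observed set, so the AIC sequence restarts (logged as
non-comparable) at that point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .fit import FitError, FitResult, fit_ml
from .model import ModelSpec, format_model_spec
from .trait_io import CorrMatrix

__all__ = ["SearchStep", "SearchTrace", "stepwise_prune", "compare_aic"]


@dataclass(frozen=True)
class SearchStep:
    spec: ModelSpec
    chi2: float
    df: int
    aic: float
    action: str  # "start", "drop path X->Y", "drop cov X~~Y", "remove X"
    comparable: bool  # AIC comparable with the previous step


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)
    removed_variables: list[str] = field(default_factory=list)

    @property
    def final(self) -> ModelSpec:
        return self.steps[-1].spec

    def actions(self) -> list[str]:
        return [s.action for s in self.steps[1:]]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "action": s.action,
                    "chi2": s.chi2,
                    "df": s.df,
                    "aic": s.aic,
                    "aic_comparable": s.comparable,
                    "model": format_model_spec(s.spec),
                }
                for s in self.steps
            ],
            indent=2,
        )


def compare_aic(a: FitResult, b: FitResult) -> tuple[FitResult, float, bool]:
    """Lower-AIC fit, the AIC difference (a - b), and comparability.

    AICs are comparable only when both fits model the same observed
    variables; otherwise the preference is still returned but flagged.
    """
    comparable = set(a.spec.observed) == set(b.spec.observed)
    if not comparable:
        warnings.warn(
            "AIC compared across different observed-variable sets",
            stacklevel=2,
        )
    delta = a.aic - b.aic
    return (a if delta <= 0 else b), delta, comparable


def _droppable(spec: ModelSpec) -> list[tuple[str, ModelSpec]]:
    candidates: list[tuple[str, ModelSpec]] = []
    for s, t in sorted(spec.paths):
        candidates.append(
            (f"drop path {s}->{t}", spec.drop_path(s, t))
        )
    for a, b in sorted(tuple(sorted(c)) for c in spec.covariances):
        candidates.append((f"drop cov {a}~~{b}", spec.drop_covariance(a, b)))
    return candidates


def _marginalise_dead_ends(
    spec: ModelSpec, outcome: str
) -> tuple[ModelSpec, list[str]]:
    """Repeatedly remove observed structural variables with no outgoing paths."""
    removed: list[str] = []
    changed = True
    while changed:
        changed = False
        for v in spec.observed:
            if v == outcome or spec.indicator_of(v) is not None:
                continue
            if spec.children(v):
                continue
            for parent in spec.parents(v):
                spec = spec.drop_path(parent, v)
            spec = spec.drop_variable(v)
            removed.append(v)
            changed = True
            break
    return spec, removed


def stepwise_prune(
    prior: ModelSpec,
    moments: CorrMatrix,
    outcome: str | None = None,
    n_restarts: int = 2,
    seed: int = 0,
) -> SearchTrace:
    """Backward AIC search from ``prior`` on a moment matrix.

    ``outcome`` (default: the unique structural sink of the prior) is
    protected from removal.  Candidate fits that fail to converge are
    skipped with a warning.  Deterministic for fixed seed and inputs.
    """
    if outcome is None:
        sinks = [
            v
            for v in prior.variables
            if not prior.children(v)
            and prior.indicator_of(v) is None
            and prior.parents(v)
        ]
        if len(sinks) != 1:
            raise ValueError(
                f"cannot infer the outcome variable (sinks: {sinks}); "
                "pass outcome= explicitly"
            )
        outcome = sinks[0]

    def _fit(spec: ModelSpec) -> FitResult:
        return fit_ml(
            spec, moments, n_restarts=n_restarts, seed=seed, compute_se=False
        )

    trace = SearchTrace()
    current_spec, removed = _marginalise_dead_ends(prior, outcome)
    trace.removed_variables.extend(removed)
    current = _fit(current_spec)
    if not current.converged:
        raise FitError("prior model did not converge")
    trace.steps.append(
        SearchStep(current_spec, current.chi2, current.df, current.aic,
                   "start", True)
    )
    while True:
        best_action: str | None = None
        best_fit: FitResult | None = None
        for action, candidate in _droppable(current.spec):
            try:
                cand_fit = _fit(candidate)
            except FitError as err:
                warnings.warn(f"{action}: fit failed ({err})", stacklevel=2)
                continue
            if not cand_fit.converged:
                warnings.warn(f"{action}: did not converge; skipped",
                              stacklevel=2)
                continue
            if cand_fit.aic < current.aic - 1e-9 and (
                best_fit is None or cand_fit.aic < best_fit.aic - 1e-9
            ):
                best_action, best_fit = action, cand_fit
        if best_fit is None:
            break
        pruned, removed = _marginalise_dead_ends(best_fit.spec, outcome)
        if removed:
            trace.removed_variables.extend(removed)
            refit = _fit(pruned)
            trace.steps.append(
                SearchStep(best_fit.spec, best_fit.chi2, best_fit.df,
                           best_fit.aic, best_action, True)
            )
            trace.steps.append(
                SearchStep(pruned, refit.chi2, refit.df, refit.aic,
                           f"remove {', '.join(removed)}", False)
            )
            current = refit
        else:
            trace.steps.append(
                SearchStep(best_fit.spec, best_fit.chi2, best_fit.df,
                           best_fit.aic, best_action, True)
            )
            current = best_fit
    return trace
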