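"""Information criteria, parameter counting and forward covariate selection."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm_core import ModelSpec, count_parameters_dims, fit as fit_hmm
from .preprocess import CovariateSpec, standardize_covariates


def count_parameters(spec: ModelSpec) -> int:
    """Free parameter count: N(2*4 + 2) emission + N(N-1)(1+p) transition.

    The initial distribution follows the stationary-at-entry rule and adds
    no parameters.
    """
    return count_parameters_dims(spec.n_states, spec.n_design)


def aic(loglik: float, k: int) -> float:
    return -2.0 * loglik + 2.0 * k


def bic(loglik: float, k: int, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


@dataclass
class SelectionStep:
    """One forward-selection step: every candidate evaluated, one chosen."""

    step: int
    candidates: dict = field(default_factory=dict)  # name -> model record
    chosen: str | None = None


@dataclass
class SelectionPath:
    criterion: str
    steps: list = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return [s.chosen for s in self.steps if s.chosen is not None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for name, rec in s.candidates.items():
                rows.append({"step": s.step, "model": name, **rec,
                             "chosen": name == s.chosen})
        df = pd.DataFrame(rows)
        if not df.empty and "criterion_value" in df:
            best = df.loc[df["chosen"], "criterion_value"].min()
            df["delta"] = df["criterion_value"] - best
        return df


def forward_select(
    batches: pd.DataFrame,
    pool: CovariateSpec,
    criterion: str = "BIC",
    n_states: int = 3,
    fit_kwargs: dict | None = None,
    max_steps: int | None = None,
) -> SelectionPath:
    """Greedy forward selection of covariates into the transition model.

    Starts from the covariate-free baseline; at each step fits the current
    model plus each remaining candidate and adds the one minimizing the
    criterion, stopping when no candidate improves it.  Ties (criterion
    difference < 1e-6) go to the model with fewer parameters, then to the
    lexicographically smaller name.  Every evaluated model is recorded;
    candidates whose fit fails are skipped with a warning.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    fit_kwargs = dict(fit_kwargs or {})
    path = SelectionPath(criterion=criterion)

    def evaluate(chosen_names: list[str]) -> dict:
        cs = CovariateSpec([pool[name] for name in chosen_names])
        if cs.covariates:
            df, fitted_cs = standardize_covariates(batches, cs)
        else:
            df, fitted_cs = batches, cs
        spec = ModelSpec(n_states=n_states, covariate_spec=fitted_cs)
        fm = fit_hmm(spec, df, **fit_kwargs)
        rec = {
            "loglik": fm.loglik,
            "k": fm.k,
            "n": fm.n_batches,
            "aic": aic(fm.loglik, fm.k),
            "bic": bic(fm.loglik, fm.k, fm.n_batches),
        }
        rec["criterion_value"] = rec[criterion.lower()]
        return rec

    base = evaluate([])
    path.steps.append(SelectionStep(step=0, candidates={"baseline": base}, chosen="baseline"))
    best_value = base["criterion_value"]
    chosen: list[str] = []
    remaining = [c.name for c in pool.covariates]
    step_no = 0
    while remaining and (max_steps is None or step_no < max_steps):
        step_no += 1
        step = SelectionStep(step=step_no)
        results = {}
        for name in sorted(remaining):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rec = evaluate(chosen + [name])
            except Exception as exc:  # recorded, not fatal
                warnings.warn(f"fit with candidate {name!r} failed: {exc}")
                step.candidates[f"+{name}"] = {"error": str(exc)}
                continue
            step.candidates[f"+{name}"] = rec
            results[name] = rec
        if not results:
            path.steps.append(step)
            break
        vmin = min(r["criterion_value"] for r in results.values())
        tied = [n for n, r in results.items() if r["criterion_value"] - vmin < 1e-6]
        winner = min(tied, key=lambda n: (results[n]["k"], n))
        if results[winner]["criterion_value"] < best_value - 1e-9:
            step.chosen = f"+{winner}"
            best_value = results[winner]["criterion_value"]
            chosen.append(winner)
            remaining.remove(winner)
            path.steps.append(step)
        else:
            path.steps.append(step)
            break
    return path
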