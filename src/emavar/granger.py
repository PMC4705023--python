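"""Granger-causality Wald tests and their cross-model aggregation.

Within one fitted model, variable x Granger-causes variable y when the
coefficients of x's lags in y's equation are jointly nonzero (Wald test,
chi-square reference with df = number of unconstrained cause-lag
coefficients). Across the ranked valid models of a search, each ordered
pair is summarized as a directed edge weighted by the proportion of valid
models in which the test is significant, together with a sign class
derived from the cause-lag coefficient signs:

* positive / negative — all unconstrained cause-lag coefficients share
  that sign in every contributing model;
* mixed_within — signs differ across lags inside a model;
* mixed_across — contributing models disagree with each other.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .var_engine import VarFit

__all__ = ["GrangerEdge", "GrangerSummary", "granger_wald", "sign_classify", "summarize"]


@dataclass(frozen=True)
class GrangerEdge:
    cause: str
    effect: str
    proportion: float
    sign_class: str
    best_model_p: float

    def to_dict(self) -> dict:
        return {
            "cause": self.cause,
            "effect": self.effect,
            "proportion": self.proportion,
            "sign_class": self.sign_class,
            "best_model_p": self.best_model_p,
        }


@dataclass(frozen=True)
class GrangerSummary:
    edges: tuple[GrangerEdge, ...]
    n_valid_models: int
    per_model: tuple[dict, ...] = ()

    @property
    def is_none(self) -> bool:
        return len(self.edges) == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_valid_models": self.n_valid_models,
                "edges": [e.to_dict() for e in self.edges],
                "per_model": list(self.per_model),
            },
            indent=2,
        )


def _cause_lag_labels(fit: VarFit, cause: str, effect: str) -> list[str]:
    labels = [f"L{lag}.{cause}" for lag in range(1, fit.spec.lag + 1)]
    return [lab for lab in labels if (effect, lab) not in fit.constraints]


def granger_wald(fit: VarFit, cause: str, effect: str) -> dict:
    """Wald test of the joint null that all of cause's unconstrained lag
    coefficients in effect's equation are zero.

    When every relevant coefficient is already constrained the null holds
    by construction: W=0, df=0, p=1, flagged ``all_constrained``.
    """
    if cause not in fit.variable_names or effect not in fit.variable_names:
        raise ValueError(f"{cause!r} or {effect!r} not endogenous in this fit")
    if cause == effect:
        raise ValueError("cause and effect must differ")
    free = _cause_lag_labels(fit, cause, effect)
    if not free:
        return {"W": 0.0, "df": 0, "p": 1.0, "all_constrained": True}
    eq_labels, cov = fit.cov_params[effect]
    idx = [eq_labels.index(lab) for lab in free]
    b = fit.coefficients.loc[effect, free].to_numpy(dtype=float)
    sub = cov[np.ix_(idx, idx)]
    w = float(b @ np.linalg.solve(sub, b))
    df = len(free)
    return {"W": w, "df": df, "p": float(stats.chi2.sf(w, df)), "all_constrained": False}


def sign_classify(fit: VarFit, cause: str, effect: str) -> str:
    """Sign pattern of the unconstrained cause-lag coefficients in one model."""
    free = _cause_lag_labels(fit, cause, effect)
    if not free:
        raise ValueError("all cause-lag coefficients are constrained; no sign defined")
    signs = np.sign(fit.coefficients.loc[effect, free].to_numpy(dtype=float))
    if np.all(signs > 0):
        return "positive"
    if np.all(signs < 0):
        return "negative"
    return "mixed_within"


def summarize(valid_models: list, alpha: float = 0.05) -> GrangerSummary:
    """Aggregate per-model Granger tests over the ranked valid models.

    ``valid_models`` is the search output: (spec, fit, report) triples in
    criterion order, best first. Tests run on the pruned (final) fits —
    the models the search actually reports. The proportion's denominator
    is the full valid-model count; a fully-constrained pair simply counts
    as non-significant in that model.
    """
    edges: list[GrangerEdge] = []
    per_model: list[dict] = []
    if not valid_models:
        return GrangerSummary(edges=(), n_valid_models=0)
    names = valid_models[0][1].variable_names
    tests: dict[tuple[str, str], list[tuple[int, dict, str]]] = {}
    for rank, (_spec, fit, _report) in enumerate(valid_models):
        detail = {"rank": rank + 1, "spec": _spec.describe(), "tests": {}}
        for cause in names:
            for effect in names:
                if cause == effect:
                    continue
                res = granger_wald(fit, cause, effect)
                sign = (
                    None
                    if res["all_constrained"]
                    else sign_classify(fit, cause, effect)
                )
                detail["tests"][f"{cause}->{effect}"] = {**res, "sign": sign}
                tests.setdefault((cause, effect), []).append((rank, res, sign))
        per_model.append(detail)
    n = len(valid_models)
    for cause in names:
        for effect in names:
            if cause == effect:
                continue
            entries = tests[(cause, effect)]
            significant = [(r, res, s) for r, res, s in entries if res["p"] < alpha]
            if not significant:
                continue
            signs = {s for _, _, s in significant}
            sign_class = signs.pop() if len(signs) == 1 else "mixed_across"
            best = min(significant, key=lambda e: e[0])
            edges.append(
                GrangerEdge(
                    cause=cause,
                    effect=effect,
                    proportion=len(significant) / n,
                    sign_class=sign_class,
                    best_model_p=float(best[1]["p"]),
                )
            )
    return GrangerSummary(edges=tuple(edges), n_valid_models=n, per_model=tuple(per_model))
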