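"""Exhaustive, redundancy-pruned search over candidate VAR structures.

The search space is the Cartesian product of lag order (1..max_lag),
weekday dummies (only when timestamps are enabled and dates exist), log
transformation, and a per-variable outlier-dummy severity level (none,
3.5, 3.0 and optionally 2.5 residual SDs). The trend flag is decided from
the data before enumeration (Phillips-Perron per variable) and therefore
does not multiply the space.

Candidates are visited simplest-first. A candidate is *redundant* — skipped,
not fitted — when an already-valid tested spec shares its lag/weekday/log/
trend factors and has a weaker-or-equal outlier configuration: escalation to
heavier outlier dummying happens only where simpler structures failed the
validity gate. Each non-redundant spec is materialized, fitted, pruned under
the chosen information criterion and passed through the four-test validity
gate; valid models are ranked ascending by criterion.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, replace

from .data_io import EmaDataset, RunConfig
from .diagnostics import trend_needed, validity_report
from .granger import GrangerSummary, summarize
from .spec_builder import OUTLIER_LEVELS, ModelSpec, detect_outliers, dominates, materialize
from .var_engine import CollinearityError, DegenerateFitError, fit_var, prune_parameters

__all__ = ["SearchResult", "enumerate_space", "is_redundant", "run_search"]

log = logging.getLogger("emavar.search")


@dataclass(frozen=True)
class SearchResult:
    enumerated: int
    tested: int
    skipped_redundant: int
    valid_models: tuple  # (ModelSpec, VarFit, ValidityReport), criterion order
    criterion_used: str
    records: tuple  # one bookkeeping dict per enumerated spec, in visit order
    trend_included: bool
    granger: GrangerSummary | None = None

    @property
    def tested_percentage(self) -> float:
        return 100.0 * self.tested / self.enumerated if self.enumerated else 0.0

    def to_json(self) -> str:
        payload = {
            "enumerated": self.enumerated,
            "tested": self.tested,
            "skipped_redundant": self.skipped_redundant,
            "criterion": self.criterion_used,
            "trend_included": self.trend_included,
            "records": list(self.records),
            "valid_models": [
                {
                    "rank": i + 1,
                    "spec": spec.describe(),
                    "k": fit.k,
                    "logL": fit.logL,
                    "AIC": fit.aic,
                    "BIC": fit.bic,
                }
                for i, (spec, fit, _rep) in enumerate(self.valid_models)
            ],
        }
        return json.dumps(payload, indent=2)


def enumerate_space(dataset: EmaDataset, config: RunConfig, trend: bool = False) -> list[ModelSpec]:
    """All candidate specs, ordered simplest-first.

    Order: ascending lag, weekday off before on, log off before on, then
    per-variable outlier severity lexicographically (a linear extension of
    the complexity partial order, so every spec is visited after anything
    that could make it redundant).
    """
    V = len(dataset.variable_names)
    weekday_options = [False]
    if config.timestamps_enabled and dataset.dates is not None:
        weekday_options.append(True)
    levels = OUTLIER_LEVELS if config.allow_25_sd else OUTLIER_LEVELS[:3]
    specs = []
    for lag in range(1, config.max_lag + 1):
        for weekday in weekday_options:
            for log_flag in (False, True):
                for combo in itertools.product(levels, repeat=V):
                    specs.append(
                        ModelSpec(
                            lag=lag,
                            weekday=weekday,
                            log_transform=log_flag,
                            outlier_levels=combo,
                            trend=trend,
                            user_exogenous=tuple(config.exogenous_selection),
                        )
                    )
    return specs


def is_redundant(spec: ModelSpec, valid_so_far: list[ModelSpec]) -> tuple[bool, ModelSpec | None]:
    """Whether an already-valid simpler spec makes this candidate redundant."""
    for valid in valid_so_far:
        if dominates(valid, spec):
            return True, valid
    return False, None


def _resolve_outliers(dataset: EmaDataset, spec: ModelSpec, base_cache: dict) -> ModelSpec:
    """Fill in the outlier day indices from the escalation base's residuals.

    Days are detected on the residuals of the *same* spec with outlier
    level none (single pass; no re-detection after pruning), so detection
    is deterministic within each spec family.
    """
    if all(lv is None for lv in spec.outlier_levels):
        return replace(spec, outlier_days=((),) * len(spec.outlier_levels))
    key = (spec.lag, spec.weekday, spec.log_transform)
    if key not in base_cache:
        base = spec.base
        base_cache[key] = fit_var(materialize(dataset, base), base)
    base_fit = base_cache[key]
    days = []
    for var, level in zip(dataset.variable_names, spec.outlier_levels):
        if level is None:
            days.append(())
        else:
            e = base_fit.residuals[var].to_numpy()
            days.append(detect_outliers(e, level, lag_offset=spec.lag))
    return replace(spec, outlier_days=tuple(days))


def run_search(dataset: EmaDataset, config: RunConfig) -> SearchResult:
    """Run the full enumerate -> filter -> fit -> prune -> validate loop.

    Deterministic given dataset and config. Returns all bookkeeping: every
    enumerated spec is either tested (fitted, or recorded as infeasible)
    or skipped as redundant with its dominating spec recorded.
    """
    if config.selected_variables:
        dataset = dataset.select(config.selected_variables)
    if len(dataset.variable_names) < 2:
        raise ValueError("a Granger analysis run needs at least 2 endogenous variables")

    # trend decision precedes enumeration: one system-wide linear trend
    # column if any selected variable looks trend-stationary
    trend_flags = {
        name: trend_needed(dataset.values[name].to_numpy(), alpha=config.alpha)
        for name in dataset.variable_names
    }
    trend = any(res["include_trend"] for res in trend_flags.values())

    specs = enumerate_space(dataset, config, trend=trend)
    base_cache: dict = {}
    valid_specs: list[ModelSpec] = []
    valid_models = []
    records = []
    tested = 0
    skipped = 0
    for spec in specs:
        redundant, dominator = is_redundant(spec, valid_specs)
        if redundant:
            skipped += 1
            records.append(
                {
                    "spec": spec.describe(),
                    "status": "skipped_redundant",
                    "dominated_by": dominator.describe(),
                }
            )
            log.info("skipped (redundant): %s", spec.describe())
            continue
        tested += 1
        try:
            resolved = _resolve_outliers(dataset, spec, base_cache)
            mat = materialize(dataset, resolved)
            fit = fit_var(mat, resolved)
            fit = prune_parameters(mat, fit, config.criterion, config.alpha)
            report = validity_report(fit, config.alpha)
        except (ValueError, CollinearityError, DegenerateFitError) as exc:
            records.append(
                {"spec": spec.describe(), "status": "infeasible", "reason": str(exc)}
            )
            log.info("infeasible: %s (%s)", spec.describe(), exc)
            continue
        rec = {
            "spec": resolved.describe(),
            "status": "tested",
            "valid": report.overall_valid,
            "k": fit.k,
            "logL": fit.logL,
            "AIC": fit.aic,
            "BIC": fit.bic,
            "n_constraints": len(fit.constraints),
            "outlier_days": [list(d) for d in resolved.outlier_days],
            "failures": report.failures(),
            "stability_p": None,
            "max_eigenvalue_modulus": report.stability["max_eigenvalue_modulus"],
            "white_noise_p": {v: r["p"] for v, r in report.white_noise.items()},
            "homoscedasticity_p": {v: r["p"] for v, r in report.homoscedasticity.items()},
            "normality_p": {v: r["p"] for v, r in report.normality.items()},
        }
        records.append(rec)
        log.info(
            "tested: %s -> %s", resolved.describe(), "valid" if report.overall_valid else "invalid"
        )
        if report.overall_valid:
            valid_specs.append(spec)  # domination compares severity levels
            valid_models.append((resolved, fit, report))

    crit = config.criterion
    ranked = tuple(
        sorted(
            valid_models,
            key=lambda item: (
                item[1].aic if crit == "AIC" else item[1].bic,
                item[1].k,
                valid_models.index(item),  # enumeration order breaks remaining ties
            ),
        )
    )
    for rank, (spec, _fit, _rep) in enumerate(ranked):
        for rec in records:
            if rec.get("status") == "tested" and rec["spec"] == spec.describe() and "rank" not in rec:
                rec["rank"] = rank + 1
                break
    result = SearchResult(
        enumerated=len(specs),
        tested=tested,
        skipped_redundant=skipped,
        valid_models=ranked,
        criterion_used=crit,
        records=tuple(records),
        trend_included=trend,
        granger=summarize(list(ranked), alpha=config.alpha),
    )
    assert result.tested + result.skipped_redundant == result.enumerated
    return result
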