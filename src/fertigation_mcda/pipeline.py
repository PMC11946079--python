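"""End-to-end evaluation: screening, weighting, scoring and ranking.

Orchestrates the full chain on a tidy trial table: aggregate replicates
-> screen indicators (Spearman correlations + user stability flags) ->
entropy weights (per category and/or across all indicators) ->
composite scores -> virtual-ideal TOPSIS ranking. Deterministic for a
given dataset and configuration.

The evaluation model groups indicators into three dimensions — yield,
quality (hardness, vitamin C, soluble protein, lycopene, titratable
acidity, soluble sugars, nitrate, soluble solids, moisture) and
efficiency (WUE, PFP) — mirroring how designed fertigation trials are
usually scored.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import Treatment, input_reduction, packaged_treatment_table, range_analysis
from .entropy import EntropyResult, IndicatorMatrix, entropy_evaluate
from .synthetic import SyntheticTrial, aggregate_replicates
from .topsis import TopsisResult, normalize_matrix, topsis_rank

__all__ = [
    "EvaluationModel",
    "RunReport",
    "default_evaluation_model",
    "spearman_matrix",
    "screen_indicators",
    "run_evaluation",
]

Direction = Literal["benefit", "cost"]

#: Default directions for the standard indicator panel: fruit hardness,
#: titratable acidity and nitrate content count against a treatment.
DEFAULT_DIRECTIONS: dict[str, Direction] = {
    "yield": "benefit",
    "Hd": "cost",
    "VC": "benefit",
    "SP": "benefit",
    "LC": "benefit",
    "TA": "cost",
    "SS": "benefit",
    "NA": "cost",
    "SSC": "benefit",
    "MC": "benefit",
    "WUE": "benefit",
    "PFP": "benefit",
}

DEFAULT_CATEGORIES: dict[str, str] = {
    "yield": "yield",
    "Hd": "quality",
    "VC": "quality",
    "SP": "quality",
    "LC": "quality",
    "TA": "quality",
    "SS": "quality",
    "NA": "quality",
    "SSC": "quality",
    "MC": "quality",
    "WUE": "efficiency",
    "PFP": "efficiency",
}


@dataclass(frozen=True)
class EvaluationModel:
    """Which indicators enter the evaluation, with direction and category."""

    directions: Mapping[str, Direction]
    categories: Mapping[str, str]
    included: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        included = self.included or tuple(self.directions)
        object.__setattr__(self, "included", tuple(included))
        for ind in self.included:
            if ind not in self.directions or ind not in self.categories:
                raise ValueError(f"indicator {ind!r} lacks direction or category metadata")
        by_cat: dict[str, int] = {}
        for ind in self.included:
            by_cat[self.categories[ind]] = by_cat.get(self.categories[ind], 0) + 1
        if not by_cat:
            raise ValueError("evaluation model includes no indicators")
        for cat, n in by_cat.items():
            if n < 1:
                raise ValueError(f"category {cat!r} has no indicators")

    @property
    def category_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ind in self.included:
            cat = self.categories[ind]
            if cat not in seen:
                seen.append(cat)
        return tuple(seen)

    def indicators_in(self, category: str) -> list[str]:
        return [i for i in self.included if self.categories[i] == category]


def default_evaluation_model() -> EvaluationModel:
    return EvaluationModel(directions=DEFAULT_DIRECTIONS, categories=DEFAULT_CATEGORIES)


def spearman_matrix(X: IndicatorMatrix | pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Spearman rank correlations (average-rank ties).

    Constant indicators have undefined rank correlation; they are
    excluded from the matrix and reported in the second return value.
    """
    values = X.values if isinstance(X, IndicatorMatrix) else X
    if values.shape[0] < 3:
        raise ValueError("need at least 3 alternatives for rank correlation")
    constant = [c for c in values.columns if values[c].nunique() == 1]
    kept = values.drop(columns=constant)
    if kept.shape[1] < 2:
        raise ValueError("fewer than 2 non-constant indicators")
    rho, _ = stats.spearmanr(kept.to_numpy())
    rho = np.asarray(rho)
    if rho.ndim == 0:  # scipy collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=kept.columns, columns=kept.columns), constant


def screen_indicators(
    model: EvaluationModel,
    unstable: Iterable[str] = (),
) -> EvaluationModel:
    """Drop user-flagged unstable indicators (advisory, config-driven).

    Removing every indicator of a category is refused — each evaluation
    dimension must stay represented.
    """
    drop = set(unstable)
    kept = tuple(i for i in model.included if i not in drop)
    for cat in model.category_names:
        if not any(model.categories[i] == cat for i in kept):
            raise ValueError(f"screening would empty category {cat!r}")
    return replace(model, included=kept)


@dataclass(frozen=True)
class RunReport:
    """Reproducible record of one full evaluation run."""

    inputs_digest: str
    config: dict
    model: EvaluationModel
    matrix: IndicatorMatrix
    screening: pd.DataFrame  # Spearman matrix
    constant_indicators: tuple[str, ...]
    category_results: dict[str, EntropyResult]
    category_scores: pd.DataFrame  # composite score per treatment per category
    global_result: EntropyResult | None
    topsis: TopsisResult
    range_tables: dict[str, pd.DataFrame]
    reductions: dict[str, float] | None
    warnings: tuple[str, ...]

    @property
    def ranking(self) -> tuple[str, ...]:
        return self.topsis.ranking

    @property
    def best_treatment(self) -> str:
        return self.topsis.best

    def summary(self) -> dict:
        """JSON-ready digest naming the top alternative and key tables."""
        return {
            "inputs_digest": self.inputs_digest,
            "config": self.config,
            "best_treatment": self.best_treatment,
            "ranking": list(self.ranking),
            "closeness": {str(k): float(v) for k, v in self.topsis.closeness.items()},
            "category_best": {
                cat: str(self.category_scores[cat].idxmax()) for cat in self.category_scores
            },
            "reductions": self.reductions,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _digest(records: pd.DataFrame) -> str:
    payload = records.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_evaluation(
    trial: SyntheticTrial | pd.DataFrame,
    model: EvaluationModel | None = None,
    unstable: Iterable[str] = (),
    mode: Literal["category", "global", "both"] = "both",
    method: Literal["classical", "improved"] = "improved",
    k_coef: float = 1.0,
    delta: float = 0.01,
    alpha: float = 0.9,
    beta: float = 0.1,
    treatments: list[Treatment] | None = None,
    reduction_pair: tuple[str, str] | None = ("T5", "T7"),
) -> RunReport:
    """Run the full evaluation chain and return a reproducible report.

    ``trial`` is either a generated SyntheticTrial or a tidy records
    table (year, treatment, replicate, indicator, value). Entropy
    weights are computed within each category, a single TOPSIS over all
    included indicators ranks the treatments (weights from the global
    entropy block when mode permits, otherwise category blocks scaled
    by their indicator share), and the water/fertilizer savings of
    ``reduction_pair`` (candidate, baseline) are reported from the
    treatment table.
    """
    warnings: list[str] = []
    if model is None:
        model = default_evaluation_model()
    if isinstance(trial, SyntheticTrial):
        records = trial.records
        matrix_full = aggregate_replicates(trial)
    else:
        records = trial
        required = {"year", "treatment", "replicate", "indicator", "value"}
        missing = required - set(records.columns)
        if missing:
            raise ValueError(f"aggregate stage: records missing columns {sorted(missing)}")
        if records["indicator"].isna().any():
            # the nitrate indicator is literally named "NA"; pandas eats it
            # unless the CSV was read with keep_default_na=False
            raise ValueError(
                "aggregate stage: NaN indicator names — if read from CSV, "
                "use keep_default_na=False so the 'NA' indicator survives"
            )
        yearly = records.groupby(["treatment", "indicator", "year"], sort=False)["value"].mean()
        mean = yearly.groupby(["treatment", "indicator"], sort=False).mean().unstack("indicator")
        matrix_full = IndicatorMatrix(
            values=mean,
            directions={c: model.directions.get(c, "benefit") for c in mean.columns},
            categories={c: model.categories.get(c, "quality") for c in mean.columns},
        )

    model = screen_indicators(model, unstable)
    present = [i for i in model.included if i in matrix_full.values.columns]
    absent = sorted(set(model.included) - set(present))
    if absent:
        warnings.append(f"indicators missing from data and skipped: {absent}")
    model = replace(model, included=tuple(present))
    matrix = matrix_full.subset(list(model.included))

    screening, constant = spearman_matrix(matrix)
    if constant:
        warnings.append(f"constant indicators excluded from correlation: {constant}")

    category_results: dict[str, EntropyResult] = {}
    cat_scores: dict[str, pd.Series] = {}
    for cat in model.category_names:
        cols = model.indicators_in(cat)
        if len(cols) == 1:
            # single-indicator category: the (shifted) share itself is the score
            from .entropy import direction_adjust, nonneg_shift, normalize_proportional

            sub = matrix.subset(cols)
            adjusted = direction_adjust(sub.values, sub.directions)
            Z = nonneg_shift(normalize_proportional(adjusted), delta)
            cat_scores[cat] = Z[cols[0]].rename("S")
            warnings.append(f"category {cat!r} has one indicator; weight fixed at 1")
        else:
            res = entropy_evaluate(matrix.subset(cols), method=method, k_coef=k_coef, delta=delta)
            category_results[cat] = res
            cat_scores[cat] = res.scores
    category_scores = pd.DataFrame(cat_scores)

    global_result: EntropyResult | None = None
    if mode in ("global", "both"):
        global_result = entropy_evaluate(matrix, method=method, k_coef=k_coef, delta=delta)
        topsis_weights = (
            global_result.weights_improved if method == "improved" else global_result.weights_classical
        )
    else:
        # category mode: block weights scaled by the category's indicator share
        parts = []
        for cat in model.category_names:
            cols = model.indicators_in(cat)
            if cat in category_results:
                res = category_results[cat]
                w = res.weights_improved if method == "improved" else res.weights_classical
            else:
                w = pd.Series(1.0, index=cols)
            parts.append(w * (len(cols) / len(model.included)))
        topsis_weights = pd.concat(parts).reindex(list(model.included))

    decision = normalize_matrix(matrix, weights=topsis_weights)
    topsis = topsis_rank(decision, alpha=alpha, beta=beta)

    range_tables: dict[str, pd.DataFrame] = {}
    if list(matrix.values.index) == [f"T{i}" for i in range(1, 10)]:
        from .design import build_l9_design

        design = build_l9_design()
        for ind in model.included:
            res = range_analysis(
                design, matrix.values[ind].to_numpy(), direction=model.directions[ind]
            )
            range_tables[ind] = res.to_frame()

    reductions = None
    if reduction_pair is not None:
        tt = treatments if treatments is not None else packaged_treatment_table()
        by_id = {t.id: t for t in tt}
        cand, base = reduction_pair
        if cand in by_id and base in by_id:
            reductions = input_reduction(by_id[cand], by_id[base])
        else:
            warnings.append(f"reduction pair {reduction_pair} not in treatment table")

    config = {
        "mode": mode,
        "method": method,
        "k_coef": k_coef,
        "delta": delta,
        "alpha": alpha,
        "beta": beta,
        "unstable": sorted(set(unstable)),
        "included": list(model.included),
        "reduction_pair": list(reduction_pair) if reduction_pair else None,
    }
    return RunReport(
        inputs_digest=_digest(records),
        config=config,
        model=model,
        matrix=matrix,
        screening=screening,
        constant_indicators=tuple(constant),
        category_results=category_results,
        category_scores=category_scores,
        global_result=global_result,
        topsis=topsis,
        range_tables=range_tables,
        reductions=reductions,
        warnings=tuple(warnings),
    )
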