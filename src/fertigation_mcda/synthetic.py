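"""Synthetic two-year orthogonal fertigation trials with known ground truth.

Emulates a completely randomized greenhouse trial: 9 treatments on an
L9(3^4) array, 3 replicate plots each, 2 seasons, 12 evaluation
indicators (yield; 9 fruit-quality measures; WUE and PFP). Each
additive indicator is generated as

    value = (baseline + sum_j effect_j(level_j) + year_offset) * (1 + CV * eps)

with eps standard normal, i.e. additive factor effects on the natural
scale and multiplicative Gaussian plot noise — this keeps strictly
positive indicators positive at plausible CVs (a resampling guard
catches the rare negative draw). WUE and PFP are not generated
independently: they are derived per plot from the generated yield and
the treatment's irrigation volume / season fertilizer total, so the
downstream efficiency equations hold identically.

Default magnitudes are plausible for greenhouse tomato and the default
factor-effect signs reflect the qualitative behaviour of deficit
fertigation trials (irrigation dominant, stage fertilizer secondary);
they are deliberately not calibrated to any measured dataset.

The configuration records its own ground truth: the optimal level of
every factor for every indicator, and the dominant treatment when one
exists — so recovery of known answers is testable end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .design import (
    FERTILIZER_LEVELS,
    OrthogonalDesign,
    build_l9_design,
)
from .entropy import IndicatorMatrix

__all__ = [
    "IndicatorSpec",
    "SyntheticTrialConfig",
    "SyntheticTrial",
    "default_config",
    "generate_trial",
    "aggregate_replicates",
    "make_dominant_scenario",
    "save_scenario",
    "load_scenario",
]

FACTOR_NAMES = ("IA", "FI", "FII", "FIII")

#: Seasonal irrigation volumes (m^3 ha^-1) per irrigation level per year,
#: matching the trial's metered deliveries at 50% / 75% / 100% ET_c.
DEFAULT_IRRIGATION_VOLUMES: dict[int, dict[int, float]] = {
    1: {2023: 1525.0, 2024: 1475.0},
    2: {2023: 2287.5, 2024: 2212.5},
    3: {2023: 3050.0, 2024: 2950.0},
}


@dataclass(frozen=True)
class IndicatorSpec:
    """Generation recipe for one indicator.

    ``effects[factor]`` is the additive contribution of each of the three
    levels (same units as ``baseline``). ``derived`` marks WUE/PFP-style
    indicators computed from yield instead of generated directly.
    """

    name: str
    baseline: float
    unit: str
    direction: Literal["benefit", "cost"]
    category: Literal["yield", "quality", "efficiency"]
    effects: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    year_offsets: Mapping[int, float] = field(default_factory=dict)
    cv: float = 0.05
    derived: Literal["wue", "pfp"] | None = None

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError(f"indicator {self.name!r}: baseline must be > 0")
        if self.cv < 0:
            raise ValueError(f"indicator {self.name!r}: CV must be >= 0")
        if self.derived is None:
            missing = set(FACTOR_NAMES) - set(self.effects)
            if missing:
                raise ValueError(f"indicator {self.name!r}: missing effects for {sorted(missing)}")
            for fac, eff in self.effects.items():
                if len(eff) != 3 or not np.isfinite(eff).all():
                    raise ValueError(f"indicator {self.name!r}: factor {fac} needs 3 finite effects")

    def optimal_levels(self) -> dict[str, int]:
        """Configured optimum per factor: argmax effect (benefit) / argmin (cost), 1-based."""
        if self.derived is not None:
            raise ValueError(f"indicator {self.name!r} is derived; optimum not configured directly")
        pick = np.argmax if self.direction == "benefit" else np.argmin
        return {fac: int(pick(np.asarray(self.effects[fac])) + 1) for fac in FACTOR_NAMES}


def _default_panel(cv: float = 0.05) -> tuple[IndicatorSpec, ...]:
    """12-indicator panel: yield, 9 quality measures, derived WUE and PFP."""

    def spec(name, baseline, unit, direction, category, ia, f1, f2, f3):
        return IndicatorSpec(
            name=name,
            baseline=baseline,
            unit=unit,
            direction=direction,
            category=category,
            effects={"IA": ia, "FI": f1, "FII": f2, "FIII": f3},
            year_offsets={2023: 0.01 * baseline, 2024: -0.01 * baseline},
            cv=cv,
        )

    return (
        spec("yield", 55000, "kg ha-1", "benefit", "yield",
             (-12000, -4000, 0), (0, -500, -1000), (-2500, -1200, 0), (-800, 0, -400)),
        spec("Hd", 6.0, "N", "cost", "quality",
             (0.7, 0.1, 0.0), (0.0, 0.05, 0.1), (0.15, 0.0, 0.05), (0.1, 0.05, 0.0)),
        spec("VC", 24.0, "mg 100g-1", "benefit", "quality",
             (-7.0, -1.2, 0.0), (-2.0, -1.0, 0.0), (-1.0, 0.0, -0.5), (-1.5, 0.0, -0.5)),
        spec("SP", 2.2, "mg g-1", "benefit", "quality",
             (-0.9, -0.3, 0.0), (0.0, -0.1, -0.2), (-0.4, -0.2, 0.0), (-0.2, 0.0, -0.1)),
        spec("LC", 8.5, "mg 100g-1", "benefit", "quality",
             (-3.0, 0.0, -0.7), (-0.5, 0.0, -0.3), (-0.8, -0.4, 0.0), (-0.5, 0.0, -0.2)),
        spec("TA", 0.45, "%", "cost", "quality",
             (0.15, 0.02, 0.0), (0.02, 0.01, 0.0), (0.0, 0.01, 0.03), (0.0, 0.02, 0.03)),
        spec("SS", 4.8, "%", "benefit", "quality",
             (-1.2, 0.0, -0.5), (0.0, -0.1, -0.3), (-0.5, -0.2, 0.0), (-0.4, 0.0, -0.1)),
        spec("NA", 140.0, "mg kg-1", "cost", "quality",
             (80.0, 15.0, 0.0), (0.0, 10.0, 25.0), (5.0, 0.0, 10.0), (0.0, 5.0, 12.0)),
        spec("SSC", 5.4, "%", "benefit", "quality",
             (-0.6, 0.0, -0.2), (0.0, -0.1, -0.2), (-0.2, 0.0, -0.1), (-0.3, 0.0, -0.1)),
        spec("MC", 93.5, "%", "benefit", "quality",
             (-2.5, -0.8, 0.0), (-0.3, -0.1, 0.0), (0.0, -0.1, -0.3), (-0.2, 0.0, -0.1)),
        IndicatorSpec("WUE", 20.0, "kg m-3", "benefit", "efficiency", cv=cv, derived="wue"),
        IndicatorSpec("PFP", 25.0, "kg kg-1", "benefit", "efficiency", cv=cv, derived="pfp"),
    )


@dataclass(frozen=True)
class SyntheticTrialConfig:
    """Full recipe for one simulated trial (seed included)."""

    seed: int
    indicators: tuple[IndicatorSpec, ...]
    years: tuple[int, ...] = (2023, 2024)
    replicates: int = 3
    design: OrthogonalDesign = field(default_factory=build_l9_design)
    irrigation_volumes: Mapping[int, Mapping[int, float]] = field(
        default_factory=lambda: DEFAULT_IRRIGATION_VOLUMES
    )
    fertilizer_levels: tuple[float, float, float] = FERTILIZER_LEVELS

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.years) < 1:
            raise ValueError("need at least one year")
        names = [s.name for s in self.indicators]
        if len(set(names)) != len(names):
            raise ValueError("duplicate indicator names")
        derived = {s.derived for s in self.indicators if s.derived} - {None}
        if derived and "yield" not in names:
            raise ValueError("derived WUE/PFP indicators require a 'yield' indicator")
        for level in (1, 2, 3):
            vols = self.irrigation_volumes.get(level, {})
            for year in self.years:
                if year not in vols:
                    raise ValueError(f"no irrigation volume for level {level}, year {year}")

    def run_irrigation(self, run: int, year: int) -> float:
        """Seasonal irrigation volume of design row ``run`` (0-based) in ``year``."""
        level = int(self.design.runs[run, 0])
        return float(self.irrigation_volumes[level][year])

    def run_total_fertilizer(self, run: int) -> float:
        """Season fertilizer total of design row ``run``, kg ha^-1."""
        return float(
            sum(self.fertilizer_levels[self.design.runs[run, j] - 1] for j in (1, 2, 3))
        )


def default_config(seed: int = 0, cv: float = 0.05, replicates: int = 3) -> SyntheticTrialConfig:
    """Study-condition defaults: 2 years x 9 treatments x 3 replicates x 12 indicators."""
    return SyntheticTrialConfig(seed=seed, indicators=_default_panel(cv), replicates=replicates)


@dataclass(frozen=True)
class SyntheticTrial:
    """Tidy records plus the generator's ground truth."""

    records: pd.DataFrame  # columns: year, treatment, replicate, indicator, value
    truth: dict
    config: SyntheticTrialConfig

    @property
    def plots_per_year(self) -> int:
        one_year = self.records[self.records["year"] == self.records["year"].iloc[0]]
        return one_year.groupby(["treatment", "replicate"]).ngroups


def _noiseless_run_value(spec: IndicatorSpec, config: SyntheticTrialConfig, run: int, year: int) -> float:
    value = spec.baseline
    for j, fac in enumerate(FACTOR_NAMES):
        value += spec.effects[fac][config.design.runs[run, j] - 1]
    return value + spec.year_offsets.get(year, 0.0)


def _derived_truth(spec: IndicatorSpec, config: SyntheticTrialConfig) -> dict[str, int]:
    """Exact optimum for WUE/PFP: enumerate noiseless level means on the design."""
    from .design import range_analysis

    yield_spec = next(s for s in config.indicators if s.name == "yield")
    values = []
    for run in range(9):
        per_year = []
        for year in config.years:
            y = _noiseless_run_value(yield_spec, config, run, year)
            if spec.derived == "wue":
                per_year.append(y / config.run_irrigation(run, year))
            else:
                per_year.append(y / config.run_total_fertilizer(run))
        values.append(float(np.mean(per_year)))
    res = range_analysis(config.design, values, direction=spec.direction)
    return dict(res.optimal_level)


def _compute_truth(config: SyntheticTrialConfig) -> dict:
    optimal: dict[str, dict[str, int]] = {}
    for spec in config.indicators:
        if spec.derived is None:
            optimal[spec.name] = spec.optimal_levels()
        else:
            optimal[spec.name] = _derived_truth(spec, config)
    # dominant treatment: strictly best on every benefit-adjusted indicator
    noiseless = _noiseless_matrix(config)
    adjusted = noiseless.copy()
    for spec in config.indicators:
        if spec.direction == "cost":
            adjusted[spec.name] = -adjusted[spec.name]
    dominant = None
    for tid in adjusted.index:
        others = adjusted.drop(index=tid)
        if bool((adjusted.loc[tid] > others.max(axis=0)).all()):
            dominant = str(tid)
            break
    return {"optimal_level": optimal, "dominant_treatment": dominant}


def _noiseless_matrix(config: SyntheticTrialConfig) -> pd.DataFrame:
    """Per-treatment noiseless values averaged over years (9 x m)."""
    data: dict[str, list[float]] = {}
    yield_spec = next((s for s in config.indicators if s.name == "yield"), None)
    for spec in config.indicators:
        col = []
        for run in range(9):
            per_year = []
            for year in config.years:
                if spec.derived is None:
                    per_year.append(_noiseless_run_value(spec, config, run, year))
                elif spec.derived == "wue":
                    y = _noiseless_run_value(yield_spec, config, run, year)
                    per_year.append(y / config.run_irrigation(run, year))
                else:
                    y = _noiseless_run_value(yield_spec, config, run, year)
                    per_year.append(y / config.run_total_fertilizer(run))
            col.append(float(np.mean(per_year)))
        data[spec.name] = col
    return pd.DataFrame(data, index=list(config.design.run_ids))


_MAX_RESAMPLE = 100


def generate_trial(config: SyntheticTrialConfig) -> SyntheticTrial:
    """Simulate the trial; equal seeds give identical datasets."""
    rng = np.random.default_rng(config.seed)
    additive = [s for s in config.indicators if s.derived is None]
    derived = [s for s in config.indicators if s.derived is not None]
    rows: list[tuple] = []
    for year in config.years:
        for run, tid in enumerate(config.design.run_ids):
            for rep in range(1, config.replicates + 1):
                values: dict[str, float] = {}
                for spec in additive:
                    mean = _noiseless_run_value(spec, config, run, year)
                    value = mean * (1.0 + spec.cv * rng.standard_normal())
                    tries = 0
                    while value <= 0 and tries < _MAX_RESAMPLE:
                        value = mean * (1.0 + spec.cv * rng.standard_normal())
                        tries += 1
                    if value <= 0:
                        raise RuntimeError(
                            f"could not draw a positive value for {spec.name!r} "
                            f"(mean {mean:.3g}, CV {spec.cv}); check the effect sizes"
                        )
                    values[spec.name] = value
                for spec in derived:
                    y = values["yield"]
                    if spec.derived == "wue":
                        values[spec.name] = y / config.run_irrigation(run, year)
                    else:
                        values[spec.name] = y / config.run_total_fertilizer(run)
                for spec in config.indicators:  # keep declared indicator order
                    rows.append((year, tid, rep, spec.name, values[spec.name]))
    records = pd.DataFrame(rows, columns=["year", "treatment", "replicate", "indicator", "value"])
    return SyntheticTrial(records=records, truth=_compute_truth(config), config=config)


def aggregate_replicates(trial: SyntheticTrial) -> IndicatorMatrix:
    """Per-treatment means (over replicates, then years) as a 9 x m matrix."""
    records = trial.records
    expected = len(trial.config.years) * trial.config.replicates
    counts = records.groupby(["treatment", "indicator"], sort=False)["value"].count()
    short = counts[counts != expected]
    if len(short):
        tid, ind = short.index[0]
        raise ValueError(f"incomplete records for treatment {tid!r}, indicator {ind!r}")
    yearly = (
        records.groupby(["treatment", "indicator", "year"], sort=False)["value"].mean()
    )
    mean = yearly.groupby(["treatment", "indicator"], sort=False).mean().unstack("indicator")
    order = [s.name for s in trial.config.indicators]
    mean = mean.loc[list(trial.config.design.run_ids), order]
    directions = {s.name: s.direction for s in trial.config.indicators}
    categories = {s.name: s.category for s in trial.config.indicators}
    return IndicatorMatrix(values=mean, directions=directions, categories=categories)


def make_dominant_scenario(
    config: SyntheticTrialConfig,
    target: str = "T5",
    effect_frac: float = 0.10,
    margin_sds: float = 3.0,
) -> SyntheticTrialConfig:
    """Rewrite effects so ``target`` strictly dominates every other treatment.

    Every indicator becomes additive (WUE/PFP included) with a per-factor
    effect of ``effect_frac`` x baseline favouring the target's level.
    Any two distinct runs of the L9 array disagree in exactly 3 columns,
    so the target's margin over any rival is 3 x effect_frac x baseline;
    the effect is enlarged if needed to keep that margin at least
    ``margin_sds`` plot-noise standard deviations.
    """
    if target not in config.design.run_ids:
        raise ValueError(f"unknown target treatment {target!r}")
    run = list(config.design.run_ids).index(target)
    target_levels = config.design.runs[run]
    new_specs = []
    for spec in config.indicators:
        frac = max(effect_frac, margin_sds * spec.cv / 3.0)
        delta = frac * spec.baseline
        sign = -1.0 if spec.direction == "benefit" else 1.0  # off-target levels are worse
        effects = {}
        for j, fac in enumerate(FACTOR_NAMES):
            eff = [sign * delta] * 3
            eff[target_levels[j] - 1] = 0.0
            effects[fac] = tuple(eff)
        new_specs.append(
            dataclasses.replace(spec, effects=effects, derived=None)
        )
    return dataclasses.replace(config, indicators=tuple(new_specs))


def save_scenario(config: SyntheticTrialConfig, path: str | Path) -> None:
    """Write a scenario to YAML (design is the standard L9 and not serialized)."""
    doc = {
        "seed": config.seed,
        "years": list(config.years),
        "replicates": config.replicates,
        "irrigation_volumes": {
            int(l): {int(y): float(v) for y, v in vols.items()}
            for l, vols in config.irrigation_volumes.items()
        },
        "fertilizer_levels": list(config.fertilizer_levels),
        "indicators": [
            {
                "name": s.name,
                "baseline": s.baseline,
                "unit": s.unit,
                "direction": s.direction,
                "category": s.category,
                "effects": {k: list(v) for k, v in s.effects.items()},
                "year_offsets": {int(y): float(v) for y, v in s.year_offsets.items()},
                "cv": s.cv,
                "derived": s.derived,
            }
            for s in config.indicators
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path: str | Path) -> SyntheticTrialConfig:
    doc = yaml.safe_load(Path(path).read_text())
    specs = tuple(
        IndicatorSpec(
            name=d["name"],
            baseline=d["baseline"],
            unit=d.get("unit", ""),
            direction=d["direction"],
            category=d["category"],
            effects={k: tuple(v) for k, v in d.get("effects", {}).items()},
            year_offsets={int(y): float(v) for y, v in d.get("year_offsets", {}).items()},
            cv=d.get("cv", 0.05),
            derived=d.get("derived"),
        )
        for d in doc["indicators"]
    )
    return SyntheticTrialConfig(
        seed=doc["seed"],
        indicators=specs,
        years=tuple(doc.get("years", (2023, 2024))),
        replicates=doc.get("replicates", 3),
        irrigation_volumes={
            int(l): {int(y): float(v) for y, v in vols.items()}
            for l, vols in doc.get("irrigation_volumes", DEFAULT_IRRIGATION_VOLUMES).items()
        },
        fertilizer_levels=tuple(doc.get("fertilizer_levels", FERTILIZER_LEVELS)),
    )
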