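"""Orthogonal trial design, treatment table, irrigation arithmetic and range analysis.

The trial screens four factors at three levels each with an L9(3^4)
orthogonal array: irrigation amount (IA, as a fraction of crop
evapotranspiration ET_c) and the fertilizer rate applied at each of three
growth stages (FI seedling, FII flowering/fruit-set, FIII peak fruit).
Nine treatments T1..T9 cover the array; each pair of factor levels
co-occurs exactly once, so factor-level response means are directly
comparable (Taguchi range analysis).

Units follow field convention: irrigation volumes in m^3 ha^-1,
fertilizer rates in kg ha^-1, and the evaporation-pan model in
mm x m^2 -> litres (1 mm over 1 m^2 = 1 L).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "OrthogonalDesign",
    "Treatment",
    "IrrigationSchedule",
    "RangeAnalysisResult",
    "FERTILIZER_LEVELS",
    "IRRIGATION_FRACTIONS",
    "STAGE_PAN_COEFFICIENTS",
    "build_l9_design",
    "load_treatment_table",
    "packaged_treatment_table",
    "irrigation_requirement",
    "range_analysis",
    "input_reduction",
]

#: Stage fertilizer rates tested, kg ha^-1 (levels 1..3).
FERTILIZER_LEVELS: tuple[float, float, float] = (562.5, 750.0, 937.5)

#: Irrigation regimes as fractions of ET_c: severe deficit (DIS),
#: mild deficit (DIM), full irrigation (FI).
IRRIGATION_FRACTIONS: tuple[float, float, float] = (0.5, 0.75, 1.0)

IRRIGATION_REGIME_NAMES: tuple[str, str, str] = ("DIS", "DIM", "FI")

#: Pan coefficients K_cp per growth stage (field-calibrated).
STAGE_PAN_COEFFICIENTS: dict[str, float] = {
    "seedling": 0.6,
    "flowering": 1.3,
    "peak_fruit": 1.1,
}

FactorRole = Literal["irrigation", "stage1_fert", "stage2_fert", "stage3_fert"]

# The 9x4 level-index array, row order T1..T9, column order IA, FI, FII, FIII.
# Reconstructed from the treatment codes (e.g. T5 = DIM / FI 750 / FII 937.5 /
# FIII 562.5 -> levels 2,2,3,1); it is a standard L9(3^4) array.
_L9_LEVELS = np.array(
    [
        [1, 1, 1, 1],
        [1, 2, 2, 2],
        [1, 3, 3, 3],
        [2, 1, 2, 3],
        [2, 2, 3, 1],
        [2, 3, 1, 2],
        [3, 1, 3, 2],
        [3, 2, 1, 3],
        [3, 3, 2, 1],
    ],
    dtype=int,
)

TREATMENT_IDS: tuple[str, ...] = tuple(f"T{i}" for i in range(1, 10))


@dataclass(frozen=True)
class Factor:
    """One design factor with its three physical level values.

    ``levels`` are ET_c fractions for the irrigation factor and
    kg ha^-1 rates for the fertilizer factors; they must be strictly
    increasing so that level indices are unambiguous.
    """

    name: str
    role: FactorRole
    levels: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.levels) != 3:
            raise ValueError(f"factor {self.name!r} must have exactly 3 levels")
        if not (self.levels[0] < self.levels[1] < self.levels[2]):
            raise ValueError(f"factor {self.name!r} levels must be strictly increasing")


def _default_factors() -> tuple[Factor, ...]:
    return (
        Factor("IA", "irrigation", IRRIGATION_FRACTIONS),
        Factor("FI", "stage1_fert", FERTILIZER_LEVELS),
        Factor("FII", "stage2_fert", FERTILIZER_LEVELS),
        Factor("FIII", "stage3_fert", FERTILIZER_LEVELS),
    )


@dataclass(frozen=True)
class OrthogonalDesign:
    """An L9(3^4) array: 9 runs x 4 factors, cells are level indices 1..3."""

    runs: np.ndarray
    factors: tuple[Factor, ...] = field(default_factory=_default_factors)
    run_ids: tuple[str, ...] = TREATMENT_IDS

    def __post_init__(self) -> None:
        runs = np.asarray(self.runs, dtype=int)
        object.__setattr__(self, "runs", runs)
        if runs.shape != (9, 4):
            raise ValueError(f"expected a 9x4 array, got shape {runs.shape}")
        self.validate()

    def validate(self) -> None:
        """Check column balance and pairwise orthogonality (exact, integer)."""
        for j in range(4):
            counts = np.bincount(self.runs[:, j], minlength=4)[1:4]
            if not np.all(counts == 3):
                raise ValueError(f"column {j} is unbalanced: level counts {counts}")
        for a in range(4):
            for b in range(a + 1, 4):
                pairs = {(int(x), int(y)) for x, y in zip(self.runs[:, a], self.runs[:, b])}
                if len(pairs) != 9:
                    raise ValueError(f"columns {a} and {b} are not orthogonal")

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def level_value(self, run: int, factor: int) -> float:
        """Physical value of ``factor`` in run ``run`` (0-based indices)."""
        return self.factors[factor].levels[self.runs[run, factor] - 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.runs, index=list(self.run_ids), columns=list(self.factor_names))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("id").to_csv(path)


def build_l9_design() -> OrthogonalDesign:
    """The trial's L9(3^4) array, row order T1..T9, columns IA, FI, FII, FIII."""
    return OrthogonalDesign(runs=_L9_LEVELS.copy())


@dataclass(frozen=True)
class Treatment:
    """One design run: yearly irrigation volumes plus three stage fertilizer rates."""

    id: str
    irrigation_volume: Mapping[int, float]  # year -> m^3 ha^-1
    fert_stage1: float
    fert_stage2: float
    fert_stage3: float

    def __post_init__(self) -> None:
        for stage, rate in self.fert_rates.items():
            if rate not in FERTILIZER_LEVELS:
                raise ValueError(
                    f"treatment {self.id}: stage {stage} rate {rate} is not one of {FERTILIZER_LEVELS}"
                )
        for year, vol in self.irrigation_volume.items():
            if not vol > 0:
                raise ValueError(f"treatment {self.id}: non-positive irrigation volume in {year}")

    @property
    def fert_rates(self) -> dict[int, float]:
        return {1: self.fert_stage1, 2: self.fert_stage2, 3: self.fert_stage3}

    @property
    def total_fertilizer(self) -> float:
        """Season total across the three stage applications, kg ha^-1."""
        return self.fert_stage1 + self.fert_stage2 + self.fert_stage3


def _treatments_from_frame(df: pd.DataFrame, source: str) -> list[Treatment]:
    required = {"id", "year", "irrigation_m3_ha", "fert1_kg_ha", "fert2_kg_ha", "fert3_kg_ha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{source}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{source}: no treatment rows")
    for col in ("irrigation_m3_ha", "fert1_kg_ha", "fert2_kg_ha", "fert3_kg_ha", "year"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"{source}: non-numeric value in column {col!r}, row {row}")
        df[col] = pd.to_numeric(df[col])
    dupes = df.duplicated(subset=["id", "year"])
    if dupes.any():
        row = df.loc[dupes.idxmax()]
        raise ValueError(f"{source}: duplicate entry for ({row['id']}, {int(row['year'])})")
    treatments: list[Treatment] = []
    for tid, grp in df.groupby("id", sort=False):
        ferts = grp[["fert1_kg_ha", "fert2_kg_ha", "fert3_kg_ha"]].drop_duplicates()
        if len(ferts) != 1:
            raise ValueError(f"{source}: treatment {tid} has year-dependent fertilizer rates")
        f1, f2, f3 = ferts.iloc[0]
        volumes = {int(y): float(v) for y, v in zip(grp["year"], grp["irrigation_m3_ha"])}
        treatments.append(Treatment(str(tid), volumes, float(f1), float(f2), float(f3)))
    ids = {t.id for t in treatments}
    expected = set(TREATMENT_IDS)
    if ids != expected:
        raise ValueError(f"{source}: expected treatments {sorted(expected)}, got {sorted(ids)}")
    treatments.sort(key=lambda t: int(t.id[1:]))
    return treatments


def load_treatment_table(path: str | Path) -> list[Treatment]:
    """Read a treatment table CSV (one row per treatment x year) and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no treatment rows") from None
    return _treatments_from_frame(df, str(path))


def packaged_treatment_table() -> list[Treatment]:
    """The packaged two-year treatment fixture (volumes and stage rates)."""
    with resources.as_file(
        resources.files("fertigation_mcda").joinpath("data/table1_treatments.csv")
    ) as p:
        return load_treatment_table(p)


@dataclass(frozen=True)
class IrrigationSchedule:
    """Inputs to the evaporation-pan irrigation model I = Ep * Kcp * A."""

    pan_evaporation_mm: float
    area_m2: float
    stage: Literal["seedling", "flowering", "peak_fruit"] = "flowering"
    pan_coefficient: float | None = None  # default: stage-calibrated K_cp

    def __post_init__(self) -> None:
        if self.pan_evaporation_mm < 0:
            raise ValueError("pan evaporation must be >= 0")
        if self.area_m2 <= 0:
            raise ValueError("irrigated area must be > 0")
        if self.stage not in STAGE_PAN_COEFFICIENTS:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.pan_coefficient is not None and self.pan_coefficient <= 0:
            raise ValueError("pan coefficient must be > 0")

    @property
    def kcp(self) -> float:
        if self.pan_coefficient is not None:
            return self.pan_coefficient
        return STAGE_PAN_COEFFICIENTS[self.stage]


def irrigation_requirement(schedule: IrrigationSchedule) -> float:
    """Irrigation requirement in litres: I = Ep (mm) x K_cp x A (m^2)."""
    return schedule.pan_evaporation_mm * schedule.kcp * schedule.area_m2


@dataclass(frozen=True)
class RangeAnalysisResult:
    """Taguchi range analysis of a per-run response on an orthogonal design.

    ``level_means[f][l]`` is the mean response over the three runs with
    factor ``f`` at level ``l+1``; the range R ranks factor influence and
    the best level mean picks the optimum (direction-aware).
    """

    factor_names: tuple[str, ...]
    level_means: dict[str, np.ndarray]  # factor -> length-3 array of k-bar
    ranges: dict[str, float]  # factor -> R = max(k-bar) - min(k-bar)
    factor_order: tuple[str, ...]  # descending R, stable in input order
    optimal_level: dict[str, int]  # factor -> level index 1..3
    direction: Literal["benefit", "cost"]

    def to_frame(self) -> pd.DataFrame:
        rows = {
            f: list(self.level_means[f]) + [self.ranges[f], self.optimal_level[f]]
            for f in self.factor_names
        }
        return pd.DataFrame.from_dict(
            rows, orient="index", columns=["k1", "k2", "k3", "R", "optimal_level"]
        ).rename_axis("factor")


def range_analysis(
    design: OrthogonalDesign,
    responses: Sequence[float] | np.ndarray,
    direction: Literal["benefit", "cost"] = "benefit",
) -> RangeAnalysisResult:
    """Level-mean range analysis of one response over the design's 9 runs.

    ``responses`` holds one (replicate-averaged) value per run, in design
    row order. Optimal level is the argmax of the level means for a
    benefit response, argmin for a cost response; ties resolve to the
    lowest level index.
    """
    y = np.asarray(responses, dtype=float)
    if y.shape != (9,):
        raise ValueError(f"expected 9 responses (one per run), got shape {y.shape}")
    if direction not in ("benefit", "cost"):
        raise ValueError(f"direction must be 'benefit' or 'cost', got {direction!r}")
    level_means: dict[str, np.ndarray] = {}
    ranges: dict[str, float] = {}
    optimal: dict[str, int] = {}
    for j, fac in enumerate(design.factors):
        kbar = np.array([y[design.runs[:, j] == l].mean() for l in (1, 2, 3)])
        level_means[fac.name] = kbar
        ranges[fac.name] = float(kbar.max() - kbar.min())
        optimal[fac.name] = int(np.argmax(kbar) + 1 if direction == "benefit" else np.argmin(kbar) + 1)
    names = design.factor_names
    order = tuple(sorted(names, key=lambda f: -ranges[f]))
    return RangeAnalysisResult(
        factor_names=names,
        level_means=level_means,
        ranges=ranges,
        factor_order=order,
        optimal_level=optimal,
        direction=direction,
    )


def input_reduction(candidate: Treatment, baseline: Treatment) -> dict[str, float]:
    """Percent water and fertilizer savings of ``candidate`` relative to ``baseline``.

    Returns ``water_pct`` per year (keyed ``water_pct_<year>``) and
    ``fert_pct`` for the season fertilizer total, each as
    100 x (baseline - candidate) / baseline; positive means the candidate
    uses less input.
    """
    out: dict[str, float] = {}
    for year, base_vol in baseline.irrigation_volume.items():
        if base_vol <= 0:
            raise ValueError(f"baseline {baseline.id}: non-positive volume in {year}")
        if year not in candidate.irrigation_volume:
            raise ValueError(f"candidate {candidate.id}: missing year {year}")
        out[f"water_pct_{year}"] = 100.0 * (base_vol - candidate.irrigation_volume[year]) / base_vol
    base_f = baseline.total_fertilizer
    if base_f <= 0:
        raise ValueError(f"baseline {baseline.id}: non-positive total fertilizer")
    out["fert_pct"] = 100.0 * (base_f - candidate.total_fertilizer) / base_f
    return out
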