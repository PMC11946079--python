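"""Entropy-based objective indicator weighting and composite scoring.

The entropy weight method assigns larger weights to indicators whose
values are more dispersed across alternatives (lower Shannon entropy of
the column's proportional shares). Two weighting schemes are provided:

* classical: H_i = (1 - E_i) / sum(1 - E)
* improved exponential form with a dispersion coefficient k:
  H_x proportional to exp(k*(sum(E) - E_x + 1)) - exp(k*E_x),
  which is non-negative and non-increasing in E_x for entropies in
  [0, 1], and compresses weight spread relative to the classical scheme
  when entropies are tightly clustered.

Cost-direction indicators are converted to benefit orientation before
normalization with the min-max complement x' = max(x) - x + min(x),
which preserves non-negativity. Entropies are computed on the
unshifted proportional shares with the 0*ln(0) = 0 convention; a small
non-negative shift (default 0.01) is applied only to the matrix used
for composite scoring, guarding against zero cells there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "IndicatorMatrix",
    "EntropyResult",
    "direction_adjust",
    "normalize_proportional",
    "nonneg_shift",
    "entropy",
    "classical_weights",
    "improved_weights",
    "composite_scores",
    "entropy_evaluate",
]

Direction = Literal["benefit", "cost"]


@dataclass(frozen=True)
class IndicatorMatrix:
    """Alternatives x indicators raw values with per-indicator metadata.

    ``values`` is indexed by alternative id with one column per indicator.
    ``directions`` marks each indicator benefit (more is better) or cost;
    ``categories`` optionally groups indicators (yield / quality /
    efficiency) for per-category weighting.
    """

    values: pd.DataFrame
    directions: Mapping[str, Direction]
    categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[0] < 2 or self.values.shape[1] < 1:
            raise ValueError("need at least 2 alternatives and 1 indicator")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()][0]
            raise ValueError(f"missing cells in indicator {bad!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in indicator matrix")
        unknown = set(self.values.columns) - set(self.directions)
        if unknown:
            raise ValueError(f"no direction given for indicators {sorted(unknown)}")
        for name, d in self.directions.items():
            if d not in ("benefit", "cost"):
                raise ValueError(f"indicator {name!r}: direction must be benefit or cost")

    @property
    def indicators(self) -> list[str]:
        return list(self.values.columns)

    @property
    def alternatives(self) -> list[str]:
        return [str(a) for a in self.values.index]

    def subset(self, indicators: list[str]) -> "IndicatorMatrix":
        return IndicatorMatrix(
            values=self.values[indicators].copy(),
            directions={k: self.directions[k] for k in indicators},
            categories={k: v for k, v in self.categories.items() if k in indicators},
        )


def direction_adjust(X: pd.DataFrame, directions: Mapping[str, Direction]) -> pd.DataFrame:
    """Benefit-orient every column: cost columns get x' = max(x) - x + min(x)."""
    out = X.copy().astype(float)
    for col in out.columns:
        if directions.get(col, "benefit") == "cost":
            out[col] = out[col].max() - out[col] + out[col].min()
    return out


def normalize_proportional(X: pd.DataFrame) -> pd.DataFrame:
    """Column-wise proportional shares y_ij = x_ij / sum_i x_ij (columns sum to 1)."""
    sums = X.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"indicator {zero.index[0]!r} has zero column sum")
    return X / sums


def nonneg_shift(Y: pd.DataFrame, delta: float = 0.01) -> pd.DataFrame:
    """Add a strictly positive constant to every cell to remove zeros."""
    if delta <= 0:
        raise ValueError("shift delta must be > 0")
    return Y + delta


def entropy(Y: pd.DataFrame) -> pd.Series:
    """Shannon entropy per indicator, scaled to [0, 1] by k = 1/ln(n).

    E_i = -(1/ln n) * sum_j y_ij ln y_ij with 0*ln(0) taken as 0.
    A uniform column gives E = 1; a one-hot column gives E = 0.
    """
    n = Y.shape[0]
    if n < 2:
        raise ValueError("entropy needs at least 2 alternatives (ln n = 0 otherwise)")
    y = Y.to_numpy(dtype=float)
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("normalized shares must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(y), 0.0)
    e = -terms.sum(axis=0) / np.log(n)
    # clip the tiny negative round-off at the entropy extremes
    return pd.Series(np.clip(e, 0.0, 1.0), index=Y.columns, name="E")


def classical_weights(E: pd.Series) -> pd.Series:
    """Classical entropy weights H_i = (1 - E_i) / sum(1 - E)."""
    d = 1.0 - E
    total = d.sum()
    if total <= 0:
        raise ValueError("all entropies are 1: classical weights undefined")
    return (d / total).rename("H_classical")


def improved_weights(E: pd.Series, k_coef: float = 1.0) -> pd.Series:
    """Exponential-form entropy weights with dispersion coefficient ``k_coef``.

    H_x = [exp(k(S - E_x + 1)) - exp(k E_x)] / sum_l [exp(k(S - E_l + 1)) - exp(k E_l)]
    with S = sum(E). Non-increasing in E_x; equal entropies give equal
    weights 1/m. Smaller k compresses the spread between weights.
    """
    if k_coef <= 0:
        raise ValueError("k_coef must be > 0")
    if len(E) < 2:
        raise ValueError("need at least 2 indicators")
    e = E.to_numpy(dtype=float)
    s = e.sum()
    num = np.exp(k_coef * (s - e + 1.0)) - np.exp(k_coef * e)
    total = num.sum()
    if total <= 0:
        raise ValueError("degenerate weight denominator (entropies outside [0, 1]?)")
    return pd.Series(num / total, index=E.index, name="H_improved")


def composite_scores(Z: pd.DataFrame, H: pd.Series) -> pd.Series:
    """Weighted sum per alternative: S_a = sum_indicators H_i * z_ai."""
    if list(Z.columns) != list(H.index):
        if set(Z.columns) != set(H.index):
            raise ValueError("weights do not match matrix indicators")
        H = H.reindex(Z.columns)
    if not np.isclose(H.sum(), 1.0):
        raise ValueError("weights must sum to 1")
    return (Z * H).sum(axis=1).rename("S")


@dataclass(frozen=True)
class EntropyResult:
    """Everything the entropy pipeline produces for one indicator block."""

    normalized: pd.DataFrame  # proportional shares y_ij
    shifted: pd.DataFrame  # y_ij + delta, used for scoring
    entropies: pd.Series
    k_const: float  # 1 / ln(n)
    weights_classical: pd.Series
    weights_improved: pd.Series
    scores: pd.Series  # composite scores under the selected scheme
    method: Literal["classical", "improved"]


def entropy_evaluate(
    matrix: IndicatorMatrix,
    method: Literal["classical", "improved"] = "improved",
    k_coef: float = 1.0,
    delta: float = 0.01,
    entropy_on_shifted: bool = False,
) -> EntropyResult:
    """Run the full weighting chain on one indicator block.

    Direction adjustment -> proportional normalization -> entropy ->
    both weight schemes -> composite scores on the shifted matrix using
    the selected scheme's weights.
    """
    adjusted = direction_adjust(matrix.values, matrix.directions)
    if (adjusted.to_numpy() < 0).any():
        raise ValueError("indicator values must be non-negative after direction adjustment")
    Y = normalize_proportional(adjusted)
    Z = nonneg_shift(Y, delta)
    # shifted-entropy variant re-normalizes so shares still sum to 1
    E = entropy(normalize_proportional(Z) if entropy_on_shifted else Y)
    Hc = classical_weights(E)
    Hx = improved_weights(E, k_coef)
    H = Hx if method == "improved" else Hc
    S = composite_scores(Z, H)
    return EntropyResult(
        normalized=Y,
        shifted=Z,
        entropies=E,
        k_const=1.0 / np.log(matrix.values.shape[0]),
        weights_classical=Hc,
        weights_improved=Hx,
        scores=S,
        method=method,
    )
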