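"""TOPSIS ranking with virtual positive/negative ideal solutions.

Classical TOPSIS ranks alternatives by relative closeness to the
positive ideal solution Z+ (column-wise best) and remoteness from the
negative ideal Z- (column-wise worst). When several alternatives sit
near the ideal, the closeness coefficients bunch together; extrapolated
virtual ideals

    V+ = 2 Z+ - Z-        V- = 2 Z- - Z+

stretch the reference frame. Each alternative gets distances to the real
ideals (D+, D-) and the virtual ideals (F+, F-); these blend linearly
with weights alpha (real) and beta (virtual), defaults 0.9 / 0.1:

    S+ = alpha D+ + beta F+       S- = alpha D- + beta F-
    C  = S- / (S+ + S-)

With beta > 0 an alternative sitting exactly on Z+ scores
C = (alpha + 2 beta) / (alpha + 3 beta) = 11/12 at the defaults
(symmetrically 1/12 at Z-), so C never saturates at 0 or 1 and keeps
discriminating among near-ideal alternatives. alpha=1, beta=0 recovers
classical TOPSIS exactly.

All distances are root-weighted-Euclidean, sqrt(sum_j w_j (ref_j - z_j)^2).
Virtual ideals may have negative coordinates; distances are unaffected
and no clipping is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .entropy import IndicatorMatrix, direction_adjust

__all__ = [
    "DecisionMatrix",
    "IdealSolutions",
    "TopsisResult",
    "normalize_matrix",
    "ideal_solutions",
    "weighted_distance",
    "combined_distances",
    "closeness",
    "rank_alternatives",
    "topsis_rank",
]

DEFAULT_ALPHA = 0.9
DEFAULT_BETA = 0.1


@dataclass(frozen=True)
class DecisionMatrix:
    """Benefit-oriented normalized values plus indicator weights."""

    Z: pd.DataFrame  # n alternatives x m indicators
    weights: pd.Series  # per indicator, sums to 1

    def __post_init__(self) -> None:
        w = self.weights.reindex(self.Z.columns)
        if w.isna().any():
            raise ValueError("weights do not cover all indicators")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError(f"weights must sum to 1, got {w.sum():.6f}")
        object.__setattr__(self, "weights", w)


def normalize_matrix(
    X: IndicatorMatrix,
    weights: pd.Series | Sequence[float] | None = None,
    scheme: Literal["vector", "minmax"] = "vector",
) -> DecisionMatrix:
    """Benefit-orient cost columns, then normalize column-wise.

    ``vector`` (the TOPSIS standard) divides each column by its Euclidean
    norm; ``minmax`` rescales to [0, 1]. Uniform weights are used when
    none are given.
    """
    adjusted = direction_adjust(X.values, X.directions)
    if scheme == "vector":
        norms = np.sqrt((adjusted**2).sum(axis=0))
        zero = norms[norms == 0]
        if len(zero):
            raise ValueError(f"indicator {zero.index[0]!r} has zero norm")
        Z = adjusted / norms
    elif scheme == "minmax":
        span = adjusted.max() - adjusted.min()
        zero = span[span == 0]
        if len(zero):
            raise ValueError(f"indicator {zero.index[0]!r} is constant under minmax scaling")
        Z = (adjusted - adjusted.min()) / span
    else:
        raise ValueError(f"unknown normalization scheme {scheme!r}")
    if weights is None:
        w = pd.Series(1.0 / Z.shape[1], index=Z.columns)
    else:
        w = pd.Series(np.asarray(weights, dtype=float), index=Z.columns) if not isinstance(
            weights, pd.Series
        ) else weights.astype(float)
    return DecisionMatrix(Z=Z, weights=w)


@dataclass(frozen=True)
class IdealSolutions:
    """Real (Z+, Z-) and virtual (V+ = 2Z+ - Z-, V- = 2Z- - Z+) ideal points."""

    z_plus: pd.Series
    z_minus: pd.Series
    v_plus: pd.Series
    v_minus: pd.Series


def ideal_solutions(D: DecisionMatrix | pd.DataFrame) -> IdealSolutions:
    """Column-wise max/min ideals and their virtual extrapolations."""
    Z = D.Z if isinstance(D, DecisionMatrix) else D
    z_plus = Z.max(axis=0)
    z_minus = Z.min(axis=0)
    return IdealSolutions(
        z_plus=z_plus,
        z_minus=z_minus,
        v_plus=2 * z_plus - z_minus,
        v_minus=2 * z_minus - z_plus,
    )


def weighted_distance(
    row: np.ndarray | pd.Series,
    ref: np.ndarray | pd.Series,
    w: np.ndarray | pd.Series,
) -> float:
    """Root-weighted-Euclidean distance sqrt(sum w_j (ref_j - row_j)^2)."""
    r = np.asarray(row, dtype=float)
    q = np.asarray(ref, dtype=float)
    wv = np.asarray(w, dtype=float)
    if r.shape != q.shape or r.shape != wv.shape:
        raise ValueError("row, reference and weights must have equal length")
    if np.any(wv < 0):
        raise ValueError("weights must be non-negative")
    return float(np.sqrt(np.sum(wv * (q - r) ** 2)))


def combined_distances(
    d_plus: np.ndarray,
    d_minus: np.ndarray,
    f_plus: np.ndarray,
    f_minus: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> tuple[np.ndarray, np.ndarray]:
    """Blend real and virtual distances: S± = alpha·D± + beta·F±."""
    if alpha < 0 or beta < 0:
        raise ValueError("alpha and beta must be >= 0")
    if alpha + beta == 0:
        raise ValueError("alpha + beta must be > 0")
    return alpha * np.asarray(d_plus) + beta * np.asarray(f_plus), alpha * np.asarray(
        d_minus
    ) + beta * np.asarray(f_minus)


def closeness(s_plus: np.ndarray, s_minus: np.ndarray) -> np.ndarray:
    """Closeness coefficient C = S- / (S+ + S-), in [0, 1]; larger is better."""
    sp = np.asarray(s_plus, dtype=float)
    sm = np.asarray(s_minus, dtype=float)
    total = sp + sm
    if np.any(total <= 0):
        raise ValueError("S+ + S- must be > 0 (degenerate identical alternatives?)")
    return sm / total


@dataclass(frozen=True)
class TopsisResult:
    """Distance table, closeness coefficients and ranking for one decision."""

    table: pd.DataFrame  # D+, D-, F+, F-, S+, S-, C, rank per alternative
    ranking: tuple[str, ...]  # alternative ids, best first
    alpha: float
    beta: float

    @property
    def best(self) -> str:
        return self.ranking[0]

    @property
    def closeness(self) -> pd.Series:
        return self.table["C"]


def rank_alternatives(C: pd.Series) -> tuple[str, ...]:
    """Order ids by descending closeness; ties keep input (id) order."""
    order = C.sort_values(ascending=False, kind="stable")
    return tuple(str(i) for i in order.index)


def topsis_rank(
    D: DecisionMatrix,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> TopsisResult:
    """Full virtual-ideal TOPSIS on a prepared decision matrix."""
    ideals = ideal_solutions(D)
    w = D.weights.to_numpy()
    rows = D.Z.to_numpy()
    d_plus = np.array([weighted_distance(r, ideals.z_plus, w) for r in rows])
    d_minus = np.array([weighted_distance(r, ideals.z_minus, w) for r in rows])
    f_plus = np.array([weighted_distance(r, ideals.v_plus, w) for r in rows])
    f_minus = np.array([weighted_distance(r, ideals.v_minus, w) for r in rows])
    s_plus, s_minus = combined_distances(d_plus, d_minus, f_plus, f_minus, alpha, beta)
    C = closeness(s_plus, s_minus)
    table = pd.DataFrame(
        {
            "D_plus": d_plus,
            "D_minus": d_minus,
            "F_plus": f_plus,
            "F_minus": f_minus,
            "S_plus": s_plus,
            "S_minus": s_minus,
            "C": C,
        },
        index=D.Z.index,
    )
    ranking = rank_alternatives(table["C"])
    table["rank"] = table["C"].rank(ascending=False, method="first").astype(int)
    return TopsisResult(table=table, ranking=ranking, alpha=alpha, beta=beta)
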