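"""Model-human agreement metrics: Lin's concordance, bootstrap intervals,
and the personalization-bias analysis comparing how a model shifts its
per-player emotion predictions against how observers shift theirs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "lin_ccc",
    "pearson_r",
    "bootstrap_ci",
    "emotion_bias",
    "bias_correlation",
    "variance_scaled_pearson",
    "BiasCorrelation",
    "EvaluationReport",
]


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient.

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)`` with
    population (1/n) moments; penalizes location and scale shifts as well as
    decorrelation. Defined as 0 (with a warning) when both inputs are
    constant.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length sequences of length >= 2")
    vx, vy = x.var(), y.var()
    dm = x.mean() - y.mean()
    denom = vx + vy + dm * dm
    if denom == 0:
        warnings.warn("constant identical inputs: concordance undefined, returning 0")
        return 0.0
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    return float(2.0 * sxy / denom)


def pearson_r(x, y) -> float:
    """Plain Pearson correlation; 0 with a warning for constant input."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant input: correlation undefined, returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval of ``statistic`` over row resamples.

    Rows of ``data`` are the resampling unit; pass one row per observer for a
    cluster bootstrap.
    """
    data = np.asarray(data)
    n = data.shape[0]
    if n < 1:
        raise ValueError("empty data")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    for i in range(B):
        stats[i] = statistic(data[rng.integers(0, n, size=n)])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def emotion_bias(
    specific_expectations: Mapping[str, np.ndarray],
    generic_expectations: Mapping[str, np.ndarray],
    outcome_order: Sequence[str] = ("CC", "CD", "DC", "DD"),
) -> np.ndarray:
    """Per-(outcome x emotion) shift of a player's expected emotions.

    Inputs map outcome pair labels to length-20 expectation vectors; the
    result is the flattened 80-entry difference (specific minus generic) in
    outcome-major order.
    """
    rows = []
    for oc in outcome_order:
        rows.append(
            np.asarray(specific_expectations[oc], dtype=float)
            - np.asarray(generic_expectations[oc], dtype=float)
        )
    return np.concatenate(rows)


def variance_scaled_pearson(model_delta, empirical_delta) -> float:
    """Pearson correlation damped by relative model dispersion.

    ``r * min(1, sd(model) / sd(empirical))``: a model that captures the
    direction of the bias but undershoots its magnitude is credited less.
    """
    r = pearson_r(model_delta, empirical_delta)
    m = np.asarray(model_delta, dtype=float).std()
    e = np.asarray(empirical_delta, dtype=float).std()
    if e == 0:
        return r
    return float(r * min(1.0, m / e))


@dataclass(frozen=True)
class BiasCorrelation:
    ccc: float
    pearson: float
    scaled_pearson: float


@dataclass(frozen=True)
class EvaluationReport:
    """Bundle of agreement metrics for one model run.

    ``per_player_bias`` maps player ids to their :class:`BiasCorrelation`.
    """

    ccc_overall: float
    ccc_ci: tuple[float, float]
    ccc_per_emotion: Mapping[str, float]
    per_player_bias: Mapping[str, "BiasCorrelation"]
    bootstrap_B: int
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ccc_overall <= 1.0):
            raise ValueError("ccc must lie in [-1, 1]")
        if self.ccc_ci[0] > self.ccc_ci[1]:
            raise ValueError("CI bounds must be ordered")


def bias_correlation(model_delta, empirical_delta) -> BiasCorrelation:
    """Agreement between a model's predicted bias vector and the empirical one."""
    return BiasCorrelation(
        ccc=lin_ccc(model_delta, empirical_delta),
        pearson=pearson_r(model_delta, empirical_delta),
        scaled_pearson=variance_scaled_pearson(model_delta, empirical_delta),
    )
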