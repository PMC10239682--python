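"""Priors over minds and exact Bayesian inversion of the forward models.

Minds live on a finite grid (discretized preference weights and belief), so
conditioning on an observed action is exhaustive enumeration: posterior weight
is prior weight times the softmax policy's likelihood of the action, renormalized.
No approximation is involved, which keeps every downstream quantity exactly
reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .game import Action
from .planning import (
    BASE_COLUMNS,
    PUBLIC_COLUMNS,
    PlanningConfig,
    ReputationExpectation,
    reputation_expectation,
    support_policy,
)

__all__ = [
    "MindPrior",
    "MindPosterior",
    "uniform_grid_prior",
    "prior_from_marginals",
    "base_marginal",
    "invert",
    "posterior_expectations",
    "fit_prior_from_attributions",
    "belief_rating_to_prob",
]

#: Attribution-dataset dimension names, in support-column order.
ATTRIBUTION_DIMENSIONS = (
    "money_base",
    "aia_base",
    "dia_base",
    "money_repu",
    "aia_repu",
    "dia_repu",
    "pi_a2",
)


def belief_rating_to_prob(k) -> np.ndarray:
    """Map a 6-point belief confidence rating (1..6) onto [0, 1]."""
    k = np.asarray(k, dtype=float)
    if np.any(k < 1) or np.any(k > 6):
        raise ValueError("belief ratings must lie in 1..6")
    return (k - 1.0) / 5.0


def _digest(*arrays: np.ndarray) -> str:
    h = hashlib.sha1()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


@dataclass(frozen=True)
class MindPrior:
    """A discrete joint prior over minds.

    ``support`` is (n, k) with columns named by ``columns``; ``weights`` is a
    probability vector over the rows. ``variant`` tags the intended model:
    ``"base"`` (4 columns, anonymous model / naive observer), ``"generic"``
    or ``"specific:<player_id>"`` (7 columns, public model).
    """

    support: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    columns: tuple[str, ...]
    variant: str = "generic"

    def __post_init__(self) -> None:
        support = np.asarray(self.support, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "weights", weights)
        if support.ndim != 2 or support.shape[0] != weights.shape[0]:
            raise ValueError("support and weights must align on rows")
        if support.shape[1] != len(self.columns):
            raise ValueError("support width must match column names")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(support < -1e-12) or np.any(support > 1 + 1e-12):
            raise ValueError("support values must lie in [0, 1]")

    @property
    def token(self) -> str:
        """Content hash used to key caches."""
        return _digest(self.support, self.weights)

    @property
    def n_points(self) -> int:
        return self.support.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.support[:, self.columns.index(name)]

    def means(self) -> dict[str, float]:
        m = self.weights @ self.support
        return dict(zip(self.columns, map(float, m)))

    def reweighted(self, weights: np.ndarray, variant: str | None = None) -> "MindPrior":
        return MindPrior(self.support, weights, self.columns, variant or self.variant)


@dataclass(frozen=True)
class MindPosterior(MindPrior):
    """A prior updated on one observed action; keeps the conditioning record."""

    a1: Action = Action.C
    pot: float = 0.0
    model_variant: str = "public"


def _cartesian(grids: list[np.ndarray]) -> np.ndarray:
    mesh = np.meshgrid(*grids, indexing="ij")
    return np.column_stack([m.ravel() for m in mesh])


def prior_from_marginals(
    grids: list[np.ndarray],
    marginals: list[np.ndarray],
    columns: tuple[str, ...],
    variant: str = "generic",
) -> MindPrior:
    """Outer-product joint prior from per-dimension grids and marginal weights."""
    support = _cartesian([np.asarray(g, dtype=float) for g in grids])
    w = np.ones(1)
    for m in marginals:
        m = np.asarray(m, dtype=float)
        w = np.outer(w, m / m.sum()).ravel()
    return MindPrior(support, w, columns, variant)


def uniform_grid_prior(
    variant: str = "generic", n_w: int = 5, n_pi: int = 6
) -> MindPrior:
    """Uniform joint grid prior; the default weakly-informative prior.

    Weight dimensions get ``n_w`` points on [0, 1]; the belief gets ``n_pi``
    points (6 matches the empirical rating scale).
    """
    columns = BASE_COLUMNS if variant == "base" else PUBLIC_COLUMNS
    grids = [np.linspace(0, 1, n_w)] * (len(columns) - 1) + [np.linspace(0, 1, n_pi)]
    marginals = [np.ones(len(g)) for g in grids]
    return prior_from_marginals(grids, marginals, columns, variant)


def base_marginal(prior: MindPrior) -> MindPrior:
    """Marginalize a 7-column prior down to its base-model (4-column) prior."""
    if prior.columns == BASE_COLUMNS:
        return prior
    idx = [prior.columns.index(c) for c in BASE_COLUMNS]
    sub = prior.support[:, idx]
    # collapse duplicate (w_base, pi_a2) rows, summing weight
    uniq, inv = np.unique(sub, axis=0, return_inverse=True)
    w = np.bincount(inv, weights=prior.weights, minlength=len(uniq))
    return MindPrior(uniq, w / w.sum(), BASE_COLUMNS, "base")


def invert(
    prior: MindPrior,
    a1: Action,
    pot: float,
    cfg: PlanningConfig,
    repu: ReputationExpectation | None = None,
) -> MindPosterior:
    """Condition a prior on one observed action by exhaustive-grid Bayes.

    For the public variant the embedded naive-observer table is computed from
    the prior's own base marginal unless supplied.
    """
    if cfg.model_variant == "public":
        if prior.support.shape[1] != 7:
            raise ValueError("public inversion requires a 7-column prior")
        if repu is None:
            repu = reputation_expectation(base_marginal(prior), pot, cfg)
    if cfg.lam == 0:
        # constant likelihood: the posterior is the prior, bit for bit
        w, total = prior.weights, 1.0
    else:
        lik = support_policy(prior.support, pot, cfg, repu)[:, 0 if a1 is Action.C else 1]
        w = prior.weights * lik
        total = w.sum()
    if total <= 0:
        raise ValueError("all-zero likelihood: degenerate posterior")
    return MindPosterior(
        support=prior.support,
        weights=w / total,
        columns=prior.columns,
        variant=prior.variant,
        a1=a1,
        pot=float(pot),
        model_variant=cfg.model_variant,
    )


def posterior_expectations(post: MindPrior) -> dict[str, float]:
    """Weighted mean of each support dimension."""
    return post.means()


def fit_prior_from_attributions(
    data: pd.DataFrame,
    variant: str = "generic",
    n_w: int = 5,
    n_pi: int = 6,
    alpha: float = 1.0,
) -> MindPrior:
    """Fit a grid prior to observer attribution ratings.

    Each dimension's marginal is the add-``alpha`` smoothed histogram of its
    ratings snapped to the nearest grid point; the joint is their outer
    product (independence assumption). Belief ratings arrive on the 1..6
    scale and are mapped to [0, 1].
    """
    if len(data) == 0:
        raise ValueError("empty attribution dataset")
    columns = BASE_COLUMNS if variant == "base" else PUBLIC_COLUMNS
    dim_of_col = {
        "w_money_base": "money_base",
        "w_aia_base": "aia_base",
        "w_dia_base": "dia_base",
        "w_money_repu": "money_repu",
        "w_aia_repu": "aia_repu",
        "w_dia_repu": "dia_repu",
        "pi_a2": "pi_a2",
    }
    grids, marginals = [], []
    for col in columns:
        dim = dim_of_col[col]
        grid = np.linspace(0, 1, n_pi if col == "pi_a2" else n_w)
        ratings = data.loc[data["dimension"] == dim, "rating"].to_numpy(dtype=float)
        if ratings.size == 0:
            raise ValueError(f"no ratings for dimension {dim!r}")
        if col == "pi_a2":
            ratings = belief_rating_to_prob(ratings)
        elif np.any(ratings < 0) or np.any(ratings > 1):
            raise ValueError(f"ratings for {dim!r} must lie in [0, 1]")
        nearest = np.abs(ratings[:, None] - grid[None, :]).argmin(axis=1)
        counts = np.bincount(nearest, minlength=len(grid)).astype(float) + alpha
        grids.append(grid)
        marginals.append(counts / counts.sum())
    return prior_from_marginals(grids, marginals, columns, variant)
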