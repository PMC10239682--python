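"""Forward models of player decision-making.

Two variants are supported. In the *anonymous* model a player weighs only the
objective base features (own money, advantageous inequity, disadvantageous
inequity) against a reference point and a belief about the opponent. The
*public* model adds second-order reputation utilities: the player anticipates,
via a depth-1 embedded naive observer, what others would infer about their
base preferences from each action, and weighs those inferences too.

All heavy computation is vectorized over a support matrix of candidate minds
(one row per grid point), which is what makes exhaustive-grid inversion cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import log_softmax

from .game import Action, GameOutcome, base_features, value_transform

__all__ = [
    "BASE_COLUMNS",
    "PUBLIC_COLUMNS",
    "REPU_SIGNS",
    "PlayerMind",
    "PlanningConfig",
    "ReputationExpectation",
    "default_pi_money_marginal",
    "expected_base_utility",
    "expected_public_utility",
    "action_policy",
    "naive_observer_expectation",
    "reputation_expectation",
    "sample_player",
    "support_expected_utilities",
    "support_policy",
    "expected_feature_utils",
    "outcome_feature_utils",
    "repu_feature_utils",
]

#: Support-matrix column order for the anonymous (base) model.
BASE_COLUMNS = ("w_money_base", "w_aia_base", "w_dia_base", "pi_a2")
#: Support-matrix column order for the public model.
PUBLIC_COLUMNS = (
    "w_money_base",
    "w_aia_base",
    "w_dia_base",
    "w_money_repu",
    "w_aia_repu",
    "w_dia_repu",
    "pi_a2",
)

#: Signs of the reputation utility terms per feature (money, aia, dia):
#: opposite to the corresponding base-utility signs.
REPU_SIGNS = np.array([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class PlayerMind:
    """The latent mental contents of a single simulated player.

    ``pi_money`` is the optional reference point (prior expected winnings in
    USD); when ``None`` the planning config's discrete marginal is used.
    """

    w_money_base: float = 0.0
    w_aia_base: float = 0.0
    w_dia_base: float = 0.0
    w_money_repu: float = 0.0
    w_aia_repu: float = 0.0
    w_dia_repu: float = 0.0
    pi_a2: float = 0.5
    pi_money: float | None = None

    def __post_init__(self) -> None:
        for name in PUBLIC_COLUMNS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.pi_money is not None and self.pi_money < 0:
            raise ValueError("pi_money must be >= 0")

    def as_row(self) -> np.ndarray:
        """The mind as a 1x7 support row in :data:`PUBLIC_COLUMNS` order."""
        return np.array([[getattr(self, c) for c in PUBLIC_COLUMNS]])


def default_pi_money_marginal(pots: Sequence[float]) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Equal-weight three-point reference marginal: {0, median pot, max pot}."""
    pots = sorted(float(p) for p in pots)
    vals = (0.0, float(np.median(pots)), float(max(pots)))
    return vals, (1 / 3, 1 / 3, 1 / 3)


@dataclass(frozen=True)
class PlanningConfig:
    """Global planning constants: rationality, reference marginal, variant."""

    lam: float = 1.0
    pi_money_values: tuple[float, ...] = (0.0, 643.99, 207_365.0)
    pi_money_weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    model_variant: str = "public"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.model_variant not in ("anonymous", "public"):
            raise ValueError(f"unknown model_variant {self.model_variant!r}")
        if len(self.pi_money_values) != len(self.pi_money_weights):
            raise ValueError("pi_money marginal values/weights length mismatch")
        if any(v < 0 for v in self.pi_money_values):
            raise ValueError("pi_money values must be >= 0")
        if not math.isclose(sum(self.pi_money_weights), 1.0, abs_tol=1e-9):
            raise ValueError("pi_money marginal weights must sum to 1")

    def with_variant(self, variant: str) -> "PlanningConfig":
        return replace(self, model_variant=variant)

    def token(self) -> tuple:
        """Hashable identity used for caching reputation tables."""
        return (self.lam, self.pi_money_values, self.pi_money_weights)


@dataclass(frozen=True)
class ReputationExpectation:
    """Naive-observer posterior means E[w_f_base | a1] for both actions.

    ``table[a]`` is a length-3 array ordered (money, aia, dia).
    """

    pot: float
    table: Mapping[Action, np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        for a in (Action.C, Action.D):
            arr = np.asarray(self.table[a], dtype=float)
            if arr.shape != (3,) or np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError("reputation expectations must be 3 values in [0, 1]")

    def __getitem__(self, a: Action) -> np.ndarray:
        return np.asarray(self.table[a], dtype=float)


# ---------------------------------------------------------------------------
# vectorized utility engine
# ---------------------------------------------------------------------------

def _nubar(amount: float, cfg: PlanningConfig, pi_money: float | None) -> float:
    """Reference-adjusted value of a payoff, marginalized over pi_money."""
    if pi_money is not None:
        return value_transform(amount - pi_money)
    vals = np.asarray(cfg.pi_money_values)
    wts = np.asarray(cfg.pi_money_weights)
    return float(wts @ value_transform(amount - vals))


def outcome_feature_utils(
    W_base: np.ndarray,
    a1: Action,
    a2: Action,
    pot: float,
    cfg: PlanningConfig,
    pi_money: float | None = None,
) -> np.ndarray:
    """Per-feature base utilities of a realized outcome, (n, 3).

    Columns (money, aia, dia); money is reference-adjusted, inequity terms
    carry the aversion (negative) sign.
    """
    feats = base_features(GameOutcome(a1, a2, float(pot)))
    terms = np.array(
        [
            _nubar(feats.money, cfg, pi_money),
            -value_transform(feats.ai),
            -value_transform(feats.di),
        ]
    )
    return np.asarray(W_base, dtype=float) * terms


def expected_feature_utils(
    W_base: np.ndarray,
    pi_a2: np.ndarray,
    a1: Action,
    pot: float,
    cfg: PlanningConfig,
    pi_money: float | None = None,
) -> np.ndarray:
    """Per-feature expected base utilities of choosing ``a1``, (n, 3).

    The expectation integrates over the opponent's action with weight
    ``pi_a2`` on cooperation.
    """
    u_c = outcome_feature_utils(W_base, a1, Action.C, pot, cfg, pi_money)
    u_d = outcome_feature_utils(W_base, a1, Action.D, pot, cfg, pi_money)
    pi = np.asarray(pi_a2, dtype=float)[:, None]
    return pi * u_c + (1.0 - pi) * u_d


def repu_feature_utils(
    W_repu: np.ndarray,
    a1: Action,
    pot: float,
    repu: ReputationExpectation,
) -> np.ndarray:
    """Per-feature reputation utilities of choosing ``a1``, (n, 3)."""
    terms = REPU_SIGNS * value_transform(repu[a1] * pot)
    return np.asarray(W_repu, dtype=float) * terms


def support_expected_utilities(
    support: np.ndarray,
    pot: float,
    cfg: PlanningConfig,
    repu: ReputationExpectation | None = None,
    pi_a2_override: float | None = None,
    pi_money: float | None = None,
) -> np.ndarray:
    """Expected utilities of both actions for every support row, (n, 2).

    Columns are ordered (C, D). ``support`` has :data:`BASE_COLUMNS` layout
    for the anonymous variant and :data:`PUBLIC_COLUMNS` for the public one.
    ``pi_a2_override`` replaces the belief column with a constant (used for
    own-action counterfactual policies conditioned on the realized a2).
    """
    support = np.asarray(support, dtype=float)
    W_base = support[:, :3]
    pi = support[:, -1] if pi_a2_override is None else np.full(len(support), pi_a2_override)
    eu = np.empty((support.shape[0], 2))
    for j, a1 in enumerate((Action.C, Action.D)):
        u = expected_feature_utils(W_base, pi, a1, pot, cfg, pi_money).sum(axis=1)
        if cfg.model_variant == "public":
            if support.shape[1] != 7:
                raise ValueError("public variant requires a 7-column support")
            if repu is None:
                raise ValueError("public variant requires a reputation expectation")
            u = u + repu_feature_utils(support[:, 3:6], a1, pot, repu).sum(axis=1)
        eu[:, j] = u
    return eu


def support_policy(
    support: np.ndarray,
    pot: float,
    cfg: PlanningConfig,
    repu: ReputationExpectation | None = None,
    pi_a2_override: float | None = None,
    pi_money: float | None = None,
) -> np.ndarray:
    """Softmax action policy P(a1) for every support row, (n, 2), (C, D).

    Computed in the log domain so extreme lambdas stay finite.
    """
    eu = support_expected_utilities(support, pot, cfg, repu, pi_a2_override, pi_money)
    return np.exp(log_softmax(cfg.lam * eu, axis=1))


# ---------------------------------------------------------------------------
# scalar API (single minds)
# ---------------------------------------------------------------------------

def expected_base_utility(mind: PlayerMind, a1: Action, pot: float, cfg: PlanningConfig) -> float:
    """Expected base utility E[U_base(a1)] of one mind choosing ``a1``."""
    row = mind.as_row()
    u = expected_feature_utils(row[:, :3], row[:, 6], a1, pot, cfg, mind.pi_money)
    return float(u.sum())


def expected_public_utility(
    mind: PlayerMind,
    a1: Action,
    pot: float,
    repu: ReputationExpectation,
    cfg: PlanningConfig,
) -> float:
    """Expected base + reputation utility of one mind choosing ``a1``."""
    row = mind.as_row()
    base = expected_base_utility(mind, a1, pot, cfg)
    return base + float(repu_feature_utils(row[:, 3:6], a1, pot, repu).sum())


def action_policy(
    mind: PlayerMind,
    pot: float,
    cfg: PlanningConfig,
    repu: ReputationExpectation | None = None,
) -> dict[Action, float]:
    """Choice distribution of one mind: softmax of expected utility."""
    if cfg.model_variant == "public" and repu is None:
        raise ValueError("public variant requires a reputation expectation")
    p = support_policy(
        mind.as_row() if cfg.model_variant == "public" else mind.as_row()[:, [0, 1, 2, 6]],
        pot,
        cfg,
        repu,
        pi_money=mind.pi_money,
    )[0]
    return {Action.C: float(p[0]), Action.D: float(p[1])}


# ---------------------------------------------------------------------------
# embedded naive observer
# ---------------------------------------------------------------------------

_REPU_CACHE: dict[tuple, ReputationExpectation] = {}


def reputation_expectation(base_prior, pot: float, cfg: PlanningConfig) -> ReputationExpectation:
    """Posterior means a naive observer would infer about base preferences.

    The embedded loop is depth-1: a rational observer inverts the *anonymous*
    model on the observed action under ``base_prior``. Results are cached per
    (prior, pot, lambda, reference marginal).
    """
    key = (base_prior.token, float(pot), cfg.token())
    hit = _REPU_CACHE.get(key)
    if hit is not None:
        return hit
    anon = cfg.with_variant("anonymous")
    support = np.asarray(base_prior.support, dtype=float)
    if support.shape[1] != 4:
        raise ValueError("naive observer requires a base-variant prior (4 columns)")
    prior_w = np.asarray(base_prior.weights, dtype=float)
    lik = support_policy(support, pot, anon)  # (n, 2) for (C, D)
    table = {}
    for j, a1 in enumerate((Action.C, Action.D)):
        w = prior_w * lik[:, j]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"degenerate naive-observer posterior for a1={a1.value}")
        w = w / total
        table[a1] = w @ support[:, :3]
    out = ReputationExpectation(pot=float(pot), table=table)
    _REPU_CACHE[key] = out
    return out


def naive_observer_expectation(
    a1: Action, pot: float, base_prior, cfg: PlanningConfig
) -> np.ndarray:
    """E[w_f_base | a1] for the three base features, (3,)."""
    return reputation_expectation(base_prior, pot, cfg)[a1]


def prior_mean_reputation(base_prior, pot: float) -> ReputationExpectation:
    """Action-independent reputation table used by the inverse-planning lesion:
    the naive observer never updates, so both actions map to the prior mean."""
    support = np.asarray(base_prior.support, dtype=float)
    w = np.asarray(base_prior.weights, dtype=float)
    mean = w @ support[:, :3]
    return ReputationExpectation(pot=float(pot), table={Action.C: mean, Action.D: mean})


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_player(prior, n: int, seed: int | np.random.Generator) -> list[PlayerMind]:
    """Draw ``n`` i.i.d. minds from a discrete prior's support."""
    if n < 1:
        raise ValueError("n must be >= 1")
    support = np.asarray(prior.support, dtype=float)
    weights = np.asarray(prior.weights, dtype=float)
    if support.size == 0:
        raise ValueError("empty prior support")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = rng.choice(len(support), size=n, p=weights)
    cols = list(prior.columns)
    minds = []
    for i in idx:
        kwargs = dict(zip(cols, support[i]))
        minds.append(PlayerMind(**kwargs))
    return minds
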