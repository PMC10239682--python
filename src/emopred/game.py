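"""The one-shot cooperate/defect game: actions, outcomes, payoffs and the
objective "base features" (money, advantageous/disadvantageous inequity)
shared by every downstream module.

Payoffs follow the symmetric split-or-steal rule on a single pot: mutual
cooperation splits the pot evenly, mutual defection destroys it, and a lone
defector takes everything.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "Action",
    "GameOutcome",
    "BaseFeatures",
    "payoffs",
    "base_features",
    "value_transform",
    "pot_grid",
    "POT_MIN",
    "POT_MAX",
    "OUTCOME_PAIRS",
]

#: Empirical range of pot sizes (USD) used in the default pot grids.
POT_MIN = 2.0
POT_MAX = 207_365.0


class Action(enum.Enum):
    """One of the two moves available to each player."""

    C = "C"  #: cooperate ("Split")
    D = "D"  #: defect ("Steal")

    def __invert__(self) -> "Action":
        return Action.D if self is Action.C else Action.C

    def __repr__(self) -> str:  # compact reprs in conditioning records
        return f"Action.{self.value}"


#: The four (a1, a2) action pairs in canonical order.
OUTCOME_PAIRS = (
    (Action.C, Action.C),
    (Action.C, Action.D),
    (Action.D, Action.C),
    (Action.D, Action.D),
)


@dataclass(frozen=True, order=True)
class GameOutcome:
    """A fully realized game condition ``(a1, a2, pot)``.

    Hashable and ordered so conditions can key datasets and caches.
    """

    a1: Action
    a2: Action
    pot: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pot) and self.pot > 0):
            raise ValueError(f"pot must be finite and > 0, got {self.pot!r}")

    @property
    def pair(self) -> str:
        """Two-letter outcome label, e.g. ``"CD"``."""
        return self.a1.value + self.a2.value


class BaseFeatures(NamedTuple):
    """Objective situation features for player 1.

    ``money`` is player 1's payoff; ``ai``/``di`` are the advantageous and
    disadvantageous inequity (at most one is nonzero).
    """

    money: float
    ai: float
    di: float


def payoffs(outcome: GameOutcome) -> tuple[float, float]:
    """Return ``(r1, r2)``, the monetary payoffs to the two players."""
    pot = outcome.pot
    if outcome.a1 is Action.C and outcome.a2 is Action.C:
        return pot / 2.0, pot / 2.0
    if outcome.a1 is Action.C and outcome.a2 is Action.D:
        return 0.0, pot
    if outcome.a1 is Action.D and outcome.a2 is Action.C:
        return pot, 0.0
    return 0.0, 0.0


def base_features(outcome: GameOutcome) -> BaseFeatures:
    """Compute player 1's objective base features for an outcome."""
    r1, r2 = payoffs(outcome)
    return BaseFeatures(money=r1, ai=max(r1 - r2, 0.0), di=max(r2 - r1, 0.0))


def value_transform(x):
    """Nonlinear subjective value of a signed dollar amount.

    A sign-adjusted logarithm, ``sign(x) * log(1 + |x|)``: odd, strictly
    increasing, concave on gains, and fixing the origin. Accepts scalars or
    arrays; raises on non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("value_transform requires finite input")
    out = np.sign(arr) * np.log1p(np.abs(arr))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def pot_grid(n: int = 8, lo: float = POT_MIN, hi: float = POT_MAX) -> np.ndarray:
    """``n`` pot sizes log-spaced over ``[lo, hi]`` (USD)."""
    if n < 1 or lo <= 0 or hi < lo:
        raise ValueError("need n >= 1 and 0 < lo <= hi")
    if n == 1:
        return np.array([math.sqrt(lo * hi)])
    return np.geomspace(lo, hi, n)
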