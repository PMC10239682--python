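"""Computed appraisals: how a sampled mind evaluates a realized outcome.

For each base feature (money, aia, dia) we compute the achieved utility (AU),
the prediction error against the pre-outcome expectation (PE), and two
counterfactual contrasts — against the player's own unchosen action (CFa1,
weighted by how likely the player was to choose it given the revealed
opponent action) and against the opponent's unchosen action (CFa2, weighted
by the player's belief the opponent would make it). Reputation features are
deterministic given the player's own action, so they carry only AU and CFa1.
Together with the opponent-action surprise |PE pi_a2| this yields a
19-component vector in a fixed canonical order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .game import Action, GameOutcome
from .planning import (
    PlanningConfig,
    ReputationExpectation,
    expected_feature_utils,
    outcome_feature_utils,
    repu_feature_utils,
    support_policy,
)
from .inversion import MindPosterior, MindPrior

__all__ = [
    "COMPONENTS",
    "SOCIAL_LESION_COMPONENTS",
    "AppraisalSample",
    "appraisal_matrix",
    "compute_appraisal_distribution",
    "standardize",
    "apply_scale",
]

_FEATURES = ("money", "aia", "dia")

#: Canonical appraisal component order (length 19).
COMPONENTS: tuple[str, ...] = tuple(
    f"{kind}_{f}_base" for kind in ("au", "pe", "cf_a1", "cf_a2") for f in _FEATURES
) + tuple(f"{kind}_{f}_repu" for kind in ("au", "cf_a1") for f in _FEATURES) + (
    "abs_pe_pi_a2",
)

#: The two-component basis retained by the social lesion.
SOCIAL_LESION_COMPONENTS: tuple[str, ...] = ("au_money_base", "pe_money_base")


@dataclass(frozen=True)
class AppraisalSample:
    """A weighted set of appraisal vectors for one game condition.

    ``psi`` is (n, p) with columns named by ``components``; ``weights`` sum
    to one. ``scale`` records per-component divisors applied by
    :func:`standardize` (``None`` when raw).
    """

    psi: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    outcome: GameOutcome
    components: tuple[str, ...] = COMPONENTS
    prior_token: str = ""
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "weights", w)
        if psi.ndim != 2 or psi.shape[1] != len(self.components):
            raise ValueError("psi width must match component names")
        if psi.shape[0] != w.shape[0]:
            raise ValueError("psi and weights must align on rows")
        if not np.all(np.isfinite(psi)):
            raise ValueError("appraisal values must be finite")
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
            raise ValueError("weights must be nonnegative and sum to 1")

    def expectation(self) -> np.ndarray:
        """Weighted mean appraisal vector, (p,)."""
        return self.weights @ self.psi

    def column(self, name: str) -> np.ndarray:
        return self.psi[:, self.components.index(name)]

    def project(self, components: Sequence[str]) -> "AppraisalSample":
        """Restrict to a subset of components (e.g. the social-lesion basis)."""
        idx = [self.components.index(c) for c in components]
        scale = None if self.scale is None else self.scale[idx]
        return replace(self, psi=self.psi[:, idx], components=tuple(components), scale=scale)


def appraisal_matrix(
    support: np.ndarray,
    outcome: GameOutcome,
    cfg: PlanningConfig,
    repu: ReputationExpectation,
) -> np.ndarray:
    """Appraisal vectors for every candidate mind, (n, 19).

    ``support`` uses the 7-column public layout. All terms are computed under
    the same reference-point marginal as planning.
    """
    support = np.asarray(support, dtype=float)
    if support.shape[1] != 7:
        raise ValueError("appraisals require a 7-column public support")
    a1, a2, pot = outcome.a1, outcome.a2, outcome.pot
    W_base, W_repu, pi = support[:, :3], support[:, 3:6], support[:, 6]

    au_base = outcome_feature_utils(W_base, a1, a2, pot, cfg)
    eu_base = expected_feature_utils(W_base, pi, a1, pot, cfg)
    pe_base = au_base - eu_base

    # probability the player would have chosen the other action, with the
    # belief updated to a point mass on the revealed opponent action
    pol = support_policy(
        support, pot, cfg, repu, pi_a2_override=1.0 if a2 is Action.C else 0.0
    )
    p_not_a1 = pol[:, 1 if a1 is Action.C else 0][:, None]
    u_alt_a1 = outcome_feature_utils(W_base, ~a1, a2, pot, cfg)
    cf_a1_base = (u_alt_a1 - au_base) * p_not_a1

    pi_not_a2 = (pi if a2 is Action.D else 1.0 - pi)[:, None]
    u_alt_a2 = outcome_feature_utils(W_base, a1, ~a2, pot, cfg)
    cf_a2_base = (u_alt_a2 - au_base) * pi_not_a2

    au_repu = repu_feature_utils(W_repu, a1, pot, repu)
    cf_a1_repu = (repu_feature_utils(W_repu, ~a1, pot, repu) - au_repu) * p_not_a1

    abs_pe = np.abs((1.0 if a2 is Action.C else 0.0) - pi)[:, None]

    return np.hstack([au_base, pe_base, cf_a1_base, cf_a2_base, au_repu, cf_a1_repu, abs_pe])


def compute_appraisal_distribution(
    post: MindPrior,
    outcome: GameOutcome,
    cfg: PlanningConfig,
    repu: ReputationExpectation,
) -> AppraisalSample:
    """Appraisal distribution over a posterior's (or lesioned prior's) support.

    One appraisal vector per support point, weights copied from ``post``. The
    conditioning action of a posterior must match the outcome.
    """
    if isinstance(post, MindPosterior) and post.a1 is not outcome.a1:
        raise ValueError(
            f"posterior conditioned on a1={post.a1.value} cannot appraise "
            f"an outcome with a1={outcome.a1.value}"
        )
    psi = appraisal_matrix(post.support, outcome, cfg, repu)
    return AppraisalSample(
        psi=psi, weights=post.weights.copy(), outcome=outcome, prior_token=post.token
    )


def _pooled_sd(samples: Sequence[AppraisalSample]) -> np.ndarray:
    """Per-component weighted SD pooled across conditions (equal condition weight)."""
    k = len(samples)
    mean = sum(s.expectation() for s in samples) / k
    var = sum(s.weights @ (s.psi - mean) ** 2 for s in samples) / k
    return np.sqrt(var)


def standardize(
    samples: Sequence[AppraisalSample],
) -> tuple[list[AppraisalSample], np.ndarray]:
    """Scale each component to unit pooled SD across all conditions.

    Returns the scaled samples and the scale record (the divisors), which must
    be reused on any further sample fed to a transform fit on these. Components
    with zero pooled variance keep scale 1 with a warning.
    """
    if not samples:
        raise ValueError("no samples to standardize")
    if any(s.scale is not None for s in samples):
        raise ValueError("samples are already standardized")
    sd = _pooled_sd(samples)
    zero = sd <= 0
    if np.any(zero):
        names = [samples[0].components[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance appraisal components left unscaled: {names}")
        sd = np.where(zero, 1.0, sd)
    return [apply_scale(s, sd) for s in samples], sd


def apply_scale(sample: AppraisalSample, scale: np.ndarray) -> AppraisalSample:
    """Apply a previously recorded scale to a raw sample."""
    scale = np.asarray(scale, dtype=float)
    if sample.scale is not None:
        raise ValueError("sample is already scaled")
    return replace(sample, psi=sample.psi / scale, scale=scale)


def resample(sample: AppraisalSample, n: int, seed: int | np.random.Generator) -> AppraisalSample:
    """Compress a sample to at most ``n`` mixture components.

    Draws ``n`` support points with replacement by weight, then deduplicates;
    the result approximates the full distribution at a fraction of the cost
    of carrying the whole grid through likelihood evaluations.
    """
    if n >= sample.psi.shape[0]:
        return sample
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(sample.psi.shape[0], size=n, p=sample.weights)
    uniq, counts = np.unique(idx, return_counts=True)
    return replace(sample, psi=sample.psi[uniq], weights=counts / counts.sum())
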