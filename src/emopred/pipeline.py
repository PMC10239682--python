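"""Glue between the inference modules and the concept-learning layer.

These helpers assemble the per-condition appraisal sample maps that the
fitting, prediction and evaluation code consume: full-model maps (posterior
weighted), inverse-planning-lesion maps (prior weighted, prior-based
reputation loop), and their standardized counterparts.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .appraisal import AppraisalSample, apply_scale, compute_appraisal_distribution, resample, standardize
from .concepts import condition_key, lesion_inverse_planning, predict_emotions
from .game import Action, GameOutcome, OUTCOME_PAIRS
from .inversion import MindPrior, base_marginal, invert
from .planning import PlanningConfig, reputation_expectation

__all__ = [
    "posterior_sample_map",
    "lesion_sample_map",
    "standardize_map",
    "scale_map",
    "resample_map",
    "prediction_table",
    "outcome_expectations",
]


def _keyed(sample: AppraisalSample, player_id=None):
    key = condition_key(sample.outcome.a1, sample.outcome.a2, sample.outcome.pot)
    return key if player_id is None else (player_id, *key)


def posterior_sample_map(
    prior: MindPrior,
    cfg: PlanningConfig,
    pots: Iterable[float],
    player_id=None,
) -> dict[tuple, AppraisalSample]:
    """Full-model appraisal samples for every outcome x pot condition.

    Minds are conditioned on the observed a1 (exact grid inversion) before
    appraising; the embedded reputation loop inverts the anonymous model
    under the prior's base marginal.
    """
    base = base_marginal(prior)
    out = {}
    for pot in pots:
        repu = reputation_expectation(base, pot, cfg)
        posts = {a1: invert(prior, a1, pot, cfg, repu) for a1 in (Action.C, Action.D)}
        for a1, a2 in OUTCOME_PAIRS:
            s = compute_appraisal_distribution(
                posts[a1], GameOutcome(a1, a2, pot), cfg, repu
            )
            out[_keyed(s, player_id)] = s
    return out


def lesion_sample_map(
    prior: MindPrior,
    cfg: PlanningConfig,
    pots: Iterable[float],
    player_id=None,
) -> dict[tuple, AppraisalSample]:
    """Inverse-planning-lesion appraisal samples (prior weights throughout)."""
    out = {}
    for pot in pots:
        for a1, a2 in OUTCOME_PAIRS:
            s = lesion_inverse_planning(prior, GameOutcome(a1, a2, pot), cfg)
            out[_keyed(s, player_id)] = s
    return out


def standardize_map(
    samples: Mapping[tuple, AppraisalSample],
) -> tuple[dict[tuple, AppraisalSample], np.ndarray]:
    """Standardize a sample map in a deterministic key order; returns the scale."""
    keys = sorted(samples)
    scaled, scale = standardize([samples[k] for k in keys])
    return dict(zip(keys, scaled)), scale


def scale_map(
    samples: Mapping[tuple, AppraisalSample], scale: np.ndarray
) -> dict[tuple, AppraisalSample]:
    """Apply a training scale record to a raw sample map."""
    return {k: apply_scale(s, scale) for k, s in samples.items()}


def resample_map(
    samples: Mapping[tuple, AppraisalSample], n: int, seed: int
) -> dict[tuple, AppraisalSample]:
    """Compress every sample to at most ``n`` mixture components."""
    rng = np.random.default_rng(seed)
    return {k: resample(samples[k], n, rng) for k in sorted(samples)}


def prediction_table(transform, samples: Mapping[tuple, AppraisalSample]) -> dict[tuple, np.ndarray]:
    """Expected emotion vector per condition key."""
    return {k: predict_emotions(transform, s)[1] for k, s in samples.items()}


def outcome_expectations(
    predictions: Mapping[tuple, np.ndarray], player_id=None
) -> dict[str, np.ndarray]:
    """Average predicted emotions per outcome pair (pooling pot sizes)."""
    acc: dict[str, list[np.ndarray]] = {}
    for key, vec in predictions.items():
        if player_id is not None:
            if key[0] != player_id:
                continue
            key = key[1:]
        acc.setdefault(key[0] + key[1], []).append(np.asarray(vec))
    return {oc: np.mean(vecs, axis=0) for oc, vecs in acc.items()}
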