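"""Synthetic observer data with the statistical structure the analysis assumes.

A :class:`SynthWorld` bundles a ground-truth generic prior, planning config,
pot grid and a sparse ground-truth concept transform. From it one can draw
attribution datasets (noisy preference/belief ratings), emotion datasets
(noisy draws from the true appraisal-to-emotion mixture) and perturbed
"specific player" priors with their own datasets — everything the prior
fitting, MAP learning, lesioning and evaluation code needs, with no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .appraisal import COMPONENTS, AppraisalSample
from .concepts import EMOTIONS, ConceptTransform, DEFAULT_K, canonicalize_beta, collinear_groups
from .game import Action, OUTCOME_PAIRS, pot_grid
from .inversion import ATTRIBUTION_DIMENSIONS, MindPrior, invert, prior_from_marginals
from .planning import PUBLIC_COLUMNS, PlanningConfig, default_pi_money_marginal
from .pipeline import posterior_sample_map, scale_map, standardize_map

__all__ = [
    "SynthWorld",
    "make_world",
    "perturb_prior",
    "generate_attribution_dataset",
    "generate_emotion_dataset",
    "generate_specific_players",
]


@dataclass(frozen=True)
class SynthWorld:
    """Ground truth for a synthetic study."""

    prior: MindPrior
    cfg: PlanningConfig
    pots: np.ndarray = field(repr=False)
    transform: ConceptTransform
    scale: np.ndarray = field(repr=False)  # appraisal standardization record
    samples: dict = field(repr=False)  # condition key -> standardized AppraisalSample
    rating_noise: float = 0.1

    def sample_map_for(self, prior: MindPrior, player_id=None) -> dict:
        """Standardized full-model appraisal samples for an arbitrary prior,
        using the world's own (training) scale record."""
        raw = posterior_sample_map(prior, self.cfg, self.pots, player_id)
        return scale_map(raw, self.scale)


def make_world(
    seed: int = 0,
    n_w: int = 3,
    n_pi: int = 6,
    n_pots: int = 8,
    lam: float = 1.0,
    k: float = DEFAULT_K,
    beta_sparsity: float = 0.3,
    beta_magnitude: tuple[float, float] = (0.5, 2.0),
    emotion_noise_sd: float = 0.08,
    rating_noise: float = 0.1,
) -> SynthWorld:
    """Construct a ground-truth world.

    The generic prior has Dirichlet-perturbed (mildly non-uniform) marginals
    on a grid; the true transform has ``beta_sparsity`` of its weights nonzero
    with magnitudes in ``beta_magnitude`` and random sign, defined on the
    standardized appraisal basis.
    """
    rng = np.random.default_rng(seed)
    grids = [np.linspace(0, 1, n_w)] * 6 + [np.linspace(0, 1, n_pi)]
    marginals = [rng.dirichlet(np.full(len(g), 5.0)) for g in grids]
    prior = prior_from_marginals(grids, marginals, PUBLIC_COLUMNS, "generic")

    pots = pot_grid(n_pots)
    vals, wts = default_pi_money_marginal(pots)
    cfg = PlanningConfig(lam=lam, pi_money_values=vals, pi_money_weights=wts)

    samples, scale = standardize_map(posterior_sample_map(prior, cfg, pots))

    p, m = len(COMPONENTS), len(EMOTIONS)
    mask = rng.random((p, m)) < beta_sparsity
    mag = rng.uniform(*beta_magnitude, size=(p, m))
    sign = rng.choice([-1.0, 1.0], size=(p, m))
    beta = np.where(mask, sign * mag, 0.0)
    # express the truth in the identifiable canonical form: the appraisal
    # basis has exactly anti-collinear column pairs (PE vs CFa2 per base
    # feature), where only the signed sum of weights has meaning
    beta = canonicalize_beta(beta, collinear_groups(samples.values()))
    b = logit(rng.uniform(0.25, 0.55, size=m))
    sigma2 = np.full(m, emotion_noise_sd**2)
    transform = ConceptTransform(beta, b, sigma2, k=k, tau=1.0)

    return SynthWorld(
        prior=prior,
        cfg=cfg,
        pots=pots,
        transform=transform,
        scale=scale,
        samples=samples,
        rating_noise=rating_noise,
    )


def _truncnorm_unit(center: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Truncated-Normal draws on [0, 1] centred at ``center``."""
    center = np.asarray(center, dtype=float)
    if sd == 0:
        return center
    a = (0.0 - center) / sd
    b = (1.0 - center) / sd
    out = truncnorm.rvs(a, b, loc=center, scale=sd, size=center.shape, random_state=rng)
    return np.atleast_1d(out)


def generate_attribution_dataset(
    world: SynthWorld,
    n_observers: int,
    seed: int = 0,
    prior: MindPrior | None = None,
    player_id: str = "generic",
    trials_per_observer: int = 8,
) -> pd.DataFrame:
    """Noisy preference/belief ratings in the attribution CSV schema.

    Each observer sees trials balanced over a1 with random pots; the rated
    mind is drawn from the true posterior given a1, weights are perturbed by
    truncated-Normal noise and the belief is reported on the 1..6 scale.
    """
    rng = np.random.default_rng(seed)
    prior = prior if prior is not None else world.prior
    post = {
        (a1, float(pot)): invert(prior, a1, pot, world.cfg)
        for a1 in (Action.C, Action.D)
        for pot in world.pots
    }
    rows = []
    weight_dims = ATTRIBUTION_DIMENSIONS[:6]
    for obs in range(n_observers):
        for t in range(trials_per_observer):
            a1 = Action.C if t % 2 == 0 else Action.D
            pot = float(rng.choice(world.pots))
            po = post[(a1, pot)]
            mind = po.support[rng.choice(po.n_points, p=po.weights)]
            noisy_w = _truncnorm_unit(mind[:6], world.rating_noise, rng)
            noisy_pi = float(_truncnorm_unit(mind[6:7], world.rating_noise, rng)[0])
            belief_rating = int(np.clip(np.rint(noisy_pi * 5) + 1, 1, 6))
            common = dict(
                observer_id=f"{player_id}-obs{obs}", player_id=player_id,
                a1=a1.value, pot=pot,
            )
            for dim, val in zip(weight_dims, noisy_w):
                rows.append({**common, "dimension": dim, "rating": float(val)})
            rows.append({**common, "dimension": "pi_a2", "rating": belief_rating})
    return pd.DataFrame(rows)


def generate_emotion_dataset(
    world: SynthWorld,
    n_observers: int,
    trials_per_observer: int = 8,
    seed: int = 0,
    samples: dict | None = None,
    player_id: str = "generic",
) -> pd.DataFrame:
    """Noisy emotion-intensity predictions in the emotion CSV schema.

    Each observer completes ``trials_per_observer`` trials balanced over the
    four outcomes (two each at the default of eight), pots drawn from the pot
    grid. Per trial, an appraisal vector is drawn from the condition's
    standardized posterior sample and the emotion vector from the true
    transform's Gaussian kernel, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    samples = samples if samples is not None else world.samples
    t = world.transform
    sd = np.sqrt(t.sigma2)
    rows = []
    per_outcome = trials_per_observer // len(OUTCOME_PAIRS)
    if per_outcome < 1 or trials_per_observer % len(OUTCOME_PAIRS) != 0:
        raise ValueError("trials_per_observer must be a positive multiple of 4")
    for obs in range(n_observers):
        for a1, a2 in OUTCOME_PAIRS:
            for _ in range(per_outcome):
                pot = float(rng.choice(world.pots))
                key = (a1.value, a2.value, round(pot, 6))
                if player_id != "generic":
                    key = (player_id, *key)
                s: AppraisalSample = samples[key]
                psi = s.psi[rng.choice(s.psi.shape[0], p=s.weights)]
                mu = expit(t.k * psi @ t.beta + t.b)
                e = np.clip(mu + rng.normal(0.0, sd), 0.0, 1.0)
                rows.append(
                    {
                        "observer_id": f"{player_id}-eobs{obs}",
                        "player_id": player_id,
                        "a1": a1.value,
                        "a2": a2.value,
                        "pot": pot,
                        **dict(zip(EMOTIONS, map(float, e))),
                    }
                )
    return pd.DataFrame(rows)


def perturb_prior(
    prior: MindPrior, scale: float, rng: np.random.Generator, variant: str
) -> MindPrior:
    """Tilt a prior's log-weights with per-dimension-level noise.

    Each grid level of each support dimension receives an independent Normal
    offset (scaled by ``scale``) added to the log-weights of all points at
    that level — i.e. a random exponential tilt of every marginal. ``scale=0``
    returns an identical distribution.
    """
    logw = np.log(np.clip(prior.weights, 1e-300, None))
    for d in range(prior.support.shape[1]):
        levels, idx = np.unique(prior.support[:, d], return_inverse=True)
        eta = rng.normal(0.0, scale, size=len(levels))
        logw = logw + eta[idx]
    w = np.exp(logw - logw.max())
    return MindPrior(prior.support, w / w.sum(), prior.columns, variant)


def generate_specific_players(
    world: SynthWorld,
    m_players: int = 20,
    perturb_scale: float = 1.0,
    seed: int = 0,
    n_observers_per_player: int = 25,
    n_attrib_observers_per_player: int = 0,
) -> tuple[dict[str, MindPrior], dict, pd.DataFrame, pd.DataFrame | None]:
    """Perturbed per-player priors plus their emotion (and optional
    attribution) datasets.

    Returns ``(priors, sample_map, emotion_df, attribution_df)`` where
    ``sample_map`` holds standardized full-model appraisal samples keyed
    ``(player_id, a1, a2, pot)`` for every player and condition.
    """
    rng = np.random.default_rng(seed)
    priors: dict[str, MindPrior] = {}
    sample_map: dict = {}
    emotion_frames = []
    attrib_frames = []
    for i in range(m_players):
        pid = f"player{i:02d}"
        prior = perturb_prior(world.prior, perturb_scale, rng, f"specific:{pid}")
        priors[pid] = prior
        smap = world.sample_map_for(prior, player_id=pid)
        sample_map.update(smap)
        emotion_frames.append(
            generate_emotion_dataset(
                world,
                n_observers_per_player,
                seed=int(rng.integers(2**31)),
                samples=smap,
                player_id=pid,
            )
        )
        if n_attrib_observers_per_player > 0:
            attrib_frames.append(
                generate_attribution_dataset(
                    world,
                    n_attrib_observers_per_player,
                    seed=int(rng.integers(2**31)),
                    prior=prior,
                    player_id=pid,
                )
            )
    emotion_df = pd.concat(emotion_frames, ignore_index=True)
    attrib_df = pd.concat(attrib_frames, ignore_index=True) if attrib_frames else None
    return priors, sample_map, emotion_df, attrib_df
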