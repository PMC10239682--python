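"""Emotion concepts: the learned map from appraisal distributions to the 20
emotion intensities, plus its MAP fitting, cross-validation and lesions.

A transform consists of a weight matrix ``beta`` (one column per emotion), an
intercept vector, and a per-emotion observation variance. A condition's
emotion likelihood is a weighted Gaussian mixture over the condition's
appraisal support: each support point contributes a kernel centred at
``inv_logit(k * psi_i @ beta + b)``. Sparsity in ``beta`` comes from an
independent Laplace prior on every weight, optimized by proximal gradient
ascent (soft-thresholding the l1 term); all 20 emotions are fit jointly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .appraisal import COMPONENTS, SOCIAL_LESION_COMPONENTS, AppraisalSample, compute_appraisal_distribution
from .game import Action, GameOutcome
from .inversion import MindPrior, base_marginal
from .planning import PlanningConfig, prior_mean_reputation

__all__ = [
    "EMOTIONS",
    "ConceptTransform",
    "FitInfo",
    "FitReport",
    "CVResult",
    "condition_key",
    "predict_emotions",
    "log_likelihood",
    "fit_map",
    "select_tau_cv",
    "beta_confidence",
    "lesion_inverse_planning",
    "lesion_social",
]

#: Canonical emotion label order (length 20).
EMOTIONS: tuple[str, ...] = (
    "Devastation",
    "Disappointment",
    "Contempt",
    "Disgust",
    "Envy",
    "Fury",
    "Annoyance",
    "Embarrassment",
    "Regret",
    "Guilt",
    "Confusion",
    "Surprise",
    "Sympathy",
    "Amusement",
    "Relief",
    "Respect",
    "Gratitude",
    "Pride",
    "Excitement",
    "Joy",
)

#: Logistic steepness constant of the appraisal-to-emotion link.
DEFAULT_K = 0.4


def condition_key(a1, a2, pot) -> tuple[str, str, float]:
    """Hashable condition key shared by datasets and sample maps."""
    a1 = a1.value if isinstance(a1, Action) else str(a1)
    a2 = a2.value if isinstance(a2, Action) else str(a2)
    return a1, a2, round(float(pot), 6)


@dataclass(frozen=True)
class ConceptTransform:
    """Parameters of the appraisal-to-emotion map."""

    beta: np.ndarray = field(repr=False)  # (p, 20)
    b: np.ndarray = field(repr=False)  # (20,)
    sigma2: np.ndarray = field(repr=False)  # (20,)
    k: float = DEFAULT_K
    tau: float = 1.0
    components: tuple[str, ...] = COMPONENTS
    emotions: tuple[str, ...] = EMOTIONS

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        b = np.asarray(self.b, dtype=float)
        s2 = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "sigma2", s2)
        p, m = len(self.components), len(self.emotions)
        if beta.shape != (p, m) or b.shape != (m,) or s2.shape != (m,):
            raise ValueError("transform parameter shapes are inconsistent")
        if np.any(s2 <= 0):
            raise ValueError("sigma2 must be strictly positive")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @classmethod
    def default(
        cls,
        components: Sequence[str] = COMPONENTS,
        k: float = DEFAULT_K,
        tau: float = 1.0,
    ) -> "ConceptTransform":
        p, m = len(components), len(EMOTIONS)
        return cls(np.zeros((p, m)), np.zeros(m), np.full(m, 0.04), k, tau, tuple(components))

    def to_json(self) -> str:
        return json.dumps(
            {
                "beta": self.beta.tolist(),
                "b": self.b.tolist(),
                "sigma2": self.sigma2.tolist(),
                "k": self.k,
                "tau": self.tau,
                "components": list(self.components),
                "emotions": list(self.emotions),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ConceptTransform":
        d = json.loads(text)
        return cls(
            np.array(d["beta"]),
            np.array(d["b"]),
            np.array(d["sigma2"]),
            d["k"],
            d["tau"],
            tuple(d["components"]),
            tuple(d["emotions"]),
        )


def predict_emotions(
    t: ConceptTransform, sample: AppraisalSample
) -> tuple[np.ndarray, np.ndarray]:
    """Per-support-point emotion means and their mixture expectation.

    Returns ``(mu, expectation)`` with ``mu`` of shape (n, 20) and the
    expectation the sample-weighted average, both in (0, 1). The sample must
    carry the same component basis (and scaling) the transform was fit on.
    """
    if sample.components != t.components:
        raise ValueError("sample components do not match the transform basis")
    mu = expit(t.k * sample.psi @ t.beta + t.b)
    return mu, sample.weights @ mu


# ---------------------------------------------------------------------------
# likelihood and MAP fitting
# ---------------------------------------------------------------------------

def _prepare_groups(
    data: pd.DataFrame,
    samples: Mapping[tuple, AppraisalSample],
    emotions: Sequence[str],
    by_player: bool = False,
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Group emotion rows by condition and pair them with their appraisal mix.

    With ``by_player`` the sample map is keyed ``(player_id, a1, a2, pot)``.
    """
    cols = ["player_id", "a1", "a2", "pot"] if by_player else ["a1", "a2", "pot"]
    groups = []
    for key, df in data.groupby(cols, sort=True):
        skey = (key[0], *condition_key(*key[1:])) if by_player else condition_key(*key)
        if skey not in samples:
            raise KeyError(f"no appraisal sample for condition {skey}")
        s = samples[skey]
        keep = s.weights > 0
        groups.append(
            (
                np.ascontiguousarray(s.psi[keep]),
                np.log(s.weights[keep]),
                np.ascontiguousarray(df[list(emotions)].to_numpy(dtype=float)),
            )
        )
    return groups


def _ll_terms(groups, beta, b, ls2, k, want_grad=True):
    """Mixture log-likelihood and (optionally) its gradient in (beta, b, ls2)."""
    s2 = np.exp(ls2)
    log_norm = float(np.sum(-0.5 * np.log(2.0 * np.pi * s2)))
    inv2 = 1.0 / (2.0 * s2)
    ll = 0.0
    gB = np.zeros_like(beta) if want_grad else None
    gb = np.zeros_like(b) if want_grad else None
    gs2 = np.zeros_like(s2) if want_grad else None
    for psi, logw, E in groups:
        mu = expit(k * psi @ beta + b)  # (N, 20)
        quad_e = (E * E) @ inv2  # (m,)
        quad_m = (mu * mu) @ inv2  # (N,)
        cross = E @ (mu / s2).T  # (m, N)
        a = logw[None, :] + cross - quad_e[:, None] - quad_m[None, :] + log_norm
        amax = a.max(axis=1, keepdims=True)
        se = np.exp(a - amax)
        ssum = se.sum(axis=1)
        ll += float(np.log(ssum).sum() + amax.sum())
        if not want_grad:
            continue
        R = se / ssum[:, None]  # responsibilities (m, N)
        r0 = R.sum(axis=0)
        G_mu = (R.T @ E - r0[:, None] * mu) / s2
        G_z = G_mu * mu * (1.0 - mu)
        gB += k * psi.T @ G_z
        gb += G_z.sum(axis=0)
        S = (E * E).sum(axis=0) - 2.0 * (E * (R @ mu)).sum(axis=0) + r0 @ (mu * mu)
        gs2 += S / (2.0 * s2 * s2) - E.shape[0] / (2.0 * s2)
    if want_grad:
        return ll, gB, gb, gs2 * s2  # chain rule to log-variance space
    return ll


def log_likelihood(
    t: ConceptTransform,
    data: pd.DataFrame,
    samples: Mapping[tuple, AppraisalSample],
    by_player: bool = False,
) -> float:
    """Total mixture log-likelihood of an emotion dataset under a transform."""
    groups = _prepare_groups(data, samples, t.emotions, by_player)
    return _ll_terms(groups, t.beta, t.b, np.log(t.sigma2), t.k, want_grad=False)


@dataclass(frozen=True)
class FitInfo:
    """Outcome record of one MAP optimization run."""

    converged: bool
    n_iter: int
    objective: float
    trace: tuple[float, ...] = ()


_LS2_BOUNDS = (np.log(1e-5), 0.0)


def collinear_groups(
    samples: Iterable[AppraisalSample], tol: float = 1e-9
) -> list[tuple[list[int], np.ndarray]]:
    """Find sets of appraisal columns that are exactly (anti-)collinear.

    The appraisal basis contains provable degeneracies — for every base
    feature, PE equals minus the opponent counterfactual CFa2 pointwise, so
    only the difference of their weights is identifiable. Returns
    ``(indices, signs)`` per collinear set, signs relative to the first
    member, computed from pooled weighted correlations.
    """
    samples = list(samples)
    X = np.vstack([s.psi for s in samples])
    w = np.concatenate([s.weights for s in samples])
    w = w / w.sum()
    m = w @ X
    Xc = X - m
    cov = (Xc * w[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    p = X.shape[1]
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    R = np.zeros((p, p))
    nz = sd > 0
    R[np.ix_(nz, nz)] = cov[np.ix_(nz, nz)] / np.outer(sd[nz], sd[nz])
    for i in range(p):
        for j in range(i + 1, p):
            if abs(R[i, j]) >= 1.0 - tol:
                parent[find(j)] = find(i)
    out = []
    for root in set(map(find, range(p))):
        members = [i for i in range(p) if find(i) == root]
        if len(members) > 1:
            signs = np.array([1.0] + [np.sign(R[members[0], j]) for j in members[1:]])
            out.append((members, signs))
    return out


def canonicalize_beta(beta: np.ndarray, groups: list[tuple[list[int], np.ndarray]]) -> np.ndarray:
    """Minimal-norm representation of beta on exactly collinear column sets.

    Within a collinear set only the signed sum of weights matters; spreading
    it evenly (with the appropriate signs) picks the unique minimum-l2 point
    of the likelihood-equivalent, minimum-l1 solution set, making restarts
    comparable. Never decreases the MAP objective.
    """
    beta = np.array(beta, dtype=float, copy=True)
    for members, signs in groups:
        c = signs @ beta[members]  # identifiable combination, (n_emotions,)
        beta[members] = np.outer(signs, c / len(members))
    return beta


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def fit_map(
    data: pd.DataFrame,
    samples: Mapping[tuple, AppraisalSample],
    tau: float,
    init_seed: int = 0,
    k: float = DEFAULT_K,
    components: Sequence[str] = COMPONENTS,
    max_iter: int = 3000,
    tol: float = 1e-6,
    patience: int = 5,
    keep_trace: bool = False,
) -> tuple[ConceptTransform, FitInfo]:
    """MAP fit of the concept transform under a per-weight Laplace prior.

    Maximizes ``log L + M * log Laplace(beta; 0, tau)`` (M = number of emotion
    vectors, so data and prior keep a constant balance across dataset sizes)
    by proximal gradient ascent: the smooth part is climbed with
    Barzilai-Borwein spectral steps safeguarded by backtracking, the l1 term
    is handled by soft-thresholding beta. Only improving steps are accepted,
    so the objective trace is monotone; convergence is declared after
    ``patience`` consecutive relative improvements below ``tol``. The returned
    beta is canonicalized on exactly collinear appraisal columns (see
    :func:`collinear_groups`).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    groups = _prepare_groups(data, samples, EMOTIONS, by_player=False)
    M = int(sum(E.shape[0] for _, _, E in groups))
    pen = M / tau
    p = len(components)
    rng = np.random.default_rng(init_seed)

    E_all = np.vstack([E for _, _, E in groups])
    resid = np.vstack([E - E.mean(axis=0) for _, _, E in groups])
    beta = rng.normal(0.0, 0.1, size=(p, len(EMOTIONS)))
    b = logit(np.clip(E_all.mean(axis=0), 1e-3, 1.0 - 1e-3))
    ls2_init = np.clip(np.log(np.clip(resid.var(axis=0), 1e-6, None)), *_LS2_BOUNDS)

    def pack(beta, b, ls2):
        return np.concatenate([beta.ravel(), b, ls2])

    def unpack(x):
        nb = p * len(EMOTIONS)
        return (
            x[:nb].reshape(p, len(EMOTIONS)),
            x[nb : nb + len(EMOTIONS)],
            x[nb + len(EMOTIONS) :],
        )

    def smooth_grad(x):
        bta, bb, ls = unpack(x)
        ll, gB, gb, gls2 = _ll_terms(groups, bta, bb, ls, k)
        return ll, pack(gB, gb, gls2)

    def penalized_obj(x):
        bta, bb, ls = unpack(x)
        ll = _ll_terms(groups, bta, bb, ls, k, want_grad=False)
        return ll - pen * np.abs(bta).sum()

    trace: list[float] = []

    def climb(x, bounds, iters, tol_):
        """Proximal BB ascent within log-variance ``bounds``; monotone."""

        def prox(x, step):
            bta, bb, ls = unpack(x)
            return pack(_soft(bta, step * pen), bb, np.clip(ls, *bounds))

        x = prox(x, 0.0)
        ll, g = smooth_grad(x)
        bta = unpack(x)[0]
        obj = ll - pen * np.abs(bta).sum()
        step = 1.0 / max(M, 1)
        flat = 0
        it = 0
        done = False
        for it in range(1, iters + 1):
            accepted = False
            while step > 1e-18:
                x_n = prox(x + step * g, step)
                obj_n = penalized_obj(x_n)
                if np.isfinite(obj_n) and obj_n >= obj:
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                done = True
                break
            rel = (obj_n - obj) / (abs(obj) + 1.0)
            ll_n, g_n = smooth_grad(x_n)
            dx = x_n - x
            dg = g_n - g
            curv = -(dx @ dg)  # positive where the smooth part is locally concave
            step = float(dx @ dx / curv) if curv > 1e-12 else step * 2.0
            step = float(np.clip(step, 1e-12, 1e6))
            x, g, obj = x_n, g_n, obj_n
            if keep_trace:
                trace.append(obj)
            flat = flat + 1 if rel < tol_ else 0
            if flat >= patience:
                done = True
                break
        return x, obj, it, done

    # phase 1 (annealing): a generous kernel-variance floor keeps mixture
    # responsibilities soft, steering every restart into the same basin
    x0 = pack(beta, b, np.maximum(ls2_init, np.log(0.09)))
    x1, _, it1, _ = climb(x0, (np.log(0.09), 0.0), min(500, max_iter), max(tol, 1e-8))
    # phase 2: release the floor and polish
    x, obj, it2, converged = climb(x1, _LS2_BOUNDS, max_iter, tol)

    beta, b, ls2 = unpack(x)
    beta = canonicalize_beta(beta, collinear_groups(samples.values()))
    obj = penalized_obj(pack(beta, b, ls2))
    t = ConceptTransform(beta, b, np.exp(ls2), k, tau, tuple(components))
    info = FitInfo(
        converged=converged, n_iter=it1 + it2, objective=float(obj), trace=tuple(trace)
    )
    return t, info


# ---------------------------------------------------------------------------
# cross-validation over the Laplace scale
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVResult:
    """Hyperparameter search record plus held-out predictions per player."""

    folds: tuple[tuple[object, ...], ...]
    tau_per_fold: tuple[float, ...]
    scores: dict  # (fold_index, tau) -> mean per-row held-in score
    transforms: dict  # tau -> ConceptTransform fit on the generic data
    predictions: dict  # (player_id, a1, a2, pot) -> (20,) expectation


def select_tau_cv(
    generic_data: pd.DataFrame,
    generic_samples: Mapping[tuple, AppraisalSample],
    specific_data: pd.DataFrame,
    specific_samples: Mapping[tuple, AppraisalSample],
    tau_grid: Sequence[float],
    k_folds: int = 4,
    seed: int = 0,
    **fit_kwargs,
) -> CVResult:
    """Grid-search the Laplace scale by K-fold CV over the specific players.

    For every tau the transform is fit once on the generic training data.
    Players are partitioned into folds; within a fold iteration, generalization
    (mean per-row log-likelihood) on the players *outside* the fold selects
    tau — ties within one standard error resolved toward the smallest
    (sparsest) tau — and the winning transform predicts the held-out players.
    Every player therefore receives predictions from a tau selected without
    its own data.
    """
    tau_grid = sorted(float(t) for t in tau_grid)
    players = sorted(specific_data["player_id"].unique().tolist())
    rng = np.random.default_rng(seed)
    order = [players[i] for i in rng.permutation(len(players))]
    fold_sizes = np.full(k_folds, len(players) // k_folds)
    fold_sizes[: len(players) % k_folds] += 1
    folds, start = [], 0
    for fs in fold_sizes:
        folds.append(tuple(order[start : start + fs]))
        start += fs

    transforms = {
        tau: fit_map(generic_data, generic_samples, tau, **fit_kwargs)[0]
        for tau in tau_grid
    }

    # per-player mean log-likelihood per tau, computed once
    player_score: dict[tuple[object, float], float] = {}
    for pid, df in specific_data.groupby("player_id", sort=True):
        for tau, t in transforms.items():
            player_score[(pid, tau)] = (
                log_likelihood(t, df, specific_samples, by_player=True) / len(df)
            )

    scores: dict[tuple[int, float], float] = {}
    tau_per_fold = []
    predictions: dict[tuple, np.ndarray] = {}
    for fi, heldout in enumerate(folds):
        cv_players = [p for p in players if p not in heldout]
        per_tau = {}
        for tau in tau_grid:
            vals = np.array([player_score[(p, tau)] for p in cv_players])
            per_tau[tau] = (vals.mean(), vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
            scores[(fi, tau)] = float(vals.mean())
        best_tau = max(per_tau, key=lambda t: per_tau[t][0])
        threshold = per_tau[best_tau][0] - per_tau[best_tau][1]
        chosen = min(t for t in tau_grid if per_tau[t][0] >= threshold)
        tau_per_fold.append(chosen)
        t = transforms[chosen]
        for key, s in specific_samples.items():
            if key[0] in heldout:
                predictions[key] = predict_emotions(t, s)[1]
    return CVResult(
        folds=tuple(folds),
        tau_per_fold=tuple(tau_per_fold),
        scores=scores,
        transforms=transforms,
        predictions=predictions,
    )


# ---------------------------------------------------------------------------
# restart-based confidence intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitReport:
    """Summary of many randomly initialized MAP fits.

    Saturation flags a weight whose 99% restart interval excludes zero.
    """

    expectation: np.ndarray = field(repr=False)  # (p, 20)
    lo95: np.ndarray = field(repr=False)
    hi95: np.ndarray = field(repr=False)
    lo99: np.ndarray = field(repr=False)
    hi99: np.ndarray = field(repr=False)
    saturated: np.ndarray = field(repr=False)  # bool (p, 20)
    n_restarts: int = 0
    objectives: tuple[float, ...] = ()
    best: ConceptTransform | None = None

    def __post_init__(self) -> None:
        if np.any(self.lo99 > self.lo95 + 1e-12) or np.any(self.hi99 < self.hi95 - 1e-12):
            raise ValueError("99% intervals must contain 95% intervals")


def beta_confidence(
    fit: Callable[[int], tuple[ConceptTransform, FitInfo]],
    n_restarts: int = 50,
    seed: int = 0,
) -> FitReport:
    """Empirical restart intervals of the beta weights.

    ``fit`` maps an init seed to a fitted transform; restart seeds are spawned
    deterministically from ``seed``.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_restarts)
    betas, objs, best = [], [], None
    for s in seeds:
        t, info = fit(int(s))
        betas.append(t.beta)
        objs.append(info.objective)
        if best is None or info.objective > best[1].objective:
            best = (t, info)
    B = np.stack(betas)  # (R, p, 20)
    lo95, hi95 = np.quantile(B, [0.025, 0.975], axis=0)
    lo99, hi99 = np.quantile(B, [0.005, 0.995], axis=0)
    saturated = (lo99 > 0) | (hi99 < 0)
    return FitReport(
        expectation=B.mean(axis=0),
        lo95=lo95,
        hi95=hi95,
        lo99=lo99,
        hi99=hi99,
        saturated=saturated,
        n_restarts=n_restarts,
        objectives=tuple(objs),
        best=best[0],
    )


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def lesion_inverse_planning(
    prior: MindPrior, outcome: GameOutcome, cfg: PlanningConfig
) -> AppraisalSample:
    """Appraisal distribution with inverse planning blocked.

    Support weights stay at the prior (no conditioning on a1) and the embedded
    naive-observer loop is likewise prior-based, so the reputation table is
    the prior mean for either action. Appraisal computation itself is
    unchanged and still depends on the realized actions.
    """
    repu = prior_mean_reputation(base_marginal(prior), outcome.pot)
    return compute_appraisal_distribution(prior, outcome, cfg, repu)


def lesion_social(sample: AppraisalSample) -> AppraisalSample:
    """Restrict an appraisal sample to the monetary AU/PE basis.

    Planning (and hence the sample's weights) is left intact; only the
    appraisal basis shrinks to ``(au_money_base, pe_money_base)``.
    """
    return sample.project(SOCIAL_LESION_COMPONENTS)
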