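import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from emopred import synthdata
from emopred.appraisal import COMPONENTS, SOCIAL_LESION_COMPONENTS, AppraisalSample
from emopred.concepts import (
    EMOTIONS,
    ConceptTransform,
    FitReport,
    beta_confidence,
    canonicalize_beta,
    collinear_groups,
    condition_key,
    fit_map,
    lesion_inverse_planning,
    lesion_social,
    log_likelihood,
    predict_emotions,
    select_tau_cv,
)
from emopred.game import Action, GameOutcome
from emopred.planning import prior_mean_reputation
from emopred.inversion import base_marginal

C, D = Action.C, Action.D


@pytest.fixture(scope="module")
def tiny_world():
    return synthdata.make_world(seed=3, n_w=2, n_pi=3, n_pots=2, lam=0.3)


@pytest.fixture(scope="module")
def tiny_data(tiny_world):
    return synthdata.generate_emotion_dataset(tiny_world, 40, seed=11)


def _sample(psi, weights=None, components=COMPONENTS):
    n = psi.shape[0]
    w = np.full(n, 1.0 / n) if weights is None else weights
    return AppraisalSample(
        psi=psi, weights=w, outcome=GameOutcome(C, C, 10.0), components=tuple(components)
    )


class TestConceptTransform:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            ConceptTransform(np.zeros((18, 20)), np.zeros(20), np.ones(20))
        with pytest.raises(ValueError):
            ConceptTransform(np.zeros((19, 20)), np.zeros(20), np.zeros(20))
        with pytest.raises(ValueError):
            ConceptTransform(np.zeros((19, 20)), np.zeros(20), np.ones(20), k=0.0)

    def test_twenty_emotions(self):
        assert len(EMOTIONS) == 20
        assert EMOTIONS[0] == "Devastation" and EMOTIONS[-1] == "Joy"

    def test_json_roundtrip(self):
        t = ConceptTransform.default(tau=2.5)
        t2 = ConceptTransform.from_json(t.to_json())
        np.testing.assert_array_equal(t.beta, t2.beta)
        assert t2.tau == 2.5 and t2.components == COMPONENTS


class TestPredictEmotions:
    def test_zero_beta_constant_inverse_logit_b(self, rng):
        b = rng.normal(size=20)
        t = ConceptTransform(np.zeros((19, 20)), b, np.full(20, 0.01))
        mu, exp = predict_emotions(t, _sample(rng.normal(size=(7, 19))))
        np.testing.assert_allclose(exp, expit(b), atol=1e-12)
        np.testing.assert_allclose(mu, expit(b)[None, :].repeat(7, axis=0))

    def test_monotone_in_positive_weight(self):
        beta = np.zeros((19, 20))
        beta[4, 2] = 1.3
        t = ConceptTransform(beta, np.zeros(20), np.full(20, 0.01))
        lo = predict_emotions(t, _sample(np.zeros((1, 19))))[1][2]
        psi = np.zeros((1, 19))
        psi[0, 4] = 2.0
        hi = predict_emotions(t, _sample(psi))[1][2]
        assert hi > lo

    def test_single_sample_closed_form(self):
        beta = np.full((19, 20), 0.1)
        b = np.full(20, -0.3)
        t = ConceptTransform(beta, b, np.full(20, 0.01))
        psi = np.arange(19.0)[None, :]
        _, exp = predict_emotions(t, _sample(psi))
        np.testing.assert_allclose(exp, expit(0.4 * (psi @ beta)[0] - 0.3), atol=1e-12)

    def test_outputs_in_unit_interval(self, rng):
        t = ConceptTransform(rng.normal(size=(19, 20)), rng.normal(size=20), np.ones(20))
        mu, exp = predict_emotions(t, _sample(rng.normal(size=(30, 19))))
        assert np.all((mu > 0) & (mu < 1)) and np.all((exp > 0) & (exp < 1))

    def test_component_mismatch_rejected(self, rng):
        t = ConceptTransform.default(components=SOCIAL_LESION_COMPONENTS)
        with pytest.raises(ValueError):
            predict_emotions(t, _sample(rng.normal(size=(3, 19))))


def _emotion_rows(vectors, a1="C", a2="C", pot=10.0):
    rows = []
    for i, e in enumerate(vectors):
        rows.append(
            {"observer_id": f"o{i}", "player_id": "generic", "a1": a1, "a2": a2,
             "pot": pot, **dict(zip(EMOTIONS, e))}
        )
    return pd.DataFrame(rows)


class TestLogLikelihood:
    def test_single_component_plain_gaussian(self, rng):
        t = ConceptTransform(
            rng.normal(size=(19, 20)) * 0.1, rng.normal(size=20), np.full(20, 0.04)
        )
        psi = rng.normal(size=(1, 19))
        e = rng.uniform(0.2, 0.8, size=(3, 20))
        data = _emotion_rows(e)
        samples = {condition_key("C", "C", 10.0): _sample(psi)}
        mu = expit(0.4 * psi @ t.beta + t.b)[0]
        expected = norm.logpdf(e, loc=mu, scale=0.2).sum()
        assert log_likelihood(t, data, samples) == pytest.approx(expected, rel=1e-12)

    def test_duplicated_components_unchanged(self, rng):
        t = ConceptTransform(rng.normal(size=(19, 20)) * 0.1, np.zeros(20), np.full(20, 0.09))
        psi = rng.normal(size=(4, 19))
        e = rng.uniform(0.2, 0.8, size=(5, 20))
        data = _emotion_rows(e)
        single = {condition_key("C", "C", 10.0): _sample(psi)}
        doubled = {
            condition_key("C", "C", 10.0): _sample(
                np.vstack([psi, psi]), np.full(8, 1 / 8)
            )
        }
        assert log_likelihood(t, data, single) == pytest.approx(
            log_likelihood(t, data, doubled), rel=1e-12
        )

    def test_two_component_mixture_hand_value(self):
        # 2 mixture components, check against direct density arithmetic
        rng = np.random.default_rng(5)
        t = ConceptTransform(rng.normal(size=(19, 20)) * 0.2, np.zeros(20), np.full(20, 0.04))
        psi = rng.normal(size=(2, 19))
        e = rng.uniform(0.3, 0.7, size=(1, 20))
        data = _emotion_rows(e)
        samples = {condition_key("C", "C", 10.0): _sample(psi, np.array([0.25, 0.75]))}
        mu = expit(0.4 * psi @ t.beta + t.b)
        dens = 0.25 * np.prod(norm.pdf(e[0], mu[0], 0.2)) + 0.75 * np.prod(
            norm.pdf(e[0], mu[1], 0.2)
        )
        assert log_likelihood(t, data, samples) == pytest.approx(np.log(dens), rel=1e-10)

    def test_missing_condition_raises(self, rng):
        t = ConceptTransform.default()
        with pytest.raises(KeyError):
            log_likelihood(t, _emotion_rows(rng.uniform(size=(2, 20))), {})


class TestFitMap:
    def test_tau_must_be_positive(self, tiny_data, tiny_world):
        with pytest.raises(ValueError):
            fit_map(tiny_data, tiny_world.samples, tau=0.0)

    def test_tiny_tau_collapses_beta(self, tiny_data, tiny_world):
        t, info = fit_map(tiny_data, tiny_world.samples, tau=1e-3, init_seed=0)
        assert np.all(t.beta == 0.0)
        grand = tiny_data[list(EMOTIONS)].mean().to_numpy()
        _, exp = predict_emotions(t, next(iter(tiny_world.samples.values())))
        np.testing.assert_allclose(exp, expit(t.b), atol=1e-12)
        # intercepts stay close to the grand means when beta is silenced
        assert np.abs(expit(t.b) - grand).max() < 0.1

    def test_monotone_objective_trace(self, tiny_data, tiny_world):
        _, info = fit_map(tiny_data, tiny_world.samples, tau=20.0, init_seed=1, keep_trace=True)
        trace = np.array(info.trace)
        assert np.all(np.diff(trace) >= -1e-9)

    def test_reproducible_per_seed(self, tiny_data, tiny_world):
        t1, _ = fit_map(tiny_data, tiny_world.samples, tau=20.0, init_seed=4)
        t2, _ = fit_map(tiny_data, tiny_world.samples, tau=20.0, init_seed=4)
        np.testing.assert_array_equal(t1.beta, t2.beta)

    def test_large_tau_approaches_unpenalized_fit(self, rng):
        # single condition, single mixture component: logistic regression in
        # disguise; with a huge tau the penalty is negligible and the fitted
        # mean must approach the sample mean of a well-specified model
        psi = np.vstack([np.eye(3), -np.eye(3)]) @ rng.normal(size=(3, 2))
        psi = np.hstack([psi, np.zeros((6, 17))])
        true_beta = np.zeros((19, 20))
        true_beta[0, :5] = 1.0
        mu = expit(0.4 * psi @ true_beta)
        frames = []
        for i, p in enumerate(psi):
            e = np.clip(mu[i] + rng.normal(0, 0.02, size=(40, 20)), 0, 1)
            frames.append(_emotion_rows(e, pot=float(i + 1)))
        data = pd.concat(frames, ignore_index=True)
        samples = {
            condition_key("C", "C", float(i + 1)): _sample(psi[i : i + 1])
            for i in range(len(psi))
        }
        t, info = fit_map(data, samples, tau=1e6, init_seed=0)
        pred = expit(0.4 * psi @ t.beta + t.b)
        assert np.abs(pred - mu).max() < 0.02

    def test_matches_convex_solver_on_toy(self, rng):
        # one mixture component per condition and fixed variance scale:
        # the MAP objective is an l1-penalized smooth program a generic
        # solver can also climb; compare achieved penalized objectives
        from scipy.optimize import minimize

        psi = rng.normal(size=(3, 19))
        e = rng.uniform(0.3, 0.7, size=(6, 20))
        data = pd.concat(
            [_emotion_rows(e[2 * i : 2 * i + 2], pot=float(i + 1)) for i in range(3)],
            ignore_index=True,
        )
        samples = {
            condition_key("C", "C", float(i + 1)): _sample(psi[i : i + 1])
            for i in range(3)
        }
        tau = 5.0
        t, info = fit_map(data, samples, tau=tau, init_seed=0)
        M = len(data)

        def neg_obj(x):
            beta = x[: 19 * 20].reshape(19, 20)
            b = x[19 * 20 : 19 * 20 + 20]
            ls2 = np.clip(x[-20:], np.log(1e-5), 0.0)
            ll = 0.0
            for i in range(3):
                mu = expit(0.4 * psi[i] @ beta + b)
                rows = e[2 * i : 2 * i + 2]
                ll += norm.logpdf(rows, mu, np.exp(0.5 * ls2)).sum()
            # smooth |.| surrogate tight enough at this tolerance
            return -(ll - (M / tau) * np.sqrt(beta**2 + 1e-12).sum())

        x0 = np.concatenate([np.zeros(19 * 20), logit(e.mean(0)), np.log(e.var(0) + 1e-3)])
        res = minimize(neg_obj, x0, method="L-BFGS-B", options={"maxiter": 2000})
        assert info.objective >= -res.fun - 1.0


class TestCollinearity:
    def test_pe_cfa2_pairs_detected(self, tiny_world):
        groups = collinear_groups(tiny_world.samples.values())
        pairs = {frozenset(COMPONENTS[i] for i in members) for members, _ in groups}
        for f in ("money", "aia", "dia"):
            assert any({f"pe_{f}_base", f"cf_a2_{f}_base"} <= p for p in pairs)

    def test_pe_equals_minus_cfa2_pointwise(self, tiny_world):
        # the provable identity behind the degeneracy
        for s in tiny_world.samples.values():
            for f in ("money", "aia", "dia"):
                np.testing.assert_allclose(
                    s.column(f"pe_{f}_base"), -s.column(f"cf_a2_{f}_base"), atol=1e-9
                )

    def test_canonicalize_preserves_fit_and_penalty(self, tiny_world, rng):
        groups = collinear_groups(tiny_world.samples.values())
        beta = rng.normal(size=(19, 20))
        canon = canonicalize_beta(beta, groups)
        s = next(iter(tiny_world.samples.values()))
        np.testing.assert_allclose(s.psi @ canon, s.psi @ beta, atol=1e-8)
        assert np.abs(canon).sum() <= np.abs(beta).sum() + 1e-12

    def test_canonical_idempotent(self, tiny_world, rng):
        groups = collinear_groups(tiny_world.samples.values())
        canon = canonicalize_beta(rng.normal(size=(19, 20)), groups)
        np.testing.assert_allclose(canonicalize_beta(canon, groups), canon, atol=1e-12)


@pytest.fixture(scope="module")
def cv_setup(tiny_world):
    gen = synthdata.generate_emotion_dataset(tiny_world, 40, seed=21)
    priors, spec_samples, spec_emo, _ = synthdata.generate_specific_players(
        tiny_world, 8, perturb_scale=1.0, seed=22, n_observers_per_player=6
    )
    return gen, spec_samples, spec_emo


class TestSelectTauCV:
    def test_single_tau_trivially_selected(self, tiny_world, cv_setup):
        gen, spec_samples, spec_emo = cv_setup
        cv = select_tau_cv(gen, tiny_world.samples, spec_emo, spec_samples, [20.0], k_folds=4)
        assert cv.tau_per_fold == (20.0,) * 4

    def test_every_player_held_out_once(self, tiny_world, cv_setup):
        gen, spec_samples, spec_emo = cv_setup
        cv = select_tau_cv(gen, tiny_world.samples, spec_emo, spec_samples, [20.0], k_folds=4)
        players = sorted(spec_emo["player_id"].unique())
        seen = [p for fold in cv.folds for p in fold]
        assert sorted(seen) == players
        predicted = {k[0] for k in cv.predictions}
        assert predicted == set(players)

    def test_uneven_folds_allowed(self, tiny_world, cv_setup):
        gen, spec_samples, spec_emo = cv_setup
        cv = select_tau_cv(gen, tiny_world.samples, spec_emo, spec_samples, [20.0], k_folds=3)
        sizes = sorted(len(f) for f in cv.folds)
        assert sizes == [2, 3, 3]

    def test_selects_workable_tau_over_degenerate_one(self, tiny_world, cv_setup):
        # 1e-3 forces an all-zero transform; a moderate scale must win
        gen, spec_samples, spec_emo = cv_setup
        cv = select_tau_cv(
            gen, tiny_world.samples, spec_emo, spec_samples, [1e-3, 20.0], k_folds=4
        )
        assert all(t == 20.0 for t in cv.tau_per_fold)


class TestBetaConfidence:
    def test_identical_restarts_zero_width(self):
        t = ConceptTransform.default()
        fake = lambda seed: (t, type("I", (), {"objective": 1.0})())
        rep = beta_confidence(fake, n_restarts=5, seed=0)
        np.testing.assert_array_equal(rep.lo99, rep.hi99)
        assert not rep.saturated.any()  # all-zero beta never saturates

    def test_saturation_semantics(self):
        rng = np.random.default_rng(0)

        def fake(seed):
            local = np.random.default_rng(seed)
            beta = np.zeros((19, 20))
            beta[0, 0] = 1.0 + 0.01 * local.normal()  # tight, away from zero
            beta[1, 1] = 0.05 * local.normal()  # straddles zero
            return (
                ConceptTransform(beta, np.zeros(20), np.ones(20)),
                type("I", (), {"objective": float(local.normal())})(),
            )

        rep = beta_confidence(fake, n_restarts=40, seed=1)
        assert rep.saturated[0, 0]
        assert not rep.saturated[1, 1]
        assert np.all(rep.lo99 <= rep.lo95) and np.all(rep.hi95 <= rep.hi99)

    def test_interval_nesting_enforced(self):
        with pytest.raises(ValueError):
            FitReport(
                expectation=np.zeros((1, 1)),
                lo95=np.array([[0.0]]),
                hi95=np.array([[1.0]]),
                lo99=np.array([[0.5]]),  # narrower than 95: invalid
                hi99=np.array([[1.0]]),
                saturated=np.array([[False]]),
            )


class TestLesions:
    def test_ip_lesion_uses_prior_weights(self, tiny_world):
        outcome = GameOutcome(C, D, float(tiny_world.pots[0]))
        s = lesion_inverse_planning(tiny_world.prior, outcome, tiny_world.cfg)
        np.testing.assert_array_equal(s.weights, tiny_world.prior.weights)

    def test_ip_lesion_invariant_to_a1_of_weights(self, tiny_world):
        # weights are prior weights whichever action is realized
        pot = float(tiny_world.pots[0])
        s1 = lesion_inverse_planning(tiny_world.prior, GameOutcome(C, C, pot), tiny_world.cfg)
        s2 = lesion_inverse_planning(tiny_world.prior, GameOutcome(D, C, pot), tiny_world.cfg)
        np.testing.assert_array_equal(s1.weights, s2.weights)

    def test_ip_lesion_manual_substitution_oracle(self, tiny_world):
        from emopred.appraisal import compute_appraisal_distribution

        pot = float(tiny_world.pots[1])
        outcome = GameOutcome(C, D, pot)
        repu = prior_mean_reputation(base_marginal(tiny_world.prior), pot)
        manual = compute_appraisal_distribution(tiny_world.prior, outcome, tiny_world.cfg, repu)
        auto = lesion_inverse_planning(tiny_world.prior, outcome, tiny_world.cfg)
        np.testing.assert_allclose(auto.psi, manual.psi, atol=1e-12)

    def test_ip_lesion_cf_a1_repu_identically_zero(self, tiny_world):
        # prior-based loop: both actions share the reputation table, so the
        # own-action reputation contrast vanishes
        s = lesion_inverse_planning(
            tiny_world.prior, GameOutcome(C, D, float(tiny_world.pots[0])), tiny_world.cfg
        )
        for f in ("money", "aia", "dia"):
            np.testing.assert_allclose(s.column(f"cf_a1_{f}_repu"), 0.0, atol=1e-12)

    def test_social_lesion_projects_two_columns(self, tiny_world):
        s = next(iter(tiny_world.samples.values()))
        proj = lesion_social(s)
        assert proj.components == SOCIAL_LESION_COMPONENTS
        assert proj.psi.shape[1] == 2
        np.testing.assert_array_equal(proj.weights, s.weights)
        np.testing.assert_array_equal(proj.psi[:, 0], s.column("au_money_base"))
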