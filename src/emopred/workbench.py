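"""Run configuration and the command-line interface.

A single JSON config drives every stage; all randomness flows from its seed
(or the ``--seed`` override). Subcommands mirror the pipeline stages:
``simulate``, ``invert``, ``appraise``, ``synth``, ``fit``, ``predict``,
``evaluate``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import concepts, evaluation, inversion, pipeline, synthdata
from .appraisal import COMPONENTS
from .concepts import EMOTIONS
from .game import Action, POT_MAX, POT_MIN, pot_grid
from .planning import PlanningConfig, default_pi_money_marginal, support_policy

__all__ = ["RunConfig", "cli"]


@dataclass(frozen=True)
class RunConfig:
    """Validated, round-trippable run configuration."""

    n_w: int = 5
    n_pi: int = 6
    lam: float = 1.0
    k: float = 0.4
    n_pots: int = 8
    pot_min: float = POT_MIN
    pot_max: float = POT_MAX
    pi_money_values: tuple[float, ...] | None = None  # None: derive from pots
    pi_money_weights: tuple[float, ...] | None = None
    tau_grid: tuple[float, ...] = (0.03, 0.1, 0.3, 1.0)
    k_folds: int = 4
    n_restarts: int = 50
    mixture_components: int = 64
    bootstrap_b: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_w, self.n_pi, self.n_pots, self.k_folds, self.n_restarts) < 1:
            raise ValueError("counts must be >= 1")
        if self.lam < 0 or self.k <= 0:
            raise ValueError("need lam >= 0 and k > 0")
        if not self.tau_grid or any(t <= 0 for t in self.tau_grid):
            raise ValueError("tau_grid must be nonempty and positive")
        if (self.pi_money_values is None) != (self.pi_money_weights is None):
            raise ValueError("pi_money values and weights must be given together")

    # -- serialization ------------------------------------------------------

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("pi_money_values", "pi_money_weights", "tau_grid"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def sha1(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()

    # -- derived objects ----------------------------------------------------

    def pots(self) -> np.ndarray:
        return pot_grid(self.n_pots, self.pot_min, self.pot_max)

    def planning(self, variant: str = "public") -> PlanningConfig:
        if self.pi_money_values is None:
            vals, wts = default_pi_money_marginal(self.pots())
        else:
            vals, wts = self.pi_money_values, self.pi_money_weights
        return PlanningConfig(self.lam, tuple(vals), tuple(wts), variant)

    def prior(self, attributions: pd.DataFrame | None = None) -> inversion.MindPrior:
        if attributions is None:
            return inversion.uniform_grid_prior("generic", self.n_w, self.n_pi)
        return inversion.fit_prior_from_attributions(
            attributions, "generic", self.n_w, self.n_pi
        )


def _log(stage: str, t0: float) -> None:
    print(f"[emopred] {stage} done in {time.perf_counter() - t0:.2f}s", file=sys.stderr)


def _write_json(path: Path, payload: dict, cfg: RunConfig) -> None:
    payload = {"config_sha1": cfg.sha1(), **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


@click.group()
def cli() -> None:
    """Inverse-planning emotion-prediction pipeline."""


_config_opt = click.option(
    "--config", "config_path", type=click.Path(exists=True), default=None,
    help="JSON run config (defaults used when omitted).",
)
_out_opt = click.option("--out", "out_dir", type=click.Path(), default=".", help="Output directory.")
_seed_opt = click.option("--seed", type=int, default=None, help="Override the config seed.")


def _load_cfg(config_path, seed) -> RunConfig:
    cfg = RunConfig.load(config_path) if config_path else RunConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
def simulate(config_path, out_dir, seed):
    """Marginal cooperation probability per pot and model variant."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    prior = cfg.prior()
    base = inversion.base_marginal(prior)
    rows = []
    for variant, pr in (("anonymous", base), ("public", prior)):
        pcfg = cfg.planning(variant)
        for pot in cfg.pots():
            repu = None
            if variant == "public":
                from .planning import reputation_expectation

                repu = reputation_expectation(base, pot, pcfg)
            pol = support_policy(pr.support, pot, pcfg, repu)
            rows.append(
                {
                    "pot": float(pot),
                    "model_variant": variant,
                    "prior": pr.variant,
                    "p_cooperate": float(pr.weights @ pol[:, 0]),
                }
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "choice_probabilities.csv", index=False)
    _log("simulate", t0)


@cli.command("invert")
@_config_opt
@_out_opt
@_seed_opt
@click.option("--attributions", type=click.Path(exists=True), default=None,
              help="Attribution CSV to fit the prior from.")
def invert_cmd(config_path, out_dir, seed, attributions):
    """Posterior mean preferences/belief per observed action and pot."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    attr = pd.read_csv(attributions) if attributions else None
    prior = cfg.prior(attr)
    pcfg = cfg.planning()
    rows = []
    for pot in cfg.pots():
        for a1 in (Action.C, Action.D):
            post = inversion.invert(prior, a1, pot, pcfg)
            rows.append(
                {"a1": a1.value, "pot": float(pot), **inversion.posterior_expectations(post)}
            )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "posterior_expectations.csv", index=False)
    _log("invert", t0)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@click.option("--attributions", type=click.Path(exists=True), default=None)
def appraise(config_path, out_dir, seed, attributions):
    """Expected (standardized) appraisal vector per game condition."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    attr = pd.read_csv(attributions) if attributions else None
    prior = cfg.prior(attr)
    samples, scale = pipeline.standardize_map(
        pipeline.posterior_sample_map(prior, cfg.planning(), cfg.pots())
    )
    rows = []
    for (a1, a2, pot), s in sorted(samples.items()):
        rows.append(
            {"a1": a1, "a2": a2, "pot": pot, **dict(zip(COMPONENTS, map(float, s.expectation())))}
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "appraisal_expectations.csv", index=False)
    _write_json(out / "appraisal_scale.json",
                {"components": list(COMPONENTS), "scale": scale.tolist()}, cfg)
    _log("appraise", t0)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@click.option("--n-observers", type=int, default=100)
@click.option("--n-players", type=int, default=5)
def synth(config_path, out_dir, seed, n_observers, n_players):
    """Generate a synthetic world's datasets (attribution + emotion CSVs)."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    world = synthdata.make_world(
        seed=cfg.seed, n_w=min(cfg.n_w, 3), n_pi=cfg.n_pi, n_pots=cfg.n_pots,
        lam=cfg.lam, k=cfg.k,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    attr = synthdata.generate_attribution_dataset(world, n_observers, seed=cfg.seed + 1)
    emo = synthdata.generate_emotion_dataset(world, n_observers, seed=cfg.seed + 2)
    _, _, spec_emo, _ = synthdata.generate_specific_players(
        world, n_players, seed=cfg.seed + 3
    )
    attr.to_csv(out / "attributions_generic.csv", index=False)
    emo.to_csv(out / "emotions_generic.csv", index=False)
    spec_emo.to_csv(out / "emotions_specific.csv", index=False)
    _write_json(out / "true_transform.json",
                json.loads(world.transform.to_json()), cfg)
    _log("synth", t0)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@click.option("--emotions", "emotions_path", type=click.Path(exists=True), required=True,
              help="Generic emotion dataset CSV.")
@click.option("--attributions", type=click.Path(exists=True), default=None)
@click.option("--tau", type=float, default=None, help="Skip CV and fit at this tau.")
def fit(config_path, out_dir, seed, emotions_path, attributions, tau):
    """Fit the concept transform on a generic emotion dataset."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    data = pd.read_csv(emotions_path)
    attr = pd.read_csv(attributions) if attributions else None
    prior = cfg.prior(attr)
    samples, scale = pipeline.standardize_map(
        pipeline.posterior_sample_map(prior, cfg.planning(), cfg.pots())
    )
    samples = pipeline.resample_map(samples, cfg.mixture_components, cfg.seed)
    tau = tau if tau is not None else cfg.tau_grid[0]
    transform, info = concepts.fit_map(data, samples, tau, init_seed=cfg.seed, k=cfg.k)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(
        out / "transform.json",
        {
            **json.loads(transform.to_json()),
            "scale": scale.tolist(),
            "converged": info.converged,
            "n_iter": info.n_iter,
            "objective": info.objective,
            "seed": cfg.seed,
        },
        cfg,
    )
    _log("fit", t0)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@click.option("--transform", "transform_path", type=click.Path(exists=True), required=True)
@click.option("--attributions", type=click.Path(exists=True), default=None)
def predict(config_path, out_dir, seed, transform_path, attributions):
    """Predicted emotion expectations per condition under a fitted transform."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    payload = json.loads(Path(transform_path).read_text())
    transform = concepts.ConceptTransform.from_json(json.dumps(payload))
    scale = np.array(payload["scale"])
    attr = pd.read_csv(attributions) if attributions else None
    prior = cfg.prior(attr)
    samples = pipeline.scale_map(
        pipeline.posterior_sample_map(prior, cfg.planning(), cfg.pots()), scale
    )
    preds = pipeline.prediction_table(transform, samples)
    rows = [
        {"a1": k[0], "a2": k[1], "pot": k[2], **dict(zip(EMOTIONS, map(float, v)))}
        for k, v in sorted(preds.items())
    ]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
    _log("predict", t0)


@cli.command()
@_config_opt
@_out_opt
@_seed_opt
@click.option("--predictions", "predictions_path", type=click.Path(exists=True), required=True)
@click.option("--emotions", "emotions_path", type=click.Path(exists=True), required=True)
def evaluate(config_path, out_dir, seed, predictions_path, emotions_path):
    """Concordance between predicted and empirical per-condition emotions."""
    t0 = time.perf_counter()
    cfg = _load_cfg(config_path, seed)
    preds = pd.read_csv(predictions_path)
    emp = pd.read_csv(emotions_path)
    emp_means = emp.groupby(["a1", "a2", "pot"], sort=True)[list(EMOTIONS)].mean()
    merged = preds.set_index(["a1", "a2", "pot"]).join(
        emp_means, how="inner", lsuffix="_model", rsuffix="_emp"
    )
    x = merged[[f"{e}_model" for e in EMOTIONS]].to_numpy().ravel()
    y = merged[[f"{e}_emp" for e in EMOTIONS]].to_numpy().ravel()
    per_emotion = {
        e: evaluation.lin_ccc(
            merged[f"{e}_model"].to_numpy(), merged[f"{e}_emp"].to_numpy()
        )
        for e in EMOTIONS
    }
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_json(
        out / "evaluation.json",
        {"ccc_overall": evaluation.lin_ccc(x, y), "ccc_per_emotion": per_emotion,
         "n_conditions": int(len(merged)), "seed": cfg.seed},
        cfg,
    )
    _log("evaluate", t0)


if __name__ == "__main__":
    cli()
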