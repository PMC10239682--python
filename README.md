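# emopred

A generative model of how observers predict a game player's emotions in a
one-shot, public cooperate/defect ("split or steal") game.

The pipeline has three stages:

1. **Inverse planning** (`emopred.planning`, `emopred.inversion`) — a forward
   model of approximately rational play over six preference weights (money,
   advantageous- and disadvantageous-inequity aversion, each in a first-order
   "base" and second-order "reputation" flavour) plus a belief about the
   opponent. The public-game variant embeds a depth-1 naive observer that
   anticipates what others would infer about the player's base preferences.
   Minds live on a finite grid, so Bayesian conditioning on an observed action
   is exact enumeration.
2. **Computed appraisals** (`emopred.appraisal`) — for each candidate mind and
   realized outcome, a 19-component vector of achieved utilities, prediction
   errors, own- and opponent-action counterfactuals, and opponent surprise.
3. **Emotion concepts** (`emopred.concepts`) — a learned sparse transform
   (19×20 weights, logistic link, Gaussian-mixture likelihood over the
   appraisal posterior) mapping appraisal distributions to quantitative
   predictions of 20 emotions. Fitting is MAP with an independent Laplace
   prior per weight (proximal gradient with annealing), the prior scale is
   chosen by K-fold cross-validation over individuated test players, and
   restart-based confidence intervals flag saturated weights. Two lesions are
   included: blocking inverse planning (prior-weighted appraisals) and
   removing all non-monetary appraisals.

`emopred.synthdata` generates synthetic observer datasets (preference/belief
attributions and emotion ratings, generic and per-player) with the structure
the analysis assumes, so the whole pipeline is testable offline.
`emopred.evaluation` provides Lin's concordance correlation, bootstrap CIs and
the personalization-bias analysis. `emopred.pipeline` and `emopred.workbench`
tie the stages together behind a JSON config and a CLI.

## CLI

```sh
emopred simulate --config config.json --out out/   # P(cooperate) per pot/variant
emopred invert   --config config.json --out out/   # posterior mean preferences
emopred appraise --config config.json --out out/   # expected appraisals per condition
emopred synth    --config config.json --out out/   # synthetic datasets
emopred fit      --emotions out/emotions_generic.csv --out out/
emopred predict  --transform out/transform.json --out out/
emopred evaluate --predictions out/predictions.csv --emotions out/emotions_generic.csv --out out/
```

All commands accept `--config PATH` (JSON `RunConfig`; unknown keys rejected),
`--out DIR` and `--seed INT`. Every source of randomness flows from the config
seed or its override.

## Notes

- The appraisal basis contains an exact identity — each base feature's
  prediction error equals minus its opponent-action counterfactual — so
  concept weights on such column pairs are identifiable only up to their
  difference. Fitted weights are therefore reported in a canonical
  minimal-norm form (see `concepts.collinear_groups` /
  `concepts.canonicalize_beta`).
- Conditions are CSV-serializable everywhere: attribution datasets are long
  format (`observer_id, player_id, a1, pot, dimension, rating`), emotion
  datasets are wide format (`observer_id, player_id, a1, a2, pot` plus the 20
  canonical emotion columns).
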