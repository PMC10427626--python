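# advpercept

A desk-scale, fully offline pipeline for generating L∞-bounded adversarial
image stimuli and analyzing two-alternative forced-choice (2AFC)
psychophysics data. The package replaces ImageNet-scale classifier
ensembles and human participants with a verifiable synthetic testbed:
parametric shape/texture image populations, small differentiable scorers
trained in-repo (pure NumPy, hand-derived exact gradients), and simulated
Bernoulli observers with known ground-truth bias.

## What's inside

| module | role |
| --- | --- |
| `advpercept.synthetic_data` | synthetic image populations, toy scorer training, simulated 2AFC observers, the frozen default testbed |
| `advpercept.model_interface` | differentiable-scorer contract, temperature calibration, logit-mean ensembling, foveated ("retinal") blur |
| `advpercept.coarse_classes` | fine→coarse log-sum-exp score aggregation, coarse probabilities, paired-target class subsampling |
| `advpercept.adversarial_attack` | iterative sign-gradient attacks with ε-ball and range clipping, expectation-over-transformation (EOT) robustness, flipped-perturbation controls |
| `advpercept.stimuli` | experiment pair construction (E1–E5), session assembly with catch trials, PNG + manifest I/O |
| `advpercept.image_metrics` | perturbation edge strength (bilateral filter + Canny), multi-scale SSIM, luminance/contrast |
| `advpercept.behavior_analysis` | catch-trial exclusions, perceptual bias, ANN forced-choice observers, t tests, mixed ANOVA with partial η², Spearman, permutation nulls |

All scorers expose exact input-pixel gradients (vector–Jacobian
products); the geometric transforms and the retinal blur are linear
operators whose adjoints are implemented explicitly, so attack gradients
are exact and are verified against finite differences in the tests.

## CLI

```sh
# train and save the default synthetic testbed
advpercept make-testbed --out testbed/ --seed 0

# attack a PNG with a scorer ensemble
advpercept attack --source img.png --ensemble testbed/member_a0.npz,testbed/member_a1.npz \
    --mapping testbed/mapping.cfg --target boxy --epsilon 16 --seed 0 \
    --out adv.png --delta-out delta.npz

# build a full 104-trial session (8 catch trials) of stimulus pairs
advpercept build-session --experiment E4 --classes round,pointy \
    --epsilons 2,4,8,16 --seed 0 --out session/

# analyze a response table
advpercept analyze --responses responses.csv --manifest session/manifest.json \
    --experiment E4 --stats bias,ttest,anova,perm --seed 0 --out report.json
```

## File formats

- **Mapping config** — one line per coarse category, `name: idx,idx,...`
  with 0-based fine-class indices (a converter for 1-based lists is
  provided in `load_mapping`).
- **Response tables** — CSV with columns `participant_id, pair_id,
  question_class, epsilon, chosen_side, chose_adversarial_consistent,
  is_catch, catch_correct` (`catch_correct` is empty exactly on
  non-catch rows).
- **Stimuli** — 8-bit PNGs (what an observer would see) plus a JSON
  manifest linking trials to files, question class, consistency side, ε
  and generator provenance; fractional perturbations can be kept
  losslessly via `--delta-out`.

## Notes on defaults

- Attack defaults: step size α = 1 intensity level, iteration count
  2·ε, one fresh transform per EOT step, `sgn(0) = 0`, reflect padding
  for out-of-frame regions, rotation sampled one-sided from U(0, π/6)
  (a symmetric option exists).
- The retinal blur defaults to a no-op (σ_min = σ_max = 0); its profile
  is linear in eccentricity and interpolates a small bank of Gaussian
  levels.
- Edge-strength parameters default to values calibrated for
  perturbation-scale inputs; counts are parameter-dependent, so report
  them together with their `EdgeParams`.
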