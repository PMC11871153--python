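# Methods

This note documents the models, conventions and design choices behind
`leadgraph`, in the order a user meets them: the adjacency-graph estimator,
the graph augmentation proper, the classic augmentation suite, the
composition/tuning policy, the synthetic cohort generator, the reference
classifier and the robustness protocol.

## Lead-correlation adjacency graph

The augmentation graph's weight `A_ij` is the expectation, over records of
a cohort split, of the lag-0 normalized cross-correlation between leads
*i* and *j*.  Conventions, all chosen so that the weight is a true Pearson
correlation:

- Per-record means and standard deviations use the population convention
  (divide by T), and the centered cross-product sum is divided by T as
  well, so the self-correlation of any non-constant signal is exactly 1
  and every weight lies in [−1, 1].
- The expectation is the **unweighted mean over records**, one correlation
  per record per pair — not a single correlation of concatenated records.
  Per-record averaging keeps long records from dominating and matches the
  interpretation of "average correlation of the lead measurements".
- The diagonal is fixed to 0: a lead never contributes to its own
  surrogate.
- Weights keep their sign.  On a 12-lead ECG, aVR genuinely anti-correlates
  with the lateral leads, and that sign carries real geometry into the
  surrogate.
- A record in which a lead is constant has no defined correlation for that
  lead's pairs; such records are excluded from the affected pairs only and
  the exclusions logged.  A pair excluded in every record gets weight 0
  with a warning, never NaN.
- By default the graph is estimated from the **training split only**, so no
  held-out information leaks into the augmentation.  `split=None` averages
  over everything, for cohorts without split tags.

Sampling-rate heterogeneity is allowed and logged but not resampled: the
lag-0 correlation never uses the rate, and resampling is a user decision.

## Graph augmentation

For lead *i* of a record, the surrogate is `X̃^(i) = Σ_{j≠i} A_ij X^(j)`.
The augmented lead is the convex combination
`X̂^(i) = (1 − λ) X^(i) + λ X̃^(i)` with `λ ~ U(0, α)` drawn fresh per
mixed lead, the whole operation gated by a Bernoulli(p) draw.

Choices a user can make, with their defaults:

- **Gate scope** (`scope`, default `per-lead`): the Bernoulli gate is drawn
  independently per lead, matching a reading in which the gate applies
  "every time X̂ is computed"; `per-record` gates all leads together.
- **Weight normalization** (`normalize_weights`, default off): the raw
  weighted sum over L−1 leads can have an amplitude very different from the
  original lead (and additive sensor noise attenuates every `A_ij` by a
  common factor, shrinking the surrogate further).  With normalization the
  sum is divided by `Σ_j |A_ij|`, which cancels that attenuation and keeps
  the surrogate's amplitude comparable to the original.  The default stays
  with the plain weighted sum; both paths are tested.
- λ is never reused across leads, and the operation consumes only the
  random generator passed by the caller — no global seeding — so seeded
  pipelines are reproducible under any mapping order.

All surrogates are computed from the **original** record before any lead is
replaced: mixing lead 1 can never contaminate lead 2's surrogate within one
application.  The suite asserts this by construction, together with the
linearity of the surrogate in the record's signals and the endpoint
identities (λ=0 and p=0 are bit-exact no-ops, λ=1 reproduces the surrogate
exactly).

## Classic augmentations and the shared intensity

Four standard single-lead operations read one shared intensity γ:

| operation | effect | how γ enters |
|---|---|---|
| `gauss_noise` | i.i.d. Gaussian noise per sample | variance = γ · s², s = the lead's own sd |
| `time_transform` | cut or zero-pad then re-interpolate to length T | window = round(T·γ/100) samples |
| `smooth` | Gaussian-kernel moving average, half-width l ~ U{1..5} | kernel sd = γ·l |
| `mask` | one contiguous zero run at a random start | width = round(T·γ/100) |

Conventions: γ = 0 makes every operation the exact identity (the contract
the composition policy relies on); window sizes round half-to-even;
interpolation is linear (the 1-D analogue of bilinear); smoothing pads by
reflection and its kernel sums to 1, so constants are preserved exactly;
noise on a constant lead is skipped in the default relative mode (zero
variance), with an absolute-variance mode (`absolute=True`, variance = γ)
available.  Making the noise variance *relative* to the lead's variance
keeps γ dimensionless and comparable across leads and datasets.

One tension is worth knowing: γ is a percentage for the windowed
operations but a variance multiplier for the noise, so γ ≈ 10 means a mild
10 % mask yet a brutal 10× variance noise.  The shared parameter is the
point — RandAugment tunes a single magnitude — and in practice the grid
search settles on small γ with a larger operation count N when the noise
op is enabled.

`apply_classic` samples N operations uniformly **with replacement**
(RandAugment's convention) and applies them in sampled order to every lead
independently, with fresh randomness per lead per operation; labels are
never touched.

## Composition and tuning

`compose` applies the graph stage first and the classic stage second, and
offers no reverse order: classic, lead-wise perturbations corrupt exactly
the cross-lead correlations the adjacency matrix encodes, so mixing after
them would blend already-degraded leads.  The order is observable — the
surrogate is linear, so noise injected before mixing propagates into every
mixed lead — and the suite asserts it via that construction.

`grid_search` sweeps RandAugment's (N, γ) over a user grid with seeded
replicates per cell and reports mean ± sd validation macro-F1 plus the
argmax cell.  Graph-stage parameters (p, α) are held fixed during the
classic grid: the graph stage is one method with its own two knobs, and a
separate small grid can be run over them if desired.  Replicate seeds
derive from a `SeedSequence` of the caller's seed, so tables are exactly
reproducible.

## Synthetic dipole cohorts

The generator emulates the measurement geometry that motivates the whole
method: each record is a latent planar dipole trajectory d(t) — three
Gaussian pulses per beat with distinct directions, loosely P/QRS/T-like —
projected onto L unit vectors at configurable angles, plus i.i.d. Gaussian
sensor noise.  Per-beat timing jitter is ±2 % of the beat period and
per-beat amplitude jitter has sd 5 %; both are fixed constants.
Per-record **angle jitter** rotates each lead's direction by
N(0, `angle_jitter_sd`²), emulating electrode misplacement — the very
perturbation the graph augmentation trains against.

With `dipole_isotropy` the centered trajectory is whitened per record
(eigendecomposition of its 2×2 second-moment matrix), which makes the
lead-pair correlation equal to cos(θ_i − θ_j) *exactly* at zero noise and
zero jitter — the analytic oracle every graph test leans on.  Sensor noise
attenuates all correlations toward zero; angle jitter widens the
per-record spread of pair correlations.  Both directions are asserted.

Two-class tasks come from `make_separable_task`: class 1 differs from
class 0 only by scaling the QRS-like pulse's amplitude by
(1 + `effect_size`), so effect 0 gives statistically identical classes and
learnability rises smoothly with the effect.

What the generator does **not** emulate: real P-QRS-T morphology,
arrhythmia dynamics, baseline wander, powerline artifacts, inter-patient
morphology variation, or a 3-D torso volume conductor.  Passing tests show
the algorithms are correct against a controlled geometry, not that the
measured effect sizes transfer to clinical ECG cohorts.

## Reference classifier

The harness trains one small fixed 1-D CNN, implemented directly on numpy
with hand-written forward/backward passes (which is also what makes exact
input gradients available to the attack):

| layer | spec |
|---|---|
| conv blocks ×4 | kernel 7, 'same' padding, ReLU, average-pool 2; channels L→16→24→32→32 |
| head | global average pool over time → dropout 0.1 → linear → K logits |

Multi-class heads use softmax cross-entropy, multi-label heads per-class
sigmoid BCE with a fixed 0.5 decision threshold.  The optimizer is Adam
(lr 0.001, β = 0.9/0.999), batch size 32, l2 coefficient 1e-5 added to
weight gradients.  He-normal initialization; inputs are standardized per
lead with training-split statistics.  Inputs must be at least 16 samples
long (four pool halvings).  The backward pass is verified against central
finite differences in the suite.  The trainer accepts any augmenter as a
`(record, rng) → record` callable and applies it to **training batches
only** — validation and test signals are never augmented.

## Robustness protocol

`adversarial_sweep` perturbs each test signal by
`ε · sd_lead · sign(∂loss/∂input)` (single-step gradient sign; an iterated
projected variant is available) and reports macro-F1 per ε.  Expressing ε
in units of the per-lead training-set standard deviation makes sweeps
comparable across datasets.  The ε = 0 row evaluates the untouched signals
through the identical prediction path, so it equals the clean macro-F1
bit-for-bit.

`robustness_experiment` is the flagship comparison: one synthetic cohort,
split 70/15/15; the graph fitted on the training split; two arms —
classic-only and graph-then-classic — trained over the *same* list of
seeds; the sweep run on the test split; the report carries per-run values,
per-arm mean ± sd curves, and the seed-paired differences at every ε.  The
qualitative outcome — whether the graph arm is at least as robust at the
largest ε — is recorded as pass/fail and surfaced loudly on failure; it is
a 5-seed mean of a noisy difference, so the record and the per-seed table,
not a hard assertion, are the contract.  Runs at the reference conditions
have produced both small positive and occasionally small negative means,
with the graph arm consistently showing the lower replicate variance.

**Reference conditions** (`evaluate.reference_robustness_conditions`): a
2,000-record, 8-lead, 256-sample two-class cohort with sensor noise 0.4,
angle jitter 0.2 rad and effect size 0.3 — chosen to give moderate clean
difficulty while keeping the inter-lead correlation structure clearly
present (mean row sum of |A| ≈ 0.6); classic stage (N = 2, γ = 0.5),
selected by this package's own grid search on validation macro-F1; graph
stage at its defaults (p = 0.5, α = 0.3, unnormalized); 14 training
epochs; ε ∈ {0, 0.01, 0.02, 0.05}; 5 paired seeds per arm.  These sizes
keep the full experiment at a few CPU-minutes.

## Determinism

Every stochastic operation consumes a caller-supplied
`numpy.random.Generator`; nothing seeds globally.  Derived seeds come from
`SeedSequence` spawning.  The packed-array (HDF5) writer disables object
timestamps, so identical pipelines produce byte-identical files — the CLI
determinism checks hash output files directly.

## Known limitations

- The synthetic dipole is planar and rank-2 per record; real cardiac
  sources are 3-D and the lead set over-determines them differently.
- The reference CNN is far smaller than the deep architectures used on
  clinical benchmarks; absolute F1 levels and robustness gaps here are not
  forecasts for those models.
- The headline robustness direction at desk scale is stochastic at 5-seed
  resolution (see above); scaling seeds or records sharpens it.
- WFDB support reads single-file, format-16 header/record pairs only.
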