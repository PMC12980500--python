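# Methods

This note documents the models, procedures and numerical choices behind
`ecgxai`. The package evaluates *attribution methods* — algorithms that
assign each point of an input signal a relevance score for one model
prediction — on deep 1D convolutional classifiers of median-beat ECGs.
Because clinical ECG archives cannot be redistributed, every experiment runs
on a synthetic generator whose planted features provide ground truth that
real data cannot.

## Synthetic median-beat generator

A median beat is modelled as a sum of five Gaussian bumps (P, Q, R, S, T):

    s_lead(t) = Σ_w  a_{lead,w} · exp( −(t − c_w)² / (2 σ_w²) )  + ε(t)

with per-lead amplitudes `a` (mV), shared centres `c` and widths `σ`
(seconds), and additive white Gaussian noise ε with SD `noise_sd`
(default 0.03 mV, a typical residual noise level for an averaged median
beat). Records are 1.2 s at 500 Hz (600 samples, R peak centred) over the 8
independent leads I, II, V1–V6. Neither the record length nor the stored
amplitude units are universal conventions; both are configurable.

Nine diagnostic classes are planted as morphological deviations from the
sinus-rhythm baseline:

| class | modifier | note |
|---|---|---|
| sinus rhythm | none (baseline) | discriminative region: the upright P wave |
| atrial fibrillation | P amplitude → 0 | absent atrial activity |
| sinus bradycardia | T centre +80 ms, width ×1.15 | longer T-to-next-P gap |
| sinus tachycardia | T centre −70 ms, width ×0.90 | shorter gap |
| 1° AV block | P-to-R spacing set to 240 ms | > 200 ms criterion |
| RBBB | QRS widths ×2.2, Q/S centres spread, V1 net positive | wide QRS, rSR′-like V1 |
| LBBB | QRS widths ×2.2, spread, V1 net negative, tall lateral R | wide QRS |
| low QRS voltage | Q/R/S amplitudes ×0.30 | peaks < 0.5 mV |
| LVH | Q/R/S amplitudes ×1.80 | high voltage |

Two deliberate proxies deserve emphasis. First, a single median beat carries
no rhythm strip, so the rate-based classes (brady/tachycardia, AF) are
*morphology proxies*: rate is expressed through T–P spacing and AF through
the absent P wave only. Second, the rate modifiers touch only the T wave so
that heart rate does not confound the PR interval — first-degree AV block
must be identifiable from P position alone.

Records whose rhythm is none of the four named classes receive an
ectopic-atrial proxy (inverted P wave). Without it they would be
morphologically identical to sinus rhythm while carrying a negative
sinus-rhythm label, making that class unlearnable by construction.

**Labels.** Class marginals follow the emulated archive composition
(sinus rhythm 62.9%, AF 6.2%, bradycardia 10.8%, tachycardia 7.2%, AV block
6.1%, RBBB 8.3%, LBBB 4.2%, low voltage 3.6%, LVH 7.1%). Labels co-occur
only when compatible; sampling is hierarchical (rhythm categorical;
conduction-block categorical; voltage categorical; AV block Bernoulli with
its rate rescaled by 1/P(P wave present)) so that every marginal equals its
configured prevalence exactly while incompatible pairs (AF + sinus rhythm,
RBBB + LBBB, low voltage + LVH, AF + AV block) never co-occur.

**Patient grouping.** Each patient draws latent offsets once — amplitude
scale N(1, 0.08) per wave, timing shift N(0, 4 ms), width scale N(1, 0.05) —
shared by all of that patient's records (count 1 + Poisson(mean − 1), mean
4.5 by default). Splits are by patient, never by record.

**Ground-truth relevance.** Each record's mask marks where its class
modifiers changed the noiseless signal relative to the baseline beat
(|Δ| > 0.01 mV, computed by differencing). The class-level region
(`class_discriminative_region`) is the same computation with the identity
latent and is used as the "oracle" ranking in the perturbation experiment.

**What passing tests do and do not show.** The generator produces idealized,
stationary Gaussian-bump beats with a single global noise level; it has no
baseline wander, electrode artefacts, beat-to-beat morphology variation,
inter-class feature correlation beyond the rule table, or label noise.
Results here validate the *mechanics* of the four evaluations (axioms,
bookkeeping, direction of effects) — they do not predict the correlation or
degradation values any particular clinical model would produce.

## Task model

A 1D ResNet: residual blocks of two same-padded convolutions (kernel 7),
each convolution followed by batch normalization, dropout and ReLU; the
channel dimension doubles and the spatial dimension halves every
`halve_every` (default 2) convolutional layers; global average pooling and
a single linear unit with sigmoid complete the binary classifier. Shortcuts
are 1-kernel convolution projections wherever shape changes. The builder
validates the spatial schedule and refuses depths that would halve a
length-1 signal, naming the offending layer: with 600-sample inputs the
full 22-layer/11-halving schedule is infeasible, which is one reason the
**desk profile** (8 conv layers, base 16 channels — final 256 — on L = 600)
is the default; the deep schedule is retained for longer inputs (e.g.
4096 samples → final length 2).

The network and its training loop are implemented directly on NumPy with
hand-written forward/backward passes. This is a deliberate design: the
attribution methods need backward passes that autodiff frameworks do not
expose uniformly (guided ReLU gating, DeepLift multiplier propagation), and
a single explicit layer graph makes the three backward modes (`grad`,
`guided`, `deeplift`) small, auditable variations of one code path. All
tensors are float64 so the exact axioms (summation-to-delta) hold to 1e−6
and tighter through deep compositions.

Training: Adam (lr 1e−3 default), binary cross-entropy, shuffled
mini-batches, early stopping on validation AUROC (patience 5) with the
best-validation snapshot restored, and an optional stop-at-target AUROC.
The decision threshold is chosen by Youden's J on the validation set.
Dropout is active only during training; inference and attribution always
run the deterministic network. Optimizer settings live in config; they are
conventional defaults, not tuned values. Everything is a pure function of
(config, data, seeds); reproducibility is asserted by double-run
comparison in the tests.

**Randomization units.** The cascading-randomization experiment walks
weight layers output-first: the linear head, then each block's convolutions
from the deepest block back to the input. A block's projection shortcut and
each convolution's batch normalization (affine parameters *and* running
statistics — stale statistics would leak trained information) are
re-initialized together with their convolution, so the walk has
`n_conv_layers + 1` steps and never leaves a half-randomized block behind
a trained shortcut.

## Attribution methods

All 12 methods attribute the *pre-sigmoid score*: probabilities saturate on
confidently classified records and their gradients vanish, which would
flatten the maps. Defaults (changeable per run): IG 64 path steps;
SmoothGrad 32 samples at noise SD = 0.1 × input range; Shapley sampling 32
contiguous time segments × 256 permutation samples; SHAP variants 16
baselines drawn from the training set; GradCAM taps the last convolutional
block. Baselines default to the all-zero (flat) signal, the natural "no
signal" reference for a zero-centred median beat.

Method notes:

- **Saliency** |∂score/∂x|; **Gradient*Input** x ⊙ ∂score/∂x (signed).
- **Integrated gradients** uses the midpoint Riemann rule; its completeness
  residual is checked at 512 steps (< 1% relative error on trained desk
  models; the rule is exact for linear models at any step count).
- **DeepLift** implements the rescale rule via a dual forward pass
  (input + baseline) and multiplier backpropagation; for networks of linear
  operations and ReLUs summation-to-delta holds to float precision.
  Unsupported layer types raise a capability error rather than silently
  degrading to gradients.
- **Shapley sampling** partitions the time axis into contiguous segments
  spanning all leads jointly (keeping the coalition space tractable); each
  permutation contributes telescoping marginals, so efficiency
  (Σ φ = score(x) − score(baseline)) is exact for every sample and the
  estimator is unbiased. The segment value is broadcast uniformly to its
  points.
- **Guided backpropagation** gates every ReLU's backward signal on
  (forward input > 0) AND (incoming gradient > 0).
- **GradCAM** weights tap-layer channels by time-averaged gradients,
  ReLU-clamps the weighted sum, linearly upsamples to the input length and
  replicates across the 8 lead rows — post-convolution channels mix leads,
  so per-lead resolution is not recoverable; maps are elementwise ≥ 0 by
  construction. **Guided GradCAM** is the elementwise product with guided
  backpropagation.
- **SmoothGrad** (and IG + SmoothGrad) averages base-method maps over
  Gaussian-perturbed inputs; with zero noise it returns the base map
  exactly. **GradientSHAP** takes the expectation of (x − b) ⊙ gradient
  over random baselines and uniform path positions; **DeepLiftSHAP**
  averages DeepLift over the baseline set.

Verification is by independent oracles rather than a reference library:
finite-difference gradients, closed forms on linear models, hand-tracked
multiplier examples, an exhaustive-permutation Shapley oracle, and the
self-validating axioms above.

## Map processing

Before correlation-based comparisons (experiments 1–3), maps are smoothed
with a Savitzky–Golay filter (31-sample window, order-3 polynomial,
per lead; edges by polynomial extrapolation of the terminal fits). The
filter reproduces polynomials up to degree 3 exactly, so smooth attribution
structure survives while sample-level gradient noise is suppressed. Whether
smoothing applies to experiments 2 and 3 as well as 1 is a switch
(default on for all three); the perturbation ranking of experiment 4 always
uses raw absolute attributions.

Similarity between two maps is the per-lead Pearson (or Spearman)
correlation averaged unweighted over the 8 leads — "pointwise, then
averaged" is read as per-lead-then-average; a pooled-flatten variant exists
behind a flag for sensitivity analysis. A constant lead on either side
contributes 0 and is counted (`n_degenerate_leads`); the score is flagged
degenerate (value exactly 0) only when every lead is constant — GradCAM can
legitimately emit all-zero maps, and dropping them silently would bias
aggregates. The arithmetic is grouped so similarity(A, B) == similarity(B, A)
bit-exactly. Aggregation reports mean ± sample SD (n−1; seeds are a sample
of initializations), SD 0 for singletons, and omits empty groups with a
warning instead of writing silent zeros.

Point ranking for perturbation orders all 8·L points by descending |value|
with deterministic (lead, time) tie-breaking.

## The four experiments

1. **Inter-method similarity** — all method-pair similarities per record on
   one trained model; emitted as a symmetric matrix with unit diagonal.
2. **Self-consistency** — all unordered seed-pair similarities per method
   across models retrained with different initializations
   (s seeds → s(s−1)/2 pairs).
3. **Cascading randomization** — for k = 0..n layers, re-initialize the top
   k units of the output-first walk, re-attribute, correlate against the
   k = 0 maps, and record the randomized model's AUROC. Step 0 is exactly 1
   by construction. Randomizing only the head can flip the sign of signed
   maps wholesale (the head is a 1-unit projection), so sanity checks assert
   the *decline* of correlation at full randomization rather than
   monotonicity through k = 1. By default the experiment runs on the
   atrial-fibrillation model, configurable to all classes.
4. **Remove-and-debias perturbation** — rank once from the unperturbed
   map (recompute-per-step available behind a flag), then repeatedly mask
   the top `step_frac` (default 1%) of not-yet-masked points (per record,
   jointly over leads), replacing each with the linear interpolation of its
   nearest *unmasked* same-lead neighbours (constant extension at
   boundaries, zero if a lead is fully masked) multiplied by N(1, σ = 0.25)
   noise — the figure-caption reading; an additive mode is provided since
   the prose admits both. AUROC is recomputed after each of the 30 steps
   (30% total). AUROC per step is averaged over available seeds.

**Oracle separation and step size.** The sanity check that ground-truth
ranking degrades AUROC faster than random ranking uses 6 steps of 5%
(the same 30% total). The planted region is only ~6% of points: at 1% steps
each masked point is imputed from still-intact neighbours and the waveform
is locally rebuilt, so neither ranking does measurable damage to an
easily-separable task; only when a step covers the whole feature region is
the interpolation forced to bridge it, flattening the wave. The paper-style
1%×30 schedule remains the default for the experiment itself and its
bookkeeping is verified exactly.

## Problem sizes and numerical choices

Desk-scale defaults keep every stage tractable on one CPU: the separability
gate trains the 8-conv/8-channel profile on a 450-patient (~2000-record)
dataset per class, stopping once validation AUROC ≥ 0.95 (every class
passes 0.9; the AV-block timing class is the slowest because its feature —
relative P position — requires the largest receptive field). Experiment
fixtures train a 4-conv/8-channel atrial-fibrillation model on 300 patients
(the absent-P feature is local, so the shallow profile suffices, reaching
test AUROC ≈ 0.98). Attribution examples use records stratified to include
both label values. CSV reports are written with 6-significant-digit floats
so identical runs are byte-identical; all randomness descends from one
global seed via fixed per-stage offsets.

## Known limitations

- The generator's simplifications (above) mean quantitative results do not
  transfer to clinical data; only the evaluation mechanics do.
- DeepLift supports exactly the layer vocabulary of the task model
  (convolution, batch norm, ReLU, dropout, pooling, linear, residual adds).
- Shapley segments are time-contiguous and lead-joint; per-lead segmentation
  is configurable but quadratically more expensive.
- GradCAM's lead-replicated maps score 0 per-lead correlation against any
  lead-varying map by construction of its upsampling — an inherent property
  of activation-space methods at coarse temporal resolution, visible as low
  GradCAM rows in the inter-method matrix.
- The multiplicative perturbation noise is mean-1, so features encoded as
  average local amplitude are only mildly disturbed by it; destruction comes
  from interpolation bridging, not from the noise itself.
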