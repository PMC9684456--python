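# Methods

`afuq` re-implements, end to end, a weak-supervision pipeline for atrial
fibrillation (AF) detection on short ECG segments, together with the
uncertainty-estimation and calibration machinery used to judge how far the
resulting models can be trusted. Because the clinical telemetry this kind of
study runs on is private, the package ships a synthetic ECG cohort generator
that reproduces the *statistical* structure the analysis depends on, so that
every stage — surrogate training, weak labelling under domain shift, label
cleaning, uncertainty estimation, statistical comparison — runs and is tested
without any external data.

## Synthetic ECG cohorts

Segments are 10 s, 4 leads, 240 Hz, in millivolt-scale units. A segment is
synthesized from a parametric beat template: Gaussian bumps for the P, Q, R,
S and T waves placed at beat times whose RR intervals are drawn from a
log-normal distribution with a configurable mean (heart rate) and coefficient
of variation (CV). The two rhythm classes differ exactly where they differ on
a rhythm strip:

* **sinus** — regular RR (CV 0.02 by default), P-wave present (relative
  amplitude 0.15);
* **AF** — irregular RR (CV 0.25), no P-wave, plus a 4–9 Hz "fibrillatory"
  baseline oscillation (relative amplitude 0.10).

The log-normal RR model is positive and right-skewed, which is all the
analysis needs from RR irregularity. Leads are correlated copies of one
source waveform with linearly decreasing gains and an independent noise floor
(0.01 mV): the classifier requires a 4-lead input, but inter-lead physiology
carries no information here and is out of scope.

Artifacts are injected on a contiguous random region of a segment:
broadband Gaussian noise (high-frequency artifact), a <1 Hz sinusoidal
drift (baseline wander), or a flat run (sensor drop-off, which also sets the
drop-off flag). A segment is flagged *noisy* iff the affected fraction
reaches 1/4 of the record — the same criterion the noise annotation uses.
The out-of-distribution (OOD) class — the analog of segments a human
reviewer abstains on — is drawn from the boundary region between the two
classes: intermediate RR irregularity (CV 0.06–0.14), a faint P-wave,
slight fibrillatory activity, and a moderate artifact over at least a
quarter of the record, so the segment carries genuinely conflicting rhythm
cues. (An earlier design used a paced-rhythm template under severe
artifact, but a trained classifier maps that confidently into the AF class,
which defeats the purpose of an abstain analog.)

Cohorts have per-patient structure (segment timestamps at least one hour
apart) so the curation rules are exercised; class mix, noise rate, OOD rate
and drop-off rate are per-segment Bernoulli draws. Every generator is a pure
function of its seed.

**Separability.** On clean default presets, a one-feature classifier
(threshold on the detected-RR CV at 0.08) reaches ≥95% accuracy. This is
deliberate: the downstream claims are about *label quality and calibration*,
not about squeezing accuracy out of a hard task, and a separable task keeps
the whole pipeline testable on a CPU in minutes.

**Domain shift.** The gap between the external (diagnostic-ECG-like) cohort
used to train the surrogate and the target (ICU-telemetry-like) cohort is a
parameter offset triple: amplitude scaling 0.75, +0.035 mV noise floor,
+12 bpm heart-rate shift. The magnitude was calibrated so the surrogate
degrades on the target roughly as the original study observed for its
label-generation model (F1 dropping toward ~0.6–0.8 with substantially
overconfident AF calls, i.e. a weak-label error rate of roughly 10–30%
depending on the realization). A weaker shift makes weak labels nearly
perfect and the label-cleaning stage vacuous; a much stronger one collapses
the surrogate to a single-class labeller.

**What the generator does not emulate:** real ECG morphology variation
(ectopy, bundle branch block, pacemakers as an in-distribution class),
recording-device transfer functions, real ICU noise spectra, and per-patient
rhythm persistence (class draws are independent across segments). Passing
tests therefore demonstrate that the *pipeline machinery* behaves as the
method prescribes under the stated statistical structure — not that the
classifier would reach any particular performance on real telemetry.

## Classifier

The classifier is a 13-block 1-D dilated CNN: each block is convolution
(kernel 3) → batch normalization → ReLU → 30% dropout, with per-block
dilation non-decreasing from 1 to 8 (default schedule
1,1,2,2,2,4,4,4,4,8,8,8,8) and dilated max-pooling (window 2, stride 2,
dilation equal to the block's) after blocks 6 and 11. Global average pooling
over time and a single linear unit produce one logit, so any input of at
least 64 samples maps to p(AF) ∈ (0,1). Channel widths are not part of the
published architecture; the default is 16 channels per block, the narrowest
width at which we found training with 30% per-block dropout to be reliably
stable at these data sizes. A `scale` multiplier shrinks or widens all
blocks for smoke tests.

No autodiff framework is used: forward and backward passes are hand-written
on BLAS-backed GEMMs in float32, with activations kept in channels-major
`(channels, batch, time)` layout so each kernel tap is a single GEMM over
the flattened batch. Gradient correctness is established by central
finite-difference checks in float64 in the test suite. Dropout masks are
drawn as uint8 threshold tests (the drop probability is quantized to 1/256
and the inverted scaling uses the effective keep rate, so the expectation is
exact); this keeps mask generation cheap enough for Monte Carlo sampling.

**Batch-normalization statistics and dropout.** At the widths used here,
dropout noise is a large fraction of each channel's activation variance.
Running statistics accumulated during training therefore describe
*dropout-noised* activations; a deterministic pass sees systematically
smaller variance, which damps the logits, while Monte Carlo passes match
them. The layer keeps two running-statistic sets, and both are re-estimated
after training by gradient-free sweeps with the final weights: one with
dropout off (serving deterministic inference) and one with dropout active
under a seeded mask stream (serving Monte Carlo inference — the
training-accumulated values reflect batches computed under still-changing
weights and noticeably destabilize dropout sampling if left as-is). This is
the usual "BN re-estimation" device applied per inference mode; with very
wide networks the sets coincide and the distinction disappears.
Momentum is 0.3 (rather than the common 0.1) because desk-scale epochs
contain only a handful of batches and the statistics must track within an
epoch. At inference the batch-norm affine is folded into the convolution
weights, saving one full tensor pass per block.

## Training

Adam (learning rate 0.01, weight decay 1e-4, β = 0.9/0.999) on binary
cross-entropy, batch size 128, at most 200 epochs with early stopping after
10 epochs without improvement of the monitored loss; probabilities are
clamped to [1e-7, 1−1e-7] before logs. The parameters and batch-norm
statistics of the best monitored epoch are restored at the end. The
monitored loss is configurable: validation loss on a stratified held-out
split (default, 10%) or training loss. The desk-scale experiment monitors
training loss for the weak-label models because their validation splits are
both small (~100 samples) and label-noisy, which makes validation-loss
early stopping erratic; the surrogate, whose external validation labels are
clean, monitors validation loss.

A cleaning hook may be attached to training: it is called once per epoch and
may only *shrink* the active-sample mask (monotone, permanent pruning). If a
round would empty a class it is skipped with a warning.

## Confident learning

Implemented from scratch for the binary case. With observed (weak) labels
ỹ and model probabilities p: the per-class threshold t_j is the mean
predicted probability of class j over samples observed-labelled j. Sample i
is confidently assigned to the class with the largest p_j among classes with
p_j ≥ t_j (ties qualify; an exact probability tie resolves to the observed
label); samples meeting no threshold stay unassigned. Counting assignments
against observed labels gives the 2×2 confident joint C[ỹ, y*]; the
off-diagonal samples are the candidate label errors and are pruned. The
number of flagged samples always equals the off-diagonal sum of C.

Cleaning runs every 3 epochs on the currently active training samples, with
deterministic (dropout-off) in-training predictions — iterative cleaning
makes cross-validated probabilities unnecessary and the thresholds are
recomputed from active samples each round. A `burn_in` parameter (default 0)
delays the first round; the desk-scale experiment sets it to 5 because at a
12-epoch budget "epoch 3" means a quarter-trained model, whose confident
joint prunes the wrong samples, whereas in a 200-epoch run the same rule
fires when the model is already competent.

## Uncertainty estimation

All modes sample T probabilities per segment and summarize with their mean
(the aggregate prediction, thresholded at 0.5 for classification) and
sample standard deviation (the uncertainty estimate):

* **epistemic** — T dropout-active forward passes (Monte Carlo dropout) on
  the unaugmented input;
* **aleatoric** — T deterministic passes on independently augmented views:
  10% of time points zeroed, positions uniform without replacement and
  shared across leads (test-time augmentation);
* **combined** — joint sampling, dropout active and an independent masked
  view per pass;
* **none** — the always-confident baseline: one deterministic pass, std
  defined as 0.

T defaults to 30; the desk experiment uses 10–12 passes, which is enough to
order group uncertainties stably. Batched evaluation vectorizes over
segments with per-segment augmentation streams derived independently from
one master seed; the single-segment entry point is the batch path with
batch size 1, so both are reproducible and mutually consistent.

## Evaluation

Classification metrics (F1, PPV, sensitivity, specificity) come from the
2×2 confusion table at threshold 0.5. Calibration: Brier score, NLL (same
clamping as training), and ECE with 10 equal-width bins over [0,1],
right-open except the last; empty bins contribute zero, and the bin table
(the reliability-curve data) is returned alongside the scalar. Group
comparisons of uncertainty distributions use the two-tailed Mann-Whitney U
test — U by pair counting with half-credit ties, p-value by exact null
enumeration when n₁·n₂ ≤ 400 and the data are tie-free, otherwise the
tie-corrected normal approximation with continuity correction — with
step-down Holm correction at family level α = 0.01 applied within each
requested family of comparisons (the exact family the original analysis
corrected over is not stated; this artifact corrects within each named
grouping set and says so). Cohen's kappa uses marginal-product expected
agreement.

## The desk-scale experiment

`afuq.pipeline.run_experiment` reproduces the full study design on synthetic
cohorts: train the surrogate on an external labelled cohort (70/30
stratified split), curate the target pool (drop-off rejection → 1-hour
spacing → per-patient initial cap → boxplot-whisker cap, the whisker step
iterated to a fixed point so curation is idempotent), weak-label it with the
surrogate, train "weak labels only" and "confident learning" models on those
labels, and evaluate the 3 models × 4 uncertainty modes grid on a labelled
target-distribution test set, including clean/noisy and ID/OOD uncertainty
comparisons. Test-set noise (27%) and OOD (9%) fractions follow the observed
proportions of the original labelled set.

Problem sizes are chosen for a single CPU: external cohort ≈ 800 segments
(6 training epochs for the surrogate), target pool ≈ 500 after curation and
test set 240, with 12 epochs for the weak-label models. The pool is kept
small *relative to the epoch budget* on purpose: cleaning shows its value
only once training on raw weak labels has had time to fit the label errors,
which is what a 200-epoch run on a large pool does — at desk scale the same
regime is reached by shrinking the pool instead of extending the schedule.
The headline directions (the surrogate is the worst-calibrated model on
shifted data; confident learning does not classify worse than raw weak
labels; Monte Carlo dropout does not worsen calibration; noisy and OOD
inputs carry higher uncertainty) are assessed over three independent
replicates because single desk-scale runs are noisy.

## Known limitations

* Desk-scale training (tens of optimizer steps) makes per-seed metric
  values noisy; only directions and orderings replicated across seeds are
  meaningful.
* The narrow network makes Monte Carlo dropout means biased toward the
  class whose features carry more signal energy (AF); the dual-statistics
  device removes the deterministic-pass mismatch but not this sampling
  bias. Wider networks shrink it.
* Binary confident learning only; no multi-class joint, no count-based rank
  pruning, no noise-rate reweighting of the loss.
* The external-dataset adapter (class mapping, lead selection, 500→240 Hz
  polyphase resampling) is tested against synthetic metadata in the public
  release's layout; the release itself is not bundled or downloaded.
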