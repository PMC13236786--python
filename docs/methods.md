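# Methods

## Data model and geometry

A trial is a 500-Hz gaze record (x, y in screen pixels) collected while a
six-item search array is on screen, plus metadata: participant id, a dense
1-based trial index, target location 0–5, distractor location 0–5 or absent,
and response time (ms). Screen coordinates follow the raster convention
(origin top-left, y downward); all angular quantities are computed in the
conventional mathematical frame by negating y, so "counterclockwise" and
"polar angle" mean what they usually mean.

The six candidate locations are equally spaced (60°) on a circle of
configurable eccentricity around central fixation, which is the pixel-grid
center ((w−1)/2, (h−1)/2) — (1279.5, 719.5) on the 2560×1440 display the
defaults assume. Two variants exist: the *horizontal* arrangement (angles
0°, 60°, …, 300°) and the *vertical* one (30°, …, 330°). Location indices
are assigned counterclockwise from the smallest non-negative angle; any
fixed assignment works because labels and logits share it. Eccentricity
(default 400 px) and stimulus radius (75 px) are configuration values used
only by geometry-dependent analyses (chunk assignment, display overlays);
they are not recoverable from the trace format itself.

## Preprocessing

Missing samples (tracker dropouts) are replaced by the fixation coordinate;
traces shorter than the 600-sample window (the array disappears at response)
are fixation-padded at the end, and longer ones — a clock-alignment artifact
— are truncated. The result is a fully observed (trials × 2 × 600) tensor
in raw pixel units; no standardisation is applied by default (the network's
optimiser is scale-adaptive, and raw pixels keep the attribution maps in
screen units). Participants whose average proportion of missing samples
exceeds the group mean by more than two sample standard deviations (n−1
convention; strict inequality, so a zero-variance group excludes nobody) are
flagged for exclusion. The proportion averages trials with equal weight
rather than pooling samples; per-trial weighting is the natural reading when
trials are the experimental unit.

## Splitting and training

Validation is every third trial per participant in presentation order
(1-based ranks divisible by 3), a two-thirds/one-third split; distractor
analyses first drop distractor-absent trials and split the remainder the
same way. Any fixed rank offset yields identical counts when trial counts
are divisible by three, which all cohort shapes used here satisfy.

Training mini-batches hold 64 trials (the final batch takes the remainder,
giving ⌈n/64⌉ updates per cycle) and are reshuffled each cycle under a seed,
so runs are exactly reproducible. The optimiser is Adam with the standard
moment-decay constants (0.9, 0.999, ε = 10⁻⁸), initial learning rate 10⁻³
decaying by γ = 0.9 after every training/validation cycle. Weights start
from fan-in-scaled uniform initialisation with a recorded seed. Dropout
(p = 0.25, inverted scaling) acts only during training passes; validation is
always evaluated with frozen weights and dropout off, and its loss is the
mean cross-entropy over all validation trials, not a mean of batch means.
Early stopping tracks the minimum validation loss with patience 10 (ties
count as non-improvement) and restores the minimum-loss snapshot; a
`max_epochs` cap (default 200) is a safety net on top. Note the learning
rate after e cycles is 10⁻³·0.9ᵉ, so most learning happens within the first
few dozen cycles — cohort size, not epoch count, is the main lever on what
the network can extract.

The linear head (7,616 → 64 → 32 → 6) deliberately applies no activation
between its three transforms; the only nonlinearities are the post-convolution
ReLU and the max pooling. The convolution is unpadded: 600 → 598 positions,
pooled 5-fold to 119, times 64 features = 7,616 — this arithmetic is forced,
a padded convolution would give 7,680.

## Statistical summaries

The unit of inference is the participant. Confidence intervals are
percentile bootstraps (default 10,000 resamples) over participant means —
percentile rather than BCa for simplicity and exact reproducibility under a
seed. t-tests (against 1/6, or paired against the heuristic) report
two-sided p-values even where the hypothesis is directional; this is
conservative.

The hierarchical accuracy model is

    C_i ~ Binomial(N_i, p_i)
    p_i ~ Beta(α, β)
    α ~ Exponential(rate 0.1)     β ~ Exponential(rate 0.05)

The exponential parameters are read as *rates* (prior means 10 and 20), so
the prior group mean α/(α+β) centers near 1/3 — deliberately closer to
chance than a typical trained-network accuracy; a flag covers the
scale-parameter reading. The posterior over (log α, log β, logit p_i) is
sampled with Hamiltonian Monte Carlo: leapfrog integration with jittered
step counts (up to 32), dual-averaging step-size adaptation targeting 0.8
acceptance, and a diagonal mass matrix re-estimated midway through warm-up.
Four chains of 1,000 iterations are run and the first half of each chain is
discarded as warm-up (warm-up handling is otherwise unspecified in the
model's provenance; half-and-half is the common default). Split-R̂ and bulk
effective sample size come from arviz; an R̂ above 1.05 on any parameter is
surfaced as a warning on the fit object, never swallowed. The HPDI is the
narrowest contiguous window containing the requested mass, found by a
sorted-window search. On the recovery benchmark used in the tests (80
participants, p_i ~ Beta(4, 16), N_i = 80) the sampler attains R̂ ≈ 1.00 and
ESS in the thousands.

## Saccade heuristics

The comparator metric divides the display into six half-open 60° wedges
[θ−30°, θ+30°), each centered on a location angle; a wedge boundary belongs
to the higher wedge, so the wedges tile the circle exactly. The first
saccade is detected by a velocity threshold: the first run of at least 5
consecutive samples (10 ms) whose central-difference speed exceeds
1.0 px/sample; its landing is the gaze at the run's end. For event
detection, dropouts are filled by *holding the last position* rather than
jumping to fixation — center-filling would fabricate large spurious
velocities at every gap. Vendor-parsed event tables can be supplied instead
of the built-in detector, whose equivalence to any particular vendor parser
is not claimed. The per-participant capture rate counts distractor-chunk
landings among trials with a detected saccade; participants with none are
omitted with a warning. The min-mean-distance baseline assigns each trial
the location minimising the mean gaze-to-location distance over the whole
trace, ties to the lowest index (a center-parked trace is equidistant from
all six and yields index 0).

## Attribution

Contributions are computed per query-reference pair by backpropagating
multipliers, then averaged over the reference set (by convention the first
100 validation trials). Linear layers and the convolution propagate
multipliers exactly; the ReLU uses the rescale rule (Δout/Δin, gradient
fallback when |Δin| < 10⁻⁹); each pooling window routes its entire output
difference through the window element with the largest absolute activation
difference. This routing choice makes completeness *exact*: summed over all
1,200 input cells, contributions equal the query logit minus the mean
background logit for every class, to floating-point precision (the package
raises if the relative residual exceeds 10⁻³, which would signal an
unsupported layer). On an affine network (unit pooling, ReLU biased into
its linear region) the procedure reduces to weight × (input − background
mean), the closed-form Shapley solution, and is tested against it. Dropout
never participates (attribution runs in evaluation mode). Exact Shapley
enumeration over 1,200 inputs is out of scope; the linear closed form is
used only as an oracle.

Global importance is the mean absolute contribution over the 12
feature × class cells per sample; per-trial peaks break ties to the earliest
sample and are reported in ms (sample × 2). Spatial summaries rotate each
trial rigidly about fixation to align distractor (or target) locations,
estimate density with an isotropic Gaussian KDE whose bandwidth follows the
two-dimensional Silverman rule h = σ̄·n^(−1/6) (σ̄ = mean of the x and y
sample SDs; the exponent is configurable because the one-dimensional n^(−1/5)
variant is also defensible), evaluate it on a 10-px grid, and max-normalise
for display (mass-normalisation is the other reading of "normalised"; max
makes heatmaps visually comparable). The polar histogram bins peak
positions by angle (bin 0 centered on the alignment angle) and colours bins
by mean peak time. Trial filters (correct predictions; first saccade not in
a given chunk) are composable boolean masks, not hard-coded subsets.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, not
oculomotor physiology. Per trial: target uniform over six locations; a
distractor on exactly half the trials (the configured fraction), uniform
over the remaining five; fixation with Gaussian pixel noise until a
lognormal saccade latency (median 200 ms, σ = 0.2); a logistic-profile
saccade (duration 34 ± 5 ms) either directly to the target or — with
probability `capture_prob`, default 0.3 — first to the distractor, dwelling
150 ms before a corrective saccade to the target; response at target arrival
plus a decision lag (250 ± 60 ms), truncated at the 1,200-ms window, after
which the trace simply ends. Samples drop out independently at rate 0.02;
position noise is 0.5 px SD per axis per sample, a realistic video-tracker
figure that keeps noise speeds well under the detector threshold. The
default desk-scale cohort is 12 participants × 120 trials; larger reference cohort
shapes (72×480 etc.) are properties of human datasets and are exercised
via metadata-only tables where only bookkeeping is at stake.

The null control regenerates traces with `capture_prob = 0` and reassigns
the distractor labels of distractor-present trials uniformly over all six
locations, independently of everything — any classifier's expected accuracy
is exactly 1/6. Because reassignment ignores the target, a null label may
collide with the target location; null tables are an in-memory control and
intentionally exempt from the distractor ≠ target interchange invariant.

What the simulator does *not* reproduce — main-sequence velocity profiles,
drifts and microsaccades, blinks with recovery artifacts, participant-level
idiosyncrasy, covert-attention trials — bounds what green tests show: they
validate the pipeline's mechanics and its sensitivity/specificity under
known ground truth, not performance figures on human data.

## Problem sizes in the validation suite

The end-to-end checks train on cohorts chosen as the smallest that land
clearly in the intended regime: 8×90 (capture 0) for the separable-signal
check, where validation accuracy exceeds 90 % within 30 cycles; 8×90 null
for the chance-level check against the 95 % binomial band; and 24×160
(capture 0.3) for the distractor analysis, where ~1,300 training trials give
the network enough capture examples to clear the chance band decisively and
the filtered attribution subset (correct predictions, first saccade not
target-directed) still holds dozens of trials. The hierarchical-model
recovery benchmark uses 80 participants × 80 trials.

## Known limitations

* The detector is a plain velocity-threshold device; it has no saccade
  amplitude model and will merge saccades separated by under 2 ms of
  subthreshold speed.
* The HMC sampler is purpose-built for this 80-odd-dimensional posterior;
  it has no divergence diagnostics beyond acceptance tracking and R̂/ESS.
* Attribution assumes the stride-1 convolution of the reference
  architecture.
* The CSV interchange format stores one row per sample and is deliberately
  simple; very large cohorts would warrant a binary container.
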