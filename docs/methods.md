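# Methods

`wormcast` forecasts the remainder of a *C. elegans* lifespan assay from its
first days and tells the experimenter when the forecast is reliable enough to
stop counting. This note documents the models, the simulator behind the
training data, the numerical choices, and what the tests do and do not show.

## The forecasting problem

A lifespan assay tracks a population of age-synchronized worms, split across
several Petri plates of 10–15 animals, with one live count (and one image)
per plate per day until everyone is dead. Assays run 30–60 days and the
counting is manual and tedious. If, partway through, a model can predict the
rest of each plate's survival curve with known confidence, the assay can be
halted and the predicted tail used in place of the uncounted days.

The unit of prediction is the plate; plate forecasts are summed into the
condition-level curve that survival statistics are computed on.

## Survival model and simulator

Plate lifespans are modelled as 2-parameter Weibull: the fraction alive at
day *t* is

    S(t) = exp(-(t/b)^a)

with shape `a` (dimensionless; steepness of the mortality drop, 3–10 for
realistic cohorts) and scale `b` (days; since `b·Γ(1+1/a) ≈ b` for the
shapes used here, `b` is read as the mean lifespan). The ranges the package
targets are 10–15 worms per plate and `b` in 10–57 days, spanning short-lived
wild-type through long-lived *daf-2*-like cohorts.

`generate_curve` draws an independent continuous Weibull lifetime per worm
and records the death on day `ceil(lifetime)` — a worm dying in `(d-1, d]`
is first *seen* dead on day `d`. This makes the daily live count exactly
binomial around `n·S(t)` and keeps worm identities exchangeable for
trajectory assignment. A deterministic variant (`method="deterministic"`)
rounds `n·S(t)` instead, for users who want noise-free curves.

The label horizon default is `max_days=120`. Although the largest scale is
57 days, a Weibull with `b=57` and moderate shape keeps a substantial
fraction of the cohort alive well past day 60, so a 60-day horizon would
routinely be unable to represent extinction; 120 days covers `a ≥ 3` at
`b = 57` with per-plate overflow probability below ~0.2%. Overflowing
lifetimes either raise (`on_horizon="error"`, the default contract) or are
capped at the horizon (`on_horizon="truncate"`, what dataset generation
uses).

**Capture gaps.** Manual assays skip weekends; the recorded curve holds the
count of the last captured day, producing steps. `apply_capture_gaps`
emulates this: with probability 0.5 per curve, 2 consecutive days out of
every 7 (random phase) hold the previous value. The first and last days are
never gapped, so initial count and extinction are preserved. Worm positions
on gap days are treated consistently with the counts: the observed curve
(after gapping) drives death-day assignment, so deaths surface at catch-up
days in both modalities.

**Trajectories and rendering.** Positions live in a centred "food lawn" disc
(default 70% of the image side) because bacterial food placed centrally
keeps worms away from the dish edge. A worm that is alive on day *d* gets a
fresh uniform position in the lawn (the day-to-day displacement is the
movement signal); a worm first counted dead on day *d* keeps its day *d−1*
position forever — this mirrors the actual labeling rule, where "did not
move between days" *is* the death criterion. Frames are single-channel
8-bit: constant gray background (128) with filled circles (intensity 255,
radius 2 px at the 64 px default side) at each worm position; positions and
radii are configurable and nothing downstream depends on the defaults.

## Dataset construction

For a curve with first death on day F and extinction on day L, one training
sample is built for every current day `k` in `[F, L-1]`: inputs are the
counts and frames for days `0..k`, the label is the count vector on an
absolute-day axis of length `max_days` (zero beyond extinction), and the
loss is masked to days `> k`. A curve therefore yields `L − F` samples.
Prefixes are padded at the *front* when batched, so the recurrent state at
the last timestep always describes the current day; masked steps leave the
LSTM state untouched.

The train/validation split (default 80/20) operates on whole curves, never
samples: two samples of one curve differ by a single day and would otherwise
leak across the split.

## Model

Three input modes plus one coordinate variant:

* **bimodal_images** (default): a 3-block stride-2 CNN (channels 8/16/32,
  3×3 kernels, ReLU, global average pooling) encodes each frame to a 32-d
  embedding; an LSTM (width 64) summarizes the embedding sequence; a second
  LSTM (width 32) summarizes the count series (scaled by 1/16, the maximum
  worms per plate); the concatenated final hidden states feed a two-layer
  head (→64→`max_days`).
* **counts_only** / **images_only**: one branch removed.
* **bimodal_coords**: frames replaced by a per-day 16×2 coordinate matrix
  (lexicographically sorted, zero-filled), linearly embedded before the
  sequence LSTM.

The architecture widths are this package's choices; no claim is made that
they match any particular prior implementation. The network is built on a
small in-repo reverse-mode autodiff (`wormcast.nn`) whose every primitive is
verified against central finite differences in the test suite; training is
single-threaded numpy and bit-reproducible given the seeds.

Training minimizes masked MSE with SGD (reference hyperparameters: 100
epochs, learning rate 0.001, batch size 16; `momentum` defaults to 0). The
best-validation parameter state is checkpointed and restored. Raw head
outputs are post-processed at prediction time: clipped to `[0, initial]`,
then forced non-increasing by a running minimum seeded at the last observed
count. Training uses raw outputs; the post-processing is a deployment
contract, since a count curve cannot rise.

## Uncertainty and error propagation

Given a trained model and a plate prefix, `estimate_plate` generates N
(default 30) perturbed inputs by adding i.i.d. `N(0, sigma²)` noise
(`sigma = 1` worm) to the count series, clipped at zero and left unrounded
(the model consumes real-valued counts). Frames are not perturbed by
default: unit-variance intensity noise is meaningless for binary blob
images; an optional mode jitters blob *centres* by a pixel sigma instead.
The N post-processed predictions give a per-day sample mean and an
(N−1)-denominator standard deviation.

Condition-level: the condition count is the plain sum of plate counts, so
the law of error propagation reduces to the root sum of squares of the
plate standard deviations. The confidence interval is

    C ± z_{α/2} · S_C / √n ,   n = number of plates,

implemented exactly as the reference procedure prints it. Note the √n
divisor shrinks the band relative to the usual convention for a variance of
a *sum* (S_C already aggregates the plates); `sqrt_n_divisor=False` disables
it. The divisor is kept as the printed default rather than silently fixed;
its practical effect is an earlier halting day.

## Halting criterion

The CI bounds over all days form two survival curves (shared observed
prefix, diverging future). Both are rounded half-up to integers,
re-monotonized, and compared with an unweighted Mantel–Cox log-rank test
(hypergeometric O−E and variance per distinct death day, chi-square with
1 df; survivors at the last day right-censored; if the total variance is
zero the O−E sum is identically zero and the test reports p = 1). When
p > α (default 5%), the bounds are statistically indistinguishable, the
prediction is declared reliable, and the current day is the proposed
halting day. The search starts on the first day every plate in the
condition has recorded a death — earlier, plate-level uncertainty is
unfounded. The log-rank implementation is in-repo; an established survival
library is used in tests only, as an independent oracle.

## Evaluation protocol

At the halting day k the predicted condition curve (observed prefix +
summed per-plate predicted suffixes) is scored against the full reference:

* **MAE (%)**: mean absolute difference of survival percentages
  (`count·100/initial`) over the *future* days only (k+1 through reference
  extinction) — the past is observed, so it carries no error;
* **mean lifespan**: average reconstructed death day (deaths on day d
  contribute d); with `ceil` death-day reconstruction this sits ~0.5 day
  above the continuous Weibull mean, which the tests account for;
* **log-rank p** between reference and predicted condition curves;
* **baseline**: `scipy.optimize.curve_fit` of `initial·exp(-(t/b)^a)` to the
  observed prefix (initialization a₀=5, b₀ = last day above 50% survival;
  bounds a∈[0.5,100], b∈[1,200]), extrapolated and scored over the same
  window.

## Scaled problem sizes

Full-scale training (thousands of curves, 64 px frames, 100 epochs) is a
multi-hour numpy run. The test suite and the acceptance script use a scaled
configuration chosen as the package's reference small-compute setting:
200 training curves, shape a∈[5,10], scale b∈[12,20] days, 16×16 frames
(blob radius 1), horizon 32 days, and a two-stage SGD schedule (40 epochs at
lr 0.05 + 10 at 0.01, momentum 0.9) selected by watching validation MSE
to convergence (~1.5 worms² per plate-day). Held-out evaluation uses 5
conditions of 4 plates each, drawn from the same parameter ranges with gap
distortions, N=30 perturbation replicates.

## What the synthetic world does and does not show

The generator reproduces the statistical skeleton of real assays — Weibull
decay, small integer cohorts, frozen dead worms, weekend steps — but not
worm locomotion, body posture, occlusions, edge escapes, detection errors,
or heterogeneous subpopulations that deviate from a single Weibull. Two
consequences matter when reading test results:

* The Weibull curve-fit baseline is *stronger* here than on real data
  (it fits the very model family that generated the data), so the margin by
  which the neural forecast beats it is smaller than would be expected on
  real assays.
* The rendered frames carry no information about future counts beyond what
  the count series already contains (movement ⇔ alive), so the bimodal
  model's advantage over counts-only is small at this scale; on real data
  the image stream is the primary signal. The images-only model is clearly
  worst, as expected, since it must infer counts from blob patterns.

## Known limitations

* Predictions before the first drop day are out of the training regime
  (warned, not forbidden).
* The halting criterion eventually halts *any* predictor near extinction,
  because both CI bounds collapse onto the nearly-finished observed prefix;
  the criterion is informative mid-assay, not at the end.
* The √n divisor in the CI (kept as printed) makes bands narrow for
  multi-plate conditions; halting tends to fire one to three days before
  the mean lifespan in the scaled runs.
* Single-threaded numpy training does not scale to GPU-sized experiments.
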