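# Methods

This note documents the models implemented in `aosim`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerically delicate choices.

## Synaptic device model

Long-term potentiation/depression is the saturating-exponential family

    G_LTP(P) = B_P·[1 − exp(−P/A_P)] + G_min,
    G_LTD(P) = G_max − B_D·[1 − exp(−P/A_D)],
    B_X      = (G_max − G_min)/[1 − exp(−P_max/A_X)],

with both phases pinned exactly to [G_min, G_max] over P ∈ [0, P_max].
The depression curve is written so that it *starts* at G_max and decays to
G_min — the algebraically equivalent form with the offset at G_min would
place G_LTD(0) at 2·G_min − G_max, which contradicts how a
potentiate-then-depress cycle is measured.  The nonlinearity constant *A*
(units: pulses) may be negative, flipping curvature; |A| ≫ P_max gives
near-linear updates.  All evaluations use `expm1`/`log1p` to stay accurate
for |A| up to 10⁶.

**Fitting.**  Endpoints are taken from the trace extremes, which pins the
amplitude through B and leaves a one-parameter nonlinear least-squares
problem per phase.  The scalar fit runs over log|A| from seven log-spaced
starts on each sign branch (Levenberg–Marquardt; non-finite residuals
clipped), and the lowest-cost branch wins.  On a noiseless synthetic trace
the generating (A_P, A_D) are recovered to well below 1% relative error;
at 1%-of-span Gaussian read noise the median error across seeds stays
below 10%.  A trace whose increments are not monotone-dominant raises a
`FitQualityWarning` but still returns the best fit.

**Short-term behaviour.**  EPSC relaxation is a single exponential
`g0 + Δg·exp(−t/τ)` with τ configurable (≈700 s for the redox-stabilized
device, ≈5 s for the pristine one); the paired-pulse facilitation index is
100·A₂/A₁.

## Synthetic sensing data

The generator emulates a three-channel receptor array at the level of its
*readout statistics*, not its physics:

* **Affinity profile.**  The mean `G_max` matrix at the 3 ppm reference
  concentration anchors the PA column to the measured 170.3/146.1/119.6 μS
  triple.  The BA/VA/HA columns are synthetic (no printed numbers exist):
  hOR51E1 is assigned a short-chain preference (PA > BA > VA > HA),
  hOR51E2 a butyrate peak (BA > VA > PA > HA), hOR52D1 a long-chain
  preference (HA > VA > BA > PA), making the four odorant response vectors
  mutually distinct — a chain-length-complementary receptor code.
* **Noise.**  Additive i.i.d. Gaussian per measurement, SD 2.0 μS — 4% of
  the ~50 μS span of mean responses.  This puts neighbouring single-odorant
  classes 3–6 SDs apart and neighbouring mixture classes 1–3 SDs apart, so
  single odorants are cleanly separable while mixtures genuinely overlap:
  a multinomial-logistic ceiling on the default mixed-task inference set is
  ≈85–92% depending on the dataset seed.  That overlap, not the network,
  limits mixed-odorant accuracy — which is the regime the recognition
  results require.
* **Concentration.**  Linear: G(c) = baseline + (G_ref − baseline)·c/3 ppm,
  consistent with slope-based 3σ/S detection limits.  Baselines default to
  100 μS per channel.
* **Mixtures.**  The equimolar 1/n sum rule, implemented in its general
  fraction-weighted form Σ_o f_o·G_ref[channel, o]; it is linear in the
  composition vector.

Not emulated: receptor-binding kinetics, drift, channel cross-talk,
humidity/temperature effects, non-Gaussian tails.  Passing tests therefore
demonstrate the pipeline's behaviour under an idealized, stationary noise
model — not robustness on real sensor data.

## Pattern refinement

The observed training-response range is split into nine equal-width
regions shared across channels (boundaries overridable).  Bins are
half-open [low, high) with the last bin closed and ties going up; values
outside the range clamp to the edge regions with a logged warning.  The
margin around the observed range defaults to zero.  Each channel triple
becomes a 9 × 3 one-hot-per-column binary grid labelled by its
composition; flattened row-major it is the 27-wide network input.

The mixed task uses nine classes: the six equimolar two-odorant mixtures
plus the first three three-odorant mixtures in composition order.  The
class list is explicit configuration, not hard-coded, because the
described inventory (six pairs, four triples — ten compositions) exceeds
the nine-output network it feeds; we keep the nine-class reading and the
27×27×9 architecture.

Dataset sizes default to 216 training / 40 inference patterns for the
single-odorant task and 2194/366 for the mixed task, with per-class counts
differing by at most one.  Train and inference splits come from
independent seeded substreams.

## Device-aware network and training rule

Weights are differential pairs w = (G⁺ − G⁻)/(G_max − G_min) ∈ [−1, 1];
each member moves only along the device's LTP curve by integer pulses, so
the minimum weight increment is ≈1/P_max and updates inherit the curve's
state-dependent step size.  A desired Δw maps to
round(|Δw|·span / local LTP slope) pulses (stochastic rounding of the
remainder, ≤10 pulses per synapse per step) on G⁺ if Δw > 0, else on G⁻.
When a member reaches 99% of saturation the pair is reprogrammed to the
minimal-pulse configuration with the same weight.  Architectures and
learning rates are fixed at 27×14×4 with 0.03/0.0001 (single) and 27×27×9
(mixed); training samples one pattern per step uniformly with replacement
and evaluates every 100 steps (one epoch).

The update rule is error-driven rather than textbook mean-squared-error
backpropagation, for a concrete hardware reason: with these learning rates
and a 1/P_max weight granularity, full sigmoid-derivative MSE gradients
are two to three orders of magnitude below one pulse, so a plain
implementation programs *zero* pulses and never leaves chance level.  The
implemented rule keeps the published rates and architecture and changes
only how the error converts into pulses — each choice standard for
pulse-programmed synapse arrays:

1. **Cross-entropy residual** at the output: δ₂ = y − t (no extra
   sigmoid-derivative factor).
2. **Dead zone** (0.3): residuals smaller than the dead zone program
   nothing — sub-pulse corrections only dither the array.
3. **Margin gating** (0.1): a pattern whose target output already leads
   its runner-up by the margin is skipped entirely (perceptron-style
   error-driven learning); a converged network stops burning pulses and
   holds its solution.
4. **Sign-preserving hidden delta**: δ₁ = W₂δ₂ without derivative damping
   (as in resilient/Manhattan-style schemes); the update keeps the true
   gradient's sign per weight while its magnitude stays commensurate with
   the pulse step.
5. **Bipolar input encoding** (0 → −1): every input line participates in
   every update, which is what makes four-class convergence inside one
   100-step epoch possible at all.
6. **Asymmetric initialization**: input-side weights uniform ±0.1 (learned
   structure dominates quickly), output-side uniform ±1.0 (a rich readout
   for the slow 10⁻⁴ second-layer rate).

Under these defaults the single-odorant task reaches 100% inference
accuracy at the first 100-step epoch across test seeds and holds a
90–100% band thereafter; the mixed task climbs over ~30k steps to a
≈87–89% plateau with peaks of ≈88–92% over 150,000 steps — at or near the
dataset's statistical ceiling.  Device nonlinearity degrades this:
a device with |A| = P_max/20 trains to strictly lower accuracy than a
near-linear one under paired seeds, reproducing the linearity→accuracy
link qualitatively.  An `ideal` mode (float weights) and a `none`
quantization mode (continuous conductance updates) provide device-free
and continuous-limit baselines used by the gradient-sign and
continuous-limit oracle tests.

## Sensor statistics

* ΔF/F₀(%) = 100·(F₀ − F)/F₀ (F₀ > 0 enforced; anti-quenching allowed).
* PCA: column-mean centering (optional unit-variance scaling, off by
  default since all channels share μS), eigen-decomposition of the
  covariance, components by decreasing variance, each loading's
  largest-magnitude entry made positive for a reproducible orientation.
  Verified against an independent SVD route to 10⁻¹⁰.
* Detection limit: 3σ/S with σ the SD of ≥10 seeded blank replicates and
  S the least-squares calibration slope; slopes ≤ 0 are an error.
* Equimolar mixture enumeration: all unordered k-subsets with fractions
  1/k (6 pairs and 4 triples for the four-acid panel).

## Reproducibility and numerics

One global seed drives a pipeline run; stage seeds are
`blake2b(global_seed:stage_name) mod 2³¹`, so any stage replays in
isolation and a rerun is byte-identical (checksums in the run report).
Floating-point file output uses 6 significant digits; tests compare with
explicit tolerances except where byte-identity is the contract.
Tie-breaks: arg-max predictions resolve to the lowest class index; region
assignment sends boundary values up.  Degenerate inputs (all-equal
responses, zero noise, zero training steps) are either handled (noiseless
sampling, baseline-only trajectories) or rejected with explicit errors
(degenerate region range).

## Problem sizes

Default runs are desk-scale: the single task trains 1000 steps (~2 s),
the mixed task 150,000 steps (~1 min on one core); the acceptance script
repeats the mixed run over five seeds.  The device property suite checks
monotonicity exhaustively up to P_max = 500 and runs 50-seed Monte-Carlo
recovery studies.

## Known limitations

* The training rule is a reconstruction: the published description fixes
  architecture, rates and schedule but not loss, initialization or the
  gradient-to-pulse mapping; the choices above are documented, but other
  reconstructions could match the same reported trajectories.
* Off-PA affinities, region boundaries and the mixed class inventory are
  synthetic/configured stand-ins for unavailable tables; all are
  overridable by configuration when real values exist.
* Accuracy on the mixed task is ceiling-limited by the synthetic noise
  model; conclusions about absolute mixed-odorant accuracy transfer to
  real data only insofar as the 2 μS noise scale does.
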