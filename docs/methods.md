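# Methods

## The recognition problem

One crank revolution of the prosthetic-side leg is split into four phases
by the crank angle φc (pedal crank vs. horizontal): pedaling
(−45°, 45°], upper buffer (45°, 135°], relaxation (135°, 225°] and the
remaining quadrant (225°, 315°] as the lower buffer, so the four bands
tile the circle. During riding the phases occur in the order pedaling →
lower buffer → relaxation → upper buffer; with the intervals above that
means φc *decreases* along the stroke, which is how the simulator's
default rotation is oriented (`SimConfig.direction = -1`; `+1` gives the
opposite convention). φc is not measurable outside the lab, so the phase
is inferred from five instantaneous kinematic channels: knee and ankle
horizontal/vertical accelerations (kx, ky, hx, hy) and the knee angle a.
The knee angle alone is ambiguous — every angle between the cycle
extremes is visited twice per revolution, once flexing and once extending
— which is why the acceleration channels are needed at all.

## Synthetic data generator

The package ships a generator because no reference recordings are
distributed. It emulates the *structure* of the real signals, not any
individual subject:

- **Crank model**: constant cadence, φc(t) = (φ0 + direction·6·rpm·t)
  mod 360. Defaults: 60 rpm, 100 Hz sampling, 50 cycles, start at
  pedaling onset (φ0 = 45°).
- **Knee angle**: a monotone piecewise-cubic (PCHIP) periodic curve
  through the four phase-onset anchors, defaulting to the midpoints of
  the static-experiment ranges: 85.5° (pedaling), 107° (lower buffer,
  the cycle maximum), 96.5° (relaxation), 74.5° (upper buffer, the
  minimum). PCHIP keeps each inter-anchor segment monotone, so the
  extremes land exactly on the buffer anchors and each anchor is attained
  exactly at its onset crank angle.
- **Accelerations**: the ankle rides the circular pedal path, so its
  clean acceleration is a pure first harmonic of the crank frequency
  (amplitude `accel_amplitude`, default 5 m/s²); the knee gets half the
  amplitude plus a 30 % second harmonic with a small phase lead. This is
  deliberately not a multi-body linkage model — it is the simplest signal
  family that is periodic, phase-informative and has the right harmonic
  content.
- **Vibration noise**: Gaussian white noise band-passed to 5–20 Hz
  (4th-order Butterworth, zero-phase) emulating frame and stump
  vibration, scaled per channel so the realized SNR on (noisy − clean)
  equals `vibration_snr_db` exactly (default 10 dB). The knee angle
  channel is noise-free, matching an interference-proof angle sensor.

What the generator does **not** reproduce: inter-subject variability,
cadence drift and pedaling asymmetry, sensor bias/drift, impulsive road
shocks, or any cross-channel noise correlation. Results on this benchmark
therefore demonstrate the pipeline's mechanics (denoising gain, tuning
gain, correct bookkeeping), not field performance on amputee recordings.
At the default 10 dB SNR the group-median features are almost perfectly
separable and all four classifiers saturate near 100 %; the differences
between methods only open up under harsher noise (see the README's
−15 dB example).

## Denoising

Each acceleration channel is decomposed into a full wavelet-packet tree
(db4, level 3 by default; both configurable — the basis and depth are
conventional choices for 100 Hz kinematics, no claim of optimality).
Every leaf subband except the lowest-frequency one is shrunk with the
combined soft-hard rule

    G = sgn(g)·(|g| − k·α)  if |g| > α,   else 0,

k = 0 being the hard threshold, k = 1 the soft one, and k = 0.5 the
default mix. The threshold is the universal value α = τ·√(2 ln D) with
D = signal length and τ = median(|c|)/0.6745 over the highest-frequency
subband (noise-dominated for these signals); τ is a *scale* (standard
deviation), the only reading under which the threshold has signal units.
One global α is applied to all detail subbands by default;
`per_subband=True` re-estimates τ and α per subband with D the subband
size, which adapts better to band-limited noise. Boundary handling is
symmetric extension with the output truncated to the input length.
Reconstruction uses the full thresholded tree. The lowest band — which
holds the ≤ 6 Hz pedaling harmonics — is never touched, so the procedure
can only remove energy from noise-dominated bands; with band-limited
5–20 Hz noise and a τ estimated in the quiet top band the default global
threshold is conservative (small SNR gain, near-zero signal distortion),
while the per-subband mode is the aggressive variant.

## Classifier

Binary soft-margin SVMs with the standard kernels (RBF
exp(−γ‖u−v‖²) as the working choice; linear, polynomial, sigmoid
available for the kernel-comparison grid). The quadratic program is
solved by scikit-learn's SVC; everything else — kernel evaluation, the
explicit support-vector decision sum, tie handling (decision value 0 →
+1), the multiclass tree, serialization — is owned by this package, and
the decision values are verified against an explicit summation oracle in
the tests.

Multiclass structure: a three-node peeling tree. SVM1 separates pedaling
from everything else; SVM2, trained only on non-pedaling samples,
separates the lower buffer; SVM3 separates relaxation from the upper
buffer. Prediction is sequential and short-circuits at the first +1 vote;
a sample rejected three times is upper buffer. An alternative two-node
"pair vs. pair" scheme is deliberately not implemented: splitting four
phase clusters into two composite super-classes asks the first hyperplane
to separate classes that are not geometrically adjacent, and the peeling
tree is the design the evaluation tables describe (per-node Classifier
1/2/3 metrics).

## Swarm tuning

(C, γ) are searched in log₁₀ coordinates over C ∈ [10⁻², 10²],
γ ∈ [10⁻³, 10¹] (no published bounds; this box spans the usual RBF
regimes) by a global-best PSO: 20 particles, 200 iterations, c1 = 1.5,
c2 = 1.7, per-dimension r1, r2, velocities clamped to half the range,
positions clamped to the box, ties broken by particle index, and an early
stop after 30 iterations without a gbest gain above 10⁻⁶. Fitness is the
ten-fold stratified CV recognition rate of the tree trained with the
candidate pair (shared across the three nodes by default; a 6-D per-node
mode exists).

The inertia weight is adapted per particle by the piecewise rule

    ω = (ωmax − ωmin)(K − Kmin)/(Kavg − Kmin) + ωmin   if K ≤ Kavg
    ω = ωmax                                            if K > Kavg

with ωmax = 0.9, ωmin = 0.4 (conventional bounds). This rule treats K as
a quantity being minimized: the swarm minimum gets ωmin and fine-tunes
while at-or-above-average particles keep exploring at ωmax. Since the
optimizer maximizes fitness, it feeds the rule the negated fitness by
default. The alternative reading — feeding raw fitness, so the *best*
particles keep the largest inertia — is available as
`literal_inertia=True`; it is far more exploratory and measurably stalls
final convergence (sphere-test precision ~10⁻² instead of ~10⁻⁸), but
that exploration is exactly what the rugged 64-dimensional PSO-BP weight
search benefits from, so `compare_models` uses it there (see below).

## Baselines

**BP**: a 5-m-4 sigmoid network with squared-error loss, full-batch
gradient descent at learning rate 0.7, uniform(−0.5, 0.5) seeded init,
stopping at 500 epochs or global error < 10⁻³. Hidden size
m = round(√(n+l)) + α_const with α_const = 3, giving the reference 6
hidden nodes for 5 inputs / 4 outputs (the literal sum n+l+α_const = 12
is selectable via `rule="sum"` but contradicts that reference
configuration). Output is the argmax over the four output nodes, ties to
the lowest phase.

**PSO-BP**: the same architecture with all n·m + m + m·l + l = 64 weights
and thresholds encoded as the particle position in [−5, 5]⁶⁴ (wide enough
for saturated sigmoid units on standardized inputs), scored by K-fold
validation accuracy of the fixed network. Two deliberate deviations from
the kernel-search defaults, both because the fitness here is quantized in
1/n steps and the landscape is multimodal: the full iteration budget is
kept (the stagnation early-stop would fire long before the swarm
settles), and the exploratory `literal_inertia` reading is used. An
optional `polish=True` runs gradient BP from the swarm's best weights.

## Evaluation

Training and evaluation follow a group-level protocol: each (cycle,
phase) segment is collapsed to its median feature vector ("group"), so 50
cycles yield 200 groups, split 25/25 cycles into 100 training and 100
testing groups. Standardization parameters come from the training split
only. Per-node precision/recall treat node i as a binary problem on the
samples whose predicted path reaches it; F1 = 2PR/(P+R);
G = √(P·R) ≥ F1 with equality iff P = R; the precision summary uses the
population standard deviation (divisor 3). Displayed cells are rounded
half-up to two decimals.

`compare_models` trains all four models (BP, default SVM with C = 2,
γ = 1, PSO-BP, PSO-SVM) on the identical split. For desk-scale runtime
the (C, γ) swarm inside it is scaled down to 10 particles × 30 iterations
with early stopping — on this 2-D landscape that reliably matches a dense
grid-search oracle's best CV fitness (tested to within 0.01) — while the
PSO-BP weight search keeps 20 × 200.

## Numerical notes and limitations

- Degenerate inputs: all-equal swarm fitnesses → ωmin; zero-variance
  features standardize to zeros with scale 1; empty threshold-estimation
  subbands, single-class SVM training sets, missing phases, zero-division
  metric denominators and too-short signals all raise (or warn and return
  0 where the metric definition allows it).
- Decision-value agreement between the vectorized kernel path and the
  explicit sum is ~10⁻⁸; sign-symmetry under label flips holds only to
  the QP solver's convergence tolerance (~10⁻³).
- Determinism: every stochastic component (generator noise, splits, fold
  shuffling, swarm, weight init) is driven by an explicit integer seed;
  fixed seeds give bit-identical outputs.
- The published headline recognition rates were measured on undeposited
  human-subject recordings; nothing here claims to reproduce them from
  raw data. The package reproduces the evaluation arithmetic exactly and
  the method's qualitative behaviour (denoising gain, tuned ≥ default
  ordering) on the synthetic benchmark.
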