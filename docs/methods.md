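# Methods

`swarmsr` implements a particle swarm optimizer augmented with centroid
opposition-based learning (COBL) and a cosine-similarity mutation strategy
(SMCPSO), a benchmark suite to evaluate it, and a hybrid training scheme in
which the swarm searches the weight space of a small super-resolution CNN
to supply the initial point for stochastic gradient descent.  This note
records the model, the numerical choices, and what the desk-scale
experiments do and do not show.

## The optimizer

All three variants share the canonical global-best PSO core.  Each of N
particles carries a position `x`, velocity `v`, and personal best `pbest`;
the swarm tracks a global best `gbest`.  Per iteration, componentwise:

    v' = w v + c1 r1 (pbest − x) + c2 r2 (gbest − x),   r1, r2 ~ U(0,1)
    x' = x + v'

with `w` decreasing linearly 0.9 → 0.4 over the planned iterations,
`c1 = c2 = 2.0`, velocities clamped to ±0.2·(upper − lower) per dimension,
and positions clipped into bounds with the clipped velocity component
zeroed.  None of these constants is prescribed by the method itself; they
are the standard inertia-weight PSO settings and are exposed in
`SwarmConfig`.

**Centroid opposition (COBL).**  After each position update every particle
is mirrored through the swarm centroid `M = mean(xᵢ)`: `ox = 2M − x`.
Components falling outside the swarm's dynamic envelope
`[a_j, b_j] = [min_i x_{i,j}, max_i x_{i,j}]` are redrawn uniformly between
the envelope edge and the centroid (below: `[a_j, M_j]`; above:
`[M_j, b_j]`).  A mirror is adopted when its objective value is strictly
lower than the particle's current value; adoption zeroes the particle's
velocity.  Two points here were design choices forced by behavior rather
than stated by the method:

- *Repair anchors are the dynamic envelope, not the original bounds.*
  Redrawing across the full original box keeps injecting full-range
  randomness; the envelope-anchored repair makes the opposition step
  contractive around the occupied region, which is what lets it converge.
- *Velocity reset on adoption.*  Teleporting a particle while keeping its
  old velocity leaves the swarm in a permanent high-energy churn (the
  envelope never contracts and COBL underperforms plain PSO everywhere).
  Treating adoption as a restart of that particle's motion restores the
  expected behavior.

**Cosine-similarity mutation (SMCPSO).**  Aggregation around the incumbent
is measured by `Cos(gbest, xᵢ)`; particles whose similarity exceeds the
swarm mean `Cos_a` form the mutation region.  Every `mutation_period`
iterations (default 100, the only period the method ever states), each
region member is re-initialized uniformly in the original bounds with
probability δ(k), its velocity zeroed and its personal memory reset.  The
mutation factor decays linearly,

    δ(k) = ((Tmax − k)·Mstart + k·Mend) / Tmax,   Mstart = 0.5, Mend = 0.05,

written in convex-combination form so the endpoints are exact in floating
point.  The particle holding `gbest` is exempt, so the incumbent solution
survives every sweep and `gbest` is non-increasing by construction.  A
particle sitting exactly at the origin has undefined cosine similarity; it
is assigned similarity 0 and therefore never mutates.  The similarity
reference is `gbest` (the displayed formula); a `pbest` variant is
available behind `similarity_reference="pbest"`.

**Budget accounting.**  `SwarmConfig` stops either on a function-evaluation
budget (`eval_budget`; position updates, opposite evaluations, and mutation
re-evaluations all count) or on an iteration count (`max_iterations`).  The
benchmark protocol uses 10,000 *iterations* at N = 40: under a
10,000-*evaluation* budget (124 iterations for the opposition variants) no
variant approaches the reference results, whereas at 10,000 iterations the
reported values are reproduced; the source protocol's own per-run wall
times are only consistent with the iteration reading.  Under the iteration
reading PSO spends half the evaluations of COBL/SMCPSO per run — that
asymmetry is inherited from the protocol being reproduced, not introduced
here.

## Benchmark objectives

Shifted/rotated multimodal functions in the CEC 2013 style, with bounds
[−100, 100]^D and biases −900, −800, … stepping by 100 (skipping zero) for
F6…F20.  Registered: F6 rotated Rosenbrock (rescale 2.048/100, +1 offset in
z-space), F8 rotated Ackley, F10 rotated Griewank with the Λ^100 diagonal
conditioning (rescale 600/100), F11 Rastrigin, F12 rotated Rastrigin
(rescale 5.12/100), F19 expanded Griewank-plus-Rosenbrock (rescale 5/100).
Instances are self-generated from a seed: the shift is drawn uniformly in
80% of the box and the rotation is the Q factor (sign-fixed) of a Gaussian
matrix.  Function ids are hashed with CRC-32 so instances are stable across
processes.  Each instance satisfies `f(shift) = bias` exactly, which the
test suite checks analytically and against a 2-D dense-grid oracle.

Expected behavior at the benchmark protocol (N=40, D=30, 10,000
iterations, 20 runs, mean best): F8 ≈ −679 for every variant — the rotated
Ackley plateau one basin-depth above the −700 optimum, which no variant
escapes at this budget; F10 ≈ −500 for SMCPSO/COBL (full bias recovery)
versus ≈ −465 for plain PSO.  On Rastrigin D=30 SMCPSO's mean error is
below plain PSO's (≈24 vs ≈27); at D=10 with 5,000 iterations every variant
nearly solves the function (errors 1.5–1.7, per-run std ≈1.1) and the
comparison is a statistical tie — a floor effect, not a method difference.

## The super-resolution network

A small FSRCNN-style CNN in pure NumPy (float64): 5×5 feature extraction
(d filters) → 1×1 shrink (s) → m mapping 3×3 layers → 1×1 expand →
9×9 transposed convolution with stride = scale, geometry fixed so output =
scale × input exactly (pad/output-pad (4,1), (3,0), (3,1) for scales 2, 3,
4).  Activations are per-channel PReLU, slopes trained.  Presets: `d=56,
s=12, m=4` (the full-size lineage architecture) and the desk preset `d=16,
s=4, m=1` (2,049 parameters) used throughout the tests so the particle
dimension stays meaningful for swarm search.  Convolutions use im2col; the
transposed convolution is computed in scatter/gather form to avoid large
intermediates.  Analytic gradients match central finite differences to
1e−4 relative error (tested on the desk preset).  The cost is
`J(θ) = (1/n) Σᵢ ‖F(Yᵢ;θ) − Xᵢ‖²` — summed over each HR patch's pixels,
averaged over the batch — so gradient magnitudes are ≈256× a per-pixel-mean
convention, and step sizes below are calibrated to that scale.

`flatten`/`unflatten` bridge the network to a flat parameter vector with a
fixed layer-ordered layout; round trips are bit-exact and every vector
entry maps to exactly one parameter.

## Hybrid swarm → SGD training

The swarm minimizes `J` on a fixed fitness subset (default 64 patch pairs)
over the flat parameter space; its best particle initializes SGD on the
full patch set.  Two choices matter and were made after the obvious
alternative failed:

- *Particles are initialized as seeded network initializations* (He-normal
  weights, zero biases, slopes 0.25), particle 0 being exactly the
  initialization the SGD-alone baseline uses, with search bounds ±3
  He-sigmas per layer (slopes in [0, 0.5]).  Uniform-in-box initialization
  instead drives the swarm into a degenerate predict-the-mean basin with
  saturated slopes and dead channels that gradient descent refines poorly.
  With network-shaped particles the swarm phase is a guided search over
  trainable configurations, and elitism guarantees the hybrid starts no
  worse (on the fitness subset) than the baseline it is compared against.
- *The SGD phase uses heavy-ball momentum 0.9* (the standard setting in
  this architecture lineage; `sgd_momentum=0` recovers the plain update,
  which `sgd_step` implements and the tests check in isolation).  Plain
  SGD plateaus ≈2 dB short of solutions the same network demonstrably
  represents.

Desk defaults: 8 particles, 300 swarm iterations, mutation sweep every 100,
α = 1e−4 (the conservative member of the usual {1e−2, 1e−3, 1e−4} ladder —
larger steps diverge under the patch-summed cost), batch 16.  The
reference-scale configuration (50 particles, 10,000 iterations) is
reachable through `HybridConfig`.  An optional `sgd_schedule` runs phased
step decay; the bicubic-comparison experiment uses
(1e−4, 300) → (5e−5, 300) → (2e−5, 200) → (1e−5, 100).

## Synthetic data

`generate_corpus` emulates a small textured training corpus: band-limited
Gaussian noise (spectral cutoff 0.25 cycles/pixel — the LR Nyquist
frequency at scale 2, so textures carry energy a plain interpolator cannot
restore sharply), linear gradients, and anti-aliased random
ellipses/rectangles (4× supersampled), mixed 7:2:7 per 16 images, plus
σ = 0.01 Gaussian noise, clipped to [0, 1].  LR images come from separable
bicubic decimation with the two-lobe Keys kernel (a = −0.5), the kernel
stretched by the scale factor when decimating (anti-alias pre-filter),
taps clamped at the borders and rows normalized so constants round-trip
exactly.  The kernel sits behind a single operation (`bicubic_resample`)
because the exact down-sampling dialect is the one unstated degree of
freedom in the degradation model.

What the generator does **not** emulate: natural-image 1/f statistics,
camera noise, compression artifacts, or anything resembling real
radiographs.  Passing desk-scale tests therefore shows the machinery is
correct and the method's comparative claims hold under a controlled
degradation, not that the trained desk network transfers to real imagery.

## Desk-scale experiment sizes

Chosen so the full suite runs comfortably on one CPU: 16 images of 64×64,
every fourth held out; 8×8 LR patches, stride 6 for training (300 patches)
and 8 for evaluation; desk preset at scale 2.  The hybrid-vs-SGD comparison
uses 5 seeds × 25 epochs with a matched gradient budget per arm (a diverged
run counts as infinitely bad); the bicubic comparison trains one seed for
900 epochs with the step-decay schedule and compares mean PSNR over the
held-out pairs against bicubic upsampling of the same LR inputs.

## Quality metrics

MSE, PSNR `10·log10((2ⁿ−1)²/MSE)` (+∞ at zero error, reported as `inf`),
and SSIM from *global* image statistics with C1 = (0.01·255)²,
C2 = (0.03·255)² — the single-window form, symmetric by construction (the
denominator uses μx² + μy²).  An 11×11 Gaussian-window SSIM
(`ssim_windowed`, via scikit-image) is provided for comparison with common
practice; on smooth fixtures the two agree within 0.05.  RGB inputs are
reduced to BT.601 luminance first.  Classification metrics are one-vs-rest
accuracy, precision, sensitivity, F1, and specificity from a K×K confusion
matrix (rows = truth); undefined ratios are NaN with a logged warning,
never silently zero.

## Known limitations

- The benchmark registry covers the six functions the package's claims
  rest on, not the full F6–F20 suite; composition functions are out of
  scope.
- Training is CPU NumPy: suitable for the desk preset and corpus, roughly
  three orders of magnitude too slow for full-scale SR training.
- PSNR/SSIM conventions (luminance channel, no border crop) are fixed
  choices; published SR tables vary in both, which is why external-dataset
  numbers are not a comparison surface here.
- On low-dimensional, easy landscapes (e.g., Rastrigin D=10 at generous
  budgets) the three optimizer variants are statistically
  indistinguishable; the method's advantage appears on harder,
  higher-dimensional instances.
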