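# Methods

This note records the modelling and numerical choices behind `emgmm`: what
is simulated, which constants matter, what the synthetic data do and do not
emulate, and where the design was genuinely open.

## EMG processing and activation dynamics

Raw 1000 Hz EMG is enveloped with a 200 ms mean-absolute-value window
stepped every 10 ms; windows are fully contained in the signal, so a 10 s
record yields 981 envelope samples at 100 Hz spacing (the first output
corresponds to the first complete window). Envelopes are divided by the
per-channel MVC level and *not* clipped at 1 — dynamic contractions can
exceed a static MVC.

The recursion u(t) = α·e(t−d) − β₁·u(t−1) − β₂·u(t−2) runs at 100 Hz with
zero initial conditions; the electromechanical delay d = 40 ms is applied as
a 4-sample shift at that rate. The recursion coefficients are not uniquely
fixed by the problem; the defaults are β₁ = −1.0, β₂ = 0.25 (double real
pole at 0.5, comfortably stable) and α = 1 + β₁ + β₂ = 0.25, which enforces
unity steady-state gain so a sustained excitation e maps to u = e. u is
clipped to [0, 1] after the recursion so the nonlinear map's domain holds.
The activation nonlinearity a = (e^{Au} − 1)/(e^A − 1) uses A = −1 by
default (A = 0 is handled as the identity limit). All four constants are
configurable under the `activation` config key.

## Musculoskeletal model

Four Hill-type muscles with contractile and parallel-elastic elements:

* CE length: l_CE = (l_θ₌₀/100)·l_opt − s·(ma_wrist·θ_w + ma_MCP·θ_MCP),
  angles in radians, s = +1 for flexors and −1 for extensors, so a muscle
  shortens under the motion it drives. A non-positive computed length is a
  model degeneracy (see "Degenerate parameters" below).
* Active force: F0_CE · a · exp(−(l̃−1)²/w) with l̃ = l_CE/l_opt and Gaussian
  width w = 0.45 — a standard smooth force-length curve whose exact shape is
  not critical here, since validation rests on behavioral properties and
  round-trip recovery rather than on matching a particular muscle atlas.
* Passive force: K_PEE·(l_CE − l_opt)² once stretched beyond l_opt,
  consistent with K_PEE's units of N/m². No force-velocity element is
  modelled.

Joint moments are Σ s·ma·F per joint; muscles with ma = 0 contribute
nothing. The planar link-segment dynamics are I·θ̈ = M − b·θ̇ per joint,
integrated semi-implicitly at 100 Hz (velocity first, position second) with
the damping term treated implicitly — unconditionally stable at any b/I.
Angles clamp at the joint limits (wrist [−75°, 75°], MCP [−10°, 90°]) with
velocity zeroed. Gravity is omitted (the plane's orientation is
unspecified), and the base posture for all simulations is wrist 0°, MCP 45°
with zero velocity.

Inertia defaults are I_wrist = 5·10⁻³, I_MCP = 1·10⁻³ kg·m². Damping
defaults are b_wrist = 3.0 and b_MCP = 1.5 N·m·s/rad: with mid-range generic
parameters (F0 ≈ 505 N, ma ≈ 0.0255 m) a burst of activation produces
moments of several N·m, and these damping values place the resulting joint
velocities in the physiological range of roughly 100–400 deg/s, so that
limit-to-limit transitions take on the order of a second and the simulated
kinematics remain sensitive to the muscle parameters. Much lighter damping
turns the model bang-bang — every trajectory slams between joint stops
nearly instantaneously regardless of parameters — which would make
personalization unidentifiable. All dynamics constants live under the
`dynamics` config key.

The per-cycle simulation loop is compiled with numba; the elementary
operations (`ce_length`, `muscle_force`, `joint_moments`,
`forward_dynamics_step`) are plain Python reference implementations, and the
test suite checks the compiled kernel against chaining them sample by
sample.

## Parameter vector and bounds

The 22 optimizable values flatten in the order [ECRL, EDC, FCR, FDS] ×
[l_opt, F0_CE, ma_wrist, ma_MCP, l_θ₌₀, K_PEE], omitting the structurally
zero MCP moment arms of ECRL and FCR. Bounds: l_opt ∈ [0.1, 0.5] m,
F0_CE ∈ [10, 1000] N, moment arms ∈ [0.001, 0.05] m, l_θ₌₀ ∈ [75, 125] %,
K_PEE ∈ [10, 200] N/m². Updates and optimizers operate on this vector; the
structural zeros are simply absent from it and can never be modified.

## State, action, reward

Keypoints of a measured cycle are the four extrema of the wrist and MCP
series (earliest index on ties), sorted chronologically, plus four
midpoints. The extrema define only three interior gaps; the eighth keypoint
closes the cycle circularly — the midpoint from the last extremum to the
first plus the cycle length, taken modulo the cycle. Midpoints are floored
to whole samples. For a constant series this degenerates gracefully to
keypoints at 0 and the half-cycle.

Each state element is the signed error (measured − estimated, normalized by
ROM) averaged over a 50-sample (500 ms) window centered on a keypoint;
boundary windows are clipped with the averaging length reduced accordingly.
The 16-vector concatenates eight wrist elements then eight MCP elements.
The reward is −‖S‖₁. Actions scale to parameter updates by
ΔP = 0.05·(B_U − B_L)∗A, and parameters clip to their bounds after every
update.

## DDPG pretraining

Actor 16→100 (ReLU)→22 (tanh) and critic with separate 100-unit state and
action branches joined by elementwise addition, both weights-only. Open
details were resolved as follows:

* critic nonlinearity: a single ReLU applied after the addition layer
  (configurable in principle; the branch outputs are linear);
* weight initialization: uniform in ±1/√fan-in from the seeded generator;
* optimizer: Adam at the specified learning rate 10⁻³ with L2 = 0. The
  networks are small enough that gradients are hand-derived (and verified
  against finite differences in the tests). Plain SGD is selectable but
  learns far too slowly at this rate to be useful within the training
  schedules used here;
* updates are skipped until the buffer holds one full minibatch (100);
* exploration noise follows x ← x + 0.15·(0 − x) + σ·𝒩(0,1) per step with σ
  decaying multiplicatively by 10⁻⁴ per step from 0.30 (floor 0), the usual
  discretization of an OU process with those printed constants; noisy
  actions are clipped to [−1, 1] so the 5% update bound also holds during
  exploration;
* episodes cycle through the training subjects; each episode resets the
  parameters to the generic model and runs 20 update steps, cycling through
  the subject's data cycles one per step. The state observed after an
  update is computed on the *next* cycle (keypoints recomputed per cycle),
  so consecutive steps share a single simulation;
* no terminal-state special-casing: episode ends are time-limit
  truncations, so targets bootstrap across them.

The full training schedule is 1000 episodes; with the compiled simulator
this takes ~25 s per policy on one CPU, so it is also what the benchmark
uses. Note the printed OU decay (10⁻⁴/step) anneals exploration from 0.30
to ~0.04 precisely over those 20,000 steps — the hyperparameters are
internally consistent at that length, and materially shorter schedules
leave both exploration high and the policy visibly undertrained. The
library default is a 100-episode desk-scale run for quick interactive use;
`DdpgHyperparams(episodes=...)` selects either.

## Personalization and convergence

With the policy frozen, personalization starts from the generic parameters
and applies noiseless actions, one data cycle per update step (cycling).
Δr_m = r_m − r_{m−1} is undefined at m = 1, so the 3-value sliding mean of
Δr can first be evaluated at m = 4; the procedure stops at the first step
where it is nonpositive and returns the parameters evaluated at that step.
A hard cap of 200 steps guards against non-convergence, returning the
best-reward parameters seen with a warning. The procedure is fully
deterministic given (policy, cycles, initial parameters).

With three training cycles the 3-step window telescopes to
(r_m − r_{m−3})/3, i.e. it compares rewards on the *same* cycle one loop
apart — cycle-to-cycle amplitude variation then perturbs the stopping rule
much less than raw consecutive differences would.

## Simulated annealing baseline

Parameters are normalized to [0, 1]²²; the objective is the sum over
training cycles, joints and samples of the squared ROM-normalized error.
The annealer mirrors the documented defaults of common bounded-SA solvers:
T₀ = 100, exponential cooling T = T₀·0.95^⌊k/20⌋, Gaussian proposals with
per-coordinate step min(T, 1) clipped to the box, logistic acceptance
1/(1 + e^{ΔF/T}) for uphill moves, best-so-far tracking (so the result is
never worse than the start), optional reannealing every N acceptances
(default interval 10,000 — effectively off at the 5000-evaluation desk
budget). Equivalence to any particular solver is behavioral, not bit-level.
Degenerate proposals score +∞ and are effectively rejected.

## Synthetic subjects and data cycles

A synthetic subject is a ground-truth parameter vector drawn uniformly
within ±ρ·range of the generic (mid-range) model, clipped to bounds, plus
per-channel EMG gains in [0.85, 1.15] (imperfect MVC normalization) and an
angle-noise level (default σ = 1°). Burst amplitudes are a subject trait
drawn once in [0.3, 0.9] per channel: the emulated recording protocol paces
subjects against a displayed virtual hand, so effort is stereotyped within
a subject, varying only ±0.05 cycle-to-cycle (plus ±0.1 s timing jitter and
2% multiplicative EMG noise).

Each 10-s cycle drives the four channels with raised-cosine bursts — ECRL
then FCR (wrist extension/flexion) in the first half, EDC then FDS (MCP
extension/flexion) in the second — matching the protocol's movement order.
The emitted EMG (drive × gain × noise, clipped at 0, already at 100 Hz) is
simulated with the subject's true parameters to produce the noiseless
angles; "measured" angles add Gaussian noise and clip to the joint limits.
Because the angles are simulated *from the emitted EMG*, the true
parameters reproduce the σ = 0 measured angles exactly — perfect recovery
is attainable by construction, and the true parameters are a global
minimizer (objective 0) of the SA objective on their own noise-free data.

What the generator does **not** emulate: raw-EMG interference patterns and
firing statistics (envelopes are emitted directly; the 1000 Hz path is
exercised separately by the envelope unit tests), electrode-placement
variability and crosstalk, fatigue or other nonstationarity across cycles,
and any mismatch between the model family and real limb dynamics. Passing
tests therefore demonstrate correct and well-conditioned personalization
machinery under the model's own dynamics — not estimation accuracy on real
limbs.

## Degenerate parameters

Extreme corners of the parameter box (short l_opt and l_θ₌₀ with large
moment arms at large joint excursions) can drive the computed CE length
non-positive. The public `simulate_cycle` raises `ModelDegeneracyError` in
that case. Optimizers need a defined behavior instead: the SA objective
returns +∞ (the proposal is rejected), while the RL loops floor the CE
length at 1 mm — physically a fully slack muscle — so that exploration can
pass through and recover from infeasible excursions without aborting a
training run.

## Evaluation harness and problem sizes

NRMSE = RMSE/ROM per joint, averaged with equal weight across the two
joints, then across cycles, then across subjects (equal subject weighting;
cycle counts are balanced by construction). The leave-one-subject-out
harness pretrains one policy per fold on the remaining subjects' training
cycles, personalizes the held-out subject on its own training cycles, runs
SA on the same cycles, and scores generic/RL/SA models on the held-out
subject's three test cycles. Wall times are logged but never asserted.

The standard benchmark (tests and `scripts/acceptance.py`) uses 4 subjects,
ρ = 0.2, nine cycles each (3 train + 3 test used), 1000-episode policies,
SA at 5000 evaluations, replicated over 5 seeds — about seven minutes on
one CPU. Typical outcomes: generic NRMSE ≈ 0.09, RL-personalized ≈ 0.04 in
~10 update steps, SA ≈ 0.01 at ~1500× the simulation cost. The RL-vs-SA gap
in accuracy (SA nearly reaches the noise floor here) is wider than one
would expect on real data, where model mismatch limits every method;
synthetic data generated by the model itself is exactly the regime where an
exhaustive optimizer can win outright.

## Known limitations

* The actor/critic have no biases, so the policy is odd-symmetric-ish
  around zero state and cannot encode state-independent corrections.
* The critic is piecewise-linear in the action, so it cannot represent an
  interior optimum in action magnitude; the convergence-stopping rule, not
  the policy itself, prevents overshoot near the optimum.
* Personalization quality varies across seeds: an occasional fold sees a
  policy whose update direction misgeneralizes to the held-out subject, in
  which case the stopping rule returns parameters close to (rarely slightly
  worse than) generic.
* The 2-DOF model ignores individual fingers, tendon compliance, pennation
  and force-velocity effects.
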