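# Methods

This note documents the model as implemented: its assumptions, parameters,
numerical choices, the design decisions that were genuinely open, and what
the synthetic tasks do and do not establish.

## Oscillator dynamics and frequency calibration

All dynamics run on a fixed 2 ms grid (`dt = 0.002 s`); a trial is 500
steps (1 s), the first 250 of which are the inter-trial interval (ITI)
without stimulus input. Phase pairs follow the discrete update

    ΔE = −C·I − Damp·J(r > r_min)·E + B,   ΔI = +C·E − Damp·J(r > r_min)·I

integrated by forward Euler exactly as written — no higher-order scheme; the
damping term is the only radius control. Processing-unit triplets use
`Damp = .3`, `r_min = 1`; the controller uses `Damp = .003`, `r_min = .05`
so its amplitude decays slowly across trials.

**Calibration.** In the continuum limit the oscillation frequency is
C/(2π) per unit time, suggesting C = 2π·f·dt. The discrete map, however,
advances phase by arctan(C) per undamped step and by arctan(C/(1−Damp)) per
damped step, so at gamma-band couplings the small-angle value overshoots:
C = 0.5027 yields 42.5 Hz rather than 40 Hz. Because the frequency targets
(40 Hz processing, 5 Hz controller) are the primitive quantities and C is
merely the knob that realizes them, `coupling_for_frequency` calibrates C by
Brent root-finding on the phase-slope frequency of the actual burst-free
trajectory (C ≈ 0.47623 for 40 Hz; 0.06279 for 5 Hz, where the correction
is ~0.07%). The calibration is deterministic and cached.

**Initial conditions.** Triplet phases are initialized uniformly at random
at radius r_min (a desynchronized start, so any synchronization is
attributable to bursts). The controller starts at amplitude 1 — elevated
control at task onset that then decays toward its attractor — since an
amplitude that "decays across trials" must begin above r_min, and a
controller born at r_min would be inert for the first trials, leaving the
modules unprotected exactly when initial learning happens. The controller's
phase is never reset at trial boundaries; it runs freely.

**Numerical safeguards.** With fast couplings and weak damping the Euler
map grows even on damped steps (√((1−Damp)² + C²) > 1), so in the degraded
corner of the parameter exploration (controller at gamma speed) the
controller amplitude diverges. A purely numerical radius cap (1e6) keeps
arithmetic finite there; functional regimes never approach it (radius stays
below ~1e2, and the burst probability saturates around amplitude 2).
Logistic functions are evaluated with `scipy.special.expit` where their
argument can be large.

## Rate dynamics and the gate

Rate neurons are memoryless on the grid: Δx = −x + f(net − bias)·G(E), so
x tracks its gated drive within one step and decays fully when the gate
closes. Multi-layer nodes use the logistic f with a fixed bias of 5 (biases
are not learned); linear-family nodes use the identity without bias. The
input layer passes the external drive (magnitude 1 per active feature)
through linearly for both families — pushing a unit drive through the
biased logistic would leave the whole multi-layer network at f(−4) ≈ 0.018
and unlearnable, whereas the linear pass-through places initial hidden nets
(≈ 4 active inputs × mean weight 1.25) at the bias midpoint. Learning
consumes the per-trial maxima X_i = max_t x_i(t); since there is no input
during the ITI, this equals the maximum over the stimulation window. x is
not clipped; linear nodes may transiently go negative, but the per-trial
maxima (initialized at 0) are non-negative.

## Architecture

* Linear (RW) family: layer 1 = stimulus features, layer 2 = 3 modules × 3
  response nodes. Readout pools same-response nodes across modules by max
  (a gated-out module cannot vote) with ties broken toward the lowest
  index. The no-synchrony variant is a single 3×3 map (with all gates at 1
  the three modules are redundant replicas).
* Multi-layer (BP) family: layer 1 = cue + stimulus features, layer 2 = 3
  modules × 4 hidden nodes, layer 3 = 3 shared response nodes. The module
  size (4) is a free choice — the reference architecture leaves it open —
  and results are mildly size-sensitive: larger modules learn the cued
  tasks somewhat faster. The no-synchrony variant keeps the same hidden
  width as one undifferentiated layer.
* Weights initialize uniform(0, 1) × bias/2 (multi-layer) or × 1 (linear).

Learning rules, applied once at trial end with the one-hot correct response
as target: the full linear model uses the co-activation-gated delta rule
ΔW = β(T−X_o)·X_i·X_o (the X_o factor makes only co-activated pairs
eligible, which is what lets gating protect dormant modules, at a known
plasticity cost); the no-synchrony linear model uses the classic rule
β(T−X_o)·X_i. Both multi-layer variants use standard backpropagation of
squared error with logistic derivatives on the trial maxima; protection in
the full model emerges from the gated activations alone, verified by a
finite-difference gradient check against the static (gain ≡ 1) network.

## Control and reinforcement learning

Bursts to the processing unit are emitted on every time step of the trial
(ITI included): B_i = pointer_i · pMFC(t) · U(t) with pMFC(t) a Bernoulli
draw at p = expit(10(E_pMFC − 1)) and U(t) a *single* standard-Gaussian
draw shared by all nodes in that step. The sharing is normative —
independent noise would destroy the binding mechanism. Error feedback
re-energizes the controller during the next trial's ITI: steps fire with a
Gaussian-bump probability peaking 200 ms after feedback (SD 25 ms) and
carry the previous trial's δ⁻ as amplitude.

RL parameters follow the family of the synaptic learner: value learning
rate α = .1 (linear) / .01 (multi-layer), switch leak σ = .5 / .8, switch
threshold .5, inhibition −2 decaying by 10% at the end of *every* trial
(not only after switches), softmax selection over Q + Inh. On trial 1 the
pointed module is chosen uniformly at random.

**Value prior.** The initial Q is family-specific, mirroring the
family-specific α and σ. The multi-layer family uses an optimistic prior
(Q₀ = 1): while its slow network is still at chance the expected negative
error is at most (2/3)·V, so with a neutral prior (V = .5) the accumulator
asymptotes at 1/3 and the stay/switch mechanism could never fire — the
model would be unable to "try another strategy" and degenerates into a
single-module learner. The linear family uses a neutral prior (Q₀ = .5): it
masters a rule within the first trials of a block, and with σ = .5 an
optimistic prior is degenerate (a single δ⁻ = 1 error satisfies
(1−σ)·δ⁻ = threshold and would reset the accumulator on every lapse).
Q = 0 is absorbing under the multiplicative value update, so some positive
prior is required in any case. Both priors are user-overridable (`q_init`).

Per-trial order of operations: simulate 500 steps → readout → reward →
value estimate, prediction errors, value update → switch accumulator (and
possibly re-selection + inhibition tag) → inhibition decay → synaptic
learning step. δ⁻ is carried to the next trial's ITI burst schedule.

## Tasks

Six equal blocks, rule order A B C A B C; rules are the three cyclic
permutations of features onto responses. The 1-dimensional task has 360
trials (each feature exactly 20× per 60-trial block, shuffled). The cued
task has 3600 trials and N ∈ {2, 3} stimulus dimensions plus a cue
dimension whose active feature marks the relevant stimulus dimension.
Because the number of feature combinations (18 or 81) does not divide a
600-trial block, exact balance is impossible; blocks are built by shuffled
tilings of the full combination list truncated to block length, so
per-block counts differ by at most one. Chance accuracy is 1/3 throughout.

## Analyses

* Zero-lag synchrony: Pearson correlation of two excitatory traces
  (per-trial; averaged over node pairs between groups); constant traces
  return NaN.
* dPAC per trial over all 500 samples: |mean_t a_t(e^{iφ_t} − Φ̄)| with
  Φ̄ the mean phase vector; φ is the analytic (Hilbert) phase of the
  controller trace, computed over the whole concatenated run so trial edges
  do not distort the transform; a_t is the mean |E| over processing nodes.
* Time-frequency power: complex Morlet convolution, frequencies 1–10 Hz in
  10 linear steps (configurable), wavelet width σ = 4/(2πf), support ±4σ,
  reflect padding; power is the squared magnitude, reported raw (no dB
  baseline — any such normalization would cancel in the error-minus-correct
  contrast anyway). The feedback contrast averages ITI windows classified
  by the correctness of the preceding feedback.

## Problem sizes used in the test suite

Scaled-down study conditions are first-class presets, chosen once: the
linear-family behavioral checks use the full 360-trial task with 5
replications; the multi-layer stability comparison uses the 3-dimensional
task shortened to 1200 trials (bin size 10) with 3 paired replications;
the oscillator-parameter property uses a 120-trial task at 2 replications.
Replication r uses task seed r and model seed r. The binned-metric
machinery keeps the 120-bin convention whenever the trial count allows and
otherwise falls back to the largest block-aligned bin count.

## What the synthetic conditions do and do not show

The tasks are deterministic, fully balanced, noise-free mappings with
binary reward; all gamma oscillators share one exact frequency, and there
are no conduction delays. Passing tests therefore demonstrate the
computational mechanism — burst-driven binding, gating-based weight
protection, error-driven control — not robustness to heterogeneous
frequencies, graded rewards, probabilistic feedback, or sensory noise.
Within-block accuracy of the multi-layer family on the hardest (3-D) task
plateaus well below ceiling at these problem sizes, so its stability
advantage is assessed relative to the no-synchrony baseline rather than as
absolute retention. Extensions explicitly out of scope: learned phase
offsets between areas, multiple simultaneous pointers, contextual features
for inferring *which* module to select, and the stochastic-binarization
(Boltzmann) learning family, for which only the architectural hook exists.
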