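# Methods

## Model

`tcfit` simulates a single-compartment conductance-based thalamocortical
(TC) relay neuron and fits its three relay-critical parameters from spike
features. The membrane equation is

    C_m dV/dt = -I_L - I_Na - I_K - I_T - I_Gi→Th - I_SM

with

    I_L  = g_L (V - E_L)
    I_Na = g_Na m∞³(V) h (V - E_Na)
    I_K  = g_K · 0.75 (1 - h)⁴ (V - E_K)
    I_T  = g_T p∞²(V) r (V - E_T)

Sodium activation `m` and T-type calcium activation `p` are instantaneous
sigmoids (midpoints −37 and −60 mV); the slow gates relax as

    dh/dt = (h∞(V) - h) / τ_h(V),    h∞ midpoint −41 mV
    dr/dt = 2.5 (r∞(V) - r) / τ_r(V),  r∞ midpoint −84 mV,
    τ_r(V) = 28 + exp(-(V + 25)/10.5) ms.

`I_Gi→Th` is a constant current standing in for pallidal inhibition and
`I_SM` the sensorimotor pulse input. The three fitted parameters are
`(I_Gi→Th, g_T, E_T)`; the reference ("parkinsonian") triple is
(−3.5, 3, 120).

**Background constants.** C_m = 1, g_L = 0.05, E_L = −70, g_Na = 3,
E_Na = 50, g_K = 5, E_K = −75 (reduced-TC-model literature values). All
are plain `TCParams` fields and overridable; none are fitted.

**Sign conventions.** The membrane equation subtracts both external
currents. With the shipped values (I_Gi→Th = −3.5, pulse amplitude +5)
the literal subtraction makes the pallidal term depolarizing and the
pulse train hyperpolarizing. Default configuration flips the pulse sign
(`flip_sign_sm=True`) so the sensorimotor input is depolarizing, and
keeps the pallidal term literal (`flip_sign_gi=False`). The alternative
— flipping the pallidal term so a negative I_Gi→Th hyperpolarizes — was
measured and rejected for the default: with g_L = 0.05 a constant
−3.5 current rests the cell near −140 mV, where it is silent, every
pulse is missed, and I_T ≈ 0 along the whole trace, leaving E_T with no
influence on the output at all. Both flags remain available per run.

In the default regime the parkinsonian triple fires tonically and fails
relay through multi-spike ("bad") responses in every pulse window
(RI = 0), while the normal-state triple (−0.5, 1, 120) — weaker
pallidal drive, weaker T conductance — relays one spike per pulse
(RI = 1). The normal/parkinsonian thresholds RI > 0.9 / RI < 0.5 follow
the relay-fidelity convention.

## Stimuli

The standard input is the Heaviside-product square pulse train

    I_SM(t) = A · H(sin(2πt/ρ)) · (1 − H(sin(2π(t + δ)/ρ)))

with A = 5 pA/μm², ρ = 25 ms, δ = 5 ms; it is ON over (ρ/2 − δ, ρ/2]
within each period, so pulse onsets are known analytically and carried
with the trace. The Poisson train reuses A and δ with exponential
inter-onset gaps (default mean 25 ms); gaps below δ are redrawn, giving
the exponential conditioned on gap ≥ δ (mean δ + 25 ms) and no pulse
overlap. The generator's defaults are the comparison conditions; the
Poisson statistics are a package choice made once, since only the pulse
shape of that input is standardized.

What the synthetic data does and does not emulate: traces are noiseless
model output on the integration grid. There is no channel noise,
synaptic conductance dynamics, electrode filtering, or spike-sorting
error, so passing tests demonstrate correct inverse-problem machinery on
clean data, not robustness to the artifacts of real recordings.

## Relay scoring and spike features

Spikes are maximal contiguous excursions with V ≥ −25 mV (threshold
configurable); the spike time/peak is the excursion maximum. Samples
before `t_discard` (default 100 ms) are excluded. Each pulse opens a
response window `[onset, onset + w)` with w = ρ by default, truncated at
the next onset; 0 spikes in a window = missed, ≥ 2 = bad, and

    error index = (missed + bad) / total inputs,   RI = 1 − error index.

Spikes between windows are ignored by default (`orphans_are_bad=True`
charges them to the preceding input).

Four features summarize a trace: RI, spike count N, mean spike peak PK
(sentinel = threshold when no spike exists, keeping the objective
defined everywhere), and mean strictly-subthreshold voltage ST. The
fitness between candidate ("rec") and reference ("ori") features is

    q = Σ_trials [ w₁(RI_rec−RI_ori)² + w₂(N_rec−N_ori)²
                 + w₃(PK_rec−PK_ori)² + w₄(ST_rec−ST_ori)² ].

Default weights are 1/scale² with scale = max(|reference feature|, 1),
so each term is O(1) for an O(scale) mismatch; unit weights are a flag
away. Recovery quality is the squared key-parameter error
e_T = Σ(fitted − given)², reported as ln e_T.

### Why the fitness sums over several trials

With the square-wave trial alone the feature map cannot determine three
parameters: RI saturates at 0 in the parkinsonian regime, N is integer,
and the two continuous summaries (PK, ST) admit a compensation ridge —
raising g_T while lowering E_T leaves g_T·(V̄ − E_T), hence the T-current
along the visited voltage band, nearly unchanged. Numerically, the
fitness minimized over (I_Gi→Th, g_T) at E_T fixed 15 mV away from the
truth reaches ~1e-16, indistinguishable from the true zero. The default
experiment therefore scores the square-wave standard plus three
Poisson-train probes (`n_poisson_trials=3`); irregular gaps probe
different depths of T-current recovery and turn the ridge into a funnel
whose floor rises monotonically away from the truth.
`n_poisson_trials=0` restores the single-trial objective.

## Particle swarm optimizer

Velocity/position updates are the standard two-attractor rule with
c₁ = c₂ = 2, fresh uniform r₁, r₂ per dimension per update, velocity
clamped to v_max = 0.2·(hi − lo) per dimension, and positions clamped to
the box with the clamped component's velocity zeroed. Five inertia
schemes:

* `constant` — ω = 0.7;
* `linear` — ω from ω_max = 0.9 to ω_min = 0.4 linearly in k/k_max;
* `concave1` — ω = ω_min (ω_max/ω_min)^(1/(1 + 10k/k_max)), steep
  early, flat late (never quite reaching ω_min);
* `concave2` — the quadratic with the same endpoints and zero slope at
  k_max;
* `improved` — per particle, per iteration: particles whose current
  fitness beats the swarm mean follow `concave1` (controlled
  exploitation); the rest get ω = α + (1 − α)L with α annealed from 0.8
  to 0.2 and L advanced through the logistic map L ← 4L(1 − L)
  (swarm-global state, advanced once per chaotic draw, seeded away from
  the map's eventually-fixed points). Ties take the concave branch.

q_avg is the mean of the current iteration's finite fitnesses.
Non-finite objective values are treated as +∞ and counted. The run
stops at k_max or when the global best drops below `q_stop`
(default 1e-8; a looser threshold measurably stops while E_T is still
~1 off truth, which would defeat the recovery experiment). Identical
seeds reproduce the full history bit-for-bit.

## Recovery experiment

`ExperimentConfig` defaults define the study: truth (−3.5, 3, 120),
search box I_Gi→Th ∈ [−10, 0], g_T ∈ [0, 10], E_T ∈ [90, 140]
(bracketing all plausible mis-convergences), dt = 0.05 ms over 500 ms
with 100 ms discarded, 20 particles, 50 iterations, five replicate
seeds derived from one master seed and shared across schemes (paired
comparison), medians reported. These problem sizes are the package's
chosen experiment scale; `SimConfig` alone defaults to the finer
dt = 0.01 ms / 1000 ms grid for standalone simulation.

## Numerical choices

* Fixed-step RK4; the applied current is held constant across each step
  (it is piecewise-constant anyway). Convergence on smooth segments is
  4th order (verified by step-halving).
* Deterministic everywhere: the objective is an exact function of the
  candidate triple, so fitness comparisons are reproducible.
* Divergence guard at |V| > 200 mV aborts with the offending step;
  gates leaving [0, 1] by more than 1e-6 raise a warning. Degenerate
  candidates (diverging or spiking everywhere) receive +∞ fitness and
  are rejected by the swarm rather than crashing the run.
* Threshold comparisons: spikes use V ≥ threshold, subthreshold samples
  V < threshold, so every sample is classified exactly once.

## Known limitations

* **E_T is weakly identifiable at the default experiment scale.** Even
  with the multi-trial objective, the funnel around the truth in the
  E_T direction is shallow (floor fitness ~1e-8 at |ΔE_T| ≈ 0.5 vs
  ~2.5e-7 at |ΔE_T| ≈ 10) and textured by discontinuities wherever a
  marginal pulse gains or loses a spike. At 20 particles × 50
  iterations all five schemes — including the adaptive one — typically
  stall at ln e_T ≈ 2–6, recovering I_Gi→Th to ~1e-2 and g_T to ~0.2
  but leaving E_T several mV off. For calibration, the same optimizer
  budget on a smooth sphere objective reaches gbest ≈ 1e-4 (constant ω)
  to 2e-8 (adaptive scheme), so sub-0.1-mV recovery of E_T demands
  either a much larger search budget, a longer/richer stimulus
  protocol, or trajectory-level (not feature-level) comparison.
* Relay scoring assumes non-overlapping response windows; for Poisson
  inputs with short gaps windows are truncated, which biases RI upward
  slightly relative to a fixed-width definition.
* The pallidal drive is a constant current, not a conductance; its
  hyperpolarizing variant pushes the resting potential far below the
  physiological range (see Sign conventions) rather than saturating at
  a synaptic reversal potential.
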