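# Methods

`synrecon` simulates synaptic reconsolidation: the phenomenon that
consolidated (LTP-stabilized) synapses degrade when weak reactivation
coincides with protein-synthesis inhibition (PSI), while either alone leaves
them intact.  The mechanism is a finite, shared pool of stabilizing entities
with an activity-dependent, PSI-immune reservoir.  This note documents the
model equations as implemented, the parameter choices that were genuinely
open, the numerical scheme, what the compressed test conditions do and do
not show, and known limitations.

## Model layers

**Spiking front end (0.1 ms).**  A leaky integrate-and-fire neuron with
conductance-based excitation receives input from N presynaptic Poisson-like
neurons (N drawn per repeat from Binomial(400, 0.5); mean 200, SD 10).  All
conductances are dimensionless multiples of the leak conductance:

    tau_m dV/dt = (V_rest - V) + g_exc (V_exc - V) + g_adapt (V_adapt - V),
    g_exc = beta g_ampa + (1 - beta) g_nmda.

AMPA is a first-order filter of the presynaptic spike trains (tau 5 ms)
with per-spike increments Delta g_j = g0 [w_- + (w_j + 1)(w_+ - w_-)/2],
w_+ = 3 w_-; NMDA is a second-order low-pass of AMPA (tau 100 ms, no
voltage dependence).  A spike is fired when V >= theta; V resets to
V_rest, theta jumps to 100 mV and relaxes with tau_thr = 2 ms (the only
refractory mechanism), and the adaptation conductance (reversal -80 mV,
tau 250 ms) increments by 10.  The adaptation reversal is not listed with
the membrane constants; we use the inhibitory reversal potential, the
natural choice for spike-triggered self-inhibition, and expose it.

**Plasticity induction (triplet STDP).**  Exponential traces x+ (per
synapse, tau 16.8 ms), y- (33.7 ms) and y_triplet (114 ms); at each
postsynaptic spike I+ = A+ x+ y_triplet(t-eps) (the slow trace read before
its own increment), at each presynaptic spike I- = A- y-.  Inductions are
*impulses*: their magnitudes add directly to the slow variables they drive
(weight, gate accumulator gamma, co-activity I^A) — the standard discrete
form of the triplet rule.  The alternative reading (divide impulses by the
target's time constant) makes the gate unreachable: an entire HFS delivers
a summed drive of order 1, which divided by tau_gamma = 600 s could never
cross theta_gamma = 0.37.

**Write-protected synapse (100 ms).**  Weight w, tag T and scaffold z share
the bistable force f(x) = x - x^3 and are chained w <-> T <-> z with gates:
G = H(gamma - 0.37) couples w and T; the plasticity-product availability p
(driven to 1 by a 60-s dopamine pulse coincident with HFS, decaying with
2000 s) couples T and z.  A consolidated scaffold (z > 0) is destabilized
by -a_b/tau_z H(z) whenever the synapse is unbound (b = 0); since a_b = 1
exceeds max f = 2/(3 sqrt 3), an unbound big scaffold decays with
certainty (~160 s from z = 1 to 0).  Euler-Maruyama with per-variable,
per-synapse independent noise sigma = 1e-2 s^-1/2.

**Stabilizer pool (100 ms).**  Binding of unbound big synapses at rate
k1 N_A + k3 N_A*, unbinding at k2(I^A) + k4(I^A) with logistic activity
dependence between k0 and k0 + m; the release branch (susceptible vs
immune) and the binding source are chosen in proportion to the rates.
During PSI, N_A is held at zero and susceptible releases are discarded; at
PSI offset the susceptible pool replenishes so that
N_A + N_A* + N_bound = N_A,tot = 2e4 again.

**State-based model (1 s).**  Seven states; 1-3 weak, 4-7 strong (weight
2); %fEPSP = (N_weak + 2 N_strong)/1200 * 100.  HFS moves all weak-basal
synapses to strong-basal and opens the transient cascade 4 -> 5 -> 6
(p(t), c(t) with 10- and 30-min time courses); 6 <-> 7 is stabilizer
binding/unbinding, state 6 decays to the strong basal state at tau_l and
state 7 only at tau_r = 1e-4 per min.  The state-6 decay target is the
strong basal state (the basal-state convention of the six-state scheme);
routing it to the weak basal state instead is exposed as a switch
(`six_to_three`).  The model has no spiking front end; its co-activity
comes from the reduced model's pulse filter.

**Reduced model (0.1 s).**  Mean-field ODEs for the bound count n_ASyn and
reservoir n_A* with the same rate constants, plus the filtered activity
tau_A dI/dt = -I + omega sum_k delta(t - t_k) driven by nominal
stimulation pulse times.

## The co-activity operating point (omega, g0)

The unbinding half-activations (I0_4 = 0.045 < I0_2 = 0.057, slope 0.003)
define the designed operating point of the model: sustained 0.1-Hz
stimulation must raise I^A to the order of these constants so that
unbinding toward the reservoir (k4) and, during PSI, reservoir consumption
(k2) are activity-controlled.  Two calibrations pin this point, done once
and frozen:

- `g0` (conductance scale, calibration routine `experiments.calibrate_g0`)
  is bisected so that steady 0.1-Hz LFS at the initial synapse mixture
  holds the population-mean I^A near 0.08 (~5-6 postsynaptic spikes per
  volley).  Result: g0 = 50.7.  Post-LTP volleys are larger and hold I^A
  near 0.105.
- `omega` = 1.05 s, so the reduced filter's 0.1-Hz steady state
  (omega x 0.1 Hz x jump scaling = 0.105) matches the full model's
  post-LTP co-activity — the regime in which the reduced model is always
  initialized.

A substantially larger omega (e.g. the order-5 value one might read from
the constant table) would put the LFS steady state a decade above both
half-activations; the activity dependence would then be binary and
paradigm 4 (continuous stimulation through PSI) could not retain its
reservoir.  The operating point ~0.08-0.1 saturates both logistics during
stimulation and relaxes them to baseline within ~5 min of silence
(tau_A = 150 s), which is also what makes the activity-gated variants
(theta_act = 0.01) switch cleanly.

## Paradigm timelines

All paradigms: 0.1-Hz background stimulation with one 100-Hz/60-s HFS at
minute 20 (dopamine pulse coincident), total span 10 h, final monitoring
LFS from hour 8.  The PSI windows are package defaults chosen from the
measured reservoir budgets (the sources only cartoon them):

- p1: LFS 0-40 min; PSI 100-200 min; no stimulation during PSI.
- p2: p1 plus LFS 150-170 min (inside PSI).
- p3: initial LFS extended to 100 min (abutting PSI onset), otherwise p2.
- p4: continuous LFS; PSI 100-140 min.

Budget arithmetic (full scale): the reservoir at PSI onset is ~850 after a
40-min LFS block and ~1450 after continuous LFS.  Losses are k0 N_big
(~0.1/s) without stimulation and (k0+m) N_big (~0.5/s) with stimulation.
p1 loses ~570 < 850 (persists); p2 additionally loses ~570 during its
20-min window (depletes near minute 170, scaffolds collapse before PSI
ends); p3's larger buildup absorbs the same insult; p4's loss rate is
maximal throughout, so its PSI must be shorter than its buildup allows
(~40 min for a ~1.3x margin).  These are knife-edge budgets by
construction — the model sits near the boundary conditions it is meant to
map.

## Numerical scheme

- Membrane potential: exponential Euler (exact for conductances frozen
  within the step).  Forward Euler is unstable during synchronous volleys
  (g_exc ~ 10^3 violates dt (1+g)/tau_m < 2) and was replaced; all other
  deterministic updates are forward Euler, SDEs Euler-Maruyama, trace and
  filter decays exact exponential factors (so induction magnitudes match
  the event-driven analytic solution to machine precision).
- Pool transitions: first-order probabilities rate*dt with a validity
  guard; the fused kernel and the state-based stepper use the exact form
  1 - exp(-rate*dt), which is always a valid Bernoulli probability.
- Decayed quantities flush to zero below 1e-30 (denormal arithmetic is two
  orders of magnitude slower and physically meaningless); silent 100-ms
  blocks relax the neuron analytically.  Both shortcuts reproduce the
  step-by-step updates exactly (verified by the engine-vs-modules
  equivalence test).
- The fused numba kernel is bit-reproducible given a repeat seed; repeat
  seeds derive from the master seed via `numpy.random.SeedSequence.spawn`.

## The N_big follower of the reduced model

The number of consolidated synapses N_big enters the reduced ODEs as the
binding capacity.  Two follower rules are implemented:

- `follower="surplus"` (default): dN_big/dt = -(N_big - n_ASyn - 16)_+ /
  tau_big with tau_big = 160 s, the scaffold collapse time.  Synapses in
  excess of the bound count (beyond the small binding-equilibrium surplus)
  are losing their scaffolds at exactly that rate in the full model, so
  this rule is phase-independent: it does not matter whether reservoir
  depletion happens during or after a stimulation block.  The margin and
  tau_big were fitted once against a 6-repeat full-model ensemble on the
  boundary-condition protocol and frozen.
- `follower="slope"`: N_big decays at the phi-delayed, eta-windowed slope
  of n_ASyn when that slope is steeper than theta_big.  This published
  form is kept and unit-tested, but it has two structural error modes
  found empirically: once its gate opens, n_ASyn (which tracks N_big with
  an absolute offset whenever binding is tight) sustains the triggering
  slope, producing runaway decay; and its slope threshold cannot separate
  the fast binding-equilibrium shift at stimulation onset from a
  post-stimulation unbinding collapse, which breaks the monotonicity of
  the boundary map in PSI duration.  theta_big is read per hour (-80/h);
  the printed per-second magnitude could never be crossed by a bound count
  of order 200.

With the surplus follower, reduced trajectories of reservoir and bound
count track full-model ensemble means within a few entities everywhere,
the boundary map is exactly non-increasing in PSI duration, equals 1
without PSI, and is U-shaped along the stimulation axis — short and long
stimulation persist, intermediate durations degrade.

## State-based pool constants

The state-based unbinding constants (k0 = 0.02, m = 0.25) are read per
minute, like every other rate of that model; per-second values empty the
reservoir ~60x too fast and give per-step probabilities above 1 at the
model's 1-s step.  The binding constants are re-derived rather than taken
from the constant table: the tabulated k1/k3 ratio (1/100) clamps the
reservoir at its exchange equilibrium ~ (k1/k3) N_A ~ 100 entities, far
too small to span any PSI window, so consolidation would degrade in every
paradigm.  Two structural requirements fix the orders of magnitude:
k1 N_A >> k3 N_A* (the reservoir must be growth-limited, not drained by
routine rebinding) and k3 N_A* >> tau_l (binding must be maintained from
the reservoir during PSI while it lasts).  We use k1 = 1/30 and
k3 = 1/300 per minute.  With these, the reservoir reaches ~3600 (40-min
LFS) or ~13000+ (continuous LFS) at PSI onset and the four paradigms
classify exactly as in the write-protected model.  The paradigm-2
depression of %fEPSP is modest (~6 points) though highly significant:
synapses that are still in the stable unbound state when PSI ends rebind
and are rescued, so only those that decayed past the strong basal state
during PSI are lost.

## The compressed ("fast") preset

Production figure runs use the full time scales; the test suite and the
acceptance script run a tenfold-compressed preset that is an exact time
rescaling of the slow subsystem: durations /10, slow time constants
(tau_w/T/z/gamma/A, 1/k_down) /10, all pool rates x10 with the pool size
unchanged (absolute reservoir budgets, and hence classification margins,
are preserved), sigma x sqrt(10), LFS at 1 Hz so each block delivers the
same number of volleys, and the reduced-model dt at 10 ms.  The spiking
front end keeps its physiological time constants, and HFS keeps its native
100 Hz / 60 s shape so the induction cascade (gate crossing, dopamine
window, scaffold consolidation) is driven by the same number of pairings.
The state-based model is stepped in real-time units with its protocol
clock compressed.  What the compressed tests show: the classification
logic, reservoir budgets and statistical separations of the full-scale
model, exactly rescaled.  What they do not show: slow-noise phenomena at
the original time scale (barrier escapes scale exactly only because
sigma^2 tau is held fixed) and any property of the spiking statistics at
0.1-Hz inter-volley intervals (volleys are independent at both rates
because all synaptic traces decay within ~1 s).

## Statistics

Paradigm outcomes are compared on the per-repeat time-averaged trace over
the final 30 simulated minutes (scaled with the preset), across 10
independent repeats, with a two-sided Welch two-sample test; equivalence
statements use overlap within 3 combined s.e.m.  For the write-protected
delayed-decay variant, "indistinguishable until the final stimulation" is
operationalized as: the gated trace remains in the consolidated regime and
lies closer to the control than to the ungated (decayed) trace — a strict
equivalence test cannot pass because the tag equation's scaffold coupling
(which the variant deliberately does not gate) deterministically relaxes
the weight of collapsed synapses by a few percent.

## Known limitations

- The boundary-condition budgets are intentionally marginal; per-repeat
  depletion outcomes near the boundary are stochastic, and a small
  fraction of paradigm-2 repeats can survive (or paradigm-1 repeats
  collapse) at the compressed scale.
- The mean-field reduced model has a ~20-s phase error at the depletion
  kink relative to full-model ensembles (a few entities against ensemble
  s.e.m. that can be smaller than one entity at the kink).
- The state-based model's paradigm-2 effect size is bounded by PSI-offset
  rescue (above).
- No heterosynaptic competition, no LTD-induction pathway, no inhibitory
  input, no NMDA voltage dependence — all outside the scope of the model
  family implemented here.
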