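# synrecon

A stochastic, multi-scale simulator of **synaptic reconsolidation**: the
degradation of consolidated (LTP-stabilized) synapses when weak synaptic
reactivation coincides with protein-synthesis inhibition (PSI), and their
persistence when either occurs alone.

The model stabilizes consolidated synapses through a finite pool of
N_A,tot = 2×10⁴ stabilizing entities shared by all synapses of a
postsynaptic cell.  An entity can be bound to a big synapse, free and
PSI-susceptible (N_A), or free and PSI-immune (N_A*, "the reservoir"):

    A + Syn  ⇌(k1 N_A / k2(Iᴬ))  A·Syn  ⇌(k4(Iᴬ) / k3 N_A*)  A* + Syn

Binding is fast and activity-independent; unbinding is slow and grows with
the synapse's co-activity Iᴬ through a logistic rate
k(Iᴬ) = k0 + m / (1 + exp((I0 − Iᴬ)/r)).  During PSI, N_A ≡ 0 and
susceptible releases are lost, so consolidation survives exactly as long as
the reservoir — which grows with pre-PSI activity and drains faster with
activity during PSI.  That arithmetic produces the *boundary conditions* of
reconsolidation, including a U-shaped dependence on stimulation duration.

This pool is layered onto two consolidation models:

- a **write-protected model**: per-synapse bistable weight/tag/scaffold
  variables (double-well force f(x) = x − x³) driven by a leaky
  integrate-and-fire neuron with conductance synapses and triplet-STDP
  induction (time steps 0.1 ms / 100 ms);
- a **state-based model**: 1000 synapses in a 7-state Markov scheme whose
  seventh state is the stabilizer-bound state (time step 1 s);

plus a **reduced two-dimensional mean-field model** of (n_ASyn, n_A*) used
to map the boundary conditions on a stimulation-duration × PSI-duration
grid.

The science, parameter choices and numerical scheme are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Reconsolidation in the write-protected model at the tenfold-compressed
preset — stimulation paradigm 2 (a 20-min LFS block inside the PSI window)
against its no-PSI control:

```python
from synrecon.experiments import RunConfig, run_pair, end_window_stats

cfg = RunConfig(paradigm="p2", model="write_protected",
                n_repeats=10, seed=1, fast=True)
res_psi, res_ctl, p = run_pair(cfg)
print("end-of-run mean weight, PSI    :", end_window_stats(res_psi).mean())
print("end-of-run mean weight, control:", end_window_stats(res_ctl).mean())
print("Welch p-value:", p)
```

prints

```
end-of-run mean weight, PSI    : -0.015041814746317744
end-of-run mean weight, control: 0.9845594896111847
Welch p-value: 2.3526926092274342e-08
```

The control stays at the consolidated weight (w ≈ +1); with PSI the
reservoir depletes during the mid-PSI stimulation block, scaffolds collapse
and the population weight falls toward the weak state — a highly
significant difference.  Paradigms 1 (no stimulation during PSI), 3 (longer
initial stimulation) and 4 (continuous stimulation, shorter PSI) all remain
statistically indistinguishable from their controls.

The same comparison for the state-based model uses
`model="state_based"` (%fEPSP readout), and the delayed-decay variants are
selected with `variant="activity_gated_noise"` (write-protected) or
`variant="activity_gated_beta"` (state-based).

## Command line

```bash
synrecon run-full --paradigm p2 --seed 1 --fast --out results
synrecon run-state-based --paradigm p2 --seed 1 --fast --out results
synrecon run-reduced --seed 1 --fast --out results
synrecon map-boundary --seed 1 --fast --grid-size 26 --out results
```

Outputs are TSV time series (t, mean, s.e.m.), a TSV boundary matrix, and a
JSON manifest with the configuration hash.

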