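"""Leaky integrate-and-fire postsynaptic neuron with conductance-based
excitation (fast AMPA + slow NMDA component), an adaptive threshold and
spike-triggered adaptation.

All conductances are dimensionless multiples of the leak conductance, so the
membrane equation carries no capacitance parameter:

    tau_m dV/dt = (V_rest - V) + g_exc (V_exc - V) + g_adapt (V_adapt - V)

with g_exc = beta * g_ampa + (1 - beta) * g_nmda.  A spike is emitted when
V >= theta; V resets to V_rest, theta jumps to theta_spike (100 mV) and
relaxes back with tau_thr, which is the only source of refractoriness.
Integration is forward Euler at dt = 0.1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "NumericalDivergenceError",
    "step_neuron",
]


class NumericalDivergenceError(RuntimeError):
    """A state variable became non-finite; the message names the variable."""


@dataclass
class NeuronParams:
    """Membrane, threshold and conductance parameters.

    The adaptation reversal potential ``V_adapt`` implements spike-triggered
    self-inhibition and defaults to the inhibitory reversal potential
    (-80 mV), the natural choice for a hyperpolarizing conductance.
    """

    tau_m: float = 20e-3          # s
    V_rest: float = -70.0         # mV
    V_exc: float = 0.0            # mV
    V_adapt: float = -80.0        # mV
    tau_thr: float = 2e-3         # s
    theta_rest: float = -50.0     # mV
    theta_spike: float = 100.0    # mV
    tau_ampa: float = 5e-3        # s
    tau_nmda: float = 100e-3      # s
    beta_ampa_frac: float = 0.5   # relative AMPA contribution
    tau_adapt: float = 250e-3     # s
    g_spike: float = 10.0         # adaptation increment per spike

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_thr", "tau_ampa", "tau_nmda", "tau_adapt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.beta_ampa_frac <= 1.0:
            raise ValueError("beta_ampa_frac must lie in [0, 1]")


@dataclass
class NeuronState:
    V: float = -70.0
    theta: float = -50.0
    g_ampa: float = 0.0
    g_nmda: float = 0.0
    g_adapt: float = 0.0

    @classmethod
    def resting(cls, params: NeuronParams) -> "NeuronState":
        return cls(V=params.V_rest, theta=params.theta_rest)


def step_neuron(state: NeuronState, dg_sum: float, params: NeuronParams,
                dt: float = 1e-4) -> tuple[NeuronState, bool]:
    """Advance the neuron by one Euler step.

    ``dg_sum`` is the summed conductance increment of all presynaptic spikes
    arriving in this step (Sum_j Delta g_j).  Update order: threshold
    relaxation, conductances (jump then decay), membrane, spike test; a spike
    resets V, sets theta to theta_spike and increments g_adapt by g_spike.
    """
    p = params
    theta = state.theta + dt * (p.theta_rest - state.theta) / p.tau_thr
    g_ampa = state.g_ampa + dg_sum
    g_nmda = state.g_nmda + dt * (g_ampa - state.g_nmda) / p.tau_nmda
    g_ampa = g_ampa - dt * g_ampa / p.tau_ampa
    g_adapt = state.g_adapt - dt * state.g_adapt / p.tau_adapt
    g_exc = p.beta_ampa_frac * g_ampa + (1.0 - p.beta_ampa_frac) * g_nmda
    # exponential-Euler membrane update: exact for conductances frozen over
    # the step and unconditionally stable during large synchronous volleys
    # (forward Euler would violate its stability bound there)
    g_tot = 1.0 + g_exc + g_adapt
    V_inf = (p.V_rest + g_exc * p.V_exc + g_adapt * p.V_adapt) / g_tot
    V = V_inf + (state.V - V_inf) * np.exp(-dt * g_tot / p.tau_m)
    for name, val in (("g_ampa", g_ampa), ("g_nmda", g_nmda),
                      ("g_adapt", g_adapt), ("V", V), ("theta", theta)):
        if not np.isfinite(val):
            raise NumericalDivergenceError(
                f"neuron variable {name!r} became non-finite"
            )
    spiked = V >= theta
    if spiked:
        V = p.V_rest
        theta = p.theta_spike
        g_adapt += p.g_spike
    return NeuronState(V=V, theta=theta, g_ampa=g_ampa, g_nmda=g_nmda,
                       g_adapt=g_adapt), bool(spiked)
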