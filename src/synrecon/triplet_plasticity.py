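"""Minimal triplet STDP rule: spike traces, plasticity-induction impulses and
the slow co-activity variable that drives stabilizer unbinding.

Three exponential traces are maintained: a presynaptic trace x+ per synapse
(tau_x = 16.8 ms), a fast postsynaptic trace y- (tau_y = 33.7 ms) and a slow
postsynaptic trace y_triplet (tau_triplet = 114 ms).  Potentiation induction

    I+ = A+ * x+(t) * y_triplet(t - eps)

fires at postsynaptic spikes (the slow trace is read just before its own
increment); depression induction I- = A- * y-(t) fires at presynaptic spikes.

Impulse convention: delta-driven inductions are per-event impulses of
magnitude I added directly to their slow target variables (weight drive,
gate drive, co-activity), independent of the integration step -- the
standard discrete form of the triplet rule.  Trace decay between events uses
the exact exponential factor, so induction magnitudes match the event-driven
analytic solution to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TripletParams",
    "TraceState",
    "update_traces",
    "induction",
    "drive_weight",
    "drive_gate",
    "update_coactivity",
    "heaviside",
]


def heaviside(x):
    """H(x) = 1 for x >= 0, else 0 (the H(0) = 1 convention, applied to all
    tie-breaks)."""
    return np.where(np.asarray(x) >= 0.0, 1.0, 0.0)


@dataclass
class TripletParams:
    A_plus: float = 5e-4
    A_minus: float = 2e-4
    tau_x: float = 16.8e-3      # s, presynaptic trace
    tau_y: float = 33.7e-3      # s, fast postsynaptic trace
    tau_triplet: float = 114e-3  # s, slow postsynaptic trace
    tau_A: float = 150.0        # s, co-activity low-pass

    def __post_init__(self) -> None:
        if min(self.A_plus, self.A_minus, self.tau_x, self.tau_y,
               self.tau_triplet, self.tau_A) <= 0:
            raise ValueError("all triplet parameters must be positive")


@dataclass
class TraceState:
    """Traces for one postsynaptic neuron with n synapses.

    ``x_plus`` and ``I_A`` are per-synapse arrays; the postsynaptic traces
    are scalars shared by all synapses.  Everything starts at 0.
    """

    x_plus: np.ndarray
    y_minus: float = 0.0
    y_triplet: float = 0.0
    I_A: np.ndarray = None

    @classmethod
    def zeros(cls, n_synapses: int) -> "TraceState":
        return cls(x_plus=np.zeros(n_synapses), I_A=np.zeros(n_synapses))

    @property
    def n_synapses(self) -> int:
        return self.x_plus.size


def update_traces(state: TraceState, pre_spikes: np.ndarray, post_spike: bool,
                  params: TripletParams, dt: float) -> TraceState:
    """Increment traces at their own spikes, then decay by one step.

    Mirrors the per-step order used in the induction loop: inductions are
    computed from pre-increment values, then traces are incremented and
    decayed.
    """
    x = state.x_plus + np.asarray(pre_spikes, dtype=float)
    y_m = state.y_minus + (1.0 if post_spike else 0.0)
    y_t = state.y_triplet + (1.0 if post_spike else 0.0)
    return TraceState(
        x_plus=x * np.exp(-dt / params.tau_x),
        y_minus=y_m * np.exp(-dt / params.tau_y),
        y_triplet=y_t * np.exp(-dt / params.tau_triplet),
        I_A=state.I_A,
    )


def induction(state: TraceState, pre_spikes: np.ndarray, post_spike: bool,
              params: TripletParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-synapse LTP drive I+ and LTD drive I- for the current step.

    Must be called before :func:`update_traces` for the same step, so that
    y_triplet is read at (t - eps) and x+ excludes this step's presynaptic
    increments.
    """
    pre = np.asarray(pre_spikes, dtype=bool)
    I_plus = np.zeros(state.n_synapses)
    if post_spike:
        I_plus = params.A_plus * state.x_plus * state.y_triplet
    I_minus = np.where(pre, params.A_minus * state.y_minus, 0.0)
    return I_plus, I_minus


def drive_weight(I_plus, I_minus, w, z) -> np.ndarray:
    """Weight drive: potentiation saturates at w = 1, depression at w = -1,
    each boosted when the scaffold disagrees with the weight."""
    I_plus, I_minus, w, z = map(np.asarray, (I_plus, I_minus, w, z))
    pos = np.maximum(z - w, 0.0)
    neg = np.maximum(w - z, 0.0)
    return I_plus * (1.0 + pos) * (1.0 - w) - I_minus * (1.0 + neg) * (1.0 + w)


def drive_gate(I_plus, I_minus, w, z, gamma) -> np.ndarray:
    """Gate drive: induction counts toward the gate only when it opposes the
    current weight/scaffold relation, scaled by the remaining gate headroom."""
    I_plus, I_minus, w, z, gamma = map(np.asarray, (I_plus, I_minus, w, z, gamma))
    return (I_plus * heaviside(w - z) + I_minus * heaviside(z - w)) * (1.0 - gamma)


def update_coactivity(state: TraceState, I_plus, I_minus,
                      params: TripletParams, dt: float) -> TraceState:
    """Leaky integration of the summed induction impulses with tau_A = 150 s.

    The impulses accumulated over the step add directly (per the impulse
    convention), so a sustained induction flux c settles at I_A = tau_A * c.
    """
    I_A = state.I_A * np.exp(-dt / params.tau_A) + np.asarray(I_plus) + np.asarray(I_minus)
    return TraceState(x_plus=state.x_plus, y_minus=state.y_minus,
                      y_triplet=state.y_triplet, I_A=I_A)
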