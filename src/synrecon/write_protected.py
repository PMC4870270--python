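"""Write-protected synapse model extended with binding-dependent
destabilization.

Each synapse carries three bistable variables -- weight w, tag T, scaffold z
-- that share the double-well force f(x) = -x(x-1)(x+1) and are coupled in a
chain w <-> T <-> z.  The w-T coupling is controlled by a per-synapse gate G
(opened when the low-passed induction drive gamma crosses theta_gamma), the
T-z coupling by the global availability p of plasticity-related products
(driven by a dopamine signal).  A consolidated scaffold (z > 0) is stable
only while the synapse is bound to a stabilizing entity (b = 1); when
unbound, the term -a_b/tau_z * H(z) tilts the potential and the big state
decays with certainty (a_b = 1 exceeds max f = 2/(3*sqrt(3)) on (0, 1]).

Integration is Euler-Maruyama at dt = 100 ms with independent Gaussian white
noise per synapse and per variable; in the ``activity_gated_noise`` variant
the w and T noise terms are switched off whenever the synapse's co-activity
falls below theta_act (the scaffold noise is never gated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .triplet_plasticity import heaviside

__all__ = [
    "WPParams",
    "WPSynapses",
    "GlobalGate",
    "bistable_force",
    "step_synapse",
    "update_p",
    "conductance_from_weight",
    "init_synapses",
    "VARIANTS",
]

VARIANTS = ("original", "activity_gated_noise")

#: Default synaptic conductance scale, calibrated once with
#: :func:`synrecon.experiments.calibrate_g0` so that steady 0.1-Hz LFS holds
#: the mean co-activity at the designed operating point (~0.08, above both
#: unbinding half-activations); see docs/methods.md.
G0_DEFAULT = 50.7


@dataclass
class WPParams:
    tau_w: float = 200.0        # s
    tau_T: float = 200.0        # s
    tau_z: float = 200.0        # s
    a_wT: float = 3.5           # tag <- weight coupling (gated by G)
    a_Tz: float = 3.5           # scaffold <- tag coupling (gated by p)
    a_Tw: float = 1.3           # weight <- tag coupling (gated by 1-G)
    a_zT: float = 0.95          # tag <- scaffold coupling (gated by 1-p)
    a_b: float = 1.0            # destabilization strength when unbound
    sigma: float = 1e-2         # noise intensity, s^(-1/2)
    tau_gamma: float = 600.0    # s, gate accumulator decay
    theta_gamma: float = 0.37   # gate threshold
    kappa: float = 1.0          # s, unit-carrying factor of the gamma drive
    k_up: float = 1.0           # s^-1, dopamine-driven rise of p
    k_down: float = 1.0 / 2000.0  # s^-1, decay of p
    theta_act: float = 0.01     # co-activity threshold for gated noise
    w_minus: float = 0.05       # small-synapse conductance fraction
    k_w: float = 3.0            # w_plus / w_minus
    g0: float = G0_DEFAULT      # conductance scale (calibrated)

    def __post_init__(self) -> None:
        if not 0.0 < self.theta_gamma < 1.0:
            raise ValueError("theta_gamma must lie in (0, 1)")
        for name in ("tau_w", "tau_T", "tau_z", "tau_gamma", "k_up", "k_down"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def w_plus(self) -> float:
        return self.k_w * self.w_minus


@dataclass
class GlobalGate:
    """Plasticity-related-product availability p and dopamine signal D."""

    p: float = 0.0
    D: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass
class WPSynapses:
    """State arrays for a population of write-protected synapses."""

    w: np.ndarray
    T: np.ndarray
    z: np.ndarray
    gamma: np.ndarray
    b: np.ndarray                # int8 bound flags
    force_unbound: np.ndarray    # bool: keep the synapse artificially unbound

    @property
    def n(self) -> int:
        return self.w.size

    def copy(self) -> "WPSynapses":
        return WPSynapses(*(a.copy() for a in
                            (self.w, self.T, self.z, self.gamma, self.b,
                             self.force_unbound)))


def bistable_force(x):
    """f(x) = -x(x-1)(x+1) = x - x^3, the double-well force with stable
    fixed points at +-1 and an unstable one at 0."""
    x = np.asarray(x, dtype=float)
    return x - x ** 3


def step_synapse(syn: WPSynapses, gate: GlobalGate, drives, params: WPParams,
                 noise: np.ndarray, dt: float = 0.1,
                 variant: str = "original") -> WPSynapses:
    """One Euler-Maruyama step of all synapses.

    ``drives`` is the tuple (I_w, I_gamma, I_A) of per-synapse induction
    impulses accumulated over the step (added directly, impulse convention)
    and the current co-activity.  ``noise`` has shape (3, n): standard normal
    draws for w, T, z.  The gate G = H(gamma - theta_gamma) is evaluated from
    the pre-step gamma.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    I_w, I_gamma, I_A = (np.asarray(a, dtype=float) for a in drives)
    p = params
    sq = p.sigma * np.sqrt(dt)
    G = heaviside(syn.gamma - p.theta_gamma)
    ngate = heaviside(I_A - p.theta_act) if variant == "activity_gated_noise" else 1.0

    w, T, z, b = syn.w, syn.T, syn.z, syn.b.astype(float)
    with np.errstate(invalid="ignore"):
        dw = dt * (bistable_force(w) / p.tau_w
                   + p.a_Tw / (4 * p.tau_w) * (1.0 - G) * (T - w))
        dT = dt * (bistable_force(T) / p.tau_T
                   + p.a_wT / (4 * p.tau_T) * G * (w - T)
                   + p.a_zT / (4 * p.tau_T) * (1.0 - gate.p) * (z - T))
        dz = dt * (bistable_force(z) / p.tau_z
                   + p.a_Tz / (4 * p.tau_z) * gate.p * (T - z)
                   + p.a_b / p.tau_z * heaviside(z) * (b - 1.0))
        w_new = w + dw + ngate * sq * noise[0] + I_w
        T_new = T + dT + ngate * sq * noise[1]
        z_new = z + dz + sq * noise[2]
    gamma_new = np.clip(
        syn.gamma - dt * syn.gamma / p.tau_gamma + p.kappa * I_gamma, 0.0, 1.0
    )
    for name, arr in (("w", w_new), ("T", T_new), ("z", z_new)):
        bad = ~np.isfinite(arr)
        if bad.any():
            raise FloatingPointError(
                f"synapse variable {name!r} non-finite at id(s) "
                f"{np.flatnonzero(bad)[:5].tolist()}"
            )
    return WPSynapses(w=w_new, T=T_new, z=z_new, gamma=gamma_new, b=syn.b,
                      force_unbound=syn.force_unbound)


def update_p(gate: GlobalGate, params: WPParams, dt: float = 0.1) -> GlobalGate:
    """dp/dt = D k_up (1 - p) - k_down p (Euler).  With D held at 1, p
    approaches k_up / (k_up + k_down)."""
    p_new = gate.p + dt * (gate.D * params.k_up * (1.0 - gate.p)
                           - params.k_down * gate.p)
    return GlobalGate(p=float(np.clip(p_new, 0.0, 1.0)), D=gate.D)


def conductance_from_weight(w, params: WPParams) -> np.ndarray:
    """Affine map from w in [-1, 1] to Delta g in [g0 w_-, g0 w_+]."""
    w = np.asarray(w, dtype=float)
    return params.g0 * (params.w_minus
                        + (w + 1.0) * (params.w_plus - params.w_minus) / 2.0)


def init_synapses(n: int, frac_big: float = 1.0 / 3.0,
                  seed: int = 0) -> WPSynapses:
    """round(n * frac_big) randomly chosen synapses start big, consolidated
    and bound ((w,T,z) = (1,1,1), b = 1); the rest small and unbound."""
    if not 0.0 <= frac_big <= 1.0:
        raise ValueError("frac_big must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_big = int(round(n * frac_big))
    big = np.zeros(n, dtype=bool)
    big[rng.choice(n, size=n_big, replace=False)] = True
    val = np.where(big, 1.0, -1.0)
    return WPSynapses(
        w=val.copy(), T=val.copy(), z=val.copy(),
        gamma=np.zeros(n),
        b=big.astype(np.int8),
        force_unbound=np.zeros(n, dtype=bool),
    )
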