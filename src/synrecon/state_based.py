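"""Seven-state Markov model of a population of synapses with dynamic
stabilization.

States 1-3 are weak (stable, intermediate, basal), states 4-6 strong (basal,
intermediate, stable); a seventh state extends the strong branch: 6 <-> 7
transitions are the binding/unbinding of a stabilizing entity from the
shared pool, so state 7 (bound) is the most stable state while state 6 now
decays back to the strong basal state comparatively fast (rate tau_l).

At baseline, only 3 <-> 4 exchange (rates alpha, beta).  An HFS at t0 moves
every weak-basal synapse to the strong basal state and switches on the
consolidation cascade 4 -> 5 -> 6 with the transient rates

    p(t) = (t - t0)/50 min * exp(1 - (t - t0)/10 min)   per minute,
    c(t) = (t - t0)/30 min * exp(1 - (t - t0)/30 min)   per minute.

The model has no intrinsic activity dependence; the co-activity I_A that
sets the unbinding rates is supplied externally (from the reduced model's
activity filter).  In the ``activity_gated_beta`` variant the 4 -> 3 rate is
gated by H(I_A - theta_act), which freezes decay during stimulation-free
periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stabilizer_pool import PoolParams, PoolState, step_pool

__all__ = [
    "SBParams",
    "SBPopulation",
    "SB_VARIANTS",
    "fepsp",
    "hfs_rates",
    "init_population",
    "apply_hfs",
    "step_population",
]

SB_VARIANTS = ("original", "activity_gated_beta")
_MIN = 60.0


@dataclass
class SBParams:
    """Transition rates are per minute, as published."""

    alpha: float = 0.017       # min^-1, weak basal -> strong basal
    beta: float = 0.067        # min^-1, strong basal -> weak basal
    tau_e: float = 0.017       # min^-1, intermediate -> basal
    tau_l: float = 0.01        # min^-1, stable -> basal
    tau_r: float = 1e-4        # min^-1, state-7 decay (slowest process)
    n_synapses: int = 1000
    n_weak0: int = 800
    n_strong0: int = 200
    theta_act: float = 0.01    # co-activity threshold of the gated variant
    six_to_three: bool = False  # route the state-6 decay to state 3 instead
    # of the strong basal state 4 (alternative reading; default keeps the
    # basal-state convention of the original six-state scheme)
    pool: PoolParams = field(default_factory=PoolParams.state_based)

    def __post_init__(self) -> None:
        if self.n_weak0 + self.n_strong0 != self.n_synapses:
            raise ValueError("n_weak0 + n_strong0 must equal n_synapses")
        if min(self.alpha, self.beta, self.tau_e, self.tau_l, self.tau_r) < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class SBPopulation:
    states: np.ndarray          # int8, values 1..7
    pool: PoolState
    t_hfs: float = None         # time of the (single) HFS, or None

    def counts(self) -> np.ndarray:
        """Occupancy of states 1..7 (index 0 unused)."""
        return np.bincount(self.states, minlength=8)

    @property
    def n(self) -> int:
        return self.states.size


def init_population(params: SBParams, seed: int = 0) -> SBPopulation:
    """800 weak-basal (state 3) and 200 strong-basal (state 4) synapses;
    the reservoir starts empty and no synapse is bound."""
    rng = np.random.default_rng(seed)
    states = np.full(params.n_synapses, 3, dtype=np.int8)
    strong = rng.choice(params.n_synapses, size=params.n_strong0, replace=False)
    states[strong] = 4
    return SBPopulation(states=states, pool=PoolState.full(params.pool))


def fepsp(counts: np.ndarray) -> float:
    """Relative field EPSP in percent: weak states weigh 1, strong states
    (4-7) weigh 2, normalized so the 800/200 initial split reads 100 %."""
    counts = np.asarray(counts)
    if counts.size == 7:  # accept bare 1..7 vectors
        counts = np.concatenate([[0], counts])
    weak = counts[1:4].sum()
    strong = counts[4:8].sum()
    return (weak + 2 * strong) / 1200.0 * 100.0


def hfs_rates(t_since_hfs: float) -> tuple[float, float, float]:
    """Time courses of the consolidation cascade after HFS.

    Returns (p_rate, c_rate, alpha_pulse) with the rates converted to s^-1;
    ``alpha_pulse`` is 1.0 exactly at the HFS time (the delta pulse that
    moves all weak-basal synapses to the strong basal state).
    """
    if t_since_hfs < 0:
        raise ValueError("t_since_hfs must be non-negative")
    t_min = t_since_hfs / _MIN
    p = (t_min / 50.0) * np.exp(1.0 - t_min / 10.0) / _MIN
    c = (t_min / 30.0) * np.exp(1.0 - t_min / 30.0) / _MIN
    return p, c, 1.0 if t_since_hfs == 0 else 0.0


def apply_hfs(pop: SBPopulation, t0: float) -> SBPopulation:
    """Move every weak-basal synapse to the strong basal state and start
    (or restart) the p(t)/c(t) consolidation clocks."""
    states = pop.states.copy()
    states[states == 3] = 4
    return SBPopulation(states=states, pool=pop.pool, t_hfs=t0)


def step_population(pop: SBPopulation, t: float, I_A: float,
                    psi_active: bool, params: SBParams, dt: float,
                    rng: np.random.Generator,
                    variant: str = "original") -> SBPopulation:
    """One stochastic step; each synapse makes at most one transition.

    Binding/unbinding (6 <-> 7) is delegated to the stabilizer pool; all
    other transitions are independent per-synapse events with probability
    rate * dt.  ``t`` is absolute time (seconds), used against the HFS clock.
    """
    if variant not in SB_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {SB_VARIANTS}")
    states = pop.states.copy()
    n = states.size

    # -- stabilizer kinetics: 6 -> 7 binding, 7 -> 6 unbinding -------------
    b = (states == 7).astype(np.int8)
    is_big = (states == 6) | (states == 7)
    if pop.pool.psi_active != psi_active:
        from .stabilizer_pool import set_psi
        pool = set_psi(pop.pool, psi_active, int(b.sum()), params.pool)
    else:
        pool = pop.pool
    b_before = b.copy()
    # binding is fast relative to the 1-s step, so the exact per-step
    # probabilities are used rather than the first-order form
    pool = step_pool(pool, is_big, b, np.full(n, I_A), params.pool, dt, rng,
                     exact_prob=True)
    changed = b != b_before
    states[changed & (b == 1)] = 7
    states[changed & (b == 0)] = 6

    # -- rate-driven transitions for synapses that did not just (un)bind ---
    if pop.t_hfs is not None and t >= pop.t_hfs:
        p_rate, c_rate, _ = hfs_rates(t - pop.t_hfs)
    else:
        p_rate, c_rate = 0.0, 0.0
    alpha = params.alpha / _MIN
    beta = params.beta / _MIN
    if variant == "activity_gated_beta" and I_A < params.theta_act:
        beta = 0.0
    tau_e = params.tau_e / _MIN
    tau_l = params.tau_l / _MIN
    tau_r = params.tau_r / _MIN
    for rate, pr in (("alpha", alpha), ("beta", beta + p_rate),
                     ("cascade", c_rate + tau_e), ("taus", tau_l + tau_r)):
        if pr * dt >= 1.0:
            raise ValueError(
                f"transition probability {rate} * dt >= 1; reduce dt"
            )

    u = rng.random(n)
    idle = ~changed
    old = pop.states  # decide transitions from the pre-step states
    six_target = 3 if params.six_to_three else 4

    sel = idle & (old == 1)
    states[sel & (u < tau_l * dt)] = 3
    sel = idle & (old == 2)
    states[sel & (u < tau_e * dt)] = 3
    sel = idle & (old == 3)
    states[sel & (u < alpha * dt)] = 4
    sel = idle & (old == 4)
    states[sel & (u < beta * dt)] = 3
    states[sel & (u >= beta * dt) & (u < (beta + p_rate) * dt)] = 5
    sel = idle & (old == 5)
    states[sel & (u < c_rate * dt)] = 6
    states[sel & (u >= c_rate * dt) & (u < (c_rate + tau_e) * dt)] = 4
    sel = idle & (old == 6)
    states[sel & (u < tau_l * dt)] = six_target
    # state-7 decay: rare, releases its entity into the susceptible pool
    sel = idle & (old == 7)
    decayed = sel & (u < tau_r * dt)
    n_dec = int(decayed.sum())
    if n_dec:
        states[decayed] = 4
        if not pool.psi_active:
            pool = PoolState(N_A=pool.N_A + n_dec, N_A_star=pool.N_A_star,
                             psi_active=pool.psi_active)
    return SBPopulation(states=states, pool=pool, t_hfs=pop.t_hfs)
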