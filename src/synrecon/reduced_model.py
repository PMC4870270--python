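"""Reduced two-dimensional mean-field model of the stabilizer dynamics.

Tracks the mean number of bound synapses n_ASyn and the mean reservoir size
n_A* of a postsynaptic cell with N_big consolidated synapses:

    d n_ASyn / dt = -(k2 + k4) n_ASyn + (k1 n_A + k3 n_A*) (N_big - n_ASyn)
    d n_A*   / dt = -k3 n_A* (N_big - n_ASyn) + k4 n_ASyn

with n_A = N_A,tot - n_ASyn - n_A* (forced to 0 during PSI) and unbinding
rates evaluated at the global filtered activity I_A, a leaky integral of the
stimulation pulse train.  The number of consolidated synapses N_big follows
the bound count with a short delay: N_big decays at the delayed slope of
n_ASyn whenever that slope is steeper (more negative) than a threshold.

All state arrays may be vectors, which lets the boundary-condition mapper
integrate an entire grid of (stimulation duration, PSI duration) cells in
one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .stabilizer_pool import PoolParams, unbinding_rate

__all__ = [
    "ReducedParams",
    "ReducedState",
    "filter_activity",
    "step_reduced",
    "update_Nbig",
    "handoff_from_full",
    "integrate_windows",
    "map_boundary",
]


@dataclass
class ReducedParams:
    # phi, eta and theta_big are empirical constants of the N_big follower.
    # theta_big is printed as magnitude 80 with units 1/s, which no slope of
    # a bound count of order 200 can reach; it is read per hour.  The
    # follower is a deliberately crude approximation: it tracks the
    # unbinding collapse after reservoir depletion but cannot fully separate
    # it from fast binding-equilibrium shifts at stimulation onset; see
    # docs/methods.md for its error modes.
    phi: float = 72.0            # s, delay of the N_big decay
    theta_big: float = -80.0 / 3600.0  # s^-1, slope threshold of the follower
    eta: float = 10.0            # s, finite-difference window for the slope
    omega: float = 1.05          # s, filter increment per stimulation pulse,
    # calibrated so the 0.1-Hz steady state matches the full model's
    # post-LTP co-activity (the printed 5.4 s puts it a decade above the
    # unbinding half-activations; see docs/methods.md)
    tau_A: float = 150.0         # s, activity filter time constant
    pool: PoolParams = field(default_factory=PoolParams.write_protected)
    dt: float = 0.1              # s
    # The default N_big follower is surplus-based: consolidated synapses in
    # excess of the bound count (beyond the small binding-equilibrium
    # surplus) lose their scaffold at the collapse rate 1/tau_big.  This is
    # phase-independent (it does not matter whether depletion happens during
    # or after a stimulation block), which the delayed-slope follower is
    # not; the latter remains available as follower="slope".
    follower: str = "surplus"
    tau_big: float = 160.0       # s, scaffold collapse time when unbound
    surplus_margin: float = 16.0  # binding-equilibrium surplus (synapses)

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.phi < 0:
            raise ValueError("eta must be positive and phi non-negative")
        if self.follower not in ("surplus", "slope"):
            raise ValueError("follower must be 'surplus' or 'slope'")


@dataclass
class ReducedState:
    """Mean-field state; every field broadcasts over an arbitrary number of
    independently simulated cells."""

    n_ASyn: np.ndarray
    n_A_star: np.ndarray
    N_big: np.ndarray
    I_A: np.ndarray
    history: np.ndarray = None   # ring buffer of n_ASyn, shape (L, m)
    hist_idx: int = 0
    hist_filled: int = 0

    @classmethod
    def create(cls, n_ASyn, n_A_star, N_big, I_A, params: ReducedParams):
        arrs = [np.atleast_1d(np.asarray(a, dtype=float))
                for a in (n_ASyn, n_A_star, N_big, I_A)]
        m = max(a.size for a in arrs)
        arrs = [np.broadcast_to(a, (m,)).copy() for a in arrs]
        L = int(np.ceil(params.phi / params.dt)) + 1
        hist = np.tile(arrs[0], (max(L, 2), 1))  # primed flat
        return cls(*arrs, history=hist, hist_idx=0,
                   hist_filled=hist.shape[0])

    @property
    def m(self) -> int:
        return self.n_ASyn.size


def filter_activity(I_A, n_pulses, params: ReducedParams,
                    dt: float) -> np.ndarray:
    """Exponential decay with tau_A plus omega/tau_A per stimulation pulse
    (a delta impulse through the first-order filter)."""
    return (np.asarray(I_A, dtype=float) * np.exp(-dt / params.tau_A)
            + np.asarray(n_pulses, dtype=float) * params.omega / params.tau_A)


def _lookup(state: ReducedState, lag_steps: int) -> np.ndarray:
    """n_ASyn value ``lag_steps`` steps ago from the ring buffer."""
    L = state.history.shape[0]
    return state.history[(state.hist_idx - 1 - lag_steps) % L]


def update_Nbig(state: ReducedState, params: ReducedParams,
                dt: float) -> ReducedState:
    """Decay N_big at the delayed slope of n_ASyn when steep enough.

    slope s(t - phi) = [n_ASyn(t - phi + eta) - n_ASyn(t - phi)] / eta;
    dN_big/dt = s * H(theta_big - s).  No-op until the history buffer spans
    phi seconds.
    """
    lag = int(round(params.phi / dt))
    lag_recent = max(lag - int(round(params.eta / dt)), 0)
    if state.hist_filled <= lag:
        return state
    slope = (_lookup(state, lag_recent) - _lookup(state, lag)) / params.eta
    dN = np.where(slope <= params.theta_big, slope, 0.0) * dt
    # no hard clamp of n_ASyn to N_big: the (N_big - n_ASyn) factor in the
    # binding flux enforces the bound softly, and a hard clamp couples the
    # follower back onto its own input (runaway decay during fast binding
    # transients)
    N_big = np.maximum(state.N_big + dN, 0.0)
    return replace(state, N_big=N_big)


def step_reduced(state: ReducedState, psi_active, params: ReducedParams,
                 dt: float = None) -> ReducedState:
    """One Euler step of the two-dimensional mean-field system (plus the
    N_big follower).  ``psi_active`` may be scalar or per-cell."""
    if dt is None:
        dt = params.dt
    pp = params.pool
    psi = np.broadcast_to(np.asarray(psi_active, dtype=bool), state.n_ASyn.shape)
    k2 = unbinding_rate(state.I_A, "k2", pp)
    k4 = unbinding_rate(state.I_A, "k4", pp)
    n_A = np.where(psi, 0.0,
                   np.maximum(pp.N_A_tot - state.n_ASyn - state.n_A_star, 0.0))
    on = pp.k1 * n_A + pp.k3 * state.n_A_star
    free_big = np.maximum(state.N_big - state.n_ASyn, 0.0)
    d_syn = -(k2 + k4) * state.n_ASyn + on * free_big
    d_star = -pp.k3 * state.n_A_star * free_big + k4 * state.n_ASyn
    n_ASyn = np.clip(state.n_ASyn + dt * d_syn, 0.0, None)
    n_A_star = np.maximum(state.n_A_star + dt * d_star, 0.0)

    hist = state.history
    hist[state.hist_idx] = n_ASyn
    new = replace(state, n_ASyn=n_ASyn, n_A_star=n_A_star,
                  hist_idx=(state.hist_idx + 1) % hist.shape[0],
                  hist_filled=min(state.hist_filled + 1, hist.shape[0]))
    if params.follower == "slope":
        return update_Nbig(new, params, dt)
    surplus = np.maximum(new.N_big - new.n_ASyn - params.surplus_margin, 0.0)
    return replace(new, N_big=np.maximum(
        new.N_big - dt * surplus / params.tau_big, 0.0))


def handoff_from_full(snapshot: dict, params: ReducedParams) -> ReducedState:
    """Initialize the reduced model from a full-simulation snapshot
    (typically taken at t = 60 min, the end of the common initiation phase).

    Required keys: ``N_big``, ``n_bound``, ``n_A_star``, ``I_A`` (the mean
    per-synapse co-activity).  The history buffer is primed flat.
    """
    missing = [k for k in ("N_big", "n_bound", "n_A_star", "I_A")
               if k not in snapshot]
    if missing:
        raise KeyError(f"snapshot missing field(s): {missing}")
    return ReducedState.create(
        n_ASyn=snapshot["n_bound"], n_A_star=snapshot["n_A_star"],
        N_big=snapshot["N_big"], I_A=snapshot["I_A"], params=params,
    )


def integrate_windows(state: ReducedState, params: ReducedParams,
                      t0: float, t_end: float,
                      stim_windows: np.ndarray, stim_rate: float,
                      psi_windows: np.ndarray,
                      record_every: float = 10.0):
    """Integrate cells forward from t0 to t_end.

    ``stim_windows`` and ``psi_windows`` have shape (m, 2); degenerate
    windows (end <= start) mean "absent".  Stimulation delivers periodic
    pulses at ``stim_rate`` starting at each window's opening.  Returns
    (times, recorder dict of trajectories, final state).
    """
    dt = params.dt
    m = state.m
    stim = np.atleast_2d(stim_windows)
    psi = np.atleast_2d(psi_windows)
    n_steps = int(round((t_end - t0) / dt))
    rec_stride = max(int(round(record_every / dt)), 1)
    n_rec = n_steps // rec_stride + 1
    out = {k: np.empty((n_rec, m)) for k in ("n_ASyn", "n_A_star", "N_big", "I_A")}
    times = np.empty(n_rec)
    psi_was = np.zeros(m, dtype=bool)
    i_rec = 0
    for i in range(n_steps + 1):
        t = t0 + i * dt
        if i % rec_stride == 0 and i_rec < n_rec:
            times[i_rec] = t
            for k in ("n_ASyn", "n_A_star", "N_big", "I_A"):
                out[k][i_rec] = getattr(state, k)
            i_rec += 1
        if i == n_steps:
            break
        # pulses in (t, t + dt] for each cell's stimulation window
        rel0 = (t - stim[:, 0]) * stim_rate
        rel1 = (t + dt - stim[:, 0]) * stim_rate
        in_win = (t + dt > stim[:, 0]) & (t < stim[:, 1]) & (stim[:, 1] > stim[:, 0])
        pulses = np.where(in_win,
                          np.floor(rel1 + 1e-9) - np.floor(rel0 + 1e-9), 0.0)
        pulses = np.clip(pulses, 0.0, None)
        I_A = filter_activity(state.I_A, pulses, params, dt)
        state = replace(state, I_A=I_A)
        psi_now = (t >= psi[:, 0]) & (t < psi[:, 1])
        # PSI offset: the susceptible pool replenishes (handled implicitly,
        # n_A is recomputed from conservation each step)
        state = step_reduced(state, psi_now, params, dt)
        psi_was = psi_now
    return times[:i_rec], {k: v[:i_rec] for k, v in out.items()}, state


def map_boundary(stim_durations, psi_durations, init: ReducedState,
                 params: ReducedParams, center: float = 9000.0,
                 t0: float = 3600.0, t_end: float = 16800.0,
                 stim_rate: float = 0.1) -> np.ndarray:
    """Remaining fraction of consolidated synapses on a (stimulation
    duration x PSI duration) grid, both windows centered on ``center``.

    Returns a matrix of N_big(t_end) / N_big(t0) with shape
    (len(stim_durations), len(psi_durations)).
    """
    s = np.asarray(stim_durations, dtype=float)
    d = np.asarray(psi_durations, dtype=float)
    S, D = np.meshgrid(s, d, indexing="ij")
    m = S.size
    stim_w = np.column_stack([center - S.ravel() / 2, center + S.ravel() / 2])
    psi_w = np.column_stack([center - D.ravel() / 2, center + D.ravel() / 2])
    if init.m == 1:
        state = ReducedState.create(
            np.full(m, init.n_ASyn[0]), np.full(m, init.n_A_star[0]),
            np.full(m, init.N_big[0]), np.full(m, init.I_A[0]), params)
    elif init.m == m:
        state = init
    else:
        raise ValueError("init must have 1 cell or one per grid cell")
    N0 = state.N_big.copy()
    _, _, final = integrate_windows(state, params, t0, t_end,
                                    stim_w, stim_rate, psi_w,
                                    record_every=t_end - t0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(N0 > 0, final.N_big / N0, 1.0)
    return frac.reshape(S.shape)
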