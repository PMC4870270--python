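"""Experiment orchestration: full spiking runs, reduced-model runs,
state-based runs, ensemble averaging and file output.

A full run layers three time scales: the leaky integrate-and-fire neuron and
STDP traces at 0.1 ms, the synapse SDEs / gates / stabilizer pool at 100 ms,
and the protocol events (stimulation blocks, PSI, dopamine) on the scale of
minutes to hours.  Each repeat simulates one postsynaptic neuron whose
presynaptic count is drawn from a binomial law with mean 200; results are
averaged across repeats (10 by default) with the s.e.m. reported.

The ``fast`` preset compresses every timeline tenfold while scaling the slow
rate constants up tenfold and the noise by sqrt(10) -- an exact time
rescaling of the slow subsystem, with the LFS rate raised to 1 Hz so each
block delivers the same number of volleys.  HFS keeps its native shape.
Classification of the paradigms (persist vs. degrade) is preserved because
the absolute stabilizer budgets are untouched; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy import stats

from . import _engine
from .neuron import NeuronParams, NumericalDivergenceError
from .protocols import (Protocol, StimBlock, build_paradigm, generate_hfs,
                        generate_lfs, scale_protocol, HFS_DURATION)
from .reduced_model import (ReducedParams, ReducedState, handoff_from_full,
                            integrate_windows, map_boundary)
from .stabilizer_pool import PoolParams, PoolState, set_psi
from .state_based import (SBParams, apply_hfs, fepsp, init_population,
                          step_population)
from .triplet_plasticity import TripletParams
from .write_protected import WPParams, init_synapses

__all__ = [
    "RunConfig",
    "RunResult",
    "ModelParams",
    "build_params",
    "run_full",
    "run_reduced",
    "run_state_based",
    "run_pair",
    "end_window_stats",
    "welch_p",
    "calibrate_g0",
    "write_result",
    "read_config",
    "FAST_FACTOR",
]

FAST_FACTOR = 10.0
_MODELS = ("write_protected", "state_based", "reduced")


@dataclass
class RunConfig:
    paradigm: str = "p2"
    model: str = "write_protected"
    variant: str = "original"
    n_repeats: int = 10
    seed: int = 0
    fast: bool = False
    psi: bool = True                  # False: control condition (no PSI)
    dt_neuron: float = 1e-4
    dt_syn: float = 0.1
    dt_sb: float = 1.0
    record_every: float = 10.0        # s, recording stride
    n_presyn_trials: int = 400        # binomial law for the presynaptic count
    n_presyn_prob: float = 0.5        # (mean 200, SD 10)
    frac_big: float = 1.0 / 3.0
    protocol_overrides: dict = field(default_factory=dict)
    param_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.dt_neuron <= 0 or self.dt_syn <= 0 or self.dt_sb <= 0:
            raise ValueError("time steps must be positive")
        ratio = self.dt_syn / self.dt_neuron
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("dt_syn must be an integer multiple of dt_neuron")

    def hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass
class ModelParams:
    neuron: NeuronParams
    triplet: TripletParams
    wp: WPParams
    pool: PoolParams
    reduced: ReducedParams
    sb: SBParams
    time_scale: float = 1.0


def build_params(config: RunConfig) -> ModelParams:
    """Default parameter set, with the fast preset's exact time rescaling
    applied when requested, then any explicit overrides."""
    f = FAST_FACTOR if config.fast else 1.0
    wp = WPParams()
    pool = PoolParams.write_protected()
    triplet = TripletParams()
    reduced = ReducedParams()
    sb = SBParams()
    if f != 1.0:
        wp = dataclasses.replace(
            wp, tau_w=wp.tau_w / f, tau_T=wp.tau_T / f, tau_z=wp.tau_z / f,
            tau_gamma=wp.tau_gamma / f, k_down=wp.k_down * f,
            sigma=wp.sigma * np.sqrt(f))
        # all pool rates scale with time (exact rescaling; the pool size and
        # hence all reservoir budgets stay absolute).  Binding probabilities
        # then exceed the first-order regime, so the kernel evaluates the
        # exact per-step form 1 - exp(-rate dt).
        pool = dataclasses.replace(pool, k0=pool.k0 * f, m=pool.m * f,
                                   k1=pool.k1 * f, k3=pool.k3 * f)
        triplet = dataclasses.replace(triplet, tau_A=triplet.tau_A / f)
        reduced = dataclasses.replace(
            reduced, tau_A=reduced.tau_A / f, omega=reduced.omega / f,
            phi=reduced.phi / f, eta=reduced.eta / f,
            theta_big=reduced.theta_big * f, dt=reduced.dt / f,
            tau_big=reduced.tau_big / f, pool=pool)
        # the state-based model is stepped in real-time units with its clock
        # compressed (see run_state_based), so its rates are left as printed
    params = ModelParams(neuron=NeuronParams(), triplet=triplet, wp=wp,
                         pool=pool, reduced=reduced, sb=sb, time_scale=f)
    for key, val in config.param_overrides.items():
        group, _, name = key.partition(".")
        target = getattr(params, group, None)
        if target is None or not hasattr(target, name):
            raise KeyError(f"unknown parameter override {key!r}")
        setattr(params, group, dataclasses.replace(target, **{name: val}))
    return params


@dataclass
class RunResult:
    times: np.ndarray
    traces: np.ndarray            # (n_repeats, n_rec) weight or %fEPSP
    pool_series: dict             # name -> (n_repeats, n_rec)
    repeat_seeds: list
    config: RunConfig
    snapshots: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def mean(self) -> np.ndarray:
        return self.traces.mean(axis=0)

    @property
    def sem(self) -> Optional[np.ndarray]:
        n = self.traces.shape[0]
        if n < 2:
            return None  # s.e.m. undefined for a single repeat
        return self.traces.std(axis=0, ddof=1) / np.sqrt(n)


def _protocol_for(config: RunConfig) -> Protocol:
    proto = build_paradigm(config.paradigm, config.protocol_overrides or None)
    if not config.psi:
        proto = dataclasses.replace(proto, psi_window=None)
    if config.fast:
        proto = scale_protocol(proto, FAST_FACTOR)
    return proto


def _spike_arrays(proto: Protocol, n_neurons: int, dt: float,
                  seed_seq: np.random.SeedSequence):
    """Jittered presynaptic spikes as (step, synapse) arrays, time-sorted,
    with same-step duplicates per neuron merged to a single spike."""
    seeds = seed_seq.generate_state(len(proto.lfs_blocks) + len(proto.hfs_events))
    parts_t, parts_i = [], []
    si = 0
    for blk in proto.lfs_blocks:
        ts = generate_lfs(blk, n_neurons, int(seeds[si])).merged()
        parts_t.append(ts[0]); parts_i.append(ts[1]); si += 1
    for t0 in proto.hfs_events:
        ts = generate_hfs(t0, n_neurons, int(seeds[si])).merged()
        parts_t.append(ts[0]); parts_i.append(ts[1]); si += 1
    if not parts_t:
        return (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int32))
    times = np.concatenate(parts_t)
    ids = np.concatenate(parts_i)
    steps = np.floor(times / dt).astype(np.int64)
    key = steps * np.int64(n_neurons) + ids
    key = np.unique(key)  # merge collisions within one neuron step
    return (key // n_neurons).astype(np.int64), (key % n_neurons).astype(np.int32)


def _window_blocks(window, dt_s: float, n_blocks: int):
    if window is None:
        return np.array([-1, -1], dtype=np.int64)
    a, b = window
    return np.array([max(int(round(a / dt_s)), 0),
                     min(int(round(b / dt_s)), n_blocks)], dtype=np.int64)


def run_full(config: RunConfig, params: Optional[ModelParams] = None,
             snapshot_time: Optional[float] = None,
             protocol: Optional[Protocol] = None) -> RunResult:
    """Run the full write-protected model for ``config.n_repeats`` neurons.

    Returns per-repeat mean-weight traces and pool time series; if
    ``snapshot_time`` is given (seconds), a reduced-model handoff snapshot
    is taken per repeat at that time.  An explicit ``protocol`` overrides
    the paradigm named in the config.
    """
    if params is None:
        params = build_params(config)
    proto = protocol if protocol is not None else _protocol_for(config)
    dt_n, dt_s = config.dt_neuron, config.dt_syn
    spb = int(round(dt_s / dt_n))
    n_blocks = int(round(proto.duration / dt_s))
    rec_stride = max(int(round(config.record_every / dt_s)), 1)
    n_rec = n_blocks // rec_stride
    par = _engine.pack_params(params.neuron, params.triplet, params.wp,
                              params.pool)
    psi_b = _window_blocks(proto.psi_window, dt_s, n_blocks)
    dopa_b = _window_blocks(proto.dopamine_window, dt_s, n_blocks)
    snap_block = (int(round(snapshot_time / dt_s))
                  if snapshot_time is not None else -1)
    gated = config.variant == "activity_gated_noise"

    master = np.random.SeedSequence(config.seed)
    traces = np.empty((config.n_repeats, n_rec))
    pool_series = {k: np.empty((config.n_repeats, n_rec))
                   for k in ("N_A", "N_A_star", "n_bound", "N_big", "I_A")}
    times = None
    snapshots = []
    repeat_seeds = []
    for rep, child in enumerate(master.spawn(config.n_repeats)):
        st = child.generate_state(3)
        repeat_seeds.append(int(st[0]) % (2 ** 31))
        rng = np.random.default_rng(child)
        n_syn = int(rng.binomial(config.n_presyn_trials, config.n_presyn_prob))
        n_syn = max(n_syn, 1)
        syn = init_synapses(n_syn, config.frac_big, seed=int(st[1]) % (2 ** 31))
        spk_step, spk_syn = _spike_arrays(proto, n_syn, dt_n,
                                          np.random.SeedSequence(int(st[2]) % (2 ** 31)))
        x_val = np.zeros(n_syn)
        x_last = np.zeros(n_syn, dtype=np.int64)
        IA = np.zeros(n_syn)
        rec = {k: np.empty(n_rec) for k in
               ("t", "mw", "NA", "NAs", "nb", "nbig", "IA")}
        snap = np.full(5, np.nan)
        ret = _engine.run_wp(
            repeat_seeds[-1], n_blocks, spb, dt_n, dt_s, spk_step, spk_syn,
            syn.w, syn.T, syn.z, syn.gamma, syn.b, syn.force_unbound,
            x_val, x_last, IA, psi_b, dopa_b, snap_block, gated, par,
            rec_stride, rec["t"], rec["mw"], rec["NA"], rec["NAs"],
            rec["nb"], rec["nbig"], rec["IA"], snap)
        if ret < 0:
            raise NumericalDivergenceError(
                f"full-model divergence in repeat {rep}")
        times = rec["t"]
        traces[rep] = rec["mw"]
        pool_series["N_A"][rep] = rec["NA"]
        pool_series["N_A_star"][rep] = rec["NAs"]
        pool_series["n_bound"][rep] = rec["nb"]
        pool_series["N_big"][rep] = rec["nbig"]
        pool_series["I_A"][rep] = rec["IA"]
        if snap_block > 0:
            snapshots.append(dict(N_big=snap[0], n_bound=snap[1],
                                  N_A=snap[2], n_A_star=snap[3], I_A=snap[4],
                                  n_synapses=n_syn))
    return RunResult(times=times, traces=traces, pool_series=pool_series,
                     repeat_seeds=repeat_seeds, config=config,
                     snapshots=snapshots)


# --------------------------------------------------------------------------
# reduced-model runs


def run_reduced(config: RunConfig, params: Optional[ModelParams] = None,
                snapshot: Optional[dict] = None,
                grid: Optional[tuple] = None):
    """Reduced-model run started from a full-model snapshot at the end of
    the common 60-min initiation phase.

    If no snapshot is supplied, a single full repeat is simulated up to the
    handoff time to produce one (with a warning-free regenerate).  For
    ``config.paradigm == 'fig3_grid'`` (or an explicit ``grid`` of
    stimulation/PSI duration axes) the boundary map is returned as well.
    """
    if config.paradigm not in ("fig3", "fig3_grid"):
        raise ValueError(
            "reduced-model runs target the boundary-condition protocol; "
            "use paradigm 'fig3' or 'fig3_grid'"
        )
    if params is None:
        params = build_params(config)
    f = params.time_scale
    handoff_t = 3600.0 / f
    if snapshot is None:
        cfg = dataclasses.replace(config, model="write_protected",
                                  n_repeats=1, paradigm="fig3", psi=True)
        full = run_full(cfg, params=params, snapshot_time=handoff_t)
        snapshot = full.snapshots[0]
    rp = params.reduced
    state = handoff_from_full(snapshot, rp)

    proto = _protocol_for(config)
    if config.paradigm == "fig3_grid" or grid is not None:
        if grid is None:
            axis = np.linspace(0.0, 2.5 * 3600.0 / f, 26)
            grid = (axis, axis)
        stim_rate = 0.1 * f
        frac = map_boundary(grid[0], grid[1], state, rp,
                            center=9000.0 / f, t0=handoff_t,
                            t_end=proto.duration, stim_rate=stim_rate)
        return frac, grid, snapshot
    # single trajectory for the protocol's post-handoff windows
    stim_after = [(b.t_start, b.t_end) for b in proto.lfs_blocks
                  if b.t_end > handoff_t]
    rate = proto.lfs_blocks[0].rate if proto.lfs_blocks else 0.1 * f
    stim_w = np.array(stim_after[:1] or [(0.0, -1.0)])
    psi_w = np.array([proto.psi_window if proto.psi_window else (0.0, -1.0)])
    times, rec, final = integrate_windows(
        state, rp, handoff_t, proto.duration, stim_w, rate, psi_w,
        record_every=config.record_every)
    return times, rec, final


# --------------------------------------------------------------------------
# state-based runs


def _sb_activity_series(proto: Protocol, rp: ReducedParams,
                        dt: float) -> np.ndarray:
    """Global co-activity I_A(t) on the state-based grid, from the reduced
    model's pulse filter driven by the protocol's stimulation times."""
    n_steps = int(round(proto.duration / dt))
    pulses = np.zeros(n_steps)
    for blk in proto.lfs_blocks:
        t = blk.nominal_pulse_times()
        idx = np.floor(t / dt).astype(int)
        np.add.at(pulses, idx[idx < n_steps], 1.0)
    for t0 in proto.hfs_events:
        t = t0 + np.arange(int(100 * HFS_DURATION)) / 100.0
        idx = np.floor(t / dt).astype(int)
        np.add.at(pulses, idx[idx < n_steps], 1.0)
    I = np.empty(n_steps)
    x = 0.0
    decay = np.exp(-dt / rp.tau_A)
    for i in range(n_steps):
        x = x * decay + pulses[i] * rp.omega / rp.tau_A
        I[i] = x
    return I


def run_state_based(config: RunConfig,
                    params: Optional[ModelParams] = None) -> RunResult:
    """%fEPSP traces of the extended state-based model across repeats."""
    if params is None:
        params = build_params(config)
    proto = _protocol_for(config)
    sb = params.sb
    ts = params.time_scale
    dt = config.dt_sb / ts
    n_steps = int(round(proto.duration / dt))
    rec_stride = max(int(round(config.record_every / dt)), 1)
    n_rec = n_steps // rec_stride
    I_series = _sb_activity_series(proto, params.reduced, dt)
    hfs_t = proto.hfs_events[0] if proto.hfs_events else None
    psi = proto.psi_window
    variant = ("activity_gated_beta"
               if config.variant in ("activity_gated_beta", "activity_gated_noise")
               else "original")

    master = np.random.SeedSequence(config.seed)
    traces = np.empty((config.n_repeats, n_rec))
    pool_series = {k: np.empty((config.n_repeats, n_rec))
                   for k in ("N_A", "N_A_star", "n_bound")}
    times = np.arange(1, n_rec + 1) * rec_stride * dt
    repeat_seeds = []
    for rep, child in enumerate(master.spawn(config.n_repeats)):
        rng = np.random.default_rng(child)
        repeat_seeds.append(int(child.generate_state(1)[0]) % (2 ** 31))
        pop = init_population(sb, seed=repeat_seeds[-1])
        i_rec = 0
        for i in range(n_steps):
            t = i * dt
            if hfs_t is not None and pop.t_hfs is None and t >= hfs_t:
                pop = apply_hfs(pop, hfs_t)
            psi_now = bool(psi and psi[0] <= t < psi[1])
            # the HFS clock runs in compressed time under the fast preset
            pop2 = step_population(pop, _scaled_time(t, pop.t_hfs, ts),
                                  float(I_series[i]), psi_now, sb, dt * ts,
                                  rng, variant=variant)
            pop = pop2
            if (i + 1) % rec_stride == 0:
                counts = pop.counts()
                traces[rep, i_rec] = fepsp(counts)
                pool_series["N_A"][rep, i_rec] = pop.pool.N_A
                pool_series["N_A_star"][rep, i_rec] = pop.pool.N_A_star
                pool_series["n_bound"][rep, i_rec] = counts[7]
                i_rec += 1
    return RunResult(times=times, traces=traces, pool_series=pool_series,
                     repeat_seeds=repeat_seeds, config=config)


def _scaled_time(t: float, t_hfs, ts: float) -> float:
    """Absolute time passed to the state-based stepper: distances from the
    HFS are stretched back to real time so the p(t)/c(t) cascade keeps its
    published shape under the fast preset."""
    if t_hfs is None or ts == 1.0:
        return t
    return t_hfs + (t - t_hfs) * ts


# --------------------------------------------------------------------------
# statistics and pairs


def end_window_stats(result: RunResult, window: Optional[float] = None
                     ) -> np.ndarray:
    """Per-repeat time-averaged trace value over the final window (default:
    the last 30 simulated minutes, scaled with the preset)."""
    if window is None:
        window = 1800.0 / (FAST_FACTOR if result.config.fast else 1.0)
    t_end = result.times[-1]
    mask = result.times >= t_end - window
    return result.traces[:, mask].mean(axis=1)


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch two-sample p-value."""
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def run_pair(config: RunConfig, params: Optional[ModelParams] = None):
    """Run a paradigm with PSI and its control; return both results and the
    Welch p-value of the end-of-run time-averaged traces."""
    runner = {"write_protected": run_full,
              "state_based": run_state_based}[config.model]
    res_psi = runner(dataclasses.replace(config, psi=True), params=params)
    res_ctl = runner(dataclasses.replace(config, psi=False,
                                         seed=config.seed + 1), params=params)
    p = welch_p(end_window_stats(res_psi), end_window_stats(res_ctl))
    return res_psi, res_ctl, p


# --------------------------------------------------------------------------
# calibration


def calibrate_g0(target_IA: float = 0.08, g0_lo: float = 2.0,
                 g0_hi: float = 300.0, n_iter: int = 10, seed: int = 1234,
                 duration: float = 900.0) -> float:
    """Bisection on the conductance scale g0 so that steady 0.1-Hz LFS holds
    the population-mean co-activity at the designed operating point.

    Mean I_A during LFS rises monotonically with g0 (larger volleys, more
    postsynaptic spikes per volley, larger triplet impulses).  The target
    0.08 sits just above the unbinding half-activations, so LFS saturates
    both unbinding rates while silence relaxes them to baseline.
    """
    def mean_IA(g0: float) -> float:
        cfg = RunConfig(paradigm="p1", model="write_protected", n_repeats=1,
                        seed=seed, fast=False, psi=False)
        params = build_params(cfg)
        params.wp = dataclasses.replace(params.wp, g0=g0)
        proto = Protocol(duration=duration,
                         lfs_blocks=(StimBlock(0.0, duration, 0.1),),
                         name="calibration")
        res = run_full(cfg, params=params, protocol=proto)
        ia = res.pool_series["I_A"][0]
        sel = res.times > duration / 2
        return float(ia[sel].mean())

    lo, hi = g0_lo, g0_hi
    if mean_IA(hi) < target_IA:
        return hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if mean_IA(mid) < target_IA:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# I/O


def write_result(result: RunResult, out_dir) -> Path:
    """Write TSV time series and a JSON manifest; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sem = result.sem
    cols = [result.times, result.mean]
    header = "t_s\tmean"
    if sem is not None:
        cols.append(sem)
        header += "\tsem"
    np.savetxt(out / "trace.tsv", np.column_stack(cols), delimiter="\t",
               header=header, comments="")
    pool_cols = [result.times] + [v.mean(axis=0)
                                  for v in result.pool_series.values()]
    np.savetxt(out / "pool.tsv", np.column_stack(pool_cols), delimiter="\t",
               header="t_s\t" + "\t".join(result.pool_series), comments="")
    manifest = dict(config=asdict(result.config),
                    config_hash=result.config.hash(),
                    repeat_seeds=result.repeat_seeds)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return out


def read_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown or ill-typed fields
    raise a schema error naming the field."""
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise ValueError("config root must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    try:
        return RunConfig(**doc)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config: {exc}") from exc
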