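import dataclasses

import numpy as np
import pytest

from synrecon import experiments as ex
from synrecon.neuron import NeuronState, step_neuron
from synrecon.protocols import Protocol, StimBlock, build_paradigm
from synrecon.stabilizer_pool import PoolParams
from synrecon.triplet_plasticity import (TraceState, drive_gate, drive_weight,
                                         induction, update_coactivity,
                                         update_traces)
from synrecon.write_protected import (GlobalGate, conductance_from_weight,
                                      init_synapses, step_synapse, update_p)


class TestConfig:
    def test_round_trip(self, tmp_path):
        cfg = ex.RunConfig(paradigm="p3", n_repeats=2, seed=5, fast=True)
        path = tmp_path / "cfg.yaml"
        path.write_text("\n".join(f"{k}: {v}" for k, v in
                                  dict(paradigm="p3", n_repeats=2, seed=5,
                                       fast=True).items()))
        loaded = ex.read_config(path)
        assert loaded.paradigm == "p3" and loaded.n_repeats == 2
        assert loaded.fast is True

    def test_unknown_field_named_in_error(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("paradigm: p1\nbanana: 3\n")
        with pytest.raises(ValueError, match="banana"):
            ex.read_config(path)

    def test_step_ratio_validated(self):
        with pytest.raises(ValueError, match="integer multiple"):
            ex.RunConfig(dt_neuron=3e-4, dt_syn=0.1)

    def test_hash_stable(self):
        a = ex.RunConfig(seed=1).hash()
        b = ex.RunConfig(seed=1).hash()
        c = ex.RunConfig(seed=2).hash()
        assert a == b != c


class TestFastPreset:
    def test_exact_time_rescaling(self):
        full = ex.build_params(ex.RunConfig(fast=False))
        fast = ex.build_params(ex.RunConfig(fast=True))
        assert fast.wp.tau_w == full.wp.tau_w / 10
        assert fast.wp.k_down == full.wp.k_down * 10
        assert fast.wp.sigma == pytest.approx(full.wp.sigma * np.sqrt(10))
        for name in ("k0", "m", "k1", "k3"):
            assert getattr(fast.pool, name) == getattr(full.pool, name) * 10
        assert fast.pool.N_A_tot == full.pool.N_A_tot
        assert fast.triplet.tau_A == full.triplet.tau_A / 10
        # spiking front end is untouched
        assert fast.neuron.tau_m == full.neuron.tau_m
        assert fast.triplet.A_plus == full.triplet.A_plus

    def test_param_override_paths(self):
        cfg = ex.RunConfig(param_overrides={"wp.g0": 12.0})
        assert ex.build_params(cfg).wp.g0 == 12.0
        with pytest.raises(KeyError):
            ex.build_params(ex.RunConfig(param_overrides={"wp.nope": 1}))


@pytest.fixture(scope="module")
def short_result():
    cfg = ex.RunConfig(paradigm="p1", n_repeats=2, seed=21, fast=True)
    proto = Protocol(duration=120.0,
                     lfs_blocks=(StimBlock(0.0, 120.0, 1.0),),
                     name="short")
    return cfg, proto, ex.run_full(cfg, protocol=proto)


class TestRunFull:
    def test_bit_identical_under_same_master_seed(self, short_result):
        cfg, proto, first = short_result
        again = ex.run_full(cfg, protocol=proto)
        np.testing.assert_array_equal(first.traces, again.traces)
        for k in first.pool_series:
            np.testing.assert_array_equal(first.pool_series[k],
                                          again.pool_series[k])

    def test_seed_changes_trajectories(self, short_result):
        cfg, proto, first = short_result
        other = ex.run_full(dataclasses.replace(cfg, seed=22), protocol=proto)
        assert not np.array_equal(first.traces, other.traces)

    def test_stabilizer_conservation_without_psi(self, short_result):
        _, _, res = short_result
        total = (res.pool_series["N_A"] + res.pool_series["N_A_star"]
                 + res.pool_series["n_bound"])
        np.testing.assert_array_equal(total, 20000.0)

    def test_sem_requires_two_repeats(self, short_result):
        _, _, res = short_result
        assert res.sem is not None
        single = dataclasses.replace(res, traces=res.traces[:1])
        assert single.sem is None

    def test_write_result_outputs(self, tmp_path, short_result):
        _, _, res = short_result
        out = ex.write_result(res, tmp_path / "run")
        trace = np.loadtxt(out / "trace.tsv", skiprows=1)
        assert trace.shape[1] == 3  # t, mean, sem
        manifest = (out / "manifest.json").read_text()
        assert res.config.hash() in manifest


class TestPresynapticCount:
    def test_binomial_law_mean_200(self):
        cfg = ex.RunConfig()
        assert cfg.n_presyn_trials * cfg.n_presyn_prob == 200.0


class TestEngineMatchesModularPath:
    """The fused kernel must reproduce the composition of the per-module
    reference operations (deterministic setting: sigma = 0, pool frozen)."""

    def test_deterministic_equivalence(self):
        cfg = ex.RunConfig(paradigm="p1", n_repeats=1, seed=33, fast=False)
        params = ex.build_params(cfg)
        params.wp = dataclasses.replace(params.wp, sigma=0.0)
        params.pool = PoolParams.write_protected(k1=0.0, k3=0.0, k0=0.0, m=0.0)
        proto = Protocol(duration=10.0,
                         lfs_blocks=(StimBlock(0.0, 10.0, 1.0, jitter_sd=0.0),),
                         hfs_events=(), name="equiv")
        n_syn = 8
        dt_n, dt_s = cfg.dt_neuron, cfg.dt_syn
        spb = int(round(dt_s / dt_n))

        # --- engine route (via run_full internals) ------------------------
        from synrecon import _engine
        syn_e = init_synapses(n_syn, 0.5, seed=1)
        spk_step, spk_syn = ex._spike_arrays(proto, n_syn, dt_n,
                                             np.random.SeedSequence(2))
        n_blocks = int(round(proto.duration / dt_s))
        par = _engine.pack_params(params.neuron, params.triplet, params.wp,
                                  params.pool)
        rec = {k: np.empty(n_blocks) for k in "abcdefg"}
        x_val = np.zeros(n_syn)
        x_last = np.zeros(n_syn, np.int64)
        IA_e = np.zeros(n_syn)
        _engine.run_wp(7, n_blocks, spb, dt_n, dt_s, spk_step, spk_syn,
                       syn_e.w, syn_e.T, syn_e.z, syn_e.gamma, syn_e.b,
                       syn_e.force_unbound, x_val, x_last, IA_e,
                       np.array([-1, -1], np.int64), np.array([-1, -1], np.int64),
                       -1, False, par, 1, *rec.values(), np.empty(5))

        # --- modular route ------------------------------------------------
        syn_m = init_synapses(n_syn, 0.5, seed=1)
        traces = TraceState.zeros(n_syn)
        neuron = NeuronState.resting(params.neuron)
        gate = GlobalGate()
        spikes_by_step = {}
        for s, j in zip(spk_step, spk_syn):
            spikes_by_step.setdefault(int(s), []).append(int(j))
        for k in range(n_blocks):
            gate = update_p(gate, params.wp, dt_s)
            acc_w = np.zeros(n_syn)
            acc_g = np.zeros(n_syn)
            acc_A = np.zeros(n_syn)
            for s in range(k * spb, (k + 1) * spb):
                pre = np.zeros(n_syn, bool)
                dg = 0.0
                for j in spikes_by_step.get(s, ()):
                    pre[j] = True
                    dg += conductance_from_weight(syn_m.w[j], params.wp)
                neuron, post = step_neuron(neuron, dg, params.neuron, dt_n)
                ip, im = induction(traces, pre, post, params.triplet)
                acc_w += drive_weight(ip, im, syn_m.w, syn_m.z)
                acc_g += drive_gate(ip, im, syn_m.w, syn_m.z, syn_m.gamma)
                acc_A += ip + im
                traces = update_traces(traces, pre, post, params.triplet, dt_n)
            syn_m = step_synapse(syn_m, gate, (acc_w, acc_g, traces.I_A),
                                 params.wp, np.zeros((3, n_syn)), dt_s)
            traces = update_coactivity(traces, acc_A * 0, acc_A,
                                       params.triplet, dt_s)

        np.testing.assert_allclose(syn_e.w, syn_m.w, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(syn_e.T, syn_m.T, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(syn_e.z, syn_m.z, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(syn_e.gamma, syn_m.gamma, rtol=1e-9,
                                   atol=1e-12)
        np.testing.assert_allclose(IA_e, traces.I_A, rtol=1e-8, atol=1e-12)


class TestRunReduced:
    def test_requires_boundary_protocol(self):
        with pytest.raises(ValueError, match="fig3"):
            ex.run_reduced(ex.RunConfig(paradigm="p1", model="reduced"))

    def test_snapshot_driven_run(self):
        cfg = ex.RunConfig(paradigm="fig3", model="reduced", fast=True)
        snap = dict(N_big=190.0, n_bound=190.0, n_A_star=700.0, I_A=0.0)
        times, rec, final = ex.run_reduced(cfg, snapshot=snap)
        assert times[0] == pytest.approx(360.0)
        assert rec["n_ASyn"].shape[0] == times.size
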