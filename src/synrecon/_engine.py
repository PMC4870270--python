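"""Fused simulation kernel for the full write-protected model.

The layered dynamics (leaky integrate-and-fire neuron and STDP traces at
0.1 ms; synapse SDEs, gates and stabilizer pool at 100 ms) are integrated in
a single jitted loop.  The per-module operations in :mod:`neuron`,
:mod:`triplet_plasticity`, :mod:`write_protected` and
:mod:`stabilizer_pool` implement the identical update rules and serve as the
reference in the equivalence tests; this kernel exists purely for speed.

Per-synapse presynaptic traces decay lazily (value plus last-event step), so
the cost per neuron step is independent of the synapse count except at
spikes.  All randomness comes from numba's own generator, seeded once per
repeat, which makes runs bit-reproducible for a given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# -- parameter vector layout ------------------------------------------------
_PARAM_NAMES = [
    # neuron
    "tau_m", "V_rest", "V_exc", "V_adapt", "tau_thr", "theta_rest",
    "theta_spike", "tau_ampa", "tau_nmda", "beta_ampa", "tau_adapt",
    "g_spike",
    # triplet
    "A_plus", "A_minus", "tau_x", "tau_y", "tau_triplet", "tau_A",
    # write-protected synapse
    "tau_w", "tau_T", "tau_z", "a_wT", "a_Tz", "a_Tw", "a_zT", "a_b",
    "sigma", "tau_gamma", "theta_gamma", "kappa", "k_up", "k_down",
    "theta_act", "w_minus", "k_w", "g0",
    # pool
    "k1", "k3", "k0", "m", "r", "I0_2", "I0_4", "N_A_tot",
]
_P = {name: i for i, name in enumerate(_PARAM_NAMES)}


def pack_params(neuron_p, triplet_p, wp_p, pool_p) -> np.ndarray:
    """Flatten the four parameter dataclasses into the kernel's vector."""
    v = np.empty(len(_PARAM_NAMES))
    vals = dict(
        tau_m=neuron_p.tau_m, V_rest=neuron_p.V_rest, V_exc=neuron_p.V_exc,
        V_adapt=neuron_p.V_adapt, tau_thr=neuron_p.tau_thr,
        theta_rest=neuron_p.theta_rest, theta_spike=neuron_p.theta_spike,
        tau_ampa=neuron_p.tau_ampa, tau_nmda=neuron_p.tau_nmda,
        beta_ampa=neuron_p.beta_ampa_frac, tau_adapt=neuron_p.tau_adapt,
        g_spike=neuron_p.g_spike,
        A_plus=triplet_p.A_plus, A_minus=triplet_p.A_minus,
        tau_x=triplet_p.tau_x, tau_y=triplet_p.tau_y,
        tau_triplet=triplet_p.tau_triplet, tau_A=triplet_p.tau_A,
        tau_w=wp_p.tau_w, tau_T=wp_p.tau_T, tau_z=wp_p.tau_z,
        a_wT=wp_p.a_wT, a_Tz=wp_p.a_Tz, a_Tw=wp_p.a_Tw, a_zT=wp_p.a_zT,
        a_b=wp_p.a_b, sigma=wp_p.sigma, tau_gamma=wp_p.tau_gamma,
        theta_gamma=wp_p.theta_gamma, kappa=wp_p.kappa, k_up=wp_p.k_up,
        k_down=wp_p.k_down, theta_act=wp_p.theta_act, w_minus=wp_p.w_minus,
        k_w=wp_p.k_w, g0=wp_p.g0,
        k1=pool_p.k1, k3=pool_p.k3, k0=pool_p.k0, m=pool_p.m, r=pool_p.r,
        I0_2=pool_p.I0_2, I0_4=pool_p.I0_4, N_A_tot=float(pool_p.N_A_tot),
    )
    for name, i in _P.items():
        v[i] = vals[name]
    return v


@njit(cache=True, inline="always")
def _logistic_rate(I, k0, m, I0, r):
    x = (I0 - I) / r
    if x > 500.0:
        x = 500.0
    elif x < -500.0:
        x = -500.0
    return k0 + m / (1.0 + np.exp(x))


@njit(cache=True)
def run_wp(seed, n_blocks, spb, dt_n, dt_s,
           spk_step, spk_syn,
           w, T, z, gamma, b, force_unbound,
           x_val, x_last, IA,
           psi_b, dopa_b, snapshot_block, gated_noise,
           par,
           rec_stride, rec_t, rec_mw, rec_NA, rec_NAs, rec_nb, rec_nbig,
           rec_IA, snap):
    """Integrate the full model for ``n_blocks`` synapse steps of ``spb``
    neuron sub-steps each.  State arrays are updated in place; recorded
    series are written every ``rec_stride`` blocks."""
    np.random.seed(seed)
    N = w.size
    # neuron state
    V = par[_V_REST]
    theta = par[_TH_REST]
    g_ampa = 0.0
    g_nmda = 0.0
    g_adapt = 0.0
    y_minus = 0.0
    y_trip = 0.0
    p = 0.0
    # initially bound entities are subtracted from the susceptible pool;
    # the immune reservoir starts empty
    nb0 = 0
    for j in range(N):
        nb0 += b[j]
    N_A = par[_NA_TOT] - nb0
    N_A_star = 0.0

    ln_fx = -dt_n / par[_TAU_X]
    f_y = np.exp(-dt_n / par[_TAU_Y])
    f_t = np.exp(-dt_n / par[_TAU_TRIP])
    # block-level relaxation factors for the silent fast path, chosen to
    # match the per-step updates exactly (exponential Euler for V, forward
    # Euler for theta)
    f_m_block = np.exp(-dt_n * spb / par[_TAU_M])
    f_thr_block = (1.0 - dt_n / par[_TAU_THR]) ** spb
    f_A = np.exp(-dt_s / par[_TAU_A])
    sq = par[_SIGMA] * np.sqrt(dt_s)
    w_plus = par[_K_W] * par[_W_MINUS]
    half = (w_plus - par[_W_MINUS]) / 2.0

    Iw_acc = np.zeros(N)
    Ig_acc = np.zeros(N)
    IA_acc = np.zeros(N)
    cur = np.empty(N, dtype=np.int32)  # pre-spiking synapses this step
    order = np.empty(N, dtype=np.int64)

    ptr = 0
    n_spk = spk_step.size
    psi_prev = False
    i_rec = 0

    for k in range(n_blocks):
        # --- global gates -------------------------------------------------
        D = 1.0 if (dopa_b[0] <= k < dopa_b[1]) else 0.0
        p = p + dt_s * (D * par[_K_UP] * (1.0 - p) - par[_K_DOWN] * p)
        if p > 1.0:
            p = 1.0
        psi_now = psi_b[0] <= k < psi_b[1]
        if psi_now and not psi_prev:
            N_A = 0.0
        elif psi_prev and not psi_now:
            nb = 0
            for j in range(N):
                nb += b[j]
            N_A = par[_NA_TOT] - N_A_star - nb
        psi_prev = psi_now

        for j in range(N):
            Iw_acc[j] = 0.0
            Ig_acc[j] = 0.0
            IA_acc[j] = 0.0

        # --- neuron + induction sub-loop ---------------------------------
        step0 = k * spb
        # fast path: with no presynaptic spikes this block, fully decayed
        # conductances and traces, and V below theta_rest, the neuron cannot
        # spike; V and theta relax analytically and the sub-loop is skipped
        n_sub = spb
        if (y_minus == 0.0 and y_trip == 0.0
                and g_ampa == 0.0 and g_nmda == 0.0 and g_adapt == 0.0
                and V < par[_TH_REST]
                and (ptr >= n_spk or spk_step[ptr] >= step0 + spb)):
            dV = (V - par[_V_REST]) * f_m_block
            if -1e-20 < dV < 1e-20:
                dV = 0.0
            V = par[_V_REST] + dV
            dth = (theta - par[_TH_REST]) * f_thr_block
            if -1e-20 < dth < 1e-20:
                dth = 0.0
            theta = par[_TH_REST] + dth
            n_sub = 0
        for s_off in range(n_sub):
            s = step0 + s_off
            ncur = 0
            dg_sum = 0.0
            while ptr < n_spk and spk_step[ptr] == s:
                j = spk_syn[ptr]
                cur[ncur] = j
                ncur += 1
                dg_sum += par[_G0] * (par[_W_MINUS] + (w[j] + 1.0) * half)
                I_m = par[_A_MINUS] * y_minus
                if I_m > 0.0:
                    IA_acc[j] += I_m
                    diff = w[j] - z[j]
                    pos = diff if diff > 0.0 else 0.0
                    Iw_acc[j] -= I_m * (1.0 + pos) * (1.0 + w[j])
                    if z[j] >= w[j]:
                        Ig_acc[j] += I_m * (1.0 - gamma[j])
                ptr += 1
            # neuron update (same order as neuron.step_neuron)
            theta += dt_n * (par[_TH_REST] - theta) / par[_TAU_THR]
            g_ampa += dg_sum
            g_nmda += dt_n * (g_ampa - g_nmda) / par[_TAU_NMDA]
            g_ampa -= dt_n * g_ampa / par[_TAU_AMPA]
            g_adapt -= dt_n * g_adapt / par[_TAU_ADAPT]
            g_exc = par[_BETA] * g_ampa + (1.0 - par[_BETA]) * g_nmda
            # exponential-Euler membrane update (stable for large volleys)
            g_tot = 1.0 + g_exc + g_adapt
            V_inf = (par[_V_REST] + g_exc * par[_V_EXC]
                     + g_adapt * par[_V_ADAPT]) / g_tot
            dV = (V - V_inf) * np.exp(-dt_n * g_tot / par[_TAU_M])
            if -1e-20 < dV < 1e-20:
                dV = 0.0
            V = V_inf + dV
            spiked = V >= theta
            if spiked:
                V = par[_V_REST]
                theta = par[_TH_SPIKE]
                g_adapt += par[_G_SPIKE]
                if y_trip > 0.0:
                    yt = y_trip
                    for j in range(N):
                        xv = x_val[j]
                        if xv > 1e-12:
                            xv *= np.exp(ln_fx * (s - x_last[j]))
                            if xv > 1e-12:
                                I_p = par[_A_PLUS] * xv * yt
                                IA_acc[j] += I_p
                                diff = z[j] - w[j]
                                pos = diff if diff > 0.0 else 0.0
                                Iw_acc[j] += I_p * (1.0 + pos) * (1.0 - w[j])
                                if w[j] >= z[j]:
                                    Ig_acc[j] += I_p * (1.0 - gamma[j])
            # trace increments (after inductions), then decay
            for i in range(ncur):
                j = cur[i]
                x_val[j] = x_val[j] * np.exp(ln_fx * (s - x_last[j])) + 1.0
                x_last[j] = s
            if spiked:
                y_minus += 1.0
                y_trip += 1.0
            y_minus *= f_y
            y_trip *= f_t
            # flush decayed variables to zero before they reach denormal
            # range (denormal arithmetic is ~100x slower and the values are
            # physically meaningless)
            if y_minus < 1e-30:
                y_minus = 0.0
            if y_trip < 1e-30:
                y_trip = 0.0
            if g_ampa < 1e-30:
                g_ampa = 0.0
            if g_nmda < 1e-30:
                g_nmda = 0.0
            if g_adapt < 1e-30:
                g_adapt = 0.0
            if not (np.isfinite(V) and np.isfinite(g_ampa)):
                return -1  # numerical divergence; caller raises

        # --- synapse SDE step (Euler-Maruyama, dt = dt_s) -----------------
        for j in range(N):
            G = 1.0 if gamma[j] >= par[_TH_GAMMA] else 0.0
            ng = 1.0
            if gated_noise and IA[j] < par[_THETA_ACT]:
                ng = 0.0
            bf = b[j] * 1.0
            fw = w[j] - w[j] ** 3
            fT = T[j] - T[j] ** 3
            fz = z[j] - z[j] ** 3
            Hz = 1.0 if z[j] >= 0.0 else 0.0
            dw = dt_s * (fw / par[_TAU_W]
                         + par[_A_TW] / (4.0 * par[_TAU_W]) * (1.0 - G) * (T[j] - w[j]))
            dT = dt_s * (fT / par[_TAU_TT]
                         + par[_A_WT] / (4.0 * par[_TAU_TT]) * G * (w[j] - T[j])
                         + par[_A_ZT] / (4.0 * par[_TAU_TT]) * (1.0 - p) * (z[j] - T[j]))
            dz = dt_s * (fz / par[_TAU_Z]
                         + par[_A_TZ] / (4.0 * par[_TAU_Z]) * p * (T[j] - z[j])
                         + par[_A_B] / par[_TAU_Z] * Hz * (bf - 1.0))
            w[j] += dw + ng * sq * np.random.normal() + Iw_acc[j]
            T[j] += dT + ng * sq * np.random.normal()
            z[j] += dz + sq * np.random.normal()
            g = gamma[j] - dt_s * gamma[j] / par[_TAU_GAMMA] + par[_KAPPA] * Ig_acc[j]
            if g < 1e-30:
                g = 0.0
            elif g > 1.0:
                g = 1.0
            gamma[j] = g
            IA[j] = IA[j] * f_A + IA_acc[j]
            if IA[j] < 1e-30:
                IA[j] = 0.0

        # --- stabilizer pool step (random sequential order) ---------------
        for j in range(N):
            if force_unbound[j] and b[j] == 1:
                b[j] = 0
                if not psi_now:
                    N_A += 1.0
        for j in range(N):
            order[j] = j
        for j in range(N - 1, 0, -1):
            i = np.random.randint(0, j + 1)
            tmp = order[j]
            order[j] = order[i]
            order[i] = tmp
        for idx in range(N):
            j = order[idx]
            if b[j] == 0:
                if z[j] < 0.0 or force_unbound[j]:
                    continue
                r_on = par[_K1] * N_A + par[_K3] * N_A_star
                if r_on <= 0.0:
                    continue
                if np.random.random() < 1.0 - np.exp(-r_on * dt_s):
                    if np.random.random() < par[_K1] * N_A / r_on:
                        N_A -= 1.0
                    else:
                        N_A_star -= 1.0
                    b[j] = 1
            else:
                k2 = _logistic_rate(IA[j], par[_K0], par[_M], par[_I02], par[_R])
                k4 = _logistic_rate(IA[j], par[_K0], par[_M], par[_I04], par[_R])
                r_off = k2 + k4
                if np.random.random() < 1.0 - np.exp(-r_off * dt_s):
                    b[j] = 0
                    if np.random.random() < k2 / r_off:
                        if not psi_now:
                            N_A += 1.0
                    else:
                        N_A_star += 1.0

        # --- recording / snapshot ----------------------------------------
        if (k + 1) == snapshot_block:
            nb = 0
            nbig = 0
            mIA = 0.0
            for j in range(N):
                nb += b[j]
                if z[j] >= 0.0:
                    nbig += 1
                mIA += IA[j]
            snap[0] = nbig
            snap[1] = nb
            snap[2] = N_A
            snap[3] = N_A_star
            snap[4] = mIA / N
        if (k + 1) % rec_stride == 0:
            mw = 0.0
            mIA = 0.0
            nb = 0
            nbig = 0
            for j in range(N):
                mw += w[j]
                mIA += IA[j]
                nb += b[j]
                if z[j] >= 0.0:
                    nbig += 1
            rec_t[i_rec] = (k + 1) * dt_s
            rec_mw[i_rec] = mw / N
            rec_NA[i_rec] = N_A
            rec_NAs[i_rec] = N_A_star
            rec_nb[i_rec] = nb
            rec_nbig[i_rec] = nbig
            rec_IA[i_rec] = mIA / N
            i_rec += 1
    return i_rec


# index constants used inside the kernel (module-level so numba treats them
# as compile-time literals)
_TAU_M = _P["tau_m"]; _V_REST = _P["V_rest"]; _V_EXC = _P["V_exc"]
_V_ADAPT = _P["V_adapt"]; _TAU_THR = _P["tau_thr"]; _TH_REST = _P["theta_rest"]
_TH_SPIKE = _P["theta_spike"]; _TAU_AMPA = _P["tau_ampa"]
_TAU_NMDA = _P["tau_nmda"]; _BETA = _P["beta_ampa"]; _TAU_ADAPT = _P["tau_adapt"]
_G_SPIKE = _P["g_spike"]; _A_PLUS = _P["A_plus"]; _A_MINUS = _P["A_minus"]
_TAU_X = _P["tau_x"]; _TAU_Y = _P["tau_y"]; _TAU_TRIP = _P["tau_triplet"]
_TAU_A = _P["tau_A"]; _TAU_W = _P["tau_w"]; _TAU_TT = _P["tau_T"]
_TAU_Z = _P["tau_z"]; _A_WT = _P["a_wT"]; _A_TZ = _P["a_Tz"]
_A_TW = _P["a_Tw"]; _A_ZT = _P["a_zT"]; _A_B = _P["a_b"]
_SIGMA = _P["sigma"]; _TAU_GAMMA = _P["tau_gamma"]
_TH_GAMMA = _P["theta_gamma"]; _KAPPA = _P["kappa"]; _K_UP = _P["k_up"]
_K_DOWN = _P["k_down"]; _THETA_ACT = _P["theta_act"]
_W_MINUS = _P["w_minus"]; _K_W = _P["k_w"]; _G0 = _P["g0"]
_K1 = _P["k1"]; _K3 = _P["k3"]; _K0 = _P["k0"]; _M = _P["m"]
_R = _P["r"]; _I02 = _P["I0_2"]; _I04 = _P["I0_4"]; _NA_TOT = _P["N_A_tot"]
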