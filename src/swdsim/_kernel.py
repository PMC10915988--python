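"""Numba-compiled fixed-step integrators.

Gating variables advance by exponential Euler using pre-computed
per-cell-type coefficient tables on a fine voltage grid (see
``kinetics.build_gating_tables``); the membrane potential advances by
exponential Euler on the instantaneous total conductance.  Synapses are
conductance-based: AMPA and phasic GABA-A use bi-exponential gates kept
as per-neuron rise/decay traces, GABA-B uses an aggregated two-stage
G-protein cascade per postsynaptic neuron, and tonic GABA-A is a constant
Cl- conductance.  Presynaptic spikes are delivered through a circular
delay buffer.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .kinetics import V_GRID_MIN, V_GRID_STEP, N_GATES

# parameter-row layout (per neuron / per cell type)
NP = 19
IP_C = 0        # membrane capacitance (uF/cm^2)
IP_GNA = 1      # fast Na+ (mS/cm^2)
IP_GK = 2       # delayed-rectifier K+
IP_GL = 3       # non-specific leak
IP_EL = 4       # leak reversal (mV)
IP_GKL = 5      # K+ leak
IP_GT = 6       # T-type Ca2+
IP_GCAN = 7     # Ca2+-activated non-selective cation
IP_GNAP = 8     # persistent Na+
IP_GH = 9       # anomalous rectifier
IP_GM = 10      # slow K+ (adaptation)
IP_EGABAA = 11  # phasic GABA-A reversal (mV)
IP_ECL = 12     # tonic GABA-A (Cl-) reversal (mV)
IP_GTONIC = 13  # tonic extrasynaptic GABA-A conductance
IP_TAUCA = 14   # Ca2+ pool decay (ms)
IP_CAGAIN = 15  # Ca2+ influx per unit T current
IP_KDCAN = 16   # half-activation [Ca2+] of I_CAN (mM)
IP_TAUCAN = 17  # I_CAN activation time constant (ms)
IP_GBBAR = 18   # maximal GABA-B conductance density

# fixed reversal potentials (mV)
E_NA = 50.0
E_K = -95.0
E_T = 120.0
E_H = -43.0
E_CAN = -20.0
E_AMPA = 0.0
CA_REST = 5e-5  # mM

# GABA-B cascade constants (Destexhe-style G-protein scheme, n = 4)
GB_K1 = 0.5     # receptor activation by transmitter (/ms per unit trace)
GB_K2 = 0.0083  # receptor deactivation (/ms)
GB_K3 = 0.1     # G-protein production (/ms)
GB_K4 = 0.025   # G-protein decay (/ms)
GB_KD = 1.0     # half-activation of the K+ channel (a.u.^4)
GB_N = 4
GB_TAU_T = 1.0  # transmitter trace decay (ms)

SPIKE_THRESHOLD = 0.0   # mV, upward crossing
REFRACTORY = 2.0        # ms

# receptor kinetics (ms); index 0 = AMPA, 1 = GABA-A
SYN_TAU_RISE = (0.5, 0.5)
SYN_TAU_DECAY = (2.5, 7.0)


def biexp_norm(tau_r: float, tau_d: float) -> float:
    """Peak-normalisation factor of g(t) = N (e^{-t/tau_d} - e^{-t/tau_r})."""
    tp = tau_r * tau_d / (tau_d - tau_r) * np.log(tau_d / tau_r)
    return 1.0 / (np.exp(-tp / tau_d) - np.exp(-tp / tau_r))


@njit(cache=True, inline="always")
def _interp(table, row, f, i0):
    a = table[row, i0]
    return a + (table[row, i0 + 1] - a) * f


@njit(cache=True)
def run_single_cell(P, A, B, dt, I_inj, V0, record_gates):
    """Integrate one neuron under an injected-current protocol.

    Returns (V trace at every step, spike times, gate trace or empty,
    status) where status 0 = ok, 1 = numerical blow-up.
    """
    n_steps = I_inj.size
    V = V0
    gates = np.empty(N_GATES)
    f0 = (V - V_GRID_MIN) / V_GRID_STEP
    i0 = min(max(int(f0), 0), A.shape[1] - 2)
    fr = f0 - i0
    for g in range(N_GATES):
        gates[g] = _interp(A, g, fr, i0)
    Ca = CA_REST
    mCAN = 0.0
    out = np.empty(n_steps)
    gtrace = np.empty((N_GATES, n_steps)) if record_gates else np.empty((0, 0))
    spikes = np.empty(n_steps // 80 + 8)
    n_spk = 0
    last_spk = -1e9
    blow = 0
    for k in range(n_steps):
        t = k * dt
        f0 = (V - V_GRID_MIN) / V_GRID_STEP
        i0 = int(f0)
        if i0 < 0:
            i0 = 0
        elif i0 > A.shape[1] - 2:
            i0 = A.shape[1] - 2
        fr = f0 - i0
        if fr < 0.0:
            fr = 0.0
        elif fr > 1.0:
            fr = 1.0
        for g in range(N_GATES):
            a = _interp(A, g, fr, i0)
            b = _interp(B, g, fr, i0)
            gates[g] = a + (gates[g] - a) * b
        gna = P[IP_GNA] * gates[0] * gates[0] * gates[0] * gates[1]
        gk = P[IP_GK] * gates[2] * gates[2] * gates[2] * gates[2]
        gm = P[IP_GM] * gates[3]
        gt = P[IP_GT] * gates[4] * gates[4] * gates[5]
        gh = P[IP_GH] * gates[6]
        gnap = P[IP_GNAP] * gates[7]
        gcan = P[IP_GCAN] * mCAN
        gtot = (gna + gnap) + (gk + gm + P[IP_GKL]) + gt + gh + gcan \
            + P[IP_GL] + P[IP_GTONIC]
        num = (gna + gnap) * E_NA + (gk + gm + P[IP_GKL]) * E_K + gt * E_T \
            + gh * E_H + gcan * E_CAN + P[IP_GL] * P[IP_EL] \
            + P[IP_GTONIC] * P[IP_ECL] + I_inj[k]
        Vinf = num / gtot
        Vold = V
        V = Vinf + (V - Vinf) * np.exp(-dt * gtot / P[IP_C])
        if not np.isfinite(V) or abs(V) > 200.0:
            blow = 1
            break
        # Ca2+ pool driven by the (inward) T current, relaxes to rest
        it = gt * (V - E_T)
        if it < 0.0:
            Ca -= dt * P[IP_CAGAIN] * it
        Ca = CA_REST + (Ca - CA_REST) * (1.0 - dt / P[IP_TAUCA])
        cr = Ca * Ca
        kd = P[IP_KDCAN] * P[IP_KDCAN]
        minf = cr / (cr + kd)
        mCAN = minf + (mCAN - minf) * np.exp(-dt / P[IP_TAUCAN])
        if Vold < SPIKE_THRESHOLD and V >= SPIKE_THRESHOLD and (t - last_spk) >= REFRACTORY:
            if n_spk < spikes.size:
                spikes[n_spk] = t
                n_spk += 1
            last_spk = t
        out[k] = V
        if record_gates:
            for g in range(N_GATES):
                gtrace[g, k] = gates[g]
    return out, spikes[:n_spk].copy(), gtrace, blow


@njit(cache=True)
def run_network(
    P,              # (N, NP) per-neuron parameters (mutated by perturbations)
    type_id,        # (N) index into the gating tables
    AT, BT,         # (n_types, N_GATES, n_grid) gating tables
    dt, n_steps,
    conn_ptr,       # (N+1) CSR over presynaptic neuron
    conn_post, conn_rec, conn_w, conn_d,   # (M) target, receptor, weight, delay steps
    buf,            # (L, N, 3) delay ring buffer, zeroed
    gain,           # (N, 3) postsynaptic receptor gain (AMPA, GABAA, GABAB)
    bg_rate, bg_w,  # (N) background Poisson drive: events/ms, peak conductance
    p_step, p_kind, p_scale, p_ptr, p_idx,  # perturbation schedule
    eeg_mask,       # (N) 1 for neurons contributing to the EEG proxy
    vrec_ids,       # (R) neuron ids with voltage recording (1 kHz)
    seed,
    V0, gates0,     # (N), (N, N_GATES) initial state
    spk_t, spk_id,  # pre-allocated spike output
):
    np.random.seed(seed)
    N = P.shape[0]
    L = buf.shape[0]
    per_ms = int(round(1.0 / dt))
    n_ms = n_steps // per_ms
    eeg = np.zeros(n_ms)
    vrec = np.zeros((vrec_ids.size, n_ms))

    V = V0.copy()
    gates = gates0.copy()
    Ca = np.full(N, CA_REST)
    mCAN = np.zeros(N)
    grA = np.zeros(N)
    gdA = np.zeros(N)
    grG = np.zeros(N)
    gdG = np.zeros(N)
    Tb = np.zeros(N)
    rB = np.zeros(N)
    sB = np.zeros(N)
    last_spk = np.full(N, -1e9)
    bg_next = np.empty(N)
    for i in range(N):
        if bg_rate[i] > 0.0:
            bg_next[i] = -np.log(np.random.random()) / bg_rate[i]
        else:
            bg_next[i] = 1e18

    frA = np.exp(-dt / SYN_TAU_RISE[0])
    fdA = np.exp(-dt / SYN_TAU_DECAY[0])
    frG = np.exp(-dt / SYN_TAU_RISE[1])
    fdG = np.exp(-dt / SYN_TAU_DECAY[1])
    fT = np.exp(-dt / GB_TAU_T)
    normA = 1.0 / (np.exp(-_TPA / SYN_TAU_DECAY[0]) - np.exp(-_TPA / SYN_TAU_RISE[0]))
    normG = 1.0 / (np.exp(-_TPG / SYN_TAU_DECAY[1]) - np.exp(-_TPG / SYN_TAU_RISE[1]))

    n_spk = 0
    cap = spk_t.size
    p_i = 0
    n_pert = p_step.size
    status = 0
    fail_t = -1.0
    fail_id = -1

    for k in range(n_steps):
        t = k * dt
        # scheduled conductance perturbations
        while p_i < n_pert and p_step[p_i] <= k:
            kind = p_kind[p_i]
            sc = p_scale[p_i]
            for j in range(p_ptr[p_i], p_ptr[p_i + 1]):
                i = p_idx[j]
                if kind == 0:
                    P[i, IP_GKL] *= sc
                elif kind == 1:
                    P[i, IP_GT] *= sc
                elif kind == 2:
                    P[i, IP_GCAN] *= sc
                elif kind == 3:
                    P[i, IP_GTONIC] *= sc
                elif kind == 4:
                    gain[i, 1] *= sc
                elif kind == 5:
                    gain[i, 0] *= sc
                elif kind == 6:
                    gain[i, 2] *= sc
            p_i += 1

        # deliver delayed synaptic events
        slot = k % L
        for i in range(N):
            w = buf[slot, i, 0]
            if w != 0.0:
                grA[i] += w
                gdA[i] += w
                buf[slot, i, 0] = 0.0
            w = buf[slot, i, 1]
            if w != 0.0:
                grG[i] += w
                gdG[i] += w
                buf[slot, i, 1] = 0.0
            w = buf[slot, i, 2]
            if w != 0.0:
                Tb[i] += w
                buf[slot, i, 2] = 0.0

        eeg_acc = 0.0
        for i in range(N):
            # synaptic state
            grA[i] *= frA
            gdA[i] *= fdA
            grG[i] *= frG
            gdG[i] *= fdG
            Tb[i] *= fT
            r = rB[i] + dt * (GB_K1 * Tb[i] * (1.0 - rB[i]) - GB_K2 * rB[i])
            if r < 0.0:
                r = 0.0
            elif r > 1.0:
                r = 1.0
            rB[i] = r
            s = sB[i] + dt * (GB_K3 * r - GB_K4 * sB[i])
            if s < 0.0:
                s = 0.0
            sB[i] = s

            # background excitatory drive
            while t >= bg_next[i]:
                grA[i] += bg_w[i]
                gdA[i] += bg_w[i]
                bg_next[i] += -np.log(np.random.random()) / bg_rate[i]

            gA = normA * (gdA[i] - grA[i]) * gain[i, 0]
            gG = normG * (gdG[i] - grG[i]) * gain[i, 1]
            s4 = s * s * s * s
            gB = P[i, IP_GBBAR] * s4 / (s4 + GB_KD) * gain[i, 2]

            # gating update via tables
            tid = type_id[i]
            f0 = (V[i] - V_GRID_MIN) / V_GRID_STEP
            i0 = int(f0)
            if i0 < 0:
                i0 = 0
            elif i0 > AT.shape[2] - 2:
                i0 = AT.shape[2] - 2
            fr = f0 - i0
            if fr < 0.0:
                fr = 0.0
            elif fr > 1.0:
                fr = 1.0
            for g in range(N_GATES):
                a0 = AT[tid, g, i0]
                a = a0 + (AT[tid, g, i0 + 1] - a0) * fr
                b0 = BT[tid, g, i0]
                b = b0 + (BT[tid, g, i0 + 1] - b0) * fr
                gates[i, g] = a + (gates[i, g] - a) * b

            gna = P[i, IP_GNA] * gates[i, 0] * gates[i, 0] * gates[i, 0] * gates[i, 1]
            gk = P[i, IP_GK] * gates[i, 2] * gates[i, 2] * gates[i, 2] * gates[i, 2]
            gm = P[i, IP_GM] * gates[i, 3]
            gt = P[i, IP_GT] * gates[i, 4] * gates[i, 4] * gates[i, 5]
            gh = P[i, IP_GH] * gates[i, 6]
            gnap = P[i, IP_GNAP] * gates[i, 7]
            gcan = P[i, IP_GCAN] * mCAN[i]
            gtot = (gna + gnap) + (gk + gm + P[i, IP_GKL]) + gt + gh + gcan \
                + P[i, IP_GL] + P[i, IP_GTONIC] + gA + gG + gB
            num = (gna + gnap) * E_NA + (gk + gm + P[i, IP_GKL]) * E_K + gt * E_T \
                + gh * E_H + gcan * E_CAN + P[i, IP_GL] * P[i, IP_EL] \
                + P[i, IP_GTONIC] * P[i, IP_ECL] \
                + gA * E_AMPA + gG * P[i, IP_EGABAA] + gB * E_K
            Vinf = num / gtot
            Vold = V[i]
            Vnew = Vinf + (Vold - Vinf) * np.exp(-dt * gtot / P[i, IP_C])
            if not np.isfinite(Vnew) or abs(Vnew) > 200.0:
                status = 1
                fail_t = t
                fail_id = i
                break
            V[i] = Vnew

            it = gt * (Vnew - E_T)
            if it < 0.0:
                Ca[i] -= dt * P[i, IP_CAGAIN] * it
            Ca[i] = CA_REST + (Ca[i] - CA_REST) * (1.0 - dt / P[i, IP_TAUCA])
            cr = Ca[i] * Ca[i]
            kd = P[i, IP_KDCAN] * P[i, IP_KDCAN]
            minf = cr / (cr + kd)
            mCAN[i] = minf + (mCAN[i] - minf) * np.exp(-dt / P[i, IP_TAUCAN])

            if eeg_mask[i] == 1:
                eeg_acc -= gA * (Vnew - E_AMPA) + gG * (Vnew - P[i, IP_EGABAA]) \
                    + gB * (Vnew - E_K)

            # spike detection and event scatter
            if Vold < SPIKE_THRESHOLD and Vnew >= SPIKE_THRESHOLD and (t - last_spk[i]) >= REFRACTORY:
                last_spk[i] = t
                if n_spk < cap:
                    spk_t[n_spk] = t
                    spk_id[n_spk] = i
                    n_spk += 1
                else:
                    status = 2
                for c in range(conn_ptr[i], conn_ptr[i + 1]):
                    buf[(k + conn_d[c]) % L, conn_post[c], conn_rec[c]] += conn_w[c]
        if status == 1:
            break

        ms = k // per_ms
        eeg[ms] += eeg_acc / per_ms
        if k % per_ms == 0:
            for ri in range(vrec_ids.size):
                vrec[ri, ms] = V[vrec_ids[ri]]

    return eeg, vrec, n_spk, status, fail_t, fail_id


# peak times of the bi-exponential gates, needed inside the jitted kernel
_TPA = SYN_TAU_RISE[0] * SYN_TAU_DECAY[0] / (SYN_TAU_DECAY[0] - SYN_TAU_RISE[0]) \
    * np.log(SYN_TAU_DECAY[0] / SYN_TAU_RISE[0])
_TPG = SYN_TAU_RISE[1] * SYN_TAU_DECAY[1] / (SYN_TAU_DECAY[1] - SYN_TAU_RISE[1]) \
    * np.log(SYN_TAU_DECAY[1] / SYN_TAU_RISE[1])
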