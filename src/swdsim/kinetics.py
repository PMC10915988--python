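"""Voltage-dependent gating kinetics for the ionic currents in the model.

All schemes are standard single-compartment Hodgkin-Huxley formulations:
Traub-Miles style fast Na+/K+ spike currents with a per-type threshold
shift ``VT``, a slow non-inactivating K+ current (I_M) for spike-frequency
adaptation, low-threshold T-type Ca2+ currents with separate relay-cell
(TC) and reticular (NRT) kinetics, a hyperpolarization-activated mixed
cation current (I_h), and an instantaneously activating persistent Na+
current (I_NaP).

Rates are expressed at body temperature; time constants are in ms and
voltages in mV.  Each gating variable x relaxes as
``dx/dt = (x_inf(V) - x) / tau_x(V)``.

The module exposes the analytic ``x_inf``/``tau_x`` curves (used by the
reference right-hand side and by tests) and a table builder that
pre-computes exponential-Euler update coefficients on a fine voltage grid
for the compiled integrators.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GATING_REGISTRY",
    "gating_steady_state",
    "gating_time_constant",
    "build_gating_tables",
    "V_GRID_MIN",
    "V_GRID_MAX",
    "V_GRID_STEP",
    "N_GATES",
    "GATE_NAMES",
]

# voltage grid for the pre-computed update tables
V_GRID_MIN = -130.0
V_GRID_MAX = 60.0
V_GRID_STEP = 0.05

# gating-state layout used by the integrators
GATE_NAMES = ("m_Na", "h_Na", "n_K", "p_M", "m_T", "h_T", "m_h", "m_NaP")
N_GATES = len(GATE_NAMES)

_TINY = 1e-9


def _vtrap(x, y):
    """x / (exp(x/y) - 1) with the removable singularity filled in."""
    x = np.asarray(x, dtype=float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 - x / y / 2.0), x / (np.expm1(np.clip(x / y, -50, 50)) + _TINY))
    return out


# ---------------------------------------------------------------------------
# fast spike currents (Traub-Miles form, threshold shift VT)
# ---------------------------------------------------------------------------

def _na_m_alpha(V, VT):
    return 0.32 * _vtrap(-(V - VT - 13.0), 4.0)


def _na_m_beta(V, VT):
    return 0.28 * _vtrap(V - VT - 40.0, 5.0)


def _na_h_alpha(V, VT):
    return 0.128 * np.exp(np.clip(-(V - VT - 17.0) / 18.0, -50, 50))


def _na_h_beta(V, VT):
    return 4.0 / (1.0 + np.exp(np.clip(-(V - VT - 40.0) / 5.0, -50, 50)))


def _k_n_alpha(V, VT):
    return 0.032 * _vtrap(-(V - VT - 15.0), 5.0)


def _k_n_beta(V, VT):
    return 0.5 * np.exp(np.clip(-(V - VT - 10.0) / 40.0, -50, 50))


def _from_rates(alpha, beta):
    tau = 1.0 / (alpha + beta + _TINY)
    return alpha * tau, tau


# ---------------------------------------------------------------------------
# slow K+ current I_M (adaptation); tau scaled by a per-type tau_max
# ---------------------------------------------------------------------------

def _m_p_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))


def _m_p_tau(V, tau_max=1000.0):
    return tau_max / (3.3 * np.exp((V + 35.0) / 20.0) + np.exp(-(V + 35.0) / 20.0))


# ---------------------------------------------------------------------------
# T-type Ca2+ current, relay-cell kinetics (Huguenard-McCormick style)
# ---------------------------------------------------------------------------

def _t_tc_m_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 57.0) / 6.2))


def _t_tc_m_tau(V):
    return 0.17 + 0.27 / (np.exp(-(V + 131.6) / 16.7) + np.exp((V + 16.8) / 18.2))


def _t_tc_h_inf(V):
    return 1.0 / (1.0 + np.exp((V + 81.0) / 4.0))


def _t_tc_h_tau(V):
    V = np.asarray(V, dtype=float)
    lo = np.exp(np.clip((V + 467.0) / 66.6, -50, 50)) / 3.7
    hi = (28.0 + np.exp(np.clip(-(V + 21.9) / 10.5, -50, 50))) / 3.7
    return np.where(V < -81.0, lo, hi)


# ---------------------------------------------------------------------------
# T-type Ca2+ current, reticular-cell kinetics (slower, more depolarized)
# ---------------------------------------------------------------------------

def _t_nrt_m_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 52.0) / 7.4))


def _t_nrt_m_tau(V):
    return 0.44 + 0.15 / (np.exp((V + 27.0) / 10.0) + np.exp(-(V + 102.0) / 15.0))


def _t_nrt_h_inf(V):
    return 1.0 / (1.0 + np.exp((V + 80.0) / 5.0))


def _t_nrt_h_tau(V):
    return 22.7 + 0.27 / (np.exp((V + 48.0) / 4.0) + np.exp(-(V + 407.0) / 50.0))


# ---------------------------------------------------------------------------
# I_h (anomalous rectifier) and persistent Na+
# ---------------------------------------------------------------------------

def _h_m_inf(V):
    return 1.0 / (1.0 + np.exp((V + 75.0) / 5.5))


def _h_m_tau(V):
    return 1.0 / (np.exp(-14.59 - 0.086 * V) + np.exp(-1.87 + 0.0701 * V))


def _nap_m_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 57.9) / 6.4))


# ---------------------------------------------------------------------------
# public registry
# ---------------------------------------------------------------------------

def _na_m(V, VT=-55.0):
    return _from_rates(_na_m_alpha(V, VT), _na_m_beta(V, VT))


def _na_h(V, VT=-55.0):
    return _from_rates(_na_h_alpha(V, VT), _na_h_beta(V, VT))


def _k_n(V, VT=-55.0):
    return _from_rates(_k_n_alpha(V, VT), _k_n_beta(V, VT))


#: (current, variable) -> (steady_state(V), time_constant(V)), with the
#: direction of the variable ('act' increases with V, 'inact' decreases).
GATING_REGISTRY = {
    ("I_Na", "m"): (lambda V: _na_m(V)[0], lambda V: _na_m(V)[1], "act"),
    ("I_Na", "h"): (lambda V: _na_h(V)[0], lambda V: _na_h(V)[1], "inact"),
    ("I_K", "n"): (lambda V: _k_n(V)[0], lambda V: _k_n(V)[1], "act"),
    ("I_M", "p"): (_m_p_inf, _m_p_tau, "act"),
    ("I_T", "m"): (_t_tc_m_inf, _t_tc_m_tau, "act"),
    ("I_T", "h"): (_t_tc_h_inf, _t_tc_h_tau, "inact"),
    ("I_T_NRT", "m"): (_t_nrt_m_inf, _t_nrt_m_tau, "act"),
    ("I_T_NRT", "h"): (_t_nrt_h_inf, _t_nrt_h_tau, "inact"),
    ("I_h", "m"): (_h_m_inf, _h_m_tau, "inact"),
    ("I_NaP", "m"): (_nap_m_inf, lambda V: np.full_like(np.asarray(V, dtype=float), 0.1), "act"),
}


def gating_steady_state(current_name: str, variable: str, V: float) -> float:
    """Steady-state value of a gating variable at membrane potential ``V``.

    Raises ``KeyError`` naming the registered pairs if the
    (current, variable) pair is unknown, and ``ValueError`` on non-finite V.
    """
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    key = (current_name, variable)
    if key not in GATING_REGISTRY:
        known = sorted(GATING_REGISTRY)
        raise KeyError(f"unknown gating pair {key!r}; registered pairs: {known}")
    inf, _, _ = GATING_REGISTRY[key]
    return float(inf(V))


def gating_time_constant(current_name: str, variable: str, V: float) -> float:
    """Relaxation time constant (ms) of a gating variable at ``V``."""
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    key = (current_name, variable)
    if key not in GATING_REGISTRY:
        known = sorted(GATING_REGISTRY)
        raise KeyError(f"unknown gating pair {key!r}; registered pairs: {known}")
    _, tau, _ = GATING_REGISTRY[key]
    return float(tau(V))


def build_gating_tables(VT: float, tau_m_max: float, it_kind: int, dt: float):
    """Pre-compute exponential-Euler coefficients on the voltage grid.

    For each gating variable the update is
    ``x <- A[V] + (x - A[V]) * B[V]`` with ``A = x_inf`` and
    ``B = exp(-dt / tau_x)``.

    Parameters
    ----------
    VT : threshold shift of the fast spike currents (mV).
    tau_m_max : peak time constant of I_M (ms).
    it_kind : 0 (no T current needed, relay kinetics used as filler),
        1 relay-cell kinetics, 2 reticular kinetics.
    dt : integration step (ms).

    Returns ``(A, B)`` arrays of shape ``(N_GATES, n_grid)`` (float64).
    """
    V = np.arange(V_GRID_MIN, V_GRID_MAX + V_GRID_STEP / 2, V_GRID_STEP)
    n = V.size
    A = np.empty((N_GATES, n))
    B = np.empty((N_GATES, n))

    def put(i, inf, tau):
        A[i] = inf
        B[i] = np.exp(-dt / np.maximum(tau, 1e-3))

    a, t = _from_rates(_na_m_alpha(V, VT), _na_m_beta(V, VT))
    put(0, a, t)
    a, t = _from_rates(_na_h_alpha(V, VT), _na_h_beta(V, VT))
    put(1, a, t)
    a, t = _from_rates(_k_n_alpha(V, VT), _k_n_beta(V, VT))
    put(2, a, t)
    put(3, _m_p_inf(V), _m_p_tau(V, tau_m_max))
    if it_kind == 2:
        put(4, _t_nrt_m_inf(V), _t_nrt_m_tau(V))
        put(5, _t_nrt_h_inf(V), _t_nrt_h_tau(V))
    else:
        put(4, _t_tc_m_inf(V), _t_tc_m_tau(V))
        put(5, _t_tc_h_inf(V), _t_tc_h_tau(V))
    put(6, _h_m_inf(V), _h_m_tau(V))
    # persistent Na+ activates effectively instantaneously
    A[7] = _nap_m_inf(V)
    B[7] = 0.0
    return A, B
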