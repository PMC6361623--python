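"""Voltage- and calcium-gated channel kinetics for BL neuron models.

Each gating variable x follows first-order kinetics

    dx/dt = (x_inf(V) - x) / tau_x(V)

with the steady state either given directly as a Boltzmann sigmoid or as
alpha/(alpha+beta) from forward/backward rate functions.  The principal-cell
(PN) channel set comprises the spike currents (I_Na, I_DR), subthreshold
currents (I_M, I_H, I_Nap, I_A), a high-voltage-activated calcium current
(I_Ca) and a slow calcium-gated after-hyperpolarization current (I_sAHP)
whose activation depends on an intracellular calcium pool rather than on
voltage.  Fast-spiking interneurons (FSIs) carry only fast Na/K currents
with fast-spiking kinetics (``fsi_*`` gates); those kinetics, like the
transient A-type scheme, are documented stand-ins calibrated against the
printed cell-level constraints (sub-millisecond spike width, non-adapting
repetitive firing).

Units: mV, ms.  Rates are 1/ms.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "GATES",
    "GATE_IDS",
    "CHANNELS",
    "eval_gate",
    "sahp_rates",
    "sahp_xinf",
    "SAHP_TAU_MS",
    "CA_FLOOR",
]

# floor applied to the calcium argument of the sAHP rates (log10 singularity)
CA_FLOOR = 1e-10
SAHP_TAU_MS = 48.0


def _expm1_ratio(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x / y) - 1), patched at the removable singularity x -> 0."""
    x = np.asarray(x, dtype=float)
    arg = x / y
    small = np.abs(arg) < 1e-7
    safe = np.where(small, 1.0, arg)
    out = np.where(small, y * (1.0 - arg / 2.0), x / np.expm1(safe))
    return out


# ---------------------------------------------------------------------------
# PN gating laws
# ---------------------------------------------------------------------------

def _na_m(v):
    # alpha = -0.4 (V+30) / (exp(-(V+30)/7.2) - 1)
    alpha = 0.4 * _expm1_ratio(-(v + 30.0), 7.2)
    beta = 0.124 * _expm1_ratio(v + 30.0, 7.2)
    s = alpha + beta
    return alpha / s, 0.6156 / s


def _na_h(v):
    alpha = 0.03 * _expm1_ratio(-(v + 45.0), 1.5)
    beta = 0.01 * _expm1_ratio(v + 45.0, 1.5)
    xinf = 1.0 / (np.exp((v + 50.0) / 4.0) + 1.0)
    return xinf, 0.6156 / (alpha + beta)


def _dr_n(v):
    alpha = np.exp(-0.1144 * (v + 15.0))
    beta = np.exp(-0.0801 * (v + 15.0))
    xinf = 1.0 / (np.exp((-v - 15.0) / 11.0) + 1.0)
    return xinf, 50.0 * beta / (1.0 + alpha)


def _h_q(v):
    alpha = np.exp(0.0832 * (v + 75.0))
    beta = np.exp(0.0333 * (v + 75.0))
    xinf = 1.0 / (np.exp((v + 81.0) / 8.0) + 1.0)
    return xinf, beta / (0.0081 * (1.0 + alpha))


def _km_m(v):
    alpha = 0.016 * np.exp(-(v + 52.7) / 23.0)
    beta = 0.016 * np.exp((v + 52.7) / 18.8)
    xinf = 1.0 / (np.exp((-v - 52.7) / 10.3) + 1.0)
    return xinf, 1.0 / (alpha + beta)


def _ca_m(v):
    xinf = 1.0 / (np.exp((-v - 30.0) / 11.0) + 1.0)
    tau = 2.5 / (np.exp(-(v + 37.1) / 32.3) + np.exp((v + 37.1) / 32.3))
    return xinf, tau


def _ca_h(v):
    xinf = 1.0 / (np.exp((v + 12.6) / 18.9) + 1.0)
    return xinf, np.full_like(np.asarray(v, dtype=float), 420.0)


def _nap_m(v):
    xinf = 1.0 / (np.exp((-v - 48.0) / 5.0) + 1.0)
    tau = 2.5 + 14.0 * np.exp(-(v + 40.0) / 10.0)
    return xinf, tau


# Transient A-type stand-in: sigmoid activation near -50 mV, steep
# inactivation near -83 mV; the inactivation midpoint is calibrated against
# the printed resting potential and input resistance of the PN model.
def _a_m(v):
    v = np.asarray(v, dtype=float)
    xinf = 1.0 / (1.0 + np.exp(-(v + 50.0) / 15.0))
    return xinf, np.full_like(v, 2.0)


def _a_h(v):
    v = np.asarray(v, dtype=float)
    xinf = 1.0 / (1.0 + np.exp((v + 83.0) / 4.0))
    return xinf, np.full_like(v, 20.0)


# ---------------------------------------------------------------------------
# FSI gating laws (fast-spiking stand-in; temperature factor 5 on h and n)
# ---------------------------------------------------------------------------

_FSI_PHI = 5.0


def _fsi_m(v):
    alpha = 0.1 * _expm1_ratio(-(v + 35.0), 10.0)
    beta = 4.0 * np.exp(-(v + 60.0) / 18.0)
    s = alpha + beta
    return alpha / s, 1.0 / s


def _fsi_h(v):
    alpha = 0.07 * np.exp(-(v + 58.0) / 20.0)
    beta = 1.0 / (np.exp(-0.1 * (v + 28.0)) + 1.0)
    s = alpha + beta
    return alpha / s, 1.0 / (_FSI_PHI * s)


def _fsi_n(v):
    alpha = 0.01 * _expm1_ratio(-(v + 34.0), 10.0)
    beta = 0.125 * np.exp(-(v + 44.0) / 80.0)
    s = alpha + beta
    return alpha / s, 1.0 / (_FSI_PHI * s)


# ---------------------------------------------------------------------------
# sAHP calcium-gated rates
# ---------------------------------------------------------------------------

def sahp_rates(ca):
    """Forward/backward rates of the slow AHP gate as a function of the
    (dimensionless) calcium pool value.  The rate laws depend on
    log10(Ca^2); the argument is floored at CA_FLOOR."""
    ca = np.maximum(np.asarray(ca, dtype=float), CA_FLOOR)
    lg = np.log10(ca * ca)
    alpha = 0.0048 / np.exp(-5.0 * lg - 17.5)
    beta = 0.012 / np.exp(2.0 * lg + 20.0)
    return alpha, beta


def sahp_xinf(ca):
    alpha, beta = sahp_rates(ca)
    return alpha / (alpha + beta)


# ---------------------------------------------------------------------------
# Registries
# ---------------------------------------------------------------------------

#: gate name -> callable(V) -> (x_inf, tau_ms)
GATES = {
    "na_m": _na_m,
    "na_h": _na_h,
    "dr_n": _dr_n,
    "h_q": _h_q,
    "km_m": _km_m,
    "ca_m": _ca_m,
    "ca_h": _ca_h,
    "nap_m": _nap_m,
    "a_m": _a_m,
    "a_h": _a_h,
    "fsi_m": _fsi_m,
    "fsi_h": _fsi_h,
    "fsi_n": _fsi_n,
}

#: stable integer ids used by the simulation kernels' lookup tables
GATE_IDS = {name: i for i, name in enumerate(GATES)}

#: channel name -> (activation gate, p, inactivation gate or None, q)
#: reversal potentials live in the archetype configs.
CHANNELS = {
    "I_Na": ("na_m", 3, "na_h", 1),
    "I_DR": ("dr_n", 1, None, 0),
    "I_M": ("km_m", 2, None, 0),
    "I_H": ("h_q", 1, None, 0),
    "I_Ca": ("ca_m", 2, "ca_h", 1),
    "I_Nap": ("nap_m", 1, None, 0),
    "I_A": ("a_m", 1, "a_h", 1),
    "I_sAHP": ("sahp", 1, None, 0),
    "I_Na_fsi": ("fsi_m", 3, "fsi_h", 1),
    "I_DR_fsi": ("fsi_n", 4, None, 0),
}


def eval_gate(gate: str, v):
    """Evaluate (x_inf, tau_ms) of a named voltage-dependent gate."""
    try:
        fn = GATES[gate]
    except KeyError:
        raise KeyError(f"unknown gate {gate!r}") from None
    return fn(np.asarray(v, dtype=float))
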