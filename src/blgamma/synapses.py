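"""Receptor dynamics, short-term plasticity and gap junctions.

Chemical transmission uses pulse-driven first-order receptor kinetics: a
presynaptic spike opens a transmitter gate (ON = 1) for a fixed 1-ms window,
during which the open fraction r relaxes toward alpha/(alpha+beta) with rate
alpha+beta; afterwards it decays with rate beta,

    dr/dt = alpha * ON * (1 - r) - beta * r.

The synaptic current is I = w * g_max * STP * r * (V - E), with the NMDA
conductance additionally scaled by the voltage-dependent magnesium block
s(V) = 1 / (1 + 0.33 exp(-0.06 V)).  Parameter tables give rise/decay time
constants instead of rate constants; :func:`rates_from_time_constants` maps
(tau_rise, tau_decay) to (alpha, beta) by matching the 10-90% rise time of
the dual-exponential conductance with the same time constants and its decay
e-fold time.

Short-term presynaptic depression multiplies two factors d1 (fast) and d2
(slow) on each presynaptic spike; both recover exponentially toward 1 and
the product is floored at the connection class's D limit.  Facilitation
machinery (factor F >= 1) is implemented but no default connection class
uses it.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ReceptorSpec",
    "ReceptorState",
    "StpSpec",
    "StpState",
    "GapJunction",
    "mg_block",
    "rates_from_time_constants",
    "dual_exponential",
    "step_receptor",
    "step_stp",
    "gap_current",
    "calibrate_gap_conductance",
    "load_synapse_classes",
    "draw_weights",
    "TRANSMITTER_PULSE_MS",
]

TRANSMITTER_PULSE_MS = 1.0
_LN9 = math.log(9.0)


def mg_block(v):
    """Voltage dependence of the NMDA magnesium block, in (0, 1)."""
    return 1.0 / (1.0 + 0.33 * np.exp(-0.06 * np.asarray(v, dtype=float)))


def dual_exponential(t, tau_rise: float, tau_decay: float):
    """Peak-normalized dual-exponential conductance waveform."""
    t = np.asarray(t, dtype=float)
    if tau_decay <= tau_rise:
        raise ValueError("decay time constant must exceed rise time constant")
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    norm = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    out = (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm
    return np.where(t >= 0, out, 0.0)


def _dual_exp_rise_1090(tau_rise: float, tau_decay: float) -> float:
    """10-90% rise time of the dual-exponential waveform (numeric)."""
    from scipy.optimize import brentq

    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    f = lambda t, level: dual_exponential(t, tau_rise, tau_decay) - level
    t10 = brentq(f, 0.0, tp, args=(0.1,))
    t90 = brentq(f, t10, tp, args=(0.9,))
    return t90 - t10


def rates_from_time_constants(tau_rise: float, tau_decay: float,
                              pulse_ms: float = TRANSMITTER_PULSE_MS):
    """Map (tau_rise, tau_decay) to pulse-model rate constants (alpha, beta).

    beta = 1/tau_decay (decay e-fold); alpha is set so the saturating rise
    during the transmitter pulse has the same 10-90% rise time as the
    dual-exponential with these time constants, i.e. alpha + beta =
    ln(9) / t_1090.  For slow-rising receptors whose rise outlasts the
    transmitter pulse (NMDA), the rise is necessarily truncated at the pulse
    duration; the decay remains exact.
    """
    beta = 1.0 / tau_decay
    total = _LN9 / _dual_exp_rise_1090(tau_rise, tau_decay)
    alpha = total - beta
    if alpha <= 0:
        raise ValueError("rise faster than decay required (alpha <= 0)")
    return alpha, beta


@dataclass(frozen=True)
class ReceptorSpec:
    kind: str  # AMPA | NMDA | GABA_A
    reversal: float  # mV
    alpha: float  # 1/ms
    beta: float  # 1/ms
    g_max: float  # nS
    weight_mean: float
    weight_spread: float  # SD by default; variance in "var" mode
    tau_rise: float
    tau_decay: float

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0 or self.g_max <= 0:
            raise ValueError("rate constants and g_max must be positive")
        if self.tau_decay <= self.tau_rise:
            raise ValueError("decay must be slower than rise")


@dataclass
class ReceptorState:
    r: float = 0.0
    on_until: float = -np.inf  # absolute time when the transmitter gate shuts

    def open_gate(self, t_ms: float, pulse_ms: float = TRANSMITTER_PULSE_MS):
        self.on_until = t_ms + pulse_ms


@dataclass(frozen=True)
class StpSpec:
    d_min: float  # floor on d1*d2
    d1: float
    d2: float
    tau_d1: float
    tau_d2: float
    f: float = 1.0  # facilitation constant (>= 1); unused by default
    tau_f: float = 100.0


@dataclass
class StpState:
    d1: float = 1.0
    d2: float = 1.0
    F: float = 1.0


def step_receptor(state: ReceptorState, spec: ReceptorSpec, dt_ms: float,
                  t_ms: float = 0.0) -> ReceptorState:
    """Advance the receptor ODE by dt with the exact exponential update.

    The transmitter gate is treated as constant over the step (engine step
    << pulse duration)."""
    if t_ms < state.on_until:
        r_inf = spec.alpha / (spec.alpha + spec.beta)
        k = spec.alpha + spec.beta
        state.r = r_inf + (state.r - r_inf) * math.exp(-k * dt_ms)
    else:
        state.r *= math.exp(-spec.beta * dt_ms)
    return state


def step_stp(state: StpState, spec: StpSpec, presynaptic_spike: bool,
             dt_ms: float) -> tuple[StpState, float]:
    """Advance the plasticity factors and return the conductance multiplier.

    Between spikes each factor relaxes exponentially toward 1; on a spike
    the d factors are multiplied by their per-spike constants and F by f.
    The returned multiplier is F * max(d1*d2, d_min)."""
    state.d1 = 1.0 + (state.d1 - 1.0) * math.exp(-dt_ms / spec.tau_d1)
    state.d2 = 1.0 + (state.d2 - 1.0) * math.exp(-dt_ms / spec.tau_d2)
    state.F = 1.0 + (state.F - 1.0) * math.exp(-dt_ms / spec.tau_f)
    if presynaptic_spike:
        state.d1 *= spec.d1
        state.d2 *= spec.d2
        state.F = max(state.F * spec.f, 1.0)
    mult = state.F * max(state.d1 * state.d2, spec.d_min)
    return state, mult


@dataclass(frozen=True)
class GapJunction:
    conductance: float  # nS
    comp_a: int
    comp_b: int


def gap_current(v_a: float, v_b: float, g_nS: float):
    """Symmetric electrical coupling: returns (I_a, I_b) in pA, currents
    INTO each endpoint; I_a = g (V_b - V_a) = -I_b."""
    i_a = g_nS * (np.asarray(v_b, float) - np.asarray(v_a, float))
    return i_a, -i_a


# ---------------------------------------------------------------------------
# Parameter tables
# ---------------------------------------------------------------------------

_KIND_BY_KEY = {"ampa": "AMPA", "nmda": "NMDA", "gaba": "GABA_A"}


def load_synapse_classes(spread_mode: str | None = None) -> dict:
    """Load the connection-class table.

    Returns {class_name: {"receptors": {kind: ReceptorSpec}, "stp": StpSpec}}
    plus "_meta" with distribution settings and the gap-junction target
    coupling coefficient."""
    text = (
        importlib.resources.files("blgamma.configs")
        .joinpath("synapses.yaml")
        .read_text()
    )
    cfg = yaml.safe_load(text)
    mode = spread_mode or cfg.get("weight_spread_mode", "sd")
    if mode not in ("sd", "var"):
        raise ValueError("weight_spread_mode must be 'sd' or 'var'")
    out: dict = {
        "_meta": {
            "spread_mode": mode,
            "distribution": cfg.get("weight_distribution", "normal"),
            "pulse_ms": float(cfg.get("transmitter_pulse_ms", TRANSMITTER_PULSE_MS)),
            "gap_coupling_coefficient": float(
                cfg["gap_junction"]["coupling_coefficient"]
            ),
        }
    }
    for name, entry in cfg["classes"].items():
        receptors = {}
        for key, kind in _KIND_BY_KEY.items():
            if key not in entry:
                continue
            r = entry[key]
            alpha, beta = rates_from_time_constants(
                float(r["tau_rise"]), float(r["tau_decay"])
            )
            receptors[kind] = ReceptorSpec(
                kind=kind,
                reversal=float(r["reversal"]),
                alpha=alpha,
                beta=beta,
                g_max=float(r["g_max"]),
                weight_mean=float(r["strength"][0]),
                weight_spread=float(r["strength"][1]),
                tau_rise=float(r["tau_rise"]),
                tau_decay=float(r["tau_decay"]),
            )
        stp = entry.get("stp")
        stp_spec = None
        if stp is not None:
            stp_spec = StpSpec(
                d_min=float(stp["d_min"]),
                d1=float(stp["d1"]),
                d2=float(stp["d2"]),
                tau_d1=float(stp["tau_d1"]),
                tau_d2=float(stp["tau_d2"]),
            )
        out[name] = {"receptors": receptors, "stp": stp_spec}
    return out


def draw_weights(spec: ReceptorSpec, n: int, rng: np.random.Generator,
                 spread_mode: str = "sd", distribution: str = "normal"):
    """Per-connection weights: normal(mean, sd), truncated at 0.05*mean."""
    sd = spec.weight_spread if spread_mode == "sd" else math.sqrt(spec.weight_spread)
    if distribution != "normal":
        raise ValueError(f"unsupported weight distribution {distribution!r}")
    w = rng.normal(spec.weight_mean, sd, size=n)
    return np.maximum(w, 0.05 * spec.weight_mean)


# ---------------------------------------------------------------------------
# Gap-junction calibration (inverse problem for the coupling coefficient)
# ---------------------------------------------------------------------------

def measure_coupling_coefficient(fsi_model, g_nS: float,
                                 step_pA: float = -50.0,
                                 settle_ms: float = 1500.0,
                                 step_ms: float = 500.0) -> float:
    """Steady-state dV_B/dV_A for two resting FSIs coupled at the soma."""
    from . import engine

    res = engine.simulate_pair_with_gap(
        fsi_model, g_nS, step_pA=step_pA, settle_ms=settle_ms, step_ms=step_ms
    )
    return res


def calibrate_gap_conductance(fsi_model, target_cc: float,
                              tol: float = 0.02) -> float:
    """Find the gap conductance reproducing a steady-state coupling
    coefficient, by bisection on the two-cell virtual experiment."""
    from scipy.optimize import brentq

    if not (0.0 < target_cc < 0.5):
        raise ValueError("target coupling coefficient must lie in (0, 0.5)")

    def err(g):
        return measure_coupling_coefficient(fsi_model, g) - target_cc

    lo, hi = 1e-4, 5.0
    if err(lo) > 0 or err(hi) < 0:
        raise RuntimeError("coupling-coefficient root not bracketed")
    g = brentq(err, lo, hi, xtol=1e-4, rtol=1e-3)
    return float(g)
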