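"""Cell archetypes of the BL network model.

Three conductance-based archetypes are defined: adapting principal neurons
(PN_A), continuously firing principal neurons (PN_C) and fast-spiking
interneurons (FSI).  Principal cells have a soma plus two dendrites (each
split into a proximal and distal electrical compartment); FSIs have a soma
and one dendrite.  Membrane dynamics follow the Hodgkin-Huxley formalism

    C_m dV/dt = -g_L (V - E_L) - g_c (V - V_neighbor) - sum I_int - sum I_syn + I_inj

with the intrinsic current of each channel I = gbar m^p h^q (V - E).

Archetype parameters (geometry, densities, reversals) are declarative YAML
documents shipped with the package; :func:`load_archetype` builds a
:class:`NeuronModel` from them.  A tolerance-controlled reference ODE
solution (:func:`reference_solution`) is provided as an independent check of
the fixed-step simulation kernels.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from . import channels as chan

__all__ = [
    "Compartment",
    "ChannelSpec",
    "CalciumPool",
    "NeuronModel",
    "load_archetype",
    "eval_gating",
    "adaptation_ratio",
    "measure_passive",
    "fsi_spike_halfwidth",
    "spike_halfwidth",
    "detect_spikes",
    "reference_solution",
    "SPIKE_THRESHOLD_MV",
    "SPIKE_REFRACTORY_MS",
]

# spike detection convention: upward crossing with absolute refractory
SPIKE_THRESHOLD_MV = -20.0
SPIKE_REFRACTORY_MS = 2.0

ADAPTATION_CUTOFF = 1.5

_ARCHETYPE_FILES = {"PN_A": "pn_a.yaml", "PN_C": "pn_a.yaml", "FSI": "fsi.yaml"}
# PN_C differs from PN_A only in the somatic sAHP density
_PN_C_SAHP = 0.2


@dataclass(frozen=True)
class Compartment:
    """A cylindrical compartment; surface area is pi * d * L (sides only)."""

    name: str
    diameter: float  # um
    length: float  # um
    parent: int  # index of parent compartment, -1 for the root
    specific_capacitance: float  # uF/cm^2
    axial_resistivity: float  # Ohm-cm
    specific_leak_conductance: float  # mS/cm^2
    leak_reversal: float  # mV

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("compartment dimensions must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.diameter * self.length

    @property
    def capacitance_pF(self) -> float:
        # uF/cm^2 * um^2 -> pF   (1 um^2 = 1e-8 cm^2; 1 uF = 1e6 pF)
        return self.specific_capacitance * self.area_um2 * 1e-2

    @property
    def leak_conductance_nS(self) -> float:
        # mS/cm^2 * um^2 -> nS
        return self.specific_leak_conductance * self.area_um2 * 1e-2


@dataclass(frozen=True)
class ChannelSpec:
    """One channel population in one compartment."""

    current_name: str
    compartment: int
    density: float  # mS/cm^2
    reversal: float  # mV
    activation_gate: str
    p: int
    inactivation_gate: str | None
    q: int

    def conductance_nS(self, area_um2: float) -> float:
        return self.density * area_um2 * 1e-2


@dataclass(frozen=True)
class CalciumPool:
    """Dimensionless somatic calcium pool feeding the sAHP gate.

    d[Ca]/dt = -influx_scale * I_Ca(soma, mA/cm^2) - [Ca]/tau ; inward
    calcium current (negative) raises the pool.  The pool value is clamped
    to be non-negative."""

    decay_time_constant: float  # ms
    influx_scale: float
    compartment: int = 0


@dataclass(frozen=True)
class NeuronModel:
    archetype: str
    compartments: tuple[Compartment, ...]
    channel_specs: tuple[ChannelSpec, ...]
    ca_pool: CalciumPool | None = None

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def compartment_index(self, name: str) -> int:
        for i, c in enumerate(self.compartments):
            if c.name == name:
                return i
        raise KeyError(name)

    def axial_conductance_nS(self, child: int) -> float:
        """Coupling conductance between a compartment and its parent,
        from the series half-cylinder axial resistances."""
        c = self.compartments[child]
        if c.parent < 0:
            raise ValueError("root compartment has no parent coupling")
        p = self.compartments[c.parent]

        def half_res_ohm(comp: Compartment) -> float:
            area = math.pi * (comp.diameter / 2.0) ** 2  # um^2
            return comp.axial_resistivity * 1e4 * (comp.length / 2.0) / area

        return 1e9 / (half_res_ohm(c) + half_res_ohm(p))

    def without_channels(self) -> "NeuronModel":
        """Leak-only copy (all voltage-gated densities zeroed)."""
        return replace(self, channel_specs=(), ca_pool=None)

    def with_density(self, current_name: str, density: float) -> "NeuronModel":
        specs = tuple(
            replace(s, density=density) if s.current_name == current_name else s
            for s in self.channel_specs
        )
        return replace(self, channel_specs=specs)


def _read_config(archetype: str) -> dict:
    try:
        fname = _ARCHETYPE_FILES[archetype]
    except KeyError:
        raise KeyError(f"unknown archetype {archetype!r}") from None
    text = (
        importlib.resources.files("blgamma.configs").joinpath(fname).read_text()
    )
    return yaml.safe_load(text)


def load_archetype(archetype: str) -> NeuronModel:
    """Build a NeuronModel for 'PN_A', 'PN_C' or 'FSI' from its config."""
    cfg = _read_config(archetype)
    passive = cfg["passive"]
    reversals = cfg["reversals"]

    comps: list[Compartment] = []
    name_to_idx: dict[str, int] = {}
    specs: list[ChannelSpec] = []
    for entry in cfg["compartments"]:
        parent = -1 if entry["parent"] is None else name_to_idx[entry["parent"]]
        idx = len(comps)
        name_to_idx[entry["name"]] = idx
        comps.append(
            Compartment(
                name=entry["name"],
                diameter=float(entry["diameter"]),
                length=float(entry["length"]),
                parent=parent,
                specific_capacitance=float(passive["cm"]),
                axial_resistivity=float(passive["ra"]),
                specific_leak_conductance=float(entry["g_leak"]),
                leak_reversal=float(passive["e_leak"]),
            )
        )
        for cur, density in entry.get("channels", {}).items():
            density = float(density)
            if archetype == "PN_C" and cur == "I_sAHP":
                density = _PN_C_SAHP
            act, p, inact, q = chan.CHANNELS[cur]
            specs.append(
                ChannelSpec(
                    current_name=cur,
                    compartment=idx,
                    density=density,
                    reversal=float(reversals[cur]),
                    activation_gate=act,
                    p=p,
                    inactivation_gate=inact,
                    q=q,
                )
            )

    pool = None
    if cfg.get("calcium"):
        pool = CalciumPool(
            decay_time_constant=float(cfg["calcium"]["tau_ms"]),
            influx_scale=float(cfg["calcium"]["influx_scale"]),
            compartment=0,
        )
    return NeuronModel(
        archetype=archetype,
        compartments=tuple(comps),
        channel_specs=tuple(specs),
        ca_pool=pool,
    )


# ---------------------------------------------------------------------------
# Gating evaluation
# ---------------------------------------------------------------------------

def eval_gating(current_name: str, v, ca=None):
    """Return {gate_role: (x_inf, tau_ms)} for a named current.

    ``ca`` (pool units, >= 0) is required for I_sAHP and ignored otherwise.
    """
    if current_name not in chan.CHANNELS:
        raise KeyError(f"unknown channel {current_name!r}")
    act, p, inact, q = chan.CHANNELS[current_name]
    out = {}
    if act == "sahp":
        if ca is None:
            raise ValueError("I_sAHP gating requires a calcium value")
        xinf = chan.sahp_xinf(ca)
        out["activation"] = (xinf, np.full_like(np.asarray(xinf, float),
                                                chan.SAHP_TAU_MS))
        return out
    out["activation"] = chan.eval_gate(act, v)
    if inact is not None:
        out["inactivation"] = chan.eval_gate(inact, v)
    return out


# ---------------------------------------------------------------------------
# Spike metrics
# ---------------------------------------------------------------------------

def detect_spikes(t_ms: np.ndarray, v_mv: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = SPIKE_REFRACTORY_MS) -> np.ndarray:
    """Spike times from upward threshold crossings with a refractory gate."""
    v = np.asarray(v_mv)
    above = v >= threshold
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    out: list[float] = []
    for i in idx:
        if not out or t_ms[i] - out[-1] >= refractory:
            out.append(float(t_ms[i]))
    return np.asarray(out)


def adaptation_ratio(spike_times) -> tuple[float, str]:
    """Last-to-first interspike-interval ratio and firing class.

    Returns (nan, 'undefined') for fewer than 3 spikes; class is
    'adapting' iff ratio > 1.5."""
    st = np.sort(np.asarray(spike_times, dtype=float))
    if st.size < 3:
        return float("nan"), "undefined"
    isis = np.diff(st)
    ratio = float(isis[-1] / isis[0])
    return ratio, ("adapting" if ratio > ADAPTATION_CUTOFF else "continuous")


def spike_halfwidth(t_ms: np.ndarray, v_mv: np.ndarray,
                    dvdt_thresh: float = 20.0) -> float:
    """Width of the first spike at half amplitude.

    Amplitude is measured from spike threshold (first point where dV/dt
    exceeds ``dvdt_thresh`` mV/ms before the peak) to the peak; the width is
    the time spent above the threshold-to-peak midline.  Returns nan if no
    spike is present."""
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    spikes = detect_spikes(t, v)
    if spikes.size == 0:
        return float("nan")
    i_cross = int(np.searchsorted(t, spikes[0]))
    # peak of the first spike
    i_end = min(i_cross + int(3.0 / (t[1] - t[0])), t.size - 1)
    i_peak = i_cross + int(np.argmax(v[i_cross:i_end]))
    dvdt = np.gradient(v, t)
    pre = np.flatnonzero(dvdt[:i_peak] >= dvdt_thresh)
    i_thr = int(pre[0]) if pre.size else i_cross
    half = 0.5 * (v[i_thr] + v[i_peak])
    above = v >= half
    i_up = i_thr + int(np.argmax(above[i_thr:]))
    after = np.flatnonzero(~above[i_peak:])
    if after.size == 0:
        return float("nan")
    i_down = i_peak + int(after[0])

    def _interp(i_lo: int) -> float:
        if i_lo == 0 or v[i_lo] == v[i_lo - 1]:
            return t[i_lo]
        f = (half - v[i_lo - 1]) / (v[i_lo] - v[i_lo - 1])
        return t[i_lo - 1] + f * (t[i_lo] - t[i_lo - 1])

    return float(_interp(i_down) - _interp(i_up))


# ---------------------------------------------------------------------------
# Passive characterization and FSI spike width (single-cell protocols)
# ---------------------------------------------------------------------------

def measure_passive(neuron: NeuronModel, step_pA: float = -20.0,
                    settle_ms: float = 3000.0, step_ms: float = 500.0,
                    dt_ms: float = 0.05):
    """Resting potential, input resistance and membrane time constant.

    The cell is equilibrated in isolation (no synapses, no noise), then a
    small hyperpolarizing somatic step is applied.  R_in is the steady-state
    voltage deflection over the injected current; tau_m is a
    single-exponential fit of the somatic charging curve.

    Returns (V_rest mV, R_in MOhm, tau_m ms).  Raises RuntimeError if the
    resting state has not converged within 5 s.
    """
    from . import engine
    from scipy.optimize import curve_fit

    total = settle_ms + step_ms
    if settle_ms > 5000.0:
        raise ValueError("settle time beyond the 5-s convergence budget")
    res = engine.simulate_cell(
        neuron, duration_ms=total, dt_ms=dt_ms,
        i_inj=[(0, step_pA, settle_ms, settle_ms + step_ms)],
        record_stride=1,
    )
    t, v = res.time_ms, res.voltage[0]
    i_settle = int(round(settle_ms / dt_ms))
    # convergence check: drift over the final 500 ms of the settle phase
    tail = v[i_settle - int(500 / dt_ms):i_settle]
    if np.abs(tail[-1] - tail[0]) > 0.05:
        raise RuntimeError("no steady state reached before the current step")
    v_rest = float(v[i_settle - 1])
    v_ss = float(np.mean(v[-int(50 / dt_ms):]))
    r_in = (v_ss - v_rest) / step_pA * 1e3  # mV/pA -> MOhm

    # single-exponential fit of the charging onset (first 200 ms; free
    # amplitude, since slow subthreshold-channel relaxation makes the full
    # response multi-exponential)
    fit_ms = min(200.0, step_ms)
    n_fit = int(round(fit_ms / dt_ms))
    tc = t[i_settle:i_settle + n_fit] - t[i_settle]
    dv = v[i_settle:i_settle + n_fit] - v_rest

    def charging(tt, tau, amp):
        return amp * (1.0 - np.exp(-tt / tau))

    (tau_m, _amp), _ = curve_fit(charging, tc, dv, p0=[25.0, v_ss - v_rest])
    return v_rest, float(r_in), float(tau_m)


def fsi_spike_halfwidth(neuron: NeuronModel, i_inj_pA: float = 200.0,
                        duration_ms: float = 500.0, dt_ms: float = 0.05) -> float:
    """Half-amplitude width of the first spike under a somatic step."""
    from . import engine

    res = engine.simulate_cell(
        neuron, duration_ms=duration_ms + 200.0, dt_ms=dt_ms,
        i_inj=[(0, i_inj_pA, 200.0, 200.0 + duration_ms)], record_stride=1,
    )
    return spike_halfwidth(res.time_ms, res.voltage[0])


# ---------------------------------------------------------------------------
# Reference ODE solution (independent of the fixed-step kernels)
# ---------------------------------------------------------------------------

def reference_solution(neuron: NeuronModel, duration_ms: float,
                       i_inj=(), v0: float | None = None,
                       rtol: float = 1e-8, atol: float = 1e-8,
                       max_step: float = 0.25, t_eval=None):
    """High-accuracy solution of the single-cell ODE system via scipy.

    ``i_inj`` is a list of (compartment, amplitude_pA, t_on, t_off).
    Returns (t, V[ncomp, nt]).  Used as an oracle for the production
    integrator; shares no integration code with it.
    """
    from scipy.integrate import solve_ivp

    ncomp = neuron.n_compartments
    comps = neuron.compartments
    cm = np.array([c.capacitance_pF for c in comps])
    gl = np.array([c.leak_conductance_nS for c in comps])
    el = np.array([c.leak_reversal for c in comps])
    parent = np.array([c.parent for c in comps])
    g_ax = np.array(
        [neuron.axial_conductance_nS(i) if comps[i].parent >= 0 else 0.0
         for i in range(ncomp)]
    )
    specs = [s for s in neuron.channel_specs]
    areas = np.array([comps[s.compartment].area_um2 for s in specs])
    gbar = np.array([s.conductance_nS(a) for s, a in zip(specs, areas)])
    erev = np.array([s.reversal for s in specs])

    # state layout: V (ncomp) | per-spec activation | per-spec inactivation
    n_act = len(specs)
    has_h = np.array([s.inactivation_gate is not None for s in specs])
    h_index = np.cumsum(has_h) - 1
    n_h = int(has_h.sum())
    has_ca = neuron.ca_pool is not None

    v_init = v0 if v0 is not None else comps[0].leak_reversal

    def gate_inf_tau(s: ChannelSpec, role: str, v, ca):
        g = eval_gating(s.current_name, v, ca=ca)
        return g[role]

    y0 = np.empty(ncomp + n_act + n_h + (1 if has_ca else 0))
    y0[:ncomp] = v_init
    ca0 = chan.CA_FLOOR
    for k, s in enumerate(specs):
        xinf, _ = gate_inf_tau(s, "activation", v_init, ca0)
        y0[ncomp + k] = float(xinf)
        if has_h[k]:
            hinf, _ = gate_inf_tau(s, "inactivation", v_init, ca0)
            y0[ncomp + n_act + h_index[k]] = float(hinf)
    if has_ca:
        y0[-1] = ca0

    spec_comp = np.array([s.compartment for s in specs])
    is_sahp = np.array([s.current_name == "I_sAHP" for s in specs])
    is_ca_cur = np.array([s.current_name == "I_Ca" for s in specs])
    p_exp = np.array([s.p for s in specs], dtype=float)
    q_exp = np.array([s.q for s in specs], dtype=float)

    def rhs(t, y):
        v = y[:ncomp]
        m = np.clip(y[ncomp:ncomp + n_act], 0.0, 1.0)
        h = np.clip(y[ncomp + n_act:ncomp + n_act + n_h], 0.0, 1.0)
        ca = max(y[-1], 0.0) if has_ca else 0.0

        i_comp = gl * (v - el)  # pA, outward positive
        dy = np.zeros_like(y)
        g_open = gbar * m ** p_exp
        if n_h:
            g_open = g_open * np.where(has_h, h[h_index] ** q_exp, 1.0)
        i_spec = g_open * (v[spec_comp] - erev)
        np.add.at(i_comp, spec_comp, i_spec)

        # axial
        for i in range(ncomp):
            p = parent[i]
            if p >= 0:
                ia = g_ax[i] * (v[i] - v[p])
                i_comp[i] += ia
                i_comp[p] -= ia
        for (comp, amp, t_on, t_off) in i_inj:
            if t_on <= t < t_off:
                i_comp[comp] -= amp
        dy[:ncomp] = -i_comp / cm

        for k, s in enumerate(specs):
            xinf, tau = gate_inf_tau(s, "activation", v[spec_comp[k]], ca)
            dy[ncomp + k] = (float(xinf) - m[k]) / float(tau)
            if has_h[k]:
                hinf, htau = gate_inf_tau(s, "inactivation", v[spec_comp[k]], ca)
                dy[ncomp + n_act + h_index[k]] = (float(hinf) - h[h_index[k]]) / float(htau)

        if has_ca:
            pool = neuron.ca_pool
            k_ca = np.flatnonzero(is_ca_cur & (spec_comp == pool.compartment))
            i_ca_density = 0.0  # mA/cm^2
            for k in k_ca:
                area = comps[spec_comp[k]].area_um2
                i_ca_density += i_spec[k] / (area * 10.0)  # pA / um^2 -> mA/cm^2
            dy[-1] = -pool.influx_scale * i_ca_density - ca / pool.decay_time_constant
            if y[-1] <= 0.0 and dy[-1] < 0.0:
                dy[-1] = 0.0
        return dy

    sol = solve_ivp(rhs, (0.0, duration_ms), y0, method="LSODA",
                    rtol=rtol, atol=atol, max_step=max_step, t_eval=t_eval,
                    dense_output=False)
    if not sol.success:
        raise RuntimeError(f"reference solver failed: {sol.message}")
    return sol.t, sol.y[:ncomp]
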