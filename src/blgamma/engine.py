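"""Network state assembly and fixed-step simulation driver.

Builds flat state arrays from a placement + connectivity graph (or from a
single neuron for virtual-electrode protocols) and advances them with the
compiled kernels in :mod:`blgamma._kernels` at a fixed dt of 50 us.
Recording follows the model's conventions: somatic voltage at 1-ms
resolution by default, per-compartment membrane currents (for the LFP
forward model) averaged over 1-ms windows, spike times at dt resolution.

Runs are deterministic under (model, seed): connection weights and delays
are drawn from seeded generators at build time and the background-noise
kernel uses counter-based per-cell streams derived from the master seed by
stable hashing of the cell index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from . import cells as cell_mod
from . import drive as drive_mod
from . import synapses as syn_mod
from .cells import NeuronModel, load_archetype
from .network import ConnectivityGraph, Placement

__all__ = [
    "TraceSet",
    "NetworkSimulation",
    "simulate_cell",
    "simulate_pair_with_gap",
    "calibrate_background",
    "DT_MS",
]

DT_MS = 0.05
STEPS_PER_MS = int(round(1.0 / DT_MS))

_TABLE_V_MIN = -120.0
_TABLE_V_MAX = 60.0
_TABLE_DV = 0.02

_EXC_TARGET = {"PN_A": "a-dend-prox", "PN_C": "a-dend-prox", "FSI": "fsi-dend"}
_INH_TARGET = {"PN_A": "soma", "PN_C": "soma", "FSI": "soma"}

_CLASS_OF_EDGE = {
    "PN_PN": "PN_PN",
    "PN_FSI": "PN_FSI",
    "FSI_PN": "FSI_PN",
    "FSI_FSI": "FSI_FSI",
    "AFF_PN": "AFF_PN",
    "AFF_FSI": "AFF_FSI",
}

_table_cache: dict = {}


def _gate_tables(dt: float):
    """(xinf, exp(-dt/tau)) lookup tables on a shared voltage grid."""
    key = round(dt, 9)
    if key not in _table_cache:
        from . import channels as chan

        grid = np.arange(_TABLE_V_MIN, _TABLE_V_MAX + _TABLE_DV / 2, _TABLE_DV)
        ngates = len(chan.GATES)
        xinf = np.empty((ngates, grid.size))
        texp = np.empty((ngates, grid.size))
        for name, gid in chan.GATE_IDS.items():
            xi, tau = chan.eval_gate(name, grid)
            xinf[gid] = xi
            texp[gid] = np.exp(-dt / np.maximum(tau, 1e-6))
        mg = syn_mod.mg_block(grid)
        _table_cache[key] = (xinf, texp, mg)
    return _table_cache[key]


@dataclass
class TraceSet:
    """Recorded series of one simulation run."""

    dt_ms: float
    rec_stride: int
    voltage: np.ndarray  # (n_rows, n_rec_comps)
    rec_comps: np.ndarray  # global compartment indices of the columns
    spikes: pd.DataFrame  # columns cell_id, time_ms
    comp_table: pd.DataFrame  # comp, cell, name (all compartments)
    imem: np.ndarray | None = None  # (n_ms, ncomp) pA, 1-ms means
    clamp_current: np.ndarray | None = None  # (n_steps,) pA at dt
    duration_ms: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.voltage.shape[0]) * self.dt_ms * self.rec_stride

    @property
    def imem_time_ms(self) -> np.ndarray:
        n = 0 if self.imem is None else self.imem.shape[0]
        return np.arange(n) + 0.5

    def spike_trains(self, n_cells: int) -> list[np.ndarray]:
        out = [np.empty(0)] * n_cells
        for cid, grp in self.spikes.groupby("cell_id"):
            out[int(cid)] = grp["time_ms"].to_numpy()
        return out

    def save(self, path):
        np.savez_compressed(
            path,
            dt_ms=self.dt_ms,
            rec_stride=self.rec_stride,
            voltage=self.voltage,
            rec_comps=self.rec_comps,
            spike_cell=self.spikes["cell_id"].to_numpy(),
            spike_t=self.spikes["time_ms"].to_numpy(),
            comp_cell=self.comp_table["cell"].to_numpy(),
            comp_name=self.comp_table["name"].to_numpy().astype("U16"),
            imem=self.imem if self.imem is not None else np.empty((0, 0)),
            duration_ms=self.duration_ms,
        )

    @classmethod
    def load(cls, path) -> "TraceSet":
        z = np.load(path, allow_pickle=False)
        imem = z["imem"]
        return cls(
            dt_ms=float(z["dt_ms"]),
            rec_stride=int(z["rec_stride"]),
            voltage=z["voltage"],
            rec_comps=z["rec_comps"],
            spikes=pd.DataFrame(
                {"cell_id": z["spike_cell"], "time_ms": z["spike_t"]}
            ),
            comp_table=pd.DataFrame(
                {
                    "comp": np.arange(len(z["comp_cell"])),
                    "cell": z["comp_cell"],
                    "name": z["comp_name"],
                }
            ),
            imem=None if imem.size == 0 else imem,
            duration_ms=float(z["duration_ms"]),
        )


class _StateBuilder:
    """Accumulates flat kernel arrays."""

    def __init__(self, dt: float):
        self.dt = dt
        # compartments
        self.parent: list[int] = []
        self.g_ax: list[float] = []
        self.cm: list[float] = []
        self.g_leak: list[float] = []
        self.e_leak: list[float] = []
        self.comp_cell: list[int] = []
        self.comp_name: list[str] = []
        # channels
        self.ch = {k: [] for k in
                   ("comp", "gate_a", "p", "gate_h", "q", "g", "e",
                    "sahp", "capool", "is_ca")}
        # pools
        self.ca_tau: list[float] = []
        self.ca_k: list[float] = []
        self.ca_comp: list[int] = []
        self.ca_factor: list[float] = []
        # synapses
        self.syn = {k: [] for k in
                    ("comp", "g", "e", "alpha", "beta", "is_nmda", "stp",
                     "pre_cell", "delay_steps", "aff_src")}
        self.stp = {k: [] for k in ("dmin", "c1", "c2", "tau1", "tau2")}
        # cells
        self.soma_comp: list[int] = []
        self.cell_archetype: list[str] = []
        self.gaps: list[tuple[int, int, float]] = []
        self._local_index: list[dict] = []

    def add_cell(self, neuron: NeuronModel) -> int:
        from . import channels as chan

        cell_id = len(self.soma_comp)
        base = len(self.parent)
        local = {}
        for i, comp in enumerate(neuron.compartments):
            local[comp.name] = base + i
            self.parent.append(-1 if comp.parent < 0 else base + comp.parent)
            self.g_ax.append(
                neuron.axial_conductance_nS(i) if comp.parent >= 0 else 0.0
            )
            self.cm.append(comp.capacitance_pF)
            self.g_leak.append(comp.leak_conductance_nS)
            self.e_leak.append(comp.leak_reversal)
            self.comp_cell.append(cell_id)
            self.comp_name.append(comp.name)
        self._local_index.append(local)
        self.soma_comp.append(base)
        self.cell_archetype.append(neuron.archetype)

        pool_idx = -1
        if neuron.ca_pool is not None:
            pool_idx = len(self.ca_tau)
            pc = base + neuron.ca_pool.compartment
            area = neuron.compartments[neuron.ca_pool.compartment].area_um2
            self.ca_tau.append(neuron.ca_pool.decay_time_constant)
            self.ca_k.append(neuron.ca_pool.influx_scale)
            self.ca_comp.append(pc)
            self.ca_factor.append(1.0 / (area * 10.0))

        for spec in neuron.channel_specs:
            comp = neuron.compartments[spec.compartment]
            is_sahp = spec.current_name == "I_sAHP"
            is_ca = spec.current_name == "I_Ca" and spec.compartment == 0
            self.ch["comp"].append(base + spec.compartment)
            self.ch["gate_a"].append(
                -1 if is_sahp else chan.GATE_IDS[spec.activation_gate]
            )
            self.ch["p"].append(spec.p)
            self.ch["gate_h"].append(
                -1 if spec.inactivation_gate is None
                else chan.GATE_IDS[spec.inactivation_gate]
            )
            self.ch["q"].append(spec.q)
            self.ch["g"].append(spec.conductance_nS(comp.area_um2))
            self.ch["e"].append(spec.reversal)
            self.ch["sahp"].append(is_sahp)
            self.ch["capool"].append(pool_idx if (is_sahp or is_ca) else -1)
            self.ch["is_ca"].append(is_ca)
        return cell_id

    def comp_of(self, cell_id: int, name: str) -> int:
        return self._local_index[cell_id][name]

    def add_receptor(self, spec: syn_mod.ReceptorSpec, comp: int, weight: float,
                     stp_idx: int, pre_cell: int, delay_steps: int,
                     aff_src: int = -1) -> int:
        s = self.syn
        s["comp"].append(comp)
        s["g"].append(spec.g_max * weight)
        s["e"].append(spec.reversal)
        s["alpha"].append(spec.alpha)
        s["beta"].append(spec.beta)
        s["is_nmda"].append(spec.kind == "NMDA")
        s["stp"].append(stp_idx)
        s["pre_cell"].append(pre_cell)
        s["delay_steps"].append(delay_steps)
        s["aff_src"].append(aff_src)
        return len(s["comp"]) - 1

    def add_stp(self, spec: syn_mod.StpSpec) -> int:
        self.stp["dmin"].append(spec.d_min)
        self.stp["c1"].append(spec.d1)
        self.stp["c2"].append(spec.d2)
        self.stp["tau1"].append(spec.tau_d1)
        self.stp["tau2"].append(spec.tau_d2)
        return len(self.stp["dmin"]) - 1


class NetworkSimulation:
    """A runnable simulation built from placement + wiring (or manually)."""

    def __init__(self, placement: Placement | None, graph: ConnectivityGraph | None,
                 seed: int = 0, dt_ms: float = DT_MS,
                 afferent_trains: list | None = None,
                 synapse_classes: dict | None = None,
                 with_background: bool = True,
                 background_scale: dict | None = None,
                 weight_scale: dict | None = None,
                 v_init: float = -70.0):
        self.dt = dt_ms
        self.seed = int(seed)
        self.v_init = v_init
        self.builder = _StateBuilder(dt_ms)
        self.placement = placement
        self.graph = graph
        self.with_background = with_background
        self.background_scale = dict(background_scale or {})
        # per-edge-type multiplier on synaptic weights (reduced-scale
        # in-degree compensation)
        self.weight_scale = dict(weight_scale or {})
        self.models: dict[str, NeuronModel] = {}
        self.afferent_trains = afferent_trains or []
        self._probe_events: list = []
        self._aff_edges: list[tuple[int, int, int]] = []
        if placement is not None:
            classes = synapse_classes or syn_mod.load_synapse_classes()
            self._build_from_graph(placement, graph, classes)

    # -- manual construction hooks (single-cell / few-cell protocols) -------

    def add_cell(self, neuron: NeuronModel) -> int:
        return self.builder.add_cell(neuron)

    def add_probe_synapse(self, cell_id: int, comp_name: str,
                          spec: syn_mod.ReceptorSpec, weight: float,
                          event_times_ms, stp_spec: syn_mod.StpSpec | None = None):
        """Attach a synapse driven by an explicit presynaptic event list."""
        b = self.builder
        stp_idx = b.add_stp(stp_spec) if stp_spec is not None else -1
        comp = b.comp_of(cell_id, comp_name)
        idx = b.add_receptor(spec, comp, weight, stp_idx, -1, 0, aff_src=-2)
        self._probe_events.append((idx, np.asarray(event_times_ms, float)))
        return idx

    def set_afferent_trains(self, trains):
        self.afferent_trains = trains

    def add_gap_junction(self, cell_a: int, cell_b: int, g_nS: float,
                         comp_name: str = "soma"):
        b = self.builder
        b.gaps.append((b.comp_of(cell_a, comp_name), b.comp_of(cell_b, comp_name),
                       g_nS))

    # -- graph assembly ------------------------------------------------------

    def _model(self, archetype: str) -> NeuronModel:
        if archetype not in self.models:
            self.models[archetype] = load_archetype(archetype)
        return self.models[archetype]

    def _build_from_graph(self, placement, graph, classes):
        b = self.builder
        rng = np.random.default_rng(self.seed + 101)
        meta = classes["_meta"]
        for arch in placement.archetypes:
            b.add_cell(self._model(arch))

        edges = graph.edges
        etype = edges["type"].to_numpy()
        src = edges["src"].to_numpy()
        dst = edges["dst"].to_numpy()
        w_col = edges["weight"].to_numpy(float)
        wn_col = edges["weight_nmda"].to_numpy(float)
        delays = edges["delay_ms"].to_numpy(float)
        delay_steps = np.round(delays / self.dt).astype(np.int64)

        max_chem_delay = delays[etype != "GAP"].max() if len(edges) else 0.0
        if max_chem_delay >= cell_mod.SPIKE_REFRACTORY_MS:
            raise ValueError(
                "conduction delay exceeds the refractory period; the single "
                "in-flight event queue per synapse would drop events"
            )

        gap_cc = meta["gap_coupling_coefficient"]
        gap_g = _default_gap_conductance(gap_cc)

        for row in range(len(edges)):
            et = etype[row]
            if et == "GAP":
                b.gaps.append(
                    (b.comp_of(src[row], "soma"), b.comp_of(dst[row], "soma"), gap_g)
                )
                continue
            cls = classes[_CLASS_OF_EDGE[et]]
            receptors = cls["receptors"]
            stp_spec = cls["stp"]
            is_aff = et.startswith("AFF_")
            post_arch = placement.archetypes[dst[row]]
            exc = "AMPA" in receptors
            target = _EXC_TARGET[post_arch] if exc else _INH_TARGET[post_arch]
            comp = b.comp_of(dst[row], target)
            pre_cell = -1 if is_aff else src[row]
            main = receptors["AMPA" if exc else "GABA_A"]
            wscale = self.weight_scale.get(et, 1.0)
            w = w_col[row]
            if not np.isfinite(w):
                w = float(syn_mod.draw_weights(main, 1, rng,
                                               meta["spread_mode"],
                                               meta["distribution"])[0])
            w *= wscale
            stp_idx = b.add_stp(stp_spec) if stp_spec is not None else -1
            s0 = b.add_receptor(main, comp, w, stp_idx, pre_cell,
                                int(delay_steps[row]),
                                aff_src=src[row] if is_aff else -1)
            if is_aff:
                self._aff_edges.append((src[row], s0, int(delay_steps[row])))
            if "NMDA" in receptors:
                nm = receptors["NMDA"]
                wn = wn_col[row]
                if not np.isfinite(wn):
                    wn = float(syn_mod.draw_weights(nm, 1, rng,
                                                    meta["spread_mode"],
                                                    meta["distribution"])[0])
                wn *= wscale
                s1 = b.add_receptor(nm, comp, wn, -1, pre_cell,
                                    int(delay_steps[row]),
                                    aff_src=src[row] if is_aff else -1)
                if is_aff:
                    self._aff_edges.append((src[row], s1, int(delay_steps[row])))

    # -- array finalization --------------------------------------------------

    def _finalize(self, duration_ms, rec_comps, record_imem, vc, i_inj,
                  rec_stride):
        b = self.builder
        dt = self.dt
        n_steps = int(round(duration_ms / dt))
        ncomp = len(b.parent)
        ncell = len(b.soma_comp)

        arr = {}
        arr["parent"] = np.asarray(b.parent, np.int64)
        arr["g_ax"] = np.asarray(b.g_ax, float)
        arr["cm"] = np.asarray(b.cm, float)
        arr["g_leak"] = np.asarray(b.g_leak, float)
        arr["e_leak"] = np.asarray(b.e_leak, float)
        arr["v"] = np.full(ncomp, self.v_init, float)

        xinf_tab, exp_tab, mg_tab = _gate_tables(dt)
        # channel states initialized at steady state for v_init
        ch_m = np.empty(len(b.ch["comp"]))
        ch_h = np.ones_like(ch_m)
        ti = int(round((self.v_init - _TABLE_V_MIN) / _TABLE_DV))
        for k in range(ch_m.size):
            if b.ch["sahp"][k]:
                from . import channels as chan

                ch_m[k] = float(chan.sahp_xinf(chan.CA_FLOOR))
            else:
                ch_m[k] = xinf_tab[b.ch["gate_a"][k], ti]
                if b.ch["gate_h"][k] >= 0:
                    ch_h[k] = xinf_tab[b.ch["gate_h"][k], ti]

        nsyn = len(b.syn["comp"])
        alpha = np.asarray(b.syn["alpha"], float)
        beta = np.asarray(b.syn["beta"], float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rinf = np.where(alpha + beta > 0, alpha / (alpha + beta), 0.0)

        # outgoing CSR over receptor instances
        pre = np.asarray(b.syn["pre_cell"], np.int64) if nsyn else np.empty(0, np.int64)
        order = np.argsort(pre, kind="stable")
        out_syn = order[pre[order] >= 0].astype(np.int64)
        out_ptr = np.zeros(ncell + 1, np.int64)
        if out_syn.size:
            np.add.at(out_ptr[1:], pre[out_syn], 1)
        out_ptr = np.cumsum(out_ptr)
        out_delay = (
            np.asarray(b.syn["delay_steps"], np.int64)[out_syn]
            if out_syn.size else np.empty(0, np.int64)
        )

        # afferent schedule
        aff_steps: list[int] = []
        aff_syn: list[int] = []
        for (aid, sidx, dsteps) in getattr(self, "_aff_edges", []):
            if aid < len(self.afferent_trains):
                tr = np.asarray(self.afferent_trains[aid], float)
                for ts in tr:
                    aff_steps.append(int(round(ts / dt)) + dsteps)
                    aff_syn.append(sidx)
        for (sidx, times) in getattr(self, "_probe_events", []):
            for ts in times:
                aff_steps.append(int(round(ts / dt)))
                aff_syn.append(sidx)
        if aff_steps:
            aff_steps = np.asarray(aff_steps, np.int64)
            aff_syn_a = np.asarray(aff_syn, np.int64)
            o = np.argsort(aff_steps, kind="stable")
            arr["aff_step"], arr["aff_syn"] = aff_steps[o], aff_syn_a[o]
        else:
            arr["aff_step"] = np.empty(0, np.int64)
            arr["aff_syn"] = np.empty(0, np.int64)

        # OU background
        ou_ge0 = np.zeros(ncell)
        ou_gi0 = np.zeros(ncell)
        ou_ae = np.zeros(ncell)
        ou_ai = np.zeros(ncell)
        ou_de = np.ones(ncell)
        ou_di = np.ones(ncell)
        ou_on = np.zeros(ncell, np.bool_)
        if self.with_background:
            for cidx, arch in enumerate(b.cell_archetype):
                kind = "FSI" if arch == "FSI" else "PN"
                e_spec, i_spec = drive_mod.OU_SPECS[kind]
                scale_e = self.background_scale.get(kind, {}).get("e", 1.0)
                scale_i = self.background_scale.get(kind, {}).get("i", 1.0)
                ou_ge0[cidx] = e_spec.g0 * scale_e
                ou_gi0[cidx] = i_spec.g0 * scale_i
                ou_ae[cidx] = drive_mod.ou_amplitude(
                    drive_mod.OuSpec(e_spec.g0 * scale_e, e_spec.sd * scale_e,
                                     e_spec.tau, e_spec.reversal), dt)
                ou_ai[cidx] = drive_mod.ou_amplitude(
                    drive_mod.OuSpec(i_spec.g0 * scale_i, i_spec.sd * scale_i,
                                     i_spec.tau, i_spec.reversal), dt)
                ou_de[cidx] = math.exp(-dt / e_spec.tau)
                ou_di[cidx] = math.exp(-dt / i_spec.tau)
                ou_on[cidx] = True

        inj = i_inj or []
        arr["inj_comp"] = np.asarray(
            [b.comp_of(c, "soma") if isinstance(c, int) else c
             for (c, *_rest) in inj], np.int64
        ) if inj else np.empty(0, np.int64)
        arr["inj_amp"] = np.asarray([x[1] for x in inj], float)
        arr["inj_on"] = np.asarray([x[2] for x in inj], float)
        arr["inj_off"] = np.asarray([x[3] for x in inj], float)

        gaps = b.gaps
        arr["gap_a"] = np.asarray([g[0] for g in gaps], np.int64)
        arr["gap_b"] = np.asarray([g[1] for g in gaps], np.int64)
        arr["gap_g"] = np.asarray([g[2] for g in gaps], float)

        vc_comp, vc_hold = -1, 0.0
        if vc is not None:
            vc_cell, vc_hold = vc
            vc_comp = b.comp_of(vc_cell, "soma")
            if not (-100.0 <= vc_hold <= 20.0):
                raise ValueError("clamp holding potential out of range")

        n_ms = n_steps // STEPS_PER_MS
        rec_rows = (n_steps + rec_stride - 1) // rec_stride

        est_rate = 120.0  # Hz, generous spike-buffer headroom
        max_spikes = int(ncell * (duration_ms / 1000.0) * est_rate) + 10000

        state = dict(
            n_steps=n_steps,
            dt=dt,
            v=arr["v"],
            parent=arr["parent"],
            g_ax=arr["g_ax"],
            cm=arr["cm"],
            g_leak=arr["g_leak"],
            e_leak=arr["e_leak"],
            tab_xinf=xinf_tab,
            tab_exp=exp_tab,
            v_min=_TABLE_V_MIN,
            dv_inv=1.0 / _TABLE_DV,
            mg_table=mg_tab,
            ch_comp=np.asarray(b.ch["comp"], np.int64),
            ch_gate_a=np.asarray(b.ch["gate_a"], np.int64),
            ch_p=np.asarray(b.ch["p"], np.int64),
            ch_gate_h=np.asarray(b.ch["gate_h"], np.int64),
            ch_q=np.asarray(b.ch["q"], np.int64),
            ch_g=np.asarray(b.ch["g"], float),
            ch_e=np.asarray(b.ch["e"], float),
            ch_m=ch_m,
            ch_h=ch_h,
            ch_sahp=np.asarray(b.ch["sahp"], np.bool_),
            ch_capool=np.asarray(b.ch["capool"], np.int64),
            ch_is_ca=np.asarray(b.ch["is_ca"], np.bool_),
            sahp_exp=math.exp(-dt / 48.0),
            ca_val=np.full(len(b.ca_tau), 1e-10),
            ca_decay=np.exp(-dt / np.asarray(b.ca_tau, float))
            if b.ca_tau else np.empty(0),
            ca_k=np.asarray(b.ca_k, float),
            ca_comp=np.asarray(b.ca_comp, np.int64),
            ca_factor=np.asarray(b.ca_factor, float),
            syn_comp=np.asarray(b.syn["comp"], np.int64),
            syn_g=np.asarray(b.syn["g"], float),
            syn_e=np.asarray(b.syn["e"], float),
            syn_rinf=rinf,
            syn_exp_on=np.exp(-(alpha + beta) * dt),
            syn_exp_off=np.exp(-beta * dt),
            syn_is_nmda=np.asarray(b.syn["is_nmda"], np.bool_),
            syn_r=np.zeros(nsyn),
            syn_on_until=np.full(nsyn, -np.inf),
            syn_pending_step=np.full(nsyn, K.I64_NONE, np.int64),
            syn_stp=np.asarray(b.syn["stp"], np.int64),
            pulse_ms=syn_mod.TRANSMITTER_PULSE_MS,
            stp_d1=np.ones(len(b.stp["dmin"])),
            stp_d2=np.ones(len(b.stp["dmin"])),
            stp_dmin=np.asarray(b.stp["dmin"], float),
            stp_c1=np.asarray(b.stp["c1"], float),
            stp_c2=np.asarray(b.stp["c2"], float),
            stp_e1=np.exp(-dt / np.asarray(b.stp["tau1"], float))
            if b.stp["dmin"] else np.empty(0),
            stp_e2=np.exp(-dt / np.asarray(b.stp["tau2"], float))
            if b.stp["dmin"] else np.empty(0),
            out_ptr=out_ptr,
            out_syn=out_syn,
            out_delay_steps=out_delay,
            aff_step=arr["aff_step"],
            aff_syn=arr["aff_syn"],
            soma_comp=np.asarray(b.soma_comp, np.int64),
            ou_ge=ou_ge0.copy(),
            ou_gi=ou_gi0.copy(),
            ou_ge0=ou_ge0,
            ou_gi0=ou_gi0,
            ou_ae=ou_ae,
            ou_ai=ou_ai,
            ou_de=ou_de,
            ou_di=ou_di,
            ou_on=ou_on,
            noise_seed=np.uint64(self.seed),
            inj_comp=arr["inj_comp"],
            inj_amp=arr["inj_amp"],
            inj_on=arr["inj_on"],
            inj_off=arr["inj_off"],
            gap_a=arr["gap_a"],
            gap_b=arr["gap_b"],
            gap_g=arr["gap_g"],
            vc_comp=vc_comp,
            vc_hold=vc_hold,
            vc_out=np.zeros(n_steps if vc_comp >= 0 else 0),
            spike_thresh=cell_mod.SPIKE_THRESHOLD_MV,
            refractory_ms=cell_mod.SPIKE_REFRACTORY_MS,
            last_spike=np.full(ncell, -1e9),
            spike_cell=np.zeros(max_spikes, np.int64),
            spike_t=np.zeros(max_spikes),
            n_spikes_io=np.zeros(1, np.int64),
            rec_stride=rec_stride,
            rec_comp=rec_comps,
            v_out=np.zeros((rec_rows, rec_comps.size)),
            steps_per_ms=STEPS_PER_MS,
            imem_on=record_imem,
            imem_out=np.zeros((n_ms if record_imem else 0, ncomp)),
        )
        return state

    def run(self, duration_ms: float, seed: int | None = None,
            record_cells=None, record_comps=None, record_imem: bool = False,
            vc=None, i_inj=None, rec_stride: int = STEPS_PER_MS) -> TraceSet:
        """Advance the network for ``duration_ms`` and return recordings.

        ``record_cells``: cell ids whose somatic V is stored (default all);
        ``record_comps``: explicit global compartment indices (overrides);
        ``vc``: (cell_id, hold_mV) somatic voltage clamp;
        ``i_inj``: list of (cell_id, amp_pA, t_on_ms, t_off_ms).
        """
        if seed is not None:
            self.seed = int(seed)
        b = self.builder
        if duration_ms < 0 or abs(
            round(duration_ms / self.dt) * self.dt - duration_ms
        ) > 1e-9:
            raise ValueError("duration must be a non-negative multiple of dt")
        if record_comps is not None:
            rec_comps = np.asarray(record_comps, np.int64)
        else:
            cells_sel = (
                range(len(b.soma_comp)) if record_cells is None else record_cells
            )
            rec_comps = np.asarray([b.soma_comp[c] for c in cells_sel], np.int64)
        if np.any(rec_comps >= len(b.parent)):
            raise ValueError("recorder attached to nonexistent compartment")

        state = self._finalize(duration_ms, rec_comps, record_imem, vc,
                               i_inj, rec_stride)
        comp_table = pd.DataFrame(
            {
                "comp": np.arange(len(b.parent)),
                "cell": b.comp_cell,
                "name": b.comp_name,
            }
        )
        if state["n_steps"] > 0:
            status, bad = K.run_steps(
                state["n_steps"], state["dt"],
                state["v"], state["parent"], state["g_ax"], state["cm"],
                state["g_leak"], state["e_leak"],
                state["tab_xinf"], state["tab_exp"], state["v_min"],
                state["dv_inv"], state["mg_table"],
                state["ch_comp"], state["ch_gate_a"], state["ch_p"],
                state["ch_gate_h"], state["ch_q"], state["ch_g"], state["ch_e"],
                state["ch_m"], state["ch_h"], state["ch_sahp"],
                state["ch_capool"], state["ch_is_ca"],
                state["sahp_exp"], state["ca_val"], state["ca_decay"],
                state["ca_k"], state["ca_comp"], state["ca_factor"],
                state["syn_comp"], state["syn_g"], state["syn_e"],
                state["syn_rinf"], state["syn_exp_on"], state["syn_exp_off"],
                state["syn_is_nmda"], state["syn_r"], state["syn_on_until"],
                state["syn_pending_step"], state["syn_stp"], state["pulse_ms"],
                state["stp_d1"], state["stp_d2"], state["stp_dmin"],
                state["stp_c1"], state["stp_c2"], state["stp_e1"], state["stp_e2"],
                state["out_ptr"], state["out_syn"], state["out_delay_steps"],
                state["aff_step"], state["aff_syn"],
                state["soma_comp"], state["ou_ge"], state["ou_gi"],
                state["ou_ge0"], state["ou_gi0"], state["ou_ae"], state["ou_ai"],
                state["ou_de"], state["ou_di"], state["ou_on"],
                state["noise_seed"],
                state["inj_comp"], state["inj_amp"], state["inj_on"],
                state["inj_off"],
                state["gap_a"], state["gap_b"], state["gap_g"],
                state["vc_comp"], state["vc_hold"], state["vc_out"],
                state["spike_thresh"], state["refractory_ms"],
                state["last_spike"], state["spike_cell"], state["spike_t"],
                state["n_spikes_io"],
                state["rec_stride"], state["rec_comp"], state["v_out"],
                state["steps_per_ms"], state["imem_on"], state["imem_out"],
            )
            if status == K.ERR_NONFINITE:
                raise FloatingPointError(
                    f"non-finite somatic voltage in cell {bad}"
                )
            if status == K.ERR_SPIKE_OVERFLOW:
                raise RuntimeError(f"spike buffer overflow at cell {bad}")

        nsp = int(state["n_spikes_io"][0])
        spikes = pd.DataFrame(
            {
                "cell_id": state["spike_cell"][:nsp],
                "time_ms": state["spike_t"][:nsp],
            }
        )
        return TraceSet(
            dt_ms=self.dt,
            rec_stride=rec_stride,
            voltage=state["v_out"],
            rec_comps=rec_comps,
            spikes=spikes,
            comp_table=comp_table,
            imem=state["imem_out"] if record_imem else None,
            clamp_current=state["vc_out"] if vc is not None else None,
            duration_ms=duration_ms,
            meta={"seed": self.seed, "dt_ms": self.dt},
        )


def _default_gap_conductance(target_cc: float) -> float:
    """Gap conductance for the configured coupling coefficient (cached
    calibration on the two-cell virtual experiment)."""
    key = round(target_cc, 6)
    if key not in _gap_cache:
        _gap_cache[key] = syn_mod.calibrate_gap_conductance(
            load_archetype("FSI"), target_cc
        )
    return _gap_cache[key]


_gap_cache: dict = {}


# ---------------------------------------------------------------------------
# Single-cell / pair protocols
# ---------------------------------------------------------------------------

def _single(neuron: NeuronModel, v_init: float) -> NetworkSimulation:
    sim = NetworkSimulation(None, None, seed=0, with_background=False,
                            v_init=v_init)
    sim._probe_events = []
    sim.add_cell(neuron)
    return sim


def simulate_cell(neuron: NeuronModel, duration_ms: float, dt_ms: float = DT_MS,
                  i_inj=None, record_stride: int = 1, vc=None,
                  synapses=None, v_init: float = -70.0,
                  record_imem: bool = False) -> "SingleCellResult":
    """Simulate one isolated neuron (no noise, no network).

    ``i_inj``: list of (compartment_index_or_0, amp_pA, t_on, t_off) applied
    to the soma; ``synapses``: list of (ReceptorSpec, comp_name, weight,
    StpSpec|None, event_times_ms) probe synapses; ``vc``: hold_mV somatic
    voltage clamp.
    """
    sim = _single(neuron, v_init)
    if synapses:
        for (spec, comp_name, w, stp_spec, events) in synapses:
            sim.add_probe_synapse(0, comp_name, spec, w, events, stp_spec)
    inj = [(0, amp, on, off) for (_c, amp, on, off) in (i_inj or [])]
    ts = sim.run(duration_ms, record_comps=np.arange(neuron.n_compartments),
                 record_imem=record_imem, vc=(0, vc) if vc is not None else None,
                 i_inj=inj, rec_stride=record_stride)
    return SingleCellResult(ts)


@dataclass
class SingleCellResult:
    traces: TraceSet

    @property
    def time_ms(self):
        return self.traces.time_ms

    @property
    def voltage(self):
        return self.traces.voltage.T  # (ncomp, nt)

    @property
    def spike_times(self):
        return self.traces.spikes["time_ms"].to_numpy()

    @property
    def clamp_current(self):
        return self.traces.clamp_current

    @property
    def imem(self):
        return self.traces.imem


def simulate_pair_with_gap(fsi: NeuronModel, g_nS: float, step_pA: float = -50.0,
                           settle_ms: float = 1500.0, step_ms: float = 500.0) -> float:
    """Two resting FSIs coupled at the soma; returns steady dV_B/dV_A."""
    sim = _single(fsi, v_init=-70.0)
    sim.add_cell(fsi)
    sim.add_gap_junction(0, 1, g_nS)
    total = settle_ms + step_ms
    ts = sim.run(total, i_inj=[(0, step_pA, settle_ms, total)], rec_stride=20)
    t = ts.time_ms
    v = ts.voltage  # (rows, 2 somata)
    pre = (t > settle_ms - 100.0) & (t < settle_ms)
    post = t > total - 50.0
    dva = v[post, 0].mean() - v[pre, 0].mean()
    dvb = v[post, 1].mean() - v[pre, 1].mean()
    return float(dvb / dva)


# ---------------------------------------------------------------------------
# Background-noise rebalancing (used after connection ablations)
# ---------------------------------------------------------------------------

def calibrate_background(make_sim, target_rates: dict, seed: int,
                         probe_ms: float = 2000.0, discard_ms: float = 500.0,
                         tol: float = 0.10, max_iter: int = 6):
    """Scale per-archetype OU mean conductances until population rates match
    ``target_rates`` ({'PN': Hz, 'FSI': Hz}) within ``tol`` (relative).

    ``make_sim(background_scale)`` must return a fresh NetworkSimulation.
    Returns (background_scale, achieved_rates, converged)."""
    scale = {"PN": {"e": 1.0, "i": 1.0}, "FSI": {"e": 1.0, "i": 1.0}}
    rates = {}
    for it in range(max_iter):
        sim = make_sim(scale)
        ts = sim.run(probe_ms, seed=seed)
        arch = np.asarray(sim.builder.cell_archetype)
        is_fsi = arch == "FSI"
        window_s = (probe_ms - discard_ms) / 1000.0
        sp = ts.spikes[ts.spikes["time_ms"] >= discard_ms]
        counts = np.bincount(sp["cell_id"].to_numpy().astype(int),
                             minlength=arch.size)
        rates = {
            "PN": counts[~is_fsi].mean() / window_s,
            "FSI": counts[is_fsi].mean() / window_s,
        }
        ok = all(
            abs(rates[k] - target_rates[k]) <= tol * max(target_rates[k], 1e-9)
            for k in target_rates
        )
        if ok:
            return scale, rates, True
        for k in target_rates:
            measured = max(rates[k], 0.02)
            f = (target_rates[k] / measured) ** 0.5
            f = min(max(f, 0.6), 1.6)
            scale[k]["e"] *= f
    return scale, rates, False
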