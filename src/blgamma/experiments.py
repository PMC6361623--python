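"""Reproducible in-silico experiments on reduced-scale BL models.

The standard reduced model keeps the full model's cell proportions,
connection probabilities, spatial ranges and synaptic parameters, shrinking
counts and box edge together (density preserved).  Two reduced-scale
corrections define the standard operating conditions (see docs/methods.md):

* in-degree compensation — box clipping lowers realized in-degrees well
  below the full-scale means, so the weights of the inhibitory-loop
  connection classes (PN->FSI, FSI->PN, FSI->FSI) are multiplied by the
  ratio of the full-scale mean in-degree to the realized one, preserving
  each cell's total synaptic conductance per class;
* background rebalancing — per-archetype scaling of the OU point-
  conductance means so population rates remain in the in vivo range
  (PNs ~1 Hz, FSIs tens of Hz), the same procedure applied after
  connection ablations.

Protocols: connection-type ablations (with automatic rate rebalancing),
two-ensemble competition under graded afferent drive, gamma-phase-
conditioned synaptic-current analyses, and deterministic fixture bundles
used by the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import analysis, drive, engine, lfp as lfp_mod, network

__all__ = [
    "FULL_SCALE_INDEGREES",
    "DEFAULT_BACKGROUND_SCALE",
    "Protocol",
    "CompetitionConfig",
    "indegree_weight_compensation",
    "build_reduced_model",
    "spontaneous_run",
    "run_ablation",
    "run_competition",
    "phase_conditioned_psc",
    "epsc_sensitivity_by_phase",
    "pn_burst_triggered_fsi_rate",
    "make_fixtures",
]

#: mean in-degrees realized by the full 27,000-cell wiring
FULL_SCALE_INDEGREES = {
    "PN_PN": 24.98,
    "FSI_PN": 42.6,
    "PN_FSI": 214.8,
    "FSI_FSI": 21.6,
}

#: standard background rebalancing of the reduced model (see module doc)
DEFAULT_BACKGROUND_SCALE = {
    "PN": {"e": 1.2, "i": 1.3},
    "FSI": {"e": 1.0, "i": 1.0},
}

#: classes whose weights are compensated for clipped in-degrees; the
#: PN->PN class is left uncompensated (recurrent excitation at the full
#: compensation ratio destabilizes the reduced network, and its role in
#: gamma generation is modest)
COMPENSATED_CLASSES = ("FSI_PN", "PN_FSI", "FSI_FSI")

ANALYSIS_DISCARD_MS = 500.0


def indegree_weight_compensation(placement: network.Placement,
                                 graph: network.ConnectivityGraph,
                                 classes=COMPENSATED_CLASSES) -> dict:
    """Per-class weight multipliers = full-scale mean in-degree / realized."""
    pn = placement.pn_index
    fsi = placement.fsi_index
    target_of = {"PN_PN": pn, "FSI_PN": pn, "PN_FSI": fsi, "FSI_FSI": fsi}
    out = {}
    for cls in classes:
        realized = graph.in_degree(cls)[target_of[cls]].mean()
        if realized > 0:
            out[cls] = FULL_SCALE_INDEGREES[cls] / realized
    return out


@dataclass
class Protocol:
    """Manifest of one reproducible run."""

    name: str = "spontaneous"
    n_cells: int = 1000
    duration_ms: float = 10000.0
    seed: int = 1
    ablate: str | None = None  # edge type removed ("FSI_FSI" also drops GAP)
    rebalance: bool = True
    afferent_mode: str = "surrogate"  # surrogate | poisson | none
    afferent_rate_hz: float = 2.0
    background_scale: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_BACKGROUND_SCALE.items()
    })

    def manifest(self) -> dict:
        return asdict(self)


def _afferent_trains(protocol: Protocol, recipe: network.Recipe):
    if protocol.afferent_mode == "none":
        return []
    rng_seed = protocol.seed + 1009
    if protocol.afferent_mode == "poisson":
        rng = np.random.default_rng(rng_seed)
        return [
            drive.poisson_train(
                np.full(int(protocol.duration_ms), protocol.afferent_rate_hz),
                rng,
            )
            for _ in range(recipe.n_afferents)
        ]
    profiles, rates = drive.synthetic_donor_pool(30, 10000.0, seed=rng_seed)
    return drive.surrogate_trains(
        profiles, rates, recipe.n_afferents, seed=rng_seed + 1,
        duration_ms=protocol.duration_ms,
    )


def build_reduced_model(protocol: Protocol):
    """Placement + wiring + weight compensation + afferent trains.

    Returns (recipe, placement, graph, weight_scale, trains)."""
    recipe = network.reduced_recipe(protocol.n_cells)
    placement, graph = network.build_network(recipe, protocol.seed)
    weight_scale = indegree_weight_compensation(placement, graph)
    trains = _afferent_trains(protocol, recipe)
    if protocol.ablate is not None:
        graph = graph.without_type(protocol.ablate)
        if protocol.ablate == "FSI_FSI":
            graph = graph.without_type("GAP")
    return recipe, placement, graph, weight_scale, trains


def spontaneous_run(protocol: Protocol, record_imem: bool = True,
                    record_cells=None, vc=None):
    """Run a protocol; returns (sim, traces, placement, recipe).

    Ablation protocols rebalance the background noise first so population
    rates match the unperturbed model's."""
    recipe, placement, graph, wscale, trains = build_reduced_model(protocol)
    bscale = protocol.background_scale
    if protocol.ablate is not None and protocol.rebalance:
        base = Protocol(**{**protocol.manifest(), "ablate": None})
        target = _baseline_rates(base)

        def make_sim(scale):
            merged = {
                k: {d: bscale.get(k, {}).get(d, 1.0) * scale[k][d]
                    for d in ("e", "i")}
                for k in scale
            }
            return engine.NetworkSimulation(
                placement, graph, seed=protocol.seed,
                afferent_trains=trains, weight_scale=wscale,
                background_scale=merged,
            )

        rel, achieved, ok = engine.calibrate_background(
            make_sim, target, seed=protocol.seed,
            probe_ms=min(2000.0, protocol.duration_ms),
        )
        bscale = {
            k: {d: bscale.get(k, {}).get(d, 1.0) * rel[k][d]
                for d in ("e", "i")}
            for k in rel
        }
    sim = engine.NetworkSimulation(
        placement, graph, seed=protocol.seed, afferent_trains=trains,
        weight_scale=wscale, background_scale=bscale,
    )
    ts = sim.run(protocol.duration_ms, record_imem=record_imem,
                 record_cells=record_cells, vc=vc)
    ts.meta["manifest"] = protocol.manifest()
    ts.meta["weight_scale"] = wscale
    ts.meta["background_scale"] = bscale
    return sim, ts, placement, recipe


_baseline_rate_cache: dict = {}


def _baseline_rates(protocol: Protocol) -> dict:
    key = (protocol.n_cells, protocol.seed, protocol.afferent_mode)
    if key not in _baseline_rate_cache:
        probe = Protocol(**{**protocol.manifest(),
                            "duration_ms": 2000.0, "ablate": None})
        sim, ts, placement, _ = spontaneous_run(probe, record_imem=False,
                                                record_cells=[0])
        arch = np.asarray(sim.builder.cell_archetype)
        sp = ts.spikes[ts.spikes.time_ms >= ANALYSIS_DISCARD_MS]
        counts = np.bincount(sp["cell_id"].to_numpy().astype(int),
                             minlength=arch.size)
        w = (2000.0 - ANALYSIS_DISCARD_MS) / 1000.0
        _baseline_rate_cache[key] = {
            "PN": counts[arch != "FSI"].mean() / w,
            "FSI": counts[arch == "FSI"].mean() / w,
        }
    return _baseline_rate_cache[key]


# ---------------------------------------------------------------------------
# Population-rate helpers
# ---------------------------------------------------------------------------

def _population_spikes(ts, sim, kind: str) -> np.ndarray:
    arch = np.asarray(sim.builder.cell_archetype)
    sel = arch == "FSI" if kind == "FSI" else arch != "FSI"
    ids = np.flatnonzero(sel)
    sp = ts.spikes
    return sp[np.isin(sp["cell_id"].to_numpy().astype(int), ids)][
        "time_ms"].to_numpy()


def pn_burst_triggered_fsi_rate(pn_spikes_ms, fsi_spikes_ms, duration_ms,
                                window_ms: float = 100.0,
                                percentile: float = 75.0,
                                smooth_ms: float = 3.0):
    """Mean FSI population rate around bursts of PN activity.

    Bursts are 1-ms time points where the (lightly smoothed) PN population
    rate exceeds the given percentile of its distribution.  Returns
    (lags_ms, mean FSI spike count per ms)."""
    from scipy.ndimage import gaussian_filter1d

    pn = analysis.bin_spikes(pn_spikes_ms, duration_ms)
    fsi = analysis.bin_spikes(fsi_spikes_ms, duration_ms)
    pn_s = gaussian_filter1d(pn, smooth_ms)
    thr = np.percentile(pn_s, percentile)
    w = int(window_ms)
    centers = np.flatnonzero(pn_s > thr)
    centers = centers[(centers >= w) & (centers < len(pn) - w)]
    if centers.size == 0:
        return np.arange(-w, w + 1), np.full(2 * w + 1, np.nan)
    acc = np.zeros(2 * w + 1)
    for c in centers:
        acc += fsi[c - w: c + w + 1]
    return np.arange(-w, w + 1), acc / centers.size


# ---------------------------------------------------------------------------
# Ablation experiment
# ---------------------------------------------------------------------------

def run_ablation(protocol: Protocol, baseline: Protocol | None = None,
                 ppc_freqs=None) -> dict:
    """Compare an ablated run against the unperturbed baseline.

    Returns a report with, per condition: center-electrode LFP Welch
    spectrum and gamma peak, per-cell-type PPC entrainment across
    frequencies, the PN-burst-triggered FSI rate curve, and population
    rates."""
    if protocol.ablate is None:
        raise ValueError("ablation protocol requires an edge type")
    if baseline is None:
        baseline = Protocol(**{**protocol.manifest(), "ablate": None})
    if ppc_freqs is None:
        ppc_freqs = [4.0, 8.0, 16.0, 24.0, 32.0, 40.0, 48.0, 56.0, 64.0,
                     72.0, 80.0, 96.0, 128.0]
    report = {"manifest": protocol.manifest()}
    for label, proto in (("baseline", baseline), ("ablated", protocol)):
        sim, ts, placement, recipe = spontaneous_run(proto)
        center = np.full(3, recipe.box_um / 2.0)
        rec = lfp_mod.compute_lfp(ts, placement, [center])
        x = rec.potentials[int(ANALYSIS_DISCARD_MS):, 0]
        f, pxx = analysis.welch_spectrum(x, rec.fs_hz)
        entr = _ppc_by_frequency(ts, sim, placement, x, rec.fs_hz, ppc_freqs)
        pn_sp = _population_spikes(ts, sim, "PN")
        fsi_sp = _population_spikes(ts, sim, "FSI")
        lags, trig = pn_burst_triggered_fsi_rate(pn_sp, fsi_sp,
                                                 proto.duration_ms)
        arch = np.asarray(sim.builder.cell_archetype)
        sp = ts.spikes[ts.spikes.time_ms >= ANALYSIS_DISCARD_MS]
        counts = np.bincount(sp["cell_id"].to_numpy().astype(int),
                             minlength=arch.size)
        w = (proto.duration_ms - ANALYSIS_DISCARD_MS) / 1000.0
        report[label] = {
            "freqs": f,
            "power": pxx,
            "gamma_peak_hz": analysis.gamma_peak(
                x, rec.fs_hz, search_band=(10.0, 100.0)),
            "ppc_freqs": np.asarray(ppc_freqs),
            "ppc": entr,
            "trigger_lags_ms": lags,
            "fsi_rate_triggered": trig,
            "rates": {"PN": counts[arch != "FSI"].mean() / w,
                      "FSI": counts[arch == "FSI"].mean() / w},
        }
    return report


def _ppc_by_frequency(ts, sim, placement, lfp_series, fs, freqs,
                      max_cells: int = 120, radius_um: float = 300.0):
    """Mean PPC of PN and FSI spiking to the LFP per frequency band.

    Cells are restricted to within ``radius_um`` of the electrode at the
    model center."""
    arch = np.asarray(sim.builder.cell_archetype)
    center = np.full(3, placement.box_um / 2.0)
    dist = np.linalg.norm(placement.positions - center, axis=1)
    near = dist <= radius_um
    trains = ts.spike_trains(arch.size)
    out = {"PN": [], "FSI": []}
    for f0 in freqs:
        band = (max(f0 * 0.75, 1.0), min(f0 * 1.25, fs / 2 * 0.95))
        phase, _ = analysis.band_phase(lfp_series, fs, band=band, order=2)
        for kind in ("PN", "FSI"):
            sel = (arch == "FSI") if kind == "FSI" else (arch != "FSI")
            ids = np.flatnonzero(sel & near)[:max_cells]
            vals = []
            for cid in ids:
                st = trains[cid] - ANALYSIS_DISCARD_MS
                st = st[st >= 0]
                r = analysis.entrainment(st, phase, fs)
                if np.isfinite(r.ppc):
                    vals.append(r.ppc)
            out[kind].append(np.mean(vals) if vals else np.nan)
    return {k: np.asarray(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Two-ensemble competition
# ---------------------------------------------------------------------------

@dataclass
class CompetitionConfig:
    n_cells: int = 1000
    seed: int = 1
    duration_ms: float = 5000.0
    group_size: int = 200
    rate1_hz: float = 20.0
    rate2_hz: float = 5.0
    mode: str = "random"  # random | spheroid
    overlap: bool = True  # spheroid mode: overlapping vs segregated
    spheroid_radius_um: float = 270.0
    background_scale: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_BACKGROUND_SCALE.items()
    })


def _assign_groups(cfg: CompetitionConfig, placement: network.Placement,
                   rng: np.random.Generator):
    pn = placement.pn_index
    if cfg.mode == "random":
        perm = rng.permutation(pn)
        return perm[:cfg.group_size], perm[cfg.group_size:2 * cfg.group_size]
    box = placement.box_um
    if cfg.overlap:
        c1 = c2 = np.full(3, box / 2.0)
    else:
        off = min(cfg.spheroid_radius_um + 60.0, box / 2.0 - 10.0)
        c1 = np.full(3, box / 2.0) - np.array([off, 0.0, 0.0])
        c2 = np.full(3, box / 2.0) + np.array([off, 0.0, 0.0])
    groups = []
    used: set = set()
    for c in (c1, c2):
        d = np.linalg.norm(placement.positions[pn] - c, axis=1)
        order = pn[np.argsort(d)]
        sel = [int(i) for i in order if int(i) not in used][:cfg.group_size]
        used.update(sel)
        groups.append(np.asarray(sel))
    return groups[0], groups[1]


_FULL_SCALE_EXTRINSIC_INDEGREE = 2.97


def _group_afferents(recipe, placement, group1, group2, rng):
    """Afferent edge table with each afferent dedicated to one group.

    The per-afferent fan-out is chosen so each group PN receives the same
    mean number of extrinsic inputs as a full-scale PN (~3); a fixed
    fan-out of 40 into a small dedicated group would otherwise multiply
    the per-cell drive several-fold."""
    half = recipe.n_afferents // 2
    rows = []
    for a in range(recipe.n_afferents):
        pool = group1 if a < half else group2
        n_aff_pool = half if a < half else recipe.n_afferents - half
        fan = int(round(_FULL_SCALE_EXTRINSIC_INDEGREE * len(pool)
                        / max(n_aff_pool, 1)))
        fan_a = min(max(fan, 1), len(pool))
        for t in rng.choice(pool, size=fan_a, replace=False):
            rows.append((a, int(t), "AFF_PN"))
    df = pd.DataFrame(rows, columns=["src", "dst", "type"])
    df["weight"] = np.nan
    df["weight_nmda"] = np.nan
    df["delay_ms"] = network.conduction_delay(np.zeros(len(df)), rng)
    return df, half


def run_competition(cfg: CompetitionConfig) -> dict:
    """Drive two PN ensembles with independent Poisson afferent sets and
    quantify their interaction.

    Returns per-group rates, gamma-band pairwise spike cross-correlation
    strength, PN-FSI spike coherence (with the autocorrelation-corrected
    cross-correlation), plus the FSI population rate."""
    recipe = network.reduced_recipe(cfg.n_cells)
    placement, graph = network.build_network(recipe, cfg.seed,
                                             with_afferents=False)
    rng = np.random.default_rng(cfg.seed + 77)
    group1, group2 = _assign_groups(cfg, placement, rng)
    if len(group1) == 0 or len(group2) == 0:
        raise ValueError("empty PN group")
    aff, half = _group_afferents(recipe, placement, group1, group2, rng)
    graph = network.ConnectivityGraph(
        edges=pd.concat([graph.edges, aff], ignore_index=True),
        n_cells=placement.n_cells, n_afferents=recipe.n_afferents,
    )
    wscale = indegree_weight_compensation(placement, graph)
    trains = []
    for a in range(recipe.n_afferents):
        rate = cfg.rate1_hz if a < half else cfg.rate2_hz
        trains.append(drive.poisson_train(
            np.full(int(cfg.duration_ms), rate), rng))
    sim = engine.NetworkSimulation(
        placement, graph, seed=cfg.seed, afferent_trains=trains,
        weight_scale=wscale, background_scale=cfg.background_scale,
    )
    ts = sim.run(cfg.duration_ms, record_imem=False)

    arch = np.asarray(sim.builder.cell_archetype)
    trains_out = ts.spike_trains(arch.size)
    duration = cfg.duration_ms

    def rate_of(ids):
        n = sum(((trains_out[i] >= ANALYSIS_DISCARD_MS).sum()) for i in ids)
        return n / len(ids) / ((duration - ANALYSIS_DISCARD_MS) / 1000.0)

    fsi_ids = np.flatnonzero(arch == "FSI")
    fsi_all = np.sort(np.concatenate(
        [trains_out[i] for i in fsi_ids] or [np.empty(0)]))

    def group_metrics(ids):
        pooled = np.sort(np.concatenate([trains_out[i] for i in ids]))
        xc_gamma = _group_gamma_sync(trains_out, ids, duration, rng)
        f, coh, lags, cxc = analysis.spike_coherence(pooled, fsi_all, duration)
        gsel = (f >= 40) & (f <= 100)
        return {
            "rate_hz": rate_of(ids),
            "xcorr_gamma": xc_gamma,
            "coherence_freqs": f,
            "coherence": coh,
            "gamma_coherence": float(np.nanmean(coh[gsel])),
            "corrected_xcorr_lags": lags,
            "corrected_xcorr": cxc,
        }

    return {
        "config": asdict(cfg),
        "group1": group_metrics(group1),
        "group2": group_metrics(group2),
        "fsi_rate_hz": rate_of(fsi_ids) if len(fsi_ids) else float("nan"),
        "weight_scale": wscale,
    }


def _group_gamma_sync(trains_out, ids, duration, rng,
                      band=(40.0, 100.0), n_splits: int = 8,
                      max_lag_ms: float = 100.0):
    """Gamma-band spike synchrony within a group.

    The group is split into random halves and the unnormalized pairwise
    cross-correlogram of the pooled half-trains (mean coincidence count
    per cell pair, 1-ms bins, +-100 ms lags) is Fourier transformed; the
    returned value is its mean gamma-band power.  Like pairwise spike
    cross-correlations, this grows with both phase locking and firing
    rate — synchronous spiking, not a rate-normalized locking index."""
    from scipy import signal as _sig

    ids = np.asarray(ids)
    nlag = int(max_lag_ms)
    nfft = 2 * nlag + 1
    win = np.hanning(nfft)
    freqs = np.fft.rfftfreq(nfft, d=1e-3)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    vals = []
    for _ in range(n_splits):
        perm = rng.permutation(ids)
        half = len(ids) // 2
        a = analysis.bin_spikes(
            np.concatenate([trains_out[i] for i in perm[:half]]), duration)
        b = analysis.bin_spikes(
            np.concatenate([trains_out[i] for i in perm[half:]]), duration)
        if a.sum() < 2 or b.sum() < 2:
            continue
        full = _sig.correlate(b - b.mean(), a - a.mean(), mode="full",
                              method="fft")
        mid = a.size - 1
        xc = full[mid - nlag: mid + nlag + 1] / (half * (len(ids) - half))
        spec = np.abs(np.fft.rfft(np.fft.ifftshift(xc * win))) ** 2
        vals.append(float(spec[sel].mean()))
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# Gamma-phase-conditioned synaptic currents
# ---------------------------------------------------------------------------

def phase_conditioned_psc(psc: np.ndarray, lfp_phase: np.ndarray,
                          spike_times_ms, fs_hz: float,
                          n_phase_bins: int = 24, min_cycles: int = 50):
    """Cycle-aligned mean synaptic current split by spike / no-spike cycles.

    Gamma cycles are delineated by downward phase wraps; each cycle's PSC
    is resampled onto a common phase grid.  Returns (phase_centers,
    mean_spike_cycles, mean_no_spike_cycles, difference)."""
    import warnings as _w

    psc = np.asarray(psc, float)
    wraps = np.flatnonzero(np.diff(lfp_phase) < -math.pi)
    if wraps.size < min_cycles:
        _w.warn(f"only {wraps.size} gamma cycles available")
    spikes_idx = np.round(np.asarray(spike_times_ms, float)
                          * fs_hz / 1000.0).astype(int)
    grid = (np.arange(n_phase_bins) + 0.5) / n_phase_bins * 2 * math.pi - math.pi
    acc = {True: np.zeros(n_phase_bins), False: np.zeros(n_phase_bins)}
    cnt = {True: 0, False: 0}
    for k in range(wraps.size - 1):
        i0, i1 = wraps[k] + 1, wraps[k + 1] + 1
        if i1 - i0 < 4:
            continue
        has_spike = bool(np.any((spikes_idx >= i0) & (spikes_idx < i1)))
        ph = lfp_phase[i0:i1]
        order = np.argsort(ph)
        acc[has_spike] += np.interp(grid, ph[order], psc[i0:i1][order])
        cnt[has_spike] += 1
    mean_sp = (acc[True] / cnt[True] if cnt[True]
               else np.full(n_phase_bins, np.nan))
    mean_no = (acc[False] / cnt[False] if cnt[False]
               else np.full(n_phase_bins, np.nan))
    return grid, mean_sp, mean_no, mean_sp - mean_no


def epsc_sensitivity_by_phase(epsc_strength: np.ndarray,
                              spike_flags: np.ndarray,
                              phases: np.ndarray,
                              n_quadrants: int = 4,
                              n_strength_bins: int = 10) -> pd.DataFrame:
    """Spike probability vs EPSC strength per gamma-phase quadrant.

    Inputs are per-cycle summaries: EPSC strength, whether a spike
    occurred, and the cycle's reference phase.  Strengths are decile
    binned; degenerate bins are merged.  Returns a tidy DataFrame
    (quadrant, strength_bin, strength_mid, p_spike, n)."""
    import warnings as _w

    s = np.asarray(epsc_strength, float)
    fl = np.asarray(spike_flags, bool)
    ph = np.mod(np.asarray(phases, float) + math.pi, 2 * math.pi) - math.pi
    quad = np.floor((ph + math.pi) / (2 * math.pi) * n_quadrants).astype(int)
    quad = np.clip(quad, 0, n_quadrants - 1)
    edges = np.unique(np.quantile(s, np.linspace(0, 1, n_strength_bins + 1)))
    if edges.size < 3:
        _w.warn("degenerate strength distribution; bins merged")
    rows = []
    for q in range(n_quadrants):
        m = quad == q
        if not m.any():
            _w.warn(f"empty phase quadrant {q}")
            continue
        which = np.clip(np.searchsorted(edges, s[m], side="right") - 1,
                        0, max(edges.size - 2, 0))
        for b in range(max(edges.size - 1, 1)):
            bm = which == b
            if bm.sum() == 0:
                continue
            rows.append({
                "quadrant": q,
                "strength_bin": b,
                "strength_mid": float(s[m][bm].mean()),
                "p_spike": float(fl[m][bm].mean()),
                "n": int(bm.sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixtures(kind: str, seed: int = 0):
    """Deterministic small inputs exercising every module.

    Kinds: 'two_cell_motif', 'fifty_cell_net', 'reduced_bl_1000',
    'synthetic_lfp_grid'."""
    rng = np.random.default_rng(seed)
    if kind == "two_cell_motif":
        pos = np.array([[100.0, 100.0, 100.0], [160.0, 100.0, 100.0]])
        placement = network.Placement(
            archetypes=np.array(["PN_C", "FSI"]), positions=pos,
            orientations=np.tile([0.0, 0.0, 1.0], (2, 1)),
            box_um=300.0, min_spacing_um=25.0,
        )
        edges = pd.DataFrame({
            "src": [0, 1], "dst": [1, 0],
            "type": ["PN_FSI", "FSI_PN"],
            "weight": [7.0, 12.0], "weight_nmda": [7.0, np.nan],
            "delay_ms": [0.91, 0.91],
        })
        return placement, network.ConnectivityGraph(edges=edges, n_cells=2)
    if kind == "fifty_cell_net":
        recipe = network.reduced_recipe(50)
        return network.build_network(recipe, seed)
    if kind == "reduced_bl_1000":
        recipe = network.reduced_recipe(1000)
        placement, graph = network.build_network(recipe, seed)
        return recipe, placement, graph
    if kind == "synthetic_lfp_grid":
        return _synthetic_lfp_grid(rng)
    raise ValueError(f"unknown fixture kind {kind!r}")


def _synthetic_lfp_grid(rng, n=9, nt=2000, spacing_um=125.0):
    """9x9x9 Z-scored gamma-envelope field with injected translating
    Gaussian blobs and known ground truth (synthetic fixture).

    The background emulates a real band-limited Hilbert envelope: white
    noise smoothed over ~15 ms in time and ~1 site in space."""
    from scipy.ndimage import gaussian_filter

    env = rng.normal(size=(nt, n, n, n))
    env = gaussian_filter(env, sigma=(15.0, 0.8, 0.8, 0.8))
    env *= 0.08 / env.std()
    truth = []
    specs = [
        # (t0 ms, duration ms, start site, end site, peak Z, sigma sites)
        (400, 120, (2.0, 4.0, 4.0), (5.2, 4.0, 4.0), 4.0, 1.6),
        (1200, 100, (6.0, 6.0, 3.0), (6.0, 6.0, 3.0), 3.2, 1.2),
    ]
    axes = np.arange(n)
    X, Y, Z = np.meshgrid(axes, axes, axes, indexing="ij")
    for (t0, dur, p0, p1, peak, sig) in specs:
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        for k in range(dur):
            frac = k / max(dur - 1, 1)
            c = p0 + frac * (p1 - p0)
            a = peak * math.sin(math.pi * (0.1 + 0.8 * frac))
            d2 = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
            env[t0 + k] += a * np.exp(-d2 / (2 * sig**2))
        truth.append({
            "onset_ms": t0, "duration_ms": dur, "peak_z": peak,
            "path_length_um": float(np.linalg.norm(p1 - p0) * spacing_um),
        })
    return env, truth, spacing_um
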