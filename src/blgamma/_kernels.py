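"""Fixed-step integration kernels (numba-compiled).

One step advances, in order: channel gating (exponential Euler on voltage
lookup tables), synaptic receptor states and spike deliveries, short-term
plasticity recovery, per-cell OU background conductances (counter-based
per-cell RNG streams, so streams are stable under changes in cell count),
then an implicit (backward-Euler) voltage update solved directly on each
cell's compartment tree (Hines elimination with conductances frozen over
the step).  Spikes are detected at somata as upward threshold crossings
with an absolute refractory period and enqueued onto outgoing synapses at
their per-edge delays.

Sign conventions: membrane currents are outward-positive (pA); injected and
clamp currents are inward-positive.  The per-compartment membrane current
recorded for the LFP is capacitive + ionic + synaptic + background (axial,
gap-junction and electrode currents excluded) averaged over each 1-ms
window.

Compartment ordering contract: parent index < child index for every
compartment (somata are roots).
"""

from __future__ import annotations

import numpy as np
from numba import njit

I64_NONE = np.iinfo(np.int64).max

OK = 0
ERR_NONFINITE = 1
ERR_SPIKE_OVERFLOW = 2

_TWO_PI = 6.283185307179586


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _to_unit(z):
    return (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _normals(seed, cell, step):
    h1 = _mix64(seed ^ _mix64(np.uint64(cell) + np.uint64(0x51ED2701)))
    h1 = _mix64(h1 ^ np.uint64(step))
    h2 = _mix64(h1)
    u1 = _to_unit(h1)
    u2 = _to_unit(h2)
    if u1 < 1e-300:
        u1 = 1e-300
    r = np.sqrt(-2.0 * np.log(u1))
    return r * np.cos(_TWO_PI * u2), r * np.sin(_TWO_PI * u2)


@njit(cache=True, inline="always")
def _ipow(x, n):
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=True)
def run_steps(
    n_steps, dt,
    # compartments
    v, parent, g_ax, cm, g_leak, e_leak,
    # gate lookup tables (shared V grid)
    tab_xinf, tab_exp, v_min, dv_inv, mg_table,
    # channel instances
    ch_comp, ch_gate_a, ch_p, ch_gate_h, ch_q, ch_g, ch_e,
    ch_m, ch_h, ch_sahp, ch_capool, ch_is_ca,
    # calcium pools
    sahp_exp, ca_val, ca_decay, ca_k, ca_comp, ca_factor,
    # synapses (receptor instances)
    syn_comp, syn_g, syn_e, syn_rinf, syn_exp_on, syn_exp_off,
    syn_is_nmda, syn_r, syn_on_until, syn_pending_step, syn_stp,
    pulse_ms,
    # STP states
    stp_d1, stp_d2, stp_dmin, stp_c1, stp_c2, stp_e1, stp_e2,
    # outgoing connectivity (per cell, CSR over receptor instances)
    out_ptr, out_syn, out_delay_steps,
    # afferent event schedule (sorted by step)
    aff_step, aff_syn,
    # OU background (per cell; soma targets)
    soma_comp, ou_ge, ou_gi, ou_ge0, ou_gi0, ou_ae, ou_ai, ou_de, ou_di,
    ou_on, noise_seed,
    # injections (comp, amp pA, on ms, off ms)
    inj_comp, inj_amp, inj_on, inj_off,
    # gap junctions
    gap_a, gap_b, gap_g,
    # voltage clamp (single compartment or -1)
    vc_comp, vc_hold, vc_out,
    # spike detection / output
    spike_thresh, refractory_ms, last_spike, spike_cell, spike_t, n_spikes_io,
    # recording
    rec_stride, rec_comp, v_out, steps_per_ms, imem_on, imem_out,
):
    ncomp = v.shape[0]
    nchan = ch_comp.shape[0]
    nsyn = syn_comp.shape[0]
    ncell = soma_comp.shape[0]
    npool = ca_val.shape[0]
    n_tab = tab_xinf.shape[1]
    max_spikes = spike_cell.shape[0]

    a_g = np.zeros(ncomp)
    a_ge = np.zeros(ncomp)
    b_ext = np.zeros(ncomp)
    diag = np.zeros(ncomp)
    rhs = np.zeros(ncomp)
    v_old = np.zeros(ncomp)
    imem_accum = np.zeros(ncomp)
    pool_g = np.zeros(npool)
    pool_ge = np.zeros(npool)
    v_prev_soma = np.empty(ncell)
    for c in range(ncell):
        v_prev_soma[c] = v[soma_comp[c]]

    aff_i = 0
    nsp = n_spikes_io[0]
    status = OK
    bad_cell = -1
    inv_spm = 1.0 / steps_per_ms

    for step in range(n_steps):
        t = step * dt

        for i in range(ncomp):
            a_g[i] = g_leak[i]
            a_ge[i] = g_leak[i] * e_leak[i]
            b_ext[i] = 0.0
            v_old[i] = v[i]
        for p in range(npool):
            pool_g[p] = 0.0
            pool_ge[p] = 0.0

        # ---- channels
        for k in range(nchan):
            c = ch_comp[k]
            vv = v[c]
            if ch_sahp[k]:
                ca = ca_val[ch_capool[k]]
                if ca < 1e-10:
                    ca = 1e-10
                lg = np.log10(ca * ca)
                alpha = 0.0048 / np.exp(-5.0 * lg - 17.5)
                beta = 0.012 / np.exp(2.0 * lg + 20.0)
                xinf = alpha / (alpha + beta)
                ch_m[k] = xinf + (ch_m[k] - xinf) * sahp_exp
            else:
                ti = int((vv - v_min) * dv_inv + 0.5)
                if ti < 0:
                    ti = 0
                elif ti >= n_tab:
                    ti = n_tab - 1
                ga = ch_gate_a[k]
                xinf = tab_xinf[ga, ti]
                ch_m[k] = xinf + (ch_m[k] - xinf) * tab_exp[ga, ti]
                gh = ch_gate_h[k]
                if gh >= 0:
                    hinf = tab_xinf[gh, ti]
                    ch_h[k] = hinf + (ch_h[k] - hinf) * tab_exp[gh, ti]
            g_open = ch_g[k] * _ipow(ch_m[k], ch_p[k])
            if ch_gate_h[k] >= 0:
                g_open *= _ipow(ch_h[k], ch_q[k])
            a_g[c] += g_open
            a_ge[c] += g_open * ch_e[k]
            if ch_is_ca[k] and ch_capool[k] >= 0:
                pool_g[ch_capool[k]] += g_open
                pool_ge[ch_capool[k]] += g_open * ch_e[k]

        # ---- afferent deliveries scheduled for this step
        while aff_i < aff_step.shape[0] and aff_step[aff_i] <= step:
            if aff_step[aff_i] == step:
                s = aff_syn[aff_i]
                syn_on_until[s] = t + pulse_ms
                j = syn_stp[s]
                if j >= 0:
                    stp_d1[j] *= stp_c1[j]
                    stp_d2[j] *= stp_c2[j]
            aff_i += 1

        # ---- synaptic deliveries, receptor update, conductance accumulation
        for s in range(nsyn):
            if syn_pending_step[s] == step:
                syn_pending_step[s] = I64_NONE
                syn_on_until[s] = t + pulse_ms
                j = syn_stp[s]
                if j >= 0:
                    stp_d1[j] *= stp_c1[j]
                    stp_d2[j] *= stp_c2[j]
            if t < syn_on_until[s]:
                syn_r[s] = syn_rinf[s] + (syn_r[s] - syn_rinf[s]) * syn_exp_on[s]
            else:
                syn_r[s] *= syn_exp_off[s]
            g_eff = syn_g[s] * syn_r[s]
            j = syn_stp[s]
            if j >= 0:
                d = stp_d1[j] * stp_d2[j]
                if d < stp_dmin[j]:
                    d = stp_dmin[j]
                g_eff *= d
            c = syn_comp[s]
            if syn_is_nmda[s]:
                ti = int((v[c] - v_min) * dv_inv + 0.5)
                if ti < 0:
                    ti = 0
                elif ti >= n_tab:
                    ti = n_tab - 1
                g_eff *= mg_table[ti]
            a_g[c] += g_eff
            a_ge[c] += g_eff * syn_e[s]

        # ---- STP recovery toward 1
        for j in range(stp_d1.shape[0]):
            stp_d1[j] = 1.0 + (stp_d1[j] - 1.0) * stp_e1[j]
            stp_d2[j] = 1.0 + (stp_d2[j] - 1.0) * stp_e2[j]

        # ---- OU background at somata
        for cidx in range(ncell):
            if ou_on[cidx]:
                n1, n2 = _normals(noise_seed, cidx, step)
                ou_ge[cidx] = ou_ge0[cidx] + (ou_ge[cidx] - ou_ge0[cidx]) * ou_de[cidx] \
                    + ou_ae[cidx] * n1
                ou_gi[cidx] = ou_gi0[cidx] + (ou_gi[cidx] - ou_gi0[cidx]) * ou_di[cidx] \
                    + ou_ai[cidx] * n2
                sc = soma_comp[cidx]
                ge = ou_ge[cidx] if ou_ge[cidx] > 0.0 else 0.0
                gi = ou_gi[cidx] if ou_gi[cidx] > 0.0 else 0.0
                a_g[sc] += ge + gi
                a_ge[sc] += gi * (-75.0)

        # ---- injections
        for q in range(inj_comp.shape[0]):
            if inj_on[q] <= t and t < inj_off[q]:
                b_ext[inj_comp[q]] += inj_amp[q]

        # ---- gap junctions (explicit in V)
        for q in range(gap_a.shape[0]):
            ig = gap_g[q] * (v[gap_b[q]] - v[gap_a[q]])
            b_ext[gap_a[q]] += ig
            b_ext[gap_b[q]] -= ig

        # ---- semi-implicit voltage solve (Crank-Nicolson, Hines per tree;
        # conductances frozen over the step, gates staggered)
        for i in range(ncomp):
            diag[i] = cm[i] / dt + 0.5 * a_g[i]
            rhs[i] = (cm[i] / dt - 0.5 * a_g[i]) * v[i] + a_ge[i] + b_ext[i]
        for i in range(ncomp):
            p = parent[i]
            if p >= 0:
                diag[i] += 0.5 * g_ax[i]
                diag[p] += 0.5 * g_ax[i]
                ia = 0.5 * g_ax[i] * (v[i] - v[p])
                rhs[i] -= ia
                rhs[p] += ia
        for i in range(ncomp - 1, 0, -1):
            p = parent[i]
            if p >= 0:
                f = 0.5 * g_ax[i] / diag[i]
                diag[p] -= f * 0.5 * g_ax[i]
                rhs[p] += f * rhs[i]
        clamp_i = 0.0
        for i in range(ncomp):
            p = parent[i]
            if i == vc_comp:
                clamp_i = diag[i] * vc_hold - rhs[i]
                v[i] = vc_hold
            elif p < 0:
                v[i] = rhs[i] / diag[i]
            else:
                # v[p] already holds the parent's post-step voltage
                v[i] = (rhs[i] + 0.5 * g_ax[i] * v[p]) / diag[i]

        if vc_comp >= 0:
            vc_out[step] = clamp_i

        # ---- membrane-current accumulation (1-ms mean); ionic part taken
        # at the step midpoint so per-cell totals obey Kirchhoff exactly
        if imem_on:
            for i in range(ncomp):
                imem_accum[i] += a_g[i] * 0.5 * (v[i] + v_old[i]) - a_ge[i] \
                    + cm[i] * (v[i] - v_old[i]) / dt
            if (step + 1) % steps_per_ms == 0:
                ms = step // steps_per_ms
                if ms < imem_out.shape[0]:
                    for i in range(ncomp):
                        imem_out[ms, i] = imem_accum[i] * inv_spm
                        imem_accum[i] = 0.0

        # ---- calcium pools (post-step voltage; inward I_Ca raises the pool)
        for p in range(npool):
            i_density = (pool_g[p] * v[ca_comp[p]] - pool_ge[p]) * ca_factor[p]
            ca = ca_val[p] * ca_decay[p] - ca_k[p] * i_density * dt
            ca_val[p] = ca if ca > 0.0 else 0.0

        # ---- spike detection and propagation
        for cidx in range(ncell):
            sc = soma_comp[cidx]
            vv = v[sc]
            if not np.isfinite(vv):
                status = ERR_NONFINITE
                bad_cell = cidx
                break
            if (
                vv >= spike_thresh
                and v_prev_soma[cidx] < spike_thresh
                and t - last_spike[cidx] >= refractory_ms
            ):
                if nsp >= max_spikes:
                    status = ERR_SPIKE_OVERFLOW
                    bad_cell = cidx
                    break
                spike_cell[nsp] = cidx
                spike_t[nsp] = t
                nsp += 1
                last_spike[cidx] = t
                for e in range(out_ptr[cidx], out_ptr[cidx + 1]):
                    syn_pending_step[out_syn[e]] = step + out_delay_steps[e]
            v_prev_soma[cidx] = vv
        if status != OK:
            break

        # ---- voltage recording
        if step % rec_stride == 0:
            row = step // rec_stride
            if row < v_out.shape[0]:
                for j in range(rec_comp.shape[0]):
                    v_out[row, j] = v[rec_comp[j]]

    n_spikes_io[0] = nsp
    return status, bad_cell
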