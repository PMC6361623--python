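"""Spectral, burst-detection, entrainment and coherence analyses for LFP
and spike data.

Conventions follow the model's analysis pipeline:

* time-frequency decomposition with 7-cycle complex Morlet wavelets on a
  quarter-octave frequency grid from 1 to 256 Hz;
* band-limited phase/amplitude from a zero-phase Butterworth filter
  (forward-backward) followed by the Hilbert analytic signal;
* single-electrode gamma bursts: 60-80 Hz envelope exceeding its mean by
  2 SD, with burst duration the span where the envelope stays above 25%
  of the burst peak;
* spatiotemporal bursts on an electrode grid: 4-D watershed (3 space x 1
  time, 6-neighborhood in space, adjacency in time, no diagonals) on the
  Z-scored gamma envelope discretized into 0.1 bins; events must peak
  above 2 Z and are delineated at 25% of their peak;
* spike-field entrainment by the resultant vector length (RV) and the
  pairwise phase consistency (PPC), which is unbiased by spike count;
* spike-train coherence from the FFTs of lag-limited cross- and
  autocorrelations, Coherence = XCorr / sqrt(ACorr_a * ACorr_b), whose
  inverse FFT is the autocorrelation-corrected cross-correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "Spectrogram",
    "BurstEvent",
    "EntrainmentResult",
    "morlet_spectrogram",
    "band_phase",
    "detect_bursts_1d",
    "watershed_segments_1d",
    "burst_amplitude_duration_map",
    "detect_bursts_4d",
    "entrainment",
    "rv_ppc",
    "plv_unbiased",
    "spike_coherence",
    "welch_spectrum",
    "power_law_removed",
    "gamma_peak",
    "bin_spikes",
]

GAMMA_BAND = (60.0, 80.0)
MID_GAMMA_HZ = 64.0


# ---------------------------------------------------------------------------
# Spectral decomposition
# ---------------------------------------------------------------------------

@dataclass
class Spectrogram:
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    amplitude: np.ndarray  # (n_freq, n_time), >= 0
    phase: np.ndarray  # (n_freq, n_time), radians

    def power(self) -> np.ndarray:
        return self.amplitude**2

    def nearest_freq_index(self, f_hz: float) -> int:
        return int(np.argmin(np.abs(self.freqs_hz - f_hz)))


def quarter_octave_freqs(fmin: float = 1.0, fmax: float = 256.0) -> np.ndarray:
    n = int(round(4 * math.log2(fmax / fmin)))
    return fmin * 2.0 ** (np.arange(n + 1) / 4.0)


def morlet_spectrogram(x, fs_hz: float, fmin: float = 1.0,
                       fmax: float = 256.0, n_cycles: float = 7.0) -> Spectrogram:
    """Complex Morlet decomposition on a quarter-octave grid.

    Amplitude is the modulus and phase the angle of the complex
    coefficients; wavelets carry ``n_cycles`` cycles (Gaussian SD
    n_cycles / (2 pi f))."""
    x = np.asarray(x, dtype=float)
    freqs = quarter_octave_freqs(fmin, fmax)
    freqs = freqs[freqs <= fs_hz / 2.0]
    nt = x.size
    nfft = int(2 ** math.ceil(math.log2(2 * nt)))
    X = np.fft.rfft(x - x.mean(), nfft)
    fgrid = np.fft.rfftfreq(nfft, d=1.0 / fs_hz)
    amp = np.empty((freqs.size, nt))
    ph = np.empty((freqs.size, nt))
    for i, f0 in enumerate(freqs):
        sigma_f = f0 / n_cycles  # spectral SD of the Gaussian envelope
        H = np.exp(-0.5 * ((fgrid - f0) / sigma_f) ** 2)
        # one-sided kernel -> the inverse transform is an analytic signal
        analytic = np.fft.ifft(
            np.concatenate([
                (X * H) * 2.0,
                np.zeros(nfft - X.size, dtype=complex),
            ])
        )[:nt]
        amp[i] = np.abs(analytic)
        ph[i] = np.angle(analytic)
    return Spectrogram(
        freqs_hz=freqs, time_ms=np.arange(nt) * 1000.0 / fs_hz,
        amplitude=amp, phase=ph,
    )


def band_phase(x, fs_hz: float, band=GAMMA_BAND, order: int = 4):
    """Zero-phase Butterworth bandpass then Hilbert transform.

    Returns (phase, amplitude) series.  Requires fs >= 4x the band top."""
    lo, hi = band
    if fs_hz < 4.0 * hi:
        raise ValueError("sampling rate must be at least 4x the band top")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz,
                        output="sos")
    y = signal.sosfiltfilt(sos, np.asarray(x, float))
    analytic = signal.hilbert(y)
    return np.angle(analytic), np.abs(analytic)


def welch_spectrum(x, fs_hz: float, nperseg_ms: float = 500.0,
                   step_ms: float = 250.0):
    """Welch periodogram with Hamming windows (500-ms tapers, 250-ms steps
    by default).  Returns (freqs_hz, power)."""
    x = np.asarray(x, float)
    nperseg = min(int(round(nperseg_ms * fs_hz / 1000.0)), x.size)
    noverlap = nperseg - int(round(step_ms * fs_hz / 1000.0))
    noverlap = min(max(noverlap, 0), nperseg - 1)
    return signal.welch(x, fs=fs_hz, window="hamming", nperseg=nperseg,
                        noverlap=noverlap)


def power_law_removed(f, p, exclude_band=(30.0, 100.0),
                      fit_range=(2.0, 200.0)):
    """Divide a spectrum by a 1/f^a power-law fit (log-log linear fit that
    excludes ``exclude_band``).  Returns the residual ratio spectrum."""
    f = np.asarray(f, float)
    p = np.asarray(p, float)
    mask = (f >= fit_range[0]) & (f <= fit_range[1])
    mask &= ~((f >= exclude_band[0]) & (f <= exclude_band[1]))
    mask &= p > 0
    if mask.sum() < 3:
        raise ValueError("too few points for a power-law fit")
    b, a = np.polyfit(np.log10(f[mask]), np.log10(p[mask]), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = 10 ** (a + b * np.log10(np.maximum(f, 1e-12)))
        resid = np.where(f > 0, p / fit, 0.0)
    return resid


def gamma_peak(x, fs_hz: float, search_band=(40.0, 100.0),
               nperseg_ms: float = 500.0) -> float:
    """Peak frequency (Hz) of the spectrum after removing a 1/f^a
    power-law fit, searched within ``search_band`` (default: the gamma
    range, 40-100 Hz)."""
    f, p = welch_spectrum(x, fs_hz, nperseg_ms=nperseg_ms)
    resid = power_law_removed(f, p)
    sel = (f >= search_band[0]) & (f <= search_band[1])
    return float(f[sel][np.argmax(resid[sel])])


# ---------------------------------------------------------------------------
# Burst events
# ---------------------------------------------------------------------------

@dataclass
class BurstEvent:
    peak_amplitude: float  # envelope units (Z for grid bursts)
    peak_time_ms: float
    onset_ms: float
    offset_ms: float
    # spatiotemporal features (grid bursts only)
    volume_sites: int = 0
    path_length_um: float = 0.0
    net_displacement_um: float = 0.0
    speed_um_per_ms: float = 0.0
    peak_plv: float = float("nan")
    peak_site: tuple | None = None
    member_count: int = 0
    label: int = -1

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


def detect_bursts_1d(x, fs_hz: float, band=GAMMA_BAND, order: int = 4,
                     thresh_sd: float = 2.0, edge_frac: float = 0.25,
                     min_duration_ms: float = 0.0) -> list[BurstEvent]:
    """Gamma bursts on a single trace.

    The band envelope must exceed mean + ``thresh_sd`` SD; each contiguous
    supra-threshold region yields one event whose duration is the span
    around the peak where the envelope stays above ``edge_frac`` of the
    event peak."""
    _, env = band_phase(x, fs_hz, band=band, order=order)
    dt = 1000.0 / fs_hz
    thresh = env.mean() + thresh_sd * env.std()
    above = env > thresh
    if not above.any():
        return []
    lab, n = ndimage.label(above)
    events = []
    for k in range(1, n + 1):
        idx = np.flatnonzero(lab == k)
        ipk = idx[np.argmax(env[idx])]
        peak = env[ipk]
        lim = edge_frac * peak
        i0 = ipk
        while i0 > 0 and env[i0 - 1] > lim:
            i0 -= 1
        i1 = ipk
        while i1 < env.size - 1 and env[i1 + 1] > lim:
            i1 += 1
        ev = BurstEvent(
            peak_amplitude=float(peak), peak_time_ms=ipk * dt,
            onset_ms=i0 * dt, offset_ms=(i1 + 1) * dt,
        )
        if ev.duration_ms >= min_duration_ms:
            events.append(ev)
    # merge events that share the same extended support
    merged: list[BurstEvent] = []
    for ev in sorted(events, key=lambda e: e.onset_ms):
        if merged and ev.onset_ms < merged[-1].offset_ms:
            if ev.peak_amplitude > merged[-1].peak_amplitude:
                merged[-1] = ev
            continue
        merged.append(ev)
    return merged


def _discretize(a: np.ndarray, step: float) -> np.ndarray:
    if step <= 0:
        return a
    return np.floor(a / step) * step


def watershed_segments_1d(power: np.ndarray, bin_step: float | None = None,
                          cycle_samples: int = 1) -> np.ndarray:
    """Watershed labels of a 1-D power series.

    ``bin_step`` defaults to half the mean absolute power change between
    successive cycles (samples spaced ``cycle_samples`` apart); the series
    is discretized to that step before segmentation so shallow ripples do
    not split peaks.  Returns an integer label per sample (0 = none)."""
    from skimage.segmentation import watershed

    p = np.asarray(power, float)
    if bin_step is None:
        dp = np.abs(np.diff(p[::max(cycle_samples, 1)]))
        bin_step = 0.5 * dp.mean() if dp.size else 0.0
    pd = _discretize(p, bin_step)
    # unmarked watershed: basins flood from the local minima of -pd, i.e.
    # one segment per (plateau-aware) local maximum of the power series
    return watershed(-pd)


def burst_amplitude_duration_map(power: np.ndarray, fs_hz: float,
                                 freq_hz: float = MID_GAMMA_HZ,
                                 pct_bin: float = 5.0, dur_bin_ms: float = 5.0):
    """Joint distribution of burst peak-amplitude percentile and duration.

    ``power`` is the mid-gamma wavelet power series.  Bursts are watershed
    segments of the discretized power; each contributes its peak power
    percentile (rank-transformed across bursts, binned in steps of
    ``pct_bin``) and segment duration (binned in ``dur_bin_ms``).
    Returns (hist (n_pct_bins, n_dur_bins), pct_edges, dur_edges, bursts
    DataFrame)."""
    import pandas as pd

    p = np.asarray(power, float)
    cycle_samples = max(int(round(fs_hz / freq_hz)), 1)
    lab = watershed_segments_1d(p, cycle_samples=cycle_samples)
    dt = 1000.0 / fs_hz
    peaks, durs = [], []
    for k in np.unique(lab):
        if k == 0:
            continue
        idx = np.flatnonzero(lab == k)
        peaks.append(p[idx].max())
        durs.append(idx.size * dt)
    peaks = np.asarray(peaks)
    durs = np.asarray(durs)
    if peaks.size == 0:
        return (np.zeros((0, 0)), np.empty(0), np.empty(0),
                pd.DataFrame(columns=["peak_power", "duration_ms",
                                      "percentile"]))
    pct = 100.0 * (np.argsort(np.argsort(peaks)) + 0.5) / peaks.size
    pct_edges = np.arange(0.0, 100.0 + pct_bin, pct_bin)
    dur_edges = np.arange(0.0, durs.max() + 2 * dur_bin_ms, dur_bin_ms)
    hist, _, _ = np.histogram2d(pct, durs, bins=[pct_edges, dur_edges])
    df = pd.DataFrame(
        {"peak_power": peaks, "duration_ms": durs, "percentile": pct}
    )
    return hist / hist.sum(), pct_edges, dur_edges, df


def detect_bursts_4d(env_z: np.ndarray, spacing_um: float,
                     dt_ms: float = 1.0, z_bin: float = 0.1,
                     peak_thresh_z: float = 2.0, edge_frac: float = 0.25,
                     merge_h: float | None = None,
                     phases: np.ndarray | None = None) -> list[BurstEvent]:
    """Spatiotemporal gamma bursts on an electrode grid.

    ``env_z``: Z-scored (and edge-corrected) gamma envelopes of shape
    (n_time, nx, ny, nz); ``phases`` optionally carries the matching
    gamma phases for peak-synchrony (PLV) estimation.

    The field is discretized into ``z_bin`` bins and segmented with a 4-D
    watershed whose connectivity is adjacency along each axis (6-neighbor
    in space, +-1 in time, no diagonals).  A segment qualifies as a burst
    if its peak exceeds ``peak_thresh_z``; members are trimmed at
    ``edge_frac`` of the peak.  Features per burst: peak Z, duration
    (time span with >= 1 member site above the edge), volume (number of
    distinct sites whose envelope reached ``peak_thresh_z``), path length
    of the member-centroid trajectory, speed = path / duration, and the
    debiased pairwise PLV over the 3x3x3 neighborhood of the peak site."""
    from skimage.segmentation import watershed

    a = np.asarray(env_z, float)
    if a.ndim != 4:
        raise ValueError("expected a (time, x, y, z) array")
    ad = _discretize(a, z_bin)
    structure = ndimage.generate_binary_structure(4, 1)
    # one basin per plateau-aware local maximum of the discretized field,
    # flooded with axis-adjacency (6-neighborhood in space) connectivity.
    # Maxima shallower than merge_h (default two amplitude bins) are
    # suppressed first, extending the discretization's purpose of ignoring
    # sub-bin power ripples.
    if merge_h is None:
        merge_h = 2.0 * z_bin
    if merge_h > 0:
        from skimage.morphology import h_maxima

        peaks = h_maxima(ad, merge_h, footprint=structure)
    else:
        from skimage.morphology import local_maxima

        peaks = local_maxima(ad, footprint=structure)
    markers, _ = ndimage.label(peaks, structure=structure)
    lab = watershed(-ad, markers=markers, connectivity=structure)

    # only regions whose maximum exceeds the peak criterion are bursts;
    # select them without touching the (many) sub-threshold regions
    labs = np.unique(lab)
    maxima = ndimage.maximum(a, labels=lab, index=labs)
    candidates = labs[maxima > peak_thresh_z]

    events: list[BurstEvent] = []
    for k, peak in zip(candidates,
                       maxima[np.isin(labs, candidates)]):
        region = lab == k
        member = region & (a >= edge_frac * peak)
        if not member.any():
            continue
        tidx, xi, yi, zi = np.nonzero(member)
        t0, t1 = tidx.min(), tidx.max()
        # volume: distinct sites that reached the burst threshold
        supra = member & (a >= peak_thresh_z)
        if supra.any():
            _, sx, sy, sz = np.nonzero(supra)
            volume = np.unique(np.stack([sx, sy, sz], 1), axis=0).shape[0]
        else:
            volume = 0
        # centroid trajectory: path = summed step displacement, plus the
        # net start-to-end displacement as a jitter-robust summary
        path = 0.0
        prev = None
        first = last = None
        for tt in range(t0, t1 + 1):
            sel = tidx == tt
            if not sel.any():
                prev = None
                continue
            c = np.array([xi[sel].mean(), yi[sel].mean(), zi[sel].mean()])
            if prev is not None:
                path += float(np.linalg.norm(c - prev)) * spacing_um
            prev = c
            if first is None:
                first = c
            last = c
        net = (float(np.linalg.norm(last - first)) * spacing_um
               if first is not None else 0.0)
        duration = (t1 - t0 + 1) * dt_ms
        flat_peak = np.unravel_index(np.argmax(np.where(region, a, -np.inf)),
                                     a.shape)
        plv = float("nan")
        if phases is not None:
            plv = _neighborhood_plv(phases, flat_peak, (t0, t1))
        events.append(
            BurstEvent(
                peak_amplitude=float(peak),
                peak_time_ms=flat_peak[0] * dt_ms,
                onset_ms=t0 * dt_ms,
                offset_ms=(t1 + 1) * dt_ms,
                volume_sites=int(volume),
                path_length_um=path,
                net_displacement_um=net,
                speed_um_per_ms=path / duration if duration > 0 else 0.0,
                peak_plv=plv,
                peak_site=tuple(int(q) for q in flat_peak[1:]),
                member_count=int(member.sum()),
                label=int(k),
            )
        )
    return events


def _neighborhood_plv(phases, flat_peak, t_span):
    """Debiased pairwise PLV over the 3x3x3 neighborhood of the peak site
    during the burst's time span."""
    _, px, py, pz = flat_peak
    t0, t1 = t_span
    nx, ny, nz = phases.shape[1:]
    sites = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                x, y, z = px + dx, py + dy, pz + dz
                if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                    sites.append(phases[t0:t1 + 1, x, y, z])
    vals = []
    for i in range(len(sites)):
        for j in range(i + 1, len(sites)):
            v = plv_unbiased(sites[i] - sites[j])
            if np.isfinite(v):
                vals.append(v)
    return float(np.sqrt(max(np.mean(vals), 0.0))) if vals else float("nan")


def plv_unbiased(phase_diff: np.ndarray) -> float:
    """Debiased squared phase-locking value of a phase-difference series.

    The naive squared resultant R^2 of n samples has expectation 1/n under
    independence; the estimator (n R^2 - 1)/(n - 1) removes that bias."""
    d = np.asarray(phase_diff, float)
    n = d.size
    if n < 2:
        return float("nan")
    r2 = np.abs(np.mean(np.exp(1j * d))) ** 2
    return float((n * r2 - 1.0) / (n - 1.0))


# ---------------------------------------------------------------------------
# Entrainment
# ---------------------------------------------------------------------------

@dataclass
class EntrainmentResult:
    rv: float  # resultant vector length in [0, 1]
    mean_phase: float  # radians
    ppc: float  # pairwise phase consistency
    n_spikes: int


def rv_ppc(phases: np.ndarray) -> tuple[float, float, float]:
    """(RV, mean phase, PPC) of spike phases.

    PPC is the average cosine of all pairwise phase differences,
    equivalently (n R^2 - 1)/(n - 1); its expectation is 0 for uniform
    independent phases regardless of n."""
    ph = np.asarray(phases, float)
    n = ph.size
    z = np.mean(np.exp(1j * ph))
    rv = float(np.abs(z))
    mean_phase = float(np.angle(z))
    ppc = float((n * rv**2 - 1.0) / (n - 1.0)) if n >= 2 else float("nan")
    return rv, mean_phase, ppc


def entrainment(spike_times_ms, phase_series: np.ndarray, fs_hz: float,
                min_spikes_rv: int = 10) -> EntrainmentResult:
    """Entrainment of a spike train to a band-limited phase series.

    Each spike is assigned the instantaneous phase at its time; RV
    requires ``min_spikes_rv`` spikes (NaN otherwise), PPC requires 2."""
    st = np.asarray(spike_times_ms, float)
    idx = np.round(st * fs_hz / 1000.0).astype(int)
    idx = idx[(idx >= 0) & (idx < len(phase_series))]
    n = idx.size
    if n < 2:
        return EntrainmentResult(float("nan"), float("nan"), float("nan"), n)
    rv, mp, ppc = rv_ppc(phase_series[idx])
    if n < min_spikes_rv:
        rv, mp = float("nan"), float("nan")
    return EntrainmentResult(rv, mp, ppc, n)


# ---------------------------------------------------------------------------
# Spike-train coherence
# ---------------------------------------------------------------------------

def bin_spikes(spike_times_ms, duration_ms: float,
               bin_ms: float = 1.0) -> np.ndarray:
    n = int(round(duration_ms / bin_ms))
    idx = np.floor(np.asarray(spike_times_ms, float) / bin_ms).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    out = np.zeros(n)
    np.add.at(out, idx, 1.0)
    return out


def spike_coherence(train_a_ms, train_b_ms, duration_ms: float,
                    max_lag_ms: float = 100.0, bin_ms: float = 1.0):
    """Coherence spectrum and autocorrelation-corrected cross-correlation.

    Lag-limited cross- and autocorrelations of the 1-ms binned trains are
    Fourier transformed; Coherence(f) = XCorr(f)/sqrt(ACorr_a ACorr_b),
    and the inverse transform of the coherence gives the corrected
    cross-correlation.  Returns (freqs_hz, coherence, lags_ms,
    corrected_xcorr) or NaNs if either train is empty."""
    a = bin_spikes(train_a_ms, duration_ms, bin_ms)
    b = bin_spikes(train_b_ms, duration_ms, bin_ms)
    nlag = int(round(max_lag_ms / bin_ms))
    nfft = 2 * nlag + 1
    lags = (np.arange(nfft) - nlag) * bin_ms
    if a.sum() == 0 or b.sum() == 0:
        nanarr = np.full(nfft, np.nan)
        freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=bin_ms / 1000.0))
        return freqs, nanarr, lags, nanarr

    am = a - a.mean()
    bm = b - b.mean()

    def corr(x, y):
        full = signal.correlate(x, y, mode="full", method="fft")
        mid = x.size - 1
        return full[mid - nlag: mid + nlag + 1] / x.size

    # positive lag = train_b follows train_a
    xc = corr(bm, am)
    aa = corr(am, am)
    bb = corr(bm, bm)

    # window the correlation functions to suppress hard-edge ringing
    win = np.hanning(nfft)
    Fx = np.fft.fft(np.fft.ifftshift(xc * win))
    Fa = np.fft.fft(np.fft.ifftshift(aa * win)).real
    Fb = np.fft.fft(np.fft.ifftshift(bb * win)).real
    Fa = np.maximum(Fa, 1e-15)
    Fb = np.maximum(Fb, 1e-15)
    coh = Fx / np.sqrt(Fa * Fb)
    corrected = np.fft.fftshift(np.fft.ifft(coh).real)
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=bin_ms / 1000.0))
    coh_shifted = np.abs(np.fft.fftshift(coh))
    pos = freqs >= 0
    return freqs[pos], coh_shifted[pos], lags, corrected
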