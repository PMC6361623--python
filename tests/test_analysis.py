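"""Spectral, burst, entrainment and coherence algorithms, checked against
constructed ground truth and closed forms."""

import numpy as np
import pytest
from scipy import special

from blgamma import analysis, experiments

FS = 1000.0


def _gamma_burst(t_ms, center, width, freq=70.0, amp=1.0):
    env = amp * np.exp(-0.5 * ((t_ms - center) / width) ** 2)
    return env * np.sin(2 * np.pi * freq * t_ms / 1000.0)


class TestBandPhase:
    def test_pure_sinusoid_phase_and_amplitude(self):
        t = np.arange(0, 4000) / FS
        x = 2.0 * np.sin(2 * np.pi * 70.0 * t)
        phase, amp = analysis.band_phase(x, FS)
        core = slice(500, 3500)
        assert np.allclose(amp[core], 2.0, rtol=0.02)
        dphi = np.diff(np.unwrap(phase[core]))
        assert np.mean(dphi) * FS / (2 * np.pi) == pytest.approx(70.0,
                                                                 rel=0.01)

    def test_zero_phase_symmetry(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=3000)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [60, 80], btype="bandpass", fs=FS, output="sos")
        y = sosfiltfilt(sos, x)
        y_rev = sosfiltfilt(sos, x[::-1])[::-1]
        # time-reversal symmetry away from the edge transients
        core = slice(300, 2700)
        assert np.allclose(y[core], y_rev[core], atol=2e-3)

    def test_chirp_attenuated_outside_band(self):
        from scipy.signal import chirp

        t = np.arange(0, 8000) / FS
        x = chirp(t, f0=10.0, f1=250.0, t1=8.0)
        _, amp = analysis.band_phase(x, FS)
        finst = 10.0 + (250.0 - 10.0) * t / 8.0
        in_band = (finst > 62) & (finst < 78)
        two_oct_out = (finst < 70 / 4) | (finst > 70 * 4)
        assert amp[two_oct_out].max() < 0.1 * amp[in_band].max()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            analysis.band_phase(np.zeros(100), 200.0, band=(60, 80))


class TestMorlet:
    def test_quarter_octave_grid(self):
        f = analysis.quarter_octave_freqs(1.0, 256.0)
        assert f[0] == 1.0 and f[-1] == pytest.approx(256.0)
        assert np.allclose(np.diff(np.log2(f)), 0.25)

    def test_single_tone_localized(self):
        t = np.arange(0, 4000) / FS
        x = np.sin(2 * np.pi * 64.0 * t)
        spec = analysis.morlet_spectrogram(x, FS)
        i64 = spec.nearest_freq_index(64.0)
        prof = spec.amplitude[:, 1000:3000].mean(axis=1)
        assert np.argmax(prof) == i64
        assert np.all(spec.amplitude >= 0)


class TestBursts1d:
    def test_constant_envelope_no_events(self):
        t = np.arange(0, 20000) / FS
        x = np.sin(2 * np.pi * 70.0 * t)  # constant envelope
        events = analysis.detect_bursts_1d(x, FS)
        # only filter edge transients may register; nothing in the bulk
        assert all(e.peak_time_ms < 300 or e.peak_time_ms > 19700
                   for e in events)

    def test_single_injected_burst_duration(self):
        t_ms = np.arange(0, 20000.0)
        rng = np.random.default_rng(1)
        x = 0.3 * rng.normal(size=t_ms.size)
        width = 40.0
        x += _gamma_burst(t_ms, 10000.0, width, amp=5.0)
        events = analysis.detect_bursts_1d(x, FS)
        assert len(events) == 1
        ev = events[0]
        # 25%-of-peak span of a Gaussian envelope: 2*sqrt(2 ln 4)*sigma
        expected = 2.0 * np.sqrt(2.0 * np.log(4.0)) * width
        assert ev.duration_ms == pytest.approx(expected, abs=18.0)
        assert abs(ev.peak_time_ms - 10000.0) < 10.0

    def test_two_bursts_ordered(self):
        t_ms = np.arange(0, 30000.0)
        rng = np.random.default_rng(2)
        x = 0.3 * rng.normal(size=t_ms.size)
        x += _gamma_burst(t_ms, 10000.0, 30.0, amp=4.0)
        x += _gamma_burst(t_ms, 20500.0, 30.0, amp=4.0)
        events = analysis.detect_bursts_1d(x, FS)
        assert len(events) == 2
        assert events[0].peak_time_ms < events[1].peak_time_ms

    def test_amplitude_scale_invariance(self):
        t_ms = np.arange(0, 20000.0)
        rng = np.random.default_rng(3)
        x = 0.3 * rng.normal(size=t_ms.size)
        x += _gamma_burst(t_ms, 9000.0, 35.0, amp=4.0)
        e1 = analysis.detect_bursts_1d(x, FS)
        e2 = analysis.detect_bursts_1d(x * 17.0, FS)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert a.onset_ms == b.onset_ms and a.offset_ms == b.offset_ms


class TestWatershed1d:
    def test_monotone_ramp_single_segment(self):
        lab = analysis.watershed_segments_1d(np.linspace(0, 1, 500))
        assert len(np.unique(lab)) == 1

    def test_single_peak_matches_region_growing(self):
        x = np.exp(-0.5 * ((np.arange(500) - 250) / 40.0) ** 2)
        lab = analysis.watershed_segments_1d(x, bin_step=0.0)
        assert len(np.unique(lab)) == 1

    def test_two_peaks_split_at_valley(self):
        g = np.arange(1000.0)
        x = (np.exp(-0.5 * ((g - 300) / 50) ** 2)
             + 0.8 * np.exp(-0.5 * ((g - 700) / 50) ** 2))
        lab = analysis.watershed_segments_1d(x, bin_step=0.01)
        assert len(np.unique(lab)) == 2
        assert lab[300] != lab[700]
        boundary = np.flatnonzero(np.diff(lab))[0]
        assert 400 < boundary < 600

    def test_percentiles_uniform_by_construction(self):
        rng = np.random.default_rng(4)
        power = np.abs(np.cumsum(rng.normal(size=30000))) + 1.0
        hist, pct_edges, dur_edges, df = analysis.burst_amplitude_duration_map(
            power, FS)
        if len(df) > 20:
            h, _ = np.histogram(df["percentile"], bins=np.arange(0, 101, 20))
            assert h.max() - h.min() <= max(2, 0.2 * len(df))


class TestBursts4d:
    @pytest.fixture(scope="class")
    def grid_fixture(self):
        return experiments.make_fixtures("synthetic_lfp_grid", seed=5)

    def test_ground_truth_recovery(self, grid_fixture):
        env, truth, spacing = grid_fixture
        events = analysis.detect_bursts_4d(env, spacing_um=spacing)
        big = [e for e in events if e.peak_amplitude > 2.5]
        assert len(big) == len(truth)
        big.sort(key=lambda e: e.onset_ms)
        for ev, tr in zip(big, truth):
            assert abs(ev.peak_amplitude - tr["peak_z"]) < 0.5
            assert tr["onset_ms"] <= ev.peak_time_ms <= (
                tr["onset_ms"] + tr["duration_ms"])
            assert ev.duration_ms <= tr["duration_ms"] + 20.0
        moving, stationary = big[0], big[1]
        # the centroid path accumulates noise jitter, so the start-to-end
        # displacement is compared with the injected translation
        assert moving.net_displacement_um == pytest.approx(
            truth[0]["path_length_um"], rel=0.35)
        assert stationary.net_displacement_um < 0.5 * moving.net_displacement_um
        assert moving.path_length_um >= moving.net_displacement_um
        assert moving.speed_um_per_ms == pytest.approx(
            moving.path_length_um / moving.duration_ms)

    def test_volume_matches_bruteforce_site_count(self, grid_fixture):
        env, truth, spacing = grid_fixture
        events = analysis.detect_bursts_4d(env, spacing_um=spacing)
        ev = max(events, key=lambda e: e.peak_amplitude)
        w = slice(int(ev.onset_ms), int(ev.offset_ms))
        brute = np.any(env[w] >= 2.0, axis=0).sum()
        assert 0 < ev.volume_sites <= brute

    def test_separated_blobs_are_distinct_events(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(6)
        env = gaussian_filter(rng.normal(size=(600, 9, 9, 9)),
                              sigma=(15.0, 0.8, 0.8, 0.8))
        env *= 0.1 / env.std()
        g = np.arange(9)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        blob1 = 3.5 * np.exp(-((X - 2) ** 2 + (Y - 2) ** 2 + (Z - 2) ** 2) / 4)
        blob2 = 3.5 * np.exp(-((X - 7) ** 2 + (Y - 7) ** 2 + (Z - 7) ** 2) / 4)
        env[100:160] += blob1
        env[400:460] += blob2
        events = [e for e in analysis.detect_bursts_4d(env, 125.0)
                  if e.peak_amplitude > 2.5]
        assert len(events) == 2

    def test_events_partition_supra_threshold_members(self, grid_fixture):
        env, truth, spacing = grid_fixture
        events = analysis.detect_bursts_4d(env, spacing_um=spacing)
        counts = np.zeros(env.shape, dtype=int)
        # reconstruct membership from labels: each (site,time) may belong
        # to at most one event region by construction of the watershed
        labels = [e.label for e in events]
        assert len(labels) == len(set(labels))

    def test_grid_without_time_axis_rejected(self):
        with pytest.raises(ValueError):
            analysis.detect_bursts_4d(np.zeros((9, 9, 9)), 125.0)


class TestEntrainment:
    def test_perfect_locking(self):
        phases = np.full(50, 1.2)
        rv, mp, ppc = analysis.rv_ppc(phases)
        assert rv == pytest.approx(1.0)
        assert mp == pytest.approx(1.2)
        assert ppc == pytest.approx(1.0)

    def test_uniform_phases_rv_near_zero_ppc_unbiased(self):
        rng = np.random.default_rng(7)
        ppcs = []
        for _ in range(200):
            ph = rng.uniform(-np.pi, np.pi, size=20)
            _, _, ppc = analysis.rv_ppc(ph)
            ppcs.append(ppc)
        # unbiased: expectation 0 regardless of n
        assert np.mean(ppcs) == pytest.approx(0.0, abs=0.02)

    def test_von_mises_closed_form(self):
        rng = np.random.default_rng(8)
        ph = rng.vonmises(0.0, 1.0, size=1000)
        rv, _, ppc = analysis.rv_ppc(ph)
        expected = special.i1(1.0) / special.i0(1.0)
        assert rv == pytest.approx(expected, abs=0.03)
        assert ppc == pytest.approx(rv**2, abs=0.05)

    def test_entrainment_sentinels(self):
        phase = np.zeros(1000)
        r = analysis.entrainment([1.0, 2.0, 3.0], phase, FS)
        assert np.isnan(r.rv)  # < 10 spikes
        assert np.isfinite(r.ppc)
        r2 = analysis.entrainment([1.0], phase, FS)
        assert np.isnan(r2.ppc)

    def test_plv_unbiased_zero_for_independent(self):
        rng = np.random.default_rng(9)
        vals = [analysis.plv_unbiased(rng.uniform(-np.pi, np.pi, 50))
                for _ in range(300)]
        assert np.mean(vals) == pytest.approx(0.0, abs=0.02)


class TestSpikeCoherence:
    def test_identical_trains_full_coherence(self):
        rng = np.random.default_rng(10)
        train = np.sort(rng.uniform(0, 30000, size=600))
        f, coh, lags, cxc = analysis.spike_coherence(train, train, 30000.0)
        assert np.nanmax(np.abs(coh - 1.0)) < 1e-6

    def test_independent_trains_low_coherence(self):
        rng = np.random.default_rng(11)
        a = np.sort(rng.uniform(0, 60000, size=1200))
        b = np.sort(rng.uniform(0, 60000, size=1200))
        f, coh, _, _ = analysis.spike_coherence(a, b, 60000.0)
        assert np.nanmedian(coh) < 0.25

    def test_jittered_offset_copy_peaks_at_lag(self):
        rng = np.random.default_rng(12)
        a = np.sort(rng.uniform(100, 59000, size=2000))
        b = a + 4.0 + rng.normal(0, 2.0, size=a.size)
        f, coh, lags, cxc = analysis.spike_coherence(a, b, 60000.0)
        assert lags[np.argmax(cxc)] == pytest.approx(4.0, abs=2.0)

    def test_empty_train_sentinel(self):
        f, coh, lags, cxc = analysis.spike_coherence([], [1.0, 2.0], 100.0)
        assert np.all(np.isnan(coh))


class TestSpectrumHelpers:
    def test_gamma_peak_of_synthetic_bump(self):
        rng = np.random.default_rng(13)
        t = np.arange(0, 30000) / FS
        # pink-ish background + 64-Hz bump
        from scipy.signal import sosfilt, butter

        sos = butter(1, 40.0, fs=FS, output="sos")
        x = sosfilt(sos, rng.normal(size=t.size)) * 3
        x += 0.8 * np.sin(2 * np.pi * 64.0 * t) * (
            1 + 0.5 * np.sin(2 * np.pi * 0.5 * t))
        assert analysis.gamma_peak(x, FS) == pytest.approx(64.0, abs=3.0)
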