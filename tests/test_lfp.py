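"""Line-source forward model: closed-form limits, refinement consistency,
superposition, density/edge corrections, electrode grids."""

import numpy as np
import pytest

from blgamma import engine, lfp, network


class TestLineSource:
    def test_zero_current_zero_potential(self):
        phi = lfp.line_source_potential([0, 0, 0], [0, 0, 10], 0.0,
                                        [50, 0, 5])
        assert phi == 0.0

    def test_far_field_matches_point_source(self):
        ds = 10.0
        i_nA = 2.0
        for d in (200.0, 500.0):
            phi = lfp.line_source_potential([0, 0, 0], [0, 0, ds], i_nA,
                                            [d, 0, ds / 2])
            point = i_nA * 1e3 / (4 * np.pi * lfp.SIGMA_S_PER_M * d)
            assert phi == pytest.approx(point, rel=0.01)

    def test_subdivision_consistency(self):
        """10 collinear sub-segments carrying I/10 give the same potential
        as the single segment within 0.1%."""
        start, end = np.array([0.0, 0, 0]), np.array([0.0, 0, 100.0])
        electrode = np.array([35.0, 10.0, 40.0])
        whole = lfp.line_source_potential(start, end, 1.0, electrode)
        parts = 0.0
        for k in range(10):
            a = start + (end - start) * k / 10
            b = start + (end - start) * (k + 1) / 10
            parts += lfp.line_source_potential(a, b, 0.1, electrode)
        assert parts == pytest.approx(whole, rel=1e-3)

    def test_near_axis_guard(self):
        phi = lfp.line_source_potential([0, 0, 0], [0, 0, 10], 1.0,
                                        [0.0, 0.0, 20.0], guard_um=1.0)
        assert np.isfinite(phi)


@pytest.fixture(scope="module")
def single_cell_trace(pn_c_module=None):
    """One PN driven by a suprathreshold apical EPSC, with membrane
    currents recorded."""
    from blgamma import cells, synapses

    pn = cells.load_archetype("PN_C")
    classes = synapses.load_synapse_classes()
    ampa = classes["PN_PN"]["receptors"]["AMPA"]
    res = engine.simulate_cell(
        pn, duration_ms=400.0, record_stride=1, record_imem=True,
        synapses=[(ampa, "a-dend-dist", 60.0, None, [300.0])],
    )
    placement = network.Placement(
        archetypes=np.array(["PN_C"]),
        positions=np.array([[0.0, 0.0, 0.0]]),
        orientations=np.array([[0.0, 0.0, 1.0]]),
        box_um=1.0, min_spacing_um=0.0,
    )
    return res, placement


class TestComputeLfp:
    def test_linearity_in_source_currents(self, single_cell_trace):
        res, placement = single_cell_trace
        el = [np.array([40.0, 0.0, 0.0])]
        rec1 = lfp.compute_lfp(res.traces, placement, el)
        doubled = res.traces
        import copy

        t2 = copy.copy(doubled)
        t2.imem = doubled.imem * 2.0
        rec2 = lfp.compute_lfp(t2, placement, el)
        assert np.allclose(rec2.potentials, 2.0 * rec1.potentials)

    def test_spike_field_negative_near_soma_positive_at_dendrite(
            self, single_cell_trace):
        res, placement = single_cell_trace
        near_soma = lfp.compute_lfp(res.traces, placement,
                                    [np.array([30.0, 0.0, 0.0])])
        near_dend = lfp.compute_lfp(res.traces, placement,
                                    [np.array([30.0, 0.0, 300.0])])
        w = slice(300, 310)
        assert near_soma.potentials[w, 0].min() < 0
        # dendritic return current renders the far pole positive
        assert near_dend.potentials[w, 0].max() > 0

    def test_amplitude_decays_with_lateral_distance(self, single_cell_trace):
        res, placement = single_cell_trace
        amps = []
        for d in (30.0, 60.0, 120.0, 240.0, 480.0):
            rec = lfp.compute_lfp(res.traces, placement,
                                  [np.array([d, 0.0, 0.0])])
            amps.append(np.abs(rec.potentials[295:320, 0]).max())
        assert all(a > b for a, b in zip(amps, amps[1:]))
        # exponential fit of the decay is decent (log-linear correlation)
        r = np.corrcoef(np.array([30, 60, 120, 240, 480.0]),
                        np.log(amps))[0, 1]
        assert r < -0.9

    def test_far_field_falls_at_least_like_dipole(self, single_cell_trace):
        """Per-cell current conservation makes the far field fall at least
        as fast as 1/d^2 (cell extent ~600 um -> probe at 10x)."""
        res, placement = single_cell_trace
        d1, d2 = 6000.0, 12000.0
        a = []
        for d in (d1, d2):
            rec = lfp.compute_lfp(res.traces, placement,
                                  [np.array([d, 0.0, 0.0])])
            a.append(np.abs(rec.potentials[295:320, 0]).max())
        assert a[0] / a[1] >= (d2 / d1) ** 2 * 0.9

    def test_missing_currents_rejected(self, single_cell_trace):
        res, placement = single_cell_trace
        import copy

        t = copy.copy(res.traces)
        t.imem = None
        with pytest.raises(ValueError):
            lfp.compute_lfp(t, placement, [np.zeros(3)])


class TestDensityCorrection:
    def test_printed_endpoints_and_default(self):
        lo = lfp.density_correction(9.84e3, 2.5e4)
        hi = lfp.density_correction(9.84e3, 2.0e5)
        assert lo == pytest.approx(1.9, abs=0.05)
        assert hi == pytest.approx(7.5, abs=0.05)
        assert 0.5 * (lo + hi) == pytest.approx(4.7, abs=0.05)
        assert lfp.density_correction() == pytest.approx(4.7, abs=0.05)

    def test_equal_densities_unity(self):
        assert lfp.density_correction(5e4, 5e4) == 1.0

    def test_invalid_densities(self):
        with pytest.raises(ValueError):
            lfp.density_correction(0.0, 1e4)


class TestElectrodeGrid:
    def test_full_scale_grid_geometry(self):
        pts, shape = lfp.electrode_grid(1400.0)
        assert shape == (9, 9, 9) and len(pts) == 729
        xs = np.unique(pts[:, 0])
        assert np.allclose(np.diff(xs), 125.0)
        assert xs.max() - xs.min() == pytest.approx(1000.0)
        assert xs.min() >= 200.0 and xs.max() <= 1200.0

    def test_center_index(self):
        assert lfp.center_electrode_index((9, 9, 9)) == 4 * 81 + 4 * 9 + 4


class TestEdgeCorrection:
    def _make_record(self, gains, seed=0, n=3, nt=20000):
        """Synthetic grid: common pink-ish noise + gamma bump whose
        amplitude per electrode is scaled by ``gains``."""
        rng = np.random.default_rng(seed)
        t = np.arange(nt) / 1000.0
        base = rng.normal(size=(nt, n**3))
        from scipy.signal import sosfilt, butter

        sos = butter(2, 30.0, fs=1000.0, output="sos")
        slow = sosfilt(sos, rng.normal(size=(nt, n**3)), axis=0) * 4
        gamma = np.sin(2 * np.pi * 65.0 * t)[:, None] * (
            1.0 + 0.3 * rng.normal(size=(nt, 1)))
        pot = base + slow + gamma * np.asarray(gains)[None, :]
        return lfp.LfpRecord(potentials=pot, positions=np.zeros((n**3, 3)),
                             grid_shape=(n, n, n))

    def test_homogeneous_spectra_give_unity(self):
        rec = self._make_record(np.ones(27))
        F = lfp.edge_correction(rec)
        assert np.allclose(F, 1.0, atol=0.15)
        assert F[lfp.center_electrode_index((3, 3, 3))] == pytest.approx(1.0)

    def test_attenuated_edges_recover_inverse_ratio(self):
        gains = np.ones(27)
        gains[0] = 0.5  # corner electrode: gamma amplitude halved
        rec = self._make_record(gains)
        F = lfp.edge_correction(rec)
        # brute-force oracle: gamma fraction ratio from the same spectra
        assert F[0] < 0.6  # power scales with amplitude^2 -> ~0.25 fraction
        assert F[13] == pytest.approx(1.0)

    def test_requires_grid(self):
        rec = lfp.LfpRecord(potentials=np.zeros((100, 2)),
                            positions=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            lfp.edge_correction(rec)
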