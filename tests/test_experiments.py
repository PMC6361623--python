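"""Experiment protocols: fixtures, manifests, group assignment, and the
phase-conditioned synaptic-current analyses on constructed data."""

import numpy as np
import pytest

from blgamma import analysis, experiments, network


class TestFixtures:
    def test_two_cell_motif(self):
        placement, graph = experiments.make_fixtures("two_cell_motif")
        assert placement.n_cells == 2
        assert set(graph.edges["type"]) == {"PN_FSI", "FSI_PN"}

    def test_fifty_cell_net_runs(self):
        placement, graph = experiments.make_fixtures("fifty_cell_net", seed=3)
        assert placement.n_cells == 50
        intrinsic = graph.edges[~graph.edges["type"].str.startswith("AFF")]
        assert not np.any(intrinsic["src"] == intrinsic["dst"])

    def test_reduced_bl_1000_recipe(self):
        recipe, placement, graph = experiments.make_fixtures(
            "reduced_bl_1000", seed=1)
        assert placement.n_cells == 1000
        assert recipe.density_per_mm3 == pytest.approx(
            network.full_recipe().density_per_mm3)
        # all connection classes realized
        assert {"PN_PN", "PN_FSI", "FSI_PN", "FSI_FSI", "GAP",
                "AFF_PN"} <= set(graph.edges["type"])

    def test_fixtures_deterministic(self):
        a = experiments.make_fixtures("synthetic_lfp_grid", seed=9)
        b = experiments.make_fixtures("synthetic_lfp_grid", seed=9)
        assert np.array_equal(a[0], b[0])

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            experiments.make_fixtures("bogus")


class TestProtocol:
    def test_manifest_roundtrip(self):
        p = experiments.Protocol(seed=4, ablate="FSI_PN", duration_ms=1234.0)
        m = p.manifest()
        p2 = experiments.Protocol(**m)
        assert p2 == p

    def test_ablation_removes_only_named_type(self):
        proto = experiments.Protocol(seed=2, n_cells=300, ablate="FSI_PN",
                                     afferent_mode="none")
        _, _, graph, _, _ = experiments.build_reduced_model(proto)
        base = experiments.Protocol(seed=2, n_cells=300, afferent_mode="none")
        _, _, g0, _, _ = experiments.build_reduced_model(base)
        assert len(graph.of_type("FSI_PN")) == 0
        for et in ("PN_PN", "PN_FSI", "FSI_FSI", "GAP"):
            assert len(graph.of_type(et)) == len(g0.of_type(et))

    def test_weight_compensation_ratios(self):
        recipe, placement, graph = experiments.make_fixtures(
            "reduced_bl_1000", seed=1)
        ws = experiments.indegree_weight_compensation(placement, graph)
        pn = placement.pn_index
        realized = graph.in_degree("FSI_PN")[pn].mean()
        assert ws["FSI_PN"] == pytest.approx(42.6 / realized)
        assert "PN_PN" not in ws


class TestGroupAssignment:
    @pytest.fixture(scope="class")
    def placement(self):
        recipe = network.reduced_recipe(1000)
        return network.place_cells(recipe, seed=6)

    def test_random_groups_disjoint(self, placement):
        cfg = experiments.CompetitionConfig(seed=0, group_size=100)
        rng = np.random.default_rng(0)
        g1, g2 = experiments._assign_groups(cfg, placement, rng)
        assert len(set(g1) & set(g2)) == 0
        assert len(g1) == len(g2) == 100
        arch = placement.archetypes
        assert np.all(arch[g1] != "FSI") and np.all(arch[g2] != "FSI")

    def test_segregated_spheroids_are_separated(self, placement):
        cfg = experiments.CompetitionConfig(seed=0, group_size=60,
                                            mode="spheroid", overlap=False)
        rng = np.random.default_rng(1)
        g1, g2 = experiments._assign_groups(cfg, placement, rng)
        c1 = placement.positions[g1].mean(axis=0)
        c2 = placement.positions[g2].mean(axis=0)
        assert np.linalg.norm(c1 - c2) > cfg.spheroid_radius_um
        # overlap mode: groups share the same region
        cfg2 = experiments.CompetitionConfig(seed=0, group_size=60,
                                             mode="spheroid", overlap=True)
        h1, h2 = experiments._assign_groups(cfg2, placement,
                                            np.random.default_rng(2))
        d = np.linalg.norm(placement.positions[h1].mean(axis=0)
                           - placement.positions[h2].mean(axis=0))
        assert d < 100.0


class TestBurstTriggeredRate:
    def test_fsi_follows_pn_bursts_in_construction(self):
        rng = np.random.default_rng(3)
        duration = 20000.0
        burst_times = np.arange(500.0, duration - 500.0, 200.0)
        pn = np.concatenate([
            t + rng.uniform(0, 2, size=30) for t in burst_times
        ])
        fsi = np.concatenate([
            t + 6.0 + rng.uniform(0, 2, size=20) for t in burst_times
        ])
        lags, rate = experiments.pn_burst_triggered_fsi_rate(
            pn, fsi, duration, smooth_ms=1.0)
        peak_lag = lags[np.nanargmax(rate)]
        assert 0 < peak_lag < 15


class TestPhaseConditionedPsc:
    def _phase_series(self, nt, freq=64.0, fs=1000.0):
        t = np.arange(nt) / fs
        return np.angle(np.exp(1j * 2 * np.pi * freq * t))

    def test_phase_independent_currents_flat_difference(self):
        rng = np.random.default_rng(4)
        nt = 60000
        phase = self._phase_series(nt)
        psc = rng.normal(size=nt)
        spikes = rng.uniform(0, nt, size=400)
        grid, m_sp, m_no, diff = experiments.phase_conditioned_psc(
            psc, phase, spikes, 1000.0)
        assert np.nanstd(diff) < 0.2

    def test_injected_epsc_on_spike_cycles_recovered(self):
        rng = np.random.default_rng(5)
        nt = 60000
        fs = 1000.0
        phase = self._phase_series(nt, freq=64.0)
        psc = 0.05 * rng.normal(size=nt)
        wraps = np.flatnonzero(np.diff(phase) < -np.pi)
        spike_cycles = wraps[::2]
        spikes = []
        for i0 in spike_cycles[:-1]:
            # inject a negative (inward) deflection on "spike" cycles
            psc[i0 + 3: i0 + 9] -= 1.0
            spikes.append((i0 + 5) / fs * 1000.0)
        grid, m_sp, m_no, diff = experiments.phase_conditioned_psc(
            psc, phase, np.asarray(spikes), fs)
        assert np.nanmin(diff) < -0.5
        assert np.nanmax(np.abs(m_no)) < 0.25


class TestEpscSensitivity:
    def test_phase_independent_spiking_uniform_across_quadrants(self):
        rng = np.random.default_rng(6)
        n = 20000
        strength = rng.exponential(1.0, size=n)
        p = 1.0 / (1.0 + np.exp(-(strength - 1.0)))
        flags = rng.random(n) < p
        phases = rng.uniform(-np.pi, np.pi, size=n)
        df = experiments.epsc_sensitivity_by_phase(strength, flags, phases)
        piv = df.pivot_table(index="strength_bin", columns="quadrant",
                             values="p_spike")
        spread = (piv.max(axis=1) - piv.min(axis=1)).mean()
        assert spread < 0.08
        # monotone dependence on strength within each quadrant
        for q in range(4):
            sub = df[df.quadrant == q].sort_values("strength_bin")
            assert sub["p_spike"].iloc[-1] > sub["p_spike"].iloc[0]

    def test_phase_gated_spiking_detected(self):
        rng = np.random.default_rng(7)
        n = 20000
        strength = rng.exponential(1.0, size=n)
        phases = rng.uniform(-np.pi, np.pi, size=n)
        gate = np.abs(phases) > np.pi / 2  # spiking allowed near the trough
        p = gate * (1.0 / (1.0 + np.exp(-(strength - 1.0))))
        flags = rng.random(n) < p
        df = experiments.epsc_sensitivity_by_phase(strength, flags, phases)
        by_q = df.groupby("quadrant")["p_spike"].mean()
        assert max(by_q[0], by_q[3]) > 2 * max(by_q[1], by_q[2], 1e-9)
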