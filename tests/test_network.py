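"""Placement, wiring statistics and delays, checked against brute-force
pair enumeration and analytic expectations."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from blgamma import network


@pytest.fixture(scope="module")
def small_net():
    recipe = network.reduced_recipe(1000)
    placement = network.place_cells(recipe, seed=7)
    graph = network.wire_intrinsic(placement, recipe, seed=8)
    return recipe, placement, graph


class TestPlacement:
    def test_counts_and_spacing(self, small_net):
        recipe, placement, _ = small_net
        arch = placement.archetypes
        assert (arch == "PN_A").sum() == recipe.n_pn_a
        assert (arch == "PN_C").sum() == recipe.n_pn_c
        assert (arch == "FSI").sum() == recipe.n_fsi
        assert np.all(placement.positions >= 0)
        assert np.all(placement.positions <= recipe.box_um)
        d, _ = cKDTree(placement.positions).query(placement.positions, k=2)
        assert d[:, 1].min() > recipe.min_spacing_um

    def test_full_recipe_counts_and_density(self):
        full = network.full_recipe()
        assert (full.n_pn_a, full.n_pn_c, full.n_fsi) == (17280, 7020, 2700)
        assert full.density_per_mm3 == pytest.approx(27000 / 1.4**3)
        assert full.density_per_mm3 == pytest.approx(9840, rel=0.001)

    def test_reduced_recipe_preserves_density(self):
        red = network.reduced_recipe(1000)
        assert red.density_per_mm3 == pytest.approx(
            network.full_recipe().density_per_mm3, rel=1e-6)

    def test_determinism(self):
        recipe = network.reduced_recipe(200)
        p1 = network.place_cells(recipe, seed=3)
        p2 = network.place_cells(recipe, seed=3)
        assert np.array_equal(p1.positions, p2.positions)
        assert np.array_equal(p1.archetypes, p2.archetypes)

    def test_orientations_are_unit(self, small_net):
        _, placement, _ = small_net
        norms = np.linalg.norm(placement.orientations, axis=1)
        assert np.allclose(norms, 1.0)

    def test_infeasible_packing_raises(self):
        recipe = network.Recipe(n_pn_a=500, n_pn_c=0, n_fsi=0, box_um=100.0,
                                min_spacing_um=40.0)
        with pytest.raises(RuntimeError):
            network.place_cells(recipe, seed=0)


class TestDelays:
    def test_printed_constants(self):
        assert network.conduction_delay(0.0) == pytest.approx(0.85)
        assert network.conduction_delay(1000.0) == pytest.approx(1.85)

    def test_fluctuation_bounds(self, rng):
        d = network.conduction_delay(np.zeros(10000), rng)
        assert d.min() >= 0.75
        assert d.max() <= 0.95

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            network.conduction_delay(-1.0)


class TestIntrinsicWiring:
    def test_no_autapses_and_typed_ranges(self, small_net):
        recipe, placement, graph = small_net
        e = graph.edges
        assert not np.any(e["src"].to_numpy() == e["dst"].to_numpy())
        pos = placement.positions
        for etype in ("PN_FSI", "FSI_PN", "FSI_FSI", "GAP"):
            sub = graph.of_type(etype)
            d = np.linalg.norm(pos[sub["src"]] - pos[sub["dst"]], axis=1)
            assert d.max() <= recipe.fsi_range_um + 1e-9
        pp = graph.of_type("PN_PN")
        d = np.linalg.norm(pos[pp["src"]] - pos[pp["dst"]], axis=1)
        assert d.max() <= 600.0

    def test_pn_pn_indegree_matches_bruteforce_expectation(self, small_net):
        """Mean in-degree vs the analytic expectation from brute-force
        pair enumeration (sum of distance-bin probabilities)."""
        recipe, placement, graph = small_net
        pn = placement.pn_index
        pos = placement.positions[pn]
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        expect = network._pn_pn_prob(dist.ravel(), recipe.pn_pn_bins).sum()
        expected_mean = expect / len(pn)
        realized = graph.in_degree("PN_PN")[pn].mean()
        sd = np.sqrt(expect) / len(pn)  # Poisson-binomial SEM of the mean
        assert abs(realized - expected_mean) < 3 * sd + 0.05

    def test_pn_fsi_outcome_probabilities(self, small_net):
        recipe, placement, graph = small_net
        pos = placement.positions
        pn, fsi = placement.pn_index, placement.fsi_index
        tree = cKDTree(pos[fsi])
        lists = tree.query_ball_point(pos[pn], r=recipe.fsi_range_um)
        n_pairs = sum(len(x) for x in lists)
        n_fp = len(graph.of_type("FSI_PN"))
        n_pf = len(graph.of_type("PN_FSI"))
        # FSI->PN edges arise with p = 0.34 + 0.16, PN->FSI with 0.12 + 0.16
        assert n_fp / n_pairs == pytest.approx(0.50, abs=0.02)
        assert n_pf / n_pairs == pytest.approx(0.28, abs=0.02)

    def test_fsi_fsi_conditional_probabilities(self):
        """Chemical FSI-FSI probabilities conditioned on electrical
        coupling, pooled over seeds, within 3 binomial SD."""
        recipe = network.Recipe(n_pn_a=0, n_pn_c=0, n_fsi=120, box_um=280.0)
        stats = {"coupled": [0, 0], "uncoupled": [0, 0]}  # [uni+bi edges, pairs]
        chem_counts = {"coupled": [0, 0, 0], "uncoupled": [0, 0, 0]}
        for seed in range(12):
            placement = network.place_cells(recipe, seed=seed)
            graph = network.wire_intrinsic(placement, recipe, seed=seed + 100)
            pos = placement.positions
            pairs = cKDTree(pos).query_pairs(recipe.fsi_range_um)
            gap = set()
            for _, r in graph.of_type("GAP").iterrows():
                gap.add((min(r.src, r.dst), max(r.src, r.dst)))
            chem = {}
            for _, r in graph.of_type("FSI_FSI").iterrows():
                key = (min(r.src, r.dst), max(r.src, r.dst))
                chem[key] = chem.get(key, 0) + 1
            for pair in pairs:
                key = tuple(sorted(pair))
                kind = "coupled" if key in gap else "uncoupled"
                n = chem.get(key, 0)
                chem_counts[kind][n] += 1
        for kind, (p_uni, p_bi) in (("coupled", (0.50, 0.25)),
                                    ("uncoupled", (0.19, 0.03))):
            none, uni, bi = chem_counts[kind]
            total = none + uni + bi
            for observed, p in ((uni, p_uni), (bi, p_bi)):
                sd = np.sqrt(p * (1 - p) * total)
                assert abs(observed - p * total) < 3 * sd + 2

    def test_gap_edges_symmetric_storage(self, small_net):
        _, _, graph = small_net
        gap = graph.of_type("GAP")
        keys = set(zip(gap["src"], gap["dst"]))
        for (s, d) in keys:
            assert (d, s) not in keys  # stored once per pair


class TestAfferents:
    def test_extrinsic_indegree_binomial(self):
        recipe = network.reduced_recipe(1000)
        placement = network.place_cells(recipe, seed=1)
        aff = network.wire_afferents(placement, recipe, seed=2)
        pn = placement.pn_index
        deg = np.bincount(aff[aff["type"] == "AFF_PN"]["dst"],
                          minlength=placement.n_cells)[pn]
        n, p = recipe.n_afferents, recipe.afferent_fan_out / len(pn)
        assert deg.mean() == pytest.approx(n * p, rel=0.05)
        assert deg.std() == pytest.approx(np.sqrt(n * p * (1 - p)), rel=0.1)

    def test_zero_rate_edge_cases(self):
        recipe = network.Recipe(n_pn_a=30, n_pn_c=10, n_fsi=5, box_um=300.0,
                                n_afferents=4, afferent_fan_out=10)
        placement = network.place_cells(recipe, seed=0)
        aff = network.wire_afferents(placement, recipe, seed=1)
        per_aff = aff[aff["type"] == "AFF_PN"].groupby("src").size()
        assert (per_aff == 10).all()


class TestSerialization:
    def test_roundtrip(self, small_net):
        recipe, placement, graph = small_net
        p2 = network.Placement.from_table(placement.to_table(),
                                          box_um=recipe.box_um)
        assert np.allclose(p2.positions, placement.positions)
        assert np.array_equal(p2.archetypes, placement.archetypes)
        g2 = network.ConnectivityGraph.from_table(graph.to_table(),
                                                  n_cells=graph.n_cells)
        assert g2.edges.equals(graph.edges.reset_index(drop=True))
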