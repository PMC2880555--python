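import numpy as np
import pytest
from dataclasses import replace

import columnet as cn
from columnet.network import (
    PROJ_CODE,
    ConnectivityParams,
    NetworkSpec,
    build_connectivity,
    build_layer4,
    build_patterns,
    attach_noise,
    count_cells,
    count_synapses,
    expected_synapse_counts,
    layout,
)


class TestLayout:
    def test_degenerate_single_minicolumn(self):
        spec = NetworkSpec(n_hypercolumns=1, n_minicolumns_per_hc=1)
        geo = layout(spec)
        assert geo.mc_centers.shape == (1, 2)
        # 30 pyramidal z positions span 500 µm
        z = geo.positions[geo.cells_of_type("pyramidal"), 2]
        assert len(z) == 30
        assert z.max() - z.min() == pytest.approx(500.0)
        assert len(np.unique(z)) == 30

    def test_standard_grid_geometry(self):
        spec = NetworkSpec()
        geo = layout(spec)
        assert geo.mc_centers.shape == (441, 2)
        # all centres inside the 1.5 mm square
        assert np.all((geo.mc_centers >= 0) & (geo.mc_centers <= 1500.0))
        # pairwise distances bounded by the square diagonal
        from scipy.spatial.distance import pdist

        assert pdist(geo.mc_centers).max() <= 1500.0 * np.sqrt(2)

    def test_minicolumn_cells_share_xy_interneurons_at_z_centre(self, tiny_spec):
        geo = layout(tiny_spec)
        for m in range(tiny_spec.n_minicolumns):
            cells = np.flatnonzero(geo.cell_mc == m)
            assert np.ptp(geo.positions[cells, 0]) == 0
            assert np.ptp(geo.positions[cells, 1]) == 0
        inter = geo.positions[geo.cell_type_code != 0, 2]
        assert np.all(inter == 0.0)

    def test_hypercolumns_are_contiguous_blocks(self):
        spec = NetworkSpec()
        geo = layout(spec)
        # bounding boxes of distinct hypercolumns do not overlap (7x7 blocks)
        boxes = []
        for hc in range(9):
            c = geo.mc_centers[geo.mc_hc == hc]
            boxes.append((c[:, 0].min(), c[:, 0].max(), c[:, 1].min(), c[:, 1].max()))
        for i in range(9):
            for j in range(i + 1, 9):
                a, b = boxes[i], boxes[j]
                disjoint_x = a[1] < b[0] or b[1] < a[0]
                disjoint_y = a[3] < b[2] or b[3] < a[2]
                assert disjoint_x or disjoint_y


class TestCounts:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            ({}, 14_553),  # standard network
            ({"n_hypercolumns": 1, "n_minicolumns_per_hc": 1}, 33),
            # modularity-scan variant: 4 hc, 67 pyr, RSNP removed
            (
                {"n_hypercolumns": 4, "n_pyr_per_mc": 67, "rsnp_enabled": False},
                4 * 49 * 68,
            ),
        ],
    )
    def test_count_cells(self, kwargs, expected):
        assert count_cells(NetworkSpec(**kwargs)) == expected

    def test_empty_table_counts_zero(self, tiny_spec):
        spec = replace(
            tiny_spec, n_hypercolumns=1, n_minicolumns_per_hc=1,
            rsnp_enabled=False,
            connectivity=ConnectivityParams(
                local_pyr_pyr_p=0.0, basket_pyr_p=0.0, basket_basket_p=0.0,
                lr_pyr_in_degree=0, rsnp_lr_in_degree=0, n_closest_baskets=0,
            ),
        )
        net = cn.build_network(spec)
        assert count_synapses(net.connectivity) == 0

    def test_realized_count_within_3_sigma_of_expectation(self):
        spec = NetworkSpec(
            n_hypercolumns=3, n_minicolumns_per_hc=5, n_pyr_per_mc=10,
            connectivity=ConnectivityParams(
                lr_pyr_in_degree=10, rsnp_lr_in_degree=5, n_closest_baskets=3
            ),
        )
        net = cn.build_network(spec)
        realized, report = count_synapses(net.connectivity, spec)
        mean, sd = report["total"]["mean"], np.sqrt(report["total"]["var"])
        assert abs(realized - mean) <= 3 * sd
        for name, row in report.items():
            if name == "total" or "realized" not in row:
                continue
            assert abs(row["realized"] - row["mean"]) <= max(
                3 * np.sqrt(row["var"]), 1e-9
            )


class TestConnectivityRules:
    def test_no_self_edges_and_unique_pairs_per_projection(self, tiny_network):
        tbl = tiny_network.connectivity
        assert np.all(tbl.pre != tbl.post)
        keys = set(zip(tbl.pre.tolist(), tbl.post.tolist(), tbl.projection.tolist()))
        assert len(keys) == len(tbl)

    def test_long_range_in_degree_is_exact(self, tiny_spec, tiny_network):
        tbl = tiny_network.connectivity
        sel = tbl.projection == PROJ_CODE["pyr_pyr_global"]
        posts, counts = np.unique(tbl.post[sel], return_counts=True)
        pyr = tiny_network.geometry.cells_of_type("pyramidal")
        assert set(posts) == set(pyr)
        assert np.all(counts == tiny_spec.connectivity.lr_pyr_in_degree)

    def test_long_range_sources_are_same_pattern_other_hypercolumn(self, tiny_network):
        geo, pat = tiny_network.geometry, tiny_network.patterns
        tbl = tiny_network.connectivity
        sel = tbl.projection == PROJ_CODE["pyr_pyr_global"]
        pre, post = tbl.pre[sel], tbl.post[sel]
        assert np.all(geo.cell_hc[pre] != geo.cell_hc[post])
        assert np.all(
            pat.mc_pattern[geo.cell_mc[pre]] == pat.mc_pattern[geo.cell_mc[post]]
        )

    def test_local_in_degree_matches_binomial_expectation(self):
        spec = NetworkSpec(n_hypercolumns=1, n_minicolumns_per_hc=4,
                           n_pyr_per_mc=30)
        net = cn.build_network(spec)
        tbl = net.connectivity
        sel = tbl.projection == PROJ_CODE["pyr_pyr_local"]
        n_pyr = len(net.geometry.cells_of_type("pyramidal"))
        mean_in = np.count_nonzero(sel) / n_pyr
        expected = 0.25 * 29
        sd = np.sqrt(n_pyr * 29 * 0.25 * 0.75) / n_pyr
        assert abs(mean_in - expected) <= 4 * sd

    def test_single_minicolumn_has_no_long_range_and_no_rsnp_afferents(self):
        spec = NetworkSpec(n_hypercolumns=1, n_minicolumns_per_hc=1)
        net = cn.build_network(spec)
        tbl = net.connectivity
        assert np.count_nonzero(tbl.projection == PROJ_CODE["pyr_pyr_global"]) == 0
        assert np.count_nonzero(tbl.projection == PROJ_CODE["pyr_rsnp_global"]) == 0

    def test_determinism_identical_seeds(self, tiny_spec):
        a = cn.build_network(tiny_spec).connectivity
        b = cn.build_network(tiny_spec).connectivity
        for attr in ("pre", "post", "projection", "target", "delay_ms",
                     "g_ampa", "g_nmda", "g_gaba"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))

    def test_different_seed_differs(self, tiny_spec):
        other = replace(tiny_spec, seeds={"connectivity": 99})
        a = cn.build_network(tiny_spec).connectivity
        b = cn.build_network(other).connectivity
        assert len(a) != len(b) or not np.array_equal(a.pre, b.pre)

    def test_excitation_gain_scales_only_recurrent_excitation(self, tiny_spec):
        base = cn.build_network(tiny_spec).connectivity
        scaled = cn.build_network(replace(tiny_spec, excitation_gain=2.0)).connectivity
        assert np.array_equal(base.pre, scaled.pre)  # wiring unchanged
        gain_projs = [PROJ_CODE[p] for p in
                      ("pyr_pyr_local", "pyr_pyr_global", "pyr_rsnp_global")]
        in_gain = np.isin(base.projection, gain_projs)
        assert np.allclose(scaled.g_ampa[in_gain], 2 * base.g_ampa[in_gain])
        assert np.allclose(scaled.g_nmda[in_gain], 2 * base.g_nmda[in_gain])
        assert np.allclose(scaled.g_ampa[~in_gain], base.g_ampa[~in_gain])
        assert np.allclose(scaled.g_gaba, base.g_gaba)

    def test_nmda_disabled_zeroes_nmda_conductance(self, tiny_spec):
        net = cn.build_network(replace(tiny_spec, nmda_enabled=False))
        assert np.all(net.connectivity.g_nmda == 0)

    def test_delays_follow_distance_rule(self, tiny_network):
        tbl = tiny_network.connectivity
        pos = tiny_network.geometry.positions
        d = np.linalg.norm(pos[tbl.pre] - pos[tbl.post], axis=1)
        assert tbl.delay_ms == pytest.approx(d / 200.0 + 0.5)
        assert np.all(tbl.delay_ms >= 0.5)

    def test_in_degree_exceeding_pool_is_configuration_error(self, tiny_spec):
        bad = replace(
            tiny_spec,
            connectivity=replace(tiny_spec.connectivity, lr_pyr_in_degree=500),
        )
        with pytest.raises(ValueError, match="in-degree"):
            cn.build_network(bad)


class TestPatterns:
    def test_patterns_partition_minicolumns(self, tiny_spec, tiny_network):
        pat = tiny_network.patterns
        seen = np.zeros(tiny_spec.n_minicolumns, dtype=int)
        for p in range(pat.n_patterns):
            seen[pat.minicolumns(p)] += 1
        assert np.all(seen == 1)  # each mc in exactly one pattern

    def test_pattern_spans_every_hypercolumn_once(self, tiny_spec, tiny_network):
        geo = tiny_network.geometry
        for p in range(tiny_network.patterns.n_patterns):
            mcs = tiny_network.patterns.minicolumns(p)
            assert sorted(geo.mc_hc[mcs]) == list(range(tiny_spec.n_hypercolumns))


class TestNoiseAndLayer4:
    def test_noise_disabled_gives_no_bindings(self, tiny_spec):
        spec = replace(tiny_spec, noise_enabled=False)
        geo = layout(spec)
        assert len(attach_noise(spec, geo)) == 0

    def test_noise_parameters_and_targets(self, tiny_spec, tiny_network):
        nb = tiny_network.noise
        pyr = tiny_network.geometry.cells_of_type("pyramidal")
        # two sub-sources per pyramidal cell summing to 300 /s at 0.08 nS
        assert len(nb) == 2 * len(pyr)
        assert nb.g_peak == 0.08
        per_cell = {}
        for c, r in zip(nb.cell_ids, nb.rate):
            per_cell[c] = per_cell.get(c, 0.0) + r
        assert all(r == pytest.approx(300.0) for r in per_cell.values())

    def test_layer4_five_cells_per_minicolumn(self, tiny_spec, tiny_network):
        l4 = tiny_network.layer4
        assert l4.n_cells == tiny_spec.n_minicolumns * 5
        for m in range(tiny_spec.n_minicolumns):
            assert len(l4.cells_of_mc(m)) == 5

    def test_layer4_feedforward_in_degree_expectation(self):
        spec = NetworkSpec(n_hypercolumns=1, n_minicolumns_per_hc=8)
        net = cn.build_network(spec)
        edges = net.layer4.edges
        n_pyr = 8 * 30
        mean_in = len(edges) / n_pyr
        # 5 cells x 50% connectivity -> expected in-degree 2.5
        sd = np.sqrt(n_pyr * 5 * 0.25) / n_pyr
        assert mean_in == pytest.approx(2.5, abs=4 * sd)
        assert np.all(edges.g_ampa > 0)
        assert np.all(edges.g_gaba == 0)


class TestExpectedCounts:
    def test_standard_network_expectation_near_1_8_million(self):
        rep = expected_synapse_counts(NetworkSpec())
        assert rep["total"]["mean"] == pytest.approx(1.8e6, rel=0.08)

    def test_fixed_in_degree_projections_have_zero_variance(self):
        rep = expected_synapse_counts(NetworkSpec())
        assert rep["pyr_basket"]["var"] == 0
        assert rep["pyr_pyr_global"]["var"] == 0
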