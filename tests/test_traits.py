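import math

import numpy as np
import pytest

from rootvec import (
    Root,
    RootNode,
    RootSystem,
    depth_profile,
    diameter_stats,
    distal_cumulative,
    fitter_indices,
    generate_root_system,
    orientation_profile,
    segment_measures,
    surface_proportions,
    trait_table,
    translate_system,
)
from rootvec.errors import AnalysisError, GeometryError

from conftest import sparse_params


class TestSegmentMeasures:
    @pytest.mark.parametrize(
        "n1, n2, expected",
        [
            # 3-4-5 cylinder: surface pi*0.1*5, volume (pi/4)*0.01*5
            (
                RootNode(0, 0, 0.1),
                RootNode(3, 4, 0.1),
                (5.0, 0.5 * math.pi, math.pi / 4 * 0.01 * 5),
            ),
            # tapering segment uses the mean diameter for surface
            (RootNode(0, 0, 0.2), RootNode(0, 1, 0.1), (1.0, math.pi * 0.15, None)),
            (RootNode(2, 2, 0.3), RootNode(2, 2, 0.3), (0.0, 0.0, 0.0)),
        ],
    )
    def test_closed_forms(self, n1, n2, expected):
        length, surface, volume = segment_measures(n1, n2)
        assert length == pytest.approx(expected[0])
        assert surface == pytest.approx(expected[1])
        if expected[2] is not None:
            assert volume == pytest.approx(expected[2])

    def test_frustum_volume_exceeds_mean_cylinder(self):
        # frustum of d 0.2 -> 0.1 over 1 cm vs cylinder at mean diameter 0.15
        _, _, volume = segment_measures(RootNode(0, 0, 0.2), RootNode(0, 1, 0.1))
        assert volume == pytest.approx(math.pi / 12 * (0.04 + 0.02 + 0.01))
        assert volume > math.pi / 4 * 0.15**2 / 2  # sanity: above half-cylinder

    def test_negative_diameter_rejected(self):
        with pytest.raises(GeometryError):
            segment_measures(RootNode(0, 0, -0.1), RootNode(1, 0, 0.1))


class TestDistalCumulative:
    def test_whole_tree_from_base(self, toy_system):
        value = distal_cumulative(toy_system, "main", 0.0, "surface")
        assert value == pytest.approx(1.25 * math.pi)

    def test_past_lateral_excludes_its_subtree(self, toy_system):
        value = distal_cumulative(toy_system, "main", 6.0, "surface")
        assert value == pytest.approx(0.4 * math.pi)

    def test_lateral_at_exact_query_position_included(self, toy_system):
        value = distal_cumulative(toy_system, "main", 5.0, "surface")
        assert value == pytest.approx(0.5 * math.pi + 0.25 * math.pi)

    def test_zero_at_tip(self, toy_system):
        assert distal_cumulative(toy_system, "main", 10.0, "surface") == pytest.approx(0.0)

    def test_unknown_root_rejected(self, toy_system):
        with pytest.raises(AnalysisError):
            distal_cumulative(toy_system, "ghost", 0.0, "surface")

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("measure", ["length", "surface", "volume"])
    def test_matches_exhaustive_tipward_enumeration(self, seed, measure):
        """Brute-force oracle: clip each segment independently and recurse subtrees."""
        system = generate_root_system(sparse_params(seed))
        rng = np.random.default_rng(seed + 1000)
        mi = ["length", "surface", "volume"].index(measure)

        def subtree_sum(rid):
            total = 0.0
            r = system[rid]
            for a, b in zip(r.polyline[:-1], r.polyline[1:]):
                total += segment_measures(a, b)[mi]
            for c in system.children_of(rid):
                total += subtree_sum(c.id)
            return total

        roots = sorted(system.roots)
        for _ in range(10):
            rid = roots[rng.integers(len(roots))]
            root = system[rid]
            pos = float(rng.uniform(0.0, root.length))
            arcs = root.arc_lengths()
            expected = 0.0
            for i, (a, b) in enumerate(zip(root.polyline[:-1], root.polyline[1:])):
                if arcs[i + 1] <= pos:
                    continue
                lo = max(arcs[i], pos)
                start = root.point_at(lo)
                expected += segment_measures(start, b)[mi]
            for c in system.children_of(rid):
                if c.insertion_position >= pos:
                    expected += subtree_sum(c.id)
            got = distal_cumulative(system, rid, pos, measure)
            assert got == pytest.approx(expected, abs=1e-9)

    def test_base_value_equals_trait_table_tree_totals(self):
        system = generate_root_system(sparse_params(9))
        table = trait_table(system).set_index("id")
        for base in system.base_roots():
            ids = system.subtree_ids(base.id)
            expected = table.loc[ids, "surface_cm2"].sum()
            got = distal_cumulative(system, base.id, 0.0, "surface")
            assert got == pytest.approx(expected, abs=1e-9)

    def test_non_increasing_along_root(self):
        system = generate_root_system(sparse_params(4))
        base = system.base_roots()[0]
        values = [
            distal_cumulative(system, base.id, p, "surface")
            for p in np.linspace(0, base.length, 40)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))


class TestDepthProfile:
    def test_vertical_root_one_cm_per_bin(self):
        s = RootSystem()
        s.add(Root("r", [RootNode(5, 0, 0.1), RootNode(5, 10, 0.1)], order=1))
        prof = depth_profile(s, bin_size=1.0)
        np.testing.assert_allclose(prof.lengths[0], np.ones(10))

    def test_diagonal_root_sqrt2_per_bin(self):
        s = RootSystem()
        s.add(Root("r", [RootNode(0, 0, 0.1), RootNode(10, 10, 0.1)], order=1))
        prof = depth_profile(s, bin_size=1.0)
        np.testing.assert_allclose(prof.lengths[0], np.full(10, math.sqrt(2)), atol=1e-9)

    def test_horizontal_root_single_bin(self):
        s = RootSystem()
        s.add(Root("r", [RootNode(0, 2.5, 0.1), RootNode(8, 2.5, 0.1)], order=1))
        prof = depth_profile(s, bin_size=1.0)
        assert prof.lengths[0].sum() == pytest.approx(8.0)
        assert prof.lengths[0][np.argmax(prof.lengths[0])] == pytest.approx(8.0)

    @pytest.mark.parametrize("bin_size", [0.5, 1.0, 2.5])
    def test_conserves_per_order_totals(self, bin_size):
        system = generate_root_system(sparse_params(6))
        prof = depth_profile(system, bin_size=bin_size)
        table = trait_table(system)
        for i, order in enumerate(prof.orders):
            total = table.loc[table["order"] == order, "length_cm"].sum()
            assert prof.lengths[i].sum() == pytest.approx(total, abs=1e-6)


class TestDiameterStats:
    def _system_with_orders(self, specs):
        """specs: list of (order, diameters list); builds 2-node roots."""
        s = RootSystem()
        k = 0
        for order, diams in specs:
            for d in diams:
                s.add(Root(f"r{k}", [RootNode(0, k, d), RootNode(1, k, d)], order=order))
                k += 1
        return s

    def test_identical_samples_share_a_letter(self):
        s = self._system_with_orders([(1, [0.2, 0.3, 0.25]), (2, [0.2, 0.3, 0.25])])
        stats = diameter_stats(s).set_index("order")
        assert stats.loc[1, "letters"] == stats.loc[2, "letters"]

    def test_separated_orders_get_distinct_letters(self):
        rng = np.random.default_rng(0)
        d1 = 0.9 + 0.05 * rng.standard_normal(30)
        d2 = 0.15 + 0.03 * rng.standard_normal(30)
        from scipy import stats as sps

        assert sps.ttest_ind(d1, d2, equal_var=False).pvalue < 0.01  # oracle
        s = self._system_with_orders([(1, d1), (2, d2)])
        table = diameter_stats(s).set_index("order")
        assert set(table.loc[1, "letters"]).isdisjoint(set(table.loc[2, "letters"]))

    def test_single_order_gets_letter_a(self):
        s = self._system_with_orders([(1, [0.2, 0.25])])
        assert diameter_stats(s)["letters"].tolist() == ["a"]

    def test_order_with_one_root_reported_without_letter(self):
        s = self._system_with_orders([(1, [0.4, 0.45, 0.42]), (2, [0.1])])
        table = diameter_stats(s).set_index("order")
        assert table.loc[2, "letters"] == ""
        assert table.loc[2, "n"] == 1

    def test_three_orders_chain(self):
        rng = np.random.default_rng(1)
        s = self._system_with_orders(
            [
                (1, 0.45 + 0.02 * rng.standard_normal(20)),
                (2, 0.20 + 0.02 * rng.standard_normal(20)),
                (3, 0.10 + 0.01 * rng.standard_normal(20)),
            ]
        )
        letters = diameter_stats(s)["letters"].tolist()
        assert len(set(letters)) == 3  # all pairwise distinguishable


class TestSurfaceProportions:
    def test_toy_system_80_20(self, toy_system):
        props = surface_proportions(toy_system)
        assert props[1] == pytest.approx(0.8)
        assert props[2] == pytest.approx(0.2)

    def test_single_order_is_one(self):
        s = RootSystem()
        s.add(Root("r", [RootNode(0, 0, 0.1), RootNode(0, 5, 0.1)], order=1))
        assert surface_proportions(s) == {1: pytest.approx(1.0)}

    def test_fractions_sum_to_one(self):
        system = generate_root_system(sparse_params(8))
        assert sum(surface_proportions(system).values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_surface_rejected(self):
        s = RootSystem()
        s.add(Root("r", [RootNode(0, 0, 0.0), RootNode(0, 5, 0.0)], order=1))
        with pytest.raises(AnalysisError):
            surface_proportions(s)


class TestOrientationProfile:
    def test_vertical_root_zero_degrees(self):
        r = Root("r", [RootNode(5, float(i), 0.1) for i in range(11)], order=1)
        prof = orientation_profile(r, window=1.0)
        np.testing.assert_allclose(prof.angles, 0.0, atol=1e-12)

    def test_horizontal_root_ninety_degrees(self):
        r = Root("r", [RootNode(float(i), 5, 0.1) for i in range(11)], order=1)
        prof = orientation_profile(r, window=1.0)
        np.testing.assert_allclose(prof.angles, 90.0, atol=1e-12)

    def test_quarter_circle_tracks_analytic_tangent(self):
        # quarter circle radius 10 from vertical heading to horizontal
        radius = 10.0
        theta = np.linspace(0, math.pi / 2, 400)
        pts = [
            RootNode(radius * (1 - math.cos(t)), radius * math.sin(t), 0.1) for t in theta
        ]
        r = Root("r", pts, order=1)
        prof = orientation_profile(r, window=0.5)
        analytic = np.degrees(prof.positions / radius)  # tangent angle at arc s
        interior = slice(5, -5)
        assert np.max(np.abs(prof.angles[interior] - analytic[interior])) < 2.0
        assert np.all(np.diff(prof.angles) > -1e-6)  # monotone bend

    def test_zero_length_root_rejected(self):
        r = Root("r", [RootNode(1, 1, 0.1), RootNode(1, 1, 0.1)], order=1)
        with pytest.raises(GeometryError):
            orientation_profile(r)


class TestFitterIndices:
    def _herringbone(self, n_laterals):
        s = RootSystem()
        s.add(Root("axis", [RootNode(5, 0, 0.2), RootNode(5, 20, 0.2)], order=1))
        for i in range(n_laterals):
            pos = 4.0 * (i + 1)
            s.add(
                Root(
                    f"lat{i}",
                    [RootNode(5, pos, 0.1), RootNode(8, pos, 0.1)],
                    order=2,
                    parent_id="axis",
                    insertion_position=pos,
                )
            )
        return s

    def test_herringbone_altitude_equals_magnitude(self):
        table = fitter_indices(self._herringbone(3)).iloc[0]
        assert table["magnitude"] == 4
        assert table["altitude"] == 4
        # exterior path length: axis tip at 4 links, laterals at 2, 3, 4
        assert table["exterior_path_length"] == 4 + 2 + 3 + 4

    def test_unbranched_axis_is_a_single_link(self):
        s = RootSystem()
        s.add(Root("axis", [RootNode(0, 0, 0.2), RootNode(0, 9, 0.2)], order=1))
        row = fitter_indices(s).iloc[0]
        assert (row["magnitude"], row["altitude"], row["exterior_path_length"]) == (1, 1, 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_networkx_link_graph_oracle(self, seed):
        import networkx as nx

        system = generate_root_system(sparse_params(seed))
        result = fitter_indices(system).set_index("tree_id")
        for base in system.base_roots():
            G = nx.DiGraph()
            tip_of = {}

            def build(rid, entry):
                children = sorted(
                    system.children_of(rid),
                    key=lambda r: (r.insertion_position, r.id),
                )
                prev = entry
                for i, child in enumerate(children):
                    v = f"{rid}/junction{i}"
                    G.add_edge(prev, v)
                    build(child.id, v)
                    prev = v
                tip = f"{rid}/tip"
                G.add_edge(prev, tip)
                tip_of.setdefault(rid, tip)

            build(base.id, "base")
            depths = nx.single_source_shortest_path_length(G, "base")
            tips = [n for n in G.nodes if G.out_degree(n) == 0]
            row = result.loc[base.id]
            assert row["magnitude"] == len(tips)
            assert row["altitude"] == max(depths[t] for t in tips)
            assert row["exterior_path_length"] == sum(depths[t] for t in tips)


class TestTranslationInvariance:
    def test_traits_unchanged_under_rigid_translation(self):
        system = generate_root_system(sparse_params(2))
        moved = translate_system(system, 3.7, -1.2)
        t0 = trait_table(system)
        t1 = trait_table(moved)
        for col in ["length_cm", "surface_cm2", "volume_cm3", "mean_diameter_cm"]:
            np.testing.assert_allclose(t0[col], t1[col], atol=1e-9)
        assert surface_proportions(system) == pytest.approx(surface_proportions(moved))
        f0 = fitter_indices(system)
        f1 = fitter_indices(moved)
        assert f0.equals(f1)
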