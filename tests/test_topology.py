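"""Mesh-topology metrics against brute-force oracles and invariants."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnnkit.geometry import ParameterError
from pnnkit.nodes import NodeSet
from pnnkit.topology import (
    build_graph,
    connected_fraction,
    mean_degree,
    mean_internode_distance,
    r95,
    summarize_many,
    summarize_topology,
)

from .conftest import brute_force_metrics, brute_force_r95

THREE_COLLINEAR = np.array([[0, 0, 0], [0.5, 0, 0], [5, 0, 0]], dtype=float)


class TestBuildGraph:
    def test_exact_edge_set_small(self):
        g = build_graph(THREE_COLLINEAR, 0.7)
        assert {tuple(e) for e in g.edges} == {(0, 1)}

    def test_empty_cloud(self):
        g = build_graph(np.empty((0, 3)), 0.7)
        assert g.n_nodes == 0 and g.n_edges == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ParameterError):
            build_graph(THREE_COLLINEAR, 0.0)

    def test_matches_brute_force(self, random_cloud):
        g = build_graph(random_cloud, 1.0)
        oracle = brute_force_metrics(random_cloud, 1.0)
        assert {tuple(e) for e in g.edges} == oracle["edges"]


class TestMetrics:
    def test_connected_fraction_examples(self):
        close = np.array([[0, 0, 0], [0.5, 0, 0], [1.0, 0, 0]], dtype=float)
        assert connected_fraction(build_graph(close, 0.7)) == 100.0
        assert connected_fraction(build_graph(THREE_COLLINEAR, 0.7)) == \
            pytest.approx(66.6667, abs=1e-3)

    def test_mean_internode_distance_examples(self):
        two = np.array([[0, 0, 0], [0.6, 0, 0]])
        assert mean_internode_distance(build_graph(two, 0.7)) == \
            pytest.approx(0.6)
        tri = np.array([[0, 0, 0], [0.5, 0, 0], [0.25, 0.25 * np.sqrt(3), 0]])
        assert mean_internode_distance(build_graph(tri, 0.7)) == \
            pytest.approx(0.5)
        assert math.isnan(mean_internode_distance(build_graph(two, 0.1)))

    def test_mean_degree_examples(self):
        quad = np.array([[0, 0, 0], [0.1, 0, 0], [0, 0.1, 0], [0.1, 0.1, 0]])
        assert mean_degree(build_graph(quad, 0.7)) == pytest.approx(3.0)
        far = np.array([[0, 0, 0], [10, 0, 0]])
        assert mean_degree(build_graph(far, 0.7)) == 0.0

    @pytest.mark.parametrize("threshold", [0.7, 1.0, 1.5])
    def test_all_metrics_match_brute_force(self, rng, threshold):
        for _ in range(20):
            n = int(rng.integers(2, 61))
            coords = rng.uniform(0, 5.0, size=(n, 3))
            g = build_graph(coords, threshold)
            oracle = brute_force_metrics(coords, threshold)
            assert connected_fraction(g) == pytest.approx(
                oracle["pct_connected"], rel=1e-9)
            assert mean_degree(g) == pytest.approx(
                oracle["mean_degree"], rel=1e-9)
            if not math.isnan(oracle["mean_internode_dist"]):
                assert mean_internode_distance(g) == pytest.approx(
                    oracle["mean_internode_dist"], rel=1e-9)


class TestR95:
    def test_sweep_floor_for_tight_cluster(self, rng):
        coords = rng.uniform(0, 0.28, size=(10, 3))  # max pairwise < 0.5
        assert r95(coords) == 0.7

    def test_line_of_unit_spacing(self):
        coords = np.column_stack(
            [np.arange(20) * 1.0, np.zeros(20), np.zeros(20)])
        assert r95(coords, step=0.05) == pytest.approx(1.0)

    def test_permanent_outliers_unreached(self, rng):
        close = rng.uniform(0, 1.0, size=(94, 3))
        far = np.array([[100.0 + 10 * i, 0, 0] for i in range(6)])
        assert math.isnan(r95(np.vstack([close, far])))

    def test_fewer_than_two_nodes_flagged(self):
        with pytest.warns(UserWarning):
            assert math.isnan(r95(np.array([[1.0, 2.0, 3.0]])))

    def test_matches_exhaustive_sweep(self, rng):
        for _ in range(15):
            coords = rng.uniform(0, 4.0, size=(int(rng.integers(5, 40)), 3))
            got, expect = r95(coords), brute_force_r95(coords)
            if math.isnan(expect):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-9)

    def test_consistency_at_returned_threshold(self, rng):
        for _ in range(20):
            coords = rng.uniform(0, 3.0, size=(30, 3))
            v = r95(coords)
            if math.isnan(v):
                continue
            assert connected_fraction(build_graph(coords, v)) >= 95.0
            if v > 0.7:
                assert connected_fraction(
                    build_graph(coords, v - 0.05)) < 95.0

    def test_invalid_params(self):
        with pytest.raises(ParameterError):
            r95(THREE_COLLINEAR, start=-1.0)
        with pytest.raises(ParameterError):
            r95(THREE_COLLINEAR, start=1.0, max_threshold=0.5)


class TestSummaries:
    def test_collinear_assembled_record(self):
        m = summarize_topology(NodeSet("p1", THREE_COLLINEAR))
        assert m.n_nodes == 3
        assert m.pct_connected == pytest.approx(66.6667, abs=1e-3)
        assert m.mean_internode_dist == pytest.approx(0.5)
        assert m.mean_degree == pytest.approx(2 / 3)

    def test_empty_nodeset_flagged(self):
        with pytest.warns(UserWarning):
            m = summarize_topology(NodeSet("empty", np.empty((0, 3))))
        assert m.n_nodes == 0 and math.isnan(m.r95)
        assert not m.r95_reached

    def test_batch_group_means_recomputed_by_hand(self, rng):
        sets = [NodeSet(f"p{i}", rng.uniform(0, 3, size=(25, 3)))
                for i in range(10)]
        table = summarize_many(sets)
        hand = np.mean([summarize_topology(s).mean_degree for s in sets])
        assert table["mean_degree"].mean() == pytest.approx(hand, rel=1e-12)


class TestInvariants:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, seed):
        coords = np.random.default_rng(seed).uniform(0, 4, size=(30, 3))
        prev_cf, prev_deg = -1.0, -1.0
        for t in (0.5, 0.8, 1.2, 2.0):
            g = build_graph(coords, t)
            cf, deg = connected_fraction(g), mean_degree(g)
            assert cf >= prev_cf and deg >= prev_deg
            prev_cf, prev_deg = cf, deg

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_isometry_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 4, size=(25, 3))
        # random rotation (QR of a Gaussian matrix) + translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q.T + rng.uniform(-10, 10, size=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = summarize_topology(NodeSet("a", coords))
            b = summarize_topology(NodeSet("b", moved))
        assert a.n_nodes == b.n_nodes
        assert a.pct_connected == pytest.approx(b.pct_connected, abs=1e-9)
        assert a.mean_degree == pytest.approx(b.mean_degree, abs=1e-9)
        if not math.isnan(a.mean_internode_dist):
            assert a.mean_internode_dist == pytest.approx(
                b.mean_internode_dist, rel=1e-9)
        if not math.isnan(a.r95):
            assert a.r95 == pytest.approx(b.r95, abs=1e-9)
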