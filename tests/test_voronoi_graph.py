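"""Voronoi vertex/edge computation against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy.spatial import Voronoi, cKDTree

from cavipath import (
    Frame,
    Sphere,
    compute_voronoi_graph,
    perturb_positions,
    verify_vertex,
    weighted_distance,
)
from cavipath import synthetic_fixtures as sf
from cavipath.voronoi_graph import VoronoiVertex, export_graph_json, graph_to_networkx

from oracles import brute_force_vertices


def random_frame(n, seed, box=10.0, rmin=1.0, rmax=2.0):
    rng = np.random.default_rng(seed)
    frame = Frame(coords=rng.uniform(0, box, (n, 3)), radii=rng.uniform(rmin, rmax, n))
    return perturb_positions(frame, 1e-6, seed=seed)


class TestWeightedDistance:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0, 0, 0), -1.0),  # center of the unit sphere
            ((1, 0, 0), 0.0),  # on the surface
            ((3, 0, 0), 2.0),  # outside
        ],
    )
    def test_unit_sphere_cases(self, p, expected):
        s = Sphere(np.zeros(3), 1.0)
        assert weighted_distance(np.array(p, float), s) == pytest.approx(expected)


class TestVertices:
    def test_tetra_cage_closed_form(self):
        frame = perturb_positions(sf.make_tetra_cage(2.0, 1.0), 1e-6, seed=7)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        interior = [v for v in graph.vertices if v.clearance < 1.0]
        assert len(interior) == 1
        assert interior[0].clearance == pytest.approx(
            2.0 * np.sqrt(3.0 / 8.0) - 1.0, abs=1e-6
        )
        np.testing.assert_allclose(interior[0].position, 0.0, atol=1e-5)

    def test_fewer_than_four_spheres_is_an_error(self):
        frame = Frame(coords=np.eye(3), radii=np.ones(3))
        with pytest.raises(ValueError, match="4 spheres"):
            compute_voronoi_graph(frame)

    def test_random_vertices_satisfy_defining_properties(self):
        frame = random_frame(20, seed=1)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        assert graph.n_vertices > 0
        for v in graph.vertices:
            assert verify_vertex(v, frame, tol=1e-6).passed

    def test_verify_vertex_rejects_wrong_clearance(self):
        frame = perturb_positions(sf.make_tetra_cage(2.0, 1.0), 1e-6, seed=7)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        v = graph.vertices[0]
        bad = VoronoiVertex(
            position=v.position, clearance=v.clearance + 0.01, generators=v.generators
        )
        report = verify_vertex(bad, frame, tol=1e-6)
        assert not report.passed
        assert report.tangency_residuals.max() == pytest.approx(0.01, abs=1e-6)

    def test_small_instance_matches_brute_force_enumeration(self):
        frame = random_frame(7, seed=11, box=8.0)
        lo, hi = frame.bounding_box(5.0)
        oracle = brute_force_vertices(frame.coords, frame.radii, lo, hi)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0, trace_edges=False)
        assert graph.n_vertices == len(oracle)
        if oracle:
            tree = cKDTree([v for v, _ in oracle])
            d, _ = tree.query([v.position for v in graph.vertices])
            assert d.max() < 1e-6

    def test_equal_radii_reduce_to_point_voronoi(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 10, (20, 3))
        frame = perturb_positions(Frame(coords=pts, radii=np.full(20, 1.5)), 1e-6, seed=0)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0, trace_edges=False)
        lo, hi = frame.bounding_box(5.0)
        ref = Voronoi(frame.coords).vertices
        ref = ref[np.all((ref >= lo) & (ref <= hi), axis=1)]
        ours = np.array([v.position for v in graph.vertices])
        assert len(ours) == len(ref)
        d, _ = cKDTree(ref).query(ours)
        assert d.max() < 1e-6
        # clearances equal circumradius minus common radius
        for v in graph.vertices:
            circum = np.linalg.norm(v.position - frame.coords[v.generators[0]])
            assert v.clearance == pytest.approx(circum - 1.5, abs=1e-9)

    def test_contained_sphere_is_ignored(self):
        frame = sf.make_tetra_cage(4.0, 1.0)
        coords = np.vstack([frame.coords, frame.coords[0]])
        radii = np.r_[frame.radii, 0.2]  # inside atom 0
        frame2 = perturb_positions(Frame(coords=coords, radii=radii), 1e-6, seed=2)
        graph = compute_voronoi_graph(frame2, bounding_margin=3.0, trace_edges=False)
        for v in graph.vertices:
            assert 4 not in v.generators


class TestEdges:
    def test_graph_consistency_on_random_frame(self):
        frame = random_frame(20, seed=5)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        n_inc = np.zeros(graph.n_vertices, int)
        for e in graph.edges:
            for ep in e.endpoints:
                if ep is not None:
                    assert 0 <= ep < graph.n_vertices
                    n_inc[ep] += 1
            a, b = e.endpoints
            for ep in (a, b):
                if ep is not None:
                    assert set(e.generators) <= set(graph.vertices[ep].generators)
        # each non-degenerate vertex has exactly 4 incident edges
        assert np.all(n_inc == 4)

    def test_edge_samples_are_equidistant_to_generators(self):
        frame = random_frame(20, seed=5)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        for e in graph.edges:
            P = frame.coords[list(e.generators)]
            R = frame.radii[list(e.generators)]
            d = np.linalg.norm(e.samples[:, None, :3] - P[None], axis=2) - R
            np.testing.assert_allclose(d, e.samples[:, 3:4].repeat(3, axis=1), atol=1e-6)

    def test_unbounded_edges_clip_at_expanded_box(self):
        frame = perturb_positions(sf.make_tetra_cage(2.0, 1.0), 1e-6, seed=7)
        graph = compute_voronoi_graph(frame, bounding_margin=2.0)
        lo, hi = graph.box
        unbounded = [e for e in graph.edges if e.endpoints[1] is None]
        assert unbounded  # tetra rays reach the box
        for e in unbounded:
            assert np.all(e.samples[:, :3] >= lo - 1e-6)
            assert np.all(e.samples[:, :3] <= hi + 1e-6)


class TestExport:
    def test_json_and_graphml(self, tmp_path):
        frame = random_frame(10, seed=9)
        graph = compute_voronoi_graph(frame, bounding_margin=5.0)
        export_graph_json(graph, tmp_path / "g.json")
        assert (tmp_path / "g.json").stat().st_size > 0
        nxg = graph_to_networkx(graph)
        assert nxg.number_of_nodes() == graph.n_vertices
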