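"""Time graph construction, greedy identities, dead ends, and dynamic paths."""

import numpy as np
import pytest

from cavipath import (
    Cavity,
    TimeEdge,
    TimeGraph,
    assign_identity_numbers,
    build_time_graph,
    extract_dynamic_path,
    forbid_splits,
    map_cavities_between_frames,
    remove_dead_ends,
)
from cavipath.cavity_tracing import export_time_graph_json, time_graph_to_networkx


def sphere_cavity(center, radius, frame, cid):
    return Cavity(
        frame_index=frame,
        cavity_id=cid,
        centers=np.array([center], float),
        radii=np.array([radius], float),
    )


def toy_graph(n_frames, edges, volumes=None):
    """TimeGraph from explicit (frame, cav_t, cav_t1, volume) edge tuples."""
    nodes = {}
    for f, ct, ct1, vol in edges:
        nodes.setdefault((f, ct), {"volume": 1.0, "identity": None})
        nodes.setdefault((f + 1, ct1), {"volume": 1.0, "identity": None})
    for key, vol in (volumes or {}).items():
        nodes.setdefault(key, {"volume": vol, "identity": None})["volume"] = vol
    tg = TimeGraph(
        frames=list(range(n_frames)),
        nodes=nodes,
        edges=[
            TimeEdge(frame_t=f, cavity_t=ct, cavity_t1=ct1, circle_radius=1.5, intersection_volume=vol)
            for f, ct, ct1, vol in edges
        ],
    )
    return tg


class TestCorrespondence:
    def test_identical_frames_map_bijectively(self):
        cavs0 = [sphere_cavity((0, 0, 0), 2.0, 0, 0), sphere_cavity((10, 0, 0), 2.0, 0, 1)]
        cavs1 = [sphere_cavity((0, 0, 0), 2.0, 1, 0), sphere_cavity((10, 0, 0), 2.0, 1, 1)]
        edges = map_cavities_between_frames(cavs0, cavs1, r_ic=1.4, a=0.1)
        assert {(e.cavity_t, e.cavity_t1) for e in edges} == {(0, 0), (1, 1)}
        for e in edges:
            assert e.circle_radius == pytest.approx(2.0)  # self-overlap: great circle

    def test_translated_apart_gives_no_edges(self):
        cavs0 = [sphere_cavity((0, 0, 0), 2.0, 0, 0)]
        cavs1 = [sphere_cavity((50, 0, 0), 2.0, 1, 0)]
        assert map_cavities_between_frames(cavs0, cavs1, r_ic=1.4) == []

    def test_strictly_greater_than_r_ic(self):
        # circle radius exactly sqrt(3)/2 * 2 for equal r=2, d=2 -> 1.732...
        cavs0 = [sphere_cavity((0, 0, 0), 2.0, 0, 0)]
        cavs1 = [sphere_cavity((2.0, 0, 0), 2.0, 1, 0)]
        circ = np.sqrt(2.0**2 - 1.0**2)
        assert map_cavities_between_frames(cavs0, cavs1, r_ic=circ) == []
        assert len(map_cavities_between_frames(cavs0, cavs1, r_ic=circ - 1e-9)) == 1

    def test_raising_r_ic_never_adds_edges(self):
        rng = np.random.default_rng(8)
        cavs0 = [
            Cavity(0, i, rng.uniform(0, 8, (5, 3)), rng.uniform(1.0, 2.5, 5))
            for i in range(3)
        ]
        cavs1 = [
            Cavity(1, i, rng.uniform(0, 8, (5, 3)), rng.uniform(1.0, 2.5, 5))
            for i in range(3)
        ]
        prev = None
        for r_ic in (0.5, 1.0, 1.4, 2.0):
            pairs = {
                (e.cavity_t, e.cavity_t1)
                for e in map_cavities_between_frames(cavs0, cavs1, r_ic=r_ic, a=0.2)
            }
            if prev is not None:
                assert pairs <= prev
            prev = pairs

    def test_split_fixture_maps_one_to_two(self, dumbbell_run):
        traj, script, cavs_per_frame, tg = dumbbell_run
        split_frame = script[0][0]
        edges = [e for e in tg.edges if e.frame_t == split_frame - 1]
        assert len(edges) == 2
        assert {e.cavity_t for e in edges} == {0}
        assert {e.cavity_t1 for e in edges} == {0, 1}
        assert all(e.circle_radius > 1.4 for e in edges)


class TestIdentities:
    def test_persistent_cavity_keeps_one_identity(self):
        tg = toy_graph(10, [(t, 0, 0, 5.0) for t in range(9)])
        assign_identity_numbers(tg)
        assert {v["identity"] for v in tg.nodes.values()} == {0}

    def test_split_larger_volume_inherits(self):
        tg = toy_graph(2, [(0, 0, 0, 9.0), (0, 0, 1, 4.0)])
        assign_identity_numbers(tg)
        assert tg.nodes[(1, 0)]["identity"] == tg.nodes[(0, 0)]["identity"]
        assert tg.nodes[(1, 1)]["identity"] != tg.nodes[(0, 0)]["identity"]

    def test_merge_larger_volume_inherits(self):
        tg = toy_graph(2, [(0, 0, 0, 4.0), (0, 1, 0, 9.0)])
        assign_identity_numbers(tg)
        assert tg.nodes[(1, 0)]["identity"] == tg.nodes[(0, 1)]["identity"]

    def test_identities_unique_within_frame(self, dumbbell_run):
        _, _, _, tg = dumbbell_run
        for t in tg.frames:
            idents = [tg.nodes[k]["identity"] for k in tg.nodes_at(t)]
            assert len(idents) == len(set(idents))

    def test_matching_never_matches_a_node_twice(self):
        tg = toy_graph(
            2,
            [(0, 0, 0, 9.0), (0, 0, 1, 8.0), (0, 1, 0, 7.0), (0, 1, 1, 1.0)],
        )
        assign_identity_numbers(tg)
        # greedy: (0,0)->(1,0) matched first; (0,0)->(1,1) skipped;
        # (0,1)->(1,0) skipped; (0,1)->(1,1) matched.
        assert tg.nodes[(1, 0)]["identity"] == tg.nodes[(0, 0)]["identity"]
        assert tg.nodes[(1, 1)]["identity"] == tg.nodes[(0, 1)]["identity"]

    def test_volume_tie_broken_by_identity_then_cavity(self):
        tg = toy_graph(2, [(0, 0, 0, 5.0), (0, 0, 1, 5.0)])
        assign_identity_numbers(tg)
        assert tg.nodes[(1, 0)]["identity"] == tg.nodes[(0, 0)]["identity"]
        assert tg.nodes[(1, 1)]["identity"] == 1


class TestDeadEnds:
    def test_persistent_chain_unchanged(self):
        tg = assign_identity_numbers(toy_graph(5, [(t, 0, 0, 5.0) for t in range(4)]))
        out = remove_dead_ends(tg)
        assert set(out.nodes) == set(tg.nodes)

    def test_vanishing_branch_truncated_to_split(self):
        edges = [(t, 0, 0, 9.0) for t in range(9)]  # trunk frames 0..9
        edges += [(2, 0, 1, 3.0)]  # split at frame 2 -> branch cavity 1
        edges += [(3, 1, 1, 3.0), (4, 1, 1, 3.0)]  # branch lives frames 3..5
        tg = assign_identity_numbers(toy_graph(10, edges))
        out = remove_dead_ends(tg)
        for t in (3, 4, 5):
            assert (t, 1) not in out.nodes
        for t in range(10):
            assert (t, 0) in out.nodes

    def test_final_frame_survivor_retained(self):
        tg = assign_identity_numbers(toy_graph(3, [(0, 0, 0, 5.0), (1, 0, 0, 5.0)]))
        out = remove_dead_ends(tg)
        assert (2, 0) in out.nodes


class TestForbidSplits:
    def test_no_splits_graph_unchanged(self):
        tg = assign_identity_numbers(toy_graph(4, [(t, 0, 0, 5.0) for t in range(3)]))
        out = forbid_splits(tg)
        assert set(out.nodes) == set(tg.nodes)

    def test_unmatched_split_child_dropped(self):
        tg = assign_identity_numbers(toy_graph(2, [(0, 0, 0, 9.0), (0, 0, 1, 4.0)]))
        out = forbid_splits(tg)
        assert (1, 0) in out.nodes
        assert (1, 1) not in out.nodes

    def test_chains_are_simple_paths(self, dumbbell_run):
        _, _, _, tg = dumbbell_run
        out = forbid_splits(tg)
        by_identity = {}
        for k, v in out.nodes.items():
            by_identity.setdefault(v["identity"], []).append(k)
        for ident, keys in by_identity.items():
            frames = sorted(f for f, _ in keys)
            assert len(frames) == len(set(frames))
            assert frames == list(range(frames[0], frames[-1] + 1))


class TestDynamicPaths:
    def test_adjacent_selection_single_edge(self):
        tg = assign_identity_numbers(toy_graph(2, [(0, 0, 0, 5.0)]))
        path = extract_dynamic_path(tg, [(0, 0), (1, 0)])
        assert path.nodes == [(0, 0), (1, 0)]

    def test_path_through_split_to_chosen_branch(self, dumbbell_run):
        _, script, _, tg = dumbbell_run
        split_frame = script[0][0]
        last = tg.frames[-1]
        for branch in (0, 1):
            path = extract_dynamic_path(tg, [(0, 0), (last, branch)])
            assert path is not None
            assert path.nodes[0] == (0, 0)
            assert path.nodes[-1] == (last, branch)
            assert len(path.nodes) == last + 1
            assert path.nodes[split_frame - 1] == (split_frame - 1, 0)

    def test_disconnected_selections_yield_no_path(self):
        tg = assign_identity_numbers(
            toy_graph(3, [(0, 0, 0, 5.0)], volumes={(2, 5): 1.0})
        )
        assert extract_dynamic_path(tg, [(0, 0), (2, 5)]) is None

    def test_dfs_prefers_larger_intersection_volume(self):
        edges = [(0, 0, 0, 2.0), (0, 0, 1, 9.0), (1, 0, 0, 5.0), (1, 1, 0, 5.0)]
        tg = assign_identity_numbers(toy_graph(3, edges))
        path = extract_dynamic_path(tg, [(0, 0), (2, 0)])
        assert path.nodes[1] == (1, 1)  # via the higher-volume edge

    def test_selection_order_enforced(self):
        tg = assign_identity_numbers(toy_graph(2, [(0, 0, 0, 5.0)]))
        with pytest.raises(ValueError):
            extract_dynamic_path(tg, [(1, 0), (0, 0)])


class TestEventReconstruction:
    def test_scripted_split_and_counts(self, dumbbell_run):
        traj, script, cavs_per_frame, tg = dumbbell_run
        split_frame, kind = script[0]
        assert kind == "split"
        counts = [len(c) for c in cavs_per_frame]
        assert counts == [1] * split_frame + [2] * (traj.n_frames - split_frame)


class TestExport:
    def test_json_and_networkx(self, tmp_path):
        tg = assign_identity_numbers(toy_graph(3, [(0, 0, 0, 5.0), (1, 0, 0, 5.0)]))
        export_time_graph_json(tg, tmp_path / "tg.json")
        assert (tmp_path / "tg.json").stat().st_size > 0
        g = time_graph_to_networkx(tg)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
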