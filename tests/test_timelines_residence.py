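"""Split/merge timeline tables, evolution profiles, and residence grids."""

import numpy as np
import pytest

from cavipath import (
    Cavity,
    assign_identity_numbers,
    evolution_profile,
    residence_probability,
    split_merge_timeline,
)
from cavipath.timelines_residence import export_dx, stable_core_count
from cavipath.volumetrics import cavity_occupancy_grid

from test_cavity_tracing import sphere_cavity, toy_graph


class TestSplitMergeTimeline:
    def test_single_persistent_cavity(self):
        tg = assign_identity_numbers(toy_graph(5, [(t, 0, 0, 5.0) for t in range(4)]))
        rows, events = split_merge_timeline(tg)
        assert len(events) == 0
        assert set(rows["identity"]) == {0}
        assert list(rows["frame"]) == list(range(5))

    def test_merge_then_split_event_list(self):
        edges = [
            (0, 0, 0, 9.0),  # i0 continues
            (0, 1, 0, 4.0),  # i1 merges into i0 at frame 1
            (1, 0, 0, 9.0),  # i0 continues
            (1, 0, 1, 3.0),  # i0 splits at frame 2
        ]
        tg = assign_identity_numbers(toy_graph(3, edges))
        rows, events = split_merge_timeline(tg)
        assert len(events) == 2
        merge = events[events["event"] == "merge"].iloc[0]
        split = events[events["event"] == "split"].iloc[0]
        assert merge["frame"] == 1 and merge["parents"] == "0+1" and merge["children"] == "0"
        assert split["frame"] == 2 and split["parents"] == "0" and split["children"] == "0+2"

    def test_empty_range(self):
        tg = assign_identity_numbers(toy_graph(3, [(0, 0, 0, 5.0)]))
        rows, events = split_merge_timeline(tg, t_range=(10, 20))
        assert len(rows) == 0 and len(events) == 0

    def test_row_thickness_is_volume(self):
        tg = assign_identity_numbers(
            toy_graph(2, [(0, 0, 0, 5.0)], volumes={(0, 0): 42.0, (1, 0): 17.0})
        )
        rows, _ = split_merge_timeline(tg)
        assert list(rows["volume"]) == [42.0, 17.0]


class TestEvolutionProfile:
    def test_unit_sphere_interval(self):
        tg = assign_identity_numbers(toy_graph(1, [], volumes={(0, 0): 1.0}))
        cav = sphere_cavity((0, 0, 0), 1.0, 0, 0)
        profiles = evolution_profile(tg, [[cav]], axis=(0.0, 0.0, 1.0))
        assert len(profiles) == 1
        assert profiles[0].min_projection[0] == pytest.approx(-1.0)
        assert profiles[0].max_projection[0] == pytest.approx(1.0)

    def test_channel_profile_spans_tube(self, channel_pipeline):
        from cavipath import build_time_graph

        _, _, _, _, cavities = channel_pipeline
        tg = assign_identity_numbers(build_time_graph([cavities], a=0.2))
        profiles = evolution_profile(tg, [cavities], axis=(0.0, 0.0, 1.0))
        p = profiles[0]
        assert p.max_projection[0] - p.min_projection[0] >= 0.8 * 12.0

    def test_absent_frame_flagged(self):
        tg = assign_identity_numbers(
            toy_graph(2, [], volumes={(0, 0): 1.0, (1, 0): 1.0})
        )
        cav = sphere_cavity((0, 0, 0), 1.0, 0, 0)
        profiles = evolution_profile(tg, [[cav], []], axis=(0.0, 0.0, 1.0))
        p0 = [p for p in profiles if p.identity == tg.nodes[(0, 0)]["identity"]][0]
        assert p0.present == [True, False]
        assert np.isnan(p0.min_projection[1])

    def test_zero_axis_rejected(self):
        tg = assign_identity_numbers(toy_graph(1, [], volumes={(0, 0): 1.0}))
        with pytest.raises(ValueError):
            evolution_profile(tg, [[sphere_cavity((0, 0, 0), 1.0, 0, 0)]], axis=(0, 0, 0))

    def test_intervals_contain_all_sphere_projections(self, cage_pipeline):
        from cavipath import build_time_graph

        _, _, _, _, cavities = cage_pipeline
        tg = assign_identity_numbers(build_time_graph([cavities], a=0.2))
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)
        profiles = evolution_profile(tg, [cavities], axis=axis)
        for p in profiles:
            cav = cavities[p.identity]
            proj = cav.centers @ axis
            assert p.min_projection[0] <= proj.min() + 1e-9
            assert p.max_projection[0] >= proj.max() - 1e-9


class TestResidenceProbability:
    def test_single_frame_equals_occupancy(self):
        cav = sphere_cavity((0, 0, 0), 1.0, 0, 0)
        res = residence_probability([[cav]], a=0.2)
        occ = cavity_occupancy_grid(cav, 0.2)
        np.testing.assert_array_equal(res.grid.occupancy, occ.occupancy.astype(float))
        assert set(np.unique(res.grid.occupancy)) <= {0.0, 1.0}

    def test_static_cavity_core_is_one(self):
        frames = [[sphere_cavity((0, 0, 0), 1.0, t, 0)] for t in range(10)]
        res = residence_probability(frames, a=0.2)
        k = tuple(int(d // 2) for d in res.grid.dims)
        assert res.grid.occupancy[k] == 1.0
        assert res.n_frames == 10

    def test_three_of_four_frames_gives_three_quarters(self):
        present = [[sphere_cavity((0, 0, 0), 1.0, t, 0)] for t in range(3)]
        frames = present + [[]]
        res = residence_probability(frames, a=0.2)
        center_idx = tuple(
            int(np.floor((0.0 - res.grid.origin[k]) / 0.2)) for k in range(3)
        )
        assert res.grid.occupancy[center_idx] == pytest.approx(0.75)

    def test_values_are_multiples_of_one_over_T(self):
        rng = np.random.default_rng(3)
        frames = []
        for t in range(5):
            frames.append(
                [Cavity(t, 0, rng.uniform(0, 3, (3, 3)), rng.uniform(0.5, 1.2, 3))]
            )
        res = residence_probability(frames, a=0.3)
        vals = np.unique(res.grid.occupancy)
        np.testing.assert_allclose(vals * 5, np.round(vals * 5), atol=1e-12)
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_threshold_recovers_intersection_of_frames(self):
        # two alternating positions; only the overlap has value 1
        a_cav = sphere_cavity((0, 0, 0), 1.0, 0, 0)
        b_cav = sphere_cavity((0.5, 0, 0), 1.0, 1, 0)
        res = residence_probability([[a_cav], [b_cav]], a=0.1)
        T = 2
        core = res.grid.occupancy > (T - 0.5) / T
        # cubes in the intersection of the two spheres
        xs = [res.grid.cube_centers_1d(k) for k in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        inside_a = X**2 + Y**2 + Z**2 < 1.0
        inside_b = (X - 0.5) ** 2 + Y**2 + Z**2 < 1.0
        np.testing.assert_array_equal(core, inside_a & inside_b)

    def test_stable_core_count(self):
        frames = [[sphere_cavity((0, 0, 0), 1.0, t, 0)] for t in range(4)]
        res = residence_probability(frames, a=0.2)
        assert stable_core_count(res, 0.9) == int(np.count_nonzero(res.grid.occupancy == 1.0))


class TestDxExport:
    def test_grid_written_with_counts_and_data(self, tmp_path):
        cav = sphere_cavity((0, 0, 0), 1.0, 0, 0)
        res = residence_probability([[cav]], a=0.5)
        p = tmp_path / "grid.dx"
        export_dx(res.grid, p)
        text = p.read_text()
        nx_, ny, nz = res.grid.dims
        assert f"counts {nx_} {ny} {nz}" in text
        assert f"items {nx_ * ny * nz}" in text
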