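"""Shared fixtures: expensive pipeline runs are computed once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cavipath import (
    FilterParams,
    build_cavities,
    compute_voronoi_graph,
    connected_components,
    filter_graph,
    perturb_positions,
)
from cavipath import synthetic_fixtures as sf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DEFAULT_PARAMS = FilterParams(probe_radius=1.4, occlusion_threshold=0.15, n_rays=256)


def pipeline_frame(frame, params=DEFAULT_PARAMS, seed=0, margin=5.0):
    """Perturb → Voronoi → filter → components → cavities for one frame."""
    f = perturb_positions(frame, epsilon=1e-6, seed=seed)
    graph = compute_voronoi_graph(f, bounding_margin=margin)
    filtered = filter_graph(graph, f, params, seed=seed)
    comps = connected_components(filtered)
    cavities = build_cavities(comps, filtered, params.probe_radius, frame=f)
    return f, graph, filtered, comps, cavities


@pytest.fixture(scope="session")
def cage_pipeline():
    """Closed 80-atom shell cage run through the static pipeline."""
    return pipeline_frame(sf.make_closed_cage(6.0, 1.8, 80))


@pytest.fixture(scope="session")
def channel_pipeline():
    """Single channel-tube frame (bottleneck 2.0 Å) through the static pipeline."""
    traj = sf.make_channel_tube(12.0, 2.0, n_frames=1)
    return pipeline_frame(traj.frames[0])


@pytest.fixture(scope="session")
def dumbbell_run():
    """Full 10-frame splitting-dumbbell pipeline plus its event script."""
    from cavipath import assign_identity_numbers, build_time_graph

    traj, script = sf.make_splitting_dumbbell(n_frames=10)
    cavs_per_frame = []
    for frame in traj:
        cavs_per_frame.append(pipeline_frame(frame)[4])
    tg = build_time_graph(cavs_per_frame, r_ic=1.4, a=0.2)
    assign_identity_numbers(tg)
    return traj, script, cavs_per_frame, tg


@pytest.fixture()
def rng():
    return np.random.default_rng(20231115)
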