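"""Shared fixtures: hand-written Amira fixtures and small synthetic spindles."""

import numpy as np
import pytest

from spindlegraph.graph_model import MTClass, Microtubule, Spindle, preprocess
from spindlegraph.synthetic import SpindleRecipe, generate_spindle

# A minimal valid HxSpatialGraph: one 3-point microtubule from (0,0,0) to
# (1000,0,0), labelled as a KMT.  Hand-authored; its length is 1000 nm by
# hand-summing the two 500 nm segments.
MINIMAL_AM = """\
# AmiraMesh 3D ASCII 2.0

define VERTEX 2
define EDGE 1
define POINT 3

Parameters {
    ContentType "HxSpatialGraph"
}

VERTEX { float[3] VertexCoordinates } @1
EDGE { int[2] EdgeConnectivity } @2
EDGE { int NumEdgePoints } @3
POINT { float[3] EdgePointCoordinates } @4
EDGE { int KMT } @5

@1
0 0 0
1000 0 0

@2
0 1

@3
3

@4
0 0 0
500 0 0
1000 0 0

@5
1
"""


@pytest.fixture
def minimal_am_text():
    return MINIMAL_AM


@pytest.fixture(scope="session")
def small_spindle():
    """A small noiseless straight-fiber spindle with ground truth."""
    recipe = SpindleRecipe(
        seed=11, n_fiber_pairs=2, kmts_per_fiber=4, n_nonkmt=5,
        noise_sigma_nm=0.0, fiber_length_um=(3.0, 0.0),
    )
    graph, truth = generate_spindle(recipe)
    spindle = preprocess(Spindle.from_spatial_graph(graph, graph_id=1))
    return spindle, truth


def straight_kmt(mt_id, start, end, n=11, fiber_id=None):
    pts = np.linspace(np.asarray(start, float), np.asarray(end, float), n)
    return Microtubule(mt_id=mt_id, points=pts, mt_class=MTClass.KMT, fiber_id=fiber_id)


def random_polyline(rng, n_points=None, step=30.0, box=2000.0):
    """A random-walk polyline inside a box, for oracle instances."""
    n = n_points or int(rng.integers(5, 40))
    start = rng.uniform(0, box, 3)
    steps = rng.normal(size=(n - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    # mild persistence so tracks look filament-like
    for i in range(1, len(steps)):
        steps[i] = 0.7 * steps[i - 1] + 0.3 * steps[i]
        steps[i] /= np.linalg.norm(steps[i])
    return start + np.vstack([[0, 0, 0], np.cumsum(steps * step, axis=0)])


def random_instance(rng, n_mts=25, kmt_fraction=0.5):
    """A random Spindle (no poles needed) for brute-force comparisons."""
    mts = []
    for i in range(n_mts):
        pts = random_polyline(rng)
        is_kmt = rng.random() < kmt_fraction
        mts.append(
            Microtubule(
                mt_id=i,
                points=pts,
                mt_class=MTClass.KMT if is_kmt else MTClass.NON_KMT,
                plus_end_index="first" if is_kmt else None,
            )
        )
    return Spindle(graph_id=1, microtubules=mts)
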