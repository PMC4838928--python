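import numpy as np
import pytest

import hdmascreen as h


@pytest.fixture(scope="session")
def screen_spec():
    """The 2 x 50 x 3^4 four-factor screen layout."""
    return h.reference_design()


@pytest.fixture(scope="session")
def screen_map(screen_spec):
    return h.build_design(screen_spec)


@pytest.fixture(scope="session")
def small_spec():
    """A 2 x 3 x 2^2 layout small enough for exhaustive checks."""
    return h.DesignSpec(
        parallel_replicates=2,
        serial_chambers=3,
        n_levels=2,
        factors=(
            h.FactorDef("A", "uM", (0.0, 1.0)),
            h.FactorDef("B", "uM", (0.0, 2.0)),
        ),
    )


@pytest.fixture(scope="session")
def small_map(small_spec):
    return h.build_design(small_spec)


def match_detections(detected, truth, radius=4.0):
    """Nearest-centroid matching of detected cells to ground truth.

    Returns (tp, fp, fn, truth_idx) where truth_idx[i] is the matched truth
    row for detection i, or -1.
    """
    from scipy.spatial import cKDTree

    if len(truth) == 0 or len(detected) == 0:
        return 0, len(detected), len(truth), np.full(len(detected), -1)
    tree = cKDTree(truth[["y", "x"]].to_numpy())
    d, idx = tree.query(detected[["y", "x"]].to_numpy())
    matched = d < radius
    tp = len(np.unique(idx[matched]))
    return tp, int(len(detected) - matched.sum()), int(len(truth) - tp), np.where(matched, idx, -1)
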