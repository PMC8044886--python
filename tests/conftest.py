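import numpy as np
import pytest

import patchvote as pv


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def seg_image():
    """One default segmentation-benchmark field with ground truth."""
    return pv.render_image(pv.segmentation_test_spec(), seed=11)


@pytest.fixture(scope="session")
def known_basis_od():
    """OD image built from the canonical stain vectors with known maps."""
    gen = np.random.default_rng(7)
    h = gen.uniform(0.05, 2.0, (120, 120))
    e = gen.uniform(0.05, 2.0, (120, 120))
    od = (h[..., None] * pv.CANONICAL_HEMATOXYLIN
          + e[..., None] * pv.CANONICAL_EOSIN)
    return od, h, e


def centroid_match_f1(truth_centroids, found_centroids, radius=10.0):
    """Greedy one-to-one centroid matching F1 (the detection oracle)."""
    from scipy.spatial import cKDTree

    if len(found_centroids) == 0 or len(truth_centroids) == 0:
        return 0.0
    tree = cKDTree(truth_centroids)
    used, tp = set(), 0
    for c in found_centroids:
        for j in sorted(tree.query_ball_point(c, radius)):
            if j not in used:
                used.add(j)
                tp += 1
                break
    precision = tp / len(found_centroids)
    recall = tp / len(truth_centroids)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
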