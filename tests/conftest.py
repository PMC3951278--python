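"""Shared fixtures: deterministic seeds and one rendered section scene.

The rendered macroscopy scene is expensive (alternate sequential filtering
dominates), so it is built once per session and shared by the bundle,
segmentation and end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import stematlas as sa

# one fixed seed convention for the whole suite (date of the test freeze)
SUITE_SEED = 20260926


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def scene():
    """Section scene with 120 planted bundles (ground truth)."""
    return sa.make_scene(seed=3, n_bundles=120)


@pytest.fixture(scope="session")
def section_image(scene):
    """Rendered grey-level macroscopy image of the session scene."""
    return sa.render_section_image(scene, resolution=0.005, seed=4)


@pytest.fixture(scope="session")
def section_resolution():
    return 0.005


@pytest.fixture(scope="session")
def slice_contour(section_image, section_resolution):
    return sa.segment_slice_contour(section_image, section_resolution)


@pytest.fixture(scope="session")
def detected_bundles(section_image, section_resolution, slice_contour):
    return sa.detect_bundles(section_image, section_resolution,
                             contour=slice_contour)


@pytest.fixture(scope="session")
def small_scene():
    """Smaller scene for tests that re-render or re-filter images."""
    return sa.make_scene(seed=11, size=1.8, n_bundles=25)


@pytest.fixture(scope="session")
def small_image(small_scene):
    return sa.render_section_image(small_scene, resolution=0.006, seed=12)


def match_points(truth: np.ndarray, detected: np.ndarray,
                 radius: float) -> tuple[float, float]:
    """(recall, precision) by optimal one-to-one matching within `radius`."""
    from scipy.optimize import linear_sum_assignment
    if len(truth) == 0 or len(detected) == 0:
        return 0.0, 0.0
    d = np.hypot(truth[:, None, 0] - detected[None, :, 0],
                 truth[:, None, 1] - detected[None, :, 1])
    ri, ci = linear_sum_assignment(d)
    ok = int(np.sum(d[ri, ci] <= radius))
    return ok / len(truth), ok / len(detected)
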