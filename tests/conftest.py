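"""Shared fixtures: small synthetic stacks reused across test modules."""

import numpy as np
import pytest

from lpschip import imaging, quantify

SMALL_SHAPE = (3, 512, 512)
SMALL_LAYOUT = imaging.CellLayout(n_cells=120)


@pytest.fixture(scope="session")
def icam_threshold():
    """Top-1% threshold from dummies calibrated to a projected q99 of 9."""
    dummies = [imaging.generate_dummy_stack(imaging.NoiseModel(q99=9.0),
                                            shape=SMALL_SHAPE, seed=100 + i)
               for i in range(2)]
    imgs = [quantify.project(d, "marker", "max") for d in dummies]
    return quantify.noise_threshold(imgs, dummy_set="icam")


@pytest.fixture(scope="session")
def vecad_threshold():
    dummies = [imaging.generate_dummy_stack(imaging.NoiseModel(q99=14.0),
                                            shape=SMALL_SHAPE, seed=200 + i)
               for i in range(2)]
    imgs = [quantify.project(d, "marker", "max") for d in dummies]
    return quantify.noise_threshold(imgs, dummy_set="vecad")


@pytest.fixture(scope="session")
def marker_scene():
    """One marker stack with its truth, normal-condition calibration."""
    return imaging.generate_marker_stack(f=0.0931, shape=SMALL_SHAPE,
                                         layout=SMALL_LAYOUT, seed=42)


@pytest.fixture(scope="session")
def thp1_scene():
    """THP-1 scene with planted distances (the study's condition means)."""
    return imaging.generate_thp1_scene(
        wall_x_px=205, n_adhered=20, distances_um=[16.79, 32.82, 22.98],
        shape=SMALL_SHAPE, seed=9)
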