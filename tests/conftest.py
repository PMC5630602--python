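"""Shared fixtures.

The expensive objects (kernel banks, correlation stacks on the standard
synthetic fixtures) are session-scoped so the detector runs once and the
many assertions about its output share the result.
"""

from __future__ import annotations

import numpy as np
import pytest

from filaquant import (
    CordNetworkSpec,
    FibreFieldSpec,
    build_kernel_bank,
    correlate,
)
from filaquant import synthetic as syn
from filaquant.tubes import local_contrast_map

#: the standard fibre analysis scale: 0.5 um pixels, 1.5 um wide fibres
#: imaged with ~0.5 um optical blur
FIBRE_PIXEL_UM = 0.5
FIBRE_WIDTH_UM = 1.5
FIBRE_BLUR_UM = 0.5

#: the standard tube analysis scale: 2 um pixels, 12 um wide cords
CORD_PIXEL_UM = 2.0


@pytest.fixture(scope="session")
def fibre_bank():
    """Full fibre bank: 10-80 um by 10, base orientation step 5 deg."""
    return build_kernel_bank(
        np.arange(10.0, 81.0, 10.0),
        np.arange(0.0, 180.0, 5.0),
        width_px=FIBRE_WIDTH_UM / FIBRE_PIXEL_UM,
        pixel_size_um=FIBRE_PIXEL_UM,
        blur_px=FIBRE_BLUR_UM / FIBRE_PIXEL_UM,
    )


@pytest.fixture(scope="session")
def small_bank():
    """Cheap bank for unit tests: 4 lengths, 8 orientations, no refine."""
    return build_kernel_bank(
        [6.0, 10.0, 14.0, 18.0],
        np.arange(0.0, 180.0, 22.5),
        width_px=2.0,
        pixel_size_um=1.0,
        refine_orientations=False,
    )


@pytest.fixture(scope="session")
def fibre_mixture():
    """Two-population fibre field: 40 segments, 15 vs 60 um, fixed seed."""
    spec = FibreFieldSpec(
        n_segments=40,
        length_sampler=syn.choice([15.0, 60.0]),
        seed=7,
    )
    image, truth, label = syn.generate_fibre_field(spec)
    return spec, image, truth, label


@pytest.fixture(scope="session")
def fibre_mixture_stack(fibre_mixture, fibre_bank):
    _, image, _, _ = fibre_mixture
    return correlate(image, fibre_bank)


@pytest.fixture(scope="session")
def cord_bank():
    """Cord-scale bank: 50-600 um by 50, base step 10 deg, wide kernels
    matched to the contrast-map ridge width."""
    return build_kernel_bank(
        np.arange(50.0, 601.0, 50.0),
        np.arange(0.0, 180.0, 10.0),
        width_px=16.0,
        pixel_size_um=CORD_PIXEL_UM,
        blur_px=2.0,
    )


@pytest.fixture(scope="session")
def cord_mixture():
    """Two-population cord network: 30 cords, 150 vs 450 um, fixed seed.

    Cords are straight and non-crossing so the full-path truth label is
    commensurable with what a straight-kernel detector can measure.
    """
    spec = CordNetworkSpec(
        shape_px=(1024, 1024),
        n_cords=30,
        length_sampler=syn.choice([150.0, 450.0]),
        turn_sigma_rad=0.0,
        branch_prob=0.0,
        min_clearance_um=30.0,
        seed=5,
    )
    image, truth, label = syn.generate_cord_network(spec)
    return spec, image, truth, label


@pytest.fixture(scope="session")
def cord_mixture_stack(cord_mixture, cord_bank):
    _, image, _, _ = cord_mixture
    contrast = local_contrast_map(image)
    return contrast, correlate(contrast, cord_bank)
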