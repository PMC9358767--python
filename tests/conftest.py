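"""Shared fixtures: all phantoms are generated programmatically."""

import numpy as np
import pytest

from scutegrow.segment import (build_rag, extract_surface,
                               propagate_contours, threshold_segment)
from scutegrow.synth import (ShellSpec, make_shell_mesh, tessellate_mesh,
                             voxelize_labeled_shell)


@pytest.fixture(scope="session")
def shell_spec():
    return ShellSpec(length_mm=20.0, height_mm=14.0, width_mm=11.0,
                     n_scutes=370, rng_seed=1)


@pytest.fixture(scope="session")
def shell_mesh(shell_spec):
    return make_shell_mesh(shell_spec)


@pytest.fixture(scope="session")
def template370(shell_spec, shell_mesh):
    """(labeled mesh, ground truth) of the default 370-scute shell."""
    return tessellate_mesh(
        shell_mesh, shell_spec.n_scutes, relax_iters=10, rng_seed=1,
        shell_thickness_mm=shell_spec.shell_thickness_mm,
    )


@pytest.fixture(scope="session")
def phantom_valley(shell_spec, template370):
    """370-scute phantom, valley depth 0.5, noise sd 5, 0.15 mm."""
    labeled, _ = template370
    return voxelize_labeled_shell(
        labeled, shell_spec, voxel_spacing_mm=0.15, valley_depth=0.5,
        noise_sd=5.0,
    )


@pytest.fixture(scope="session")
def phantom_flat(shell_spec, template370):
    """Same phantom with no intensity valley (valley_depth 0)."""
    labeled, _ = template370
    return voxelize_labeled_shell(
        labeled, shell_spec, voxel_spacing_mm=0.15, valley_depth=0.0,
        noise_sd=5.0,
    )


@pytest.fixture(scope="session")
def segmented_phantom(phantom_valley):
    """Distance-modified segmentation of the valley phantom + RAG + surface."""
    vol, truth_labels, seeds = phantom_valley
    mask = threshold_segment(vol, 50.0)
    pred = propagate_contours(vol, mask, seeds, mode="distance_modified")
    rag = build_rag(pred)
    surface = extract_surface(pred)
    return pred, rag, surface


# ------------------------------------------------- 6-scute cube phantom

CUBE_SIDE = 10.0
CUBE_THICKNESS = 0.2
CUBE_SPACING = 0.1


@pytest.fixture(scope="session")
def cube_spec():
    return ShellSpec(CUBE_SIDE, CUBE_SIDE, CUBE_SIDE, boxiness=20.0,
                     shell_thickness_mm=CUBE_THICKNESS, n_scutes=12,
                     rng_seed=0)


@pytest.fixture(scope="session")
def cube_tessellation(cube_spec):
    """Near-cube tiled into 6 scutes with sites at the face centers."""
    mesh = make_shell_mesh(cube_spec)
    h = CUBE_SIDE / 2 * 0.999
    sites = np.array(
        [[h, 0, 0], [-h, 0, 0], [0, h, 0], [0, -h, 0], [0, 0, h], [0, 0, -h]]
    )
    return tessellate_mesh(mesh, 6, relax_iters=0, rng_seed=0, sites=sites,
                           shell_thickness_mm=CUBE_THICKNESS)


@pytest.fixture(scope="session")
def cube_phantom(cube_spec, cube_tessellation):
    labeled, _ = cube_tessellation
    return voxelize_labeled_shell(
        labeled, cube_spec, voxel_spacing_mm=CUBE_SPACING, valley_depth=0.0,
        noise_sd=0.0,
    )
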