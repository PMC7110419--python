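"""Shared, session-scoped fixtures.

Two synthetic sphere heads are built once per session:

* ``head32`` — 32 electrodes, 18 mm edge target: the cheap workhorse used by
  most solver/sweep tests;
* ``head64`` — 64 electrodes, 14 mm edge target: the full-size fixture used
  by the acceptance-level limit-case checks.

The ROI is a small ball near the top of the brain compartment with the
default (surface-normal) orientation.
"""

from __future__ import annotations

import numpy as np
import pytest

from tesopt import (
    BRAIN,
    ConductivityMap,
    ConstraintSet,
    alpha_sweep,
    assemble_fem,
    build_transfer_matrix,
    build_volume_weights,
    define_roi_orientation,
    generate_sphere_head,
)

ROI_CENTER = np.array([0.0, 0.0, 0.072])
ROI_RADIUS = 0.009


def _make_head(edge, n_electrodes, seed):
    mesh, electrodes = generate_sphere_head(
        target_edge_length=edge, n_electrodes=n_electrodes, seed=seed
    )
    system = assemble_fem(mesh, ConductivityMap())
    brain = mesh.elements_with_label(BRAIN)
    T = build_transfer_matrix(system, electrodes, brain)
    return mesh, electrodes, system, T


def _make_problem(mesh, T, mode="exact"):
    centroids = mesh.centroids()[T.element_index]
    inside = np.linalg.norm(centroids - ROI_CENTER, axis=1) <= ROI_RADIUS
    roi_elements = T.element_index[inside]
    target = define_roi_orientation(mesh, T, roi_elements)
    weights = build_volume_weights(mesh, T, target.roi_local, mode=mode)
    return target, weights


@pytest.fixture(scope="session")
def head32():
    return _make_head(0.018, 32, seed=7)


@pytest.fixture(scope="session")
def prob32(head32):
    mesh, _, _, T = head32
    return _make_problem(mesh, T)


@pytest.fixture(scope="session")
def head64():
    return _make_head(0.014, 64, seed=7)


@pytest.fixture(scope="session")
def prob64(head64):
    mesh, _, _, T = head64
    return _make_problem(mesh, T)


@pytest.fixture(scope="session")
def prob64_approx(head64):
    """Approximate volume weights (Gamma_nonROI = Gamma), used by the
    WLS <-> dirmax equivalence checks whose statements assume one shared
    quadratic form."""
    mesh, _, _, T = head64
    return _make_problem(mesh, T, mode="approximate")


I_MAX = 1e-3  # 1 mA budget used throughout


@pytest.fixture(scope="session")
def sweep_int32(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    return alpha_sweep(
        T, weights, target, ConstraintSet(i_max=I_MAX), nonroi_mode="integral", n_points=16
    )


@pytest.fixture(scope="session")
def sweep_elem32(head32, prob32):
    _, _, _, T = head32
    target, weights = prob32
    return alpha_sweep(
        T,
        weights,
        target,
        ConstraintSet(i_max=I_MAX),
        nonroi_mode="elementwise",
        n_points=12,
    )
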