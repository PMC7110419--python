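"""Optimization ingredients: targets, volume weights, patterns, constraints.

The montage optimizers work on an element subset covered by the transfer
matrix (normally the brain compartment).  A target is an ROI (subset of those
elements) with a desired orientation field ``d`` (3N, zero off-ROI); volume
weights are the diagonal matrices Gamma / Gamma_nonROI carrying each
element's volume (repeated for x, y, z); current patterns come in an
independent (L-1) and an expanded (L, Kirchhoff-closed) form related by the
expansion matrix H = [I; -1 ... -1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import TransferMatrix
from .mesh import BRAIN, HeadMesh

__all__ = [
    "TargetSpec",
    "VolumeWeights",
    "ConstraintSet",
    "expand_pattern",
    "reduce_pattern",
    "expansion_matrix",
    "build_volume_weights",
    "define_roi_orientation",
    "brain_surface_faces",
]


def expansion_matrix(n_electrodes: int) -> np.ndarray:
    """H (L x L-1): maps independent patterns to expanded ones."""
    H = np.vstack([np.eye(n_electrodes - 1), -np.ones(n_electrodes - 1)])
    return H


def expand_pattern(i: np.ndarray) -> np.ndarray:
    """Expanded pattern: append the reference current closing Kirchhoff's law.

    The last entry is computed as the negative partial sum, so the total is
    zero bit-consistently.
    """
    i = np.asarray(i, dtype=float)
    return np.concatenate([i, [-i.sum()]])


def reduce_pattern(i_exp: np.ndarray) -> np.ndarray:
    """Inverse of :func:`expand_pattern`; rejects patterns with net current."""
    i_exp = np.asarray(i_exp, dtype=float)
    scale = np.abs(i_exp).sum()
    if scale > 0 and abs(i_exp.sum()) > 1e-12 * scale:
        raise ValueError(f"expanded pattern sums to {i_exp.sum():.3e} A, not zero")
    return i_exp[:-1].copy()


@dataclass
class TargetSpec:
    """ROI element subset with an orientation field.

    ``roi_local`` indexes into the transfer-matrix element subset; ``d`` is
    the flattened 3N orientation field, zero outside the ROI.
    """

    roi_local: np.ndarray
    d: np.ndarray
    roi_volume: float
    orientation: np.ndarray | None = None  # the single averaged unit vector, if used

    def __post_init__(self) -> None:
        self.roi_local = np.asarray(self.roi_local, dtype=np.int64)
        self.d = np.asarray(self.d, dtype=float)
        mask = np.zeros(self.d.size // 3, dtype=bool)
        mask[self.roi_local] = True
        off = self.d.reshape(-1, 3)[~mask]
        if off.size and np.abs(off).max() > 0:
            raise ValueError("orientation field d must vanish outside the ROI")


@dataclass
class VolumeWeights:
    """Diagonal volume matrices as 3N vectors (m^3 per entry).

    ``mode='exact'`` zeroes the ROI entries of ``gamma_nonroi``;
    ``mode='approximate'`` keeps ``gamma_nonroi = gamma`` (the ROI is usually
    a tiny volume fraction, so both are nearly identical; the approximate
    form makes the low-alpha closed form an exact WLS solution).
    """

    gamma: np.ndarray
    gamma_nonroi: np.ndarray
    mode: str
    roi_volume: float
    nonroi_volume: float
    roi_local: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def nonroi_mask_elements(self) -> np.ndarray:
        mask = np.ones(self.gamma.size // 3, dtype=bool)
        mask[self.roi_local] = False
        return mask


def build_volume_weights(
    mesh: HeadMesh,
    transfer: TransferMatrix,
    roi_local: np.ndarray,
    mode: str = "exact",
) -> VolumeWeights:
    """Volume weights over the transfer matrix's element subset."""
    if mode not in ("exact", "approximate"):
        raise ValueError(f"mode must be 'exact' or 'approximate', got {mode!r}")
    roi_local = np.asarray(roi_local, dtype=np.int64)
    vols = mesh.element_volumes()[transfer.element_index]
    gamma = np.repeat(vols, 3)
    gamma_nonroi = gamma.copy()
    if mode == "exact":
        idx = (3 * roi_local[:, None] + np.arange(3)).ravel()
        gamma_nonroi[idx] = 0.0
    roi_volume = float(vols[roi_local].sum())
    return VolumeWeights(
        gamma=gamma,
        gamma_nonroi=gamma_nonroi,
        mode=mode,
        roi_volume=roi_volume,
        nonroi_volume=float(vols.sum()) - roi_volume,
        roi_local=roi_local,
    )


@dataclass
class ConstraintSet:
    """Safety constraints for the montage optimizers.

    Exactly one of ``alpha_I`` (non-ROI field-energy integral, V^2/m^2 * m^3)
    and ``alpha_E`` (per-element field bound, V/m, scalar or per-element
    vector) may be active for directional maximization.  ``i_max`` (A) bounds
    the total budget via ||i~||_1 <= 2 i_max; per-electrode box limits default
    to +/- i_max.
    """

    i_max: float
    alpha_I: float | None = None
    alpha_E: float | np.ndarray | None = None
    i_min_vec: np.ndarray | None = None
    i_max_vec: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.i_max > 0:
            raise ValueError("i_max must be positive")
        if self.alpha_I is not None and self.alpha_E is not None:
            raise ValueError("only one of alpha_I / alpha_E may be set")
        if self.alpha_I is not None and not self.alpha_I > 0:
            raise ValueError("alpha_I must be positive")

    def box(self, n_electrodes: int) -> tuple[np.ndarray, np.ndarray]:
        lo = (
            np.full(n_electrodes, -self.i_max)
            if self.i_min_vec is None
            else np.asarray(self.i_min_vec, dtype=float)
        )
        hi = (
            np.full(n_electrodes, self.i_max)
            if self.i_max_vec is None
            else np.asarray(self.i_max_vec, dtype=float)
        )
        if lo.shape != (n_electrodes,) or hi.shape != (n_electrodes,):
            raise ValueError("per-electrode limits must have length L")
        if np.any(lo > 0) or np.any(hi < 0):
            raise ValueError("per-electrode limits must satisfy i_min <= 0 <= i_max")
        return lo, hi


# ---------------------------------------------------------------------------
# ROI orientation
# ---------------------------------------------------------------------------

def brain_surface_faces(mesh: HeadMesh, label: int = BRAIN):
    """Outward-oriented boundary faces of a tissue compartment.

    Returns (face_centroids, unit_normals, face_areas); normals point out of
    the compartment.
    """
    elems = mesh.elements_with_label(label)
    if elems.size == 0:
        raise ValueError(f"no elements with label {label}")
    tets = mesh.tets[elems]
    # local faces opposite each vertex, ordered so the normal points outward
    local = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
    faces = tets[:, local].reshape(-1, 3)                   # (4*nel, 3)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = faces[counts[inv] == 1]
    p = mesh.nodes[boundary]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    normals = cross / np.linalg.norm(cross, axis=1, keepdims=True)
    centroids = p.mean(axis=1)
    return centroids, normals, area


def define_roi_orientation(
    mesh: HeadMesh,
    transfer: TransferMatrix,
    roi_elements: np.ndarray,
    d_user: np.ndarray | None = None,
    surface_label: int = BRAIN,
) -> TargetSpec:
    """Build a target: ROI subset plus orientation field.

    Default scheme: each ROI element's centroid is projected to the nearest
    compartment-boundary face, the outward face normals are averaged with
    element-volume weights, and the resulting single unit vector is
    replicated over the ROI.  A user-supplied ``d`` field (3N, or per-ROI-
    element (n_roi, 3)) is passed through unchanged.
    """
    roi_elements = np.asarray(roi_elements, dtype=np.int64)
    if roi_elements.size == 0:
        raise ValueError("ROI is empty")
    pos = {int(g): i for i, g in enumerate(transfer.element_index)}
    try:
        roi_local = np.array([pos[int(g)] for g in roi_elements], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"ROI element {exc} is outside the transfer-matrix subset") from exc
    vols = mesh.element_volumes()[transfer.element_index]
    roi_volume = float(vols[roi_local].sum())

    n_sub = transfer.n_elements
    if d_user is not None:
        d_user = np.asarray(d_user, dtype=float)
        if d_user.shape == (3 * n_sub,):
            d = d_user.copy()
        elif d_user.shape == (roi_elements.size, 3):
            d = np.zeros(3 * n_sub)
            d.reshape(-1, 3)[roi_local] = d_user
        elif d_user.shape == (3,):
            d = np.zeros(3 * n_sub)
            d.reshape(-1, 3)[roi_local] = d_user
        else:
            raise ValueError(f"unsupported orientation shape {d_user.shape}")
        return TargetSpec(roi_local=roi_local, d=d, roi_volume=roi_volume)

    face_c, face_n, _ = brain_surface_faces(mesh, surface_label)
    cent = mesh.centroids()[roi_elements]
    from scipy.spatial import cKDTree

    _, nearest = cKDTree(face_c).query(cent)
    avg = (vols[roi_local, None] * face_n[nearest]).sum(axis=0)
    norm = float(np.linalg.norm(avg))
    if norm < 1e-9 * vols[roi_local].sum():
        raise ValueError(
            "ROI surface normals average to ~zero (antipodal normals); "
            "supply an orientation explicitly"
        )
    unit = avg / norm
    d = np.zeros(3 * n_sub)
    d.reshape(-1, 3)[roi_local] = unit
    return TargetSpec(roi_local=roi_local, d=d, roi_volume=roi_volume, orientation=unit)
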