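"""Trabecular morphometry: BV/TV, MIL fabric tensor, degree of anisotropy.

Analyses run on the high-resolution binary bone image (before the 1 mm
continuum down-sampling), inside a cylindrical region of interest fitted to
the trabecular compartment with its axis parallel to the superior/inferior
image axis.

The mean intercept length MIL(w) for a direction w is the total test-line
length inside the ROI divided by the number of bone/background crossings
encountered; fitting the ellipsoid ``w^T H w = 1 / MIL(w)^2`` over a
quasi-uniform set of hemisphere directions gives the fabric tensor.  The
MIL eigen-lengths are ``1/sqrt(eig(H))``; the degree of anisotropy is
``DA = 1 - L_min / L_max`` (0 isotropic, approaching 1 strongly oriented)
and the trabecular orientation is the angle between the principal (longest
MIL) eigenvector and the axial direction, folded to [0, 90] degrees by
antipodal symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import convex_hull_image

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class FabricEstimationError(ValueError):
    """MIL sampling failed (too many directions without crossings, or a
    non-positive-definite fit)."""


@dataclass
class ROICylinder:
    """Axis-aligned cylindrical region of interest (axis = image z)."""

    center_x: float  # mm
    center_y: float  # mm
    radius: float  # mm
    z_min: float  # mm
    z_max: float  # mm

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")

    def contains_mask(self, shape, spacing) -> np.ndarray:
        """Boolean grid of voxels whose centres lie inside the cylinder."""
        sp = np.asarray(spacing, dtype=float)
        x = (np.arange(shape[0]) + 0.5) * sp[0] - self.center_x
        y = (np.arange(shape[1]) + 0.5) * sp[1] - self.center_y
        z = (np.arange(shape[2]) + 0.5) * sp[2]
        in_disc = (x[:, None] ** 2 + y[None, :] ** 2) <= self.radius**2
        in_z = (z >= self.z_min) & (z <= self.z_max)
        return in_disc[:, :, None] & in_z[None, None, :]


@dataclass
class FabricTensor:
    H: np.ndarray  # symmetric 3x3 MIL ellipsoid tensor
    mil_lengths: np.ndarray  # (3,) descending
    eigenvectors: np.ndarray  # columns matching mil_lengths
    DA: float
    n_directions_used: int

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def fit_largest_cylinder(bone_mask: np.ndarray, spacing, z_min: float, z_max: float) -> ROICylinder:
    """Largest axis-parallel cylinder inside the trabecular compartment.

    For each axial slice between the endplate planes the convex support of
    the trabecular voxels is taken; the inscribed-circle (Euclidean
    distance transform maximum) of the intersection of all slice supports
    gives the cylinder's centre and radius.
    """
    sp = np.asarray(spacing, dtype=float)
    z = (np.arange(bone_mask.shape[2]) + 0.5) * sp[2]
    ks = np.flatnonzero((z >= z_min) & (z <= z_max))
    if len(ks) == 0:
        raise ValueError("no slices between z_min and z_max")
    support = np.ones(bone_mask.shape[:2], dtype=bool)
    any_slice = False
    for k in ks:
        sl = bone_mask[:, :, k]
        if not sl.any():
            support[:] = False
            break
        any_slice = True
        support &= convex_hull_image(sl)
    if not any_slice or not support.any():
        raise ValueError("empty trabecular support between the endplate planes")
    edt = ndimage.distance_transform_edt(support, sampling=sp[:2])
    ci, cj = np.unravel_index(int(np.argmax(edt)), edt.shape)
    radius = float(edt[ci, cj])
    if radius <= 0:
        raise ValueError("no inscribed circle found")
    return ROICylinder(
        center_x=(ci + 0.5) * sp[0],
        center_y=(cj + 0.5) * sp[1],
        radius=radius,
        z_min=float(z[ks[0]] - sp[2] / 2),
        z_max=float(z[ks[-1]] + sp[2] / 2),
    )


def bvtv(binary_roi: np.ndarray) -> float:
    """Bone volume fraction: bone voxels over total voxels in the ROI."""
    binary_roi = np.asarray(binary_roi)
    if binary_roi.size == 0:
        raise ValueError("empty ROI")
    return float(np.count_nonzero(binary_roi) / binary_roi.size)


def hemisphere_directions(n: int, seed: int = 0) -> np.ndarray:
    """Deterministic quasi-uniform directions on the upper hemisphere
    (Fibonacci lattice; the seed rotates the lattice about z)."""
    i = np.arange(n)
    zc = (i + 0.5) / n
    phi = i * _GOLDEN_ANGLE + np.random.default_rng(seed).uniform(0, 2 * np.pi)
    s = np.sqrt(1.0 - zc**2)
    return np.stack([s * np.cos(phi), s * np.sin(phi), zc], axis=1)


def _mil_one_direction(bone, roi, spacing, direction, line_spacing, step):
    """(total in-ROI line length, crossings) for parallel lines along one
    direction."""
    sp = np.asarray(spacing, dtype=float)
    shape = np.asarray(bone.shape)
    extent = shape * sp
    d = direction / np.linalg.norm(direction)
    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    center = extent / 2.0
    corners = (np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T * extent) - center
    p1 = corners @ e1
    p2 = corners @ e2
    t = corners @ d
    g1 = np.arange(p1.min(), p1.max() + line_spacing, line_spacing)
    g2 = np.arange(p2.min(), p2.max() + line_spacing, line_spacing)
    ts = np.arange(t.min(), t.max() + step, step)
    # sample points: origins (len1*len2, 3) + ts*d
    origins = (g1[:, None, None] * e1[None, None, :] + g2[None, :, None] * e2[None, None, :]).reshape(-1, 3)
    pts = origins[:, None, :] + ts[None, :, None] * d[None, None, :] + center
    idx = np.floor(pts / sp).astype(np.int64)
    valid = np.all((idx >= 0) & (idx < shape), axis=2)
    flat = np.where(
        valid,
        (idx[..., 0] * shape[1] + idx[..., 1]) * shape[2] + idx[..., 2],
        0,
    )
    in_roi = np.where(valid, roi.ravel()[flat], False)
    is_bone = np.where(valid, bone.ravel()[flat], False) & in_roi
    pair_in = in_roi[:, :-1] & in_roi[:, 1:]
    crossings = int(np.count_nonzero(pair_in & (is_bone[:, :-1] != is_bone[:, 1:])))
    length = float(np.count_nonzero(pair_in)) * step
    return length, crossings


def mil_fabric_tensor(
    bone_mask: np.ndarray,
    roi_mask: np.ndarray,
    spacing,
    n_directions: int = 512,
    line_spacing: float | None = None,
    seed: int = 0,
) -> FabricTensor:
    """Fit the MIL fabric tensor over a quasi-uniform hemisphere of
    directions.

    ``line_spacing`` defaults to two voxel edges; line sampling steps one
    voxel edge, and a crossing is any bone/background change between
    consecutive in-ROI samples.  Directions yielding zero crossings are
    dropped; more than 20% dropped raises (structure too dense or sparse
    for MIL).
    """
    bone_mask = np.asarray(bone_mask, dtype=bool)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if bone_mask.shape != roi_mask.shape:
        raise ValueError("bone and ROI masks must have the same shape")
    n_in = np.count_nonzero(bone_mask & roi_mask)
    if n_in == 0 or n_in == np.count_nonzero(roi_mask):
        raise ValueError("ROI must contain both bone and background")
    sp = np.asarray(spacing, dtype=float) if np.ndim(spacing) else np.repeat(float(spacing), 3)
    if sp.size == 1:
        sp = np.repeat(sp, 3)
    step = float(sp.min())
    if line_spacing is None:
        line_spacing = 2.0 * step

    dirs = hemisphere_directions(n_directions, seed=seed)
    mils, kept = [], []
    for d in dirs:
        length, crossings = _mil_one_direction(bone_mask, roi_mask, sp, d, line_spacing, step)
        if crossings == 0 or length == 0:
            continue
        mils.append(length / crossings)
        kept.append(d)
    if len(kept) < 0.8 * n_directions:
        raise FabricEstimationError(
            f"only {len(kept)}/{n_directions} directions produced crossings"
        )
    kept = np.asarray(kept)
    mils = np.asarray(mils)

    # least-squares ellipsoid fit  n^T H n = 1 / MIL^2
    n1, n2, n3 = kept[:, 0], kept[:, 1], kept[:, 2]
    A = np.stack([n1**2, n2**2, n3**2, 2 * n1 * n2, 2 * n1 * n3, 2 * n2 * n3], axis=1)
    b = 1.0 / mils**2
    coef, *_ = np.linalg.lstsq(A, b, rcond=None)
    H = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    w, V = np.linalg.eigh(H)
    if np.any(w <= 0):
        # extremely oriented structures (e.g. ideal parallel plates) have a
        # near-degenerate fabric: the 1/MIL^2 values along the structure are
        # ~0 and the fit can dip marginally negative.  Clamp those to a small
        # positive floor; anything clearly negative is a failed fit.
        if w.min() < -0.05 * w.max():
            raise FabricEstimationError("fitted MIL tensor is not positive definite")
        w = np.maximum(w, 1e-6 * w.max())
    lengths = 1.0 / np.sqrt(w)  # ascending w -> descending lengths
    order = np.argsort(lengths)[::-1]
    lengths = lengths[order]
    V = V[:, order]
    DA = 1.0 - lengths[-1] / lengths[0]
    return FabricTensor(
        H=H,
        mil_lengths=lengths,
        eigenvectors=V,
        DA=float(DA),
        n_directions_used=len(kept),
    )


def degree_of_anisotropy(mil_lengths) -> float:
    """DA = 1 - L_min / L_max of the MIL eigen-lengths (0 = isotropic)."""
    L = np.asarray(mil_lengths, dtype=float)
    if np.any(L <= 0):
        raise ValueError("MIL lengths must be positive")
    return float(1.0 - L.min() / L.max())


def trabecular_orientation(tensor: FabricTensor) -> float:
    """Deviation (degrees) of the principal MIL eigenvector from the
    superior/inferior axis, folded to [0, 90] by antipodal symmetry."""
    v1 = tensor.principal_direction
    v1 = v1 / np.linalg.norm(v1)
    return float(np.degrees(np.arccos(min(1.0, abs(v1[2])))))
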