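"""Grayscale image operations on 3-D scan volumes.

Conventions used throughout the package: volumes are indexed ``data[i, j, k]``
with the third index running along the superior/inferior (axial) direction;
voxel indices are 0-based and the world position of a voxel centre is
``(index + 0.5) * spacing`` mm.  Two kinds of volume exist: ``raw`` scanner
output (any float/int range, possibly negative) and ``gray8`` (integers in
[0, 255], the working representation for the modulus law E = alpha * GS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball


class DegenerateImageError(ValueError):
    """Raised when a volume has no usable signal (e.g. all non-positive)."""


class SegmentationError(ValueError):
    """Raised when continuum segmentation finds no foreground."""


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (the convention used wherever grayscale
    becomes integer; numpy's default rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = np.atleast_1d(np.asarray(spacing, dtype=float))
    if s.size == 1:
        s = np.repeat(s, 3)
    if s.size != 3 or np.any(s <= 0):
        raise ValueError(f"spacing must be a positive scalar or triple, got {spacing!r}")
    return (float(s[0]), float(s[1]), float(s[2]))


@dataclass
class ImageVolume:
    """A 3-D scalar grid with physical voxel spacing in mm.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar voxel values; third axis is superior/inferior.
    spacing : float or (3,) sequence
        Voxel edge length(s) in mm.
    kind : {"raw", "gray8"}
        ``gray8`` volumes hold integers in [0, 255].
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    kind: str = "raw"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        self.spacing = _as_spacing(self.spacing)
        if self.kind not in ("raw", "gray8"):
            raise ValueError(f"kind must be 'raw' or 'gray8', got {self.kind!r}")
        if self.kind == "gray8":
            if self.data.size and (self.data.min() < 0 or self.data.max() > 255):
                raise ValueError("gray8 volume has values outside [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_centers_axial(self) -> np.ndarray:
        """World z-coordinate (mm) of each axial slice's voxel centres."""
        return (np.arange(self.shape[2]) + 0.5) * self.spacing[2]


@dataclass
class LabelMask:
    """Integer label grid over {0: background, 1: bone, 2: cement}."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label mask must be 3-D")
        self.spacing = _as_spacing(self.spacing)
        extra = set(np.unique(self.labels)) - {0, 1, 2}
        if extra:
            raise ValueError(f"labels outside {{0,1,2}}: {sorted(extra)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


def normalize_grayscale(volume: ImageVolume, reference_max: float | None = None) -> ImageVolume:
    """Truncate negatives and rescale a raw volume to 8-bit grayscale.

    Negative raw values are clamped to zero, then values are scaled by
    ``255 / M`` where ``M`` is ``reference_max`` if given (for consistency
    across specimens scanned under the same settings) and otherwise the
    volume's own post-truncation maximum.

    Raises
    ------
    DegenerateImageError
        If the post-truncation maximum is zero and no reference is supplied.
    """
    if volume.kind != "raw":
        raise ValueError("normalize_grayscale expects a raw volume")
    clipped = np.clip(volume.data.astype(float), 0.0, None)
    if reference_max is None:
        m = float(clipped.max()) if clipped.size else 0.0
        if m <= 0:
            raise DegenerateImageError("volume has no positive values and no reference_max")
    else:
        m = float(reference_max)
        if m <= 0:
            raise ValueError("reference_max must be positive")
    scaled = round_half_away(clipped * (255.0 / m))
    data = np.clip(scaled, 0, 255).astype(np.uint8)
    return ImageVolume(data, volume.spacing, kind="gray8")


def convert_scanner_grayscale(volume: ImageVolume, gain: float, offset: float) -> ImageVolume:
    """Affine grayscale map between scanner conventions (e.g. HR-pQCT to
    micro-CT): ``value -> clamp(round(gain * value + offset), 0, 255)``.

    The gain/offset come from an external cross-scanner phantom calibration;
    deriving them is outside this package.
    """
    if volume.kind != "gray8":
        raise ValueError("convert_scanner_grayscale expects a gray8 volume")
    mapped = round_half_away(gain * volume.data.astype(float) + offset)
    return ImageVolume(np.clip(mapped, 0, 255).astype(np.uint8), volume.spacing, kind="gray8")


def _overlap_matrix(n_src: int, src_h: float, n_tgt: int, tgt_h: float) -> np.ndarray:
    """1-D fractional-overlap weights, shape (n_tgt, n_src): entry (i, j) is
    the length of [i*t,(i+1)*t) ∩ [j*s,(j+1)*s)."""
    src_lo = np.arange(n_src) * src_h
    src_hi = src_lo + src_h
    tgt_lo = np.arange(n_tgt) * tgt_h
    tgt_hi = tgt_lo + tgt_h
    lo = np.maximum(tgt_lo[:, None], src_lo[None, :])
    hi = np.minimum(tgt_hi[:, None], src_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def downsample_partial_volume(volume: ImageVolume, target_spacing) -> ImageVolume:
    """Down-sample with a partial-volume (fractional geometric overlap) filter.

    Each target voxel's value is the volume-weighted mean of every source
    voxel overlapping it; target voxels at the boundary that are only partly
    covered by the source grid are normalised by the covered volume only.
    This is a box filter, not interpolation, so the mean intensity of the
    volume is conserved.  The output keeps the input ``kind`` (gray8 output
    is re-rounded half-away-from-zero).
    """
    tgt = _as_spacing(target_spacing)
    src = volume.spacing
    if any(t < s - 1e-12 for t, s in zip(tgt, src)):
        raise ValueError(f"target spacing {tgt} finer than source spacing {src}")
    shape = volume.shape
    n_tgt = [max(1, int(np.ceil(shape[a] * src[a] / tgt[a] - 1e-9))) for a in range(3)]
    mats = [_overlap_matrix(shape[a], src[a], n_tgt[a], tgt[a]) for a in range(3)]

    acc = volume.data.astype(float)
    # apply the 1-D overlap matrix along each axis in turn
    acc = np.tensordot(mats[0], acc, axes=(1, 0))
    acc = np.tensordot(mats[1], acc.transpose(1, 0, 2), axes=(1, 0)).transpose(1, 0, 2)
    acc = np.tensordot(mats[2], acc.transpose(2, 0, 1), axes=(1, 0)).transpose(1, 2, 0)
    w = [m.sum(axis=1) for m in mats]  # covered length per target cell
    norm = w[0][:, None, None] * w[1][None, :, None] * w[2][None, None, :]
    out = acc / norm
    if volume.kind == "gray8":
        out = np.clip(round_half_away(out), 0, 255).astype(np.uint8)
    return ImageVolume(out, tgt, kind=volume.kind)


def segment_continuum(
    volume: ImageVolume,
    bone_threshold: float | None = None,
    cement_planes: tuple[float, float] = (0.0, np.inf),
    closing_radius_voxels: int = 3,
) -> LabelMask:
    """Segment a gray8 volume into continuum bone and cement masks.

    Voxels at or above ``bone_threshold`` (default: Otsu over the nonzero
    voxels) are foreground; morphological closing with a ball of
    ``closing_radius_voxels`` followed by hole filling turns the porous
    trabecular region into a continuum solid; only the largest connected
    component is kept.  Foreground voxels whose axial centre lies outside
    the slab between the two ``cement_planes`` (mm) are labelled cement (2),
    the rest bone (1).
    """
    if volume.kind != "gray8":
        raise ValueError("segment_continuum expects a gray8 volume")
    data = volume.data
    if bone_threshold is None:
        nz = data[data > 0]
        if nz.size == 0:
            raise SegmentationError("volume is entirely zero")
        bone_threshold = float(threshold_otsu(nz))
    fg = data >= bone_threshold
    if not fg.any():
        raise SegmentationError(f"no voxels at or above threshold {bone_threshold}")
    if closing_radius_voxels > 0:
        r = closing_radius_voxels
        # pad so the closing does not erode foreground touching the volume edge
        padded = np.pad(fg, r, mode="edge")
        padded = ndimage.binary_closing(padded, structure=ball(r))
        fg = padded[r:-r, r:-r, r:-r]
    fg = ndimage.binary_fill_holes(fg)
    comp, n = ndimage.label(fg)
    if n > 1:
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        fg = comp == int(np.argmax(sizes))
    if not fg.any():
        raise SegmentationError("segmentation produced empty foreground")

    z = volume.voxel_centers_axial()
    z0, z1 = sorted(float(p) for p in cement_planes)
    is_cement_slice = (z < z0) | (z > z1)
    labels = np.zeros(volume.shape, dtype=np.uint8)
    labels[fg] = 1
    labels[fg & is_cement_slice[None, None, :]] = 2
    return LabelMask(labels, volume.spacing)
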