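"""Synthetic micro-CT-like vertebra phantoms and compression-test curves.

The phantom emulates a vertebral body potted for mechanical testing: a
roughly cylindrical body with a solid cortical shell and a trabecular
interior, capped above and below by uniform cement slabs, on an isotropic
voxel grid with 8-bit-range grayscale and additive scanner noise.  The
trabecular texture is an anisotropic correlated Gaussian random field
(white noise blurred by an ellipsoidal kernel elongated along the body
axis) thresholded at the quantile that realises the requested bone volume
fraction, which gives continuous, seedable control over both BV/TV and the
degree of anisotropy seen by the fabric-tensor analysis.

Curves emulate a displacement-controlled compression to failure: a smooth
quadratic toe region, a linear region of known slope (the ground-truth
apparent stiffness) and a post-yield load plateau, with optional additive
load noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from vertefem.image_ops import ImageVolume, LabelMask
from vertefem.mech_curves import DEFAULT_WINDOW_MM, LoadDisplacementCurve


@dataclass
class PhantomSpec:
    """Geometry, texture and grayscale parameters of a synthetic vertebra.

    Defaults give a desk-sized specimen: 24 mm diameter, 20 mm body height,
    4 mm cement endcaps, 0.5 mm voxels.
    """

    body_radius: float = 12.0  # mm
    body_height: float = 20.0  # mm
    endcap_height: float = 4.0  # mm
    shell_thickness: float = 1.5  # mm
    voxel_spacing: float = 0.5  # mm, isotropic
    trabecular_bvtv_target: float = 0.40  # fraction of bone in the interior
    anisotropy_stretch: float = 2.0  # axial elongation of the texture kernel
    texture_scale_mm: float = 0.6  # transverse correlation scale of the field
    bone_gray_mean: float = 180.0
    cement_gray: float = 110.0
    background_gray: float = 5.0
    noise_sd: float = 4.0  # grayscale units
    lateral_margin: float = 1.0  # mm of background around the body
    seed: int = 0

    def __post_init__(self):
        for name in ("body_radius", "body_height", "endcap_height", "voxel_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.shell_thickness < 0 or self.shell_thickness >= self.body_radius:
            raise ValueError("shell_thickness must be in [0, body_radius)")
        if not (0.05 < self.trabecular_bvtv_target < 0.95):
            raise ValueError("trabecular_bvtv_target must be in (0.05, 0.95)")
        if self.anisotropy_stretch < 1:
            raise ValueError("anisotropy_stretch must be >= 1")
        for name in ("bone_gray_mean", "cement_gray", "background_gray"):
            g = getattr(self, name)
            if not (0 <= g <= 255):
                raise ValueError(f"{name} must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomTruth:
    """Ground truth realised by :func:`generate_phantom`.

    ``region_labels`` is the continuum truth (0 background, 1 bone body
    including trabecular pores, 2 cement) used to score segmentation;
    ``trabecular_mask`` is the voxel-level bone microstructure inside the
    shell, used by morphometry; ``cement_planes`` are the axial coordinates
    (mm) of the cement/bone interfaces.
    """

    realized_bvtv: float
    axis: tuple[float, float, float]
    region_labels: np.ndarray
    trabecular_mask: np.ndarray
    bone_mask: np.ndarray  # all bone voxels (shell + trabeculae)
    cement_planes: tuple[float, float]
    center_xy: tuple[float, float]  # mm
    interior_radius: float  # mm
    spec: PhantomSpec


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Generate a seeded synthetic vertebra volume with known ground truth.

    Returns a ``raw`` float volume (grayscale-valued, with noise that may
    dip below zero, to be run through :func:`image_ops.normalize_grayscale`
    with ``reference_max=255``) and the realised ground truth.  The same
    spec and seed always produce bit-identical output.
    """
    h = spec.voxel_spacing
    half_xy = spec.body_radius + spec.lateral_margin
    nx = ny = int(np.ceil(2 * half_xy / h))
    nz = int(np.ceil((spec.body_height + 2 * spec.endcap_height) / h))

    cx = cy = nx * h / 2.0
    x = (np.arange(nx) + 0.5) * h - cx
    y = (np.arange(ny) + 0.5) * h - cy
    z = (np.arange(nz) + 0.5) * h
    r2 = x[:, None] ** 2 + y[None, :] ** 2
    in_cyl = r2 <= spec.body_radius**2
    in_shell = in_cyl & (r2 > (spec.body_radius - spec.shell_thickness) ** 2)
    in_core = in_cyl & ~in_shell

    z_lo = spec.endcap_height
    z_hi = spec.endcap_height + spec.body_height
    is_cap = (z < z_lo) | (z >= z_hi)
    is_body = ~is_cap

    region = np.zeros((nx, ny, nz), dtype=np.uint8)
    region[in_cyl[:, :, None] & is_cap[None, None, :]] = 2
    region[in_cyl[:, :, None] & is_body[None, None, :]] = 1

    # anisotropic correlated random field for the trabecular texture
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((nx, ny, nz))
    s_xy = spec.texture_scale_mm / h
    field = ndimage.gaussian_filter(noise, sigma=(s_xy, s_xy, s_xy * spec.anisotropy_stretch))

    core3d = in_core[:, :, None] & is_body[None, None, :]
    core_vals = field[core3d]
    thr = np.quantile(core_vals, 1.0 - spec.trabecular_bvtv_target)
    trab = np.zeros_like(core3d)
    trab[core3d] = core_vals >= thr
    realized = float(trab[core3d].mean())

    shell3d = in_shell[:, :, None] & is_body[None, None, :]
    bone = trab | shell3d

    data = np.full((nx, ny, nz), spec.background_gray, dtype=float)
    data[region == 2] = spec.cement_gray
    data[bone] = spec.bone_gray_mean
    if spec.noise_sd > 0:
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)

    vol = ImageVolume(data, h, kind="raw")
    truth = PhantomTruth(
        realized_bvtv=realized,
        axis=(0.0, 0.0, 1.0),
        region_labels=region,
        trabecular_mask=trab,
        bone_mask=bone,
        cement_planes=(z_lo, z_hi),
        center_xy=(cx, cy),
        interior_radius=spec.body_radius - spec.shell_thickness,
        spec=spec,
    )
    return vol, truth


def truth_label_mask(truth: PhantomTruth) -> LabelMask:
    """Continuum ground-truth labels as a LabelMask (for scoring)."""
    return LabelMask(truth.region_labels.copy(), truth.spec.voxel_spacing)


@dataclass
class CurveSpec:
    """Parameters of a synthetic load-displacement curve.

    The linear region between the toe and the plateau must span at least
    the 0.6 mm stiffness-analysis window plus one sample.
    """

    true_stiffness: float  # kN/mm
    toe_length: float = 0.2  # mm
    plateau_load: float = np.inf  # kN
    sample_step: float = 0.005  # mm (~20 Hz sampling at 1 mm/min)
    total_displacement: float = 2.5  # mm
    noise_sd: float = 0.0  # kN
    seed: int = 0

    def __post_init__(self):
        if self.true_stiffness <= 0:
            raise ValueError("true_stiffness must be positive")
        if self.toe_length < 0 or self.sample_step <= 0 or self.total_displacement <= 0:
            raise ValueError("lengths must be non-negative, step and total positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        window = DEFAULT_WINDOW_MM
        if self.total_displacement < self.toe_length + window + self.sample_step - 1e-12:
            raise ValueError(
                "total_displacement too short: the linear region must span the "
                f"{window} mm analysis window"
            )
        if np.isfinite(self.plateau_load):
            onset = self._plateau_onset()
            if onset < self.toe_length + window + self.sample_step - 1e-12:
                raise ValueError(
                    "plateau starts before a full analysis window fits in the linear region"
                )

    def _plateau_onset(self) -> float:
        # displacement at which the linear ramp reaches plateau_load
        load_at_toe = 0.5 * self.true_stiffness * self.toe_length
        return self.toe_length + (self.plateau_load - load_at_toe) / self.true_stiffness


def generate_curve(spec: CurveSpec) -> LoadDisplacementCurve:
    """Synthesize a toe / linear / plateau compression curve.

    The toe is the quadratic ramp ``k d^2 / (2 t)`` (slope 0 at the origin,
    slope k at the toe end, C1-continuous into the linear region); the
    linear region has slope ``true_stiffness``; the load saturates at
    ``plateau_load``.  Noise is additive i.i.d. Gaussian on the load.
    """
    k, t = spec.true_stiffness, spec.toe_length
    d = np.arange(0.0, spec.total_displacement + spec.sample_step / 2, spec.sample_step)
    if t > 0:
        load = np.where(d < t, k * d**2 / (2 * t), k * t / 2 + k * (d - t))
    else:
        load = k * d
    if np.isfinite(spec.plateau_load):
        load = np.minimum(load, spec.plateau_load)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        load = load + rng.normal(0.0, spec.noise_sd, size=load.shape)
    return LoadDisplacementCurve(displacement=d, load=load, specimen_id=f"synthetic-{spec.seed}")
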