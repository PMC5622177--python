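"""Readers and writers for volumes (TIFF stacks, MetaImage) and curves (CSV).

Array convention: in memory, volumes are ``data[i, j, k]`` with k axial;
on disk both TIFF stacks and MetaImage store slices as ``[z, y, x]``, so
axes are transposed on the way in and out.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from vertefem.image_ops import ImageVolume, LabelMask
from vertefem.mech_curves import LoadDisplacementCurve


def read_volume(path, spacing=None, kind: str = "raw") -> ImageVolume:
    """Read a volume from a MetaImage (.mhd/.mha) or multi-page TIFF.

    MetaImage carries its own spacing; for TIFF, ``spacing`` (mm) is
    required.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".mhd", ".mha"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        sp = img.GetSpacing()  # (x, y, z)
        return ImageVolume(data, sp, kind=kind)
    if suffix in (".tif", ".tiff"):
        if spacing is None:
            raise ValueError("TIFF volumes need an explicit spacing (mm)")
        data = tifffile.imread(str(path))
        if data.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF stack, got shape {data.shape}")
        return ImageVolume(data.transpose(2, 1, 0), spacing, kind=kind)
    raise ValueError(f"unsupported volume format: {path.name}")


def write_volume(path, volume: ImageVolume) -> None:
    """Write a volume as MetaImage (.mhd/.raw pair or .mha) or TIFF stack."""
    path = Path(path)
    suffix = path.suffix.lower()
    zyx = np.ascontiguousarray(volume.data.transpose(2, 1, 0))
    if suffix in (".mhd", ".mha"):
        img = sitk.GetImageFromArray(zyx)
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        sitk.WriteImage(img, str(path))
    elif suffix in (".tif", ".tiff"):
        tifffile.imwrite(str(path), zyx)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def write_label_mask(path, mask: LabelMask) -> None:
    write_volume(path, ImageVolume(mask.labels.astype(np.uint8), mask.spacing, kind="gray8"))


def read_label_mask(path, spacing=None) -> LabelMask:
    vol = read_volume(path, spacing=spacing, kind="gray8")
    return LabelMask(vol.data, vol.spacing)


def read_curve_csv(path, load_unit: str | None = None, specimen_id: str | None = None) -> LoadDisplacementCurve:
    """Read a two-column load-displacement CSV.

    Columns must be named ``displacement_mm`` and either ``load_kN`` or
    ``load_N`` (case-insensitive); the header declares the unit unless
    ``load_unit`` overrides it.  Loads are stored as kN.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "displacement_mm" not in cols:
        raise ValueError(f"{path}: missing displacement_mm column")
    disp = df[cols["displacement_mm"]].to_numpy(dtype=float)
    if load_unit is None:
        if "load_kn" in cols:
            load, load_unit = df[cols["load_kn"]].to_numpy(dtype=float), "kN"
        elif "load_n" in cols:
            load, load_unit = df[cols["load_n"]].to_numpy(dtype=float), "N"
        else:
            raise ValueError(f"{path}: missing load_kN or load_N column")
    else:
        load_col = next((cols[c] for c in ("load_kn", "load_n", "load") if c in cols), None)
        if load_col is None:
            raise ValueError(f"{path}: no load column found")
        load = df[load_col].to_numpy(dtype=float)
    if load_unit.lower() == "n":
        load = load / 1000.0
    sid = specimen_id if specimen_id is not None else Path(path).stem
    return LoadDisplacementCurve(displacement=disp, load=load, specimen_id=sid)


def write_curve_csv(path, curve: LoadDisplacementCurve) -> None:
    pd.DataFrame(
        {"displacement_mm": curve.displacement, "load_kN": curve.load}
    ).to_csv(path, index=False)
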