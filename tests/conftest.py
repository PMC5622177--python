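import numpy as np
import pytest

from vertefem.image_ops import (
    LabelMask,
    downsample_partial_volume,
    normalize_grayscale,
    segment_continuum,
)
from vertefem.meshing import build_voxel_mesh
from vertefem.phantom import PhantomSpec, generate_phantom


def small_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A desk-sized phantom that keeps FE solves under a second."""
    kwargs = dict(
        body_radius=5.0,
        body_height=7.0,
        endcap_height=2.0,
        shell_thickness=1.0,
        voxel_spacing=0.5,
        trabecular_bvtv_target=0.40,
        anisotropy_stretch=2.0,
        noise_sd=2.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def process_phantom(vol, truth, target_spacing=1.0, closing_radius=2):
    """The image chain: normalize -> down-sample -> segment -> mesh."""
    gray = normalize_grayscale(vol, reference_max=255)
    gray_ds = downsample_partial_volume(gray, target_spacing)
    mask = segment_continuum(
        gray_ds, cement_planes=truth.cement_planes, closing_radius_voxels=closing_radius
    )
    return gray_ds, mask, build_voxel_mesh(mask)


def all_bone_mesh_and_gray(seed: int = 0):
    """Phantom processed with cement relabelled as bone, so the whole model
    follows the grayscale law and K(alpha) is exactly proportional to alpha."""
    vol, truth = generate_phantom(small_phantom_spec(seed=seed))
    gray_ds, mask, _ = process_phantom(vol, truth)
    labels = mask.labels.copy()
    labels[labels == 2] = 1
    return build_voxel_mesh(LabelMask(labels, mask.spacing)), gray_ds


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """10x10x10 mm cube of 1 mm voxels (1000 elements)."""
    return build_voxel_mesh(LabelMask(np.ones((10, 10, 10), dtype=np.uint8), 1.0))


@pytest.fixture(scope="session")
def demo_pipeline(tmp_path_factory):
    """The packaged synthetic study (6 specimens, alpha_true = 0.008, 3/3
    split) materialized and run end to end; shared because it is the most
    expensive fixture in the suite."""
    from vertefem.workflow_stats import make_demo_config, run_pipeline

    workdir = tmp_path_factory.mktemp("demo")
    cfg = make_demo_config(workdir, n_specimens=6, alpha_true=0.008, seed=3)
    out = workdir / "out"
    report = run_pipeline(cfg, out_dir=out)
    return {"config": cfg, "report": report, "out_dir": out, "alpha_true": 0.008}
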