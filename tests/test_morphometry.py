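import math

import numpy as np
import pytest

from vertefem.morphometry import (
    FabricTensor,
    ROICylinder,
    bvtv,
    degree_of_anisotropy,
    fit_largest_cylinder,
    mil_fabric_tensor,
    trabecular_orientation,
)
from vertefem.phantom import generate_phantom

from conftest import small_phantom_spec


def cylinder_mask(shape=(50, 50, 30), spacing=0.5, radius=10.0):
    x = (np.arange(shape[0]) + 0.5) * spacing - shape[0] * spacing / 2
    r2 = x[:, None] ** 2 + x[None, :] ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[r2 <= radius**2] = True
    return mask


class TestCylinderFit:
    def test_recovers_perfect_cylinder(self):
        mask = cylinder_mask()
        roi = fit_largest_cylinder(mask, (0.5, 0.5, 0.5), 0.0, 15.0)
        assert roi.radius == pytest.approx(10.0, abs=0.5)
        assert roi.center_x == pytest.approx(12.5, abs=0.5)
        assert roi.center_y == pytest.approx(12.5, abs=0.5)

    def test_cone_limited_by_narrowest_slice(self):
        shape = (50, 50, 30)
        x = (np.arange(50) + 0.5) * 0.5 - 12.5
        r2 = x[:, None] ** 2 + x[None, :] ** 2
        cone = np.zeros(shape, dtype=bool)
        for k in range(30):
            r = 10.0 - 5.0 * k / 29
            cone[:, :, k] = r2 <= r**2
        roi = fit_largest_cylinder(cone, (0.5, 0.5, 0.5), 0.0, 15.0)
        assert roi.radius == pytest.approx(5.0, abs=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fit_largest_cylinder(np.zeros((5, 5, 5), bool), (1, 1, 1), 0.0, 5.0)


class TestBvtv:
    def test_all_bone_is_one(self):
        assert bvtv(np.ones((4, 4, 4), bool)) == 1.0

    def test_checkerboard_is_half(self):
        idx = np.indices((8, 8, 8)).sum(axis=0)
        assert bvtv(idx % 2 == 0) == pytest.approx(0.5, abs=0.01)

    def test_phantom_target_recovered_in_roi(self):
        spec = small_phantom_spec(seed=1, trabecular_bvtv_target=0.45,
                                  anisotropy_stretch=1.0, body_radius=8.0)
        vol, truth = generate_phantom(spec)
        roi = ROICylinder(
            center_x=truth.center_xy[0], center_y=truth.center_xy[1],
            radius=truth.interior_radius,
            z_min=truth.cement_planes[0], z_max=truth.cement_planes[1],
        )
        m = roi.contains_mask(truth.trabecular_mask.shape, vol.spacing)
        assert bvtv(truth.trabecular_mask[m]) == pytest.approx(0.45, abs=0.02)
        assert truth.realized_bvtv == pytest.approx(0.45, abs=0.02)


class TestFabric:
    def fabric_of_phantom(self, stretch, seed=7, n_directions=96):
        spec = small_phantom_spec(seed=seed, body_radius=8.0, body_height=12.0,
                                  noise_sd=0.0, anisotropy_stretch=stretch)
        vol, truth = generate_phantom(spec)
        roi = ROICylinder(
            center_x=truth.center_xy[0], center_y=truth.center_xy[1],
            radius=truth.interior_radius * 0.8,
            z_min=truth.cement_planes[0] + 1.0, z_max=truth.cement_planes[1] - 1.0,
        )
        m = roi.contains_mask(truth.trabecular_mask.shape, vol.spacing)
        return mil_fabric_tensor(truth.trabecular_mask, m, vol.spacing,
                                 n_directions=n_directions, seed=0)

    def test_isotropic_phantom_low_da(self):
        assert self.fabric_of_phantom(1.0).DA < 0.15

    def test_deterministic_given_seed(self):
        t1 = self.fabric_of_phantom(2.0)
        t2 = self.fabric_of_phantom(2.0)
        np.testing.assert_array_equal(t1.H, t2.H)

    def test_parallel_plates_in_plane_principal_direction(self):
        shape = (40, 40, 40)
        bone = np.zeros(shape, dtype=bool)
        for z0 in range(0, 40, 8):  # period 8 voxels, half filled
            bone[:, :, z0:z0 + 4] = True
        t = mil_fabric_tensor(bone, np.ones(shape, bool), 0.5, n_directions=128, seed=0)
        angle_from_axis = math.degrees(math.acos(abs(t.principal_direction[2])))
        assert t.DA > 0.5
        assert angle_from_axis > 80.0  # within 10 degrees of the x-y plane

    def test_da_rotation_invariance_about_axis(self):
        spec = small_phantom_spec(seed=3, body_radius=8.0, noise_sd=0.0,
                                  anisotropy_stretch=2.0)
        vol, truth = generate_phantom(spec)
        bone = truth.trabecular_mask
        roi = ROICylinder(
            center_x=truth.center_xy[0], center_y=truth.center_xy[1],
            radius=truth.interior_radius * 0.8,
            z_min=truth.cement_planes[0] + 1.0, z_max=truth.cement_planes[1] - 1.0,
        )
        m = roi.contains_mask(bone.shape, vol.spacing)
        da = mil_fabric_tensor(bone, m, vol.spacing, n_directions=96, seed=0).DA
        da_rot = mil_fabric_tensor(
            np.rot90(bone, axes=(0, 1)).copy(), np.rot90(m, axes=(0, 1)).copy(),
            vol.spacing, n_directions=96, seed=0,
        ).DA
        assert abs(da - da_rot) <= 0.05

    def test_single_phase_roi_rejected(self):
        with pytest.raises(ValueError):
            mil_fabric_tensor(np.ones((8, 8, 8), bool), np.ones((8, 8, 8), bool), 1.0)


class TestDerivedScalars:
    def test_isotropic_eigenvalues_give_zero_da(self):
        assert degree_of_anisotropy([1.0, 1.0, 1.0]) == 0.0

    @pytest.mark.parametrize(
        "v1,expected",
        [
            ((0.0, 0.0, 1.0), 0.0),
            ((1 / np.sqrt(2), 0.0, 1 / np.sqrt(2)), 45.0),
            ((0.0, 0.0, -1.0), 0.0),  # antipodal fold
        ],
    )
    def test_orientation_analytic_cases(self, v1, expected):
        V = np.eye(3)
        V[:, 0] = v1
        t = FabricTensor(H=np.eye(3), mil_lengths=np.array([2.0, 1.0, 1.0]),
                         eigenvectors=V, DA=0.5, n_directions_used=1)
        assert trabecular_orientation(t) == pytest.approx(expected, abs=1e-9)
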