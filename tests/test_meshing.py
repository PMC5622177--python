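import numpy as np
import pytest

from vertefem.image_ops import ImageVolume, LabelMask
from vertefem.meshing import (
    MaterialField,
    assign_materials,
    build_voxel_mesh,
    read_abaqus_inp,
    write_abaqus_inp,
)


def mask_from(labels, spacing=1.0):
    return LabelMask(np.asarray(labels, dtype=np.uint8), spacing)


class TestVoxelMesh:
    def test_single_voxel(self):
        m = build_voxel_mesh(mask_from(np.ones((1, 1, 1))))
        assert m.n_nodes == 8 and m.n_elements == 1

    def test_two_adjacent_voxels_share_a_face(self):
        labels = np.zeros((2, 1, 1))
        labels[:, 0, 0] = 1
        m = build_voxel_mesh(mask_from(labels))
        assert m.n_nodes == 12 and m.n_elements == 2
        shared = set(m.elements[0]) & set(m.elements[1])
        assert len(shared) == 4

    def test_l_shape_node_count(self):
        labels = np.zeros((2, 2, 1))
        labels[0, 0, 0] = labels[1, 0, 0] = labels[0, 1, 0] = 1
        m = build_voxel_mesh(mask_from(labels))
        assert m.n_nodes == 16 and m.n_elements == 3

    def test_full_block_node_formula(self):
        W, H, D = 4, 3, 5
        m = build_voxel_mesh(mask_from(np.ones((W, H, D))))
        assert m.n_nodes == (W + 1) * (H + 1) * (D + 1)
        assert m.n_elements == W * H * D

    def test_face_sets_come_from_cement(self):
        labels = np.ones((2, 2, 4))
        labels[:, :, 0] = 2
        labels[:, :, 3] = 2
        m = build_voxel_mesh(mask_from(labels))
        assert np.allclose(m.nodes[m.node_sets["bottom_face"], 2], 0.0)
        assert np.allclose(m.nodes[m.node_sets["top_face"], 2], 4.0)
        assert len(m.element_sets["cement"]) == 8
        assert len(m.element_sets["bone"]) == 8

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            build_voxel_mesh(mask_from(np.zeros((2, 2, 2))))


class TestMaterials:
    def gray(self, values):
        return ImageVolume(np.asarray(values, dtype=np.uint8), 1.0, "gray8")

    def test_linear_grayscale_law(self):
        m = build_voxel_mesh(mask_from(np.ones((1, 1, 1))))
        mats = assign_materials(m, self.gray(np.full((1, 1, 1), 100)), alpha=0.00904)
        assert mats.E_ele[0] == pytest.approx(0.904)

    def test_floor_applies_to_zero_gray(self):
        m = build_voxel_mesh(mask_from(np.ones((1, 1, 1))))
        mats = assign_materials(m, self.gray(np.zeros((1, 1, 1))), alpha=0.008, E_floor=0.001)
        assert mats.E_ele[0] == 0.001

    def test_cement_gets_fixed_modulus(self):
        labels = np.ones((1, 1, 2))
        labels[0, 0, 1] = 2
        m = build_voxel_mesh(mask_from(labels))
        mats = assign_materials(m, self.gray(np.full((1, 1, 2), 200)), alpha=0.008)
        cem = m.element_sets["cement"][0]
        bone = m.element_sets["bone"][0]
        assert mats.E_ele[cem] == 2.45
        assert mats.E_ele[bone] == pytest.approx(1.6)

    def test_alpha_linearity_before_floor(self):
        rng = np.random.default_rng(0)
        labels = np.ones((3, 3, 3))
        gray = self.gray(rng.integers(50, 255, (3, 3, 3)))
        m = build_voxel_mesh(mask_from(labels))
        m1 = assign_materials(m, gray, alpha=0.004, E_floor=1e-9)
        m2 = assign_materials(m, gray, alpha=0.008, E_floor=1e-9)
        np.testing.assert_allclose(m2.E_ele, 2 * m1.E_ele)

    def test_nonpositive_alpha_rejected(self):
        m = build_voxel_mesh(mask_from(np.ones((1, 1, 1))))
        with pytest.raises(ValueError):
            assign_materials(m, self.gray(np.ones((1, 1, 1))), alpha=0.0)


class TestAbaqusRoundTrip:
    def test_single_element_exact(self, tmp_path):
        m = build_voxel_mesh(mask_from(np.ones((1, 1, 1)), spacing=0.5))
        mats = MaterialField(E_ele=np.array([1.234]), nu=0.3)
        p = tmp_path / "one.inp"
        write_abaqus_inp(p, m, mats)
        m2, mats2 = read_abaqus_inp(p)
        assert m2.n_nodes == 8 and m2.n_elements == 1
        np.testing.assert_allclose(np.sort(m2.nodes, axis=0), np.sort(m.nodes, axis=0))
        assert mats2.E_ele[0] == pytest.approx(1.234)

    def test_two_distinct_moduli_two_sections(self, tmp_path):
        labels = np.ones((2, 1, 1))
        m = build_voxel_mesh(mask_from(labels))
        mats = MaterialField(E_ele=np.array([1.0, 2.0]), nu=0.3)
        p = tmp_path / "two.inp"
        write_abaqus_inp(p, m, mats)
        text = p.read_text()
        assert text.count("*SOLID SECTION") == 2
        _, mats2 = read_abaqus_inp(p)
        np.testing.assert_allclose(np.sort(mats2.E_ele), [1.0, 2.0])

    def test_phantom_mesh_round_trip_preserves_everything(self, tmp_path):
        rng = np.random.default_rng(3)
        labels = (rng.random((4, 4, 4)) < 0.7).astype(np.uint8)
        labels[0, 0, 0] = 1
        # keep the largest component only so the mesh is connected
        from scipy import ndimage

        comp, n = ndimage.label(labels)
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        labels = (comp == np.argmax(sizes)).astype(np.uint8)
        m = build_voxel_mesh(mask_from(labels, spacing=0.77))
        gray = ImageVolume(rng.integers(1, 255, (4, 4, 4), dtype=np.uint8), 0.77, "gray8")
        mats = assign_materials(m, gray, alpha=0.008)
        p = tmp_path / "ph.inp"
        write_abaqus_inp(p, m, mats)
        m2, mats2 = read_abaqus_inp(p)
        assert m2.n_elements == m.n_elements
        np.testing.assert_allclose(m2.nodes, m.nodes, rtol=1e-6)
        np.testing.assert_allclose(np.sort(mats2.E_ele), np.sort(mats.E_ele), rtol=1e-6)
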