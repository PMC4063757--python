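import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from qbtrack.formats import (DWIVolume, FormatError, GradientTable, ImageGrid,
                             Tractogram, read_dwi, read_label_volume,
                             read_tractogram, rotate_gradient_table,
                             write_dwi, write_label_volume, write_tractogram)
from qbtrack.formats import read_lookup_table, write_lookup_table

from conftest import voxel_dwi, tensor_signal


class TestGradientTable:
    def test_acquisition_scheme_counts(self, gtab):
        assert gtab.n_volumes == 56
        assert gtab.b0_mask.sum() == 1
        assert len(gtab.gradients) == 55

    def test_directions_are_unit_norm(self, gtab):
        assert np.allclose(np.linalg.norm(gtab.gradients, axis=1), 1.0,
                           atol=1e-6)

    def test_no_b0_rejected(self):
        with pytest.raises(FormatError):
            GradientTable(np.full(10, 2000.0), np.tile([1.0, 0, 0], (10, 1)))

    def test_zero_vector_with_nonzero_b_rejected(self):
        bvals = np.array([0.0, 2000.0])
        bvecs = np.array([[0.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(FormatError):
            GradientTable(bvals, bvecs)


class TestRotateGradientTable:
    def test_identity_rotations_leave_table_unchanged(self, gtab):
        out = rotate_gradient_table(gtab, [np.eye(3)] * gtab.n_volumes)
        assert np.allclose(out.bvecs, gtab.bvecs)
        assert np.array_equal(out.bvals, gtab.bvals)

    def test_quarter_turn_about_z(self, gtab):
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        gt = GradientTable(np.array([0.0, 2000.0]),
                           np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        out = rotate_gradient_table(gt, [np.eye(3), Rz])
        assert np.allclose(out.bvecs[1], [0.0, 1.0, 0.0], atol=1e-12)

    def test_reflection_rejected(self, gtab):
        flip = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(FormatError):
            rotate_gradient_table(gtab, [flip] * gtab.n_volumes)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(0, 10_000))
    def test_rotation_composes_and_preserves_norm(self, gtab, s1, s2):
        R1 = Rotation.random(rng=s1).as_matrix()
        R2 = Rotation.random(rng=s2).as_matrix()
        n = gtab.n_volumes
        once = rotate_gradient_table(rotate_gradient_table(gtab, [R1] * n),
                                     [R2] * n)
        combined = rotate_gradient_table(gtab, [R2 @ R1] * n)
        assert np.allclose(once.bvecs, combined.bvecs, atol=1e-6)
        assert np.allclose(np.linalg.norm(once.gradients, axis=1), 1.0,
                           atol=1e-6)


class TestImageGrid:
    def test_voxel_size_from_affine(self):
        g = ImageGrid.isotropic((4, 5, 6), 2.2)
        assert np.allclose(g.voxel_size, 2.2)

    def test_world_voxel_round_trip(self):
        rng = np.random.default_rng(0)
        aff = np.eye(4)
        aff[:3, :3] = np.diag([2.2, 2.2, 2.2])
        aff[:3, 3] = [-30.0, 10.0, 5.0]
        g = ImageGrid((10, 10, 10), aff)
        ijk = rng.uniform(0, 9, size=(20, 3))
        assert np.allclose(g.world_to_voxel(g.voxel_to_world(ijk)), ijk)

    def test_singular_affine_rejected(self):
        aff = np.zeros((4, 4))
        aff[3, 3] = 1.0
        with pytest.raises(FormatError):
            ImageGrid((2, 2, 2), aff)


class TestDwiIO:
    def test_round_trip(self, tmp_path, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        dwi = voxel_dwi(sig, gtab, shape=(3, 4, 5))
        write_dwi(dwi, tmp_path / "d.nii.gz", tmp_path / "bvals",
                  tmp_path / "bvecs")
        back = read_dwi(tmp_path / "d.nii.gz", tmp_path / "bvals",
                        tmp_path / "bvecs")
        assert np.allclose(back.data, dwi.data, rtol=1e-6)
        assert np.allclose(back.gtab.bvecs, dwi.gtab.bvecs, atol=1e-9)
        assert back.gtab.b0_mask.sum() == 1
        assert len(back.gtab.gradients) == 55

    def test_volume_count_mismatch_rejected(self, tmp_path, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        dwi = voxel_dwi(sig, gtab)
        write_dwi(dwi, tmp_path / "d.nii.gz", tmp_path / "bvals",
                  tmp_path / "bvecs")
        bad = np.concatenate([gtab.bvals, [2000.0]])
        np.savetxt(tmp_path / "bvals_bad", bad[None, :])
        vecs = np.vstack([gtab.bvecs, [[1.0, 0, 0]]])
        np.savetxt(tmp_path / "bvecs_bad", vecs.T)
        with pytest.raises(FormatError):
            read_dwi(tmp_path / "d.nii.gz", tmp_path / "bvals_bad",
                     tmp_path / "bvecs_bad")

    def test_multiple_b0s_averaged(self, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        bvals = np.concatenate([[0.0], gtab.bvals])
        bvecs = np.vstack([[0.0, 0, 0], gtab.bvecs])
        g2 = GradientTable(bvals, bvecs)
        data = np.concatenate([[900.0], sig])
        dwi = voxel_dwi(data, g2)
        assert np.isclose(dwi.b0_reference()[0, 0, 0], 950.0)


class TestTrkIO:
    def _grid(self):
        return ImageGrid.isotropic((10, 12, 8), 2.2)

    def test_empty_tractogram_round_trip(self, tmp_path):
        tg = Tractogram([], self._grid(), step_mm=1.1)
        write_tractogram(tg, tmp_path / "e.trk")
        back = read_tractogram(tmp_path / "e.trk", grid=self._grid())
        assert len(back) == 0

    def test_points_preserved_within_tolerance(self, tmp_path):
        rng = np.random.default_rng(3)
        start = rng.uniform(2, 5, size=3)
        d = np.array([0.0, 1.0, 0.0])
        sl = start + 1.1 * np.arange(5)[:, None] * d
        tg = Tractogram([sl], self._grid(), step_mm=1.1)
        write_tractogram(tg, tmp_path / "t.trk")
        back = read_tractogram(tmp_path / "t.trk", grid=self._grid())
        assert len(back) == 1
        assert np.abs(back.streamlines[0] - sl).max() <= 1e-3

    def test_header_records_voxel_size(self, tmp_path):
        import nibabel as nib

        tg = Tractogram([np.zeros((2, 3)) + [[1, 1, 1], [1, 2.1, 1]]],
                        self._grid(), step_mm=1.1)
        write_tractogram(tg, tmp_path / "t.trk")
        hdr = nib.streamlines.load(str(tmp_path / "t.trk")).header
        assert np.allclose(hdr["voxel_sizes"], (2.2, 2.2, 2.2), atol=1e-5)

    def test_grid_mismatch_rejected(self, tmp_path):
        tg = Tractogram([np.array([[1.0, 1, 1], [1, 2.1, 1]])],
                        self._grid(), step_mm=1.1)
        write_tractogram(tg, tmp_path / "t.trk")
        other = ImageGrid.isotropic((10, 12, 8), 2.0)
        with pytest.raises(FormatError):
            read_tractogram(tmp_path / "t.trk", grid=other)


class TestLabelIO:
    def test_round_trip_is_bit_identical(self, tmp_path):
        from qbtrack.formats import LabelVolume

        rng = np.random.default_rng(1)
        labels = rng.integers(0, 4, size=(6, 6, 4)).astype(np.int32)
        lut = {1: "a", 2: "b", 3: "c"}
        vol = LabelVolume(labels, lut, ImageGrid.isotropic((6, 6, 4), 2.2))
        write_label_volume(vol, tmp_path / "l.nii.gz", tmp_path / "lut.tsv")
        back = read_label_volume(tmp_path / "l.nii.gz", tmp_path / "lut.tsv")
        assert np.array_equal(back.labels, labels)
        assert back.lookup == lut

    def test_lookup_accepts_comma_and_tab(self, tmp_path):
        (tmp_path / "lut.csv").write_text("1,area_a\n2\tarea_b\n")
        assert read_lookup_table(tmp_path / "lut.csv") == \
            {1: "area_a", 2: "area_b"}

    def test_unknown_label_rejected(self):
        from qbtrack.formats import LabelVolume

        labels = np.ones((2, 2, 2), dtype=np.int32) * 7
        with pytest.raises(FormatError):
            LabelVolume(labels, {1: "a"}, ImageGrid.isotropic((2, 2, 2), 2.2))
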