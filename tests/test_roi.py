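"""Sphere-ROI extraction from NIfTI volumes and cohort manifests."""

import nibabel as nib
import numpy as np
import pytest

from ecdcm.cohort import (CohortConfig, generate_cohort, render_nifti,
                          write_manifest)
from ecdcm.exceptions import ArgumentError, DataError, ManifestError, ROIError
from ecdcm.roi import (DEFAULT_ROIS, ROISet, extract_roi_timeseries,
                       read_cohort_manifest)


@pytest.fixture
def small_rois():
    return ROISet(labels=("a", "b"),
                  coordinates=np.array([[0.0, 0.0, 0.0],
                                        [20.0, 0.0, 0.0]]),
                  radius_mm=6.0)


def _image(data, voxel=4.0, origin=(-20.0, -20.0, -20.0)):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = origin
    return nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)


class TestExtraction:
    def test_default_roi_set_matches_study_definition(self):
        assert DEFAULT_ROIS.radius_mm == 8.0
        assert DEFAULT_ROIS.labels[4] == "L-dlPFC"
        assert tuple(DEFAULT_ROIS.coordinates[4]) == (-39.0, 34.0, 37.0)
        assert DEFAULT_ROIS.labels == ("L-PCC", "R-PCC", "L-ACC", "R-ACC",
                                       "L-dlPFC", "R-dlPFC", "mPFC")

    def test_constant_volume_gives_constant_series(self, small_rois):
        img = _image(np.full((11, 11, 11, 5), 3.25))
        out = extract_roi_timeseries(img, small_rois)
        assert out.shape == (5, 2)
        assert np.allclose(out, 3.25)

    def test_sphere_mean_matches_brute_force_voxel_loop(self, small_rois):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 1, (11, 11, 11, 4))
        img = _image(data)
        out = extract_roi_timeseries(img, small_rois)
        # independent brute-force loop over every voxel
        affine = img.affine
        for k, c in enumerate(small_rois.coordinates):
            acc = []
            for i in range(11):
                for j in range(11):
                    for l in range(11):
                        mm = affine[:3, :3] @ [i, j, l] + affine[:3, 3]
                        if np.sum((mm - c) ** 2) <= small_rois.radius_mm ** 2:
                            acc.append(data[i, j, l, :])
            assert np.allclose(out[:, k], np.mean(acc, axis=0))

    def test_extraction_invariant_to_storage_order(self, small_rois):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 1, (11, 12, 13, 3))
        img = _image(data)
        out = extract_roi_timeseries(img, small_rois)
        # permute spatial axes and fix the affine accordingly
        perm = (2, 0, 1, 3)
        data_p = np.transpose(data, perm)
        P = np.zeros((4, 4))
        P[3, 3] = 1.0
        for new_ax, old_ax in enumerate(perm[:3]):
            P[old_ax, new_ax] = 1.0
        img_p = nib.Nifti1Image(np.ascontiguousarray(data_p).astype(
            np.float32), img.affine @ P)
        out_p = extract_roi_timeseries(img_p, small_rois)
        assert np.allclose(out, out_p, atol=1e-5)

    def test_discard_commutes_with_extraction(self, small_rois):
        rng = np.random.default_rng(2)
        data = rng.normal(0, 1, (11, 11, 11, 8))
        img = _image(data)
        a = extract_roi_timeseries(img, small_rois, discard_initial=3)
        b = extract_roi_timeseries(img, small_rois)[3:]
        assert np.allclose(a, b)

    def test_empty_sphere_names_the_roi(self):
        img = _image(np.zeros((11, 11, 11, 2)))
        rois = ROISet(labels=("far",),
                      coordinates=np.array([[500.0, 0.0, 0.0]]),
                      radius_mm=2.0)
        with pytest.raises(ROIError, match="far"):
            extract_roi_timeseries(img, rois)

    def test_3d_image_rejected(self, small_rois):
        img = _image(np.zeros((11, 11, 11)))
        with pytest.raises(DataError):
            extract_roi_timeseries(img, small_rois)

    def test_eigenvariate_summary_on_coherent_sphere(self, small_rois):
        # all voxels share one time course: eigenvariate == that course
        t = np.sin(np.linspace(0, 6, 10))
        data = np.zeros((11, 11, 11, 10))
        data[:] = t
        img = _image(data)
        out = extract_roi_timeseries(img, small_rois, summary="eigenvariate")
        corr = np.corrcoef(out[:, 0], t)[0, 1]
        assert corr > 0.999

    def test_roundtrip_through_synthetic_nifti(self, base4):
        cfg = CohortConfig(base_A=base4, node_labels=("a", "b", "c", "d"),
                           group_sizes={"CN": 1, "EMCI": 1, "LMCI": 1,
                                        "AD": 1},
                           n_volumes=20, discard_initial=0, seed=3)
        rec = generate_cohort(cfg)[0]
        rois = ROISet(labels=("a", "b", "c", "d"),
                      coordinates=np.array([[-30.0, -30.0, 0.0],
                                            [30.0, -30.0, 0.0],
                                            [-30.0, 30.0, 0.0],
                                            [30.0, 30.0, 10.0]]),
                      radius_mm=8.0)
        img = render_nifti(rec, rois, voxel_mm=4.0)
        out = extract_roi_timeseries(img, rois)
        assert np.allclose(out, rec.roi_series, atol=1e-6)


class TestRoiTables:
    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "rois.tsv"
        DEFAULT_ROIS.to_tsv(path)
        back = ROISet.from_tsv(path)
        assert back.labels == DEFAULT_ROIS.labels
        assert np.allclose(back.coordinates, DEFAULT_ROIS.coordinates)
        assert back.radius_mm == 8.0

    def test_yaml_parsing(self, tmp_path):
        path = tmp_path / "rois.yaml"
        path.write_text(
            "radius: 6\nrois:\n"
            "  - {label: x, x: 1, y: 2, z: 3}\n"
            "  - {label: y, x: -1, y: 0, z: 5}\n")
        rois = ROISet.from_yaml(path)
        assert rois.labels == ("x", "y")
        assert rois.radius_mm == 6.0

    def test_invalid_radius_rejected(self):
        with pytest.raises(ArgumentError):
            ROISet(labels=("a",), coordinates=np.zeros((1, 3)),
                   radius_mm=0.0)


class TestManifest:
    def test_well_formed_manifest_roundtrips(self, tmp_path, base4):
        cfg = CohortConfig(base_A=base4, node_labels=("a", "b", "c", "d"),
                           group_sizes={"CN": 1, "EMCI": 1, "LMCI": 1,
                                        "AD": 1},
                           n_volumes=140, seed=6)
        records = generate_cohort(cfg)
        path = tmp_path / "manifest.tsv"
        write_manifest(records, path, series_dir=tmp_path / "series")
        back = read_cohort_manifest(path)
        assert len(back) == 4
        for orig, rec in zip(records, back):
            assert rec.subject_id == orig.subject_id
            assert rec.group == orig.group
            assert rec.scores["mmse"] == pytest.approx(orig.scores["mmse"],
                                                       rel=1e-9)
            assert np.allclose(rec.roi_series, orig.roi_series, atol=1e-9)
            assert rec.tr == orig.tr

    def test_unknown_group_label_names_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("subject_id\tgroup\tmmse\tcdr\tseries\n"
                        "s1\tCN\t29\t0\t\n"
                        "s2\tMCI\t27\t0.5\t\n")
        with pytest.raises(ManifestError, match="line 3.*MCI"):
            read_cohort_manifest(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("subject_id\tgroup\tmmse\n s1\tCN\t29\n")
        with pytest.raises(ManifestError, match="cdr"):
            read_cohort_manifest(path)

    def test_missing_series_file_names_line(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("subject_id\tgroup\tmmse\tcdr\tseries\n"
                        "s1\tCN\t29\t0\tnope.tsv\n")
        with pytest.raises(ManifestError, match="line 2"):
            read_cohort_manifest(path)
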