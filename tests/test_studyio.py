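"""On-disk formats: k-space dialect, NIfTI, manifest, processed outputs."""

import json

import numpy as np
import pytest

from hypersi import (
    CircleROI,
    KSpace,
    MagnitudeImage,
    Manifest,
    PolygonROI,
    QuadROI,
    QuantResult,
    StudyRecord,
)
from hypersi.errors import (
    FormatError,
    SchemaError,
    TruncationError,
    ValidationError,
)
from hypersi import studyio


@pytest.fixture
def sample_kspace(rng):
    data = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
    return KSpace(data.astype(np.complex64).astype(np.complex128),
                  "29Si", (64.0, 64.0), {"study": "demo"})


class TestKSpaceDialect:
    def test_declared_shape_round_trip(self, tmp_path, sample_kspace):
        p = studyio.write_kspace(sample_kspace, tmp_path / "a.ksp")
        back = studyio.read_kspace(p)
        assert back.shape == (32, 32)
        assert back.nucleus == "29Si"
        assert back.fov_mm == (64.0, 64.0)
        assert back.meta == {"study": "demo"}
        # float32 payload: values preserved exactly for float32-representable input
        assert np.array_equal(back.data, sample_kspace.data)

    def test_write_read_write_byte_identical(self, tmp_path, sample_kspace):
        p1 = studyio.write_kspace(sample_kspace, tmp_path / "a.ksp")
        p2 = studyio.write_kspace(studyio.read_kspace(p1), tmp_path / "b.ksp")
        assert p1.read_bytes() == p2.read_bytes()

    def test_payload_size_mismatch_is_truncation_error(self, tmp_path):
        header = json.dumps({
            "byteorder": "little", "dims": [32, 32],
            "fov_mm": [64.0, 64.0], "nucleus": "29Si",
        })
        payload = np.zeros(2040 * 2, dtype="<f4").tobytes()  # 2040 complex, not 1024
        path = tmp_path / "bad.ksp"
        path.write_bytes(header.encode() + b"\n" + payload)
        with pytest.raises(TruncationError):
            studyio.read_kspace(path)

    @pytest.mark.parametrize("missing", ["dims", "nucleus", "fov_mm", "byteorder"])
    def test_missing_header_field_named(self, tmp_path, missing):
        header = {
            "byteorder": "little", "dims": [2, 2],
            "fov_mm": [64.0, 64.0], "nucleus": "29Si",
        }
        del header[missing]
        path = tmp_path / "bad.ksp"
        path.write_bytes(json.dumps(header).encode() + b"\n" + b"\x00" * 32)
        with pytest.raises(FormatError, match=missing):
            studyio.read_kspace(path)

    def test_non_json_header_rejected(self, tmp_path):
        path = tmp_path / "bad.ksp"
        path.write_bytes(b"not json\n" + b"\x00" * 64)
        with pytest.raises(FormatError):
            studyio.read_kspace(path)


class TestAnatomicalNifti:
    def test_nominal_geometry_round_trip(self, tmp_path, rng):
        from hypersi import AnatomicalVolume

        stack = rng.random((22, 256, 256)).astype(np.float32).astype(float)
        vol = AnatomicalVolume(stack, (0.25, 0.25), 0.75)
        p = studyio.write_anatomical(vol, tmp_path / "anat.nii")
        back = studyio.read_anatomical(p)
        assert back.n_slices == 22
        assert back.pixel_spacing_mm == (0.25, 0.25)
        assert back.slice_thickness_mm == pytest.approx(0.75)
        assert np.allclose(back.slices, stack, atol=1e-7)

    def test_2d_file_becomes_single_slice(self, tmp_path, rng):
        import nibabel as nib

        arr = rng.random((16, 16)).astype(np.float32)
        nib.save(nib.Nifti1Image(arr, np.eye(4)), str(tmp_path / "flat.nii"))
        vol = studyio.read_anatomical(tmp_path / "flat.nii")
        assert vol.n_slices == 1

    def test_non_image_file_rejected(self, tmp_path):
        path = tmp_path / "junk.nii"
        path.write_bytes(b"this is not an image")
        with pytest.raises(FormatError):
            studyio.read_anatomical(path)


def _sample_manifest(n_per_cohort=3):
    from hypersi.model import COHORTS

    quad = QuadROI(((10, 10), (200, 10), (200, 240), (10, 240)))
    body = PolygonROI(((20, 20), (180, 30), (170, 220), (30, 210)))
    studies = []
    for cohort in COHORTS:
        for rep in range(n_per_cohort):
            sid = f"{cohort}_{rep}"
            studies.append(StudyRecord(
                study_id=sid,
                cohort=cohort,
                silicon_path=f"{sid}.ksp",
                anatomical_path=f"{sid}.nii",
                phantom_reference=40.0 + rep,
                display_slice=11,
                roi_quad=quad,
                tumor_rois=(CircleROI((100.5, 120.25), 7.0),),
                nontumor_rois=(CircleROI((140.0, 80.0), 7.0),),
                body_roi=body,
            ))
    return Manifest(studies=tuple(studies))


class TestManifest:
    def test_twelve_row_cohort_layout(self, tmp_path):
        m = _sample_manifest(3)
        p = studyio.write_manifest(m, tmp_path / "m.csv")
        back = studyio.read_manifest(p)
        assert len(back.studies) == 12
        cohorts = {s.cohort for s in back.studies}
        assert len(cohorts) == 4

    def test_csv_and_xlsx_are_equivalent(self, tmp_path):
        m = _sample_manifest(2)
        back_csv = studyio.read_manifest(studyio.write_manifest(m, tmp_path / "m.csv"))
        back_xlsx = studyio.read_manifest(studyio.write_manifest(m, tmp_path / "m.xlsx"))
        assert back_csv == back_xlsx

    def test_round_trip_preserves_rois(self, tmp_path):
        m = _sample_manifest(1)
        back = studyio.read_manifest(studyio.write_manifest(m, tmp_path / "m.csv"))
        s0 = back.studies[0]
        assert s0.tumor_rois[0] == CircleROI((100.5, 120.25), 7.0)
        assert s0.roi_quad.vertices == ((10, 10), (200, 10), (200, 240), (10, 240))
        assert s0.body_roi.vertices[1] == (180.0, 30.0)

    def test_empty_manifest_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "study_id,cohort,silicon_path,anatomical_path,"
            "phantom_reference,display_slice\n"
        )
        with pytest.raises(ValidationError):
            studyio.read_manifest(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("study_id,cohort\na,targeted\n")
        with pytest.raises(SchemaError, match="silicon_path"):
            studyio.read_manifest(path)

    def test_unknown_cohort_lists_allowed_values(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "study_id,cohort,silicon_path,anatomical_path,"
            "phantom_reference,display_slice\n"
            "a,placebo,a.ksp,a.nii,1.0,0\n"
        )
        with pytest.raises(ValidationError, match="biological_control"):
            studyio.read_manifest(path)

    def test_duplicate_study_id_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "study_id,cohort,silicon_path,anatomical_path,"
            "phantom_reference,display_slice\n"
            "a,targeted,a.ksp,a.nii,1.0,0\n"
            "a,preblocked,b.ksp,b.nii,1.0,0\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            studyio.read_manifest(path)

    def test_relative_paths_resolved_against_manifest_dir(self, tmp_path):
        m = _sample_manifest(1)
        back = studyio.read_manifest(studyio.write_manifest(m, tmp_path / "m.csv"))
        assert back.studies[0].silicon_path.startswith(str(tmp_path))


class TestWriteOutputs:
    def _artifacts(self, rng):
        from hypersi.coregister import composite_overlay

        processed = MagnitudeImage(rng.random((16, 16)), (0.25, 0.25))
        anat = MagnitudeImage(rng.random((16, 16)), (0.25, 0.25))
        si = MagnitudeImage(processed.pixels / processed.pixels.max(), (0.25, 0.25))
        overlay = composite_overlay(
            MagnitudeImage(anat.pixels / anat.pixels.max(), (0.25, 0.25)), si)
        quant = QuantResult("s1", 4.0, 2.0, 10.0, 2.0, 2.0, 4.0, 3.0)
        study = StudyRecord("s1", "targeted", "x.ksp", "x.nii", 1.0, 0)
        return study, processed, overlay, quant

    def test_deterministic_files_with_study_prefix(self, tmp_path, rng):
        study, processed, overlay, quant = self._artifacts(rng)
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        d1.mkdir(), d2.mkdir()
        files1 = studyio.write_outputs(study, processed, overlay, quant, d1)
        files2 = studyio.write_outputs(study, processed, overlay, quant, d2)
        assert len(files1) >= 3
        assert all(f.name.startswith("s1") for f in files1)
        for f1, f2 in zip(files1, files2):
            assert f1.read_bytes() == f2.read_bytes()

    def test_processed_nifti_round_trip(self, tmp_path, rng):
        study, processed, overlay, quant = self._artifacts(rng)
        studyio.write_outputs(study, processed, overlay, quant, tmp_path)
        back = studyio.read_image_nifti(tmp_path / "s1_processed.nii")
        assert np.allclose(back.pixels, processed.pixels, atol=1e-7)

    def test_unwritable_dir_rejected(self, tmp_path, rng):
        study, processed, overlay, quant = self._artifacts(rng)
        with pytest.raises(OSError):
            studyio.write_outputs(study, processed, overlay, quant,
                                  tmp_path / "does_not_exist")
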