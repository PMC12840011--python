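"""Contour model, rasterization against the brute-force oracle, and I/O."""

import json
import warnings

import numpy as np
import pytest

from iovkit import (
    ContourParseError,
    CoordinateError,
    GridMismatchError,
    ImageGrid,
    ObserverCohort,
    PlanarContour,
    StructureDelineation,
    rasterize,
    read_contours,
    write_contours,
)
from iovkit.contours import read_alias_table, read_mask_nifti, write_mask_nifti

from conftest import brute_rasterize, make_volume, star_polygon

SQUARE = ((0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0))


def delineation(contours, observer="o1", name="PTV1"):
    return StructureDelineation(observer, name, contours=list(contours))


class TestPlanarContour:
    def test_two_vertices_rejected(self):
        with pytest.raises(ContourParseError, match="vertices"):
            PlanarContour(z=0.0, vertices=((0.0, 0.0), (1.0, 1.0)))

    def test_zero_area_rejected(self):
        with pytest.raises(ContourParseError, match="zero area"):
            PlanarContour(z=0.0, vertices=((0.0, 0.0), (1.0, 1.0), (2.0, 2.0)))

    def test_bad_role_rejected(self):
        with pytest.raises(ValueError):
            PlanarContour(z=0.0, vertices=SQUARE, role="island")


class TestRasterize:
    def test_axis_aligned_square_fills_100_voxels(self):
        # voxel centres at half-integers: the square edges sit on voxel boundaries
        grid = ImageGrid((0.5, 0.5, 0.0), (1.0, 1.0, 4.0), (40, 40, 12))
        sq = PlanarContour(z=4.0, vertices=SQUARE)
        vol = rasterize(delineation([sq]), grid)
        assert vol.count() == 100
        assert vol.voxels[:, :, 1].sum() == 100
        assert np.array_equal(vol.voxels, brute_rasterize([sq], grid))

    def test_square_minus_identical_hole_is_empty(self, ct_grid):
        outer = PlanarContour(z=0.0, vertices=SQUARE)
        hole = PlanarContour(z=0.0, vertices=SQUARE, role="hole")
        assert rasterize(delineation([outer, hole]), ct_grid).is_empty()

    def test_nested_hole_ring(self):
        grid = ImageGrid((0.5, 0.5, 0.0), (1.0, 1.0, 4.0), (40, 40, 12))
        outer = PlanarContour(z=0.0, vertices=SQUARE)
        inner = ((3.0, 3.0), (7.0, 3.0), (7.0, 7.0), (3.0, 7.0))
        hole = PlanarContour(z=0.0, vertices=inner, role="hole")
        vol = rasterize(delineation([outer, hole]), grid)
        assert vol.count() == 100 - 16
        assert brute_rasterize([outer, hole], grid).sum() == vol.count()

    def test_circle_area_convergence(self):
        # strict-interior voxel count within 2% of pi*r^2 for an off-lattice centre
        grid = ImageGrid((-20.0, -20.0, 0.0), (1.0, 1.0, 4.0), (41, 41, 1))
        theta = 2 * np.pi * np.arange(720) / 720
        circ = PlanarContour(
            z=0.0, vertices=tuple(zip(0.5 + 10 * np.cos(theta), 0.5 + 10 * np.sin(theta)))
        )
        vol = rasterize(delineation([circ]), grid)
        assert vol.count() == pytest.approx(np.pi * 100, rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_pointwise(self, ct_grid, seed):
        rng = np.random.default_rng(seed)
        contours = [
            PlanarContour(z=4.0 * k, vertices=star_polygon(rng, (18, 20), 12.0))
            for k in range(3)
        ]
        vol = rasterize(delineation(contours), ct_grid)
        assert np.array_equal(vol.voxels, brute_rasterize(contours, ct_grid))

    def test_contour_off_slice_is_a_coordinate_error(self, ct_grid):
        c = PlanarContour(z=-7.0, vertices=SQUARE)
        with pytest.raises(CoordinateError):
            rasterize(delineation([c]), ct_grid)

    def test_contour_outside_xy_extent_is_an_error(self, ct_grid):
        far = tuple((x + 100.0, y) for x, y in SQUARE)
        with pytest.raises(CoordinateError, match="extent"):
            rasterize(delineation([PlanarContour(z=0.0, vertices=far)]), ct_grid)

    def test_mask_backed_delineation_passthrough_and_grid_check(self, ct_grid, iso_grid):
        mask = make_volume(ct_grid, np.s_[0:3, 0:3, 0:3])
        d = StructureDelineation("o1", "brainstem", mask=mask)
        assert rasterize(d, ct_grid) is mask
        with pytest.raises(GridMismatchError):
            rasterize(d, iso_grid)


class TestCohort:
    def test_omissions_counted_not_imputed(self, ct_grid):
        cohort = ObserverCohort(ct_grid, [f"RO{i}" for i in range(1, 11)])
        sq = [PlanarContour(z=0.0, vertices=SQUARE)]
        for oid in cohort.observers:
            cohort.add(StructureDelineation(oid, "PTV1", contours=sq))
        for oid in cohort.observers[:7]:
            cohort.add(StructureDelineation(oid, "pituitary", contours=sq))
        assert cohort.n("pituitary") == 7
        assert cohort.n("PTV1") == 10
        assert set(cohort.volumes("pituitary")) == set(cohort.observers[:7])

    def test_duplicate_structures_merged_by_union(self, caplog):
        ct_grid = ImageGrid((0.5, 0.5, 0.0), (1.0, 1.0, 4.0), (40, 40, 12))
        cohort = ObserverCohort(ct_grid, ["o1"])
        left = PlanarContour(z=0.0, vertices=SQUARE)
        right = PlanarContour(z=0.0, vertices=tuple((x + 20, y) for x, y in SQUARE))
        cohort.add(StructureDelineation("o1", "PTV1", contours=[left]))
        with caplog.at_level("WARNING"):
            cohort.add(StructureDelineation("o1", "PTV1", contours=[right]))
        assert "merging by union" in caplog.text
        assert cohort.volume("o1", "PTV1").count() == 200


class TestJsonDialect:
    def _cohort(self, grid):
        rng = np.random.default_rng(3)
        cohort = ObserverCohort(grid, ["obs-a", "obs-b"])
        for oid in cohort.observers:
            for name in ("PTV1", "brainstem"):
                contours = [
                    PlanarContour(z=4.0 * k, vertices=star_polygon(rng, (20, 20), 10.0))
                    for k in range(2)
                ]
                cohort.add(StructureDelineation(oid, name, contours=contours))
        return cohort

    def test_round_trip_preserves_vertices_and_labels(self, ct_grid, tmp_path):
        cohort = self._cohort(ct_grid)
        path = tmp_path / "cohort.json"
        write_contours(cohort, path)
        back = read_contours(path, dialect="json")
        assert back.observers == cohort.observers
        assert set(back.structures) == set(cohort.structures)
        assert back.grid.is_same(cohort.grid)
        for key, d in cohort.structures.items():
            got = back.structures[key]
            for c0, c1 in zip(d.contours, got.contours):
                assert c1.role == c0.role and c1.z == pytest.approx(c0.z, abs=1e-9)
                assert np.allclose(c1.vertices, c0.vertices, atol=1e-6)

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"observers": []}')  # no grid
        with pytest.raises(ContourParseError, match="malformed"):
            read_contours(path, dialect="json")

    def test_degenerate_roi_polygon_is_a_parse_error(self, ct_grid, tmp_path):
        doc = {
            "grid": {"origin": [0, 0, 0], "spacing": [1, 1, 4], "size": [40, 40, 12]},
            "observers": [
                {
                    "id": "o1",
                    "structures": [
                        {"name": "PTV1", "contours": [{"z": 0.0, "vertices": [[0, 0], [1, 1]]}]}
                    ],
                }
            ],
        }
        path = tmp_path / "degen.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ContourParseError, match="PTV1"):
            read_contours(path, dialect="json")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_contours(tmp_path / "x.json", dialect="xml")


class TestAliases:
    def test_alias_mapping_and_verbatim_fallback(self, ct_grid, tmp_path):
        csv_path = tmp_path / "alias.csv"
        csv_path.write_text("raw_name,canonical_name\nBrain Stem,brainstem\n")
        alias = read_alias_table(csv_path)
        doc = {
            "grid": {"origin": [0, 0, 0], "spacing": [1, 1, 4], "size": [40, 40, 12]},
            "observers": [
                {
                    "id": "o1",
                    "structures": [
                        {"name": "Brain Stem", "contours": [{"z": 0.0, "vertices": list(map(list, SQUARE))}]},
                        {"name": "MysteryROI", "contours": [{"z": 0.0, "vertices": list(map(list, SQUARE))}]},
                    ],
                }
            ],
        }
        path = tmp_path / "c.json"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="MysteryROI"):
            cohort = read_contours(path, dialect="json", alias=alias)
        assert ("o1", "brainstem") in cohort.structures
        assert ("o1", "MysteryROI") in cohort.structures

    def test_alias_table_requires_columns(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("a,b\n1,2\n")
        with pytest.raises(ContourParseError):
            read_alias_table(bad)


class TestDicomRt:
    def _write_rtstruct(self, path, rois):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "RTSTRUCT"
        ds.StructureSetROISequence = []
        ds.ROIContourSequence = []
        for num, (name, contours) in enumerate(rois.items(), start=1):
            roi = Dataset()
            roi.ROINumber = num
            roi.ROIName = name
            roi.ReferencedFrameOfReferenceUID = generate_uid()
            ds.StructureSetROISequence.append(roi)
            rc = Dataset()
            rc.ReferencedROINumber = num
            rc.ContourSequence = []
            for z, verts in contours:
                item = Dataset()
                item.ContourGeometricType = "CLOSED_PLANAR"
                item.NumberOfContourPoints = len(verts)
                item.ContourData = [float(v) for x, y in verts for v in (x, y, z)]
                rc.ContourSequence.append(item)
            ds.ROIContourSequence.append(rc)
        pydicom.dcmwrite(path, ds, enforce_file_format=True)

    def test_read_rtstruct_file(self, tmp_path):
        ct_grid = ImageGrid((0.5, 0.5, 0.0), (1.0, 1.0, 4.0), (40, 40, 12))
        path = tmp_path / "observerX.dcm"
        self._write_rtstruct(path, {"PTV1": [(0.0, SQUARE), (4.0, SQUARE)]})
        cohort = read_contours(path, dialect="dicom-rt", grid=ct_grid)
        assert cohort.observers == ["observerX"]
        vol = cohort.volume("observerX", "PTV1")
        assert vol.count() == 200

    def test_dicom_requires_grid(self, tmp_path):
        with pytest.raises(ValueError, match="grid"):
            read_contours(tmp_path, dialect="dicom-rt")


class TestNifti:
    def test_mask_round_trip(self, ct_grid, tmp_path):
        vol = make_volume(ct_grid, np.s_[5:15, 5:15, 2:5])
        path = tmp_path / "mask.nii.gz"
        write_mask_nifti(vol, path)
        back = read_mask_nifti(path, ct_grid)
        assert back == vol

    def test_affine_mismatch_rejected(self, ct_grid, iso_grid, tmp_path):
        vol = make_volume(ct_grid, np.s_[0:2, 0:2, 0:2])
        path = tmp_path / "mask.nii.gz"
        write_mask_nifti(vol, path)
        with pytest.raises(GridMismatchError):
            read_mask_nifti(path, iso_grid)
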