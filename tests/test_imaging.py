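"""Imaging I/O, polygon rasterization and the lesion selection rules."""

import json
import math

import numpy as np
import pytest

from deltarad import imaging
from deltarad.imaging import (
    ImageSlice,
    ImagingError,
    LesionRecord,
    PatientIneligibleError,
    apply_exclusion_window,
    largest_diameter,
    polygon_to_mask,
    read_slice,
    select_target_lesions,
    write_slice,
)


# ---------------------------------------------------------------------------
# point-in-polygon oracle (even-odd crossing test, boundary included)
# ---------------------------------------------------------------------------


def _on_segment(px, py, x1, y1, x2, y2, eps=1e-9):
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    if abs(cross) > eps:
        return False
    return min(x1, x2) - eps <= px <= max(x1, x2) + eps and (
        min(y1, y2) - eps <= py <= max(y1, y2) + eps
    )


def point_in_polygon(px, py, vertices):
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if _on_segment(px, py, x1, y1, x2, y2):
            return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def oracle_mask(vertices, shape):
    mask = np.zeros(shape, dtype=bool)
    for row in range(shape[0]):
        for col in range(shape[1]):
            mask[row, col] = point_in_polygon(col + 0.5, row + 0.5, vertices)
    return mask


def _image(shape=(8, 8), spacing=(1.0, 1.0), fill=0):
    return ImageSlice(np.full(shape, fill, dtype=np.int32), spacing)


# ---------------------------------------------------------------------------
# slice I/O
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("fmt,suffix", [("text", ".txt"), ("png16", ".png")])
def test_slice_roundtrip(tmp_path, fmt, suffix):
    rng = np.random.default_rng(0)
    image = ImageSlice(
        rng.integers(-1000, 2000, size=(12, 10)).astype(np.int32), (0.98, 0.98)
    )
    path = tmp_path / f"slice{suffix}"
    write_slice(image, path, fmt=fmt)
    back = read_slice(path)
    np.testing.assert_array_equal(back.pixels, image.pixels)
    assert back.pixel_spacing_mm == (0.98, 0.98)


def test_text_grid_identity_read(tmp_path):
    path = tmp_path / "zeros.txt"
    path.write_text("0 0 0\n0 0 0\n0 0 0\n")
    (tmp_path / "zeros.txt.json").write_text(json.dumps({"spacing_mm": 1.0}))
    image = read_slice(path)
    assert image.shape == (3, 3)
    assert image.pixels.sum() == 0
    assert image.pixel_spacing_mm == (1.0, 1.0)


def test_missing_spacing_sidecar_is_an_error(tmp_path):
    path = tmp_path / "nospacing.txt"
    path.write_text("1 2\n3 4\n")
    with pytest.raises(ImagingError, match="sidecar"):
        read_slice(path)


def test_dicom_rescale_applied(tmp_path):
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian

    meta = FileMetaDataset()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
    ds = FileDataset(str(tmp_path / "ct.dcm"), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.Rows = ds.Columns = 4
    ds.PixelSpacing = [0.98, 0.98]
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = -1024.0
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.full((4, 4), 1024, dtype=np.uint16).tobytes()
    ds.save_as(tmp_path / "ct.dcm", enforce_file_format=True)

    image = read_slice(tmp_path / "ct.dcm")
    assert image.pixels.max() == 0 and image.pixels.min() == 0
    assert image.pixel_spacing_mm == (0.98, 0.98)


# ---------------------------------------------------------------------------
# polygon rasterization
# ---------------------------------------------------------------------------


def test_axis_aligned_square_covers_sixteen_pixels():
    mask = polygon_to_mask([(0, 0), (4, 0), (4, 4), (0, 4)], _image())
    assert mask.sum() == 16
    assert mask[:4, :4].all()


def test_triangle_matches_boundary_inclusive_oracle():
    vertices = [(0, 0), (2, 0), (0, 2)]
    mask = polygon_to_mask(vertices, _image((4, 4)))
    np.testing.assert_array_equal(mask, oracle_mask(vertices, (4, 4)))


def test_collinear_vertices_rejected():
    with pytest.raises(ImagingError, match="zero area|invalid"):
        polygon_to_mask([(0, 0), (2, 2), (4, 4)], _image())


def test_polygon_outside_bounds_rejected():
    with pytest.raises(ImagingError, match="outside"):
        polygon_to_mask([(-1, 0), (5, 0), (2, 5)], _image((4, 4)))


def test_random_star_polygons_match_oracle():
    rng = np.random.default_rng(13)
    shape = (12, 12)
    for _ in range(100):
        n = rng.integers(3, 9)
        angles = np.sort(rng.uniform(0, 2 * math.pi, n))
        radii = rng.uniform(1.0, 5.0, n)
        vertices = [
            (6 + r * math.cos(a), 6 + r * math.sin(a)) for r, a in zip(radii, angles)
        ]
        try:
            mask = polygon_to_mask(vertices, _image(shape))
        except ImagingError:
            continue  # degenerate draw (no covered center)
        np.testing.assert_array_equal(mask, oracle_mask(vertices, shape))


# ---------------------------------------------------------------------------
# diameter
# ---------------------------------------------------------------------------


def test_diameter_of_single_pixel_is_zero():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    assert largest_diameter(mask, (1.0, 1.0)) == 0.0


def test_diameter_two_pixels_scaled_by_spacing():
    mask = np.zeros((3, 12), dtype=bool)
    mask[1, 0] = mask[1, 10] = True
    assert largest_diameter(mask, (0.98, 0.98)) == pytest.approx(9.8)


def test_diameter_matches_brute_force_on_random_blob():
    rng = np.random.default_rng(3)
    mask = np.zeros((20, 20), dtype=bool)
    rows, cols = rng.integers(0, 20, 50), rng.integers(0, 20, 50)
    mask[rows, cols] = True
    spacing = (0.7, 1.3)
    pts = [
        (r * spacing[0], c * spacing[1]) for r, c in zip(*np.nonzero(mask))
    ]
    brute = max(
        math.dist(p, q) for p in pts for q in pts
    )
    assert largest_diameter(mask, spacing) == pytest.approx(brute)


def test_diameter_invariant_under_translation_and_rotation():
    rng = np.random.default_rng(4)
    mask = np.zeros((30, 30), dtype=bool)
    mask[10:18, 8:13] = rng.random((8, 5)) > 0.3
    d = largest_diameter(mask, (1.0, 1.0))
    assert largest_diameter(np.roll(mask, (5, -3), axis=(0, 1)), (1.0, 1.0)) == pytest.approx(d)
    assert largest_diameter(np.rot90(mask), (1.0, 1.0)) == pytest.approx(d)


def test_empty_mask_has_no_diameter():
    with pytest.raises(ImagingError):
        largest_diameter(np.zeros((3, 3), dtype=bool), (1.0, 1.0))


# ---------------------------------------------------------------------------
# HU exclusion window
# ---------------------------------------------------------------------------


def test_exclusion_window_noop_when_all_in_range():
    image = _image(fill=40)
    mask = np.ones((8, 8), dtype=bool)
    np.testing.assert_array_equal(apply_exclusion_window(image, mask), mask)


def test_exclusion_window_removes_air_pixel():
    pixels = np.full((4, 4), 40, dtype=np.int32)
    pixels[1, 1] = -950
    image = ImageSlice(pixels, (1.0, 1.0))
    kept = apply_exclusion_window(image, np.ones((4, 4), dtype=bool))
    assert not kept[1, 1] and kept.sum() == 15


def test_exclusion_window_empty_result_names_lesion():
    image = _image(fill=500)
    with pytest.raises(ImagingError, match="L7"):
        apply_exclusion_window(image, np.ones((8, 8), dtype=bool), lesion_id="L7")


# ---------------------------------------------------------------------------
# target lesion selection
# ---------------------------------------------------------------------------


def _record(lesion_id, diameter):
    image = _image((4, 4), fill=40)
    mask = np.zeros((4, 4), dtype=bool)
    mask[1, 1] = True
    return LesionRecord(
        lesion_id=lesion_id,
        patient_id="P1",
        timepoint="baseline",
        image=image,
        mask=mask,
        largest_diameter_mm=diameter,
    )


def test_selection_keeps_top_five_at_least_five_mm():
    diameters = [3, 6, 8, 12, 5.5, 20, 9]
    lesions = [_record(f"L{i}", d) for i, d in enumerate(diameters)]
    kept = select_target_lesions(lesions, max_n=5)
    assert [l.largest_diameter_mm for l in kept] == [20, 12, 9, 8, 6]


def test_all_small_lesions_make_patient_ineligible():
    lesions = [_record(f"L{i}", d) for i, d in enumerate([2, 3, 4.9])]
    with pytest.raises(PatientIneligibleError):
        select_target_lesions(lesions)


def test_exactly_five_eligible_all_kept_in_size_order():
    lesions = [_record(f"L{i}", d) for i, d in enumerate([5, 6, 7, 8, 9])]
    kept = select_target_lesions(lesions, max_n=5)
    assert [l.largest_diameter_mm for l in kept] == [9, 8, 7, 6, 5]


def test_selection_never_exceeds_max_and_ties_break_by_id():
    lesions = [_record(f"L{i}", 10) for i in range(7)]
    kept = select_target_lesions(lesions, max_n=5)
    assert [l.lesion_id for l in kept] == ["L0", "L1", "L2", "L3", "L4"]


def test_selection_rejects_mixed_patients():
    a, b = _record("L0", 10), _record("L1", 10)
    b.patient_id = "P2"
    with pytest.raises(ImagingError, match="single patient"):
        select_target_lesions([a, b])
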