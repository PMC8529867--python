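"""Image and ROI input/output plus lesion selection rules.

Conventions used throughout the package:

* pixels are indexed ``[row, col]``; polygon coordinates are ``(x, y)`` with
  ``x`` along columns and ``y`` along rows, both 0-based;
* the center of pixel ``(row, col)`` is at ``(x, y) = (col + 0.5, row + 0.5)``;
* all gray values are Hounsfield units stored as integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon

HU_MIN = -2048
HU_MAX = 4096

#: Offset added to HU when writing 16-bit PNGs (values must be non-negative).
PNG_HU_OFFSET = 1024

BASELINE = "baseline"
POST = "post"
TIMEPOINTS = (BASELINE, POST)


class ImagingError(ValueError):
    """Raised for invalid images, ROIs or metadata."""


class PatientIneligibleError(ImagingError):
    """Raised when no lesion of a patient survives the selection rules."""


@dataclass
class ImageSlice:
    """A single 2D axial CT slice in Hounsfield units.

    Parameters
    ----------
    pixels:
        2D integer array of HU values.
    pixel_spacing_mm:
        Physical size of one pixel as ``(row, col)`` in millimetres.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_id: str = ""
    patient_id: str = ""
    timepoint: str = BASELINE

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ImagingError("image must be a non-empty 2D grid")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ImagingError("HU values must be integers")
        sr, sc = float(self.pixel_spacing_mm[0]), float(self.pixel_spacing_mm[1])
        if sr <= 0 or sc <= 0:
            raise ImagingError("pixel spacing must be positive on both axes")
        self.pixel_spacing_mm = (sr, sc)
        lo, hi = int(self.pixels.min()), int(self.pixels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ImagingError(
                f"HU values outside [{HU_MIN}, {HU_MAX}]: range [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LesionRecord:
    """One lesion at one timepoint: image, mask and its largest diameter.

    ``lesion_id`` is stable across timepoints so that baseline and
    post-therapy measurements of the same lesion can be matched.
    """

    lesion_id: str
    patient_id: str
    timepoint: str
    image: ImageSlice
    mask: np.ndarray
    largest_diameter_mm: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        validate_mask(self.mask, self.image)
        if self.largest_diameter_mm < 0:
            raise ImagingError("largest diameter must be non-negative")


def validate_mask(mask: np.ndarray, image: ImageSlice) -> None:
    if mask.shape != image.shape:
        raise ImagingError(
            f"mask shape {mask.shape} does not match image shape {image.shape}"
        )
    if not mask.any():
        raise ImagingError("mask has no true pixel")


def make_lesion_record(
    image: ImageSlice,
    mask: np.ndarray,
    lesion_id: str,
    flags: Sequence[str] = (),
) -> LesionRecord:
    """Assemble a :class:`LesionRecord`, measuring the largest diameter."""
    mask = np.asarray(mask, dtype=bool)
    return LesionRecord(
        lesion_id=lesion_id,
        patient_id=image.patient_id,
        timepoint=image.timepoint,
        image=image,
        mask=mask,
        largest_diameter_mm=largest_diameter(mask, image.pixel_spacing_mm),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Reading and writing slices
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ImagingError(
            f"missing metadata sidecar {sidecar.name}: pixel spacing is required "
            "and is never assumed"
        )
    return json.loads(sidecar.read_text())


def _spacing_from_meta(meta: dict, path: Path) -> tuple[float, float]:
    if "spacing_mm" not in meta:
        raise ImagingError(f"no spacing_mm in sidecar for {path.name}")
    spacing = meta["spacing_mm"]
    if np.isscalar(spacing):
        spacing = (spacing, spacing)
    return float(spacing[0]), float(spacing[1])


def read_slice(
    path: str | Path,
    fmt: str | None = None,
    patient_id: str = "",
    timepoint: str = BASELINE,
) -> ImageSlice:
    """Read a CT slice from DICOM, 16-bit PNG (+ JSON sidecar) or text grid.

    ``fmt`` is inferred from the file suffix when not given:
    ``.dcm`` → DICOM, ``.png`` → PNG16, ``.txt`` → plain text HU grid.
    PNG and text images require a ``<name>.<ext>.json`` sidecar with
    ``spacing_mm``; PNG values are unsigned and are shifted back by
    ``hu_offset`` (default ``1024``).
    """
    path = Path(path)
    if not path.exists():
        raise ImagingError(f"no such image file: {path}")
    if fmt is None:
        fmt = {".dcm": "dicom", ".dicom": "dicom", ".png": "png16", ".txt": "text"}.get(
            path.suffix.lower()
        )
        if fmt is None:
            raise ImagingError(f"cannot infer image format from suffix: {path.name}")

    if fmt == "dicom":
        import pydicom

        ds = pydicom.dcmread(str(path))
        if not hasattr(ds, "PixelSpacing"):
            raise ImagingError(f"DICOM file {path.name} has no PixelSpacing")
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = np.asarray(ds.pixel_array, dtype=np.float64) * slope + intercept
        pixels = np.rint(hu).astype(np.int32)
    elif fmt == "png16":
        from PIL import Image

        meta = _read_sidecar(path)
        spacing = _spacing_from_meta(meta, path)
        offset = int(meta.get("hu_offset", PNG_HU_OFFSET))
        raw = np.asarray(Image.open(path), dtype=np.int64)
        pixels = (raw - offset).astype(np.int32)
    elif fmt == "text":
        meta = _read_sidecar(path)
        spacing = _spacing_from_meta(meta, path)
        pixels = np.loadtxt(path, dtype=np.int32, ndmin=2)
    else:
        raise ImagingError(f"unknown image format: {fmt!r}")

    return ImageSlice(
        pixels=pixels,
        pixel_spacing_mm=spacing,
        slice_id=path.stem,
        patient_id=patient_id,
        timepoint=timepoint,
    )


def write_slice(image: ImageSlice, path: str | Path, fmt: str | None = None) -> Path:
    """Write a slice as 16-bit PNG or text grid, with a JSON spacing sidecar."""
    path = Path(path)
    if fmt is None:
        fmt = {".png": "png16", ".txt": "text"}.get(path.suffix.lower())
        if fmt is None:
            raise ImagingError(f"cannot infer image format from suffix: {path.name}")
    meta = {"spacing_mm": list(image.pixel_spacing_mm)}
    if fmt == "png16":
        from PIL import Image

        shifted = image.pixels.astype(np.int64) + PNG_HU_OFFSET
        if shifted.min() < 0 or shifted.max() > 65535:
            raise ImagingError("HU values do not fit a 16-bit PNG after offset")
        meta["hu_offset"] = PNG_HU_OFFSET
        Image.fromarray(shifted.astype(np.uint16)).save(path)
    elif fmt == "text":
        np.savetxt(path, image.pixels, fmt="%d")
    else:
        raise ImagingError(f"unknown image format: {fmt!r}")
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_mask(path: str | Path, image: ImageSlice) -> np.ndarray:
    """Read a 0/1 mask stored as a text grid or PNG, congruent with ``image``."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        mask = np.asarray(Image.open(path)) > 0
    else:
        mask = np.loadtxt(path, dtype=np.int64, ndmin=2) > 0
    validate_mask(mask, image)
    return mask


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.asarray(mask, dtype=np.uint8), fmt="%d")
    return path


# ---------------------------------------------------------------------------
# ROI rasterization and measurement
# ---------------------------------------------------------------------------


def polygon_to_mask(vertices: Sequence[tuple[float, float]], image: ImageSlice) -> np.ndarray:
    """Rasterize a free-hand polygon to a pixel mask.

    A pixel belongs to the ROI iff its center lies inside the polygon
    (even–odd rule); centers exactly on the boundary are included.  The
    polygon must be simple (non-self-intersecting), have at least three
    distinct vertices, positive area, and lie within the image bounds.
    """
    verts = [(float(x), float(y)) for x, y in vertices]
    if len({v for v in verts}) < 3:
        raise ImagingError("polygon needs at least 3 distinct vertices")
    poly = Polygon(verts)
    if not poly.is_valid:
        raise ImagingError("polygon is self-intersecting or otherwise invalid")
    if poly.area <= 0:
        raise ImagingError("polygon has zero area (degenerate, e.g. collinear points)")
    nrow, ncol = image.shape
    minx, miny, maxx, maxy = poly.bounds
    if minx < 0 or miny < 0 or maxx > ncol or maxy > nrow:
        raise ImagingError("polygon extends outside the image bounds")

    cols, rows = np.meshgrid(np.arange(ncol) + 0.5, np.arange(nrow) + 0.5)
    points = shapely.points(cols.ravel(), rows.ravel())
    inside = shapely.covers(poly, points).reshape(nrow, ncol)
    if not inside.any():
        raise ImagingError("polygon covers no pixel center")
    return inside


def largest_diameter(mask: np.ndarray, spacing_mm: tuple[float, float] | float) -> float:
    """Largest diameter of a mask: max pairwise distance between pixel centers, mm."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ImagingError("empty mask has no diameter")
    if np.isscalar(spacing_mm):
        spacing_mm = (float(spacing_mm), float(spacing_mm))
    rows, cols = np.nonzero(mask)
    pts = np.column_stack([rows * spacing_mm[0], cols * spacing_mm[1]])
    if len(pts) == 1:
        return 0.0
    if len(pts) > 200:
        # pairwise max is attained on the convex hull; fall back for degenerate sets
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    from scipy.spatial.distance import pdist

    return float(pdist(pts).max())


def apply_exclusion_window(
    image: ImageSlice,
    mask: np.ndarray,
    low_hu: float = -100.0,
    high_hu: float = 300.0,
    lesion_id: str = "",
) -> np.ndarray:
    """Drop mask pixels whose HU falls outside ``[low_hu, high_hu]``.

    Automates the manual exclusion of air, streak artifacts and dense
    calcifications from the ROI.
    """
    if low_hu >= high_hu:
        raise ImagingError("exclusion window requires low_hu < high_hu")
    validate_mask(np.asarray(mask, dtype=bool), image)
    kept = mask & (image.pixels >= low_hu) & (image.pixels <= high_hu)
    if not kept.any():
        label = f" for lesion {lesion_id}" if lesion_id else ""
        raise ImagingError(f"exclusion window removed every ROI pixel{label}")
    return kept


def select_target_lesions(
    lesions: Sequence[LesionRecord],
    max_n: int = 5,
    min_diameter_mm: float = 5.0,
) -> list[LesionRecord]:
    """Apply the target-lesion rules: drop lesions below the minimum diameter,
    keep at most ``max_n``, largest first (ties broken by lesion id).

    Raises :class:`PatientIneligibleError` when no lesion survives, mirroring
    the cohort exclusion flow.
    """
    if not lesions:
        raise PatientIneligibleError("no lesions supplied")
    patients = {les.patient_id for les in lesions}
    timepoints = {les.timepoint for les in lesions}
    if len(patients) > 1 or len(timepoints) > 1:
        raise ImagingError(
            "select_target_lesions expects a single patient and timepoint, got "
            f"patients={sorted(patients)} timepoints={sorted(timepoints)}"
        )
    eligible = [les for les in lesions if les.largest_diameter_mm >= min_diameter_mm]
    if not eligible:
        raise PatientIneligibleError(
            f"patient {lesions[0].patient_id}: all {len(lesions)} lesions are below "
            f"{min_diameter_mm} mm"
        )
    eligible.sort(key=lambda les: (-les.largest_diameter_mm, les.lesion_id))
    return eligible[: int(max_n)]
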