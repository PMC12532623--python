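"""From a single axial CT slice to the normalized 200x100 silhouette.

The stage mirrors the standard radiographic workflow: binarize the slice
at a bone threshold of 200 HU (air and soft tissue go black, bone goes
white), pick the enclosed air cavity — the sinus — inside an operator
supplied region of interest, and normalize it onto the fixed 200x100
canvas with the sinus in black on white.

Conventions, used everywhere: 0-based pixel coordinates, origin top-left,
ROIs are half-open boxes [x0, x1) x [y0, y1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .silhouette import CANVAS_HEIGHT, CANVAS_WIDTH, BinarySilhouette

BONE_THRESHOLD_HU = 200
_MARGIN_PX = 4  # white margin kept around the foreground before rescaling

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class PreprocessError(ValueError):
    pass


class SinusNotFoundError(PreprocessError):
    """No enclosed sub-threshold component inside the ROI."""


@dataclass(frozen=True)
class HUSlice:
    """A 2D raster of Hounsfield units with optional pixel spacing (mm)."""

    values: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)  # (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] < 16 or v.shape[1] < 16:
            raise PreprocessError(f"HU slice must be a 2D grid of at least 16x16, got {v.shape}")
        object.__setattr__(self, "values", v.astype(np.int32))


@dataclass(frozen=True)
class ROI:
    """Half-open pixel box [x0, x1) x [y0, y1), 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise PreprocessError(f"degenerate ROI {self}")

    def validate_against(self, shape: tuple[int, int]) -> None:
        h, w = shape
        if self.x0 < 0 or self.y0 < 0 or self.x1 > w or self.y1 > h:
            raise PreprocessError(f"ROI {self} falls outside a {w}x{h} slice")


def threshold_hu(hu: HUSlice, threshold: int = BONE_THRESHOLD_HU) -> np.ndarray:
    """Binarize at the bone threshold: < threshold -> black (0),
    >= threshold -> white (1). Returns a uint8 {0,1} array."""
    return (hu.values >= threshold).astype(np.uint8)


def extract_sinus_silhouette(bone_map: np.ndarray, roi: ROI) -> np.ndarray:
    """Isolate the sinus cavity inside the ROI.

    The sinus is the largest 4-connected black (sub-threshold) component
    that does not touch the ROI border — i.e. an air pocket fully enclosed
    by bone. Returns a uint8 {0,1} image of the ROI with that component
    black and everything else white.
    """
    bone_map = np.asarray(bone_map)
    roi.validate_against(bone_map.shape)
    window = bone_map[roi.y0:roi.y1, roi.x0:roi.x1]
    black = window == 0
    lab, nlab = ndimage.label(black, structure=_FOUR_CONN)
    if nlab == 0:
        raise SinusNotFoundError("no sub-threshold pixels inside the ROI")
    border_labels = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]
    ]))
    candidates = [l for l in range(1, nlab + 1) if l not in border_labels]
    if not candidates:
        raise SinusNotFoundError(
            "every sub-threshold component touches the ROI border; "
            "no enclosed sinus cavity found"
        )
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=candidates)
    winner = candidates[int(np.argmax(sizes))]
    return (lab != winner).astype(np.uint8)


def normalize_canvas(silhouette: np.ndarray, case_id: str = "", session: str = "") -> BinarySilhouette:
    """Fit a binary sinus image onto the standard 200x100 canvas.

    Crops to the foreground bounding box plus a fixed 4-pixel white
    margin, rescales preserving aspect ratio to fit 200x100, re-binarizes
    at 0.5 after interpolation, and centers on a white canvas.
    """
    arr = np.asarray(silhouette)
    fg = arr == 0
    if not fg.any():
        raise PreprocessError("empty foreground: nothing to normalize")
    ys, xs = np.nonzero(fg)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    crop = fg[y0:y1, x0:x1]
    h, w = crop.shape
    # fit the foreground into the canvas minus the 4-px margin band; the
    # margin is fixed in output pixels, which makes re-normalization a no-op
    scale = min((CANVAS_WIDTH - 2 * _MARGIN_PX) / w, (CANVAS_HEIGHT - 2 * _MARGIN_PX) / h)
    new_h = max(1, int(round(h * scale)))
    new_w = max(1, int(round(w * scale)))
    resized = resize(crop.astype(float), (new_h, new_w), order=1,
                     anti_aliasing=scale < 1.0, mode="edge")
    fg_new = resized >= 0.5
    canvas = np.zeros((CANVAS_HEIGHT, CANVAS_WIDTH), dtype=bool)
    oy = (CANVAS_HEIGHT - new_h) // 2
    ox = (CANVAS_WIDTH - new_w) // 2
    canvas[oy:oy + new_h, ox:ox + new_w] = fg_new
    if not canvas.any() or canvas.all():
        raise PreprocessError("normalization produced a degenerate silhouette")
    return BinarySilhouette(pixels=(~canvas).astype(np.uint8), case_id=case_id, session=session)


def preprocess_slice(hu: HUSlice, roi: ROI, threshold: int = BONE_THRESHOLD_HU,
                     case_id: str = "", session: str = "") -> BinarySilhouette:
    """Full pipeline: threshold -> enclosed-cavity extraction -> canvas."""
    bone = threshold_hu(hu, threshold)
    sil = extract_sinus_silhouette(bone, roi)
    return normalize_canvas(sil, case_id=case_id, session=session)


# ---------------------------------------------------------------------------
# HU raster input dialects


def read_hu_csv(path: str | Path, spacing_mm: tuple[float, float] = (1.0, 1.0)) -> HUSlice:
    """CSV of integer Hounsfield values, one row per image row."""
    values = np.loadtxt(str(path), delimiter=",", dtype=np.int32, ndmin=2)
    return HUSlice(values=values, spacing_mm=spacing_mm)


def read_hu_png16(path: str | Path, offset: int = 1024,
                  spacing_mm: tuple[float, float] = (1.0, 1.0)) -> HUSlice:
    """16-bit grayscale PNG storing HU + offset (default 1024, so air
    -1000 HU is stored as 24)."""
    from PIL import Image

    img = Image.open(str(path))
    arr = np.asarray(img, dtype=np.int32)
    if arr.ndim != 2:
        raise PreprocessError("expected a single-channel 16-bit PNG")
    return HUSlice(values=arr - offset, spacing_mm=spacing_mm)


def read_dicom_slice(path: str | Path) -> HUSlice:
    """Optional adapter: one axial frame from a single-slice DICOM file,
    applying the rescale slope/intercept to get Hounsfield units."""
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise PreprocessError("reading DICOM requires the optional pydicom dependency") from exc
    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    if arr.ndim == 3:
        arr = arr[0]
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [1.0, 1.0])
    return HUSlice(values=np.rint(hu).astype(np.int32),
                   spacing_mm=(float(spacing[0]), float(spacing[1])))
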