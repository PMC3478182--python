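"""Core image and mask data types plus file I/O.

The analysis substrate is an 8-bit RGB fluorescence capture of the two
maxillary central incisors under ~405 nm illumination: sound enamel
fluoresces brightly in the green channel while hypomineralized (fluorotic)
enamel appears darker.  Masks are labelled rasters drawn per tooth
(pixel value 1 = UR1, 2 = UL1, 0 = background); everything outside the
masks is excluded from analysis.

Coordinate convention shared by every module: 0-based, ``x`` = column index
increasing rightward, ``y`` = row index increasing downward (so the gingival
side of an upper incisor is towards the image top).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage
from scipy import ndimage

TOOTH_LABELS = ("UR1", "UL1")
#: pixel value used for each tooth in the labelled mask raster
MASK_VALUE = {"UR1": 1, "UL1": 2}

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


class ImageFormatError(ValueError):
    """Raised when a file cannot be decoded as 8-bit RGB (or a labelled mask)."""


@dataclass
class FluorescenceImage:
    """8-bit RGB fluorescence capture with optional physical scale.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` uint8 array, channel order R, G, B.
    subject_id
        Identifier of the imaged subject.
    capture_index
        1 for the original capture, >= 2 for repeat captures.
    mm_per_pixel
        Physical pixel pitch in mm, if known.  When absent, the blur
        method reports lesion area in pixels and flags the unit.
    """

    pixels: np.ndarray
    subject_id: str = ""
    capture_index: int = 1
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (h, w, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.height < 1 or self.width < 1:
            raise ValueError("image must have at least one pixel")
        if self.capture_index < 1:
            raise ValueError("capture_index must be >= 1")
        if self.mm_per_pixel is not None and not self.mm_per_pixel > 0:
            raise ValueError("mm_per_pixel must be positive when present")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class GreenChannelImage:
    """Single-channel brightness grid taken from the G channel.

    ``values`` may be float (e.g. after mean blurring) but always lies in
    [0, 255]; ``provenance`` names the source image.
    """

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 255):
            raise ValueError("brightness values must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ToothMask:
    """Binary region of one central incisor (True = inside the tooth)."""

    tooth_label: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.tooth_label not in TOOTH_LABELS:
            raise ValueError(f"tooth_label must be one of {TOOTH_LABELS}")
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be a 2-D grid")
        if not self.pixels.any():
            raise ValueError("a constructed ToothMask must contain pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())

    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        rows = np.flatnonzero(self.pixels.any(axis=1))
        cols = np.flatnonzero(self.pixels.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]), int(cols[-1])

    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid of the mask."""
        ys, xs = np.nonzero(self.pixels)
        return float(xs.mean()), float(ys.mean())


@dataclass
class LossMap:
    """Per-pixel fluorescence loss (brightness units on the 0-255 scale).

    Values are non-negative, zero outside the tooth mask, and — once a
    threshold has been applied — every retained value is at least the
    threshold.
    """

    values: np.ndarray
    threshold_applied: bool
    method_tag: str
    threshold_level: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method_tag not in ("blur", "hull"):
            raise ValueError("method_tag must be 'blur' or 'hull'")
        if self.values.size and self.values.min() < 0:
            raise ValueError("loss values must be non-negative")
        if self.threshold_applied and self.threshold_level > 0:
            nz = self.values[self.values > 0]
            if nz.size and nz.min() < self.threshold_level:
                raise ValueError("thresholded map contains sub-threshold values")


@dataclass
class FluorosisMetrics:
    """The (Area, ΔF, ΔQ) triple produced by either analysis technique.

    For the blur technique ΔF is a percentage loss relative to the local
    blurred (sound) estimate, Area is mm² (or pixels when no scale is known)
    and ΔQ = ΔF × Area.  For the convex-hull technique Area is the fraction
    of the tooth classed as fluorotic, ΔF the mean fractional loss over
    those pixels, and ΔQ the mean fractional loss over the whole tooth
    (which equals Area × ΔF by construction).
    """

    method_tag: str
    area: float
    delta_f: float
    delta_q: float
    n_lesion_px: int
    area_unit: str  # "mm2", "px" (blur without scale) or "fraction" (hull)
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.area < 0 or self.delta_f < 0 or self.n_lesion_px < 0:
            raise ValueError("metrics must be non-negative")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_image(path: str | Path) -> FluorescenceImage:
    """Read an 8-bit RGB fluorescence image (PNG or BMP).

    Indexed, grayscale and 16-bit files are rejected rather than silently
    converted or rescaled.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"{path}: file does not exist")
    try:
        img = PILImage.open(path)
    except Exception as exc:  # pragma: no cover - PIL error text varies
        raise ImageFormatError(f"{path}: cannot decode image ({exc})") from exc
    if img.mode != "RGB":
        raise ImageFormatError(
            f"{path}: expected 8-bit RGB, got mode {img.mode!r}"
        )
    arr = np.asarray(img, dtype=np.uint8)
    return FluorescenceImage(pixels=arr, subject_id=path.stem)


def write_image(image: FluorescenceImage, path: str | Path) -> None:
    """Write an image to PNG or BMP; read_image round-trips bit-exactly."""
    PILImage.fromarray(image.pixels, mode="RGB").save(Path(path))


def extract_green(image: FluorescenceImage) -> GreenChannelImage:
    """Keep only the green channel; R and B are discarded."""
    return GreenChannelImage(
        values=image.pixels[:, :, 1].copy(),
        provenance=image.subject_id,
    )


def _largest_component(binary: np.ndarray) -> np.ndarray:
    """Largest 8-connected component (masks must be single components)."""
    labels, n = ndimage.label(binary, structure=_EIGHT_CONN)
    if n <= 1:
        return binary
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def read_mask_set(path: str | Path, image: FluorescenceImage) -> list[ToothMask]:
    """Read the labelled mask raster for an image.

    Returns one :class:`ToothMask` per tooth present in the file; absent
    labels simply yield no mask (``mask_tools.check_analyzable`` turns that
    into a missing-mask exclusion).  If a label splits into several
    components only the largest is kept.
    """
    path = Path(path)
    if not path.exists():
        raise ImageFormatError(f"{path}: mask file does not exist")
    arr = np.asarray(PILImage.open(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path}: mask must be a single-channel labelled raster")
    if arr.shape != (image.height, image.width):
        raise ValueError(
            f"{path}: mask dimensions {arr.shape} do not match image "
            f"({image.height}, {image.width})"
        )
    masks: list[ToothMask] = []
    for label in TOOTH_LABELS:
        binary = arr == MASK_VALUE[label]
        if binary.any():
            masks.append(ToothMask(label, _largest_component(binary)))
    return masks


def write_mask_set(masks: list[ToothMask], shape: tuple[int, int], path: str | Path) -> None:
    """Write masks as an indexed PNG (0 background, 1 = UR1, 2 = UL1)."""
    canvas = np.zeros(shape, dtype=np.uint8)
    for mask in masks:
        if mask.pixels.shape != shape:
            raise ValueError("mask dimensions do not match the target shape")
        canvas[mask.pixels] = MASK_VALUE[mask.tooth_label]
    img = PILImage.fromarray(canvas, mode="P")
    palette = [0, 0, 0, 220, 40, 40, 40, 90, 220] + [0] * (256 * 3 - 9)
    img.putpalette(palette)
    img.save(Path(path))


def mask_union(masks: list[ToothMask]) -> np.ndarray:
    """Boolean union of a set of tooth masks."""
    if not masks:
        raise ValueError("no masks given")
    out = np.zeros_like(masks[0].pixels, dtype=bool)
    for mask in masks:
        out |= mask.pixels
    return out
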