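"""Mask validation, exclusion rules and automatic reference-area selection.

A subject is analyzable only when both central-incisor masks exist and the
incisors are not separated by a large diastema; excluded subjects are
retained in outputs with their reason rather than silently dropped.

The reference area (needed by the blur technique as the "base level" for
its 2-SD pixel selection) is selected automatically: a gingival anchor
point is triangulated above the two masks, a ray is cast from it through
each tooth's centroid, and the brightest-median square window centred on
that ray inside the incisal half of the mask becomes the reference patch.
Brightest-median (rather than brightest single pixel) makes the choice
robust to specular highlights and shot noise, and steers the patch away
from dark (lesioned) regions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import GreenChannelImage, ToothMask

REASON_MISSING_MASK = "missing_mask"
REASON_LARGE_DIASTEMA = "large_diastema"

#: default diastema threshold as a fraction of image width
DEFAULT_MAX_GAP_FRAC = 0.05
#: default gingival offset as a fraction of mean mask height
DEFAULT_GINGIVAL_OFFSET_FRAC = 0.25
DEFAULT_PATCH_PX = 9


@dataclass
class AnalyzabilityReport:
    subject_id: str
    analyzable: bool
    reasons: tuple[str, ...]
    diastema_gap_px: int | None = None

    def __post_init__(self) -> None:
        if self.analyzable != (len(self.reasons) == 0):
            raise ValueError("analyzable must be true iff reasons is empty")


@dataclass
class ReferenceArea:
    """A sound-enamel patch inside a tooth mask used as the base level."""

    pixels: np.ndarray
    centroid: tuple[float, float]  # (x, y)
    source: str = "auto_triangulation"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if not self.pixels.any():
            raise ValueError("reference area must be non-empty")


def _horizontal_gap(left: ToothMask, right: ToothMask) -> int:
    """Pixel gap between the bounding boxes of two side-by-side masks.

    Abutting or overlapping boxes give 0.
    """
    _, l_min, _, l_max = left.bbox()
    _, r_min, _, r_max = right.bbox()
    return max(0, r_min - l_max - 1)


def check_analyzable(
    masks: list[ToothMask],
    max_gap: float | None = None,
    *,
    max_gap_frac: float = DEFAULT_MAX_GAP_FRAC,
    subject_id: str = "",
) -> AnalyzabilityReport:
    """Apply the study's exclusion rules to a subject's mask set.

    ``missing_mask`` fires when fewer than two labelled tooth masks exist
    (missing, fractured or restored incisor); ``large_diastema`` when the
    horizontal gap between the two mask bounding boxes exceeds ``max_gap``
    (default ``max_gap_frac`` of the image width).  Report-only: callers
    drop non-analyzable subjects from downstream statistics.
    """
    reasons: list[str] = []
    gap: int | None = None
    if len(masks) < 2:
        reasons.append(REASON_MISSING_MASK)
    else:
        a, b = sorted(masks[:2], key=lambda m: m.centroid()[0])
        if max_gap is None:
            max_gap = max_gap_frac * a.pixels.shape[1]
        gap = _horizontal_gap(a, b)
        if gap > max_gap:
            reasons.append(REASON_LARGE_DIASTEMA)
    return AnalyzabilityReport(
        subject_id=subject_id,
        analyzable=not reasons,
        reasons=tuple(reasons),
        diastema_gap_px=gap,
    )


def locate_gingival_point(
    masks: list[ToothMask],
    offset_frac: float = DEFAULT_GINGIVAL_OFFSET_FRAC,
) -> tuple[float, float]:
    """Triangulate a gingival anchor point above the two incisor masks.

    Returns the (x, y) point at the horizontal midpoint of the two mask
    centroids, offset above the higher of the two mask top edges by
    ``offset_frac`` of the mean mask height (gingival side = image top),
    clamped to the image.
    """
    if len(masks) < 2:
        raise ValueError(
            "gingival-point triangulation needs both incisor masks; "
            "subject should be excluded (missing_mask)"
        )
    a, b = masks[:2]
    x = (a.centroid()[0] + b.centroid()[0]) / 2.0
    tops = []
    heights = []
    for m in (a, b):
        r0, _, r1, _ = m.bbox()
        tops.append(r0)
        heights.append(r1 - r0 + 1)
    y = min(tops) - offset_frac * (sum(heights) / 2.0)
    h, w = a.pixels.shape
    return (float(np.clip(x, 0, w - 1)), float(np.clip(y, 0, h - 1)))


def _ray_candidates(
    point: tuple[float, float],
    centroid: tuple[float, float],
    shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Integer (row, col) pixels along the ray point -> centroid -> image edge."""
    h, w = shape
    px, py = point
    dx, dy = centroid[0] - px, centroid[1] - py
    norm = float(np.hypot(dx, dy))
    if norm == 0:
        return [(int(round(py)), int(round(px)))]
    dx, dy = dx / norm, dy / norm
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    t = 0.0
    while True:
        x, y = px + t * dx, py + t * dy
        if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
            break
        rc = (int(round(y)), int(round(x)))
        if rc not in seen:
            seen.add(rc)
            out.append(rc)
        t += 0.5
    return out


def select_reference_area(
    masks: list[ToothMask],
    gingival_point: tuple[float, float],
    green: GreenChannelImage,
    patch_px: int = DEFAULT_PATCH_PX,
) -> dict[str, ReferenceArea]:
    """Pick the per-tooth reference patch along the gingival ray.

    For each tooth, candidate centres are the ray pixels in the incisal
    half of the mask whose ``patch_px``-sided square window lies fully
    inside the mask; the window with the brightest median green value wins,
    ties broken by the smallest (y, then x) centre.  Deterministic for
    fixed inputs.
    """
    if patch_px < 3:
        raise ValueError("patch_px must be at least 3")
    g = np.asarray(green.values, dtype=float)
    lo = (patch_px - 1) // 2
    hi = patch_px // 2
    out: dict[str, ReferenceArea] = {}
    for mask in masks:
        r0, c0, r1, c1 = mask.bbox()
        if patch_px > (r1 - r0 + 1) or patch_px > (c1 - c0 + 1):
            raise ValueError(
                f"{mask.tooth_label}: patch_px={patch_px} exceeds the mask "
                "extent; try a smaller patch_px"
            )
        mid_row = (r0 + r1) / 2.0
        best: tuple[float, int, int] | None = None  # (-median, row, col)
        for row, col in _ray_candidates(gingival_point, mask.centroid(), mask.pixels.shape):
            if row < mid_row:  # only the incisal half
                continue
            rs, re = row - lo, row + hi + 1
            cs, ce = col - lo, col + hi + 1
            if rs < 0 or cs < 0 or re > mask.pixels.shape[0] or ce > mask.pixels.shape[1]:
                continue
            if not mask.pixels[rs:re, cs:ce].all():
                continue
            med = float(np.median(g[rs:re, cs:ce]))
            key = (-med, row, col)
            if best is None or key < best:
                best = key
        if best is None:
            raise ValueError(
                f"{mask.tooth_label}: no {patch_px}x{patch_px} window fits inside "
                "the mask along the gingival ray; try a smaller patch_px"
            )
        _, row, col = best
        pixels = np.zeros_like(mask.pixels)
        pixels[row - lo:row + hi + 1, col - lo:col + hi + 1] = True
        out[mask.tooth_label] = ReferenceArea(
            pixels=pixels, centroid=(float(col), float(row))
        )
    return out
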