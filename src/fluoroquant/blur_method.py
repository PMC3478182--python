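"""The unsharp-mask ("blur") fluorosis quantification technique.

A mean blur of pre-determined window size replaces each in-tooth pixel by
the average of its surrounding pixels; this blurred image acts as the local
sound-enamel estimate.  Subtracting the original from the blur leaves the
diffuse fluorescence loss, pixels more than ``k_sd`` standard deviations
above the reference-area base level are classed as fluorotic, and the
metrics are

* ``Area_blur``  — lesion extent (mm² when the pixel pitch is known,
  otherwise pixels, flagged),
* ``ΔF_blur``   — mean percentage fluorescence loss of lesion pixels
  relative to the local blurred estimate,
* ``ΔQ_blur``   — the product ΔF_blur × Area_blur.

Defaults follow the published optimum: a 30-pixel blur with a 2-SD pixel
selection.  The blur is mask-aware by default: windows are renormalized by
the in-mask pixel count so the dark background never leaks into edge
windows and manufactures spurious loss along the tooth outline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_model import FluorosisMetrics, GreenChannelImage, LossMap, ToothMask
from .mask_tools import ReferenceArea


@dataclass(frozen=True)
class BlurParams:
    blur_size_px: int = 30
    k_sd: float = 2.0
    mask_aware: bool = True

    def __post_init__(self) -> None:
        if self.blur_size_px < 1:
            raise ValueError("blur_size_px must be >= 1")
        if self.k_sd < 0:
            raise ValueError("k_sd must be >= 0")


def _window_sums(a: np.ndarray, size: int) -> np.ndarray:
    """Sum of ``a`` over a size×size window at every pixel (integral image).

    The window at (r, c) spans rows r-(size-1)//2 .. r+size//2 and the
    same columns: for even sizes the extra row/column falls down/right.
    Out-of-image cells contribute zero.
    """
    lo = (size - 1) // 2
    hi = size // 2
    h, w = a.shape
    s = np.zeros((h + 1, w + 1), dtype=float)
    s[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
    r1 = np.clip(np.arange(h) - lo, 0, h)
    r2 = np.clip(np.arange(h) + hi + 1, 0, h)
    c1 = np.clip(np.arange(w) - lo, 0, w)
    c2 = np.clip(np.arange(w) + hi + 1, 0, w)
    return (
        s[np.ix_(r2, c2)] - s[np.ix_(r1, c2)] - s[np.ix_(r2, c1)] + s[np.ix_(r1, c1)]
    )


def mean_blur(
    green: GreenChannelImage, mask: ToothMask, params: BlurParams = BlurParams()
) -> GreenChannelImage:
    """Mean-filter the green channel over the tooth mask.

    When ``mask_aware`` (the default) out-of-mask pixels are excluded from
    each window average and the divisor is the in-mask count; otherwise the
    window mean is taken over all in-image pixels, background included.
    The output is zero outside the mask.
    """
    g = np.asarray(green.values, dtype=float)
    m = mask.pixels.astype(float)
    size = params.blur_size_px
    if params.mask_aware:
        num = _window_sums(g * m, size)
        den = _window_sums(m, size)
    else:
        num = _window_sums(g, size)
        den = _window_sums(np.ones_like(g), size)
    bad = mask.pixels & (den < 0.5)
    if bad.any():  # cannot happen for a window centred on an in-mask pixel
        raise RuntimeError("blur window without any contributing pixel")
    out = np.zeros_like(g)
    np.divide(num, den, out=out, where=den > 0.5)
    out[~mask.pixels] = 0.0
    return GreenChannelImage(values=out, provenance=green.provenance)


def unsharp_difference(
    green: GreenChannelImage, blurred: GreenChannelImage, mask: ToothMask
) -> LossMap:
    """Loss map = max(0, blur − original), in-mask.

    The blur acts as the sound-area control, so pixels darker than the
    local blurred estimate carry positive loss; brighter-than-blur pixels
    clamp to zero (there is no negative fluorosis).
    """
    g = np.asarray(green.values, dtype=float)
    b = np.asarray(blurred.values, dtype=float)
    if g.shape != b.shape or g.shape != mask.pixels.shape:
        raise ValueError("image, blur and mask dimensions must match")
    loss = np.clip(b - g, 0.0, None)
    loss[~mask.pixels] = 0.0
    return LossMap(values=loss, threshold_applied=False, method_tag="blur")


def select_lesion_pixels(
    loss: LossMap,
    mask: ToothMask,
    reference: ReferenceArea,
    params: BlurParams = BlurParams(),
) -> np.ndarray:
    """2-SD pixel selection from the reference-area base level.

    The base level is the mean and SD of the loss map over the reference
    area; lesion pixels are in-mask pixels with loss > mean + k_sd·SD.
    Degenerate rule: when the reference SD is zero, every pixel above the
    base mean is selected.
    """
    if loss.threshold_applied:
        raise ValueError("select_lesion_pixels expects an unthresholded loss map")
    base = loss.values[reference.pixels]
    if base.size == 0:
        raise ValueError("empty reference area")
    mean = float(base.mean())
    sd = float(base.std(ddof=0))
    threshold = mean + params.k_sd * sd if sd > 0 else mean
    return mask.pixels & (loss.values > threshold)


def blur_metrics(
    loss: LossMap,
    lesion_mask: np.ndarray,
    blurred: GreenChannelImage,
    mm_per_pixel: float | None = None,
) -> FluorosisMetrics:
    """Compute (Area_blur, ΔF_blur, ΔQ_blur) from the selected lesion.

    ΔF_blur is the mean over lesion pixels of 100·loss/blur (percent loss
    relative to the local sound estimate).  Lesion pixels where the blurred
    estimate is zero are skipped from the ΔF mean (division guard) and
    counted in ``n_skipped``.  An empty lesion yields (0, 0, 0).
    """
    lesion = np.asarray(lesion_mask, dtype=bool)
    n_lesion = int(lesion.sum())
    b = np.asarray(blurred.values, dtype=float)
    valid = lesion & (b > 0)
    n_skipped = n_lesion - int(valid.sum())
    if valid.any():
        delta_f = float(np.mean(100.0 * loss.values[valid] / b[valid]))
    else:
        delta_f = 0.0
    if mm_per_pixel is not None:
        area = n_lesion * mm_per_pixel**2
        unit = "mm2"
    else:
        area = float(n_lesion)
        unit = "px"
    if n_lesion == 0:
        area = 0.0
    return FluorosisMetrics(
        method_tag="blur",
        area=area,
        delta_f=delta_f,
        delta_q=delta_f * area,
        n_lesion_px=n_lesion,
        area_unit=unit,
        n_skipped=n_skipped,
    )


def run_blur(
    green: GreenChannelImage,
    mask: ToothMask,
    reference: ReferenceArea,
    params: BlurParams = BlurParams(),
    mm_per_pixel: float | None = None,
) -> tuple[FluorosisMetrics, dict]:
    """Full blur pipeline for one tooth; returns metrics and intermediates."""
    blurred = mean_blur(green, mask, params)
    loss = unsharp_difference(green, blurred, mask)
    lesion = select_lesion_pixels(loss, mask, reference, params)
    metrics = blur_metrics(loss, lesion, blurred, mm_per_pixel)
    return metrics, {"blurred": blurred, "loss": loss, "lesion_mask": lesion}
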