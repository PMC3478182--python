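"""Seeded synthetic tooth phantoms and dose-response populations.

No fluorescence image set for this problem is publicly deposited, so the
package carries a generator that emulates the salient features of QLF
captures of the two maxillary central incisors:

* green-channel-dominant pixels (R and B are fixed fractions of G),
* two rounded (superellipse) incisor masks separated by a small gap,
* smooth concave sound-enamel brightness (brightest mid-tooth),
* diffuse fluorosis lesions built by quantile-thresholding a smooth
  correlated random field and attenuating brightness inside by a
  fractional depth — diffuse lesions may extend across the whole surface,
  which is precisely what defeats discrete-lesion caries software,
* optional confounders (stain patch, demarcated opacity, missing tooth),
* repeat captures with translation / illumination-gain / noise jitter,
* whole populations whose per-interval TF-score distributions are
  calibrated to the published per-water-interval means and SDs, with a
  monotone TF -> (lesion area fraction, depth fraction) map.

Everything is deterministic under the spec seed; ground truth is recorded
exactly as realized (pixel counts), not as the requested target.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import norm

from .image_model import (
    MASK_VALUE,
    FluorescenceImage,
    ToothMask,
    write_image,
    write_mask_set,
)

CONFOUNDERS = ("stain_patch", "demarcated_opacity", "missing_tooth")

#: per-water-interval TF-score (mean, SD) targets, lowest to highest
#: fluoride interval — the study-population calibration.
DEFAULT_INTERVAL_TF: tuple[tuple[float, float], ...] = (
    (0.70, 0.93),
    (1.01, 1.02),
    (1.28, 1.30),
    (1.65, 1.47),
    (2.30, 1.90),
)

#: water-fluoride interval bounds (ppm); the top interval is open above but
#: sampled uniformly up to ``PopulationSpec.ppm_upper``.
INTERVAL_PPM_BOUNDS = ((0.0, 0.20), (0.20, 0.60), (0.60, 0.90), (0.90, 1.60), (1.60, None))

#: monotone anchors TF -> (lesion area fraction, lesion depth fraction);
#: linear between anchors, clamped above TF 5.  Magnitudes sit inside the
#: observed ranges of the hull metrics on the study population.
DEFAULT_LESION_ANCHORS: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.00, 0.00),
    (1.0, 0.10, 0.04),
    (3.0, 0.35, 0.08),
    (5.0, 0.70, 0.15),
)

TF_MAX = 7


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one two-incisor phantom image."""

    image_size: tuple[int, int] = (200, 300)  # (rows, cols)
    tooth_size: tuple[int, int] = (130, 90)  # (height, width) of each incisor
    diastema_px: int = 4
    base_brightness: float = 180.0
    gradient_amplitude: float = 18.0
    lesion_area_fraction: float | tuple[float, float] = 0.2
    lesion_depth_fraction: float | tuple[float, float] = 0.08
    lesion_texture_scale: float = 8.0
    confounders: tuple[str, ...] = ()
    noise_sd: float = 2.0
    seed: int = 0
    subject_id: str = "phantom"
    mm_per_pixel: float | None = None

    def __post_init__(self) -> None:
        for a in np.atleast_1d(self.lesion_area_fraction):
            if not 0 <= a <= 1:
                raise ValueError("lesion_area_fraction must lie in [0, 1]")
        for d in np.atleast_1d(self.lesion_depth_fraction):
            if not 0 <= d < 1:
                raise ValueError("lesion_depth_fraction must lie in [0, 1)")
        for c in self.confounders:
            if c not in CONFOUNDERS:
                raise ValueError(f"unknown confounder {c!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _per_tooth(value: float | tuple[float, float]) -> tuple[float, float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return float(arr[0]), float(arr[0])
    return float(arr[0]), float(arr[1])


def _superellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], half: tuple[float, float]
) -> np.ndarray:
    """Rounded-rectangle incisor outline (superellipse, exponent 4)."""
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    hy, hx = half
    return ((np.abs(cols - cx) / hx) ** 4 + (np.abs(rows - cy) / hy) ** 4) <= 1.0


def make_phantom(
    spec: PhantomSpec,
) -> tuple[FluorescenceImage, list[ToothMask], dict[str, tuple[float, float]]]:
    """Render one phantom; returns (image, masks, realized ground truth).

    Ground truth maps tooth label -> (realized lesion area fraction,
    realized mean depth fraction), counted from the generator's own lesion
    field, not the requested targets.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    th, tw = spec.tooth_size
    cy = h / 2.0
    gap = spec.diastema_px
    centers = {
        "UR1": (cy, w / 2.0 - gap / 2.0 - tw / 2.0),  # patient right = image left
        "UL1": (cy, w / 2.0 + gap / 2.0 + tw / 2.0),
    }
    areas = dict(zip(("UR1", "UL1"), _per_tooth(spec.lesion_area_fraction)))
    depths = dict(zip(("UR1", "UL1"), _per_tooth(spec.lesion_depth_fraction)))

    g = np.zeros((h, w), dtype=float)
    masks: list[ToothMask] = []
    truth: dict[str, tuple[float, float]] = {}
    rows, cols = np.ogrid[:h, :w]
    for label in ("UR1", "UL1"):
        mask = _superellipse_mask((h, w), centers[label], (th / 2.0, tw / 2.0))
        ccy, ccx = centers[label]
        # strictly concave brightness dome peaking mid-tooth
        dome = 1.0 - 0.5 * ((cols - ccx) / (tw / 2.0)) ** 2 - 0.5 * (
            (rows - ccy) / (th / 2.0)
        ) ** 2
        g[mask] = spec.base_brightness + spec.gradient_amplitude * dome[mask]
        a, d = areas[label], depths[label]
        lesion = np.zeros((h, w), dtype=bool)
        if a > 0:
            field_ = ndimage.gaussian_filter(
                rng.standard_normal((h, w)), spec.lesion_texture_scale
            )
            thr = np.quantile(field_[mask], 1.0 - a)
            lesion = mask & (field_ > thr)
            g[lesion] *= 1.0 - d
        realized_area = lesion.sum() / mask.sum()
        truth[label] = (float(realized_area), d if lesion.any() else 0.0)
        masks.append(ToothMask(label, mask))

    if "stain_patch" in spec.confounders:
        # localized deep loss: stain over fluorosis exhibits greater loss
        m = masks[int(rng.integers(2))].pixels
        ys, xs = np.nonzero(m)
        i = int(rng.integers(ys.size))
        r = max(4, th // 12)
        patch = (rows - ys[i]) ** 2 + (cols - xs[i]) ** 2 <= r**2
        g[patch & m] *= 0.5
    if "demarcated_opacity" in spec.confounders:
        m = masks[int(rng.integers(2))].pixels
        ys, xs = np.nonzero(m)
        i = int(rng.integers(ys.size))
        r0, c0 = ys[i], xs[i]
        patch = np.zeros((h, w), dtype=bool)
        patch[r0 : r0 + th // 8, c0 : c0 + tw // 6] = True
        g[patch & m] *= 0.7  # sharp-edged drop
    if "missing_tooth" in spec.confounders:
        drop = masks.pop()  # UL1 mask absent (missing/fractured/restored)
        truth.pop(drop.tooth_label)

    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union |= m.pixels
    g[~union] = 10.0  # dark gingival background
    if spec.noise_sd > 0:
        g = g + rng.normal(0.0, spec.noise_sd, size=(h, w))
    g = np.clip(np.round(g), 0, 255)
    pixels = np.stack(
        [
            np.clip(np.round(0.32 * g), 0, 255),
            g,
            np.clip(np.round(0.18 * g), 0, 255),
        ],
        axis=-1,
    ).astype(np.uint8)
    image = FluorescenceImage(
        pixels=pixels,
        subject_id=spec.subject_id,
        capture_index=1,
        mm_per_pixel=spec.mm_per_pixel,
    )
    return image, masks, truth


def make_repeat(
    image: FluorescenceImage,
    masks: list[ToothMask],
    translation: tuple[int, int] = (0, 0),
    gain: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[FluorescenceImage, list[ToothMask]]:
    """Simulate a repeat capture: small translation, global gain, fresh noise.

    Masks are re-derived by the same translation; the returned image has
    ``capture_index = 2``.  A translation that pushes the teeth outside
    the frame is an error.
    """
    dy, dx = translation
    h, w = image.height, image.width
    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union |= m.pixels
    ys, xs = np.nonzero(union)
    if (
        ys.min() + dy < 0
        or ys.max() + dy >= h
        or xs.min() + dx < 0
        or xs.max() + dx >= w
    ):
        raise ValueError("translation pushes the teeth outside the frame")
    rng = np.random.default_rng(seed)
    shifted = np.zeros_like(image.pixels, dtype=float)
    src = image.pixels.astype(float)
    rs = slice(max(0, dy), h + min(0, dy))
    cs = slice(max(0, dx), w + min(0, dx))
    rs0 = slice(max(0, -dy), h + min(0, -dy))
    cs0 = slice(max(0, -dx), w + min(0, -dx))
    shifted[rs, cs] = src[rs0, cs0]
    out = shifted * gain
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    new_masks = []
    for m in masks:
        p = np.zeros_like(m.pixels)
        p[rs, cs] = m.pixels[rs0, cs0]
        new_masks.append(ToothMask(m.tooth_label, p))
    repeat = FluorescenceImage(
        pixels=out,
        subject_id=image.subject_id,
        capture_index=2,
        mm_per_pixel=image.mm_per_pixel,
    )
    return repeat, new_masks


# ---------------------------------------------------------------------------
# population generator
# ---------------------------------------------------------------------------

def tf_to_lesion(
    tf: float | np.ndarray,
    anchors: tuple[tuple[float, float, float], ...] = DEFAULT_LESION_ANCHORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Monotone map TF score -> (lesion area fraction, depth fraction)."""
    a = np.asarray(anchors, dtype=float)
    tf = np.asarray(tf, dtype=float)
    area = np.interp(tf, a[:, 0], a[:, 1])
    depth = np.interp(tf, a[:, 0], a[:, 2])
    return area, depth


def _discretized_mean(mu: float, sigma: float) -> float:
    """Mean of round(N(mu, sigma)) clipped to [0, TF_MAX]."""
    ks = np.arange(0, TF_MAX + 1)
    upper = norm.cdf((ks + 0.5 - mu) / sigma)
    lower = norm.cdf((ks - 0.5 - mu) / sigma)
    p = upper - lower
    p[0] = norm.cdf((0.5 - mu) / sigma)
    p[-1] = 1.0 - norm.cdf((TF_MAX - 0.5 - mu) / sigma)
    return float((ks * p).sum())


def calibrate_latent_mean(target_mean: float, sigma: float) -> float:
    """Latent normal mean whose discretized/clipped TF mean hits the target.

    Rounding and clipping to [0, 7] bias the realized mean upward for
    low-fluoride intervals; this one-dimensional root solve removes that
    bias so generated populations match the published interval means.
    """
    return float(
        brentq(lambda m: _discretized_mean(m, sigma) - target_mean, -6.0, TF_MAX + 2.0)
    )


@dataclass(frozen=True)
class PopulationSpec:
    """Study-population generator: five water intervals, TF dose response."""

    n_per_interval: int = 30
    interval_tf: tuple[tuple[float, float], ...] = DEFAULT_INTERVAL_TF
    tooth_correlation: float = 0.8
    lesion_anchors: tuple[tuple[float, float, float], ...] = DEFAULT_LESION_ANCHORS
    repeat_fraction: float = 0.08
    seed: int = 0
    # measurement-noise model for the metrics-level mode: multiplicative
    # lognormal CV plus a small additive floor, consistent with the very
    # good repeatability (ICC ~0.95) of the imaging pipeline.
    measurement_cv: float = 0.15
    area_noise_floor: float = 0.01
    depth_noise_floor: float = 0.004
    ppm_upper: float = 3.0
    blur_tooth_px: int = 8000  # nominal tooth size for blur-area scaling

    def __post_init__(self) -> None:
        if len(self.interval_tf) != 5:
            raise ValueError("exactly five water intervals are required")
        if self.n_per_interval < 2:
            raise ValueError("statistics need at least 2 subjects per interval")
        m = np.asarray(self.lesion_anchors, dtype=float)
        if (np.diff(m[:, 1]) < 0).any() or (np.diff(m[:, 2]) < 0).any():
            raise ValueError("tf_to_lesion map must be monotone non-decreasing")


def _draw_tf(
    rng: np.random.Generator, n: int, mean: float, sd: float, rho: float
) -> np.ndarray:
    """(n, 2) correlated TF scores for the two incisors (calibrated)."""
    mu = calibrate_latent_mean(mean, sd)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    latent = mu + sd * np.column_stack([z1, z2])
    return np.clip(np.round(latent), 0, TF_MAX).astype(int)


def _measured(
    rng: np.random.Generator, true: np.ndarray, cv: float, floor: float
) -> np.ndarray:
    noisy = true * np.exp(rng.normal(0.0, cv, size=true.shape)) + np.abs(
        rng.normal(0.0, floor, size=true.shape)
    )
    return np.clip(noisy, 0.0, 1.0)


def make_population(
    spec: PopulationSpec = PopulationSpec(),
    render: str = "metrics",
    out_dir: str | Path | None = None,
    phantom_size: tuple[int, int] = (160, 240),
    phantom_noise_sd: float = 2.0,
) -> pd.DataFrame:
    """Generate a five-interval dose-response population.

    ``render="metrics"`` (fast) draws per-tooth method metrics directly
    from the TF -> lesion map plus the measurement-noise model — the
    substrate for replicate-heavy statistical simulations.

    ``render="images"`` additionally renders a phantom image and mask per
    capture (written under ``out_dir``); metric columns are left to the
    analysis pipeline.  Approximately equal interval sizes mirror the
    study design.

    Returns a long table with one row per subject × capture × tooth.
    """
    if render not in ("metrics", "images"):
        raise ValueError("render must be 'metrics' or 'images'")
    if render == "images" and out_dir is None:
        raise ValueError("render='images' requires out_dir")
    rng = np.random.default_rng(spec.seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    sid = 0
    for interval, ((mean, sd), bounds) in enumerate(
        zip(spec.interval_tf, INTERVAL_PPM_BOUNDS)
    ):
        lo, hi = bounds
        hi = spec.ppm_upper if hi is None else hi
        n = spec.n_per_interval
        ppm = rng.uniform(lo, hi, size=n)
        tf = _draw_tf(rng, n, mean, sd, spec.tooth_correlation)
        area_true, depth_true = tf_to_lesion(tf, spec.lesion_anchors)
        repeat = rng.random(n) < spec.repeat_fraction
        for i in range(n):
            sid += 1
            subject = f"S{sid:04d}"
            captures = (1, 2) if repeat[i] else (1,)
            image_paths: dict[int, tuple[str, str]] = {}
            if render == "images":
                pspec = PhantomSpec(
                    image_size=phantom_size,
                    tooth_size=(int(phantom_size[0] * 0.65), int(phantom_size[1] * 0.3)),
                    lesion_area_fraction=tuple(area_true[i]),
                    lesion_depth_fraction=tuple(depth_true[i]),
                    noise_sd=phantom_noise_sd,
                    seed=int(rng.integers(0, 2**31)),
                    subject_id=subject,
                )
                image, masks, _ = make_phantom(pspec)
                for cap in captures:
                    if cap == 1:
                        img_c, masks_c = image, masks
                    else:
                        img_c, masks_c = make_repeat(
                            image,
                            masks,
                            translation=tuple(rng.integers(-3, 4, size=2)),
                            gain=float(rng.normal(1.0, 0.03)),
                            noise_sd=phantom_noise_sd,
                            seed=int(rng.integers(0, 2**31)),
                        )
                    ipath = out_dir / f"{subject}_c{cap}.png"
                    mpath = out_dir / f"{subject}_c{cap}_mask.png"
                    write_image(img_c, ipath)
                    write_mask_set(masks_c, (img_c.height, img_c.width), mpath)
                    image_paths[cap] = (str(ipath), str(mpath))
            for cap in captures:
                for t, label in enumerate(("UR1", "UL1")):
                    row = {
                        "subject_id": subject,
                        "water_ppm": float(ppm[i]),
                        "water_interval": interval,
                        "capture_index": cap,
                        "tooth": label,
                        "tf": int(tf[i, t]),
                        "true_area": float(area_true[i, t]),
                        "true_depth": float(depth_true[i, t]),
                    }
                    if render == "metrics":
                        a = _measured(
                            rng,
                            np.array([area_true[i, t]]),
                            spec.measurement_cv,
                            spec.area_noise_floor,
                        )[0]
                        d = _measured(
                            rng,
                            np.array([depth_true[i, t]]),
                            spec.measurement_cv,
                            spec.depth_noise_floor,
                        )[0]
                        a2 = _measured(
                            rng,
                            np.array([area_true[i, t]]),
                            spec.measurement_cv,
                            spec.area_noise_floor,
                        )[0]
                        d2 = _measured(
                            rng,
                            np.array([depth_true[i, t]]),
                            spec.measurement_cv,
                            spec.depth_noise_floor,
                        )[0]
                        row.update(
                            area_ch=float(a),
                            delta_f_ch=float(d),
                            delta_q_ch=float(a * d),
                            area_blur=float(a2 * spec.blur_tooth_px),
                            delta_f_blur=float(100.0 * d2),
                            delta_q_blur=float(a2 * spec.blur_tooth_px * 100.0 * d2),
                        )
                    else:
                        ipath, mpath = image_paths[cap]
                        row.update(image_path=ipath, mask_path=mpath)
                    rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(out_dir / "subjects.csv", index=False)
    return df
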