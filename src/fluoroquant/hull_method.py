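"""The convex-hull ("clean surface") fluorosis quantification technique.

Each in-mask pixel becomes a point (x, y, brightness).  The 3-D convex
hull of this cloud is computed (Quickhull, via scipy/qhull) and its upper
facets — those whose outward normal has a positive brightness component —
are rendered back to an image by planar interpolation.  The result is the
"clean" tooth surface: a reconstruction of sound enamel in which dark
(lesioned) areas are filled by interpolation between surrounding bright
areas.  Only the upper envelope is rendered; the lower facets would
reconstruct the lesions themselves.

Subtracting the captured (opened) image from the clean surface gives the
fluorescence-loss map, which is thresholded (default 5 out of 255, chosen
low to retain mild fluorosis) to remove background noise: pixels strictly
below the threshold are set to zero, all others keep their raw value.

Metrics:

* ``Area_ch`` — fraction of the tooth area classed as fluorosis,
* ``ΔF_ch``  — mean fractional loss (loss/clean) over those pixels,
* ``ΔQ_ch``  — mean fractional loss over the entire tooth surface,
  equal to Area_ch × ΔF_ch by construction.

Hulls are built per tooth so a diastema gap never becomes part of a facet.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import disk

from .image_model import FluorosisMetrics, GreenChannelImage, LossMap, ToothMask

_RANK_TOL = 1e-9
_BARY_TOL = 1e-9


@dataclass(frozen=True)
class HullParams:
    threshold_level: int = 5
    opening_radius_px: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.threshold_level <= 255:
            raise ValueError("threshold_level must lie in [0, 255]")
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")


@dataclass
class CleanSurface:
    """Reconstructed sound-enamel brightness, defined in-mask.

    Values dominate the (opened) input brightness at every in-mask pixel
    and stay within its in-mask [min, max] range.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def open_image(
    green: GreenChannelImage, mask: ToothMask, params: HullParams = HullParams()
) -> GreenChannelImage:
    """Grayscale morphological opening restricted to the mask.

    Out-of-mask pixels are treated as mask-border replication (each is
    filled with its nearest in-mask value before the opening), not as
    zero, so the tooth outline does not erode.  A radius of 0 disables
    the step.
    """
    g = np.asarray(green.values, dtype=float)
    if params.opening_radius_px == 0:
        out = g.copy()
        out[~mask.pixels] = 0.0
        return GreenChannelImage(values=out, provenance=green.provenance)
    filled = g
    if (~mask.pixels).any():
        idx = ndimage.distance_transform_edt(
            ~mask.pixels, return_distances=False, return_indices=True
        )
        filled = g[tuple(idx)]
    footprint = disk(params.opening_radius_px).astype(bool)
    opened = ndimage.grey_opening(filled, footprint=footprint, mode="nearest")
    opened[~mask.pixels] = 0.0
    return GreenChannelImage(values=opened, provenance=green.provenance)


def _upper_envelope_1d(t: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Upper concave envelope of points (t, z) evaluated at each t."""
    order = np.argsort(t, kind="stable")
    ts, zs = t[order], z[order]
    chain: list[tuple[float, float]] = []
    for ti, zi in zip(ts, zs):
        if chain and chain[-1][0] == ti:
            if zi <= chain[-1][1]:
                continue
            chain.pop()
        while len(chain) >= 2:
            (x1, y1), (x2, y2) = chain[-2], chain[-1]
            # pop while the middle point lies on/below the segment (1, new)
            if (x2 - x1) * (zi - y1) - (y2 - y1) * (ti - x1) >= 0:
                chain.pop()
            else:
                break
        chain.append((float(ti), float(zi)))
    cx = np.array([p[0] for p in chain])
    cz = np.array([p[1] for p in chain])
    env_sorted = np.interp(ts, cx, cz)
    env = np.empty_like(env_sorted)
    env[order] = env_sorted
    return env


def upper_hull_surface(green_opened: GreenChannelImage, mask: ToothMask) -> CleanSurface:
    """Render the upper envelope of the (x, y, brightness) convex hull.

    Each upper facet is rasterized over its (x, y) projection by planar
    (barycentric) interpolation; pixels on facet edges take the value from
    the lexicographically-first facet.  Degenerate inputs: a coplanar
    point cloud reproduces the (planar) brightness exactly; collinear
    pixels use the 1-D upper concave envelope; fewer than 3 points is an
    error.
    """
    values = np.asarray(green_opened.values, dtype=float)
    ys, xs = np.nonzero(mask.pixels)
    z = values[ys, xs]
    n = z.size
    if n < 3:
        raise ValueError("upper hull needs at least 3 in-mask pixels")

    env_flat = np.full(n, np.nan)
    pts = np.column_stack([xs.astype(float), ys.astype(float), z])
    centered = pts - pts.mean(axis=0)
    sv3 = np.linalg.svd(centered, compute_uv=False)
    svxy = np.linalg.svd(centered[:, :2], compute_uv=False)

    if svxy[1] <= _RANK_TOL * max(svxy[0], 1.0):
        # pixels collinear in the image plane
        u = np.linalg.svd(centered[:, :2], compute_uv=True)[2][0]
        t = centered[:, :2] @ u
        env_flat = _upper_envelope_1d(t, z)
    elif sv3[2] <= _RANK_TOL * max(sv3[0], 1.0):
        # all points on one (non-vertical) plane: the hull is the plane
        env_flat = z.copy()
    else:
        try:
            hull = ConvexHull(pts)
        except QhullError:
            # near-degenerate cloud: fall back to the exact planar answer
            env_flat = z.copy()
        else:
            eq = hull.equations
            up = eq[:, 2] > 1e-12
            simplices = hull.simplices[up]
            eqs = eq[up]
            order = sorted(
                range(len(simplices)), key=lambda i: tuple(sorted(simplices[i]))
            )
            idx_img = np.full(mask.pixels.shape, -1, dtype=np.int64)
            idx_img[ys, xs] = np.arange(n)
            h, w = mask.pixels.shape
            for fi in order:
                tri = pts[simplices[fi]]
                a, b, c, off = eqs[fi]
                v0 = tri[1, :2] - tri[0, :2]
                v1 = tri[2, :2] - tri[0, :2]
                denom = v0[0] * v1[1] - v0[1] * v1[0]
                if abs(denom) < 1e-12:
                    continue
                c0 = max(int(np.floor(tri[:, 0].min())), 0)
                c1 = min(int(np.ceil(tri[:, 0].max())), w - 1)
                r0 = max(int(np.floor(tri[:, 1].min())), 0)
                r1 = min(int(np.ceil(tri[:, 1].max())), h - 1)
                sub = idx_img[r0:r1 + 1, c0:c1 + 1]
                flat = sub[sub >= 0]
                if flat.size == 0:
                    continue
                flat = flat[np.isnan(env_flat[flat])]
                if flat.size == 0:
                    continue
                px = xs[flat] - tri[0, 0]
                py = ys[flat] - tri[0, 1]
                l1 = (px * v1[1] - py * v1[0]) / denom
                l2 = (v0[0] * py - v0[1] * px) / denom
                inside = (l1 >= -_BARY_TOL) & (l2 >= -_BARY_TOL) & (l1 + l2 <= 1 + _BARY_TOL)
                if not inside.any():
                    continue
                sel = flat[inside]
                env_flat[sel] = -(a * xs[sel] + b * ys[sel] + off) / c
            rem = np.flatnonzero(np.isnan(env_flat))
            if rem.size:
                # numerical cracks between facets: exact min over facet planes
                planes = (
                    -(
                        eqs[:, 0, None] * xs[rem]
                        + eqs[:, 1, None] * ys[rem]
                        + eqs[:, 3, None]
                    )
                    / eqs[:, 2, None]
                )
                env_flat[rem] = planes.min(axis=0)

    env_flat = np.clip(env_flat, z.min(), z.max())
    env_flat = np.maximum(env_flat, z)  # hard upper-envelope guarantee
    surface = np.zeros_like(values)
    surface[ys, xs] = env_flat
    return CleanSurface(values=surface)


def loss_and_threshold(
    clean: CleanSurface,
    green_opened: GreenChannelImage,
    mask: ToothMask,
    params: HullParams = HullParams(),
) -> LossMap:
    """Loss = clean − opened image, with sub-threshold pixels zeroed.

    Pixels with loss strictly below ``threshold_level`` are set to zero;
    all others keep their raw value (a loss exactly at the threshold is
    retained).
    """
    g = np.asarray(green_opened.values, dtype=float)
    if clean.values.shape != g.shape or g.shape != mask.pixels.shape:
        raise ValueError("surface, image and mask dimensions must match")
    raw = np.clip(clean.values - g, 0.0, None)
    raw[~mask.pixels] = 0.0
    raw[raw < params.threshold_level] = 0.0
    return LossMap(
        values=raw,
        threshold_applied=True,
        method_tag="hull",
        threshold_level=float(params.threshold_level),
    )


def hull_metrics(loss: LossMap, clean: CleanSurface, mask: ToothMask) -> FluorosisMetrics:
    """Compute (Area_ch, ΔF_ch, ΔQ_ch) from the thresholded loss map.

    Pixels where the clean surface is zero are skipped with a count
    (division guard).  ΔQ_ch — the mean fractional loss over the whole
    tooth — equals Area_ch × ΔF_ch by construction.
    """
    if not loss.threshold_applied:
        raise ValueError("hull_metrics expects a thresholded loss map")
    n_mask = mask.n_pixels
    lesion = mask.pixels & (loss.values > 0)
    valid = clean.values > 0
    n_skipped = int((lesion & ~valid).sum())
    lesion_valid = lesion & valid
    n_lesion = int(lesion_valid.sum())
    area = n_lesion / n_mask
    if n_lesion:
        delta_f = float(np.mean(loss.values[lesion_valid] / clean.values[lesion_valid]))
    else:
        delta_f = 0.0
    return FluorosisMetrics(
        method_tag="hull",
        area=area,
        delta_f=delta_f,
        delta_q=area * delta_f,
        n_lesion_px=n_lesion,
        area_unit="fraction",
        n_skipped=n_skipped,
    )


def run_hull(
    green: GreenChannelImage, mask: ToothMask, params: HullParams = HullParams()
) -> tuple[FluorosisMetrics, dict]:
    """Full convex-hull pipeline for one tooth; returns metrics and intermediates."""
    opened = open_image(green, mask, params)
    clean = upper_hull_surface(opened, mask)
    loss = loss_and_threshold(clean, opened, mask, params)
    metrics = hull_metrics(loss, clean, mask)
    return metrics, {"opened": opened, "clean": clean, "loss": loss}
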