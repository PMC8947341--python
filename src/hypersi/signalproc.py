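"""Per-study noise estimation, thresholding, masking and normalization.

The silicon images carry Rayleigh-distributed background (the magnitude of
complex Gaussian receiver noise). Each study estimates its own background
from the four image corners — regions guaranteed to be away from the
subject — so day-to-day noise variation never leaks into the displayed
signal. Pixels below a fixed multiple of the mean corner background
(5× by default) are removed. Two normalizations follow: division by the
study's silicon-oil phantom reference (cancels scanner drift between
sessions), then division of the whole study set by the single universal
peak so the images can be compared as a set on one [0, 1] scale.

Noise statistics are always computed on the reconstructed magnitude image
*before* any masking or normalization: the corner patches define the
background and must not be zeroed by a subject-region mask.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .model import MagnitudeImage, NoiseStats, NormalizedSet, QuadROI

__all__ = [
    "corner_background",
    "threshold_denoise",
    "apply_roi_mask",
    "phantom_normalize",
    "set_normalize",
    "polygon_mask",
    "NoiseStats",
    "NormalizedSet",
    "QuadROI",
]


def corner_background(
    img: MagnitudeImage, corner_fraction: float = 0.125
) -> NoiseStats:
    """Pooled background statistics from four corner patches.

    Each patch spans ``round(corner_fraction · dim)`` pixels per axis
    (minimum 1); with the default fraction of 1/8 on a 256 × 256 image the
    patches are the canonical 32 × 32 corner sections. The mean and the
    sample (n−1) standard deviation are computed over the pooled pixels of
    all four patches.
    """
    if not 0 < corner_fraction <= 0.5:
        raise ValueError(
            f"corner_fraction must be in (0, 0.5], got {corner_fraction}"
        )
    rows, cols = img.shape
    pr = max(1, round(corner_fraction * rows))
    pc = max(1, round(corner_fraction * cols))
    px = img.pixels
    pooled = np.concatenate([
        px[:pr, :pc].ravel(),
        px[:pr, cols - pc:].ravel(),
        px[rows - pr:, :pc].ravel(),
        px[rows - pr:, cols - pc:].ravel(),
    ])
    n = pooled.size
    mean_bg = float(pooled.mean())
    std_bg = float(pooled.std(ddof=1)) if n > 1 else 0.0
    return NoiseStats(mean_bg=mean_bg, std_bg=std_bg, n_pixels=int(n))


def threshold_denoise(
    img: MagnitudeImage, noise: NoiseStats, multiplier: float = 5.0
) -> MagnitudeImage:
    """Zero every pixel below ``multiplier × mean background``.

    The comparison is strict: a pixel exactly at the threshold survives.
    Surviving pixels are unchanged, so the operation is idempotent for a
    fixed :class:`NoiseStats`.
    """
    if multiplier < 0:
        raise ValueError(f"threshold multiplier must be >= 0, got {multiplier}")
    cutoff = multiplier * noise.mean_bg
    out = np.where(img.pixels < cutoff, 0.0, img.pixels)
    return img.evolve(out, "denoised")


def polygon_mask(shape: tuple, vertices) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside a polygon.

    Even–odd (ray crossing) rule on pixel centers ``(col+0.5, row+0.5)``;
    pixels whose center falls exactly on the boundary count as inside.
    """
    rows, cols = shape
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    py = np.arange(rows, dtype=float)[:, None] + 0.5
    px = np.arange(cols, dtype=float)[None, :] + 0.5
    inside = np.zeros((rows, cols), dtype=bool)
    on_edge = np.zeros((rows, cols), dtype=bool)
    eps = 1e-9
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        straddles = (y1 <= py) != (y2 <= py)  # broadcasts to (rows, 1)
        if np.any(straddles):
            # x of the edge at each ray height; y2 != y1 wherever straddles
            dy = y2 - y1 if y2 != y1 else 1.0
            xint = x1 + (py - y1) * (x2 - x1) / dy
            inside ^= straddles & (px < xint)
        # boundary test: point on the closed segment
        ex, ey = x2 - x1, y2 - y1
        seg_len2 = ex * ex + ey * ey
        if seg_len2 == 0:
            on_edge |= (np.abs(px - x1) < eps) & (np.abs(py - y1) < eps)
            continue
        cross = (px - x1) * ey - (py - y1) * ex
        t = ((px - x1) * ex + (py - y1) * ey) / seg_len2
        on_edge |= (np.abs(cross) <= eps * np.sqrt(seg_len2)) & (t >= -eps) & (t <= 1 + eps)
    return inside | on_edge


def apply_roi_mask(img: MagnitudeImage, roi: QuadROI) -> MagnitudeImage:
    """Zero every pixel whose center falls outside the quadrangle ROI.

    Used to negate signal from outside the subject (syringe tip, spilled
    particles) before peak finding and comparison.
    """
    mask = polygon_mask(img.shape, roi.as_array())
    out = np.where(mask, img.pixels, 0.0)
    return img.evolve(out, "masked")


def phantom_normalize(img: MagnitudeImage, reference: float) -> MagnitudeImage:
    """Divide the image by the study's silicon-oil phantom reference.

    Scaling the acquired signal and the phantom by a common scanner drift
    factor leaves the normalized image unchanged — the stated purpose of
    the phantom scan.
    """
    if not reference > 0:
        raise ValueError(f"phantom reference must be > 0, got {reference}")
    return img.evolve(img.pixels / float(reference), "phantom_normalized")


def set_normalize(images: list) -> NormalizedSet:
    """Divide every study by the single peak across the whole set.

    Division by one common constant preserves every between-study intensity
    ratio; after it the global maximum over the set is exactly 1, so the
    images share one display scale.
    """
    if not images:
        raise ValidationError("set_normalize needs at least one image")
    peaks = [float(im.pixels.max()) for im in images]
    universal = max(peaks)
    if universal <= 0:
        raise ValidationError(
            "all images in the set are zero; cannot determine a universal peak"
        )
    normalized = [
        im.evolve(im.pixels / universal, "set_normalized") for im in images
    ]
    return NormalizedSet(
        images=normalized, universal_peak=universal, per_study_peaks=peaks
    )
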