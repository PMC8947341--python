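"""SNR/CNR quantification over circular ROIs and cohort ANOVA.

Two ratios summarize how well the processed silicon signal registers to the
tumor sites:

* ``SNR = |mu_t − mu_b| / sigma_b`` — tumor ROI against an equal-sized
  circle shifted to a non-tumor region;
* ``CNR = |mu_t − mu_m| / sigma_m`` — tumor ROI against the whole torso
  excluding the tumor regions.

ROIs are 7 mm diameter circles by convention (placed from the anatomical
image and prior colonoscopy in the original workflow; from the manifest
here). Both ratios are invariant under any positive affine rescaling of the
image, so the normalization stage they are computed on does not matter.
Cohorts are compared with one-way ANOVA built from explicit sums of squares
(auditable against hand computation), with the p-value from the F survival
function.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sstats

from .errors import UndefinedStatisticError, ValidationError
from .model import CircleROI, CohortComparison, MagnitudeImage, QuantResult

__all__ = [
    "circle_mask",
    "snr",
    "cnr",
    "quantify_study",
    "cohort_anova",
    "CircleROI",
    "QuantResult",
    "CohortComparison",
]


def circle_mask(
    shape: tuple, spacing_mm: tuple, roi: CircleROI
) -> np.ndarray:
    """Rasterize a circular ROI: pixel centers within diameter/2 (in mm).

    The center is given in pixel coordinates; distances are measured in mm
    through the per-axis pixel spacing, so the mask is correct on
    anisotropic grids too.
    """
    rows, cols = shape
    cx, cy = roi.center
    if not (0 <= cx <= cols and 0 <= cy <= rows):
        raise ValidationError(
            f"ROI center {roi.center} outside image bounds {(cols, rows)}"
        )
    sy, sx = float(spacing_mm[0]), float(spacing_mm[1])
    py = (np.arange(rows, dtype=float)[:, None] + 0.5 - cy) * sy
    px = (np.arange(cols, dtype=float)[None, :] + 0.5 - cx) * sx
    mask = px * px + py * py <= (roi.diameter_mm / 2.0) ** 2
    if not mask.any():
        raise ValidationError(
            f"ROI at {roi.center} with diameter {roi.diameter_mm} mm covers "
            "no pixel centers"
        )
    return mask


def _roi_stats(values: np.ndarray) -> tuple[float, float]:
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, std


def snr(
    img: MagnitudeImage, tumor: CircleROI, background: CircleROI
) -> tuple[float, float, float, float]:
    """Signal-to-noise ratio: returns ``(mu_t, mu_b, sigma_b, snr)``.

    ``background`` is an equal-area circle shifted away from the tumors; the
    two ROIs must not overlap. Zero background variance makes the ratio
    undefined and raises.
    """
    tmask = circle_mask(img.shape, img.pixel_spacing_mm, tumor)
    bmask = circle_mask(img.shape, img.pixel_spacing_mm, background)
    if np.any(tmask & bmask):
        raise ValidationError("tumor and background ROIs overlap")
    mu_t = float(img.pixels[tmask].mean())
    mu_b, sigma_b = _roi_stats(img.pixels[bmask])
    if sigma_b <= 0:
        raise UndefinedStatisticError(
            "background ROI has zero variance; SNR is undefined"
        )
    return mu_t, mu_b, sigma_b, abs(mu_t - mu_b) / sigma_b


def cnr(
    img: MagnitudeImage, tumor: CircleROI, body_mask_minus_tumors: np.ndarray
) -> tuple[float, float, float]:
    """Contrast-to-noise ratio: returns ``(mu_m, sigma_m, cnr)``.

    ``body_mask_minus_tumors`` is the torso mask with every tumor ROI pixel
    already removed; overlap with the tumor ROI is a validation error.
    """
    tmask = circle_mask(img.shape, img.pixel_spacing_mm, tumor)
    body = np.asarray(body_mask_minus_tumors, dtype=bool)
    if body.shape != img.shape:
        raise ValidationError("body mask shape does not match the image")
    if np.any(body & tmask):
        raise ValidationError("body mask still contains tumor ROI pixels")
    if not body.any():
        raise ValidationError("body mask is empty")
    mu_t = float(img.pixels[tmask].mean())
    mu_m, sigma_m = _roi_stats(img.pixels[body])
    if sigma_m <= 0:
        raise UndefinedStatisticError(
            "torso region has zero variance; CNR is undefined"
        )
    return mu_m, sigma_m, abs(mu_t - mu_m) / sigma_m


def quantify_study(
    img: MagnitudeImage,
    study_id: str,
    tumor_rois: tuple,
    background: CircleROI,
    body_mask: np.ndarray,
) -> QuantResult:
    """Full per-study quantification over possibly several tumor sites.

    ``mu_t`` pools the pixels of all tumor ROIs (the mean intensity at the
    position of the tumors); the SNR background is the supplied shifted
    circle and the CNR reference is the torso mask minus every tumor ROI.
    """
    if not tumor_rois:
        raise ValidationError(f"study {study_id!r}: no tumor ROIs supplied")
    tmask = np.zeros(img.shape, dtype=bool)
    for roi in tumor_rois:
        tmask |= circle_mask(img.shape, img.pixel_spacing_mm, roi)
    bmask = circle_mask(img.shape, img.pixel_spacing_mm, background)
    if np.any(tmask & bmask):
        raise ValidationError(
            f"study {study_id!r}: background ROI overlaps a tumor ROI"
        )
    body = np.asarray(body_mask, dtype=bool) & ~tmask
    if not body.any():
        raise ValidationError(f"study {study_id!r}: empty torso-minus-tumor mask")

    mu_t = float(img.pixels[tmask].mean())
    mu_b, sigma_b = _roi_stats(img.pixels[bmask])
    mu_m, sigma_m = _roi_stats(img.pixels[body])
    if sigma_b <= 0:
        raise UndefinedStatisticError(
            f"study {study_id!r}: zero background variance, SNR undefined"
        )
    if sigma_m <= 0:
        raise UndefinedStatisticError(
            f"study {study_id!r}: zero torso variance, CNR undefined"
        )
    return QuantResult(
        study_id=study_id,
        snr=abs(mu_t - mu_b) / sigma_b,
        cnr=abs(mu_t - mu_m) / sigma_m,
        mu_t=mu_t,
        mu_b=mu_b,
        sigma_b=sigma_b,
        mu_m=mu_m,
        sigma_m=sigma_m,
    )


def cohort_anova(groups: list, labels: list | None = None) -> CohortComparison:
    """One-way ANOVA from explicit between/within sums of squares.

    ``groups`` is a list of per-cohort value lists (each nonempty, at least
    two groups, more observations than groups). The F statistic is
    ``(SSB/dfB) / (SSW/dfW)`` and the p-value its survival probability
    under F(dfB, dfW). If every observation is identical the statistic is
    0/0 and undefined.
    """
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValidationError("every ANOVA group needs at least one value")
    n_total = sum(g.size for g in groups)
    k = len(groups)
    if n_total <= k:
        raise ValidationError(
            "ANOVA needs more observations than groups (positive within df)"
        )
    grand = sum(g.sum() for g in groups) / n_total
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df = (k - 1, n_total - k)
    if ssw == 0.0:
        if ssb == 0.0:
            raise UndefinedStatisticError(
                "all values identical across groups; F is 0/0"
            )
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (ssb / df[0]) / (ssw / df[1])
        p_value = float(_sstats.f.sf(f_stat, df[0], df[1]))
    return CohortComparison(
        group_labels=list(labels),
        group_values=[g.tolist() for g in groups],
        f_stat=float(f_stat),
        p_value=p_value,
        df=df,
    )
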