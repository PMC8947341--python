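"""In-memory batch orchestration of the per-study and cross-study chain.

Per study: reconstruct the zero-filled silicon k-space, estimate corner
background on the unmasked reconstruction, apply the subject-region mask,
threshold at a multiple of the mean background, divide by the phantom
reference. Across studies: divide everything by the universal peak. The
thresholded chain is the *display* image; quantification uses the same
chain without the threshold step (still masked, phantom- and
set-normalized), because a hard threshold zeroes the background and makes
the SNR/CNR denominators degenerate — the ratios themselves are invariant
to the common normalization scale.

The disk-facing CLI wraps these functions; tests and the acceptance script
drive them directly on in-memory studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import quantify as q
from . import recon, signalproc
from .errors import ValidationError
from .model import (
    DEFAULT_PARAMETERS,
    CircleROI,
    KSpace,
    MagnitudeImage,
    NoiseStats,
    PolygonROI,
    QuadROI,
    QuantResult,
)


@dataclass
class StudyInput:
    """Everything the silicon chain needs for one study."""

    study_id: str
    cohort: str
    kspace: KSpace
    phantom_reference: float
    roi_quad: Optional[QuadROI] = None
    tumor_rois: tuple = ()
    nontumor_rois: tuple = ()
    body_roi: Optional[PolygonROI] = None


@dataclass
class StudyProcessed:
    """Per-study outputs of the silicon chain (before set normalization)."""

    study_id: str
    cohort: str
    noise: NoiseStats
    display: MagnitudeImage      # masked → thresholded → phantom-normalized
    quant_image: MagnitudeImage  # masked → phantom-normalized (no threshold)
    peak: float = 0.0            # display peak before set normalization


@dataclass
class SetProcessed:
    """The full batch after cross-study normalization."""

    studies: list
    universal_peak: float
    quant_results: dict = field(default_factory=dict)
    cohort_snr: object = None
    cohort_cnr: object = None


def process_silicon_study(
    study: StudyInput,
    target_shape: tuple,
    threshold_multiplier: float = DEFAULT_PARAMETERS["threshold_multiplier"],
    corner_fraction: float = DEFAULT_PARAMETERS["corner_fraction"],
) -> StudyProcessed:
    """Run the per-study silicon chain up to phantom normalization."""
    k = recon.zero_fill(study.kspace, target_shape[0], target_shape[1])
    img = recon.reconstruct(k)
    noise = signalproc.corner_background(img, corner_fraction)
    if study.roi_quad is not None:
        img = signalproc.apply_roi_mask(img, study.roi_quad)
    display = signalproc.threshold_denoise(img, noise, threshold_multiplier)
    display = signalproc.phantom_normalize(display, study.phantom_reference)
    quant_img = signalproc.phantom_normalize(img, study.phantom_reference)
    return StudyProcessed(
        study_id=study.study_id,
        cohort=study.cohort,
        noise=noise,
        display=display,
        quant_image=quant_img,
    )


def process_study_set(
    studies: list,
    target_shape: tuple,
    threshold_multiplier: float = DEFAULT_PARAMETERS["threshold_multiplier"],
    corner_fraction: float = DEFAULT_PARAMETERS["corner_fraction"],
) -> SetProcessed:
    """Process every study, then normalize the whole set by its one peak."""
    if not studies:
        raise ValidationError("no studies to process")
    processed = [
        process_silicon_study(
            s, target_shape, threshold_multiplier, corner_fraction
        )
        for s in studies
    ]
    norm = signalproc.set_normalize([p.display for p in processed])
    for p, img, peak in zip(processed, norm.images, norm.per_study_peaks):
        p.display = img
        p.peak = peak
        # same common scale for the quantification image
        p.quant_image = p.quant_image.evolve(
            p.quant_image.pixels / norm.universal_peak, "set_normalized"
        )
    return SetProcessed(studies=processed, universal_peak=norm.universal_peak)


def quantify_set(result: SetProcessed, inputs: list) -> SetProcessed:
    """Add per-study SNR/CNR and cohort ANOVAs to a processed set.

    Studies lacking ROI annotations (tumor circles, a shifted non-tumor
    circle and a torso polygon) are skipped. ANOVAs run when at least two
    cohorts have quantified studies.
    """
    by_id = {s.study_id: s for s in inputs}
    for p in result.studies:
        src = by_id[p.study_id]
        if not (src.tumor_rois and src.nontumor_rois and src.body_roi):
            continue
        body = signalproc.polygon_mask(
            p.quant_image.shape, src.body_roi.as_array()
        )
        result.quant_results[p.study_id] = q.quantify_study(
            p.quant_image,
            p.study_id,
            src.tumor_rois,
            src.nontumor_rois[0],
            body,
        )
    groups_snr, groups_cnr, labels = [], [], []
    for cohort in _cohort_order(result):
        vals = [
            result.quant_results[p.study_id]
            for p in result.studies
            if p.cohort == cohort and p.study_id in result.quant_results
        ]
        if vals:
            labels.append(cohort)
            groups_snr.append([v.snr for v in vals])
            groups_cnr.append([v.cnr for v in vals])
    if len(labels) >= 2 and sum(len(g) for g in groups_snr) > len(labels):
        result.cohort_snr = q.cohort_anova(groups_snr, labels)
        result.cohort_cnr = q.cohort_anova(groups_cnr, labels)
    return result


def _cohort_order(result: SetProcessed) -> list:
    seen = []
    for p in result.studies:
        if p.cohort not in seen:
            seen.append(p.cohort)
    return seen


def argmax_position_mm(img: MagnitudeImage, fov_mm: tuple,
                       coarse_shape: tuple) -> tuple:
    """Physical (x_mm, y_mm) of the image's brightest pixel.

    Accounts for the fixed sub-pixel offset of zero-fill interpolation
    (fine index r·p corresponds to coarse pixel p).
    """
    i, j = np.unravel_index(int(np.argmax(img.pixels)), img.shape)
    rows, cols = img.shape
    y = recon.zerofilled_coord_to_mm(i + 0.5, fov_mm[0], coarse_shape[0], rows)
    x = recon.zerofilled_coord_to_mm(j + 0.5, fov_mm[1], coarse_shape[1], cols)
    return (x, y)
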