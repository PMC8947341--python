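"""Anatomical display preparation and silicon-on-anatomy fusion.

The proton anatomical image and the silicon image are acquired back to back
without moving the subject, so spatial registration is the identity once the
silicon k-space has been zero-filled to the anatomical grid. Display
preparation saturates the top and bottom intensity tails of the chosen
anatomical slice (1% per tail by default) to stretch contrast, then blends
the processed silicon map over the grayscale anatomy with
intensity-proportional transparency: where there is no silicon signal the
anatomy shows through unchanged.
"""

from __future__ import annotations

import math

import numpy as np
from matplotlib import colormaps

from .errors import RegistrationError, ValidationError
from .model import AnatomicalVolume, MagnitudeImage, OverlayImage


def select_slice(vol: AnatomicalVolume, index: int) -> MagnitudeImage:
    """Extract one anatomical slice with the volume's in-plane spacing."""
    if not 0 <= index < vol.n_slices:
        raise ValueError(
            f"slice index {index} out of range [0, {vol.n_slices})"
        )
    return MagnitudeImage(vol.slices[index], vol.pixel_spacing_mm)


def contrast_stretch(img: MagnitudeImage, tail_percent: float = 1.0) -> MagnitudeImage:
    """Saturate the top and bottom intensity tails and rescale to [0, 1].

    With ``n`` pixels and ``k = ceil(tail_percent/100 · n)``, the k-th
    smallest value maps to 0 and the k-th largest to 1; values between are
    linear, values beyond are clamped. ``tail_percent = 0`` is a pure
    min–max rescale. A constant image maps to all 0.5 (there is no contrast
    to stretch).
    """
    if not 0 <= tail_percent < 50:
        raise ValueError(
            f"tail_percent must be in [0, 50), got {tail_percent}"
        )
    flat = np.sort(img.pixels, axis=None)
    n = flat.size
    k = math.ceil(tail_percent / 100.0 * n)
    if k == 0:
        lo, hi = flat[0], flat[-1]
    else:
        lo, hi = flat[k - 1], flat[n - k]
    if lo == hi:
        out = np.full(img.shape, 0.5)
    else:
        out = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return img.evolve(out, "contrast_stretched")


def composite_overlay(
    anat: MagnitudeImage,
    si: MagnitudeImage,
    alpha_max: float = 0.7,
    colormap_name: str = "hot",
    source_ids: tuple = ("anatomical", "silicon"),
) -> OverlayImage:
    """Fuse a processed silicon map onto a grayscale anatomical slice.

    Per pixel, ``rgb = (1 − a)·gray(anat) + a·colormap(si)`` with
    ``a = alpha_max · si``. Both inputs must already share one grid (the
    silicon image zero-filled to the anatomical matrix) and lie in [0, 1];
    the anatomical slice is expected to have been contrast-stretched. The
    blend is a convex combination, so all output channels stay in [0, 1],
    and it is local: one silicon pixel affects exactly one output pixel.
    """
    if anat.shape != si.shape:
        raise RegistrationError(
            f"anatomical {anat.shape} and silicon {si.shape} grids differ; "
            "zero-fill the silicon k-space to the anatomical matrix first"
        )
    if not 0 <= alpha_max <= 1:
        raise ValueError(f"alpha_max must be in [0, 1], got {alpha_max}")
    if si.pixels.max() > 1.0:
        raise ValidationError(
            "silicon image exceeds 1; set-normalize before overlaying"
        )
    if anat.pixels.max() > 1.0:
        raise ValidationError(
            "anatomical slice exceeds 1; contrast-stretch before overlaying"
        )
    cmap = colormaps[colormap_name]
    colored = np.asarray(cmap(si.pixels))[..., :3]
    alpha = alpha_max * si.pixels
    gray = np.repeat(anat.pixels[..., np.newaxis], 3, axis=2)
    rgb = (1.0 - alpha)[..., np.newaxis] * gray + alpha[..., np.newaxis] * colored
    return OverlayImage(
        rgb=rgb,
        alpha_map=alpha,
        colormap_name=colormap_name,
        source_ids=tuple(source_ids),
    )


def overlay_to_uint8(overlay: OverlayImage) -> np.ndarray:
    """Quantize an overlay to 8-bit RGB with the fixed round(v·255) rule."""
    return np.round(np.clip(overlay.rgb, 0.0, 1.0) * 255.0).astype(np.uint8)
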