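"""Magnitude reconstruction from k-space, with zero-fill interpolation.

The acquisition matrix for the hyperpolarized silicon channel is small
(nominally 32 × 32, a concession to the transient hyperpolarized signal);
to co-register it with the 256 × 256 anatomical image, the k-space matrix is
symmetrically padded with zeros ("zero-filled") before the inverse Fourier
transform. Zero-filling is periodic-sinc interpolation: it refines the pixel
grid without adding information and leaves the field of view unchanged.

Conventions (fixed so outputs are bit-reproducible):

* k-space is stored DC-at-center; the transform shifts DC to the corner
  (``ifftshift``), applies the inverse FFT with 1/(rows·cols)
  normalization, and shifts the image back to centered form (``fftshift``);
* zero-fill pads ``ceil(extra/2)`` rows/cols before the data block and
  ``floor(extra/2)`` after, so the Nyquist row of an even-sized input stays
  with the leading block;
* the magnitude (modulus), not the real part, is taken after the inverse
  transform — downstream intensity statistics assume nonnegative images and
  phase is never used.

With these conventions, fine-grid pixel ``r·p`` of a zero-filled
reconstruction (upsampling factor ``r``) coincides with coarse pixel ``p``
up to the constant factor (n·m)/(N·M); :func:`mm_to_zerofilled_coord`
exposes the resulting mm ↔ fine-pixel mapping.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .model import KSpace, MagnitudeImage


def centered_ifft2(k: np.ndarray) -> np.ndarray:
    """Inverse 2D DFT of a DC-centered matrix, returning a centered image."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k)))


def centered_fft2(img: np.ndarray) -> np.ndarray:
    """Forward 2D DFT of a centered image, returning a DC-centered matrix.

    Exact inverse of :func:`centered_ifft2`; used by the synthetic study
    generator so noiseless round trips are exact.
    """
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))


def zero_fill(k: KSpace, target_rows: int, target_cols: int) -> KSpace:
    """Pad a DC-centered k-space matrix with zeros to a larger grid.

    The input coefficients are kept centered on the target grid; the field
    of view is unchanged (the reconstructed pixel spacing becomes finer).
    Energy (sum of |k|²) is preserved exactly since only zeros are added.
    """
    rows, cols = k.shape
    if target_rows < rows or target_cols < cols:
        raise ValueError(
            f"zero_fill target {(target_rows, target_cols)} is smaller than "
            f"the input {(rows, cols)}; cropping is not supported"
        )
    extra_r = target_rows - rows
    extra_c = target_cols - cols
    before_r = (extra_r + 1) // 2
    before_c = (extra_c + 1) // 2
    padded = np.pad(
        k.data,
        ((before_r, extra_r - before_r), (before_c, extra_c - before_c)),
    )
    return KSpace(padded, k.nucleus, k.fov_mm, dict(k.meta))


def reconstruct(k: KSpace) -> MagnitudeImage:
    """Reconstruct the magnitude image of a DC-centered k-space matrix.

    Pixel spacing is ``fov_mm / matrix dims``; the output carries the
    ``reconstructed`` provenance flag.
    """
    img = np.abs(centered_ifft2(k.data))
    rows, cols = img.shape
    spacing = (k.fov_mm[0] / rows, k.fov_mm[1] / cols)
    return MagnitudeImage(img, spacing, frozenset({"reconstructed"}))


def phantom_reference(phantom_image: MagnitudeImage) -> float:
    """Scalar reference from a silicon-oil phantom acquisition.

    The phantom is scanned just before particle injection; dividing each
    study by its phantom signal cancels day-to-day receiver drift. The
    reference is the maximum pixel magnitude of the phantom image.
    """
    ref = float(phantom_image.pixels.max())
    if ref <= 0:
        raise ValidationError(
            "phantom image is all zero; the reference must be positive"
        )
    return ref


def mm_to_zerofilled_coord(
    x_mm: float, fov_mm: float, coarse_n: int, fine_n: int
) -> float:
    """Map a physical mm position to pixel coordinates on a zero-filled grid.

    A coarse acquisition of ``coarse_n`` samples over ``fov_mm`` has pixel
    centers at ``(p + 0.5) · fov/coarse_n``. After zero-filling to
    ``fine_n`` samples, fine index ``r·p`` (with ``r = fine_n/coarse_n``)
    reproduces coarse pixel ``p``, so the fine grid is offset by
    ``(r − 1)/2`` fine pixels relative to naive center-of-pixel coordinates.
    Returns the (x or y) pixel coordinate such that a point at ``x_mm``
    lands at that coordinate on the displayed fine image.
    """
    fine_spacing = fov_mm / fine_n
    r = fine_n / coarse_n
    return x_mm / fine_spacing - (r - 1.0) / 2.0


def zerofilled_coord_to_mm(
    coord: float, fov_mm: float, coarse_n: int, fine_n: int
) -> float:
    """Inverse of :func:`mm_to_zerofilled_coord`."""
    fine_spacing = fov_mm / fine_n
    r = fine_n / coarse_n
    return (coord + (r - 1.0) / 2.0) * fine_spacing
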