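"""Domain containers shared by every pipeline stage.

The pipeline's coordinate convention, applied everywhere:

* image indices are 0-based ``(row, col)`` with row 0 the top of the
  displayed image;
* a pixel's geometric center is at ``(x, y) = (col + 0.5, row + 0.5)`` in
  pixel units, and mm coordinates are pixel units times the pixel spacing;
* region-of-interest vertices and centers are ``(x, y)`` points in pixel
  coordinates of the image they are drawn on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError

#: Allowed experimental cohorts: MUC1-targeted particles, tumors lacking the
#: antigen (biological), untargeted PEG-only particles (chemical), and
#: antigen pre-blocked animals.
COHORTS = ("targeted", "biological_control", "chemical_control", "preblocked")

#: Allowed nucleus labels for acquisitions.
NUCLEI = ("1H", "29Si")


def _as_finite_array(data, dtype, name: str) -> np.ndarray:
    arr = np.ascontiguousarray(data, dtype=dtype)
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite entries")
    return arr


@dataclass(eq=False)
class KSpace:
    """A complex 2D acquisition matrix in the spatial-frequency domain.

    ``data`` is stored DC-at-center (the zero-frequency coefficient sits at
    index ``(rows // 2, cols // 2)``). ``fov_mm`` is the field of view the
    matrix encodes; zero-filling refines the reconstructed pixel spacing but
    never changes the FOV.
    """

    data: np.ndarray
    nucleus: str
    fov_mm: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = _as_finite_array(self.data, np.complex128, "k-space data")
        if self.data.ndim != 2 or min(self.data.shape) < 2:
            raise ValidationError(
                f"k-space must be 2D with both dims >= 2, got shape {self.data.shape}"
            )
        if self.nucleus not in NUCLEI:
            raise ValidationError(
                f"unknown nucleus {self.nucleus!r}; allowed: {NUCLEI}"
            )
        self.fov_mm = (float(self.fov_mm[0]), float(self.fov_mm[1]))
        if min(self.fov_mm) <= 0:
            raise ValidationError(f"fov_mm must be positive, got {self.fov_mm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(eq=False)
class MagnitudeImage:
    """A nonnegative real 2D image with pixel spacing in mm.

    ``provenance`` records which processing stages produced the image
    (``reconstructed``, ``masked``, ``denoised``, ``phantom_normalized``,
    ``set_normalized``); stages only ever add flags.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    provenance: frozenset = frozenset()

    def __post_init__(self):
        self.pixels = _as_finite_array(self.pixels, np.float64, "image pixels")
        if self.pixels.ndim != 2:
            raise ValidationError(f"image must be 2D, got shape {self.pixels.shape}")
        if np.any(self.pixels < 0):
            raise ValidationError("magnitude image has negative pixels")
        self.pixel_spacing_mm = (
            float(self.pixel_spacing_mm[0]),
            float(self.pixel_spacing_mm[1]),
        )
        if min(self.pixel_spacing_mm) <= 0:
            raise ValidationError(
                f"pixel spacing must be positive, got {self.pixel_spacing_mm}"
            )
        self.provenance = frozenset(self.provenance)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def evolve(self, pixels: np.ndarray, *new_flags: str) -> "MagnitudeImage":
        """Return a copy with new pixel values and additional provenance."""
        return MagnitudeImage(
            pixels, self.pixel_spacing_mm, self.provenance | set(new_flags)
        )


@dataclass(eq=False)
class AnatomicalVolume:
    """A multi-slice proton anatomical acquisition.

    ``slices`` has shape ``(n_slices, rows, cols)``, ordered along the
    file's third axis.
    """

    slices: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float

    def __post_init__(self):
        self.slices = _as_finite_array(self.slices, np.float64, "anatomical slices")
        if self.slices.ndim == 2:
            self.slices = self.slices[np.newaxis]
        if self.slices.ndim != 3:
            raise ValidationError(
                f"anatomical stack must be 2D or 3D, got shape {self.slices.shape}"
            )
        self.pixel_spacing_mm = (
            float(self.pixel_spacing_mm[0]),
            float(self.pixel_spacing_mm[1]),
        )
        self.slice_thickness_mm = float(self.slice_thickness_mm)
        if min(self.pixel_spacing_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValidationError("anatomical spacing/thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]


# ---------------------------------------------------------------------------
# Regions of interest
# ---------------------------------------------------------------------------

def _segments_properly_cross(p1, p2, q1, q2) -> bool:
    """True if open segments p1p2 and q1q2 cross at an interior point."""
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(q1, q2, p1)
    d2 = orient(q1, q2, p2)
    d3 = orient(p1, p2, q1)
    d4 = orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)) and all(
        d != 0 for d in (d1, d2, d3, d4)
    )


def polygon_area(vertices) -> float:
    """Signed shoelace area of a polygon given as (x, y) vertices."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class QuadROI:
    """A four-vertex simple polygon restricting analysis to the subject.

    Typical use: exclude the injection syringe and spilled particles outside
    the torso from peak finding and normalization.
    """

    vertices: tuple  # 4 ordered (x, y) pairs in pixel coordinates

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) != 4:
            raise ValidationError(f"quad ROI needs 4 vertices, got {len(verts)}")
        if abs(polygon_area(verts)) == 0.0:
            raise ValidationError("quad ROI has zero area")
        # reject self-intersecting (bow-tie) quadrangles
        if _segments_properly_cross(verts[0], verts[1], verts[2], verts[3]) or \
           _segments_properly_cross(verts[1], verts[2], verts[3], verts[0]):
            raise ValidationError("quad ROI is self-intersecting")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


@dataclass(frozen=True)
class CircleROI:
    """A circular ROI: center in pixel coordinates, diameter in mm."""

    center: tuple  # (x, y) pixel coordinates
    diameter_mm: float

    def __post_init__(self):
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
        object.__setattr__(self, "diameter_mm", float(self.diameter_mm))
        if self.diameter_mm <= 0:
            raise ValidationError(f"ROI diameter must be positive, got {self.diameter_mm}")


@dataclass(frozen=True)
class PolygonROI:
    """A free polygon ROI (>= 3 vertices), e.g. the torso outline."""

    vertices: tuple

    def __post_init__(self):
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise ValidationError("polygon ROI needs at least 3 vertices")
        if abs(polygon_area(verts)) == 0.0:
            raise ValidationError("polygon ROI has zero area")
        object.__setattr__(self, "vertices", verts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)


# ---------------------------------------------------------------------------
# Study bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyRecord:
    """One imaging session as listed in the manifest."""

    study_id: str
    cohort: str
    silicon_path: str
    anatomical_path: str
    phantom_reference: float
    display_slice: int
    roi_quad: Optional[QuadROI] = None
    tumor_rois: tuple = ()
    nontumor_rois: tuple = ()
    body_roi: Optional[PolygonROI] = None

    def __post_init__(self):
        if self.cohort not in COHORTS:
            raise ValidationError(
                f"study {self.study_id!r}: unknown cohort {self.cohort!r}; "
                f"allowed values: {', '.join(COHORTS)}"
            )
        if not self.phantom_reference > 0:
            raise ValidationError(
                f"study {self.study_id!r}: phantom_reference must be > 0, "
                f"got {self.phantom_reference}"
            )
        object.__setattr__(self, "phantom_reference", float(self.phantom_reference))
        object.__setattr__(self, "display_slice", int(self.display_slice))
        object.__setattr__(self, "tumor_rois", tuple(self.tumor_rois))
        object.__setattr__(self, "nontumor_rois", tuple(self.nontumor_rois))


#: Built-in processing parameters; the values the workflow was designed
#: around (threshold multiple of the mean corner background, display tail
#: saturation per side, corner patch size as a fraction of each image dim).
DEFAULT_PARAMETERS = {
    "threshold_multiplier": 5.0,
    "tail_percent": 1.0,
    "corner_fraction": 0.125,
    "alpha_max": 0.7,
    "colormap": "hot",
}


@dataclass(frozen=True)
class Manifest:
    """The batch configuration: studies plus processing parameter defaults."""

    studies: tuple
    defaults: dict = field(default_factory=lambda: dict(DEFAULT_PARAMETERS))

    def __post_init__(self):
        object.__setattr__(self, "studies", tuple(self.studies))
        if not self.studies:
            raise ValidationError("manifest lists no studies (at least one required)")
        ids = [s.study_id for s in self.studies]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValidationError(f"duplicate study_id values: {dupes}")


# ---------------------------------------------------------------------------
# Statistics containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseStats:
    """Pooled background statistics from the four image corners."""

    mean_bg: float
    std_bg: float
    n_pixels: int

    def __post_init__(self):
        if not (np.isfinite(self.mean_bg) and np.isfinite(self.std_bg)):
            raise ValidationError("noise statistics must be finite")
        if self.mean_bg < 0 or self.std_bg < 0:
            raise ValidationError("noise statistics must be nonnegative")


@dataclass(eq=False)
class NormalizedSet:
    """A set of studies rescaled by the single peak across all of them.

    ``per_study_peaks[i]`` is image *i*'s maximum before division (zero for
    a study whose every pixel was removed by denoising);
    ``universal_peak`` is the maximum of those peaks. After division the
    global maximum over the set is exactly 1.
    """

    images: list
    universal_peak: float
    per_study_peaks: list


@dataclass(frozen=True)
class QuantResult:
    """Per-study SNR/CNR with the underlying ROI means and deviations.

    SNR = |mu_t - mu_b| / sigma_b over the tumor and a shifted non-tumor
    circle; CNR = |mu_t - mu_m| / sigma_m against the torso excluding the
    tumor regions. Intensities are in normalized (unitless) display units.
    """

    study_id: str
    snr: float
    cnr: float
    mu_t: float
    mu_b: float
    sigma_b: float
    mu_m: float
    sigma_m: float


@dataclass(eq=False)
class CohortComparison:
    """One-way ANOVA across cohorts of a per-study statistic."""

    group_labels: list
    group_values: list
    f_stat: float
    p_value: float
    df: tuple


@dataclass(eq=False)
class OverlayImage:
    """A fused silicon-on-anatomy display image.

    ``rgb`` is H×W×3 in [0, 1]; ``alpha_map`` is the per-pixel blend weight
    actually applied to the silicon colormap layer.
    """

    rgb: np.ndarray
    alpha_map: np.ndarray
    colormap_name: str
    source_ids: tuple
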