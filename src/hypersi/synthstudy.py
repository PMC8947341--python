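"""Synthetic dual-nuclei study generation.

No animal imaging data are distributed with this package, so every pipeline
stage is exercised on generated studies that reproduce the *structure* of
the real acquisitions: a torso-shaped multi-slice proton volume; a sparse
silicon image made of Gaussian tumor foci inside the torso plus the two
classic out-of-body confounders (a bright syringe-tip beacon and a particle
spill); Rayleigh-distributed magnitude background (complex Gaussian noise
added in k-space — the correct MR noise model); and optional symmetric hard
clipping of the k-space channels emulating RF/ADC overflow.

Cohort structure mirrors the experimental design: a targeted cohort with
the planted tumor amplitude and three control cohorts (biological,
chemical, pre-blocked) with tumor amplitude zero — the pipeline sees
intensity, not biology — while noise, beacon, spill and a per-study
lognormal scanner-drift factor (applied to both the signal and the phantom
reference, as a real receiver-gain drift would be) are retained everywhere.

Everything is deterministic under the seed, down to the generated bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .model import (
    COHORTS,
    AnatomicalVolume,
    CircleROI,
    KSpace,
    MagnitudeImage,
    Manifest,
    PolygonROI,
    QuadROI,
    StudyRecord,
)
from .pipeline import StudyInput
from .recon import centered_fft2, mm_to_zerofilled_coord
from .studyio import write_anatomical, write_kspace, write_manifest


@dataclass(frozen=True)
class SynthParams:
    """Generator settings; defaults emulate the nominal acquisition.

    Geometry is in mm over a ``fov_mm`` × ``fov_mm`` field of view
    (64 mm default): an elliptical torso, Gaussian tumor blobs
    ``((cx, cy), radius, amplitude)`` inside it, and optional syringe
    beacon / spill sources outside it. ``noise_sigma`` is the per-channel
    complex-Gaussian k-space noise; with the defaults (32 × 32 silicon
    matrix) the image-domain background sigma is ``noise_sigma/32`` = 0.05,
    so the default tumor amplitude 1.0 sits at 20 background sigmas.
    ``clip_level`` (off by default) clamps the real and imaginary k-space
    channels, reproducing the RF-overflow artifact.
    """

    seed: int = 0
    torso_center_mm: tuple = (32.0, 32.0)
    torso_axes_mm: tuple = (14.0, 26.0)  # semi-axes (x, y)
    tumors: tuple = (
        ((28.0, 40.0), 2.5, 1.0),
        ((38.0, 24.0), 3.0, 1.0),
    )
    syringe_beacon: tuple | None = ((8.0, 32.0), 10.0)  # (center, amplitude)
    syringe_radius_mm: float = 3.0
    spill: tuple | None = ((12.0, 50.0), 3.0, 3.0)  # (center, radius, amplitude)
    noise_sigma: float = 1.6
    clip_level: float | None = None
    si_matrix: int = 32
    anat_matrix: int = 256
    n_slices: int = 22
    fov_mm: float = 64.0
    anat_texture: float = 0.15
    phantom_base: float = 50.0
    drift_sigma: float = 0.2  # lognormal sigma of per-study scanner drift

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.clip_level is not None and self.clip_level <= 0:
            raise ValidationError("clip_level must be positive")
        for (c, r, a) in self.tumors:
            if a < 0:
                raise ValidationError("tumor amplitudes must be >= 0")
            if not self._inside_torso(c):
                raise ValidationError(f"tumor center {c} lies outside the torso")
        if self.syringe_beacon is not None:
            c, a = self.syringe_beacon
            if a < 0 or self._inside_torso(c):
                raise ValidationError(
                    "syringe beacon must lie outside the torso with amplitude >= 0"
                )
        if self.spill is not None:
            c, r, a = self.spill
            if a < 0 or self._inside_torso(c):
                raise ValidationError(
                    "spill must lie outside the torso with amplitude >= 0"
                )

    def _inside_torso(self, point) -> bool:
        (cx, cy), (ax, ay) = self.torso_center_mm, self.torso_axes_mm
        return ((point[0] - cx) / ax) ** 2 + ((point[1] - cy) / ay) ** 2 <= 1.0


def _mm_grid(n: int, fov: float):
    """Pixel-center mm coordinates of an n × n grid over the FOV."""
    step = fov / n
    c = (np.arange(n) + 0.5) * step
    return c[None, :], c[:, None]  # x (cols), y (rows)


def make_anatomical(p: SynthParams) -> AnatomicalVolume:
    """Render the torso as a bright ellipse stack with smooth texture.

    The ellipse axes taper toward the first and last slices, mimicking a
    body cross-section stack. With ``anat_texture = 0`` the volume takes
    exactly two levels (0 outside, 0.8 inside).
    """
    rng = np.random.default_rng([p.seed, 1])
    n = p.anat_matrix
    x, y = _mm_grid(n, p.fov_mm)
    (cx, cy), (ax, ay) = p.torso_center_mm, p.torso_axes_mm
    slices = np.zeros((p.n_slices, n, n))
    mid = (p.n_slices - 1) / 2.0
    for s in range(p.n_slices):
        taper = np.sqrt(max(0.3, 1.0 - ((s - mid) / max(mid + 0.5, 1.0)) ** 2 * 0.7))
        inside = ((x - cx) / (ax * taper)) ** 2 + ((y - cy) / (ay * taper)) ** 2 <= 1.0
        sl = np.where(inside, 0.8, 0.0)
        if p.anat_texture > 0:
            noise = rng.standard_normal((n, n))
            texture = ndimage.gaussian_filter(noise, sigma=6.0)
            texture /= max(np.abs(texture).max(), 1e-12)
            sl = np.where(inside, np.clip(sl + p.anat_texture * texture, 0, None), sl)
        slices[s] = sl
    spacing = p.fov_mm / n
    return AnatomicalVolume(
        slices=slices,
        pixel_spacing_mm=(spacing, spacing),
        slice_thickness_mm=0.75,
    )


def _render_sources(p: SynthParams) -> np.ndarray:
    """Ground-truth silicon image: a sum of Gaussian blobs on the si grid."""
    n = p.si_matrix
    x, y = _mm_grid(n, p.fov_mm)
    img = np.zeros((n, n))

    def blob(center, radius, amp):
        sig = radius / 2.0
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
        return amp * np.exp(-d2 / (2.0 * sig * sig))

    for (c, r, a) in p.tumors:
        img += blob(c, r, a)
    if p.syringe_beacon is not None:
        c, a = p.syringe_beacon
        img += blob(c, p.syringe_radius_mm, a)
    if p.spill is not None:
        c, r, a = p.spill
        img += blob(c, r, a)
    return img


def make_silicon_kspace(p: SynthParams) -> tuple[KSpace, MagnitudeImage]:
    """Forward-model a silicon acquisition: blobs → k-space → noise → clip.

    Returns the noisy (optionally clipped) k-space and the noiseless
    ground-truth magnitude image on the acquisition grid.
    """
    truth = _render_sources(p)
    k = centered_fft2(truth)
    rng = np.random.default_rng([p.seed, 2])
    if p.noise_sigma > 0:
        k = k + p.noise_sigma * (
            rng.standard_normal(k.shape) + 1j * rng.standard_normal(k.shape)
        )
    if p.clip_level is not None:
        k = (np.clip(k.real, -p.clip_level, p.clip_level)
             + 1j * np.clip(k.imag, -p.clip_level, p.clip_level))
    spacing = p.fov_mm / p.si_matrix
    kspace = KSpace(k, "29Si", (p.fov_mm, p.fov_mm), {"seed": str(p.seed)})
    gt = MagnitudeImage(truth, (spacing, spacing))
    return kspace, gt


# ---------------------------------------------------------------------------
# ROI layout and cohort assembly
# ---------------------------------------------------------------------------

#: mm offsets applied to tumor centers to obtain matched non-tumor circles
#: (same area, shifted inside the torso, clear of every tumor).
_NONTUMOR_SHIFTS_MM = ((8.0, 4.0), (-12.0, -2.0), (0.0, -10.0), (6.0, 8.0))

ROI_DIAMETER_MM = 7.0


def _to_fine(p: SynthParams, x_mm: float) -> float:
    return mm_to_zerofilled_coord(x_mm, p.fov_mm, p.si_matrix, p.anat_matrix)


def default_rois(p: SynthParams) -> dict:
    """ROI layout, in silicon fine-grid pixel coordinates, for one geometry.

    * 7 mm circles at the planted tumor centers and at shifted non-tumor
      positions inside the torso;
    * a quadrangle bounding the torso but excluding the syringe beacon and
      the spill;
    * the torso ellipse (slightly shrunk) as a 24-gon body polygon.
    """
    tumor_rois = tuple(
        CircleROI((_to_fine(p, c[0]), _to_fine(p, c[1])), ROI_DIAMETER_MM)
        for (c, r, a) in p.tumors
    )
    nontumor = []
    for (c, r, a), (dx, dy) in zip(p.tumors, _NONTUMOR_SHIFTS_MM):
        q = (c[0] + dx, c[1] + dy)
        if not p._inside_torso(q):
            raise ValidationError(
                f"shifted non-tumor ROI {q} falls outside the torso"
            )
        nontumor.append(
            CircleROI((_to_fine(p, q[0]), _to_fine(p, q[1])), ROI_DIAMETER_MM)
        )
    (cx, cy), (ax, ay) = p.torso_center_mm, p.torso_axes_mm
    margin = 1.0
    x0, x1 = cx - ax - margin, cx + ax + margin
    y0, y1 = cy - ay - margin, cy + ay + margin
    quad = QuadROI(tuple(
        (_to_fine(p, x), _to_fine(p, y))
        for (x, y) in ((x0, y0), (x1, y0), (x1, y1), (x0, y1))
    ))
    theta = np.linspace(0.0, 2.0 * np.pi, 24, endpoint=False)
    body = PolygonROI(tuple(
        (_to_fine(p, cx + 0.97 * ax * np.cos(t)),
         _to_fine(p, cy + 0.97 * ay * np.sin(t)))
        for t in theta
    ))
    return {
        "roi_quad": quad,
        "tumor_rois": tumor_rois,
        "nontumor_rois": tuple(nontumor),
        "body_roi": body,
    }


def _derived_seed(base: int, cohort_idx: int, rep: int) -> int:
    return int((base * 1_000_003 + cohort_idx * 1_009 + rep * 101 + 1) % (2 ** 31))


def make_cohort_studies(n_per_cohort: int, p: SynthParams) -> list:
    """Generate ``4 × n_per_cohort`` in-memory studies with cohort structure.

    Targeted studies keep the configured tumor amplitudes; the three control
    cohorts have tumor amplitude 0 (noise, beacon, spill retained). Each
    study gets an independent noise seed and a lognormal drift factor
    multiplying both its k-space and its phantom reference.

    Returns a list of ``(StudyInput, ground_truth, drift)`` tuples.
    """
    if n_per_cohort < 1:
        raise ValidationError("n_per_cohort must be >= 1")
    rois = default_rois(p)
    out = []
    for ci, cohort in enumerate(COHORTS):
        for rep in range(n_per_cohort):
            seed = _derived_seed(p.seed, ci, rep)
            tumors = tuple(
                (c, r, a if cohort == "targeted" else 0.0)
                for (c, r, a) in p.tumors
            )
            sp = replace(p, seed=seed, tumors=tumors)
            kspace, gt = make_silicon_kspace(sp)
            drift_rng = np.random.default_rng([p.seed, 3, ci, rep])
            drift = float(np.exp(p.drift_sigma * drift_rng.standard_normal()))
            kspace = KSpace(
                kspace.data * drift, kspace.nucleus, kspace.fov_mm, kspace.meta
            )
            study = StudyInput(
                study_id=f"{cohort}_{rep + 1:02d}",
                cohort=cohort,
                kspace=kspace,
                phantom_reference=p.phantom_base * drift,
                **rois,
            )
            out.append((study, gt, drift))
    return out


def make_study_set(
    n_per_cohort: int, p: SynthParams, outdir, manifest_format: str = "csv"
) -> tuple[Manifest, Path]:
    """Write a complete study set (k-space, NIfTI, manifest) to disk.

    Returns the manifest object and the path of the manifest file. All
    data paths inside the manifest are relative to ``outdir`` so the set
    is relocatable.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for (study, _gt, _drift) in make_cohort_studies(n_per_cohort, p):
        si_name = f"{study.study_id}_si.ksp"
        anat_name = f"{study.study_id}_anat.nii"
        write_kspace(study.kspace, outdir / si_name)
        anat = make_anatomical(
            replace(p, seed=_anat_seed(study.study_id, p.seed))
        )
        write_anatomical(anat, outdir / anat_name)
        records.append(StudyRecord(
            study_id=study.study_id,
            cohort=study.cohort,
            silicon_path=si_name,
            anatomical_path=anat_name,
            phantom_reference=study.phantom_reference,
            display_slice=p.n_slices // 2,
            roi_quad=study.roi_quad,
            tumor_rois=study.tumor_rois,
            nontumor_rois=study.nontumor_rois,
            body_roi=study.body_roi,
        ))
    manifest = Manifest(studies=tuple(records))
    suffix = "xlsx" if manifest_format == "xlsx" else "csv"
    manifest_path = write_manifest(manifest, outdir / f"manifest.{suffix}")
    return manifest, manifest_path


def _anat_seed(study_id: str, base: int) -> int:
    return int((base * 7_919 + sum(study_id.encode()) * 131 + 5) % (2 ** 31))
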