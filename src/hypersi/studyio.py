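"""Read/write every on-disk artifact of the pipeline.

Formats handled here:

* **k-space dialect** (``.ksp``): one UTF-8 JSON header line (canonical
  key order) terminated by ``\\n``, followed by the payload — little-endian
  float32, real/imaginary interleaved, row-major. The header declares
  ``dims``, ``nucleus``, ``fov_mm``, ``byteorder`` and optional ``meta``.
  Deliberately simple and self-describing; proprietary scanner directory
  layouts are out of scope.
* **NIfTI** for the anatomical volume (input) and the processed silicon
  map (output), through nibabel.
* **manifest** — one study per row, as CSV or XLSX with identical content;
  an optional ``parameters`` key/value sheet in the XLSX overrides built-in
  processing defaults.
* **PNG** overlays and **JSON/CSV** quantification sidecars.
"""

from __future__ import annotations

import json
import math
import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError, TruncationError, ValidationError
from .model import (
    DEFAULT_PARAMETERS,
    AnatomicalVolume,
    CircleROI,
    KSpace,
    MagnitudeImage,
    Manifest,
    PolygonROI,
    QuadROI,
    QuantResult,
    StudyRecord,
)

_REQUIRED_HEADER_FIELDS = ("dims", "nucleus", "fov_mm", "byteorder")

MANIFEST_COLUMNS = (
    "study_id",
    "cohort",
    "silicon_path",
    "anatomical_path",
    "phantom_reference",
    "display_slice",
)
OPTIONAL_COLUMNS = ("roi_quad", "tumor_rois", "nontumor_rois", "body_roi")


# ---------------------------------------------------------------------------
# k-space dialect
# ---------------------------------------------------------------------------

def read_kspace(path) -> KSpace:
    """Read a k-space file in the package's JSON-header dialect."""
    raw = Path(path).read_bytes()
    nl = raw.find(b"\n")
    if nl < 0:
        raise FormatError(f"{path}: no header line found")
    try:
        header = json.loads(raw[:nl].decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: malformed JSON header ({exc})") from exc
    if not isinstance(header, dict):
        raise FormatError(f"{path}: header is not a JSON object")
    for fieldname in _REQUIRED_HEADER_FIELDS:
        if fieldname not in header:
            raise FormatError(f"{path}: header missing required field {fieldname!r}")
    dims = header["dims"]
    if (not isinstance(dims, list) or len(dims) != 2
            or not all(isinstance(d, int) and d >= 2 for d in dims)):
        raise FormatError(f"{path}: header field 'dims' must be two ints >= 2")
    if header["byteorder"] != "little":
        raise FormatError(
            f"{path}: header field 'byteorder' must be 'little', "
            f"got {header['byteorder']!r}"
        )
    payload = raw[nl + 1:]
    expected = dims[0] * dims[1] * 2 * 4  # interleaved float32 pairs
    if len(payload) != expected:
        raise TruncationError(
            f"{path}: payload is {len(payload)} bytes but header dims "
            f"{dims[0]}x{dims[1]} require {expected}"
        )
    floats = np.frombuffer(payload, dtype="<f4").astype(np.float64)
    data = (floats[0::2] + 1j * floats[1::2]).reshape(dims[0], dims[1])
    meta = {str(k): str(v) for k, v in header.get("meta", {}).items()}
    return KSpace(data, header["nucleus"], tuple(header["fov_mm"]), meta)


def write_kspace(k: KSpace, path) -> Path:
    """Write a KSpace in the dialect; read→write→read is byte-identical."""
    header = {
        "byteorder": "little",
        "dims": [int(k.shape[0]), int(k.shape[1])],
        "fov_mm": [float(k.fov_mm[0]), float(k.fov_mm[1])],
        "meta": {str(a): str(b) for a, b in sorted(k.meta.items())},
        "nucleus": k.nucleus,
    }
    line = json.dumps(header, sort_keys=True, separators=(",", ":"))
    interleaved = np.empty(k.data.size * 2, dtype="<f4")
    interleaved[0::2] = k.data.real.ravel()
    interleaved[1::2] = k.data.imag.ravel()
    path = Path(path)
    path.write_bytes(line.encode("utf-8") + b"\n" + interleaved.tobytes())
    return path


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def read_anatomical(path) -> AnatomicalVolume:
    """Load a NIfTI anatomical volume; slices ordered along the third axis.

    A 2D file is accepted as a single-slice volume. Pixel spacing comes
    from the file's voxel dimensions.
    """
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except Exception as exc:
        raise FormatError(f"{path}: not a readable NIfTI image ({exc})") from exc
    zooms = img.header.get_zooms()
    if data.ndim == 2:
        data = data[..., np.newaxis]
        zooms = tuple(zooms[:2]) + (1.0,)
    if data.ndim != 3:
        raise FormatError(
            f"{path}: expected a 2D or 3D image, got {data.ndim}D"
        )
    stack = np.moveaxis(data, 2, 0)  # (n_slices, rows, cols)
    return AnatomicalVolume(
        slices=stack,
        pixel_spacing_mm=(float(zooms[0]), float(zooms[1])),
        slice_thickness_mm=float(zooms[2]),
    )


def write_anatomical(vol: AnatomicalVolume, path) -> Path:
    """Write an AnatomicalVolume as float32 NIfTI."""
    data = np.moveaxis(vol.slices, 0, 2).astype(np.float32)
    sx, sy = vol.pixel_spacing_mm
    affine = np.diag([sx, sy, vol.slice_thickness_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return Path(path)


def _write_image_nifti(img: MagnitudeImage, path) -> Path:
    sx, sy = img.pixel_spacing_mm
    affine = np.diag([sx, sy, 1.0, 1.0])
    nib.save(nib.Nifti1Image(img.pixels.astype(np.float32), affine), str(path))
    return Path(path)


def read_image_nifti(path) -> MagnitudeImage:
    """Load a 2D silicon map previously written by this package."""
    vol = read_anatomical(path)
    return MagnitudeImage(vol.slices[0], vol.pixel_spacing_mm)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def _parse_floats(text: str, what: str):
    try:
        return [float(t) for t in str(text).replace(",", " ").split()]
    except ValueError as exc:
        raise ValidationError(f"cannot parse {what}: {text!r}") from exc


def parse_quad(text: str) -> QuadROI:
    vals = _parse_floats(text, "roi_quad")
    if len(vals) != 8:
        raise ValidationError(
            f"roi_quad needs 8 numbers 'x1 y1 ... x4 y4', got {len(vals)}"
        )
    return QuadROI(tuple(zip(vals[0::2], vals[1::2])))


def parse_circles(text: str) -> tuple:
    rois = []
    for part in str(text).split(";"):
        part = part.strip()
        if not part:
            continue
        vals = _parse_floats(part, "circle ROI")
        if len(vals) != 3:
            raise ValidationError(
                f"circle ROI needs 'cx cy diameter_mm', got {part!r}"
            )
        rois.append(CircleROI((vals[0], vals[1]), vals[2]))
    return tuple(rois)


def parse_polygon(text: str) -> PolygonROI:
    vals = _parse_floats(text, "body_roi")
    if len(vals) < 6 or len(vals) % 2:
        raise ValidationError(
            "body_roi needs an even list of >= 6 numbers 'x1 y1 x2 y2 ...'"
        )
    return PolygonROI(tuple(zip(vals[0::2], vals[1::2])))


def format_quad(roi: QuadROI) -> str:
    return " ".join(_fmt(c) for xy in roi.vertices for c in xy)


def format_circles(rois) -> str:
    return "; ".join(
        f"{_fmt(r.center[0])} {_fmt(r.center[1])} {_fmt(r.diameter_mm)}"
        for r in rois
    )


def format_polygon(roi: PolygonROI) -> str:
    return " ".join(_fmt(c) for xy in roi.vertices for c in xy)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


def _rows_to_manifest(df: pd.DataFrame, defaults: dict, base: Path) -> Manifest:
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    if len(df) == 0:
        raise ValidationError("manifest lists no studies (at least one required)")
    studies = []
    for _, row in df.iterrows():
        kwargs = {}
        if not _is_missing(row.get("roi_quad")):
            kwargs["roi_quad"] = parse_quad(row["roi_quad"])
        if not _is_missing(row.get("tumor_rois")):
            kwargs["tumor_rois"] = parse_circles(row["tumor_rois"])
        if not _is_missing(row.get("nontumor_rois")):
            kwargs["nontumor_rois"] = parse_circles(row["nontumor_rois"])
        if not _is_missing(row.get("body_roi")):
            kwargs["body_roi"] = parse_polygon(row["body_roi"])
        studies.append(StudyRecord(
            study_id=str(row["study_id"]),
            cohort=str(row["cohort"]).strip(),
            silicon_path=str(base / str(row["silicon_path"])),
            anatomical_path=str(base / str(row["anatomical_path"])),
            phantom_reference=float(row["phantom_reference"]),
            display_slice=int(float(row["display_slice"])),
            **kwargs,
        ))
    return Manifest(studies=tuple(studies), defaults=defaults)


def read_manifest(path) -> Manifest:
    """Read a study manifest from CSV or XLSX.

    Relative data paths are resolved against the manifest's directory.
    XLSX files may carry a ``parameters`` sheet (``key``/``value`` columns)
    overriding the built-in processing defaults; CSV manifests use the
    built-ins.
    """
    path = Path(path)
    defaults = dict(DEFAULT_PARAMETERS)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        sheets = pd.read_excel(path, sheet_name=None)
        name = "studies" if "studies" in sheets else next(iter(sheets))
        df = sheets[name]
        params = sheets.get("parameters")
        if params is not None:
            for col in ("key", "value"):
                if col not in params.columns:
                    raise SchemaError(
                        "parameters sheet needs 'key' and 'value' columns"
                    )
            for _, prow in params.iterrows():
                defaults[str(prow["key"])] = _coerce_param(prow["value"])
    else:
        df = pd.read_csv(path)
    return _rows_to_manifest(df, defaults, path.parent)


def _coerce_param(value):
    try:
        return float(value)
    except (TypeError, ValueError):
        return str(value)


def _manifest_frame(manifest: Manifest) -> pd.DataFrame:
    rows = []
    for s in manifest.studies:
        rows.append({
            "study_id": s.study_id,
            "cohort": s.cohort,
            "silicon_path": s.silicon_path,
            "anatomical_path": s.anatomical_path,
            "phantom_reference": _fmt(s.phantom_reference),
            "display_slice": s.display_slice,
            "roi_quad": format_quad(s.roi_quad) if s.roi_quad else "",
            "tumor_rois": format_circles(s.tumor_rois) if s.tumor_rois else "",
            "nontumor_rois": format_circles(s.nontumor_rois) if s.nontumor_rois else "",
            "body_roi": format_polygon(s.body_roi) if s.body_roi else "",
        })
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS + OPTIONAL_COLUMNS)


def write_manifest(manifest: Manifest, path) -> Path:
    """Write a manifest as CSV or XLSX (chosen by file extension).

    Paths are stored as given in the StudyRecords; store them relative to
    the manifest's directory for a relocatable study set.
    """
    path = Path(path)
    df = _manifest_frame(manifest)
    if path.suffix.lower() == ".xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as xw:
            df.to_excel(xw, sheet_name="studies", index=False)
            pd.DataFrame(
                [{"key": k, "value": v} for k, v in sorted(manifest.defaults.items())]
            ).to_excel(xw, sheet_name="parameters", index=False)
    else:
        df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# processed outputs
# ---------------------------------------------------------------------------

def write_outputs(study: StudyRecord, processed: MagnitudeImage, overlay,
                  quant: QuantResult | None, outdir) -> list:
    """Write one study's processed artifacts under deterministic names.

    ``{study_id}_processed.nii`` (silicon map), ``{study_id}_overlay.png``
    and, when quantification ran, ``{study_id}_quant.json`` and
    ``{study_id}_quant.csv``. Identical inputs produce identical bytes.
    """
    from PIL import Image

    from .coregister import overlay_to_uint8

    outdir = Path(outdir)
    if not outdir.is_dir() or not os.access(outdir, os.W_OK):
        raise OSError(f"output directory {outdir} is not a writable directory")
    written = []

    p_nii = outdir / f"{study.study_id}_processed.nii"
    _write_image_nifti(processed, p_nii)
    written.append(p_nii)

    p_png = outdir / f"{study.study_id}_overlay.png"
    Image.fromarray(overlay_to_uint8(overlay), mode="RGB").save(p_png)
    written.append(p_png)

    if quant is not None:
        payload = {
            "study_id": quant.study_id, "snr": quant.snr, "cnr": quant.cnr,
            "mu_t": quant.mu_t, "mu_b": quant.mu_b, "sigma_b": quant.sigma_b,
            "mu_m": quant.mu_m, "sigma_m": quant.sigma_m,
        }
        p_json = outdir / f"{study.study_id}_quant.json"
        p_json.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
        written.append(p_json)
        p_csv = outdir / f"{study.study_id}_quant.csv"
        pd.DataFrame([payload]).to_csv(p_csv, index=False)
        written.append(p_csv)
    return written
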