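"""Readers, writers and run configuration.

Images travel as a 16-bit PNG plus a JSON sidecar holding the pixel spacing
and the linear HU mapping ``HU = stored * hu_slope + hu_intercept`` (the
same convention as DICOM's RescaleSlope/RescaleIntercept), optionally with
the phantom ground truth. DICOM files are read through pydicom; anisotropic
pixel spacing beyond 1% is rejected because every estimator assumes
isotropic spacing. Rater scores and dose descriptors are CSV tables with
validated headers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd

from .dose import DEFAULT_K
from .errors import ConfigError, DataFormatError
from .image import ImageSlice
from .phantom import DoseRecord, GroundTruth

__all__ = [
    "RunConfig",
    "write_image",
    "read_image",
    "read_dicom",
    "write_dicom",
    "read_rater_table",
    "read_dose_table",
    "write_report",
]

SIDECAR_KEYS = {"pixel_spacing_mm", "hu_intercept", "hu_slope"}


@dataclass(frozen=True)
class RunConfig:
    """Every estimator parameter in one serializable record.

    ``step_mm=None`` means half the image's pixel spacing. The config is
    hashed into each report for provenance.
    """

    step_mm: float | None = None
    plateau_fraction: float = 0.25
    gradient_threshold_hu_per_mm: float = 50.0
    window_mm: float = 5.0
    stride_px: int = 1
    fit_dof_correction: bool = False
    k_factor: float = DEFAULT_K
    reference_length_cm: float = 25.0
    seed: int = 0
    round_decimals: int = 1

    def __post_init__(self) -> None:
        if self.step_mm is not None and not (self.step_mm > 0):
            raise ConfigError("step_mm must be positive")
        if not (0 < self.plateau_fraction <= 0.5):
            raise ConfigError("plateau_fraction must be in (0, 0.5]")
        if not (self.gradient_threshold_hu_per_mm > 0):
            raise ConfigError("gradient threshold must be positive")
        if not (self.window_mm > 0) or self.stride_px < 1:
            raise ConfigError("window_mm must be > 0 and stride_px >= 1")
        if not (self.k_factor > 0) or not (self.reference_length_cm > 0):
            raise ConfigError("k factor and reference length must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def write_image(image: ImageSlice, basepath,
                ground_truth: GroundTruth | None = None,
                hu_intercept: float = -1024.0, hu_slope: float = 1.0) -> Path:
    """Write ``<base>.png`` (uint16) + ``<base>.json`` sidecar.

    Pixels are stored as ``round((HU - intercept) / slope)``; HU values are
    therefore quantized to ``hu_slope`` (exact round trip for integer HU at
    the defaults). Raises if the HU range does not fit the 16-bit store.
    """
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    stored = np.round((image.pixels - hu_intercept) / hu_slope)
    if stored.min() < 0 or stored.max() > 65535:
        raise ConfigError("HU range does not fit the 16-bit raster; adjust "
                          "hu_intercept/hu_slope")
    imageio.imwrite(base.with_suffix(".png"), stored.astype(np.uint16))
    sidecar = {
        "pixel_spacing_mm": image.pixel_spacing_mm,
        "hu_intercept": hu_intercept,
        "hu_slope": hu_slope,
        "id": image.id,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = ground_truth.to_dict()
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return base.with_suffix(".png")


def read_image(path) -> ImageSlice:
    """Read a raster+sidecar pair (pass the .png or .json path) or a DICOM
    file (.dcm)."""
    p = Path(path)
    if p.suffix.lower() == ".dcm":
        return read_dicom(p)
    base = p.with_suffix("")
    sidecar_path = base.with_suffix(".json")
    if not sidecar_path.exists():
        raise DataFormatError(f"missing sidecar {sidecar_path}")
    try:
        sidecar = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"sidecar {sidecar_path} is not valid JSON: {exc}")
    missing = SIDECAR_KEYS - set(sidecar)
    if missing:
        raise DataFormatError(
            f"sidecar {sidecar_path} lacks required keys {sorted(missing)}")
    stored = imageio.imread(base.with_suffix(".png")).astype(np.float64)
    hu = stored * sidecar["hu_slope"] + sidecar["hu_intercept"]
    return ImageSlice(hu, sidecar["pixel_spacing_mm"],
                      id=sidecar.get("id", base.name))


def read_dicom(path) -> ImageSlice:
    """Read one DICOM slice, applying RescaleSlope/RescaleIntercept to HU."""
    import pydicom

    ds = pydicom.dcmread(path)
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise DataFormatError(f"{path}: no PixelSpacing")
    sy, sx = float(spacing[0]), float(spacing[1])
    if abs(sy - sx) > 0.01 * max(sy, sx):
        raise DataFormatError(
            f"{path}: anisotropic pixel spacing {sy} x {sx} mm (>1%); the "
            "estimators require isotropic spacing")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = ds.pixel_array.astype(np.float64) * slope + intercept
    return ImageSlice(hu, (sy + sx) / 2.0, id=str(getattr(ds, "SOPInstanceUID",
                                                          Path(path).stem)))


def write_dicom(image: ImageSlice, path,
                hu_intercept: float = -1024.0, hu_slope: float = 1.0) -> Path:
    """Minimal secondary-capture DICOM writer (uint16 + rescale tags)."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    stored = np.round((image.pixels - hu_intercept) / hu_slope)
    if stored.min() < 0 or stored.max() > 65535:
        raise ConfigError("HU range does not fit uint16 with the given rescale")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.Rows, ds.Columns = image.shape
    ds.PixelSpacing = [image.pixel_spacing_mm, image.pixel_spacing_mm]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = hu_slope
    ds.RescaleIntercept = hu_intercept
    ds.PixelData = stored.astype("<u2").tobytes()
    ds.save_as(path, enforce_file_format=True)
    return Path(path)


RATER_REQUIRED = ["item"]
DOSE_REQUIRED = ["exam_id", "ctdivol_mgy", "scan_length_cm"]


def read_rater_table(path) -> pd.DataFrame:
    """Rater-score CSV: an ``item`` column plus one column per rater."""
    df = pd.read_csv(path)
    if "item" not in df.columns or df.shape[1] < 3:
        raise DataFormatError(
            f"{path}: expected header 'item' plus >= 2 rater columns, got "
            f"{list(df.columns)}")
    return df.set_index("item")


def read_dose_table(path) -> list[DoseRecord]:
    """Dose CSV with header exam_id, ctdivol_mgy, scan_length_cm[, dlp_mgy_cm]."""
    df = pd.read_csv(path)
    missing = [c for c in DOSE_REQUIRED if c not in df.columns]
    if missing:
        raise DataFormatError(
            f"{path}: missing columns {missing}; expected header "
            f"{DOSE_REQUIRED} (+ optional dlp_mgy_cm)")
    records = []
    for _, row in df.iterrows():
        dlp = float(row["dlp_mgy_cm"]) if "dlp_mgy_cm" in df.columns else None
        records.append(DoseRecord(float(row["ctdivol_mgy"]),
                                  float(row["scan_length_cm"]),
                                  dlp_mgy_cm=dlp,
                                  exam_id=str(row["exam_id"])))
    return records


def write_report(payload: dict, path, config: RunConfig | None = None) -> Path:
    """Serialize a report dict as JSON, stamped with the config and its hash."""
    out = dict(payload)
    if config is not None:
        out["config"] = config.to_dict()
        out["config_hash"] = config.config_hash
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(out, indent=2, sort_keys=True) + "\n")
    return p
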