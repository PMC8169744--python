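"""CT series I/O and model-input preprocessing.

Reads DICOM series (pydicom) or NIfTI volumes (nibabel) into an HU-valued
:class:`CTVolume`, and applies the model-input contract: clip HU to
[-800, 1200], map affinely to [-1, 1], resample to the network input size.

Agatston scoring never sees preprocessed images: the score is defined on raw
HU (threshold 130, density bins at 200/300/400), and clipping at 1200 would
corrupt the weight of dense plaque.  Scoring therefore always runs on the
original-resolution HU volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.transform import resize

__all__ = [
    "CTVolume",
    "PreprocessConfig",
    "LoadError",
    "load_series",
    "load_dicom_series",
    "load_nifti",
    "save_nifti",
    "save_label_nifti",
    "write_dicom_series",
    "clip_hu",
    "preprocess_slice",
    "preprocess_volume",
    "resample_labels",
]


class LoadError(ValueError):
    """Raised when a series cannot be read as one axial HU volume."""


@dataclass
class CTVolume:
    """Ordered stack of axial HU slices with geometric metadata.

    ``slices`` is ``(n_slices, rows, cols)`` in Hounsfield Units;
    ``pixel_spacing`` is (row, col) mm/pixel; ``slice_spacing`` is mm.
    """

    slices: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_spacing: float
    source_id: str = ""

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n_slices, rows, cols) array")
        if not np.all(np.isfinite(self.slices)):
            raise ValueError("HU values must be finite")
        if min(self.pixel_spacing) <= 0 or self.slice_spacing <= 0:
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def pixel_area_mm2(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1])


@dataclass(frozen=True)
class PreprocessConfig:
    """Model-input normalization: clip, affine map to [-1, 1], resize.

    The zero-centering constant is the midpoint of the clip window (200 HU)
    and the scale is the half-width (1000 HU), a fixed image-independent map.
    """

    clip_lo: float = -800.0
    clip_hi: float = 1200.0
    center_shift: float = 200.0
    scale: float = 1000.0
    target_size: int = 512

    def __post_init__(self):
        if self.clip_lo >= self.clip_hi:
            raise ValueError("clip_lo must be below clip_hi")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

_AXIAL_TOL = 1e-3


def _is_axial(orientation) -> bool:
    o = np.asarray(orientation, dtype=float)
    if o.size != 6:
        return False
    normal = np.cross(o[:3], o[3:])
    return abs(abs(normal[2]) - 1.0) < _AXIAL_TOL


def load_dicom_series(path) -> CTVolume:
    """Read a directory of single-frame axial DICOM files as one HU volume.

    Slices are sorted by their z position (ImagePositionPatient), so the
    on-disk file order is irrelevant.  Raises :class:`LoadError` on mixed
    series, missing rescale tags, or non-axial orientation.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise LoadError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise LoadError("directory contains a mixed DICOM series")
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise LoadError("missing RescaleSlope/RescaleIntercept tags")
        if "ImageOrientationPatient" in ds and not _is_axial(
                ds.ImageOrientationPatient):
            raise LoadError("non-axial slice orientation")

    def zpos(ds):
        if "ImagePositionPatient" in ds:
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=zpos)
    hu = np.stack([
        ds.pixel_array.astype(np.float64) * float(ds.RescaleSlope)
        + float(ds.RescaleIntercept)
        for ds in datasets
    ])
    ps = datasets[0].PixelSpacing
    zs = [zpos(ds) for ds in datasets]
    if len(zs) > 1:
        slice_spacing = float(np.median(np.diff(zs)))
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))
    return CTVolume(hu, (float(ps[0]), float(ps[1])), abs(slice_spacing),
                    source_id=str(uids.pop()))


def load_nifti(path) -> CTVolume:
    """Read a NIfTI volume (stored (x, y, z)) as an HU slice stack.

    A JSON sidecar ``<stem>.json`` with ``pixel_spacing``/``slice_spacing``
    keys overrides header zooms when present.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 3:
        raise LoadError("NIfTI volume must be rank 3")
    slices = np.transpose(data, (2, 0, 1))
    zooms = img.header.get_zooms()
    pixel_spacing = (float(zooms[0]), float(zooms[1]))
    slice_spacing = float(zooms[2])
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "pixel_spacing" in meta:
            pixel_spacing = tuple(float(v) for v in meta["pixel_spacing"])
        if "slice_spacing" in meta:
            slice_spacing = float(meta["slice_spacing"])
    return CTVolume(slices, pixel_spacing, slice_spacing, source_id=path.name)


def load_series(path) -> CTVolume:
    """Dispatch to the DICOM-directory or NIfTI loader based on ``path``."""
    path = Path(path)
    if path.is_dir():
        return load_dicom_series(path)
    if path.name.endswith((".nii", ".nii.gz")):
        return load_nifti(path)
    raise LoadError(f"cannot identify CT input at {path}")


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _affine(volume: CTVolume) -> np.ndarray:
    return np.diag([volume.pixel_spacing[0], volume.pixel_spacing[1],
                    volume.slice_spacing, 1.0])


def save_nifti(volume: CTVolume, path) -> None:
    data = np.transpose(volume.slices, (1, 2, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(volume)),
             str(path))


def save_label_nifti(labels: np.ndarray, volume: CTVolume, path) -> None:
    """Write an integer label volume aligned with ``volume``."""
    data = np.transpose(np.asarray(labels), (1, 2, 0)).astype(np.int16)
    nib.save(nib.Nifti1Image(data, _affine(volume)), str(path))


def write_dicom_series(volume: CTVolume, out_dir) -> list[Path]:
    """Export as a single-frame CT DICOM series.

    Stored values are ``HU + 1024`` as unsigned 16-bit with RescaleSlope 1 and
    RescaleIntercept -1024, so integer-valued HU volumes round-trip bit-exact
    through :func:`load_dicom_series`.  Non-integer HU are rounded.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for i, sl in enumerate(volume.slices):
        stored = np.round(sl).astype(np.int64) + 1024
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("HU out of representable export range")
        ds = Dataset()
        ds.SOPClassUID = pydicom.uid.CTImageStorage
        ds.SOPInstanceUID = generate_uid()
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i * volume.slice_spacing)]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = volume.slice_spacing
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        ds.Rows, ds.Columns = sl.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored.astype(np.uint16).tobytes()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = ds.SOPClassUID
        meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        p = out_dir / f"slice_{i:04d}.dcm"
        ds.save_as(str(p), enforce_file_format=True)
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def clip_hu(image: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()):
    return np.clip(image, cfg.clip_lo, cfg.clip_hi)


def preprocess_slice(image: np.ndarray,
                     cfg: PreprocessConfig = PreprocessConfig(),
                     pixel_spacing: tuple[float, float] | None = None):
    """Clip, normalize and resize one HU slice for the network.

    Returns ``(normalized image, new pixel_spacing)``.  The map is monotone
    non-decreasing in HU; when the slice is already ``target_size`` square no
    resampling occurs, so the geometric part is idempotent.  Pixel spacing is
    rescaled by the resize factor so physical areas are preserved downstream.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("HU values must be finite")
    x = (clip_hu(image, cfg) - cfg.center_shift) / cfg.scale
    h, w = x.shape
    t = cfg.target_size
    if (h, w) != (t, t):
        x = resize(x, (t, t), order=1, preserve_range=True,
                   anti_aliasing=False)
    if pixel_spacing is None:
        return x, None
    new_spacing = (pixel_spacing[0] * h / t, pixel_spacing[1] * w / t)
    return x, new_spacing


def preprocess_volume(volume: CTVolume,
                      cfg: PreprocessConfig = PreprocessConfig()):
    """Apply :func:`preprocess_slice` to every slice; returns a new CTVolume
    holding normalized (unitless) values with updated pixel spacing."""
    out, spacing = [], volume.pixel_spacing
    for sl in volume.slices:
        x, spacing = preprocess_slice(sl, cfg, volume.pixel_spacing)
        out.append(x)
    stack = (np.stack(out) if out
             else np.zeros((0, cfg.target_size, cfg.target_size)))
    return replace(volume, slices=stack, pixel_spacing=spacing)


def resample_labels(labels: np.ndarray, target_size: int) -> np.ndarray:
    """Nearest-neighbour resize of a (H, W) integer label image (labels must
    stay categorical)."""
    labels = np.asarray(labels)
    if labels.shape == (target_size, target_size):
        return labels.copy()
    out = resize(labels.astype(np.float64), (target_size, target_size),
                 order=0, preserve_range=True, anti_aliasing=False)
    return out.astype(labels.dtype)
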