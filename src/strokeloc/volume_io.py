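"""Reading, writing and display-windowing of CT volumes and label maps.

Arrays are indexed ``(slice, row, col)``, 0-based, slices ascending along
the scan axis.  "Left" and "right" always mean image-left / image-right
columns, never anatomical sides.  Voxel values are Hounsfield Units (HU);
DICOM stored values are converted with the rescale slope/intercept on read.

Supported formats: DICOM series (read-only, one file per slice), NIfTI-1
(``.nii``/``.nii.gz``) and ``.npz`` array bundles used for fixtures.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, GeometryError, ParameterError

HU_MIN, HU_MAX = -1024.0, 3071.0
#: Default display window emphasising grey/white-matter contrast for
#: stroke reading.
STROKE_WINDOW = (40.0, 100.0)


@dataclass
class CTVolume:
    """An ordered stack of axial CT slices in Hounsfield Units."""

    slices: np.ndarray                       # (k, H, W) float, HU
    pixel_spacing: tuple = (1.0, 1.0)        # mm per pixel (row, col)
    slice_thickness: float = 5.0             # mm
    patient_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.slices, dtype=np.float64)
        if s.ndim != 3:
            raise GeometryError("CTVolume requires a (slice,row,col) array")
        self.slices = np.clip(s, HU_MIN, HU_MAX)

    @property
    def n_slices(self):
        return self.slices.shape[0]

    @property
    def shape(self):
        return self.slices.shape


@dataclass
class LabelMap:
    """Per-pixel ground-truth class map.

    Class alphabet: 0 background, 1 normal tissue, 2 infarct core,
    3 hypoperfused (at-risk) tissue.  After collapsing for training only
    {0, 1, 2} remain.
    """

    labels: np.ndarray                       # (k, H, W) small ints
    classes: tuple = (0, 1, 2, 3)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 3:
            raise GeometryError("LabelMap requires a (slice,row,col) array")
        if not np.issubdtype(lab.dtype, np.integer):
            raise ParameterError("label values must be integers")
        self.labels = lab.astype(np.int16)

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class WindowedSlice:
    """A display-windowed slice with 8-bit grey levels."""

    gray: np.ndarray
    window: tuple = STROKE_WINDOW


def window_hu(slice_hu, low=STROKE_WINDOW[0], high=STROKE_WINDOW[1]):
    """Affine clip-and-scale of HU to grey levels in [0, 255].

    Values at or below ``low`` map to 0, at or above ``high`` to 255 and
    the mapping is affine in between.  Rounding is half-to-even, so the
    result is bit-exact across platforms.
    """
    if low >= high:
        raise ParameterError(f"window low {low} must be < high {high}")
    a = np.asarray(slice_hu, dtype=np.float64)
    g = (a - low) * (255.0 / (high - low))
    g = np.clip(np.rint(g), 0, 255).astype(np.uint8)
    return WindowedSlice(gray=g, window=(low, high))


# ---------------------------------------------------------------------------
# Reading


def _read_dicom_dir(path):
    import pydicom

    files = sorted(
        os.path.join(path, f) for f in os.listdir(path)
        if not f.startswith(".") and os.path.isfile(os.path.join(path, f))
    )
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
            _ = ds.pixel_array
        except Exception as exc:
            raise FormatError(f"unreadable DICOM file {f!r}: {exc}") from exc
        datasets.append((f, ds))
    if not datasets:
        raise FormatError(f"no readable image files in {path!r}")

    def sort_key(item):
        ds = item[1]
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    shape = None
    for f, ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = arr * slope + intercept
        if shape is None:
            shape = hu.shape
        elif hu.shape != shape:
            raise GeometryError(
                f"slice {f!r} has shape {hu.shape}, expected {shape}")
        slices.append(hu)
    ds0 = datasets[0][1]
    spacing = tuple(float(v) for v in getattr(ds0, "PixelSpacing", (1.0, 1.0)))
    thickness = float(getattr(ds0, "SliceThickness", 5.0))
    pid = str(getattr(ds0, "PatientID", ""))
    return CTVolume(np.stack(slices), spacing, thickness, pid)


def _read_nifti(path):
    import nibabel as nib

    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:
        raise FormatError(f"unreadable NIfTI file {path!r}: {exc}") from exc
    if data.ndim != 3:
        raise GeometryError(f"{path!r} is not a 3-D volume")
    # stored (col, row, slice); internal (slice, row, col)
    slices = data.transpose(2, 1, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0]))
    thickness = float(zooms[2]) if len(zooms) > 2 else 5.0
    return CTVolume(slices, spacing, thickness)


def _read_npz(path):
    try:
        with np.load(path) as z:
            kind = str(z["kind"]) if "kind" in z else "ct"
            if kind == "labels":
                return LabelMap(z["labels"].astype(np.int16))
            if kind == "probability":
                return z["probs"].astype(np.float64)
            spacing = tuple(z["pixel_spacing"]) if "pixel_spacing" in z \
                else (1.0, 1.0)
            thickness = float(z["slice_thickness"]) if "slice_thickness" in z \
                else 5.0
            pid = str(z["patient_id"]) if "patient_id" in z else ""
            return CTVolume(z["slices"], spacing, thickness, pid)
    except (KeyError, ValueError, OSError) as exc:
        raise FormatError(f"unreadable npz bundle {path!r}: {exc}") from exc


def read_volume(path, format=None):
    """Read a CT volume (or fixture bundle) into HU.

    ``format`` is one of ``dicom_dir``, ``nifti``, ``npz``; if omitted it
    is inferred from the path.
    """
    if format is None:
        if os.path.isdir(path):
            format = "dicom_dir"
        elif str(path).endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif str(path).endswith(".npz"):
            format = "npz"
        else:
            raise FormatError(f"cannot infer format of {path!r}")
    if format == "dicom_dir":
        if not os.path.isdir(path):
            raise FormatError(f"{path!r} is not a directory of DICOM files")
        return _read_dicom_dir(path)
    if format == "nifti":
        if not os.path.exists(path):
            raise FormatError(f"no such file {path!r}")
        return _read_nifti(path)
    if format == "npz":
        if not os.path.exists(path):
            raise FormatError(f"no such file {path!r}")
        return _read_npz(path)
    raise ParameterError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Writing


def write_outputs(obj, path, format=None):
    """Persist a :class:`CTVolume`, :class:`LabelMap` or probability map.

    Masks and label maps round-trip losslessly; probability maps are stored
    at full float precision.  DICOM is read-only by design.
    """
    if format is None:
        if str(path).endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif str(path).endswith(".npz"):
            format = "npz"
        else:
            raise ParameterError(f"cannot infer output format for {path!r}")
    if format not in ("nifti", "npz"):
        raise ParameterError(f"unknown output format {format!r}")

    if format == "npz":
        try:
            if isinstance(obj, CTVolume):
                np.savez(path, kind="ct", slices=obj.slices,
                         pixel_spacing=np.asarray(obj.pixel_spacing),
                         slice_thickness=obj.slice_thickness,
                         patient_id=obj.patient_id)
            elif isinstance(obj, LabelMap):
                np.savez(path, kind="labels", labels=obj.labels)
            else:
                np.savez(path, kind="probability",
                         probs=np.asarray(obj, dtype=np.float64))
        except OSError as exc:
            raise FormatError(f"cannot write {path!r}: {exc}") from exc
        return

    import nibabel as nib

    if isinstance(obj, CTVolume):
        data = obj.slices.transpose(2, 1, 0)
        zooms = (obj.pixel_spacing[1], obj.pixel_spacing[0],
                 obj.slice_thickness)
    elif isinstance(obj, LabelMap):
        data = obj.labels.transpose(2, 1, 0).astype(np.int16)
        zooms = (1.0, 1.0, 1.0)
    else:
        data = np.asarray(obj, dtype=np.float64).transpose(2, 1, 0)
        zooms = (1.0, 1.0, 1.0)
    affine = np.diag([zooms[0], zooms[1], zooms[2], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(zooms)
    try:
        nib.save(img, path)
    except OSError as exc:
        raise FormatError(f"cannot write {path!r}: {exc}") from exc
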