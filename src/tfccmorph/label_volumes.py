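"""Multi-label 3D segmentation volumes: data model, I/O and resampling.

A :class:`LabelVolume` is an integer voxel grid with physical spacing in mm.
World coordinates are voxel centers: ``world = origin + index * spacing``
(axis-aligned, no shears).  The default label schema follows the distal
radioulnar joint convention used throughout the package::

    0: background, 1: radius, 2: ulna, 3: tfcc

Extra named labels (landmarks etc.) use codes >= 10.

Supported on-disk formats are NIfTI-1 (via nibabel) and NRRD (via SimpleITK),
integer voxel types only.  The anatomical meaning of the three grid axes is
recorded as an orientation tag (default ``LPS``); readers only accept volumes
whose affine/direction is axis-aligned up to per-axis sign flips — anatomically
labelled data acquired in another frame must be reoriented before use.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FormatError, InputError, SchemaError

DEFAULT_SCHEMA: dict[int, str] = {0: "background", 1: "radius", 2: "ulna", 3: "tfcc"}

LABEL_BACKGROUND = 0
LABEL_RADIUS = 1
LABEL_ULNA = 2
LABEL_TFCC = 3
LABEL_FOVEA_LANDMARK = 10
LABEL_STYLOID_LANDMARK = 11

_ORTH_TOL = 1e-9


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical measurement axes in world (mm) coordinates.

    ``dv_axis`` dorsal-volar, ``ru_axis`` radial-ulnar, ``pd_axis``
    proximal-distal.  These supply the directions along which maximal footprint
    lengths are measured; they are declared, never inferred from the image.
    """

    dv_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    ru_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    pd_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        axes = [np.asarray(a, dtype=float) for a in
                (self.dv_axis, self.ru_axis, self.pd_axis)]
        for name, a in zip(("dv_axis", "ru_axis", "pd_axis"), axes):
            if abs(np.linalg.norm(a) - 1.0) > _ORTH_TOL:
                raise ValueError(f"{name} must have unit norm")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(axes[i] @ axes[j])) > _ORTH_TOL:
                    raise ValueError("frame axes must be mutually orthogonal")

    def matrix(self) -> np.ndarray:
        """Rows are (dv, ru, pd) unit vectors."""
        return np.array([self.dv_axis, self.ru_axis, self.pd_axis], dtype=float)


@dataclass
class LabelVolume:
    """3D integer segmentation grid with mm spacing; the pipeline's input."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_orientation: str = "LPS"
    label_schema: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_SCHEMA))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D grid with >= 1 voxel per axis")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise FormatError("label volumes must have integer voxel data")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("all spacing components must be > 0")
        present = set(np.unique(self.voxels).tolist())
        unknown = sorted(present - set(self.label_schema))
        if unknown:
            raise SchemaError(f"voxel values not in label schema: {unknown}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """World mm coordinates of voxel indices (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def copy(self) -> "LabelVolume":
        return replace(self, voxels=self.voxels.copy(),
                       label_schema=dict(self.label_schema))


# ---------------------------------------------------------------------------
# I/O

def _schema_from_sidecar(path: str) -> dict[int, str] | None:
    """Load ``<volume>.labels.json`` next to the file, if present."""
    base = path
    for ext in (".nii.gz", ".nii", ".nrrd"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    sidecar = base + ".labels.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            raw = json.load(fh)
        return {int(k): str(v) for k, v in raw.items()}
    return None


def _ras_signs(orientation: str) -> np.ndarray:
    """Per-axis sign of each oriented axis in nibabel's RAS world."""
    signs = {"R": 1, "L": -1, "A": 1, "P": -1, "S": 1, "I": -1}
    expected = ("RL", "AP", "SI")
    if len(orientation) != 3 or any(
        c not in expected[i] for i, c in enumerate(orientation)
    ):
        raise ValueError(
            f"unsupported orientation tag {orientation!r}; axes must be in "
            "(R/L, A/P, S/I) order"
        )
    return np.array([signs[c] for c in orientation], dtype=float)


def _coerce_integer(data: np.ndarray, path: str) -> np.ndarray:
    if np.issubdtype(data.dtype, np.integer):
        return data
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=0, rtol=0):
        raise FormatError(f"{path}: non-integer voxel data in a label volume")
    return rounded.astype(np.int16)


def read_volume(path: str | os.PathLike,
                label_schema: dict[int, str] | None = None) -> LabelVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD label volume.

    The schema defaults to the package convention, extended by a
    ``<volume>.labels.json`` sidecar when one exists.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    if label_schema is None:
        label_schema = _schema_from_sidecar(path) or dict(DEFAULT_SCHEMA)

    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(path)
        data = _coerce_integer(np.asanyarray(img.dataobj), path)
        affine = img.affine
        rot = affine[:3, :3]
        if np.count_nonzero(np.abs(rot) > 1e-6 * max(1.0, np.abs(rot).max())) > 3 \
                or np.any(np.abs(np.diag(rot)) < 1e-12):
            raise FormatError(
                f"{path}: affine is not axis-aligned; reorient the volume first"
            )
        spacing = tuple(float(abs(rot[i, i])) for i in range(3))
        codes = nib.aff2axcodes(affine)
        orientation = "".join(codes)
        signs = _ras_signs(orientation)
        origin = tuple(float(affine[i, 3] * signs[i]) for i in range(3))
        return LabelVolume(data, spacing, origin, orientation, label_schema)

    if path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.ReadImage(path)
        direction = np.asarray(img.GetDirection()).reshape(3, 3)
        if not np.allclose(direction, np.eye(3), atol=1e-6):
            raise FormatError(
                f"{path}: non-identity direction matrix; reorient the volume first"
            )
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = _coerce_integer(arr, path).transpose(2, 1, 0)
        spacing = tuple(float(s) for s in img.GetSpacing())
        origin = tuple(float(o) for o in img.GetOrigin())
        return LabelVolume(data, spacing, origin, "LPS", label_schema)

    raise FormatError(f"unsupported volume format: {path}")


def write_volume(volume: LabelVolume, path: str | os.PathLike) -> None:
    """Write to NIfTI or NRRD, chosen by file extension."""
    path = os.fspath(path)
    if path.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        signs = _ras_signs(volume.axis_orientation)
        affine = np.eye(4)
        for i in range(3):
            affine[i, i] = signs[i] * volume.spacing[i]
            affine[i, 3] = signs[i] * volume.origin[i]
        img = nib.Nifti1Image(volume.voxels.astype(np.int16), affine)
        nib.save(img, path)
        return
    if path.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(
            np.ascontiguousarray(volume.voxels.astype(np.int16).transpose(2, 1, 0))
        )
        img.SetSpacing(tuple(volume.spacing))
        img.SetOrigin(tuple(volume.origin))
        sitk.WriteImage(img, path, useCompression=False)
        return
    raise FormatError(f"unsupported volume format: {path}")


def write_label_sidecar(volume: LabelVolume, volume_path: str) -> str:
    """Write the label schema as a JSON sidecar next to the volume file."""
    base = volume_path
    for ext in (".nii.gz", ".nii", ".nrrd"):
        if base.endswith(ext):
            base = base[: -len(ext)]
            break
    sidecar = base + ".labels.json"
    with open(sidecar, "w") as fh:
        json.dump({str(k): v for k, v in volume.label_schema.items()}, fh, indent=1)
    return sidecar


# ---------------------------------------------------------------------------
# Operations

def extract_label_mask(volume: LabelVolume, label: int) -> np.ndarray:
    """Binary mask of one label code; same shape as the volume."""
    if label not in volume.label_schema:
        raise SchemaError(f"label {label} not in schema "
                          f"{sorted(volume.label_schema)}")
    return volume.voxels == label


def upsampling_factor(source_spacing, target_spacing) -> float:
    """Max per-axis ratio source/target, e.g. (0.1,0.1,1.1)->(0.1,0.1,0.1) = 11."""
    src = np.asarray(source_spacing, dtype=float)
    tgt = np.asarray(target_spacing, dtype=float)
    if np.any(src <= 0) or np.any(tgt <= 0):
        raise ValueError("spacing components must be > 0")
    return float(np.max(src / tgt))


def resample_labels(volume: LabelVolume, target_spacing) -> LabelVolume:
    """Nearest-neighbor resample onto a grid with the target spacing.

    Labels are categorical, so nearest-neighbor is the only interpolation
    offered.  The output covers the same physical extent (voxel-center to
    voxel-center) and shares the input origin; no label absent from the input
    can appear in the output.
    """
    tgt = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in tgt):
        raise ValueError("target spacing must be > 0")
    src = np.asarray(volume.spacing)
    shape_in = np.asarray(volume.shape)
    extent = (shape_in - 1) * src
    shape_out = np.maximum(np.rint(extent / np.asarray(tgt)).astype(int) + 1, 1)

    idx = []
    for ax in range(3):
        centers = np.arange(shape_out[ax]) * tgt[ax]  # world offsets from origin
        nearest = np.clip(np.rint(centers / src[ax]).astype(int), 0,
                          shape_in[ax] - 1)
        idx.append(nearest)
    out = volume.voxels[np.ix_(idx[0], idx[1], idx[2])]
    return LabelVolume(out, tgt, volume.origin, volume.axis_orientation,
                       dict(volume.label_schema))
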