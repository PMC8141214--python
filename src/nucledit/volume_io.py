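"""Volume and sidecar I/O.

Reads and writes 3D image and label volumes in TIFF (single multi-page file
or a directory of per-slice files) and NIfTI-1 (``.nii`` / ``.nii.gz``), plus
a JSON sidecar holding per-region modified/done flags.

Conventions
-----------
Arrays are ``(z, y, x)``, 0-based; the microscope's X-Y plane is the last two
axes. Voxel spacing is ``(dz, dy, dx)`` in micrometres. TIFF carries no
reliable spacing, so TIFF reads fall back to the light-sheet acquisition
default of 2.50 x 0.75 x 0.75 um unless an override is given; NIfTI spacing
is taken from the header. Multi-file TIFF stacks are ordered by lexicographic
filename sort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .errors import (
    FormatError,
    MetadataParseError,
    ShapeMismatchError,
    ValidationError,
)

#: (dz, dy, dx) in um for light-sheet stacks that carry no spacing of their own.
DEFAULT_SPACING: tuple[float, float, float] = (2.50, 0.75, 0.75)

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValidationError(f"spacing must be three positive numbers, got {spacing!r}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative, finite intensities; integer or floating.
    spacing : (dz, dy, dx)
        Voxel edge lengths in micrometres, each > 0.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.number):
            raise ValidationError(f"non-numeric dtype {self.data.dtype}")
        if np.issubdtype(self.data.dtype, np.floating):
            if not np.isfinite(self.data).all():
                raise ValidationError("intensities must be finite")
        if self.data.size and self.data.min() < 0:
            raise ValidationError("intensities must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D instance-label grid: 0 = background, each positive label one nucleus."""

    data: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"expected a 3D volume, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValidationError(f"labels must have an integer dtype, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted array of distinct positive labels present."""
        u = np.unique(self.data)
        return u[u > 0]


def check_pair(image: ImageVolume, labels: LabelVolume) -> None:
    """Reject an image/label pair whose shapes differ, before any editing."""
    if image.shape != labels.shape:
        raise ShapeMismatchError(
            f"image shape {image.shape} != label shape {labels.shape}"
        )


# ---------------------------------------------------------------------------
# image / label volumes


def _detect_format(path: Path, format_hint: str | None) -> str:
    if format_hint is not None:
        hint = format_hint.lower()
        if hint not in {"tiff", "nifti"}:
            raise FormatError(f"unknown format hint {format_hint!r}")
        return hint
    if path.is_dir():
        return "tiff-stack"
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return "tiff"
    raise FormatError(f"cannot infer format of {path} (expected TIFF or NIfTI)")


def _read_tiff_stack(path: Path) -> np.ndarray:
    files = sorted(
        p for p in path.iterdir() if p.is_file() and p.suffix.lower() in _TIFF_SUFFIXES
    )
    if not files:
        raise FormatError(f"no TIFF slices found in directory {path}")
    slices = []
    for f in files:
        try:
            page = tifffile.imread(f)
        except Exception as exc:  # noqa: BLE001 - tifffile raises many types
            raise FormatError(f"unreadable TIFF slice {f}: {exc}") from exc
        if page.ndim != 2:
            raise FormatError(f"slice {f} is not a single 2D page (shape {page.shape})")
        if slices and page.shape != slices[0].shape:
            raise ShapeMismatchError(
                f"slice {f} has shape {page.shape}, expected {slices[0].shape}"
            )
        slices.append(page)
    return np.stack(slices, axis=0)


def read_image(
    path,
    format_hint: str | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> ImageVolume:
    """Read a 3D volume from TIFF (file or per-slice directory) or NIfTI.

    A directory is read as a Z-stack of single-page TIFFs in lexicographic
    filename order. NIfTI spacing comes from the header; TIFF uses
    ``spacing`` or :data:`DEFAULT_SPACING`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    fmt = _detect_format(path, format_hint)
    if fmt == "tiff-stack" or (fmt == "tiff" and path.is_dir()):
        data = _read_tiff_stack(path)
        return ImageVolume(data, spacing or DEFAULT_SPACING)
    if fmt == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"unreadable TIFF file {path}: {exc}") from exc
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise FormatError(f"{path}: expected a 2D or 3D TIFF, got shape {data.shape}")
        return ImageVolume(data, spacing or DEFAULT_SPACING)
    # NIfTI: stored (x, y, z); transpose to (z, y, x) and reverse the zooms.
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D NIfTI, got shape {data.shape}")
    if spacing is None:
        zooms = img.header.get_zooms()[:3]
        spacing = tuple(float(z) for z in zooms[::-1])
        if any(s <= 0 for s in spacing):
            spacing = DEFAULT_SPACING
    return ImageVolume(np.ascontiguousarray(data.T), spacing)


def write_image(volume: ImageVolume, path, format: str | None = None) -> None:
    """Write a volume to TIFF (multi-page) or NIfTI; format inferred from suffix."""
    path = Path(path)
    fmt = _detect_format(path, format)
    data = volume.data
    if fmt == "tiff":
        if data.dtype == np.float16 or np.issubdtype(data.dtype, np.complexfloating):
            raise FormatError(f"dtype {data.dtype} not supported for TIFF output")
        tifffile.imwrite(path, data, photometric="minisblack")
        return
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    nii = nib.Nifti1Image(np.ascontiguousarray(data.T), affine)
    nii.header.set_zooms((dx, dy, dz))
    nib.save(nii, str(path))


def _smallest_uint(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValidationError("label value too large")  # pragma: no cover


def read_labels(
    path,
    format_hint: str | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> LabelVolume:
    """Read an integer label volume; non-integer voxel values are rejected."""
    vol = read_image(path, format_hint=format_hint, spacing=spacing)
    data = vol.data
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.array_equal(rounded, data):
            raise ValidationError(
                f"{path}: label volume contains non-integer voxel values"
            )
        data = rounded.astype(np.int64)
    return LabelVolume(data, vol.spacing)


def write_labels(labels: LabelVolume, path, format: str | None = None) -> None:
    """Write labels using the smallest unsigned dtype that holds the max label."""
    max_label = int(labels.data.max()) if labels.data.size else 0
    data = labels.data.astype(_smallest_uint(max_label))
    write_image(ImageVolume(data, labels.spacing), path, format=format)


# ---------------------------------------------------------------------------
# JSON region-status sidecar


@dataclass
class RegionStatus:
    modified: bool = False
    done: bool = False
    extra: dict = field(default_factory=dict)  # unknown keys, preserved


@dataclass
class RegionMetadata:
    """Per-label modified/done flags, persisted in a JSON sidecar.

    Unknown keys, at both the top level and within a region entry, round-trip
    untouched.
    """

    entries: dict[int, RegionStatus] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def status(self, label: int) -> RegionStatus:
        """Flags for ``label``; absent labels read as all-false."""
        return self.entries.get(int(label), RegionStatus())

    def set_modified(self, label: int, modified: bool = True) -> None:
        self.entries.setdefault(int(label), RegionStatus()).modified = modified

    def set_done(self, label: int, done: bool) -> None:
        self.entries.setdefault(int(label), RegionStatus()).done = done

    def drop(self, label: int) -> None:
        self.entries.pop(int(label), None)

    def stale_labels(self, labels: LabelVolume) -> list[int]:
        """Entry keys that name no label present in ``labels``."""
        present = set(int(v) for v in labels.labels())
        return sorted(k for k in self.entries if k not in present)


def read_metadata(path, labels: LabelVolume | None = None) -> RegionMetadata:
    """Read the JSON sidecar; a missing file yields empty metadata.

    If ``labels`` is given, entries referencing absent labels trigger a
    stale-entry warning (the load still succeeds).
    """
    path = Path(path)
    if not path.exists():
        return RegionMetadata()
    try:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    except json.JSONDecodeError as exc:
        raise MetadataParseError(
            f"{path}: malformed JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(raw, dict):
        raise MetadataParseError(f"{path}: expected a JSON object at top level")
    regions = raw.get("regions", {})
    if not isinstance(regions, dict):
        raise MetadataParseError(f"{path}: 'regions' must be an object")
    entries: dict[int, RegionStatus] = {}
    for key, val in regions.items():
        try:
            label = int(key)
        except ValueError as exc:
            raise MetadataParseError(f"{path}: region key {key!r} is not an integer") from exc
        if label <= 0:
            raise MetadataParseError(f"{path}: region key {label} is not positive")
        if not isinstance(val, dict):
            raise MetadataParseError(f"{path}: entry for label {label} must be an object")
        extra = {k: v for k, v in val.items() if k not in {"modified", "done"}}
        entries[label] = RegionStatus(
            modified=bool(val.get("modified", False)),
            done=bool(val.get("done", False)),
            extra=extra,
        )
    meta = RegionMetadata(
        entries=entries,
        extra={k: v for k, v in raw.items() if k not in {"version", "regions"}},
    )
    if labels is not None:
        stale = meta.stale_labels(labels)
        if stale:
            warnings.warn(
                f"sidecar {path} references labels absent from the volume: {stale}",
                stacklevel=2,
            )
    return meta


def write_metadata(meta: RegionMetadata, path) -> None:
    doc: dict = {"version": 1, **meta.extra}
    doc["regions"] = {
        str(label): {"modified": st.modified, "done": st.done, **st.extra}
        for label, st in sorted(meta.entries.items())
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def sidecar_path(labels_path) -> Path:
    """Conventional sidecar location: ``<labels>.regions.json`` next to the labels."""
    p = Path(labels_path)
    return p.with_name(p.name + ".regions.json")
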