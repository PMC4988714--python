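"""Reading and writing image and mask stacks.

A *stack* is an ordered sequence of 2-D grayscale slices sharing one
geometry. Slice index ``z`` is 0-based and preserves acquisition order
(DICOM instance number, NIfTI k-axis, or natural filename sort for slice
directories). Pixel coordinates are ``(x, y)`` = 0-based (column, row).

Supported on disk:

* DICOM series — a directory of single-frame ``.dcm`` files (pydicom);
  rescale slope/intercept applied when present, no windowing.
* NIfTI — ``.nii`` / ``.nii.gz`` volumes (nibabel), data axes (x, y, z).
* Slice directories — PNG/TIFF files, natural-sorted by filename.

Masks use labels {0 = background, 1 = left lung, 2 = right lung}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ImageStack",
    "MaskStack",
    "StackValidationError",
    "read_stack",
    "read_mask_stack",
    "write_mask_stack",
    "natural_sort_key",
]

MASK_LABELS = (0, 1, 2)

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


class StackValidationError(ValueError):
    """An in-memory stack violates its invariants."""


def natural_sort_key(name: str) -> tuple:
    """Numeric-aware sort key: ``slice2`` < ``slice10``."""
    return tuple(
        int(part) if part.isdigit() else part.lower()
        for part in re.split(r"(\d+)", name)
    )


@dataclass
class ImageStack:
    """Ordered grayscale slices with shared dimensions.

    ``data`` has shape ``(n_slices, height, width)``; ``data[z, y, x]`` is
    the pixel value V(x, y) on slice z.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise StackValidationError(
                f"stack must be (n_slices, height, width), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise StackValidationError("stack intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    def __iter__(self):
        return iter(self.data)


@dataclass
class MaskStack:
    """Per-slice label arrays over {0=background, 1=left lung, 2=right lung}."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise StackValidationError(
                f"mask stack must be (n_slices, height, width), got shape {self.data.shape}"
            )
        bad = set(np.unique(self.data)) - set(MASK_LABELS)
        if bad:
            raise StackValidationError(f"mask labels outside {MASK_LABELS}: {sorted(bad)}")
        self.data = self.data.astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    def binary(self) -> np.ndarray:
        """Collapse lung labels {1, 2} to foreground True."""
        return self.data > 0

    def __iter__(self):
        return iter(self.data)


@dataclass
class RoiStack(ImageStack):
    """An ImageStack cropped to a region of interest.

    ``offset`` = (x0, y0) of the crop in the full frame;
    ``full_shape`` = (height, width) of the original slices, so masks
    computed in ROI coordinates can be re-embedded.
    """

    offset: tuple[int, int] = (0, 0)
    full_shape: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.full_shape is None:
            self.full_shape = (self.height, self.width)


def _detect_format(path: Path) -> str:
    if path.is_file():
        return "nifti"
    if path.is_dir():
        entries = [p for p in path.iterdir() if p.is_file()]
        if any(p.suffix.lower() == ".dcm" for p in entries):
            return "dicom_dir"
        return "image_dir"
    raise FileNotFoundError(path)


def read_stack(path, format_hint: str | None = None) -> ImageStack:
    """Read an ordered grayscale stack from disk.

    Parameters
    ----------
    path
        DICOM directory, NIfTI file, or directory of PNG/TIFF slices.
    format_hint
        One of ``{"dicom_dir", "nifti", "image_dir"}``; auto-detected when
        omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _detect_format(path)
    if fmt == "nifti":
        return ImageStack(_read_nifti(path))
    if fmt == "dicom_dir":
        return ImageStack(_read_dicom_dir(path))
    if fmt == "image_dir":
        return ImageStack(_read_image_dir(path))
    raise ValueError(f"unknown format hint {fmt!r}")


def _read_nifti(path: Path) -> np.ndarray:
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 3:
        raise StackValidationError(f"{path}: expected a 3-D volume, got shape {vol.shape}")
    # nibabel axes are (x, y, z); store as (z, y, x)
    return np.transpose(vol, (2, 1, 0))


def _read_dicom_dir(path: Path) -> np.ndarray:
    import pydicom

    files = sorted(
        (p for p in path.iterdir() if p.is_file() and p.suffix.lower() == ".dcm"),
        key=lambda p: natural_sort_key(p.name),
    )
    if not files:
        raise FileNotFoundError(f"no .dcm files in {path}")
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
            arr = ds.pixel_array.astype(float)
        except Exception as exc:  # noqa: BLE001 - report the offending file
            raise IOError(f"unreadable DICOM file {f}: {exc}") from exc
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        order = getattr(ds, "InstanceNumber", None)
        slices.append((order if order is not None else len(slices), slope * arr + intercept))
    slices.sort(key=lambda t: t[0])
    return _stack_slices([s for _, s in slices], path)


def _read_image_dir(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(
        (p for p in path.iterdir() if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES),
        key=lambda p: natural_sort_key(p.name),
    )
    if not files:
        raise FileNotFoundError(f"no image slices in {path}")
    slices = []
    for f in files:
        try:
            arr = np.asarray(iio.imread(str(f)))
        except Exception as exc:  # noqa: BLE001
            raise IOError(f"unreadable image file {f}: {exc}") from exc
        if arr.ndim == 3:  # RGB(A) -> luminance by channel mean
            arr = arr[..., :3].mean(axis=-1)
        slices.append(arr.astype(float))
    return _stack_slices(slices, path)


def _stack_slices(slices: list[np.ndarray], origin) -> np.ndarray:
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise StackValidationError(
            f"{origin}: inconsistent slice dimensions {sorted(shapes)}"
        )
    return np.stack(slices)


def read_mask_stack(path, format_hint: str | None = None) -> MaskStack:
    """Read a label stack written by :func:`write_mask_stack`."""
    stack = read_stack(path, format_hint=format_hint)
    return MaskStack(stack.data.astype(np.uint8))


def write_mask_stack(masks: MaskStack, path, format: str = "nifti") -> None:
    """Write a mask stack; reading it back reproduces the labels exactly."""
    if not isinstance(masks, MaskStack):
        masks = MaskStack(np.asarray(masks))
    path = Path(path)
    if format == "nifti":
        import nibabel as nib

        vol = np.transpose(masks.data, (2, 1, 0))  # (z,y,x) -> (x,y,z)
        nib.save(nib.Nifti1Image(vol.astype(np.uint8), affine=np.eye(4)), str(path))
    elif format == "image_dir":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        ndigits = max(4, len(str(masks.n_slices)))
        for z, sl in enumerate(masks.data):
            iio.imwrite(str(path / f"mask_{z:0{ndigits}d}.png"), sl.astype(np.uint8))
    else:
        raise ValueError(f"unknown mask format {format!r}")
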