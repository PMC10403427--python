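"""Reading, writing and cropping serial-section stacks.

Conventions fixed across the whole package:

* axis order is ``(section, row, col)``, 0-based, pixel centers at integer
  coordinates;
* intensities are normalized to floating values in ``[0, 1]`` at load time,
  mapping the storage dtype's full range onto the unit interval, so losses
  and similarity metrics are dtype-independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import h5py
import numpy as np
import tifffile

__all__ = [
    "SectionStack",
    "LabelStack",
    "normalize_image",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "center_crop",
    "center_crop_labels",
]

MIN_SECTION_SIDE = 8


def normalize_image(arr: np.ndarray) -> np.ndarray:
    """Map a 2-D image of any storage dtype onto float64 values in [0, 1].

    Integer dtypes are divided by the dtype's full range; floating inputs are
    assumed to already live in [0, 1] and are only validated.
    """
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D section image, got shape {arr.shape}")
    if min(arr.shape) < MIN_SECTION_SIDE:
        raise ValueError(
            f"section of shape {arr.shape} is smaller than the "
            f"{MIN_SECTION_SIDE}-px minimum side"
        )
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        out = (arr.astype(np.float64) - info.min) / (info.max - info.min)
    else:
        out = arr.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("section contains non-finite values")
    return out


@dataclass
class SectionStack:
    """An ordered series of co-sized 2-D grayscale sections.

    Attributes
    ----------
    data
        Array of shape ``(n, rows, cols)`` with float intensities in [0, 1].
    pixel_size_nm
        Optional (y, x) in-plane voxel size metadata.
    thickness_nm
        Optional section thickness metadata.
    """

    data: np.ndarray
    pixel_size_nm: Optional[tuple[float, float]] = None
    thickness_nm: Optional[float] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one section")
        if min(self.data.shape[1:]) < MIN_SECTION_SIDE:
            raise ValueError(f"sections of shape {self.data.shape[1:]} are too small")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite values")

    @classmethod
    def from_sections(cls, sections: Sequence[np.ndarray], **meta) -> "SectionStack":
        norm = [normalize_image(s) for s in sections]
        shapes = {s.shape for s in norm}
        if len(shapes) > 1:
            raise ValueError(f"ragged section shapes: {sorted(shapes)}")
        return cls(np.stack(norm, axis=0), **meta)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.data)


@dataclass
class LabelStack:
    """Integer label maps congruent with a :class:`SectionStack`.

    Label 0 is background; a nonzero id denotes the same structure (e.g.
    neurite) on every section where it appears.
    """

    data: np.ndarray = field()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3-D, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.data[i]


_PADDED_NUM = re.compile(r"\d+")


def _sequence_files(path: Path) -> list[Path]:
    exts = {".png", ".tif", ".tiff"}
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in exts)
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF files under {path}")
    # Lexicographic order is only meaningful when numeric parts are
    # zero-padded to one width; refuse to guess otherwise.
    widths = set()
    for f in files:
        for m in _PADDED_NUM.finditer(f.stem):
            widths.add(len(m.group()))
    if len(widths) > 1:
        raise ValueError(
            "image-sequence filenames mix numeric field widths; zero-pad the "
            "indices so lexicographic order equals numeric order"
        )
    return files


def read_stack(
    path, format: str, dataset_key: Optional[str] = None
) -> SectionStack:
    """Read a section stack from disk.

    Parameters
    ----------
    path
        File (TIFF/HDF5) or directory (image sequence).
    format
        One of ``tiff_multipage``, ``image_sequence``, ``hdf5``.
    dataset_key
        HDF5 dataset name addressing a 3-D ``(section, row, col)`` array;
        required for ``hdf5``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "tiff_multipage":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D TIFF payload, got shape {arr.shape}")
        return SectionStack.from_sections(list(arr))
    if format == "image_sequence":
        if not path.is_dir():
            raise NotADirectoryError(str(path))
        import imageio.v3 as iio

        pages = []
        for f in _sequence_files(path):
            img = iio.imread(f)
            if img.ndim == 3:  # collapse RGB(A) to luminance
                img = img[..., :3].mean(axis=-1).astype(img.dtype)
            pages.append(img)
        return SectionStack.from_sections(pages)
    if format == "hdf5":
        if dataset_key is None:
            raise ValueError("hdf5 format requires a dataset_key")
        with h5py.File(path, "r") as f:
            if dataset_key not in f:
                raise KeyError(f"dataset {dataset_key!r} not in {path}")
            arr = f[dataset_key][()]
        if arr.ndim != 3:
            raise ValueError(f"expected a 3-D dataset, got shape {arr.shape}")
        return SectionStack.from_sections(list(arr))
    raise ValueError(f"unknown format {format!r}")


def write_stack(
    stack: SectionStack,
    path,
    format: str,
    dataset_key: str = "volumes/raw",
    dtype: str = "float32",
) -> None:
    """Write a stack; ``dtype`` may be ``float32`` (lossless to float precision)
    or ``uint8``/``uint16`` (quantized onto the dtype's range)."""
    path = Path(path)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        payload = np.round(stack.data * (info.max - info.min) + info.min).astype(dtype)
    else:
        payload = stack.data.astype(dtype)
    if format == "tiff_multipage":
        tifffile.imwrite(path, payload, photometric="minisblack")
    elif format == "image_sequence":
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        if np.issubdtype(payload.dtype, np.floating):
            raise ValueError("image sequences require an integer storage dtype")
        width = max(4, len(str(stack.n - 1)))
        for i, page in enumerate(payload):
            iio.imwrite(path / f"section_{i:0{width}d}.png", page)
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset_key, data=payload)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path, format: str, dataset_key: Optional[str] = None) -> LabelStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if format == "tiff_multipage":
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    elif format == "hdf5":
        if dataset_key is None:
            raise ValueError("hdf5 format requires a dataset_key")
        with h5py.File(path, "r") as f:
            arr = f[dataset_key][()]
    else:
        raise ValueError(f"unknown label format {format!r}")
    return LabelStack(np.asarray(arr))


def write_labels(
    labels: LabelStack, path, format: str, dataset_key: str = "volumes/labels"
) -> None:
    if format == "tiff_multipage":
        tifffile.imwrite(path, labels.data, photometric="minisblack")
    elif format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset_key, data=labels.data)
    else:
        raise ValueError(f"unknown label format {format!r}")


def _crop_slices(shape: tuple[int, int], size: tuple[int, int]):
    """Symmetric center-crop slices; an odd remainder leaves the extra pixel
    on the leading (top/left) side, i.e. offset = floor((dim - size) / 2)."""
    rows, cols = shape
    out_r, out_c = size
    if out_r > rows or out_c > cols:
        raise ValueError(f"crop size {size} exceeds section shape {shape}")
    r0 = (rows - out_r) // 2
    c0 = (cols - out_c) // 2
    return slice(r0, r0 + out_r), slice(c0, c0 + out_c)


def center_crop(stack: SectionStack, size: tuple[int, int]) -> SectionStack:
    """Center-crop every section to ``size`` (rows, cols)."""
    sr, sc = _crop_slices(stack.shape, size)
    return SectionStack(
        stack.data[:, sr, sc].copy(),
        pixel_size_nm=stack.pixel_size_nm,
        thickness_nm=stack.thickness_nm,
    )


def center_crop_labels(labels: LabelStack, size: tuple[int, int]) -> LabelStack:
    sr, sc = _crop_slices(labels.shape, size)
    return LabelStack(labels.data[:, sr, sc].copy())
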