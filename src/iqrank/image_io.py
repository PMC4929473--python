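"""Reading image files into a canonical grayscale representation.

All measures operate on a :class:`GrayImage`: a 2D array of non-negative,
finite intensities kept at native scale (16-bit data stays 0..65535; there
is no rescaling to [0, 1], because the histogram entropy is computed over
actual recorded gray levels).  Color inputs are reduced to one channel by
an unweighted channel mean — microscopy data is single-channel, the color
path exists only for convenience.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import ImageLoadError, EmptyDatasetError, ParameterError

MIN_SIDE = 16
SUPPORTED_EXTENSIONS = (".tif", ".tiff", ".png", ".jpg", ".jpeg")


@dataclass(frozen=True)
class GrayImage:
    """2D grayscale intensity image, the universal input unit.

    Pixels are finite and non-negative; both sides must be at least
    ``MIN_SIDE`` px, because the global statistics are meaningless on
    tiny images.
    """

    pixels: np.ndarray
    source_path: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ParameterError(f"GrayImage requires a 2D array, got ndim={px.ndim}")
        if px.shape[0] < MIN_SIDE or px.shape[1] < MIN_SIDE:
            raise ParameterError(
                f"image too small: {px.shape}, minimum is {MIN_SIDE}x{MIN_SIDE}"
            )
        if not np.all(np.isfinite(px)):
            raise ParameterError("image contains non-finite pixel values")
        if px.min() < 0:
            raise ParameterError("image contains negative pixel values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def mean(self) -> float:
        return float(self.pixels.mean())


def _to_gray(arr: np.ndarray, path: str) -> np.ndarray:
    """Reduce an array read from disk to a 2D grayscale plane."""
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # Multi-page TIFF (pages first) vs color (channels last).
        if arr.shape[-1] in (2, 3, 4) and arr.shape[0] not in (2, 3, 4):
            arr = arr[..., :3].mean(axis=-1)  # drop alpha, unweighted channel mean
        else:
            arr = arr[0]
            return _to_gray(arr, path)
    if arr.ndim != 2:
        raise ImageLoadError(f"{path}: unsupported image layout with shape {arr.shape}")
    return arr


def load_image(path: str | os.PathLike) -> GrayImage:
    """Read a TIFF/PNG/JPEG file as a :class:`GrayImage`.

    Color images are averaged over channels; multi-page TIFFs use the
    first page; integer data keeps its native scale.
    """
    path = Path(path)
    if not path.exists():
        raise ImageLoadError(f"{path}: no such file")
    ext = path.suffix.lower()
    if ext not in SUPPORTED_EXTENSIONS:
        raise ImageLoadError(f"{path}: unsupported extension {ext!r}")
    try:
        if ext in (".tif", ".tiff"):
            arr = tifffile.imread(path, key=0)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - surface reader failures with the path
        raise ImageLoadError(f"{path}: could not read image ({exc})") from exc
    if arr.dtype.kind not in "uif" or (arr.dtype.kind == "u" and arr.dtype.itemsize > 2):
        raise ImageLoadError(f"{path}: unsupported bit depth/dtype {arr.dtype}")
    gray = _to_gray(arr, str(path))
    try:
        return GrayImage(gray, source_path=str(path))
    except ParameterError as exc:
        raise ImageLoadError(f"{path}: {exc}") from exc


def save_image(img: GrayImage | np.ndarray, path: str | os.PathLike, dtype=np.uint8) -> None:
    """Write a grayscale image as TIFF/PNG, clipping to the target dtype range."""
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=np.float64)
    info = np.iinfo(dtype)
    out = np.clip(np.round(px), info.min, info.max).astype(dtype)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def list_dataset(directory: str | os.PathLike, name_filter: str | None = None) -> list[Path]:
    """Enumerate supported image files in a directory, lexicographically sorted.

    ``name_filter`` keeps only filenames containing the substring
    (case-insensitive) — e.g. filter ``"STED"`` to separate STED frames
    from confocal ones in a mixed acquisition folder.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise EmptyDatasetError(f"{directory}: not a directory")
    paths = sorted(
        p for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in SUPPORTED_EXTENSIONS
    )
    if name_filter is not None:
        needle = name_filter.lower()
        paths = [p for p in paths if needle in p.name.lower()]
    if not paths:
        raise EmptyDatasetError(
            f"{directory}: no supported image files"
            + (f" matching {name_filter!r}" if name_filter else "")
        )
    return paths
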