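"""Raster reading/writing and dataset enumeration.

Images are plain 2D :class:`numpy.ndarray` objects: grayscale images carry
intensities on their native scale (0-255 for 8-bit input), binary masks are
``uint8`` arrays over {0, 1} with foreground = 1.  RGB inputs are collapsed
to a single channel by fixed luminance weights (BT.601 by default; the green
channel alone is common in retinal work and available via ``mode="green"``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ValidationError

#: Supported RGB -> gray conversion weights (r, g, b).
GRAY_WEIGHTS: dict[str, tuple[float, float, float]] = {
    "bt601": (0.299, 0.587, 0.114),
    "bt709": (0.2126, 0.7152, 0.0722),
    "green": (0.0, 1.0, 0.0),
}

RASTER_SUFFIXES = {".png", ".tif", ".tiff", ".bmp"}


def to_gray(pixels: np.ndarray, mode: str = "bt601") -> np.ndarray:
    """Collapse an (H, W[, C]) array to a 2D float64 intensity raster.

    Idempotent on already-gray inputs.  Alpha channels are dropped before
    applying the luminance weights.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 2:
        return arr.astype(np.float64)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            return arr[:, :, 0].astype(np.float64)
        if arr.shape[2] == 4:  # RGBA: ignore alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            try:
                w = GRAY_WEIGHTS[mode]
            except KeyError:
                raise ValidationError(
                    f"unknown gray-conversion mode {mode!r}; "
                    f"choose from {sorted(GRAY_WEIGHTS)}"
                ) from None
            return arr.astype(np.float64) @ np.asarray(w, dtype=np.float64)
    raise ValidationError(f"cannot interpret array of shape {arr.shape} as an image")


def _load(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        return np.asarray(iio.imread(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"could not decode raster {path}: {exc}") from exc


def read_gray_image(path: str | Path, mode: str = "bt601") -> np.ndarray:
    """Read a raster as a 2D grayscale array on its native intensity scale.

    Parameters
    ----------
    path : path to a PNG/TIFF/BMP file (8- or 16-bit).
    mode : RGB->gray conversion, one of ``bt601``, ``bt709``, ``green``.
    """
    img = to_gray(_load(path), mode=mode)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValidationError(
            f"image {path} has shape {img.shape}; need at least 2 rows and 2 columns"
        )
    if not np.all(np.isfinite(img)):
        raise ValidationError(f"image {path} contains non-finite intensities")
    return img


def binarize(pixels: np.ndarray, threshold: float) -> np.ndarray:
    """Map values strictly above *threshold* to 1, the rest to 0 (uint8)."""
    return (np.asarray(pixels) > threshold).astype(np.uint8)


def read_mask(path: str | Path, threshold: float | None = None) -> np.ndarray:
    """Read a raster as a {0,1} binary mask.

    The default threshold is half the maximum representable value of the
    file's dtype (127.5 for 8-bit), so {0, 255} masks read back exactly.
    """
    raw = _load(path)
    gray = to_gray(raw)
    if threshold is None:
        if np.issubdtype(raw.dtype, np.integer):
            threshold = float(np.iinfo(raw.dtype).max) / 2.0
        else:
            threshold = 0.5
    if gray.shape[0] < 2 or gray.shape[1] < 2:
        raise ValidationError(
            f"mask {path} has shape {gray.shape}; need at least 2 rows and 2 columns"
        )
    return binarize(gray, threshold)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a {0,1} mask as an 8-bit PNG with values {0, 255}."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValidationError("mask values must all be 0 or 1")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def list_dataset(
    images_dir: str | Path, masks_dir: str | Path
) -> list[tuple[Path, Path]]:
    """Pair image and mask files by stem name, sorted lexicographically.

    Unmatched stems on either side raise a warning; an empty intersection is
    an error.
    """
    images_dir, masks_dir = Path(images_dir), Path(masks_dir)
    for d in (images_dir, masks_dir):
        if not d.is_dir():
            raise ValidationError(f"not a directory: {d}")

    def stems(d: Path) -> dict[str, Path]:
        return {
            p.stem: p
            for p in sorted(d.iterdir())
            if p.suffix.lower() in RASTER_SUFFIXES
        }

    imgs, msks = stems(images_dir), stems(masks_dir)
    common = sorted(imgs.keys() & msks.keys())
    unmatched = sorted((imgs.keys() | msks.keys()) - set(common))
    if not common:
        raise ValidationError(
            f"no image/mask stem names in common; unmatched: {unmatched}"
        )
    if unmatched:
        warnings.warn(f"unmatched dataset entries skipped: {unmatched}", stacklevel=2)
    return [(imgs[s], msks[s]) for s in common]
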