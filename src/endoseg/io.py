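"""Image and mask file I/O.

Images are held in memory as float arrays in [0, 1] regardless of file bit
depth: 8-bit files are divided by 255 and 16-bit by 65535 on read, and
quantised back on write.  Masks are binary {0, 1} in memory and {0, 255}
PNG on disk (boundary = nonzero on read).  PNG I/O goes through Pillow and
TIFF through tifffile.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


def read_image(path, to_gray: bool = False) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF into a float [0, 1] array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        if not to_gray:
            raise ValueError(
                f"{path} is multi-channel; pass to_gray=True for luminance conversion"
            )
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
        return np.clip(arr / _max_for_dtype(np.asarray(Image.open(path)).dtype), 0, 1)
    return arr.astype(float) / _max_for_dtype(arr.dtype)


def _max_for_dtype(dtype) -> float:
    dtype = np.dtype(dtype)
    if dtype == np.uint8:
        return 255.0
    if dtype == np.uint16:
        return 65535.0
    if dtype.kind == "f":
        return 1.0
    raise ValueError(f"unsupported image dtype {dtype}")


def write_image(path, image, bit_depth: int = 8) -> None:
    """Write a [0, 1] float image as 8-bit PNG or 8/16-bit TIFF."""
    path = Path(path)
    image = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bit_depth == 8:
        arr = np.round(image * 255.0).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(image * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        if bit_depth != 8:
            raise ValueError("PNG output supports 8-bit only; use TIFF for 16-bit")
        Image.fromarray(arr).save(path)


def read_mask(path) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel is boundary (1)."""
    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 0).astype(np.uint8)


def write_mask(path, mask) -> None:
    """Write a binary mask as a {0, 255} PNG (255 = boundary)."""
    mask = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(mask).save(Path(path))


def write_mask_display(path, mask) -> None:
    """Write a mask for display: boundary black on white background."""
    arr = np.where(np.asarray(mask) > 0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))
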