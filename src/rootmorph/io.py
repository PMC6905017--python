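"""Reading plate photographs and writing masks / measurement records."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ParameterError


def read_color_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG photograph as an H×W×3 uint8 RGB array.

    Grayscale inputs are expanded to three channels; alpha is dropped;
    deeper-than-8-bit inputs are rescaled to 8 bits with a warning.
    """
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ParameterError(f"unsupported image shape {img.shape} in {path}")
    if img.dtype != np.uint8:
        info = np.iinfo(img.dtype) if np.issubdtype(img.dtype, np.integer) else None
        warnings.warn(f"{path}: rescaling {img.dtype} image to 8 bits", stacklevel=2)
        if info is not None:
            img = (img.astype(np.float64) * (255.0 / info.max)).round().astype(np.uint8)
        else:
            mx = float(img.max()) or 1.0
            img = (img.astype(np.float64) * (255.0 / mx)).round().astype(np.uint8)
    return img


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (foreground = 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    """Read a mask PNG back as boolean (any non-zero pixel is foreground)."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 0


def write_json(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
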