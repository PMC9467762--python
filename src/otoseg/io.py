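"""Image, table and config round-trips.

8-bit grayscale PNG/TIFF in and out (losslessly); CSV tables with '.'
decimals in UTF-8; YAML configs echoed into output directories so every run
is self-describing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .exceptions import UnsupportedImageError

__all__ = ["read_image", "write_image", "write_table", "load_yaml", "dump_yaml"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale (or RGB-to-gray converted) PNG/TIFF."""
    path = Path(path)
    try:
        im = Image.open(path)
    except OSError as exc:
        raise UnsupportedImageError(f"cannot read image {path}: {exc}") from exc
    if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
        raise UnsupportedImageError(
            f"{path}: {im.mode}-mode (non-8-bit) images are not supported")
    if im.mode != "L":
        im = im.convert("L")
    return np.asarray(im, dtype=np.uint8)


def write_image(img: np.ndarray, path: str | Path) -> None:
    """Write an (H, W) uint8 array as 8-bit grayscale PNG/TIFF."""
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim != 2:
        raise UnsupportedImageError("only (H, W) uint8 arrays are written")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img, mode="L").save(path)


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.4f") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format=float_format, encoding="utf-8")


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_yaml(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=True)


def load_yaml(path: str | Path):
    try:
        with open(path, encoding="utf-8") as fh:
            return yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise UnsupportedImageError(f"malformed YAML in {path}: {exc}") from exc
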