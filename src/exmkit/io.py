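"""TIFF/CSV/JSON/YAML I/O helpers shared by the pipeline stages.

Images are written as TIFF with the pixel size embedded in the resolution
tags and duplicated in a JSON sidecar (``<image>.json``) so that round-trips
survive tools that strip tags.  Tables go through pandas CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "FormatError",
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "read_yaml",
    "write_json",
    "sha256_of",
]


class FormatError(ValueError):
    """Unreadable or unsupported file content."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(
    path, image: np.ndarray, pixel_size_um: Optional[float] = None
) -> Path:
    path = Path(path)
    kwargs = {"photometric": "minisblack"}
    if pixel_size_um:
        kwargs["resolution"] = (1.0 / pixel_size_um, 1.0 / pixel_size_um)
    tifffile.imwrite(path, np.asarray(image), **kwargs)
    meta = {"pixel_size_um": pixel_size_um, "shape": list(np.shape(image))}
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_image(path) -> tuple[np.ndarray, Optional[float]]:
    """Read a TIFF; returns (array, pixel_size_um or None)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise as a format error
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    pixel_size = None
    sidecar = _sidecar(path)
    if sidecar.exists():
        try:
            pixel_size = json.loads(sidecar.read_text()).get("pixel_size_um")
        except json.JSONDecodeError:
            pixel_size = None
    if pixel_size is None:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                if num:
                    pixel_size = den / num
    return arr, pixel_size


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such table: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc


def read_yaml(path):
    """Parse a YAML file whose root is a mapping or a sequence."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(data, (dict, list)):
        raise FormatError(f"YAML root must be a mapping or list in {path}")
    return data


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
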