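"""Volume and configuration I/O.

Volumes round-trip through MetaImage (.mhd/.raw) or NRRD via SimpleITK with
spacing metadata preserved bit-exactly; run configuration is YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import yaml

__all__ = ["write_volume", "read_volume", "load_config", "save_config", "config_hash"]

_SUPPORTED = (".mhd", ".nrrd", ".nii", ".nii.gz")


def write_volume(path, volume: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D array with spacing metadata; format chosen by extension."""
    path = Path(path)
    if not any(str(path).endswith(ext) for ext in _SUPPORTED):
        raise ValueError(f"unsupported volume format {path.suffix!r}; supported: {_SUPPORTED}")
    # SimpleITK uses (z, y, x) array order
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.moveaxis(volume, [0, 1, 2], [2, 1, 0])))
    img.SetSpacing(tuple(float(s) for s in spacing))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume back as (array in (x, y, z) order, spacing mm)."""
    path = Path(path)
    if not any(str(path).endswith(ext) for ext in _SUPPORTED):
        raise ValueError(f"unsupported volume format {path.suffix!r}; supported: {_SUPPORTED}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise IOError(f"cannot parse volume {path}: {exc}") from exc
    arr = np.moveaxis(sitk.GetArrayFromImage(img), [0, 1, 2], [2, 1, 0])
    return arr, tuple(img.GetSpacing())


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def save_config(path, config: dict) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config, fh, sort_keys=False)
        else:
            json.dump(config, fh, indent=2, sort_keys=True)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
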