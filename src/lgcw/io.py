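"""Readers, writers, and run configuration.

PNG (8/16-bit grayscale, via Pillow) and single-file NIfTI-1 (via nibabel,
volumes iterated slice-wise along the last axis) are the supported image
formats.  Intensities are read as floats without rescaling.  Label masks go
out as 16-bit PNG or uint16 NIfTI; binary masks as 8-bit PNG with values
{0, 255} or uint8 NIfTI {0, 1}.  Run configuration is a flat YAML/JSON
mapping mirroring the parameter dataclasses; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image as PILImage

from .core import EnergyParams, Image2D
from .errors import InvalidParameterError, LgcwError
from .phantom import PhantomSpec
from .watershed import WatershedParams

__all__ = [
    "read_image",
    "write_mask_png",
    "write_labels_png",
    "write_nifti",
    "write_iteration_log",
    "RunConfig",
    "load_config",
    "config_hash",
]

log = logging.getLogger("lgcw")


class ImageIOError(LgcwError, IOError):
    """Unreadable or malformed image file."""


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, format: str | None = None) -> list[Image2D]:
    """Read a grayscale image file into a list of :class:`Image2D` slices.

    PNG yields one slice; a NIfTI volume yields one slice per plane along
    its last axis, in order.  16-bit data are preserved without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    fmt = (format or ("nifti" if _is_nifti(path) else "png")).lower()
    if fmt == "png":
        try:
            with PILImage.open(path) as im:
                if im.mode not in ("L", "I", "I;16", "F"):
                    im = im.convert("I")
                arr = np.asarray(im, dtype=float)
        except Exception as exc:  # Pillow raises several unrelated types
            raise ImageIOError(f"cannot read {path} as PNG: {exc}") from exc
        log.info("read %s (PNG, %s px)", path, arr.shape)
        return [Image2D(arr)]
    if fmt == "nifti":
        try:
            vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        except Exception as exc:
            raise ImageIOError(f"cannot read {path} as NIfTI: {exc}") from exc
        if vol.ndim == 2:
            slices = [vol]
        elif vol.ndim == 3:
            slices = [vol[..., k] for k in range(vol.shape[-1])]
        else:
            raise ImageIOError(f"{path}: expected 2-D or 3-D NIfTI, got ndim={vol.ndim}")
        log.info("read %s (NIfTI, %d slice(s))", path, len(slices))
        return [Image2D(s) for s in slices]
    raise InvalidParameterError(f"unknown image format {fmt!r}")


def write_mask_png(mask: np.ndarray, path) -> None:
    """Binary mask as 8-bit PNG with values {0, 255}."""
    arr = (np.asarray(mask) != 0).astype(np.uint8) * 255
    PILImage.fromarray(arr, mode="L").save(str(path))


def write_labels_png(labels: np.ndarray, path) -> None:
    """Integer label mask as 16-bit PNG."""
    arr = np.asarray(labels)
    if arr.min() < 0 or arr.max() > np.iinfo(np.uint16).max:
        raise InvalidParameterError("labels out of uint16 range")
    PILImage.fromarray(arr.astype(np.uint16)).save(str(path))


def write_nifti(array: np.ndarray, path, dtype=np.uint8) -> None:
    nib.save(nib.Nifti1Image(np.asarray(array).astype(dtype), np.eye(4)), str(path))


def write_iteration_log(records, path) -> None:
    """Per-iteration energies as CSV (iter, E_data, E_reg, E_total)."""
    import pandas as pd

    pd.DataFrame(
        [(r.iteration, r.e_data, r.e_reg, r.e_total) for r in records],
        columns=["iter", "E_data", "E_reg", "E_total"],
    ).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Flat configuration for a pipeline run."""

    energy: EnergyParams = field(default_factory=EnergyParams)
    watershed: WatershedParams = field(default_factory=WatershedParams)
    phantom: PhantomSpec | None = None
    seed: int = 0
    verbosity: str = "INFO"


_SECTION_TYPES = {"energy": EnergyParams, "watershed": WatershedParams, "phantom": PhantomSpec}


def _build_section(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise InvalidParameterError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}"
        )
    kwargs = dict(mapping)
    for key in ("size", "center", "intensities", "gap"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are an error."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise InvalidParameterError("config root must be a mapping")
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTION_TYPES:
            setattr(cfg, key, _build_section(_SECTION_TYPES[key], value or {}))
        elif key == "seed":
            cfg.seed = int(value)
        elif key == "verbosity":
            cfg.verbosity = str(value)
        else:
            raise InvalidParameterError(f"unknown config key {key!r}")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a configuration, embedded in artifacts."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [encode(v) for v in obj]
        return obj

    payload = json.dumps(encode(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
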