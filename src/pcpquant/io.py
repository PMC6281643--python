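"""Image-stack container, TIFF/CSV I/O and run provenance.

Every image travels with a JSON sidecar recording channel names, pixel size
and (for z-stacks) the z-step, so that no stage ever addresses a channel by
index.  Every CSV written by the package starts with ``#``-prefixed
provenance lines (config hash, seed) and is read back with
``pandas.read_csv(..., comment="#")``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageStack",
    "write_field",
    "read_field",
    "write_csv",
    "read_csv",
    "config_hash",
]


@dataclass
class ImageStack:
    """Multichannel image with physical calibration.

    ``data`` is ``(C, Y, X)`` for single-plane images or ``(C, Z, Y, X)``
    for z-stacks, matched one-to-one with ``channels``.
    """

    data: np.ndarray
    channels: tuple
    pixel_size_um: float
    z_step_um: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, Y, X) or (C, Z, Y, X)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("first axis must match the number of channels")
        if self.data.ndim == 4 and self.z_step_um is None:
            raise ValueError("z-stacks need z_step_um")

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_planes(self) -> int:
        return self.data.shape[1] if self.is_stack else 1

    def channel(self, name: str) -> np.ndarray:
        """Raw channel data (2D plane or 3D z-stack) by role name."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; available: {', '.join(self.channels)}"
            ) from None
        return self.data[idx]

    def plane(self, name: str, z: int | None = None, projection: str = "max") -> np.ndarray:
        """A single 2D plane of a channel.

        For z-stacks, either a specific plane ``z`` or a projection
        (``max`` or ``mean``) across z, emulating the usual practice of
        extracting single-plane images from confocal stacks.
        """
        ch = self.channel(name)
        if ch.ndim == 2:
            return ch
        if z is not None:
            return ch[z]
        if projection == "max":
            return ch.max(axis=0)
        if projection == "mean":
            return ch.mean(axis=0)
        raise ValueError(f"unknown projection {projection!r}")


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_field(path, stack: ImageStack) -> Path:
    """Write a multichannel TIFF plus its JSON sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.data)
    sidecar = {
        "channels": list(stack.channels),
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "axes": "CZYX" if stack.is_stack else "CYX",
    }
    sidecar.update(stack.meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_field(path) -> ImageStack:
    """Read a multichannel TIFF written by :func:`write_field`."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path} for {path}")
    sidecar = json.loads(sidecar_path.read_text())
    data = tifffile.imread(path)
    meta = {
        k: v
        for k, v in sidecar.items()
        if k not in ("channels", "pixel_size_um", "z_step_um", "axes")
    }
    return ImageStack(
        data=data,
        channels=tuple(sidecar["channels"]),
        pixel_size_um=float(sidecar["pixel_size_um"]),
        z_step_um=sidecar.get("z_step_um"),
        meta=meta,
    )


def write_csv(df: pd.DataFrame, path, provenance: dict | None = None) -> Path:
    """Write a CSV with leading ``#`` provenance lines (config hash, seed...)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)
    return path


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_provenance(path) -> dict:
    """Parse the ``# key=value`` header lines of a package-written CSV."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            out[key.strip()] = value.strip()
    return out
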