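"""Calibrated 3D image stacks and their on-disk representation.

The in-memory container is a thin dataclass around a ``(z, y, x)`` numpy
array plus the physical voxel size in micrometres.  Stacks are written as
multi-page TIFF with the calibration repeated in a JSON sidecar, so that a
stack round-trips without relying on TIFF tag conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack3D", "read_stack", "write_stack"]


@dataclass
class ImageStack3D:
    """A single-channel fluorescence volume with voxel calibration.

    Parameters
    ----------
    data:
        Intensity grid, axis order ``(z, y, x)``.
    voxel_size:
        Physical voxel pitch in micrometres, ``(z, y, x)``.
    channel_label:
        Free-text stain/channel name (e.g. ``"GFAP"``).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack contains non-finite intensities")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values (z, y, x), got {self.voxel_size}")
        self.voxel_size = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def plane_area_um2(self) -> float:
        """Physical area of one XY plane in μm²."""
        _, dy, dx = self.voxel_size
        return self.data.shape[1] * dy * self.data.shape[2] * dx

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def pixel_size_yx(self) -> tuple[float, float]:
        """In-plane pitch (y, x) in μm."""
        return self.voxel_size[1], self.voxel_size[2]


def write_stack(stack: ImageStack3D, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF plus a ``.json`` calibration sidecar."""
    path = Path(path)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        np.asarray(stack.data, dtype=np.float32),
        resolution=(1.0 / dx, 1.0 / dy),
        photometric="minisblack",
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "voxel_size_um_zyx": list(stack.voxel_size),
                "channel_label": stack.channel_label,
                "shape_zyx": list(stack.shape),
            },
            indent=2,
        )
    )
    return path


def read_stack(
    path: str | Path,
    voxel_size: tuple[float, float, float] | None = None,
    channel_label: str | None = None,
) -> ImageStack3D:
    """Read a TIFF stack; calibration from the sidecar unless overridden."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if voxel_size is None:
        if "voxel_size_um_zyx" not in meta:
            raise ValueError(
                f"no voxel calibration for {path}: pass voxel_size or provide the JSON sidecar"
            )
        voxel_size = tuple(meta["voxel_size_um_zyx"])  # type: ignore[assignment]
    if channel_label is None:
        channel_label = meta.get("channel_label", "")
    return ImageStack3D(np.asarray(data, dtype=float), voxel_size, channel_label)
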