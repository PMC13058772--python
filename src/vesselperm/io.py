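"""Time-lapse stack container and multi-page TIFF + JSON sidecar I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import tifffile

from .permeability import FieldOfView

__all__ = ["TimeLapseStack", "sidecar_path", "write_stack", "read_stack"]


@dataclass
class TimeLapseStack:
    """Ordered RGB frames with timestamps and physical FOV metadata.

    ``frames`` has shape (T, ny, nx, 3), dtype uint8 or uint16; pixel (0, 0)
    is the top-left corner, x runs along image width.  ``meta`` carries any
    provenance (generating scenario, seed) and is written verbatim to the
    JSON sidecar.
    """

    frames: np.ndarray
    timestamps_min: np.ndarray
    fov: FieldOfView
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, ny, nx, 3)")
        if len(self.timestamps_min) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if np.any(np.diff(self.timestamps_min) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        ny, nx = self.frames.shape[1:3]
        if (nx, ny) != (self.fov.nx, self.fov.ny):
            raise ValueError(
                f"frame shape {nx}x{ny} px does not match FOV "
                f"{self.fov.nx}x{self.fov.ny} px"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_stack(stack: TimeLapseStack, path: str | Path) -> Path:
    """Write a multi-page RGB TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames, photometric="rgb")
    side = {
        "fov_um": [stack.fov.width_um, stack.fov.height_um],
        "shape_px": [stack.fov.nx, stack.fov.ny],
        "timestamps_min": [float(t) for t in stack.timestamps_min],
        **stack.meta,
    }
    sidecar_path(path).write_text(json.dumps(side, indent=2))
    return path


def read_stack(
    path: str | Path,
    fov: FieldOfView | None = None,
    timestamps_min: Sequence[float] | None = None,
) -> TimeLapseStack:
    """Read a multi-page TIFF stack; metadata from sidecar or explicit args.

    Explicit ``fov``/``timestamps_min`` override the sidecar; without a
    sidecar both are required.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 3:  # single page
        frames = frames[None]
    meta: dict[str, Any] = {}
    side = sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
    if fov is None:
        if "fov_um" not in meta or "shape_px" not in meta:
            raise ValueError(
                f"no sidecar at {side} and no explicit FOV given; "
                "provide physical size (--fov-um W H) and pixel shape "
                "(--shape-px NX NY)"
            )
        w, h = meta["fov_um"]
        nx, ny = meta["shape_px"]
        fov = FieldOfView(width_um=w, height_um=h, nx=int(nx), ny=int(ny))
    if timestamps_min is None:
        if "timestamps_min" not in meta:
            raise ValueError(
                f"no sidecar at {side} and no explicit timestamps given; "
                "provide --times-min"
            )
        timestamps_min = meta["timestamps_min"]
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("fov_um", "shape_px", "timestamps_min")
    }
    return TimeLapseStack(
        frames=frames,
        timestamps_min=np.asarray(timestamps_min, dtype=float),
        fov=fov,
        meta=extra,
    )
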