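"""Reading and writing alternating-gate frame stacks.

Two on-disk layouts: one lossless grayscale image file per frame with the
filename pattern ``frame{index:06d}_g{gate}.png``, or a single multi-page
TIFF.  Either way a YAML sidecar carries the acquisition configuration.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .model import AcquisitionConfig
from .simulate import GatedFrameStack

__all__ = ["write_stack", "read_stack", "SIDECAR_NAME"]

SIDECAR_NAME = "stack.yaml"
_FRAME_RE = re.compile(r"^frame(\d{6})_g([01])\.(png|tif|tiff)$")


def _container_dtype(bit_depth: int):
    if bit_depth <= 8:
        return np.uint8
    if bit_depth <= 16:
        return np.uint16
    raise ValueError(f"bit depth {bit_depth} exceeds the 16-bit container")


def write_stack(stack: GatedFrameStack, path, fmt: str = "png") -> Path:
    """Write a stack losslessly; returns the directory (or TIFF file) path.

    ``fmt='png'`` writes one file per frame plus a sidecar config;
    ``fmt='tiff'`` writes a single multi-page file plus the sidecar.
    Output is deterministic: the same stack produces identical bytes.
    """
    if stack.frames.shape[0] == 0:
        raise ValueError("refusing to write an empty stack")
    dtype = _container_dtype(stack.config.bit_depth)
    frames = stack.frames.astype(dtype)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "acquisition": stack.config.to_dict(),
        "n_frames": int(frames.shape[0]),
        "format": fmt,
    }
    if fmt == "png":
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame{i:06d}_g{i % 2}.png", frame)
    elif fmt == "tiff":
        tifffile.imwrite(path / "frames.tif", frames)
    else:
        raise ValueError(f"unknown stack format: {fmt!r}")
    (path / SIDECAR_NAME).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(path, config: Optional[AcquisitionConfig] = None) -> GatedFrameStack:
    """Read a stack written by :func:`write_stack`.

    Validates frame ordering, gate alternation, shape consistency and the
    q-bit value range.  Full-scale pixel values are accepted but the
    returned stack is flagged ``saturated``.
    """
    path = Path(path)
    sidecar = path / SIDECAR_NAME
    if config is None:
        if not sidecar.exists():
            raise FileNotFoundError(f"no sidecar config at {sidecar}")
        meta = yaml.safe_load(sidecar.read_text())
        config = AcquisitionConfig.from_dict(meta["acquisition"])
    fmt = "png"
    if sidecar.exists():
        fmt = yaml.safe_load(sidecar.read_text()).get("format", "png")

    if fmt == "tiff":
        frames = tifffile.imread(path / "frames.tif")
        if frames.ndim == 2:
            frames = frames[None]
    else:
        entries = {}
        for f in sorted(path.iterdir()):
            m = _FRAME_RE.match(f.name)
            if not m:
                continue
            idx, gate = int(m.group(1)), int(m.group(2))
            if gate != idx % 2:
                raise ValueError(f"frame {idx} labeled gate {gate}; expected {idx % 2}")
            entries[idx] = f
        if not entries:
            raise FileNotFoundError(f"no frame files found in {path}")
        n = max(entries) + 1
        missing = sorted(set(range(n)) - set(entries))
        if missing:
            raise ValueError(f"missing frame file(s): {missing}")
        imgs = [iio.imread(entries[i]) for i in range(n)]
        shapes = {im.shape for im in imgs}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent frame shapes: {sorted(shapes)}")
        frames = np.stack(imgs)

    m = 2 ** config.bit_depth - 1
    if frames.max(initial=0) > m:
        raise ValueError(
            f"pixel value {int(frames.max())} exceeds the {config.bit_depth}-bit range"
        )
    stack = GatedFrameStack(
        frames=frames,
        gate_index=np.arange(frames.shape[0]) % 2,
        config=config,
    )
    stack.saturated = bool((frames == m).any())
    return stack
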