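"""Frame container I/O.

A recording is a sequence of paired 640x480 uint16 frames: an infrared image
and a depth image whose pixel values are sensor-to-object distances in
millimeters (0 = no reading).  Two on-disk forms are supported:

* the ``.k3dv`` raw container — magic ``K3DV``, uint32 version=1, uint32
  width / height / frame_count, then per frame a uint64 timestamp in
  milliseconds followed by the infrared and depth payloads, row-major
  little-endian uint16;
* a directory of paired 16-bit TIFF/PNG images named ``ir_%06d`` /
  ``depth_%06d`` with an optional ``timestamps.csv`` (columns
  ``frame,timestamp_ms``; a nominal 30 Hz clock is assumed when absent).

Timestamps are stored per frame rather than assuming an exact 30 Hz clock:
the acquisition clock is data, not a constant.
"""

from __future__ import annotations

import re
import struct
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

MAGIC = b"K3DV"
VERSION = 1
_HEADER = struct.Struct("<4sIIII")  # magic, version, width, height, frame_count


class FormatError(ValueError):
    """File is not a recognizable frame container."""


class CorruptionError(ValueError):
    """Container truncated or inconsistent mid-stream."""


@dataclass
class FramePair:
    """One timestamped infrared + depth frame."""

    timestamp_ms: int
    infrared: np.ndarray  # (H, W) uint16
    depth: np.ndarray     # (H, W) uint16, mm; 0 = no reading

    def __post_init__(self):
        self.infrared = np.asarray(self.infrared, dtype=np.uint16)
        self.depth = np.asarray(self.depth, dtype=np.uint16)
        if self.infrared.shape != self.depth.shape:
            raise ValueError(
                f"infrared {self.infrared.shape} and depth {self.depth.shape} "
                "shapes differ"
            )


def write_sequence(frames, path) -> None:
    """Write FramePairs to a ``.k3dv`` container."""
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an empty frame sequence")
    h, w = frames[0].infrared.shape
    for i, fp in enumerate(frames):
        if fp.infrared.shape != (h, w):
            raise ValueError(f"frame {i}: shape {fp.infrared.shape} != {(h, w)}")
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, VERSION, w, h, len(frames)))
        for fp in frames:
            fh.write(struct.pack("<Q", int(fp.timestamp_ms)))
            fh.write(np.ascontiguousarray(fp.infrared, "<u2").tobytes())
            fh.write(np.ascontiguousarray(fp.depth, "<u2").tobytes())


def read_sequence(path) -> list[FramePair]:
    """Read a ``.k3dv`` container or an image-sequence directory."""
    path = Path(path)
    if path.is_dir():
        return _read_image_dir(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER.size:
        raise FormatError(f"{path}: too short for a K3DV header")
    magic, version, w, h, n = _HEADER.unpack_from(raw)
    if magic != MAGIC:
        raise FormatError(f"{path}: bad magic {magic!r}")
    if version != VERSION:
        raise FormatError(f"{path}: unsupported version {version}")
    frame_bytes = 8 + 2 * 2 * w * h
    frames = []
    off = _HEADER.size
    for i in range(n):
        if off + frame_bytes > len(raw):
            raise CorruptionError(f"{path}: truncated at frame {i}")
        (ts,) = struct.unpack_from("<Q", raw, off)
        off += 8
        ir = np.frombuffer(raw, "<u2", w * h, off).reshape(h, w)
        off += 2 * w * h
        dp = np.frombuffer(raw, "<u2", w * h, off).reshape(h, w)
        off += 2 * w * h
        frames.append(FramePair(ts, ir.copy(), dp.copy()))
    return frames


_IR_RE = re.compile(r"ir_(\d{6})\.(tif|tiff|png)$")


def _read_one(p: Path) -> np.ndarray:
    if p.suffix in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = iio.imread(p)
    return np.asarray(arr, dtype=np.uint16)


def _read_image_dir(path: Path) -> list[FramePair]:
    indexed = {}
    for p in sorted(path.iterdir()):
        m = _IR_RE.match(p.name)
        if m:
            indexed[int(m.group(1))] = p
    if not indexed:
        raise FormatError(f"{path}: no ir_%06d images found")
    ts_map = {}
    ts_csv = path / "timestamps.csv"
    if ts_csv.exists():
        import pandas as pd  # noqa: PLC0415

        df = pd.read_csv(ts_csv)
        ts_map = dict(zip(df["frame"].astype(int), df["timestamp_ms"].astype(int)))
    frames = []
    for order, idx in enumerate(sorted(indexed)):
        ir_path = indexed[idx]
        depth_path = None
        for ext in (".tif", ".tiff", ".png"):
            cand = path / f"depth_{idx:06d}{ext}"
            if cand.exists():
                depth_path = cand
                break
        if depth_path is None:
            raise FormatError(f"{path}: missing depth image for frame {idx}")
        ts = ts_map.get(idx, round(order * 1000 / 30))
        frames.append(FramePair(ts, _read_one(ir_path), _read_one(depth_path)))
    return frames


def write_image_sequence(frames, path, fmt: str = "tif") -> None:
    """Write FramePairs as paired 16-bit images plus a timestamps CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    lines = ["frame,timestamp_ms"]
    for i, fp in enumerate(frames):
        if fmt in ("tif", "tiff"):
            tifffile.imwrite(path / f"ir_{i:06d}.tif", fp.infrared)
            tifffile.imwrite(path / f"depth_{i:06d}.tif", fp.depth)
        else:
            iio.imwrite(path / f"ir_{i:06d}.png", fp.infrared)
            iio.imwrite(path / f"depth_{i:06d}.png", fp.depth)
        lines.append(f"{i},{int(fp.timestamp_ms)}")
    (path / "timestamps.csv").write_text("\n".join(lines) + "\n")
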