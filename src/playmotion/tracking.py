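"""Blob tracking: persistent identities, Kalman smoothing, depth attachment.

Blobs are associated frame-to-frame by nearest predicted centroid (greedy,
gated at 50 px/frame); unmatched blobs open new tracks with fresh numeric
identifiers, and tracks unmatched for more than 15 consecutive frames close.
Each track runs a constant-velocity Kalman filter (state: position and
velocity in x and y) whose posterior position is the smoothed centroid.

A depth reading is attached per entry by probing the depth frame at the
centroid and, when the sensor reads 0 there (e.g. subject flush against a
wall), searching growing windows (3x3, 5x5, ... up to 21x21) for the nonzero
value nearest the centroid; if none is found the entry's depth is missing
and the frame cannot contribute to the anteroposterior plane.

Child identities are confirmed outside the tracker: a whitelist of track ids
(one child may re-enter under a new id) selects and merges the tracks that
belong to a child.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .segmentation import FrameBlobs


def depth_lookup(depth_frame, centroid, max_window: int = 21) -> int | None:
    """Nearest nonzero depth reading around a centroid, or None.

    Probes the rounded centroid first, then growing centered windows up to
    ``max_window`` x ``max_window``; within the first window containing any
    nonzero reading, returns the one nearest the (real-valued) centroid by
    Euclidean distance, ties broken by raster order.
    """
    if max_window % 2 == 0:
        raise ValueError("max_window must be odd")
    depth = np.asarray(depth_frame)
    h, w = depth.shape
    fx, fy = float(centroid[0]), float(centroid[1])
    cx, cy = int(round(fx)), int(round(fy))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"centroid {centroid} outside the frame")
    if depth[cy, cx] != 0:
        return int(depth[cy, cx])
    for size in range(3, max_window + 1, 2):
        r = size // 2
        y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
        x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
        window = depth[y0:y1, x0:x1]
        ys, xs = np.nonzero(window)
        if ys.size:
            d2 = (xs + x0 - fx) ** 2 + (ys + y0 - fy) ** 2
            return int(window[ys[np.argmin(d2)], xs[np.argmin(d2)]])
    return None


class _KalmanCV:
    """Constant-velocity Kalman filter over (x, y) centroid measurements."""

    def __init__(self, x0, y0, dt=1.0, process_var=1.0, measurement_var=4.0):
        self.x = np.array([x0, y0, 0.0, 0.0])
        self.P = np.eye(4) * 100.0
        self.F = np.eye(4)
        self.F[0, 2] = self.F[1, 3] = dt
        self.H = np.zeros((2, 4))
        self.H[0, 0] = self.H[1, 1] = 1.0
        q = process_var
        self.Q = np.diag([q * dt**2 / 4, q * dt**2 / 4, q, q])
        self.R = np.eye(2) * measurement_var

    def predict(self) -> np.ndarray:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return self.x[:2].copy()

    def update(self, zx, zy) -> np.ndarray:
        z = np.array([zx, zy])
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ (z - self.H @ self.x)
        self.P = (np.eye(4) - K @ self.H) @ self.P
        return self.x[:2].copy()


@dataclass
class TrackEntry:
    timestamp_ms: int
    raw_centroid: tuple[float, float]
    smoothed_centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    ir_intensity: int | None = None
    depth_mm: int | None = None


@dataclass
class Track:
    track_id: int
    first_seen_ms: int
    entries: list[TrackEntry] = field(default_factory=list)

    @property
    def last_timestamp_ms(self) -> int:
        return self.entries[-1].timestamp_ms if self.entries else self.first_seen_ms


def associate(
    blob_frames: list[FrameBlobs],
    frames=None,
    config: RunConfig = RunConfig(),
) -> list[Track]:
    """Assign persistent identities to per-frame blobs.

    ``blob_frames`` must be time-ordered.  When the matching ``frames``
    (FramePairs, aligned so frames[i+1] produced blob_frames[i]) are given,
    each entry also records the infrared intensity at its smoothed centroid
    and a depth reading found by :func:`depth_lookup`.
    """
    active: list[tuple[Track, _KalmanCV, int]] = []  # (track, filter, misses)
    closed: list[Track] = []
    next_id = 1
    for i, fb in enumerate(blob_frames):
        preds = [(t, kf, kf.predict(), miss) for t, kf, miss in active]
        pairs = []
        for ti, (_, _, pred, _) in enumerate(preds):
            for bi, blob in enumerate(fb.blobs):
                d = float(np.hypot(pred[0] - blob.centroid[0], pred[1] - blob.centroid[1]))
                if d <= config.gate_px:
                    pairs.append((d, ti, bi))
        pairs.sort()
        used_t, used_b = set(), set()
        matches = {}
        for d, ti, bi in pairs:
            if ti in used_t or bi in used_b:
                continue
            used_t.add(ti)
            used_b.add(bi)
            matches[ti] = bi
        frame = frames[i + 1] if frames is not None else None
        new_active = []
        for ti, (track, kf, _, miss) in enumerate(preds):
            if ti in matches:
                blob = fb.blobs[matches[ti]]
                sx, sy = kf.update(*blob.centroid)
                new_active.append((track, kf, 0))
                track.entries.append(
                    _make_entry(fb.timestamp_ms, blob, (sx, sy), frame, config)
                )
            else:
                miss += 1
                if miss > config.track_timeout:
                    closed.append(track)
                else:
                    new_active.append((track, kf, miss))
        for bi, blob in enumerate(fb.blobs):
            if bi in used_b:
                continue
            kf = _KalmanCV(
                blob.centroid[0],
                blob.centroid[1],
                process_var=config.kalman_process_var,
                measurement_var=config.kalman_measurement_var,
            )
            track = Track(track_id=next_id, first_seen_ms=fb.timestamp_ms)
            next_id += 1
            track.entries.append(
                _make_entry(fb.timestamp_ms, blob, blob.centroid, frame, config)
            )
            new_active.append((track, kf, 0))
        active = new_active
    closed.extend(t for t, _, _ in active)
    closed.sort(key=lambda t: t.track_id)
    return closed


def _make_entry(ts_ms, blob, smoothed, frame, config: RunConfig) -> TrackEntry:
    ir_val = None
    depth_val = None
    if frame is not None:
        h, w = frame.infrared.shape
        cx = min(max(int(round(smoothed[0])), 0), w - 1)
        cy = min(max(int(round(smoothed[1])), 0), h - 1)
        ir_val = int(frame.infrared[cy, cx])
        depth_val = depth_lookup(frame.depth, (cx, cy), max_window=config.depth_window)
    return TrackEntry(
        timestamp_ms=int(ts_ms),
        raw_centroid=(float(blob.centroid[0]), float(blob.centroid[1])),
        smoothed_centroid=(float(smoothed[0]), float(smoothed[1])),
        bbox=blob.bbox,
        ir_intensity=ir_val,
        depth_mm=depth_val,
    )


def select_child_tracks(tracks: list[Track], id_whitelist, child_id: str | None = None) -> Track:
    """Merge the whitelisted tracks into one time-ordered child stream.

    A child who leaves and re-enters the scene accrues several track ids;
    the whitelist (confirmed by manual review) gathers them.  Absent ids are
    skipped with a warning.
    """
    wanted = set(id_whitelist)
    if not wanted:
        raise ValueError("id_whitelist must be non-empty")
    present = {t.track_id for t in tracks}
    for missing in sorted(wanted - present):
        warnings.warn(f"whitelisted track id {missing} not present", stacklevel=2)
    selected = [t for t in tracks if t.track_id in wanted]
    entries = sorted(
        (e for t in selected for e in t.entries), key=lambda e: e.timestamp_ms
    )
    first = min((t.first_seen_ms for t in selected), default=0)
    merged = Track(track_id=min(wanted), first_seen_ms=first, entries=entries)
    merged.child_id = child_id  # type: ignore[attr-defined]
    return merged


def write_tracks_jsonl(tracks: list[Track], path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for e in t.entries:
                fh.write(
                    json.dumps(
                        {
                            "track_id": t.track_id,
                            "first_seen_ms": t.first_seen_ms,
                            "timestamp_ms": e.timestamp_ms,
                            "raw_centroid": list(e.raw_centroid),
                            "smoothed_centroid": list(e.smoothed_centroid),
                            "bbox": list(e.bbox),
                            "ir_intensity": e.ir_intensity,
                            "depth_mm": e.depth_mm,
                        }
                    )
                    + "\n"
                )


def read_tracks_jsonl(path) -> list[Track]:
    by_id: dict[int, Track] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        t = by_id.setdefault(
            rec["track_id"], Track(rec["track_id"], rec["first_seen_ms"])
        )
        t.entries.append(
            TrackEntry(
                timestamp_ms=rec["timestamp_ms"],
                raw_centroid=tuple(rec["raw_centroid"]),
                smoothed_centroid=tuple(rec["smoothed_centroid"]),
                bbox=tuple(rec["bbox"]),
                ir_intensity=rec["ir_intensity"],
                depth_mm=rec["depth_mm"],
            )
        )
    return sorted(by_id.values(), key=lambda t: t.track_id)
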