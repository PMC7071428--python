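"""Synthetic 3D-camera stand-in.

Renders 640x480 infrared/depth frame sequences at 30 Hz from scripted object
trajectories, with exact ground truth (per-frame centroids, per-second
velocities per plane, matched second-by-second observation codes).  Also
provides an epoch-level synthetic "study" generator (children x labeled VM
epochs) for exercising the intensity classifiers.

What is emulated: integral 16-bit pixel values, a uniform mid-gray infrared
background with optional Gaussian noise, millimeter depth values with a
constant far-plane background, and depth dropouts (0 = no reading) while an
object is flush against a wall.  What is not: photorealism, occlusion
physics, or the real sensor's structured-light noise model.

Ground-truth metric velocities follow the pipeline's own convention: pixel
(or depth-bin) displacement per second multiplied by the depth->m/pixel
calibration line.  High metric speeds therefore correspond to large scripted
depths, which keep pixel-domain speeds inside the Fourier estimator's
unambiguous band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frameio import FramePair
from .motion import DEFAULT_CALIBRATION, CalibrationModel

FPS = 30
WIDTH, HEIGHT = 640, 480
IR_BACKGROUND = 8000     # uniform mid-gray background value
DEPTH_BACKGROUND = 4000  # constant far-plane, mm (the room is closed/finite)

#: Speed (m/s) -> observation code thresholds: below each bound maps to the
#: corresponding code (1 lying/sitting, 2 standing, 3 walking, 4 running).
CARS_SPEED_BOUNDS = ((0.05, 1), (0.5, 2), (1.5, 3))

INTENSITY_ORDER = ("SED", "LPA", "MVPA")


@dataclass
class TrajectoryScript:
    """A scripted moving object: shape, path, and sensor quirks.

    ``path`` holds ``(t_ms, x_px, y_px, depth_mm)`` knots; positions are the
    object's *centroid* and are linearly interpolated between knots.
    ``dropout_spans`` are ``(start_s, end_s)`` intervals during which the
    depth sensor reads 0 inside the object.
    """

    object_id: str
    shape: str = "rectangle"          # rectangle | ellipse
    height_px: int = 24
    width_px: int = 24
    path: list = field(default_factory=list)
    intensity: int = 30000
    dropout_spans: list = field(default_factory=list)
    cars_codes: list | None = None    # optional explicit per-second codes

    def __post_init__(self):
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (0 < self.intensity <= 65535):
            raise ValueError("intensity must be a uint16 value")
        ts = [p[0] for p in self.path]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("path timestamps must be strictly increasing")
        for t, x, y, d in self.path:
            if not (0 <= x < WIDTH and 0 <= y < HEIGHT):
                raise ValueError(f"path point at t={t} ms is outside the frame")
            if d < 0:
                raise ValueError(f"negative depth at t={t} ms")

    def at(self, t_ms) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (x, y, depth) at time(s) t_ms."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        knots = np.asarray(self.path, dtype=float)
        x = np.interp(t, knots[:, 0], knots[:, 1])
        y = np.interp(t, knots[:, 0], knots[:, 2])
        d = np.interp(t, knots[:, 0], knots[:, 3])
        return x, y, d


@dataclass
class GroundTruth:
    """Exact per-frame and per-second truth matching a rendered sequence."""

    object_id: str
    frame_times_ms: np.ndarray
    centroids: np.ndarray          # (n_frames, 2) scripted continuous (x, y)
    depth_mm: np.ndarray           # (n_frames,) scripted depth
    velocity_px: dict              # plane -> (n_seconds,) px (or mm) per second
    velocity_mps: dict             # plane -> (n_seconds,) m/s
    cars_codes: np.ndarray         # (n_seconds,) int codes 1..5

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n = len(self.cars_codes)
        vel = pd.DataFrame(
            [
                {"second": s, "plane": p, "velocity_mps": self.velocity_mps[p][s]}
                for s in range(n)
                for p in ("x", "y", "z")
            ]
        )
        vel.to_csv(out / f"truth_velocity_{self.object_id}.csv", index=False)
        pd.DataFrame(
            {"second": np.arange(n), "cars_code": self.cars_codes}
        ).to_csv(out / f"truth_cars_{self.object_id}.csv", index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "object_id": self.object_id,
                    "frame_times_ms": self.frame_times_ms.tolist(),
                    "centroids": self.centroids.tolist(),
                    "depth_mm": self.depth_mm.tolist(),
                    "velocity_px": {k: v.tolist() for k, v in self.velocity_px.items()},
                    "velocity_mps": {k: v.tolist() for k, v in self.velocity_mps.items()},
                    "cars_codes": self.cars_codes.tolist(),
                }
            )
        )


def _shape_mask(script: TrajectoryScript, cx: float, cy: float):
    """Rasterized footprint (row slice, col slice, boolean block)."""
    w, h = script.width_px, script.height_px
    x0 = int(round(cx - (w - 1) / 2))
    y0 = int(round(cy - (h - 1) / 2))
    if script.shape == "rectangle":
        block = np.ones((h, w), dtype=bool)
    else:
        yy, xx = np.mgrid[0:h, 0:w]
        block = (
            ((xx - (w - 1) / 2) / (w / 2)) ** 2 + ((yy - (h - 1) / 2) / (h / 2)) ** 2
        ) <= 1.0
    return slice(y0, y0 + h), slice(x0, x0 + w), block, x0, y0


def cars_code_for_speed(speed_mps: float) -> int:
    for bound, code in CARS_SPEED_BOUNDS:
        if speed_mps < bound:
            return code
    return 4


def _ground_truth(
    script: TrajectoryScript, frame_times: np.ndarray, duration_s: float,
    cal: CalibrationModel,
) -> GroundTruth:
    x, y, d = script.at(frame_times)
    centroids = np.column_stack([x, y])
    n_seconds = int(np.floor(duration_s))
    sec_t = np.arange(n_seconds + 1) * 1000.0
    sec_t = np.minimum(sec_t, frame_times[-1])
    sx, sy, sd = script.at(sec_t)
    v_px = {
        "x": np.diff(sx),
        "y": np.diff(sy),
        "z": np.diff(sd),  # depth bins (mm) per second
    }
    mid_depth = (sd[:-1] + sd[1:]) / 2
    scale = cal.scaling(mid_depth)
    v_mps = {p: v_px[p] * scale for p in v_px}
    if script.cars_codes is not None:
        codes = np.asarray(script.cars_codes[:n_seconds], dtype=int)
    else:
        speed = np.sqrt(sum(v_mps[p] ** 2 for p in v_mps))
        codes = np.array([cars_code_for_speed(s) for s in speed], dtype=int)
    return GroundTruth(
        object_id=script.object_id,
        frame_times_ms=frame_times,
        centroids=centroids,
        depth_mm=d,
        velocity_px=v_px,
        velocity_mps=v_mps,
        cars_codes=codes,
    )


def render_scene(
    scripts,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
) -> tuple[list[FramePair], list[GroundTruth]]:
    """Render one or more scripted objects into a shared frame sequence."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(duration_s * FPS))
    frame_times = np.round(np.arange(n_frames) * 1000.0 / FPS).astype(int)
    frames = []
    for i, t in enumerate(frame_times):
        ir = np.full((HEIGHT, WIDTH), IR_BACKGROUND, dtype=float)
        if noise_sd > 0:
            ir += rng.normal(0.0, noise_sd, size=ir.shape)
        depth = np.full((HEIGHT, WIDTH), DEPTH_BACKGROUND, dtype=np.uint16)
        for script in scripts:
            (cx,), (cy,), (cd,) = script.at(float(t))
            ys, xs, block, x0, y0 = _shape_mask(script, cx, cy)
            if x0 < 0 or y0 < 0 or ys.stop > HEIGHT or xs.stop > WIDTH:
                raise ValueError(
                    f"object {script.object_id!r} leaves the frame at t={t} ms"
                )
            ir_block = ir[ys, xs]
            ir_block[block] = script.intensity + (
                rng.normal(0.0, noise_sd, size=int(block.sum()))
                if noise_sd > 0
                else 0.0
            )
            t_s = t / 1000.0
            dropped = any(a <= t_s < b for a, b in script.dropout_spans)
            depth_block = depth[ys, xs]
            depth_block[block] = 0 if dropped else int(round(cd))
        ir = np.clip(np.round(ir), 0, 65535).astype(np.uint16)
        frames.append(FramePair(int(t), ir, depth))
    truths = [_ground_truth(s, frame_times, duration_s, cal) for s in scripts]
    return frames, truths


def render_sequence(
    script: TrajectoryScript,
    duration_s: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
) -> tuple[list[FramePair], GroundTruth]:
    """Render a single scripted object; see :func:`render_scene`."""
    frames, truths = render_scene([script], duration_s, noise_sd, seed, cal)
    return frames, truths[0]


# ---------------------------------------------------------------------------
# fixture construction helpers


def depth_for_target_velocity(
    v_mps: float, plane: str, peak_bin: int = 10, cal: CalibrationModel = DEFAULT_CALIBRATION,
    vmax: float | None = None, fps: int = FPS,
) -> float:
    """Scripted depth at which ``v_mps`` lands on FFT bin ``peak_bin``.

    The Fourier estimator reads speed from the peak bin k = a1*u (u in
    px/frame, a1 = K/vmax); pixels-per-second at bin k is k*vmax, so the
    required m/pixel scaling is v_mps / (k*vmax) and the depth follows from
    inverting the calibration line.
    """
    if vmax is None:
        vmax = {"x": 4.0, "y": 2.8, "z": 4.0}[plane]
    scaling = v_mps / (peak_bin * vmax)
    depth = (scaling - cal.intercept) / cal.slope
    if depth <= 0:
        raise ValueError(f"target velocity {v_mps} m/s too slow for bin {peak_bin}")
    return depth


def constant_velocity_script(
    plane: str,
    v_mps: float,
    duration_s: float,
    object_id: str = "obj1",
    peak_bin: int = 10,
    size_px: int = 24,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    vmax: float | None = None,
) -> TrajectoryScript:
    """Script a constant-velocity object whose metric speed is ``v_mps``.

    Motion is along ``plane``; for z (depth) a slow 1 px/frame x-drift is
    added so consecutive infrared frames differ and the object segments.
    """
    if vmax is None:
        vmax = {"x": 4.0, "y": 2.8, "z": 4.0}[plane]
    sign = 1.0 if v_mps >= 0 else -1.0
    depth = depth_for_target_velocity(abs(v_mps), plane, peak_bin, cal, vmax)
    # pixels/s at bin k is k*vmax (the depth choice makes that equal v/scaling)
    u = sign * peak_bin * vmax / FPS  # px/frame
    t_end = duration_s * 1000.0
    margin = size_px / 2 + 4
    if plane == "x":
        travel = u * FPS * duration_s
        x0 = margin if u >= 0 else WIDTH - margin
        if not (0 <= x0 + travel < WIDTH - margin + 1):
            raise ValueError("x travel does not fit in the frame")
        path = [(0.0, x0, HEIGHT / 2, depth), (t_end, x0 + travel, HEIGHT / 2, depth)]
    elif plane == "y":
        travel = u * FPS * duration_s
        y0 = margin if u >= 0 else HEIGHT - margin
        if not (0 <= y0 + travel < HEIGHT - margin + 1):
            raise ValueError("y travel does not fit in the frame")
        path = [(0.0, WIDTH / 2, y0, depth), (t_end, WIDTH / 2, y0 + travel, depth)]
    else:  # z: depth changes; x drifts to keep the infrared difference alive
        rate = v_mps / cal.scaling(depth)  # mm/s, == peak_bin * vmax
        drift = 1.0 * FPS * duration_s
        x0 = margin
        path = [
            (0.0, x0, HEIGHT / 2, depth),
            (t_end, x0 + drift, HEIGHT / 2, depth + rate * duration_s),
        ]
    return TrajectoryScript(
        object_id=object_id, shape="rectangle",
        height_px=size_px, width_px=size_px, path=path,
    )


# ---------------------------------------------------------------------------
# epoch-level synthetic study


def simulate_study(
    n_children: int = 10,
    epochs_per_child: int = 60,
    seed: int = 0,
    class_median_vm: dict | None = None,
    sdlog: float = 0.5,
    mean_shares: tuple = (0.278, 0.411, 0.311),
    share_concentration: float = 30.0,
) -> pd.DataFrame:
    """Simulate a labeled-epoch study: children x (VM value, intensity).

    Per child, intensity shares are drawn from a Dirichlet centered on the
    play-session pattern (LPA most common, then MVPA, then SED); VM values
    are class-conditional lognormals with ordered medians (SED < LPA < MVPA)
    and within-class spread ``sdlog``.  With the default medians (5/30/150)
    and sdlog 0.5, adjacent-class overlap keeps the Bayes confusion well
    under 15%.

    Returns a DataFrame with columns child_id, epoch_index, vm_value,
    intensity (the directly observed label).
    """
    if class_median_vm is None:
        class_median_vm = {"SED": 5.0, "LPA": 30.0, "MVPA": 150.0}
    rng = np.random.default_rng(seed)
    alpha = np.asarray(mean_shares, dtype=float)
    alpha = alpha / alpha.sum() * share_concentration
    rows = []
    for c in range(n_children):
        shares = rng.dirichlet(alpha)
        labels = rng.choice(INTENSITY_ORDER, size=epochs_per_child, p=shares)
        for e, lab in enumerate(labels):
            vm = rng.lognormal(mean=np.log(class_median_vm[lab]), sigma=sdlog)
            rows.append(
                {
                    "child_id": f"child{c + 1:02d}",
                    "epoch_index": e,
                    "vm_value": vm,
                    "intensity": lab,
                }
            )
    return pd.DataFrame(rows)
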