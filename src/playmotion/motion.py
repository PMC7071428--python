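"""Metric calibration, Fourier motion analysis, and vector-magnitude epochs.

The chain implemented here converts a tracked object's per-frame centroid /
depth stream into accelerometry-style activity signals:

1. **Calibration.**  A line of best fit between m/pixel scaling values and
   depth readings (mm), obtained by imaging an object of known height at
   several distances.  The study's fitted line was

       m/pixel = 1.5e-06 * depth_mm + 6.4e-04.

2. **Fourier velocity.**  For each plane (x = mediolateral pixel column,
   y = vertical pixel row, z = depth in mm) and each 1-s window of K = 30
   frames, the object's intensity value is placed at its coordinate in a 1-D
   projection array, the projection is multiplied elementwise by
   ``exp(i*2*pi*a1*q*dt)`` (q = array position index, a1 = K / vmax of the
   plane) and summed, giving one complex scalar per frame.  The FFT of the
   K scalars peaks at bin ``k = a1 * u`` for uniform motion of u px/frame,
   so the peak location encodes speed; the peak's frequency half (the
   complex encoding is one-sided) encodes its sign.  Velocity in pixels per
   window is ``K * k / a1``; multiplying by the calibration scaling at the
   window's depth converts to m/s.

   The estimator resolves velocity in steps of ``K / a1`` px/window (4 px/s
   in x and z) and is unambiguous for |u| < K/(2*a1) = vmax/2 px/frame
   (the Nyquist bin of the 30-point window).

3. **Accelerations and epochs.**  1 Hz velocity differences over standard
   gravity give per-plane acceleration in g; the per-second vector magnitude
   sqrt(ax^2+ay^2+az^2) is scaled by 1000 and aggregated into 5-s epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665  # m/s^2
PLANES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationModel:
    """Linear depth -> m/pixel scaling model."""

    slope: float       # (m/pixel) per mm of depth
    intercept: float   # m/pixel at zero depth

    def scaling(self, depth_mm) -> float | np.ndarray:
        return self.slope * np.asarray(depth_mm, dtype=float) + self.intercept


#: The study's published calibration line for its 10 ft x 10 ft play space.
DEFAULT_CALIBRATION = CalibrationModel(slope=1.5e-06, intercept=6.4e-04)


def fit_calibration(observations, true_height_m: float) -> CalibrationModel:
    """Least-squares fit of m/pixel on depth from known-height sightings.

    ``observations`` is a sequence of ``(depth_mm, object_px_height)`` pairs;
    each yields one scaling value ``true_height_m / object_px_height``.
    """
    obs = [(float(d), float(h)) for d, h in observations]
    if len(obs) < 2 or len({d for d, _ in obs}) < 2:
        raise ValueError("need observations at >=2 distinct depths to fit a line")
    if any(h <= 0 for _, h in obs):
        raise ValueError("pixel heights must be positive")
    depth = np.array([d for d, _ in obs])
    mpx = np.array([true_height_m / h for _, h in obs])
    slope, intercept = np.polyfit(depth, mpx, 1)
    return CalibrationModel(slope=float(slope), intercept=float(intercept))


# ---------------------------------------------------------------------------
# Fourier motion analysis


@dataclass
class ProjectionWindow:
    """One second of per-frame weighted projections for a single plane.

    ``positions[i]`` is the coordinate (pixel column/row for x/y, depth in mm
    for z) of frame slot i within the window, NaN when the frame was
    unevaluable; ``intensities[i]`` is the value placed at that coordinate
    (infrared intensity for x/y, the depth reading itself for z).
    """

    plane: str
    second_index: int
    positions: np.ndarray    # (K,) float, NaN = missing slot
    intensities: np.ndarray  # (K,) float
    a1: float
    dt: float                # inter-frame interval, s
    n: int = 640             # projection array length (informational)

    def __post_init__(self):
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions and intensities must align")
        if self.a1 <= 0:
            raise ValueError("a1 must be positive")


def _projection_scalar(position: float, intensity: float, a1: float, dt: float) -> complex:
    """Weighted projection -> complex scalar for one frame.

    Equivalent to building a zero 1-D array, writing ``intensity`` at index
    ``round(position)``, multiplying elementwise by ``exp(i*2*pi*a1*q*dt)``
    and summing: only the single nonzero element survives the sum.
    """
    q = round(position)
    return intensity * np.exp(1j * 2 * np.pi * a1 * q * dt)


def fourier_velocity(window: ProjectionWindow) -> float | None:
    """Signed velocity in pixels of motion per K-frame window, or None.

    Returns None when more than half of the window's frames are missing.
    A spectrum whose energy is entirely in the DC bin (stationary object)
    returns 0.0.
    """
    K = len(window.positions)
    valid = np.isfinite(window.positions) & np.isfinite(window.intensities)
    if valid.sum() < K / 2:
        return None
    s = np.zeros(K, dtype=complex)
    for i in np.flatnonzero(valid):
        s[i] = _projection_scalar(
            window.positions[i], window.intensities[i], window.a1, window.dt
        )
    mag = np.abs(np.fft.fft(s))
    half = K // 2
    # a stationary object concentrates all energy in the DC bin, while true
    # motion of >= 1 bin completes full phase cycles and cancels DC; a peak
    # that fails to rival DC is rounding jitter, not motion
    if mag[1:].max() <= 0.5 * mag[0]:
        return 0.0
    k_pos = 1 + int(np.argmax(mag[1 : half + 1]))
    k = k_pos
    if half + 1 < K:
        k_neg = half + 1 + int(np.argmax(mag[half + 1 :]))
        if mag[k_neg] > mag[k_pos]:
            k = k_neg - K  # negative-frequency half: motion in -q direction
    # uniform motion of u px/frame peaks at bin k = K*a1*u*dt, so pixels of
    # motion per window = u*K = k / (a1*dt); equals K*k/a1 at dt = 1/K s
    return float(k / (window.a1 * window.dt))


@dataclass
class VelocitySample:
    second_index: int
    plane: str
    v_px: float | None      # pixels of motion per 30-frame window, signed
    v_mps: float | None     # meters/second, signed
    depth_mm: float | None  # depth used for metric scaling


def to_mps(
    v_px: float | None,
    depth_mm: float | None,
    cal: CalibrationModel,
    vmax: float | None = None,
) -> float | None:
    """Convert a pixel velocity to m/s via the calibration line.

    Values beyond the plane's expected maximum are clipped with a warning.
    Missing depth makes the sample missing.
    """
    if v_px is None or depth_mm is None or not np.isfinite(depth_mm):
        return None
    v = float(v_px * cal.scaling(depth_mm))
    if vmax is not None and abs(v) > vmax:
        log.warning("velocity %.3f m/s exceeds vmax=%.2f; clipping", v, vmax)
        v = math.copysign(vmax, v)
    return v


# ---------------------------------------------------------------------------
# accelerations and vector-magnitude epochs


def accelerations(v_mps, timestamps_s=None) -> np.ndarray:
    """Per-sample acceleration in g from a 1 Hz velocity series.

    ``a[t] = (v[t] - v[t-1]) / dt / 9.80665`` with the first sample 0;
    NaN velocities propagate to the accelerations that use them.
    """
    v = np.asarray(
        [np.nan if x is None else float(x) for x in np.asarray(v_mps, dtype=object)],
        dtype=float,
    )
    if v.size == 0:
        return v
    if timestamps_s is None:
        dt = np.ones(v.size - 1)
    else:
        t = np.asarray(timestamps_s, dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("timestamps must be strictly increasing")
    a = np.empty_like(v)
    a[0] = 0.0 if np.isfinite(v[0]) else np.nan
    a[1:] = (v[1:] - v[:-1]) / dt / STANDARD_GRAVITY
    return a


@dataclass
class VMEpoch:
    epoch_index: int
    epoch_start_s: int
    vm_value: float | None   # unitless (g x 1000); None = missing epoch
    n_valid_seconds: int
    child_id: str | None = None


def vm_epochs(
    ax,
    ay,
    az,
    epoch_s: int = 5,
    stat: str = "mean",
    max_missing_seconds: int = 2,
    child_id: str | None = None,
) -> list[VMEpoch]:
    """Aggregate per-second triaxial accelerations into 5-s VM epochs.

    Per second, VM = sqrt(ax^2 + ay^2 + az^2) * 1000 (missing if any plane
    is missing that second); each non-overlapping epoch takes the mean (or
    sum) of its available per-second VMs and is marked missing when more
    than ``max_missing_seconds`` seconds are missing.
    """
    if stat not in ("mean", "sum"):
        raise ValueError("stat must be 'mean' or 'sum'")
    arrs = [np.asarray(a, dtype=float) for a in (ax, ay, az)]
    n = {a.size for a in arrs}
    if len(n) != 1:
        raise ValueError("plane series must be aligned (equal length)")
    vm = np.sqrt(arrs[0] ** 2 + arrs[1] ** 2 + arrs[2] ** 2) * 1000.0
    epochs = []
    for e, start in enumerate(range(0, vm.size, epoch_s)):
        chunk = vm[start : start + epoch_s]
        ok = np.isfinite(chunk)
        if chunk.size - ok.sum() > max_missing_seconds:
            value = None
        elif ok.sum() == 0:
            value = None
        else:
            value = float(chunk[ok].mean() if stat == "mean" else chunk[ok].sum())
        epochs.append(VMEpoch(e, start, value, int(ok.sum()), child_id))
    return epochs


# ---------------------------------------------------------------------------
# track -> velocities -> epochs plumbing


@dataclass
class TrackMotion:
    """Per-second velocities and epochs derived from one child's track."""

    velocities: pd.DataFrame  # columns: second, plane, v_px, v_mps, depth_mm
    epochs: list[VMEpoch] = field(default_factory=list)


def windows_from_entries(entries, config: RunConfig, t0_ms: int | None = None):
    """Slot track entries into per-second, per-plane projection windows.

    Entries are slotted by nominal frame index ``round(ts * 30 / 1000)``
    relative to ``t0_ms`` (default: first entry's second floor).  x/y windows
    carry the smoothed centroid and the infrared intensity at it; z windows
    carry the depth reading both as coordinate and as weight.
    """
    entries = sorted(entries, key=lambda e: e.timestamp_ms)
    if not entries:
        return []
    K = config.frames_per_window
    if t0_ms is None:
        t0_ms = 0
    n_seconds = int((entries[-1].timestamp_ms - t0_ms) * K / 1000 // K) + 1
    pos = {p: np.full((n_seconds, K), np.nan) for p in PLANES}
    inten = {p: np.full((n_seconds, K), np.nan) for p in PLANES}
    for e in entries:
        slot_abs = round((e.timestamp_ms - t0_ms) * K / 1000)
        sec, slot = divmod(int(slot_abs), K)
        if sec < 0 or sec >= n_seconds:
            continue
        x, y = e.smoothed_centroid
        pos["x"][sec, slot] = x
        inten["x"][sec, slot] = e.ir_intensity
        pos["y"][sec, slot] = y
        inten["y"][sec, slot] = e.ir_intensity
        if e.depth_mm is not None:
            pos["z"][sec, slot] = e.depth_mm
            inten["z"][sec, slot] = e.depth_mm
    windows = []
    dt = 1.0 / K
    sizes = {"x": 640, "y": 480, "z": 4096}
    for sec in range(n_seconds):
        for p in PLANES:
            windows.append(
                ProjectionWindow(
                    plane=p,
                    second_index=sec,
                    positions=pos[p][sec],
                    intensities=inten[p][sec],
                    a1=config.a1(p),
                    dt=dt,
                    n=sizes[p],
                )
            )
    return windows


def track_motion(
    entries,
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    config: RunConfig = RunConfig(),
    child_id: str | None = None,
) -> TrackMotion:
    """Full motion chain for one child stream: velocities -> VM epochs."""
    windows = windows_from_entries(entries, config)
    depth_by_sec: dict[int, float | None] = {}
    for w in windows:
        if w.plane == "z":
            d = float(np.nanmean(w.positions)) if np.isfinite(w.positions).any() else None
            depth_by_sec[w.second_index] = d
    rows = []
    for w in windows:
        v_px = fourier_velocity(w)
        depth = depth_by_sec.get(w.second_index)
        v_mps = to_mps(v_px, depth, cal, vmax=config.vmax(w.plane))
        rows.append(
            {
                "second": w.second_index,
                "plane": w.plane,
                "v_px": np.nan if v_px is None else v_px,
                "v_mps": np.nan if v_mps is None else v_mps,
                "depth_mm": np.nan if depth is None else depth,
            }
        )
    vel = pd.DataFrame(rows)
    accs = {}
    for p in PLANES:
        series = (
            vel[vel["plane"] == p].sort_values("second")["v_mps"].to_numpy(float)
        )
        accs[p] = accelerations(series)
    epochs = vm_epochs(
        accs["x"],
        accs["y"],
        accs["z"],
        epoch_s=config.epoch_s,
        stat=config.epoch_stat,
        max_missing_seconds=config.max_missing_seconds,
        child_id=child_id,
    )
    return TrackMotion(velocities=vel, epochs=epochs)


def epochs_to_frame(epochs: list[VMEpoch]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "child_id": [e.child_id for e in epochs],
            "epoch_index": [e.epoch_index for e in epochs],
            "epoch_start_s": [e.epoch_start_s for e in epochs],
            "vm_value": [np.nan if e.vm_value is None else e.vm_value for e in epochs],
            "n_valid_seconds": [e.n_valid_seconds for e in epochs],
        }
    )
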