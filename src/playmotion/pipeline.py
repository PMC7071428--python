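"""End-to-end orchestration helpers used by the CLI and validation scripts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .framegen import constant_velocity_script, render_sequence
from .motion import DEFAULT_CALIBRATION, CalibrationModel, track_motion
from .segmentation import segment_sequence
from .tracking import Track, associate, select_child_tracks


def extract_tracks(frames, config: RunConfig = RunConfig()) -> list[Track]:
    """Frames -> segmentation -> association: persistent blob tracks."""
    blob_frames = segment_sequence(frames, config)
    return associate(blob_frames, frames=frames, config=config)


def frames_to_motion(
    frames,
    config: RunConfig = RunConfig(),
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    id_whitelist=None,
    child_id: str | None = None,
):
    """Full chain for one recording: frames -> child track -> velocities/epochs."""
    tracks = extract_tracks(frames, config)
    if not tracks:
        raise RuntimeError("no tracks found in the recording")
    if id_whitelist is None:
        id_whitelist = [max(tracks, key=lambda t: len(t.entries)).track_id]
    child = select_child_tracks(tracks, id_whitelist, child_id=child_id)
    return track_motion(child.entries, cal=cal, config=config, child_id=child_id)


def velocity_recovery_experiment(
    velocities_by_plane: dict | None = None,
    duration_s: float = 12.0,
    config: RunConfig = RunConfig(),
    cal: CalibrationModel = DEFAULT_CALIBRATION,
    seed: int = 0,
) -> pd.DataFrame:
    """Render constant-velocity fixtures and push them through the pipeline.

    Returns one row per fixture-second with the scripted and recovered
    velocity in the fixture's motion plane, the relative error, and the
    finite-difference oracle (smoothed-centroid displacement over the
    second) for the pixel-domain estimate.
    """
    if velocities_by_plane is None:
        velocities_by_plane = {
            "x": [0.5, 1.5, 2.5, 3.5],
            "y": [0.3, 1.0, 1.8, 2.5],
            "z": [0.5, 1.5, 2.5, 3.5],
        }
    rows = []
    for plane, v_list in velocities_by_plane.items():
        for v in v_list:
            script = constant_velocity_script(plane, v, duration_s)
            frames, truth = render_sequence(
                script, duration_s, noise_sd=0.0, seed=seed, cal=cal
            )
            tm = frames_to_motion(frames, config=config, cal=cal)
            vel = tm.velocities
            sub = vel[vel["plane"] == plane].set_index("second")
            # finite-difference oracle on the smoothed positions feeding the FFT
            fd = _finite_difference_oracle(frames, plane, config, cal)
            n_sec = len(truth.velocity_mps[plane])
            for s in range(n_sec):
                if s not in sub.index:
                    continue
                est = float(sub.loc[s, "v_mps"])
                est_px = float(sub.loc[s, "v_px"])
                true = float(truth.velocity_mps[plane][s])
                rows.append(
                    {
                        "plane": plane,
                        "v_target_mps": v,
                        "second": s,
                        "v_true_mps": true,
                        "v_est_mps": est,
                        "v_est_px": est_px,
                        "fd_oracle_px": fd.get(s, np.nan),
                        "rel_err": abs(est - true) / abs(true) if true else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _finite_difference_oracle(frames, plane, config: RunConfig, cal) -> dict:
    """Smoothed-centroid (or depth) displacement per second, px (mm) / s."""
    tracks = extract_tracks(frames, config)
    if not tracks:
        return {}
    child = max(tracks, key=lambda t: len(t.entries))
    K = config.frames_per_window
    series: dict[int, dict[int, float]] = {}
    for e in child.entries:
        slot_abs = round(e.timestamp_ms * K / 1000)
        sec, slot = divmod(int(slot_abs), K)
        if plane == "x":
            val = e.smoothed_centroid[0]
        elif plane == "y":
            val = e.smoothed_centroid[1]
        else:
            if e.depth_mm is None:
                continue
            val = float(e.depth_mm)
        series.setdefault(sec, {})[slot] = val
    out = {}
    for sec, slots in series.items():
        if len(slots) < K / 2:
            continue
        first, last = min(slots), max(slots)
        if last == first:
            continue
        out[sec] = (slots[last] - slots[first]) / (last - first) * K
    return out
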