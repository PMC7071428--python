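"""Run configuration: every tunable constant of the pipeline in one flat record.

Defaults reproduce the published processing chain (difference threshold,
frame-noise threshold T, morphology sizes, depth-search window, per-plane
velocity ceilings, epoch length, intensity cut points).  A config travels with
every run so that each constant is auditable after the fact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, fields
from pathlib import Path


class ConfigError(ValueError):
    """Raised for unknown keys or malformed values in a config source."""


@dataclass
class RunConfig:
    # segmentation
    pixel_threshold: int = 1400     # |IR difference| above this marks foreground
    frame_threshold: int = 14000    # T: more foreground pixels -> frame unevaluable
    min_component: int = 375        # smallest surviving connected component, px
    disk_radius: int = 9            # closing structuring element radius, px
    square_width: int = 25          # merging dilation structuring element width, px
    thin_iterations: int = 1
    # tracking
    depth_window: int = 21          # max depth-search window around centroid, px
    gate_px: float = 50.0           # association gate, px/frame
    track_timeout: int = 15         # frames unmatched before a track closes
    kalman_process_var: float = 1.0     # px^2
    kalman_measurement_var: float = 4.0  # px^2
    # motion
    vmax_x: float = 4.0             # m/s
    vmax_y: float = 2.8             # m/s
    vmax_z: float = 4.0             # m/s
    frames_per_window: int = 30     # K: frames per 1-s Fourier window
    integer_a1: bool = False        # round a1 = K/vmax to an integer
    epoch_s: int = 5
    epoch_stat: str = "mean"        # mean | sum over the 5-s bin
    max_missing_seconds: int = 2    # per epoch; one more marks the epoch missing
    # intensity cut points on the weighted observation score
    cut_sed: float = 2.0
    cut_mvpa: float = 3.0
    # classification
    min_leaf: int = 20
    max_depth: int = 8
    n_boot: int = 2000
    # randomness
    seed: int = 0

    def vmax(self, plane: str) -> float:
        return {"x": self.vmax_x, "y": self.vmax_y, "z": self.vmax_z}[plane]

    def a1(self, plane: str) -> float:
        """Plane-specific frequency scaling constant, K / vmax."""
        a = self.frames_per_window / self.vmax(plane)
        return float(round(a)) if self.integer_a1 else a

    def replace(self, **kw) -> "RunConfig":
        unknown = set(kw) - {f.name for f in fields(self)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(
            "".join(f"{k}={v}\n" for k, v in self.to_dict().items())
        )


def _coerce(name: str, raw: str, typ):
    if typ is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"{name}: cannot parse boolean from {raw!r}")
    try:
        return typ(raw)
    except ValueError as exc:
        raise ConfigError(f"{name}: {exc}") from None


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from an optional key=value file plus overrides.

    Unknown keys are rejected (ConfigError) so that typos cannot silently
    fall back to defaults.
    """
    types = {f.name: f.type for f in fields(RunConfig)}
    resolved = {
        f.name: (bool if f.type == "bool" else type(f.default))
        for f in fields(RunConfig)
    }
    kw: dict = {}
    if path is not None:
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            k, v = (s.strip() for s in line.split("=", 1))
            if k not in resolved:
                raise ConfigError(f"{path}:{lineno}: unknown config key {k!r}")
            kw[k] = _coerce(k, v, resolved[k])
    for k, v in (overrides or {}).items():
        if k not in resolved:
            raise ConfigError(f"unknown config key {k!r}")
        kw[k] = _coerce(k, str(v), resolved[k]) if isinstance(v, str) else v
    del types
    return RunConfig(**kw)


def save_run_snapshot(config: RunConfig, out_dir, extra: dict | None = None) -> None:
    """Write the config + provenance JSON next to a run's outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.txt")
    import numpy, scipy, skimage, sklearn  # noqa: PLC0415

    meta = {
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "scikit-learn": sklearn.__version__,
        "seed": config.seed,
    }
    meta.update(extra or {})
    (out / "run.json").write_text(json.dumps(meta, indent=2))
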