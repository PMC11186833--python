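"""Run configuration: every pipeline default, round-trippable through YAML."""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import MotionModel, Optics

__all__ = ["RunConfig", "DEFAULT_CONFIG"]

# Every tunable of the workflow with its default; values are documented in
# docs/methods.md.  The simulate section encodes the study conditions: an
# 8.3 mm near-spherical pearl, ~93 frames per ring at ~68% overlap,
# 256 px frames, friction efficiency ~0.785 and sliding noise.
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_frames": 93,
        "z_plan_mm": [0.0, 0.016, 0.032],
        "semi_axes_mm": [4.15, 4.15],
        "texture_resolution": 4096,
        "optics": {
            "magnification": 1.0,
            "pixel_pitch": 3.45,
            "sensor_px": [256, 256],
            "focal_length": 5.75,
            "working_distance": None,
            "dof_half_width": 0.01,
            "blur_scale": 150.0,
            "illumination_gradient": 0.0,
        },
        "motion": {
            "efficiency": 25.13 / 32.0,
            "step_mm": 0.36,
            "arc_noise_sd": 0.05,
            "lateral_sd": 0.004,
        },
        "format": "png",
    },
    "stack": {"window": 9, "smooth_sigma": 4.0},
    "match": {"ratio": 0.75, "inlier_tol_px": 2.0, "upsampling": 1},
    "refine": {
        "max_iterations": 30,
        "tol_px": 1.0e-3,
        "optimize_radius": True,
        "optimize_focal": False,
        "max_points_per_pair": 40,
    },
    "surface": {"mesh_subdivisions": 4, "texture_canvas_width": 1024},
    "calibrate": {
        "grid_start_mm": 4.0,
        "grid_stop_mm": 7.0,
        "grid_step_mm": 0.25,
        "refine_iterations": 0,
    },
    "validate": {"measured_d_min_mm": None, "measured_d_max_mm": None},
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


@dataclass
class RunConfig:
    """Workflow configuration; unknown keys are rejected at load time."""

    data: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __getitem__(self, key):
        return self.data[key]

    def __eq__(self, other):
        return isinstance(other, RunConfig) and self.data == other.data

    @classmethod
    def from_dict(cls, override: dict | None = None) -> "RunConfig":
        cfg = cls(_merge(DEFAULT_CONFIG, override or {}))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path_or_text) -> "RunConfig":
        text = (
            Path(path_or_text).read_text()
            if isinstance(path_or_text, Path) or (
                isinstance(path_or_text, str) and "\n" not in path_or_text
                and Path(path_or_text).exists()
            )
            else str(path_or_text)
        )
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def validate(self) -> None:
        unknown = set(self.data) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        if self.data["simulate"]["n_frames"] < 2:
            raise ValueError("simulate.n_frames must be >= 2")
        self.optics()  # triggers Optics invariant checks
        self.motion()

    def optics(self) -> Optics:
        o = dict(self.data["simulate"]["optics"])
        o["sensor_px"] = tuple(o["sensor_px"])
        return Optics(**o)

    def motion(self, seed: int | None = None) -> MotionModel:
        m = dict(self.data["simulate"]["motion"])
        m["seed"] = self.data["seed"] if seed is None else seed
        return MotionModel(**m)

    def focal_grid(self) -> list[float]:
        c = self.data["calibrate"]
        start, stop, step = c["grid_start_mm"], c["grid_stop_mm"], c["grid_step_mm"]
        if step <= 0 or stop < start:
            raise ValueError("invalid focal grid")
        n = int(round((stop - start) / step)) + 1
        return [round(start + i * step, 10) for i in range(n)]
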