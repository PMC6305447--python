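"""Run configuration: one serializable object reproduces a full pipeline run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calibration import CalibrationConstants
from .phantom import PhantomTissueParams


@dataclass
class RunConfig:
    """Everything a pipeline run needs; fully serializable to YAML.

    A run is reproducible from its archived config plus ``seed``.
    """

    seed: int = 0
    # phantom
    shape: tuple[int, int, int] = (32, 32, 32)
    preset: str = "default"
    voxel_size: float = 1.2  # mm
    tissue: PhantomTissueParams = field(default_factory=PhantomTissueParams)
    noise_sigma: float = 0.0
    # acquisition
    n_dirs: int = 61
    b_shells: tuple[float, ...] = (1200.0, 2400.0)
    n_b0: int = 1
    delta: float = 0.03  # s
    # tensor estimation
    r_mode: str = "cumulant"  # or "ground_truth"
    # calibration
    calibration: CalibrationConstants = field(default_factory=CalibrationConstants)
    # source
    source_voxel: tuple[int, int, int] | str = "wm_center"
    schedule_ul_min: tuple[tuple[float, float], ...] = ((0.0, 1.8),)
    source_mode: str = "fixed_rate"
    dp: float | None = None
    c_in: float = 1.0
    p_boundary: float = 0.0  # Pa
    # solver
    dt: float = 1.0  # s
    t_end: float = 3600.0  # s
    snapshot_times: tuple[float, ...] = ()
    face_average: str = "arithmetic"
    # comparison
    dv_fraction: float = 0.05
    f_floor: float = 1e-3

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "tissue" in d and isinstance(d["tissue"], dict):
            d["tissue"] = PhantomTissueParams(**d["tissue"])
        if "calibration" in d and isinstance(d["calibration"], dict):
            d["calibration"] = CalibrationConstants(**d["calibration"])
        for key in ("shape", "b_shells", "snapshot_times"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "schedule_ul_min" in d:
            d["schedule_ul_min"] = tuple(tuple(seg) for seg in d["schedule_ul_min"])
        if "source_voxel" in d and not isinstance(d["source_voxel"], str):
            d["source_voxel"] = tuple(d["source_voxel"])
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
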