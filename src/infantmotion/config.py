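"""Run configuration with validated defaults for every pipeline stage.

All tunable constants of the video-analysis pipeline live here, so that a
single YAML file (plus a seed) fully determines a run.  Unknown keys are
rejected on load and every value is range-checked, which keeps manifests
trustworthy for reproduction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunConfig:
    # --- recording geometry ---
    fps: float = 30.0                 # frames per second
    # --- preprocessing ---
    threshold_T: int = 80             # brightness-difference binarisation threshold
    morph_iterations: int = 3         # erosion reps, then dilation reps
    morph_element: str = "square3"    # 3x3 square (8-connected)
    # --- regions ---
    rect_margin: float = 1.2          # bounding-rectangle margin fraction
    head_side: str = "top"            # head direction in image coordinates
    min_foreground_px: int = 50       # below this the body is "not detected"
    # --- kinematics ---
    E_frames: int = 300               # running-max horizon for the reference posture
    Le_frames: int = 300              # reference window (frames) for P_avg and G_avg
    movement_threshold: float = 0.01  # M_th: normalized movement judged "moving"
    cutoff_M_hz: float = 10.0         # Butterworth cutoff for movement signals
    cutoff_Gv_hz: float = 5.0         # Butterworth cutoff for body-center velocity
    # --- features ---
    band_lo_hz: float = 0.1           # spectral analysis band (excludes DC)
    band_hi_hz: float = 10.0
    welch_nperseg: int = 512
    ratio_ceiling: float = 1e3        # cap for I4/I5 when the denominator is 0
    coordination_mode: str = "pearson"  # I6 estimator ("pearson" or "cooccurrence")
    qc_min_duration_s: float = 180.0  # recordings at or below this are discarded
    qc_min_activity: float = 0.10     # whole-body movement fraction cutoff (inclusive)
    # --- selection ---
    retention_alpha: float = 0.10     # Brunner-Munzel retention level
    lump_r: float = 0.7               # |r| threshold for lumping correlated features
    # --- classification ---
    mlp_hidden_grid: tuple[int, ...] = tuple(range(2, 21))
    llgmn_components_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    tuning_repetitions: int = 10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 <= self.threshold_T <= 255:
            raise ValueError("threshold_T must lie in [0, 255]")
        if self.morph_iterations < 0:
            raise ValueError("morph_iterations must be >= 0")
        if self.morph_element not in ("square3", "cross3"):
            raise ValueError(f"unknown morph_element {self.morph_element!r}")
        if self.rect_margin < 0:
            raise ValueError("rect_margin must be >= 0")
        if self.head_side not in ("top", "bottom", "left", "right"):
            raise ValueError(f"invalid head_side {self.head_side!r}")
        if not 1 <= self.E_frames <= self.Le_frames:
            raise ValueError("need 1 <= E_frames <= Le_frames")
        if self.movement_threshold <= 0:
            raise ValueError("movement_threshold must be positive")
        nyq = self.fps / 2.0
        for name in ("cutoff_M_hz", "cutoff_Gv_hz"):
            if not 0 < getattr(self, name) < nyq:
                raise ValueError(f"{name} must lie in (0, Nyquist)")
        if not 0 <= self.band_lo_hz < self.band_hi_hz:
            raise ValueError("need 0 <= band_lo_hz < band_hi_hz")
        if not 0 < self.retention_alpha <= 1:
            raise ValueError("retention_alpha must lie in (0, 1]")
        if not 0 < self.lump_r <= 1:
            raise ValueError("lump_r must lie in (0, 1]")
        if self.tuning_repetitions < 1:
            raise ValueError("tuning_repetitions must be >= 1")
        if any(h < 1 for h in self.mlp_hidden_grid):
            raise ValueError("MLP hidden-node counts must be >= 1")
        if any(c < 1 for c in self.llgmn_components_grid):
            raise ValueError("LLGMN component counts must be >= 1")

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("mlp_hidden_grid", "llgmn_components_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["mlp_hidden_grid"] = list(self.mlp_hidden_grid)
        d["llgmn_components_grid"] = list(self.llgmn_components_grid)
        return d

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


DEFAULTS = RunConfig()
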