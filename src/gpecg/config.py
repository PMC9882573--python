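"""Pipeline configuration with strict YAML round-tripping.

Every effective parameter of the pipeline lives here so runs are fully
described by one file; unknown keys are rejected on load rather than
silently ignored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .wavelet import WaveletConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Aggregated settings for preprocess → detect → filter → benchmark."""

    band: tuple[float, float] = (5.0, 80.0)
    n_phase: int | str = "auto"  # fixed integer, or "auto" = ceil(1.1 * max beat)
    alignment: str = "r_aligned"  # or "single"
    gp_mode: str = "diag"  # or "full"
    v_n_method: str = "baseline"  # or "oracle"
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    levels: tuple[int, ...] = (-5, 0, 5, 10, 15, 20, 25, 30)
    reps: int = 5
    seed0: int = 0
    lead: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1]):
            raise ValueError("band must satisfy 0 < low < high")
        if self.alignment not in ("r_aligned", "single"):
            raise ValueError(f"unknown alignment {self.alignment!r}")
        if self.gp_mode not in ("diag", "full"):
            raise ValueError(f"unknown gp mode {self.gp_mode!r}")
        if self.v_n_method not in ("baseline", "oracle"):
            raise ValueError(f"unknown noise-variance method {self.v_n_method!r}")
        if isinstance(self.n_phase, str) and self.n_phase != "auto":
            raise ValueError("n_phase must be an integer or 'auto'")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    def save(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["levels"] = list(self.levels)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "wavelet" in raw and isinstance(raw["wavelet"], dict):
            raw["wavelet"] = WaveletConfig(**raw["wavelet"])
        for key in ("band", "levels"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
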