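"""Analysis configuration: window, missingness, binning and stride constants."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .types import ValidationError


@dataclass
class AnalysisConfig:
    """Tunable constants of the analysis pipeline.

    Defaults encode the study conventions: an 18-hour activity window
    (6 AM to midnight), days with under 10% wear treated as missing,
    baseline/end medians over at most 14 calendar days, 12 x 15-minute
    post-inhalation bins, and a constant stride model for the digital
    six-minute walk distance (the device's stride algorithm is proprietary,
    so the stride is an explicit, configurable parameter here).
    """

    activity_window_start_hour: int = 6
    activity_window_end_hour: int = 24
    min_wear_fraction: float = 0.10
    baseline_max_days: int = 14
    end_window_days: int = 14
    fas_min_baseline_days: int = 3
    fas_min_end_days: int = 3
    n_bins: int = 12
    bin_minutes: int = 15
    stride_length_m: float = 0.78
    resting_hr_window_min: int = 5
    #: exclude a session on ANY unworn follow-up minute (True) or tolerate a
    #: partially worn first 15-minute bin (False, default)
    strict_alignment: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.activity_window_start_hour < self.activity_window_end_hour <= 24):
            raise ValidationError("activity window hours must satisfy 0 <= start < end <= 24")
        if not (0 < self.min_wear_fraction <= 1):
            raise ValidationError("min_wear_fraction must lie in (0, 1]")
        for name in (
            "baseline_max_days",
            "end_window_days",
            "fas_min_baseline_days",
            "fas_min_end_days",
            "n_bins",
            "bin_minutes",
            "resting_hr_window_min",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.stride_length_m <= 0:
            raise ValidationError("stride_length_m must be positive")

    @property
    def window_minutes(self) -> int:
        return (self.activity_window_end_hour - self.activity_window_start_hour) * 60

    @property
    def horizon_minutes(self) -> int:
        """Length of the post-inhalation analysis horizon."""
        return self.n_bins * self.bin_minutes

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
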