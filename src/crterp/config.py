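"""Pipeline configuration.

Defaults are the analysis constants of the study design: epochs from
-50 to 550 ms around stimulus onset at 512 Hz, a +/-100 uV rejection
threshold, a 1-30 Hz second-order Butterworth band, the 10-electrode /
15-timepoint / p<0.005 spatiotemporal cluster criterion, the p<0.01 /
30 ms ROI criterion, and the microstate fitting windows 145-300,
295-405 and 405-470 ms.

Configs round-trip through a flat ``key: value`` YAML file.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid or unknown configuration values."""


@dataclass
class PipelineConfig:
    """Scalar constants of the analysis chain.

    All times in ms, amplitudes in uV, frequencies in Hz.
    """

    epoch_window: tuple[float, float] = (-50.0, 550.0)
    srate: float = 512.0
    reject_threshold: float = 100.0
    band: tuple[float, float] = (1.0, 30.0)
    filter_order: int = 2
    cluster_min_electrodes: int = 10
    cluster_min_timepoints: int = 15
    cluster_alpha: float = 0.005
    roi_alpha: float = 0.01
    roi_min_duration: float = 30.0
    fit_windows: tuple[tuple[float, float], ...] = (
        (145.0, 300.0),
        (295.0, 405.0),
        (405.0, 470.0),
    )
    source_windows: tuple[tuple[float, float], ...] = (
        (145.0, 205.0),
        (210.0, 300.0),
        (405.0, 470.0),
    )
    source_alpha: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.epoch_window = tuple(float(v) for v in self.epoch_window)
        self.band = tuple(float(v) for v in self.band)
        self.fit_windows = tuple(tuple(float(v) for v in w) for w in self.fit_windows)
        self.source_windows = tuple(
            tuple(float(v) for v in w) for w in self.source_windows
        )
        if self.srate <= 0:
            raise ConfigError("srate must be positive")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ConfigError(f"epoch_window {self.epoch_window} is not ordered")
        for name in ("reject_threshold", "cluster_alpha", "roi_alpha", "source_alpha",
                     "roi_min_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("filter_order", "cluster_min_electrodes", "cluster_min_timepoints"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if not 0 < self.band[0] < self.band[1]:
            raise ConfigError(f"band {self.band} is not ordered and positive")
        for w in self.fit_windows + self.source_windows:
            if w[0] >= w[1]:
                raise ConfigError(f"window {w} is not ordered")
        for a in (self.cluster_alpha, self.roi_alpha, self.source_alpha):
            if not a < 1:
                raise ConfigError("alpha levels must be < 1")

    # -- persistence ---------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a flat key: value YAML file; unknown keys are errors."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key: value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict:
        d = asdict(self)
        # YAML-friendly: tuples to lists
        return json.loads(json.dumps(d))

    def digest(self) -> str:
        """Short stable hash of the configuration, used in run logs."""
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
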