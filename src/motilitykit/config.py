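"""Run configuration.

Defaults mirror the standard analysis settings: a 50x50 px structure
window moved in 5 px increments, a 128-bin histogram smoothed over 5
bins for thresholding, a 6-12 h migration-rate fit window, and 30 min
imaging cadence. Every run writes its effective configuration next to
its outputs so results are reproducible from the directory alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from motilitykit.errors import InputError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    window: int = 50  # px
    stride: int = 5  # px
    n_bins: int = 128
    smoothing_width: int = 5  # bins
    min_peak_separation: int = 10  # bins
    rate_window: tuple[float, float] = (6.0, 12.0)  # hours
    frame_interval: float = 0.5  # hours
    pixel_size: float = 1.0  # um per pixel
    min_track_points: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        if "rate_window" in raw:
            raw["rate_window"] = tuple(float(v) for v in raw["rate_window"])
        return cls(**raw)

    def write(self, directory: "str | Path") -> Path:
        """Write the effective config (plus package version) to a run directory."""
        from motilitykit import __version__

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        payload = dataclasses.asdict(self)
        payload["rate_window"] = list(self.rate_window)
        payload["motilitykit_version"] = __version__
        out = directory / "config.yaml"
        out.write_text(yaml.safe_dump(payload, sort_keys=True))
        return out
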