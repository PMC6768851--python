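"""Seeded synthetic data with known ground truth.

Generators for the three observable families the package analyzes:

* :func:`synthesize_scratch_timelapse` — a confluent, textured monolayer
  with a central low-texture scratch band that closes linearly in time,
  emulating phase-contrast wound-healing imaging (default cadence one
  frame every 30 minutes);
* :func:`synthesize_tracks` — drift-plus-diffusion cell trajectories
  sampled at a fixed interval (default ~16 minutes, 55 cycles, the
  cadence of organotypic slice-culture time-lapse imaging);
* :func:`synthesize_group_tables` — per-field count tables and grouped
  continuous measurements with a specified true effect.

Every generator is a pure function of its parameters and seed, and
returns a :class:`GroundTruth` record alongside the data so downstream
estimators can be tested for parameter recovery.

The monolayer texture model is i.i.d. Gaussian pixel noise: the band
geometry and the local-SD contrast between scratch and monolayer are
what the downstream algorithm consumes, and i.i.d. noise keeps the
analytic ground truth exact. Real phase-contrast texture is spatially
correlated; see the methods note for what this does and does not cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from motilitykit.errors import ParameterError
from motilitykit.scratch import ImageStack
from motilitykit.tracks import CellTrack

__all__ = [
    "ScratchSimParams",
    "TrackSimParams",
    "GroupSpec",
    "GroundTruth",
    "synthesize_scratch_timelapse",
    "synthesize_tracks",
    "synthesize_group_tables",
    "scratch_band_width",
]


@dataclass(frozen=True)
class ScratchSimParams:
    """Parameters of the linear-closure scratch time-lapse model.

    The scratch is a single centered vertical band whose width shrinks
    linearly at ``closure_rate`` pixels per hour (total width decrease).
    Pixels inside the band are i.i.d. Normal(scratch_mean, scratch_sd);
    all other pixels are i.i.d. Normal(monolayer_mean, monolayer_sd).
    ``monolayer_sd >> scratch_sd`` provides the local-texture contrast
    that scratch segmentation relies on.
    """

    image_width: int = 600
    image_height: int = 400
    initial_scratch_width: int = 300
    closure_rate: float = 20.0  # px/h, total band-width decrease
    frame_interval: float = 0.5  # hours
    n_frames: int = 49  # 24 h at 30 min cadence
    monolayer_mean: float = 120.0
    monolayer_sd: float = 30.0
    scratch_mean: float = 120.0
    scratch_sd: float = 3.0
    blur_sigma: float = 0.0  # optional optics blur; analytic invariants need 0
    seed: int = 0

    def validate(self) -> None:
        if self.image_width < 1 or self.image_height < 1:
            raise ParameterError("image dimensions must be positive")
        if not 0 < self.initial_scratch_width < self.image_width:
            raise ParameterError(
                "initial_scratch_width must be in (0, image_width)"
            )
        if self.closure_rate < 0:
            raise ParameterError("closure_rate must be >= 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if not self.monolayer_sd > self.scratch_sd >= 0:
            raise ParameterError("require monolayer_sd > scratch_sd >= 0")
        if self.blur_sigma < 0:
            raise ParameterError("blur_sigma must be >= 0")


@dataclass(frozen=True)
class TrackSimParams:
    """Parameters of the drift-plus-diffusion trajectory model.

    Each track gets a fixed random heading (persistent migration) and a
    uniform random start position; per step the displacement is
    ``drift_speed * frame_interval`` micrometers along the heading plus
    isotropic Gaussian noise with per-axis standard deviation
    ``diffusion_sd * sqrt(frame_interval)``. Positions are stored in
    pixels via ``pixel_size``.
    """

    n_tracks: int = 100
    drift_speed: float = 6.0  # um/h
    diffusion_sd: float = 2.0  # um per sqrt(hour)
    frame_interval: float = 16.0 / 60.0  # hours (~16 min)
    n_cycles: int = 55
    pixel_size: float = 0.62  # um per pixel
    field_size: float = 512.0  # px, square field for start positions
    seed: int = 0

    def validate(self) -> None:
        if self.n_tracks < 1:
            raise ParameterError("n_tracks must be >= 1")
        if self.drift_speed < 0:
            raise ParameterError("drift_speed must be >= 0")
        if self.diffusion_sd < 0:
            raise ParameterError("diffusion_sd must be >= 0")
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be > 0")
        if self.n_cycles < 2:
            raise ParameterError("n_cycles must be >= 2")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """One group of a synthetic grouped dataset."""

    name: str
    n: int
    mean: float
    sd: float = 1.0


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters recorded alongside every dataset."""

    true_closure_rate: float | None = None  # px/h
    true_closure_rate_fraction: float | None = None  # scratch fraction/h
    true_drift_speed: float | None = None  # um/h
    true_group_effect: float | None = None  # ratio or shift, per generator
    extras: dict = field(default_factory=dict)


def scratch_band_width(params: ScratchSimParams, t: float) -> int:
    """Band width in whole pixels at time ``t`` hours (linear closure)."""
    return int(round(max(0.0, params.initial_scratch_width - params.closure_rate * t)))


def synthesize_scratch_timelapse(
    params: ScratchSimParams,
) -> tuple[ImageStack, GroundTruth]:
    """Generate a wound-healing time-lapse with linearly closing scratch.

    Frame ``k`` (at ``t = k * frame_interval``) has a centered vertical
    band of width ``round(max(0, initial_scratch_width - closure_rate*t))``
    pixels drawn from the scratch intensity distribution; every other
    pixel is drawn from the monolayer distribution. Identical
    ``(params, seed)`` give a bit-identical stack.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    H, W = params.image_height, params.image_width
    frames = np.empty((params.n_frames, H, W), dtype=np.float64)
    times = np.arange(params.n_frames) * params.frame_interval
    for k, t in enumerate(times):
        frame = rng.normal(params.monolayer_mean, params.monolayer_sd, (H, W))
        w = scratch_band_width(params, t)
        if w > 0:
            start = (W - w) // 2
            frame[:, start : start + w] = rng.normal(
                params.scratch_mean, params.scratch_sd, (H, w)
            )
        if params.blur_sigma > 0:
            frame = gaussian_filter(frame, params.blur_sigma)
        frames[k] = frame
    truth = GroundTruth(
        true_closure_rate=params.closure_rate,
        true_closure_rate_fraction=params.closure_rate / params.image_width,
        extras={"initial_fraction": params.initial_scratch_width / params.image_width},
    )
    return ImageStack(frames=frames, timestamps=times), truth


def synthesize_tracks(
    params: TrackSimParams,
) -> tuple[list[CellTrack], GroundTruth]:
    """Generate drift-plus-diffusion cell trajectories.

    Deterministic given the seed. With ``diffusion_sd == 0`` every step
    length is exactly ``drift_speed * frame_interval`` micrometers, so
    path-length mean speed recovers ``drift_speed`` exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    dt = params.frame_interval
    t = np.arange(params.n_cycles) * dt
    tracks: list[CellTrack] = []
    for i in range(params.n_tracks):
        start_px = rng.uniform(0.0, params.field_size, size=2)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        drift_um = params.drift_speed * dt * np.array(
            [np.cos(heading), np.sin(heading)]
        )
        noise_um = rng.normal(
            0.0, params.diffusion_sd * np.sqrt(dt), size=(params.n_cycles - 1, 2)
        )
        steps_px = (drift_um + noise_um) / params.pixel_size
        pos = np.vstack([start_px, start_px + np.cumsum(steps_px, axis=0)])
        tracks.append(
            CellTrack(
                track_id=f"track{i:04d}",
                t=t.copy(),
                x=pos[:, 0],
                y=pos[:, 1],
                pixel_size=params.pixel_size,
            )
        )
    truth = GroundTruth(true_drift_speed=params.drift_speed)
    return tracks, truth


def synthesize_group_tables(
    groups: list[GroupSpec],
    seed: int = 0,
    kind: str = "continuous",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format grouped table with a recorded true effect.

    ``kind="continuous"`` draws Normal(mean, sd) values; the recorded
    effect is the location shift of each group's mean relative to the
    first (reference) group. ``kind="counts"`` draws Poisson(mean)
    per-field counts (emulating invaded-cell counts, several imaged
    fields per insert); the recorded effect is the ratio of each group's
    mean to the reference group's mean.

    Returns a DataFrame with columns ``value, group, field`` and the
    ground truth (``true_group_effect`` is the non-reference/reference
    effect of the second group; per-group effects are in ``extras``).
    """
    if len(groups) < 2:
        raise ParameterError("need at least two groups")
    if any(g.n < 1 for g in groups):
        raise ParameterError("every group needs n >= 1")
    if kind not in ("continuous", "counts"):
        raise ParameterError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in groups:
        if kind == "continuous":
            values = rng.normal(g.mean, g.sd, g.n)
        else:
            if g.mean < 0:
                raise ParameterError("count group mean must be >= 0")
            values = rng.poisson(g.mean, g.n).astype(float)
        for j, v in enumerate(values):
            rows.append({"value": v, "group": g.name, "field": j})
    table = pd.DataFrame(rows)
    ref = groups[0]
    if kind == "continuous":
        effects = {g.name: g.mean - ref.mean for g in groups[1:]}
    else:
        effects = {g.name: g.mean / ref.mean if ref.mean else np.nan for g in groups[1:]}
    truth = GroundTruth(
        true_group_effect=effects[groups[1].name],
        extras={"per_group_effect": effects, "kind": kind, "reference": ref.name},
    )
    return table, truth
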