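"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np


class StageLabel(str, Enum):
    """Cell-cycle stage inferred from SPB foci: one focus, or two separated by
    less / more than 2 μm."""

    PRE_MITOTIC = "pre-mitotic"
    SHORT_SPINDLE = "short-spindle"
    LONG_SPINDLE = "long-spindle"


@dataclass
class SpindleTrajectory:
    """Per-cell time series of 3D spindle length.

    Times are minutes on a uniform grid with t = 0 at SPB separation (spindle
    formation); lengths are μm and non-negative.
    """

    times: np.ndarray
    lengths: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape or self.times.ndim != 1:
            raise ValueError("times and lengths must be 1D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("trajectory needs at least two samples")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, self.frame_interval, atol=1e-9):
            raise ValueError("times must form a uniform grid at frame_interval")
        if not np.any(np.isclose(self.times, 0.0)):
            raise ValueError("trajectory must contain t = 0 (SPB separation)")
        if np.any(self.lengths < 0):
            raise ValueError("lengths must be >= 0")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SisterTrack:
    """Sister-chromatid (lacO/lacI-GFP dot) behaviour for one cell.

    ``separation_time`` is minutes relative to spindle formation and may be
    negative (separation before SPB separation); ``None`` means separation was
    never observed (censored).  ``fate`` is "failed" when both sisters end at
    the same pole, "accurate" when they reach opposite poles.
    """

    separation_time: Optional[float]
    fate: str
    times: Optional[np.ndarray] = None
    inter_sister_distance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.fate not in ("accurate", "failed"):
            raise ValueError(f"unknown fate {self.fate!r}")


@dataclass
class CellRecord:
    """One simulated (or measured) cell with whatever ground truth is known."""

    cell_id: str
    trajectory: SpindleTrajectory
    sister_track: Optional[SisterTrack] = None
    true_class: Optional[str] = None
    true_anaphase_onset: Optional[float] = None
    barrel_ratio_true: Optional[float] = None
    orientation: tuple[float, float] = (0.0, 0.0)  # (azimuth rad, z-tilt rad)
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.true_class is not None and self.true_class not in (
            "normal",
            "immediate",
            "failed",
        ):
            raise ValueError(f"unknown phenotype class {self.true_class!r}")


@dataclass
class ImageStack:
    """Multi-channel 4D intensity volume with physical voxel geometry.

    ``data`` has axes (channel, t, z, y, x); ``channel_map`` maps channel name
    to index along the first axis.  ``ground_truth`` carries sidecar metadata
    (known focus coordinates, true spindle lengths, barrel ratio) when the
    stack was rendered synthetically.
    """

    data: np.ndarray
    pixel_size_xy: float
    z_step: float
    frame_interval: float
    channel_map: dict[str, int]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 5:
            raise ValueError("data must have axes (channel, t, z, y, x)")
        if self.pixel_size_xy <= 0 or self.z_step <= 0 or self.frame_interval <= 0:
            raise ValueError("voxel sizes and frame interval must be > 0")
        if sorted(self.channel_map.values()) != list(range(self.data.shape[0])):
            raise ValueError("channel_map must index every channel exactly once")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[1])

    def channel(self, name: str) -> np.ndarray:
        """Return the (t, z, y, x) volume of one named channel."""
        return self.data[self.channel_map[name]]

    def volume(self, name: str, frame: int) -> np.ndarray:
        """Return the (z, y, x) volume of one channel at one frame."""
        return self.channel(name)[frame]


@dataclass
class FocusDetection:
    """A sub-voxel localized fluorescent focus in physical coordinates (μm)."""

    frame: int
    channel: str
    x: float
    y: float
    z: float
    integrated_intensity: float
    n_foci_found: int = 1

    @property
    def coords(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class RegionQuant:
    """Integrated-fluorescence measurement with local background subtraction.

    The inner 5×5 box holds signal plus local background; the 11-pixel ring
    between the 6×6 and 5×5 boxes samples background alone, which is scaled by
    the area ratio 25/11 and subtracted.
    """

    inner_sum: float
    outer_sum: float

    @property
    def ring_sum(self) -> float:
        return self.outer_sum - self.inner_sum

    @property
    def background_estimate(self) -> float:
        return self.ring_sum * (25.0 / 11.0)

    @property
    def signal(self) -> float:
        return self.inner_sum - self.background_estimate
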