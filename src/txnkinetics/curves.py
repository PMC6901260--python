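"""Acquisition schedules and recovery-curve containers.

The FRAP acquisition protocols of the study are represented as an
:class:`AcquisitionSchedule`: a number of pre-bleach frames followed by one or
more (duration, frame-interval) segments after the bleach.  Two presets mirror
the published protocols:

``sf-frap``
    splicing-factor (confocal) FRAP: 5 pre-bleach frames, post-bleach imaging
    at 4 frames per 2 s (0.5 s interval); the total post-bleach span is not
    printed and defaults to 60 s here.
``mrna-frap``
    mRNA (3D-FRAP) protocol: 6 pre-bleach frames and three post-bleach
    segments, 45 s / 90 s / 480 s.  The printed intra-segment intervals
    ("every 3 msec" and "every 30 msec") are inconsistent with the stated
    durations and with EM-CCD frame rates; this preset uses 0.3 s / 6 s / 30 s.
    The literal printed values are kept as ``mrna-frap-printed`` for
    reference; they cannot be simulated at any admissible time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Pre-bleach frame count plus ordered (duration_s, interval_s) segments."""

    n_prebleach: int
    segments: tuple[tuple[float, float], ...]
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "segments", tuple(tuple(map(float, s)) for s in self.segments))
        if self.n_prebleach < 0:
            raise ConfigurationError("n_prebleach must be >= 0")
        if not self.segments:
            raise ConfigurationError("schedule needs at least one post-bleach segment")
        for dur, iv in self.segments:
            if dur <= 0 or iv <= 0:
                raise ConfigurationError(
                    f"segment durations and intervals must be positive, got ({dur}, {iv})"
                )
        if self.n_frames < 2:
            raise ConfigurationError("schedule must contain at least 2 frames")

    @property
    def prebleach_interval(self) -> float:
        return self.segments[0][1]

    def prebleach_times(self) -> np.ndarray:
        """Frame times before the bleach (negative seconds, bleach at 0)."""
        iv = self.prebleach_interval
        return -iv * np.arange(self.n_prebleach, 0, -1)

    def postbleach_times(self) -> np.ndarray:
        """Frame times from the bleach onward; the bleach frame is t = 0."""
        times = [0.0]
        t0 = 0.0
        for dur, iv in self.segments:
            n = int(round(dur / iv))
            times.extend(t0 + iv * np.arange(1, n + 1))
            t0 += n * iv
        return np.asarray(times)

    def frame_times(self) -> np.ndarray:
        return np.concatenate([self.prebleach_times(), self.postbleach_times()])

    @property
    def n_frames(self) -> int:
        return self.n_prebleach + len(self.postbleach_times())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_prebleach": self.n_prebleach,
            "segments": [list(s) for s in self.segments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionSchedule":
        return cls(
            n_prebleach=int(d["n_prebleach"]),
            segments=tuple(tuple(s) for s in d["segments"]),
            name=d.get("name", ""),
        )


SCHEDULE_PRESETS: dict[str, AcquisitionSchedule] = {
    "sf-frap": AcquisitionSchedule(n_prebleach=5, segments=((60.0, 0.5),), name="sf-frap"),
    "mrna-frap": AcquisitionSchedule(
        n_prebleach=6, segments=((45.0, 0.3), (90.0, 6.0), (480.0, 30.0)), name="mrna-frap"
    ),
    "mrna-frap-printed": AcquisitionSchedule(
        n_prebleach=6, segments=((45.0, 0.003), (90.0, 6.0), (480.0, 0.030)),
        name="mrna-frap-printed",
    ),
}


def get_schedule(ref: str | AcquisitionSchedule) -> AcquisitionSchedule:
    if isinstance(ref, AcquisitionSchedule):
        return ref
    if ref not in SCHEDULE_PRESETS:
        raise ConfigurationError(
            f"unknown schedule preset {ref!r}; available: {sorted(SCHEDULE_PRESETS)}"
        )
    return SCHEDULE_PRESETS[ref]


@dataclass
class RecoveryCurve:
    """A normalized FRAP time series with replicate statistics.

    ``times`` are seconds from the bleach (negative for pre-bleach frames,
    the bleach frame at 0), ``mean``/``sem`` are across replicates or
    simulated sites, ``n`` is the replicate count.
    """

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    schedule: AcquisitionSchedule | None = None
    n_prebleach: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.times) == len(self.mean) == len(self.sem)):
            raise ConfigurationError("times, mean and sem must share length")
        if np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("curve times must be strictly increasing")

    @property
    def post_mask(self) -> np.ndarray:
        return self.times >= 0

    def post(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.post_mask
        return self.times[m], self.mean[m]

    def prebleach_mean(self) -> float:
        pre = self.mean[~self.post_mask]
        return float(pre.mean()) if pre.size else float("nan")


@dataclass
class Trajectory:
    """Time course of the simulated channels, summed over a site."""

    times: np.ndarray
    total_ms2: np.ndarray
    total_bleached: np.ndarray
    intron_signal: np.ndarray
    exon_signal: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        for name in ("total_ms2", "total_bleached", "intron_signal", "exon_signal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ConfigurationError(f"{name} length does not match times")

    def to_frame(self):
        """Tidy table (one row per time point) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times,
                "total_ms2": self.total_ms2,
                "total_bleached": self.total_bleached,
                "unbleached": self.total_ms2 - self.total_bleached,
                "intron_signal": self.intron_signal,
                "exon_signal": self.exon_signal,
            }
        )
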