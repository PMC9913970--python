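"""Per-track motility statistics.

All speeds are reported in um/min (the field's convention) while positions
are stored in um and time in seconds; the single unit conversion ``60 / dt``
is applied here and nowhere else.

Definitions
-----------
instantaneous velocity
    ``v_i = |p_i - p_{i-1}| / dt``, one value per frame interval.
mean track speed
    total path length divided by track duration; identical to the arithmetic
    mean of interval speeds at uniform sampling (both are computed and the
    identity asserted).
track displacement length
    straight-line distance between first and last position.
pausing phase (arrest event)
    maximal run of consecutive intervals with instantaneous velocity strictly
    below the threshold (4 um/min in vivo, 2 um/min in spheroids — supplied
    by configuration, never hard-coded), lasting at least ``min_duration``
    (default 30 s, i.e. one interval).
arrest coefficient
    fraction of intervals spent below the threshold, in [0, 1]; undefined
    (NaN) for a track with no intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .compartments import DEFAULT_APPROACH_BAND_UM, classify_track
from .tracks import Track, TrackSet

__all__ = [
    "VelocitySeries",
    "ArrestEvent",
    "MotilitySummary",
    "DEFAULT_PAUSE_THRESHOLD_UM_MIN",
    "SPHEROID_PAUSE_THRESHOLD_UM_MIN",
    "DEFAULT_MIN_PAUSE_S",
    "instantaneous_velocity",
    "mean_track_speed",
    "track_displacement_length",
    "path_length",
    "detect_pauses",
    "arrest_coefficient",
    "fraction_paused_cells",
    "summarize_track",
    "summarize_cohort",
]

#: Pause threshold used for the in vivo (DSFC) model, um/min.
DEFAULT_PAUSE_THRESHOLD_UM_MIN = 4.0
#: Pause threshold for the spheroid model, where cells move slower, um/min.
SPHEROID_PAUSE_THRESHOLD_UM_MIN = 2.0
#: Minimum pause duration, seconds (one 30 s interval).
DEFAULT_MIN_PAUSE_S = 30.0


@dataclass(frozen=True)
class VelocitySeries:
    """Per-interval speeds of one track, um/min."""

    track_id: int
    speeds: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "speeds", np.asarray(self.speeds, dtype=float))

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass(frozen=True)
class ArrestEvent:
    """One pausing phase: a maximal below-threshold run of intervals."""

    start_frame: int
    end_frame: int  # inclusive index of the last interval's end frame
    duration_s: float
    mean_speed: float


@dataclass
class MotilitySummary:
    """One row of the per-track summary table."""

    track_id: int
    experiment_id: str
    group: str
    n_intervals: int
    mean_track_speed: float
    track_displacement_length: float
    path_length: float
    arrest_coefficient: float
    n_pauses: int
    pausing_durations_s: list[float] = field(default_factory=list)
    total_paused_s: float = 0.0
    compartment: str | None = None


def instantaneous_velocity(track: Track) -> VelocitySeries:
    """Interval speeds ``|p_i - p_{i-1}| / dt`` in um/min.

    A single-position track yields an empty series (with a warning); gap
    frames split the track so no speed spans a gap.
    """
    if len(track) < 2:
        warnings.warn(
            f"track {track.track_id}: fewer than 2 positions, empty velocity series",
            stacklevel=2,
        )
        return VelocitySeries(track.track_id, np.empty(0), track.dt)
    parts = []
    for seg in track.segments():
        steps = np.linalg.norm(np.diff(seg.positions, axis=0), axis=1)
        parts.append(steps / seg.dt * 60.0)
    speeds = np.concatenate(parts) if parts else np.empty(0)
    return VelocitySeries(track.track_id, speeds, track.dt)


def path_length(track: Track) -> float:
    """Total distance travelled along the track, um (within segments)."""
    return float(
        sum(
            np.linalg.norm(np.diff(seg.positions, axis=0), axis=1).sum()
            for seg in track.segments()
        )
    )


def mean_track_speed(track: Track) -> float:
    """Mean track speed = path length / duration, um/min.

    At uniform sampling this equals the arithmetic mean of interval speeds;
    the identity is asserted as an internal consistency check.
    """
    vs = instantaneous_velocity(track)
    if len(vs) == 0:
        return float("nan")
    mean_of_speeds = float(np.mean(vs.speeds))
    duration_min = len(vs) * track.dt / 60.0
    by_path = path_length(track) / duration_min
    assert abs(by_path - mean_of_speeds) < 1e-9 * max(1.0, mean_of_speeds)
    return mean_of_speeds


def track_displacement_length(track: Track) -> float:
    """Straight-line distance between first and last position, um."""
    if len(track) == 0:
        return float("nan")
    return float(np.linalg.norm(track.positions[-1] - track.positions[0]))


def detect_pauses(
    vs: VelocitySeries,
    threshold: float,
    min_duration_s: float = DEFAULT_MIN_PAUSE_S,
) -> list[ArrestEvent]:
    """Maximal runs of consecutive intervals with speed strictly below threshold.

    Each run of k intervals lasts ``k * dt`` seconds; runs shorter than
    ``min_duration_s`` are discarded (default 30 s keeps every single-interval
    run at 30 s sampling). Every interval inside an event is individually
    below threshold — a deterministic, local rule that is at least as strict
    as requiring the run-average to be below threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    below = vs.speeds < threshold
    events: list[ArrestEvent] = []
    if not below.any():
        return events
    padded = np.diff(np.concatenate([[0], below.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    for s, e in zip(starts, ends):
        duration = (e - s) * vs.dt
        if duration >= min_duration_s:
            events.append(
                ArrestEvent(
                    start_frame=int(s),
                    end_frame=int(e),
                    duration_s=float(duration),
                    mean_speed=float(np.mean(vs.speeds[s:e])),
                )
            )
    return events


def arrest_coefficient(vs: VelocitySeries, threshold: float) -> float:
    """Fraction of intervals spent below the speed threshold, in [0, 1].

    The per-cell surrogate for stable target engagement. NaN (missing, not
    zero) for an empty series.
    """
    if len(vs) == 0:
        return float("nan")
    return float(np.mean(vs.speeds < threshold))


def fraction_paused_cells(
    series: Iterable[VelocitySeries],
    threshold: float,
    min_duration_s: float = DEFAULT_MIN_PAUSE_S,
) -> float:
    """Percentage of tracks exhibiting at least one pausing phase."""
    series = list(series)
    if not series:
        raise ValueError("need at least one velocity series")
    n_paused = sum(bool(detect_pauses(vs, threshold, min_duration_s)) for vs in series)
    return 100.0 * n_paused / len(series)


def summarize_track(
    track: Track,
    surface=None,
    threshold: float = DEFAULT_PAUSE_THRESHOLD_UM_MIN,
    min_duration_s: float = DEFAULT_MIN_PAUSE_S,
    approach_band: float = DEFAULT_APPROACH_BAND_UM,
) -> MotilitySummary:
    """All per-track metrics in one record (one summary row per track)."""
    vs = instantaneous_velocity(track) if len(track) >= 2 else VelocitySeries(
        track.track_id, np.empty(0), track.dt
    )
    pauses = detect_pauses(vs, threshold, min_duration_s) if len(vs) else []
    return MotilitySummary(
        track_id=track.track_id,
        experiment_id=track.experiment_id,
        group=track.group,
        n_intervals=len(vs),
        mean_track_speed=float(np.mean(vs.speeds)) if len(vs) else float("nan"),
        track_displacement_length=track_displacement_length(track),
        path_length=path_length(track),
        arrest_coefficient=arrest_coefficient(vs, threshold),
        n_pauses=len(pauses),
        pausing_durations_s=[p.duration_s for p in pauses],
        total_paused_s=float(sum(p.duration_s for p in pauses)),
        compartment=(
            classify_track(surface, track, approach_band) if surface is not None else None
        ),
    )


def summarize_cohort(
    ts: TrackSet,
    surface=None,
    threshold: float = DEFAULT_PAUSE_THRESHOLD_UM_MIN,
    min_duration_s: float = DEFAULT_MIN_PAUSE_S,
    approach_band: float = DEFAULT_APPROACH_BAND_UM,
    min_intervals: int = 4,
) -> pd.DataFrame:
    """Per-track summary table for a whole cohort.

    Tracks with fewer than ``min_intervals`` intervals (default 4, i.e. 2 min
    of observation) are excluded: the arrest coefficient of a 1–2 interval
    track is degenerate. Set ``min_intervals=0`` to keep everything.
    """
    rows = []
    for tr in ts:
        if tr.n_intervals < min_intervals:
            continue
        s = summarize_track(tr, surface, threshold, min_duration_s, approach_band)
        rows.append(
            {
                "track_id": s.track_id,
                "experiment_id": s.experiment_id,
                "group": s.group,
                "compartment": s.compartment,
                "n_intervals": s.n_intervals,
                "mean_track_speed": s.mean_track_speed,
                "track_displacement_length": s.track_displacement_length,
                "path_length": s.path_length,
                "arrest_coefficient": s.arrest_coefficient,
                "n_pauses": s.n_pauses,
                "total_paused_s": s.total_paused_s,
            }
        )
    columns = [
        "track_id",
        "experiment_id",
        "group",
        "compartment",
        "n_intervals",
        "mean_track_speed",
        "track_displacement_length",
        "path_length",
        "arrest_coefficient",
        "n_pauses",
        "total_paused_s",
    ]
    return pd.DataFrame(rows, columns=columns)
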