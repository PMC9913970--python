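"""Core track data model, CSV readers/writers, and frame-to-frame spot linking.

A *spot* is one cell detection in one movie frame (x, y, z in micrometres at
time t). A *track* is the time-ordered sequence of spots belonging to one
cell; tracks are sampled uniformly (default every 30 s over a 30 min movie,
i.e. 61 frames). Two on-disk dialects are supported: the package's tidy CSV
and the position-export CSV produced by Imaris.

Missing detections are not interpolated: a track with gap frames is split
into contiguous segments at analysis time (see :meth:`Track.segments`), so
no velocity sample is ever fabricated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotRecord",
    "Track",
    "TrackSet",
    "TrackFormatError",
    "TrackIntegrityError",
    "read_tracks",
    "write_tracks",
    "link_spots",
    "DEFAULT_DT_S",
    "DEFAULT_FIELD_EXTENT_UM",
    "DEFAULT_MOVIE_DURATION_S",
]

#: Frame interval of the imaging protocol, seconds.
DEFAULT_DT_S = 30.0
#: Imaged volume: 509 x 509 um field of view, 60 um z-depth.
DEFAULT_FIELD_EXTENT_UM = (509.0, 509.0, 60.0)
#: Movie duration, seconds (61 frames at 30 s).
DEFAULT_MOVIE_DURATION_S = 1800.0

TIDY_COLUMNS = ["experiment_id", "group", "track_id", "frame", "t_s", "x_um", "y_um", "z_um"]


class TrackFormatError(ValueError):
    """A track table is missing required columns or has unparseable rows."""


class TrackIntegrityError(ValueError):
    """A track table violates a structural invariant (e.g. duplicate frames)."""


@dataclass(frozen=True)
class SpotRecord:
    """One cell detection in one frame.

    ``track_id`` is ``None`` for unlinked detections (input to
    :func:`link_spots`).
    """

    experiment_id: str
    group: str
    frame: int
    t: float
    x: float
    y: float
    z: float
    track_id: int | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise TrackIntegrityError(f"frame must be >= 0, got {self.frame}")
        if not np.all(np.isfinite([self.t, self.x, self.y, self.z])):
            raise TrackIntegrityError("spot coordinates/time must be finite")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Track:
    """One cell's time-ordered 3D positions at uniform frame interval.

    Parameters
    ----------
    track_id
        Identifier, unique within an ``experiment_id``.
    positions
        ``(n, 3)`` array of positions in micrometres.
    frames
        ``(n,)`` strictly increasing non-negative frame indices. Consecutive
        frame indices are ``dt`` seconds apart; a jump of more than one frame
        is a gap (missing detection).
    dt
        Frame interval in seconds (default 30).
    """

    track_id: int
    positions: np.ndarray
    frames: np.ndarray
    dt: float = DEFAULT_DT_S
    experiment_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.frames = np.asarray(self.frames, dtype=int)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrackIntegrityError("positions must have shape (n, 3)")
        if self.positions.shape[0] != self.frames.shape[0]:
            raise TrackIntegrityError("positions and frames length mismatch")
        if len(self.frames) and self.frames[0] < 0:
            raise TrackIntegrityError("frames must be non-negative")
        if np.any(np.diff(self.frames) <= 0):
            raise TrackIntegrityError(
                f"track {self.track_id}: frames must be strictly increasing"
            )
        if not np.all(np.isfinite(self.positions)):
            raise TrackIntegrityError(f"track {self.track_id}: non-finite coordinates")
        if self.dt <= 0:
            raise TrackIntegrityError("dt must be positive")

    def __len__(self) -> int:
        return self.positions.shape[0]

    @property
    def n_intervals(self) -> int:
        return max(len(self) - 1, 0)

    @property
    def times(self) -> np.ndarray:
        """Observation times in seconds (frame index times dt)."""
        return self.frames * self.dt

    @property
    def duration_s(self) -> float:
        return float((self.frames[-1] - self.frames[0]) * self.dt) if len(self) else 0.0

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))

    def segments(self) -> list["Track"]:
        """Split at gap frames into tracks with contiguous frame indices.

        A gapless track returns ``[self]``. Velocities must only ever be
        computed within a segment.
        """
        if not self.has_gaps:
            return [self]
        breaks = np.flatnonzero(np.diff(self.frames) > 1) + 1
        out = []
        for i, chunk in enumerate(np.split(np.arange(len(self)), breaks)):
            out.append(
                Track(
                    track_id=self.track_id,
                    positions=self.positions[chunk],
                    frames=self.frames[chunk],
                    dt=self.dt,
                    experiment_id=self.experiment_id,
                    group=self.group,
                )
            )
        return out

    def translated(self, offsets: np.ndarray) -> "Track":
        """Return a copy with per-spot ``offsets`` (n, 3) added."""
        return replace(self, positions=self.positions + np.asarray(offsets, dtype=float))


@dataclass
class TrackSet:
    """A collection of tracks from one or more imaging experiments."""

    tracks: list[Track] = field(default_factory=list)
    field_extent: tuple[float, float, float] = DEFAULT_FIELD_EXTENT_UM
    movie_duration_s: float = DEFAULT_MOVIE_DURATION_S
    drift_corrected: bool = False

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for tr in self.tracks:
            key = (tr.experiment_id, tr.track_id)
            if key in seen:
                raise TrackIntegrityError(
                    f"duplicate track_id {tr.track_id} in experiment {tr.experiment_id!r}"
                )
            seen.add(key)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def n_spots(self) -> int:
        return sum(len(t) for t in self.tracks)

    @property
    def experiment_ids(self) -> list[str]:
        return sorted({t.experiment_id for t in self.tracks})

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table, one row per spot."""
        if not self.tracks:
            return pd.DataFrame(columns=TIDY_COLUMNS)
        parts = []
        for tr in self.tracks:
            parts.append(
                pd.DataFrame(
                    {
                        "experiment_id": tr.experiment_id,
                        "group": tr.group,
                        "track_id": tr.track_id,
                        "frame": tr.frames,
                        "t_s": tr.times,
                        "x_um": tr.positions[:, 0],
                        "y_um": tr.positions[:, 1],
                        "z_um": tr.positions[:, 2],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        dt: float = DEFAULT_DT_S,
        **kwargs,
    ) -> "TrackSet":
        """Build a TrackSet from a tidy long-format table."""
        missing = [c for c in TIDY_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
        dup = df.duplicated(subset=["experiment_id", "track_id", "frame"])
        if dup.any():
            rows = (df.index[dup] + 2).tolist()[:5]  # 1-based + header
            raise TrackIntegrityError(
                f"duplicate (track_id, frame) pairs, e.g. at file line(s) {rows}"
            )
        tracks = []
        for (exp, tid), g in df.groupby(["experiment_id", "track_id"], sort=True):
            g = g.sort_values("frame")
            tracks.append(
                Track(
                    track_id=int(tid),
                    positions=g[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                    frames=g["frame"].to_numpy(dtype=int),
                    dt=dt,
                    experiment_id=str(exp),
                    group=str(g["group"].iloc[0]),
                )
            )
        return cls(tracks=tracks, **kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_IMARIS_REQUIRED = ["position x", "position y", "position z", "trackid", "id"]


def _read_imaris_position(path) -> pd.DataFrame:
    """Parse an Imaris position-export CSV into the tidy schema.

    Header names are matched case-insensitively after trimming. When a
    "Time" column is present it is taken as the 1-based frame index
    (Imaris convention); otherwise frames are numbered by order of
    appearance within each track.
    """
    raw = pd.read_csv(path)
    colmap = {c.strip().lower(): c for c in raw.columns}
    missing = [c for c in _IMARIS_REQUIRED if c not in colmap]
    if missing:
        raise TrackFormatError(
            f"Imaris position export missing column(s): {', '.join(missing)}"
        )
    df = pd.DataFrame(
        {
            "track_id": raw[colmap["trackid"]].astype(int),
            "x_um": raw[colmap["position x"]].astype(float),
            "y_um": raw[colmap["position y"]].astype(float),
            "z_um": raw[colmap["position z"]].astype(float),
        }
    )
    if "time" in colmap:
        df["frame"] = raw[colmap["time"]].astype(int) - 1
    else:
        df["frame"] = df.groupby("track_id").cumcount()
    df["experiment_id"] = ""
    df["group"] = ""
    df["t_s"] = df["frame"] * DEFAULT_DT_S
    return df[TIDY_COLUMNS]


def read_tracks(path, dialect: str = "tidy", dt: float = DEFAULT_DT_S, **kwargs) -> TrackSet:
    """Read a track table.

    Parameters
    ----------
    path
        CSV file path or file-like object.
    dialect
        ``"tidy"`` for the package schema
        (experiment_id, group, track_id, frame, t_s, x_um, y_um, z_um) or
        ``"imaris_position"`` for an Imaris position export
        ("Position X/Y/Z", "Time", "TrackID", "ID").
    dt
        Frame interval in seconds.

    Raises
    ------
    TrackFormatError
        If a required column is absent (the error names it).
    TrackIntegrityError
        If a (track_id, frame) pair is duplicated.
    """
    if dialect == "tidy":
        df = pd.read_csv(path)
    elif dialect == "imaris_position":
        df = _read_imaris_position(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return TrackSet.from_frame(df, dt=dt, **kwargs)


def write_tracks(ts: TrackSet, path, coord_decimals: int = 3) -> None:
    """Write a TrackSet as a tidy CSV (coordinates rounded to ``coord_decimals``).

    Round-trips through :func:`read_tracks`: ``read(write(ts)) == ts`` up to
    the declared coordinate precision.
    """
    df = ts.to_frame()
    df.to_csv(path, index=False, float_format=f"%.{coord_decimals}f")


def write_tracks_imaris(ts: TrackSet, path) -> None:
    """Write an Imaris-position-dialect CSV (for interoperability tests)."""
    df = ts.to_frame()
    out = pd.DataFrame(
        {
            "Position X": df["x_um"],
            "Position Y": df["y_um"],
            "Position Z": df["z_um"],
            "Unit": "um",
            "Time": df["frame"] + 1,
            "TrackID": df["track_id"],
            "ID": np.arange(len(df)),
        }
    )
    out.to_csv(path, index=False, float_format="%.3f")


# ---------------------------------------------------------------------------
# Spot linking
# ---------------------------------------------------------------------------


def link_spots(
    spots: Sequence[SpotRecord] | pd.DataFrame,
    max_step: float,
    dt: float = DEFAULT_DT_S,
) -> TrackSet:
    """Link per-frame detections into tracks by greedy mutual nearest neighbours.

    For each consecutive frame pair, a spot in frame f is linked to a spot in
    frame f+1 iff each is the other's nearest neighbour and their distance is
    at most ``max_step`` (micrometres). Unmatched spots in frame f+1 start new
    tracks. The procedure is deterministic: candidate links are ranked by
    distance, ties broken by the lower spot index within the frame.

    This is a simple stand-in for commercial tracking software, adequate when
    cells are separated by more than twice the largest per-frame displacement
    (under that guarantee it recovers ground-truth identities exactly); it is
    not a global assignment and performs no gap closing.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    if isinstance(spots, pd.DataFrame):
        df = spots.copy()
        need = ["frame", "x_um", "y_um", "z_um"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
        if "experiment_id" not in df.columns:
            df["experiment_id"] = ""
        if "group" not in df.columns:
            df["group"] = ""
    else:
        df = pd.DataFrame(
            {
                "experiment_id": [s.experiment_id for s in spots],
                "group": [s.group for s in spots],
                "frame": [s.frame for s in spots],
                "x_um": [s.x for s in spots],
                "y_um": [s.y for s in spots],
                "z_um": [s.z for s in spots],
            }
        )

    tracks: list[Track] = []
    next_id = 0
    for exp, g in df.groupby("experiment_id", sort=True):
        group_label = str(g["group"].iloc[0])
        frames_present = np.sort(g["frame"].unique())
        by_frame = {
            int(f): sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float)
            for f, sub in g.groupby("frame")
        }
        # open tracks: list of (positions list, frames list); index = open slot
        open_prev: list[int] = []  # indices into `alive` of tracks present in prev frame
        alive: list[tuple[list[np.ndarray], list[int]]] = []
        prev_pts: np.ndarray | None = None
        prev_frame: int | None = None
        for f in frames_present:
            pts = by_frame[int(f)]
            n = pts.shape[0]
            assigned = np.full(n, -1, dtype=int)  # alive-track index per spot
            if prev_pts is not None and prev_frame is not None and f == prev_frame + 1:
                m = prev_pts.shape[0]
                if m and n:
                    d = np.linalg.norm(prev_pts[:, None, :] - pts[None, :, :], axis=2)
                    nn_fwd = np.argmin(d, axis=1)  # prev -> cur
                    nn_bwd = np.argmin(d, axis=0)  # cur -> prev
                    cand = [
                        (d[i, nn_fwd[i]], i, int(nn_fwd[i]))
                        for i in range(m)
                        if nn_bwd[nn_fwd[i]] == i and d[i, nn_fwd[i]] <= max_step
                    ]
                    used_prev: set[int] = set()
                    used_cur: set[int] = set()
                    for dist, i, j in sorted(cand):
                        if i in used_prev or j in used_cur:
                            continue
                        used_prev.add(i)
                        used_cur.add(j)
                        assigned[j] = open_prev[i]
            new_open: list[int] = []
            for j in range(n):
                if assigned[j] >= 0:
                    k = assigned[j]
                else:
                    alive.append(([], []))
                    k = len(alive) - 1
                alive[k][0].append(pts[j])
                alive[k][1].append(int(f))
                new_open.append(k)
            open_prev = new_open
            prev_pts = pts
            prev_frame = int(f)
        for pos_list, frame_list in alive:
            tracks.append(
                Track(
                    track_id=next_id,
                    positions=np.asarray(pos_list),
                    frames=np.asarray(frame_list),
                    dt=dt,
                    experiment_id=str(exp),
                    group=group_label,
                )
            )
            next_id += 1
    return TrackSet(tracks=tracks)
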