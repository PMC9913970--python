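"""Spheroid rejection kinetics: relative volume change between two time points.

Spheroid volumes are consumed as exported measurements (um^3) at an early
(4 h) and a late (18 h) coculture time point. The early volume of each
spheroid is set to 100% and the late volume expressed relative to it, so
values below 100% indicate rejection (shrinkage) and above 100% growth.
Normalization is per spheroid, then averaged per condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = [
    "VolumeSeries",
    "VolumeValidityError",
    "T_EARLY_H",
    "T_LATE_H",
    "relative_volume",
    "condition_summary",
    "read_volumes",
    "write_volumes",
]

T_EARLY_H = 4.0
T_LATE_H = 18.0

VOLUME_COLUMNS = ["spheroid_id", "condition", "t_h", "volume_um3"]


class VolumeValidityError(ValueError):
    """A volume measurement is missing or non-positive."""


@dataclass(frozen=True)
class VolumeSeries:
    """One spheroid's volume at the early and late time points."""

    spheroid_id: str
    condition: str
    volume_early: float
    volume_late: float
    t_early_h: float = T_EARLY_H
    t_late_h: float = T_LATE_H

    def __post_init__(self) -> None:
        if not (self.volume_early > 0 and self.volume_late > 0):
            raise VolumeValidityError(
                f"spheroid {self.spheroid_id}: volumes must be positive"
            )


def relative_volume(vs: VolumeSeries) -> float:
    """Late volume as a percentage of the early volume: ``100 * V_late / V_early``.

    Scale-invariant (multiplying both volumes by c > 0 changes nothing);
    exceeds 100 iff the spheroid grew.
    """
    return 100.0 * vs.volume_late / vs.volume_early


def condition_summary(series: Iterable[VolumeSeries]) -> pd.DataFrame:
    """Mean +/- SD of relative volume per condition.

    Returns a DataFrame indexed by condition with columns ``mean_relative``,
    ``sd_relative`` and ``n``. SD is the sample standard deviation (ddof=1;
    0 for a single spheroid).
    """
    rows = [
        {"condition": vs.condition, "relative": relative_volume(vs)} for vs in series
    ]
    df = pd.DataFrame(rows, columns=["condition", "relative"])
    if df.empty:
        return pd.DataFrame(
            columns=["mean_relative", "sd_relative", "n"],
            index=pd.Index([], name="condition"),
        )
    out = df.groupby("condition")["relative"].agg(
        mean_relative="mean",
        sd_relative=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
        n="count",
    )
    return out


def read_volumes(path) -> list[VolumeSeries]:
    """Read a long-format volume CSV (spheroid_id, condition, t_h, volume_um3).

    Spheroids missing either time point are dropped (they cannot be
    normalized); a summary of exclusions is attached to the returned list via
    the ``n_excluded`` attribute on the DataFrame is not needed — callers can
    compare lengths.
    """
    df = pd.read_csv(path)
    missing = [c for c in VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise VolumeValidityError(f"missing required column(s): {', '.join(missing)}")
    out = []
    for (sid, cond), g in df.groupby(["spheroid_id", "condition"], sort=True):
        early = g.loc[g["t_h"] == g["t_h"].min(), "volume_um3"]
        late = g.loc[g["t_h"] == g["t_h"].max(), "volume_um3"]
        if g["t_h"].nunique() < 2:
            continue
        out.append(
            VolumeSeries(
                spheroid_id=str(sid),
                condition=str(cond),
                volume_early=float(early.iloc[0]),
                volume_late=float(late.iloc[0]),
                t_early_h=float(g["t_h"].min()),
                t_late_h=float(g["t_h"].max()),
            )
        )
    return out


def write_volumes(series: Iterable[VolumeSeries], path) -> None:
    """Write volume series in the long CSV format."""
    rows = []
    for vs in series:
        rows.append(
            {
                "spheroid_id": vs.spheroid_id,
                "condition": vs.condition,
                "t_h": vs.t_early_h,
                "volume_um3": vs.volume_early,
            }
        )
        rows.append(
            {
                "spheroid_id": vs.spheroid_id,
                "condition": vs.condition,
                "t_h": vs.t_late_h,
                "volume_um3": vs.volume_late,
            }
        )
    pd.DataFrame(rows, columns=VOLUME_COLUMNS).to_csv(path, index=False)
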