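"""Vectorial dynamic body acceleration (VeDBA) from raw tri-axial data.

Raw 5-s samples are split into a static (gravitational) component — a
two-sample running mean per axis — and a dynamic component, whose
absolute values enter

    VeDBA = sqrt(A_x^2 + A_y^2 + A_z^2)

VeDBA is preferred over ODBA because the vector norm is invariant to
fixed rotations of the sensor, which matters for collars that can spin
around the animal's neck.  Taking absolute dynamic values before the
norm is numerically redundant (squares discard sign) but kept so the
audit columns match the conventional definition.

Edge rules: the first sample of each contiguous segment has
``static = raw`` (hence dynamic 0); a gap longer than the nominal
cadence restarts the smoothing window.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger("quollmove")

__all__ = ["static_acceleration", "compute_vedba", "aggregate_step_vedba"]


def static_acceleration(raw: np.ndarray, segments: np.ndarray | None = None,
                        window: int = 2) -> np.ndarray:
    """Running-mean static component over ``window`` consecutive samples.

    With the default two-sample window, ``static[i] = (raw[i-1]+raw[i])/2``
    for i >= 1 and ``static[0] = raw[0]``; ``segments`` labels contiguous
    runs (the window restarts at each segment boundary).
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if n == 0:
        return raw.copy()
    if segments is None:
        segments = np.zeros(n, dtype=int)
    segments = np.asarray(segments)
    pos = np.arange(n)
    starts = np.flatnonzero(np.r_[True, segments[1:] != segments[:-1]])
    seg_start = starts[np.searchsorted(starts, pos, side="right") - 1]
    k = np.minimum(window, pos - seg_start + 1)  # samples available in window
    c = np.concatenate([[0.0], np.cumsum(raw)])
    return (c[pos + 1] - c[pos + 1 - k]) / k


def _segment_labels(timestamps: pd.Series, cadence_s: float) -> np.ndarray:
    dt = timestamps.diff().dt.total_seconds().to_numpy()
    new = np.isnan(dt) | (dt > cadence_s + 1e-9)
    return np.cumsum(new)


def compute_vedba(records: pd.DataFrame, window: int = 2,
                  cadence_s: float = 5.0) -> pd.DataFrame:
    """Per-sample VeDBA with static/dynamic audit columns.

    ``records`` needs columns ``individual_id, timestamp, ax, ay, az``
    (``temperature`` is carried through).  Sorted per individual;
    smoothing restarts across gaps > cadence.
    """
    out_parts = []
    for _, grp in records.groupby("individual_id", sort=False):
        grp = grp.sort_values("timestamp", kind="stable").copy()
        seg = _segment_labels(grp["timestamp"], cadence_s)
        sq = np.zeros(len(grp))
        for axis in ("ax", "ay", "az"):
            static = static_acceleration(grp[axis].to_numpy(), seg, window)
            dba = np.abs(grp[axis].to_numpy() - static)
            grp[f"static_{axis[1]}"] = static
            grp[f"dba_{axis[1]}"] = dba
            sq += dba**2
        grp["vedba"] = np.sqrt(sq)
        out_parts.append(grp)
    return pd.concat(out_parts, ignore_index=True) if out_parts else records.copy()


def aggregate_step_vedba(
    vedba: pd.DataFrame,
    steps: pd.DataFrame,
    night_start_hour: int = 18,
    night_end_hour: int = 6,
    utc_offset_hours: float = 8.0,
) -> pd.DataFrame:
    """Mean VeDBA and temperature per observed step.

    A sample belongs to a step when ``t_start < timestamp <= t_end``
    (so a sample at a fix instant belongs to the step ending there),
    intersected with the nocturnal window evaluated on local clock
    time; diurnal samples are discarded.  Steps with no samples get
    ``NaN`` markers.
    """
    steps = steps.copy()
    steps["mean_vedba"] = np.nan
    steps["mean_temperature"] = np.nan
    for ind, acc in vedba.groupby("individual_id", sort=False):
        mask = steps["individual_id"] == ind
        if not mask.any():
            continue
        acc = acc.sort_values("timestamp", kind="stable")
        ts = acc["timestamp"]
        local_h = ((ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0)
                   + utc_offset_hours) % 24.0
        if night_start_hour > night_end_hour:
            night = (local_h >= night_start_hour) | (local_h < night_end_hour)
        else:
            night = (local_h >= night_start_hour) & (local_h < night_end_hour)
        acc = acc[night.to_numpy()]
        if len(acc) == 0:
            log.warning("individual %s: no nocturnal accelerometer samples", ind)
            continue
        t = acc["timestamp"].to_numpy()
        v = acc["vedba"].to_numpy()
        temp = acc["temperature"].to_numpy() if "temperature" in acc else np.full(len(acc), np.nan)
        sub = steps[mask]
        t_start = sub["t_start"].to_numpy()
        t_end = sub["t_end"].to_numpy()
        if t_start.size and (t[0] > t_end.max() or t[-1] < t_start.min()):
            log.warning("individual %s: accelerometer and GPS clocks disjoint", ind)
            continue
        # (t_start, t_end] membership via sorted search
        lo = np.searchsorted(t, t_start, side="right")
        hi = np.searchsorted(t, t_end, side="right")
        cv = np.concatenate([[0.0], np.cumsum(v)])
        ct = np.concatenate([[0.0], np.cumsum(temp)])
        n = (hi - lo).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_v = np.where(n > 0, (cv[hi] - cv[lo]) / n, np.nan)
            mean_t = np.where(n > 0, (ct[hi] - ct[lo]) / n, np.nan)
        steps.loc[mask, "mean_vedba"] = mean_v
        steps.loc[mask, "mean_temperature"] = mean_t
    return steps
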