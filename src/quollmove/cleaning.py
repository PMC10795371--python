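"""GPS fix screening and conversion to bursts and movement steps.

Filter order is fixed: HDOP screen, then the maximum-speed screen, then
exclusion windows (trap nights, predation events), then burst
construction.  The cleaning report decomposes removals exactly, so
``n_output = n_input - sum(removals)`` always holds.

Conventions: turning angles are counter-clockwise positive in
``(-pi, pi]``; the first step of each burst has no defined turning
angle; the HDOP rule removes strictly ``> hdop_max`` (a fix at exactly
10 is kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .io import ValidationError

__all__ = [
    "CleaningReport",
    "filter_hdop",
    "filter_speed",
    "exclude_windows",
    "build_bursts",
    "bursts_to_steps",
    "clean_fixes",
]

STEP_COLUMNS = [
    "stratum_id", "individual_id", "season", "age", "case", "burst_id",
    "start_x", "start_y", "end_x", "end_y", "t_start", "t_end",
    "sl", "ta", "log10_sl", "cos_ta",
]


@dataclass
class CleaningReport:
    n_input: int = 0
    n_removed_hdop: int = 0
    n_removed_speed: int = 0
    n_removed_windows: int = 0
    n_removed_short_bursts: int = 0
    n_output: int = 0

    def validate(self) -> None:
        removed = (self.n_removed_hdop + self.n_removed_speed
                   + self.n_removed_windows + self.n_removed_short_bursts)
        if self.n_output != self.n_input - removed:
            raise AssertionError("cleaning report does not decompose removals")

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def filter_hdop(fixes: pd.DataFrame, hdop_max: float = 10.0):
    """Drop fixes with HDOP strictly greater than ``hdop_max``."""
    if (fixes["hdop"] < 0).any():
        raise ValidationError("negative hdop values")
    keep = fixes["hdop"] <= hdop_max
    return fixes[keep].reset_index(drop=True), int((~keep).sum())


def _speed_pass(t: np.ndarray, x: np.ndarray, y: np.ndarray, vmax: float) -> np.ndarray:
    """Forward pass: drop any fix unreachable from the last retained fix."""
    keep = np.ones(len(t), dtype=bool)
    last = 0
    for i in range(1, len(t)):
        dt = t[i] - t[last]
        if dt <= 0:
            if x[i] != x[last] or y[i] != y[last]:
                raise ValidationError("zero time difference between distinct positions")
            continue
        dist = np.hypot(x[i] - x[last], y[i] - y[last])
        if dist > vmax * dt:
            keep[i] = False
        else:
            last = i
    return keep


def filter_speed(fixes: pd.DataFrame, vmax: float = 4.5):
    """Remove fixes implying travel faster than ``vmax`` (m/s).

    A fix is removed when its distance from the last *retained* fix of
    the same individual exceeds ``vmax`` times the elapsed time; a speed
    exactly equal to ``vmax`` is kept.  After the pass every retained
    consecutive pair implies speed <= vmax.
    """
    parts = []
    removed = 0
    for _, grp in fixes.groupby("individual_id", sort=False):
        t = grp["timestamp"].astype("int64").to_numpy() / 1e9
        keep = _speed_pass(t, grp["x"].to_numpy(), grp["y"].to_numpy(), vmax)
        removed += int((~keep).sum())
        parts.append(grp[keep])
    out = pd.concat(parts, ignore_index=True) if parts else fixes.iloc[0:0]
    return out, removed


def exclude_windows(fixes: pd.DataFrame, windows) -> tuple[pd.DataFrame, int]:
    """Remove fixes inside any half-open window ``[start, end)``.

    ``windows`` is an iterable of ``(individual_id, start, end)``;
    ``individual_id`` of ``None``/``"*"`` applies to everyone.  Window
    bounds are compared against the fix timestamps as given (use
    local-time-consistent bounds for trap-night exclusions).
    """
    drop = np.zeros(len(fixes), dtype=bool)
    ts = fixes["timestamp"]
    for ind, start, end in windows:
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start.tzinfo is None and getattr(ts.dt, "tz", None) is not None:
            start, end = start.tz_localize("UTC"), end.tz_localize("UTC")
        inside = (ts >= start) & (ts < end)
        if ind not in (None, "*"):
            inside &= fixes["individual_id"] == ind
        drop |= inside.to_numpy()
    return fixes[~drop].reset_index(drop=True), int(drop.sum())


def build_bursts(
    fixes: pd.DataFrame,
    fix_interval_min: float = 30.0,
    tolerance_min: float = 3.0,
    min_locations: int = 3,
):
    """Split per-individual fix sequences at gaps > interval + tolerance
    and drop bursts with fewer than ``min_locations`` fixes.

    Returns ``(fixes_with_burst_id, n_removed_short)``; ``burst_id`` is
    globally unique and ordered.
    """
    max_gap = pd.Timedelta(minutes=fix_interval_min + tolerance_min)
    parts = []
    removed = 0
    burst_counter = 0
    for ind, grp in fixes.groupby("individual_id", sort=False):
        gaps = grp["timestamp"].diff()
        new_burst = (gaps > max_gap) | gaps.isna()
        local_id = new_burst.cumsum()
        for _, burst in grp.groupby(local_id.values):
            if len(burst) < min_locations:
                removed += len(burst)
                continue
            burst = burst.copy()
            burst["burst_id"] = burst_counter
            burst_counter += 1
            parts.append(burst)
    if parts:
        out = pd.concat(parts, ignore_index=True)
    else:
        out = fixes.iloc[0:0].copy()
        out["burst_id"] = pd.Series(dtype=int)
    return out, removed


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    wrapped = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


def bursts_to_steps(bursted: pd.DataFrame, individuals_meta: dict | None = None) -> pd.DataFrame:
    """One observed step per consecutive fix pair inside each burst.

    The turning angle of a step is measured from the previous step's
    heading (counter-clockwise positive); the first step of every burst
    has ``ta = NaN`` and is kept as a step but excluded from
    turning-angle fitting.
    """
    individuals_meta = individuals_meta or bursted.attrs.get("individuals", {})
    if len(bursted) == 0:
        steps = pd.DataFrame(columns=[
            "individual_id", "season", "age", "case", "burst_id",
            "start_x", "start_y", "end_x", "end_y", "t_start", "t_end",
            "sl", "ta", "prev_heading",
        ])
    else:
        ind = bursted["individual_id"].to_numpy()
        burst = bursted["burst_id"].to_numpy()
        x = bursted["x"].to_numpy()
        y = bursted["y"].to_numpy()
        t = bursted["timestamp"].to_numpy()
        same = burst[1:] == burst[:-1]  # burst ids are globally unique
        i0 = np.flatnonzero(same)       # step i0 -> i0+1
        dx, dy = x[i0 + 1] - x[i0], y[i0 + 1] - y[i0]
        sl = np.hypot(dx, dy)
        heading = np.arctan2(dy, dx)
        # a turning angle exists when the preceding fix pair is in-burst
        has_prev = np.zeros(len(i0), dtype=bool)
        has_prev[1:] = i0[1:] == i0[:-1] + 1
        prev_heading = np.full(len(i0), np.nan)
        prev_heading[1:] = np.where(has_prev[1:], heading[:-1], np.nan)
        ta = np.where(has_prev, _wrap_angle(heading - prev_heading), np.nan)
        seasons = np.array([individuals_meta.get(i, {}).get("season", "") for i in ind[i0]])
        ages = np.array(
            [individuals_meta.get(i, {}).get("age", np.nan) for i in ind[i0]], dtype=float
        )
        steps = pd.DataFrame(
            {
                "individual_id": ind[i0],
                "season": seasons,
                "age": ages,
                "case": "observed",
                "burst_id": burst[i0],
                "start_x": x[i0], "start_y": y[i0],
                "end_x": x[i0 + 1], "end_y": y[i0 + 1],
                "t_start": t[i0], "t_end": t[i0 + 1],
                "sl": sl,
                "ta": ta,
                "prev_heading": prev_heading,
            }
        )
    if len(steps):
        steps["stratum_id"] = np.arange(len(steps))
        with np.errstate(divide="ignore"):
            steps["log10_sl"] = np.log10(steps["sl"])
        steps["cos_ta"] = np.cos(steps["ta"])
    else:
        for col in ("stratum_id", "log10_sl", "cos_ta"):
            steps[col] = pd.Series(dtype=float)
    return steps


def clean_fixes(
    fixes: pd.DataFrame,
    config: StudyConfig,
    exclusions=(),
    individuals_meta: dict | None = None,
):
    """Full cleaning pipeline: HDOP -> speed -> windows -> bursts -> steps.

    Returns ``(steps, bursted_fixes, report)``.
    """
    report = CleaningReport(n_input=len(fixes))
    fixes1, report.n_removed_hdop = filter_hdop(fixes, config.hdop_max)
    fixes2, report.n_removed_speed = filter_speed(fixes1, config.vmax)
    fixes3, report.n_removed_windows = exclude_windows(fixes2, exclusions)
    bursted, report.n_removed_short_bursts = build_bursts(
        fixes3,
        fix_interval_min=config.fix_interval_min,
        tolerance_min=config.burst_tolerance_min,
        min_locations=config.min_burst_locations,
    )
    report.n_output = len(bursted)
    report.validate()
    meta = individuals_meta if individuals_meta is not None else fixes.attrs.get("individuals", {})
    bursted.attrs["individuals"] = meta
    steps = bursts_to_steps(bursted, meta)
    return steps, bursted, report
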