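"""Joint-position-sense performance metrics.

For each prompted test movement the signed reproduction error is
``Error = AKA − TKA`` (actual minus target knee angle, same convention).
Per test and movement group (squats vs stretches), the average mean error
AME aggregates those signed errors — by default as the absolute value of
their mean — and the training effect per participant is the improvement
``IE = AME_pre − AME_post`` (positive = smaller error after training).
Outliers are screened with a single-pass z-score rule (|z| > 2.5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolSchedule
from .streams import KneeAngleSeries

log = logging.getLogger(__name__)

#: movement classes pooled into the two test groups
MOVEMENT_GROUPS = {
    "half_squat": "squat",
    "deep_squat": "squat",
    "stretch_45": "stretch",
    "stretch_0": "stretch",
}


@dataclass
class MovementSegment:
    movement_class: str
    window: tuple[float, float]
    TKA: float
    AKA: float
    convention: str

    @property
    def AE(self) -> float:
        """Signed reproduction error of this movement."""
        return self.AKA - self.TKA

    @property
    def movement_group(self) -> str:
        return MOVEMENT_GROUPS.get(self.movement_class, self.movement_class)


@dataclass
class ParticipantMetrics:
    participant: str
    group: str
    movement_group: str
    ame_pre: float
    ame_post: float
    n_pre: int
    n_post: int

    @property
    def ie(self) -> float:
        return self.ame_pre - self.ame_post


def error(aka: float, tka: float) -> float:
    """Signed reproduction error ``AKA − TKA`` (both in the same angle
    convention)."""
    return float(aka) - float(tka)


def segment_tests(
    series: KneeAngleSeries,
    schedule: ProtocolSchedule,
    central_fraction: float = 0.6,
) -> list[MovementSegment]:
    """Cut a knee-angle series into one segment per scheduled movement.

    AKA is the mean angle over the central ``central_fraction`` of the hold
    window (the transitions at either end are excluded), expressed in the
    schedule entry's angle convention.  Windows outside the recording raise;
    windows with fewer than 3 samples are dropped with a log message.
    """
    if not schedule.entries:
        return []
    t0, t1 = float(series.times[0]), float(series.times[-1])
    segments = []
    for entry in schedule.entries:
        if entry.start < t0 - 1e-9 or entry.end > t1 + 1e-9:
            raise ValueError(
                f"schedule window [{entry.start}, {entry.end}] outside recorded span [{t0}, {t1}]"
            )
        margin = (entry.end - entry.start) * (1.0 - central_fraction) / 2.0
        lo, hi = entry.start + margin, entry.end - margin
        mask = (series.times >= lo) & (series.times <= hi)
        if mask.sum() < 3:
            log.warning("dropping segment %s: only %d samples in window", entry.label, mask.sum())
            continue
        aka_included = float(series.included_deg[mask].mean())
        aka = aka_included if entry.convention == "included" else 180.0 - aka_included
        segments.append(
            MovementSegment(
                movement_class=entry.movement_class,
                window=(entry.start, entry.end),
                TKA=entry.target_deg,
                AKA=aka,
                convention=entry.convention,
            )
        )
    return segments


def ame(errors, mode: str = "abs_of_mean") -> float:
    """Average mean error of one movement group's signed errors.

    Default is the absolute value of the mean error; ``mean_of_abs`` gives
    the mean magnitude instead (the two differ whenever errors cancel, e.g.
    ``[5, -5]`` → 0 vs 5).
    """
    errs = np.asarray(list(errors), dtype=float)
    if errs.size == 0:
        raise ValueError("AME of an empty error list is undefined")
    if mode == "abs_of_mean":
        return float(abs(errs.mean()))
    if mode == "mean_of_abs":
        return float(np.abs(errs).mean())
    raise ValueError(f"unknown AME mode {mode!r}")


def ie(ame_pre: float, ame_post: float) -> float:
    """Improvement of error trajectory: pre-test AME minus post-test AME;
    positive values mean the participant got more accurate."""
    if ame_pre < 0 or ame_post < 0:
        raise ValueError("AME values are magnitudes and must be >= 0")
    return float(ame_pre) - float(ame_post)


def remove_outliers(
    values,
    z_threshold: float = 2.5,
    ddof: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass z-score screen: drop points with |z| > threshold.

    z-scores use the full list's mean and (by default sample, n−1) SD.
    Degenerate lists (length < 2 or zero SD) pass through untouched.
    Returns ``(kept, removed)``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 2:
        return vals, np.array([])
    sd = vals.std(ddof=ddof)
    if sd == 0:
        log.info("outlier screen skipped: zero SD")
        return vals, np.array([])
    z = (vals - vals.mean()) / sd
    keep = np.abs(z) <= z_threshold
    if (~keep).any():
        log.info("outlier screen removed %d of %d values", (~keep).sum(), vals.size)
    return vals[keep], vals[~keep]


def participant_metrics(
    participant: str,
    group: str,
    pre_segments: list[MovementSegment],
    post_segments: list[MovementSegment],
    ame_mode: str = "abs_of_mean",
) -> list[ParticipantMetrics]:
    """AME pre/post and IE per movement group (squat, stretch) for one
    participant."""
    out = []
    groups = sorted(
        {s.movement_group for s in pre_segments} | {s.movement_group for s in post_segments}
    )
    for mg in groups:
        pre = [s.AE for s in pre_segments if s.movement_group == mg]
        post = [s.AE for s in post_segments if s.movement_group == mg]
        if not pre or not post:
            log.warning("participant %s: movement group %s missing a phase", participant, mg)
            continue
        out.append(
            ParticipantMetrics(
                participant=participant,
                group=group,
                movement_group=mg,
                ame_pre=ame(pre, ame_mode),
                ame_post=ame(post, ame_mode),
                n_pre=len(pre),
                n_post=len(post),
            )
        )
    return out
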