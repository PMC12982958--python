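"""Two-stage IMU calibration and knee-angle extraction.

The study's sensor setup estimates the knee angle from two IMUs, one on the
biceps femoris (thigh) and one on the midshank.  Calibration has two
stages:

1. *Flat-surface baseline* — with the sensors lying parallel on a desk,
   ~14 s of orientation at 74 Hz (a 1000-sample buffer) is averaged into a
   single baseline quaternion ``q0``.
2. *Upright-pose reference* — with the sensors attached and the participant
   standing still, each sensor's mean orientation ``q_ref`` is recorded and
   an offset ``q_T = conj(q_ref) ⊗ q0`` computed, cancelling the mounting
   bias due to limb shape.

During play each measured quaternion ``q_R`` is calibrated as
``q_R ⊗ q_T``; the rotation between the calibrated shank and thigh frames
gives the knee angle (Y Euler component), so that upright stance always
reads as a fully straight leg (180° included angle).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import quaternions as qt
from .streams import KneeAngleSeries, SensorStream

KNEE_SENSORS = ("thigh_BF", "midshank")


@dataclass
class CalibrationResult:
    """Fitted calibration state for the two knee sensors."""

    q0: np.ndarray                      # flat-surface baseline (4,)
    q_ref: dict[str, np.ndarray]        # upright-pose mean per sensor
    q_T: dict[str, np.ndarray]          # composed offset per sensor
    buffer_len: int = 1000

    def to_json(self, path) -> None:
        payload = {
            "q0": list(self.q0),
            "q_ref": {k: list(v) for k, v in self.q_ref.items()},
            "q_T": {k: list(v) for k, v in self.q_T.items()},
            "buffer_len": self.buffer_len,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            q0=np.asarray(payload["q0"], dtype=float),
            q_ref={k: np.asarray(v, dtype=float) for k, v in payload["q_ref"].items()},
            q_T={k: np.asarray(v, dtype=float) for k, v in payload["q_T"].items()},
            buffer_len=int(payload["buffer_len"]),
        )


def _tail_buffer(stream: SensorStream, buffer_len: int) -> np.ndarray:
    """Last ``buffer_len`` quaternions of a calibration recording (a 14 s
    recording at 74 Hz holds 1036 samples; the averaged buffer keeps 1000)."""
    if len(stream) == 0:
        raise ValueError(f"empty calibration recording for sensor {stream.sensor_id}")
    return stream.quats[-buffer_len:]


def calibrate(
    flat: dict[str, SensorStream],
    upright: dict[str, SensorStream],
    buffer_len: int = 1000,
) -> CalibrationResult:
    """Compute the calibration offsets from flat-surface and upright-pose
    recordings of the two knee sensors."""
    for name, rec in (("flat", flat), ("upright", upright)):
        missing = [s for s in KNEE_SENSORS if s not in rec]
        if missing:
            raise ValueError(f"{name} recording missing sensors: {missing}")
    # sensors lie parallel on the flat surface: one shared baseline, averaged
    # across both sensors' buffers
    per_sensor_flat = [
        qt.average_quaternions(_tail_buffer(flat[s], buffer_len)) for s in KNEE_SENSORS
    ]
    q0 = qt.average_quaternions(np.stack(per_sensor_flat))
    q_ref = {
        s: qt.average_quaternions(_tail_buffer(upright[s], buffer_len)) for s in KNEE_SENSORS
    }
    q_T = {s: qt.compute_offset(q0, q_ref[s]) for s in KNEE_SENSORS}
    return CalibrationResult(q0=q0, q_ref=q_ref, q_T=q_T, buffer_len=buffer_len)


def pair_streams(
    thigh: SensorStream, shank: SensorStream
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-neighbour pairing of two live streams.

    For each thigh sample, the closest shank sample within half the nominal
    sample period is taken; unmatched samples are dropped.  No resampling or
    interpolation — the hardware pairs whole sensor frames.  Returns
    ``(times, thigh_quats, shank_quats)`` on the thigh clock.
    """
    if len(thigh) == 0 or len(shank) == 0:
        raise ValueError("cannot pair empty streams")
    t0 = max(thigh.span[0], shank.span[0])
    t1 = min(thigh.span[1], shank.span[1])
    if t0 > t1:
        raise ValueError("sensor streams have no temporal overlap")
    half_period = 0.5 / thigh.nominal_rate
    idx = np.searchsorted(shank.times, thigh.times)
    idx = np.clip(idx, 1, len(shank) - 1) if len(shank) > 1 else np.zeros(len(thigh), int)
    left = idx - 1
    choose_left = np.abs(shank.times[left] - thigh.times) <= np.abs(shank.times[idx] - thigh.times)
    nearest = np.where(choose_left, left, idx)
    ok = np.abs(shank.times[nearest] - thigh.times) <= half_period + 1e-12
    if not np.any(ok):
        raise ValueError("no stream samples pair within half a sample period")
    return thigh.times[ok], thigh.quats[ok], shank.quats[nearest[ok]]


class KneeAngleEstimator(BaseEstimator, TransformerMixin):
    """Estimate knee angles from thigh/shank IMU streams.

    Parameters
    ----------
    buffer_len : int
        Number of trailing samples averaged from each 14 s calibration
        recording (the hardware buffer holds 1000).
    convention : {"included", "flexion"}
        Output angle convention; included = 180° − flexion.

    Attributes
    ----------
    calibration_ : CalibrationResult
        Baseline, per-sensor references and composed offsets after ``fit``.
    """

    def __init__(self, buffer_len: int = 1000, convention: str = "included"):
        self.buffer_len = buffer_len
        self.convention = convention

    def fit(self, X: dict[str, dict[str, SensorStream]], y=None):
        """Fit from ``{"flat": {...}, "upright": {...}}`` recordings."""
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be >= 1")
        if not isinstance(X, dict) or not {"flat", "upright"} <= set(X):
            raise ValueError("fit expects {'flat': streams, 'upright': streams}")
        self.calibration_ = calibrate(X["flat"], X["upright"], self.buffer_len)
        return self

    def transform(self, X: dict[str, SensorStream]) -> KneeAngleSeries:
        """Per-sample calibrate → relative rotation → Y-angle pipeline."""
        if not hasattr(self, "calibration_"):
            raise ValueError("KneeAngleEstimator is not fitted")
        missing = [s for s in KNEE_SENSORS if s not in X]
        if missing:
            raise ValueError(f"in-task streams missing sensors: {missing}")
        times, q_thigh, q_shank = pair_streams(X["thigh_BF"], X["midshank"])
        cal = self.calibration_
        thigh_cal = qt.apply_calibration(q_thigh, cal.q_T["thigh_BF"])
        shank_cal = qt.apply_calibration(q_shank, cal.q_T["midshank"])
        q_knee = qt.knee_relative_rotation(thigh_cal, shank_cal)
        flexion = qt.knee_angle_y(q_knee, convention="flexion")
        return KneeAngleSeries(times=times, included_deg=180.0 - np.atleast_1d(flexion))


def stream_knee_angle(
    thigh: SensorStream,
    shank: SensorStream,
    calib: CalibrationResult,
    convention: str = "included",
) -> KneeAngleSeries:
    """Functional form of :meth:`KneeAngleEstimator.transform` for an
    already-computed calibration."""
    est = KneeAngleEstimator(buffer_len=calib.buffer_len, convention=convention)
    est.calibration_ = calib
    return est.transform({"thigh_BF": thigh, "midshank": shank})
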