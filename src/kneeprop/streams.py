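"""Time-indexed sensor containers and their plain-text file formats.

Three stream types cover the study's raw data: orientation streams from the
wearable IMUs (unit quaternions at a nominal 74 Hz), multi-channel surface
EMG from seven lower-limb muscles, and derived knee-angle series.  Each has
a strict CSV schema and a lossless (17-significant-digit) writer so that a
written dataset round-trips bit-exactly through its own reader.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: valid IMU placement labels
SENSOR_IDS = ("thigh_BF", "midshank", "trunk")

#: fixed muscle order: tibialis anterior, gastrocnemius medialis, gluteus
#: medius, gastrocnemius lateralis, peroneus longus, biceps femoris,
#: rectus femoris
MUSCLES = ("TA", "GAM", "GLM", "GL", "PL", "BF", "RF")

_FLOAT_FMT = "%.17g"


class SchemaError(ValueError):
    """Malformed input file or stream (bad header, labels, ordering...)."""


@dataclass
class SensorStream:
    """Orientation samples ``(time, unit quaternion)`` from one IMU."""

    sensor_id: str
    times: np.ndarray          # (n,) seconds, strictly increasing
    quats: np.ndarray          # (n, 4) scalar-first unit quaternions
    nominal_rate: float = 74.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.quats = np.asarray(self.quats, dtype=float)
        if self.sensor_id not in SENSOR_IDS:
            raise SchemaError(f"unknown sensor_id {self.sensor_id!r}; expected one of {SENSOR_IDS}")
        if self.quats.shape != (self.times.size, 4):
            raise SchemaError("quaternion array must be (n_samples, 4)")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SchemaError(f"sensor {self.sensor_id}: timestamps must be strictly increasing")
        norms = np.linalg.norm(self.quats, axis=1)
        if self.times.size and not np.allclose(norms, 1.0, atol=1e-6):
            raise SchemaError(f"sensor {self.sensor_id}: non-unit quaternion on ingest")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class EMGStream:
    """Multi-channel EMG voltages; channels follow :data:`MUSCLES` order."""

    times: np.ndarray          # (n,) seconds, strictly increasing
    data: np.ndarray           # (n, 7)
    fs: float
    channels: tuple[str, ...] = MUSCLES

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.times.size, len(self.channels)):
            raise SchemaError("EMG data must be (n_samples, n_channels)")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise SchemaError("EMG timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])

    def window(self, start: float, end: float) -> np.ndarray:
        """Channel-major slice ``(7, n)`` of samples with start <= t <= end."""
        mask = (self.times >= start) & (self.times <= end)
        return self.data[mask].T


@dataclass
class KneeAngleSeries:
    """Knee angle over time; canonical storage is the included angle
    (180° = fully straight leg), with flexion = 180° − included."""

    times: np.ndarray
    included_deg: np.ndarray
    convention: str = "included"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.included_deg = np.asarray(self.included_deg, dtype=float)
        if self.included_deg.shape != self.times.shape:
            raise SchemaError("angle and time arrays must have equal length")
        if self.included_deg.size and (
            self.included_deg.min() < -1e-9 or self.included_deg.max() > 180.0 + 1e-9
        ):
            raise SchemaError("included knee angle out of [0, 180] degrees")
        self.included_deg = np.clip(self.included_deg, 0.0, 180.0)

    def __len__(self) -> int:
        return self.times.size

    @property
    def flexion_deg(self) -> np.ndarray:
        return 180.0 - self.included_deg

    def in_convention(self, convention: str) -> np.ndarray:
        if convention == "included":
            return self.included_deg
        if convention == "flexion":
            return self.flexion_deg
        raise ValueError(f"unknown angle convention {convention!r}")


# ---------------------------------------------------------------------------
# CSV I/O


def write_sensor_csv(path, streams: dict[str, SensorStream] | SensorStream) -> None:
    """Write one or more IMU streams to ``time_s,sensor_id,qw,qx,qy,qz``."""
    if isinstance(streams, SensorStream):
        streams = {streams.sensor_id: streams}
    frames = []
    for sid, s in streams.items():
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times,
                    "sensor_id": sid,
                    "qw": s.quats[:, 0],
                    "qx": s.quats[:, 1],
                    "qy": s.quats[:, 2],
                    "qz": s.quats[:, 3],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensor_csv(path, nominal_rate: float = 74.0) -> dict[str, SensorStream]:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", "sensor_id", "qw", "qx", "qy", "qz"]
    if list(df.columns) != expected:
        raise SchemaError(f"sensor CSV {path}: expected columns {expected}, got {list(df.columns)}")
    out: dict[str, SensorStream] = {}
    for sid, grp in df.groupby("sensor_id", sort=False):
        out[str(sid)] = SensorStream(
            sensor_id=str(sid),
            times=grp["time_s"].to_numpy(),
            quats=grp[["qw", "qx", "qy", "qz"]].to_numpy(),
            nominal_rate=nominal_rate,
        )
    return out


def write_emg_csv(path, stream: EMGStream) -> None:
    df = pd.DataFrame(stream.data, columns=list(stream.channels))
    df.insert(0, "time_s", stream.times)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_emg_csv(path, fs: float | None = None) -> EMGStream:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_s", *MUSCLES]
    if list(df.columns) != expected:
        raise SchemaError(f"EMG CSV {path}: expected columns {expected}, got {list(df.columns)}")
    times = df["time_s"].to_numpy()
    if fs is None:
        fs = 1.0 / float(np.median(np.diff(times))) if times.size > 1 else 0.0
    return EMGStream(times=times, data=df[list(MUSCLES)].to_numpy(), fs=fs)


def write_angle_csv(path, series: KneeAngleSeries) -> None:
    pd.DataFrame({"time_s": series.times, "included_deg": series.included_deg}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_angle_csv(path) -> KneeAngleSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "included_deg"]:
        raise SchemaError(f"angle CSV {path}: unexpected columns {list(df.columns)}")
    return KneeAngleSeries(times=df["time_s"].to_numpy(), included_deg=df["included_deg"].to_numpy())
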