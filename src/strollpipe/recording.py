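"""In-memory container and plain-text I/O for raw IMU recordings.

A recording holds one stream per body-worn sensor. Acceleration is in m/s²,
angular rate in rad/s, sample times in seconds on a common time base. The
gyroscope is optional (the daily-life calf configuration records
acceleration only).

On disk a recording is a directory with one whitespace-delimited table per
sensor (``timestamp_s ax ay az [gx gy gz]``) plus a ``meta.json`` sidecar
carrying placement, nominal rate, units and free-form metadata.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError

PLACEMENTS = ("left_foot", "right_foot", "low_back", "calf")

GRAVITY = 9.81  # m/s², +z when upright at calibration posture


@dataclass
class SensorStream:
    """One sensor's time series.

    ``acc`` has shape (n, 3) with axes x = anterior, y = left, z = up at the
    calibration posture; ``gyr`` is (n, 3) or ``None`` when only acceleration
    was recorded.
    """

    placement: str
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray | None
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.gyr is not None:
            self.gyr = np.asarray(self.gyr, dtype=float)
        if self.placement not in PLACEMENTS:
            raise InvalidArgumentError(f"unknown placement {self.placement!r}")
        if self.rate <= 0:
            raise InvalidArgumentError("nominal rate must be positive")
        if self.t.ndim != 1 or self.acc.shape != (self.t.size, 3):
            raise InvalidArgumentError("acc must be (n, 3) matching t")
        if self.gyr is not None and self.gyr.shape != (self.t.size, 3):
            raise InvalidArgumentError("gyr must be (n, 3) matching t")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise InvalidArgumentError("sample times must be strictly increasing")
        for arr in (self.t, self.acc) + (() if self.gyr is None else (self.gyr,)):
            if not np.all(np.isfinite(arr)):
                raise InvalidArgumentError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0


@dataclass
class RawImuRecording:
    """A set of synchronized sensor streams plus free-form metadata."""

    sensors: dict[str, SensorStream]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sensors:
            raise InvalidArgumentError("recording has no sensor streams")
        spans = [(s.t[0], s.t[-1], 1.0 / s.rate) for s in self.sensors.values()]
        t0 = max(a for a, _, _ in spans)
        t1 = min(b for _, b, _ in spans)
        tol = max(dt for _, _, dt in spans)
        for a, b, _ in spans:
            if a - t0 < -tol - 1e-9 or b - t1 > tol + 1e-9:
                # all streams must cover the same interval within one sample
                raise InvalidArgumentError("sensor streams do not cover a common interval")

    def __getitem__(self, placement: str) -> SensorStream:
        return self.sensors[placement]

    def __contains__(self, placement: str) -> bool:
        return placement in self.sensors

    @property
    def duration(self) -> float:
        return max(s.duration for s in self.sensors.values())


def write_recording(rec: RawImuRecording, outdir: str) -> None:
    """Write one delimited table per sensor plus a ``meta.json`` sidecar."""
    os.makedirs(outdir, exist_ok=True)
    sidecar: dict = {"sensors": {}, "meta": rec.meta}
    for name, s in rec.sensors.items():
        cols = [s.t[:, None], s.acc]
        header = "timestamp_s ax ay az"
        if s.gyr is not None:
            cols.append(s.gyr)
            header += " gx gy gz"
        np.savetxt(
            os.path.join(outdir, f"{name}.txt"),
            np.hstack(cols),
            header=header,
            fmt="%.9g",
        )
        sidecar["sensors"][name] = {
            "placement": s.placement,
            "rate_hz": s.rate,
            "has_gyro": s.gyr is not None,
            "units": {"acc": "m/s^2", "gyr": "rad/s", "t": "s"},
        }
    with open(os.path.join(outdir, "meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1, default=float)


def read_recording(indir: str) -> RawImuRecording:
    with open(os.path.join(indir, "meta.json")) as fh:
        sidecar = json.load(fh)
    sensors = {}
    for name, info in sidecar["sensors"].items():
        data = np.loadtxt(os.path.join(indir, f"{name}.txt"), ndmin=2)
        gyr = data[:, 4:7] if info["has_gyro"] else None
        sensors[name] = SensorStream(
            placement=info["placement"],
            t=data[:, 0],
            acc=data[:, 1:4],
            gyr=gyr,
            rate=float(info["rate_hz"]),
        )
    return RawImuRecording(sensors=sensors, meta=sidecar.get("meta", {}))
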