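"""Walk-test gait features: preprocessing, event detection, four feature families.

The pipeline is: :func:`preprocess` (resample to 100 Hz, remove gyroscope
offset) → :func:`detect_gait_events` (per-foot initial/final contacts from
the sagittal angular rate) → the family extractors
(:func:`compute_spatiotemporal`, :func:`compute_frequency`,
:func:`compute_complexity`, :func:`compute_asymmetry`), all wrapped by
:func:`extract_features`.

Feature names are drawn from a registry so the catalog can be extended
without API change; every emitted vector includes ``gait_speed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    InsufficientGaitError,
    InvalidArgumentError,
    MissingSideError,
    TooShortError,
    UndefinedFeatureError,
)
from .recording import GRAVITY, RawImuRecording, SensorStream

TARGET_RATE = 100.0

# ---------------------------------------------------------------------------
# feature registry


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    family: str  # spatiotemporal | frequency | complexity | asymmetry
    units: str
    sensor: str


def _registry() -> dict[str, FeatureSpec]:
    specs: list[FeatureSpec] = []

    def add(name, family, units, sensor):
        specs.append(FeatureSpec(name, family, units, sensor))

    for name, units in [
        ("gait_speed", "m/s"), ("stride_time_mean", "s"), ("stride_time_sd", "s"),
        ("stride_time_cv", "-"), ("step_time_mean", "s"), ("step_time_sd", "s"),
        ("step_time_cv", "-"), ("cadence", "steps/min"), ("stride_length_mean", "m"),
        ("stance_time_mean", "s"), ("swing_time_mean", "s"),
        ("stance_fraction", "-"), ("swing_fraction", "-"),
    ]:
        add(name, "spatiotemporal", units, "feet")
    for axis in ("v", "ml", "ap"):
        add(f"dom_freq_{axis}", "frequency", "Hz", "low_back")
        add(f"dom_amp_{axis}", "frequency", "(m/s^2)^2/Hz", "low_back")
        add(f"harmonicity_{axis}", "frequency", "-", "low_back")
        add(f"harmonic_ratio_{axis}", "frequency", "-", "low_back")
    for axis in ("v", "ml", "ap"):
        add(f"sample_entropy_{axis}", "complexity", "-", "low_back")
    add("step_regularity", "complexity", "-", "low_back")
    add("stride_regularity", "complexity", "-", "low_back")
    add("regularity_symmetry", "complexity", "-", "low_back")
    for q in ("step_time", "stance_time", "swing_time"):
        add(f"si_{q}", "asymmetry", "%", "feet")
        add(f"ratio_{q}", "asymmetry", "-", "feet")
    return {s.name: s for s in specs}


FEATURE_REGISTRY: dict[str, FeatureSpec] = _registry()

_AXIS_COLUMN = {"ap": 0, "ml": 1, "v": 2}  # sensor frame: x anterior, y left, z up


@dataclass
class FeatureVector:
    """Mapping feature name → value, with registry metadata attached."""

    values: dict[str, float] = field(default_factory=dict)

    def update(self, other: dict[str, float]) -> None:
        for name, val in other.items():
            if name not in FEATURE_REGISTRY:
                raise InvalidArgumentError(f"feature {name!r} not in registry")
            if not np.isfinite(val):
                raise UndefinedFeatureError([name], f"non-finite value for {name!r}")
            self.values[name] = float(val)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_frame(self, measurement_id: str = "m0") -> pd.DataFrame:
        rows = [
            {
                "measurement_id": measurement_id,
                "feature": name,
                "value": val,
                "units": FEATURE_REGISTRY[name].units,
                "family": FEATURE_REGISTRY[name].family,
            }
            for name, val in self.values.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class GaitEventSeries:
    """Per-foot initial-contact and final-contact times (seconds).

    Per foot, ``fc[j] < ic[j]`` brackets swing ``j`` and exactly one final
    contact falls between consecutive initial contacts.
    """

    feet: dict[str, dict[str, np.ndarray]]

    def __post_init__(self) -> None:
        for foot, ev in self.feet.items():
            ic, fc = np.asarray(ev["ic"], float), np.asarray(ev["fc"], float)
            if np.any(np.diff(ic) <= 0) or np.any(np.diff(fc) <= 0):
                raise InvalidArgumentError(f"{foot}: event times must be strictly increasing")
            between = np.searchsorted(fc, ic)
            if np.any(np.diff(between) > 1):
                raise InvalidArgumentError(
                    f"{foot}: more than one final contact between consecutive initial contacts")
            self.feet[foot] = {"ic": ic, "fc": fc}

    def stride_times(self, foot: str) -> np.ndarray:
        return np.diff(self.feet[foot]["ic"])


# ---------------------------------------------------------------------------
# preprocessing


def _stationary_mask(stream: SensorStream, window_s: float = 1.0) -> np.ndarray:
    """Samples inside windows with both gyro and accel essentially quiet."""
    fs = stream.rate
    w = max(int(window_s * fs), 2)
    gyr_norm = np.linalg.norm(stream.gyr, axis=1)
    acc_dev = np.abs(np.linalg.norm(stream.acc, axis=1) - GRAVITY)

    def rolling_std(x):
        s = pd.Series(x).rolling(w, center=True, min_periods=w // 2)
        return s.std().to_numpy()

    g_std = rolling_std(gyr_norm)
    a_std = rolling_std(acc_dev)
    with np.errstate(invalid="ignore"):
        return (g_std < 0.05) & (a_std < 0.1)


def preprocess(recording: RawImuRecording, target_rate: float = TARGET_RATE) -> RawImuRecording:
    """Resample every stream to a uniform grid and remove gyroscope offset.

    Linear interpolation onto a ``target_rate`` grid; the per-axis gyroscope
    offset is the median over detected stationary samples (whole-recording
    median when fewer than 1% of samples qualify) and is subtracted.
    Acceleration is unchanged apart from resampling.
    """
    out = {}
    for name, s in recording.sensors.items():
        if s.duration < 2.0:
            raise TooShortError(f"{name}: need at least 2 s of data")
        grid = s.t[0] + np.arange(int(np.floor(s.duration * target_rate)) + 1) / target_rate
        acc = np.column_stack([np.interp(grid, s.t, s.acc[:, i]) for i in range(3)])
        gyr = None
        if s.gyr is not None:
            gyr = np.column_stack([np.interp(grid, s.t, s.gyr[:, i]) for i in range(3)])
            rs = SensorStream(s.placement, grid, acc, gyr, target_rate)
            mask = _stationary_mask(rs)
            if np.count_nonzero(mask) < 0.01 * mask.size:
                offset = np.median(gyr, axis=0)
            else:
                offset = np.median(gyr[mask], axis=0)
            gyr = gyr - offset
        out[name] = SensorStream(s.placement, grid, acc, gyr, target_rate)
    return RawImuRecording(sensors=out, meta=dict(recording.meta))


# ---------------------------------------------------------------------------
# gait events


def _interp_zero_crossing(t: np.ndarray, x: np.ndarray, i: int) -> float:
    """Linear-interpolated time of the zero crossing between samples i and i+1."""
    x0, x1 = x[i], x[i + 1]
    if x1 == x0:
        return float(t[i])
    return float(t[i] + (t[i + 1] - t[i]) * (-x0) / (x1 - x0))


def detect_gait_events(
    recording: RawImuRecording,
    prominence: float = 0.5,
    min_separation: float = 0.4,
) -> GaitEventSeries:
    """Detect per-foot initial and final contacts from the sagittal gyro.

    Mid-swing is located at angular-rate maxima; the initial contact is the
    first zero crossing after mid-swing and the final contact the last zero
    crossing before it.
    """
    feet = {}
    for foot in ("left_foot", "right_foot"):
        if foot not in recording:
            raise MissingSideError(f"no {foot} sensor in recording")
        s = recording[foot]
        if s.gyr is None:
            raise InvalidArgumentError(f"{foot}: gyroscope required for event detection")
        g = s.gyr[:, 1]
        fs = s.rate
        peaks, _ = sps.find_peaks(g, prominence=prominence,
                                  distance=max(int(min_separation * fs), 1))
        neg = g <= 0
        ics, fcs = [], []
        for p in peaks:
            after = np.flatnonzero(neg[p:])
            before = np.flatnonzero(neg[:p])
            if after.size == 0 or before.size == 0:
                continue
            i_ic = p + after[0] - 1      # crossing between i_ic and i_ic+1
            i_fc = before[-1]            # crossing between i_fc and i_fc+1
            ic = _interp_zero_crossing(s.t, g, i_ic)
            fc = _interp_zero_crossing(s.t, g, i_fc)
            if ics and ic <= ics[-1]:
                continue
            if fcs and fc <= fcs[-1]:
                continue
            ics.append(ic)
            fcs.append(fc)
        if len(ics) < 5:  # fewer than 4 strides
            raise InsufficientGaitError(f"{foot}: fewer than 4 strides detected")
        feet[foot] = {"ic": np.asarray(ics), "fc": np.asarray(fcs)}
    return GaitEventSeries(feet=feet)


def _turn_mask(intervals: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Flag intervals longer than ``factor`` × median (turning strides)."""
    if intervals.size == 0:
        return np.zeros(0, dtype=bool)
    return intervals > factor * np.median(intervals)


# ---------------------------------------------------------------------------
# spatio-temporal family


def compute_spatiotemporal(
    events: GaitEventSeries,
    path_length: float = 14.0,
    duration: float | None = None,
    distance: float | None = None,
    turn_factor: float = 1.5,
) -> dict[str, float]:
    """Stride-level timing statistics plus gait speed.

    Gait speed is walked distance over elapsed walking time. The distance is
    either supplied directly (``distance``) or inferred as (number of turning
    intervals + 1) × ``path_length``, where turning strides are those longer
    than ``turn_factor`` × the median stride and are excluded from the stride
    statistics.
    """
    if path_length <= 0:
        raise InvalidArgumentError("path_length must be positive")
    stride_all, stance_all, swing_all = [], [], []
    n_turns = 0
    first_ic = math.inf
    last_ic = -math.inf
    for foot, ev in events.feet.items():
        ic, fc = ev["ic"], ev["fc"]
        st = np.diff(ic)
        turns = _turn_mask(st, turn_factor)
        n_turns += int(np.count_nonzero(turns))
        stride_all.append(st[~turns])
        # stance of stride k: ic[k] -> fc of swing k+1 (toe-off)
        kmax = min(ic.size - 1, fc.size - 1)
        stance = fc[1:kmax + 1] - ic[:kmax]
        swing = ic[1:kmax + 1] - fc[1:kmax + 1]
        keep = ~turns[:kmax]
        stance_all.append(stance[keep])
        swing_all.append(swing[keep])
        first_ic = min(first_ic, ic[0])
        last_ic = max(last_ic, ic[-1])
    stride_times = np.concatenate(stride_all)
    if stride_times.size == 0:
        raise InsufficientGaitError("zero usable strides")

    # step times from interleaved initial contacts of opposite feet
    merged = sorted(
        [(tt, foot) for foot, ev in events.feet.items() for tt in ev["ic"]]
    )
    steps = []
    for (t0, f0), (t1, f1) in zip(merged[:-1], merged[1:]):
        if f0 != f1:
            steps.append(t1 - t0)
    steps = np.asarray(steps)
    steps = steps[~_turn_mask(steps, turn_factor)]
    if steps.size == 0:
        raise InsufficientGaitError("zero usable steps")

    elapsed = duration if duration is not None else last_ic - first_ic
    if distance is None:
        if n_turns == 0:
            raise InvalidArgumentError(
                "no turning intervals detected; supply the walked distance")
        distance = (n_turns + 1) * path_length
    speed = distance / elapsed

    stance = np.concatenate(stance_all)
    swing = np.concatenate(swing_all)
    cycle = stance.mean() + swing.mean()
    return {
        "gait_speed": speed,
        "stride_time_mean": stride_times.mean(),
        "stride_time_sd": stride_times.std(ddof=1) if stride_times.size > 1 else 0.0,
        "stride_time_cv": (stride_times.std(ddof=1) / stride_times.mean()
                           if stride_times.size > 1 else 0.0),
        "step_time_mean": steps.mean(),
        "step_time_sd": steps.std(ddof=1) if steps.size > 1 else 0.0,
        "step_time_cv": steps.std(ddof=1) / steps.mean() if steps.size > 1 else 0.0,
        "cadence": 60.0 / steps.mean(),
        "stride_length_mean": speed * stride_times.mean(),
        "stance_time_mean": stance.mean(),
        "swing_time_mean": swing.mean(),
        "stance_fraction": stance.mean() / cycle,
        "swing_fraction": swing.mean() / cycle,
    }


# ---------------------------------------------------------------------------
# frequency family


def _band_power(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    m = (f >= lo) & (f <= hi)
    return float(np.trapezoid(p[m], f[m])) if np.count_nonzero(m) > 1 else 0.0


def compute_frequency(
    recording: RawImuRecording,
    events: GaitEventSeries,
    band: tuple[float, float] = (0.3, 5.0),
    n_harmonics: int = 20,
) -> dict[str, float]:
    """Welch dominant frequency/amplitude, index of harmonicity, harmonic ratio.

    The harmonic ratio uses the first ``n_harmonics`` harmonics of the stride
    frequency: even/odd for the anterior-posterior and vertical axes,
    odd/even for mediolateral. Harmonic magnitudes are exact DFT bins of the
    signal cropped to an integer number of strides.
    """
    if "low_back" not in recording:
        raise MissingSideError("low-back sensor required for frequency features")
    s = recording["low_back"]
    fs = s.rate
    # crop to an integer number of strides of one (reference) foot
    foot = sorted(events.feet)[0]
    ic = events.feet[foot]["ic"]
    i0, i1 = np.searchsorted(s.t, [ic[0], ic[-1]])
    n_strides = ic.size - 1

    out: dict[str, float] = {}
    degenerate: list[str] = []
    for axis, col in _AXIS_COLUMN.items():
        x = s.acc[:, col] - s.acc[:, col].mean()
        if np.allclose(x, 0.0, atol=1e-12):
            degenerate += [f"dom_freq_{axis}", f"dom_amp_{axis}",
                           f"harmonicity_{axis}", f"harmonic_ratio_{axis}"]
            continue
        nper = min(x.size, 4096)
        f, p = sps.welch(x, fs=fs, nperseg=nper)
        m = (f >= band[0]) & (f <= band[1])
        j = int(np.argmax(p[m]))
        f0 = float(f[m][j])
        out[f"dom_freq_{axis}"] = f0
        out[f"dom_amp_{axis}"] = float(p[m][j])
        # index of harmonicity: power at f0 over summed power at first 6 harmonics
        half = max(2 * (f[1] - f[0]), 0.1)
        num = _band_power(f, p, f0 - half, f0 + half)
        den = sum(_band_power(f, p, k * f0 - half, k * f0 + half) for k in range(1, 7))
        out[f"harmonicity_{axis}"] = num / den if den > 0 else np.nan

        # harmonic ratio on exact stride-harmonic DFT bins
        seg = x[i0:i1]
        spec = np.abs(np.fft.rfft(seg - seg.mean()))
        mags = []
        for k in range(1, n_harmonics + 1):
            b = k * n_strides
            mags.append(spec[b] if b < spec.size else 0.0)
        mags = np.asarray(mags)
        even, odd = mags[1::2].sum(), mags[0::2].sum()
        if axis == "ml":
            out[f"harmonic_ratio_{axis}"] = odd / even if even > 0 else np.nan
        else:
            out[f"harmonic_ratio_{axis}"] = even / odd if odd > 0 else np.nan
    if degenerate:
        raise UndefinedFeatureError(degenerate)
    return out


# ---------------------------------------------------------------------------
# complexity family


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2,
                   max_n: int = 3000) -> float:
    """Sample entropy SampEn(m, r = r_frac × SD) with Chebyshev distance.

    Computed on at most ``max_n`` samples (the leading window) to bound the
    O(n²) pair count. Raises for constant input (r = 0).
    """
    x = np.asarray(x, float)[:max_n]
    sd = x.std()
    if sd == 0:
        raise UndefinedFeatureError(["sample_entropy"], "constant signal: r = 0")
    r = r_frac * sd
    n = x.size

    def count_matches(mm: int) -> int:
        npts = n - mm
        total = 0
        chunk = 512
        templ = np.column_stack([x[k:k + npts] for k in range(mm)])
        for start in range(0, npts, chunk):
            block = templ[start:start + chunk]  # (c, mm)
            d = np.abs(block[:, None, :] - templ[None, :, :]).max(axis=2)
            within = d < r
            total += int(within.sum()) - block.shape[0]  # drop self-matches
            # subtract double-counted pairs later; keep ordered-pair count
        return total

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0 or a == 0:
        return np.inf
    return float(-np.log(a / b))


def _unbiased_autocorr(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    n = x.size
    full = sps.correlate(x, x, mode="full")[n - 1:n + max_lag]
    counts = n - np.arange(max_lag + 1)
    ac = full / counts
    return ac / ac[0]


def compute_complexity(
    recording: RawImuRecording,
    max_lag_s: float = 4.0,
    sampen_window_s: float = 30.0,
) -> dict[str, float]:
    """Sample entropy per trunk axis plus step/stride regularity.

    Regularity follows the autocorrelation convention: the value of the
    unbiased, lag-0-normalized autocorrelation of the vertical trunk
    acceleration at the step lag (first dominant peak) and the stride lag
    (peak nearest twice the step lag); their ratio is the symmetry index.
    """
    if "low_back" not in recording:
        raise MissingSideError("low-back sensor required for complexity features")
    s = recording["low_back"]
    fs = s.rate
    if s.duration < 60.0:
        raise TooShortError("complexity features need at least 60 s")
    max_lag = int(max_lag_s * fs)
    if s.t.size < 10 * max_lag:
        raise TooShortError("series shorter than 10x the autocorrelation lag searched")

    out: dict[str, float] = {}
    for axis, col in _AXIS_COLUMN.items():
        x = s.acc[:, col]
        out[f"sample_entropy_{axis}"] = sample_entropy(
            x, max_n=int(sampen_window_s * fs))

    xv = s.acc[:, _AXIS_COLUMN["v"]]
    ac = _unbiased_autocorr(xv, max_lag)
    lags = np.arange(ac.size) / fs
    peaks, _ = sps.find_peaks(ac, distance=max(int(0.25 * fs), 1))
    peaks = peaks[(lags[peaks] >= 0.25) & (lags[peaks] <= max_lag_s)]
    if peaks.size == 0:
        raise UndefinedFeatureError(["step_regularity", "stride_regularity"],
                                    "no periodic structure in autocorrelation")
    step_peak = peaks[0]
    target = 2 * lags[step_peak]
    stride_peak = peaks[np.argmin(np.abs(lags[peaks] - target))]
    out["step_regularity"] = float(ac[step_peak])
    out["stride_regularity"] = float(ac[stride_peak])
    out["regularity_symmetry"] = (float(ac[step_peak] / ac[stride_peak])
                                  if ac[stride_peak] != 0 else np.nan)
    return out


# ---------------------------------------------------------------------------
# asymmetry family


def symmetry_index(left: float, right: float) -> float:
    """SI = |L − R| / (0.5 (L + R)) × 100%."""
    return abs(left - right) / (0.5 * (left + right)) * 100.0


def compute_asymmetry(events: GaitEventSeries, turn_factor: float = 1.5) -> dict[str, float]:
    """Symmetry index and max/min left-right ratio for step, stance, swing time."""
    for foot in ("left_foot", "right_foot"):
        if foot not in events.feet:
            raise MissingSideError(f"events for {foot} missing")
        if events.feet[foot]["ic"].size < 5:
            raise InsufficientGaitError(f"{foot}: fewer than 4 strides")

    per_side: dict[str, dict[str, float]] = {}
    # step time of a foot: interval from the opposite foot's IC to this foot's IC
    ics = {f: events.feet[f]["ic"] for f in ("left_foot", "right_foot")}
    for foot, other in (("left_foot", "right_foot"), ("right_foot", "left_foot")):
        vals = []
        for tt in ics[foot]:
            prev = ics[other][ics[other] < tt]
            if prev.size:
                dt = tt - prev[-1]
                vals.append(dt)
        vals = np.asarray(vals)
        vals = vals[~_turn_mask(vals, turn_factor)]
        ic, fc = events.feet[foot]["ic"], events.feet[foot]["fc"]
        kmax = min(ic.size - 1, fc.size - 1)
        stance = fc[1:kmax + 1] - ic[:kmax]
        swing = ic[1:kmax + 1] - fc[1:kmax + 1]
        per_side[foot] = {
            "step_time": float(np.mean(vals)),
            "stance_time": float(np.mean(stance[~_turn_mask(stance, turn_factor)])),
            "swing_time": float(np.mean(swing[~_turn_mask(swing, turn_factor)])),
        }

    out: dict[str, float] = {}
    for q in ("step_time", "stance_time", "swing_time"):
        lv, rv = per_side["left_foot"][q], per_side["right_foot"][q]
        out[f"si_{q}"] = symmetry_index(lv, rv)
        out[f"ratio_{q}"] = max(lv, rv) / min(lv, rv)
    return out


# ---------------------------------------------------------------------------
# wrapper


def extract_features(
    recording: RawImuRecording,
    path_length: float = 14.0,
    distance: float | None = None,
    already_preprocessed: bool = False,
) -> FeatureVector:
    """Full 2MWT feature vector from a raw three-sensor recording."""
    rec = recording if already_preprocessed else preprocess(recording)
    events = detect_gait_events(rec)
    if distance is None:
        distance = rec.meta.get("distance_m")
    fv = FeatureVector()
    fv.update(compute_spatiotemporal(events, path_length=path_length, distance=distance))
    fv.update(compute_frequency(rec, events))
    fv.update(compute_complexity(rec))
    fv.update(compute_asymmetry(events))
    return fv
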