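"""Daily-life walking ability from a single calf-worn sensor.

A multi-day recording is cut into 10-second epochs, each epoch is labelled
gait / non-gait / off-body, steps are counted from acceleration-norm peaks,
and per-epoch gait speed is obtained by double-integrating the
anterior-posterior linear acceleration over swing phases bounded by
zero-velocity updates (ZUPT) at detected stance. Per calendar day this
yields the three walking-ability measures: step count, average gait speed
and maximum gait speed, with an 8-hour minimum wear time for validity and
exclusion of gait epochs at or below 0.05 m/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ContractViolationError, NoZuptWarning, TooShortError
from .recording import GRAVITY, RawImuRecording

EPOCH_S = 10.0
SPEED_FLOOR = 0.05  # m/s; epochs at or below are excluded from daily summaries
MIN_WEAR_H = 8.0
STEP_BAND = (0.5, 3.0)  # Hz, detection band for steps and gait classification


@dataclass
class Epoch:
    """One 10-second slice of the calf recording."""

    start_time: float
    t: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray | None
    rate: float
    label: str | None = None
    speed: float | None = None

    @property
    def duration(self) -> float:
        return EPOCH_S


@dataclass
class WalkingAbilitySummary:
    """Per-day walking-ability measures."""

    day: int
    avg_speed: float | None
    max_speed: float | None
    steps: int
    wear_time_h: float
    valid: bool
    n_gait_epochs: int = 0
    n_excluded_epochs: int = 0


# ---------------------------------------------------------------------------
# epoching and classification


def split_epochs(recording: RawImuRecording) -> list[Epoch]:
    """Cut the calf stream into consecutive 10-s epochs; drop the remainder."""
    s = recording["calf"] if "calf" in recording else next(iter(recording.sensors.values()))
    per = int(round(EPOCH_S * s.rate))
    n_ep = s.t.size // per
    if n_ep == 0:
        raise TooShortError("recording shorter than one 10-s epoch")
    epochs = []
    for k in range(n_ep):
        sl = slice(k * per, (k + 1) * per)
        epochs.append(
            Epoch(
                start_time=float(s.t[sl.start]),
                t=s.t[sl],
                acc=s.acc[sl],
                gyr=None if s.gyr is None else s.gyr[sl],
                rate=s.rate,
            )
        )
    return epochs


@dataclass
class RuleBasedClassifier:
    """Default gait/non-gait/off-body epoch labeller.

    Gait when the step-band (0.5–3 Hz) power fraction of the detrended
    acceleration norm exceeds ``power_fraction`` and its SD exceeds
    ``activity_floor``; off-body when the norm SD stays below
    ``stillness_floor`` for the whole epoch; otherwise non-gait. Any object
    with the same ``__call__(epoch) -> label`` contract may replace it.
    """

    power_fraction: float = 0.35
    activity_floor: float = 0.4   # m/s²
    stillness_floor: float = 0.01  # m/s²

    def __call__(self, epoch: Epoch) -> str:
        norm = np.linalg.norm(epoch.acc, axis=1)
        sd = norm.std()
        if sd < self.stillness_floor:
            return "off_body"
        if sd < self.activity_floor:
            return "non_gait"
        x = norm - norm.mean()
        f, p = sps.welch(x, fs=epoch.rate, nperseg=min(x.size, 256))
        total = np.trapezoid(p[f > 0.1], f[f > 0.1])
        band = (f >= STEP_BAND[0]) & (f <= STEP_BAND[1])
        frac = np.trapezoid(p[band], f[band]) / total if total > 0 else 0.0
        return "gait" if frac > self.power_fraction else "non_gait"


def classify_epochs(epochs: list[Epoch], classifier=None) -> list[Epoch]:
    """Label every epoch in place (and return the list)."""
    clf = classifier if classifier is not None else RuleBasedClassifier()
    for ep in epochs:
        ep.label = clf(ep)
    return epochs


# ---------------------------------------------------------------------------
# steps


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def count_epoch_steps(epoch: Epoch, prominence: float = 1.0,
                      min_separation: float = 0.25,
                      rel_prominence: float = 0.3) -> int:
    """Steps in one epoch: peaks of the band-passed acceleration norm.

    A fixed prominence floor rejects noise; a relative threshold (fraction
    of the 95th-percentile peak prominence in the epoch) rejects filter
    ripple between genuine step peaks, which keeps the count invariant to
    overall signal amplitude.
    """
    norm = np.linalg.norm(epoch.acc, axis=1)
    x = _bandpass(norm - norm.mean(), epoch.rate, *STEP_BAND)
    peaks, props = sps.find_peaks(x, prominence=prominence,
                                  distance=max(int(min_separation * epoch.rate), 1))
    if peaks.size == 0:
        return 0
    prom = props["prominences"]
    keep = prom >= rel_prominence * np.percentile(prom, 95)
    return int(np.count_nonzero(keep))


def count_steps(epochs: list[Epoch], prominence: float = 1.0,
                min_separation: float = 0.25, rel_prominence: float = 0.3) -> int:
    """Total steps over all gait-labelled epochs.

    Consecutive gait epochs are counted on their concatenated signal so that
    steps straddling an epoch boundary are not lost to filter edge effects.
    """
    gait = sorted((e for e in epochs if e.label == "gait"), key=lambda e: e.start_time)
    if not gait:
        return 0
    runs: list[list[Epoch]] = [[gait[0]]]
    for ep in gait[1:]:
        prev = runs[-1][-1]
        if abs(ep.start_time - (prev.start_time + EPOCH_S)) < 0.5 / ep.rate:
            runs[-1].append(ep)
        else:
            runs.append([ep])
    total = 0
    for run in runs:
        norm = np.concatenate([np.linalg.norm(e.acc, axis=1) for e in run])
        fs = run[0].rate
        x = _bandpass(norm - norm.mean(), fs, *STEP_BAND)
        peaks, props = sps.find_peaks(x, prominence=prominence,
                                      distance=max(int(min_separation * fs), 1))
        if peaks.size == 0:
            continue
        prom = props["prominences"]
        total += int(np.count_nonzero(prom >= rel_prominence * np.percentile(prom, 95)))
    return total


# ---------------------------------------------------------------------------
# linear acceleration


def _principal_horizontal(lin: np.ndarray, vertical: np.ndarray) -> np.ndarray:
    """Project out the vertical, return the first principal horizontal component."""
    vhat = vertical / np.linalg.norm(vertical)
    horiz = lin - np.outer(lin @ vhat, vhat)
    hc = horiz - horiz.mean(axis=0)
    cov = hc.T @ hc / max(hc.shape[0] - 1, 1)
    w, vecs = np.linalg.eigh(cov)
    e = vecs[:, -1]
    return horiz @ e


def linear_acceleration(epoch: Epoch, gravity_cutoff: float = 0.25,
                        fusion_gain: float = 0.02):
    """Gravity-free acceleration and its anterior-posterior component.

    With a gyroscope, a complementary attitude filter tracks the gravity
    direction (the accelerometer corrects gyro drift with gain
    ``fusion_gain``); acceleration-only epochs (the usual daily-life
    configuration) estimate gravity per axis by low-pass filtering at
    ``gravity_cutoff`` Hz. Returns ``(linear, ap)`` where ``ap`` is the
    principal horizontal component (its sign is arbitrary).
    """
    if epoch.label != "gait":
        raise ContractViolationError("linear_acceleration requires a gait-labelled epoch")
    acc = epoch.acc
    fs = epoch.rate
    if epoch.gyr is not None:
        dt = 1.0 / fs
        g_dir = acc[0] / max(np.linalg.norm(acc[0]), 1e-9)
        gravity = np.empty_like(acc)
        for i in range(acc.shape[0]):
            if i:
                # rotate the gravity estimate by -omega dt, then nudge toward accel
                omega = epoch.gyr[i]
                g_dir = g_dir - np.cross(omega, g_dir) * dt
                a_dir = acc[i] / max(np.linalg.norm(acc[i]), 1e-9)
                g_dir = (1 - fusion_gain) * g_dir + fusion_gain * a_dir
                g_dir = g_dir / max(np.linalg.norm(g_dir), 1e-9)
            gravity[i] = GRAVITY * g_dir
        lin = acc - gravity
        vertical = gravity.mean(axis=0)
    else:
        sos = sps.butter(2, gravity_cutoff, btype="lowpass", fs=fs, output="sos")
        gravity = sps.sosfiltfilt(sos, acc, axis=0)
        lin = acc - gravity
        vertical = gravity.mean(axis=0)
    ap = _principal_horizontal(lin, vertical)
    return lin, ap


# ---------------------------------------------------------------------------
# ZUPT segmentation and per-epoch speed


def zupt_segment(
    epoch: Epoch,
    threshold: float = 1.0,
    min_stance_s: float = 0.08,
    smooth_s: float = 0.15,
    gyro_threshold: float = 0.5,
):
    """Partition a gait epoch into alternating stance/swing intervals.

    The detection statistic is the smoothed angular-rate norm when a
    gyroscope is present, else the smoothed magnitude of the high-passed
    deviation of the acceleration norm from gravity. Stance intervals are
    maximal below-threshold runs of at least ``min_stance_s``. Returns a
    list of ``(start_idx, end_idx, phase)`` tuples tiling the epoch, or
    ``None`` (with a warning) when no stance is found.
    """
    if epoch.label != "gait":
        raise ContractViolationError("zupt_segment requires a gait-labelled epoch")
    fs = epoch.rate
    w = max(int(smooth_s * fs), 2)
    if epoch.gyr is not None:
        stat = np.linalg.norm(epoch.gyr, axis=1)
        stat = np.convolve(stat, np.ones(w) / w, mode="same")
        thr = gyro_threshold
    else:
        # local variability of the norm: insensitive to the slow baseline
        # leakage that narrow-band filtering of sharp swing bursts produces
        norm = np.linalg.norm(epoch.acc, axis=1)
        stat = (
            pd.Series(norm - GRAVITY)
            .rolling(w, center=True, min_periods=2)
            .std()
            .bfill()
            .ffill()
            .to_numpy()
        )
        thr = threshold

    below = stat < thr
    n = below.size
    edges = np.flatnonzero(np.diff(below.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [n]])
    min_run = max(int(min_stance_s * fs), 1)
    runs = []
    for s0, s1 in zip(starts, ends):
        phase = "stance" if (below[s0] and (s1 - s0) >= min_run) else "swing"
        runs.append([s0, s1, phase])
    # merge adjacent equal phases (short below-threshold runs became swing)
    merged = [runs[0]]
    for r in runs[1:]:
        if r[2] == merged[-1][2]:
            merged[-1][1] = r[1]
        else:
            merged.append(r)
    if not any(r[2] == "stance" for r in merged):
        warnings.warn("no stance interval found in gait epoch", NoZuptWarning)
        return None
    return [tuple(r) for r in merged]


def epoch_speed(
    epoch: Epoch,
    intervals,
    ap: np.ndarray,
    drift_correction: bool = True,
) -> float | None:
    """Gait speed of one epoch from swing-phase double integration.

    Per swing bounded by stance on both sides: velocity is the cumulative
    trapezoidal integral of the AP linear acceleration starting at zero
    (the zero-velocity update), optionally drift-corrected by removing the
    linear velocity trend forced to zero at both stance anchors;
    displacement is the integral of the corrected velocity. The epoch
    distance is the sum of absolute per-swing displacements over 10 s.
    """
    if intervals is None:
        return None
    dt = 1.0 / epoch.rate
    distance = 0.0
    n_swings = 0
    last = len(intervals) - 1
    for k, (s0, s1, phase) in enumerate(intervals):
        if phase != "swing":
            continue
        a = ap[s0:s1]
        if a.size < 2:
            continue
        if 0 < k < last:
            # interior swing: anchors on both sides
            v = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) / 2.0) * dt])
            if drift_correction:
                v = v - np.linspace(0.0, v[-1], v.size)
        elif k == 0 and last > 0:
            # partial swing cut by the epoch start: integrate backwards from
            # the zero-velocity anchor at its end (no two-anchor detrend)
            ar = a[::-1]
            v = np.concatenate([[0.0], np.cumsum((ar[1:] + ar[:-1]) / 2.0) * dt])[::-1]
        elif k == last and k > 0:
            # partial swing cut by the epoch end: forward from its start anchor
            v = np.concatenate([[0.0], np.cumsum((a[1:] + a[:-1]) / 2.0) * dt])
        else:
            continue  # whole epoch is one swing: no anchor at all
        disp = np.trapezoid(v, dx=dt)
        distance += abs(disp)
        n_swings += 1
    if n_swings == 0:
        return None
    return distance / EPOCH_S


def attach_epoch_speeds(epochs: list[Epoch], drift_correction: bool = True) -> list[Epoch]:
    """Compute and store per-epoch speeds for all gait-labelled epochs."""
    for ep in epochs:
        if ep.label != "gait":
            continue
        _, ap = linear_acceleration(ep)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NoZuptWarning)
            intervals = zupt_segment(ep)
        ep.speed = epoch_speed(ep, intervals, ap, drift_correction=drift_correction)
    return epochs


# ---------------------------------------------------------------------------
# daily summaries


def summarize_day(
    epochs: list[Epoch],
    day: int = 0,
    max_speed_stat: str = "p95",
    speed_floor: float = SPEED_FLOOR,
    min_wear_h: float = MIN_WEAR_H,
) -> WalkingAbilitySummary:
    """Collapse one calendar day of labelled epochs into the summary measures.

    ``max_speed_stat`` is ``"p95"`` (default, robust to single-epoch
    integration noise) or ``"max"`` for the literal maximum.
    """
    wear_h = EPOCH_S * sum(1 for e in epochs if e.label != "off_body") / 3600.0
    gait = [e for e in epochs if e.label == "gait" and e.speed is not None]
    kept = [e.speed for e in gait if e.speed > speed_floor]
    excluded = len(gait) - len(kept)
    if kept:
        avg = float(np.mean(kept))
        mx = float(np.max(kept)) if max_speed_stat == "max" else float(
            np.percentile(kept, 95))
        mx = max(mx, avg)  # enforce maximum >= average
    else:
        avg = mx = None
    steps = count_steps(epochs)
    return WalkingAbilitySummary(
        day=day,
        avg_speed=avg,
        max_speed=mx,
        steps=steps,
        wear_time_h=wear_h,
        valid=wear_h >= min_wear_h,
        n_gait_epochs=len(kept),
        n_excluded_epochs=excluded,
    )


def process_daily_recording(
    recording: RawImuRecording,
    classifier=None,
    max_speed_stat: str = "p95",
    drift_correction: bool = True,
) -> list[WalkingAbilitySummary]:
    """Full daily-life chain: epochs → labels → speeds → per-day summaries.

    Day boundaries fall at local midnight; the recording's metadata key
    ``start_of_day_s`` gives the clock offset of sample time zero.
    """
    epochs = split_epochs(recording)
    classify_epochs(epochs, classifier)
    attach_epoch_speeds(epochs, drift_correction=drift_correction)
    offset = float(recording.meta.get("start_of_day_s", 0.0))
    by_day: dict[int, list[Epoch]] = {}
    for ep in epochs:
        by_day.setdefault(int((ep.start_time + offset) // 86400), []).append(ep)
    return [
        summarize_day(eps, day=day, max_speed_stat=max_speed_stat)
        for day, eps in sorted(by_day.items())
    ]


def summaries_to_frame(summaries: list[WalkingAbilitySummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "day": s.day,
                "avg_speed_mps": s.avg_speed,
                "max_speed_mps": s.max_speed,
                "steps": s.steps,
                "wear_h": s.wear_time_h,
                "valid": s.valid,
            }
            for s in summaries
        ]
    )
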