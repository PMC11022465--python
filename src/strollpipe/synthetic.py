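"""Synthetic gait and cohort generators with exact ground truth.

Three generators cover everything the pipeline consumes:

* :func:`generate_2mwt_signals` — a three-sensor (both feet + low back)
  walk-test recording with known stride events,
* :func:`generate_daily_recording` — a multi-hour single calf-sensor
  recording built from an activity timeline (gait / sedentary / standing /
  off-body bouts) with a known step count and per-bout speeds,
* :func:`generate_cohort` — a longitudinal feature/outcome table whose
  features share one dominant latent "walking capacity" factor and whose
  outcomes carry planted confounding and effect-modification paths.

Signal model (deliberately minimal, but rich enough that every feature the
pipeline extracts has a recoverable ground truth): the sagittal foot angular
rate is a small negative stance plateau plus a half-sine swing peak; the calf
anterior-posterior acceleration during each swing is a single-period sinusoid
whose double integral is exactly one stride length with zero velocity at both
stance anchors; the trunk oscillates at step and stride frequency with
asymmetry entering through odd harmonics. Additive white Gaussian noise is
applied everywhere except off-body bouts, which are pure zero-variance
gravity so wear-time detection has something detectable.

One top-level seed fans out to per-stream child seeds by stable hashing of
stream names, so adding a stream never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .recording import GRAVITY, RawImuRecording, SensorStream

# ---------------------------------------------------------------------------
# seeding


def child_seed(seed: int, stream: str) -> int:
    """Derive a deterministic per-stream seed from a top-level seed."""
    return zlib.crc32(f"{int(seed)}:{stream}".encode()) & 0x7FFFFFFF


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stream))


# ---------------------------------------------------------------------------
# ground-truth containers


@dataclass
class GaitTruth:
    """Requested gait parameters; ``gait_speed = stride_length / stride_time``.

    Exactly one of the three spatio-temporal parameters may be omitted and is
    derived from the other two; if all three are given they must agree.
    """

    stride_time: float | None = None
    stride_length: float | None = None
    gait_speed: float | None = None
    asymmetry_ratio: float = 1.0
    stride_time_cv: float = 0.0

    def __post_init__(self) -> None:
        given = [v is not None for v in (self.stride_time, self.stride_length, self.gait_speed)]
        if sum(given) < 2:
            raise InvalidArgumentError("need at least two of stride_time, stride_length, gait_speed")
        if self.stride_time is None:
            self.stride_time = self.stride_length / self.gait_speed
        elif self.stride_length is None:
            self.stride_length = self.gait_speed * self.stride_time
        elif self.gait_speed is None:
            self.gait_speed = self.stride_length / self.stride_time
        elif abs(self.gait_speed - self.stride_length / self.stride_time) > 1e-9:
            raise InvalidArgumentError("gait_speed must equal stride_length / stride_time")
        if self.stride_time <= 0 or self.stride_length <= 0:
            raise InvalidArgumentError("stride_time and stride_length must be positive")
        if self.asymmetry_ratio < 1:
            raise InvalidArgumentError("asymmetry_ratio must be >= 1")
        if not 0 <= self.stride_time_cv < 0.5:
            raise InvalidArgumentError("stride_time_cv must be in [0, 0.5)")


@dataclass
class Bout:
    label: str  # gait | sedentary | standing | off_body
    duration: float
    truth: GaitTruth | None = None

    def __post_init__(self) -> None:
        if self.label not in ("gait", "sedentary", "standing", "off_body"):
            raise InvalidArgumentError(f"unknown activity label {self.label!r}")
        if self.duration <= 0:
            raise InvalidArgumentError("bout duration must be positive")
        if self.label == "gait" and self.truth is None:
            raise InvalidArgumentError("gait bouts need a GaitTruth")


@dataclass
class ActivityTimeline:
    """Ordered, contiguous, non-overlapping activity bouts."""

    bouts: list[Bout]

    def __post_init__(self) -> None:
        if not self.bouts:
            raise InvalidArgumentError("timeline has no bouts")

    @property
    def total_duration(self) -> float:
        return float(sum(b.duration for b in self.bouts))


@dataclass
class DayTruth:
    """Exact ground truth emitted alongside a daily recording."""

    steps: int
    bout_speeds: list[float]
    wear_time_s: float
    gait_time_s: float


# ---------------------------------------------------------------------------
# two-minute walk test


def _stride_sequence(truth: GaitTruth, t_start: float, t_stop: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Per-stride durations covering [t_start, t_stop]; returns stride times."""
    strides = []
    elapsed = t_start
    while True:
        tk = truth.stride_time
        if truth.stride_time_cv > 0:
            tk = tk * (1.0 + truth.stride_time_cv * rng.standard_normal())
            tk = max(tk, 0.4 * truth.stride_time)
        if elapsed + tk > t_stop:
            break
        strides.append(tk)
        elapsed += tk
    if not strides:
        raise InvalidArgumentError("duration too short for a single stride")
    return np.asarray(strides)


def _swing_waveform(t: np.ndarray, fc: float, ic: float, amp: float, plateau: float) -> np.ndarray:
    """Half-sine swing peak on [fc, ic] riding on a negative stance plateau."""
    u = (t - fc) / (ic - fc)
    w = np.zeros_like(t)
    m = (u >= 0) & (u <= 1)
    w[m] = amp * np.sin(np.pi * u[m]) - plateau
    return w


def generate_2mwt_signals(
    truth: GaitTruth,
    duration: float = 120.0,
    rate: float = 104.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    gyro_bias: np.ndarray | None = None,
    stance_fraction: float = 0.6,
    lead_in: float = 2.0,
    lead_out: float = 1.5,
):
    """Simulate a two-minute walk test with three sensors.

    Returns ``(recording, events)`` where ``events`` maps each foot to exact
    initial-contact (``ic``) and final-contact (``fc``) times. The subject
    stands still for ``lead_in`` seconds before walking (this is also what
    the gyroscope-offset estimator relies on in real protocols).
    """
    if duration <= 0 or rate <= 0:
        raise InvalidArgumentError("duration and rate must be positive")
    a = truth.asymmetry_ratio
    rng_ev = _rng(seed, "2mwt/events")
    strides = _stride_sequence(truth, lead_in, duration - lead_out, rng_ev)
    n_str = strides.size
    r_ic = lead_in + np.concatenate([[0.0], np.cumsum(strides)])  # right ICs, n+1
    step_left = (a / (1.0 + a)) * strides
    l_ic = r_ic[:-1] + step_left  # left ICs, one per stride

    swing = (1.0 - stance_fraction) * strides
    r_fc = np.concatenate([[r_ic[0] - swing[0]], r_ic[:-1] + stance_fraction * strides])
    l_fc = np.concatenate(
        [[l_ic[0] - swing[0]], l_ic[:-1] + stance_fraction * strides[1:]]
    )
    events = {
        "left_foot": {"ic": l_ic, "fc": l_fc},
        "right_foot": {"ic": r_ic, "fc": r_fc},
    }

    n = int(np.floor(duration * rate)) + 1
    t = np.arange(n) / rate
    plateau = 0.15  # rad/s; small negative stance value so crossings bracket swing

    def foot_stream(name: str, ic: np.ndarray, fc: np.ndarray) -> SensorStream:
        gy = np.zeros(n)
        ax = np.zeros(n)
        az = np.full(n, GRAVITY)
        # stance plateau between each IC and the following FC
        for j in range(len(ic) - 1):
            m = (t >= ic[j]) & (t < fc[j + 1])
            gy[m] = -plateau
        for j in range(len(fc)):
            ic_j = ic[j]
            fc_j = fc[j]
            sdur = ic_j - fc_j
            amp = max(1.5, 2.5 * truth.stride_length / sdur)
            m = (t >= fc_j) & (t <= ic_j)
            u = (t[m] - fc_j) / sdur
            gy[m] = amp * np.sin(np.pi * u) - plateau
            ax[m] = (2.0 * np.pi * truth.stride_length / sdur**2) * np.sin(2 * np.pi * u)
            az[m] += 1.5 * np.sin(np.pi * u)
        acc = np.column_stack([ax, np.zeros(n), az])
        gyr = np.column_stack([np.zeros(n), gy, np.zeros(n)])
        if gyro_bias is not None:
            gyr = gyr + np.asarray(gyro_bias, dtype=float)
        if noise_sd > 0:
            r = _rng(seed, f"2mwt/noise/{name}")
            acc = acc + noise_sd * r.standard_normal(acc.shape)
            gyr = gyr + 0.1 * noise_sd * r.standard_normal(gyr.shape)
        return SensorStream(placement=name, t=t, acc=acc, gyr=gyr, rate=rate)

    # trunk: continuous stride phase, step frequency = 2 x stride frequency
    phase = np.zeros(n)
    walking = (t >= r_ic[0]) & (t <= r_ic[-1])
    edges = np.searchsorted(r_ic, t[walking], side="right") - 1
    edges = np.clip(edges, 0, n_str - 1)
    tw = t[walking]
    phase[walking] = 2 * np.pi * (edges + (tw - r_ic[edges]) / strides[edges])
    v = truth.gait_speed
    av, aap, aml = 0.25 + 1.2 * v, 0.2 + 0.8 * v, 0.15 + 0.5 * v
    asym = a - 1.0
    vert = av * (np.sin(2 * phase) + 0.25 * np.sin(4 * phase) + 0.5 * asym * np.sin(phase))
    apx = aap * (np.sin(2 * phase + 0.4) + 0.2 * np.sin(4 * phase + 0.4) + 0.4 * asym * np.sin(phase))
    mlx = aml * np.sin(phase)
    zero_out = ~walking
    for sig in (vert, apx, mlx):
        sig[zero_out] = 0.0
    acc_tr = np.column_stack([apx, mlx, GRAVITY + vert])
    gyr_tr = np.column_stack([0.05 * np.sin(phase), 0.05 * np.sin(2 * phase), np.zeros(n)])
    if gyro_bias is not None:
        gyr_tr = gyr_tr + np.asarray(gyro_bias, dtype=float)
    if noise_sd > 0:
        r = _rng(seed, "2mwt/noise/low_back")
        acc_tr = acc_tr + noise_sd * r.standard_normal(acc_tr.shape)
        gyr_tr = gyr_tr + 0.1 * noise_sd * r.standard_normal(gyr_tr.shape)
    trunk = SensorStream(placement="low_back", t=t, acc=acc_tr, gyr=gyr_tr, rate=rate)

    rec = RawImuRecording(
        sensors={
            "left_foot": foot_stream("left_foot", l_ic, l_fc),
            "right_foot": foot_stream("right_foot", r_ic, r_fc),
            "low_back": trunk,
        },
        meta={
            "protocol": "2mwt",
            "distance_m": float(truth.stride_length * n_str),
            "accel_range": "configured 8g equivalent; not clipped",
            "truth": {
                "stride_time": truth.stride_time,
                "stride_length": truth.stride_length,
                "gait_speed": truth.gait_speed,
                "asymmetry_ratio": truth.asymmetry_ratio,
                "stride_time_cv": truth.stride_time_cv,
            },
        },
    )
    return rec, events


# ---------------------------------------------------------------------------
# daily life

SWING_FRACTION_DAILY = 0.5


def generate_daily_recording(
    timeline: ActivityTimeline,
    rate: float = 52.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    include_gyro: bool = False,
    start_of_day_s: float = 8 * 3600.0,
):
    """Simulate a single calf-sensor daily-life recording from a timeline.

    Returns ``(recording, day_truth)``. Gait bouts produce step-periodic
    acceleration whose per-swing double integral equals the stride length;
    off-body bouts are exact zero-variance gravity. The true step count is
    ``floor(bout_duration / step_time)`` summed over gait bouts.
    """
    if rate <= 0:
        raise InvalidArgumentError("rate must be positive")
    total = timeline.total_duration
    n = int(round(total * rate))
    t = np.arange(n) / rate
    acc = np.zeros((n, 3))
    acc[:, 2] = GRAVITY
    gyr = np.zeros((n, 3)) if include_gyro else None
    noisy = np.ones(n, dtype=bool)

    steps = 0
    bout_speeds: list[float] = []
    wear = 0.0
    gait_time = 0.0
    t0 = 0.0
    for bi, bout in enumerate(timeline.bouts):
        t1 = t0 + bout.duration
        m = (t >= t0) & (t < t1)
        tau = t[m] - t0
        rng = _rng(seed, f"daily/bout/{bi}")
        if bout.label == "off_body":
            noisy[m] = False
        elif bout.label == "sedentary":
            acc[m, 0] += 0.25 * np.sin(2 * np.pi * 0.03 * tau + rng.uniform(0, 2 * np.pi))
            wear += bout.duration
        elif bout.label == "standing":
            acc[m, 0] += 0.08 * np.sin(2 * np.pi * 0.4 * tau + rng.uniform(0, 2 * np.pi))
            wear += bout.duration
        else:  # gait
            tr = bout.truth
            wear += bout.duration
            gait_time += bout.duration
            steps += int(np.floor(bout.duration / (tr.stride_time / 2.0)))
            bout_speeds.append(tr.gait_speed)
            bidx = np.flatnonzero(m)
            s = 0.0
            while True:
                tk = tr.stride_time
                if tr.stride_time_cv > 0:
                    tk = max(tk * (1 + tr.stride_time_cv * rng.standard_normal()),
                             0.4 * tr.stride_time)
                if s + tk > bout.duration:
                    break
                lk = tr.gait_speed * tk
                sdur = SWING_FRACTION_DAILY * tk
                sw0 = s + (1.0 - SWING_FRACTION_DAILY) * tk
                i0, i1 = np.searchsorted(tau, [sw0, sw0 + sdur])
                u = (tau[i0:i1] - sw0) / sdur
                amp_ap = 2.0 * np.pi * lk / sdur**2
                sw_idx = bidx[i0:i1]
                acc[sw_idx, 0] += amp_ap * np.sin(2 * np.pi * u)
                acc[sw_idx, 1] += 0.3 * np.sin(2 * np.pi * u)
                if gyr is not None:
                    gyr[sw_idx, 1] += (2.5 * lk / sdur) * np.sin(np.pi * u)
                # gentle vertical bounce at step frequency over the full stride
                j0, j1 = np.searchsorted(tau, [s, s + tk])
                acc[bidx[j0:j1], 2] += 0.4 * np.sin(
                    2 * np.pi * (2.0 / tk) * (tau[j0:j1] - s)
                )
                s += tk
        t0 = t1

    if noise_sd > 0:
        r = _rng(seed, "daily/noise")
        noise = noise_sd * r.standard_normal((n, 3))
        acc[noisy] += noise[noisy]
        if gyr is not None:
            gnoise = 0.1 * noise_sd * r.standard_normal((n, 3))
            gyr[noisy] += gnoise[noisy]

    rec = RawImuRecording(
        sensors={"calf": SensorStream(placement="calf", t=t, acc=acc, gyr=gyr, rate=rate)},
        meta={"protocol": "daily", "start_of_day_s": float(start_of_day_s)},
    )
    return rec, DayTruth(steps=steps, bout_speeds=bout_speeds, wear_time_s=wear,
                         gait_time_s=gait_time)


def make_daily_timeline(
    hours: float = 9.0,
    gait_fraction: float = 0.25,
    truth: GaitTruth | None = None,
    off_body_hours: float = 0.0,
    bout_minutes: float = 10.0,
    seed: int = 0,
) -> ActivityTimeline:
    """Convenience builder: alternate gait and non-gait bouts over a day."""
    if truth is None:
        truth = GaitTruth(stride_time=1.2, gait_speed=1.0)
    rng = _rng(seed, "timeline")
    total = hours * 3600.0
    bouts: list[Bout] = []
    if off_body_hours > 0:
        bouts.append(Bout("off_body", off_body_hours * 3600.0))
        total -= off_body_hours * 3600.0
    elapsed = 0.0
    while elapsed < total - 1.0:
        dur = min(bout_minutes * 60.0 * rng.uniform(0.5, 1.5), total - elapsed)
        if rng.uniform() < gait_fraction:
            bouts.append(Bout("gait", dur, truth))
        else:
            bouts.append(Bout(str(rng.choice(["sedentary", "standing"])), dur))
        elapsed += dur
    return ActivityTimeline(bouts)


# ---------------------------------------------------------------------------
# longitudinal cohort

#: planted path coefficients at unit strength (see docs/methods.md for the
#: power arithmetic behind these choices)
_CONF_OUTCOME_PATH = 0.04   # outcome units per confounder unit (avg-speed scale)
_MOD_INTERACTION = 0.16     # interaction coefficient on the avg-speed scale


def default_feature_loadings() -> dict[str, float]:
    """Loadings of the gait-feature panel on the latent capacity factor."""
    return {
        "stride_time_mean": -0.85, "stride_time_cv": -0.55, "step_time_mean": -0.8,
        "cadence": 0.9, "stride_length_mean": 0.85, "stance_fraction": -0.6,
        "swing_fraction": 0.6, "dom_freq_v": 0.8, "dom_amp_v": 0.7,
        "harmonic_ratio_v": 0.5, "harmonic_ratio_ap": 0.45, "harmonicity_v": 0.4,
        "sample_entropy_v": -0.35, "step_regularity": 0.5, "stride_regularity": 0.45,
        "si_step_time": -0.3, "si_stance_time": -0.25, "ratio_step_time": -0.3,
    }


def default_extra_factors() -> dict[str, dict[str, float]]:
    """Two minor orthogonal factors (asymmetry and variability structure)."""
    return {
        "asymmetry": {"si_step_time": 0.7, "si_stance_time": 0.65, "ratio_step_time": 0.7},
        "variability": {"stride_time_cv": 0.6, "sample_entropy_v": 0.55,
                        "stride_regularity": -0.5},
    }


@dataclass
class CohortSpec:
    """Generative description of a longitudinal cohort.

    The latent per-measurement "walking capacity" drives the 2MWT gait speed,
    all gait features (through ``feature_loadings``), and the daily-life
    outcomes. ``confounder_strength`` scales the latent → covariate → outcome
    path of the planted confounder; ``modifier_strength`` scales the
    speed × covariate interaction of the planted effect modifier. Strength
    1.0 is the documented default condition.
    """

    n_subjects: int = 30
    sessions_per_subject: int = 3
    latent_capacity_sd: float = 1.0
    feature_loadings: dict[str, float] = field(default_factory=default_feature_loadings)
    extra_factor_loadings: dict[str, dict[str, float]] = field(
        default_factory=default_extra_factors)
    confounder_strength: float = 1.0
    modifier_strength: float = 1.0
    feature_noise_sd: float = 0.5
    outcome_noise_sd: dict[str, float] = field(
        default_factory=lambda: {"avg_speed": 0.05, "max_speed": 0.05, "steps": 400.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidArgumentError("n_subjects must be >= 2")
        if self.sessions_per_subject < 1:
            raise InvalidArgumentError("sessions_per_subject must be >= 1")
        sds = [self.latent_capacity_sd, self.feature_noise_sd,
               *self.outcome_noise_sd.values()]
        if any(s < 0 for s in sds):
            raise InvalidArgumentError("all noise SDs must be >= 0")


def generate_cohort(spec: CohortSpec):
    """Generate ``(feature_table, outcome_table, truth)`` for a cohort.

    Both tables are indexed by measurement and carry ``subject_id``,
    ``session`` and ``walking_aid`` metadata columns. The outcome table also
    carries the 2MWT ``gait_speed`` predictor and the three candidate
    covariates ``cov_confounder``, ``cov_modifier``, ``cov_null``. ``truth``
    records the planted structure (which covariate truly confounds or
    modifies, and the generating coefficients).
    """
    rng = _rng(spec.seed, "cohort")
    ns, kses = spec.n_subjects, spec.sessions_per_subject
    n = ns * kses
    subj = np.repeat(np.arange(ns), kses)
    sess = np.tile(np.arange(kses), ns)

    a_subj = spec.latent_capacity_sd * rng.standard_normal(ns)  # subject level
    latent = a_subj[subj] + 0.5 * rng.standard_normal(n)        # per measurement

    speed = np.clip(0.7 + 0.25 * latent, 0.1, None)

    feat_names = list(spec.feature_loadings)
    extra_scores = {name: rng.standard_normal(n) for name in spec.extra_factor_loadings}
    feats = {}
    for fname in feat_names:
        x = spec.feature_loadings[fname] * latent
        for facname, loads in spec.extra_factor_loadings.items():
            if fname in loads:
                x = x + loads[fname] * extra_scores[facname]
        feats[fname] = x + spec.feature_noise_sd * rng.standard_normal(n)

    # confounder_strength scales BOTH paths: latent -> covariate -> outcome,
    # so zero strength yields a covariate unrelated to speed and outcome
    z_conf = (spec.confounder_strength * latent
              + 1.25 * rng.standard_normal(n))
    z_mod = rng.standard_normal(n)
    z_null = rng.standard_normal(n)

    g_conf = spec.confounder_strength * _CONF_OUTCOME_PATH
    d_mod = spec.modifier_strength * _MOD_INTERACTION
    speed_c = speed - 0.7  # interaction on centered speed keeps the planted
    # coefficient identical while adding less marginal outcome variance
    b_avg = 0.03 * rng.standard_normal(ns)[subj]   # subject random intercepts
    b_max = 0.05 * rng.standard_normal(ns)[subj]
    b_steps = 300.0 * rng.standard_normal(ns)[subj]
    sd = spec.outcome_noise_sd

    avg = (0.30 + 0.10 * speed + g_conf * z_conf + d_mod * speed_c * z_mod
           + b_avg + sd["avg_speed"] * rng.standard_normal(n))
    mx = (avg + 0.20 + 0.15 * speed + 1.5 * g_conf * z_conf
          + b_max + sd["max_speed"] * rng.standard_normal(n))
    steps = (1000.0 + 1800.0 * speed + 2000.0 * g_conf * z_conf
             + 5000.0 * d_mod * speed_c * z_mod
             + b_steps + sd["steps"] * rng.standard_normal(n))
    steps = np.maximum(steps, 0.0)

    meta = {
        "subject_id": [f"S{int(i):03d}" for i in subj],
        "session": sess,
        "walking_aid": np.zeros(n, dtype=int),
    }
    idx = pd.Index([f"M{int(i):04d}" for i in range(n)], name="measurement_id")
    feature_table = pd.DataFrame({**meta, **feats}, index=idx)
    outcome_table = pd.DataFrame(
        {**meta, "gait_speed": speed, "avg_speed": avg, "max_speed": mx,
         "steps": steps, "cov_confounder": z_conf, "cov_modifier": z_mod,
         "cov_null": z_null},
        index=idx,
    )
    truth = {
        "confounder": "cov_confounder" if spec.confounder_strength > 0 else None,
        "modifier": "cov_modifier" if spec.modifier_strength > 0 else None,
        "null": "cov_null",
        "beta": {"avg_speed": 0.10, "max_speed": 0.15, "steps": 1800.0},
        "confounder_outcome_path": g_conf,
        "interaction_coefficient": d_mod,
        "subject_intercept_sd": {"avg_speed": 0.03, "max_speed": 0.05, "steps": 300.0},
        "latent": latent,
    }
    return feature_table, outcome_table, truth


METADATA_COLUMNS = ("subject_id", "session", "walking_aid")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the gait-feature columns of a cohort feature table."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]
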