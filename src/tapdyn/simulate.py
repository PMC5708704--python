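"""Synthetic keystroke cohort simulator.

Generates labelled keystroke logs with the statistical structure the
classifier exploits, so the whole pipeline can be exercised and validated
without any participant data.

Each simulated subject types a stream of keys whose hands are drawn
independently from a fixed frequency table (left/right roughly balanced, a
small share of space-bar presses) and whose columns follow an English-typing
column-frequency profile.  Hold times and inter-key latencies are drawn from
log-normal distributions — human keystroke timings are positive and
right-skewed — parameterised by target mean and standard deviation per hand
(hold) and per direction class (latency).  Defaults keep hold times in the
typical 60-140 ms band and latencies in the 50-800 ms band, with an
occasional pause (a latency drawn well above the 800 ms pause threshold).

Disease effects are applied on top of a subject's baseline parameters:

* bradykinetic slowing — a shift of the hold-time mean (and of latencies,
  which inherit it through the same draw);
* increased movement variability — inflation of the timing variance (which
  also raises the log-normal's skewness and kurtosis);
* optional extra right-tail skew — an additive exponential component;
* unilateral asymmetry — one side's hold times, and latencies of pairs
  *ending* on that side, are multiplied by a factor >= 1 (controls always
  have factor exactly 1);
* more frequent hesitation pauses.

Between-subject variability (slow vs fast typists, idiosyncratic direction
preferences) is injected by drawing each subject's baseline parameters
around the population defaults; without it, subject-level feature means
would collapse onto the group values and any nonzero effect would be
trivially separable.
"""

from __future__ import annotations

import datetime
import string
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .log_io import KeystrokeEvent, KeystrokeLog, SubjectRecord

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "Cohort",
    "simulate_subject",
    "simulate_cohort",
]

#: Hand draw probabilities while typing English text (space ~ word boundary).
HAND_P: Dict[str, float] = {"L": 0.46, "R": 0.46, "S": 0.08}

#: Column draw probabilities within a hand zone (columns 1-5, centre-heavy).
COLUMN_P: Tuple[float, ...] = (0.10, 0.24, 0.28, 0.26, 0.12)

#: Population baseline timing targets (ms).
BASE_HOLD_MEAN = {"L": 100.0, "R": 100.0, "S": 95.0}
BASE_HOLD_SD = {"L": 15.0, "R": 15.0, "S": 14.0}
BASE_LATENCY_MEAN = {
    "LL": 230.0, "RR": 225.0, "LR": 190.0, "RL": 195.0,
    "LS": 240.0, "RS": 235.0, "SL": 250.0, "SR": 245.0, "SS": 260.0,
}
BASE_LATENCY_SD = {d: 55.0 for d in BASE_LATENCY_MEAN}

#: Between-subject spread of baseline parameters (ms).
SUBJECT_SPEED_SD = 10.0        # common shift of all of a subject's means
HAND_OFFSET_SD = 3.0           # per-hand idiosyncrasy around the common level
DIRECTION_OFFSET_SD = 8.0      # per-direction idiosyncrasy
SUBJECT_SCALE_SD = 2.5         # spread of a subject's timing SDs

_PAUSE_RANGE_MS = (1500.0, 8000.0)  # above the 800 ms threshold, below session gap
_SESSION_START = 9 * 3_600_000      # 09:00:00.000 in ms since midnight


@dataclass(frozen=True)
class SubjectProfile:
    """Fully specified timing model for one simulated subject."""

    subject_id: str
    has_pd: bool
    seed: int
    n_keystrokes: int = 2500
    hold_mean: Dict[str, float] = field(default_factory=lambda: dict(BASE_HOLD_MEAN))
    hold_sd: Dict[str, float] = field(default_factory=lambda: dict(BASE_HOLD_SD))
    latency_mean: Dict[str, float] = field(default_factory=lambda: dict(BASE_LATENCY_MEAN))
    latency_sd: Dict[str, float] = field(default_factory=lambda: dict(BASE_LATENCY_SD))
    asymmetry: float = 1.0
    affected_side: Optional[str] = None  # "L" or "R"; None for symmetric subjects
    pause_rate: float = 0.02
    skew_tail_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.n_keystrokes < 2:
            raise ValueError("n_keystrokes must be at least 2")
        if self.asymmetry < 1.0:
            raise ValueError("asymmetry factor must be >= 1")
        if not self.has_pd and self.asymmetry != 1.0:
            raise ValueError("control profiles must have asymmetry factor 1")
        if self.asymmetry > 1.0 and self.affected_side not in ("L", "R"):
            raise ValueError("asymmetry > 1 requires an affected side")
        if not 0 <= self.pause_rate < 1:
            raise ValueError("pause_rate must be in [0, 1)")
        for d in (self.hold_mean, self.hold_sd):
            if any(v <= 0 for v in d.values()):
                raise ValueError("hold location/scale parameters must be positive")
        for d in (self.latency_mean, self.latency_sd):
            if any(v <= 0 for v in d.values()):
                raise ValueError("latency location/scale parameters must be positive")


def _lognormal_params(mean: np.ndarray, sd: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    # moment-match a log-normal to a target mean and SD
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, np.sqrt(sigma2)


def _ms_to_time(ms: float) -> datetime.time:
    ms = int(round(ms)) % 86_400_000
    s, msec = divmod(ms, 1000)
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    return datetime.time(h, m, sec, msec * 1000)


def simulate_subject(profile: SubjectProfile) -> KeystrokeLog:
    """Generate one subject's keystroke log from their timing profile.

    Empirical per-category moments converge to the profile targets as the
    keystroke count grows (the asymmetry factor scales the affected side's
    whole distribution, so an affected mean is ``factor`` times its target).
    Deterministic given the profile seed.
    """
    rng = np.random.default_rng(profile.seed)
    n = profile.n_keystrokes

    hands = rng.choice(list(HAND_P), size=n, p=list(HAND_P.values()))
    columns = rng.choice(np.arange(1, 6), size=n, p=COLUMN_P)

    h_mean = np.array([profile.hold_mean[h] for h in hands])
    h_sd = np.array([profile.hold_sd[h] for h in hands])
    mu, sigma = _lognormal_params(h_mean, h_sd)
    holds = rng.lognormal(mean=mu, sigma=sigma)
    if profile.affected_side is not None:
        holds = np.where(hands == profile.affected_side, holds * profile.asymmetry, holds)

    directions = np.array([a + b for a, b in zip(hands[:-1], hands[1:])])
    l_mean = np.array([profile.latency_mean[d] for d in directions])
    l_sd = np.array([profile.latency_sd[d] for d in directions])
    mu, sigma = _lognormal_params(l_mean, l_sd)
    latencies = rng.lognormal(mean=mu, sigma=sigma)
    if profile.affected_side is not None:
        latencies = np.where(
            np.char.endswith(directions.astype(str), profile.affected_side),
            latencies * profile.asymmetry,
            latencies,
        )
    if profile.skew_tail_ms > 0:
        holds = holds + rng.exponential(profile.skew_tail_ms, size=n)
        latencies = latencies + rng.exponential(profile.skew_tail_ms, size=n - 1)
    pauses = rng.random(n - 1) < profile.pause_rate
    latencies = np.where(pauses, rng.uniform(*_PAUSE_RANGE_MS, size=n - 1), latencies)

    holds = np.round(holds, 1)
    latencies = np.round(latencies, 1)
    stamps = _SESSION_START + np.concatenate([[0.0], np.cumsum(latencies)])

    events = []
    for i in range(n):
        last = i == n - 1
        events.append(
            KeystrokeEvent(
                timestamp=_ms_to_time(stamps[i]),
                hand=str(hands[i]),
                column=int(columns[i]),
                hold_ms=float(holds[i]),
                next_direction=None if last else str(directions[i]),
                latency_ms=None if last else float(latencies[i]),
            )
        )
    return KeystrokeLog(subject_id=profile.subject_id, events=events)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and disease effect sizes.

    Defaults emulate the analysis cohort the classifier targets: 20 mild-PD
    subjects and 33 controls, each contributing at least 2000 keystrokes,
    with PD expressed as a +25 ms hold-mean shift, a doubling of timing
    variance, a 1.3x unilateral slowing of the affected side, and twice the
    baseline pause rate.  Set every effect to its null value (0 shift,
    inflation 1, asymmetry (1, 1), factor 1) for a label-free null cohort.
    """

    n_pd: int = 20
    n_control: int = 33
    seed: int = 0
    n_keystrokes_range: Tuple[int, int] = (2000, 3000)
    hold_shift_ms: float = 25.0
    variance_inflation: float = 2.0
    skew_tail_ms: float = 0.0
    asymmetry_range: Tuple[float, float] = (1.3, 1.3)
    pause_rate_factor: float = 2.0
    base_pause_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_pd <= 0 or self.n_control <= 0:
            raise ValueError("n_pd and n_control must both be positive")
        if self.hold_shift_ms < 0 or self.variance_inflation < 1 or self.skew_tail_ms < 0:
            raise ValueError("effect sizes must be non-negative (inflation >= 1)")
        if not 1 <= self.asymmetry_range[0] <= self.asymmetry_range[1]:
            raise ValueError("asymmetry_range must satisfy 1 <= lo <= hi")
        if self.pause_rate_factor < 1:
            raise ValueError("pause_rate_factor must be >= 1")

    @property
    def is_null(self) -> bool:
        return (
            self.hold_shift_ms == 0
            and self.variance_inflation == 1
            and self.skew_tail_ms == 0
            and self.asymmetry_range == (1.0, 1.0)
            and self.pause_rate_factor == 1
        )

    @classmethod
    def null(cls, **kwargs) -> "CohortSpec":
        """A cohort with no disease effect at all (labels are pure noise)."""
        return cls(
            hold_shift_ms=0.0,
            variance_inflation=1.0,
            skew_tail_ms=0.0,
            asymmetry_range=(1.0, 1.0),
            pause_rate_factor=1.0,
            **kwargs,
        )


@dataclass
class Cohort:
    logs: Dict[str, KeystrokeLog]
    subjects: list
    labels: Dict[str, bool]
    profiles: Dict[str, SubjectProfile]


def _draw_profile(spec: CohortSpec, rng: np.random.Generator, has_pd: bool) -> SubjectProfile:
    sid = "".join(rng.choice(list(string.ascii_lowercase + string.digits), size=10))
    speed = rng.normal(0.0, SUBJECT_SPEED_SD)
    scale = max(1.0, rng.normal(0.0, SUBJECT_SCALE_SD))
    sd_mult = np.sqrt(spec.variance_inflation) if has_pd else 1.0
    shift = spec.hold_shift_ms if has_pd else 0.0

    hold_mean = {
        h: BASE_HOLD_MEAN[h] + speed + shift + rng.normal(0.0, HAND_OFFSET_SD)
        for h in BASE_HOLD_MEAN
    }
    hold_sd = {h: (BASE_HOLD_SD[h] + scale) * sd_mult for h in BASE_HOLD_SD}
    latency_mean = {
        d: BASE_LATENCY_MEAN[d] + speed + shift + rng.normal(0.0, DIRECTION_OFFSET_SD)
        for d in BASE_LATENCY_MEAN
    }
    latency_sd = {d: (BASE_LATENCY_SD[d] + scale) * sd_mult for d in BASE_LATENCY_SD}

    if has_pd and spec.asymmetry_range[1] > 1:
        asym = float(rng.uniform(*spec.asymmetry_range))
        side = str(rng.choice(["L", "R"]))
    else:
        asym, side = 1.0, None
    return SubjectProfile(
        subject_id=sid,
        has_pd=has_pd,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_keystrokes=int(rng.integers(*spec.n_keystrokes_range, endpoint=True)),
        hold_mean=hold_mean,
        hold_sd=hold_sd,
        latency_mean=latency_mean,
        latency_sd=latency_sd,
        asymmetry=asym,
        affected_side=side,
        pause_rate=min(
            0.5,
            spec.base_pause_rate * (spec.pause_rate_factor if has_pd else 1.0),
        ),
        skew_tail_ms=spec.skew_tail_ms if has_pd else 0.0,
    )


def _draw_metadata(profile: SubjectProfile, rng: np.random.Generator) -> SubjectRecord:
    side = {"L": "Left", "R": "Right", None: "None"}[profile.affected_side]
    if profile.has_pd:
        return SubjectRecord(
            subject_id=profile.subject_id,
            has_pd=True,
            diagnosis_year=int(rng.integers(2012, 2017)),
            tremors=bool(rng.random() < 0.5),
            sidedness=side,
            updrs=int(rng.integers(1, 3)),
            impact="Mild",
            levodopa=False,
            other_meds="" if rng.random() < 0.6 else "MAO-B",
            birth_year=int(rng.integers(1937, 1968)),
            gender="M" if rng.random() < 0.5 else "F",
        )
    return SubjectRecord(
        subject_id=profile.subject_id,
        has_pd=False,
        sidedness="None",
        impact="NA",
        levodopa=False,
        birth_year=int(rng.integers(1937, 1968)),
        gender="M" if rng.random() < 0.5 else "F",
    )


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a labelled cohort: keystroke logs, metadata, ground truth.

    Byte-identical under the same master seed.  The metadata table is
    consistent with the logs (the recorded sidedness is the simulated
    affected side; PD subjects are mild-severity and levodopa-free, so the
    default eligibility screen keeps the whole cohort).
    """
    rng = np.random.default_rng(spec.seed)
    logs, subjects, labels, profiles = {}, [], {}, {}
    for has_pd, count in ((True, spec.n_pd), (False, spec.n_control)):
        for _ in range(count):
            profile = _draw_profile(spec, rng, has_pd)
            profiles[profile.subject_id] = profile
            logs[profile.subject_id] = simulate_subject(profile)
            subjects.append(_draw_metadata(profile, rng))
            labels[profile.subject_id] = has_pd
    return Cohort(logs=logs, subjects=subjects, labels=labels, profiles=profiles)
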