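"""Hold/latency feature extraction from keystroke logs.

The classifier sees each subject as a vector of 27 timing features computed
from their whole keystroke stream.  The *Hold* group (9 features) describes
vertical finger movement: the first four sample moments (mean, standard
deviation, skewness, excess kurtosis) of key hold times, separately for the
left and the right hand, plus the signed left-minus-right mean difference as
an asymmetry measure.  The *Latency* group (18 features) describes movement
between keys: the same four moments of the key-down-to-key-down latency for
each ordered-pair direction class LR, RL, LL, RR, plus two signed asymmetry
differences (mean LR - mean RL, mean LL - mean RR).

Space-involving pairs (LS/RS/SL/SR/SS) are classified and counted but never
enter the latency features, and space-bar hold times enter neither hand's
hold features.  Latencies longer than the pause threshold (800 ms by default)
are pauses in typing, not movement, and are dropped before any statistic is
computed.

Moment conventions (used everywhere in the package): standard deviation with
the n-1 denominator; adjusted (bias-corrected) Fisher-Pearson skewness;
bias-corrected excess kurtosis (normal -> 0).  Skewness and kurtosis are
unstable in small samples, so they are reported as missing below ``min_n``
observations (default 30) and imputed downstream.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .log_io import KeystrokeLog, SubjectRecord

__all__ = [
    "PAUSE_THRESHOLD_MS",
    "HOLD_FEATURES",
    "LATENCY_FEATURES",
    "FEATURE_NAMES",
    "LATENCY_DIRECTIONS",
    "MomentStats",
    "FeatureVector",
    "Ineligible",
    "EligibilityRule",
    "classify_direction",
    "filter_pauses",
    "compute_moment_stats",
    "extract_features",
    "screen_subjects",
    "features_to_frame",
    "mirror_hands",
    "mirror_features",
]

#: Latencies above this are pauses in typing and are excluded (inclusive
#: boundary: exactly 800 ms is retained, anything greater is dropped).
PAUSE_THRESHOLD_MS = 800.0

#: Direction classes whose latencies contribute to the feature vector.
LATENCY_DIRECTIONS = ("LR", "RL", "LL", "RR")

_MOMENTS = ("mean", "sd", "skew", "kurt")

HOLD_FEATURES: Tuple[str, ...] = tuple(
    f"hold_{hand}_{m}" for hand in ("L", "R") for m in _MOMENTS
) + ("hold_diff_L_R",)

LATENCY_FEATURES: Tuple[str, ...] = tuple(
    f"latency_{d}_{m}" for d in LATENCY_DIRECTIONS for m in _MOMENTS
) + ("latency_diff_LR_RL", "latency_diff_LL_RR")

FEATURE_NAMES: Tuple[str, ...] = HOLD_FEATURES + LATENCY_FEATURES

assert len(HOLD_FEATURES) == 9 and len(LATENCY_FEATURES) == 18


def classify_direction(first_hand: str, second_hand: str) -> str:
    """Two-letter direction class of an ordered keystroke pair.

    Total over the hand enum: ``SS`` is returned as an explicit class even
    though it is excluded from latency statistics downstream.
    """
    for h in (first_hand, second_hand):
        if h not in ("L", "R", "S"):
            raise ValueError(f"hand must be L, R or S, got {h!r}")
    return first_hand + second_hand


@dataclass
class PauseFilterReport:
    n_input: int = 0
    n_removed: int = 0
    n_flagged_low: int = 0


def filter_pauses(
    pairs: Sequence[Tuple[str, float]],
    max_latency_ms: float = PAUSE_THRESHOLD_MS,
    min_latency_ms: float = 0.0,
) -> Tuple[list, PauseFilterReport]:
    """Drop ordered pairs whose latency exceeds the pause threshold.

    The boundary is inclusive: a latency equal to ``max_latency_ms`` is
    retained.  Latencies below ``min_latency_ms`` are retained but counted in
    the report (suspiciously fast pairs may indicate clock glitches).
    """
    report = PauseFilterReport(n_input=len(pairs))
    kept = []
    for direction, latency in pairs:
        if latency < 0:
            raise ValueError(f"negative latency {latency} in pair filter")
        if latency > max_latency_ms:
            report.n_removed += 1
            continue
        if latency < min_latency_ms:
            report.n_flagged_low += 1
        kept.append((direction, latency))
    return kept, report


@dataclass(frozen=True)
class MomentStats:
    """First four sample moments of a timing distribution.

    Undefined values (too few observations, or zero spread for the shape
    moments) are NaN.
    """

    mean: float
    sd: float
    skewness: float
    kurtosis: float
    n: int


def compute_moment_stats(values: Sequence[float], min_n: int = 30) -> MomentStats:
    """Mean, sample SD, adjusted skewness and excess kurtosis of ``values``.

    Never raises on degenerate input: an empty sample yields all-NaN stats,
    and skewness/kurtosis are NaN whenever ``n < min_n`` or the sample has
    zero spread.
    """
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n == 0:
        return MomentStats(math.nan, math.nan, math.nan, math.nan, 0)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if n >= 2 else math.nan
    if n >= min_n and sd > 0:
        skewness = float(stats.skew(x, bias=False))
        kurtosis = float(stats.kurtosis(x, fisher=True, bias=False))
    else:
        skewness = math.nan
        kurtosis = math.nan
    return MomentStats(mean, sd, skewness, kurtosis, n)


@dataclass(frozen=True)
class EligibilityRule:
    """Screening rules for the analysis subset.

    Only subjects with a large keystroke sample give stable higher moments,
    only mild-severity PD belongs in an *early*-detection cohort, and
    levodopa masks the very motor symptoms being measured.
    """

    min_keystrokes: int = 2000
    severity_allowed: frozenset = frozenset({"Mild"})
    exclude_levodopa: bool = True

    def __post_init__(self) -> None:
        if self.min_keystrokes <= 0:
            raise ValueError("min_keystrokes must be positive")


@dataclass(frozen=True)
class Ineligible:
    """Returned by :func:`extract_features` when a log fails screening."""

    subject_id: str
    reasons: Tuple[str, ...]


@dataclass(frozen=True)
class FeatureVector:
    """The 27 named features for one subject, partitioned 9 Hold / 18 Latency."""

    subject_id: str
    n_keystrokes: int
    values: Mapping[str, float]
    direction_counts: Mapping[str, int] = field(default_factory=dict)
    n_pauses_removed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            raise ValueError("feature vector must contain exactly the 27 named features in order")

    @property
    def hold_group(self) -> dict:
        return {k: self.values[k] for k in HOLD_FEATURES}

    @property
    def latency_group(self) -> dict:
        return {k: self.values[k] for k in LATENCY_FEATURES}

    def to_series(self) -> pd.Series:
        s = pd.Series(dict(self.values), name=self.subject_id)
        return s


def _moments_dict(prefix: str, ms: MomentStats) -> dict:
    return {
        f"{prefix}_mean": ms.mean,
        f"{prefix}_sd": ms.sd,
        f"{prefix}_skew": ms.skewness,
        f"{prefix}_kurt": ms.kurtosis,
    }


def extract_features(
    log: KeystrokeLog,
    rule: Optional[EligibilityRule] = EligibilityRule(),
    pause_threshold_ms: float = PAUSE_THRESHOLD_MS,
    min_n: int = 30,
) -> Union[FeatureVector, Ineligible]:
    """Compute the 27-feature vector for one subject's keystroke log.

    Hold statistics come from per-key hold times split by hand (space-bar
    presses excluded); latency statistics come from pause-filtered LR/RL/LL/RR
    pairs only.  Asymmetry features are signed mean differences.  Pass
    ``rule=None`` to extract features from a log that fails the keystroke
    minimum (e.g. for exploratory work).
    """
    n_keys = len(log.events)
    if rule is not None and n_keys < rule.min_keystrokes:
        return Ineligible(
            log.subject_id,
            (f"min_keystrokes: {n_keys} < {rule.min_keystrokes}",),
        )

    holds = {"L": [], "R": []}
    pairs = []
    direction_counts: Counter = Counter()
    for ev in log.events:
        if ev.hand in holds:
            holds[ev.hand].append(ev.hold_ms)
        if ev.latency_ms is not None:
            direction_counts[ev.next_direction] += 1
            pairs.append((ev.next_direction, ev.latency_ms))

    kept, pause_report = filter_pauses(pairs, max_latency_ms=pause_threshold_ms)
    by_direction = {d: [] for d in LATENCY_DIRECTIONS}
    for direction, latency in kept:
        if direction in by_direction:
            by_direction[direction].append(latency)

    values: dict = {}
    hand_stats = {h: compute_moment_stats(holds[h], min_n=min_n) for h in ("L", "R")}
    for h in ("L", "R"):
        values.update(_moments_dict(f"hold_{h}", hand_stats[h]))
    values["hold_diff_L_R"] = hand_stats["L"].mean - hand_stats["R"].mean

    dir_stats = {
        d: compute_moment_stats(by_direction[d], min_n=min_n)
        for d in LATENCY_DIRECTIONS
    }
    for d in LATENCY_DIRECTIONS:
        values.update(_moments_dict(f"latency_{d}", dir_stats[d]))
    values["latency_diff_LR_RL"] = dir_stats["LR"].mean - dir_stats["RL"].mean
    values["latency_diff_LL_RR"] = dir_stats["LL"].mean - dir_stats["RR"].mean

    ordered = {name: float(values[name]) for name in FEATURE_NAMES}
    return FeatureVector(
        subject_id=log.subject_id,
        n_keystrokes=n_keys,
        values=ordered,
        direction_counts=dict(direction_counts),
        n_pauses_removed=pause_report.n_removed,
    )


@dataclass
class ScreeningResult:
    eligible: list
    exclusions: dict  # subject_id -> tuple of reasons
    tallies: Counter


def screen_subjects(
    subjects: Sequence[SubjectRecord],
    keystroke_counts: Mapping[str, int],
    rule: EligibilityRule = EligibilityRule(),
) -> ScreeningResult:
    """Apply the eligibility rules to a cohort.

    A subject fails on any of: too few captured keystrokes (total, across all
    direction classes), PD severity outside the allowed set, or levodopa use.
    Subjects with a keystroke log but no metadata row are excluded with reason
    ``metadata_missing``.
    """
    by_id = {s.subject_id: s for s in subjects}
    eligible, exclusions, tallies = [], {}, Counter()
    for sid in sorted(set(by_id) | set(keystroke_counts)):
        reasons = []
        rec = by_id.get(sid)
        if rec is None:
            reasons.append("metadata_missing")
        else:
            count = keystroke_counts.get(sid, 0)
            if count < rule.min_keystrokes:
                reasons.append("min_keystrokes")
            if rec.has_pd and rec.impact not in rule.severity_allowed:
                reasons.append("severity")
            if rule.exclude_levodopa and rec.levodopa:
                reasons.append("levodopa")
        if reasons:
            exclusions[sid] = tuple(reasons)
            tallies.update(reasons)
        else:
            eligible.append(sid)
    return ScreeningResult(eligible=eligible, exclusions=exclusions, tallies=tallies)


def features_to_frame(
    vectors: Iterable[FeatureVector],
    labels: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Assemble feature vectors into the canonical subjects-by-features table.

    Columns: the 27 features in fixed order, then ``n_keystrokes``, and
    ``label`` (0/1) when labels are supplied; index is ``subject_id``.
    """
    rows = []
    for fv in vectors:
        row = dict(fv.values)
        row["n_keystrokes"] = fv.n_keystrokes
        if labels is not None:
            row["label"] = int(labels[fv.subject_id])
        rows.append(pd.Series(row, name=fv.subject_id))
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    return df


_HAND_MIRROR = {"L": "R", "R": "L", "S": "S"}


def mirror_hands(log: KeystrokeLog) -> KeystrokeLog:
    """Swap every left/right hand label (and direction letters) in a log."""
    events = []
    for ev in log.events:
        d = ev.next_direction
        events.append(
            replace(
                ev,
                hand=_HAND_MIRROR[ev.hand],
                next_direction=None if d is None else _HAND_MIRROR[d[0]] + _HAND_MIRROR[d[1]],
            )
        )
    return KeystrokeLog(subject_id=log.subject_id, events=events)


def mirror_features(values: Mapping[str, float]) -> dict:
    """The feature vector of the hand-mirrored log, computed by relabelling.

    Per-hand and per-direction statistics swap (L<->R, LR<->RL, LL<->RR) and
    the three signed asymmetry differences negate.
    """
    swap = {}
    for name in FEATURE_NAMES:
        if name.startswith("hold_diff") or name.startswith("latency_diff"):
            swap[name] = -values[name]
        elif name.startswith("hold_"):
            _, hand, m = name.split("_")
            swap[name] = values[f"hold_{_HAND_MIRROR[hand]}_{m}"]
        else:
            _, d, m = name.split("_")
            swap[name] = values[f"latency_{_HAND_MIRROR[d[0]] + _HAND_MIRROR[d[1]]}_{m}"]
    return swap
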