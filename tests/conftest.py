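import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tapdyn.features import FEATURE_NAMES
from tapdyn.log_io import KeystrokeEvent, KeystrokeLog, SubjectRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def ms_to_time(ms: float) -> datetime.time:
    ms = int(round(ms)) % 86_400_000
    s, msec = divmod(ms, 1000)
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    return datetime.time(h, m, sec, msec * 1000)


def make_log(subject_id, rows):
    """Build a KeystrokeLog from (ms_since_midnight, hand, col, hold, latency) rows.

    Direction classes are derived from consecutive hands; a None latency
    marks a session break.
    """
    events = []
    for i, (ts, hand, col, hold, lat) in enumerate(rows):
        nxt = rows[i + 1][1] if i + 1 < len(rows) else None
        last_of_session = lat is None or nxt is None
        events.append(
            KeystrokeEvent(
                timestamp=ms_to_time(ts),
                hand=hand,
                column=col,
                hold_ms=hold,
                next_direction=None if last_of_session else hand + nxt,
                latency_ms=None if last_of_session else lat,
            )
        )
    return KeystrokeLog(subject_id=subject_id, events=events)


def random_feature_frame(rng, n_per_class=8, separation=0.0):
    """A labelled 27-feature frame: standard-normal noise plus a mean shift
    of ``separation`` on every feature for the positive class."""
    n = 2 * n_per_class
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1] += separation
    ids = [f"subj{i:04d}" for i in range(n)]
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES), index=pd.Index(ids, name="subject_id"))
    return df, y


@pytest.fixture
def screening_fixture():
    """Ten subjects with hand-worked eligibility outcomes.

    Survivors: ctrl_big (control, plenty of keys), pd_mild_ok, ctrl_boundary
    (exactly at the keystroke minimum) and pd_mild_edge.
    """

    def ctrl(sid, **kw):
        return SubjectRecord(subject_id=sid, has_pd=False, impact="NA",
                             birth_year=1950, gender="F", **kw)

    def pd(sid, impact="Mild", levodopa=False):
        return SubjectRecord(subject_id=sid, has_pd=True, impact=impact,
                             levodopa=levodopa, birth_year=1950, gender="M",
                             sidedness="Left", diagnosis_year=2015)

    subjects = [
        ctrl("ctrl_big"),
        pd("pd_mild_ok"),
        ctrl("ctrl_short"),
        pd("pd_severe", impact="Severe"),
        pd("pd_mild_levo", levodopa=True),
        pd("pd_medium_short", impact="Medium"),
        ctrl("ctrl_boundary"),
        ctrl("ctrl_nolog"),
        pd("pd_mild_edge"),
    ]
    counts = {
        "ctrl_big": 5000,
        "pd_mild_ok": 2500,
        "ctrl_short": 1999,
        "pd_severe": 3000,
        "pd_mild_levo": 4000,
        "pd_medium_short": 1000,
        "ctrl_boundary": 2000,
        "pd_mild_edge": 2001,
        "orphan_log": 3000,  # log present, no metadata row
    }
    expected_eligible = {"ctrl_big", "pd_mild_ok", "ctrl_boundary", "pd_mild_edge"}
    expected_reasons = {
        "ctrl_short": ("min_keystrokes",),
        "pd_severe": ("severity",),
        "pd_mild_levo": ("levodopa",),
        "pd_medium_short": ("min_keystrokes", "severity"),
        "ctrl_nolog": ("min_keystrokes",),
        "orphan_log": ("metadata_missing",),
    }
    return subjects, counts, expected_eligible, expected_reasons
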