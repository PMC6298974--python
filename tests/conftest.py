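import numpy as np
import pytest

from sfg.session import ObserverParams, SessionData, TaskDesign, TrialRecord
from sfg.stimgen import ChordTimebase, build_frequency_pool


@pytest.fixture(scope="session")
def pool():
    return build_frequency_pool()


@pytest.fixture(scope="session")
def timebase():
    return ChordTimebase()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_design():
    return TaskDesign(n_trials=200)


@pytest.fixture
def default_observer():
    return ObserverParams()


def make_fixture_session(counts, fa_catch=0, n_catch=100, mean_rt=0.5, session_id="fx0"):
    """Build a session with exact outcome counts.

    ``counts`` maps coherence -> (n_hits, n_misses).  Hit RTs are spread
    deterministically around ``mean_rt``; figure onset is fixed at 1.0 s.
    """
    trials = []
    tid = 0
    for c, (n_hits, n_miss) in sorted(counts.items()):
        for i in range(n_hits):
            rt = mean_rt + 0.01 * (i - n_hits / 2)
            trials.append(TrialRecord(tid, "figure", c, 1.0, 1.0 + rt, "hit", 1.0))
            tid += 1
        for _ in range(n_miss):
            trials.append(TrialRecord(tid, "figure", c, 1.0, None, "miss", 0.0))
            tid += 1
    for i in range(n_catch):
        if i < fa_catch:
            trials.append(TrialRecord(tid, "catch", None, None, 1.5, "false_alarm", 0.0))
        else:
            trials.append(TrialRecord(tid, "catch", None, None, None, "correct_rejection", 1.5))
        tid += 1
    return SessionData(session_id, "fx", trials)
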