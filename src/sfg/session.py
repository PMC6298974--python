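"""Go/No-Go figure-detection session simulator.

A synthetic observer stands in for a trained macaque: it holds a touch bar
through each stimulus and releases it when it detects the embedded figure
(Go) or spuriously (false alarm).  The observer is parametric —

* detection probability follows a logistic psychometric function of
  log-coherence, rising from the false-alarm floor to a lapse-limited
  asymptote;
* false alarms arise from a uniform release hazard over the stimulus,
  calibrated to a per-stimulus false-alarm probability;
* reaction times are shifted-exponential, with mean latency shrinking as
  coherence grows.

Sessions mix figure trials (60%, coherence levels equiprobable) with
ground-only catch trials (40%), exactly allocated and randomly ordered.
The resulting trial logs carry the statistical structure the analysis
pipeline expects: coherence-dependent hit rates and reaction times and a
coherence-independent false-alarm rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .stimgen import ParameterError

__all__ = [
    "TaskDesign",
    "ObserverParams",
    "TrialRecord",
    "SessionData",
    "allocate_trials",
    "observer_hit_probability",
    "simulate_trial",
    "simulate_session",
    "simulate_sessions",
]

#: Columns of the session-log CSV schema (one row per trial).
TRIAL_COLUMNS = [
    "trial_id",
    "condition",
    "coherence",
    "figure_onset",
    "response_time",
    "outcome",
    "reward_volume",
    "excluded",
]


@dataclass(frozen=True)
class TaskDesign:
    """Parameters of the Go/No-Go detection task.

    Defaults follow the behavioural paradigm: 60% figure trials with
    coherence levels {4, 6, 8, 10, 12}, 40% ground-only catch trials,
    3-s stimuli with the 1-s figure starting 0.3-2 s after stimulus onset
    (on the 50-ms chord grid), a 1-s inter-trial interval and a 3-s
    penalty time-out for errors.
    """

    n_trials: int = 1000
    figure_trial_fraction: float = 0.6
    coherence_levels: tuple[int, ...] = (4, 6, 8, 10, 12)
    stimulus_len: float = 3.0
    figure_duration: float = 1.0
    onset_range: tuple[float, float] = (0.3, 2.0)
    onset_grid: float = 0.05
    iti: float = 1.0
    penalty_timeout: float = 3.0
    motor_grace: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 < self.figure_trial_fraction < 1.0):
            raise ParameterError("figure_trial_fraction must lie in (0, 1)")
        if self.n_trials < 0:
            raise ParameterError("n_trials must be non-negative")

    @property
    def hit_window(self) -> float:
        """Release window after figure onset that scores as a hit."""
        return self.figure_duration + self.motor_grace


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric, false-alarm and reaction-time parameters of the observer.

    ``hit_threshold_coherence`` is the midpoint (c50) of the logistic
    psychometric function in log-coherence; ``hit_slope`` its steepness.
    ``fa_rate_per_stimulus`` is the probability of a spurious release over
    one full-length stimulus.  Hit reaction times are
    ``rt_floor + Exponential(mean = rt_scale / (1 + rt_coherence_gain * c))``.
    """

    hit_asymptote: float = 0.95
    hit_threshold_coherence: float = 4.5
    hit_slope: float = 3.0
    fa_rate_per_stimulus: float = 0.12
    rt_floor: float = 0.30
    rt_scale: float = 0.35
    rt_coherence_gain: float = 0.08
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("hit_asymptote", "fa_rate_per_stimulus"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be a probability, got {v}")
        if self.fa_rate_per_stimulus > self.hit_asymptote:
            raise ParameterError("false-alarm floor exceeds the hit asymptote")
        if self.rt_floor <= 0:
            raise ParameterError("rt_floor must be positive")


@dataclass
class TrialRecord:
    """One Go/No-Go trial.

    ``response_time`` is measured from stimulus onset; ``None`` means the
    bar was held for the whole stimulus.  ``figure_onset`` and ``coherence``
    are ``None`` on catch trials.
    """

    trial_id: int
    condition: str                    # "figure" | "catch"
    coherence: int | None
    figure_onset: float | None
    response_time: float | None
    outcome: str                      # hit | miss | false_alarm | correct_rejection
    reward_volume: float
    excluded: bool = False


@dataclass
class SessionData:
    """A session's worth of trials plus the design that produced them."""

    session_id: str
    subject_id: str
    trials: list[TrialRecord]
    design: TaskDesign = field(default_factory=TaskDesign)
    observer: ObserverParams | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([t.__dict__ for t in self.trials], columns=TRIAL_COLUMNS)
        df.insert(0, "session_id", self.session_id)
        df.insert(1, "subject_id", self.subject_id)
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        design: TaskDesign | None = None,
        observer: ObserverParams | None = None,
    ) -> "SessionData":
        """Rebuild a session from the CSV trial schema."""
        trials = []
        for row in df.itertuples(index=False):
            trials.append(
                TrialRecord(
                    trial_id=int(row.trial_id),
                    condition=str(row.condition),
                    coherence=None if pd.isna(row.coherence) else int(row.coherence),
                    figure_onset=None if pd.isna(row.figure_onset) else float(row.figure_onset),
                    response_time=None if pd.isna(row.response_time) else float(row.response_time),
                    outcome=str(row.outcome),
                    reward_volume=float(row.reward_volume),
                    excluded=bool(row.excluded),
                )
            )
        session_id = str(df["session_id"].iloc[0]) if "session_id" in df and len(df) else "s0"
        subject_id = str(df["subject_id"].iloc[0]) if "subject_id" in df and len(df) else "sim"
        return cls(session_id, subject_id, trials, design or TaskDesign(), observer)


def allocate_trials(
    design: TaskDesign, rng: np.random.Generator
) -> list[tuple[str, int | None]]:
    """Exact trial allocation for one session, in randomized order.

    Exactly ``floor(n_trials * figure_trial_fraction)`` figure trials are
    created, split as evenly as possible (difference at most one) across
    the coherence levels; the remainder are catch trials.  The sequence is
    then permuted with ``rng``.
    """
    n_fig = int(math.floor(design.n_trials * design.figure_trial_fraction))
    if n_fig > 0 and not design.coherence_levels:
        raise ParameterError("figure trials requested but no coherence levels given")
    k = len(design.coherence_levels)
    trials: list[tuple[str, int | None]] = []
    for i, c in enumerate(design.coherence_levels):
        n_level = n_fig // k + (1 if i < n_fig % k else 0)
        trials.extend(("figure", int(c)) for _ in range(n_level))
    trials.extend(("catch", None) for _ in range(design.n_trials - n_fig))
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def observer_hit_probability(coherence: float, params: ObserverParams) -> float:
    """Detection probability at a given figure coherence.

    Logistic in log-coherence, bounded below by the false-alarm rate
    (guessing floor) and above by the lapse-limited asymptote:

    ``p = fa + (asymptote - fa) / (1 + (c50 / c) ** slope)``

    At zero coherence (no figure) the probability equals the false-alarm
    rate; at the threshold coherence it is the midpoint of floor and
    asymptote.
    """
    fa = params.fa_rate_per_stimulus
    if coherence <= 0:
        return fa
    x = params.hit_slope * (math.log(coherence) - math.log(params.hit_threshold_coherence))
    return fa + (params.hit_asymptote - fa) / (1.0 + math.exp(-x))


def _draw_onset(design: TaskDesign, rng: np.random.Generator) -> float:
    """Figure onset, uniform over the allowed range on the chord grid."""
    lo, hi = design.onset_range
    g = design.onset_grid
    k_lo, k_hi = int(round(lo / g)), int(round(hi / g))
    return g * int(rng.integers(k_lo, k_hi + 1))


def simulate_trial(
    stimulus_meta: tuple[str, int | None, float | None],
    params: ObserverParams,
    design: TaskDesign,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> TrialRecord:
    """Simulate one trial given (condition, coherence, figure_onset).

    Catch trials: a spurious release occurs with probability
    ``fa_rate_per_stimulus`` at a time uniform over the stimulus, otherwise
    the bar is held (correct rejection, fixed large reward).  Figure
    trials: the same uniform release hazard operates until figure onset
    (so the pre-figure false-alarm probability is
    ``fa_rate * onset / stimulus_len``); if no false alarm pre-empts it,
    the figure is detected with :func:`observer_hit_probability` and the
    release follows at ``onset + rt_floor + Exp(...)``.  A release inside
    the hit window scores a hit with a reward that decreases with reaction
    time; anything else is a miss.
    """
    condition, coherence, onset = stimulus_meta
    fa = params.fa_rate_per_stimulus

    if condition == "catch":
        if rng.random() < fa:
            t = float(rng.uniform(0.0, design.stimulus_len))
            return TrialRecord(trial_id, "catch", None, None, t, "false_alarm", 0.0)
        return TrialRecord(trial_id, "catch", None, None, None, "correct_rejection", 1.5)

    if onset is None:
        onset = _draw_onset(design, rng)
    coherence = int(coherence or 0)

    # spurious-release hazard, truncated at figure onset
    if rng.random() < fa:
        t_fa = float(rng.uniform(0.0, design.stimulus_len))
        if t_fa < onset:
            return TrialRecord(
                trial_id, "figure", coherence, onset, t_fa, "false_alarm", 0.0
            )

    if rng.random() < observer_hit_probability(coherence, params):
        mean_rt = params.rt_scale / (1.0 + params.rt_coherence_gain * coherence)
        rt = params.rt_floor + float(rng.exponential(mean_rt))
        response = onset + rt
        if rt <= design.hit_window:
            reward = max(0.1, 1.2 - rt)
            return TrialRecord(trial_id, "figure", coherence, onset, response, "hit", reward)
        return TrialRecord(trial_id, "figure", coherence, onset, response, "miss", 0.0)

    return TrialRecord(trial_id, "figure", coherence, onset, None, "miss", 0.0)


def simulate_session(
    design: TaskDesign,
    params: ObserverParams,
    session_id: str = "s0",
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
) -> SessionData:
    """Simulate a complete session; reproducible from (seed, design, params)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng if rng is not None else params.seed)
    trials = []
    for i, (condition, coherence) in enumerate(allocate_trials(design, rng)):
        trials.append(simulate_trial((condition, coherence, None), params, design, rng, i))
    return SessionData(session_id, subject_id, trials, design, params)


def simulate_sessions(
    n_sessions: int,
    design: TaskDesign,
    params: ObserverParams,
    rng: np.random.Generator | int | None = None,
    subject_id: str = "sim",
) -> list[SessionData]:
    """Simulate several sessions with independent per-session seeds."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [
        simulate_session(design, params, f"s{i:03d}", rng, subject_id)
        for i in range(n_sessions)
    ]
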