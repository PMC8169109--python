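"""Trial classification and session-level behavioral metrics.

Implements the four-outcome trial taxonomy of lick-based auditory
discrimination tasks (hit / miss / correct rejection / false alarm), the
derived session metrics

    performance = (H + CR) / (H + CR + FA + M)
    hit_rate    = H / (H + M)
    fa_rate     = FA / (FA + CR)

and the condition contrasts used to quantify optogenetic manipulation
effects (laser ON vs OFF) and delay-duration effects across subjects.

Three task variants share the same metric definitions and differ only in
how the response window is anchored:

* ``dms`` — delayed match-to-sample: sample tone, delay, test tone; the
  1 s response window starts at test-tone offset.
* ``delayed_go_nogo`` — sample tone, delay, response cue; the decision
  depends on the sample, and the window starts at response-cue offset.
* ``go_nogo`` — start cue, delay, sample tone; the decision depends on
  the sample, and the window starts at sample-tone offset.

Time zero is always the onset of the sample tone (the stimulus that
carries the decision-relevant frequency), for every variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaskConfig",
    "Trial",
    "Session",
    "SessionMetrics",
    "ConditionComparison",
    "OUTCOMES",
    "classify_trial",
    "classify_session",
    "session_metrics",
    "metrics_by_delay",
    "laser_contrast",
    "choose_test",
]

OUTCOMES = ("hit", "miss", "cr", "fa")

TASK_TYPES = ("dms", "delayed_go_nogo", "go_nogo")


@dataclass(frozen=True)
class TaskConfig:
    """Timing of one trial, in seconds.

    All event times downstream are expressed relative to sample-tone
    onset.  ``test_duration`` doubles as the response-cue duration in the
    delayed go/no-go variant.
    """

    task_type: str = "dms"
    sample_duration: float = 0.2
    delay_duration: float = 1.5
    test_duration: float = 0.2
    response_window_duration: float = 1.0
    iti: float = 10.0

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task_type {self.task_type!r}")
        for name in ("sample_duration", "delay_duration", "test_duration",
                     "response_window_duration", "iti"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def response_window(self, delay_duration: float | None = None) -> tuple[float, float]:
        """Half-open response window ``[start, start + duration)``.

        ``delay_duration`` overrides the config delay (trials within one
        experiment may use different delays).
        """
        delay = self.delay_duration if delay_duration is None else delay_duration
        if self.task_type in ("dms", "delayed_go_nogo"):
            # window opens at the offset of the test tone / response cue
            start = self.sample_duration + delay + self.test_duration
        else:  # go_nogo: window opens at sample-tone offset
            start = self.sample_duration
        return (start, start + self.response_window_duration)

    def test_onset(self, delay_duration: float | None = None) -> float:
        delay = self.delay_duration if delay_duration is None else delay_duration
        return self.sample_duration + delay

    def delay_end(self, delay_duration: float | None = None) -> float:
        """End of the delay period = onset of the test tone / response cue."""
        return self.test_onset(delay_duration)


@dataclass
class Trial:
    """One behavioral trial; all times in seconds from sample onset."""

    trial_id: int
    sample_stimulus: float
    test_stimulus: float | None
    is_match: bool
    delay_duration: float
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    laser_window: tuple[float, float] | None = None
    distractor_window: tuple[float, float] | None = None
    outcome: str | None = None

    def __post_init__(self) -> None:
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        if self.lick_times.size and np.any(np.diff(self.lick_times) < 0):
            raise ValueError(f"trial {self.trial_id}: lick_times not sorted")

    @property
    def laser_on(self) -> bool:
        return self.laser_window is not None


@dataclass
class Session:
    """A list of trials from one subject under one task configuration."""

    trials: list[Trial]
    task: TaskConfig = field(default_factory=TaskConfig)
    subject_id: str = "subject-0"

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


@dataclass(frozen=True)
class SessionMetrics:
    """Outcome counts and the derived fractions for one set of trials."""

    H: int
    M: int
    CR: int
    FA: int
    performance: float
    hit_rate: float
    fa_rate: float

    @property
    def n_trials(self) -> int:
        return self.H + self.M + self.CR + self.FA

    @property
    def miss_rate(self) -> float:
        return 1.0 - self.hit_rate

    @property
    def cr_rate(self) -> float:
        return 1.0 - self.fa_rate


@dataclass
class ConditionComparison:
    """Across-subject contrast of one metric between two conditions."""

    metric: str
    per_subject_on: np.ndarray
    per_subject_off: np.ndarray
    test_name: str
    statistic: float
    p_value: float
    mean_on: float
    mean_off: float
    sem_on: float
    sem_off: float

    @property
    def delta(self) -> float:
        """mean(ON) − mean(OFF)."""
        return self.mean_on - self.mean_off

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


# ---------------------------------------------------------------------------
# trial classification
# ---------------------------------------------------------------------------

def classify_trial(trial: Trial, cfg: TaskConfig) -> str:
    """Classify one trial as ``hit``/``miss``/``cr``/``fa``.

    A trial counts as a lick response iff at least one lick falls in the
    half-open response window.  Licks outside the window — including
    delay-period licks — are ignored for classification.

    For DMS trials, ``is_match`` must be consistent with the stimulus
    identities.
    """
    if trial.is_match is None:
        raise ValueError(f"trial {trial.trial_id}: missing match flag")
    if cfg.task_type == "dms" and trial.test_stimulus is not None:
        if bool(trial.is_match) != (trial.sample_stimulus == trial.test_stimulus):
            raise ValueError(
                f"trial {trial.trial_id}: is_match inconsistent with stimuli "
                f"({trial.sample_stimulus} vs {trial.test_stimulus})"
            )
    lo, hi = cfg.response_window(trial.delay_duration)
    licks = trial.lick_times
    if licks.size and licks.min() < -cfg.iti:
        raise ValueError(f"trial {trial.trial_id}: lick time beyond trial span")
    responded = bool(np.any((licks >= lo) & (licks < hi)))
    if trial.is_match:
        return "hit" if responded else "miss"
    return "fa" if responded else "cr"


def classify_session(session: Session) -> Session:
    """Return the session with every trial's ``outcome`` filled in."""
    for trial in session.trials:
        trial.outcome = classify_trial(trial, session.task)
    return session


# ---------------------------------------------------------------------------
# session metrics
# ---------------------------------------------------------------------------

def session_metrics(trials: Iterable[Trial], permissive: bool = False) -> SessionMetrics:
    """Outcome counts and derived rates for a set of classified trials.

    With ``permissive=True`` an undefined rate (no match trials, or no
    nonmatch trials) becomes NaN instead of raising.
    """
    counts = {k: 0 for k in OUTCOMES}
    for t in trials:
        if t.outcome not in counts:
            raise ValueError(f"trial {t.trial_id} is unclassified ({t.outcome!r})")
        counts[t.outcome] += 1
    H, M, CR, FA = counts["hit"], counts["miss"], counts["cr"], counts["fa"]
    total = H + M + CR + FA
    if total == 0:
        raise ValueError("no trials")

    def _rate(num: int, den: int, what: str) -> float:
        if den == 0:
            if permissive:
                return math.nan
            raise ZeroDivisionError(f"{what} undefined: denominator is zero")
        return num / den

    return SessionMetrics(
        H=H, M=M, CR=CR, FA=FA,
        performance=(H + CR) / total,
        hit_rate=_rate(H, H + M, "hit_rate"),
        fa_rate=_rate(FA, FA + CR, "fa_rate"),
    )


def metrics_by_delay(sessions: Sequence[Session], metric: str = "performance") -> pd.DataFrame:
    """Aggregate a session metric across subjects, grouped by delay duration.

    Subjects contributing several sessions at the same delay have their
    trials pooled before the metric is computed.  Returns one row per
    delay level with columns ``delay_s``, ``mean``, ``sem``, ``n_subjects``;
    ``sem`` is NaN for a single subject (documented convention).
    """
    if not sessions:
        raise ValueError("no sessions")
    pooled: dict[tuple[float, str], list[Trial]] = {}
    for s in sessions:
        for t in s.trials:
            pooled.setdefault((t.delay_duration, s.subject_id), []).append(t)
    rows = []
    by_delay: dict[float, list[float]] = {}
    for (delay, _subj), trials in pooled.items():
        value = getattr(session_metrics(trials, permissive=True), metric)
        by_delay.setdefault(delay, []).append(value)
    for delay in sorted(by_delay):
        vals = np.asarray(by_delay[delay], dtype=float)
        sem = stats.sem(vals) if vals.size > 1 else math.nan
        rows.append({"delay_s": delay, "mean": vals.mean(), "sem": sem,
                     "n_subjects": vals.size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistical test selection and laser contrasts
# ---------------------------------------------------------------------------

def choose_test(paired_a: Sequence[float], paired_b: Sequence[float],
                alpha_norm: float = 0.05) -> str:
    """Pick the across-subject test from the normality of paired differences.

    Shapiro–Wilk on (a − b): normal-looking differences (p ≥ alpha_norm)
    get the paired t-test, otherwise the Wilcoxon rank-sum test (the
    nonparametric fallback used throughout this kind of study).  Returns
    ``"degenerate"`` when the differences have zero variance.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.allclose(diffs, diffs[0]):
        return "degenerate"
    p_norm = stats.shapiro(diffs).pvalue
    return "paired t-test" if p_norm >= alpha_norm else "wilcoxon rank-sum"


def _subject_metric(trials: list[Trial], metric: str) -> float:
    return getattr(session_metrics(trials, permissive=True), metric)


def laser_contrast(sessions: Sequence[Session], metric: str = "performance") -> ConditionComparison:
    """Per-subject laser ON vs OFF contrast of a session metric.

    Trials are pooled per subject across sessions and split by the
    presence of a laser window; the across-subject test is chosen by
    :func:`choose_test`.  Every subject must contribute both ON and OFF
    trials.
    """
    if metric not in ("performance", "hit_rate", "fa_rate"):
        raise ValueError(f"unknown metric {metric!r}")
    on: dict[str, list[Trial]] = {}
    off: dict[str, list[Trial]] = {}
    for s in sessions:
        for t in s.trials:
            (on if t.laser_on else off).setdefault(s.subject_id, []).append(t)
    subjects = sorted(set(on) | set(off))
    for subj in subjects:
        if subj not in on or subj not in off:
            raise ValueError(f"subject {subj!r} lacks laser ON or OFF trials")
    vals_on = np.array([_subject_metric(on[s], metric) for s in subjects])
    vals_off = np.array([_subject_metric(off[s], metric) for s in subjects])
    test_name = choose_test(vals_on, vals_off)
    if test_name == "paired t-test":
        res = stats.ttest_rel(vals_on, vals_off)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test_name == "wilcoxon rank-sum":
        res = stats.ranksums(vals_on, vals_off)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:  # degenerate: identical metrics in both conditions
        statistic, p = 0.0, 1.0
    return ConditionComparison(
        metric=metric,
        per_subject_on=vals_on,
        per_subject_off=vals_off,
        test_name=test_name,
        statistic=statistic,
        p_value=p,
        mean_on=float(vals_on.mean()),
        mean_off=float(vals_off.mean()),
        sem_on=float(stats.sem(vals_on)) if vals_on.size > 1 else math.nan,
        sem_off=float(stats.sem(vals_off)) if vals_off.size > 1 else math.nan,
    )
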