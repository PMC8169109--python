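"""Synthetic sessions and spike trains with the structure the analyses assume.

The behavioral generator draws trial outcomes from Bernoulli hit/false-alarm
probabilities, optionally shifted on laser-ON trials when the laser window
overlaps an "effective" window (stimulus plus early delay, 0.2-1.0 s from
sample onset by default).  The shift is gated on >= 50% overlap of the laser
window with the effective window, so a laser confined to the late delay
leaves behavior untouched — the dissociation the analysis pipeline is meant
to detect.

The spike generator is an inhomogeneous Poisson process whose intensity is
piecewise: a flat baseline ``r0``; a stimulus-locked step of amplitude
``a_pref`` or ``a_nonpref`` depending on the sample identity; an exponential
decay of that amplitude after stimulus offset; and a hard truncation of the
evoked component at ``t_end_from_onset`` seconds after stimulus ONSET
(1.0 s for the working-memory condition).  Tying the truncation to onset
rather than offset reflects the observation that delay activity spans a
fixed interval from stimulus onset regardless of stimulus duration.  The
passive-listening preset truncates much earlier (0.5 s), emulating the
shorter stimulus trace seen outside the task context; that value is a
modeling choice, not a measured constant.

Sampling is by per-bin thinning at 1 ms resolution, treating the rate as
constant within a bin — exact enough for statistics computed on 100 ms
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .behavior import Session, TaskConfig, Trial
from .spiketrains import SpikeTrain, Unit

__all__ = [
    "BehaviorGenConfig",
    "UnitGenConfig",
    "PASSIVE_T_END_FROM_ONSET",
    "WM_T_END_FROM_ONSET",
    "simulate_session",
    "rate_function",
    "expected_spike_count",
    "simulate_unit",
    "simulate_population",
    "laser_shift_applies",
    "mixture_sampler",
    "passive_preset",
]

#: evoked-activity truncation (s from stimulus onset) in the WM condition
WM_T_END_FROM_ONSET = 1.0
#: passive-listening preset: a much shorter stimulus trace
PASSIVE_T_END_FROM_ONSET = 0.5

#: the two sample tones (Hz) of the two-tone discrimination
DEFAULT_STIMULI = (3000.0, 12000.0)


@dataclass(frozen=True)
class BehaviorGenConfig:
    """Parameters of the behavioral session generator.

    ``p_hit`` / ``p_fa`` are the lick probabilities on match / nonmatch
    trials.  When a trial carries a laser window that overlaps the
    ``effective_window`` by at least half the laser window's length, the
    probabilities are shifted by ``delta_p_hit_laser`` / ``delta_p_fa_laser``
    and clamped to [0, 1] (set ``clamp=False`` to make an out-of-range
    shifted probability an error instead).
    """

    n_match_trials: int = 100
    n_nonmatch_trials: int = 100
    p_hit: float = 0.88
    p_fa: float = 0.32
    laser_window: tuple[float, float] | None = None
    delta_p_hit_laser: float = 0.0
    delta_p_fa_laser: float = 0.0
    effective_window: tuple[float, float] = (0.2, 1.0)
    distractor_window: tuple[float, float] | None = None
    laser_fraction: float = 0.5
    stimuli: tuple[float, float] = DEFAULT_STIMULI
    clamp: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_match_trials + self.n_nonmatch_trials < 1:
            raise ValueError("need at least one trial")
        for name in ("p_hit", "p_fa", "laser_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def laser_shift_applies(laser_window: tuple[float, float] | None,
                        effective_window: tuple[float, float]) -> bool:
    """True when at least half of the laser window lies inside the
    effective window."""
    if laser_window is None:
        return False
    lo, hi = laser_window
    if hi <= lo:
        return False
    overlap = max(0.0, min(hi, effective_window[1]) - max(lo, effective_window[0]))
    return overlap / (hi - lo) >= 0.5


def _shifted(p: float, delta: float, clamp: bool) -> float:
    q = p + delta
    if not 0.0 <= q <= 1.0:
        if not clamp:
            raise ValueError(f"shifted probability {q} outside [0, 1] "
                             "and clamping is disabled")
        q = min(1.0, max(0.0, q))
    return q


def simulate_session(cfg: BehaviorGenConfig, task: TaskConfig | None = None,
                     subject_id: str = "subject-0") -> Session:
    """Draw one session of classified trials.

    Match and nonmatch trials are randomly interleaved; when a laser
    window is configured, laser-ON and laser-OFF trials are randomly
    interleaved as well (``laser_fraction`` ON).  Lick times on hit/FA
    trials are drawn uniformly inside the response window — only window
    membership matters downstream.
    """
    task = task or TaskConfig()
    rng = np.random.default_rng(cfg.seed)
    lo_stim, hi_stim = sorted(cfg.stimuli)

    is_match_flags = np.array([True] * cfg.n_match_trials
                              + [False] * cfg.n_nonmatch_trials)
    rng.shuffle(is_match_flags)
    n = is_match_flags.size
    if cfg.laser_window is not None:
        n_on = int(round(cfg.laser_fraction * n))
        laser_flags = np.zeros(n, dtype=bool)
        laser_flags[rng.choice(n, size=n_on, replace=False)] = True
    else:
        laser_flags = np.zeros(n, dtype=bool)

    shift_active = laser_shift_applies(cfg.laser_window, cfg.effective_window)
    window = task.response_window()
    trials = []
    for i in range(n):
        match = bool(is_match_flags[i])
        on = bool(laser_flags[i])
        sample = float(rng.choice([lo_stim, hi_stim]))
        test = sample if match else (hi_stim if sample == lo_stim else lo_stim)
        if match:
            p = cfg.p_hit
            if on and shift_active:
                p = _shifted(p, cfg.delta_p_hit_laser, cfg.clamp)
        else:
            p = cfg.p_fa
            if on and shift_active:
                p = _shifted(p, cfg.delta_p_fa_laser, cfg.clamp)
        licked = rng.random() < p
        if licked:
            n_licks = int(rng.integers(1, 4))
            licks = np.sort(rng.uniform(window[0], window[1], size=n_licks))
        else:
            licks = np.empty(0)
        trials.append(Trial(
            trial_id=i,
            sample_stimulus=sample,
            test_stimulus=test,
            is_match=match,
            delay_duration=task.delay_duration,
            lick_times=licks,
            laser_window=cfg.laser_window if on else None,
            distractor_window=cfg.distractor_window,
            outcome=("hit" if licked else "miss") if match
                    else ("fa" if licked else "cr"),
        ))
    return Session(trials=trials, task=task, subject_id=subject_id)


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitGenConfig:
    """Intensity-function parameters of one simulated unit.

    Rates in Hz, times in seconds from sample onset.  With
    ``a_pref == a_nonpref`` the unit is non-selective by construction.
    """

    r0: float = 4.0
    a_pref: float = 20.0
    a_nonpref: float = 5.0
    preferred_stimulus: float = 3000.0
    stim_onset: float = 0.0
    stim_duration: float = 0.2
    tau_delay: float = 0.5
    t_end_from_onset: float = WM_T_END_FROM_ONSET
    condition: str = "WM"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.a_pref < 0 or self.a_nonpref < 0:
            raise ValueError("rates and amplitudes must be >= 0")
        if self.tau_delay <= 0:
            raise ValueError("tau_delay must be > 0")
        if self.t_end_from_onset < 0:
            raise ValueError("t_end_from_onset must be >= 0")
        if self.condition not in ("WM", "passive"):
            raise ValueError(f"unknown condition {self.condition!r}")


def passive_preset(cfg: UnitGenConfig) -> UnitGenConfig:
    """Passive-listening variant of a unit config: same tuning, shorter
    evoked trace."""
    return replace(cfg, condition="passive",
                   t_end_from_onset=PASSIVE_T_END_FROM_ONSET)


def rate_function(t, stimulus: float, cfg: UnitGenConfig) -> np.ndarray | float:
    """Instantaneous firing rate r(t; s) in Hz; vectorized over ``t``.

    Piecewise: baseline ``r0`` before the stimulus and after the hard
    truncation at ``stim_onset + t_end_from_onset``; ``r0 + a_s`` during
    the stimulus; ``r0 + a_s * exp(-(t - offset)/tau_delay)`` between
    stimulus offset and the truncation point.
    """
    t_arr = np.asarray(t, dtype=float)
    a = cfg.a_pref if stimulus == cfg.preferred_stimulus else cfg.a_nonpref
    onset = cfg.stim_onset
    offset = onset + cfg.stim_duration
    t_trunc = onset + cfg.t_end_from_onset
    r = np.full_like(t_arr, cfg.r0)
    in_stim = (t_arr >= onset) & (t_arr < min(offset, t_trunc))
    r[in_stim] = cfg.r0 + a
    in_decay = (t_arr >= offset) & (t_arr < t_trunc)
    r[in_decay] = cfg.r0 + a * np.exp(-(t_arr[in_decay] - offset) / cfg.tau_delay)
    return r if np.ndim(t) else float(r)


def expected_spike_count(cfg: UnitGenConfig, stimulus: float,
                         t_start: float, t_stop: float,
                         dt: float = 0.001) -> float:
    """Numerical integral of the rate function over the trial span (for
    calibration checks)."""
    centers = np.arange(t_start, t_stop, dt) + dt / 2
    return float(np.sum(rate_function(centers, stimulus, cfg)) * dt)


def simulate_unit(cfg: UnitGenConfig, session: Session,
                  t_start: float = -0.7, t_stop: float | None = None,
                  dt: float = 0.001, unit_id: str | None = None) -> Unit:
    """Sample one unit's spike trains for every trial of a session.

    Inhomogeneous Poisson sampling by per-bin thinning at ``dt``
    resolution: each bin spikes with probability ``r * dt`` and the spike
    lands uniformly inside the bin.  Reproducible under ``cfg.seed``.
    """
    if not session.trials:
        raise ValueError("empty session")
    task = session.task
    if t_stop is None:
        t_stop = task.delay_end(max(t.delay_duration for t in session.trials))
    rng = np.random.default_rng(cfg.seed)
    centers = np.arange(t_start, t_stop, dt) + dt / 2
    lefts = centers - dt / 2
    # the two stimuli share the rate profile shape; precompute per identity
    stim_ids = sorted({t.sample_stimulus for t in session.trials})
    prob = {s: np.clip(rate_function(centers, s, cfg) * dt, 0.0, 1.0)
            for s in stim_ids}
    uid = unit_id or f"unit-{cfg.seed if cfg.seed is not None else 0}"
    trains = []
    for trial in session.trials:
        u = rng.random(centers.size)
        p = prob[trial.sample_stimulus]
        hit = u < p
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(hit, u / np.where(p > 0, p, 1.0), 0.0)
        times = lefts[hit] + frac[hit] * dt
        trains.append(SpikeTrain(unit_id=uid, trial_id=trial.trial_id,
                                 spike_times=np.sort(times)))
    return Unit(unit_id=uid, condition=cfg.condition, trains=trains,
                t_start=t_start, t_stop=t_stop, session=session)


def simulate_population(n_units: int,
                        cfg_sampler: Callable[[np.random.Generator], UnitGenConfig],
                        session: Session, seed: int | None = None,
                        t_start: float = -0.7, t_stop: float | None = None,
                        ) -> list[Unit]:
    """Independent units with per-unit seeds spawned from a master seed.

    ``cfg_sampler`` draws a :class:`UnitGenConfig` from the provided RNG
    (its ``seed`` field is overwritten with the spawned per-unit seed).
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    ss = np.random.SeedSequence(seed)
    sampler_rng = np.random.default_rng(ss.spawn(1)[0])
    unit_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_units)]
    units = []
    for i, unit_seed in enumerate(unit_seeds):
        cfg = replace(cfg_sampler(sampler_rng), seed=unit_seed)
        units.append(simulate_unit(cfg, session, t_start=t_start,
                                   t_stop=t_stop, unit_id=f"unit-{i:03d}"))
    return units


def mixture_sampler(frac_selective: float,
                    selective: UnitGenConfig,
                    null: UnitGenConfig | None = None,
                    ) -> Callable[[np.random.Generator], UnitGenConfig]:
    """Sampler drawing selective units with probability ``frac_selective``
    and otherwise a matched non-selective unit (equal amplitudes)."""
    if null is None:
        a = 0.5 * (selective.a_pref + selective.a_nonpref)
        null = replace(selective, a_pref=a, a_nonpref=a)

    def sample(rng: np.random.Generator) -> UnitGenConfig:
        return selective if rng.random() < frac_selective else null

    return sample
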