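"""Unit filtering, PSTH estimation and baseline-referenced significance.

Spike times are trial-aligned seconds with 0 = sample-tone onset.  The
baseline period is the 0.5 s immediately preceding sample onset; all
interval memberships are half-open ``[start, end)`` so that consecutive
bins partition time exactly.

The analysis chain implemented here mirrors standard practice for
trial-based single-unit recordings:

1. keep units whose whole-session mean rate exceeds 2 Hz;
2. estimate PSTHs at 10 ms resolution, smoothed with a Gaussian kernel
   (sigma = 100 ms) truncated at +/-4 sigma and edge-renormalized;
3. screen units for task relatedness with paired t-tests of epoch rate
   against baseline rate;
4. build 100 ms-bin significance timecourses: a population Wilcoxon
   rank-sum per bin, plus the fraction of units individually significant
   in that bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import Session, TaskConfig

__all__ = [
    "SpikeTrain",
    "Unit",
    "PSTH",
    "EpochWindow",
    "include_units",
    "epoch_rate",
    "epoch_rates",
    "baseline_rates",
    "make_psth",
    "responsiveness",
    "default_epoch_set",
    "bin_significance_timecourse",
    "BASELINE_WINDOW",
]

#: default baseline period, seconds relative to sample onset
BASELINE_WINDOW = (-0.5, 0.0)


@dataclass
class SpikeTrain:
    """Spike times of one unit on one trial (seconds from sample onset)."""

    unit_id: str
    trial_id: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size and np.any(np.diff(self.spike_times) < 0):
            raise ValueError(
                f"unit {self.unit_id} trial {self.trial_id}: spikes not sorted")

    def count_in(self, start: float, end: float) -> int:
        """Number of spikes in the half-open window [start, end)."""
        lo, hi = np.searchsorted(self.spike_times, (start, end), side="left")
        return int(hi - lo)


@dataclass
class Unit:
    """All trials of one unit, with the recorded span per trial.

    ``trains`` holds exactly one (possibly empty) spike train per session
    trial, in session trial order.  ``t_start``/``t_stop`` give the
    recorded span common to every trial.
    """

    unit_id: str
    condition: str  # "WM" | "passive"
    trains: list[SpikeTrain]
    t_start: float
    t_stop: float
    session: Session | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trains)

    @property
    def span(self) -> float:
        return self.t_stop - self.t_start

    def total_spikes(self) -> int:
        return int(sum(t.spike_times.size for t in self.trains))

    def mean_rate(self) -> float:
        """Whole-session mean firing rate in Hz."""
        if not self.trains or self.span <= 0:
            return 0.0
        return self.total_spikes() / (self.n_trials * self.span)


@dataclass
class PSTH:
    """Binned, optionally kernel-smoothed firing-rate timecourse."""

    bin_edges: np.ndarray  # length n_bins + 1, seconds
    rate: np.ndarray       # Hz per bin
    n_trials: int
    smoothing_sigma: float
    smoothed: bool

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class EpochWindow:
    """A labeled analysis window, referenced to sample or delay onset.

    Windows quoted "of the delay" are delay-onset-referenced and convert
    to absolute trial time by adding the sample duration.
    """

    label: str
    start: float
    end: float
    reference: str = "sample_onset"  # or "delay_onset"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"epoch {self.label!r}: start must precede end")
        if self.reference not in ("sample_onset", "delay_onset"):
            raise ValueError(f"unknown reference {self.reference!r}")

    def resolve(self, sample_duration: float = 0.2) -> tuple[float, float]:
        """Absolute (start, end) in seconds from sample onset."""
        off = sample_duration if self.reference == "delay_onset" else 0.0
        return (self.start + off, self.end + off)

    @property
    def width(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# unit inclusion
# ---------------------------------------------------------------------------

def include_units(units: list[Unit], min_rate: float = 2.0,
                  isi_qc: bool = False, isi_threshold: float = 0.002,
                  max_short_isi_frac: float = 0.01) -> list[Unit]:
    """Keep units whose whole-session mean rate strictly exceeds ``min_rate``.

    With ``isi_qc=True`` units whose inter-spike-interval distribution
    contains more than ``max_short_isi_frac`` intervals shorter than
    ``isi_threshold`` (refractory-period violations, a contamination
    signature) are also dropped.
    """
    kept = []
    for u in units:
        if not (u.mean_rate() > min_rate):
            continue
        if isi_qc:
            isis = np.concatenate(
                [np.diff(t.spike_times) for t in u.trains if t.spike_times.size > 1]
                or [np.empty(0)])
            if isis.size and np.mean(isis < isi_threshold) > max_short_isi_frac:
                continue
        kept.append(u)
    return kept


# ---------------------------------------------------------------------------
# rates in windows
# ---------------------------------------------------------------------------

def epoch_rate(train: SpikeTrain, window: EpochWindow,
               sample_duration: float = 0.2) -> float:
    """Firing rate (Hz) of one train in a half-open epoch window."""
    start, end = window.resolve(sample_duration)
    if end <= start:
        raise ValueError("zero-length window")
    return train.count_in(start, end) / (end - start)


def epoch_rates(unit: Unit, window: EpochWindow,
                sample_duration: float | None = None) -> np.ndarray:
    """Per-trial firing rates of a unit in one epoch window."""
    if sample_duration is None:
        sample_duration = (unit.session.task.sample_duration
                           if unit.session is not None else 0.2)
    start, end = window.resolve(sample_duration)
    if end <= start:
        raise ValueError("zero-length window")
    width = end - start
    return np.array([t.count_in(start, end) / width for t in unit.trains])


def baseline_rates(unit: Unit, window: tuple[float, float] = BASELINE_WINDOW) -> np.ndarray:
    """Per-trial firing rates over the pre-stimulus baseline period."""
    lo, hi = window
    if unit.t_start > lo:
        raise ValueError(
            f"unit {unit.unit_id}: recording starts at {unit.t_start} s, "
            f"baseline needs {lo} s of pre-stimulus data")
    width = hi - lo
    return np.array([t.count_in(lo, hi) / width for t in unit.trains])


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma: float, bin_width: float) -> np.ndarray:
    """Unit-sum Gaussian kernel sampled at bin resolution, cut at +/-4 sigma."""
    half = int(math.ceil(4.0 * sigma / bin_width))
    x = np.arange(-half, half + 1) * bin_width
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def _smooth(rate: np.ndarray, sigma: float, bin_width: float) -> np.ndarray:
    # edge renormalization: dividing by the kernel mass actually inside the
    # span keeps a constant-rate input constant up to the edges
    kernel = _gaussian_kernel(sigma, bin_width)
    num = np.convolve(rate, kernel, mode="same")
    den = np.convolve(np.ones_like(rate), kernel, mode="same")
    return num / den


def make_psth(unit_or_units: Unit | list[Unit], bin_width: float = 0.01,
              sigma: float = 0.1, t_start: float | None = None,
              t_stop: float | None = None, trial_filter=None) -> PSTH:
    """Trial-averaged firing-rate timecourse.

    For a single unit the unsmoothed per-bin rate is
    ``count / (n_trials * bin_width)``, so rate * bin_width * n_trials
    sums exactly to the total spike count.  For a list of units the
    population PSTH is the unweighted mean of the per-unit PSTHs.
    ``sigma=0`` disables smoothing.  ``trial_filter`` is an optional
    predicate on session trials (requires ``unit.session``).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if isinstance(unit_or_units, Unit):
        return _unit_psth(unit_or_units, bin_width, sigma, t_start, t_stop, trial_filter)
    units = list(unit_or_units)
    if not units:
        raise ValueError("no units")
    psths = [_unit_psth(u, bin_width, sigma, t_start, t_stop, trial_filter)
             for u in units]
    edges = psths[0].bin_edges
    for p in psths[1:]:
        if p.bin_edges.shape != edges.shape or not np.allclose(p.bin_edges, edges):
            raise ValueError("units have mismatched PSTH bin grids")
    return PSTH(
        bin_edges=edges,
        rate=np.mean([p.rate for p in psths], axis=0),
        n_trials=int(np.mean([p.n_trials for p in psths])),
        smoothing_sigma=sigma,
        smoothed=sigma > 0,
    )


def _unit_psth(unit: Unit, bin_width: float, sigma: float,
               t_start: float | None, t_stop: float | None, trial_filter) -> PSTH:
    t0 = unit.t_start if t_start is None else t_start
    t1 = unit.t_stop if t_stop is None else t_stop
    trains = unit.trains
    if trial_filter is not None:
        if unit.session is None:
            raise ValueError("trial_filter requires unit.session")
        trains = [tr for tr, trial in zip(trains, unit.session.trials)
                  if trial_filter(trial)]
    if not trains:
        raise ValueError(f"unit {unit.unit_id}: no trials after filtering")
    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    for tr in trains:
        idx = np.floor((tr.spike_times - t0) / bin_width).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        np.add.at(counts, idx, 1)
    rate = counts / (len(trains) * bin_width)
    if sigma > 0:
        rate = _smooth(rate, sigma, bin_width)
    return PSTH(bin_edges=edges, rate=rate, n_trials=len(trains),
                smoothing_sigma=sigma, smoothed=sigma > 0)


# ---------------------------------------------------------------------------
# responsiveness screen
# ---------------------------------------------------------------------------

def default_epoch_set(task: TaskConfig, delay_bin: float = 0.1) -> list[EpochWindow]:
    """Sample epoch plus successive delay bins, tiling to the delay end."""
    epochs = [EpochWindow("sample", 0.0, task.sample_duration)]
    n = int(round(task.delay_duration / delay_bin))
    for i in range(n):
        epochs.append(EpochWindow(f"delay_{i}", i * delay_bin, (i + 1) * delay_bin,
                                  reference="delay_onset"))
    return epochs


def responsiveness(unit: Unit, epochs: list[EpochWindow] | None = None,
                   alpha: float = 0.05, task: TaskConfig | None = None,
                   ) -> tuple[bool, dict[str, float]]:
    """Task-relatedness screen: paired t-test of epoch rate vs baseline rate.

    Each configured epoch is tested with a paired t-test of the per-trial
    epoch rate against the per-trial baseline rate; the unit is flagged
    task-related if any epoch reaches p < alpha.  No multiple-comparison
    correction is applied.  Epochs with zero-variance differences are
    skipped with a warning.
    """
    if unit.n_trials < 5:
        raise ValueError(f"unit {unit.unit_id}: need >= 5 trials, "
                         f"got {unit.n_trials}")
    if task is None:
        task = unit.session.task if unit.session is not None else TaskConfig()
    if epochs is None:
        epochs = default_epoch_set(task)
    base = baseline_rates(unit)
    pvals: dict[str, float] = {}
    for ep in epochs:
        rates = epoch_rates(unit, ep, task.sample_duration)
        diffs = rates - base
        if np.allclose(diffs, diffs[0]):
            warnings.warn(f"unit {unit.unit_id}: zero-variance differences in "
                          f"epoch {ep.label!r}, skipped")
            continue
        pvals[ep.label] = float(stats.ttest_rel(rates, base).pvalue)
    flagged = any(p < alpha for p in pvals.values())
    return flagged, pvals


# ---------------------------------------------------------------------------
# bin-wise significance timecourse
# ---------------------------------------------------------------------------

def bin_significance_timecourse(units: list[Unit], binwidth: float = 0.1,
                                alpha: float = 0.05, t_start: float = 0.0,
                                t_stop: float | None = None) -> pd.DataFrame:
    """Per-bin baseline-referenced significance across a population.

    For each consecutive ``binwidth`` bin from ``t_start``:

    * ``pop_p`` — Wilcoxon rank-sum comparing per-unit mean bin rates with
      per-unit mean baseline rates (population-level test);
    * ``frac_significant`` — fraction of units whose own per-trial bin
      rates differ from their baseline rates (rank-sum, p < alpha).

    The per-unit comparison draws its baseline sample from sub-bins of the
    same width as the analysis bin (the baseline period tiled at
    ``binwidth``), so that under a flat rate the two rate samples are
    identically distributed — comparing a 100 ms bin against rates
    estimated over the whole 500 ms baseline would differ in dispersion
    even at equal mean.  Returns a DataFrame with one row per bin.
    """
    if len(units) < 3:
        raise ValueError("need at least 3 units for the population test")
    if t_stop is None:
        t_stop = min(u.t_stop for u in units)
    n_bins = int(round((t_stop - t_start) / binwidth))
    if n_bins < 1:
        raise ValueError("empty bin grid")

    base_lo, base_hi = BASELINE_WINDOW
    n_sub = max(1, int((base_hi - base_lo) / binwidth))
    sub_edges = [(base_lo + k * binwidth, base_lo + (k + 1) * binwidth)
                 for k in range(n_sub)]
    unit_base_trials = [
        np.concatenate([[t.count_in(lo, hi) / binwidth for t in u.trains]
                        for lo, hi in sub_edges])
        for u in units]
    unit_base_means = np.array([baseline_rates(u).mean() for u in units])

    rows = []
    for i in range(n_bins):
        lo = t_start + i * binwidth
        hi = lo + binwidth
        bin_means = np.empty(len(units))
        n_sig = 0
        for j, u in enumerate(units):
            rates = np.array([t.count_in(lo, hi) / binwidth for t in u.trains])
            bin_means[j] = rates.mean()
            if np.ptp(np.concatenate([rates, unit_base_trials[j]])) == 0:
                continue  # all values identical: rank-sum is vacuous
            p_unit = stats.ranksums(rates, unit_base_trials[j]).pvalue
            if p_unit < alpha:
                n_sig += 1
        if np.ptp(np.concatenate([bin_means, unit_base_means])) == 0:
            pop_p = 1.0
        else:
            pop_p = float(stats.ranksums(bin_means, unit_base_means).pvalue)
        rows.append({
            "bin_start": lo, "bin_end": hi,
            "pop_p": pop_p, "pop_significant": pop_p < alpha,
            "frac_significant": n_sig / len(units),
        })
    return pd.DataFrame(rows)
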