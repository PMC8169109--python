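"""Threshold-sweep ROC selectivity with a permutation null.

For each 100 ms epoch, single-trial firing rates are split by the sample
identity into preferred and nonpreferred groups.  Twelve threshold levels
are placed evenly across the pooled range of rates; at each threshold the
fraction of preferred (TPR) and nonpreferred (FPR) trials with activity
strictly greater than the threshold is computed, and the area under the
resulting curve — closed with (0,0) and (1,1) — is the selectivity
statistic.  An AUC of 0.5 means the two rate distributions are
indistinguishable in that epoch; 1 means every preferred-trial rate
exceeded every nonpreferred-trial rate; 0 means the reverse.

Significance comes from a permutation test: trials are repeatedly
redistributed into two groups of the original sizes, independent of the
actual sample identity, and the actual AUC is compared with the null
distribution of redistributed AUCs.  The default convention is two-sided
at a total level of 5% — the actual value must fall in the extreme 2.5%
of either tail — with p reported as twice the smaller tail proportion
(add-one smoothed for Monte-Carlo sampling, exact when all splits are
enumerated).

Because the threshold sweep uses strict inequality, the statistic is not
exactly antisymmetric under swapping the groups; the discrepancy is
bounded by the threshold spacing and vanishes as the number of thresholds
grows, where the statistic converges to the Mann-Whitney (tie half-credit)
AUC.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import Session
from .spiketrains import EpochWindow, Unit, epoch_rates

__all__ = [
    "SelectivityConfig",
    "PermutationResult",
    "ROCTimecourse",
    "assign_preferred",
    "roc_value",
    "permutation_test",
    "roc_timecourse",
    "population_selectivity",
    "compare_conditions",
]


@dataclass(frozen=True)
class SelectivityConfig:
    """Knobs of the epoch-wise ROC analysis.

    ``tail_convention``: ``"total"`` treats "top or bottom 5%" as a
    two-sided test at total level alpha (2.5% per tail, the default);
    ``"per_tail"`` uses alpha in each tail.
    """

    epoch_width: float = 0.1
    n_thresholds: int = 12
    n_permutations: int = 5000
    alpha: float = 0.05
    tail_convention: str = "total"
    preferred_window: EpochWindow | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.tail_convention not in ("total", "per_tail"):
            raise ValueError(f"unknown tail_convention {self.tail_convention!r}")


@dataclass
class PermutationResult:
    p_value: float
    significant: bool
    auc: float
    method: str  # "exhaustive" | "monte-carlo"
    n_permutations: int


@dataclass
class ROCTimecourse:
    """Per-epoch selectivity of one unit."""

    unit_id: str
    condition: str
    epochs: list[tuple[float, float]]  # absolute (start, end), s from sample onset
    auc: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    preferred_stimulus: float


# ---------------------------------------------------------------------------
# preferred-stimulus assignment
# ---------------------------------------------------------------------------

def assign_preferred(unit: Unit, window: EpochWindow | None = None,
                     session: Session | None = None,
                     min_trials: int = 5) -> float:
    """Stimulus evoking the higher mean rate in ``window`` (default: the
    sample epoch).

    The assignment is made once and used for every epoch of the unit's
    timecourse.  Exact ties break toward the lower frequency,
    deterministically.
    """
    session = session or unit.session
    if session is None:
        raise ValueError("unit has no session reference")
    sample_dur = session.task.sample_duration
    if window is None:
        window = EpochWindow("sample", 0.0, sample_dur)
    samples = np.array([t.sample_stimulus for t in session.trials])
    stim_ids = sorted(set(samples))
    if len(stim_ids) < 2:
        raise ValueError("need at least two distinct sample stimuli")
    counts = {s: int(np.sum(samples == s)) for s in stim_ids}
    for s, c in counts.items():
        if c < min_trials:
            raise ValueError(f"stimulus {s} has only {c} trials "
                             f"(need >= {min_trials})")
    rates = epoch_rates(unit, window, sample_dur)
    means = {s: rates[samples == s].mean() for s in stim_ids}
    best = max(stim_ids, key=lambda s: (means[s], -s))  # ties -> lower freq
    return float(best)


# ---------------------------------------------------------------------------
# threshold-sweep ROC statistic
# ---------------------------------------------------------------------------

def _auc_from_tpr_fpr(tpr: np.ndarray, fpr: np.ndarray) -> np.ndarray:
    """Trapezoid AUC of curves given per-threshold TPR/FPR, last axis in
    ascending-threshold order.

    TPR and FPR are both nonincreasing in the threshold, so reversing the
    threshold axis and closing with (0,0) and (1,1) yields a curve already
    sorted by FPR then TPR.
    """
    shape = tpr.shape[:-1] + (1,)
    x = np.concatenate([np.zeros(shape), fpr[..., ::-1], np.ones(shape)], axis=-1)
    y = np.concatenate([np.zeros(shape), tpr[..., ::-1], np.ones(shape)], axis=-1)
    return np.trapezoid(y, x, axis=-1)


def roc_value(pref_rates, nonpref_rates, n_thresholds: int = 12) -> float:
    """Threshold-sweep AUC for one epoch.

    Thresholds are ``n_thresholds`` evenly spaced levels spanning the
    pooled [min, max] of the two rate lists; exceedance is strict, so a
    rate exactly at a threshold counts as non-exceeding.  A degenerate
    pooled range (all rates equal) returns 0.5.
    """
    pref = np.asarray(pref_rates, dtype=float)
    nonpref = np.asarray(nonpref_rates, dtype=float)
    if pref.size == 0 or nonpref.size == 0:
        raise ValueError("both rate lists must be non-empty")
    if n_thresholds < 2:
        raise ValueError("n_thresholds must be >= 2")
    pooled = np.concatenate([pref, nonpref])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        return 0.5
    thresholds = np.linspace(lo, hi, n_thresholds)
    tpr = np.mean(pref[:, None] > thresholds[None, :], axis=0)
    fpr = np.mean(nonpref[:, None] > thresholds[None, :], axis=0)
    return float(_auc_from_tpr_fpr(tpr, fpr))


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

def _null_aucs(values: np.ndarray, n1: int, group1_idx: np.ndarray,
               thresholds: np.ndarray) -> np.ndarray:
    """AUCs for many regroupings at once.

    ``group1_idx`` is (P, n1): for each of P splits, the indices assigned
    to the nominally-preferred group.  Thresholds are fixed because the
    pooled sample — hence its range — is invariant under regrouping.
    """
    n = values.size
    n2 = n - n1
    exceed = (values[:, None] > thresholds[None, :]).astype(float)  # (n, K)
    totals = exceed.sum(axis=0)                                     # (K,)
    g1 = exceed[group1_idx].sum(axis=1)                             # (P, K)
    tpr = g1 / n1
    fpr = (totals[None, :] - g1) / n2
    return _auc_from_tpr_fpr(tpr, fpr)


def _two_sided_p(null: np.ndarray, actual: float, tail_convention: str,
                 exhaustive: bool) -> float:
    eps = 1e-12
    n_hi = int(np.sum(null >= actual - eps))
    n_lo = int(np.sum(null <= actual + eps))
    if exhaustive:
        tail = min(n_hi, n_lo) / null.size
    else:
        # add-one smoothing: the actual split counts as one realization
        tail = (min(n_hi, n_lo) + 1) / (null.size + 1)
    if tail_convention == "total":
        return min(1.0, 2.0 * tail)
    return min(1.0, tail)


def permutation_test(pref_rates, nonpref_rates,
                     cfg: SelectivityConfig | None = None,
                     seed: int | None = None) -> PermutationResult:
    """Permutation significance of the threshold-sweep AUC.

    Trials are redistributed into two groups of the original sizes.  When
    the number of distinct splits is at most ``cfg.n_permutations`` the
    null is enumerated exhaustively (p exact); otherwise
    ``cfg.n_permutations`` seeded shuffles are drawn and p carries
    add-one smoothing, (r + 1) / (N + 1), capped at 1.
    """
    cfg = cfg or SelectivityConfig()
    pref = np.asarray(pref_rates, dtype=float)
    nonpref = np.asarray(nonpref_rates, dtype=float)
    if pref.size == 0 or nonpref.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n = pref.size, pref.size + nonpref.size
    if n < 6:
        raise ValueError("need a combined n of at least 6 trials")
    values = np.concatenate([pref, nonpref])
    actual = roc_value(pref, nonpref, cfg.n_thresholds)

    lo, hi = values.min(), values.max()
    if hi == lo:  # degenerate: statistic is constant under regrouping
        return PermutationResult(p_value=1.0, significant=False, auc=0.5,
                                 method="degenerate", n_permutations=0)
    thresholds = np.linspace(lo, hi, cfg.n_thresholds)

    n_splits = comb(n, n1)
    if n_splits <= cfg.n_permutations:
        idx = np.array(list(combinations(range(n), n1)), dtype=np.intp)
        null = _null_aucs(values, n1, idx, thresholds)
        p = _two_sided_p(null, actual, cfg.tail_convention, exhaustive=True)
        method, n_used = "exhaustive", n_splits
    else:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        perms = rng.permuted(
            np.tile(np.arange(n, dtype=np.intp), (cfg.n_permutations, 1)), axis=1)
        null = _null_aucs(values, n1, perms[:, :n1], thresholds)
        p = _two_sided_p(null, actual, cfg.tail_convention, exhaustive=False)
        method, n_used = "monte-carlo", cfg.n_permutations
    return PermutationResult(p_value=p, significant=p < cfg.alpha, auc=actual,
                             method=method, n_permutations=n_used)


# ---------------------------------------------------------------------------
# timecourses and population summaries
# ---------------------------------------------------------------------------

def _epoch_grid(t_stop: float, width: float) -> list[tuple[float, float]]:
    n = int(round(t_stop / width))
    return [(i * width, (i + 1) * width) for i in range(n)]


def _unit_epoch_seed(cfg_seed: int | None, unit_id: str, epoch_index: int) -> int:
    base = 0 if cfg_seed is None else int(cfg_seed)
    h = zlib.crc32(unit_id.encode())
    return int(np.random.SeedSequence((base, h, epoch_index))
               .generate_state(1)[0] % (2 ** 31))


def roc_timecourse(unit: Unit, cfg: SelectivityConfig | None = None,
                   session: Session | None = None,
                   t_stop: float | None = None) -> ROCTimecourse:
    """Epoch-wise AUC and permutation significance for one unit.

    Consecutive ``epoch_width`` epochs tile from sample onset to the end
    of the delay period.  The preferred stimulus is assigned once from
    the configured preference window and reused for every epoch.
    """
    cfg = cfg or SelectivityConfig()
    session = session or unit.session
    if session is None:
        raise ValueError("unit has no session reference")
    task = session.task
    if t_stop is None:
        t_stop = task.delay_end()
    if t_stop > unit.t_stop + 1e-9:
        raise ValueError(f"epoch grid extends to {t_stop} s but unit recording "
                         f"ends at {unit.t_stop} s")
    preferred = assign_preferred(unit, cfg.preferred_window, session)
    samples = np.array([t.sample_stimulus for t in session.trials])
    is_pref = samples == preferred
    epochs = _epoch_grid(t_stop, cfg.epoch_width)
    aucs = np.empty(len(epochs))
    ps = np.empty(len(epochs))
    sig = np.zeros(len(epochs), dtype=bool)
    for i, (lo, hi) in enumerate(epochs):
        rates = np.array([tr.count_in(lo, hi) / (hi - lo) for tr in unit.trains])
        res = permutation_test(rates[is_pref], rates[~is_pref], cfg,
                               seed=_unit_epoch_seed(cfg.seed, unit.unit_id, i))
        aucs[i], ps[i], sig[i] = res.auc, res.p_value, res.significant
    return ROCTimecourse(unit_id=unit.unit_id, condition=unit.condition,
                         epochs=epochs, auc=aucs, p_value=ps, significant=sig,
                         preferred_stimulus=preferred)


def _check_grids(timecourses: list[ROCTimecourse]) -> list[tuple[float, float]]:
    grid = timecourses[0].epochs
    for tc in timecourses[1:]:
        if tc.epochs != grid:
            raise ValueError("epoch grids differ across units")
    return grid


def population_selectivity(units_or_timecourses,
                           cfg: SelectivityConfig | None = None) -> pd.DataFrame:
    """Mean AUC and fraction of significantly selective units per epoch.

    Accepts either a list of units (timecourses are computed with ``cfg``)
    or precomputed :class:`ROCTimecourse` objects.  Requires at least
    three units.
    """
    items = list(units_or_timecourses)
    if len(items) < 3:
        raise ValueError("need at least 3 units")
    if items and isinstance(items[0], Unit):
        items = [roc_timecourse(u, cfg) for u in items]
    grid = _check_grids(items)
    auc = np.array([tc.auc for tc in items])
    sig = np.array([tc.significant for tc in items])
    return pd.DataFrame({
        "epoch_start": [e[0] for e in grid],
        "epoch_end": [e[1] for e in grid],
        "mean_auc": auc.mean(axis=0),
        "frac_significant": sig.mean(axis=0),
        "n_units": len(items),
    })


def compare_conditions(wm: list[ROCTimecourse], passive: list[ROCTimecourse],
                       ) -> pd.DataFrame:
    """Per-epoch rank-sum comparison of unit AUC values between two
    recording conditions (e.g. task engagement vs passive listening)."""
    if len(wm) < 3 or len(passive) < 3:
        raise ValueError("need at least 3 units per condition")
    grid = _check_grids(list(wm) + list(passive))
    a = np.array([tc.auc for tc in wm])
    b = np.array([tc.auc for tc in passive])
    rows = []
    for i, (lo, hi) in enumerate(grid):
        p = float(stats.ranksums(a[:, i], b[:, i]).pvalue)
        rows.append({"epoch_start": lo, "epoch_end": hi, "p_value": p,
                     "significant": p < 0.05})
    return pd.DataFrame(rows)
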