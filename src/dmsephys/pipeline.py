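"""File formats, configuration and end-to-end orchestration.

Two flat delimited-text formats carry all data:

* **trial table** — one row per trial, header
  ``trial_id,task_type,sample_hz,test_hz,is_match,delay_s,laser_start_s,
  laser_end_s,distractor_start_s,distractor_end_s,lick_times_s``;
  ``lick_times_s`` is a semicolon-separated list, absent intervals are
  empty fields, and all times are seconds relative to sample onset.
* **spike table** — one spike per row, header
  ``unit_id,condition,trial_id,spike_time_s``.

``run_full`` executes the complete chain — simulate (or load) -> behavior
metrics -> PSTH and bin-significance -> ROC selectivity -> report — and
writes every table plus a provenance sidecar (config hash, master seed,
package version) so any output is regenerable bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import (Session, SessionMetrics, TaskConfig, Trial,
                       classify_session, laser_contrast, metrics_by_delay,
                       session_metrics)
from .selectivity import (SelectivityConfig, compare_conditions,
                          population_selectivity, roc_timecourse)
from .spiketrains import (Unit, bin_significance_timecourse, include_units,
                          make_psth, responsiveness)
from .synth import (BehaviorGenConfig, UnitGenConfig, mixture_sampler,
                    passive_preset, simulate_population, simulate_session)

logger = logging.getLogger("dmsephys")

__all__ = [
    "TRIAL_COLUMNS",
    "SPIKE_COLUMNS",
    "RunConfig",
    "GeneratorSpec",
    "AnalysisConfig",
    "ReportBundle",
    "read_trials",
    "write_trials",
    "read_spikes",
    "write_spikes",
    "load_config",
    "run_full",
]

TRIAL_COLUMNS = [
    "trial_id", "task_type", "sample_hz", "test_hz", "is_match", "delay_s",
    "laser_start_s", "laser_end_s", "distractor_start_s", "distractor_end_s",
    "lick_times_s",
]

SPIKE_COLUMNS = ["unit_id", "condition", "trial_id", "spike_time_s"]


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------

def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6f}"


def write_trials(session: Session, path: str | Path) -> Path:
    """Write a session as a flat, diff-able CSV (times in seconds)."""
    rows = []
    for t in session.trials:
        rows.append({
            "trial_id": t.trial_id,
            "task_type": session.task.task_type,
            "sample_hz": _fmt(t.sample_stimulus),
            "test_hz": _fmt(t.test_stimulus),
            "is_match": int(t.is_match),
            "delay_s": _fmt(t.delay_duration),
            "laser_start_s": _fmt(t.laser_window[0] if t.laser_window else None),
            "laser_end_s": _fmt(t.laser_window[1] if t.laser_window else None),
            "distractor_start_s": _fmt(t.distractor_window[0] if t.distractor_window else None),
            "distractor_end_s": _fmt(t.distractor_window[1] if t.distractor_window else None),
            "lick_times_s": ";".join(f"{x:.6f}" for x in t.lick_times),
        })
    path = Path(path)
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)
    return path


class SchemaError(ValueError):
    """Malformed trial/spike table; message names the row and column."""


def _parse_float(value, row: int, column: str, required: bool) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        if required:
            raise SchemaError(f"row {row}, column {column!r}: missing value")
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row}, column {column!r}: non-numeric value {value!r}") from None


def _interval(df_row, row: int, start_col: str, end_col: str):
    lo = _parse_float(df_row[start_col], row, start_col, required=False)
    hi = _parse_float(df_row[end_col], row, end_col, required=False)
    if (lo is None) != (hi is None):
        raise SchemaError(f"row {row}: interval columns {start_col!r}/{end_col!r} "
                          "must both be present or both empty")
    return None if lo is None else (lo, hi)


def read_trials(path: str | Path, task: TaskConfig | None = None) -> Session:
    """Read a trial table; validates schema, lick ordering and DMS
    match-flag consistency, raising :class:`SchemaError` with the
    offending row and column."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    task_types = set(df["task_type"]) if len(df) else set()
    if len(task_types) > 1:
        raise SchemaError(f"{path.name}: mixed task_type values {sorted(task_types)}")
    if task is None:
        task = TaskConfig(task_type=task_types.pop()) if task_types else TaskConfig()
    trials = []
    for i, r in df.iterrows():
        row = int(i) + 2  # 1-based with header line
        sample = _parse_float(r["sample_hz"], row, "sample_hz", required=True)
        test = _parse_float(r["test_hz"], row, "test_hz", required=False)
        raw_match = str(r["is_match"]).strip().lower()
        if raw_match not in ("0", "1", "true", "false"):
            raise SchemaError(f"row {row}, column 'is_match': got {r['is_match']!r}")
        is_match = raw_match in ("1", "true")
        if task.task_type == "dms":
            if test is None:
                raise SchemaError(f"row {row}, column 'test_hz': required for DMS")
            if is_match != (sample == test):
                raise SchemaError(f"row {row}, column 'is_match': inconsistent "
                                  f"with stimuli {sample} vs {test}")
        delay = _parse_float(r["delay_s"], row, "delay_s", required=True)
        lick_field = str(r["lick_times_s"]).strip()
        licks = []
        if lick_field:
            for part in lick_field.split(";"):
                licks.append(_parse_float(part, row, "lick_times_s", required=True))
        licks_arr = np.array(licks, dtype=float)
        if licks_arr.size and np.any(np.diff(licks_arr) < 0):
            raise SchemaError(f"row {row}, column 'lick_times_s': times not sorted")
        trials.append(Trial(
            trial_id=int(_parse_float(r["trial_id"], row, "trial_id", required=True)),
            sample_stimulus=sample,
            test_stimulus=test,
            is_match=is_match,
            delay_duration=delay,
            lick_times=licks_arr,
            laser_window=_interval(r, row, "laser_start_s", "laser_end_s"),
            distractor_window=_interval(r, row, "distractor_start_s",
                                        "distractor_end_s"),
        ))
    return Session(trials=trials, task=task, subject_id=path.stem)


# ---------------------------------------------------------------------------
# spike tables
# ---------------------------------------------------------------------------

def write_spikes(units: list[Unit], path: str | Path) -> Path:
    """Write spike trains, one spike per row at microsecond precision.

    A unit with no spikes at all cannot be represented in this format and
    is skipped with a warning.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(SPIKE_COLUMNS) + "\n")
        for u in units:
            if u.total_spikes() == 0:
                warnings.warn(f"unit {u.unit_id} has no spikes; omitted from "
                              f"{path.name}")
                continue
            for tr in u.trains:
                for t in tr.spike_times:
                    fh.write(f"{u.unit_id},{u.condition},{tr.trial_id},{t:.6f}\n")
    return path


def read_spikes(path: str | Path, session: Session,
                t_start: float = -0.7, t_stop: float | None = None) -> list[Unit]:
    """Read a spike table against a loaded session.

    Every spike must reference a trial of the session; out-of-order spike
    times are sorted with a warning.  The recorded span (``t_start``,
    ``t_stop``) is not part of the format and is supplied by the caller
    (default: 0.7 s of pre-stimulus data through the end of the delay).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"unit_id": str, "condition": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    if t_stop is None:
        t_stop = session.task.delay_end(
            max(t.delay_duration for t in session.trials))
    trial_ids = [t.trial_id for t in session.trials]
    known = set(trial_ids)
    orphans = set(df["trial_id"].astype(int)) - known
    if orphans:
        raise SchemaError(f"{path.name}: spikes reference unknown trial_id(s) "
                          f"{sorted(orphans)}")
    units: list[Unit] = []
    for uid, group in df.groupby("unit_id", sort=True):
        conditions = group["condition"].unique()
        if len(conditions) > 1:
            raise SchemaError(f"unit {uid}: inconsistent condition labels")
        by_trial = {int(tid): np.asarray(g["spike_time_s"], dtype=float)
                    for tid, g in group.groupby("trial_id")}
        trains = []
        from .spiketrains import SpikeTrain
        for tid in trial_ids:
            times = by_trial.get(tid, np.empty(0))
            if times.size and np.any(np.diff(times) < 0):
                warnings.warn(f"unit {uid} trial {tid}: spike times out of "
                              "order in file; sorted on load")
                times = np.sort(times)
            trains.append(SpikeTrain(unit_id=str(uid), trial_id=tid,
                                     spike_times=times))
        units.append(Unit(unit_id=str(uid), condition=str(conditions[0]),
                          trains=trains, t_start=t_start, t_stop=t_stop,
                          session=session))
    return units


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    """What to simulate: sessions per subject plus a mixed unit population."""

    behavior: BehaviorGenConfig = field(default_factory=BehaviorGenConfig)
    n_subjects: int = 8
    n_units: int = 20
    n_passive_units: int = 12
    frac_selective: float = 0.5
    unit: UnitGenConfig = field(default_factory=UnitGenConfig)


@dataclass(frozen=True)
class AnalysisConfig:
    selectivity: SelectivityConfig = field(default_factory=SelectivityConfig)
    psth_bin: float = 0.01
    psth_sigma: float = 0.1
    significance_binwidth: float = 0.1
    alpha: float = 0.05
    min_rate: float = 2.0


@dataclass(frozen=True)
class RunConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    generator: GeneratorSpec | None = field(default_factory=GeneratorSpec)
    trials_path: str | None = None
    spikes_path: str | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "dmsephys-output"
    master_seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.generator is None and self.trials_path is None:
            raise ValueError("config needs either a generator or input paths")


def _build(cls, data: dict, context: str):
    """Instantiate a (frozen) dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    task = _build(TaskConfig, data.pop("task", {}), "task")
    gen_data = data.pop("generator", {})
    generator = None
    if gen_data is not None:
        behavior = _build(BehaviorGenConfig, gen_data.pop("behavior", {}),
                          "generator.behavior")
        unit = _build(UnitGenConfig, gen_data.pop("unit", {}), "generator.unit")
        generator = _build(GeneratorSpec,
                           {**gen_data, "behavior": behavior, "unit": unit},
                           "generator")
    ana_data = data.pop("analysis", {})
    sel = _build(SelectivityConfig, ana_data.pop("selectivity", {}),
                 "analysis.selectivity")
    analysis = _build(AnalysisConfig, {**ana_data, "selectivity": sel}, "analysis")
    return _build(RunConfig, {**data, "task": task, "generator": generator,
                              "analysis": analysis}, "run config")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class ReportBundle:
    """Every table the full run produces, plus provenance."""

    session_metrics: pd.DataFrame
    delay_performance: pd.DataFrame
    laser_comparisons: pd.DataFrame | None
    psth: pd.DataFrame
    bin_significance: pd.DataFrame
    roc_timecourses: pd.DataFrame
    population_selectivity: pd.DataFrame
    condition_comparison: pd.DataFrame
    provenance: dict


def _metrics_row(subject_id: str, m: SessionMetrics) -> dict:
    return {"subject_id": subject_id, "H": m.H, "M": m.M, "CR": m.CR,
            "FA": m.FA, "performance": m.performance,
            "hit_rate": m.hit_rate, "fa_rate": m.fa_rate}


def run_full(cfg: RunConfig, output_dir: str | Path | None = None) -> ReportBundle:
    """Execute the whole chain and write every output table.

    Stages: simulate or load data; classify trials and compute behavioral
    metrics (with laser contrasts when laser trials exist); include-filter
    units and screen for task-relatedness; population PSTH and 100 ms-bin
    significance timecourse; per-unit ROC timecourses and population
    selectivity; task-vs-passive comparison when both conditions are
    present.  Identical config + seed reproduce every table bit for bit.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(output_dir or cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_begin = time.perf_counter()
    ss = np.random.SeedSequence(cfg.master_seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    # --- stage 1: data -----------------------------------------------------
    t0 = time.perf_counter()
    if cfg.generator is not None:
        gen = cfg.generator
        subj_seeds = np.random.SeedSequence(seeds[0]).spawn(gen.n_subjects)
        sessions = []
        for i, s in enumerate(subj_seeds):
            bcfg = replace(gen.behavior, seed=int(s.generate_state(1)[0] % (2 ** 31)))
            sessions.append(simulate_session(bcfg, task=cfg.task,
                                             subject_id=f"mouse-{i:02d}"))
        neural_session = sessions[0]
        sampler = mixture_sampler(gen.frac_selective, gen.unit)
        units = simulate_population(gen.n_units, sampler, neural_session,
                                    seed=seeds[1])
        passive_units = []
        if gen.n_passive_units:
            psampler = mixture_sampler(gen.frac_selective, passive_preset(gen.unit))
            passive_units = simulate_population(
                gen.n_passive_units, psampler, neural_session, seed=seeds[2])
            for i, u in enumerate(passive_units):
                u.unit_id = f"passive-{i:03d}"
        for s, p in zip(sessions, [write_trials(s, out / f"trials_{s.subject_id}.csv")
                                   for s in sessions]):
            pass
        write_spikes(units + passive_units, out / "spikes.csv")
    else:
        sessions = [read_trials(cfg.trials_path, task=cfg.task)]
        neural_session = sessions[0]
        units = read_spikes(cfg.spikes_path, neural_session) if cfg.spikes_path else []
        passive_units = [u for u in units if u.condition == "passive"]
        units = [u for u in units if u.condition != "passive"]
    logger.info("stage simulate/load: %d sessions, %d WM units, %d passive units "
                "(%.2f s)", len(sessions), len(units), len(passive_units),
                time.perf_counter() - t0)

    # --- stage 2: behavior -------------------------------------------------
    t0 = time.perf_counter()
    for s in sessions:
        classify_session(s)
    metrics_df = pd.DataFrame(
        [_metrics_row(s.subject_id, session_metrics(s.trials, permissive=True))
         for s in sessions])
    delay_df = metrics_by_delay(sessions)
    laser_df = None
    has_laser = any(t.laser_on for s in sessions for t in s.trials)
    if has_laser and len({s.subject_id for s in sessions}) >= 3:
        rows = []
        for metric in ("performance", "hit_rate", "fa_rate"):
            c = laser_contrast(sessions, metric)
            rows.append({"metric": metric, "mean_on": c.mean_on,
                         "mean_off": c.mean_off, "sem_on": c.sem_on,
                         "sem_off": c.sem_off, "delta": c.delta,
                         "test": c.test_name, "statistic": c.statistic,
                         "p_value": c.p_value})
        laser_df = pd.DataFrame(rows)
        laser_df.to_csv(out / "laser_comparisons.csv", index=False)
    metrics_df.to_csv(out / "session_metrics.csv", index=False)
    delay_df.to_csv(out / "delay_performance.csv", index=False)
    logger.info("stage behavior: %d sessions (%.2f s)", len(sessions),
                time.perf_counter() - t0)

    # --- stage 3: spike trains ---------------------------------------------
    t0 = time.perf_counter()
    ana = cfg.analysis
    n_recorded = len(units)
    units = include_units(units, min_rate=ana.min_rate)
    passive_units = include_units(passive_units, min_rate=ana.min_rate)
    task_related = [u for u in units if responsiveness(u, alpha=ana.alpha)[0]]
    psth = make_psth(units or [], bin_width=ana.psth_bin, sigma=ana.psth_sigma) \
        if units else None
    psth_df = pd.DataFrame({
        "bin_start": psth.bin_edges[:-1], "bin_end": psth.bin_edges[1:],
        "rate_hz": psth.rate}) if psth else pd.DataFrame()
    sig_df = (bin_significance_timecourse(units, binwidth=ana.significance_binwidth,
                                          alpha=ana.alpha)
              if len(units) >= 3 else pd.DataFrame())
    psth_df.to_csv(out / "population_psth.csv", index=False)
    sig_df.to_csv(out / "bin_significance.csv", index=False)
    logger.info("stage spiketrains: %d recorded, %d included, %d task-related "
                "(%.2f s)", n_recorded, len(units), len(task_related),
                time.perf_counter() - t0)

    # --- stage 4: selectivity ----------------------------------------------
    t0 = time.perf_counter()
    sel_cfg = replace(ana.selectivity, seed=seeds[3]
                      if ana.selectivity.seed is None else ana.selectivity.seed)
    wm_tcs = [roc_timecourse(u, sel_cfg) for u in units]
    passive_tcs = [roc_timecourse(u, sel_cfg) for u in passive_units]
    tc_rows = []
    for tc in wm_tcs + passive_tcs:
        for (lo, hi), auc, p, sig in zip(tc.epochs, tc.auc, tc.p_value,
                                         tc.significant):
            tc_rows.append({"unit_id": tc.unit_id, "condition": tc.condition,
                            "epoch_start": lo, "epoch_end": hi, "auc": auc,
                            "p_value": p, "significant": sig})
    tc_df = pd.DataFrame(tc_rows)
    pop_df = population_selectivity(wm_tcs) if len(wm_tcs) >= 3 else pd.DataFrame()
    cmp_df = (compare_conditions(wm_tcs, passive_tcs)
              if len(wm_tcs) >= 3 and len(passive_tcs) >= 3 else pd.DataFrame())
    tc_df.to_csv(out / "roc_timecourses.csv", index=False)
    pop_df.to_csv(out / "population_selectivity.csv", index=False)
    cmp_df.to_csv(out / "condition_comparison.csv", index=False)
    logger.info("stage selectivity: %d WM + %d passive timecourses (%.2f s)",
                len(wm_tcs), len(passive_tcs), time.perf_counter() - t0)

    # --- provenance --------------------------------------------------------
    from . import __version__
    provenance = {
        "config_hash": _config_hash(cfg),
        "master_seed": cfg.master_seed,
        "version": __version__,
        "analysis": {"psth_bin_s": ana.psth_bin, "psth_sigma_s": ana.psth_sigma,
                     "significance_binwidth_s": ana.significance_binwidth,
                     "alpha": ana.alpha,
                     "n_thresholds": sel_cfg.n_thresholds,
                     "n_permutations": sel_cfg.n_permutations,
                     "tail_convention": sel_cfg.tail_convention},
        "counts": {"sessions": len(sessions), "units_recorded": n_recorded,
                   "units_included": len(units),
                   "units_task_related": len(task_related)},
        "runtime_s": round(time.perf_counter() - t_begin, 3),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return ReportBundle(
        session_metrics=metrics_df,
        delay_performance=delay_df,
        laser_comparisons=laser_df,
        psth=psth_df,
        bin_significance=sig_df,
        roc_timecourses=tc_df,
        population_selectivity=pop_df,
        condition_comparison=cmp_df,
        provenance=provenance,
    )
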