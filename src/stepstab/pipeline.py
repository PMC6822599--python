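"""Cohort-level orchestration: trials -> events -> fits -> group inference.

``run_study`` consumes a flat list of trial recordings (each tagged with
participant, mode, condition and speed), runs the single-trial analysis
chain on every one, and assembles the group statistics of the standard
design: a paired comparison of walking vs. running in the normal
condition, and 2x2 condition x mode ANOVAs (scalar for step metrics,
SPM-based for the R^2 curves).  Walking at 1.25 m/s and running at
2.50 m/s are the default contrast cells; other speeds can be selected via
the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .events import detect_events, midstance_times, segment_steps
from .placement import (FootPlacementFit, average_r2_over_legs, build_ensembles,
                        fit_fp_regression, percent_nonsignificant_beta2)
from .preprocessing import com_state
from .spm import (AnovaTable, SPMResult, paired_t_scalar, rm_anova_2x2_scalar,
                  spm_paired_t, spm_rm_anova_2x2)
from .trial_io import AnalysisConfig, TrialRecording, read_trial

log = logging.getLogger("stepstab")


@dataclass
class TrialResult:
    """Single-trial outcomes keyed by the design cell."""

    participant: str
    mode: str
    condition: str
    speed: float
    fits: dict[str, FootPlacementFit]
    r2_avg: np.ndarray
    metrics: metrics_mod.StepMetrics
    n_steps_detected: int
    n_steps_used: int


@dataclass
class StudyResults:
    """All per-trial and group-level outcomes of one study run."""

    config: AnalysisConfig
    trials: list[TrialResult]
    paired_r2: SPMResult | None = None
    paired_width: tuple | None = None
    paired_width_sd: tuple | None = None
    anova_r2: dict[str, SPMResult] = field(default_factory=dict)
    anova_width: AnovaTable | None = None
    anova_width_sd: AnovaTable | None = None
    pct_nonsig_beta2: dict[str, np.ndarray] = field(default_factory=dict)

    # -- tidy exports ---------------------------------------------------
    def fit_table(self) -> pd.DataFrame:
        rows = []
        grid = self.config.grid
        for tr in self.trials:
            for leg, fit in tr.fits.items():
                for i, pct in enumerate(grid):
                    rows.append((tr.participant, tr.mode, tr.condition, tr.speed,
                                 leg, pct, fit.beta1[i], fit.beta2[i],
                                 fit.p_beta1[i], fit.p_beta2[i], fit.r2[i],
                                 fit.n_steps))
        return pd.DataFrame(rows, columns=["participant", "mode", "condition",
                                           "speed", "leg", "percent", "beta1",
                                           "beta2", "p1", "p2", "r2", "n_steps"])

    def metrics_table(self) -> pd.DataFrame:
        rows = [(t.participant, t.mode, t.condition, t.speed,
                 t.metrics.step_width, t.metrics.step_width_sd,
                 t.metrics.n_steps) for t in self.trials]
        return pd.DataFrame(rows, columns=["participant", "mode", "condition",
                                           "speed", "step_width",
                                           "step_width_sd", "n_steps"])

    def spm_table(self) -> pd.DataFrame:
        rows = []
        named: list[tuple[str, SPMResult]] = []
        if self.paired_r2 is not None:
            named.append(("r2_walk_vs_run", self.paired_r2))
        named += [(f"r2_anova_{k}", v) for k, v in self.anova_r2.items()]
        for name, res in named:
            for pct, stat in zip(res.grid, res.stat_curve):
                rows.append((name, res.stat_kind, pct, stat, res.threshold))
        return pd.DataFrame(rows, columns=["effect", "stat", "percent",
                                           "value", "threshold"])

    def cluster_table(self) -> pd.DataFrame:
        rows = []
        named: list[tuple[str, SPMResult]] = []
        if self.paired_r2 is not None:
            named.append(("r2_walk_vs_run", self.paired_r2))
        named += [(f"r2_anova_{k}", v) for k, v in self.anova_r2.items()]
        for name, res in named:
            for c in res.clusters:
                rows.append((name, c["start"], c["end"], c["max_stat"]))
        return pd.DataFrame(rows, columns=["effect", "start", "end", "max_stat"])

    def summary(self) -> dict:
        out: dict = {"n_trials": len(self.trials)}
        if self.paired_width is not None:
            t, df, p = self.paired_width
            out["step_width_paired_t"] = {"t": t, "df": df, "p": p}
        if self.paired_width_sd is not None:
            t, df, p = self.paired_width_sd
            out["step_width_sd_paired_t"] = {"t": t, "df": df, "p": p}
        if self.paired_r2 is not None:
            out["r2_walk_vs_run"] = {
                "threshold": self.paired_r2.threshold,
                "fwhm": self.paired_r2.fwhm,
                "clusters": self.paired_r2.clusters,
            }
        for key, tab in (("step_width_anova", self.anova_width),
                         ("step_width_sd_anova", self.anova_width_sd)):
            if tab is not None:
                out[key] = {k: v for k, v in tab.effects.items()}
                out[key + "_posthoc"] = tab.posthoc
        for k, res in self.anova_r2.items():
            out[f"r2_anova_{k}_clusters"] = res.clusters
        return out


def analyze_trial(trial: TrialRecording,
                  config: AnalysisConfig | None = None) -> TrialResult:
    """Full single-trial chain: events, ensembles, per-leg fits, metrics."""
    config = config or AnalysisConfig()
    com = com_state(trial)
    events = midstance_times(detect_events(trial, config))
    steps = segment_steps(events)
    ensembles = build_ensembles(trial, com, events, steps, config)
    fits: dict[str, FootPlacementFit] = {}
    for leg, ens in ensembles.items():
        if not ens.sufficient:
            log.info("%s %s: leg %s has %d steps (<%d); excluded",
                     trial.meta.participant, trial.meta.mode, leg, ens.n_steps,
                     config.min_steps)
            continue
        fits[leg] = fit_fp_regression(ens)
    if {"left", "right"} <= fits.keys():
        r2_avg = average_r2_over_legs(fits["left"], fits["right"])
    elif fits:
        r2_avg = next(iter(fits.values())).r2
    else:
        raise ValueError(
            f"trial {trial.meta.participant}/{trial.meta.mode}: no leg had "
            f"enough steps for the regression")
    widths = metrics_mod.step_widths(trial, events, config)
    sm = metrics_mod.summarize(widths)
    used = sum(e.n_steps for e in ensembles.values())
    log.info("%s %s/%s @%.2f: %d steps segmented, %d used",
             trial.meta.participant, trial.meta.mode, trial.meta.condition,
             trial.meta.speed, len(steps), used)
    return TrialResult(participant=trial.meta.participant, mode=trial.meta.mode,
                       condition=trial.meta.condition, speed=trial.meta.speed,
                       fits=fits, r2_avg=r2_avg, metrics=sm,
                       n_steps_detected=len(steps), n_steps_used=used)


def _cell(results: list[TrialResult], mode: str, condition: str,
          speed: float) -> dict[str, TrialResult]:
    out = {}
    for r in results:
        if r.mode == mode and r.condition == condition and abs(r.speed - speed) < 1e-6:
            out[r.participant] = r
    return out


def run_study(trials: list[TrialRecording],
              config: AnalysisConfig | None = None,
              spm_method: str = "rft") -> StudyResults:
    """Analyse a cohort of trials and run the group statistics.

    Requires every participant to cover the four default design cells
    (walking/running x normal/stabilized at the configured contrast
    speeds); missing cells raise an error naming them.
    """
    config = config or AnalysisConfig()
    results = [analyze_trial(t, config) for t in trials]
    study = StudyResults(config=config, trials=results)

    cells = {
        ("walking", "normal"): _cell(results, "walking", "normal", config.walking_speed),
        ("walking", "stabilized"): _cell(results, "walking", "stabilized",
                                         config.walking_speed),
        ("running", "normal"): _cell(results, "running", "normal", config.running_speed),
        ("running", "stabilized"): _cell(results, "running", "stabilized",
                                         config.running_speed),
    }
    participants = sorted(set.union(*(set(c) for c in cells.values())) or set())
    missing = [f"{p}:{m}/{c}" for (m, c), cell in cells.items()
               for p in participants if p not in cell]
    if missing:
        raise ValueError("missing design cells: " + ", ".join(missing))
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for group statistics")

    def stack(key, fn):
        return np.array([fn(cells[key][p]) for p in participants])

    # hypothesis 1: per-participant coefficient significance (Fig-3-style)
    for (m, c), cell in cells.items():
        if c != "normal":
            continue
        fits = [f for p in participants for f in cell[p].fits.values()]
        study.pct_nonsig_beta2[m] = percent_nonsignificant_beta2(fits, config.alpha)

    # hypothesis 2: walking vs running, normal condition
    r2_walk = stack(("walking", "normal"), lambda r: r.r2_avg)
    r2_run = stack(("running", "normal"), lambda r: r.r2_avg)
    study.paired_r2 = spm_paired_t(r2_walk, r2_run, grid=config.grid,
                                   alpha=config.alpha, method=spm_method,
                                   seed=config.seed)
    w_walk = stack(("walking", "normal"), lambda r: r.metrics.step_width)
    w_run = stack(("running", "normal"), lambda r: r.metrics.step_width)
    study.paired_width = paired_t_scalar(w_walk, w_run)
    s_walk = stack(("walking", "normal"), lambda r: r.metrics.step_width_sd)
    s_run = stack(("running", "normal"), lambda r: r.metrics.step_width_sd)
    study.paired_width_sd = paired_t_scalar(s_walk, s_run)

    # hypotheses 3/4: 2x2 condition x mode
    def cube(fn):
        # axes: participant, condition (normal, stabilized), mode (walking, running)
        arr = np.array([[[fn(cells[(m, c)][p]) for m in ("walking", "running")]
                         for c in ("normal", "stabilized")] for p in participants])
        return arr

    r2_cube = cube(lambda r: r.r2_avg)           # (n, 2, 2, nodes)
    study.anova_r2 = spm_rm_anova_2x2(r2_cube, grid=config.grid, alpha=config.alpha,
                                      method=spm_method, seed=config.seed)
    study.anova_width = rm_anova_2x2_scalar(cube(lambda r: r.metrics.step_width))
    study.anova_width_sd = rm_anova_2x2_scalar(cube(lambda r: r.metrics.step_width_sd))
    return study


def run_replication(data_dir: str | Path,
                    config: AnalysisConfig | None = None) -> StudyResults:
    """Run the study pipeline on a locally deposited real dataset.

    Expects the tabular trial layout of :mod:`stepstab.trial_io` (one
    ``*_meta.yaml`` per trial).  This is an optional integration path; it
    exits cleanly when the dataset is absent.
    """
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise FileNotFoundError(f"dataset not available: {data_dir}")
    metas = sorted(data_dir.glob("*_meta.yaml"))
    if not metas:
        raise FileNotFoundError(
            f"dataset not available: no *_meta.yaml trial files in {data_dir}")
    trials = [read_trial(m) for m in metas]
    return run_study(trials, config)
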