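"""Step width and step-width variability.

Step width is the mean absolute mediolateral separation between successive
foot placements, each read at the foot's own mid-stance where it is
stationary; step-width variability is the sample standard deviation of the
same distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import GaitEvents
from .trial_io import AnalysisConfig, TrialRecording


@dataclass
class StepMetrics:
    step_width: float        # m
    step_width_sd: float     # m
    n_steps: int


def step_widths(trial: TrialRecording, events: GaitEvents,
                config: AnalysisConfig | None = None) -> np.ndarray:
    """Per-step absolute ML separation between successive stance feet.

    Successive mid-stances of opposite sides define the steps; each foot's
    ML position is averaged over +/- ``fp_window_ms`` around its
    mid-stance.  Same-side successions (a missed contralateral mid-stance)
    are skipped.
    """
    config = config or AnalysisConfig()
    if not events.mid_stances:
        raise ValueError("mid-stances not computed; call midstance_times first")
    half_w = config.fp_window_ms / 1000.0
    t_kin = trial.kin_time
    heel_ml = {"left": trial.markers["heel_left"][:, 0],
               "right": trial.markers["heel_right"][:, 0]}

    entries = []
    for side in ("left", "right"):
        for tm in events.mid_stances.get(side, []):
            entries.append((float(tm), side))
    entries.sort()
    if len(entries) < 2:
        raise ValueError("need at least two mid-stances to compute step widths")

    def pos(tm, side):
        m = (t_kin >= tm - half_w) & (t_kin <= tm + half_w)
        if not np.any(m):
            return float(np.interp(tm, t_kin, heel_ml[side]))
        return float(np.mean(heel_ml[side][m]))

    widths = []
    for (t_prev, s_prev), (t_new, s_new) in zip(entries, entries[1:]):
        if s_prev == s_new:
            continue
        widths.append(abs(pos(t_new, s_new) - pos(t_prev, s_prev)))
    return np.asarray(widths)


def summarize(widths: np.ndarray) -> StepMetrics:
    """Mean and sample (ddof=1) standard deviation of the step widths."""
    widths = np.asarray(widths, dtype=float)
    if widths.size < 2:
        raise ValueError("need at least 2 step widths for mean and variability")
    return StepMetrics(step_width=float(np.mean(widths)),
                       step_width_sd=float(np.std(widths, ddof=1)),
                       n_steps=int(widths.size))
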