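"""Swing-normalized ensembles and the per-percentage foot-placement regression.

For every step the ML trunk CoM position and velocity during the preceding
swing are time-normalized to 0-100 % and expressed relative to the stance
foot at its mid-stance; the subsequent ML foot placement is the heel
position of the swung foot at its next mid-stance, in the same frame.
After zero-centering per percentage node, ordinary least squares without an
intercept predicts placement from the CoM state at each node:

    FP = beta1(i) * C(i) + beta2(i) * V(i) + eps(i)

The fraction of placement variance explained by the prediction, R^2(i), is
the primary outcome; R^2 above 0.5 is read as strong coupling between the
CoM state and foot placement.  Left-leg ML values are mirrored (x -1) so
both legs share sign semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .events import GaitEvents, Step
from .preprocessing import ComState
from .trial_io import AnalysisConfig, TrialRecording


@dataclass
class SwingEnsemble:
    """Step x node matrices of centered CoM state plus centered placements."""

    leg: str
    grid: np.ndarray          # swing percentage nodes
    C: np.ndarray             # steps x nodes, ML CoM position re stance origin (m)
    V: np.ndarray             # steps x nodes, ML CoM velocity (m/s)
    FP: np.ndarray            # steps, ML foot placement re stance origin (m)
    sufficient: bool = True

    @property
    def n_steps(self) -> int:
        return len(self.FP)


@dataclass
class FootPlacementFit:
    """Per-percentage regression gains, p-values and explained variance."""

    grid: np.ndarray
    beta1: np.ndarray
    beta2: np.ndarray
    r2: np.ndarray
    p_beta1: np.ndarray
    p_beta2: np.ndarray
    n_steps: int


def time_normalize_swing(times: np.ndarray, series: np.ndarray, toe_off: float,
                         heel_strike: float, grid: np.ndarray) -> np.ndarray:
    """Linearly interpolate a series onto nodes equally spaced over the swing.

    ``grid`` is in percent (0-100); nodes map to times
    ``toe_off + grid/100 * (heel_strike - toe_off)``.
    """
    if not toe_off < heel_strike:
        raise ValueError("toe_off must precede heel_strike")
    if toe_off < times[0] - 1e-9 or heel_strike > times[-1] + 1e-9:
        raise ValueError("swing interval lies outside the recorded range")
    tq = toe_off + np.asarray(grid) / 100.0 * (heel_strike - toe_off)
    return np.interp(tq, times, series)


def _windowed_mean(times: np.ndarray, series: np.ndarray, center: float,
                   half_width: float) -> float:
    """Mean of `series` within +/- half_width of `center` (point sample if 0)."""
    if half_width <= 0:
        return float(np.interp(center, times, series))
    m = (times >= center - half_width) & (times <= center + half_width)
    if not np.any(m):
        return float(np.interp(center, times, series))
    return float(np.mean(series[m]))


def build_ensembles(trial: TrialRecording, com: ComState, events: GaitEvents,
                    steps: list[Step], config: AnalysisConfig | None = None
                    ) -> dict[str, SwingEnsemble]:
    """Per-leg swing ensembles in stance-origin coordinates, zero-centered.

    For each step the stance-foot heel ML position at the origin mid-stance
    is subtracted from the CoM position and from the placement read-out
    (velocities are translation invariant); heel positions are averaged
    over a +/- ``fp_window_ms`` window where the foot is stationary.  Legs
    with fewer than ``min_steps`` steps are flagged insufficient.
    """
    config = config or AnalysisConfig()
    grid = config.grid
    t_kin = trial.kin_time
    half_w = config.fp_window_ms / 1000.0
    heel_ml = {"left": trial.markers["heel_left"][:, 0],
               "right": trial.markers["heel_right"][:, 0]}

    out: dict[str, SwingEnsemble] = {}
    for leg in ("left", "right"):
        leg_steps = [s for s in steps if s.swing_side == leg]
        C_rows, V_rows, fps = [], [], []
        for s in leg_steps:
            stance = "right" if leg == "left" else "left"
            origin = _windowed_mean(t_kin, heel_ml[stance], s.origin_midstance, half_w)
            fp = _windowed_mean(t_kin, heel_ml[leg], s.fp_midstance, half_w) - origin
            C_rows.append(time_normalize_swing(t_kin, com.position, s.toe_off,
                                               s.heel_strike, grid) - origin)
            V_rows.append(time_normalize_swing(t_kin, com.velocity, s.toe_off,
                                               s.heel_strike, grid))
            fps.append(fp)
        if not C_rows:
            out[leg] = SwingEnsemble(leg=leg, grid=grid,
                                     C=np.empty((0, grid.size)),
                                     V=np.empty((0, grid.size)),
                                     FP=np.empty(0), sufficient=False)
            continue
        C = np.asarray(C_rows)
        V = np.asarray(V_rows)
        FP = np.asarray(fps)
        if leg == "left":  # mirror so both legs share sign semantics
            C, V, FP = -C, -V, -FP
        C = C - C.mean(axis=0)
        V = V - V.mean(axis=0)
        FP = FP - FP.mean()
        out[leg] = SwingEnsemble(leg=leg, grid=grid, C=C, V=V, FP=FP,
                                 sufficient=len(FP) >= config.min_steps)
    return out


def fit_fp_regression(ensemble: SwingEnsemble) -> FootPlacementFit:
    """No-intercept OLS of placement on (C, V) at every swing node.

    Zero-centering removes the need for an offset.  Returns gains, the
    explained-variance ratio (predicted over actual placement variance,
    identical to 1 - SSE/SST on centered no-intercept fits) and two-sided
    coefficient t-test p-values with n - 2 degrees of freedom.  Rank
    deficiency at a node yields NaNs there.
    """
    n = ensemble.n_steps
    if n < 4:
        raise ValueError(f"need at least 4 steps for the regression, got {n}")
    g = ensemble.grid.size
    beta = np.full((g, 2), np.nan)
    r2 = np.full(g, np.nan)
    p1 = np.full(g, np.nan)
    p2 = np.full(g, np.nan)
    sst = float(ensemble.FP @ ensemble.FP)
    df = n - 2
    degenerate = 0
    for i in range(g):
        X = np.column_stack([ensemble.C[:, i], ensemble.V[:, i]])
        xtx = X.T @ X
        if np.linalg.matrix_rank(xtx) < 2:
            degenerate += 1
            continue
        b, _, _, _ = np.linalg.lstsq(X, ensemble.FP, rcond=None)
        pred = X @ b
        resid = ensemble.FP - pred
        sse = float(resid @ resid)
        r2[i] = float(pred @ pred) / sst if sst > 0 else np.nan
        beta[i] = b
        sigma2 = sse / df if df > 0 else np.nan
        if sigma2 == 0:
            # perfect fit: coefficients are exact
            p1[i] = 0.0
            p2[i] = 0.0
            continue
        cov = sigma2 * np.linalg.inv(xtx)
        se = np.sqrt(np.diag(cov))
        tvals = b / se
        p1[i], p2[i] = 2.0 * stats.t.sf(np.abs(tvals), df)
    if degenerate:
        warnings.warn(f"{degenerate} swing nodes were rank deficient; fits set to NaN")
    return FootPlacementFit(grid=ensemble.grid, beta1=beta[:, 0], beta2=beta[:, 1],
                            r2=r2, p_beta1=p1, p_beta2=p2, n_steps=n)


def percent_nonsignificant_beta2(fits: list[FootPlacementFit],
                                 alpha: float = 0.05) -> np.ndarray:
    """Per-node percentage of fits whose velocity gain is not significant."""
    if not fits:
        raise ValueError("no fits supplied")
    p = np.vstack([f.p_beta2 for f in fits])
    return 100.0 * np.mean(p >= alpha, axis=0)


def average_r2_over_legs(fit_left: FootPlacementFit,
                         fit_right: FootPlacementFit) -> np.ndarray:
    """Nodewise mean R^2 of the two legs (NaN where either is undefined)."""
    if fit_left.grid.size != fit_right.grid.size or \
            not np.allclose(fit_left.grid, fit_right.grid):
        raise ValueError("fits are defined on different swing grids")
    return 0.5 * (fit_left.r2 + fit_right.r2)
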