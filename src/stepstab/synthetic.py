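"""Synthetic treadmill gait with a known ML foot-placement control law.

The generator emulates the measurement chain of a foot-placement-control
experiment: trunk-cluster markers and heel markers at the kinematic rate,
vertical force and centre of pressure at the force-plate rate, for walking
(double support, duty factor > 0.5) and running (flight phases, duty
factor < 0.5) at configurable belt speeds, in a normal and an externally
stabilized condition.

Control law
-----------
Each step k draws independent latent variables

* ``w_k`` — control-relevant CoM state deviation (SD ``com_noise_sd``),
* ``z_k`` — CoM state variation in the null space of the control law
  (SD ``com_free_sd``),
* ``u_k`` — CoM state variation decoupled from the subsequent placement
  (SD ``com_decouple_sd``),
* ``eps_k`` — foot-placement residual (SD ``fp_noise_sd``),

and the mediolateral placement deviation of step k is ``d_k = w_k + eps_k``
(mirrored so both legs share sign semantics).  The swing-phase CoM deviation
relative to the stance foot is built from three basis functions of the swing
fraction tau,

    C(tau) = w*phi1(tau) + z*phi2(tau) + u*phi3(tau),

where ``phi1`` solves ``beta1(tau)*phi1 + beta2(tau)*phi1'/T = 1`` and
``phi2`` the homogeneous counterpart (= 0 on the right-hand side).  By
construction ``beta1(tau)*C(tau) + beta2(tau)*V(tau) = w`` exactly wherever
the law is in force, so an ordinary per-percentage regression of foot
placement on (C, V) recovers the configured gain profiles, and the
relative explained variance at the law nodes is
``com_noise_sd**2 / (com_noise_sd**2 + fp_noise_sd**2)``.

The decoupling channel ``u`` (zero at heel strike) attenuates the
correlation in early swing, reproducing explained-variance curves that rise
toward heel strike.  In running, the first part of the swing falls in the
flight phase: there the CoM trajectory is inherited from the previous step
(continuity) and a short blend bridges into the step's own law window, so
early-swing states carry no information about the upcoming placement — the
ground-truth profiles account for this exactly.

All ground-truth profiles (``true_beta1``, ``true_beta2``, ``true_r2``) are
the exact population regression coefficients and variance ratios implied by
the construction, obtained in closed form from the latent covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .trial_io import TrialMeta, TrialRecording

_G = 9.81


def _as_profile(value, n: int) -> np.ndarray:
    """Broadcast a scalar or resample a vector onto an n-node tau grid."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.size == n:
        return arr.astype(float)
    src = np.linspace(0.0, 1.0, arr.size)
    dst = np.linspace(0.0, 1.0, n)
    return np.interp(dst, src, arr)


@dataclass
class GeneratorParams:
    """Full parameterisation of one synthetic trial."""

    mode: str = "walking"               # walking | running
    condition: str = "normal"           # normal | stabilized
    speed: float = 1.25                 # belt speed, m/s
    n_steps: int = 60                   # analysable steps (both legs pooled)
    step_frequency: float = 1.0 / 0.55  # steps per second
    duty_factor: float = 0.62           # stance fraction of the stride
    com_amplitude: float = 0.025        # m, deterministic ML sway amplitude
    com_noise_sd: float = 0.010         # m, control-relevant state SD (w)
    beta1_profile: object = 1.5         # position gain per swing %, dimensionless
    beta2_profile: object = 0.25        # velocity gain per swing %, seconds
    fp_noise_sd: float = 0.005          # m, placement residual SD
    mean_step_width: float = 0.12       # m
    marker_noise_sd: float = 3e-4       # m, white noise on every marker axis
    kin_rate: float = 100.0             # samples/s
    force_rate: float = 1000.0          # samples/s
    seed: int = 0
    # secondary knobs
    com_free_sd: float | None = None    # m, law-null state SD (z); default 0.5*com_noise_sd
    com_decouple_sd: float = 0.0        # m, decoupled state SD (u)
    step_corr: float = 0.0              # AR(1) coefficient of (w, z, u) across steps
    bridge_frac: float = 0.16           # running: blend length after flight, swing fraction
    cop_noise_sd: float = 5e-4          # m
    force_noise_sd: float = 1.5         # N
    body_mass: float = 70.0             # kg
    grid_size: int = 101                # ground-truth profile nodes

    def __post_init__(self) -> None:
        if self.mode not in ("walking", "running"):
            raise ValueError(f"mode must be 'walking' or 'running', got {self.mode!r}")
        if self.condition not in ("normal", "stabilized"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1)")
        if self.mode == "walking" and self.duty_factor <= 0.5:
            raise ValueError("walking requires duty_factor > 0.5 (double support)")
        if self.mode == "running" and self.duty_factor >= 0.5:
            raise ValueError("running requires duty_factor < 0.5 (flight phase)")
        if self.fp_noise_sd < 0:
            raise ValueError("fp_noise_sd must be non-negative")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")
        if self.step_frequency <= 0:
            raise ValueError("step_frequency must be positive")
        if self.com_noise_sd < 0 or self.com_decouple_sd < 0:
            raise ValueError("state SDs must be non-negative")
        if not -1.0 < self.step_corr < 1.0:
            raise ValueError("step_corr must lie in (-1, 1)")
        if self.com_free_sd is None:
            self.com_free_sd = 0.5 * self.com_noise_sd
        b1 = np.atleast_1d(np.asarray(self.beta1_profile, dtype=float))
        b2 = np.atleast_1d(np.asarray(self.beta2_profile, dtype=float))
        law_active = np.any(b1 != 0) or np.any(b2 != 0)
        if law_active and np.any(b2 < 0):
            raise ValueError("beta2_profile must be non-negative")
        if law_active and np.any(b2 == 0) and not np.all(b2 == 0):
            raise ValueError("beta2_profile must be zero everywhere or positive everywhere")

    # -- derived timing -------------------------------------------------
    @property
    def step_period(self) -> float:
        return 1.0 / self.step_frequency

    @property
    def stride_period(self) -> float:
        return 2.0 / self.step_frequency

    @property
    def stance_duration(self) -> float:
        return self.duty_factor * self.stride_period

    @property
    def swing_duration(self) -> float:
        return self.stride_period - self.stance_duration

    @property
    def flight_fraction(self) -> float:
        """Fraction of the swing spent with both feet airborne (0 in walking)."""
        fl = (self.swing_duration - self.step_period) / self.swing_duration
        return max(0.0, fl)

    @property
    def law_start_fraction(self) -> float:
        """Swing fraction from which the control law is exactly in force."""
        if self.mode == "walking":
            return 0.0
        return self.flight_fraction + self.bridge_frac

    @property
    def law_active(self) -> bool:
        b1 = np.atleast_1d(np.asarray(self.beta1_profile, dtype=float))
        b2 = np.atleast_1d(np.asarray(self.beta2_profile, dtype=float))
        return bool(np.any(b1 != 0) or np.any(b2 != 0))


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    event_times: dict                    # side -> {"heel_strikes", "toe_offs"} (s)
    grid: np.ndarray                     # swing percentage nodes
    true_beta1: np.ndarray               # exact population gains per node
    true_beta2: np.ndarray
    true_r2: np.ndarray
    true_step_width: float
    true_step_width_sd: float
    com_series_clean: np.ndarray         # noiseless ML trunk CoM at kin_rate
    footfall_times: np.ndarray = field(default=None)
    footfall_x: np.ndarray = field(default=None)
    footfall_sides: np.ndarray = field(default=None)  # +1 right, -1 left


# ----------------------------------------------------------------------
# basis functions
# ----------------------------------------------------------------------

_PAD = 0.1       # tau overhang of the basis grid beyond [0, 1]
_FINE = 1201     # nodes of the internal tau grid over [-_PAD, 1 + _PAD]
PAD_SAMPLES = 2  # kinematic samples by which each law segment overhangs the swing
_BASIS_CACHE: dict = {}


def _basis(params: GeneratorParams):
    """phi1..phi3 and their tau-derivatives on a fine tau grid.

    phi1 solves beta1*phi1 + beta2*phi1'/T = 1, phi2 the homogeneous
    equation with phi2(0) = 1, phi3 = (1 + cos(pi tau)) / 2.  The grid
    overhangs [0, 1] slightly so that trajectory segments can extend a
    couple of samples past toe off and heel strike (keeping discrete
    derivatives at the swing endpoints consistent with the law).  When
    beta2 == 0 the equations are algebraic; when the law is absent
    entirely phi1 = 0 and phi2 is a fixed smooth shape.
    """
    tau = np.linspace(-_PAD, 1.0 + _PAD, _FINE)
    i0 = int(np.argmin(np.abs(tau)))
    T = params.swing_duration
    b1 = _as_profile_clamped(params.beta1_profile, tau)
    b2 = _as_profile_clamped(params.beta2_profile, tau)

    key = (b1.tobytes(), b2.tobytes(), round(T, 12), params.law_active)
    cached = _BASIS_CACHE.get(key)
    if cached is not None:
        return cached

    if not params.law_active:
        phi1 = np.zeros(_FINE)
        dphi1 = np.zeros(_FINE)
        phi2 = np.cos(np.pi * tau)
        dphi2 = -np.pi * np.sin(np.pi * tau)
    elif np.all(b2 == 0):
        with np.errstate(divide="ignore"):
            phi1 = np.where(b1 != 0, 1.0 / np.where(b1 != 0, b1, 1.0), 0.0)
        dphi1 = np.gradient(phi1, tau)
        phi2 = np.zeros(_FINE)
        dphi2 = np.zeros(_FINE)
    else:
        h = tau[1] - tau[0]
        # beta profiles at half-grid points for the RK4 midpoint stages
        tau_h = tau[:-1] + h / 2
        b1h = _as_profile_clamped(params.beta1_profile, tau_h)
        b2h = _as_profile_clamped(params.beta2_profile, tau_h)

        phi1 = np.empty(_FINE)
        phi2 = np.empty(_FINE)
        phi1[i0] = 0.5 / b1[i0] if b1[i0] != 0 else 0.0
        phi2[i0] = 1.0

        def rk4_step(y, i, j, hh, c):
            # i: start node, j: index of the midpoint coefficients
            k1 = T * (c - b1[i] * y) / b2[i]
            y2 = y + hh * k1 / 2
            k2 = T * (c - b1h[j] * y2) / b2h[j]
            y3 = y + hh * k2 / 2
            k3 = T * (c - b1h[j] * y3) / b2h[j]
            y4 = y + hh * k3
            k4 = T * (c - b1[i + (1 if hh > 0 else -1)] * y4) / b2[i + (1 if hh > 0 else -1)]
            return y + hh * (k1 + 2 * k2 + 2 * k3 + k4) / 6

        for arr, c in ((phi1, 1.0), (phi2, 0.0)):
            for i in range(i0, _FINE - 1):          # forward from tau = 0
                arr[i + 1] = rk4_step(arr[i], i, i, h, c)
            for i in range(i0, 0, -1):              # backward from tau = 0
                arr[i - 1] = rk4_step(arr[i], i, i - 1, -h, c)
        dphi1 = T * (1.0 - b1 * phi1) / b2
        dphi2 = T * (0.0 - b1 * phi2) / b2

    phi3 = 0.5 * (1.0 + np.cos(np.pi * np.clip(tau, 0.0, 1.0)))
    dphi3 = -0.5 * np.pi * np.sin(np.pi * np.clip(tau, 0.0, 1.0))
    out = (tau, (phi1, phi2, phi3), (dphi1, dphi2, dphi3))
    if len(_BASIS_CACHE) > 256:
        _BASIS_CACHE.pop(next(iter(_BASIS_CACHE)))
    _BASIS_CACHE[key] = out
    return out


def _as_profile_clamped(value, tau: np.ndarray) -> np.ndarray:
    """Profile resampled onto `tau`, clamping outside [0, 1]."""
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(tau.size, float(arr))
    src = np.linspace(0.0, 1.0, arr.size)
    return np.interp(np.clip(tau, 0.0, 1.0), src, arr)


def _interp_basis(tau_q, tau, funcs):
    return [np.interp(tau_q, tau, f) for f in funcs]


# ----------------------------------------------------------------------
# exact population profiles
# ----------------------------------------------------------------------

def _latent_cov_lags(params: GeneratorParams, n_lags: int) -> np.ndarray:
    """Covariance of [w, z, u, eps] stacked over `n_lags` consecutive steps.

    (w, z, u) follow an AR(1) across steps with coefficient ``step_corr``
    and stationary marginal variance; eps is white.
    """
    sw = params.com_noise_sd if params.law_active else 0.0
    var = np.array([sw**2, params.com_free_sd**2,
                    params.com_decouple_sd**2, params.fp_noise_sd**2])
    dim = 4 * n_lags
    lam = np.zeros((dim, dim))
    rho = params.step_corr
    for a in range(n_lags):
        for b in range(n_lags):
            for j in range(4):
                if a == b:
                    lam[4 * a + j, 4 * b + j] = var[j]
                elif j < 3:  # eps is white
                    lam[4 * a + j, 4 * b + j] = rho ** abs(a - b) * var[j]
    return lam


def _latent_cov(params: GeneratorParams) -> np.ndarray:
    """Covariance of [w, z, u, eps]_k + the same at lag one (8 x 8)."""
    lam = _latent_cov_lags(params, 2)
    # reorder from (k-1, k) to the (k, k-1) layout of the continuous model
    order = list(range(4, 8)) + list(range(0, 4))
    return lam[np.ix_(order, order)]


def _hermite(s):
    s = np.asarray(s, dtype=float)
    return (2 * s**3 - 3 * s**2 + 1, s**3 - 2 * s**2 + s,
            -2 * s**3 + 3 * s**2, s**3 - s**2)


def _hermite_d(s):
    s = np.asarray(s, dtype=float)
    return (6 * s**2 - 6 * s, 3 * s**2 - 4 * s + 1,
            -6 * s**2 + 6 * s, 3 * s**2 - 2 * s)


def _continuous_node_coefficients(params: GeneratorParams, tau_nodes: np.ndarray):
    """Continuous-time latent coefficients of (C, V) at each swing node.

    Returns (cC, cV) of shape (n, 8) over the latent basis
    [w, z, u, eps]_k ++ [w, z, u, eps]_{k-1}.  Deterministic trajectory
    components are omitted: the pipeline removes them by per-percentage
    zero-centering.  This ignores the discrete measurement chain
    (sampling, finite differences, interpolation); the ground-truth
    profiles use :func:`_measured_node_coefficients` instead, which models
    it exactly.
    """
    tau_f, funcs, dfuncs = _basis(params)
    T = params.swing_duration
    n = tau_nodes.size
    cC = np.zeros((n, 8))
    cV = np.zeros((n, 8))
    fl = params.flight_fraction
    tb = params.law_start_fraction
    pad = PAD_SAMPLES / (params.kin_rate * T)  # law-segment overhang, tau units

    law = tau_nodes >= (tb - pad if params.mode == "running" else -np.inf)
    f_law = _interp_basis(tau_nodes[law], tau_f, funcs)
    d_law = _interp_basis(tau_nodes[law], tau_f, dfuncs)
    for j in range(3):
        cC[law, j] = f_law[j]
        cV[law, j] = d_law[j] / T

    if params.mode == "running":
        inh = tau_nodes < fl + pad
        tau_prev = tau_nodes[inh] + 1.0 - fl
        f_p = _interp_basis(tau_prev, tau_f, funcs)
        d_p = _interp_basis(tau_prev, tau_f, dfuncs)
        # C = d_{k-1} - C_{k-1}(tau'),  V = -V_{k-1}(tau')   (mirrored frame)
        cC[inh, 4] = 1.0 - f_p[0]
        cC[inh, 5] = -f_p[1]
        cC[inh, 6] = -f_p[2]
        cC[inh, 7] = 1.0
        for j in range(3):
            cV[inh, 4 + j] = -d_p[j] / T

        mid = (~law) & (~inh)
        if np.any(mid):
            ta, tbb = fl + pad, tb - pad  # bridge endpoints on the swing clock
            fa = _interp_basis(np.array([1.0 + pad]), tau_f, funcs)
            da = _interp_basis(np.array([1.0 + pad]), tau_f, dfuncs)
            fb = _interp_basis(np.array([tbb]), tau_f, funcs)
            db = _interp_basis(np.array([tbb]), tau_f, dfuncs)
            Ca = np.zeros(8)
            Ma = np.zeros(8)
            Ca[4] = 1.0 - fa[0][0]
            Ca[5] = -fa[1][0]
            Ca[6] = -fa[2][0]
            Ca[7] = 1.0
            for j in range(3):
                Ma[4 + j] = -da[j][0] / T
            Cb = np.zeros(8)
            Mb = np.zeros(8)
            for j in range(3):
                Cb[j] = fb[j][0]
                Mb[j] = db[j][0] / T
            dt = (tbb - ta) * T
            s = (tau_nodes[mid] - ta) / (tbb - ta)
            h00, h10, h01, h11 = _hermite(s)
            g00, g10, g01, g11 = _hermite_d(s)
            cC[mid] = (np.outer(h00, Ca) + np.outer(h10, dt * Ma)
                       + np.outer(h01, Cb) + np.outer(h11, dt * Mb))
            cV[mid] = (np.outer(g00, Ca) + np.outer(g10, dt * Ma)
                       + np.outer(g01, Cb) + np.outer(g11, dt * Mb)) / dt
    return cC, cV


def _measured_node_coefficients(params: GeneratorParams, grid_size: int):
    """Latent coefficients of the *measured* (C, V, FP) at each swing node.

    Pushes unit impulses of every latent (w, z, u, eps at steps k-1, k,
    k+1) through the same discrete chain the pipeline applies — CoM
    trajectory synthesis, sampling at the kinematic rate, central
    differences, linear time-normalization onto the swing grid and
    stance-origin subtraction — and reads off the linear response.  By
    construction these coefficients describe the measured regressors
    exactly (sensor noise and event-detection jitter aside).

    Returns (cC, cV, cFP) with cC, cV of shape (grid_size, 12) and cFP of
    shape (12,), over [w, z, u, eps]_{k-1} ++ [..]_k ++ [..]_{k+1}.
    """
    Ts = params.step_period
    stance = params.stance_duration
    swing = params.swing_duration
    W = params.mean_step_width
    n_foot = 5
    k = 2                       # target swing, right side
    t0 = 1.0
    hs = t0 + Ts * np.arange(n_foot)
    sides = np.array([1, -1, 1, -1, 1])
    duration = np.ceil((hs[-1] + stance + 0.2) * params.kin_rate) / params.kin_rate
    kin_dt = 1.0 / params.kin_rate
    t_kin = np.arange(int(round(duration * params.kin_rate))) * kin_dt
    toe_off, heel_strike = hs[k] - swing, hs[k]
    t_nodes = toe_off + np.linspace(0.0, 1.0, grid_size) * (heel_strike - toe_off)

    def response(w, z, u, eps):
        d = (w if params.law_active else np.zeros(n_foot)) + eps
        x = np.empty(n_foot)
        x[0] = sides[0] * W / 2.0
        for j in range(1, n_foot):
            x[j] = x[j - 1] + sides[j] * (W + d[j])
        com = _com_trajectory(params, t_kin, hs, sides, x, w, z, u)
        vel = np.gradient(com, kin_dt)
        C = sides[k] * (np.interp(t_nodes, t_kin, com) - x[k - 1])
        V = sides[k] * np.interp(t_nodes, t_kin, vel)
        FP = sides[k] * (x[k] - x[k - 1]) - W
        return C, V, FP

    zero = np.zeros(n_foot)
    C0, V0, F0 = response(zero, zero, zero, zero)
    cC = np.zeros((grid_size, 12))
    cV = np.zeros((grid_size, 12))
    cFP = np.zeros(12)
    for lag, foot in enumerate((k - 1, k, k + 1)):
        for j in range(4):
            latents = [zero.copy() for _ in range(4)]
            latents[j][foot] = 1.0
            C, V, FP = response(*latents)
            col = 4 * lag + j
            cC[:, col] = C - C0
            cV[:, col] = V - V0
            cFP[col] = FP - F0
    return cC, cV, cFP


def analytic_profiles(params: GeneratorParams, grid_size: int | None = None):
    """Exact population (beta1, beta2, r2) profiles over the swing grid.

    The coefficients are the population regression of the placement
    deviation ``w + eps`` on the measured CoM state (C, V) at each node;
    r2 is the ratio of predicted to total placement variance.  Where the
    law is in force and the decoupling channel is silent these equal the
    configured gain profiles and ``sw^2 / (sw^2 + fp_noise_sd^2)``;
    elsewhere (early running swing, decoupled states) they are the exact
    attenuated values implied by the construction.
    """
    gs = grid_size or params.grid_size
    cC, cV, cFP = _measured_node_coefficients(params, gs)
    lam = _latent_cov_lags(params, 3)
    var_fp = cFP @ lam @ cFP
    if var_fp == 0:
        # degenerate: no placement variance at all
        return np.zeros(gs), np.zeros(gs), np.zeros(gs)
    beta1 = np.full(gs, np.nan)
    beta2 = np.full(gs, np.nan)
    r2 = np.zeros(gs)
    for i in range(gs):
        x = np.vstack([cC[i], cV[i]])
        sigma = x @ lam @ x.T
        gvec = x @ lam @ cFP
        b, *_ = np.linalg.lstsq(sigma, gvec, rcond=None)
        beta1[i], beta2[i] = b
        r2[i] = float(gvec @ b / var_fp)
    return beta1, beta2, np.clip(r2, 0.0, 1.0)


def analytic_r2(params: GeneratorParams, grid_size: int | None = None) -> np.ndarray:
    """Closed-form true R-squared profile over the swing grid."""
    return analytic_profiles(params, grid_size)[2]


# ----------------------------------------------------------------------
# trial synthesis
# ----------------------------------------------------------------------

def _draw_latents(rng: np.random.Generator, n: int, sd: float, rho: float) -> np.ndarray:
    x = rng.normal(0.0, 1.0, n)
    if rho != 0.0:
        for k in range(1, n):
            x[k] = rho * x[k - 1] + np.sqrt(1.0 - rho**2) * x[k]
    return sd * x


def _com_trajectory(params: GeneratorParams, t_kin: np.ndarray, hs: np.ndarray,
                    sides: np.ndarray, x: np.ndarray, w: np.ndarray,
                    z: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Clean ML CoM series: law segments, blends, constant head/tail.

    Each law segment overhangs its swing by ``PAD_SAMPLES`` kinematic
    samples so that discrete endpoint velocities stay consistent with the
    law; cubic Hermite blends (matching value and slope) connect
    consecutive segments across double support (walking) or flight +
    early-swing bridge (running).
    """
    swing = params.swing_duration
    tb = params.law_start_fraction
    W = params.mean_step_width
    A = params.com_amplitude
    n_foot = len(hs)
    kin_dt = 1.0 / params.kin_rate
    tau_f, funcs, dfuncs = _basis(params)

    def mu(tau):
        return W / 2.0 - A * np.sin(np.pi * tau)

    def dmu(tau):
        return -np.pi * A * np.cos(np.pi * tau)

    def law_value(k, tau):
        dev = (w[k] * np.interp(tau, tau_f, funcs[0])
               + z[k] * np.interp(tau, tau_f, funcs[1])
               + u[k] * np.interp(tau, tau_f, funcs[2]))
        return x[k - 1] + sides[k] * (mu(tau) + dev)

    def law_slope(k, tau):
        dev = (w[k] * np.interp(tau, tau_f, dfuncs[0])
               + z[k] * np.interp(tau, tau_f, dfuncs[1])
               + u[k] * np.interp(tau, tau_f, dfuncs[2]))
        return sides[k] * (dmu(tau) + dev) / swing

    pad_t = PAD_SAMPLES * kin_dt
    pad_tau = pad_t / swing
    gap = (hs[1] - (1.0 - tb) * swing) - hs[0]  # time between law segments
    if gap <= 2.0 * pad_t + kin_dt:
        raise ValueError(
            "timing leaves no room for the inter-segment blend; increase the "
            "double-support/bridge fraction or the kinematic rate")
    com = np.empty(t_kin.size)
    law_lo = hs - (1.0 - tb) * swing - pad_t
    law_hi = hs + pad_t
    eps_t = 1e-9
    for k in range(1, n_foot):
        m = (t_kin >= law_lo[k] - eps_t) & (t_kin <= law_hi[k] + eps_t)
        tau = (t_kin[m] - (hs[k] - swing)) / swing
        com[m] = law_value(k, tau)
        if k >= 2:
            bm = (t_kin > law_hi[k - 1] + eps_t) & (t_kin < law_lo[k] - eps_t)
            if np.any(bm):
                ta, tbb = law_hi[k - 1], law_lo[k]
                dt = tbb - ta
                s = (t_kin[bm] - ta) / dt
                pa = law_value(k - 1, 1.0 + pad_tau)
                ma = law_slope(k - 1, 1.0 + pad_tau)
                pb = law_value(k, tb - pad_tau)
                mb = law_slope(k, tb - pad_tau)
                h00, h10, h01, h11 = _hermite(s)
                com[bm] = h00 * pa + h10 * dt * ma + h01 * pb + h11 * dt * mb
    head = t_kin < law_lo[1] - eps_t
    com[head] = law_value(1, tb - pad_tau)
    tail = t_kin > law_hi[-1] + eps_t
    com[tail] = law_value(n_foot - 1, 1.0 + pad_tau)
    return com


def simulate_trial(params: GeneratorParams,
                   participant: str = "p00") -> tuple[TrialRecording, GroundTruth]:
    """Generate one synthetic trial plus its ground truth.

    Same parameters (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    Ts = params.step_period
    stance = params.stance_duration
    swing = params.swing_duration
    W = params.mean_step_width
    n_foot = params.n_steps + 4
    t0 = 1.0
    hs = t0 + Ts * np.arange(n_foot)
    sides = np.array([1 if k % 2 == 0 else -1 for k in range(n_foot)])
    duration = np.ceil((hs[-1] + stance + 0.5) * params.kin_rate) / params.kin_rate

    w = _draw_latents(rng, n_foot, params.com_noise_sd if params.law_active else 0.0,
                      params.step_corr)
    z = _draw_latents(rng, n_foot, params.com_free_sd, params.step_corr)
    u = _draw_latents(rng, n_foot, params.com_decouple_sd, params.step_corr)
    eps = rng.normal(0.0, params.fp_noise_sd, n_foot) if params.fp_noise_sd > 0 \
        else np.zeros(n_foot)
    d = (w if params.law_active else 0.0) + eps

    # mediolateral footfall positions
    x = np.empty(n_foot)
    x[0] = sides[0] * W / 2.0
    for k in range(1, n_foot):
        x[k] = x[k - 1] + sides[k] * (W + d[k])

    # ---- clean CoM trajectory on the kinematic grid -------------------
    kin_dt = 1.0 / params.kin_rate
    n_kin = int(round(duration * params.kin_rate))
    t_kin = np.arange(n_kin) * kin_dt
    com = _com_trajectory(params, t_kin, hs, sides, x, w, z, u)
    eps_t = 1e-9

    # ---- markers ------------------------------------------------------
    trunk_dx = np.array([-0.03, 0.0, 0.03])       # mean is exactly the CoM
    trunk_dy = np.array([-0.02, 0.03, -0.02])
    trunk_z = 1.35
    markers: dict[str, np.ndarray] = {}
    y_bob = 0.01 * np.sin(2 * np.pi * params.step_frequency * t_kin)
    z_bob = 0.02 * np.sin(2 * np.pi * 2 * params.step_frequency * t_kin)
    for i in range(3):
        m = np.column_stack([
            com + trunk_dx[i],
            y_bob + trunk_dy[i],
            trunk_z + z_bob,
        ])
        markers[f"trunk_{i + 1}"] = m

    speed = params.speed
    y_land = speed * stance / 2.0

    def heel_series(side: int) -> np.ndarray:
        ks = np.flatnonzero(sides == side)
        mlx = np.full(n_kin, x[ks[0]])
        apy = np.full(n_kin, y_land)
        hz = np.full(n_kin, 0.02)
        for idx, k in enumerate(ks):
            st = (t_kin >= hs[k]) & (t_kin <= hs[k] + stance + eps_t)
            mlx[st] = x[k]
            apy[st] = y_land - speed * (t_kin[st] - hs[k])
            hz[st] = 0.02
            if idx + 1 < len(ks):
                k2 = ks[idx + 1]
                sw_m = (t_kin > hs[k] + stance + eps_t) & (t_kin < hs[k2])
                tau = (t_kin[sw_m] - (hs[k] + stance)) / swing
                blend = 3 * tau**2 - 2 * tau**3
                mlx[sw_m] = x[k] + (x[k2] - x[k]) * blend
                y_off = y_land - speed * stance
                h00, h10, h01, h11 = _hermite(tau)
                apy[sw_m] = (h00 * y_off + h10 * (-speed * swing)
                             + h01 * y_land + h11 * (-speed * swing))
                hz[sw_m] = 0.02 + 0.08 * np.sin(np.pi * tau)
            else:
                after = t_kin > hs[k] + stance + eps_t
                mlx[after] = x[k]
                apy[after] = y_land - speed * stance
        return np.column_stack([mlx, apy, hz])

    markers["heel_right"] = heel_series(1)
    markers["heel_left"] = heel_series(-1)
    if params.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, params.marker_noise_sd, markers[name].shape)

    # ---- force plate --------------------------------------------------
    n_force = int(round(duration * params.force_rate))
    t_f = np.arange(n_force) / params.force_rate
    bw = params.body_mass * _G
    fz = np.zeros(n_force)
    cop_x = np.full(n_force, x[0])
    cop_y = np.zeros(n_force)

    def foot_cop(k, t):
        prog = np.clip((t - hs[k]) / stance, 0.0, 1.0)
        return x[k], y_land - speed * (t - hs[k]) + 0.25 * prog

    if params.mode == "walking":
        ds = Ts - swing
        fz[:] = bw * (1.0 + 0.04 * np.sin(2 * np.pi * 2 * params.step_frequency * t_f))
        for k in range(1, n_foot):
            seg = (t_f >= hs[k]) & (t_f < (hs[k + 1] if k + 1 < n_foot else duration + 1))
            tt = t_f[seg]
            wgt = np.clip((tt - hs[k]) / ds, 0.0, 1.0)
            x_old, y_old = foot_cop(k - 1, tt)
            x_new, y_new = foot_cop(k, tt)
            cop_x[seg] = (1 - wgt) * x_old + wgt * x_new
            cop_y[seg] = (1 - wgt) * y_old + wgt * y_new
        pre = t_f < hs[1]
        cop_x[pre], cop_y[pre] = foot_cop(0, t_f[pre])
    else:
        peak = bw * np.pi * params.stride_period / (2.0 * stance)
        for k in range(n_foot):
            seg = (t_f >= hs[k]) & (t_f <= hs[k] + stance)
            tt = t_f[seg]
            fz[seg] = peak * np.sin(np.pi * (tt - hs[k]) / stance)
            cop_x[seg], cop_y[seg] = foot_cop(k, tt)
            if k + 1 < n_foot:
                flight = (t_f > hs[k] + stance) & (t_f < hs[k + 1])
                cop_x[flight] = x[k]
                cop_y[flight] = y_land - speed * stance
    if params.force_noise_sd > 0:
        fz = fz + rng.normal(0.0, params.force_noise_sd, n_force)
    if params.cop_noise_sd > 0:
        cop_x = cop_x + rng.normal(0.0, params.cop_noise_sd, n_force)
        cop_y = cop_y + rng.normal(0.0, params.cop_noise_sd, n_force)

    meta = TrialMeta(participant=participant, mode=params.mode,
                     condition=params.condition, speed=params.speed,
                     kin_rate=params.kin_rate, force_rate=params.force_rate)
    trial = TrialRecording(markers={k: v[:n_kin] for k, v in markers.items()},
                           force={"fz": fz, "cop_x": cop_x, "cop_y": cop_y},
                           meta=meta)

    # ---- ground truth -------------------------------------------------
    events = {"left": {"heel_strikes": [], "toe_offs": []},
              "right": {"heel_strikes": [], "toe_offs": []}}
    for k in range(n_foot):
        side = "right" if sides[k] == 1 else "left"
        events[side]["heel_strikes"].append(hs[k])
        if hs[k] + stance <= duration:
            events[side]["toe_offs"].append(hs[k] + stance)
    for side in events:
        for key in events[side]:
            events[side][key] = np.asarray(events[side][key])

    beta1, beta2, r2 = analytic_profiles(params)
    sw_var = (params.com_noise_sd**2 if params.law_active else 0.0) + params.fp_noise_sd**2
    gt = GroundTruth(
        event_times=events,
        grid=np.linspace(0.0, 100.0, params.grid_size),
        true_beta1=beta1,
        true_beta2=beta2,
        true_r2=r2,
        true_step_width=W,
        true_step_width_sd=float(np.sqrt(sw_var)),
        com_series_clean=com,
        footfall_times=hs,
        footfall_x=x,
        footfall_sides=sides,
    )
    return trial, gt


# ----------------------------------------------------------------------
# presets and cohorts
# ----------------------------------------------------------------------

_STAB_FACTORS = {
    # condition effect of the external lateral stabilization preset:
    # amplitude, control-state SD, gain scale, placement-noise scale, width
    "walking": dict(amp=0.6, state=0.5, gain=0.7, noise=1.0, width=0.6),
    "running": dict(amp=0.85, state=0.8, gain=0.9, noise=1.0, width=0.85),
}

_RUN_PERIODS = {2.08: 0.38, 2.50: 0.36, 2.92: 0.34}


def preset_params(mode: str, condition: str = "normal", speed: float | None = None,
                  n_steps: int = 60, seed: int = 0, **overrides) -> GeneratorParams:
    """Study-condition presets for walking and running trials.

    Step periods are multiples of the kinematic sample interval so that
    every swing samples the CoM process at identical phases.
    """
    if mode == "walking":
        speed = 1.25 if speed is None else speed
        p = GeneratorParams(
            mode="walking", condition="normal", speed=speed, n_steps=n_steps,
            step_frequency=1.0 / 0.55, duty_factor=0.62,
            com_amplitude=0.025, com_noise_sd=0.010, com_free_sd=0.006,
            com_decouple_sd=0.0055, beta1_profile=1.5, beta2_profile=0.25,
            fp_noise_sd=0.0045, mean_step_width=0.12, seed=seed)
    elif mode == "running":
        speed = 2.50 if speed is None else speed
        period = _RUN_PERIODS.get(round(speed, 2), 0.36)
        p = GeneratorParams(
            mode="running", condition="normal", speed=speed, n_steps=n_steps,
            step_frequency=1.0 / period, duty_factor=0.38,
            com_amplitude=0.015, com_noise_sd=0.008, com_free_sd=0.005,
            com_decouple_sd=0.003, beta1_profile=1.5, beta2_profile=0.18,
            fp_noise_sd=0.0052, mean_step_width=0.05, seed=seed)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if condition == "stabilized":
        f = _STAB_FACTORS[mode]
        p = replace(
            p, condition="stabilized",
            com_amplitude=p.com_amplitude * f["amp"],
            com_noise_sd=p.com_noise_sd * f["state"],
            com_free_sd=p.com_free_sd * f["state"],
            beta1_profile=np.asarray(p.beta1_profile) * f["gain"],
            beta2_profile=np.asarray(p.beta2_profile) * f["gain"],
            fp_noise_sd=p.fp_noise_sd * f["noise"],
            mean_step_width=p.mean_step_width * f["width"])
    elif condition != "normal":
        raise ValueError(f"unknown condition {condition!r}")
    if overrides:
        p = replace(p, **overrides)
    return p


def make_cohort(n_participants: int, n_steps: int = 45, seed: int = 0,
                between_subject_sd: float = 0.12,
                speeds: Sequence[float] = (1.25, 2.08, 2.50, 2.92),
                conditions: Sequence[str] = ("normal", "stabilized"),
                **overrides) -> list[dict]:
    """Parameter sets for a synthetic cohort: speeds x conditions per person.

    Each participant draws multiplicative log-normal factors (SD
    ``between_subject_sd`` on the log scale) for CoM variability, sway
    amplitude, placement noise, step width and gain scale, applied on top
    of the mode presets; ``between_subject_sd=0`` gives identical
    participants (up to trial seeds).

    Returns one dict per participant: ``{"participant": id, "trials":
    [GeneratorParams, ...]}`` with one trial per speed x condition.
    """
    if n_participants < 2:
        raise ValueError("n_participants must be at least 2")
    cohort = []
    for p_idx in range(n_participants):
        prng = np.random.default_rng((seed * 1_000_003 + p_idx) % 2**31)
        fac = np.exp(prng.normal(0.0, between_subject_sd, 5))
        trials = []
        for i_speed, speed in enumerate(speeds):
            mode = "walking" if speed < 1.8 else "running"
            for i_cond, cond in enumerate(conditions):
                t_seed = (seed * 1_000_003 + p_idx * 8191
                          + i_speed * 17 + i_cond * 7 + 1) % 2**31
                p = preset_params(mode, cond, speed=speed, n_steps=n_steps,
                                  seed=t_seed, **overrides)
                p = replace(
                    p,
                    com_noise_sd=p.com_noise_sd * fac[0],
                    com_free_sd=p.com_free_sd * fac[0],
                    com_decouple_sd=p.com_decouple_sd * fac[0],
                    com_amplitude=p.com_amplitude * fac[1],
                    fp_noise_sd=p.fp_noise_sd * fac[2],
                    mean_step_width=p.mean_step_width * fac[3],
                    beta1_profile=np.asarray(p.beta1_profile) * fac[4],
                    beta2_profile=np.asarray(p.beta2_profile) * fac[4])
                trials.append(p)
        cohort.append({"participant": f"p{p_idx:02d}", "trials": trials})
    return cohort
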