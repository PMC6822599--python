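"""Scalar and one-dimensional (per-swing-%) group inference.

Scalar outcomes (step width, step-width variability) use classical paired
t-tests and 2x2 within-subject ANOVA; curve outcomes (the R^2 time-series)
use statistical parametric mapping: a t or F statistic at every node of
the curve with a family-wise threshold at alpha.  Thresholds come from two
independent routes,

* random field theory (RFT): the expected Euler characteristic of the
  excursion set of a smooth stationary field, with the field smoothness
  (FWHM) estimated from the normalized residual gradients, and
* permutation: the (1 - alpha) quantile of the maximum statistic over
  sign flips of the paired/contrast curves, enumerated exhaustively when
  2^n is small.

For the 2x2 within-subject design every effect is a single-df contrast, so
each F curve equals the square of the paired-t curve on that contrast —
which is also how the implementation computes it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

_FOUR_LOG2 = 4.0 * np.log(2.0)
_FWHM_CAP = 1e6


# ----------------------------------------------------------------------
# scalar tests
# ----------------------------------------------------------------------

def paired_t_scalar(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t-test; returns (t, df, two-sided p).

    Zero variance of the differences is degenerate: t is 0 (p = 1) when
    the differences are all zero, +/- inf with p = NaN otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D arrays of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if md == 0:
            return 0.0, df, 1.0
        warnings.warn("paired differences have zero variance; p undefined")
        return float(np.sign(md) * np.inf), df, float("nan")
    t = md / (sd / np.sqrt(n))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


@dataclass
class AnovaTable:
    """Within-subject ANOVA effects plus Bonferroni-adjusted post-hocs."""

    effects: dict[str, dict]                 # name -> {F, df1, df2, p}
    posthoc: dict[str, float] = field(default_factory=dict)


def _contrast_t(c: np.ndarray) -> tuple[float, int, float]:
    """One-sample t of a within-subject contrast against zero."""
    n = c.size
    sd = c.std(ddof=1)
    df = n - 1
    if sd == 0:
        return (0.0, df, 1.0) if c.mean() == 0 else (float(np.inf), df, float("nan"))
    t = c.mean() / (sd / np.sqrt(n))
    return float(t), df, float(2.0 * stats.t.sf(abs(t), df))


def rm_anova_2x2_scalar(data: np.ndarray,
                        factor_names: tuple[str, str] = ("condition", "mode")
                        ) -> AnovaTable:
    """Two-way fully within-subject ANOVA for a 2x2 design.

    ``data`` has shape (participants, 2, 2) with axes (participant,
    factor A level, factor B level).  Each effect has a single degree of
    freedom, so its F equals the squared paired t on the corresponding
    within-subject contrast.  Post-hoc simple effects (A within each B
    level and B within each A level) are Bonferroni adjusted by their
    count.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3 or data.shape[1:] != (2, 2):
        raise ValueError("data must have shape (n_participants, 2, 2)")
    if np.isnan(data).any():
        raise ValueError("missing cells in the repeated-measures design")
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    a_name, b_name = factor_names
    contrasts = {
        a_name: data[:, 0, :].mean(axis=1) - data[:, 1, :].mean(axis=1),
        b_name: data[:, :, 0].mean(axis=1) - data[:, :, 1].mean(axis=1),
        "interaction": (data[:, 0, 0] - data[:, 1, 0]) - (data[:, 0, 1] - data[:, 1, 1]),
    }
    effects = {}
    for name, c in contrasts.items():
        t, df, p = _contrast_t(c)
        effects[name] = {"F": t * t, "df1": 1, "df2": df, "p": p}
    pairs = {
        f"{a_name}@{b_name}=0": (data[:, 0, 0], data[:, 1, 0]),
        f"{a_name}@{b_name}=1": (data[:, 0, 1], data[:, 1, 1]),
        f"{b_name}@{a_name}=0": (data[:, 0, 0], data[:, 0, 1]),
        f"{b_name}@{a_name}=1": (data[:, 1, 0], data[:, 1, 1]),
    }
    posthoc = {}
    for name, (x, y) in pairs.items():
        _, _, p = paired_t_scalar(x, y)
        posthoc[name] = float(min(1.0, p * len(pairs)))
    return AnovaTable(effects=effects, posthoc=posthoc)


def rm_anova_oneway_scalar(data: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA (participants x levels)."""
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    grand = data.mean()
    subj = data.mean(axis=1, keepdims=True)
    cond = data.mean(axis=0, keepdims=True)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_err = np.sum((data - subj - cond + grand) ** 2)
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    F = (ss_cond / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    return {"F": float(F), "df1": df1, "df2": df2,
            "p": float(stats.f.sf(F, df1, df2))}


# ----------------------------------------------------------------------
# random field theory
# ----------------------------------------------------------------------

def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in node units) from normalized residuals.

    Residual curves are normalized nodewise to unit sum of squares; the
    per-gap roughness is the summed squared gradient of the normalized
    residuals, converted to resels via sqrt(lambda / 4 ln 2).  Constant
    residuals have infinite smoothness, capped at 1e6 nodes with a
    warning.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2 or R.shape[1] < 3:
        raise ValueError("need >= 2 residual curves over >= 3 nodes")
    ssq = np.sum(R**2, axis=0)
    if np.any(ssq == 0):
        warnings.warn("residuals vanish at some nodes; smoothness capped")
        return _FWHM_CAP
    eps_n = R / np.sqrt(ssq)
    grad = np.diff(eps_n, axis=1)
    lam = np.sum(grad**2, axis=0)
    resels = np.sqrt(lam / _FOUR_LOG2)
    total = resels.sum()
    if total <= 0:
        warnings.warn("constant residual field; smoothness capped")
        return _FWHM_CAP
    return float(min((R.shape[1] - 1) / total, _FWHM_CAP))


def _ec_density_t(u: float, df: int) -> float:
    """1-D Euler-characteristic density (per resel) of a t field."""
    return np.sqrt(_FOUR_LOG2) / (2.0 * np.pi) * (1.0 + u * u / df) ** (-(df - 1) / 2.0)


def _ec_density_F(u: float, df1: int, df2: int) -> float:
    """1-D EC density of an F field.

    Normalized so that the df1 = 1 case coincides with the two-sided |t|
    field density at sqrt(u) (the exact F = t^2 correspondence).
    """
    k, v = float(df1), float(df2)
    lg = (special.gammaln((v + k - 1.0) / 2.0) - special.gammaln(v / 2.0)
          - special.gammaln(k / 2.0))
    const = 2.0 * np.sqrt(np.pi) * np.exp(lg)
    x = k * u / v
    return (np.sqrt(_FOUR_LOG2) / (2.0 * np.pi) * const
            * x ** ((k - 1.0) / 2.0) * (1.0 + x) ** (-(v + k - 2.0) / 2.0))


def rft_threshold(stat_kind: str, df, fwhm: float, n_nodes: int,
                  alpha: float = 0.05, two_sided: bool = True) -> float:
    """Family-wise critical value of a smooth 1-D statistic field.

    The smallest u at which the expected Euler characteristic of the
    suprathreshold set — the survival probability plus resels times the EC
    density — drops to alpha.  In the infinitely smooth limit this is the
    ordinary single-comparison critical value.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    resels = (n_nodes - 1) / fwhm

    if stat_kind == "t":
        nu = int(df)

        def expected_ec(u):
            ec = stats.t.sf(u, nu) + resels * _ec_density_t(u, nu)
            return (2.0 if two_sided else 1.0) * ec

    elif stat_kind == "F":
        k, v = (int(df[0]), int(df[1])) if np.ndim(df) else (1, int(df))
        if k == 1:
            u_t = rft_threshold("t", v, fwhm, n_nodes, alpha, two_sided=True)
            return u_t * u_t

        def expected_ec(u):
            return stats.f.sf(u, k, v) + resels * _ec_density_F(u, k, v)

    else:
        raise ValueError(f"unknown statistic kind {stat_kind!r}")

    lo, hi = 1e-3, 1e4
    if expected_ec(lo) < alpha:  # pathological: alpha nearly 1
        return lo
    return float(optimize.brentq(lambda u: expected_ec(u) - alpha, lo, hi,
                                 xtol=1e-10, rtol=1e-12))


# ----------------------------------------------------------------------
# SPM curve inference
# ----------------------------------------------------------------------

@dataclass
class SPMResult:
    """A statistic curve over swing percentage with its critical threshold."""

    grid: np.ndarray
    stat_curve: np.ndarray
    stat_kind: str                       # "t" | "F"
    df: tuple
    fwhm: float
    threshold: float
    clusters: list[dict]
    method: str                          # "rft" | "permutation"

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0


def _clusters(grid: np.ndarray, curve: np.ndarray, threshold: float,
              two_sided: bool) -> list[dict]:
    mag = np.abs(curve) if two_sided else curve
    mask = mag > threshold
    out = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for a, b in zip(idx[::2], idx[1::2]):
        seg = mag[a:b]
        out.append({"start": float(grid[a]), "end": float(grid[b - 1]),
                    "max_stat": float(curve[a + int(np.argmax(seg))])})
    return out


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    if 2**n <= 4096:
        bits = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        return 1.0 - 2.0 * bits
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0] = 1.0  # include the identity
    return signs


def _one_sample_curve_t(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    m = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(sd > 0, m / (sd / np.sqrt(n)), 0.0)


def _perm_max_t(D: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Max-|t| null distribution over sign flips of the rows of D."""
    n = D.shape[0]
    S = _sign_matrix(n, n_perm, rng)
    means = S @ D / n
    ssq = np.sum(D**2, axis=0)                       # invariant under sign flips
    var = (ssq[None, :] - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, means / np.sqrt(var / n), 0.0)
    return np.max(np.abs(t), axis=1)


def _one_sample_spm(D: np.ndarray, grid: np.ndarray, alpha: float, method: str,
                    n_perm: int, seed: int) -> SPMResult:
    n = D.shape[0]
    tcurve = _one_sample_curve_t(D)
    resid = D - D.mean(axis=0)
    fwhm = estimate_fwhm(resid)
    if method == "rft":
        thr = rft_threshold("t", n - 1, fwhm, D.shape[1], alpha, two_sided=True)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        max_t = _perm_max_t(D, n_perm, rng)
        thr = float(np.quantile(max_t, 1.0 - alpha, method="higher"))
    else:
        raise ValueError(f"unknown method {method!r}")
    clusters = _clusters(grid, tcurve, thr, two_sided=True)
    return SPMResult(grid=grid, stat_curve=tcurve, stat_kind="t", df=(1, n - 1),
                     fwhm=fwhm, threshold=thr, clusters=clusters, method=method)


def spm_paired_t(A: np.ndarray, B: np.ndarray, grid: np.ndarray | None = None,
                 alpha: float = 0.05, method: str = "rft", n_perm: int = 1024,
                 seed: int = 0) -> SPMResult:
    """Nodewise paired t curve with a family-wise threshold.

    ``A`` and ``B`` are participant x node matrices paired by row.  The
    threshold comes from RFT or from the max-|t| permutation distribution
    over sign flips of the paired differences (exhaustive when 2^n <=
    4096); suprathreshold clusters mark swing regions with significant
    differences.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2:
        raise ValueError("A and B must be matching participant x node matrices")
    if A.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if grid is None:
        grid = np.linspace(0.0, 100.0, A.shape[1])
    return _one_sample_spm(A - B, np.asarray(grid, dtype=float), alpha, method,
                           n_perm, seed)


def spm_rm_anova_2x2(data: np.ndarray, grid: np.ndarray | None = None,
                     alpha: float = 0.05, method: str = "rft", n_perm: int = 1024,
                     seed: int = 0,
                     factor_names: tuple[str, str] = ("condition", "mode")
                     ) -> dict[str, SPMResult]:
    """Nodewise F curves of a 2x2 within design, one per effect.

    ``data`` has shape (participants, 2, 2, nodes).  Every effect is a
    single-df within-subject contrast, so its F curve is the squared
    one-sample t curve of the contrast and its threshold the squared
    two-sided t-field threshold (identical cluster decisions).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4 or data.shape[1:3] != (2, 2):
        raise ValueError("data must have shape (n, 2, 2, nodes)")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if grid is None:
        grid = np.linspace(0.0, 100.0, data.shape[3])
    grid = np.asarray(grid, dtype=float)
    a_name, b_name = factor_names
    contrasts = {
        a_name: data[:, 0, :, :].mean(axis=1) - data[:, 1, :, :].mean(axis=1),
        b_name: data[:, :, 0, :].mean(axis=1) - data[:, :, 1, :].mean(axis=1),
        "interaction": (data[:, 0, 0, :] - data[:, 1, 0, :])
                       - (data[:, 0, 1, :] - data[:, 1, 1, :]),
    }
    out = {}
    for i, (name, D) in enumerate(contrasts.items()):
        t_res = _one_sample_spm(D, grid, alpha, method, n_perm, seed + i)
        f_curve = t_res.stat_curve**2
        f_thr = t_res.threshold**2
        clusters = _clusters(grid, f_curve, f_thr, two_sided=False)
        out[name] = SPMResult(grid=grid, stat_curve=f_curve, stat_kind="F",
                              df=(1, data.shape[0] - 1), fwhm=t_res.fwhm,
                              threshold=f_thr, clusters=clusters, method=method)
    return out
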