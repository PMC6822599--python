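"""Gait-event detection from force-plate data; step segmentation.

Heel strikes and toe offs are derived from the centre of pressure (CoP)
and vertical force.  Two regimes:

* walking (no flight, double support): each heel strike launches a rapid
  mediolateral CoP sweep from the old to the new stance foot; the sweep's
  onset marks the heel strike of the receiving side and its offset the toe
  off of the leaving side.  Sweeps are located on the low-pass-filtered
  ML CoP velocity with sub-sample refinement at half of the local peak.
* running (flight phases): contacts are intervals where the filtered
  vertical force exceeds a threshold (default 20 N, 50 ms debounce), with
  edges refined by linear interpolation; sides are attributed from the ML
  CoP during contact relative to the neighbouring contacts, then forced to
  alternate by majority vote.

Mid-stance of a leg is 50 % of the time between toe off and heel strike of
the contralateral leg — the moment the stance foot is guaranteed
stationary — and serves both as the coordinate origin and as the
foot-placement read-out instant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import lowpass_filter
from .trial_io import AnalysisConfig, TrialRecording


@dataclass
class GaitEvents:
    """Per-side ordered event times in seconds."""

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    mid_stances: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for side in ("left", "right"):
            hs = self.heel_strikes.get(side, np.array([]))
            to = self.toe_offs.get(side, np.array([]))
            if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
                raise ValueError(f"{side} events are not strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for side in ("left", "right"):
            for t in self.heel_strikes.get(side, []):
                rows.append((side, "heel_strike", t))
            for t in self.toe_offs.get(side, []):
                rows.append((side, "toe_off", t))
            for t in self.mid_stances.get(side, []):
                rows.append((side, "mid_stance", t))
        df = pd.DataFrame(rows, columns=["side", "event", "time"])
        return df.sort_values(["time", "side"], kind="stable").reset_index(drop=True)


@dataclass
class Step:
    """One swing phase (toe off to heel strike) with its read-out times.

    ``origin_midstance`` is the mid-stance of the stance foot during this
    swing (the coordinate origin); ``fp_midstance`` is the first mid-stance
    of the swinging side after its landing, where the placement is read.
    """

    swing_side: str
    toe_off: float
    heel_strike: float
    origin_midstance: float
    fp_midstance: float

    def __post_init__(self) -> None:
        if not self.toe_off < self.heel_strike:
            raise ValueError("toe_off must precede heel_strike")
        if not self.origin_midstance < self.fp_midstance:
            raise ValueError("origin mid-stance must precede placement mid-stance")


def _refine_crossing(t: np.ndarray, y: np.ndarray, i: int, level: float,
                     rising: bool) -> float:
    """Linear-interpolated time where y crosses `level` at sample gap i..i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return t[i]
    f = (level - y0) / (y1 - y0)
    f = min(max(f, 0.0), 1.0)
    return t[i] + f * (t[i + 1] - t[i])


def _extrapolate_onset(t: np.ndarray, fz: np.ndarray, a: int, b: int,
                       rising: bool) -> float:
    """Contact edge time: extrapolate the 10-30 %-of-peak flank to zero force.

    The low-pass filter rounds the foot of the loading curve, biasing a
    plain threshold crossing early; the 10-30 % flank is preserved, and
    its linear extrapolation to zero force lands on the true onset to
    within a couple of milliseconds.
    """
    seg = fz[a:b]
    peak = seg.max()
    i_peak = a + int(np.argmax(seg))
    if rising:
        lo = i_peak
        while lo > 0 and fz[lo - 1] > 0.1 * peak:
            lo -= 1
        hi = lo
        while hi < i_peak and fz[hi] < 0.3 * peak:
            hi += 1
    else:
        hi = i_peak
        while hi < len(fz) - 1 and fz[hi + 1] > 0.1 * peak:
            hi += 1
        lo = hi
        while lo > i_peak and fz[lo] < 0.3 * peak:
            lo -= 1
    if hi - lo < 2:
        # flank too short for a fit; fall back to the raw crossing
        idx = max(lo - 1, 0) if rising else min(hi, len(t) - 2)
        return _refine_crossing(t, fz, idx, 0.1 * peak, rising)
    ts = t[lo:hi + 1]
    ys = fz[lo:hi + 1]
    slope, icpt = np.polyfit(ts, ys, 1)
    if slope == 0:
        return float(ts[0])
    return float(-icpt / slope)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))


def detect_events(trial: TrialRecording, config: AnalysisConfig | None = None) -> GaitEvents:
    """Detect heel-strike and toe-off times from CoP/force data."""
    config = config or AnalysisConfig()
    rate = trial.meta.force_rate
    t = trial.force_time
    fz = lowpass_filter(trial.force["fz"], rate, config.filter_cutoff, config.filter_order)
    cop_x = lowpass_filter(trial.force["cop_x"], rate, config.filter_cutoff,
                           config.filter_order)

    if np.max(fz) < config.force_threshold:
        raise ValueError("no contacts: vertical force never exceeds the threshold")

    # flight phases present -> running regime
    has_flight = np.percentile(fz, 5) < 0.25 * np.median(fz[fz > config.force_threshold])
    if has_flight:
        # contact timing is edge-critical: the narrow analysis filter smears
        # the loading onset by tens of ms, so detection uses a wider band
        fz_det = lowpass_filter(trial.force["fz"], rate,
                                min(config.detect_cutoff, 0.45 * rate),
                                config.filter_order)
        return _detect_running(t, fz_det, cop_x, rate, config)
    return _detect_walking(t, cop_x, rate, config)


def _detect_running(t, fz, cop_x, rate, config) -> GaitEvents:
    thr = config.force_threshold
    min_samp = max(1, int(round(config.debounce_ms / 1000.0 * rate)))
    mask = fz > thr
    runs = [r for r in _runs(mask) if r[1] - r[0] >= min_samp]
    if not runs:
        raise ValueError("no contacts: all force bursts shorter than the debounce window")
    # merge runs separated by sub-debounce gaps (chatter at the threshold)
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < min_samp:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    contacts = []
    for a, b in merged:
        on = _extrapolate_onset(t, fz, a, b, rising=True)
        off = _extrapolate_onset(t, fz, a, b, rising=False)
        contacts.append((on, off, a, b))

    # side attribution: ML CoP during mid-contact, relative to neighbours
    ml = np.array([np.mean(cop_x[a + (b - a) // 5: b - (b - a) // 5]) for _, _, a, b in contacts])
    score = np.empty(len(ml))
    for i in range(len(ml)):
        neigh = [ml[j] for j in (i - 1, i + 1) if 0 <= j < len(ml)]
        score[i] = ml[i] - np.mean(neigh)
    # enforce alternation: pick the parity that best matches the scores
    par = np.array([1 if i % 2 == 0 else -1 for i in range(len(ml))])
    if np.sum(score * par) < 0:
        par = -par
    naive = np.sign(score)
    if np.any(naive != par) and np.sum(naive != par) > len(ml) // 4:
        warnings.warn("running side attribution ambiguous; forced alternation")

    hs = {"left": [], "right": []}
    to = {"left": [], "right": []}
    for (on, off, _, _), s in zip(contacts, par):
        side = "right" if s > 0 else "left"
        hs[side].append(on)
        to[side].append(off)
    return GaitEvents(heel_strikes={k: np.asarray(v) for k, v in hs.items()},
                      toe_offs={k: np.asarray(v) for k, v in to.items()})


def _detect_walking(t, cop_x, rate, config) -> GaitEvents:
    vel = np.gradient(cop_x, 1.0 / rate)
    speed = np.abs(vel)
    vmax = np.percentile(speed, 98)
    if vmax <= 0:
        raise ValueError("no contacts: centre of pressure never moves")
    rough = speed > config.sweep_frac * vmax
    min_gap = max(1, int(round(0.1 * rate)))
    runs = [r for r in _runs(rough) if r[1] - r[0] >= max(2, int(round(0.02 * rate)))]
    # merge chattering segments
    merged = [list(runs[0])] if runs else []
    for a, b in runs[1:]:
        if a - merged[-1][1] < min_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    if not merged:
        raise ValueError("no contacts: no CoP sweeps found")

    hs = {"left": [], "right": []}
    to = {"left": [], "right": []}
    n = len(t)
    for a, b in merged:
        seg = speed[a:b]
        peak = seg.max()
        half = 0.5 * peak
        # expand to the half-peak crossings on both sides
        i = a + int(np.argmax(seg))
        lo = i
        while lo > 0 and speed[lo - 1] > half:
            lo -= 1
        hi = i
        while hi < n - 1 and speed[hi + 1] > half:
            hi += 1
        onset = _refine_crossing(t, speed, max(lo - 1, 0), half, rising=True)
        offset = _refine_crossing(t, speed, min(hi, n - 2), half, rising=False)
        direction = np.sign(np.mean(vel[a:b]))
        landing = "right" if direction > 0 else "left"
        leaving = "left" if landing == "right" else "right"
        hs[landing].append(onset)
        to[leaving].append(offset)
    for d in (hs, to):
        for side in d:
            d[side] = np.asarray(sorted(d[side]))
    ev = GaitEvents(heel_strikes=hs, toe_offs=to)
    _check_alternation(ev)
    return ev


def _check_alternation(events: GaitEvents) -> None:
    merged = []
    for side in ("left", "right"):
        merged += [(tt, side) for tt in events.heel_strikes[side]]
    merged.sort()
    sides = [s for _, s in merged]
    bad = sum(1 for a, b in zip(sides, sides[1:]) if a == b)
    if bad:
        warnings.warn(f"{bad} non-alternating heel strikes detected")


def midstance_times(events: GaitEvents) -> GaitEvents:
    """Add mid-stance times: midpoints of the contralateral swing phases.

    For each contralateral toe-off -> heel-strike pair the stance side
    receives a mid-stance at 50 % of that interval.  Unmatched pairs at the
    trial edges are skipped.
    """
    mid = {}
    for side, contra in (("left", "right"), ("right", "left")):
        tos = events.toe_offs.get(contra, np.array([]))
        hss = events.heel_strikes.get(contra, np.array([]))
        times = []
        for to in tos:
            nxt = hss[hss > to]
            if nxt.size == 0:
                continue
            hs = nxt[0]
            # guard against a toe-off/heel-strike inversion at the edges
            prior_to = tos[(tos > to) & (tos < hs)]
            if prior_to.size:
                continue
            times.append(0.5 * (to + hs))
        mid[side] = np.asarray(times)
    return GaitEvents(heel_strikes=events.heel_strikes, toe_offs=events.toe_offs,
                      mid_stances=mid)


def segment_steps(events: GaitEvents) -> list[Step]:
    """One Step per complete swing with both mid-stance read-outs.

    A swing of side s (toe off to the next heel strike of s) is kept when
    the contralateral leg has a mid-stance inside the swing (the origin)
    and side s has a mid-stance after its landing (the placement
    read-out).  Boundary swings lacking either are dropped.
    """
    if not events.mid_stances:
        raise ValueError("mid-stances not computed; call midstance_times first")
    steps: list[Step] = []
    for side, contra in (("left", "right"), ("right", "left")):
        tos = events.toe_offs.get(side, np.array([]))
        hss = events.heel_strikes.get(side, np.array([]))
        own_mid = events.mid_stances.get(side, np.array([]))
        contra_mid = events.mid_stances.get(contra, np.array([]))
        for to in tos:
            nxt = hss[hss > to]
            if nxt.size == 0:
                continue
            hs = nxt[0]
            origin = contra_mid[(contra_mid > to) & (contra_mid < hs)]
            if origin.size != 1:
                continue
            fp = own_mid[own_mid > hs]
            if fp.size == 0:
                continue
            steps.append(Step(swing_side=side, toe_off=float(to), heel_strike=float(hs),
                              origin_midstance=float(origin[0]), fp_midstance=float(fp[0])))
    steps.sort(key=lambda s: s.toe_off)
    return steps
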