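"""Force-plate filtering and trunk centre-of-mass state estimation.

Ground-reaction-force and centre-of-pressure channels are low-pass filtered
with a zero-phase (forward + backward) Butterworth filter before event
detection.  Kinematic marker data are deliberately left unfiltered; the
mediolateral (ML) trunk CoM is approximated by the mean of the three trunk
markers and its velocity by the discrete first derivative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal


@dataclass
class ComState:
    """ML trunk CoM position (m) and velocity (m/s) at the kinematic rate."""

    position: np.ndarray
    velocity: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        if len(self.position) != len(self.velocity):
            raise ValueError("position and velocity must have equal length")

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.position)) / self.rate


def lowpass_filter(series: np.ndarray, rate: float, cutoff: float = 10.0,
                   order: int = 2) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter.

    A recursive filter of the given order is applied forward and backward
    (``filtfilt``), which doubles the effective magnitude order and cancels
    phase lag; the gain at the cutoff frequency is therefore 0.5 rather
    than 1/sqrt(2).  Edges are handled with reflective padding of three
    filter lengths.
    """
    series = np.asarray(series, dtype=float)
    if not 0 < cutoff < rate / 2:
        raise ValueError(
            f"cutoff must lie in (0, Nyquist={rate / 2:g}) Hz, got {cutoff:g}"
        )
    if series.size <= 3 * order:
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(order, cutoff, btype="low", fs=rate, output="sos")
    padlen = min(series.size - 1, 3 * max(12, 2 * order * 3))
    return signal.sosfiltfilt(sos, series, padlen=padlen)


def trunk_com(markers: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """ML trunk CoM position: pointwise mean ML of the three trunk markers.

    Input arrays may be (n, 3) marker positions or 1-D ML series.  Marker
    dropout (non-finite samples) is rejected; no gap filling is attempted.
    """
    if len(markers) != 3:
        raise ValueError(f"expected exactly 3 trunk markers, got {len(markers)}")
    ml = []
    for i, m in enumerate(markers):
        m = np.asarray(m, dtype=float)
        x = m[:, 0] if m.ndim == 2 else m
        if not np.all(np.isfinite(x)):
            gaps = np.flatnonzero(~np.isfinite(x))
            raise ValueError(
                f"marker {i + 1} has {gaps.size} non-finite samples "
                f"(first at index {gaps[0]}); gap filling is not supported"
            )
        ml.append(x)
    if len({len(x) for x in ml}) != 1:
        raise ValueError("trunk marker series must have equal length")
    return np.mean(ml, axis=0)


def com_velocity(position: np.ndarray, rate: float) -> np.ndarray:
    """First derivative of the CoM position series, m/s.

    Central differences in the interior, one-sided at the ends.
    """
    position = np.asarray(position, dtype=float)
    if position.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(position, 1.0 / rate)


def com_state(trial, config=None) -> ComState:
    """Convenience wrapper: ComState from a :class:`TrialRecording`."""
    pos = trunk_com([trial.markers[f"trunk_{i}"] for i in (1, 2, 3)])
    vel = com_velocity(pos, trial.meta.kin_rate)
    return ComState(position=pos, velocity=vel, rate=trial.meta.kin_rate)
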