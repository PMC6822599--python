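"""Trial recordings on disk and in memory, plus run configuration.

A trial is stored as three plain-text files sharing a stem:

``<stem>_kin.csv``
    Kinematic channels at ``kin_rate``: ``time`` plus ``<marker>_{x,y,z}``
    columns for the three trunk markers and both heel markers.
``<stem>_force.csv``
    Force-plate channels at ``force_rate``: ``time``, vertical force ``fz``
    (N) and centre of pressure ``cop_x``/``cop_y`` (m).
``<stem>_meta.yaml``
    Participant id, locomotion mode, condition, belt speed, sample rates and
    the position units of the kinematic/CoP columns (``m`` or ``mm``).

Coordinate convention: x is mediolateral (positive to the participant's
right), y is anterior-posterior (positive forward), z is vertical.  Time is
in seconds from the start of the trial; the kinematic and force time bases
share their origin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MARKER_NAMES = ("trunk_1", "trunk_2", "trunk_3", "heel_left", "heel_right")
FORCE_COLUMNS = ("fz", "cop_x", "cop_y")
AXES = ("x", "y", "z")


@dataclass
class TrialMeta:
    """Metadata attached to one treadmill trial."""

    participant: str = "p00"
    mode: str = "walking"            # walking | running
    condition: str = "normal"        # normal | stabilized
    speed: float = 1.25              # belt speed, m/s
    kin_rate: float = 100.0          # marker sampling rate, samples/s
    force_rate: float = 1000.0       # force-plate sampling rate, samples/s

    def __post_init__(self) -> None:
        if self.mode not in ("walking", "running"):
            raise ValueError(f"mode must be 'walking' or 'running', got {self.mode!r}")
        if self.condition not in ("normal", "stabilized"):
            raise ValueError(
                f"condition must be 'normal' or 'stabilized', got {self.condition!r}"
            )
        if self.kin_rate <= 0 or self.force_rate <= 0:
            raise ValueError("sampling rates must be positive")


@dataclass
class TrialRecording:
    """Synchronised marker and force-plate time-series for one trial.

    ``markers`` maps each marker name to an (n, 3) position array in metres
    at ``meta.kin_rate``; ``force`` holds ``fz`` (N), ``cop_x`` and
    ``cop_y`` (m) arrays at ``meta.force_rate``.
    """

    markers: dict[str, np.ndarray]
    force: dict[str, np.ndarray]
    meta: TrialMeta

    def __post_init__(self) -> None:
        missing = [m for m in MARKER_NAMES if m not in self.markers]
        if missing:
            raise ValueError(f"missing marker channels: {', '.join(missing)}")
        lengths = {len(v) for v in self.markers.values()}
        if len(lengths) != 1:
            raise ValueError("marker arrays must all have the same length")
        for name, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r} must be an (n, 3) array")
        missing_f = [c for c in FORCE_COLUMNS if c not in self.force]
        if missing_f:
            raise ValueError(f"missing force channels: {', '.join(missing_f)}")
        flens = {len(v) for v in self.force.values()}
        if len(flens) != 1:
            raise ValueError("force arrays must all have the same length")
        # durations must agree to within one force sample
        kin_dur = len(next(iter(self.markers.values()))) / self.meta.kin_rate
        force_dur = len(self.force["fz"]) / self.meta.force_rate
        if abs(kin_dur - force_dur) > 1.0 / self.meta.force_rate + 1e-9:
            raise ValueError(
                f"kinematic ({kin_dur:.4f} s) and force ({force_dur:.4f} s) "
                "durations disagree by more than one force sample"
            )

    @property
    def kin_time(self) -> np.ndarray:
        n = len(next(iter(self.markers.values())))
        return np.arange(n) / self.meta.kin_rate

    @property
    def force_time(self) -> np.ndarray:
        return np.arange(len(self.force["fz"])) / self.meta.force_rate

    @property
    def duration(self) -> float:
        return len(self.force["fz"]) / self.meta.force_rate


@dataclass
class AnalysisConfig:
    """Tunable knobs of the analysis pipeline.

    The force low-pass filter (``filter_cutoff``/``filter_order``) is a
    zero-phase bidirectional Butterworth; kinematic data are never filtered.
    ``grid_size`` nodes span 0-100 % of the swing phase inclusive.
    """

    filter_cutoff: float = 10.0      # Hz
    filter_order: int = 2
    grid_size: int = 101             # swing-percentage nodes, 0..100 inclusive
    alpha: float = 0.05
    force_threshold: float = 20.0    # N, contact threshold for running
    detect_cutoff: float = 45.0      # Hz, force filter for contact-edge timing
    debounce_ms: float = 50.0        # minimum contact/flight duration
    sweep_frac: float = 0.4          # CoP-velocity fraction locating walking transitions
    fp_window_ms: float = 25.0       # +/- averaging window for foot-placement read-out
    min_steps: int = 4               # minimum steps per leg for a regression
    seed: int = 0
    speeds: tuple = (1.25, 2.08, 2.50, 2.92)
    walking_speed: float = 1.25      # default contrast cells
    running_speed: float = 2.50

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ValueError("grid_size must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def grid(self) -> np.ndarray:
        """Swing-percentage nodes, 0 to 100 inclusive."""
        return np.linspace(0.0, 100.0, self.grid_size)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "speeds" in known:
            known["speeds"] = tuple(known["speeds"])
        return cls(**known)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["speeds"] = list(d["speeds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def write_trial(trial: TrialRecording, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write a trial to ``<out_dir>/<stem>_{kin,force}.csv`` + metadata YAML."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    kin = {"time": trial.kin_time}
    for name in MARKER_NAMES:
        for j, ax in enumerate(AXES):
            kin[f"{name}_{ax}"] = trial.markers[name][:, j]
    kin_path = out_dir / f"{stem}_kin.csv"
    pd.DataFrame(kin).to_csv(kin_path, index=False, float_format="%.9g")

    force = {"time": trial.force_time}
    for c in FORCE_COLUMNS:
        force[c] = trial.force[c]
    force_path = out_dir / f"{stem}_force.csv"
    pd.DataFrame(force).to_csv(force_path, index=False, float_format="%.9g")

    meta_path = out_dir / f"{stem}_meta.yaml"
    meta = asdict(trial.meta)
    meta["units"] = "m"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return {"kin": kin_path, "force": force_path, "meta": meta_path}


def read_trial(path: str | Path, stem: str | None = None) -> TrialRecording:
    """Read a trial written by :func:`write_trial`.

    ``path`` may be the directory (with ``stem`` given) or the
    ``*_meta.yaml`` file itself.  Positions in millimetres (``units: mm``
    in the metadata) are converted to metres.
    """
    path = Path(path)
    if path.is_dir():
        if stem is None:
            raise ValueError("stem is required when path is a directory")
        meta_path = path / f"{stem}_meta.yaml"
    else:
        meta_path = path
        stem = path.name.removesuffix("_meta.yaml")
        path = path.parent
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file not found: {meta_path}")
    with open(meta_path) as fh:
        raw = yaml.safe_load(fh)
    units = raw.pop("units", "m")
    if units not in ("m", "mm"):
        raise ValueError(f"unsupported position units {units!r}")
    scale = 1e-3 if units == "mm" else 1.0
    meta = TrialMeta(**{k: v for k, v in raw.items() if k in TrialMeta.__dataclass_fields__})

    kin = pd.read_csv(path / f"{stem}_kin.csv")
    markers: dict[str, np.ndarray] = {}
    missing: list[str] = []
    for name in MARKER_NAMES:
        cols = [f"{name}_{ax}" for ax in AXES]
        if not all(c in kin.columns for c in cols):
            missing.append(name)
            continue
        markers[name] = kin[cols].to_numpy(dtype=float) * scale
    if missing:
        raise ValueError(f"missing marker channels: {', '.join(missing)}")

    force_df = pd.read_csv(path / f"{stem}_force.csv")
    missing_f = [c for c in FORCE_COLUMNS if c not in force_df.columns]
    if missing_f:
        raise ValueError(f"missing force channels: {', '.join(missing_f)}")
    force = {
        "fz": force_df["fz"].to_numpy(dtype=float),
        "cop_x": force_df["cop_x"].to_numpy(dtype=float) * scale,
        "cop_y": force_df["cop_y"].to_numpy(dtype=float) * scale,
    }
    return TrialRecording(markers=markers, force=force, meta=meta)


def write_results(results: "object", out_dir: str | Path) -> dict[str, Path]:
    """Write study results as tidy CSV tables plus a JSON summary.

    ``results`` is a :class:`stepstab.pipeline.StudyResults`; the import is
    deferred to keep this module free of pipeline dependencies.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    curves = results.fit_table()
    paths["fits"] = out_dir / "fit_curves.csv"
    curves.to_csv(paths["fits"], index=False)

    metrics = results.metrics_table()
    paths["metrics"] = out_dir / "step_metrics.csv"
    metrics.to_csv(paths["metrics"], index=False)

    spm = results.spm_table()
    paths["spm_curves"] = out_dir / "spm_curves.csv"
    spm.to_csv(paths["spm_curves"], index=False)

    clusters = results.cluster_table()
    paths["spm_clusters"] = out_dir / "spm_clusters.csv"
    clusters.to_csv(paths["spm_clusters"], index=False)

    paths["summary"] = out_dir / "summary.json"
    with open(paths["summary"], "w") as fh:
        json.dump(results.summary(), fh, indent=2)
    return paths
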