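"""Single-wavelength luminal Ca²⁺ sensor model.

An ER-targeted genetically encoded sensor (R-CEPIA1er type) reports free
luminal [Ca²⁺] through a one-site binding isotherm.  With the saturated
fluorescence ``F_max`` (ionomycin + high bath Ca²⁺) and the depleted
fluorescence ``F_min`` (store emptied with caffeine) recorded at the end of
each experiment, fluorescence converts to concentration as

    [Ca²⁺] = K_d · (F − F_min) / (F_max − F)

with the sensor dissociation constant K_d = 609 μM.  This module owns the
forward and inverse transforms and the estimation of ``F_min``/``F_max``
from calibration epochs; everything works in μM and AU.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CalibrationEpochAbsentError,
    DegenerateCalibrationError,
    DomainError,
    InvalidCalibrationError,
)

#: Sensor Ca²⁺ dissociation constant, μM.
SENSOR_KD_UM = 609.0

#: Recognised protocol epoch labels.
EPOCH_LABELS = frozenset(
    {
        "baseline",
        "caffeine",
        "washout",
        "ruthenium_red",
        "tetracaine",
        "ionomycin_fmax",
        "caffeine_fmin",
        "mg_block",
        "mg_relief",
    }
)


@dataclass(frozen=True)
class ProtocolEvent:
    """One pharmacological epoch of the recording protocol.

    ``agent_concentration`` is free-form metadata (e.g. ``"5 mM"``); it is
    carried through but never interpreted.
    """

    label: str
    t_start: float
    t_end: float
    agent_concentration: str | None = None

    def __post_init__(self) -> None:
        if self.label not in EPOCH_LABELS:
            raise ValueError(f"unknown epoch label {self.label!r}")
        if not self.t_start < self.t_end:
            raise ValueError("epoch requires t_start < t_end")

    def to_dict(self) -> dict:
        d = {"label": self.label, "t_start": self.t_start, "t_end": self.t_end}
        if self.agent_concentration is not None:
            d["agent_concentration"] = self.agent_concentration
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolEvent":
        return cls(
            label=d["label"],
            t_start=float(d["t_start"]),
            t_end=float(d["t_end"]),
            agent_concentration=d.get("agent_concentration"),
        )


@dataclass(frozen=True)
class SensorParams:
    """Calibration constants of the luminal sensor (μM / AU)."""

    f_min: float
    f_max: float
    kd_sensor: float = SENSOR_KD_UM

    def __post_init__(self) -> None:
        if not self.kd_sensor > 0:
            raise InvalidCalibrationError("kd_sensor must be positive")
        if not np.isfinite(self.f_min) or not np.isfinite(self.f_max):
            raise InvalidCalibrationError("f_min/f_max must be finite")
        if not self.f_max > self.f_min >= 0:
            raise InvalidCalibrationError("requires f_max > f_min >= 0")


@dataclass
class FluorescenceTrace:
    """Raw sensor time series with protocol epoch annotations.

    ``time`` is in seconds, strictly increasing (nominally 20 ms line-scan
    sampling); ``fluorescence`` in arbitrary units.
    """

    time: np.ndarray
    fluorescence: np.ndarray
    epochs: list[ProtocolEvent] = field(default_factory=list)
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must be equal-length 1-D")
        if len(self.time) < 2 or not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("fluorescence must be finite")
        t0, t1 = self.time[0], self.time[-1]
        dt = float(np.median(np.diff(self.time)))
        # an epoch may end one sample period past the last sample (half-open)
        for ev in self.epochs:
            if ev.t_start < t0 - 1e-9 or ev.t_end > t1 + dt + 1e-9:
                raise ValueError(f"epoch {ev.label} outside trace time range")

    def epoch(self, label: str) -> ProtocolEvent | None:
        """First epoch with the given label, or None."""
        for ev in self.epochs:
            if ev.label == label:
                return ev
        return None

    def epoch_mask(self, ev: ProtocolEvent) -> np.ndarray:
        return (self.time >= ev.t_start) & (self.time < ev.t_end)

    # ---- file I/O ---------------------------------------------------------

    def to_csv(self, path: str | Path, epochs_path: str | Path | None = None) -> None:
        """Write `time_s,fluorescence_au` CSV plus a sidecar epoch JSON.

        If ``epochs_path`` is None it defaults to ``<path stem>.epochs.json``.
        """
        path = Path(path)
        pd.DataFrame(
            {"time_s": self.time, "fluorescence_au": self.fluorescence}
        ).to_csv(path, index=False)
        if epochs_path is None:
            epochs_path = path.with_suffix("").with_suffix(".epochs.json")
        Path(epochs_path).write_text(
            json.dumps([ev.to_dict() for ev in self.epochs], indent=1)
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        epochs_path: str | Path | None = None,
        cell_id: str | None = None,
    ) -> "FluorescenceTrace":
        """Read a trace CSV/TSV.

        Epochs come either from the sidecar JSON (default
        ``<stem>.epochs.json`` if present) or from an optional third
        ``epoch`` column of contiguous labels.
        """
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep)
        if not {"time_s", "fluorescence_au"} <= set(df.columns):
            raise ValueError("trace file needs columns time_s,fluorescence_au")
        epochs: list[ProtocolEvent] = []
        if epochs_path is None:
            candidate = path.with_suffix("").with_suffix(".epochs.json")
            epochs_path = candidate if candidate.exists() else None
        if epochs_path is not None:
            raw = json.loads(Path(epochs_path).read_text())
            epochs = [ProtocolEvent.from_dict(d) for d in raw]
        elif "epoch" in df.columns:
            epochs = _epochs_from_column(
                df["time_s"].to_numpy(), df["epoch"].astype(str).to_numpy()
            )
        return cls(
            time=df["time_s"].to_numpy(),
            fluorescence=df["fluorescence_au"].to_numpy(),
            epochs=epochs,
            cell_id=cell_id or path.stem,
        )


def _epochs_from_column(time: np.ndarray, labels: np.ndarray) -> list[ProtocolEvent]:
    """Collapse a per-sample label column into contiguous epoch events."""
    events: list[ProtocolEvent] = []
    dt = float(np.median(np.diff(time)))
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            lab = labels[start]
            if lab in EPOCH_LABELS:
                events.append(
                    ProtocolEvent(lab, float(time[start]), float(time[i - 1]) + dt)
                )
            start = i
    return events


def robust_mean(x: np.ndarray, trim_frac: float = 0.02) -> float:
    """Mean after discarding the top and bottom ``trim_frac`` of samples.

    Guards plateau averages against onset drift and stray outliers.
    """
    x = np.sort(np.asarray(x, dtype=float))
    k = int(np.floor(trim_frac * len(x)))
    if len(x) - 2 * k < 1:
        k = 0
    return float(np.mean(x[k : len(x) - k]))


def estimate_calibration(
    trace: FluorescenceTrace,
    kd_sensor: float = SENSOR_KD_UM,
    trim_frac: float = 0.02,
    fmin_tail_frac: float = 0.25,
) -> SensorParams:
    """Estimate ``F_min``/``F_max`` from the trace's calibration epochs.

    ``F_max`` is the robust mean over the ionomycin epoch.  ``F_min`` uses
    only the last ``fmin_tail_frac`` of the depletion (caffeine) epoch: the
    store takes time to empty, so the early part of the epoch still carries
    signal and only the tail is a plateau.
    """
    ion = trace.epoch("ionomycin_fmax")
    if ion is None:
        raise CalibrationEpochAbsentError("no ionomycin_fmax epoch in trace")
    dep = trace.epoch("caffeine_fmin") or trace.epoch("caffeine")
    if dep is None:
        raise CalibrationEpochAbsentError("no caffeine_fmin/caffeine epoch in trace")

    f_max = robust_mean(trace.fluorescence[trace.epoch_mask(ion)], trim_frac)
    tail_start = dep.t_end - fmin_tail_frac * (dep.t_end - dep.t_start)
    tail = (trace.time >= tail_start) & (trace.time < dep.t_end)
    if not tail.any():
        raise CalibrationEpochAbsentError("Fmin epoch contains no samples")
    f_min = robust_mean(trace.fluorescence[tail], trim_frac)

    if not f_max > f_min:
        raise DegenerateCalibrationError(
            f"estimated f_max ({f_max:.1f}) <= f_min ({f_min:.1f})"
        )
    return SensorParams(f_min=f_min, f_max=f_max, kd_sensor=kd_sensor)


def fluorescence_to_ca(
    f: np.ndarray | float, params: SensorParams, clip_warn: bool = True
) -> np.ndarray | float:
    """Convert fluorescence (AU) to free luminal [Ca²⁺] (μM).

    Values outside ``[f_min, f_max)`` are clamped before conversion (noise
    routinely pushes samples past the calibration plateaus; clamping keeps
    the trace full-length for differentiation).  A warning is emitted when
    any sample is clamped and ``clip_warn`` is set.
    """
    f_arr = np.asarray(f, dtype=float)
    eps = 1e-6 * (params.f_max - params.f_min)
    lo, hi = params.f_min, params.f_max - eps
    n_out = int(np.count_nonzero((f_arr < lo) | (f_arr > hi)))
    if n_out and clip_warn:
        warnings.warn(
            f"{n_out} fluorescence samples outside [f_min, f_max); clamped",
            stacklevel=2,
        )
    fc = np.clip(f_arr, lo, hi)
    ca = params.kd_sensor * (fc - params.f_min) / (params.f_max - fc)
    return float(ca) if np.isscalar(f) else ca


def ca_to_fluorescence(
    ca: np.ndarray | float, params: SensorParams
) -> np.ndarray | float:
    """Forward sensor transform: free [Ca²⁺] (μM) to fluorescence (AU).

    Algebraic inverse of :func:`fluorescence_to_ca`; used by the simulator.
    """
    ca_arr = np.asarray(ca, dtype=float)
    if np.any(ca_arr < 0):
        raise DomainError("concentration must be non-negative")
    f = params.f_min + (params.f_max - params.f_min) * ca_arr / (
        ca_arr + params.kd_sensor
    )
    return float(f) if np.isscalar(ca) else f
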