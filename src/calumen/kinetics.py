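"""From calibrated Ca²⁺ traces to uptake-rate-versus-load curves.

The pump's transport rate is read out as the first derivative of the
luminal [Ca²⁺] during store refilling, plotted against the instantaneous
load.  This module segments refill phases (post-caffeine with the release
channel blocked, or the rising limb between spontaneous waves), excludes
the caffeine-washout contamination window, smooths and differentiates the
trace, and summarises cohorts by load bin.

All loads are mM and all rates mM/s here; the sensor/buffering modules
hand over μM and the conversion happens when building a :class:`CaTrace`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import InsufficientDataError, NoUptakeError
from .sensor import ProtocolEvent

#: Default load bins (mM); "intermediate" differs per profile in the
#: cohort defaults (0.3-0.4 for the headline comparison).
DEFAULT_BINS: dict[str, tuple[float, float]] = {
    "low": (0.05, 0.2),
    "intermediate": (0.3, 0.4),
    "high": (0.6, 0.8),
}

#: Post-caffeine washout exclusion, s.
WASHOUT_EXCLUSION_S = 1.0


@dataclass
class CaTrace:
    """Calibrated luminal Ca²⁺ time series (μM), free and optionally total.

    ``ca_total`` is present iff the calsequestrin correction is enabled;
    :meth:`load_mm` then reports total Ca as the load variable, otherwise
    free Ca, both converted to mM.
    """

    time: np.ndarray
    ca_free: np.ndarray
    ca_total: np.ndarray | None = None
    epochs: list[ProtocolEvent] = field(default_factory=list)
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ca_free = np.asarray(self.ca_free, dtype=float)
        if self.time.shape != self.ca_free.shape:
            raise ValueError("time and ca_free must have equal length")
        if np.any(self.ca_free < 0):
            raise ValueError("ca_free must be non-negative")
        if self.ca_total is not None:
            self.ca_total = np.asarray(self.ca_total, dtype=float)
            if self.ca_total.shape != self.time.shape:
                raise ValueError("ca_total must match trace length")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def load_mm(self) -> np.ndarray:
        """Load variable in mM: total Ca if buffered, else free Ca."""
        c = self.ca_total if self.ca_total is not None else self.ca_free
        return c / 1000.0

    def epoch(self, label: str) -> ProtocolEvent | None:
        for ev in self.epochs:
            if ev.label == label:
                return ev
        return None


@dataclass(frozen=True)
class Segment:
    """A half-open analysis window [t_start, t_end) within a trace."""

    t_start: float
    t_end: float
    kind: str = "refill"
    segment_id: int = 0

    def mask(self, time: np.ndarray) -> np.ndarray:
        return (time >= self.t_start) & (time < self.t_end)


@dataclass
class UptakeCurve:
    """Paired (load, uptake rate) points from one cell.

    Points are ordered by ascending load.  ``smoothing_meta`` records the
    derivative estimator so every downstream artefact can cite it.
    """

    load: np.ndarray  # mM
    rate: np.ndarray  # mM/s
    source_segment: str = ""
    cell_id: str = "cell"
    smoothing_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.load = np.asarray(self.load, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.load.shape != self.rate.shape:
            raise ValueError("load and rate must have equal length")
        if len(self.load) < 10:
            raise InsufficientDataError("uptake curve needs at least 10 points")
        if not (np.all(np.isfinite(self.load)) and np.all(np.isfinite(self.rate))):
            raise ValueError("uptake curve must be finite")


@dataclass
class BinSummary:
    """Across-cell mean ± SEM of per-cell bin-averaged uptake rates."""

    bin_label: str
    bin_edges: tuple[float, float]
    mean_rate: float
    sem_rate: float
    n_cells: int

    def to_dict(self) -> dict:
        return {
            "bin_label": self.bin_label,
            "bin_min_mM": self.bin_edges[0],
            "bin_max_mM": self.bin_edges[1],
            "mean_rate_mM_per_s": self.mean_rate,
            "sem_rate_mM_per_s": self.sem_rate,
            "n_cells": self.n_cells,
        }


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def extract_refill_segment(
    trace: CaTrace,
    washout_exclusion_s: float = WASHOUT_EXCLUSION_S,
    plateau_frac: float = 0.99,
    min_plateau_mm: float = 0.1,
    min_rise_mm: float = 0.05,
) -> Segment:
    """Locate the store-refill window after caffeine depletion.

    The window opens at release-channel blockade (ruthenium red onset) or
    caffeine washout — whichever is later once the first
    ``washout_exclusion_s`` seconds after washout are discarded (residual
    caffeine contaminates the first second of reuptake) — and closes when
    the trace reaches ``plateau_frac`` of its terminal plateau.

    Raises :class:`NoUptakeError` when no refill exists (pump inhibited:
    the trace stays depleted), with the reason in the message.
    """
    caff = trace.epoch("caffeine")
    rr = trace.epoch("ruthenium_red") or trace.epoch("tetracaine")
    if caff is None or rr is None:
        raise InsufficientDataError(
            "refill extraction needs caffeine followed by ruthenium_red/tetracaine"
        )
    if rr.t_start < caff.t_start:
        raise InsufficientDataError("ruthenium_red must follow caffeine")

    t_open = max(rr.t_start, caff.t_end + washout_exclusion_s)
    t_close = rr.t_end
    load = trace.load_mm()
    m = (trace.time >= t_open) & (trace.time < t_close)
    if m.sum() < 3:
        raise InsufficientDataError("refill window contains too few samples")
    t_win, c_win = trace.time[m], load[m]

    n_tail = max(3, int(0.1 * len(c_win)))
    plateau = float(np.median(c_win[-n_tail:]))
    c0 = float(np.median(c_win[: max(3, len(c_win) // 50)]))
    if plateau < min_plateau_mm or plateau - c0 < min_rise_mm:
        raise NoUptakeError(
            f"no refill detected (start {c0:.3f} mM, plateau {plateau:.3f} mM)"
        )

    above = np.nonzero(c_win >= plateau_frac * plateau)[0]
    t_end = float(t_win[above[0]]) if len(above) else float(t_win[-1])
    if t_end <= t_open:
        t_end = float(t_win[-1])
    return Segment(t_start=t_open, t_end=t_end, kind="refill")


def detect_wave_refills(
    trace: CaTrace,
    min_duration_s: float = 1.0,
    prominence_frac: float = 0.10,
    smoothing_window_s: float = 0.5,
) -> list[Segment]:
    """Find the rising limb of each spontaneous release–reuptake wave.

    Requires a ``mg_relief`` epoch (waves appear after relieving the Mg²⁺
    block of the release channel).  Nadirs and peaks are located on the
    smoothed load with prominence ≥ ``prominence_frac`` of the trace range;
    each maximal nadir→peak window at least ``min_duration_s`` long becomes
    a refill segment.  Returns an empty list when no waves qualify.
    """
    relief = trace.epoch("mg_relief")
    if relief is None:
        raise InsufficientDataError("wave detection needs an mg_relief epoch")
    m = (trace.time >= relief.t_start) & (trace.time < relief.t_end)
    t, c = trace.time[m], trace.load_mm()[m]
    if len(c) < 20:
        return []
    win = _odd_window(smoothing_window_s, float(np.median(np.diff(t))), len(c))
    cs = savgol_filter(c, win, 2)
    rng = float(cs.max() - cs.min())
    if rng <= 0:
        return []
    prom = prominence_frac * rng
    peaks, _ = find_peaks(cs, prominence=prom)
    nadirs, _ = find_peaks(-cs, prominence=prom)
    segments: list[Segment] = []
    for nad in nadirs:
        later = peaks[peaks > nad]
        if not len(later):
            break
        pk = later[0]
        if t[pk] - t[nad] >= min_duration_s:
            segments.append(
                Segment(
                    t_start=float(t[nad]),
                    t_end=float(t[pk]),
                    kind="wave_refill",
                    segment_id=len(segments),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# differentiation and summaries
# ---------------------------------------------------------------------------


def _odd_window(window_s: float, dt: float, n: int) -> int:
    w = int(round(window_s / dt))
    w = max(5, w | 1)
    if w > n:
        w = (n - 1) | 1 if n > 5 else 5
    return w


def compute_uptake_curve(
    trace: CaTrace,
    segment: Segment,
    window_s: float = 0.5,
    polyorder: int = 2,
) -> UptakeCurve:
    """Smoothed derivative of the load over a refill segment.

    A local quadratic (Savitzky–Golay) filter of width ``window_s``
    estimates both the smoothed load and its time derivative; the curve is
    the (load, d load/dt) pairing re-ordered by ascending load.
    """
    m = segment.mask(trace.time)
    if m.sum() < 20:
        raise InsufficientDataError(
            f"segment has {int(m.sum())} samples; need at least 20"
        )
    t = trace.time[m]
    c = trace.load_mm()[m]
    dt = float(np.median(np.diff(t)))
    win = _odd_window(window_s, dt, len(c))
    c_s = savgol_filter(c, win, polyorder)
    rate = savgol_filter(c, win, polyorder, deriv=1, delta=dt)
    # the filter is one-sided near the segment ends and the derivative is
    # biased by whatever kink bounds the segment (washout, wave nadir/peak);
    # drop half a window at each edge when enough samples remain
    half = win // 2
    if len(c_s) - 2 * half >= 20:
        sl = slice(half, len(c_s) - half)
        c_s, rate = c_s[sl], rate[sl]
    order = np.argsort(c_s, kind="stable")
    return UptakeCurve(
        load=c_s[order],
        rate=rate[order],
        source_segment=f"{segment.kind}[{segment.t_start:.2f},{segment.t_end:.2f})",
        cell_id=trace.cell_id,
        smoothing_meta={
            "method": "savgol",
            "window_s": window_s,
            "window_samples": win,
            "polyorder": polyorder,
        },
    )


def merge_curves(curves: list[UptakeCurve]) -> UptakeCurve:
    """Pool several segments of one cell into a single load-ordered curve."""
    if not curves:
        raise InsufficientDataError("no curves to merge")
    load = np.concatenate([c.load for c in curves])
    rate = np.concatenate([c.rate for c in curves])
    order = np.argsort(load, kind="stable")
    return UptakeCurve(
        load=load[order],
        rate=rate[order],
        source_segment="+".join(c.source_segment for c in curves),
        cell_id=curves[0].cell_id,
        smoothing_meta=curves[0].smoothing_meta,
    )


def max_rate_and_load(
    curve: UptakeCurve, plateau_rate_frac: float = 0.05
) -> tuple[float, float]:
    """Maximum uptake rate and maximum load of one cell.

    ``max_load`` is the load at which the rate first falls below
    ``plateau_rate_frac`` of the maximum on the descending (high-load) limb
    — the terminal plateau where net uptake ceases.  When the rate never
    decays that far, the largest observed load is reported.
    """
    i_max = int(np.argmax(curve.rate))
    max_rate = float(curve.rate[i_max])
    if max_rate <= 0:
        return 0.0, float(curve.load.max())
    desc = np.nonzero(curve.rate[i_max:] < plateau_rate_frac * max_rate)[0]
    if len(desc):
        max_load = float(curve.load[i_max + desc[0]])
    else:
        max_load = float(curve.load.max())
    return max_rate, max_load


def bin_rates(
    curves: list[UptakeCurve],
    bins: dict[str, tuple[float, float]] | None = None,
) -> list[BinSummary]:
    """Per-cell bin-averaged rates, then mean ± SEM across cells.

    Each cell contributes one number per bin (the mean of its rate samples
    whose load falls in the bin); the cohort statistic is the across-cell
    mean with SEM = SD/√n.  Emits a coverage warning when a bin is empty in
    at least half the cells.
    """
    if not curves:
        raise InsufficientDataError("bin_rates needs at least one curve")
    bins = dict(DEFAULT_BINS) if bins is None else bins
    _check_bins_disjoint(bins)
    out: list[BinSummary] = []
    for label, (lo, hi) in bins.items():
        per_cell = []
        for c in curves:
            m = (c.load >= lo) & (c.load < hi)
            if m.any():
                per_cell.append(float(c.rate[m].mean()))
        if len(per_cell) <= len(curves) / 2:
            warnings.warn(
                f"bin {label!r} [{lo}, {hi}) mM empty in >=50% of cells",
                stacklevel=2,
            )
        arr = np.asarray(per_cell)
        mean = float(arr.mean()) if len(arr) else float("nan")
        sem = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
        out.append(
            BinSummary(
                bin_label=label,
                bin_edges=(lo, hi),
                mean_rate=mean,
                sem_rate=sem,
                n_cells=len(arr),
            )
        )
    return out


def _check_bins_disjoint(bins: dict[str, tuple[float, float]]) -> None:
    spans = sorted(bins.values())
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"bins overlap: [{a0},{a1}) and [{b0},{b1})")
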