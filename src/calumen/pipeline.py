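"""End-to-end orchestration, configuration, I/O and cohort statistics.

``run_pipeline`` takes raw fluorescence traces through calibration,
optional calsequestrin correction, refill segmentation, differentiation
and the two-stage flux–load fits, producing a :class:`CohortReport` with
per-cell metrics, load-bin summaries and an audit manifest.  Cells that
fail any stage are excluded with a logged reason — never silently
dropped.  Identical config + seed reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .buffering import BufferParams, free_to_total
from .errors import (
    CalumenError,
    EmptyCohortError,
    InsufficientGroupError,
)
from .kinetics import (
    DEFAULT_BINS,
    BinSummary,
    CaTrace,
    UptakeCurve,
    bin_rates,
    compute_uptake_curve,
    detect_wave_refills,
    extract_refill_segment,
    max_rate_and_load,
    merge_curves,
)
from .luminal import (
    LuminalFit,
    ThermoFit,
    fit_luminal_kd,
    fit_thermo,
    luminal_activation_points,
)
from .sensor import (
    SENSOR_KD_UM,
    FluorescenceTrace,
    estimate_calibration,
    fluorescence_to_ca,
)

logger = logging.getLogger("calumen")

_PROFILES = {"hek", "myocyte"}
_MODES = {"refill", "wave"}
_ACTIVATION_MODES = {"ratio", "difference"}
_POOLING = {"per_cell", "pooled"}


@dataclass
class RunConfig:
    """Validated pipeline configuration, echoed verbatim into every output.

    ``profile`` selects the load variable: ``hek`` analyses free Ca²⁺,
    ``myocyte`` applies the calsequestrin correction and analyses total
    Ca²⁺.  ``pooling`` chooses between fitting the luminal Kd per cell and
    reporting the cohort median (default) or pooling all cells' activation
    points into one fit.
    """

    profile: str = "hek"
    mode: str = "refill"
    kd_sensor: float = SENSOR_KD_UM
    buffering: BufferParams | None = None
    bins: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BINS)
    )
    thermo_threshold: float = 0.3
    smoothing_window_s: float = 0.5
    washout_exclusion_s: float = 1.0
    activation_mode: str = "ratio"
    hill_n: float = 1.0
    fit_hill: bool = False
    pooling: str = "per_cell"
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {sorted(_PROFILES)}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {sorted(_MODES)}")
        if self.activation_mode not in _ACTIVATION_MODES:
            raise ValueError(
                f"activation_mode must be one of {sorted(_ACTIVATION_MODES)}"
            )
        if self.pooling not in _POOLING:
            raise ValueError(f"pooling must be one of {sorted(_POOLING)}")
        if self.buffering is None:
            self.buffering = BufferParams(enabled=(self.profile == "myocyte"))
        for label, edges in self.bins.items():
            lo, hi = edges
            if not lo < hi:
                raise ValueError(f"bin {label!r} has empty span")
            self.bins[label] = (float(lo), float(hi))
        if not self.thermo_threshold > 0:
            raise ValueError("thermo_threshold must be positive")
        if not self.smoothing_window_s > 0:
            raise ValueError("smoothing_window_s must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["buffering"] = self.buffering.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        buf = d.pop("buffering", None)
        if isinstance(buf, dict):
            buf = BufferParams(**buf)
        bins = d.pop("bins", None)
        kwargs = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(kwargs)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if bins is not None:
            kwargs["bins"] = {k: tuple(v) for k, v in bins.items()}
        if buf is not None:
            kwargs["buffering"] = buf
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class CellResult:
    """Per-cell analysis products (None where a stage failed)."""

    cell_id: str
    curve: UptakeCurve | None = None
    thermo: ThermoFit | None = None
    luminal: LuminalFit | None = None
    max_rate: float = float("nan")
    max_load: float = float("nan")

    def metrics(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "max_rate_mM_per_s": self.max_rate,
            "max_load_mM": self.max_load,
            "kd_lum_mM": self.luminal.kd_lum if self.luminal else float("nan"),
            "ca_max_mM": self.thermo.ca_max if self.thermo else float("nan"),
            "slope_a_per_s": self.thermo.slope_a if self.thermo else float("nan"),
        }


@dataclass
class CohortReport:
    """Cohort-level summary: per-cell metrics, bins, exclusions, manifest."""

    cells: list[CellResult]
    bins: list[BinSummary]
    excluded: list[tuple[str, str]]
    kd_lum_median: float
    kd_lum_pooled: float
    config: RunConfig

    @property
    def n_analyzed(self) -> int:
        return len(self.cells)

    @property
    def n_input(self) -> int:
        return len(self.cells) + len(self.excluded)

    def cell_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.metrics() for c in self.cells])

    def bin_table(self) -> pd.DataFrame:
        return pd.DataFrame([b.to_dict() for b in self.bins])

    def to_manifest(self) -> dict:
        return {
            "package": "calumen",
            "version": __version__,
            "config": self.config.to_dict(),
            "n_input": self.n_input,
            "n_analyzed": self.n_analyzed,
            "excluded": [
                {"cell_id": cid, "reason": why} for cid, why in self.excluded
            ],
            "kd_lum_median_mM": self.kd_lum_median,
            "kd_lum_pooled_mM": self.kd_lum_pooled,
            "bins": [b.to_dict() for b in self.bins],
        }

    def save(self, out_dir: str | Path) -> None:
        """Write cell table, bin table, per-cell curves and the manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cell_table().to_csv(out / "cells.csv", index=False)
        self.bin_table().to_csv(out / "bins.csv", index=False)
        curves_dir = out / "curves"
        curves_dir.mkdir(exist_ok=True)
        for c in self.cells:
            if c.curve is not None:
                pd.DataFrame(
                    {"load_mM": c.curve.load, "rate_mM_per_s": c.curve.rate}
                ).to_csv(curves_dir / f"{c.cell_id}.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.to_manifest(), indent=1, sort_keys=True)
        )


def calibrate_trace(trace: FluorescenceTrace, cfg: RunConfig) -> CaTrace:
    """Estimate the sensor calibration from the trace's own calibration
    epochs and convert fluorescence to free (and, for the myocyte profile,
    total) luminal Ca²⁺ in μM."""
    params = estimate_calibration(trace, kd_sensor=cfg.kd_sensor)
    ca_free = fluorescence_to_ca(trace.fluorescence, params, clip_warn=False)
    ca_total = (
        free_to_total(ca_free, cfg.buffering) if cfg.buffering.enabled else None
    )
    return CaTrace(
        time=trace.time,
        ca_free=ca_free,
        ca_total=ca_total,
        epochs=trace.epochs,
        cell_id=trace.cell_id,
    )


def analyze_cell(trace: FluorescenceTrace, cfg: RunConfig) -> CellResult:
    """Run one cell through the full chain; raises on any stage failure."""
    ca = calibrate_trace(trace, cfg)
    if cfg.mode == "wave":
        segments = detect_wave_refills(ca)
        if not segments:
            raise CalumenError("no wave refills detected")
        curves = [
            compute_uptake_curve(ca, seg, window_s=cfg.smoothing_window_s)
            for seg in segments
            if seg.mask(ca.time).sum() >= 20
        ]
        curve = merge_curves(curves)
    else:
        seg = extract_refill_segment(
            ca, washout_exclusion_s=cfg.washout_exclusion_s
        )
        curve = compute_uptake_curve(ca, seg, window_s=cfg.smoothing_window_s)
    thermo = fit_thermo(curve, threshold=cfg.thermo_threshold)
    pts = luminal_activation_points(curve, thermo, mode=cfg.activation_mode)
    luminal = fit_luminal_kd(
        pts, hill_n=cfg.hill_n, fit_hill=cfg.fit_hill, mode=cfg.activation_mode
    )
    mr, ml = max_rate_and_load(curve)
    return CellResult(
        cell_id=trace.cell_id,
        curve=curve,
        thermo=thermo,
        luminal=luminal,
        max_rate=mr,
        max_load=ml,
    )


def run_pipeline(
    traces: list[FluorescenceTrace], cfg: RunConfig
) -> CohortReport:
    """Analyze a cohort of traces; exclude failing cells with reasons.

    Raises :class:`EmptyCohortError` when no cell survives.  Writes outputs
    to ``cfg.out_dir`` when set.
    """
    cells: list[CellResult] = []
    excluded: list[tuple[str, str]] = []
    for trace in traces:
        try:
            cells.append(analyze_cell(trace, cfg))
        except CalumenError as exc:
            reason = f"{type(exc).__name__}: {exc}"
            logger.warning("cell %s excluded: %s", trace.cell_id, reason)
            excluded.append((trace.cell_id, reason))
    if not cells:
        raise EmptyCohortError(
            f"all {len(traces)} cells excluded; first reason: "
            f"{excluded[0][1] if excluded else 'none'}"
        )

    curves = [c.curve for c in cells if c.curve is not None]
    bins = bin_rates(curves, cfg.bins)
    kds = np.array([c.luminal.kd_lum for c in cells if c.luminal is not None])
    kd_median = float(np.median(kds)) if len(kds) else float("nan")
    # pooled-fit alternative: one hyperbola through all cells' points
    all_pts = [
        c.luminal.fit_points for c in cells if c.luminal is not None
    ]
    kd_pooled = float("nan")
    if all_pts:
        try:
            pooled = fit_luminal_kd(
                np.vstack(all_pts),
                hill_n=cfg.hill_n,
                fit_hill=cfg.fit_hill,
                mode=cfg.activation_mode,
            )
            kd_pooled = pooled.kd_lum
        except CalumenError:
            pass

    report = CohortReport(
        cells=cells,
        bins=bins,
        excluded=excluded,
        kd_lum_median=kd_median,
        kd_lum_pooled=kd_pooled,
        config=cfg,
    )
    if cfg.out_dir:
        report.save(cfg.out_dir)
    return report


def compare_groups(
    report_a: CohortReport,
    report_b: CohortReport,
    metric: str = "kd_lum_mM",
    welch: bool = False,
    alpha: float = 0.05,
) -> dict:
    """Unpaired two-sided t test on a per-cell metric between two cohorts.

    Pooled-variance (classic Student) by default, Welch behind a flag.
    """
    a = report_a.cell_table()[metric].dropna().to_numpy()
    b = report_b.cell_table()[metric].dropna().to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise InsufficientGroupError("each group needs at least two cells")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "metric": metric,
        "t": float(t),
        "p": float(p),
        "significant": bool(p < alpha),
        "n_a": int(len(a)),
        "n_b": int(len(b)),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
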