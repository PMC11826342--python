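"""Two-stage decomposition of the flux–load curve.

At intermediate-to-high loads the uptake rate declines roughly linearly
with load as the pump approaches its thermodynamic limit (maximum load);
at low loads the observed rate falls *below* that line, revealing a
luminal activation requirement.  The decomposition is:

1. ``fit_thermo`` — least-squares line ``rate = a·(ca_max − load)`` on
   points above a load threshold (default 0.3 mM).
2. ``luminal_activation_points`` — for low-load points, the dimensionless
   activation ``observed / predicted`` (ratio form; an absolute-difference
   variant is available for sensitivity analysis).
3. ``fit_luminal_kd`` — binding hyperbola
   ``activation = load^n / (load^n + Kd^n)`` with n fixed at 1 by default,
   yielding the apparent luminal Ca²⁺ affinity Kd.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    DegenerateFitError,
    FitFailureError,
    InsufficientHighLoadError,
    InsufficientSpanError,
)
from .kinetics import UptakeCurve

#: High-load threshold (mM) above which the back-pressure line is fitted.
THERMO_THRESHOLD_MM = 0.3


@dataclass
class ThermoFit:
    """Back-pressure line ``rate = slope_a · (ca_max − load)``.

    ``slope_a`` has units 1/s; ``ca_max`` (mM) is the x-intercept, the
    zero-flux maximum load.
    """

    slope_a: float
    ca_max: float
    fit_range_min: float
    residual_rms: float
    n_points: int = 0

    def predict(self, load: np.ndarray | float) -> np.ndarray | float:
        return self.slope_a * (self.ca_max - np.asarray(load, dtype=float))

    def to_dict(self) -> dict:
        return {
            "slope_a_per_s": self.slope_a,
            "ca_max_mM": self.ca_max,
            "fit_range_min_mM": self.fit_range_min,
            "residual_rms_mM_per_s": self.residual_rms,
            "n_points": self.n_points,
        }


@dataclass
class LuminalFit:
    """Hyperbolic luminal-activation fit; ``kd_lum`` in mM."""

    kd_lum: float
    hill_n: float
    residual_rms: float
    fit_points: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def predict(self, load: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(load, dtype=float)
        return x**self.hill_n / (x**self.hill_n + self.kd_lum**self.hill_n)

    def to_dict(self) -> dict:
        return {
            "kd_lum_mM": self.kd_lum,
            "hill_n": self.hill_n,
            "residual_rms": self.residual_rms,
            "n_points": int(len(self.fit_points)),
        }


def fit_thermo(
    curve: UptakeCurve, threshold: float = THERMO_THRESHOLD_MM
) -> ThermoFit:
    """Fit the high-load back-pressure line.

    Ordinary least squares of rate on load restricted to ``load >
    threshold``; needs at least five such points and a negative slope
    (rate decreasing with load).
    """
    m = curve.load > threshold
    if int(m.sum()) < 5:
        raise InsufficientHighLoadError(
            f"only {int(m.sum())} points above {threshold} mM; need >= 5"
        )
    x, y = curve.load[m], curve.rate[m]
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    a = -float(slope)
    if a <= 0:
        raise DegenerateFitError("uptake rate does not decline with load")
    ca_max = float(intercept) / a
    resid = y - (intercept + slope * x)
    fit = ThermoFit(
        slope_a=a,
        ca_max=ca_max,
        fit_range_min=threshold,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(m.sum()),
    )
    if not fit.ca_max > fit.fit_range_min:
        raise DegenerateFitError(
            f"fitted maximum load {ca_max:.3f} mM below fit range"
        )
    return fit


def luminal_activation_points(
    curve: UptakeCurve,
    thermo: ThermoFit,
    mode: str = "ratio",
    clip_high: float = 1.2,
    min_predicted_frac: float = 0.10,
) -> np.ndarray:
    """Low-load deviation from the back-pressure line as activation values.

    For each curve point below ``thermo.fit_range_min`` the predicted rate
    is ``a·(ca_max − load)``.  In ``ratio`` mode (default) the activation
    is observed/predicted, a dimensionless occupancy in [0, ``clip_high``];
    ``difference`` mode returns the absolute deficit
    ``predicted − observed`` (mM/s, clipped below at 0), the literal
    subtraction convention, kept for sensitivity analysis — it is fitted
    with a decaying hyperbola of free amplitude instead of an occupancy.
    Points whose predicted rate falls below ``min_predicted_frac`` of the
    largest predicted rate are dropped (the ratio degenerates as
    predicted → 0).

    Returns an (n, 2) array of (load, activation-or-deficit) pairs.
    """
    if mode not in {"ratio", "difference"}:
        raise ValueError("mode must be 'ratio' or 'difference'")
    m = curve.load < thermo.fit_range_min
    if not m.any():
        return np.empty((0, 2))
    load = curve.load[m]
    observed = curve.rate[m]
    predicted = np.asarray(thermo.predict(load), dtype=float)
    keep = predicted > min_predicted_frac * predicted.max()
    load, observed, predicted = load[keep], observed[keep], predicted[keep]
    if mode == "ratio":
        activation = np.clip(observed / predicted, 0.0, clip_high)
    else:
        activation = np.maximum(predicted - observed, 0.0)
    return np.column_stack([load, activation])


def fit_luminal_kd(
    points: np.ndarray,
    hill_n: float = 1.0,
    fit_hill: bool = False,
    mode: str = "ratio",
    min_points: int = 4,
    min_span_fold: float = 2.0,
) -> LuminalFit:
    """Fit the activation hyperbola and return the apparent luminal Kd.

    ``points`` is the (load, activation) array from
    :func:`luminal_activation_points` (``mode`` must match the one used
    there).  In ``ratio`` mode the model is the occupancy
    ``x^n/(x^n + Kd^n)``; in ``difference`` mode the deficit decays as
    ``B·Kd^n/(x^n + Kd^n)`` with the amplitude B free.  The Hill
    coefficient is fixed (default 1) unless ``fit_hill`` is set.  Requires
    ``min_points`` points spanning at least a ``min_span_fold``-fold load
    range.
    """
    if mode not in {"ratio", "difference"}:
        raise ValueError("mode must be 'ratio' or 'difference'")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < min_points:
        raise InsufficientSpanError(
            f"need >= {min_points} (load, activation) points"
        )
    x, y = pts[:, 0], pts[:, 1]
    if x.min() <= 0 or x.max() / x.min() < min_span_fold:
        raise InsufficientSpanError(
            f"load span {x.min():.3g}-{x.max():.3g} mM narrower than "
            f"{min_span_fold}-fold"
        )
    deficit = mode == "difference"

    def model(params: np.ndarray) -> np.ndarray:
        kd = params[0]
        n = params[-1] if fit_hill else hill_n
        if deficit:
            return params[1] * kd**n / (x**n + kd**n)
        return x**n / (x**n + kd**n)

    x0 = [float(np.median(x))]
    lower, upper = [1e-6], [50.0]
    if deficit:
        x0 += [float(max(y.max(), 1e-6))]
        lower += [0.0]
        upper += [np.inf]
    if fit_hill:
        x0 += [hill_n]
        lower += [0.2]
        upper += [8.0]
    res = least_squares(
        lambda p: model(p) - y, x0, bounds=(lower, upper), method="trf"
    )
    if not res.success:
        raise FitFailureError(f"hyperbola fit failed: {res.message}", res)
    kd = float(res.x[0])
    n_out = float(res.x[-1]) if fit_hill else float(hill_n)
    resid = model(res.x) - y
    return LuminalFit(
        kd_lum=kd,
        hill_n=n_out,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        fit_points=pts,
    )
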