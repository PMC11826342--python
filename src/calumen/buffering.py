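"""Calsequestrin buffering: free vs total luminal Ca²⁺.

Calsequestrin is the dominant luminal buffer of the cardiac SR.  With a
single-site isotherm (B_max = 2,700 μM, K_d = 630 μM) the total luminal
calcium at free concentration c is

    total(c) = B_max · c / (c + K_d) + c

The inverse is the positive root of the quadratic
``c² + c·(K_d + B_max − T) − K_d·T = 0``, solved in closed form (exact and
branch-safe, no iteration).  The correction is applied in the myocyte
profile only; the HEK profile analyses free Ca²⁺ directly.  Units are
whatever the parameters are expressed in (μM by default; :meth:`BufferParams.in_mm`
rescales for the mM-based kinetics code).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError

#: Calsequestrin buffering capacity, μM.
CSQ_BMAX_UM = 2700.0
#: Calsequestrin Ca²⁺ dissociation constant, μM.
CSQ_KD_UM = 630.0


@dataclass(frozen=True)
class BufferParams:
    """Single-species luminal buffer parameters."""

    b_max: float = CSQ_BMAX_UM
    kd_csq: float = CSQ_KD_UM
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.b_max < 0:
            raise DomainError("b_max must be >= 0")
        if not self.kd_csq > 0:
            raise DomainError("kd_csq must be > 0")

    def in_mm(self) -> "BufferParams":
        """Same buffer with concentrations rescaled from μM to mM."""
        return replace(self, b_max=self.b_max / 1000.0, kd_csq=self.kd_csq / 1000.0)

    def to_dict(self) -> dict:
        return {"b_max": self.b_max, "kd_csq": self.kd_csq, "enabled": self.enabled}


def free_to_total(
    ca_free: np.ndarray | float, params: BufferParams
) -> np.ndarray | float:
    """Total luminal [Ca²⁺] (bound + free) at the given free concentration."""
    c = np.asarray(ca_free, dtype=float)
    if np.any(c < 0):
        raise DomainError("free concentration must be non-negative")
    total = params.b_max * c / (c + params.kd_csq) + c
    return float(total) if np.isscalar(ca_free) else total


def total_to_free(
    ca_total: np.ndarray | float, params: BufferParams
) -> np.ndarray | float:
    """Free luminal [Ca²⁺] given the total; closed-form quadratic inverse."""
    t = np.asarray(ca_total, dtype=float)
    if np.any(t < 0):
        raise DomainError("total concentration must be non-negative")
    b = params.kd_csq + params.b_max - t
    # positive root of c^2 + b*c - kd*T = 0; formulated to avoid cancellation
    disc = np.sqrt(b * b + 4.0 * params.kd_csq * t)
    c = 2.0 * params.kd_csq * t / (disc + b) if np.ndim(t) == 0 else None
    if c is None:
        c = np.where(b >= 0, 2.0 * params.kd_csq * t / (disc + b), 0.5 * (disc - b))
    elif b < 0:
        c = 0.5 * (disc - b)
    free = np.maximum(c, 0.0)
    return float(free) if np.isscalar(ca_total) else free


def buffering_power(
    ca_free: np.ndarray | float, params: BufferParams
) -> np.ndarray | float:
    """d(total)/d(free) = 1 + B_max·K_d/(c + K_d)²; always ≥ 1."""
    c = np.asarray(ca_free, dtype=float)
    beta = 1.0 + params.b_max * params.kd_csq / (c + params.kd_csq) ** 2
    return float(beta) if np.isscalar(ca_free) else beta
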