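"""Forward kinetic simulator of a single ER/SR Ca²⁺ compartment.

One well-mixed luminal compartment exchanges Ca²⁺ with a clamped cytosol.
The state variable is the *load* x (mM): free luminal Ca²⁺ when buffering
is disabled (HEK profile) or total (calsequestrin-bound + free) Ca²⁺ when
enabled (myocyte profile).  Dynamics:

    dx/dt = J_up(x) − g(t) · ca_free(x)

with the pump flux

    J_up = v_max · drive · [(1−a₀)·xⁿ/(xⁿ + Kd_lumⁿ) + a₀] · max(0, 1 − x/ca_thermo)

— a cooperative luminal-activation factor (half-activation ``kd_lum``,
steepness ``hill_n``, basal floor ``a₀`` so a fully depleted store can
still refill) times a linear thermodynamic back-pressure that vanishes at
the maximum load ``ca_thermo``.  The release conductance g(t) follows the
protocol: passive leak at baseline, a large caffeine conductance during
depletion, zero under ruthenium red, and threshold/termination gating in
wave mode.  Release is ohmic into a zero-Ca²⁺ cytosol (permeabilized-cell
conditions), so the gradient is just ``ca_free``.

Integration is explicit fixed-step Euler at ``dt_sim`` (default 1 ms) —
the dynamics are non-stiff at these rates and a fixed step gives
bit-reproducible traces under a seed.  The observable is the free Ca²⁺
passed through the sensor isotherm and sampled at ``dt_sample`` (20 ms
line-scan period) with i.i.d. Gaussian photon noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .buffering import BufferParams, free_to_total, total_to_free
from .errors import DomainError, StabilityError
from .kinetics import CaTrace
from .sensor import FluorescenceTrace, ProtocolEvent, SensorParams, ca_to_fluorescence

#: Pump-construct presets, as (v_max scale, ca_thermo scale) relative to WT.
#: The loop mutants lower both the catalytic rate and the attainable load;
#: the disulfide-loop mutant and thapsigargin effectively silence the pump.
CONSTRUCT_SCALES: dict[str, tuple[float, float]] = {
    "WT": (1.0, 1.0),
    "NCA3": (0.6, 0.85),
    "NCA5": (0.6, 0.85),
    "C875A": (0.05, 1.0),
    "TG": (0.0, 1.0),
}

#: Calibrated WT peak-flux scale (mM/s) per profile; see
#: ``scripts/calibrate_vmax.py`` for the search that fixed these.
VMAX_DEFAULT = {"hek": 0.24, "myocyte": 0.83}

#: Default luminal half-activation (mM) per profile.
KD_LUM_DEFAULT = {"hek": 0.14, "myocyte": 0.22}

_CLAMP_FMAX_UM = 1.0e6  # sensor-saturating [Ca2+] during the ionomycin epoch


@dataclass(frozen=True)
class SimCellConfig:
    """Ground-truth parameterization of one synthetic cell.

    Concentrations (``kd_lum``, ``ca_thermo``, wave thresholds) are in mM
    and refer to the load variable (free or total Ca²⁺ depending on
    ``buffer.enabled``); conductances are 1/s acting on free Ca²⁺.
    """

    v_max: float = 0.24  # mM/s, peak pump flux scale
    kd_lum: float = 0.14  # mM, luminal half-activation
    hill_n: float = 2.25  # activation steepness
    basal_activation: float = 0.03  # activation floor a0, fraction of v_max
    ca_thermo: float = 0.8  # mM, zero-flux (maximum) load
    g_leak: float = 0.01  # 1/s, passive (non-release-channel) leak
    g_caffeine: float = 40.0  # 1/s, release during caffeine
    wave_threshold: float = 0.68  # mM, release opens above this load
    wave_term: float = 0.03  # mM, release closes below this load
    g_wave: float = 5.0  # 1/s, release conductance during a wave
    cytosolic_drive: float = 1.0  # flux multiplier for cytosolic [Ca2+]
    buffer: BufferParams = field(
        default_factory=lambda: BufferParams(enabled=False)
    )
    sensor: SensorParams = field(
        default_factory=lambda: SensorParams(f_min=100.0, f_max=1100.0)
    )
    noise_sigma: float = 5.0  # AU, Gaussian photon noise per sample
    dt_sim: float = 0.001  # s, integration step
    dt_sample: float = 0.020  # s, line-scan sampling period
    seed: int = 0
    construct: str = "WT"
    profile: str = "hek"

    def __post_init__(self) -> None:
        for name in ("v_max", "g_leak", "g_caffeine", "g_wave", "noise_sigma"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0 < self.cytosolic_drive <= 1:
            raise DomainError("cytosolic_drive must be in (0, 1]")
        if not self.wave_term < self.wave_threshold <= self.ca_thermo:
            raise DomainError("requires wave_term < wave_threshold <= ca_thermo")
        if self.dt_sim > self.dt_sample:
            raise DomainError("dt_sim must not exceed dt_sample")
        if self.construct not in CONSTRUCT_SCALES:
            raise DomainError(f"unknown construct {self.construct!r}")

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "v_max",
                "kd_lum",
                "hill_n",
                "basal_activation",
                "ca_thermo",
                "g_leak",
                "g_caffeine",
                "wave_threshold",
                "wave_term",
                "g_wave",
                "cytosolic_drive",
                "noise_sigma",
                "dt_sim",
                "dt_sample",
                "seed",
                "construct",
                "profile",
            )
        }
        d["buffer"] = self.buffer.to_dict()
        d["sensor"] = {
            "f_min": self.sensor.f_min,
            "f_max": self.sensor.f_max,
            "kd_sensor": self.sensor.kd_sensor,
        }
        return d


@dataclass(frozen=True)
class Protocol:
    """Time-ordered pharmacological protocol for one simulated recording."""

    events: tuple[ProtocolEvent, ...]
    mode: str = "depletion_refill"
    duration: float = 0.0

    def __post_init__(self) -> None:
        starts = [ev.t_start for ev in self.events]
        if starts != sorted(starts):
            raise ValueError("protocol events must be time-ordered")
        if self.duration <= 0:
            object.__setattr__(
                self, "duration", max(ev.t_end for ev in self.events)
            )


def depletion_refill_protocol(
    baseline_s: float = 5.0,
    caffeine_s: float = 15.0,
    refill_s: float = 75.0,
    calibration_tail: bool = True,
) -> Protocol:
    """Standard uptake protocol: caffeine depletion, ruthenium-red refill,
    then the Fmax (ionomycin) / Fmin (caffeine) calibration tail."""
    t = 0.0
    events = [ProtocolEvent("baseline", t, t + baseline_s)]
    t += baseline_s
    events.append(ProtocolEvent("caffeine", t, t + caffeine_s, "5 mM"))
    t += caffeine_s
    events.append(ProtocolEvent("ruthenium_red", t, t + refill_s, "15 uM"))
    t += refill_s
    if calibration_tail:
        events.append(ProtocolEvent("ionomycin_fmax", t, t + 10.0, "5 uM"))
        t += 10.0
        events.append(ProtocolEvent("caffeine_fmin", t, t + 15.0, "5 mM"))
        t += 15.0
    return Protocol(events=tuple(events), mode="depletion_refill", duration=t)


def wave_protocol(
    block_s: float = 30.0,
    relief_s: float = 120.0,
    calibration_tail: bool = True,
) -> Protocol:
    """Wave protocol: store loads under Mg²⁺ block of the release channel,
    then periodic release–reuptake waves after Mg²⁺ relief."""
    t = 0.0
    events = [ProtocolEvent("mg_block", t, t + block_s, "10 mM")]
    t += block_s
    events.append(ProtocolEvent("mg_relief", t, t + relief_s))
    t += relief_s
    if calibration_tail:
        events.append(ProtocolEvent("ionomycin_fmax", t, t + 10.0, "5 uM"))
        t += 10.0
        events.append(ProtocolEvent("caffeine_fmin", t, t + 15.0, "5 mM"))
        t += 15.0
    return Protocol(events=tuple(events), mode="wave", duration=t)


@dataclass
class SimResult:
    """One simulated recording with its ground truth."""

    trace: FluorescenceTrace  # observable: noisy fluorescence
    truth: CaTrace  # noise-free calibrated Ca (μM)
    flux_load: np.ndarray  # ground-truth (load mM, flux mM/s) samples
    wave_times: np.ndarray  # wave release onset times, s
    config: SimCellConfig


def pump_flux(
    ca: np.ndarray | float, cfg: SimCellConfig
) -> np.ndarray | float:
    """Pump flux (mM/s) at load ``ca`` (mM): activation × back-pressure."""
    c = np.asarray(ca, dtype=float)
    if np.any(c < 0):
        raise DomainError("load must be non-negative")
    n, kd, a0 = cfg.hill_n, cfg.kd_lum, cfg.basal_activation
    act = (1.0 - a0) * c**n / (c**n + kd**n) + a0
    bp = np.maximum(0.0, 1.0 - c / cfg.ca_thermo)
    j = cfg.v_max * cfg.cytosolic_drive * act * bp
    return float(j) if np.isscalar(ca) else j


def _free_of_load(x: float, cfg: SimCellConfig) -> float:
    if cfg.buffer.enabled:
        return total_to_free(x, cfg.buffer.in_mm())
    return x


def initial_load(cfg: SimCellConfig) -> float:
    """Baseline steady state: largest load where pump flux balances leak."""
    if cfg.v_max == 0.0:
        # acute pump inhibition of a previously loaded store (TG preset)
        return cfg.ca_thermo
    if cfg.g_leak == 0.0:
        return cfg.ca_thermo
    xs = np.linspace(1e-9, cfg.ca_thermo - 1e-9, 400)
    net = np.array(
        [pump_flux(x, cfg) - cfg.g_leak * _free_of_load(x, cfg) for x in xs]
    )
    pos = np.nonzero(net > 0)[0]
    if not len(pos):
        return 0.0
    from scipy.optimize import brentq

    lo = xs[pos[-1]]
    return float(brentq(lambda x: pump_flux(x, cfg) - cfg.g_leak * _free_of_load(x, cfg),
                        lo, cfg.ca_thermo - 1e-12))


# epoch codes used by the integrator
_G_LEAK, _G_CAFFEINE, _G_BLOCKED, _G_WAVE, _CLAMP_MAX, _CLAMP_MIN = range(6)

_EPOCH_CODE = {
    "baseline": _G_LEAK,
    "washout": _G_LEAK,
    "caffeine": _G_CAFFEINE,
    "ruthenium_red": _G_BLOCKED,
    "tetracaine": _G_BLOCKED,
    "mg_block": _G_BLOCKED,
    "mg_relief": _G_WAVE,
    "ionomycin_fmax": _CLAMP_MAX,
    "caffeine_fmin": _CLAMP_MIN,
}


def simulate_cell(
    cfg: SimCellConfig, protocol: Protocol | None = None
) -> SimResult:
    """Integrate one cell through a protocol and synthesise its recording.

    Identical config (including seed) gives a bit-identical result.  During
    the calibration tail the free Ca²⁺ seen by the sensor is clamped:
    ionomycin equilibrates the store with the 5 mM bath (sensor saturated),
    the final caffeine empties it (sensor floor).
    """
    if protocol is None:
        protocol = depletion_refill_protocol()

    dt = cfg.dt_sim
    nsub = int(round(cfg.dt_sample / dt))
    if abs(nsub * dt - cfg.dt_sample) > 1e-12:
        raise DomainError("dt_sample must be an integer multiple of dt_sim")
    n_samples = int(np.floor(protocol.duration / cfg.dt_sample))
    n_steps = n_samples * nsub

    # per-step epoch code (vectorized lookup against event boundaries)
    t_steps = (np.arange(n_steps) + 0.5) * dt
    code = np.full(n_steps, _G_LEAK, dtype=np.int8)
    for ev in protocol.events:
        m = (t_steps >= ev.t_start) & (t_steps < ev.t_end)
        code[m] = _EPOCH_CODE[ev.label]

    buffered = cfg.buffer.enabled
    buf_mm = cfg.buffer.in_mm() if buffered else None
    x = initial_load(cfg)
    if protocol.mode == "wave":
        # the store loads during mg_block from wherever leak left it
        x = min(x, cfg.wave_threshold * 0.9)

    step_limit = 0.1 * cfg.ca_thermo
    wave_open = False
    wave_times: list[float] = []
    free_out = np.empty(n_samples)
    load_out = np.empty(n_samples)

    g_leak, g_caf, g_wave = cfg.g_leak, cfg.g_caffeine, cfg.g_wave
    wave_hi, wave_lo = cfg.wave_threshold, cfg.wave_term
    # scalar constants for the hot loop (pump_flux/total_to_free inlined)
    n_h, a0 = cfg.hill_n, cfg.basal_activation
    kdn = cfg.kd_lum**n_h
    vd = cfg.v_max * cfg.cytosolic_drive
    cmax = cfg.ca_thermo
    if buffered:
        b_mm, kdc_mm = buf_mm.b_max, buf_mm.kd_csq
    s = 0
    for i in range(n_steps):
        c = code[i]
        if buffered and c < _CLAMP_MAX:
            b = kdc_mm + b_mm - x
            free = 0.5 * ((b * b + 4.0 * kdc_mm * x) ** 0.5 - b)
            if free < 0.0:
                free = 0.0
        else:
            free = x
        if i % nsub == 0:
            if c == _CLAMP_MAX:
                load_out[s], free_out[s] = x, _CLAMP_FMAX_UM / 1000.0
            elif c == _CLAMP_MIN:
                x = 0.0
                load_out[s], free_out[s] = 0.0, 0.0
            else:
                load_out[s], free_out[s] = x, free
            s += 1
        if c >= _CLAMP_MAX:
            continue
        if c == _G_LEAK:
            g = g_leak
        elif c == _G_CAFFEINE:
            g = g_leak + g_caf
        elif c == _G_BLOCKED:
            g = 0.0
        else:  # wave gating
            if not wave_open and x >= wave_hi:
                wave_open = True
                wave_times.append(i * dt)
            elif wave_open and x <= wave_lo:
                wave_open = False
            g = g_leak + (g_wave if wave_open else 0.0)
        # the release term is stiff during caffeine (g*dt >> 0.005):
        # sub-step so the transient is resolved independently of dt_sim
        m_sub = 1 if g * dt <= 0.005 else min(int(g * dt / 0.005) + 1, 20)
        h = dt / m_sub
        for _ in range(m_sub):
            if m_sub > 1:
                if buffered:
                    b = kdc_mm + b_mm - x
                    free = 0.5 * ((b * b + 4.0 * kdc_mm * x) ** 0.5 - b)
                    if free < 0.0:
                        free = 0.0
                else:
                    free = x
            xn = x**n_h
            bp = 1.0 - x / cmax
            if bp < 0.0:
                bp = 0.0
            flux = vd * ((1.0 - a0) * xn / (xn + kdn) + a0) * bp
            dx = h * (flux - g * free)
            if abs(dx) > step_limit:
                raise StabilityError(
                    f"|dx|={abs(dx):.3g} mM exceeds 10% of ca_thermo at "
                    f"t={i*dt:.3f}s; reduce dt_sim"
                )
            x = max(x + dx, 0.0)

    time = np.arange(n_samples) * cfg.dt_sample
    free_um = free_out * 1000.0
    f_clean = ca_to_fluorescence(free_um, cfg.sensor)
    rng = np.random.default_rng(cfg.seed)
    fluo = f_clean + rng.normal(0.0, cfg.noise_sigma, n_samples)

    trace = FluorescenceTrace(
        time=time,
        fluorescence=fluo,
        epochs=list(protocol.events),
        cell_id=f"{cfg.construct.lower()}_seed{cfg.seed}",
    )
    total_um = (
        free_to_total(free_um, cfg.buffer) if buffered else None
    )
    truth = CaTrace(
        time=time,
        ca_free=free_um,
        ca_total=total_um,
        epochs=list(protocol.events),
        cell_id=trace.cell_id,
    )
    grid = np.linspace(0.0, cfg.ca_thermo, 161)
    flux_load = np.column_stack([grid, pump_flux(grid, cfg)])
    return SimResult(
        trace=trace,
        truth=truth,
        flux_load=flux_load,
        wave_times=np.asarray(wave_times),
        config=cfg,
    )


def default_config(
    profile: str = "hek",
    construct: str = "WT",
    seed: int = 0,
    **overrides,
) -> SimCellConfig:
    """Default cell for a profile/construct combination.

    HEK profile: free-Ca load variable, Kd_lum 0.14 mM, no buffering.
    Myocyte profile: total-Ca load variable with calsequestrin buffering
    (B_max 2,700 μM, K_d 630 μM), Kd_lum 0.22 mM.  Construct presets scale
    ``v_max``/``ca_thermo`` (see :data:`CONSTRUCT_SCALES`).
    """
    if profile not in VMAX_DEFAULT:
        raise DomainError(f"unknown profile {profile!r}")
    if construct not in CONSTRUCT_SCALES:
        raise DomainError(f"unknown construct {construct!r}")
    v_scale, c_scale = CONSTRUCT_SCALES[construct]
    base = dict(
        v_max=VMAX_DEFAULT[profile] * v_scale,
        kd_lum=KD_LUM_DEFAULT[profile],
        ca_thermo=0.8 * c_scale,
        buffer=BufferParams(enabled=(profile == "myocyte")),
        construct=construct,
        profile=profile,
        seed=seed,
    )
    base.update(overrides)
    # keep the gating invariant when ca_thermo shrinks
    cfg = SimCellConfig(**base)
    if cfg.wave_threshold > cfg.ca_thermo:
        cfg = replace(cfg, wave_threshold=0.85 * cfg.ca_thermo)
    return cfg


def draw_cohort_configs(
    base_cfg: SimCellConfig, n_cells: int, cv: float = 0.15, seed: int = 0
) -> list[SimCellConfig]:
    """Per-cell configs with log-normal cell-to-cell variability.

    ``v_max`` and ``ca_thermo`` are drawn log-normally around the base
    values with fractional SD ``cv`` (mean-preserving); the wave threshold
    scales with each cell's ``ca_thermo`` draw.  Per-cell noise seeds are
    derived deterministically from ``seed``.
    """
    if n_cells < 1:
        raise DomainError("n_cells must be >= 1")
    if cv < 0:
        raise DomainError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sig = float(np.sqrt(np.log1p(cv**2)))
    configs = []
    for _ in range(n_cells):
        v = base_cfg.v_max * rng.lognormal(-0.5 * sig**2, sig)
        cm = base_cfg.ca_thermo * rng.lognormal(-0.5 * sig**2, sig)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        configs.append(
            replace(
                base_cfg,
                v_max=v,
                ca_thermo=cm,
                wave_threshold=base_cfg.wave_threshold / base_cfg.ca_thermo * cm,
                wave_term=min(base_cfg.wave_term, 0.5 * cm),
                seed=cell_seed,
            )
        )
    return configs


def simulate_cohort(
    base_cfg: SimCellConfig,
    n_cells: int,
    cv: float = 0.15,
    seed: int = 0,
    protocol: Protocol | None = None,
) -> list[SimResult]:
    """Simulate a cohort of cells drawn by :func:`draw_cohort_configs`."""
    return [
        simulate_cell(cfg, protocol)
        for cfg in draw_cohort_configs(base_cfg, n_cells, cv, seed)
    ]
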