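# Methods

## Scope and data model

The package analyses time-series recordings of an ER/SR-targeted
single-wavelength Ca²⁺ sensor in permeabilized cells, annotated with
pharmacological protocol epochs (caffeine depletion, ruthenium-red/
tetracaine block, Mg²⁺ block/relief for waves, and the terminal
ionomycin/caffeine calibration pair). Traces enter as
`time_s,fluorescence_au` CSV with epochs in a sidecar JSON or a third
label column; image processing (line-scan reduction) is upstream of this
package.

Two analysis profiles exist. The **HEK profile** analyses free luminal
Ca²⁺ directly. The **myocyte profile** converts free to total SR Ca²⁺
with the calsequestrin isotherm before differentiation, because in
cardiomyocytes the measured uptake flux overwhelmingly fills buffer sites;
loads and rates are then total-Ca referenced. The buffering relation is
applied after sensor calibration (the sensor reports free Ca²⁺). Whether
published myocyte rate axes are total-referenced is not always made
explicit; this package states its convention and records it in every
manifest.

## Sensor model

Fluorescence converts to free Ca²⁺ via the one-site isotherm
`c = K_d (F − F_min)/(F_max − F)` with K_d = 609 μM. F_max is the robust
mean (2% two-sided trim) of the ionomycin epoch; F_min uses only the last
25% of the depletion epoch, since depletion approaches its plateau
asymptotically. Published protocols do not state a plateau windowing rule;
the 25%-tail rule is this package's choice and is configurable. Samples
outside [F_min, F_max) are clamped with a warning rather than rejected —
photon noise routinely crosses the plateaus, and dropping samples would
punch holes in the derivative.

## Buffering

Calsequestrin is modeled as a single instantaneous-equilibrium species
(B_max = 2,700 μM, K_d = 630 μM): `total = B_max c/(c + K_d) + c`. The
inverse is the positive root of `c² + c(K_d + B_max − T) − K_d T = 0`,
evaluated in closed form with a cancellation-safe branch; round trips are
exact to 1e-9 across 10⁻²–10⁵ μM. Kinetic (non-instantaneous) buffering
and calsequestrin polymerization are out of scope.

## Uptake kinetics

The refill window opens at release-channel blockade and, independently,
at least 1.0 s after caffeine washout — residual caffeine contaminates the
first second of reuptake, so those samples are always excluded. The window
closes when the trace reaches 99% of its terminal plateau. A refill whose
plateau stays below 0.1 mM, or which rises less than 0.05 mM, is treated
as *no uptake* (pump-inhibited or non-expressing cell) and the cell is
excluded with that reason.

Rates are estimated with a Savitzky–Golay (local quadratic) filter,
default window 0.5 s at 20 ms sampling, applied to both the load and its
first derivative. No published smoothing convention exists for these
derivative curves; local polynomial smoothing is the standard choice that
controls derivative noise without biasing slow trends. Half a filter
window is dropped at each segment edge, where the fit becomes one-sided
and the derivative inherits whatever kink bounds the segment (washout
step, wave nadir/peak). On noiseless single-exponential refills the
estimated rate curve matches the analytic derivative within 1% at interior
loads.

Wave-mode recordings (Mg²⁺-relief epochs) are segmented by locating
nadirs and peaks on the smoothed load with prominence ≥ 10% of the trace
range; each nadir-to-peak limb at least 1 s long is analyzed as a refill
and the per-cell curve pools all limbs. With the default small passive
leak the inter-wave refill slightly underestimates the pump flux (by
`g_leak·ca_free`, ≤ 2% of the peak rate at the default 0.01 /s).

Cohort summaries average each cell's rate samples within configurable
load bins, then take mean ± SEM across cells (per-cell-first averaging;
pooled binning is available via config). Defaults: low 0.05–0.2 mM,
intermediate 0.3–0.4 mM, high 0.6–0.8 mM. Published bin edges vary
between text and figure captions for the low bin (0.05–0.2 vs 0.05–0.10);
the defaults follow the text and every report records the edges used.

## Two-stage flux–load decomposition

At loads above a threshold (default 0.3 mM) the uptake rate is fitted
with the line `rate = a (Ca_max − load)` — "inversely proportional to
load" with x-intercept Ca_max, the zero-flux maximum load. The functional
form of this thermodynamic relationship is not uniquely determined by the
data; the linear form matches the observed straight decline and keeps the
decomposition exactly invertible.

Below the threshold, each point's **activation** is the ratio
observed/predicted, clipped to [0, 1.2]; points whose predicted rate falls
below 10% of the local maximum are dropped (the ratio degenerates as the
prediction approaches zero). "Subtracting the points from the
thermodynamic relationship" admits two readings. The default ratio
convention isolates a dimensionless occupancy whose half-activation load
is directly interpretable as an apparent affinity. The literal
absolute-difference (deficit) variant is provided behind
`activation_mode="difference"` for sensitivity analysis; it conflates the
declining back-pressure line with the activation decay and therefore
biases the fitted K_d low, which the test suite demonstrates — the reason
it is not the default.

The activation points are fitted with `load^n/(load^n + K_d^n)`, Hill
coefficient fixed at n = 1 by default (a single apparent affinity is
reported; `fit_hill` frees it). The fit requires ≥ 4 points spanning a
≥ 2-fold load range. Per-cell fits are summarized by the cohort median;
a pooled fit over all cells' points is also reported.

## Forward simulator

One well-mixed luminal compartment with load variable x (free Ca²⁺, or
total when buffering is enabled):

    dx/dt = J_up(x) − g(t)·ca_free(x)
    J_up  = v_max · drive · [(1−a₀) xⁿ/(xⁿ + K_lumⁿ) + a₀] · max(0, 1 − x/Ca_max)

Release is ohmic into a zero-Ca²⁺ cytosol (`g·ca_free`), appropriate for
permeabilized cells with clamped ~150 nM cytosolic Ca²⁺; `drive ∈ (0,1]`
abstracts the cytosolic Ca²⁺ level as a flux multiplier rather than
modeling cytosolic binding sites.

Default parameters (wild type):

| parameter | HEK | myocyte | meaning |
|---|---|---|---|
| v_max (mM/s) | 0.24 | 0.83 | peak pump flux scale |
| K_lum (mM) | 0.14 | 0.22 | luminal half-activation |
| n (Hill) | 2.25 | 2.25 | activation steepness |
| a₀ | 0.03 | 0.03 | basal activation floor |
| Ca_max (mM) | 0.8 | 0.8 | zero-flux (maximum) load |
| g_leak (1/s) | 0.01 | 0.01 | passive leak |
| g_caffeine (1/s) | 40 | 40 | caffeine-activated release |
| buffering | off | B_max 2.7 mM, K_d 0.63 mM | calsequestrin |
| sensor | F_min 100, F_max 1100 AU, K_d 609 μM | same | isotherm |
| noise | 5 AU | 5 AU | Gaussian, per 20 ms sample |

Rationale for the shape parameters. The analysis side fits a Hill-1
hyperbola (one reported affinity); the *generator* uses a steeper
activation (n = 2.25) because a Hill-1 forward model cannot produce the
observed ~70% contrast between intermediate- and low-load bin means — its
bin ratio is pinned near 1.07 regardless of v_max. n = 2.25 reproduces
both profiles' bin contrasts while the Hill-1 analysis still recovers the
half-activation load within a few percent (0.145 vs 0.14; 0.220 vs 0.22 on
the default seeds). The basal floor a₀ = 0.03 exists because a strictly
cooperative pump (J → 0 like x²·²⁵) could never restart from a fully
depleted store; a few percent of basal turnover restores refill after
complete depletion and shifts the bin means by under 10%. g_caffeine = 40 /s
empties both profiles in ~1–2 s, consistent with "full depletion" under
caffeine — a smaller conductance is outrun by the myocyte pump once
buffering lowers free Ca²⁺. v_max was calibrated once per profile by a 1-D
scaling so the analyzed cohort's intermediate-bin mean lands on its anchor
(0.12 / 0.33 mM/s); `scripts/calibrate_vmax.py` reproduces the search.

Mutant presets scale (v_max, Ca_max): loop charge mutants NCA3/NCA5
(0.6×, 0.85×) — qualitative ordering only, no published magnitudes —
the disulfide-loop mutant C875A 0.05× v_max, and the pump-inhibited TG
control 0 (started from a loaded store so the depletion transient is
visible). Both inhibited presets produce traces the pipeline excludes as
no-uptake, by design.

Waves are generated by threshold gating: release opens at 0.68 mM
(scaled with each cell's Ca_max draw) with g_wave = 5 /s and closes at
0.03 mM, so waves start at high load and terminate near an empty store.

Integration is explicit fixed-step Euler at dt = 1 ms (bit-reproducible
under a seed; the dynamics are non-stiff at these rates), with automatic
substepping whenever `g·dt > 0.005` so the fast caffeine transient is
resolved independently of dt; halving dt changes sampled trajectories by
< 0.1% of the maximum load. A step exceeding 10% of Ca_max raises a
stability error instead of silently diverging. The observable passes the
free Ca²⁺ through the sensor isotherm at 20 ms sampling and adds i.i.d.
Gaussian noise; during the terminal calibration epochs the sensor input is
clamped (saturated under ionomycin, empty under caffeine).

Cohorts draw v_max and Ca_max log-normally (mean-preserving) with
fractional SD 0.15 — a typical cell-to-cell spread for expression-driven
parameters — and derive per-cell noise seeds deterministically from the
cohort seed.

What the generator does *not* emulate: spatial heterogeneity within the
line scan, photobleaching and motion artifacts, stochastic single-channel
release gating, kinetic buffering, and any drift in sensor calibration
over the recording. Passing round-trip tests therefore demonstrates that
the analysis chain is unbiased for well-mixed, stationary-calibration
recordings with Gaussian photon noise — not that it is robust to imaging
artifacts.

## Statistics

Group comparisons use the unpaired two-sided Student's t test
(pooled variance; Welch available behind a flag), significance at
P < 0.05, and all summaries are mean ± SEM with n = cells. Cells failing
any stage are excluded with a logged reason and counted in the manifest,
so input = analyzed + excluded always holds.

## Problem sizes and determinism

The shipped verification cohorts are 40 cells (HEK) and 11 cells
(myocyte) with ~2-minute simulated recordings per cell — the cohort sizes
the default parameterization is anchored to. Everything downstream of a
seed is deterministic: identical config + seed gives byte-identical
traces, tables and manifests.

## Known limitations

- The apparent K_d from the ratio convention inherits any misfit of the
  linear back-pressure model; with strongly curved high-load behavior the
  extrapolated prediction at low loads would distort the activation scale.
- The terminal-plateau rules (99% of plateau for segment end, 5% of peak
  rate for the maximum-load readout) are conventions; published analyses
  state none.
- Free-running waves sample loads only between the termination and
  threshold levels; the flux–load curve outside that range is not
  constrained by wave-mode data.
- The intact-cell paced-refill protocol (field-stimulated staircase
  refill) is not implemented; its bell-shaped load dependence is expected
  to be analyzable with the same two-stage decomposition once reduced to
  (load, rate) pairs.
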