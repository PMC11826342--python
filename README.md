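# calumen

Luminal Ca²⁺ regulation of SERCA-mediated ER/SR Ca²⁺ uptake: a tested
analysis pipeline for single-wavelength luminal Ca²⁺ sensor recordings,
together with a ground-truthed forward simulator that verifies every stage
by round-trip parameter recovery.

## The problem

The sarco/endoplasmic reticulum Ca²⁺-ATPase (SERCA2a) refills the ER/SR
Ca²⁺ store after each release event. Its transport rate depends not only on
cytosolic Ca²⁺ but on the *luminal* load [Ca²⁺]_ER/SR itself: at high loads
the rate declines toward zero as the pump approaches its thermodynamic
limit, while at low loads the rate is paradoxically suppressed — a certain
luminal Ca²⁺ level is required for optimal pumping. Quantifying that
luminal dependence from live-cell recordings requires a chain of steps,
each with its own conventions:

1. **Sensor calibration** — an ER-targeted sensor (R-CEPIA1er type,
   K_d = 609 μM) is calibrated per cell from an ionomycin-saturation epoch
   (F_max) and a caffeine-depletion epoch (F_min), then
   [Ca²⁺]_ER = K_d·(F − F_min)/(F_max − F).
2. **Buffering correction** (cardiomyocytes) — calsequestrin
   (B_max = 2,700 μM, K_d = 630 μM) links free and total SR Ca²⁺:
   total = B_max·c/(c + K_d) + c.
3. **Uptake kinetics** — the refill after caffeine depletion (release
   channel blocked with ruthenium red; the first second of washout
   excluded) is smoothed and differentiated, giving the uptake rate
   d[Ca²⁺]/dt as a function of the instantaneous load. Inter-wave refills
   of spontaneous Ca²⁺ waves sample the same relation without pharmacology.
4. **Two-stage decomposition** — a line rate = a·(Ca_max − load) fitted
   above 0.3 mM captures the thermodynamic back-pressure; the low-load
   ratio observed/predicted is a dimensionless activation, fitted with the
   hyperbola load/(load + K_d) to yield the apparent luminal affinity K_d.

The package implements this chain end to end (`calumen.sensor`,
`calumen.buffering`, `calumen.kinetics`, `calumen.luminal`,
`calumen.pipeline`) plus a forward kinetic simulator (`calumen.simulate`)
of a single luminal compartment,

    dx/dt = J_up(x) − g(t)·ca_free(x),
    J_up  = v_max·[(1−a₀)·xⁿ/(xⁿ + K_lumⁿ) + a₀]·max(0, 1 − x/Ca_max),

which regenerates depletion–refill traces, wave traces, mutant and
pump-inhibited controls with full ground truth, so recovery of K_lum,
Ca_max and the flux–load curve can be asserted quantitatively.

## Worked example

Simulate a 10-cell wild-type cohort (HEK-like profile: free-Ca load
variable, no buffering) and analyze it:

```sh
calumen simulate --profile hek --construct WT --mode refill \
    --n-cells 10 --seed 1 --out traces/
calumen analyze --profile hek --traces traces/ --out results/
```

which prints

```
analyzed 10/10 cells; median luminal Kd = 0.145 mM
  low           [0.05,0.20) mM: 0.071 ± 0.002 mM/s (n=10)
  intermediate  [0.30,0.40) mM: 0.116 ± 0.005 mM/s (n=10)
  high          [0.60,0.80) mM: 0.032 ± 0.003 mM/s (n=9)
```

Reading: the cohort's apparent luminal affinity (half-activation of the
pump by luminal Ca²⁺) is 0.145 mM — recovering the 0.14 mM the generator
was parameterized with. Uptake at intermediate loads (0.116 mM/s) is well
above uptake at low loads (0.071 mM/s) despite the smaller gradient: the
signature of luminal activation. The high-load bin mean is small because
the pump is approaching its maximum load (back-pressure). `results/`
contains per-cell curves (`curves/*.csv`), the cell and bin tables, and a
`manifest.json` echoing the exact configuration and seed;
`calumen report --in results/ --plot` reprints the tables and draws the
flux–load curves.

The same machinery handles the myocyte profile
(`--profile myocyte`, calsequestrin correction enabled, loads and rates
total-Ca referenced), wave-mode recordings (`--mode wave`), and the mutant
and control presets (`--construct NCA3|NCA5|C875A|TG`); pump-dead controls
are excluded from cohorts with explicit `no-uptake` reasons rather than
dropped silently.

Library use mirrors the CLI:

```python
import calumen as cm

cohort = cm.simulate_cohort(cm.default_config("hek", "WT"), 40, seed=1)
report = cm.run_pipeline([r.trace for r in cohort], cm.RunConfig(profile="hek"))
print(report.kd_lum_median)         # 0.145 (mM)
```

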