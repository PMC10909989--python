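# Methods

## Model and assumptions

`glycoflux` models the glucose catabolism of a starved, glucose-refed cell
population as seven phenomenological rate equations over eight species
(see README for the laws). The design assumptions, in decreasing order of
consequence:

- **Lumping.** The ten-step glycolysis pathway is reduced to one reversible
  Glu→Pyr conversion; the entire TCA cycle plus oxidative phosphorylation is
  one mitochondrial pool draining irreversibly into two sinks (OxPP and
  CellComponents). The model's purpose is end-point ECA kinetics, not
  internal metabolite resolution.
- **Capacity control.** Glucose uptake and mitochondrial uptake are
  throttled by constant boundary quantities `Capacity_G` and `Capacity_M`
  through `(Capacity − pool)` factors. The capacities are *not* state: they
  are never consumed, and only regulate the forward (inbound) flux. This is
  what produces the two metabolic phases with constant rate constants —
  phase 1 of fast glucose-to-lactate conversion, phase 2 of lactate
  re-import into the mitochondria once glucose runs out.
- **Acidification proxy.** Extracellular lactate is taken as the sole driver
  of the assay signal. CO₂/bicarbonate acidification and the
  gluconeogenetic fate of lactate are not modelled.
- **Conservation.** Each reaction transfers material 1:1, so the species
  total is invariant and equals the initial glucose load — a structural
  property used as a runtime integrity check.
- **Drug modulation.** Doses are dimensionless model units in 0–10. The
  mapping from laboratory concentrations (µM oligomycin, mM 2DG) to model
  units is not established by the data this model targets, and the package
  deliberately leaves it undefined. The R2 modulation factor
  `1 + oligo·i2 − dg2·i1` is clamped at 0 from below: beyond dose 10 the
  printed law would turn the forward rate negative (a reversed enzyme).
  Within the working range the clamp is inactive. The factor applies only to
  the forward term, never to `kr_1·Pyr`. `i2` is one shared parameter for
  oligomycin's stimulation (R2) and inhibition (R6) roles.
- **Units.** Concentrations in µM, time in minutes. Rate constants are
  carried numerically as model units; no dimensional analysis is attempted
  for the composite capacity terms. Compartment volumes are fixed at 1 and
  excluded from the ODEs.

## Parameters

The A549 preset is the reference parameter set; LLCMK2 and HepG2 are
minimal-change variants (slower uptake and stronger lactate reversibility;
lower capacities and near-zero oligomycin sensitivity, respectively).
The parameters that matter most, with defaults (A549):

| name | default | role |
| --- | --- | --- |
| `k_in` | 1.2e-4 /min/conc | glucose uptake rate |
| `Capacity_G` | 500 conc | phase-1 throttle (glycolytic capacity) |
| `Capacity_M` | 50 conc | phase-2 throttle (mitochondrial capacity) |
| `kr_3` | 0.1 /min | lactate re-import; sets the phase-2 decline |
| `i1`, `i2` | 0.1, 0.1 | per-dose-unit drug sensitivities |
| `glu_ex0` | 20 000 µM | initial extracellular glucose (20 mM refeed) |

The remaining forward rates are 1 /min and reverse rates 0.01–1 /min, fast
relative to uptake, so intermediates never accumulate appreciably.

## Numerics

- **Integrator.** LSODA (automatic stiffness handling) with rtol 1e-8 and
  atol 1e-10·`glu_ex0` (floored at 1e-12 so a zero-glucose run is well
  posed). The capacity factors create fast transients near t = 0; an
  explicit fixed-step method would need dt ≲ 1e-3 min for comparable
  accuracy, which is exactly what the test suite's independent Euler oracle
  uses.
- **No projection.** The solution is not projected onto the nonnegative
  orthant during integration (projection would silently break
  conservation); instead the result is checked post hoc against
  −1e-6·`glu_ex0` and against 1e-6 relative mass drift, and the t = 0 sample
  is pinned to the exact initial condition.
- **Sink symmetry.** The TCA drain is computed as `v5 − (v6 + v7)` so the
  right-hand side is exactly permutation-symmetric in the two terminal
  sinks when `kf_5 = kf_6` and oligomycin is absent; swept one at a time,
  the two rate constants then produce bit-identical lactate kinetics.
- **Summary conventions.** The lactate peak is the grid argmax (earliest
  index on ties). "Glucose exhausted" means `Glu_ex` below 1% of `glu_ex0`
  (the degenerate `glu_ex0 = 0` run is exhausted at t_start; never-exhausted
  runs report +∞).
- **OAT protocol.** "±10% for eleven simulations" is realized as
  multiplicative factors 0.50–1.50 in steps of 0.10, baseline included.
  The qualitative "negligible effect" threshold used in tests is 0.1%
  relative change of the lactate peak at the ±10% factors; over the full
  ±50% span even the most inert rate constant (`kr_1`) moves the peak by
  ~0.12%, so full-span assertions use the measured scale rather than the
  0.1% label. Similarly, 2DG's suppression of the terminal sinks is
  asserted mid-run (inside phase 1): the 140-min *terminal* OxPP value is
  non-monotone in dose because moderate inhibition starts the
  lactate-reconsumption phase earlier.

## Assay preprocessing conventions

- **Normalization is division** by the matched cell-free control
  (subtraction is available behind a method tag but is never the default):
  any multiplicative drift shared by sample and control cancels exactly.
  Normalization precedes replicate averaging.
- **ECAR** is a centered sliding-window least-squares slope (default window
  2.45 min ≈ 7 samples, truncated one-sided at the edges), not a two-point
  difference — robust to point-to-point sensor noise and exactly linear in
  the signal.
- **Phase metrics** smooth with a centered 5-point moving average before
  peak detection (earliest time on ties) and average ECAR over [0, 70) min
  (phase 1) and (90, end] min (phase 2).

## Calibration

The measured curve is treated as an affine image of simulated `Lac_ex`; the
per-curve affine map is profiled out by ordinary least squares inside the
objective, and the declared free parameters (default: exactly the subset
that differs between the cell-line presets) are fitted by bounded
trust-region least squares in log-parameter space, multistarted from
log-uniform draws (default 10) inside default bounds of ×/÷10 of the base
value. The finite-difference step is 1e-4 in log space — comfortably above
the ODE solver's rtol-level output noise, which would otherwise corrupt the
jacobian. Fits are deterministic given the problem seed. Joint fits share
kinetic parameters across conditions, with one affine map per curve and
known per-condition doses.

## Synthetic data generator

The generator emulates one 96-well-plate run: 400 cycles at 0.35 min, three
conditions (control, oligomycin, 2DG — default model doses 0/5/5 units,
mid-range of the 0–10 sweep domain), three replicate wells per condition
plus three cell-free wells, signal `drift(t)·(a·Lac_ex(t) + b)·(1 + ε)`
with default affine map a = 0.004 RFU/µM, b = 10 RFU, linear multiplicative
drift (defaults: intercept 1, slope 0.001/min) shared plate-wide, and
i.i.d. multiplicative Gaussian noise (default σ = 1%, a declared convention
— the instrument's true noise is not characterized here). Everything is a
pure function of the config seed.

What it does *not* emulate: the pre-starvation initial ECA spike of
unstarved cells, CO₂-driven acidification, plate-position or temperature
effects, and any nonlinearity of the sensor response. Passing recovery
tests on this generator therefore demonstrates that the estimation
machinery is correct and well conditioned under the model's own
assumptions, not that those assumptions hold for any particular instrument.

## Problem sizes

The test suite and the acceptance script use the native problem sizes of
the protocol: 400-point grids, 11-run sweeps, 3 replicates per condition,
10 optimizer starts, and a dt = 1e-3 min Euler cross-check over the full
140-min window. The noise-calibration check uses 150 replicates on a
3-point grid.

## Known limitations

- Model units for doses and rate constants are not physical units; values
  are comparable across cell lines and conditions within this model only.
- The affine RFU↔lactate map absorbs cell density and sensor gain; it is
  profiled per curve and not identifiable separately from them.
- No identifiability analysis beyond parameter-recovery tests; no global
  optimization guarantee (bounded multistart local search only); no
  Bayesian uncertainty quantification.
- No mid-run events (drug addition during acquisition), no delays, no
  stochastic kinetics.
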