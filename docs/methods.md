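# Methods

`cin-ephys` re-implements, as a tested pipeline, the intrinsic-physiology
analysis used to characterize transplanted MGE-derived cortical
interneurons (CINs) in current clamp: extraction of passive and active
membrane features from families of current-step sweeps, rule-based
fast-spiking (FS) classification, per-animal aggregation, and two-group
statistics. Because no recordings are deposited for this kind of study, the
package ships a synthetic-data generator whose traces have *exact,
closed-form ground truth*, so every stage of the analysis is testable
without any download.

## Units and data model

All quantities are carried in the units the field plots: voltage mV,
current pA, time ms, resistance MΩ, capacitance pF, frequency Hz. With
these units, `Rin[MΩ] = ΔV[mV]/(ΔI[pA]/1000)` and
`Cin[pF] = 1000·τm[ms]/Rin[MΩ]`; conversions happen only at I/O
boundaries. A `Sweep` is one uniformly sampled voltage trace (0-based time,
half-open step window `[onset, offset)`); a `StepProtocol` is one cell's
ascending current-step family. Sweeps travel as long-format TSV (one row
per sample) with a JSON sidecar for per-cell metadata; floats are written
in shortest-repr form, which round-trips float64 exactly and makes repeated
writes byte-identical. The 14 mV liquid-junction-potential correction is a
pure voltage shift applied once (guarded against double application); by
default it is applied at load time to files whose metadata marks them
uncorrected.

## Feature definitions

* **RMP** — mean of the zero-current sweep over the pre-step baseline.
* **Rin** — Ohm's law on the steady-state deflection (last 20 % of the
  step, configurable) of small negative steps (−20 to −5 pA), averaged
  across qualifying sweeps.
* **τm** — single exponential `V(t) = V_ss + A·exp(−t/τ)` fitted by
  nonlinear least squares (log-linear initialization) to the pointwise
  *average* of the qualifying small-step sweeps, starting 1 ms after onset
  over a 200 ms window (the conventional range is 100–300 ms; 200 ms is the
  midpoint). τ outside (0.5, 100) ms is flagged.
* **Cin** — 1000·τm/Rin.
* **Sag** — steady state at the end of the designated 1 s hyperpolarizing
  step (−79 → −99 mV target) minus the peak negative potential during it.
* **AP threshold** — first sample at which dV/dt (central differences)
  crosses +10 mV/ms upward. Two guards reject noise: the voltage must rise
  ≥ 20 mV above the crossing before dV/dt returns below zero, and events
  within 1 ms merge. The guards are config keys; a bare derivative
  criterion fires on noise. Optional 3-point derivative smoothing is off by
  default.
* **AP amplitude / half-width / max rise & decay** — peak minus threshold;
  time between half-height crossings located by linear interpolation;
  extrema of dV/dt between threshold and the end of the falling phase.
* **fAHP** — threshold minus the trough immediately after the AP (window:
  peak → min(next AP, +10 ms, step offset)); absent when no trough falls
  below threshold. Single-AP properties come from the first spike at
  rheobase (the minimum positive current, 5 pA grid, evoking an AP from
  −79 mV).
* **mAHP** — mean of the 500 ms pre-step baseline minus the post-train
  trough within 500 ms after step offset.
* **Train features** — initial frequency = 1000/first ISI; steady-state
  frequency = mean instantaneous frequency over the four ISIs among the
  last five APs; adaptation ratio (AR) = steady/initial; spike-height
  accommodation = last AP amplitude / first AP amplitude; F/I slope =
  unweighted OLS of initial frequency against step amplitude over all
  suprathreshold sweeps, excluding sweeps whose AP count collapses by
  > 50 % versus the previous step (depolarization block). Train analysis
  uses the first suprathreshold sweep with initial frequency strictly
  > 150 Hz and ≥ 100 APs; when no sweep qualifies (typical of adapting,
  non-FS cells) the sweep with the most APs is used and flagged
  `qualifies = False`.

### Noise-robust extremum reads

A raw minimum over an n-sample window sits ~SD·√(2 ln n) below the true
trace, which at 0.1–0.3 mV noise is comparable to the quantities being
measured. Trough values are therefore refined: the argmin is located on a
smoothed copy and a local least-squares quadratic (recentred once on its
own vertex) provides the value — exact on noiseless traces, nearly
unbiased under band-limited noise. The fAHP uses a ±0.5 ms fit; the slow
mAHP and sag troughs use 10 ms/2 ms smoothing with a ±15 ms fit and a
±1 ms local mean respectively. The threshold voltage is read from a
least-squares line over the 8 ms approach before a first spike (the
pre-spike trajectory is flat there) and over ≤ 1 ms for later spikes in a
train, where the interspike recovery is curved; the fit never reaches past
the previous AP's afterhyperpolarization.

## FS classification and statistics

A cell is FS when at least two of three strict conditions hold:
APHW < 0.26 ms, AHP > 16.5 mV, AR > 0.56. The "AHP" entering the rule is
the fAHP of the first rheobase-evoked AP — the only single-AP
afterhyperpolarization the feature set defines; this reading is a
documented choice. Missing features count as unmet conditions (so non-FS
cells failing the 150 Hz rule remain classifiable); a cell with all three
missing is unclassifiable. FS fractions are computed per animal and then
summarized as mean ± SEM across animals per group.

Group comparisons use a two-tailed two-sample t-test; Welch's form is the
default and the pooled-variance form is available, since published work
often leaves the variant unstated. `ttest_from_summary` evaluates the same
statistics from printed mean ± SEM and n (SD = SEM·√n), which lets the
published fAHP (23.7 ± 1.0, n = 9 vs 20.1 ± 0.8, n = 7) and mAHP
(7.2 ± 0.5, n = 9 vs 5.2 ± 0.4, n = 6) comparisons be verified exactly:
both reach p ≤ 0.02 under both variants (Welch p = 0.0139 and 0.0081). A
Mann–Whitney U test (exact null for combined n ≤ 20 without ties,
tie-corrected normal approximation otherwise) covers the nonparametric
route. When both groups have zero variance and equal means the degenerate
comparison is reported as t = 0, p = 1.

## The synthetic-data generator

Template-based, closed-form generation is the primary testing substrate; a
dynamic adaptive-exponential integrate-and-fire (AdEx) layer provides
qualitative realism checks where no closed form exists.

Every sweep is assembled from analytic segments aligned to the sample grid
(default 50 kHz, so a 0.26 ms half-width spans 13 samples):

* **Passive sweeps** are single-compartment RC responses from rest; the
  sag step adds a Gaussian bump (width 25 ms) centred at max(8τm, 120) ms,
  after the RC transient has decayed, so the sampled minimum equals
  steady state minus the programmed sag.
* **Spiking sweeps**: the membrane approaches threshold exponentially at
  3 mV/ms; each AP rises and falls piecewise-linearly (half-width exactly
  (rise+fall)/2), descends at 60 mV/ms onto a *parabolic* trough
  (curvature 7 mV/ms², ±0.72 ms) and recovers exponentially toward
  threshold with initial slope 5 mV/ms. Spikes take off from the
  instantaneous value of this trajectory — at short ISIs the takeoff sits
  below nominal threshold, as in real FS trains — and every per-spike
  takeoff, peak and fAHP is computed in closed form. After the step an
  alpha-function mAHP is painted whose sampled minimum is exactly the
  programmed depth. All interspike slopes sit well below the 10 mV/ms
  criterion, so derivative-based detection is exact on these traces.
  The generator never re-measures its own output: the emitted ground truth
  comes from the same closed forms as the trace.
* **Noise** is band-limited Gaussian: white noise smoothed with a 0.15 ms
  Gaussian kernel and rescaled to exactly the requested SD (zero mean per
  sweep). Recorded traces are hardware low-pass filtered, and white noise
  at 50 kHz would carry ~7 mV/ms of derivative noise, rendering a
  10 mV/ms criterion meaningless; band-limited noise is the physically
  sensible model. Its integrated autocorrelation is ≈ 0.53 ms, which the
  law-of-large-numbers tests account for via the effective sample size.

A full simulated cell carries: zero-current and −5…−20 pA sweeps from
rest, a sag step sized to a 20 mV hyperpolarization, a 5 pA rheobase
ladder, and three 50 pA-spaced suprathreshold steps whose initial
frequencies follow a programmed linear F/I relation (clamped to a 20 Hz
floor near rheobase), so the OLS F/I slope equals the programmed gain up
to grid snapping.

**Presets and cohorts.** The FS preset means (APHW 0.20 ms, fAHP 20 mV,
AR 0.75) satisfy all three classifier conditions; the non-FS means
(0.50 ms, 10 mV, 0.35) satisfy none; SDs are margin/4.5 so each condition
is cleared or violated with probability > 0.999 per cell. Cohorts sample
hierarchically (group → animal → cell) from truncated normals (±2.5 SD)
with per-cell seeds spawned from the cohort seed, making everything
reproducible bit-for-bit. The two-genotype cohort mirrors the published
comparison: FS fAHP 23.7 vs 20.1 mV and mAHP 7.2 vs 5.2 mV with SDs
back-computed from the printed SEMs (SD = SEM·√n — a reconstruction, not
the authors' data structure), AR means 0.61 vs 0.75, target FS fractions
45 % vs 56 %, and 5 vs 4 animals. Holding at −79 mV is represented by an
explicit holding-current field plus baseline offset rather than a solved
bias current; the analysis uses only the baseline value.

**AdEx layer.** `C dV/dt = −gL(V−EL) + gL·ΔT·exp((V−VT)/ΔT) + I − w`,
`τw dw/dt = a(V−EL) − w`, explicit Euler at the sweep rate (rejected when
dt ≥ τ/10), spike reset with increment b, waveform painted with the AP
template. Documented as approximate; tests compare it against a 10× finer
integration step and the RC closed form in the subthreshold limit.

## What the synthetic data does and does not show

The generator reproduces the *geometry* the feature definitions measure
(thresholds, widths, troughs, ISI schedules) with known truth, plus
realistic noise amplitude and bandwidth. It does not model channel
dynamics, spike-shape variability within a train beyond programmed
amplitude accommodation, depolarization block, electrode/bridge artifacts,
or trial-to-trial drift. Passing recovery tests therefore demonstrates
that the measurement code implements its definitions accurately and
robustly at realistic noise — not that those definitions are optimal for
any particular recording.

## Numerical choices and problem sizes

Exponential fits use `scipy.optimize.curve_fit` with log-linear
initialization and bounded τ; ties and degenerate windows raise typed
errors rather than returning silently. Feature-recovery acceptance runs a
seeded grid of 100 template cells (alternating presets; one cell in five
noiseless, the rest at 0.1–0.2 mV) and asserts *median* absolute errors —
single-sample extremum reads at 0.2 mV noise have irreducible per-cell
scatter comparable to the tolerances, so the per-cell claim is made only
on the noiseless subset. Statistical calibration uses 2000 null
replicates (n = 10 per group); the exact Mann–Whitney test is
conservative by discreteness (achievable level ≈ 0.043 at this n), which
the [0.04, 0.06] band accommodates. Detection oracle equivalence runs 50
seeded sweeps against an exhaustive scan. The two-genotype cohort runs at
4 cells per animal (36 cells); at n ≈ 10 FS cells per group the Welch
p-value on extracted fAHP fluctuates around the published ≈ 0.014, as
expected at this sample size.

## Known limitations

* The tabular sweep format is desk-scale by design; vendor formats (ABF,
  NWB) are not read — converters would map cleanly onto `Sweep` but are
  out of scope here.
* The classifier's "AHP" is taken as the rheobase-AP fAHP; if a different
  AHP measure was intended by the original rule, thresholds may shift.
* Group comparisons assume two groups; multi-group designs (ANOVA/Tukey)
  are out of scope.
* The AdEx layer is a realism probe, not a fitting target; no parameter
  estimation is provided for it.
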