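# cin-ephys

Intrinsic current-clamp electrophysiology of cortical GABAergic
interneurons (CINs): a tested, reproducible pipeline for extracting
passive and active membrane features from current-step sweep families,
classifying fast-spiking (FS) interneurons with a transparent rule, and
comparing two experimental groups — together with a synthetic-data
generator whose voltage traces carry exact, closed-form ground truth.

## Who this is for

Slice physiologists and analysts who measure intrinsic properties of
interneurons (for example, transplanted MGE-derived CINs expressing
disease-gene variants) and want the analysis chain — not just the final
statistics — to be testable. Every feature definition is implemented
against synthetic traces whose true values are known analytically, so the
pipeline's accuracy is a measured quantity, not an assumption.

## What it computes

Passive features from small negative steps from rest: resting membrane
potential (RMP, mV), input resistance by Ohm's law
(Rin[MΩ] = ΔV/(ΔI/1000)), membrane time constant from a single-exponential
fit to the averaged step response (τm, ms), capacitance
Cin[pF] = 1000·τm/Rin, and the sag of a 1 s hyperpolarizing step
(−79 → −99 mV target). Active features from a 5 pA rheobase ladder and
50 pA suprathreshold steps at a −79 mV holding level (after a 14 mV
liquid-junction correction): AP threshold at the 10 mV/ms dV/dt crossing,
amplitude, half-width at half-height, maximal rates of rise and decay,
fast afterhyperpolarization (fAHP = threshold − trough) from the first
rheobase spike, post-train medium AHP (mAHP), F/I slope from initial
frequencies (reciprocal of the first interspike interval), adaptation
ratio AR (steady-state frequency over the last five APs ÷ initial
frequency) and spike-height accommodation. Train analysis uses the first
suprathreshold sweep exceeding 150 Hz initial frequency with ≥ 100 APs.

Cells are classified FS when at least two of three strict conditions hold:

    APHW < 0.26 ms,   AHP > 16.5 mV,   AR > 0.56

FS fractions are aggregated per animal (mean ± SEM across animals per
group), and features are compared between groups with a two-tailed
two-sample t-test (Welch default, pooled available), a Mann–Whitney U
test, or — given only printed mean ± SEM and n — a summary-statistics
t-test that reconstructs SD = SEM·√n.

See `docs/methods.md` for the full model of the synthetic traces, the
noise model, and every numerical choice.

## Worked example

```python
from cin_ephys import make_fs_and_nonfs_presets, simulate_cell, ttest_from_summary
from cin_ephys.pipeline import extract_cell

fs, _ = make_fs_and_nonfs_presets()
protocol, truth = simulate_cell(fs.mean_cell(), cell_id="demo",
                                noise_sd=0.2, seed=7)
rec = extract_cell(protocol)
print(f"RMP {rec['rmp']:.1f} mV   Rin {rec['rin']:.0f} MΩ   "
      f"τm {rec['tau_m']:.1f} ms   Cin {rec['cin']:.0f} pF")
print(f"rheobase {rec['rheobase_pA']:.0f} pA   threshold {rec['v_threshold']:.1f} mV   "
      f"APHW {rec['half_width']:.3f} ms   fAHP {rec['fahp']:.1f} mV")
print(f"AR {rec['adaptation_ratio']:.2f}   mAHP {rec['mahp']:.1f} mV   "
      f"F/I {rec['fi_slope']:.2f} Hz/pA   class {rec['fs_class']} "
      f"({rec['conditions_met']}/3 conditions)")
print(ttest_from_summary(23.7, 1.0, 9, 20.1, 0.8, 7, feature="fAHP").summary())
```

prints

```
RMP -66.0 mV   Rin 150 MΩ   τm 10.3 ms   Cin 69 pF
rheobase 35 pA   threshold -41.0 mV   APHW 0.201 ms   fAHP 19.9 mV
AR 0.75   mAHP 7.0 mV   F/I 1.20 Hz/pA   class FS (3/3 conditions)
fAHP: 23.70 ± 1.00 (n=9) vs 20.10 ± 0.80 (n=7); t = 2.811, df = 13.92, p = 0.01394 [welch]
```

The first three lines are the extracted record of a simulated FS cell at
0.2 mV noise — the generator programmed this cell with Rin 150 MΩ,
τm 10 ms, rheobase threshold 33 pA (5 pA grid → 35), half-width 0.20 ms,
fAHP 20 mV, AR 0.75 and mAHP 7 mV, so each printed value can be checked
against its truth. The last line verifies a published FS fAHP group
difference from its printed summaries alone: 23.7 ± 1.0 mV (n = 9) versus
20.1 ± 0.8 mV (n = 7) gives Welch t = 2.81, p = 0.014 (p ≤ 0.02 also under
the pooled variant).

A command-line workflow covers the same steps on files:

```bash
cin-ephys simulate --seed 0 --out run/        # sweeps.tsv + ground_truth.tsv
cin-ephys extract  --input run/sweeps.tsv --out run/
cin-ephys compare  --table run/cell_records.tsv --out run/
```

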