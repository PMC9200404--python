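# spncat

Catalogue-scale evaluation of the **sustained posterior negativity (SPN)**,
the ERP difference wave elicited by visual symmetry: amplitude is more
negative at posterior electrodes (typically PO7/O1/O2/PO8, 300–1000 ms
post-stimulus) when observers view regular rather than random displays.

`spncat` is for EEG researchers who hold a *catalogue* of condition-averaged
ERP epochs — many experiments, published and unpublished — and want to audit
it the way meta-research audits a literature:

* **Extraction** — windowed cluster amplitudes, per-participant difference
  waves, paired statistics (mean, SD, `d_z = mean/SD`, t, p, directional
  proportion), P1/N1 component amplitudes.
* **Effect size & power** — a quadratic map `d̂ = a·x² + b·x + c` from
  grand-average amplitude `x` (µV) to the within-subject effect size `d_z`;
  exact power of the one-sample (paired) t-test from the noncentral t
  distribution (ncp `|d|√n`, df `n−1`); the smallest `n` reaching a target
  power; exact two-tailed sign-test thresholds for the nonparametric analogue.
* **Publication bias** — published vs unpublished comparison (Welch t,
  Mann–Whitney), DerSimonian–Laird random-effects pooling with τ², Q and I²,
  cumulative amplitude distributions with confidence bands, funnel plots and
  Egger's asymmetry regression.
* **Vibration of effects** — every SPN recomputed under alternative a priori
  electrode clusters (`{PO7,O1,O2,PO8}`, `{PO7,PO8}`, the 16-electrode
  bilateral posterior set), significance counts, χ² homogeneity tests,
  cross-cluster amplitude correlations, and one-way repeated-measures ANOVA
  with post-hoc observed power.
* **Spatio-temporal clustering** — a from-scratch cluster-based permutation
  test over electrode × time (cluster mass = Σt, per-participant sign-flip
  null, separate negative/positive null distributions), extraction of the
  most significant negative cluster, electrode-occurrence maps, and
  data-driven SPN re-extraction.
* **Synthetic catalogues** — a seeded generator emulating stage-v data
  (trial-averaged condition epochs): posterior topography, P1/N1 transients,
  a plateau-shaped regular-minus-random negativity whose expected amplitude
  follows the two-predictor regression
  `amp(µV) = 0.071 − 1.669·W − 0.416·Task`, between-participant variability,
  and a publication rule favouring stronger responses — so every analysis is
  testable without any recordings.

## Worked example

How large a sample does an SPN of a given amplitude require?

```python
from spncat import (EffectSizeModel, PowerQuery, binomial_critical_count,
                    power_one_sample_t, predict_dz, required_n)

model = EffectSizeModel(a=0.13, b=0.95, c=-0.03, r_squared=0.86, n_points=249)
for amp in (-0.5, -1.0, -1.5):
    d = predict_dz(model, amp)
    n = required_n(PowerQuery(d=d))
    print(f"SPN {amp:+.1f} uV  ->  d_z = {d:+.4f},  required n = {n}")
print(f"power at n=24 for d=0.469: {power_one_sample_t(PowerQuery(d=0.469, n=24)):.3f}")
print(f"sign-test threshold, n=24: {binomial_critical_count(24)}/24")
print(f"sign-test threshold, n=48: {binomial_critical_count(48)}/48")
```

prints

```
SPN -0.5 uV  ->  d_z = -0.4725,  required n = 38
SPN -1.0 uV  ->  d_z = -0.8500,  required n = 13
SPN -1.5 uV  ->  d_z = -1.1625,  required n = 8
power at n=24 for d=0.469: 0.595
sign-test threshold, n=24: 18/24
sign-test threshold, n=48: 32/48
```

Reading: a −0.5 µV SPN has a typical within-subject effect of `d_z ≈ −0.47`;
detecting it with 80% power (two-tailed α = .05) takes 38 participants,
while the common sample of 24 gives only ~60% power — a coin-flip-and-a-bit
chance of replicating a just-significant effect. Nonparametrically, 18 of 24
participants must show the directional effect (regular < random); doubling
the sample relaxes the threshold to two-thirds (32/48).

The full pipeline runs from one config:

```bash
spncat simulate --seed 7 --n-experiments 40 --out runs/demo
spncat extract  --catalogue runs/demo/simulate/catalogue \
                --cluster "PO7,O1,O2,PO8" --window 300:1000 --out runs/demo
spncat bias     --catalogue runs/demo/simulate/catalogue --out runs/demo
```

or `spncat report --config run.yaml` for all six stages (simulate, extract,
power, bias, vibration, stcluster) with a manifest and schema-validated
`metrics.json`.

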