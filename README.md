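# ctcap

Estimating the effective dose of a **chest-abdomen-pelvis (CAP) CT scan from
a patient's height and weight** — for the situation where the scanner's dose
report (CTDI_vol, DLP) has been lost, as happens when trauma patients move
between facilities. The package is aimed at medical physicists and
dose-tracking researchers who want the full chain behind such a predictive
model as tested, reproducible code.

It implements:

* **Scalable stylized phantoms** — a MIRD-style hermaphrodite anatomy
  (trunk/head/legs elliptical cylinders, ellipsoidal organs) scaled to any
  (height, weight) so that body mass tracks weight exactly, plus the
  deterministic 10 x 10 height x BMI design population (BMI 18-36, heights
  5'1"-6'7").
* **A desk-scale Monte Carlo dose engine** — Woodcock tracking, photoelectric
  + Klein-Nishina incoherent scattering under the kerma approximation, a
  Kramers 120 kV spectrum hardened to a 7.4 mm Al half-value layer, four
  projections (AP/PA/RLAT/LLAT) per 10 mm axial slice, helical conversion by
  1/pitch, entrance-air-kerma normalization.
* **Effective-dose assembly** — ICRP-103 tissue weighting over the
  dosimetered organs with a four-organ remainder (w = 0.12 on the mean of
  pancreas, uterus, kidney, adrenals/gall bladder), and the machine-side
  chain CTDI_w = (2/3)p + (1/3)c, CTDI_vol = CTDI_w/pitch,
  DLP = CTDI_vol x L, E = DLP x CC with CC = 0.015 mSv/(mGy cm).
* **Regression and model selection** — OLS over {H, H², W, W²} with
  exhaustive BIC subset selection, and the frozen published model
  **E (mSv) = 18 + 0.067 H(cm) − 0.11 W(kg)**.
* **Method comparison** — paired t-test and Bland-Altman agreement analysis
  (bias, ±1.96 SD limits) between the predictive model and DLP x CC, on a
  synthetic 28-patient cohort reproducing the published summary statistics
  (median height 170.25 cm, weight 72 kg, BMI 26, DLP 956.19 mGy cm, three
  BMI outliers above 36 and one at 35).

## Worked example

Predict the dose for a patient at the cohort medians, then compare the two
estimation pathways on the synthetic cohort:

```bash
$ ctcap predict --height 170.25 --weight 72
{
  "height_cm": 170.25,
  "weight_kg": 72.0,
  "bmi": 24.84038114459819,
  "effective_dose_mSv": 21.48675,
  "extrapolated": false
}
```

21.49 mSv is the height/weight model's estimate; `extrapolated` would flag a
BMI outside the 18-36 training span. The machine-side method for the median
DLP gives a lower value — the predictive model's known positive bias:

```bash
$ ctcap dlp-dose --dlp 956.19
{
  "dlp_mGy_cm": 956.19,
  "effective_dose_mSv": 14.34285
}
```

The full pipeline (phantom population → Monte Carlo organ doses → effective
doses → BIC-selected fit → cohort validation):

```bash
$ ctcap run-all --outdir run --seed 1 --n-per-axis 7 --photons 10000
selected terms ('H', 'W', 'W2'), R^2 = 0.995
{
  "bland_altman": {
    "bias_mSv": 5.926552792436534,
    "sd_diff_mSv": 5.249338821592187,
    "loa_low_mSv": -4.362151297884153,
    "loa_high_mSv": 16.21525688275722
  },
  "p_value": 2.2648120359111995e-06,
  "n_flagged_bmi": 4
}
```

The selected model carries a positive height and negative weight
coefficient (taller patients at fixed weight are slimmer and absorb more
dose per organ; heavier patients attenuate more), the plain height+weight
fit explains R² ≈ 0.96 of the simulated dose variation, and on the
validation cohort the predictive model reads on average ~6 mSv higher than
DLP x CC, a significant difference (p < 0.001) whose line of equality
nonetheless stays inside the limits of agreement. `--full` restores the
full-scale study (10 x 10 grid, 10⁶ photons/slice).

Library use mirrors the CLI: see `ctcap.run_model_development`,
`ctcap.run_validation`, and the module docstrings; `docs/methods.md`
documents the models, free parameters and limitations.

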