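# Methods

`ctcap` re-creates, end to end, a dosimetry chain for estimating the
effective dose of a chest-abdomen-pelvis (CAP) CT scan from a patient's
height and weight, and for comparing that predictive pathway against the
machine-side DLP x conversion-coefficient method. This note records the
models, the free parameters and their defaults, the numerical choices, and
what the synthetic data can and cannot establish.

## 1. Phantom model and population design

The anatomy is a MIRD-style stylized hermaphrodite: trunk, head and legs as
elliptical cylinders of soft tissue (water-equivalent, 1.04 g/cm3), organs
as ellipsoids, lungs at 0.26 g/cm3. The packaged reference corresponds to
178.6 cm / 73.2 kg; its dimensions are this package's own choice (organ
half-axes and centroids are plausible but schematic — multi-part organs are
single or paired ellipsoids, and both uterus and testes are present in every
phantom, pooled as one `uterus_testes` entry to match the dosimetered organ
list).

Scaling to an arbitrary (height H, weight W): longitudinal dimensions scale
by `H/H_ref`; every transverse dimension scales by
`sqrt((W/W_ref)/(H/H_ref))`. Body volume then scales exactly as `W/W_ref`,
so tissue densities are preserved and total phantom mass tracks the
requested weight (to <1%, dominated by geometric bookkeeping). Trunk
cross-sectional area is proportional to weight per unit height, which is
what produces the negative weight / positive height dose behaviour the
regression later recovers. A BMI plausibility envelope (default 15-45)
triggers a non-fatal extrapolation warning recorded in provenance.

The design population is a deterministic 10 x 10 grid: heights evenly
spaced over 154.94-200.66 cm (5'1" to 6'7") crossed with BMI levels evenly
spaced over 18-36, each converted to a weight. This respects the
ten-observations-per-predictor rule-of-thumb behind the 100-phantom design
while being exactly reproducible; the true height/weight list of the
original population is not recoverable.

## 2. Photon transport

The engine is a desk-scale Monte Carlo with Woodcock (delta) tracking and
two interaction channels: photoelectric absorption (full local deposition)
and incoherent scattering sampled from the Klein-Nishina distribution by
the standard two-branch rejection method. Secondary electrons deposit
locally (kerma approximation — adequate at CT energies where electron
ranges are millimetres). Coherent scattering is not transported; its share
of the total attenuation coefficient is lumped into the absorbing channel,
which slightly (a few percent below ~30 keV) overweights local deposition.
Photons falling below the low-energy cutoff (default 5 keV) deposit their
remaining energy locally, so deposited energy never exceeds emitted energy
in any run, not just in expectation.

Mass attenuation and mass energy-absorption tables for water, air,
aluminum and cortical bone are packaged as CSV on the standard compilation
grid (5-150 keV) and interpolated log-log; soft tissue and lung use the
water table at their own densities (a 1-2% approximation at CT energies).
The incoherent coefficient is built analytically from the Klein-Nishina
cross section and the medium's electron density, clipped to the tabulated
total.

A CAP acquisition is modelled as contiguous 10 mm axial slices covering the
trunk, each exposed by four parallel-beam projections (AP, PA, RLAT, LLAT)
collimated to the slice — the four-projection stand-in for a 360-degree
rotation. The per-slice photon budget (protocol default 10^4 for tests and
the reduced pipeline; 10^6 reproduces the full-scale study via
`ctcap run-all --full`) is split equally over the projections. Helical
conversion divides the summed axial doses by the pitch (default 1.375),
applied after summation (the order is irrelevant for a scalar division;
fixed for provenance clarity).

Absolute normalization: each projection delivers a stated free-in-air
entrance air kerma at the entrance plane; the simulated fluence is scaled
so the spectrum-averaged `E x (mu_en/rho)_air` reproduces it exactly. The
per-projection kerma is a genuinely free parameter (the original
measurement values are unpublished): the packaged default, 13.33 mGy per
projection per slice, was calibrated once so the reference phantom's
helical CAP effective dose lands at 13.0 mSv, the scale of the
anthropomorphic measurements, and then frozen. All organ doses are exactly
linear in this normalization, so it cannot affect regression signs,
R-squared, or any comparison statistic — only the absolute scale.

The tube spectrum is a Kramers bremsstrahlung shape at 120 kV (1 keV bins,
no characteristic lines) hardened by an aluminum thickness solved by
bisection so the air-kerma-weighted first HVL equals 7.4 mm Al (solved
filter: 10.7 mm; mean energy 63 keV). Anode angle (7 degrees) is carried as
beam metadata. Monoenergetic spectra are available for oracle tests, where
HVL = ln2 / mu_Al(E) in closed form.

Randomness: a counter-based splitmix64 stream per (slice, projection,
batch), with substream seeds derived through `numpy.random.SeedSequence`,
so results are bit-reproducible and independent of execution order.
Uncertainties are one-sigma batch statistics (default 10 batches).

## 3. Effective dose

Two pathways, deliberately kept separate:

* **Organ-dose pathway**: `E = sum_T w_T H_T`, with the tissue-weighting
  factors of the dosimetered-organ subset (brain 0.01; colon and lung 0.12;
  esophagus, liver, thymus, thyroid 0.04; remainder 0.12 applied to the
  unweighted mean of pancreas, uterus, kidney and adrenals/gall-bladder).
  These sum to 0.53, not 1.0 — undosimetered tissues (skin, breast, marrow,
  gonads-as-gonads, ...) are absent. The scheme is kept exactly as used for
  the anthropomorphic tables so those results reproduce; any full ICRP-103
  set can be supplied as a YAML config. Eyes are measured but carry no
  weighting factor and are excluded from E.
* **Machine-side pathway**: CTDI_w = (2/3)p + (1/3)c; CTDI_vol = CTDI_w /
  pitch; DLP = CTDI_vol x length; E = DLP x 0.015 mSv/(mGy cm).

Percent differences are reported relative to the mean of the two values,
`100 |a-b| / ((a+b)/2)` — the only convention consistent with the
published 9%, 5% and 33% figures simultaneously — rounded to integer
percent at the reporting layer only. OSL dosimeter readings carry a
multiplicative 1.15 energy-response correction (80 kVp calibration used at
120 kVp).

The predictive-model pathway (~21 mSv at the cohort medians) and the
organ-dose pathway (~13 mSv) sit on different absolute scales, as in the
source study; the package does not force them to agree — the entrance-kerma
normalizations behind them are independent.

## 4. Regression and selection

Candidates are H, H^2, W, W^2 with an always-included intercept. Fits are
ordinary least squares (via `statsmodels`); selection minimizes
`BIC = n ln(RSS/n) + k ln(n)` (Gaussian-likelihood form, k counting the
intercept) over all 16 subsets, with ties broken toward fewer terms then
lexicographic term order. An optional univariate screen (default on) admits
only terms with univariate p < 0.05. Numerical guard: RSS is floored at
1e-12 x TSS before the log so that exact fits compare by parsimony rather
than by floating-point noise.

The published model, E = 18 + 0.067 H - 0.11 W (R^2 = 0.96), is frozen as
`PUBLISHED_MODEL`, separate from any refit. Predictions outside the training
BMI span (18-36) carry a non-fatal extrapolation flag. Per-unit coefficient
effects can be expressed as percent of a reference dose; the reference
implied by the published "0.3%/cm" and "0.5%/kg" figures (~22.3 / 22.0 mSv)
is back-derived, not asserted.

At the full 10 x 10 / 10^4-photon scale, model development selects
(H, W, W^2) with H positive and W negative, and the plain H+W fit gives
R^2 = 0.96. On smaller grids (5 x 5) the univariate screen can drop H
(p ~ 0.11 at n = 25) and selection falls to (W, W^2): the height signal is
~0.04 mSv/cm and needs n ~ 50 to be resolved. Acceptance testing therefore
uses a 7 x 7 grid (49 phantoms, 10^4 photons/slice, ~1 minute), the
smallest design where both the selection content and the R^2 band are
stable.

## 5. Synthetic validation cohort

The real 28-patient cohort exists only as printed summaries. The generator
draws truncated-normal heights (median 170.25 cm, SD 8 cm, range 150-205)
and BMIs (median 26, SD 3.5, non-outlier range 19.5-34.4), injects exactly
three BMI values above 36 (uniform 36.5-40.5) and one at 35.0, derives
weight from BMI and height, and draws DLP lognormally (sigma_log 0.22)
around median 956.19 mGy cm with a log-scale BMI slope of 0.015 per BMI
unit (the simplest mechanism giving the observed positive BMI-DLP trend and
"very large" outlier DLPs). The SD/slope/sigma values are free parameters
chosen once from the printed dispersions (21 +/- 2 and 15 +/- 5 mSv) and
frozen.

The printed medians are mutually inconsistent at the ~5% level
(26 x 1.7025^2 = 75.4 kg, not 72 kg), so cohorts are resampled
(deterministically, up to 2000 attempts per seed) until all four realized
medians — height, weight, BMI, DLP — fall within 3% of their targets;
accepted cohorts necessarily sit where sampling fluctuation reconciles the
targets. Under these defaults the cohort reproduces: predictive-model mean
~20.9 mSv, DLP x CC mean ~15.0 mSv, Bland-Altman bias ~5.9-6.3 mSv, paired
t-test p << 0.001, and exactly four patients at or beyond the training BMI
range.

The validation stage compares the *published* predictive model against
DLP x CC by default (`ctcap run-all --validate-refit` substitutes the
refitted model); the refit sits on the Monte Carlo engine's own kerma
normalization, so validating it against DLP x CC would conflate the two
absolute scales discussed in section 3.

What the synthetic cohort does *not* establish: agreement of the two
methods on real patients (the generator encodes the association structure
it is tested against), scanner-specific mA-modulation effects, or
scan-length variation independent of DLP.

## 6. Agreement analysis

Bland-Altman differences are oriented predictive-model minus DLP x CC; the
bias is their mean, limits of agreement are bias +/- 1.96 x SD with the
n-1 sample SD. The paired t-test uses t = mean(d) / (SD(d)/sqrt(n)) on
n-1 degrees of freedom, two-sided (p-values from the scipy t
distribution). Zero-variance nonzero-mean differences are reported as
p = 0 with a degeneracy flag; all-zero differences as t = 0, p = 1. That
zero lies inside the limits of agreement is checked on synthetic cohorts
but not enforced.

## 7. Problem sizes and degenerate inputs

Default test/pipeline problem sizes are scaled down from the full study
(10^4 photons per slice instead of 10^6, 5 x 5 to 7 x 7 grids instead of
10 x 10); the statistical penalty is visible only in per-organ sigmas
(~1%), and the full scale is one flag away. Degenerate inputs fail loudly
and early: non-positive measurements, pitch <= 0, empty projections,
photon counts below the batch count, missing organs (named in the error),
rank-deficient designs, unsatisfiable cohort constraints.

## 8. Known limitations

* Stylized single-ellipsoid organs and water-equivalent media put per-organ
  doses within tens of percent of anatomical reality, not percent; the
  pipeline's claims are about structure (signs, R^2, agreement statistics),
  not organ-level accuracy.
* No bowtie filter, fan-beam divergence, tube-current modulation, electron
  transport, or coherent scattering; the beam is parallel and collimated to
  the slice.
* The tissue-weighting subset (sum 0.53) understates a full ICRP-103
  effective dose by construction; it is the right scheme for reproducing
  the anthropomorphic tables, not for prospective dosimetry.
* The two effective-dose pathways carry independent absolute
  normalizations; only one (DLP x CC) is anchored to machine output.
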