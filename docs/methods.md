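# Methods

This note documents the models, numerical choices, and limitations of
fnirskit's processing chain and of the synthetic-cohort generator used to
validate it.

## Measurement model and hemoglobin recovery

A continuous-wave fNIRS channel measures back-scattered light intensity
at two wavelengths (760 and 850 nm) across a source-detector pair at
d = 2.5 cm separation. Relative to a baseline window, the
optical-density change is ΔOD(λ, t) = −log₁₀(I(t)/⟨I⟩_baseline), and the
modified Beer-Lambert law relates it linearly to chromophore
concentration changes:

ΔOD(λ) = [ε_HbO₂(λ)·ΔHbO₂ + ε_Hb(λ)·ΔHb] · d · DPF(λ).

With two wavelengths this is a 2×2 linear system per sample, solved
exactly (`mbll_invert`); the forward map (`mbll_forward`) is its inverse,
and the round trip is an identity to machine precision (asserted at
1e-9 µmol/L in tests). Concentrations are carried in µmol/L; total
hemoglobin is always *derived* as ΔTHb = ΔHbO₂ + ΔHb, so that identity
can never drift.

Parameter choices:

* **Baseline window** — the 30 s pre-task rest, the only stimulus-free
  period preceding the task.
* **Extinction coefficients** — Prahl's compiled in-vivo molar extinction
  values, ε(760) = (586, 1548.52) and ε(850) = (1058, 691.32)
  cm⁻¹(mol/L)⁻¹ for (HbO₂, Hb): the de facto standard table in CW-NIRS
  software. Configurable; the matrix must be nonsingular (condition
  number checked at inversion).
* **Differential pathlength factors** — 6 at 760 nm and 5 at 850 nm.
  Only the *pair* {5, 6} is conventionally reported for adult head
  tissue; the assignment of the larger factor to the shorter wavelength
  follows the empirical decrease of DPF with wavelength. Both values are
  configurable.
* **DPF sensitivity** — two readings of "error from a wrong DPF" exist:
  the error in the factor itself and the error it induces in recovered
  concentrations. They coincide when the same wrong scalar is used at
  both wavelengths (concentrations rescale by exactly
  dpf_true/dpf_wrong), so `dpf_sensitivity` reports both the analytic
  scaling error max_λ |dpf_true/dpf_wrong − 1| and the empirical maximum
  relative concentration discrepancy on the supplied series. For 6 vs 5
  both equal 20%.

## Motion-artifact correction

Detection combines two statistics computed per channel:

* the centred 2 s moving standard deviation exceeding both 3× its median
  and the whole-trace sd (sustained high-variance stretches), and
* single-sample jumps |Δx| exceeding 3 robust sds (MAD-based) of the
  first difference and half the trace sd (spikes and step onsets — a 5σ
  step moves a 2 s moving sd by at most 2.5σ and would otherwise escape).

Both criteria are gated on the whole-trace spread because a smooth
high-amplitude signal (e.g. a clean evoked response) has short-window
variability far below its overall excursion; this guarantees noiseless
synthetic subjects pass through untouched, which the closed-loop tests
rely on.

Each flagged segment (padded by half a window) is modelled by a
near-interpolating smoothing spline (λ = 1e-3 in sample units, cubic by
default); subtracting it removes the artifact trajectory. The residual
is re-levelled onto a bridge between the clean levels on either side.
The level change across the segment is compared with the trace's natural
level changes over the same lag (median absolute change of a rolling
mean): if it is more than 3× larger it is treated as a baseline-shift
artifact — the bridge stays flat and the entire tail is re-levelled,
using every unflagged sample on each side for a low-variance level
estimate — otherwise a linear bridge preserves the genuine trend. The
trade-off: signal detail *inside* an artifact segment is sacrificed, and
a genuine step-like physiological change coinciding with a detected
artifact would be flattened.

## Temporal filtering and the GLM

The hemodynamic band-pass is a 3rd-order Butterworth, 0.01–0.1 Hz,
applied forward-backward (`sosfiltfilt`) for zero phase. The design
choice that matters downstream: the GLM task regressor (block boxcar
convolved with the canonical double-gamma HRF — peak 6 s, undershoot
16 s, ratio 1/6 — scaled to unit peak) is passed through the *same*
filter before fitting. Since filtering is linear, the evoked component of
filtered data is β·filter(regressor); fitting against the identically
filtered regressor therefore keeps β on the original amplitude scale
(peak evoked ΔHbO₂ in µmol/L) and avoids the attenuation bias a raw
regressor would suffer. With band-passed data the drift column is
dropped (the filter already removes DC and drift); an unfiltered design
with intercept and linear drift is available for unfiltered series, as
is optional AR(1) prewhitening (Cochrane-Orcutt) for serially correlated
residuals — OLS is the default for transparency and testability.

A single regressor spans all four task blocks by default; a four-block
design (`per_block=True`) reports the mean block β, for designs where
block-wise effects matter.

## Laterality

LI = (L − R)/(L + R) with L, R the mean band-passed ΔHbO₂ over the left
and right channels of a region during the 60 s task window. The index is
undefined — recorded but excluded from group statistics — when
L + R ≤ 1e-3 µmol/L, *including* negative denominators: mean ΔHbO₂ can
legitimately be negative, and a negative denominator silently flips the
sign of LI, misclassifying the subject. Classification uses the
conventional ±0.1 thresholds (boundaries inclusive: LI = 0.1 is left,
−0.1 is right).

## Phase-locking connectivity

Instantaneous phase is the angle of the analytic signal (Hilbert
transform) of the band-limited ΔHbO₂ — the narrowband input is what makes
a single phase meaningful, hence PLV is computed only after the 0.01–0.1
Hz band-pass. Phase is extracted on the full record, the task window is
then sliced and 10% of it trimmed at each end to limit transform edge
effects, and PLV = |⟨exp(iΔφ)⟩| is computed for all 780 pairs by one
complex matrix product. For independent phases the expected PLV is the
Rayleigh resultant mean √π/(2√N) (≈ 0.051 at N = 300), which calibrates
the chance floor. PLV is computed on HbO₂, the chromophore with the
highest contrast-to-noise in this band.

## Group inference and multiple testing

All three measure families use the same machinery: feature-wise one-way
ANOVA (features = 40 channels, 780 pairs, or 2 regions), BH-FDR over the
omnibus family, then Welch two-sample post hoc contrasts only where the
omnibus survives, BH-corrected over the three contrasts within feature.
Welch is used post hoc because group variances are not assumed equal.
`anova_from_summary` / `t_from_summary` implement the identical tests
from (mean, sd, n) triples and agree with the raw-data route to 1e-9 on
moment-matched data; the two-sample t defaults to pooled variance, the
form under which published demographic t values reproduce. The BH
implementation is the step-up with enforced monotone q-values; it is
cross-checked against statsmodels in tests but not delegated to it, since
it is shared infrastructure for every family in the package.

Correlation analyses are normality-gated: Shapiro-Wilk at α = 0.05 on
both variables selects Pearson (both normal) or Spearman, and the
two-sided p is the t transform t = r√(n−2)/√(1−r²). Outlier exclusion
defaults to |studentized residual| > 3 from the least-squares line
(an IQR rule is available) and refuses to drop more than half the data.

## The synthetic cohort

The generator is the package's study model, not a fixture. Defaults
encode the three-group design at the study's scale (n = 30/group
configurable):

* **Evoked response** — peak ΔHbO₂ of 1.0 / 0.7 / 0.4 µmol/L for
  HEALTHY / T2DM / T2DM+MDD in the six task-responsive ROIs (FPA, DLPFC,
  Broca, PMC, STG, SMA), 0.2 µmol/L elsewhere: a graded hypoactivation
  of the depressed group at physiologically typical amplitudes.
* **Laterality** — left/right amplitude ratios 1.3 / 1.1 / 0.7, applied
  as √ratio and 1/√ratio to left and right channels, so the clean-signal
  LI is exactly (ratio−1)/(ratio+1): +0.13, +0.05, −0.18. The default
  channel→ROI map assigns each ROI two left and two right channels, so
  region means are hemisphere-balanced and LI is driven by the ratio
  alone rather than by ROI placement.
* **Phase coupling** — channels of a block mix a shared unit-sd
  narrowband (0.01–0.1 Hz) oscillator with an independent one:
  x = m·common + (1−m)·independent. The default block is CH1–5 at
  m = 0.8, reduced to 0.4 in the depressed group. PLV is monotone in m
  with PLV(1) = 1.
* **Noise** — sinusoids at 1.1 Hz (cardiac), 0.25 Hz (respiratory) and
  0.1 Hz (Mayer waves) with random phases and amplitudes 0.2 / 0.1 / 0.1
  µmol/L, in-band background at 0.15 µmol/L, white noise at 0.1 µmol/L,
  and a random linear drift (sd 0.002 µmol/L·s⁻¹).
* **Artifacts** — Poisson-timed at 0.5 events/min/channel: 70%
  single-sample spikes of 10 trace-sd, 30% baseline steps of 5 trace-sd
  persisting to the end of record.
* **Clinical scores** — truncated normals per group calibrated to a
  published elderly T2DM/depression cohort (e.g. HAMD-24 22.90 ± 2.67 in
  the depressed group vs 3.25 ± 2.43 and 3.75 ± 1.45; MOCA matched
  across groups), truncated at instrument bounds.

The forward model ends in intensities I = I₀·10^(−ΔOD) with ΔHb =
−0.3·ΔHbO₂ (I₀ = 1 detector unit; both documented conventions, not
estimates), so the full inverse pipeline is exercised end to end and
noiseless subjects recover their ground truth exactly.

What the generator does **not** emulate: photon transport through
realistic head geometry, scalp/systemic physiological compartments (no
short-separation channels exist in this montage), partial-volume
wavelength dependence, subject-specific HRF variability, or
heteroscedastic noise across channels. Passing recovery tests therefore
demonstrates the *inferential chain* is correct at realistic
signal-to-noise, not that the pipeline is robust to every failure mode of
real scalp recordings.

## Validation scale

Deterministic identities (MBLL round trip, summary-vs-raw statistic
agreement, published-table reproduction) run at full precision. The
stochastic recovery suite runs 20 seeded cohorts of 90 subjects: at
default noise the per-replicate margins (group-mean β gaps of ~5 standard
errors; within-block PLV contrasts far beyond the FDR threshold) put the
expected pass rate near 100%, so the 20-replicate estimate of the ≥90%
recovery criterion is not materially less informative than a larger run.
Null calibration uses 200 label permutations of one 90-subject cohort
for both the 40-channel and 780-pair FDR families.

## Known limitations

* The 2×2 MBLL ignores scattering changes and water absorption; it is
  the standard CW approximation, not a claim of absolute quantification.
* Step-artifact re-levelling assumes the underlying level is stationary
  across the artifact; slow genuine level changes spanning an artifact
  are flattened.
* The moving-sd detector's whole-trace-sd gate means low-amplitude
  artifacts on channels with strong evoked responses can escape
  detection; the band-pass removes most of what escapes.
* PLV on 300-sample windows at 5 Hz has a chance floor of ≈ 0.05 and
  saturates near 1; group contrasts, not absolute values, are the
  interpretable quantity.
* The default channel→ROI map is a documented stand-in; analyses at ROI
  resolution should supply the montage's true map via
  `default_layout(roi_blocks=...)`.
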