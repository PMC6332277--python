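# Methods

## The assay model

The pipeline implements internal-standard qNMR: an analyte and a weighed
internal standard are co-dissolved, a 1D ¹H spectrum is acquired, and the
analyte purity (or per-tablet content) follows from the ratio of two
integrated areas together with the gravimetric and molar bookkeeping
(README, equations for `P_x` and `m_x`). The model assumes:

- areas are proportional to molar proton amounts (the defining qNMR
  assumption), valid when the repetition delay TR is long enough that
  longitudinal relaxation is complete for every quantified site;
- the analytical signals are baseline-resolved, so a fixed integration
  window captures one signal each;
- first-order (weak) coupling: the signals of the fixture system are well
  separated relative to their couplings, so multiplets are rendered as
  2^k equally weighted lines at ±J/2 combinations and second-order
  roofing is ignored.

Incomplete relaxation is modelled explicitly: after a 90° pulse the
steady-state area scales by `1 − exp(−TR/T1)`. The delay check
`TR ≥ factor × max(T1)` uses a default factor of 5 (configurable), which
the default settings satisfy: TR = 60 s ≥ 5 × 3.076 s for the
slowest-relaxing standard signal (H-3, δ 8.72). The 2,4-DNT methyl at
2.63 ppm has no measured T1; it is kept in the system definition for
realism of simulated spectra (rendered fully relaxed — it sits far from
every analytical window) but the delay check refuses to certify it, and
it is never flagged for quantification.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| spectrometer frequency | MHz | 500.06 | field of the emulated instrument |
| spectral width | Hz | 10330.578 | ≈ 20.7 ppm window centred at 6.0 ppm |
| points | — | 65536 | 0.158 Hz/point; ≥ 8 points per linewidth |
| repetition delay TR | s | 60 | ≥ 5 × longest T1 (3.076 s) |
| line broadening | Hz | 0.3 | exponential apodization; adds to FWHM |
| natural linewidth | Hz | 1.0 | simulator's intrinsic Lorentzian FWHM |
| scans | — | 32 | linear area scale factor |
| integration half-width | linewidths | 30 | see "Integration windows" |
| noise region | ppm | 10.0–10.5 | signal-free in the fixture system |
| S/N threshold | — | 150 | ≤ 1% area uncertainty gate |
| noise σ | intensity | 0.084 | gives analyte-singlet S/N ≈ 1200 at 5 mg |
| weighing CV | — | 0.002 | reproduces replicate RSDs of a few ×0.1% |

Exponential apodization of a Lorentzian line is exactly additive in FWHM,
so the 0.3 Hz line broadening is folded into the rendered linewidth
(1.3 Hz total) and no time-domain stage exists.

## What the generator emulates — and what it does not

`synthetic_data` renders, per site, a Lorentzian multiplet whose total
area is `(mass/M) · purity · n_protons · (1 − exp(−TR/T1)) · n_scans` in
intensity·ppm units; the solvent volume cancels in every ratio and is not
modelled. On top: an optional polynomial baseline, broad Gaussian
excipient humps at 3.25/3.45/3.70 ppm (σ 0.12 ppm) for tablet-matrix
samples — positions are a fixture choice in the crowded sugar/polyol
region, not a claim about real excipients — and i.i.d. Gaussian noise per
point. Gravimetric error is emulated by perturbing the *true* dissolved
masses by a 0.2% CV while computations use the nominal masses.

Not emulated: correlated/1/f noise, field inhomogeneity and shimming
artifacts, solvent and ¹³C-satellite signals, phase errors,
temperature drift, second-order coupling. Passing tests therefore
demonstrate the correctness of the integration/quantification arithmetic
and the statistical structure of the validation battery under idealized
spectra; they do not validate robustness to instrument artifacts.

## Numerical choices

- **Integration** is trapezoidal on the ppm axis with inclusive region
  endpoints; areas are in intensity·ppm but only ratios are consumed, so
  the unit choice cancels.
- **Integration windows** default to ±30 total linewidths around each
  quantification site, clipped at the midpoint to neighbouring sites. A
  Lorentzian's tails beyond ±30 FWHM hold ≈ 1/(30π) ≈ 1.1% of its area,
  so *single-region* areas are biased low by about that much; the bias is
  common to analyte and standard regions and cancels in the area ratio to
  ~10⁻⁵ relative (the residual ~0.1% deviation of the simulated
  equal-mass ratio comes from tails of neighbouring standard signals
  leaking between the 8.45 and 8.72 ppm windows). Per-region accuracy is
  therefore documented at ~1%, ratio accuracy at well under 0.5%.
- **Noise** is the RMS of a signal-free region after removing a linear
  trend; S/N = peak height / (2 × noise), the common spectrometer
  "peak-to-peak" convention, with the multiplier configurable.
- **Baseline correction** subtracts a ≤ 5th-degree polynomial
  least-squares fitted through signal-free anchor regions.
- **%RSD** uses the n−1 sample standard deviation: this reproduces the
  published precision/stability/recovery RSDs (0.48 / 0.54 / 1.81 for
  δ 8.72) exactly from the printed columns, while the population (n)
  denominator does not.
- **Recovery** is computed against the amount added,
  100·(found − present)/added, which matches the published records within
  their 2-decimal input rounding.
- **Display rounding** is decimal half-up to 2 places (4 for R²); full
  precision is kept internally.
- **Degenerate inputs** fail loudly: zero/negative masses or standard
  areas, empty site lists, sites outside the spectral window, regions
  outside the axis, under-determined baseline fits and unknown T1 in a
  delay check all raise typed errors naming the offending quantity.

## Design choices where the design was open

- The published slope/intercept of the calibration lines (0.9347/−0.0021
  for δ 8.72) are not exactly recoverable from the 2-decimal printed
  columns (a fit of those gives ≈ 0.9333/+0.0011); they were evidently
  computed from unrounded integrals. R² — which *is* stable under the
  printed rounding — is the reproduction handle; the slope is checked
  against the closed-form response factor 2·182.14/389.4 = 0.93549
  instead.
- The internal standard's certified purity is treated strictly as user
  input with fixture default 1.000: the published calibration slope
  (≈ 0.934 ≈ response factor × P_x/P_std) is consistent only with
  P_std ≈ 1, not with the reagent's nominal "95%" grade label.
- The per-tablet content equation for the external-standard (HPLC) route
  multiplies by the HPLC reference-standard purity `P_s`; the printed
  formula's `P_std` symbol is read as that purity, since the internal
  standard plays no role in an external-standard calculation.
- Repeatability RSD: the printed column recomputes to 0.42 rather than
  the published 0.43 (again a rounding artifact); only the repeatability
  mean (99.95), which is stable, is asserted.
- Three-signal summaries are unweighted means: the source records report
  the signals separately and equally.
- Simulated experiment sizes mirror the real design: 6 calibration
  levels, 6 precision replicates, 9 recovery mixtures; the stochastic
  replicate-RSD property is evaluated over 200 seeds of 6 replicates
  each, which a laptop CPU completes in seconds.

## Known limitations

- No peak picking or deconvolution: overlapping signals must be handled
  by region choice, and heavily overlapped systems are out of scope.
- Imported JCAMP-DX spectra are assumed phased and in pure absorption;
  no phase correction is provided.
- The JCAMP writer emits AFFN only (the reader also accepts SQZ/DIF/DUP).
- HPLC support is the ratio arithmetic on already-integrated peak
  responses; chromatographic processing is out of scope.
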