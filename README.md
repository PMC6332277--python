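# qnmr

An internal-standard quantitative ¹H-NMR (qNMR) assay pipeline for drug
substances, built around the tadalafil / 2,4-dinitrotoluene (2,4-DNT)
system: simulate or import 1D frequency-domain spectra, integrate the
analytical signals, compute purity and per-tablet content, and run the
method-validation battery (linearity, limit of quantification, precision,
stability, spike recovery).

It is aimed at analytical scientists who want the *computational* half of a
qNMR assay — signal bookkeeping, integration, ratio equations and
validation statistics — as tested, scriptable code, with a seeded synthetic
spectrum generator standing in for the spectrometer.

## The method

qNMR exploits the direct proportionality between a resonance's integrated
area and the number of nuclei producing it. With a weighed internal
standard dissolved alongside the analyte, the analyte purity follows from
a single area ratio:

```
P_x = (A_x/A_std) · (N_std/N_x) · (M_x/M_std) · (m_std/m_x) · P_std · 100%
```

where `A` are integrated areas, `N` proton counts of the chosen signals,
`M` molecular weights, `m` weighed masses and `P_std` the standard's
purity. Content per tablet uses the same ratio referenced to a powder
aliquot and the average tablet weight `T`:

```
m_x = (A_x/A_std) · (N_std/N_x) · (M_x/M_std) · (m_std/m_powder) · P_std · T
```

In the default system, tadalafil (M = 389.4) is quantified on its 2-proton
methylenedioxy singlet at δ 5.91 ppm against the three aromatic 1-proton
signals of 2,4-DNT (M = 182.14) at δ 8.72 (d, J = 2.5 Hz), 8.45
(dd, J = 8.5, 2.5 Hz) and 7.82 ppm (d, J = 8.5 Hz), giving one purity
value per standard signal plus their mean and %RSD. A repetition-delay
check (TR ≥ 5 × T1, limiting site H-3 with T1 = 3.076 s) and an
S/N ≥ 150 quantification gate guard the run.

## Worked example

```
$ qnmr simulate --out demo --seed 1 --noise 0.084
wrote 6 spectra + manifest.csv to demo

$ qnmr quantify --spectrum demo/sim_03.jdx --m-std 5.56 --m-x 5.14
{
  "mode": "purity",
  "units": "% purity",
  "per_signal": {
    "8.72": 100.01,
    "8.45": 99.93,
    "7.82": 99.93
  },
  "mean": 99.96,
  "rsd_percent": 0.05,
  ...
}
```

`simulate` renders the six-level calibration series (analyte/standard mass
ratios 0.47–3.88) as JCAMP-DX files. `quantify` integrates the four
analytical regions of one spectrum and applies the purity equation per
standard signal: the simulated sample is 100% pure, and the pipeline
recovers 99.93–100.01% per signal (mean 99.96%, RSD 0.05%) at the default
noise level. `validate --in demo --out demo_val` fits the calibration
series per signal (slope ≈ 0.934, the response factor
2·182.14/389.4 scaled by purity; R² ≥ 0.9999) and reports the minimum S/N
against the 150 gate. `hplc-calc` applies the external-standard arithmetic
to already-integrated HPLC peak responses for cross-method comparison.

The same functionality is available as a library:

```python
from qnmr import MixtureSpec, synthesize_spectrum, quantify_spectrum, \
    GravimetricRecord, default_regions
from qnmr.datasets import tadalafil_dnt_system

system = tadalafil_dnt_system()
analyte, standard = system
sp = synthesize_spectrum(MixtureSpec(components=((analyte, 5.0), (standard, 5.0))))
out = quantify_spectrum(sp, system, GravimetricRecord(m_std=5.0, m_x=5.0),
                        noise_region=None)
print(out.result.mean)   # 99.93 — noiseless recovery of a 100% pure sample
```

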