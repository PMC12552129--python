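# specquant

Quantitative spectroscopy toolkit for nitrogenase-like metalloenzyme
characterization: NMR-based ammonium isotopologue quantification, EPR
redox-titration analysis, and metallocluster stoichiometry bookkeeping.

## The problem

Nitrogen-fixation assays for nitrogenases and their relatives (such as the
methylthio-alkane reductase family) measure the ¹⁵NH₄⁺ produced from
¹⁵N₂ gas by NMR. Two complications make this quantitative rather than a
simple peak readout:

1. **Isotopologue background.** Protein made in unenriched media degrades
   into ammonium carrying the natural 996:4 ratio of ¹⁴N:¹⁵N, so part of
   the ¹⁵NH₄⁺ signal is background, not fixation. The ¹⁴NH₄⁺ pool is
   quantified from the water-suppressed ¹H spectrum — where ¹H bonded to
   spin-1 ¹⁴N appears as a 1:1:1 triplet split by the ¹⁴N–¹H coupling
   constant *J* = 52.5 Hz — and a 4/996 fraction of it is subtracted from
   the ¹⁵NH₄⁺ concentration measured in the ¹⁵N-HSQC-derived 1D spectrum.
2. **Heterogeneous acquisition.** Spectra are recorded with different scan
   counts and receiver gains depending on signal strength, so intensities
   must be rescaled linearly by both before any comparison, and
   concentrations are obtained by scaling fitted peak areas against a
   30 mM NH₄⁺ buffer reference measured the same way.

Peaks are modelled as Lorentzians, *L*(δ) = *h*·(w/2)²/((δ−δ₀)² + (w/2)²)
with analytic area π·*h*·*w*/2; the ¹⁵N integral error is the noise
standard deviation of the signal-free 0–1 ppm region times the fitted
FWHM, and all errors propagate in uncorrelated quadrature. The corrected
concentration converts to a total turnover number (mol ¹⁵NH₄⁺ per mol
catalytic component) through the assay volume, enzyme mass and molar
mass.

The same enzymes are characterized by EPR: redox titrations of S = 1/2
signals follow the one-electron Nernst isotherm
*A*(E) = *A*ₘₐₓ/(1 + 10^(±(E−Eₘ)/59.16 mV)) at 25 °C, spectra are
simulated as sums of first-derivative Gaussian lines at resonance fields
*B* = *h*ν/(*g*·μ_B), and subunit/cluster inventories give theoretical
complex masses and expected iron counts for comparison with ICP-OES.

All of this is exercised on synthetic data with known ground truth
(`specquant.synth`), generated with exactly the statistical structure the
analysis assumes.

## Worked example

```python
import specquant as sq

# a fixation assay sample: 2 mM ammonium from protein degradation plus
# 0.05 mM of genuinely fixed 15NH4+, and a 30 mM buffer reference
sample = sq.AmmoniumSample(conc_14n_mM=2.0,
                           conc_15n_mM=2.0 * sq.NATURAL_ABUNDANCE_FRACTION + 0.05,
                           noise_sigma=0.02, seed=7)
reference = sq.AmmoniumSample(conc_14n_mM=30.0, degradation_only=True,
                              noise_sigma=0.02, seed=8)

spectra = []
for s in (sample, reference):
    spectra.append(sq.rescale(sq.simulate_1h_spectrum(s)))
    spectra.append(sq.rescale(sq.simulate_15n_spectrum(s)))

cfg = sq.QuantConfig(assay=sq.AssayContext(sample_volume_mL=1.5,
                                           enzyme_mass_mg=5.0,
                                           enzyme_molar_mass_kDa=217.0))
result = sq.quantify_pipeline(*spectra, cfg)
print(result.summary())
```

prints

```
Ammonium quantification
=======================
[14NH4+]           2.001 +/- 0.00033 mM
[15NH4+] raw       0.05813 +/- 0.00025 mM
[15NH4+] corrected 0.0501 +/- 0.00025 mM
correction         0.004016 x [14NH4+]
total turnover     3.26 +/- 0.016
```

The ¹⁴NH₄⁺ concentration comes from the fitted triplet (its mean adjacent
spacing, available in `result.intermediates`, recovers *J* = 52.5 Hz);
the raw ¹⁵NH₄⁺ value contains the natural-abundance background
(2 mM × 4/996 ≈ 0.008 mM), which the correction removes, recovering the
true 0.05 mM excess; the turnover number says each enzyme complex turned
over ~3.3 times during the assay.

Nernst analysis works the same way from a titration curve:

```python
import numpy as np
from specquant.synth import TitrationSimConfig

curve = sq.simulate_titration(TitrationSimConfig(e_m_mV=-390.0, rel_noise=0.02,
                                                 seed=3))
print(sq.fit_nernst(curve).summary())
```

```
Nernst titration fit
====================
species:       synthetic Em=-390mV (reduction)
direction:     appears-on-reduction
n electrons:   1
temperature:   25.0 C (slope 59.16 mV/decade)
E_m:           -391.7 +/- 2.8 mV vs NHE
A_max:         1 +/- 0.018
residual RMS:  0.0296
n points:      12
```

A command line mirrors the library:
`specquant simulate-nmr | fit | quantify | simulate-titration | fit-nernst |
simulate-epr | masscheck` (see `specquant --help`).

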