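# Methods

This note documents the models, default parameters and design choices
behind `specquant`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Signal model for NMR spectra

A 1D spectrum is modelled as a sum of absorptive Lorentzian lines plus a
constant baseline plus additive white Gaussian noise. Synthetic free
induction decays are built as pre-phased complex exponentials,
`a · exp(i 2π f t) · exp(−π w t)` for a line of offset `f` (Hz from the
carrier) and natural FWHM `w` (Hz), so the real part of the discrete
Fourier transform is purely absorptive and no phase-correction step
exists anywhere in the package. The first time-domain point is halved
before transformation (the standard convention removing the constant
offset of the discrete FT); with this convention the initial amplitude
`a = 2·S/sw_ppm` produces a line of spectral area exactly `S`
(intensity·ppm), which is how the generators calibrate area to
concentration.

The processing chain mirrors routine 1D workup: exponential apodization
(`exp(−π·lb·t)`, which adds exactly `lb` Hz of Lorentzian width —
verified as a closed-form test), zero-filling (default factor 2), FFT,
and linear rescaling by scan count × receiver gain. The ppm axis is
stored strictly decreasing; all windows are `(high_ppm, low_ppm)` pairs.

Key defaults and why:

| parameter | default | rationale |
|---|---|---|
| observe frequency | 600.13 MHz | 600 MHz magnet class used for such assays |
| spectral width | 16 ppm, carrier 4.7 ppm | covers water, amide and aliphatic regions; keeps the 0–1 ppm noise region in-window |
| acquired points | 8192 complex | acquisition time ≈ 0.85 s ≈ 10× the effective decay constant at 7 Hz linewidth, so truncation ripple (< 1e-4 of peak) is negligible against the tightest fit tolerances |
| ammonium ¹H shift | 7.10 ppm | textbook NH₄⁺ position in acidified aqueous buffer; configurable |
| grey fit window | (7.6, 6.6) ppm | comfortably brackets the triplet (±0.0875 ppm at 52.5 Hz) while excluding water |
| natural linewidth | 6 Hz | small-molecule line in a protein-assay filtrate; with 1 Hz line broadening gives 7 Hz processed width |
| ¹⁴N–¹H coupling | 52.5 Hz | the characteristic coupling used for triplet identification |
| noise σ | per channel, in rescaled units | the two experiments are acquired separately with different scan counts, so their rescaled noise floors differ; `sigma_for_snr` converts a peak signal-to-noise target into σ |

## Peak fitting

Fits are simultaneous nonlinear least squares (lmfit/Levenberg–Marquardt)
of n Lorentzians parameterized by centre, FWHM and height, plus a constant
baseline in every window (real acidified-buffer baselines are not zero).
Initial guesses: centre at the detected maximum, FWHM of ten grid steps,
height read off the spectrum. Standard errors come from the covariance
matrix; the analytic area π·h·w/2 carries an uncertainty propagated from
the (h, w) covariance including their correlation. Non-convergence raises
a structured error with diagnostics — partial parameters are never
returned.

Peak detection takes all strict local maxima above a threshold (default
6× the noise σ estimated from the 0–1 ppm signal-free region), requiring
the same prominence so that noise riding on the flank of a strong line is
not reported as extra peaks; manual seed positions can be merged in, and
candidates closer than five grid steps are deduplicated keeping the
taller. A tiny numerical floor (1e-9 of the global maximum) prevents
float-rounding ripples of noiseless spectra from registering.

**Statistically-zero singlet fits.** For the ¹⁵N channel the single-line
fit must report an integral even when no signal is present (upper-bound
reporting). An unconstrained four-parameter fit to pure noise latches
onto the tallest noise spike (fitted height ≈ 3σ at whatever width
maximizes the match), which makes the reported integral systematically
exceed its own error estimate. When the window holds no maximum above six
robust standard deviations (1.4826×MAD), the fit therefore switches to an
amplitude-only linear estimate at the expected position (window centre —
the ammonium shift by construction) with the nominal linewidth. This
estimator is unbiased under the null and its integral stays within
~1 noise-based error of zero.

The ¹⁵N integral error is σ_noise × fitted FWHM (axis units), the noise
taken from the 0–1 ppm region of the same spectrum.

## Isotopologue quantification

The triplet is identified among all fitted peaks by exhaustive scoring of
3-subsets: both adjacent spacings must fall within 3 Hz of 52.5 Hz, and
the subset minimizing (mean spacing − J)² + 0.1·CV² wins, where CV is the
coefficient of variation of the three component areas (a true 1:1:1
triplet has CV ≈ 0). The summed triplet area's error is the sample
standard deviation (ddof = 1) of the three component areas.

Concentrations are ratios against a 30 mM reference measured on the same
channel; relative errors combine in quadrature (absolute contributions,
so a zero integral keeps a finite error). The ¹⁵N reference concentration
defaults to the natural-abundance content of the unenriched 30 mM
reference, 30 × 4/996 ≈ 0.1205 mM, with an override for enriched
standards. The correction `c₁₅ − (4/996)·c₁₄` uses exactly 4/996 (the
working convention for unenriched material) rather than the IUPAC 0.364%;
negative corrected values are reported and flagged, never clamped, so
replicate averages remain unbiased. Total turnover numbers scale the
corrected concentration by assay volume over enzyme moles
(mass / molar mass); the quoted error is the propagated instrumental
error scaled by the same factor, with sample-fit and reference-fit
contributions both included (and separable in the intermediates).

## Redox titrations and EPR lines

Titrations are fitted with the Nernst isotherm
`A(E) = A_max / (1 + 10^(±n(E−E_m)/s))`, slope `s = ln10·RT/nF`
(59.16 mV/decade at 25 °C, the electrode-calibration temperature). The
electron count is fixed at n = 1 by default — the titrated species are
S = 1/2 signals appearing/disappearing as one-electron couples — but can
be freed, in which case the best integer in 1..3 by residual RMS is
selected (on one-electron synthetic data this selects n = 1). The
direction (appearing on reduction vs oxidation) is chosen from the sign
of the linear amplitude–potential trend before fitting. Potentials are
handled internally versus NHE; the Ag/AgCl electrode offset (+207 mV) is
applied exactly once through explicit conversion helpers.

EPR lines are first-derivative Gaussians, peak-to-peak normalised, with
zero crossing at the resonance field B = hν/(gμ_B) (CODATA constants);
this matches the spreadsheet-style line simulation practice for rhombic
S = 1/2 spectra and is not a powder-pattern simulation. Five-point
moving-average smoothing shrinks its window at the trace ends. Radical
subtraction removes a single isotropic derivative-Gaussian at g ≈ 2.0037;
when no amplitude is supplied it is estimated by projecting the trace
onto the line shape within one peak-to-peak width of its centre, where
the radical dominates any broad species tails (≤ 1% species distortion in
the bundled scenarios).

## Stoichiometry

Masses and iron counts are exact decimal/integer arithmetic; rounding
(half-up, matching the reporting convention of integer-kDa masses)
happens only at report time. FeMoco counts 7 Fe because Mo occupies the
eighth metal site; P- and L-clusters count 8 each, [Fe₄S₄] counts 4. ICP
consistency is a plain z-score against the measured mean ± sd with a
within-1-sd verdict.

## What the synthetic data does and does not emulate

Emulated: triplet/singlet Lorentzian lineshapes with exact 1:1:1 ratios,
linear concentration × scans × gain scaling, additive white Gaussian
noise with a signal-free 0–1 ppm region, ideal Nernstian equilibration,
derivative-Gaussian EPR lines with an isotropic radical contaminant.

Not emulated: water-suppression artefacts and baseline roll, quadrupolar
relaxation asymmetry of the ¹⁴N triplet, differential relaxation between
sample and reference (no ERETIC/PULCON absolute referencing), pulse
miscalibration (a possible constant scale factor on low-SNR ¹⁵N
channels), mediator-equilibration failures in titrations, g-strain and
S = 3/2 features in EPR. Passing tests therefore demonstrate the
correctness of the computational chain under its stated statistical
assumptions, not robustness to these instrumental effects; on real data
the configurable windows, thresholds and reference concentrations are the
knobs that absorb them.

## Problem sizes and statistical test design

Simulated spectra use 8192 complex points (16384 after zero-filling),
which makes every FFT-and-fit cycle run in tens of milliseconds;
statistical suites use 20–100 seeded replicates (Nernst bias, end-to-end
recovery, noise normality), sizes at which the medians under test are
stable to well within the asserted tolerances. All stochastic tests are
seeded and deterministic.
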