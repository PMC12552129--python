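"""Synthetic spectra, titration curves and EPR traces with known truth.

Every downstream stage of the package is exercised on data produced here,
so the generators encode exactly the statistical structure the analysis
assumes:

* Water-suppressed 1H spectra of ammonium: a 1:1:1 triplet (1H coupled to
  spin-1 14N) centred at the ammonium shift, line spacing equal to the
  14N-1H coupling constant (52.5 Hz), three equal Lorentzian components.
* 15N-HSQC-derived 1D spectra: a single decoupled Lorentzian whose area
  tracks the 15NH4+ concentration; no 14N signal leaks into this channel.
* Raw signal scales linearly with concentration x scans x receiver gain;
  additive white Gaussian noise with a designated noise-only region
  between 0 and 1 ppm.
* One-electron Nernst titration curves of EPR amplitudes.
* Rhombic S = 1/2 EPR spectra as sums of first-derivative Gaussian lines
  plus an optional isotropic g ~ 2 radical.

The sample/config dataclasses double as the ground-truth record: tests
compare recovered quantities against the fields of the object that
generated the data. All randomness flows through explicit seeds.

Calibration: a rescaled (per scan, per unit gain) spectrum carries
``INTENSITY_PER_MM`` units of integrated area per mM of the species in
its channel (triplet components each carry a third). The constant is
arbitrary but shared between sample and reference, exactly as a common
spectrometer response is shared between real measurements.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .redox import (
    EPRTrace,
    TitrationCurve,
    derivative_gaussian,
    g_to_field,
    nernst_slope_mv,
)
from .spectra import FID, AcquisitionParams, Spectrum1D, apodize, fourier_transform, zero_fill

#: 15N/14N ratio of unenriched material used for background subtraction.
NATURAL_ABUNDANCE_FRACTION = 4.0 / 996.0

#: Rescaled integrated area (intensity x ppm) per mM of analyte.
INTENSITY_PER_MM = 1.0

#: Default acquisition for the 600 MHz 1H channel.
DEFAULT_ACQ_1H = AcquisitionParams(
    nucleus="1H", sfo_mhz=600.13, sw_ppm=16.0, n_points=8192, carrier_ppm=4.7
)

#: Default acquisition for the 1H-detected 15N-HSQC 1D readout.
DEFAULT_ACQ_15N = AcquisitionParams(
    nucleus="15N-HSQC-1D", sfo_mhz=600.13, sw_ppm=16.0, n_points=8192, carrier_ppm=4.7
)

__all__ = [
    "NATURAL_ABUNDANCE_FRACTION",
    "INTENSITY_PER_MM",
    "DEFAULT_ACQ_1H",
    "DEFAULT_ACQ_15N",
    "AmmoniumSample",
    "TitrationSimConfig",
    "EPRSimConfig",
    "ammonium_fid_1h",
    "ammonium_fid_15n",
    "simulate_1h_spectrum",
    "simulate_15n_spectrum",
    "simulate_titration",
    "simulate_epr",
    "sigma_for_snr",
]


@dataclass
class AmmoniumSample:
    """Ground truth for one ammonium-containing NMR sample.

    ``degradation_only`` marks samples whose entire ammonium pool derives
    from breakdown of unenriched protein, which pins the 15N concentration
    to the natural-abundance fraction of the 14N concentration. Pass
    ``conc_15n_mM=None`` with ``degradation_only=True`` to have it derived.
    """

    conc_14n_mM: float
    conc_15n_mM: float | None = None
    degradation_only: bool = False
    j_nh_hz: float = 52.5
    shift_ppm: float = 7.10
    fwhm_hz: float = 6.0
    noise_sigma: float = 0.0
    noise_sigma_15n: float | None = None  # defaults to noise_sigma
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_14n_mM < 0:
            raise ValueError("conc_14n_mM must be >= 0")
        if self.degradation_only:
            expected = self.conc_14n_mM * NATURAL_ABUNDANCE_FRACTION
            if self.conc_15n_mM is None:
                self.conc_15n_mM = expected
            elif self.conc_15n_mM != expected:
                raise ValueError(
                    "degradation_only samples must satisfy "
                    "conc_15n_mM == conc_14n_mM * 4/996"
                )
        if self.conc_15n_mM is None:
            self.conc_15n_mM = 0.0
        if self.conc_15n_mM < 0:
            raise ValueError("conc_15n_mM must be >= 0")
        if self.j_nh_hz <= 0 or self.fwhm_hz <= 0:
            raise ValueError("j_nh_hz and fwhm_hz must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_sigma_15n is None:
            self.noise_sigma_15n = self.noise_sigma
        if self.noise_sigma_15n < 0:
            raise ValueError("noise_sigma_15n must be >= 0")


def _line_fid(
    acq: AcquisitionParams,
    lines: list[tuple[float, float]],
    fwhm_hz: float,
) -> FID:
    """Noiseless pre-phased FID for Lorentzian lines of given (ppm, area).

    Each line of area S (rescaled intensity x ppm) enters the FID with
    initial amplitude 2 S / sw_ppm, which makes the discrete spectral
    integral equal S after transformation with first-point halving; the
    raw signal is then multiplied by scans x gain.
    """
    t = np.arange(acq.n_points) * acq.dwell_s
    decay = np.exp(-math.pi * fwhm_hz * t)
    samples = np.zeros(acq.n_points, dtype=complex)
    lo = acq.carrier_ppm - acq.sw_ppm / 2.0
    hi = acq.carrier_ppm + acq.sw_ppm / 2.0
    for ppm, area in lines:
        if not (lo < ppm < hi):
            raise ValueError(
                f"line at {ppm:.3f} ppm falls outside the spectral window "
                f"[{lo:.2f}, {hi:.2f}] ppm; widen sw_ppm or move carrier_ppm"
            )
        f_hz = (ppm - acq.carrier_ppm) * acq.sfo_mhz
        amp = 2.0 * area / acq.sw_ppm
        samples += amp * np.exp(2j * math.pi * f_hz * t) * decay
    samples *= acq.n_scans * acq.receiver_gain
    return FID(acq, samples)


def ammonium_fid_1h(sample: AmmoniumSample, acq: AcquisitionParams = DEFAULT_ACQ_1H) -> FID:
    """Noiseless FID of the 14NH4+ 1:1:1 triplet (1H channel)."""
    spacing_ppm = sample.j_nh_hz / acq.sfo_mhz
    area = INTENSITY_PER_MM * sample.conc_14n_mM / 3.0
    lines = [
        (sample.shift_ppm - spacing_ppm, area),
        (sample.shift_ppm, area),
        (sample.shift_ppm + spacing_ppm, area),
    ]
    return _line_fid(acq, lines, sample.fwhm_hz)


def ammonium_fid_15n(sample: AmmoniumSample, acq: AcquisitionParams = DEFAULT_ACQ_15N) -> FID:
    """Noiseless FID of the decoupled 15NH4+ singlet (HSQC-derived 1D)."""
    area = INTENSITY_PER_MM * sample.conc_15n_mM
    return _line_fid(acq, [(sample.shift_ppm, area)], sample.fwhm_hz)


def _process_and_noise(
    fid: FID,
    noise_sigma: float,
    rng: np.random.Generator,
    lb_hz: float,
    zero_fill_factor: int,
) -> Spectrum1D:
    fid = apodize(fid, lb_hz)
    fid = zero_fill(fid, zero_fill_factor)
    spec = fourier_transform(fid)
    if noise_sigma > 0:
        raw_sigma = noise_sigma * fid.params.n_scans * fid.params.receiver_gain
        spec.intensity = spec.intensity + rng.normal(0.0, raw_sigma, len(spec.intensity))
    return spec


def simulate_1h_spectrum(
    sample: AmmoniumSample,
    acq: AcquisitionParams = DEFAULT_ACQ_1H,
    lb_hz: float = 1.0,
    zero_fill_factor: int = 2,
) -> Spectrum1D:
    """Water-suppressed 1H spectrum with the 14NH4+ triplet, unrescaled.

    Additive white Gaussian noise covers the full axis, so the 0-1 ppm
    region contains noise only; ``sample.noise_sigma`` is expressed in
    rescaled intensity units. Reproducible given ``sample.seed``.
    """
    rng = np.random.default_rng(sample.seed)
    fid = ammonium_fid_1h(sample, acq)
    return _process_and_noise(fid, sample.noise_sigma, rng, lb_hz, zero_fill_factor)


def simulate_15n_spectrum(
    sample: AmmoniumSample,
    acq: AcquisitionParams = DEFAULT_ACQ_15N,
    lb_hz: float = 1.0,
    zero_fill_factor: int = 2,
) -> Spectrum1D:
    """15N-HSQC-derived 1D: a single 15NH4+ Lorentzian, unrescaled.

    Uses an independent noise stream from the 1H channel (seed offset), as
    the two experiments are acquired separately; ``noise_sigma_15n``
    (rescaled units) covers the case where the HSQC was recorded with many
    more scans than the 1H experiment and hence has a different rescaled
    noise floor.
    """
    rng = np.random.default_rng(np.uint32(sample.seed) + np.uint32(0x5EED))
    fid = ammonium_fid_15n(sample, acq)
    return _process_and_noise(fid, sample.noise_sigma_15n, rng, lb_hz, zero_fill_factor)


def sigma_for_snr(
    sample: AmmoniumSample,
    snr: float,
    acq: AcquisitionParams = DEFAULT_ACQ_1H,
    lb_hz: float = 1.0,
    channel: str = "1H",
) -> float:
    """Noise sigma (rescaled units) giving the requested peak SNR.

    SNR is defined as the height of the tallest line over the noise
    standard deviation. Line height follows from the Lorentzian closed
    form ``height = 2 * area / (pi * fwhm_ppm)`` with the processed
    linewidth ``fwhm_hz + lb_hz``.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    w_ppm = (sample.fwhm_hz + lb_hz) / acq.sfo_mhz
    if channel == "1H":
        area = INTENSITY_PER_MM * sample.conc_14n_mM / 3.0
    elif channel == "15N":
        area = INTENSITY_PER_MM * (sample.conc_15n_mM or 0.0)
    else:
        raise ValueError("channel must be '1H' or '15N'")
    height = 2.0 * area / (math.pi * w_ppm)
    return height / snr


# ---------------------------------------------------------------------------
# Redox titration curves
# ---------------------------------------------------------------------------

@dataclass
class TitrationSimConfig:
    """Ground truth for a simulated one-(or n-)electron redox titration.

    The mediator cocktail of the bench experiment is replaced by ideal
    equilibration at each set potential. ``species_sign`` selects whether
    the EPR amplitude rises on reduction or on oxidation.
    """

    e_m_mV: float
    n_electrons: int = 1
    species_sign: str = "reduction"  # amplitude appears on "reduction"|"oxidation"
    potentials_mV: np.ndarray = field(
        default_factory=lambda: np.linspace(-550.0, -150.0, 12)
    )
    a_max: float = 1.0
    rel_noise: float = 0.0
    temperature_C: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.potentials_mV = np.asarray(self.potentials_mV, dtype=float)
        if self.species_sign not in ("reduction", "oxidation"):
            raise ValueError("species_sign must be 'reduction' or 'oxidation'")
        if self.rel_noise < 0:
            raise ValueError("rel_noise must be >= 0")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")


def simulate_titration(cfg: TitrationSimConfig) -> TitrationCurve:
    """Nernstian amplitudes on the configured potential grid plus noise.

    ``A(E) = a_max / (1 + 10^(±n (E − E_m)/s))`` with the slope ``s`` for
    ``cfg.temperature_C``; Gaussian noise of standard deviation
    ``rel_noise * a_max`` is added to every point.
    """
    e = cfg.potentials_mV
    if not (e.min() < cfg.e_m_mV < e.max()):
        warnings.warn(
            f"potential grid [{e.min():.0f}, {e.max():.0f}] mV does not span "
            f"E_m = {cfg.e_m_mV:.0f} mV; the fit will extrapolate"
        )
    sign = 1.0 if cfg.species_sign == "reduction" else -1.0
    s_mv = nernst_slope_mv(cfg.temperature_C, cfg.n_electrons)
    amp = cfg.a_max / (1.0 + 10.0 ** (sign * (e - cfg.e_m_mV) / s_mv))
    errors = None
    if cfg.rel_noise > 0:
        rng = np.random.default_rng(cfg.seed)
        amp = amp + rng.normal(0.0, cfg.rel_noise * cfg.a_max, len(e))
        errors = np.full(len(e), cfg.rel_noise * cfg.a_max)
    return TitrationCurve(
        potentials_mv=e.copy(),
        amplitudes=amp,
        amplitude_errors=errors,
        species_label=f"synthetic Em={cfg.e_m_mV:.0f}mV ({cfg.species_sign})",
    )


# ---------------------------------------------------------------------------
# EPR traces
# ---------------------------------------------------------------------------

@dataclass
class EPRSimConfig:
    """Rhombic (or isotropic) S=1/2 spectrum as derivative-Gaussian lines."""

    g_values: tuple = (1.967, 1.926, 1.83)
    linewidths_mT: tuple = (3.0, 3.0, 3.0)
    weights: tuple = (1.0, 1.0, 1.0)
    freq_ghz: float = 9.35
    radical_amplitude: float = 0.0
    radical_g: float = 2.0037
    radical_width_mT: float = 1.5
    field_grid_mT: np.ndarray = field(
        default_factory=lambda: np.linspace(300.0, 400.0, 2001)
    )
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.g_values = tuple(float(v) for v in np.atleast_1d(self.g_values))
        self.linewidths_mT = tuple(float(v) for v in np.atleast_1d(self.linewidths_mT))
        self.weights = tuple(float(v) for v in np.atleast_1d(self.weights))
        if not (len(self.g_values) == len(self.linewidths_mT) == len(self.weights)):
            raise ValueError("g_values, linewidths_mT and weights must align")
        if any(g <= 0 for g in self.g_values):
            raise ValueError("g values must be positive")
        if any(w <= 0 for w in self.linewidths_mT):
            raise ValueError("linewidths must be positive")
        self.field_grid_mT = np.asarray(self.field_grid_mT, dtype=float)


def simulate_epr(cfg: EPRSimConfig) -> EPRTrace:
    """Sum of first-derivative Gaussian lines, one per principal g value.

    Each component's zero crossing falls at its resonance field
    ``h ν / (g μ_B)``; an isotropic radical line at ``radical_g`` is added
    when ``radical_amplitude`` is nonzero.
    """
    b = cfg.field_grid_mT
    y = np.zeros_like(b)
    for g, width, weight in zip(cfg.g_values, cfg.linewidths_mT, cfg.weights):
        center = g_to_field(g, cfg.freq_ghz)
        if not (b.min() <= center <= b.max()):
            warnings.warn(
                f"line centre {center:.1f} mT (g={g}) lies outside the field grid"
            )
        y += derivative_gaussian(b, center, width, weight)
    if cfg.radical_amplitude != 0.0:
        center = g_to_field(cfg.radical_g, cfg.freq_ghz)
        y += derivative_gaussian(b, center, cfg.radical_width_mT, cfg.radical_amplitude)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        y = y + rng.normal(0.0, cfg.noise_sigma, len(b))
    return EPRTrace(b.copy(), y)
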