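"""Nernst analysis of EPR-monitored redox titrations and EPR line handling.

The titration model is the one-electron Nernst isotherm: the EPR amplitude
of a species tracks the fraction of centres in the EPR-active oxidation
state,

    A(E) = A_max / (1 + 10^(±n (E − E_m) / s)),    s = ln(10)·R·T/F,

where ``E_m`` is the midpoint potential versus the normal hydrogen
electrode (NHE), ``n`` the number of electrons and ``s`` the Nernst slope
(59.16 mV per decade at 25 °C). The sign is ``+`` for a species that
appears upon reduction (amplitude high at low potential) and ``−`` for one
appearing upon oxidation.

Field/g conversion uses the resonance condition ``h·ν = g·μ_B·B``.
Lineshapes are first-derivative Gaussians, the standard continuous-wave
EPR presentation; an isotropic g ≈ 2.0 radical line can be subtracted
before comparison with simulations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.constants import R, physical_constants
from scipy.constants import h as PLANCK

FARADAY = physical_constants["Faraday constant"][0]
MU_B = physical_constants["Bohr magneton"][0]

#: Ag/AgCl (InLab Argenthal) reference electrode offset versus NHE, mV.
AG_AGCL_OFFSET_MV = 207.0

__all__ = [
    "TitrationCurve",
    "NernstModel",
    "NernstResults",
    "fit_nernst",
    "nernst_slope_mv",
    "electrode_to_nhe",
    "nhe_to_electrode",
    "g_to_field",
    "field_to_g",
    "GTensor",
    "g_average",
    "EPRTrace",
    "derivative_gaussian",
    "smooth_5pt",
    "subtract_radical",
    "FitError",
    "AG_AGCL_OFFSET_MV",
]


class FitError(RuntimeError):
    """Nonlinear fit failed; carries diagnostics instead of partial numbers."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


def nernst_slope_mv(temperature_c: float = 25.0, n_electrons: int = 1) -> float:
    """Nernst slope ln(10)·R·T/(n·F) in mV per decade (59.16 at 25 °C, n=1)."""
    t_kelvin = temperature_c + 273.15
    return math.log(10.0) * R * t_kelvin / (n_electrons * FARADAY) * 1000.0


def electrode_to_nhe(e_measured_mv: float, reference_offset_mv: float = AG_AGCL_OFFSET_MV) -> float:
    """Convert a potential measured against a reference electrode to NHE."""
    return e_measured_mv + reference_offset_mv


def nhe_to_electrode(e_nhe_mv: float, reference_offset_mv: float = AG_AGCL_OFFSET_MV) -> float:
    """Inverse of :func:`electrode_to_nhe`."""
    return e_nhe_mv - reference_offset_mv


@dataclass
class TitrationCurve:
    """(potential vs NHE, EPR amplitude) observations for one species."""

    potentials_mv: np.ndarray
    amplitudes: np.ndarray
    amplitude_errors: np.ndarray | None = None
    species_label: str = ""

    def __post_init__(self) -> None:
        self.potentials_mv = np.asarray(self.potentials_mv, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.potentials_mv) != len(self.amplitudes):
            raise ValueError("potentials and amplitudes must have equal length")
        if len(self.potentials_mv) < 5:
            raise ValueError("a titration curve needs at least 5 points")
        if len(np.unique(self.potentials_mv)) != len(self.potentials_mv):
            raise ValueError("potentials must be distinct")
        if self.amplitude_errors is not None:
            self.amplitude_errors = np.asarray(self.amplitude_errors, dtype=float)


@dataclass
class NernstResults:
    """Fitted Nernst isotherm: midpoint, plateau amplitude, uncertainties."""

    e_m_mv: float
    e_m_stderr: float
    a_max: float
    a_max_stderr: float
    n_electrons: int
    direction: str  # "appears-on-reduction" | "appears-on-oxidation"
    temperature_c: float
    residual_rms: float
    model: "NernstModel" = field(repr=False)

    @property
    def slope_mv(self) -> float:
        return nernst_slope_mv(self.temperature_c, self.n_electrons)

    def predict(self, potentials_mv: np.ndarray) -> np.ndarray:
        sign = 1.0 if self.direction == "appears-on-reduction" else -1.0
        e = np.asarray(potentials_mv, dtype=float)
        return self.a_max / (1.0 + 10.0 ** (sign * (e - self.e_m_mv) / self.slope_mv))

    def summary(self) -> str:
        lines = [
            "Nernst titration fit",
            "====================",
            f"species:       {self.model.curve.species_label or '(unnamed)'}",
            f"direction:     {self.direction}",
            f"n electrons:   {self.n_electrons}",
            f"temperature:   {self.temperature_c:.1f} C "
            f"(slope {self.slope_mv:.2f} mV/decade)",
            f"E_m:           {self.e_m_mv:+.1f} +/- {self.e_m_stderr:.1f} mV vs NHE",
            f"A_max:         {self.a_max:.4g} +/- {self.a_max_stderr:.2g}",
            f"residual RMS:  {self.residual_rms:.3g}",
            f"n points:      {len(self.model.curve.potentials_mv)}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.plot(c.potentials_mv, c.amplitudes, "o", label="data")
        grid = np.linspace(c.potentials_mv.min(), c.potentials_mv.max(), 300)
        ax.plot(grid, self.predict(grid), "-", label=f"$E_m$ = {self.e_m_mv:.0f} mV")
        ax.set_xlabel("potential (mV vs NHE)")
        ax.set_ylabel("EPR amplitude (a.u.)")
        ax.legend()
        return ax


class NernstModel:
    """Least-squares Nernst isotherm fitted to a titration curve.

    Parameters
    ----------
    curve : TitrationCurve
        Observations; potentials must bracket the transition.
    n_electrons : int or None
        Fixed electron count (default 1). ``None`` selects the best
        integer in 1..3 by residual sum of squares.
    temperature_c : float
        Titration temperature; sets the Nernst slope.
    """

    def __init__(
        self,
        curve: TitrationCurve,
        n_electrons: int | None = 1,
        temperature_c: float = 25.0,
    ):
        self.curve = curve
        self.n_electrons = n_electrons
        self.temperature_c = temperature_c

    def fit(self) -> NernstResults:
        if self.n_electrons is not None:
            return self._fit_fixed_n(self.n_electrons)
        candidates = [self._fit_fixed_n(n) for n in (1, 2, 3)]
        return min(candidates, key=lambda r: r.residual_rms)

    def _fit_fixed_n(self, n_electrons: int) -> NernstResults:
        e = self.curve.potentials_mv
        a = self.curve.amplitudes
        span = a.max() - a.min()
        if span <= 0 or span < 1e-12 * max(abs(a.max()), 1.0):
            raise FitError(
                "titration curve is flat; no transition to fit",
                {"amplitude_span": float(span)},
            )
        # direction from the amplitude trend against potential
        slope_sign = np.polyfit(e, a, 1)[0]
        direction = "appears-on-oxidation" if slope_sign > 0 else "appears-on-reduction"
        sign = -1.0 if direction == "appears-on-oxidation" else 1.0
        s_mv = nernst_slope_mv(self.temperature_c, n_electrons)

        def model(params, e):
            return params["a_max"] / (
                1.0 + 10.0 ** (sign * (e - params["e_m"]) / s_mv)
            )

        def residual(params):
            r = model(params, e) - a
            if self.curve.amplitude_errors is not None:
                r = r / self.curve.amplitude_errors
            return r

        params = lmfit.Parameters()
        # initial midpoint: potential where the amplitude crosses half range
        half = a.min() + span / 2.0
        params.add("e_m", value=float(e[np.argmin(np.abs(a - half))]))
        params.add("a_max", value=float(a.max()), min=0.0)
        out = lmfit.minimize(residual, params)
        if not out.success:
            raise FitError("Nernst fit did not converge", {"lmfit_message": out.message})
        e_m = float(out.params["e_m"].value)
        if not (e.min() <= e_m <= e.max()):
            warnings.warn(
                f"fitted E_m {e_m:.0f} mV lies outside the sampled range "
                f"[{e.min():.0f}, {e.max():.0f}] mV"
            )
        rms = float(np.sqrt(np.mean((model(out.params, e) - a) ** 2)))
        return NernstResults(
            e_m_mv=e_m,
            e_m_stderr=float(out.params["e_m"].stderr or np.nan),
            a_max=float(out.params["a_max"].value),
            a_max_stderr=float(out.params["a_max"].stderr or np.nan),
            n_electrons=n_electrons,
            direction=direction,
            temperature_c=self.temperature_c,
            residual_rms=rms,
            model=self,
        )


def fit_nernst(
    curve: TitrationCurve,
    n_electrons: int | None = 1,
    temperature_c: float = 25.0,
) -> NernstResults:
    """Fit the Nernst isotherm to a titration curve (see :class:`NernstModel`)."""
    return NernstModel(curve, n_electrons, temperature_c).fit()


# ---------------------------------------------------------------------------
# g-value / field conversion and g-tensor bookkeeping
# ---------------------------------------------------------------------------

def g_to_field(g, freq_ghz: float):
    """Resonance field in mT for effective g at the given microwave frequency."""
    g = np.asarray(g, dtype=float)
    if np.any(g <= 0) or freq_ghz <= 0:
        raise ValueError("g values and frequency must be positive")
    b_tesla = PLANCK * freq_ghz * 1e9 / (g * MU_B)
    out = b_tesla * 1000.0
    return float(out) if out.ndim == 0 else out


def field_to_g(field_mt, freq_ghz: float):
    """Effective g value at a resonance field in mT (inverse of g_to_field)."""
    field_mt = np.asarray(field_mt, dtype=float)
    if np.any(field_mt <= 0) or freq_ghz <= 0:
        raise ValueError("field and frequency must be positive")
    g = PLANCK * freq_ghz * 1e9 / (field_mt * 1e-3 * MU_B)
    return float(g) if g.ndim == 0 else g


@dataclass(frozen=True)
class GTensor:
    """One (isotropic) or three (rhombic) principal g values."""

    g_values: tuple
    freq_ghz: float = 9.35

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.g_values)
        if len(vals) not in (1, 3):
            raise ValueError("g_values must hold 1 or 3 principal values")
        if any(v <= 0 for v in vals):
            raise ValueError("g values must be positive")
        object.__setattr__(self, "g_values", vals)

    @property
    def g_average(self) -> float:
        return float(np.mean(self.g_values))


def g_average(tensor: GTensor | tuple, ndigits: int | None = None) -> float:
    """Arithmetic mean of the principal g values, optionally rounded."""
    if not isinstance(tensor, GTensor):
        tensor = GTensor(tuple(tensor))
    avg = tensor.g_average
    return round(avg, ndigits) if ndigits is not None else avg


# ---------------------------------------------------------------------------
# EPR traces: derivative-Gaussian lines, smoothing, radical subtraction
# ---------------------------------------------------------------------------

@dataclass
class EPRTrace:
    """Continuous-wave EPR trace: first-derivative intensity vs field."""

    field_mt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.field_mt = np.asarray(self.field_mt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.field_mt) != len(self.intensity):
            raise ValueError("field and intensity must have equal length")


def derivative_gaussian(
    field_mt: np.ndarray, center_mt: float, pp_width_mt: float, amplitude: float = 1.0
) -> np.ndarray:
    """First-derivative Gaussian line, peak-to-peak normalised.

    ``pp_width_mt`` is the peak-to-peak width (2 sigma of the underlying
    Gaussian); the extrema have magnitude ``amplitude`` and the zero
    crossing sits at ``center_mt``.
    """
    if pp_width_mt <= 0:
        raise ValueError("pp_width_mt must be positive")
    sigma = pp_width_mt / 2.0
    u = (np.asarray(field_mt, dtype=float) - center_mt) / sigma
    return -amplitude * u * np.exp(0.5 - 0.5 * u * u)


def smooth_5pt(trace: EPRTrace | np.ndarray) -> EPRTrace | np.ndarray:
    """Centred five-point moving average; the window shrinks at the ends.

    Reduces white-noise variance by ~1/5 in the interior while leaving
    affine (constant or linearly ramping) signals unchanged there.
    """
    y = trace.intensity if isinstance(trace, EPRTrace) else np.asarray(trace, dtype=float)
    n = len(y)
    if n < 5:
        raise ValueError("trace must have at least 5 points")
    out = np.empty_like(y)
    for i in range(n):
        half = min(2, i, n - 1 - i)
        out[i] = y[i - half : i + half + 1].mean()
    if isinstance(trace, EPRTrace):
        return EPRTrace(trace.field_mt.copy(), out)
    return out


def subtract_radical(
    trace: EPRTrace,
    g: float = 2.0037,
    pp_width_mt: float = 1.5,
    amplitude: float | None = None,
    freq_ghz: float = 9.35,
) -> EPRTrace:
    """Remove an isotropic radical line (single derivative Gaussian at g≈2).

    With ``amplitude=None`` the radical amplitude is estimated by linear
    least squares of the radical shape against the trace (exact when the
    radical is spectrally isolated); an explicit amplitude is used as is.
    A zero-amplitude model leaves the trace unchanged.
    """
    center = g_to_field(g, freq_ghz)
    shape = derivative_gaussian(trace.field_mt, center, pp_width_mt, 1.0)
    if amplitude is None:
        # project onto the line core (within one peak-to-peak width, where
        # the radical dominates) so tails of broad species lines nearby do
        # not bias the estimate
        near = np.abs(trace.field_mt - center) <= pp_width_mt
        denom = float(np.dot(shape[near], shape[near]))
        amplitude = float(np.dot(shape[near], trace.intensity[near])) / denom if denom > 0 else 0.0
    return EPRTrace(trace.field_mt.copy(), trace.intensity - amplitude * shape)
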