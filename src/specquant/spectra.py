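"""1D NMR data model and processing chain.

Containers for acquisition metadata, time-domain FIDs and frequency-domain
spectra, together with the standard processing steps applied to every
spectrum in the ammonium-quantification workflow: exponential apodization,
zero-filling, Fourier transformation onto a ppm axis, and linear rescaling
by scan count and receiver gain so that spectra acquired with different
settings become directly comparable.

Conventions
-----------
* The ppm axis is stored strictly decreasing (standard NMR display order);
  every window argument is a ``(high_ppm, low_ppm)`` pair.
* Synthetic FIDs are generated perfectly phased, so the real part of the
  transform is absorptive and no phase correction step exists.
* The first time-domain point is halved before transformation (the usual
  discrete-FT convention that removes the constant baseline offset).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AcquisitionParams",
    "FID",
    "Spectrum1D",
    "apodize",
    "zero_fill",
    "fourier_transform",
    "rescale",
    "write_spectrum",
    "read_spectrum",
    "read_jcamp",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for a 1D experiment.

    Parameters
    ----------
    nucleus : str
        Observed channel label, e.g. ``"1H"`` or ``"15N-HSQC-1D"``.
    sfo_mhz : float
        Spectrometer observe frequency in MHz (600.13 for the default
        600 MHz magnet).
    sw_ppm : float
        Spectral width in ppm.
    n_points : int
        Number of acquired complex points; must be a power of two.
    n_scans : int
        Scan count; signal scales linearly with it before rescaling.
    receiver_gain : float
        Receiver gain; signal scales linearly with it before rescaling.
    carrier_ppm : float
        Chemical shift at the centre of the spectral window.
    """

    nucleus: str = "1H"
    sfo_mhz: float = 600.13
    sw_ppm: float = 16.0
    n_points: int = 8192
    n_scans: int = 1
    receiver_gain: float = 1.0
    carrier_ppm: float = 4.7

    def __post_init__(self) -> None:
        if self.sfo_mhz <= 0:
            raise ValueError("sfo_mhz must be positive")
        if self.sw_ppm <= 0:
            raise ValueError("sw_ppm must be positive")
        if self.n_points < 2 or (self.n_points & (self.n_points - 1)) != 0:
            raise ValueError("n_points must be a power of two >= 2")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if self.receiver_gain <= 0:
            raise ValueError("receiver_gain must be positive")

    @property
    def sw_hz(self) -> float:
        """Spectral width in Hz (1 ppm equals ``sfo_mhz`` Hz)."""
        return self.sw_ppm * self.sfo_mhz

    @property
    def dwell_s(self) -> float:
        """Dwell time: seconds per complex point, 1/spectral-width-in-Hz."""
        return 1.0 / self.sw_hz


@dataclass
class FID:
    """Complex time-domain free induction decay."""

    params: AcquisitionParams
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if len(self.samples) != self.params.n_points:
            raise ValueError(
                f"samples length {len(self.samples)} does not match "
                f"n_points {self.params.n_points}"
            )

    @property
    def dwell_s(self) -> float:
        return self.params.dwell_s

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.params.n_points) * self.dwell_s


@dataclass
class Spectrum1D:
    """Real frequency-domain spectrum on a decreasing ppm axis.

    ``intensity_im`` optionally carries the dispersive (imaginary) part of
    the transform; it is propagated through rescaling but ignored by all
    fitting code.
    """

    params: AcquisitionParams
    ppm: np.ndarray
    intensity: np.ndarray
    rescaled: bool = False
    intensity_im: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.ppm) != len(self.intensity):
            raise ValueError("ppm and intensity must have the same length")
        d = np.diff(self.ppm)
        if not np.all(d < 0):
            raise ValueError("ppm axis must be strictly decreasing")
        step = d[0]
        if np.max(np.abs(d - step)) > 1e-9 * abs(step):
            raise ValueError("ppm axis spacing must be uniform")

    @property
    def dppm(self) -> float:
        """Absolute grid step in ppm."""
        return abs(float(self.ppm[1] - self.ppm[0]))

    def window(self, high_ppm: float, low_ppm: float) -> np.ndarray:
        """Boolean mask selecting ``low_ppm <= ppm <= high_ppm``."""
        if high_ppm <= low_ppm:
            raise ValueError("window must be given as (high_ppm, low_ppm)")
        return (self.ppm <= high_ppm) & (self.ppm >= low_ppm)

    def plot(self, ax=None, **kwargs):
        """Plot intensity against ppm with the axis inverted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ppm, self.intensity, **kwargs)
        if not ax.xaxis_inverted():
            ax.invert_xaxis()
        ax.set_xlabel("chemical shift (ppm)")
        ax.set_ylabel("intensity (a.u.)")
        return ax


def apodize(fid: FID, lb_hz: float) -> FID:
    """Apply an exponential window ``exp(-pi * lb_hz * t)``.

    Convolves every Lorentzian line with a Lorentzian of width ``lb_hz``,
    so fitted linewidths grow by exactly ``lb_hz``.
    """
    if lb_hz < 0:
        raise ValueError("lb_hz must be >= 0 (exponential line broadening)")
    window = np.exp(-math.pi * lb_hz * fid.times_s)
    return FID(fid.params, fid.samples * window)


def zero_fill(fid: FID, factor: int = 2) -> FID:
    """Extend the FID with trailing zeros to ``factor`` times its length."""
    if int(factor) != factor or factor < 1:
        raise ValueError("zero-fill factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return FID(fid.params, fid.samples.copy())
    n_new = fid.params.n_points * factor
    samples = np.zeros(n_new, dtype=complex)
    samples[: fid.params.n_points] = fid.samples
    return FID(replace(fid.params, n_points=n_new), samples)


def fourier_transform(fid: FID) -> Spectrum1D:
    """Transform a pre-phased FID to an absorptive spectrum.

    The first point is halved, the complex FFT is shifted so the carrier
    sits at the centre of the window, and the axis is returned in
    decreasing ppm. The real part is absorptive for a perfectly phased
    FID; the imaginary (dispersive) part is kept alongside.
    """
    if not np.all(np.isfinite(fid.samples)):
        raise ValueError("FID contains non-finite samples")
    x = fid.samples.copy()
    x[0] *= 0.5
    spec = np.fft.fftshift(np.fft.fft(x))
    freq_hz = np.fft.fftshift(np.fft.fftfreq(len(x), d=fid.dwell_s))
    ppm = fid.params.carrier_ppm + freq_hz / fid.params.sfo_mhz
    # store in decreasing-ppm display order
    return Spectrum1D(
        params=fid.params,
        ppm=ppm[::-1].copy(),
        intensity=spec.real[::-1].copy(),
        intensity_im=spec.imag[::-1].copy(),
        rescaled=False,
    )


def rescale(spectrum: Spectrum1D) -> Spectrum1D:
    """Divide intensities by ``n_scans * receiver_gain``.

    Makes spectra recorded with different scan counts and gains directly
    comparable. Applying it twice is an error.
    """
    if spectrum.rescaled:
        raise ValueError("spectrum is already rescaled")
    f = spectrum.params.n_scans * spectrum.params.receiver_gain
    im = None if spectrum.intensity_im is None else spectrum.intensity_im / f
    return Spectrum1D(
        params=spectrum.params,
        ppm=spectrum.ppm.copy(),
        intensity=spectrum.intensity / f,
        intensity_im=im,
        rescaled=True,
    )


# ---------------------------------------------------------------------------
# File I/O: 2-column CSV + JSON sidecar, and a minimal JCAMP-DX reader
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_spectrum(spectrum: Spectrum1D, csv_path: str | Path) -> None:
    """Write ``ppm,intensity`` CSV plus a JSON metadata sidecar.

    Floats are written with 17 significant digits so a round trip
    reproduces the arrays bit for bit.
    """
    csv_path = Path(csv_path)
    pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity}).to_csv(
        csv_path, index=False, float_format="%.17g"
    )
    p = spectrum.params
    meta = {
        "nucleus": p.nucleus,
        "sfo_mhz": p.sfo_mhz,
        "sw_ppm": p.sw_ppm,
        "carrier_ppm": p.carrier_ppm,
        "n_points": p.n_points,
        "n_scans": p.n_scans,
        "receiver_gain": p.receiver_gain,
        "rescaled": spectrum.rescaled,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))


def read_spectrum(csv_path: str | Path) -> Spectrum1D:
    """Read a spectrum written by :func:`write_spectrum`."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, float_precision="round_trip")
    meta = json.loads(_sidecar_path(csv_path).read_text())
    rescaled = bool(meta.pop("rescaled"))
    params = AcquisitionParams(**meta)
    return Spectrum1D(
        params=params,
        ppm=df["ppm"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        rescaled=rescaled,
    )


def read_jcamp(path: str | Path) -> Spectrum1D:
    """Read a single-file JCAMP-DX spectrum with ``(X++(Y..Y))`` data.

    Supports the plain AFFN form only (space-separated numbers, no
    compression). The ppm axis is rebuilt from ``##FIRSTX``/``##LASTX``
    and intensities are scaled by ``##YFACTOR``.
    """
    text = Path(path).read_text()
    labels: dict[str, str] = {}
    y: list[float] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            if key == "XYDATA":
                in_data = True
                continue
            if key == "END":
                in_data = False
            labels[key] = value.strip()
            continue
        if in_data:
            vals = line.replace(",", " ").split()
            # first number on each line is the X of the first Y
            y.extend(float(v) for v in vals[1:])
    if not y:
        raise ValueError(f"no XYDATA found in {path}")
    firstx = float(labels["FIRSTX"])
    lastx = float(labels["LASTX"])
    npoints = int(float(labels.get("NPOINTS", len(y))))
    if npoints != len(y):
        raise ValueError(f"NPOINTS={npoints} but {len(y)} Y values read")
    yfactor = float(labels.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx, lastx, npoints)
    intensity = np.asarray(y) * yfactor
    if ppm[0] < ppm[-1]:  # enforce decreasing display order
        ppm = ppm[::-1].copy()
        intensity = intensity[::-1].copy()
    sfo = float(labels.get(".OBSERVEFREQUENCY", "600.13"))
    # synthesise params covering the file's axis; power-of-two n_points is
    # a container requirement, the file's own grid length is kept in ppm
    n_pow2 = 1 << max(1, (npoints - 1).bit_length())
    params = AcquisitionParams(
        nucleus=labels.get(".OBSERVENUCLEUS", "1H").strip("^"),
        sfo_mhz=sfo,
        sw_ppm=abs(firstx - lastx) * npoints / max(npoints - 1, 1),
        n_points=n_pow2,
        carrier_ppm=(firstx + lastx) / 2.0,
    )
    return Spectrum1D(params=params, ppm=ppm, intensity=intensity, rescaled=True)
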