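"""IQ demodulation paths and direct spectral peak detection.

Two classical routes recover physiological motion from the quadrature
baseband pair:

* **arctangent demodulation** — the four-quadrant angle of (I, Q),
  unwrapped, is the Doppler phase 4*pi*x(t)/lambda + psi.  Its spectrum is
  linear in the displacement, so a two-tone chest motion gives exactly two
  peaks; but the path is fragile under noise and large body motion.
* **complex demodulation** — B = I + jQ is analyzed directly.  Robust to
  noise, but the nonlinear phase modulation scatters energy over Bessel
  harmonics and intermodulation lines, so simple peak reading is ambiguous
  whenever a respiration harmonic lands on the heartbeat fundamental.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .signal_model import IQSignal

__all__ = [
    "Spectrum",
    "RateEstimate",
    "arctangent_demod",
    "complex_demod",
    "magnitude_spectrum",
    "peak_detect_rates",
]


@dataclass(frozen=True)
class Spectrum:
    """One-sided magnitude spectrum on the grid k/T, k = 0..floor(N/2).

    ``magnitude`` holds raw DFT magnitudes |X[k]| with the DC bin zeroed;
    the pre-zeroing DC magnitude is kept in ``dc`` so energy bookkeeping
    remains possible.  ``source`` records the demodulation path.
    """

    frequencies: np.ndarray
    magnitude: np.ndarray
    source: str = "complex"
    n_samples: int = 0
    dc: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitude, dtype=float)
        if f.shape != m.shape or f.ndim != 1:
            raise ValueError("frequency grid and magnitudes must be 1-d and congruent")
        if np.any(m < 0):
            raise ValueError("magnitudes must be nonnegative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude", m)

    @property
    def freq_resolution(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of bins with lo <= f <= hi."""
        return (self.frequencies >= lo) & (self.frequencies <= hi)


@dataclass(frozen=True)
class RateEstimate:
    """Respiration/heart rate read directly off a spectrum (Hz)."""

    fr_hat: float
    fh_hat: float
    fr_peak: float = 0.0
    fh_peak: float = 0.0
    method: str = "peak"
    fr_ok: bool = True
    fh_ok: bool = True
    notes: tuple = field(default_factory=tuple)


def arctangent_demod(sig: IQSignal) -> np.ndarray:
    """Unwrapped Doppler phase arctan(Q/I) in rad.

    Uses the four-quadrant angle per sample, then unwraps by adding
    multiples of 2*pi so consecutive differences lie in (-pi, pi].  For a
    noiseless trace this equals 4*pi*x(t)/lambda + psi up to a constant
    multiple of 2*pi.

    Raises
    ------
    ValueError
        If any sample has I = Q = 0, where the angle is undefined; the
        message names the first offending sample index.
    """
    mag2 = sig.i**2 + sig.q**2
    bad = np.flatnonzero(mag2 == 0.0)
    if bad.size:
        raise ValueError(f"zero-magnitude IQ sample at index {bad[0]}: phase undefined")
    return np.unwrap(np.arctan2(sig.q, sig.i))


def complex_demod(sig: IQSignal, remove_dc: bool = True) -> np.ndarray:
    """Complex baseband B = I + jQ, with the sample mean removed by default.

    The DC line of the modulated signal carries no rate information, so it
    is subtracted before spectral analysis unless ``remove_dc=False``.
    """
    b = sig.complex
    if remove_dc:
        b = b - b.mean()
    return b


def magnitude_spectrum(series: np.ndarray, fs: float, source: Optional[str] = None) -> Spectrum:
    """One-sided rectangular-window magnitude spectrum.

    No taper is applied: the natural bin spacing Delta_f = Fs/N = 1/T is
    the resolution argument the whole detection problem is framed in.  For
    real input (the arctangent path) the constant offset is subtracted
    before transforming.  The DC bin is zeroed in ``magnitude`` and stashed
    in ``dc``.
    """
    x = np.asarray(series)
    if x.ndim != 1 or x.size < 16:
        raise ValueError("series must be 1-d with at least 16 samples")
    n = x.size
    if not np.iscomplexobj(x):
        x = x.astype(float) - float(np.mean(x))
        if source is None:
            source = "arctangent"
    elif source is None:
        source = "complex"
    spec = np.fft.fft(x)[: n // 2 + 1]
    mag = np.abs(spec)
    dc = float(mag[0])
    mag[0] = 0.0
    freqs = np.arange(n // 2 + 1) * (fs / n)
    return Spectrum(frequencies=freqs, magnitude=mag, source=source, n_samples=n, dc=dc)


def peak_detect_rates(
    spec: Spectrum,
    resp_band: tuple[float, float] = (0.1, 0.9),
    heart_band: tuple[float, float] = (0.8, 3.0),
    exclude_harmonics: Optional[bool] = None,
    n_harmonics: int = 4,
) -> RateEstimate:
    """Direct peak reading of the respiration and heart rates.

    The respiration rate is the largest bin in ``resp_band``; the heart
    rate is the largest bin in ``heart_band``.  With
    ``exclude_harmonics=True``, bins within one resolution bin of the
    first ``n_harmonics`` respiration harmonics are removed from the
    heart-band search first.  The default (None) enables the rule only for
    complex-path spectra, where respiration harmonics genuinely pollute
    the heart band; the arctangent path is linear in the displacement, so
    a peak at a harmonic of fr there can only be the heartbeat itself and
    must not be excluded.  Pass False for the fully naive baseline.  Ties
    break toward the lower frequency.  A band that is empty, all-zero, or
    fully excluded yields a flagged failure (``fr_ok``/``fh_ok`` False,
    rate NaN), not an exception.
    """
    if exclude_harmonics is None:
        exclude_harmonics = spec.source == "complex"
    df = spec.freq_resolution
    notes: list[str] = []
    # a bin counts as a peak only if it rises above numerical leakage
    floor = 1e-9 * float(spec.magnitude.max()) if spec.magnitude.size else 0.0

    resp_mask = spec.band_slice(*resp_band)
    fr_hat, fr_peak, fr_ok = float("nan"), 0.0, False
    if resp_mask.any():
        mags = np.where(resp_mask, spec.magnitude, -1.0)
        idx = int(np.argmax(mags))  # argmax takes the first (lowest-f) maximum
        if mags[idx] > floor:
            fr_hat, fr_peak, fr_ok = float(spec.frequencies[idx]), float(mags[idx]), True
    if not fr_ok:
        notes.append("no respiration peak in band")

    heart_mask = spec.band_slice(*heart_band)
    if exclude_harmonics and fr_ok:
        for h in range(1, n_harmonics + 1):
            heart_mask &= np.abs(spec.frequencies - h * fr_hat) > df
    fh_hat, fh_peak, fh_ok = float("nan"), 0.0, False
    if heart_mask.any():
        mags = np.where(heart_mask, spec.magnitude, -1.0)
        idx = int(np.argmax(mags))
        if mags[idx] > floor:
            fh_hat, fh_peak, fh_ok = float(spec.frequencies[idx]), float(mags[idx]), True
    if not fh_ok:
        notes.append("no heartbeat peak in band after harmonic exclusion")

    return RateEstimate(
        fr_hat=fr_hat,
        fh_hat=fh_hat,
        fr_peak=fr_peak,
        fh_peak=fh_peak,
        method="peak/" + spec.source,
        fr_ok=fr_ok,
        fh_ok=fh_ok,
        notes=tuple(notes),
    )
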