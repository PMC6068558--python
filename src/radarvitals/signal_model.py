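"""Physiological phase-modulation signal model for a CW Doppler radar.

A continuous-wave radar pointed at a person's chest receives a reflection
whose phase is modulated by the chest displacement ``x(t)``.  With an IQ
(quadrature) receiver the two baseband channels are

.. math::

    B_I(t) = \\cos(4\\pi x(t)/\\lambda + \\psi), \\qquad
    B_Q(t) = \\sin(4\\pi x(t)/\\lambda + \\psi),

where :math:`\\lambda` is the carrier wavelength (5 mm at 60 GHz) and
:math:`\\psi` is a constant residual phase combining the system phase and
the nominal range.  The chest displacement is modelled as the sum of two
tones, one for respiration and one for the heartbeat:

.. math::

    x(t) = m_r \\sin(2\\pi f_r t + \\varphi_r)
         + m_h \\sin(2\\pi f_h t + \\varphi_h).

Because the modulation is nonlinear, the complex baseband
:math:`B = B_I + jB_Q` has a line spectrum at all intermodulation
frequencies :math:`n f_h + k f_r` with Bessel-function weights; this module
provides that analytic spectrum as a closed-form oracle alongside the
time-domain simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import jv

__all__ = [
    "PhysioParams",
    "RadarConfig",
    "MotionArtifact",
    "IQSignal",
    "SpectralLine",
    "PARAM_NAMES",
    "chest_displacement",
    "baseband_iq",
    "add_awgn",
    "bessel_line_spectrum",
    "ambiguity_amplitude",
]

TWO_PI = 2.0 * math.pi

#: Canonical ordering of the 7 physiological parameters as an optimization
#: vector: amplitudes (mm), rates (Hz), phases (rad).
PARAM_NAMES = ("mr", "mh", "fr", "fh", "phi_r", "phi_h", "psi")


@dataclass(frozen=True)
class PhysioParams:
    """The 7-vector of chest-motion parameters.

    Parameters
    ----------
    mr, mh
        Respiration and heartbeat displacement amplitudes in mm.
        Typical frontal values: mr 0.8-6.0 mm, mh 0.08-0.4 mm.
    fr, fh
        Respiration and heart rates in Hz (divide bpm by 60).
    phi_r, phi_h
        Initial phases of the two tones, rad.
    psi
        Constant residual phase (system phase plus nominal-range term), rad.
    """

    mr: float
    mh: float
    fr: float
    fh: float
    phi_r: float = 0.0
    phi_h: float = 0.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mr", "mh", "fr", "fh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)!r}")

    def to_array(self) -> np.ndarray:
        """Return the parameters as a float64 vector in :data:`PARAM_NAMES` order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "PhysioParams":
        x = np.asarray(x, dtype=float)
        if x.shape != (7,):
            raise ValueError(f"expected a length-7 vector, got shape {x.shape}")
        return cls(**dict(zip(PARAM_NAMES, x.tolist())))

    def canonical(self) -> "PhysioParams":
        """Return a copy with all phases wrapped into [0, 2*pi)."""
        return replace(
            self,
            phi_r=self.phi_r % TWO_PI,
            phi_h=self.phi_h % TWO_PI,
            psi=self.psi % TWO_PI,
        )

    @property
    def fr_bpm(self) -> float:
        return self.fr * 60.0

    @property
    def fh_bpm(self) -> float:
        return self.fh * 60.0


@dataclass(frozen=True)
class RadarConfig:
    """Radar and acquisition configuration.

    wavelength is in mm (5.0 at 60 GHz), sample_rate in Hz, duration in s.
    The number of samples round(Fs*T) must be a positive integer count;
    the frequency resolution of a rectangular-window spectrum is 1/T.
    """

    wavelength: float = 5.0
    sample_rate: float = 100.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")
        n = self.sample_rate * self.duration
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValueError(f"Fs*T = {n} is not a positive integer sample count")

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.duration))

    @property
    def freq_resolution(self) -> float:
        """Spectral bin spacing Delta_f = 1/T in Hz."""
        return 1.0 / self.duration

    def times(self) -> np.ndarray:
        """Uniform sample times 0, 1/Fs, ..., (N-1)/Fs."""
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class MotionArtifact:
    """A recurring random-body-motion artifact.

    Each event adds exactly half a cycle of a sine wave to the chest
    displacement: amplitude 20 mm, period 0.5 s, recurring every 5 s by
    default.  ``first_onset`` places the first event mid-window so a 10 s
    trace contains two complete events.
    """

    amplitude: float = 20.0
    period: float = 0.5
    recurrence: float = 5.0
    first_onset: float = 2.5

    def __post_init__(self) -> None:
        if min(self.amplitude, self.period, self.recurrence) <= 0 or self.first_onset < 0:
            raise ValueError("artifact parameters must be positive (first_onset >= 0)")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Displacement contribution (mm) of all events covering times ``t``."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        if t.size == 0:
            return out
        t_end = float(t.max())
        onset = self.first_onset
        half = self.period / 2.0
        while onset <= t_end:
            mask = (t >= onset) & (t <= onset + half)
            out[mask] += self.amplitude * np.sin(TWO_PI * (t[mask] - onset) / self.period)
            onset += self.recurrence
        return out


@dataclass(frozen=True)
class IQSignal:
    """A uniformly sampled two-channel baseband trace."""

    sample_rate: float
    i: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        i = np.asarray(self.i, dtype=float)
        q = np.asarray(self.q, dtype=float)
        if i.shape != q.shape or i.ndim != 1:
            raise ValueError("I and Q must be 1-d arrays of equal length")
        object.__setattr__(self, "i", i)
        object.__setattr__(self, "q", q)

    @property
    def n_samples(self) -> int:
        return self.i.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def complex(self) -> np.ndarray:
        """The complex baseband B = I + jQ."""
        return self.i + 1j * self.q

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class SpectralLine:
    """One line of the analytic baseband spectrum at frequency n*fh + k*fr."""

    frequency: float
    n: int
    k: int
    amplitude: complex

    @property
    def magnitude(self) -> float:
        return abs(self.amplitude)


def chest_displacement(
    t: np.ndarray,
    p: PhysioParams,
    artifact: Optional[MotionArtifact] = None,
) -> np.ndarray:
    """Two-tone chest displacement x(t) in mm, optionally with body motion.

    x(t) = mr*sin(2*pi*fr*t + phi_r) + mh*sin(2*pi*fh*t + phi_h), plus the
    half-sine artifact pulse during each event window when ``artifact`` is
    given.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1:
        raise ValueError("t must be a 1-d time array")
    x = p.mr * np.sin(TWO_PI * p.fr * t + p.phi_r) + p.mh * np.sin(TWO_PI * p.fh * t + p.phi_h)
    if artifact is not None:
        x = x + artifact.waveform(t)
    return x


def phase_modulation(x: np.ndarray, p: PhysioParams, cfg: RadarConfig) -> np.ndarray:
    """Doppler phase 4*pi*x/lambda + psi (rad) for displacement x (mm)."""
    return (4.0 * math.pi / cfg.wavelength) * np.asarray(x, dtype=float) + p.psi


def baseband_iq(
    p: PhysioParams,
    cfg: RadarConfig = RadarConfig(),
    artifact: Optional[MotionArtifact] = None,
) -> IQSignal:
    """Simulate the noiseless IQ baseband trace for chest motion ``p``.

    The receiver amplitude is normalized to 1, so every noiseless sample
    lies on the unit circle: I^2 + Q^2 = 1.
    """
    t = cfg.times()
    phase = phase_modulation(chest_displacement(t, p, artifact), p, cfg)
    return IQSignal(sample_rate=cfg.sample_rate, i=np.cos(phase), q=np.sin(phase))


def add_awgn(
    sig: IQSignal,
    snr_db: float,
    seed: Optional[int | np.random.Generator] = None,
    per_channel: bool = True,
) -> IQSignal:
    """Add zero-mean white Gaussian receiver noise at the requested SNR.

    Parameters
    ----------
    snr_db
        Signal-to-noise ratio in dB; ``math.inf`` returns the input unchanged.
    seed
        Integer seed or a ``numpy.random.Generator``.
    per_channel
        If True (default) the noise variance of each channel is set from
        that channel's own power, so each real channel individually has the
        requested SNR.  If False the SNR is defined on the complex signal:
        total noise power (split evenly between I and Q) is total signal
        power divided by ``10**(snr_db/10)``.
    """
    if math.isinf(snr_db) and snr_db > 0:
        return sig
    if not math.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = 10.0 ** (-snr_db / 10.0)
    if per_channel:
        var_i = np.mean(sig.i**2) * factor
        var_q = np.mean(sig.q**2) * factor
    else:
        var_i = var_q = 0.5 * np.mean(sig.i**2 + sig.q**2) * factor
    n = sig.n_samples
    noise_i = rng.normal(0.0, math.sqrt(var_i), n)
    noise_q = rng.normal(0.0, math.sqrt(var_q), n)
    return IQSignal(sample_rate=sig.sample_rate, i=sig.i + noise_i, q=sig.q + noise_q)


def bessel_line_spectrum(
    p: PhysioParams,
    cfg: RadarConfig = RadarConfig(),
    max_order: int = 12,
    floor: float = 1e-6,
) -> list[SpectralLine]:
    """Closed-form line spectrum of the complex baseband signal.

    Expanding both phase-modulation exponentials in Bessel series gives

        B(t) = sum_{n,k} J_n(4*pi*mh/lambda) * J_k(4*pi*mr/lambda)
               * exp(j((n*fh + k*fr)*2*pi*t + n*phi_h + k*phi_r + psi)),

    a line at every intermodulation frequency n*fh + k*fr.  Lines that land
    on the same frequency (the "ambiguity" between respiration harmonics
    and the heartbeat) are summed as complex amplitudes before pruning, so
    their magnitude depends on the mutual phasing of the two movements.

    Orders |n|, |k| <= max_order are enumerated; lines with summed
    magnitude below ``floor`` are dropped.  Frequencies may be negative:
    the complex baseband spectrum is two-sided.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    arg_h = 4.0 * math.pi * p.mh / cfg.wavelength
    arg_r = 4.0 * math.pi * p.mr / cfg.wavelength
    orders = np.arange(-max_order, max_order + 1)
    jh = jv(orders, arg_h)
    jr = jv(orders, arg_r)

    # Group coincident frequencies before pruning.
    acc: dict[int, list] = {}
    for ni, n in enumerate(orders):
        for ki, k in enumerate(orders):
            freq = n * p.fh + k * p.fr
            amp = jh[ni] * jr[ki] * np.exp(1j * (n * p.phi_h + k * p.phi_r + p.psi))
            key = round(freq / max(cfg.freq_resolution * 1e-6, 1e-12))
            entry = acc.get(key)
            if entry is None:
                acc[key] = [freq, int(n), int(k), amp]
            else:
                entry[3] += amp
                if abs(jh[ni] * jr[ki]) > abs(jv(entry[1], arg_h) * jv(entry[2], arg_r)):
                    entry[1], entry[2] = int(n), int(k)
    lines = [
        SpectralLine(frequency=f, n=n, k=k, amplitude=complex(a))
        for f, n, k, a in acc.values()
        if abs(a) >= floor
    ]
    lines.sort(key=lambda ln: ln.frequency)
    return lines


def ambiguity_amplitude(
    p: PhysioParams,
    n_prime: int,
    k_prime: int,
    cfg: RadarConfig = RadarConfig(),
) -> float:
    """Spectral magnitude at an ambiguity frequency n'*fh = k'*fr.

    When the k'-th respiration harmonic coincides with the heartbeat
    fundamental (or more generally n'*fh with k'*fr), the two leading lines
    superpose coherently:

        |J_{n'}(4*pi*mh/lambda) * J_0(4*pi*mr/lambda) * e^{j n' phi_h}
         + J_0(4*pi*mh/lambda) * J_{k'}(4*pi*mr/lambda) * e^{j k' phi_r}|

    The common factor e^{j psi} drops out of the magnitude, but the phase
    difference n'*phi_h - k'*phi_r does not: the observed peak amplitude
    depends on the mutual phasing of respiration and heartbeat.
    """
    arg_h = 4.0 * math.pi * p.mh / cfg.wavelength
    arg_r = 4.0 * math.pi * p.mr / cfg.wavelength
    term_h = jv(n_prime, arg_h) * jv(0, arg_r) * np.exp(1j * n_prime * p.phi_h)
    term_r = jv(0, arg_h) * jv(k_prime, arg_r) * np.exp(1j * k_prime * p.phi_r)
    return float(abs(term_h + term_r))
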