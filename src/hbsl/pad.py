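"""Probabilistic amplitude demodulation (PAD) and the AM cascade.

A signal is modeled as the product of a slow positive modulator and a fast
carrier, ``y_t = m_t * c_t``. The modulator is ``m = exp(x)`` with ``x`` a
stationary Gaussian process (squared-exponential spectrum, lengthscale set
by the modulator timescale) and the carrier is white Gaussian. The MAP
log-modulator maximizes the joint posterior

    log p(x | y)  =  -sum_t [ x_t + y_t^2 e^{-2 x_t} / (2 s_c^2) ]
                     - (1/2) x' K^{-1} x  + const,

optimized by L-BFGS with the GP prior applied spectrally (circulant FFT
parameterization), initialized from a Gaussian-smoothed local envelope.
The m/c scale ambiguity is resolved by fixing the modulator mean to the
signal's RMS envelope level.

Running the demodulation recursively at successively slower timescales
yields an AM cascade (scalogram). Levels after the first operate on the
mean-removed log-modulator, where the Gaussian-observation analogue of the
MAP smoother has a closed form (an FFT filter with Gaussian amplitude gain,
half gain at the level's rate). Band power is measured from the *difference*
of successive log-domain levels — the fluctuation content removed when
smoothing from one rate to the next — so a pure r-Hz amplitude modulation
lands in the band labeled r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import minimize

from .audio import Waveform

__all__ = [
    "PADParams",
    "Demodulation",
    "Scalogram",
    "timescale_for_rate",
    "demodulate",
    "am_cascade",
    "corpus_band_power",
]

#: SE-spectrum lengthscale (s) with half prior power at f = rate (Hz):
#: S(f) = exp(-2 pi^2 l^2 f^2), S(rate) = 1/2  =>  l = sqrt(ln 2 / 2) / (pi * rate)
_LENGTHSCALE_CONST = math.sqrt(math.log(2.0) / 2.0) / math.pi


def timescale_for_rate(rate_hz: float) -> float:
    """GP lengthscale (seconds) whose prior half-power point sits at ``rate_hz``."""
    return _LENGTHSCALE_CONST / rate_hz


@dataclass
class PADParams:
    """Demodulation parameters.

    modulator_timescale:
        GP prior lengthscale in seconds; controls how slowly the modulator
        may vary (use :func:`timescale_for_rate` to target a cutoff rate).
    carrier_variance:
        Variance of the white Gaussian carrier prior.
    log_variance:
        Marginal prior variance of the log-modulator fluctuations.
    max_iter, tol:
        L-BFGS iteration cap and relative objective tolerance.
    """

    modulator_timescale: float
    carrier_variance: float = 1.0
    log_variance: float = 1.0
    max_iter: int = 100
    tol: float = 1e-7

    def __post_init__(self):
        if self.modulator_timescale <= 0:
            raise ValueError("modulator_timescale must be positive")
        if self.carrier_variance <= 0 or self.log_variance <= 0:
            raise ValueError("variances must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class Demodulation:
    """MAP (modulator, carrier) pair; ``modulator * carrier`` reconstructs y."""

    modulator: np.ndarray
    carrier: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective: float = float("nan")


@dataclass
class Scalogram:
    """AM cascade: one envelope row per band rate plus per-band power."""

    band_rates: np.ndarray
    band_envelopes: np.ndarray  # shape (n_bands, n_samples) at ``sample_rate``
    band_power: np.ndarray
    sample_rate: float = 0.0


def _prior_spectrum(n: int, fs: float, lengthscale: float, variance: float) -> np.ndarray:
    """Power spectrum of the SE prior at FFT bin frequencies, scaled so the
    marginal variance of x equals ``variance``; DC is unpenalized (improper
    flat prior on the mean)."""
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    s = np.exp(-2.0 * np.pi**2 * lengthscale**2 * freqs**2)
    s = np.maximum(s, 1e-8)
    s *= variance / s.mean()
    s[0] = np.inf
    return s


def demodulate(wave: Waveform, params: PADParams) -> Demodulation:
    """MAP decomposition of a waveform into positive modulator and carrier."""
    y = np.asarray(wave.samples, dtype=float)
    n = len(y)
    fs = wave.sample_rate
    if n < 2 * max(int(params.modulator_timescale * fs), 1):
        raise ValueError("signal too short for the requested modulator timescale")
    if not np.any(y):
        m = np.full(n, 0.0)
        return Demodulation(m, np.zeros(n), converged=True, n_iter=0, objective=0.0)

    spectrum = _prior_spectrum(n, fs, params.modulator_timescale, params.log_variance)
    inv_spec = 1.0 / spectrum  # DC entry becomes 0
    sc2 = params.carrier_variance
    y2 = y**2 + 1e-12 * np.mean(y**2)  # keep the data term bounded at zeros

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        e = np.exp(-2.0 * x)
        data = float(np.sum(x + y2 * e / (2.0 * sc2)))
        grad_data = 1.0 - y2 * e / sc2
        xf = np.fft.fft(x)
        prior = float(np.real(np.vdot(xf, xf * inv_spec))) / (2.0 * n)
        grad_prior = np.fft.ifft(xf * inv_spec).real
        return data + prior, grad_data + grad_prior

    # init: log of the locally smoothed envelope
    sigma = max(params.modulator_timescale * fs, 1.0)
    env0 = np.sqrt(gaussian_filter1d(y2, sigma) / sc2)
    x0 = np.log(np.maximum(env0, 1e-6 * np.max(env0)))

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": params.max_iter, "ftol": params.tol, "maxcor": 20},
    )
    x = res.x
    m = np.exp(x)
    # fix the scale: modulator mean = RMS level of the signal
    scale = np.sqrt(np.mean(y**2)) / np.mean(m)
    m = m * scale
    c = y / m
    return Demodulation(m, c, bool(res.success), int(res.nit), float(res.fun))


def _gauss_lowpass(x: np.ndarray, fs: float, rate_hz: float) -> np.ndarray:
    """FFT filter with Gaussian amplitude gain exp(-ln2 (f/rate)^2).

    Closed-form MAP smoother for the log-domain cascade levels: half
    amplitude at ``rate_hz``, unit gain at DC.
    """
    freqs = np.fft.fftfreq(len(x), d=1.0 / fs)
    gain = np.exp(-math.log(2.0) * (freqs / rate_hz) ** 2)
    return np.fft.ifft(np.fft.fft(x) * gain).real


def am_cascade(
    wave: Waveform,
    band_rates: Sequence[float] = (8.0, 4.0, 2.0, 1.0, 0.5),
    cutoff_hz: float = 10.0,
    params: PADParams | None = None,
    cascade_fs: float | None = None,
) -> Scalogram:
    """Recursive demodulation producing a scalogram and per-band AM power.

    The first (nonlinear MAP) demodulation isolates the modulator below
    ``cutoff_hz`` from the faster carrier. The mean-removed log-modulator is
    then resampled to ``cascade_fs`` and smoothed through the band rates
    (strictly decreasing); each level's envelope is a scalogram row. Band
    power at rate r_i is the mean squared difference between the levels at
    r_i and r_{i+1} (the last band keeps its full mean-removed power).
    """
    rates = np.asarray(band_rates, dtype=float)
    if len(rates) < 1 or np.any(np.diff(rates) >= 0):
        raise ValueError("band_rates must be strictly decreasing")
    if rates[0] >= wave.sample_rate / 2:
        raise ValueError("band rates must lie below the Nyquist frequency")
    if params is None:
        params = PADParams(modulator_timescale=timescale_for_rate(cutoff_hz))
    if cascade_fs is None:
        cascade_fs = max(16.0 * rates[0], 8.0 * cutoff_hz)

    if not np.any(wave.samples):
        n_ds = int(len(wave.samples) * cascade_fs / wave.sample_rate)
        return Scalogram(
            rates, np.zeros((len(rates), n_ds)), np.zeros(len(rates)), cascade_fs
        )

    demod = demodulate(wave, params)
    x = np.log(np.maximum(demod.modulator, 1e-12))
    frac = Fraction(int(round(cascade_fs)), int(round(wave.sample_rate)))
    x = sps.resample_poly(x, frac.numerator, frac.denominator)
    cascade_fs = wave.sample_rate * frac.numerator / frac.denominator
    mean_log = x.mean()
    x = x - mean_log

    # successive smoothing of the previous level; each level's incremental
    # bandwidth is chosen so the *cumulative* response at level i has
    # amplitude gain exp(-ln2 (f/r_i)^2), i.e. half amplitude at r_i
    levels = []
    prev_rate = None
    for rate in rates:
        if prev_rate is None:
            inc_rate = rate
        else:
            inc_rate = 1.0 / math.sqrt(1.0 / rate**2 - 1.0 / prev_rate**2)
        x = _gauss_lowpass(x, cascade_fs, inc_rate)
        levels.append(x)
        prev_rate = rate
    envelopes = np.exp(np.asarray(levels) + mean_log)
    power = []
    for i in range(len(rates)):
        nxt = levels[i + 1] if i + 1 < len(rates) else np.zeros_like(levels[i])
        power.append(float(np.mean((levels[i] - nxt) ** 2)))
    return Scalogram(rates, envelopes, np.asarray(power), cascade_fs)


def corpus_band_power(
    waves: Sequence[Waveform],
    band_rates: Sequence[float] = (8.0, 4.0, 2.0, 1.0, 0.5),
    **kwargs,
) -> np.ndarray:
    """Per-band AM power averaged over a corpus of waveforms."""
    if not waves:
        raise ValueError("corpus is empty")
    powers = [am_cascade(w, band_rates, **kwargs).band_power for w in waves]
    return np.mean(powers, axis=0)
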