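"""Steady-state frequency-domain analysis of pursuit responses.

The steady-state window [1.0, 5.5) s spans exactly one period (4.5 s) of the
target motion, so after resampling to 512 points every target harmonic falls
exactly on an FFT bin (spacing 1/4.5 Hz) and no taper is needed.  Gains and
phases are complex ratios of eye to target Fourier coefficients, phase in
degrees with lead positive.  Across-subject phase statistics use circular
means and the Rayleigh test for non-uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

__all__ = [
    "FrequencyResponse",
    "WINDOW",
    "N_POINTS",
    "resample_steady_state",
    "amplitude_spectrum",
    "gain_phase",
    "circular_mean_sd",
    "rayleigh_test",
    "harmonic_frequencies",
]

WINDOW = (1.0, 5.5)  # s; spans exactly one period
N_POINTS = 512

#: coefficient floor below which a gain/phase ratio is flagged undefined
TARGET_FLOOR = 1e-9


def harmonic_frequencies(harmonics, period: float = 4.5) -> np.ndarray:
    """Bin frequencies (Hz) of the given harmonic indices."""
    return np.asarray(harmonics, dtype=float) / period


@dataclass
class FrequencyResponse:
    """Per-harmonic response description.

    ``phase_deg`` is wrapped to (-180, 180]; ``phase_unwrapped_deg`` is the
    continuous version across the harmonic sequence.  ``valid`` is False
    where the target coefficient is numerically zero.
    """

    frequencies: np.ndarray  # Hz
    gain: np.ndarray
    phase_deg: np.ndarray
    phase_unwrapped_deg: np.ndarray
    amplitude_eye: np.ndarray  # deg/s
    amplitude_target: np.ndarray  # deg/s
    valid: np.ndarray


def resample_steady_state(
    t,
    series,
    window: tuple[float, float] = WINDOW,
    n: int = N_POINTS,
    interpolation: str = "cubic",
):
    """Resample a trace to ``n`` equally spaced points on ``[t0, t1)``.

    The half-open window keeps the sample spacing at exactly one period /
    ``n`` so target harmonics are leakage-free FFT bins.
    """
    t = np.asarray(t, dtype=float)
    x = np.asarray(series, dtype=float)
    t0, t1 = window
    if t[0] > t0 + 1e-9 or t[-1] < t1 - (t1 - t0) / n - 1e-9:
        raise ValueError(f"trace does not cover the window {window}")
    tq = t0 + (t1 - t0) * np.arange(n) / n
    if interpolation == "cubic":
        return CubicSpline(t, x, axis=0)(tq)
    return interp1d(t, x, axis=0, kind="linear")(tq)


def amplitude_spectrum(resampled) -> np.ndarray:
    """One-sided amplitude spectrum (same units as the input) of a
    512-point window; bin k sits at ``k / 4.5`` Hz."""
    x = np.asarray(resampled, dtype=float)
    n = x.shape[0]
    amp = np.abs(np.fft.rfft(x, axis=0)) * 2.0 / n
    amp[0] /= 2.0
    if n % 2 == 0:
        amp[-1] /= 2.0
    return amp


def gain_phase(
    eye_resampled,
    target_resampled,
    harmonics,
    period: float = 4.5,
) -> FrequencyResponse:
    """Gain and phase of the eye response relative to the target at the
    given harmonic indices (1 = fundamental)."""
    e = np.asarray(eye_resampled, dtype=float)
    g = np.asarray(target_resampled, dtype=float)
    if e.shape != g.shape:
        raise ValueError("eye and target series must share their grid")
    n = e.shape[0]
    E = np.fft.rfft(e, axis=0)
    T = np.fft.rfft(g, axis=0)
    k = np.asarray(harmonics, dtype=int)
    valid = np.abs(T[k]) > TARGET_FLOOR * n
    ratio = np.where(valid, E[k] / np.where(valid, T[k], 1.0), np.nan + 0j)
    phase = np.degrees(np.angle(ratio))
    # wrap convention: (-180, 180]
    phase = np.where(phase <= -180.0, phase + 360.0, phase)
    unwrapped = np.degrees(
        np.unwrap(np.radians(np.where(np.isnan(phase), 0.0, phase)))
    )
    return FrequencyResponse(
        frequencies=harmonic_frequencies(k, period),
        gain=np.abs(ratio),
        phase_deg=phase,
        phase_unwrapped_deg=np.where(np.isnan(phase), np.nan, unwrapped),
        amplitude_eye=np.abs(E[k]) * 2.0 / n,
        amplitude_target=np.abs(T[k]) * 2.0 / n,
        valid=valid,
    )


def circular_mean_sd(phases_deg) -> tuple[float, float, float]:
    """Circular mean, circular SD (``sqrt(-2 ln R)``) and mean resultant
    length of a set of phases in degrees.

    With ``R = 0`` the mean is undefined and returned as NaN.
    """
    ph = np.radians(np.asarray(phases_deg, dtype=float))
    if ph.size < 1:
        raise ValueError("need at least one phase")
    z = np.exp(1j * ph).mean()
    r = float(np.abs(z))
    if r < 1e-12:
        return float("nan"), float("inf"), 0.0
    mean = float(np.degrees(np.angle(z)))
    sd = float(np.degrees(np.sqrt(-2.0 * np.log(r))))
    return mean, sd, r


def rayleigh_test(phases_deg) -> float:
    """Rayleigh test p-value for non-uniformity of circular phases.

    Uses ``z = n * R^2`` with the standard finite-n corrected p-value::

        p = exp(-z) * [1 + (2z - z^2)/(4n)
                         - (24z - 132 z^2 + 76 z^3 - 9 z^4)/(288 n^2)]

    Small samples (n < 4) are permitted but the approximation is crude there.
    """
    ph = np.asarray(phases_deg, dtype=float)
    n = ph.size
    if n < 2:
        raise ValueError("Rayleigh test needs at least 2 phases")
    _, _, r = circular_mean_sd(ph)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(np.clip(p, 0.0, 1.0))
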