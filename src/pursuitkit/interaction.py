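"""Independence of horizontal and vertical pursuit components.

For a fixed motion profile on one axis, the pursuit velocity along that axis
is compared between the two conditions that differ only in the *other*
axis's profile.  Gain differences between conditions are removed first by a
through-the-origin scaling regression; the scaled difference traces are then
tested pointwise across subjects (one-sample t-test against zero) and
characterized by their amplitude spectrum on the steady-state window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .freq import N_POINTS, WINDOW, amplitude_spectrum, resample_steady_state

__all__ = [
    "DifferenceResult",
    "gain_match",
    "difference_significance",
    "difference_spectrum",
]


@dataclass
class DifferenceResult:
    """Cross-subject significance summary of scaled difference traces."""

    t: np.ndarray
    mean_diff: np.ndarray
    p_values: np.ndarray
    significant_intervals: dict  # alpha -> list of (start_s, end_s)
    fraction_significant: dict  # alpha -> float
    n_subjects: int


def gain_match(vel_a, vel_b):
    """Scale ``vel_b`` onto ``vel_a`` by least-squares regression through
    the origin.

    Returns ``(slope, r_squared, vel_b_scaled)`` where ``vel_b_scaled``
    has been divided by the slope so its gain matches ``vel_a``; ``r^2``
    is the squared correlation of the through-origin regression.
    """
    a = np.asarray(vel_a, dtype=float).ravel()
    b = np.asarray(vel_b, dtype=float).ravel()
    saa = float(a @ a)
    sbb = float(b @ b)
    if saa <= 0 or sbb <= 0:
        raise ValueError("zero-variance input")
    slope = float(a @ b) / saa
    r2 = float(a @ b) ** 2 / (saa * sbb)
    return slope, r2, np.asarray(vel_b, dtype=float) / slope


def difference_significance(
    t,
    differences,
    alphas: tuple[float, ...] = (0.01, 0.001),
    family_wise: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
) -> DifferenceResult:
    """Pointwise one-sample t-test of per-subject difference traces
    against zero (two-sided).

    ``differences`` has shape (n_subjects, n_samples); contiguous
    significant samples merge into intervals, and the fraction of time
    significant is reported per alpha level.  By default p-values are raw
    (uncorrected); ``family_wise=True`` replaces them with max-statistic
    sign-flip permutation p-values controlling the family-wise error over
    the whole window.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 2 or d.shape[0] < 3:
        raise ValueError("need difference traces from at least 3 subjects")
    t = np.asarray(t, dtype=float)
    res = stats.ttest_1samp(d, 0.0, axis=0)
    p = np.asarray(res.pvalue)
    if family_wise:
        rng = np.random.default_rng(seed)
        t_obs = np.abs(np.asarray(res.statistic))
        max_null = np.empty(n_permutations)
        for i in range(n_permutations):
            signs = rng.choice([-1.0, 1.0], size=(d.shape[0], 1))
            perm = stats.ttest_1samp(d * signs, 0.0, axis=0).statistic
            max_null[i] = np.nanmax(np.abs(perm))
        p = (1.0 + (max_null[None, :] >= t_obs[:, None]).sum(axis=1)) / (
            n_permutations + 1.0
        )
    # constant all-zero columns yield NaN p-values: not significant
    p = np.where(np.isnan(p), 1.0, p)
    intervals = {}
    fractions = {}
    dt = float(t[1] - t[0])
    for alpha in alphas:
        flag = p < alpha
        idx = np.flatnonzero(
            np.diff(np.concatenate([[0], flag.view(np.int8), [0]]))
        )
        intervals[alpha] = [
            (float(t[s]), float(t[e - 1] + dt)) for s, e in zip(idx[::2], idx[1::2])
        ]
        fractions[alpha] = float(flag.mean())
    return DifferenceResult(
        t=t,
        mean_diff=d.mean(axis=0),
        p_values=p,
        significant_intervals=intervals,
        fraction_significant=fractions,
        n_subjects=d.shape[0],
    )


def difference_spectrum(
    t,
    difference,
    response=None,
    window: tuple[float, float] = WINDOW,
    n: int = N_POINTS,
):
    """Amplitude spectrum of a difference trace on the steady-state
    analysis grid.

    Returns ``(frequencies_hz, amplitude)`` and, when a ``response`` trace
    is supplied, additionally the per-bin ratio of difference amplitude to
    response amplitude.
    """
    rs = resample_steady_state(t, difference, window=window, n=n)
    amp = amplitude_spectrum(rs)
    freqs = np.fft.rfftfreq(n, d=(window[1] - window[0]) / n)
    if response is None:
        return freqs, amp
    ra = amplitude_spectrum(resample_steady_state(t, response, window=window, n=n))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ra > 0, amp / ra, np.nan)
    return freqs, amp, ratio
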