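"""Periodic two-dimensional target trajectories for smooth-pursuit experiments.

Three trajectory kinds are supported, all sharing one period ``T``:

* **SS** (sum of sines): per axis, a fundamental sinusoid at ``1/T`` Hz plus a
  single 2nd- or 3rd-harmonic component.  Position, velocity and acceleration
  are analytic.
* **CS** (constant speed): the same geometric path traversed in the same
  direction and with the same period, but at the constant speed ``L/T`` where
  ``L`` is the one-period arc length.  Built by tabulating cumulative arc
  length on a fine grid and inverting the arc-length function by monotone
  interpolation.
* **mixed**: the x velocity of one trajectory combined with the y velocity of
  another (sharing the period), which slightly deforms the path while leaving
  each velocity component untouched.

Coordinates: x rightward positive, y upward positive; directions are measured
counter-clockwise from the rightward horizontal.  Units are degrees of visual
angle, seconds, deg/s and deg/s^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import yaml
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator

__all__ = [
    "AxisSines",
    "SumOfSinesSpec",
    "TargetTrajectory",
    "SumOfSinesTrajectory",
    "ConstantSpeedTrajectory",
    "MixedTrajectory",
    "TangentialNormal",
    "eval_sum_of_sines",
    "reparameterize_constant_speed",
    "combine_axes",
    "tangential_normal_acceleration",
    "default_paths",
    "make_trajectory",
    "PROFILES",
    "save_specs",
    "load_specs",
]

#: speed floor (deg/s) below which tangential/normal decomposition is undefined
SPEED_FLOOR = 0.5

#: default arc-length tabulation resolution (samples per period)
ARC_GRID = 4096

#: motion-profile labels: ss, cs, and the two axis combinations
PROFILES = ("ss", "cs", "ss-cs", "cs-ss")


@dataclass(frozen=True)
class AxisSines:
    """Sum-of-sines coefficients for one axis.

    ``a1``/``phi1`` are the fundamental amplitude (deg) and phase (rad);
    ``k`` is the harmonic order (2 or 3) and ``a2``/``phi2`` its amplitude
    and phase; ``offset`` is the static position offset in degrees.
    """

    a1: float
    phi1: float
    k: int
    a2: float
    phi2: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError(f"harmonic order must be 2 or 3, got {self.k}")


@dataclass(frozen=True)
class SumOfSinesSpec:
    """Full two-axis sum-of-sines target specification with period ``T`` (s)."""

    period: float
    x: AxisSines
    y: AxisSines

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")

    @property
    def f0(self) -> float:
        """Fundamental frequency in Hz."""
        return 1.0 / self.period

    def peak_speed(self, n: int = 4096) -> float:
        """Numerical peak 2-D speed over one period (deg/s)."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        v = SumOfSinesTrajectory(self).velocity(t)
        return float(np.max(np.hypot(v[:, 0], v[:, 1])))

    def validate(
        self,
        speed_bounds: tuple[float, float] = (30.0, 40.0),
        window_halfwidth: float | None = 15.0,
    ) -> None:
        """Check the printed stimulus constraints: peak speed within
        ``speed_bounds`` and position within the display half-window."""
        pk = self.peak_speed()
        if not speed_bounds[0] <= pk <= speed_bounds[1]:
            raise ValueError(
                f"peak speed {pk:.2f} deg/s outside bounds {speed_bounds}"
            )
        if window_halfwidth is not None:
            t = np.linspace(0.0, self.period, 4096, endpoint=False)
            p = SumOfSinesTrajectory(self).position(t)
            if np.max(np.abs(p)) > window_halfwidth:
                raise ValueError("path leaves the display window")


class TargetTrajectory:
    """Evaluable periodic 2-D target motion.

    Subclasses implement :meth:`position`, :meth:`velocity` and
    :meth:`acceleration`; all accept scalar or array ``t`` in seconds
    (any real value, including negative times — the motion is periodic)
    and return arrays with a trailing axis of length 2 (x, y).
    """

    period: float
    kind: str

    def position(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def velocity(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def acceleration(self, t):  # pragma: no cover - abstract
        raise NotImplementedError

    def state(self, t):
        """Return ``(position, velocity, acceleration)`` at ``t``."""
        return self.position(t), self.velocity(t), self.acceleration(t)


class SumOfSinesTrajectory(TargetTrajectory):
    """Analytic SS trajectory; derivatives are exact."""

    kind = "ss"

    def __init__(self, spec: SumOfSinesSpec):
        self.spec = spec
        self.period = spec.period
        w0 = 2.0 * np.pi / spec.period
        # per-axis (amplitude, angular frequency, phase) component lists
        self._comps = []
        for ax in (spec.x, spec.y):
            self._comps.append(
                [(ax.a1, w0, ax.phi1), (ax.a2, ax.k * w0, ax.phi2)]
            )
        self._offsets = np.array([spec.x.offset, spec.y.offset])

    def _eval(self, t, order: int):
        t = np.asarray(t, dtype=float)
        out = np.zeros(t.shape + (2,))
        for i, comps in enumerate(self._comps):
            acc = np.zeros_like(t)
            for amp, w, phi in comps:
                ph = w * t + phi
                if order == 0:
                    acc = acc + amp * np.sin(ph)
                elif order == 1:
                    acc = acc + amp * w * np.cos(ph)
                else:
                    acc = acc - amp * w * w * np.sin(ph)
            out[..., i] = acc
        if order == 0:
            out += self._offsets
        return out

    def position(self, t):
        return self._eval(t, 0)

    def velocity(self, t):
        return self._eval(t, 1)

    def acceleration(self, t):
        return self._eval(t, 2)


def eval_sum_of_sines(spec: SumOfSinesSpec, t):
    """Analytic state of a sum-of-sines target: ``(position, velocity,
    acceleration)`` at time(s) ``t``."""
    return SumOfSinesTrajectory(spec).state(t)


class ConstantSpeedTrajectory(TargetTrajectory):
    """The SS path re-traversed at constant speed ``L/T``.

    The time warp ``t_old = g(t_new)`` satisfies
    ``arclen(g(t_new)) = (L/T) * t_new`` and is built by monotone (PCHIP)
    interpolation of the tabulated inverse arc-length function.  Velocity and
    acceleration follow from the chain rule, so the speed equals ``L/T``
    up to the accuracy of the tabulated warp.
    """

    kind = "cs"

    def __init__(self, spec: SumOfSinesSpec, grid: int = ARC_GRID):
        self.spec = spec
        self.period = spec.period
        self._ss = SumOfSinesTrajectory(spec)
        T = spec.period
        tg = np.linspace(0.0, T, grid + 1)
        v = self._ss.velocity(tg)
        sp = np.hypot(v[:, 0], v[:, 1])
        if np.min(sp) < SPEED_FLOOR:
            warnings.warn(
                "SS path approaches a cusp (speed < "
                f"{SPEED_FLOOR} deg/s); CS acceleration is unbounded there",
                stacklevel=3,
            )
        s = cumulative_trapezoid(sp, tg, initial=0.0)
        self.arc_length = float(s[-1])
        if self.arc_length < 1e-9:
            raise ValueError("degenerate path: arc length ~ 0")
        # strictly increasing s -> t inverse map over one period
        self._warp = PchipInterpolator(s, tg)
        self._u = self.arc_length / T  # constant speed, deg/s

    def _g(self, t):
        """Warped source time, periodically extended to all real t."""
        t = np.asarray(t, dtype=float)
        T = self.period
        cycles = np.floor(t / T)
        s = self._u * (t - cycles * T)
        return self._warp(s) + cycles * T

    def position(self, t):
        return self._ss.position(self._g(t))

    def velocity(self, t):
        told = self._g(t)
        v = self._ss.velocity(told)
        sp = np.hypot(v[..., 0], v[..., 1])[..., None]
        return self._u * v / sp

    def acceleration(self, t):
        told = self._g(t)
        v = self._ss.velocity(told)
        a = self._ss.acceleration(told)
        sp = np.hypot(v[..., 0], v[..., 1])[..., None]
        va = np.sum(v * a, axis=-1, keepdims=True)
        u2 = self._u**2
        return a * u2 / sp**2 - v * u2 * va / sp**4


def reparameterize_constant_speed(
    spec: SumOfSinesSpec, grid: int = ARC_GRID
) -> ConstantSpeedTrajectory:
    """Re-traverse the SS path defined by ``spec`` at constant speed.

    The returned trajectory follows the identical geometric path, in the same
    direction and with the same period, at speed ``arc_length / period``.
    """
    return ConstantSpeedTrajectory(spec, grid=grid)


class MixedTrajectory(TargetTrajectory):
    """x motion from one source trajectory, y motion from another.

    Because the x position equals the running integral of the x velocity,
    the mixed trajectory is the exact component splice of its sources.
    """

    kind = "mixed"

    def __init__(self, x_source: TargetTrajectory, y_source: TargetTrajectory):
        if not np.isclose(x_source.period, y_source.period, rtol=1e-9):
            raise ValueError("sources must share the same period")
        self.period = x_source.period
        self._x = x_source
        self._y = y_source

    def _splice(self, method: str, t):
        out_x = getattr(self._x, method)(t)
        out_y = getattr(self._y, method)(t)
        out = np.empty_like(out_x)
        out[..., 0] = out_x[..., 0]
        out[..., 1] = out_y[..., 1]
        return out

    def position(self, t):
        return self._splice("position", t)

    def velocity(self, t):
        return self._splice("velocity", t)

    def acceleration(self, t):
        return self._splice("acceleration", t)


def combine_axes(
    x_source: TargetTrajectory, y_source: TargetTrajectory
) -> MixedTrajectory:
    """Combine the x velocity of ``x_source`` with the y velocity of
    ``y_source`` into a mixed trajectory sharing their common period."""
    return MixedTrajectory(x_source, y_source)


class TangentialNormal(NamedTuple):
    """Signed tangential/normal acceleration components and their unit
    vectors (normal = 90 deg counter-clockwise from the velocity)."""

    tangential: np.ndarray
    t_hat: np.ndarray
    normal: np.ndarray
    n_hat: np.ndarray


def tangential_normal_acceleration(
    velocity, acceleration, floor: float = SPEED_FLOOR
) -> TangentialNormal:
    """Decompose acceleration into components along and perpendicular to
    the instantaneous velocity.

    The tangential scalar equals the rate of change of speed; the normal
    scalar is proportional to the path curvature.  Where the speed is at or
    below ``floor`` both components (and unit vectors) are defined as zero.
    """
    v = np.asarray(velocity, dtype=float)
    a = np.asarray(acceleration, dtype=float)
    sp = np.hypot(v[..., 0], v[..., 1])
    ok = sp > floor
    safe = np.where(ok, sp, 1.0)
    t_hat = v / safe[..., None]
    # 90 deg CCW rotation of t_hat
    n_hat = np.stack([-t_hat[..., 1], t_hat[..., 0]], axis=-1)
    a_t = np.sum(a * t_hat, axis=-1)
    a_n = np.sum(a * n_hat, axis=-1)
    mask = ok[..., None]
    return TangentialNormal(
        np.where(ok, a_t, 0.0),
        np.where(mask, t_hat, 0.0),
        np.where(ok, a_n, 0.0),
        np.where(mask, n_hat, 0.0),
    )


# ---------------------------------------------------------------------------
# Default path library
# ---------------------------------------------------------------------------
# The five stock paths satisfy every stimulus constraint: period 4.5 s,
# fundamental 1/4.5 Hz plus one 2nd or 3rd harmonic per axis, 2-D peak speed
# in [30, 40] deg/s, path within a +/-15 deg window, and path 3 pairing the
# 3rd x-harmonic with the 2nd y-harmonic.  The individual coefficients are
# package choices (constraint-satisfying, user-replaceable), not measurements.

_DEFAULT_PATH_TABLE = {
    1: dict(x=(10.8, 0.25, 2, 4.4, 3.32), y=(9.5, 2.89, 3, 4.8, 0.39)),
    2: dict(x=(9.4, 0.67, 3, 4.8, 0.66), y=(8.9, 1.27, 2, 4.2, 5.56)),
    3: dict(x=(10.5, 1.13, 3, 3.5, 4.69), y=(9.5, 4.73, 2, 3.0, 3.56)),
    4: dict(x=(9.7, 3.14, 2, 3.4, 6.01), y=(10.9, 5.67, 2, 3.6, 2.48)),
    5: dict(x=(11.2, 3.01, 2, 4.6, 6.02), y=(8.6, 1.99, 3, 3.9, 2.53)),
}


def default_paths(period: float = 4.5) -> dict[int, SumOfSinesSpec]:
    """The stock library of five sum-of-sines path specifications."""
    out = {}
    for pid, axes in _DEFAULT_PATH_TABLE.items():
        out[pid] = SumOfSinesSpec(
            period=period,
            x=AxisSines(*axes["x"]),
            y=AxisSines(*axes["y"]),
        )
    return out


def make_trajectory(
    spec: SumOfSinesSpec, profile: str, grid: int = ARC_GRID
) -> TargetTrajectory:
    """Build the trajectory for one motion profile of a path.

    ``profile`` is one of ``ss`` (sum of sines), ``cs`` (constant speed),
    ``ss-cs`` (x from SS, y from CS) or ``cs-ss`` (the converse).
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
    ss = SumOfSinesTrajectory(spec)
    if profile == "ss":
        return ss
    cs = reparameterize_constant_speed(spec, grid=grid)
    if profile == "cs":
        return cs
    if profile == "ss-cs":
        return combine_axes(ss, cs)
    return combine_axes(cs, ss)


# ---------------------------------------------------------------------------
# Spec I/O (plain structured text, key: value)
# ---------------------------------------------------------------------------

def _spec_to_dict(spec: SumOfSinesSpec) -> dict:
    return {"period": spec.period, "x": asdict(spec.x), "y": asdict(spec.y)}


def _spec_from_dict(d: dict) -> SumOfSinesSpec:
    return SumOfSinesSpec(
        period=float(d["period"]),
        x=AxisSines(**d["x"]),
        y=AxisSines(**d["y"]),
    )


def save_specs(specs: dict[int, SumOfSinesSpec], path) -> None:
    """Write a path library as a structured-text (YAML) config."""
    payload = {f"path{pid}": _spec_to_dict(s) for pid, s in sorted(specs.items())}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_specs(path) -> dict[int, SumOfSinesSpec]:
    """Read a path library written by :func:`save_specs`."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    out = {}
    for key, d in payload.items():
        pid = int(str(key).removeprefix("path"))
        out[pid] = _spec_from_dict(d)
    return out
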