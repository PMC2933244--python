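"""Delay-differential pursuit models and their frequency responses.

Three model families relate eye velocity ``v_e`` to the target motion:

* **image-velocity model** (first-order lag on retinal image velocity with
  separate target/eye delays)::

      dv_e,i/dt = a * [ g_i * v_t,i(t - tau_t) - v_e,i(t - tau_e) ]

* **predictive model** — the image-velocity model with a common delay ``tau``
  plus a low-pass-filtered target-acceleration drive split into normal and
  tangential channels (weights ``c1``, ``c2`` in seconds)::

      dv_e,i/dt = a * [ g_i * v_t,i + c1 * ahat_n,i + c2 * ahat_t,i
                        - v_e,i ](t - tau)

  where each channel is the target acceleration component resolved onto the
  instantaneous tangential/normal frame, carried as a vector, and filtered by
  ``dahat/dt = b * (a_chan - ahat)``.

* **polar model** — eye speed and eye direction as the controlled variables,
  driven by speed and direction errors with rates ``a`` and ``d``.

All models are integrated by the method of steps: within successive windows
of one delay the delayed state is known from the stored dense solution, so
each window is an ordinary ODE solved with adaptive Runge-Kutta (RK45,
cubic dense output).  The eye is at rest before motion onset
(``v_e(t) = 0`` for ``t < 0``); targets are evaluable at any real time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline

from .trajectories import TargetTrajectory, tangential_normal_acceleration

__all__ = [
    "PursuitParams",
    "AVG_FIT_PARAMS",
    "VelocityTrace",
    "PeriodicSignal",
    "periodic_lowpass",
    "filter_predictive_acceleration",
    "simulate_image_velocity_model",
    "simulate_predictive_model",
    "simulate_polar_model",
    "closed_form_frequency_response",
]

#: integrator relative tolerance (adaptive RK45)
SIM_RTOL = 1e-8
SIM_ATOL = 1e-10

#: speed floor (deg/s) for unit-vector and direction computations
SPEED_FLOOR = 0.5

#: grid resolution for the steady-state predictive-acceleration filter
FILTER_GRID = 4096


@dataclass(frozen=True)
class PursuitParams:
    """Parameter set shared by the three model families.

    ``a``: response rate (1/s); ``b``: predictive low-pass filter rate (1/s);
    ``c1``/``c2``: weights of the normal/tangential predictive acceleration
    (s, so that ``c * ahat`` has velocity units); ``g_x``/``g_y``: target
    velocity gains; ``tau``: common delay (s, predictive and polar models);
    ``tau_t``/``tau_e``: separate target/eye delays (s, image-velocity
    model); ``d``: direction rate (1/s, polar model).
    """

    a: float = 7.12
    b: float = 3.47
    c1: float = 0.29
    c2: float = 0.27
    g_x: float = 0.53
    g_y: float = 0.43
    tau: float = 0.08
    tau_t: float = 0.02
    tau_e: float = 0.12
    d: float = 6.0

    def validate(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.d <= 0:
            raise ValueError("rates a, b, d must be positive")
        for name in ("tau", "tau_t", "tau_e"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.3:
                raise ValueError(f"{name}={v} outside [0, 0.3] s")
        for name in ("g_x", "g_y"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.5:
                raise ValueError(f"{name}={v} outside (0, 1.5]")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1, c2 must be non-negative")

    def replace(self, **kw) -> "PursuitParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)


#: average best-fit parameters of the predictive model (delay fixed at 80 ms)
AVG_FIT_PARAMS = PursuitParams(
    a=7.12, b=3.47, g_x=0.53, g_y=0.43, c1=0.29, c2=0.27, tau=0.08
)


@dataclass
class VelocityTrace:
    """Uniformly sampled 2-D eye-velocity trace with provenance metadata."""

    t: np.ndarray  # (n,) seconds
    v: np.ndarray  # (n, 2) deg/s
    meta: dict

    @property
    def rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# Steady-state periodic first-order low-pass filter
# ---------------------------------------------------------------------------

class PeriodicSignal:
    """Periodic signal tabulated on a uniform one-period grid; evaluable at
    any real time via a periodic cubic spline."""

    def __init__(self, samples: np.ndarray, period: float):
        samples = np.asarray(samples, dtype=float)
        self.period = period
        n = samples.shape[0]
        tg = np.linspace(0.0, period, n + 1)
        closed = np.concatenate([samples, samples[:1]], axis=0)
        self._spline = CubicSpline(tg, closed, bc_type="periodic", axis=0)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self._spline(np.mod(t, self.period))


def periodic_lowpass(samples: np.ndarray, period: float, b: float) -> np.ndarray:
    """Exact steady-state periodic response of ``dy/dt = b * (x - y)``.

    Computed spectrally: each Fourier component of the one-period input is
    scaled by ``b / (b + i*omega)``.  DC passes with unit gain.
    """
    if b <= 0:
        raise ValueError("filter rate b must be positive")
    x = np.asarray(samples, dtype=float)
    n = x.shape[0]
    X = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, d=period / n)  # Hz
    H = 1.0 / (1.0 + 1j * 2.0 * np.pi * freqs / b)
    shape = (-1,) + (1,) * (x.ndim - 1)
    return np.fft.irfft(X * H.reshape(shape), n=n, axis=0)


def filter_predictive_acceleration(
    traj: TargetTrajectory,
    b: float,
    channel: str,
    n_grid: int = FILTER_GRID,
    speed_floor: float = SPEED_FLOOR,
) -> PeriodicSignal:
    """Low-pass-filtered predictive target-acceleration channel.

    The target acceleration is decomposed into tangential and normal
    components; the requested ``channel`` (``"tangential"`` or ``"normal"``)
    is carried as a vector along its unit vector and filtered per axis by
    ``dahat/dt = b * (a_chan - ahat)``.  The returned signal is the exact
    steady-state periodic response (deg/s^2, 2-vector).
    """
    if channel not in ("tangential", "normal"):
        raise ValueError("channel must be 'tangential' or 'normal'")
    T = traj.period
    tg = np.linspace(0.0, T, n_grid, endpoint=False)
    v = traj.velocity(tg)
    a = traj.acceleration(tg)
    dec = tangential_normal_acceleration(v, a, floor=speed_floor)
    if channel == "tangential":
        vec = dec.tangential[:, None] * dec.t_hat
    else:
        vec = dec.normal[:, None] * dec.n_hat
    return PeriodicSignal(periodic_lowpass(vec, T, b), T)


# ---------------------------------------------------------------------------
# Method-of-steps DDE integration
# ---------------------------------------------------------------------------

class _History:
    """Piecewise dense solution with constant pre-history."""

    def __init__(self, y_init: np.ndarray):
        self.y_init = np.asarray(y_init, dtype=float)
        self.segments: list[tuple[float, float, object]] = []

    def __call__(self, t: float) -> np.ndarray:
        if t <= 0.0 or not self.segments:
            return self.y_init
        for t0, t1, sol in reversed(self.segments):
            if t >= t0 - 1e-12:
                return sol(min(t, t1))
        return self.y_init

    def add(self, t0: float, t1: float, sol) -> None:
        self.segments.append((t0, t1, sol))

    def sample(self, t: np.ndarray) -> np.ndarray:
        return np.stack([self(float(ti)) for ti in t], axis=0)


def _integrate_dde(
    rhs: Callable,
    lag: float,
    t_end: float,
    y0: np.ndarray,
    rtol: float = SIM_RTOL,
    atol: float = SIM_ATOL,
) -> _History:
    """Integrate ``dy/dt = rhs(t, y, y(t - lag))`` with ``y = y0`` for
    ``t <= 0``, by the method of steps (segments of one lag)."""
    y0 = np.asarray(y0, dtype=float)
    hist = _History(y0)
    if lag <= 0.0:
        sol = solve_ivp(
            lambda t, y: rhs(t, y, y),
            (0.0, t_end),
            y0,
            method="RK45",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(f"integration failed: {sol.message}")
        hist.add(0.0, t_end, sol.sol)
        return hist

    t0 = 0.0
    y = y0.copy()
    while t0 < t_end - 1e-12:
        t1 = min(t0 + lag, t_end)
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, hist(t - lag)),
            (t0, t1),
            y,
            method="RK45",
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"integration failed on [{t0:.3f}, {t1:.3f}]: {sol.message}"
            )
        if not np.all(np.isfinite(sol.y[:, -1])):  # pragma: no cover
            raise RuntimeError("non-finite state during integration")
        hist.add(t0, t1, sol.sol)
        y = sol.y[:, -1]
        t0 = t1
    return hist


def _output_grid(t_end: float, rate: float) -> np.ndarray:
    n = int(round(t_end * rate)) + 1
    return np.arange(n) / rate


# ---------------------------------------------------------------------------
# Model simulations
# ---------------------------------------------------------------------------

def simulate_image_velocity_model(
    params: PursuitParams,
    traj: TargetTrajectory,
    t_end: float = 5.7,
    rate: float = 250.0,
    rtol: float = SIM_RTOL,
) -> VelocityTrace:
    """Simulate the image-velocity model (separate target/eye delays)."""
    a, g = params.a, np.array([params.g_x, params.g_y])
    tau_t, tau_e = params.tau_t, params.tau_e

    def rhs(t, y, ylag):
        return a * (g * traj.velocity(t - tau_t) - ylag)

    hist = _integrate_dde(rhs, tau_e, t_end, np.zeros(2), rtol=rtol)
    tg = _output_grid(t_end, rate)
    return VelocityTrace(
        tg, hist.sample(tg), {"model": "image_velocity", "params": params.to_dict()}
    )


def simulate_predictive_model(
    params: PursuitParams,
    traj: TargetTrajectory,
    t_end: float = 5.7,
    rate: float = 250.0,
    rtol: float = SIM_RTOL,
    _drive: PeriodicSignal | None = None,
) -> VelocityTrace:
    """Simulate the predictive model (common delay, filtered-acceleration
    drive).  With ``c1 = c2 = 0`` this reduces exactly to the image-velocity
    model with equal delays."""
    a, g, tau = params.a, np.array([params.g_x, params.g_y]), params.tau
    drive = _drive
    if drive is None:
        drive = predictive_drive(traj, params)

    def rhs(t, y, ylag):
        td = t - tau
        return a * (g * traj.velocity(td) + drive(td) - ylag)

    hist = _integrate_dde(rhs, tau, t_end, np.zeros(2), rtol=rtol)
    tg = _output_grid(t_end, rate)
    return VelocityTrace(
        tg, hist.sample(tg), {"model": "predictive", "params": params.to_dict()}
    )


def predictive_drive(
    traj: TargetTrajectory, params: PursuitParams, n_grid: int = FILTER_GRID
) -> PeriodicSignal:
    """Combined predictive drive ``c1 * ahat_n + c2 * ahat_t`` (deg/s when
    multiplied into the model, since c1, c2 carry seconds)."""
    T = traj.period
    tg = np.linspace(0.0, T, n_grid, endpoint=False)
    v = traj.velocity(tg)
    acc = traj.acceleration(tg)
    dec = tangential_normal_acceleration(v, acc, floor=SPEED_FLOOR)
    vec = (
        params.c1 * dec.normal[:, None] * dec.n_hat
        + params.c2 * dec.tangential[:, None] * dec.t_hat
    )
    return PeriodicSignal(periodic_lowpass(vec, T, params.b), T)


def simulate_polar_model(
    params: PursuitParams,
    traj: TargetTrajectory,
    variant: str = "standard",
    t_end: float = 5.7,
    rate: float = 250.0,
    rtol: float = SIM_RTOL,
    speed_floor: float = SPEED_FLOOR,
    speed_error: str = "projection",
) -> VelocityTrace:
    """Simulate the polar (speed/direction) model.

    ``variant="standard"``: the direction rate-of-change is proportional to
    the directional error.  ``variant="directional_error"``: the *normal eye
    acceleration* (speed times direction rate) is proportional to the
    directional error, so the direction rate scales inversely with speed.
    Eye speed at or below ``speed_floor`` freezes the direction dynamics.

    ``speed_error`` selects the drive of the speed dynamics: the projection
    of the predicted target velocity onto the eye direction (default) or
    the plain speed difference ``|v_p| - v_e``.
    """
    if variant not in ("standard", "directional_error"):
        raise ValueError("variant must be 'standard' or 'directional_error'")
    if speed_error not in ("projection", "difference"):
        raise ValueError("speed_error must be 'projection' or 'difference'")
    params.validate()
    a, d, tau = params.a, params.d, params.tau
    g = np.array([params.g_x, params.g_y])
    drive = predictive_drive(traj, params)

    v0 = traj.velocity(0.0)
    theta0 = float(np.arctan2(v0[1], v0[0]))

    def v_pred(t):
        return g * traj.velocity(t) + drive(t)

    def rhs(t, y, ylag):
        speed, theta = y
        speed_lag, theta_lag = ylag
        td = t - tau
        vp = v_pred(td)
        if speed_error == "projection":
            e_hat = np.array([np.cos(theta), np.sin(theta)])
            drive_term = float(e_hat @ vp)
        else:
            drive_term = float(np.hypot(vp[0], vp[1]))
        dspeed = a * (drive_term - speed_lag)
        theta_t = np.arctan2(vp[1], vp[0])
        err = np.angle(np.exp(1j * (theta_t - theta_lag)))  # shortest arc
        if speed <= speed_floor:
            dtheta = 0.0
        elif variant == "standard":
            dtheta = d * err
        else:
            dtheta = d * err / max(speed, speed_floor)
        return np.array([dspeed, dtheta])

    hist = _integrate_dde(rhs, tau, t_end, np.array([0.0, theta0]), rtol=rtol)
    tg = _output_grid(t_end, rate)
    y = hist.sample(tg)
    v = y[:, 0:1] * np.stack([np.cos(y[:, 1]), np.sin(y[:, 1])], axis=-1)
    return VelocityTrace(
        tg,
        v,
        {"model": f"polar_{variant}", "params": params.to_dict(), "state": y},
    )


# ---------------------------------------------------------------------------
# Fast fixed-step integration for the linear models
# ---------------------------------------------------------------------------
# The image-velocity and predictive models are linear per axis with a purely
# exogenous input F(t) = a * (g*v_t + drive)(t - tau), so the input can be
# tabulated up front and the DDE reduced to dv/dt = F(t) - a*v(t - tau_e).
# A fixed-step classical RK4 with the state delay an integer number of steps
# (delayed half-step values by cubic Hermite interpolation of the stored
# solution) reproduces the adaptive integrator to ~1e-6 relative at a small
# fraction of its cost; the model fitter uses this path.

_FAST_STEP = 0.002  # s, nominal step of the fixed-step integrator


def _rk4_linear_dde(F_half: np.ndarray, a: float, m: int, h: float) -> tuple:
    """Integrate dv/dt = F(t) - a*v(t - m*h) with v = 0 for t <= 0.

    ``F_half`` holds the input on the half-step grid (2*n+1, k) for n steps
    of k decoupled components.  Returns (v, dv) on the step grid (n+1, k).
    """
    n = (F_half.shape[0] - 1) // 2
    k = F_half.shape[1]
    v = np.zeros((n + 1, k))
    dv = np.zeros((n + 1, k))
    dv[0] = F_half[0]
    zero = np.zeros(k)
    for i in range(n):
        j = i - m
        if m == 0:
            # ordinary ODE: classical RK4 on dv/dt = F(t) - a*v
            y = v[i]
            k1 = F_half[2 * i] - a * y
            k2 = F_half[2 * i + 1] - a * (y + 0.5 * h * k1)
            k3 = F_half[2 * i + 1] - a * (y + 0.5 * h * k2)
            k4 = F_half[2 * i + 2] - a * (y + h * k3)
        else:
            vlag0 = v[j] if j >= 0 else zero
            vlag1 = v[j + 1] if j + 1 >= 0 else zero
            if j >= 0:
                # cubic Hermite midpoint of the stored solution segment
                vmid = 0.5 * (vlag0 + vlag1) + h * (dv[j] - dv[j + 1]) / 8.0
            elif j == -1:
                vmid = zero  # midpoint still in the zero history
            else:
                vmid = zero
            k1 = F_half[2 * i] - a * vlag0
            k23 = -a * vmid
            k2 = F_half[2 * i + 1] + k23
            k3 = k2
            k4 = F_half[2 * i + 2] - a * vlag1
        v[i + 1] = v[i] + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        lag_next = v[i + 1 - m] if i + 1 - m >= 0 else zero
        dv[i + 1] = F_half[2 * (i + 1)] - a * lag_next
    return v, dv


def _fast_linear_simulate(
    input_fn, a: float, tau_state: float, t_end: float, rate: float
) -> np.ndarray:
    """Fixed-step solution of the linear pursuit DDE sampled on the uniform
    output grid.  ``input_fn(t)`` returns the exogenous drive (already
    including the rate ``a`` and any input delays) for an array of times."""
    if tau_state > 0:
        m = max(int(round(tau_state / _FAST_STEP)), 1)
        h = tau_state / m
    else:
        m, h = 0, _FAST_STEP
    n = int(np.ceil(t_end / h)) + 1
    t_half = 0.5 * h * np.arange(2 * n + 1)
    F = np.asarray(input_fn(t_half), dtype=float)
    v, dv = _rk4_linear_dde(F, a, m, h)
    t_grid = h * np.arange(n + 1)
    t_out = _output_grid(t_end, rate)
    out = np.empty((t_out.shape[0], v.shape[1]))
    for c in range(v.shape[1]):
        out[:, c] = CubicSpline(t_grid, v[:, c])(t_out)
    return out


def fast_simulate_image_velocity(
    params: PursuitParams, traj: TargetTrajectory, t_end: float, rate: float
) -> np.ndarray:
    """Fixed-step counterpart of :func:`simulate_image_velocity_model`;
    returns the (n, 2) velocity array on the output grid."""
    a, g = params.a, np.array([params.g_x, params.g_y])
    tau_t = params.tau_t

    def input_fn(t):
        return a * g * traj.velocity(t - tau_t)

    return _fast_linear_simulate(input_fn, a, params.tau_e, t_end, rate)


def fast_simulate_predictive(
    params: PursuitParams,
    traj: TargetTrajectory,
    t_end: float,
    rate: float,
    _drive: PeriodicSignal | None = None,
) -> np.ndarray:
    """Fixed-step counterpart of :func:`simulate_predictive_model`."""
    a, g, tau = params.a, np.array([params.g_x, params.g_y]), params.tau
    drive = _drive if _drive is not None else predictive_drive(traj, params)

    def input_fn(t):
        td = t - tau
        return a * (g * traj.velocity(td) + drive(td))

    return _fast_linear_simulate(input_fn, a, tau, t_end, rate)


# ---------------------------------------------------------------------------
# Closed-form frequency responses (linear models)
# ---------------------------------------------------------------------------

def closed_form_frequency_response(
    params: PursuitParams, model: str, omega, axis: str = "x"
):
    """Complex transfer function eye-velocity/target-velocity at angular
    frequency ``omega`` (rad/s) for the linear model families.

    ``model="eq_image_velocity"``::

        H = g * a * exp(-i w tau_t) / (i w + a * exp(-i w tau_e))

    ``model="eq_predictive_scalar_c"`` (predictive model with c1 = c2 = c,
    in which case the two channels reassemble the componentwise filtered
    acceleration)::

        H = a * (g + c * i w * b / (b + i w)) * exp(-i w tau)
            / (i w + a * exp(-i w tau))

    Gain is ``abs(H)``; phase is ``angle(H)`` in degrees, lead positive.
    The polar model is nonlinear and is rejected.
    """
    w = np.asarray(omega, dtype=float)
    g = params.g_x if axis == "x" else params.g_y
    iw = 1j * w
    if model in ("eq_image_velocity", "eq1"):
        return (
            g * params.a * np.exp(-iw * params.tau_t)
            / (iw + params.a * np.exp(-iw * params.tau_e))
        )
    if model in ("eq_predictive_scalar_c", "eq4_scalar_c"):
        if not np.isclose(params.c1, params.c2):
            raise ValueError(
                "closed form requires c1 == c2 (scalar predictive weight)"
            )
        c = params.c1
        num = params.a * (g + c * iw * params.b / (params.b + iw)) * np.exp(
            -iw * params.tau
        )
        return num / (iw + params.a * np.exp(-iw * params.tau))
    raise ValueError(
        f"no closed form for model {model!r} (polar models are nonlinear)"
    )
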