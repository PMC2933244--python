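"""Model fitting by simplex minimization of squared velocity error.

Three stock protocols mirror the analysis stages:

* **P1** — image-velocity model, each condition and axis fitted separately
  with free ``(a, g, tau_t, tau_e)``.
* **P2** — predictive model with the common delay fixed (80 ms by default),
  one fit per subject across all conditions with free
  ``(a, b, c1, c2, g_x, g_y)``.
* **P3** — predictive model with the rates and delay fixed at the P2
  estimates, free ``(g_x, g_y, c1, c2)`` per condition.

Fit quality is the variance not accounted for (VNAF): 100 x residual sum of
squares over the mean-centered total sum of squares, pooled over both axes
and also reported per axis.  Minimization is Nelder-Mead with seeded
multi-restart and quadratic box penalties keeping parameters physical.

The predictive model is linear in ``(g_x, g_y, c1, c2)``; when only those
parameters are free (P3) the objective is evaluated from four precomputed
unit-coefficient basis simulations per condition, which makes the
per-condition fits cheap without changing the objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    PursuitParams,
    fast_simulate_image_velocity,
    fast_simulate_predictive,
    simulate_image_velocity_model,
    simulate_polar_model,
    simulate_predictive_model,
)
from .preprocessing import ProcessedResponse
from .trajectories import TargetTrajectory

__all__ = [
    "FitProtocol",
    "FitResult",
    "vnaf",
    "nelder_mead_minimize",
    "fit_model",
    "protocol_p1",
    "protocol_p2",
    "protocol_p3",
    "protocol_comparison_report",
]

#: box constraints keeping parameters physical (penalty-enforced)
PARAM_BOUNDS = {
    "a": (0.5, 30.0),
    "b": (0.3, 30.0),
    "c1": (0.0, 2.0),
    "c2": (0.0, 2.0),
    "g": (0.01, 1.5),
    "g_x": (0.01, 1.5),
    "g_y": (0.01, 1.5),
    "tau": (0.0, 0.3),
    "tau_t": (0.0, 0.3),
    "tau_e": (0.0, 0.3),
    "d": (0.5, 30.0),
}

#: mid-range default start point for the simplex
DEFAULT_START = {
    "a": 6.0,
    "b": 4.0,
    "c1": 0.25,
    "c2": 0.25,
    "g": 0.7,
    "g_x": 0.7,
    "g_y": 0.7,
    "tau": 0.08,
    "tau_t": 0.05,
    "tau_e": 0.10,
    "d": 6.0,
}

PENALTY_WEIGHT = 1e8


@dataclass(frozen=True)
class FitProtocol:
    """One fitting recipe: model family, free/fixed parameter split, data
    scope, fit window and restart policy."""

    model: str  # image_velocity | predictive | polar | polar_directional_error
    free: tuple[str, ...]
    fixed: dict = field(default_factory=dict)
    scope: str = "all_conditions"  # per_axis | per_condition | all_conditions
    window: tuple[float, float] = (1.0, 5.5)
    restarts: int = 8
    seed: int = 0
    sim_rtol: float = 1e-8
    sim_fast: bool = True
    max_iter: int = 2000
    xatol: float = 1e-5

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {overlap}")
        if self.scope not in ("per_axis", "per_condition", "all_conditions"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class FitResult:
    params: PursuitParams
    free: tuple[str, ...]
    objective: float  # (deg/s)^2 summed over window
    vnaf: float  # percent, pooled over fitted axes
    vnaf_per_axis: np.ndarray
    n_iter: int
    converged: bool
    best_restart: int
    subject: str = ""
    condition: str = ""
    axis: str = ""


def protocol_p1(restarts: int = 8, seed: int = 0, **kw) -> FitProtocol:
    """Per-condition, per-axis image-velocity fits (4 free parameters)."""
    return FitProtocol(
        model="image_velocity",
        free=("a", "g", "tau_t", "tau_e"),
        scope="per_axis",
        restarts=restarts,
        seed=seed,
        **kw,
    )


def protocol_p2(
    tau: float = 0.08, fix_tau: bool = True, restarts: int = 8, seed: int = 0, **kw
) -> FitProtocol:
    """All-conditions predictive-model fit per subject.

    With ``fix_tau=False`` the delay joins the free set (the variant with
    known delay/filter-rate trade-offs).
    """
    free = ("a", "b", "c1", "c2", "g_x", "g_y")
    fixed = {"tau": tau}
    if not fix_tau:
        free = free + ("tau",)
        fixed = {}
    return FitProtocol(
        model="predictive",
        free=free,
        fixed=fixed,
        scope="all_conditions",
        restarts=restarts,
        seed=seed,
        **kw,
    )


def protocol_p3(base: PursuitParams, restarts: int = 4, seed: int = 0, **kw) -> FitProtocol:
    """Per-condition predictive fits with rates and delay fixed at the
    subject's all-conditions estimates."""
    return FitProtocol(
        model="predictive",
        free=("g_x", "g_y", "c1", "c2"),
        fixed={"a": base.a, "b": base.b, "tau": base.tau},
        scope="per_condition",
        restarts=restarts,
        seed=seed,
        **kw,
    )


# ---------------------------------------------------------------------------
# VNAF
# ---------------------------------------------------------------------------

def vnaf(model_v, data_v, per_axis: bool = False, about_zero: bool = False):
    """Variance not accounted for, percent.

    ``100 * sum((data - model)^2) / sum((data - mean(data))^2)``; when the
    inputs are 2-D the sums pool both axes (per-axis values available with
    ``per_axis=True``).  Normalization is about the data mean by default;
    ``about_zero=True`` normalizes by the raw sum of squares instead (a
    sensitivity variant).
    """
    m = np.asarray(model_v, dtype=float)
    d = np.asarray(data_v, dtype=float)
    if m.shape != d.shape:
        raise ValueError("model and data shapes differ")
    if m.ndim == 1:
        m = m[:, None]
        d = d[:, None]
    ss_res = np.sum((d - m) ** 2, axis=0)
    center = 0.0 if about_zero else d.mean(axis=0)
    ss_tot = np.sum((d - center) ** 2, axis=0)
    if np.any(ss_tot <= 0):
        raise ValueError("data variance is zero")
    per = 100.0 * ss_res / ss_tot
    pooled = 100.0 * ss_res.sum() / ss_tot.sum()
    if per_axis:
        return float(pooled), per
    return float(pooled)


# ---------------------------------------------------------------------------
# Nelder-Mead with box penalties
# ---------------------------------------------------------------------------

def nelder_mead_minimize(
    objective,
    x0,
    max_iter: int = 2000,
    xatol: float = 1e-6,
    fatol: float = 1e-9,
    bounds=None,
):
    """Simplex minimization (reflect/expand/contract/shrink coefficients
    1, 2, 0.5, 0.5) with optional box constraints enforced by a quadratic
    penalty.  Returns ``(argmin, value, trace)`` where ``trace`` is the
    best objective value after each iteration."""
    x0 = np.asarray(x0, dtype=float)
    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ValueError("objective is not finite at the start point")

    trace: list[float] = []  # best value seen after each evaluation

    def penalized(x):
        val = objective(x)
        if bounds is not None:
            for xi, (lo, hi) in zip(x, bounds):
                if xi < lo:
                    val += PENALTY_WEIGHT * (lo - xi) ** 2
                elif xi > hi:
                    val += PENALTY_WEIGHT * (xi - hi) ** 2
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    res = minimize(
        penalized,
        x0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "xatol": xatol,
            "fatol": fatol,
            "adaptive": False,
        },
    )
    return res.x, float(res.fun), {"trace": trace, "nit": res.nit, "success": res.success}


# ---------------------------------------------------------------------------
# Objective construction
# ---------------------------------------------------------------------------

def _build_params(
    free: tuple[str, ...], x: np.ndarray, fixed: dict, axis: str | None
) -> PursuitParams:
    kw = dict(fixed)
    for name, val in zip(free, x):
        kw[name] = float(val)
    if axis is not None and "g" in kw:
        kw[f"g_{axis}"] = kw.pop("g")
    elif "g" in kw:
        g = kw.pop("g")
        kw["g_x"] = kw["g_y"] = g
    return PursuitParams(**{k: v for k, v in kw.items() if k in PursuitParams.__dataclass_fields__})


def _simulate(protocol: FitProtocol, params: PursuitParams, traj, t_end, rate):
    if protocol.model == "image_velocity":
        if protocol.sim_fast:
            return fast_simulate_image_velocity(params, traj, t_end, rate)
        return simulate_image_velocity_model(
            params, traj, t_end=t_end, rate=rate, rtol=protocol.sim_rtol
        ).v
    if protocol.model == "predictive":
        if protocol.sim_fast:
            return fast_simulate_predictive(params, traj, t_end, rate)
        return simulate_predictive_model(
            params, traj, t_end=t_end, rate=rate, rtol=protocol.sim_rtol
        ).v
    variant = "standard" if protocol.model == "polar" else "directional_error"
    return simulate_polar_model(
        params, traj, variant=variant, t_end=t_end, rate=rate, rtol=protocol.sim_rtol
    ).v


def _linear_basis(protocol: FitProtocol, traj, t_end, rate):
    """Unit-coefficient basis responses of the predictive model for the
    linear parameters (g_x, g_y, c1, c2); requires a, b, tau fixed."""
    base = dict(a=protocol.fixed["a"], b=protocol.fixed["b"], tau=protocol.fixed["tau"])
    cols = {}
    for name in ("g_x", "g_y", "c1", "c2"):
        kw = dict(base, g_x=0.0, g_y=0.0, c1=0.0, c2=0.0)
        kw[name] = 1.0
        params = PursuitParams(**kw)
        if protocol.sim_fast:
            cols[name] = fast_simulate_predictive(params, traj, t_end, rate)
        else:
            cols[name] = simulate_predictive_model(
                params, traj, t_end=t_end, rate=rate, rtol=protocol.sim_rtol
            ).v
    return cols


def _restart_points(protocol: FitProtocol, rng) -> list[np.ndarray]:
    x0 = np.array([DEFAULT_START[p] for p in protocol.free])
    pts = [x0]
    for _ in range(max(protocol.restarts - 1, 0)):
        jitter = rng.uniform(0.7, 1.3, size=x0.shape)
        pts.append(x0 * jitter)
    return pts


def _run_fit_unit(
    protocol: FitProtocol,
    conds: list[str],
    data: dict[str, ProcessedResponse],
    trajectories: dict[str, TargetTrajectory],
    axis: str | None,
    rng,
    subject: str,
) -> FitResult:
    """Minimize the summed squared error for one fit unit (a set of
    conditions and optionally a single axis)."""
    first = data[conds[0]]
    t = first.t
    rate = 1.0 / float(t[1] - t[0])
    t_end = float(t[-1])
    lo, hi = protocol.window
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    ax_idx = {"x": 0, "y": 1}.get(axis) if axis else None

    datas = {}
    for c in conds:
        d = data[c].mean_v[sel]
        datas[c] = d[:, [ax_idx]] if ax_idx is not None else d

    linear = (
        protocol.model == "predictive"
        and set(protocol.free) <= {"g_x", "g_y", "c1", "c2"}
        and {"a", "b", "tau"} <= set(protocol.fixed)
    )
    if linear:
        bases = {
            c: {k: v[sel] for k, v in _linear_basis(protocol, trajectories[c], t_end, rate).items()}
            for c in conds
        }
        fixed_extra = {
            k: protocol.fixed.get(k, 0.0) for k in ("g_x", "g_y", "c1", "c2")
            if k not in protocol.free
        }

        def predict(c, x):
            coef = dict(fixed_extra)
            coef.update(zip(protocol.free, x))
            return sum(coef[k] * bases[c][k] for k in coef)

        def objective(x):
            return sum(
                float(np.sum((datas[c] - predict(c, x)) ** 2)) for c in conds
            )

    else:

        def objective(x):
            params = _build_params(protocol.free, x, protocol.fixed, axis)
            total = 0.0
            for c in conds:
                mv = _simulate(protocol, params, trajectories[c], t_end, rate)[sel]
                if ax_idx is not None:
                    mv = mv[:, [ax_idx]]
                total += float(np.sum((datas[c] - mv) ** 2))
            return total

    bounds = [PARAM_BOUNDS[p] for p in protocol.free]
    best = None
    if protocol.free:
        for ri, x0 in enumerate(_restart_points(protocol, rng)):
            x, fval, info = nelder_mead_minimize(
                objective,
                x0,
                max_iter=protocol.max_iter,
                xatol=protocol.xatol,
                bounds=bounds,
            )
            if best is None or fval < best[1]:
                best = (x, fval, info, ri)
        x, fval, info, ri = best
        converged = bool(info["success"])
        n_iter = int(info["nit"])
    else:  # evaluation mode: no optimization
        x = np.array([])
        fval = objective(x)
        converged, n_iter, ri = True, 0, 0

    params = _build_params(protocol.free, x, protocol.fixed, axis)
    # VNAF at the optimum
    model_all, data_all = [], []
    for c in conds:
        if linear:
            mv = predict(c, x)
        else:
            mv = _simulate(protocol, params, trajectories[c], t_end, rate)[sel]
            if ax_idx is not None:
                mv = mv[:, [ax_idx]]
        model_all.append(mv)
        data_all.append(datas[c])
    pooled, per = vnaf(np.concatenate(model_all), np.concatenate(data_all), per_axis=True)
    if not converged and protocol.free:
        warnings.warn(
            f"fit did not converge (subject={subject!r}, conds={conds}, axis={axis})",
            stacklevel=2,
        )
    return FitResult(
        params=params,
        free=protocol.free,
        objective=fval,
        vnaf=pooled,
        vnaf_per_axis=per,
        n_iter=n_iter,
        converged=converged,
        best_restart=ri,
        subject=subject,
        condition=conds[0] if len(conds) == 1 else "",
        axis=axis or "",
    )


def fit_model(
    protocol: FitProtocol,
    data: dict[str, ProcessedResponse],
    trajectories: dict[str, TargetTrajectory],
    subject: str = "",
) -> list[FitResult]:
    """Fit one subject's averaged responses under the given protocol.

    ``data`` and ``trajectories`` map condition labels to the averaged
    response and its target trajectory; the protocol's scope determines the
    fit units (one overall, one per condition, or one per condition and
    axis).  Returns one :class:`FitResult` per fit unit.
    """
    missing = set(data) - set(trajectories)
    if missing:
        raise ValueError(f"conditions without trajectories: {sorted(missing)}")
    rng = np.random.default_rng(protocol.seed)
    conds = sorted(data)
    results = []
    if protocol.scope == "all_conditions":
        results.append(
            _run_fit_unit(protocol, conds, data, trajectories, None, rng, subject)
        )
    elif protocol.scope == "per_condition":
        for c in conds:
            results.append(
                _run_fit_unit(protocol, [c], data, trajectories, None, rng, subject)
            )
    else:  # per_axis
        for c in conds:
            for axis in ("x", "y"):
                results.append(
                    _run_fit_unit(protocol, [c], data, trajectories, axis, rng, subject)
                )
    return results


# ---------------------------------------------------------------------------
# Protocol comparison
# ---------------------------------------------------------------------------

def _profile_group(condition: str) -> str:
    prof = condition.split("_", 1)[1]
    return {"ss": "ss", "cs": "cs"}.get(prof, "mixed")


def protocol_comparison_report(
    results_global: dict[str, list[FitResult]],
    results_per_condition: dict[str, list[FitResult]],
) -> dict:
    """Compare an all-conditions protocol against a per-condition one.

    Returns per-subject and pooled mean VNAF for both, the relative change,
    and the per-condition mean predictive weights grouped by speed profile
    (ss / cs / mixed).
    """
    if set(results_global) != set(results_per_condition):
        raise ValueError("subject sets differ between the two protocols")
    rows = []
    for sub in sorted(results_global):
        vg = float(np.mean([r.vnaf for r in results_global[sub]]))
        vp = float(np.mean([r.vnaf for r in results_per_condition[sub]]))
        rows.append({"subject": sub, "vnaf_global": vg, "vnaf_per_condition": vp})
    df = pd.DataFrame(rows)
    mean_g = float(df["vnaf_global"].mean())
    mean_p = float(df["vnaf_per_condition"].mean())
    c_rows = []
    for sub, results in results_per_condition.items():
        for r in results:
            c_rows.append(
                {
                    "subject": sub,
                    "condition": r.condition,
                    "profile": _profile_group(r.condition),
                    "c1": r.params.c1,
                    "c2": r.params.c2,
                    "c_mean": 0.5 * (r.params.c1 + r.params.c2),
                }
            )
    cdf = pd.DataFrame(c_rows)
    group_c = cdf.groupby("profile")[["c1", "c2", "c_mean"]].mean()
    return {
        "per_subject": df,
        "mean_vnaf_global": mean_g,
        "mean_vnaf_per_condition": mean_p,
        "relative_change": (mean_g - mean_p) / mean_g if mean_g else 0.0,
        "c_by_profile": group_c,
    }
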