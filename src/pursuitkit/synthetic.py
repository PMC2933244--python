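"""Synthetic eye-movement experiments with known ground truth.

The generator stands in for human recordings: for every condition (5 paths x
4 motion profiles) it simulates steady-state pursuit with the predictive
model, adds low-pass-filtered velocity noise, integrates to position, and
injects threshold-triggered catch-up saccades.  Recordings are 250 Hz
position traces of 5.7 s (1.25 periods), 10 trials per condition, optionally
averaged over two independently noisy "eyes".

Everything is driven by a single integer seed; identical specifications
produce bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .models import PursuitParams, simulate_predictive_model, AVG_FIT_PARAMS
from .trajectories import (
    PROFILES,
    SumOfSinesSpec,
    default_paths,
    make_trajectory,
)

__all__ = [
    "SyntheticSubjectSpec",
    "RawEyeRecording",
    "ExperimentBundle",
    "SUBJECT_PARAM_ROWS",
    "generate_subject",
    "make_fixture_experiment",
    "condition_label",
    "recordings_to_frame",
    "frame_to_recordings",
]

SAMPLE_RATE = 250.0  # Hz
TRIAL_DURATION = 5.7  # s, 1.25 periods

#: published per-subject best-fit parameter rows of the predictive model
#: (a 1/s, b 1/s, g_x, g_y, c1 s, c2 s, tau s) — used as generator ground
#: truth for the six synthetic subjects.
SUBJECT_PARAM_ROWS: tuple[PursuitParams, ...] = (
    PursuitParams(a=7.94, b=3.23, g_x=0.63, g_y=0.53, c1=0.24, c2=0.23, tau=0.08),
    PursuitParams(a=7.00, b=3.27, g_x=0.49, g_y=0.39, c1=0.34, c2=0.33, tau=0.08),
    PursuitParams(a=7.13, b=4.56, g_x=0.59, g_y=0.48, c1=0.23, c2=0.20, tau=0.08),
    PursuitParams(a=7.02, b=3.74, g_x=0.58, g_y=0.50, c1=0.25, c2=0.23, tau=0.08),
    PursuitParams(a=6.53, b=3.36, g_x=0.38, g_y=0.32, c1=0.34, c2=0.31, tau=0.08),
    PursuitParams(a=7.08, b=2.80, g_x=0.52, g_y=0.39, c1=0.34, c2=0.32, tau=0.08),
)


#: published per-subject VNAF (%) of the all-conditions predictive fits
#: (same rows as SUBJECT_PARAM_ROWS) and the published summary statistics
#: of the three fitting protocols — reference inputs for consistency checks.
SUBJECT_VNAF_PCT: tuple[float, ...] = (6.68, 8.34, 7.20, 6.81, 9.09, 8.22)
AVG_VNAF_FIXED_DELAY_PCT = 7.72  # all-conditions fit, delay fixed at 80 ms
AVG_VNAF_FREE_DELAY_PCT = 7.43  # all-conditions fit, delay free
AVG_VNAF_PER_CONDITION_PCT = 5.96  # per-condition fit, rates/delay fixed
IMAGE_VELOCITY_AVG_RATE = 6.2  # 1/s, image-velocity model rate on CS data

#: per-profile predictive weighting used when emulating condition-dependent
#: prediction (largest for the most predictable motion)
PROFILE_C_WEIGHTS = {"ss": 0.39, "cs": 0.21, "ss-cs": 0.29, "cs-ss": 0.29}


def condition_dependent_overrides() -> dict:
    """Per-profile overrides making the generator's predictive weighting
    depend on the speed profile (both channels share the profile weight)."""
    return {
        prof: {"c1": c, "c2": c} for prof, c in PROFILE_C_WEIGHTS.items()
    }


def condition_label(path_id: int, profile: str) -> str:
    return f"p{path_id}_{profile}"


@dataclass(frozen=True)
class SyntheticSubjectSpec:
    """Generator settings for one synthetic subject.

    ``condition_overrides`` maps a profile (``"ss"``, ``"cs"``, ``"ss-cs"``,
    ``"cs-ss"``) or a full condition label to parameter overrides, e.g.
    ``{"ss": {"c1": 0.39, "c2": 0.39}}`` to make the predictive weighting
    condition dependent.
    """

    params: PursuitParams = AVG_FIT_PARAMS
    condition_overrides: dict = field(default_factory=dict)
    noise_sd: float = 1.0  # deg/s, after low-pass filtering
    noise_cutoff_hz: float = 25.0
    saccade_threshold: float = 1.5  # deg position error; inf disables
    saccade_duration: float = 0.030  # s
    n_trials: int = 10
    binocular: bool = True
    seed: int = 0
    subject_id: str = "s1"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


@dataclass
class RawEyeRecording:
    """One trial of 250 Hz binocular-averaged eye position (degrees)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    condition: str
    trial: int
    subject: str


@dataclass
class ExperimentBundle:
    """Per-subject recording sets plus the ground-truth manifest needed to
    regenerate them bit-exactly and to score parameter recovery."""

    recordings: dict[str, list[RawEyeRecording]]  # subject -> trials
    manifest: dict


def _condition_params(
    spec: SyntheticSubjectSpec, path_id: int, profile: str
) -> PursuitParams:
    p = spec.params
    for key in (profile, condition_label(path_id, profile)):
        if key in spec.condition_overrides:
            p = p.replace(**spec.condition_overrides[key])
    return p


def _filtered_noise(rng, n: int, sd: float, cutoff_hz: float) -> np.ndarray:
    """Gaussian velocity noise low-pass filtered at ``cutoff_hz`` and
    rescaled to standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    w = rng.standard_normal(n + 200)  # pad to damp filter transients
    ba = butter(2, cutoff_hz, fs=SAMPLE_RATE)
    f = filtfilt(*ba, w)[100 : 100 + n]
    return sd * f / np.std(f)


def _minimum_jerk_step(n: int) -> np.ndarray:
    """Smooth 0->1 step profile over ``n`` samples (spline friendly)."""
    u = np.linspace(0.0, 1.0, n)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _inject_saccades(
    t: np.ndarray,
    eye_pos: np.ndarray,
    target_pos: np.ndarray,
    threshold: float,
    duration: float,
) -> np.ndarray:
    """Add catch-up saccades whenever the position error magnitude exceeds
    ``threshold``; each saccade is a smooth position step of the full error
    over ``duration`` seconds (zero net drift afterwards)."""
    if not np.isfinite(threshold):
        return eye_pos
    n = len(t)
    n_sac = max(int(round(duration * SAMPLE_RATE)), 2)
    profile = _minimum_jerk_step(n_sac)
    offset = np.zeros_like(eye_pos)
    i = 0
    while i < n:
        err = target_pos[i] - (eye_pos[i] + offset[i])
        if np.hypot(err[0], err[1]) > threshold:
            j = min(i + n_sac, n)
            seg = profile[: j - i, None] * err[None, :]
            offset[i:j] += seg
            offset[j:] += err[None, :]
            i = j + n_sac  # refractory: one saccade duration
        else:
            i += 1
    return eye_pos + offset


def _one_eye_smooth(
    rng,
    model_v: np.ndarray,
    t: np.ndarray,
    start_pos: np.ndarray,
    spec: SyntheticSubjectSpec,
) -> np.ndarray:
    """Smooth (saccade-free) noisy eye position for one eye."""
    v = model_v.copy()
    for ax in range(2):
        v[:, ax] += _filtered_noise(rng, len(t), spec.noise_sd, spec.noise_cutoff_hz)
    return start_pos[None, :] + np.stack(
        [cumulative_trapezoid(v[:, ax], t, initial=0.0) for ax in range(2)], axis=-1
    )


def generate_subject(
    spec: SyntheticSubjectSpec,
    paths: dict[int, SumOfSinesSpec] | None = None,
    path_ids: Iterable[int] | None = None,
    profiles: Iterable[str] = PROFILES,
) -> list[RawEyeRecording]:
    """Generate all trials for one synthetic subject.

    By default this produces the full condition grid (5 paths x 4 profiles
    x ``n_trials``).  ``path_ids``/``profiles`` restrict the grid, e.g. for
    quick tests.
    """
    if paths is None:
        paths = default_paths()
    if path_ids is None:
        path_ids = sorted(paths)
    rng = np.random.default_rng(spec.seed)
    t = np.arange(int(round(TRIAL_DURATION * SAMPLE_RATE)) + 1) / SAMPLE_RATE
    out: list[RawEyeRecording] = []
    for pid in path_ids:
        for profile in profiles:
            traj = make_trajectory(paths[pid], profile)
            params = _condition_params(spec, pid, profile)
            model = simulate_predictive_model(
                params, traj, t_end=TRIAL_DURATION, rate=SAMPLE_RATE
            )
            target_pos = traj.position(t)
            start = target_pos[0]
            label = condition_label(pid, profile)
            for trial in range(spec.n_trials):
                eyes = [
                    _one_eye_smooth(rng, model.v, t, start, spec)
                    for _ in range(2 if spec.binocular else 1)
                ]
                # saccades are conjugate: inject once, on the averaged trace
                pos = _inject_saccades(
                    t,
                    np.mean(eyes, axis=0),
                    target_pos,
                    spec.saccade_threshold,
                    spec.saccade_duration,
                )
                out.append(
                    RawEyeRecording(
                        t=t,
                        x=pos[:, 0],
                        y=pos[:, 1],
                        condition=label,
                        trial=trial,
                        subject=spec.subject_id,
                    )
                )
    return out


def make_fixture_experiment(
    n_subjects: int,
    param_table: Iterable[PursuitParams] = SUBJECT_PARAM_ROWS,
    seed: int = 0,
    condition_overrides: dict | None = None,
    noise_sd: float = 1.0,
    n_trials: int = 10,
    paths: dict[int, SumOfSinesSpec] | None = None,
    path_ids: Iterable[int] | None = None,
    profiles: Iterable[str] = PROFILES,
    saccade_threshold: float = 1.5,
) -> ExperimentBundle:
    """Build a multi-subject synthetic experiment with a ground-truth
    manifest (one parameter row per subject)."""
    table = list(param_table)
    if not table:
        raise ValueError("empty parameter table")
    if n_subjects > len(table):
        raise ValueError(f"only {len(table)} parameter rows available")
    recordings: dict[str, list[RawEyeRecording]] = {}
    manifest: dict = {
        "seed": seed,
        "noise_sd": noise_sd,
        "n_trials": n_trials,
        "subjects": {},
    }
    for i in range(n_subjects):
        sid = f"s{i + 1}"
        sub_spec = SyntheticSubjectSpec(
            params=table[i],
            condition_overrides=condition_overrides or {},
            noise_sd=noise_sd,
            n_trials=n_trials,
            saccade_threshold=saccade_threshold,
            seed=seed + i,
            subject_id=sid,
        )
        recordings[sid] = generate_subject(
            sub_spec, paths=paths, path_ids=path_ids, profiles=profiles
        )
        manifest["subjects"][sid] = {
            "params": table[i].to_dict(),
            "condition_overrides": condition_overrides or {},
            "seed": seed + i,
        }
    return ExperimentBundle(recordings=recordings, manifest=manifest)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def recordings_to_frame(recordings: list[RawEyeRecording]) -> pd.DataFrame:
    """Long-format table: subject, condition, trial, t_s, x_deg, y_deg."""
    frames = []
    for rec in recordings:
        frames.append(
            pd.DataFrame(
                {
                    "subject": rec.subject,
                    "condition": rec.condition,
                    "trial": rec.trial,
                    "t_s": rec.t,
                    "x_deg": rec.x,
                    "y_deg": rec.y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_recordings(df: pd.DataFrame) -> list[RawEyeRecording]:
    out = []
    for (sub, cond, trial), grp in df.groupby(
        ["subject", "condition", "trial"], sort=True
    ):
        grp = grp.sort_values("t_s")
        out.append(
            RawEyeRecording(
                t=grp["t_s"].to_numpy(),
                x=grp["x_deg"].to_numpy(),
                y=grp["y_deg"].to_numpy(),
                condition=str(cond),
                trial=int(trial),
                subject=str(sub),
            )
        )
    return out
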