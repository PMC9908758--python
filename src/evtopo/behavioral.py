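"""Questionnaire and hand-kinematics feature extraction.

Trajectory features follow the convention of continuous left-right
movement tasks: each trial is segmented into sweeps at direction
reversals of the principal (left-right) movement axis; the trajectory
norm is the magnitude of each sweep's displacement vector (not its arc
length), averaged over sweeps, and the velocity is total path length
over trial duration.  Positions are lightly smoothed (0.2 s moving
average) before reversal detection so sensor jitter near the turning
points does not fragment sweeps.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .containers import BehavioralTable, condition_factors

__all__ = ["trajectory_features", "trial_features", "questionnaire_table"]


def _principal_axis(xyz: np.ndarray) -> np.ndarray:
    centred = xyz - xyz.mean(axis=0)
    cov = centred.T @ centred
    vals, vecs = np.linalg.eigh(cov)
    axis = vecs[:, -1]
    # deterministic sign: first nonzero component positive
    nz = np.flatnonzero(np.abs(axis) > 1e-12)
    if nz.size and axis[nz[0]] < 0:
        axis = -axis
    return axis


def _reversal_indices(s: np.ndarray, hysteresis_frac: float = 0.05) -> list[int]:
    """Turning points of ``s`` with hysteresis.

    A reversal is recorded at the running extremum once the signal has
    retreated from it by more than ``hysteresis_frac`` of the overall
    range, so jitter around the turning points does not fragment sweeps.
    """
    h = hysteresis_frac * (float(s.max()) - float(s.min()))
    out: list[int] = []
    direction = 0
    mn = mx = s[0]
    ext_val = s[0]
    ext_idx = 0
    for i, v in enumerate(s):
        if direction == 0:
            mn, mx = min(mn, v), max(mx, v)
            if v - mn > h:
                direction = 1
                ext_val, ext_idx = v, i
            elif mx - v > h:
                direction = -1
                ext_val, ext_idx = v, i
            continue
        if direction == 1:
            if v >= ext_val:
                ext_val, ext_idx = v, i
            elif ext_val - v > h:
                out.append(ext_idx)
                direction = -1
                ext_val, ext_idx = v, i
        else:
            if v <= ext_val:
                ext_val, ext_idx = v, i
            elif v - ext_val > h:
                out.append(ext_idx)
                direction = 1
                ext_val, ext_idx = v, i
    return out


def trial_features(
    trial: np.ndarray, smooth_window_s: float = 0.2
) -> tuple[float, float]:
    """(trajectory_norm_cm, velocity_cm_s) for one (n_samples, 4) trial.

    Columns are t (s), x, y, z (cm) with strictly increasing timestamps.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[1] not in (3, 4) or trial.shape[0] < 2:
        raise ValueError("trial must be (n_samples >= 2, [t, x, y(, z)])")
    t = trial[:, 0]
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    xyz = trial[:, 1:]
    if xyz.shape[1] == 2:
        xyz = np.column_stack([xyz, np.zeros(len(xyz))])

    dt = float(np.median(np.diff(t)))
    win = max(1, int(round(smooth_window_s / dt)))
    smooth = uniform_filter1d(xyz, size=win, axis=0, mode="nearest")

    s = (smooth - smooth.mean(axis=0)) @ _principal_axis(smooth)
    rev = _reversal_indices(s)
    if len(rev) >= 2:
        # complete sweeps only: the partial stretches before the first and
        # after the last reversal would bias the mean low
        bounds = rev
    else:
        if not rev:
            warnings.warn(
                "no direction reversal detected; whole trial is one sweep",
                stacklevel=2,
            )
        bounds = [0] + rev + [len(s) - 1]
    norms = [
        float(np.linalg.norm(smooth[b1] - smooth[b0]))
        for b0, b1 in zip(bounds[:-1], bounds[1:])
        if b1 > b0
    ]
    traj_norm = float(np.mean(norms)) if norms else 0.0

    path = float(np.sum(np.linalg.norm(np.diff(smooth, axis=0), axis=1)))
    velocity = path / float(t[-1] - t[0])
    return traj_norm, velocity


def trajectory_features(
    trajectories: dict[tuple[str, str], list[np.ndarray]],
    smooth_window_s: float = 0.2,
) -> pd.DataFrame:
    """Per-condition subject means of sweep norm and velocity.

    ``trajectories`` maps (subject, condition) to a list of per-trial
    (n_samples, 4) arrays.  Returns a tidy frame with columns subject,
    congruency, synchrony, trajectory_norm_cm, velocity_cm_s, n_trials.
    """
    rows = []
    for (subject, cond), trials in sorted(trajectories.items()):
        congruency, synchrony = condition_factors(cond)
        feats = np.array([trial_features(tr, smooth_window_s) for tr in trials])
        rows.append(
            {
                "subject": subject,
                "congruency": congruency,
                "synchrony": synchrony,
                "trajectory_norm_cm": float(feats[:, 0].mean()),
                "velocity_cm_s": float(feats[:, 1].mean()),
                "n_trials": len(trials),
            }
        )
    return pd.DataFrame(rows)


def questionnaire_table(ratings: pd.DataFrame) -> BehavioralTable:
    """Validate questionnaire ratings into a behavioural table.

    Expects tidy columns subject, congruency, synchrony, agency_rating
    and optionally control_rating.  Ratings must lie in [0, 10]; missing
    control ratings are tolerated (NaN) and excluded listwise by the
    statistics layer, so an analysis with two missing subjects simply
    runs at n-2.
    """
    df = pd.DataFrame(ratings).copy()
    if "agency_rating" not in df.columns:
        raise ValueError("ratings table needs an agency_rating column")
    return BehavioralTable(df)
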