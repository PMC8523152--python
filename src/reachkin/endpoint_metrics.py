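"""Per-trial endpoint error measures and per-participant summaries.

For one trial the measures are the absolute error (Euclidean endpoint-to-
target distance), the error vector (endpoint minus target), the initial
directional error (unsigned angle between the home->position-at-peak-
velocity vector and the home->target vector; a feedforward-plan proxy)
and the corrective angle (unsigned angle between the direction vector at
peak velocity and the direction vector at movement end).

Across a participant's trials, the error vectors are overlaid as if all
reaches were made to a single target and decomposed into

* bias — the distance from the centroid of the overlaid endpoints to the
  target (systematic error, "accuracy"), and
* noise — the spatial standard deviation of endpoints about their own
  centroid, pooled over both coordinates (stochastic error, "precision").

The mean-squared-error identity ``mean(|e|^2) = |bias|^2 + Var_pop`` (with
population divisors) is verified on every decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .kinematics import SegmentedReach
from .traj_io import Loc1DRecord, TrialTrajectory

__all__ = [
    "UndefinedAngleError",
    "InsufficientDataError",
    "TrialMeasures",
    "BiasNoise",
    "ParticipantSummary",
    "angle_between_deg",
    "trial_measures",
    "decompose",
    "participant_summary",
    "flag_outliers",
    "fitts_check",
    "loc1d_error",
]


class UndefinedAngleError(ValueError):
    """A direction vector has zero length, so its angle is undefined."""


class InsufficientDataError(ValueError):
    """Too few trials/participants for the requested summary."""


@dataclass
class TrialMeasures:
    """Error measures for a single non-excluded reach."""

    absolute_error: float        # cm
    error_vector: np.ndarray     # cm, endpoint - target
    initial_directional_error: float  # degrees, [0, 180]
    corrective_angle: float      # degrees, [0, 180]
    movement_time: float         # s


@dataclass
class BiasNoise:
    """Overlay-based decomposition of endpoint errors for one dataset."""

    n_trials: int
    bias_vector: np.ndarray      # cm
    bias_magnitude: float        # cm
    bias_angle: float            # degrees in [-180, 180)
    noise_sd: float              # cm, pooled over x and y, divisor n-1
    mean_log_abs_error: float    # log-cm


@dataclass
class ParticipantSummary:
    """Per-participant aggregate of trial measures plus the decomposition."""

    n_trials: int
    bias_noise: BiasNoise
    mean_abs_error: float            # on the transform scale
    mean_initial_directional_error: float
    mean_corrective_angle: float
    transform: str


def angle_between_deg(u, v) -> float:
    """Unsigned angle between two 2D vectors, degrees in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise UndefinedAngleError("zero-length direction vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def trial_measures(trajectory: TrialTrajectory, seg: SegmentedReach,
                   corrective_anchor: str = "home") -> TrialMeasures:
    """Compute the per-trial error measures from a segmented reach.

    ``corrective_anchor`` selects the end-of-movement direction vector for
    the corrective angle: ``"home"`` (default) uses home->endpoint,
    ``"peak"`` uses position-at-peak->endpoint.
    """
    if seg.excluded:
        raise ValueError(f"trial {trajectory.label()} is excluded")
    home = trajectory.home
    target = trajectory.target
    endpoint = seg.endpoint
    err_vec = endpoint - target
    at_peak = trajectory.positions[seg.peak_index]
    dir_peak = at_peak - home
    init_err = angle_between_deg(dir_peak, target - home)
    if corrective_anchor == "home":
        end_vec = endpoint - home
    elif corrective_anchor == "peak":
        end_vec = endpoint - at_peak
    else:
        raise ValueError(f"unknown corrective_anchor {corrective_anchor!r}")
    corr = angle_between_deg(dir_peak, end_vec)
    return TrialMeasures(
        absolute_error=float(np.linalg.norm(err_vec)),
        error_vector=err_vec,
        initial_directional_error=init_err,
        corrective_angle=corr,
        movement_time=seg.movement_time,
    )


def decompose(error_vectors) -> BiasNoise:
    """Overlay error vectors onto a single notional target and decompose.

    bias_vector is the centroid of the overlaid errors; noise_sd is
    ``sqrt(sum |e_i - mean|^2 / (n - 1))``, pooling both coordinates.
    """
    e = np.asarray(error_vectors, float)
    if e.ndim != 2 or e.shape[1] != 2:
        raise ValueError("error_vectors must be an (n, 2) array")
    n = len(e)
    if n < 2:
        raise InsufficientDataError("need at least 2 trials to decompose")
    bias_vec = e.mean(axis=0)
    dev = e - bias_vec
    ss = float(np.sum(dev ** 2))
    noise_sd = float(np.sqrt(ss / (n - 1)))
    # mean-squared-error identity with population divisors
    mse = float(np.mean(np.sum(e ** 2, axis=1)))
    ident = float(bias_vec @ bias_vec) + ss / n
    if abs(mse - ident) > 1e-9 * max(1.0, abs(mse)):
        raise AssertionError(
            f"MSE decomposition identity violated: {mse} vs {ident}")
    abs_err = np.linalg.norm(e, axis=1)
    eps = np.finfo(float).eps
    if np.any(abs_err == 0.0):
        warnings.warn("zero absolute error replaced by machine epsilon "
                      "under the log transform")
        abs_err = np.where(abs_err == 0.0, eps, abs_err)
    return BiasNoise(
        n_trials=n,
        bias_vector=bias_vec,
        bias_magnitude=float(np.linalg.norm(bias_vec)),
        bias_angle=float(np.degrees(np.arctan2(bias_vec[1], bias_vec[0]))),
        noise_sd=noise_sd,
        mean_log_abs_error=float(np.mean(np.log(abs_err))),
    )


def participant_summary(trials, transform: str = "log") -> ParticipantSummary:
    """Aggregate a participant's trial measures.

    Absolute errors are log transformed before averaging by default,
    correcting the skew of error distributions; pass
    ``transform="identity"`` for a plain mean.
    """
    trials = list(trials)
    if len(trials) < 2:
        raise InsufficientDataError("need at least 2 non-excluded trials")
    if transform not in ("log", "identity"):
        raise ValueError(f"unknown transform {transform!r}")
    errs = np.array([t.absolute_error for t in trials])
    vectors = np.array([t.error_vector for t in trials])
    bn = decompose(vectors)
    if transform == "log":
        mean_err = bn.mean_log_abs_error
    else:
        mean_err = float(np.mean(errs))
    return ParticipantSummary(
        n_trials=len(trials),
        bias_noise=bn,
        mean_abs_error=mean_err,
        mean_initial_directional_error=float(
            np.mean([t.initial_directional_error for t in trials])),
        mean_corrective_angle=float(
            np.mean([t.corrective_angle for t in trials])),
        transform=transform,
    )


def flag_outliers(values: dict, k: float = 1.5) -> list:
    """Tukey-fence outliers among per-participant values.

    ``values`` maps participant id -> (transformed) error value.  Returns
    the ids outside [Q1 - k*IQR, Q3 + k*IQR], quartiles by linear
    interpolation.
    """
    ids = list(values.keys())
    v = np.asarray([values[i] for i in ids], float)
    if len(v) < 4:
        raise InsufficientDataError("need at least 4 participants")
    q1, q3 = np.percentile(v, [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return [i for i, x in zip(ids, v) if x < lo or x > hi]


def fitts_check(movement_times, distances, widths):
    """Fitts'-law speed-accuracy regression MT = a + b * ID.

    ID = log2(2D / W).  Returns (intercept a, slope b, Pearson r).
    """
    mt = np.asarray(movement_times, float)
    d = np.asarray(distances, float)
    w = np.asarray(widths, float)
    if np.any(d <= 0) or np.any(w <= 0):
        raise ValueError("distances and widths must be positive")
    ident = np.log2(2.0 * d / w)
    if len(np.unique(ident)) < 3:
        raise InsufficientDataError("need >= 3 distinct indices of difficulty")
    res = stats.linregress(ident, mt)
    return float(res.intercept), float(res.slope), float(res.rvalue)


def loc1d_error(records) -> dict:
    """Mean absolute localization error per participant x condition (cm)."""
    acc: dict = {}
    for r in records:
        if not isinstance(r, Loc1DRecord):
            raise TypeError("expected Loc1DRecord items")
        acc.setdefault((r.participant_id, r.condition), []).append(
            abs(r.estimate - r.true_position))
    return {key: float(np.mean(v)) for key, v in acc.items()}
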