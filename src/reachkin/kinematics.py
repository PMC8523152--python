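"""Trajectory segmentation: smoothed speed, movement onset, peak velocity,
movement termination and trial-exclusion rules.

The segmentation follows the standard event definitions for fast
center-out reaches:

* tangential speed, low-pass filtered at 8 Hz (zero-phase Butterworth);
* onset = first sample with speed above 3.5 cm/s, searched after any
  initial still period;
* for the visually guided ("main") task, termination = the first local
  speed minimum after the peak that falls below 50% of peak speed (the
  end of the first reach), falling back to the end of the trial window
  when no such minimum exists;
* for reaches without visual feedback ("loc2d"), termination = the start
  of the first quiescent period (speed < 3.5 cm/s for more than 1 s).

Accidentally initiated or unfinished trials are flagged rather than
dropped, so exclusion tallies can be reported downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .traj_io import TrialTrajectory

__all__ = [
    "ParameterError",
    "NoMovementError",
    "UnterminatedTrialError",
    "SpeedSeries",
    "SegmentedReach",
    "EXCLUSION_REASONS",
    "compute_speed",
    "detect_onset",
    "detect_termination_main",
    "detect_termination_unseen",
    "segment_trial",
    "apply_exclusions",
]

log = logging.getLogger(__name__)

# Default analysis constants (all overridable per call).
FILTER_CUTOFF_HZ = 8.0
BUTTER_ORDER = 2           # applied forward-backward -> effective 4th order
ONSET_THRESHOLD = 3.5      # cm/s
TERMINATION_FRACTION = 0.5  # of peak speed
UNSEEN_HOLD_S = 1.0
MAIN_TRIAL_WINDOW_S = 1.0  # imposed maximum movement time in the main task
NEAR_HOME_CM = 2.0
SHALLOW_Y_CM = 1.0
END_SPEED_CM_S = 10.0
LOC2D_MAX_TIME_S = 10.0
LOC2D_MAX_ERROR_CM = 20.0

EXCLUSION_REASONS = (
    "none", "accidental_near_home", "accidental_shallow_y",
    "moving_at_trial_end", "overtime", "error_too_large",
    "no_movement", "unterminated",
)


class ParameterError(ValueError):
    """An analysis parameter is invalid for the supplied data."""


class NoMovementError(RuntimeError):
    """Speed never exceeded the onset threshold."""


class UnterminatedTrialError(RuntimeError):
    """The quiescence criterion was never met."""


@dataclass
class SpeedSeries:
    """Tangential speed (cm/s) aligned with the parent trajectory's times."""

    times: np.ndarray
    speed: np.ndarray

    def __post_init__(self):
        if len(self.times) != len(self.speed):
            raise ValueError("times and speed lengths differ")

    def index_at(self, t: float) -> int:
        """Index of the sample nearest time ``t``."""
        return int(np.argmin(np.abs(self.times - t)))


@dataclass
class SegmentedReach:
    """Landmarks and exclusion state for one segmented reach."""

    onset_index: int | None
    peak_index: int | None
    termination_index: int | None
    endpoint: np.ndarray | None
    peak_speed: float | None
    movement_time: float | None
    excluded: bool = False
    exclusion_reason: str = "none"
    trial_end_index: int | None = None


def lowpass(x: np.ndarray, fs: float, cutoff: float = FILTER_CUTOFF_HZ,
            order: int = BUTTER_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Edges are handled by reflective padding so that a constant series is
    returned unchanged and no temporal lag is introduced.
    """
    if cutoff >= fs / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz is not below the Nyquist rate {fs / 2} Hz")
    b, a = signal.butter(order, cutoff / (fs / 2))
    padlen = min(3 * max(len(a), len(b)) * 4, x.shape[0] - 1)
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def compute_speed(trajectory: TrialTrajectory, cutoff: float = FILTER_CUTOFF_HZ,
                  order: int = BUTTER_ORDER,
                  filter_target: str = "speed") -> SpeedSeries:
    """Tangential speed of a reach, low-pass filtered at ``cutoff`` Hz.

    ``filter_target="speed"`` (default) differentiates the raw positions
    and smooths the resulting speed series; ``"position"`` smooths the
    positions first and differentiates the filtered path.  Differentiation
    uses central finite differences.
    """
    fs = trajectory.sampling_rate
    if filter_target not in ("speed", "position"):
        raise ParameterError(f"unknown filter_target {filter_target!r}")
    pos = trajectory.positions
    if filter_target == "position":
        pos = lowpass(pos, fs, cutoff, order)
    vel = np.gradient(pos, trajectory.times, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if filter_target == "speed":
        speed = lowpass(speed, fs, cutoff, order)
    # filtering can produce tiny negative excursions near zero speed
    np.clip(speed, 0.0, None, out=speed)
    return SpeedSeries(times=trajectory.times, speed=speed)


def detect_onset(speed: SpeedSeries, threshold: float = ONSET_THRESHOLD) -> int:
    """First sample with speed strictly above ``threshold``.

    The search starts where speed first rises above 10% of its eventual
    peak, which skips low-amplitude sensor jitter before the reach.
    """
    s = speed.speed
    peak = float(np.max(s))
    if peak <= threshold:
        raise NoMovementError(
            f"speed never exceeds the {threshold} cm/s onset threshold")
    start = int(np.argmax(s > 0.1 * peak))
    rel = np.nonzero(s[start:] > threshold)[0]
    if rel.size == 0:
        raise NoMovementError(
            f"speed never exceeds the {threshold} cm/s onset threshold "
            "after the initial still period")
    return start + int(rel[0])


def _local_minima(s: np.ndarray, lo: int, hi: int) -> list[int]:
    """Strict local minima in ``s[lo:hi]``: s[i] < s[i-1] and s[i] <= s[i+1]."""
    out = []
    for i in range(max(lo, 1), min(hi, len(s) - 1)):
        if s[i] < s[i - 1] and s[i] <= s[i + 1]:
            out.append(i)
    return out


def detect_termination_main(speed: SpeedSeries, onset: int,
                            fraction: float = TERMINATION_FRACTION,
                            end: int | None = None) -> int:
    """End of the first reach in a visually guided trial.

    Returns the first local speed minimum after the post-onset peak whose
    speed falls below ``fraction`` of the peak speed; when no qualifying
    minimum exists the last sample of the trial window is returned (this
    fallback is known to give very similar summary results).
    """
    s = speed.speed
    last = len(s) - 1 if end is None else end
    if onset >= last:
        raise ParameterError("onset must precede the end of the trial window")
    peak_idx = onset + int(np.argmax(s[onset:last + 1]))
    peak = s[peak_idx]
    for i in _local_minima(s, peak_idx + 1, last + 1):
        if s[i] < fraction * peak:
            return i
    return last


def detect_termination_unseen(speed: SpeedSeries, onset: int,
                              hold: float = UNSEEN_HOLD_S,
                              threshold: float = ONSET_THRESHOLD) -> int:
    """Termination of a no-vision reach: start of the first quiescent run.

    A quiescent run is a maximal stretch of samples with speed below
    ``threshold`` lasting longer than ``hold`` seconds.
    """
    s, t = speed.speed, speed.times
    n = len(s)
    i = onset + 1
    while i < n:
        if s[i] < threshold:
            j = i
            while j + 1 < n and s[j + 1] < threshold:
                j += 1
            if t[j] - t[i] > hold:
                return i
            i = j + 1
        else:
            i += 1
    raise UnterminatedTrialError(
        f"speed never stayed below {threshold} cm/s for more than {hold} s")


def apply_exclusions(seg: SegmentedReach, trajectory: TrialTrajectory,
                     speed: SpeedSeries | None = None,
                     near_home: float = NEAR_HOME_CM,
                     shallow_y: float = SHALLOW_Y_CM,
                     end_speed: float = END_SPEED_CM_S,
                     max_time: float = LOC2D_MAX_TIME_S,
                     max_error: float = LOC2D_MAX_ERROR_CM) -> SegmentedReach:
    """Flag accidental initiations and unfinished or invalid reaches.

    Shared rules: an endpoint closer than ``near_home`` cm to home or with
    depth (y) below ``shallow_y`` cm marks an accidental initiation; in
    the main task, speed above ``end_speed`` cm/s at the last sample of
    the trial window marks an unfinished reach.  No-vision (loc2d) trials
    are additionally invalid when movement time exceeds ``max_time`` s or
    the endpoint misses the target by more than ``max_error`` cm.
    """
    if seg.endpoint is None:
        return replace(seg, excluded=True, exclusion_reason="no_movement")
    reason = "none"
    dist_home = float(np.linalg.norm(seg.endpoint - trajectory.home))
    if dist_home < near_home:
        reason = "accidental_near_home"
    elif seg.endpoint[1] < shallow_y:
        reason = "accidental_shallow_y"
    elif trajectory.task == "main":
        end_idx = seg.trial_end_index
        if end_idx is None:
            end_idx = len(trajectory.times) - 1
        if speed is not None and speed.speed[end_idx] > end_speed:
            reason = "moving_at_trial_end"
    elif trajectory.task == "loc2d":
        err = float(np.linalg.norm(seg.endpoint - trajectory.target))
        if seg.movement_time is not None and seg.movement_time > max_time:
            reason = "overtime"
        elif err > max_error:
            reason = "error_too_large"
    if reason == "none" and seg.exclusion_reason in ("no_movement", "unterminated"):
        reason = seg.exclusion_reason
    return replace(seg, excluded=reason != "none", exclusion_reason=reason)


def segment_trial(trajectory: TrialTrajectory,
                  cutoff: float = FILTER_CUTOFF_HZ,
                  order: int = BUTTER_ORDER,
                  filter_target: str = "speed",
                  onset_threshold: float = ONSET_THRESHOLD,
                  fraction: float = TERMINATION_FRACTION,
                  hold: float = UNSEEN_HOLD_S,
                  main_window: float = MAIN_TRIAL_WINDOW_S,
                  **exclusion_kwargs) -> SegmentedReach:
    """Segment one trial end to end and apply the task's exclusion rules.

    Detection failures (no movement, no quiescence) yield an excluded
    reach with a distinct reason instead of propagating.
    """
    speed = compute_speed(trajectory, cutoff=cutoff, order=order,
                          filter_target=filter_target)
    s, t = speed.speed, speed.times
    failure = None
    onset = None
    try:
        onset = detect_onset(speed, threshold=onset_threshold)
    except NoMovementError:
        failure = "no_movement"

    if onset is None:
        seg = SegmentedReach(
            onset_index=None, peak_index=None,
            termination_index=len(s) - 1,
            endpoint=trajectory.positions[-1].copy(),
            peak_speed=float(np.max(s)), movement_time=None,
            exclusion_reason=failure,
            trial_end_index=len(s) - 1)
        seg = apply_exclusions(seg, trajectory, speed, **exclusion_kwargs)
        _log_trial(trajectory, seg)
        return seg

    if trajectory.task == "main":
        trial_end = speed.index_at(t[onset] + main_window)
        term = detect_termination_main(speed, onset, fraction=fraction,
                                       end=trial_end)
    else:
        trial_end = len(s) - 1
        try:
            term = detect_termination_unseen(speed, onset, hold=hold,
                                             threshold=onset_threshold)
        except UnterminatedTrialError:
            failure = "unterminated"
            term = trial_end

    peak = onset + int(np.argmax(s[onset:trial_end + 1]))
    seg = SegmentedReach(
        onset_index=onset, peak_index=peak, termination_index=term,
        endpoint=trajectory.positions[term].copy(),
        peak_speed=float(s[peak]),
        movement_time=float(t[term] - t[onset]),
        exclusion_reason=failure or "none",
        trial_end_index=trial_end)
    seg = apply_exclusions(seg, trajectory, speed, **exclusion_kwargs)
    _log_trial(trajectory, seg)
    return seg


def _log_trial(trajectory: TrialTrajectory, seg: SegmentedReach) -> None:
    log.info(
        "trial %s: onset=%s peak=%s term=%s excluded=%s reason=%s",
        trajectory.label(), seg.onset_index, seg.peak_index,
        seg.termination_index, seg.excluded, seg.exclusion_reason)
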