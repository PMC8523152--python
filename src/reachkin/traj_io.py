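"""Readers, writers and record types for reaching-trajectory data.

Three record families are handled:

* :class:`TrialTrajectory` — one center-out reach: metadata plus a
  time-stamped 2D position series sampled nominally at 200 Hz, in cm,
  with the home position at the origin and +y pointing away from the body.
* :class:`Loc1DRecord` — one trial of the 1D arm-localization task
  (estimate vs. true position along a tube axis).
* :class:`CohortRecord` — one row of the participant table: demographics,
  prosthetic device, usage measures and prosthesis history.

Trajectories travel as long-format CSV (one row per sample), cohort tables
as TSV mirroring the published table headers.  A transcription of the
published cohort table ships with the package and is returned by
:func:`load_packaged_cohort`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "TrialTrajectory",
    "Loc1DRecord",
    "CohortRecord",
    "TRAJECTORY_COLUMNS",
    "read_trajectories",
    "write_trajectories",
    "read_loc1d",
    "write_loc1d",
    "read_cohort",
    "write_cohort",
    "load_packaged_cohort",
]

GROUPS = ("control", "acquired", "congenital")
ARMS = ("intact_dominant", "artificial_nondominant")
TASKS = ("main", "loc2d")

#: Header of the long-format trajectory CSV.
TRAJECTORY_COLUMNS = (
    "participant", "group", "arm", "task", "trial",
    "target_x", "target_y", "t", "x", "y",
)

NOMINAL_RATE_HZ = 200.0
#: Allowed relative deviation of any sampling interval from the median.
JITTER_TOL = 0.01


def _shortest(value: float) -> str:
    """Shortest decimal text that round-trips the exact float value."""
    return repr(float(value))


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(2)
    return a


@dataclass
class TrialTrajectory:
    """A single reach: metadata plus the sampled 2D hand path (cm, s)."""

    participant_id: str
    group: str
    arm: str
    task: str
    trial_index: int
    target: np.ndarray
    times: np.ndarray
    positions: np.ndarray
    home: np.ndarray = field(default_factory=lambda: np.zeros(2))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.target = _as_point(self.target)
        self.home = _as_point(self.home)
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be a positive integer")
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValidationError("positions must be an (n, 2) array")
        n = len(self.times)
        if n < 10:
            raise ValidationError(
                f"trial {self.label()}: needs >= 10 samples, got {n}")
        if len(self.positions) != n:
            raise ValidationError(
                f"trial {self.label()}: times and positions lengths differ")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError(
                f"trial {self.label()}: times not strictly increasing")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > JITTER_TOL * med):
            raise ValidationError(
                f"trial {self.label()}: sampling jitter exceeds "
                f"{JITTER_TOL:.0%} of the nominal interval")
        if not np.allclose(self.home, 0.0):
            raise ValidationError(
                f"trial {self.label()}: home position must be (0, 0)")

    def label(self) -> str:
        return f"{self.participant_id}/{self.arm}/{self.task}/{self.trial_index}"

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.times)))


@dataclass
class Loc1DRecord:
    """One 1D localization trial along the tube axis (cm)."""

    participant_id: str
    condition: str  # "residual" | "artificial"
    true_position: float
    estimate: float
    max_reach: float

    def __post_init__(self):
        if self.condition not in ("residual", "artificial"):
            raise ValidationError(f"unknown condition {self.condition!r}")
        lo, hi = 0.25 * self.max_reach, 0.75 * self.max_reach
        if not (lo <= self.true_position <= hi):
            raise ValidationError(
                f"{self.participant_id}: true_position {self.true_position} "
                f"outside 25-75% of max reach [{lo}, {hi}]")


@dataclass
class CohortRecord:
    """One participant row of the cohort table.

    ``intact_only`` marks participants whose artificial-arm data were
    invalid (asterisked in the published table); their rows are retained
    and filtered downstream.
    """

    participant_id: str
    group: str
    age: float
    sex: str | None = None
    side: str | None = None
    level: str | None = None                 # TR | TH
    cause: str | None = None
    device_type: str | None = None           # cosmetic | mechanical | myoelectric | none
    years_since_amputation: float | None = None
    wear_time: float | None = None           # hours/week
    pal: float | None = None                 # fraction in [0, 1]
    usage_score: float | None = None         # printed z-sum
    age_first_use: float | None = None       # congenital only, years
    limbless_years: float | None = None      # acquired only, years
    residual_length: float | None = None     # cm
    intact_only: bool = False

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.pal is not None and not (0.0 <= self.pal <= 1.0):
            raise ValidationError(
                f"{self.participant_id}: PAL {self.pal} outside [0, 1]")
        if self.wear_time is not None and not (0.0 <= self.wear_time <= 168.0):
            raise ValidationError(
                f"{self.participant_id}: wear time {self.wear_time} "
                "outside [0, 168] h/week")
        if self.age_first_use is not None and self.limbless_years is not None:
            raise ValidationError(
                f"{self.participant_id}: age_first_use and limbless_years "
                "are mutually exclusive")
        if self.group == "acquired" and self.age_first_use is not None:
            raise ValidationError(
                f"{self.participant_id}: age_first_use is a congenital field")
        if self.group == "congenital" and self.limbless_years is not None:
            raise ValidationError(
                f"{self.participant_id}: limbless_years is an acquired field")


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def trajectories_to_frame(trials: Iterable[TrialTrajectory]) -> pd.DataFrame:
    """Flatten trials into the long-format trajectory table."""
    chunks = []
    for tr in trials:
        n = len(tr.times)
        chunks.append(pd.DataFrame({
            "participant": np.repeat(tr.participant_id, n),
            "group": np.repeat(tr.group, n),
            "arm": np.repeat(tr.arm, n),
            "task": np.repeat(tr.task, n),
            "trial": np.repeat(tr.trial_index, n),
            "target_x": np.repeat(tr.target[0], n),
            "target_y": np.repeat(tr.target[1], n),
            "t": tr.times,
            "x": tr.positions[:, 0],
            "y": tr.positions[:, 1],
        }))
    if not chunks:
        return pd.DataFrame(columns=list(TRAJECTORY_COLUMNS))
    return pd.concat(chunks, ignore_index=True)


def frame_to_trajectories(frame: pd.DataFrame) -> list[TrialTrajectory]:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"trajectory table missing column(s): {missing}")
    out = []
    for (pid, arm, task, trial), g in frame.groupby(
            ["participant", "arm", "task", "trial"], sort=False):
        grp = g["group"].iloc[0]
        tgt = (float(g["target_x"].iloc[0]), float(g["target_y"].iloc[0]))
        out.append(TrialTrajectory(
            participant_id=str(pid), group=str(grp), arm=str(arm),
            task=str(task), trial_index=int(trial), target=tgt,
            times=g["t"].to_numpy(float),
            positions=g[["x", "y"]].to_numpy(float),
        ))
    return out


def read_trajectories(source) -> list[TrialTrajectory]:
    """Read a long-format trajectory CSV into trial records.

    Rows are grouped by (participant, arm, task, trial); all trajectory
    invariants are enforced, so e.g. a duplicated timestamp raises a
    :class:`ValidationError` naming the offending trial.
    """
    frame = pd.read_csv(source, float_precision="round_trip")
    return frame_to_trajectories(frame)


def write_trajectories(trials: Iterable[TrialTrajectory], dest) -> None:
    trajectories_to_frame(trials).to_csv(dest, index=False,
                                         float_format=_shortest)


# ---------------------------------------------------------------------------
# 1D localization I/O
# ---------------------------------------------------------------------------

LOC1D_COLUMNS = ("participant", "condition", "true_position", "estimate",
                 "max_reach")


def read_loc1d(source) -> list[Loc1DRecord]:
    frame = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in LOC1D_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"localization table missing column(s): {missing}")
    return [
        Loc1DRecord(str(r.participant), str(r.condition),
                    float(r.true_position), float(r.estimate),
                    float(r.max_reach))
        for r in frame.itertuples()
    ]


def write_loc1d(records: Iterable[Loc1DRecord], dest) -> None:
    pd.DataFrame([{
        "participant": r.participant_id, "condition": r.condition,
        "true_position": r.true_position, "estimate": r.estimate,
        "max_reach": r.max_reach,
    } for r in records]).to_csv(dest, index=False, float_format=_shortest)


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = (
    "Participant", "Age", "Y since amp", "Gender", "Amp side", "Amp level",
    "Amp cause", "Artificial arm type", "Artificial arm wear time", "PAL",
    "Usage score", "Age at first artificial arm use",
    "Years of limbless experience", "Residual limb length",
)

_DEVICE_IN = {"Cos": "cosmetic", "Mech": "mechanical", "Myo": "myoelectric",
              "None": "none"}
_DEVICE_OUT = {v: k for k, v in _DEVICE_IN.items()}


def _group_from_id(pid: str) -> str:
    if pid.startswith("ALD"):
        return "acquired"
    if pid.startswith("CLD"):
        return "congenital"
    if pid.startswith("CO"):
        return "control"
    raise FormatError(f"cannot infer group from participant id {pid!r}")


def _opt_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s in ("", "nan"):
        return None
    return float(s)


def read_cohort(source) -> list[CohortRecord]:
    """Read a cohort TSV with the published table's headers.

    Empty cells mean "absent".  Participant ids carrying a trailing
    asterisk are flagged ``intact_only`` (valid intact-arm data only).
    """
    frame = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    # trailing all-empty columns may be trimmed for control-only tables
    required = COHORT_COLUMNS[:4]
    truly_missing = [c for c in required if c not in frame.columns]
    if truly_missing:
        raise FormatError(f"cohort table missing column(s): {truly_missing}")
    for c in missing:
        frame[c] = ""
    records = []
    for row in frame.itertuples(index=False):
        d = dict(zip(frame.columns, row))
        raw_id = d["Participant"].strip()
        if not raw_id:
            continue
        intact_only = raw_id.endswith("*")
        pid = raw_id.rstrip("*")
        device = d["Artificial arm type"].strip() or None
        records.append(CohortRecord(
            participant_id=pid,
            group=_group_from_id(pid),
            age=float(d["Age"]),
            sex=d["Gender"].strip() or None,
            side=d["Amp side"].strip() or None,
            level=d["Amp level"].strip() or None,
            cause=d["Amp cause"].strip() or None,
            device_type=_DEVICE_IN.get(device, device) if device else None,
            years_since_amputation=_opt_float(d["Y since amp"]),
            wear_time=_opt_float(d["Artificial arm wear time"]),
            pal=_opt_float(d["PAL"]),
            usage_score=_opt_float(d["Usage score"]),
            age_first_use=_opt_float(d["Age at first artificial arm use"]),
            limbless_years=_opt_float(d["Years of limbless experience"]),
            residual_length=_opt_float(d["Residual limb length"]),
            intact_only=intact_only,
        ))
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return repr(value) if isinstance(value, float) else str(value)


def write_cohort(records: Iterable[CohortRecord], dest) -> None:
    rows = []
    for r in records:
        rows.append({
            "Participant": r.participant_id + ("*" if r.intact_only else ""),
            "Age": _fmt(r.age),
            "Y since amp": _fmt(r.years_since_amputation),
            "Gender": r.sex or "",
            "Amp side": r.side or "",
            "Amp level": r.level or "",
            "Amp cause": r.cause or "",
            "Artificial arm type":
                _DEVICE_OUT.get(r.device_type, r.device_type or "") if r.device_type else "",
            "Artificial arm wear time": _fmt(r.wear_time),
            "PAL": _fmt(r.pal),
            "Usage score": _fmt(r.usage_score),
            "Age at first artificial arm use": _fmt(r.age_first_use),
            "Years of limbless experience": _fmt(r.limbless_years),
            "Residual limb length": _fmt(r.residual_length),
        })
    pd.DataFrame(rows, columns=list(COHORT_COLUMNS)).to_csv(
        dest, sep="\t", index=False)


def load_packaged_cohort() -> list[CohortRecord]:
    """Return the packaged transcription of the published cohort table."""
    text = (resources.files("reachkin") / "data" / "cohort_table.tsv").read_text()
    return read_cohort(io.StringIO(text))
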