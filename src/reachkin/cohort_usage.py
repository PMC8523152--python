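"""Prosthesis-usage scoring and prosthesis-history derivations.

The PAL (Prosthesis Activity Log) is a 27-item daily-activity
questionnaire; each item is rated never (0), sometimes (1) or very often
(2), and the score is the point sum divided by the maximum of 54, giving
a functionality fraction in [0, 1].  The combined usage score z-scores
weekly wear time and PAL against a reference population and sums them.

History derivations: for an acquired limb difference, age at amputation =
age - years since amputation and artificial-arm experience = years since
amputation - limbless years (the delay before first prosthesis use); for
a congenital limb difference, experience = age - age at first artificial
arm use.

``apply_inclusion`` implements the roster filtering for artificial-arm
analyses: participants flagged intact-only (valid intact-arm data only)
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traj_io import CohortRecord, ValidationError

__all__ = [
    "PAL_N_ITEMS",
    "PAL_MAX_POINTS",
    "HistoryDerived",
    "pal_score",
    "usage_score",
    "recompute_usage_scores",
    "derive_history",
    "apply_inclusion",
    "history_frame",
]

PAL_N_ITEMS = 27
PAL_MAX_POINTS = 2 * PAL_N_ITEMS  # 54


@dataclass
class HistoryDerived:
    """Prosthesis-history quantities derived from one cohort row."""

    participant_id: str
    group: str
    age_at_amputation: float | None  # acquired only
    experience_years: float
    included: bool
    inclusion_reason: str


def pal_score(responses) -> float:
    """PAL score: sum of 27 item points (0/1/2 each) over the maximum 54."""
    r = list(responses)
    if len(r) != PAL_N_ITEMS:
        raise ValidationError(
            f"PAL needs exactly {PAL_N_ITEMS} item ratings, got {len(r)}")
    for v in r:
        if v not in (0, 1, 2):
            raise ValidationError(f"PAL rating {v!r} outside {{0, 1, 2}}")
    return sum(r) / PAL_MAX_POINTS


def _z(value: float, ref: np.ndarray) -> float:
    sd = float(np.std(ref, ddof=1))
    if sd == 0:
        raise ValueError("zero-variance reference population")
    return (value - float(np.mean(ref))) / sd


def usage_score(wear_time: float, pal: float, reference) -> float:
    """Combined usage score: z(wear time) + z(PAL) against ``reference``.

    ``reference`` is a sequence of (wear_time, pal) pairs (>= 3 members);
    z scores use the reference mean and sample (n-1) standard deviation.
    """
    ref = np.asarray(list(reference), float)
    if ref.ndim != 2 or ref.shape[1] != 2 or len(ref) < 3:
        raise ValueError("reference needs >= 3 (wear_time, pal) pairs")
    return _z(wear_time, ref[:, 0]) + _z(pal, ref[:, 1])


def recompute_usage_scores(records, reference: str = "users") -> dict:
    """Recompute usage scores for all prosthesis users in ``records``.

    The z-normalization reference defaults to every prosthesis user
    present in the table (both groups pooled, intact-only rows included),
    which best matches published score columns; ``reference="included"``
    restricts it to non-intact-only users.
    """
    users = [r for r in records
             if r.group in ("acquired", "congenital")
             and r.wear_time is not None and r.pal is not None]
    if reference == "users":
        ref_pop = users
    elif reference == "included":
        ref_pop = [r for r in users if not r.intact_only]
    else:
        raise ValueError(f"unknown reference {reference!r}")
    pairs = [(r.wear_time, r.pal) for r in ref_pop]
    return {r.participant_id: usage_score(r.wear_time, r.pal, pairs)
            for r in users}


def derive_history(rec: CohortRecord) -> HistoryDerived:
    """Derive prosthesis-history quantities for one participant."""
    if rec.group == "acquired":
        if rec.years_since_amputation is None or rec.limbless_years is None:
            raise ValidationError(
                f"{rec.participant_id}: acquired history needs years since "
                "amputation and limbless years")
        age_amp = rec.age - rec.years_since_amputation
        exp = rec.years_since_amputation - rec.limbless_years
    elif rec.group == "congenital":
        if rec.age_first_use is None:
            raise ValidationError(
                f"{rec.participant_id}: congenital history needs age at "
                "first artificial arm use")
        age_amp = None
        exp = rec.age - rec.age_first_use
    else:
        raise ValidationError(
            f"{rec.participant_id}: no prosthesis history for controls")
    if exp < 0 or (age_amp is not None and age_amp < 0):
        raise ValidationError(
            f"{rec.participant_id}: negative derived history value")
    included = not rec.intact_only
    return HistoryDerived(
        participant_id=rec.participant_id, group=rec.group,
        age_at_amputation=age_amp, experience_years=float(exp),
        included=included,
        inclusion_reason="" if included else "intact_only")


def apply_inclusion(records) -> dict:
    """Per-group rosters for artificial-arm analyses.

    Intact-only (asterisked) rows are excluded; returns
    ``{group: [CohortRecord, ...]}`` over the groups present.
    """
    out: dict = {}
    for r in records:
        out.setdefault(r.group, [])
        if not r.intact_only:
            out[r.group].append(r)
    return out


def history_frame(records, reference: str = "users") -> pd.DataFrame:
    """Derived-history table: one row per prosthesis user.

    Columns: participant, group, included, age_at_amputation,
    experience_years, usage_score_recomputed.
    """
    scores = recompute_usage_scores(records, reference=reference)
    rows = []
    for r in records:
        if r.group not in ("acquired", "congenital"):
            continue
        try:
            h = derive_history(r)
            age_amp, exp = h.age_at_amputation, h.experience_years
        except ValidationError:
            age_amp, exp = None, None
        rows.append({
            "participant": r.participant_id,
            "group": r.group,
            "included": not r.intact_only,
            "age_at_amputation": age_amp,
            "experience_years": exp,
            "usage_score_recomputed": scores.get(r.participant_id),
        })
    return pd.DataFrame(rows, columns=[
        "participant", "group", "included", "age_at_amputation",
        "experience_years", "usage_score_recomputed"])
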