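"""Objective and subjective functional-improvement endpoints after TAVI.

Objective improvement at 6 months is a disjunctive rule: a gain of at least
10% in 6-minute-walk distance, or — when that gain is absent — a drop of at
least 50% in NT-proBNP relative to the pre-procedure value.  Deaths are
handled as follows:

* death before the 30-day follow-up from heart failure -> not improved;
  from any other cause -> excluded (no functional evaluation exists);
* death after 30 days but before 6 months -> the 30-day evaluation decides,
  overridden to not improved if the patient suffered or died of heart
  failure afterwards.

Subjective improvement is at least one NYHA class gained and/or at least a
10-point rise in KCCQ.  All thresholds are inclusive ("at least").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "PatientRecord",
    "OutcomeLabel",
    "Objective",
    "Reason",
    "Subjective",
    "DeathCause",
    "MissingDataError",
    "classify_objective",
    "classify_subjective",
    "classify_record",
    "classify_cohort",
    "records_from_dataframe",
    "tabulate_outcomes",
]

WALK_GAIN_THRESHOLD = 0.10   # >= 10% walk-distance increase
NTPROBNP_DROP_THRESHOLD = 0.50  # post <= 50% of pre
NYHA_IMPROVEMENT = 1         # classes gained
KCCQ_IMPROVEMENT = 10        # points gained
EARLY_DEATH_DAYS = 30.0
ENDPOINT_DAYS = 182.5        # 6-month landmark


class Objective(str, Enum):
    IMPROVED = "improved"
    NOT_IMPROVED = "not_improved"
    EXCLUDED = "excluded"


class Reason(str, Enum):
    WALK_TEST = "walk_test"
    BIOMARKER = "biomarker"
    NEITHER = "neither"
    DEATH_BEFORE_30D_HF = "death_before_30d_hf"
    DEATH_BEFORE_30D_OTHER_EXCLUDED = "death_before_30d_other_excluded"
    DEATH_30D_TO_6M_HF = "death_30d_to_6m_hf"
    DEATH_30D_TO_6M_CARRYFORWARD = "death_30d_to_6m_carryforward"


class Subjective(str, Enum):
    IMPROVED = "improved"
    NOT_IMPROVED = "not_improved"
    MISSING = "missing"


class DeathCause(str, Enum):
    HEART_FAILURE = "heart_failure"
    OTHER = "other"
    NONE = "none"


class MissingDataError(ValueError):
    """A survivor lacks the measurements the endpoint rule requires."""


@dataclass(frozen=True)
class PatientRecord:
    """Follow-up data for one patient (distances m, NT-proBNP pg/ml, days)."""

    id: str
    walk_base: Optional[float] = None
    walk_6m: Optional[float] = None
    walk_30d: Optional[float] = None
    ntprobnp_base: Optional[float] = None
    ntprobnp_6m: Optional[float] = None
    ntprobnp_30d: Optional[float] = None
    nyha_pre: Optional[int] = None
    nyha_post: Optional[int] = None
    kccq_pre: Optional[float] = None
    kccq_post: Optional[float] = None
    death_time: Optional[float] = None          # days since TAVI, None if alive
    death_cause: DeathCause = DeathCause.NONE
    eval_30d_available: bool = False
    hf_event_after_30d: bool = False
    low_gradient_flag: bool = False
    survival_time: Optional[float] = None       # days, capped at follow-up
    survival_status: str = "alive"              # "alive" | "dead"

    def __post_init__(self):
        object.__setattr__(self, "death_cause", DeathCause(self.death_cause))
        for name in ("walk_base", "walk_6m", "walk_30d"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("ntprobnp_base", "ntprobnp_6m", "ntprobnp_30d"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("nyha_pre", "nyha_post"):
            v = getattr(self, name)
            if v is not None and v not in (1, 2, 3, 4):
                raise ValueError(f"{name} must be an NYHA class 1-4")
        for name in ("kccq_pre", "kccq_post"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must be in [0, 100]")
        if self.death_time is not None and self.death_cause is DeathCause.NONE:
            raise ValueError("death_time set but death_cause is 'none'")


@dataclass(frozen=True)
class OutcomeLabel:
    objective: Objective
    reason: Reason
    subjective: Subjective

    def __post_init__(self):
        excluded = self.objective is Objective.EXCLUDED
        reason_excl = self.reason is Reason.DEATH_BEFORE_30D_OTHER_EXCLUDED
        if excluded != reason_excl:
            raise ValueError("excluded <=> early non-HF death, by construction")


def _meets_criteria(walk_pre, walk_post, nt_pre, nt_post,
                    walk_gain=WALK_GAIN_THRESHOLD,
                    nt_drop=NTPROBNP_DROP_THRESHOLD):
    """Apply the disjunctive improvement rule to one pair of evaluations.

    Returns (improved, reason) or raises MissingDataError listing what is
    absent.  The walk criterion is evaluated first; the biomarker criterion
    only when the walk gain is absent or unmeasurable.
    """
    walk_ok = walk_pre is not None and walk_post is not None
    nt_ok = nt_pre is not None and nt_post is not None
    if not walk_ok and not nt_ok:
        missing = [n for n, v in [("walk_pre", walk_pre), ("walk_post", walk_post),
                                  ("ntprobnp_pre", nt_pre),
                                  ("ntprobnp_post", nt_post)] if v is None]
        raise MissingDataError(
            f"cannot evaluate improvement; missing fields: {', '.join(missing)}"
        )
    if walk_ok and walk_post >= (1.0 + walk_gain) * walk_pre:
        return True, Reason.WALK_TEST
    if nt_ok and nt_post <= nt_drop * nt_pre:
        return True, Reason.BIOMARKER
    return False, Reason.NEITHER


def classify_objective(
    record: PatientRecord,
    walk_gain: float = WALK_GAIN_THRESHOLD,
    nt_drop: float = NTPROBNP_DROP_THRESHOLD,
) -> tuple[Objective, Reason]:
    """Classify objective functional improvement for one patient.

    Thresholds are inclusive and configurable for sensitivity analyses;
    the study rule is walk_gain=0.10, nt_drop=0.50.
    """
    death = record.death_time
    if death is not None and death < EARLY_DEATH_DAYS:
        if record.death_cause is DeathCause.HEART_FAILURE:
            return Objective.NOT_IMPROVED, Reason.DEATH_BEFORE_30D_HF
        return Objective.EXCLUDED, Reason.DEATH_BEFORE_30D_OTHER_EXCLUDED
    if death is not None and death <= ENDPOINT_DAYS:
        # 30-day evaluation decides, negated by subsequent heart failure
        if (record.hf_event_after_30d
                or record.death_cause is DeathCause.HEART_FAILURE):
            return Objective.NOT_IMPROVED, Reason.DEATH_30D_TO_6M_HF
        improved, _ = _meets_criteria(
            record.walk_base, record.walk_30d,
            record.ntprobnp_base, record.ntprobnp_30d,
            walk_gain, nt_drop,
        )
        if improved:
            return Objective.IMPROVED, Reason.DEATH_30D_TO_6M_CARRYFORWARD
        return Objective.NOT_IMPROVED, Reason.DEATH_30D_TO_6M_CARRYFORWARD
    improved, reason = _meets_criteria(
        record.walk_base, record.walk_6m,
        record.ntprobnp_base, record.ntprobnp_6m,
        walk_gain, nt_drop,
    )
    return (Objective.IMPROVED if improved else Objective.NOT_IMPROVED), reason


def classify_subjective(record: PatientRecord) -> Subjective:
    """NYHA class gain and/or >= 10-point KCCQ rise; missing if neither pair."""
    nyha_ok = record.nyha_pre is not None and record.nyha_post is not None
    kccq_ok = record.kccq_pre is not None and record.kccq_post is not None
    if not nyha_ok and not kccq_ok:
        return Subjective.MISSING
    if nyha_ok and record.nyha_post <= record.nyha_pre - NYHA_IMPROVEMENT:
        return Subjective.IMPROVED
    if kccq_ok and record.kccq_post >= record.kccq_pre + KCCQ_IMPROVEMENT:
        return Subjective.IMPROVED
    return Subjective.NOT_IMPROVED


def classify_record(record: PatientRecord) -> OutcomeLabel:
    objective, reason = classify_objective(record)
    return OutcomeLabel(objective, reason, classify_subjective(record))


def classify_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Classify a cohort; returns one row per patient with label columns."""
    rows = []
    for rec in records:
        label = classify_record(rec)
        rows.append({
            "id": rec.id,
            "objective": label.objective.value,
            "reason": label.reason.value,
            "subjective": label.subjective.value,
        })
    return pd.DataFrame(rows)


def _opt(row, key, cast=float):
    if key not in row:
        return None
    v = row[key]
    if v is None or (isinstance(v, float) and pd.isna(v)) or pd.isna(v):
        return None
    return cast(v)


def records_from_dataframe(df: pd.DataFrame) -> list[PatientRecord]:
    """Build PatientRecords from a cohort table (NaN becomes missing)."""
    records = []
    for _, row in df.iterrows():
        records.append(PatientRecord(
            id=str(row["id"]),
            walk_base=_opt(row, "walk_base"),
            walk_6m=_opt(row, "walk_6m"),
            walk_30d=_opt(row, "walk_30d"),
            ntprobnp_base=_opt(row, "ntprobnp_base"),
            ntprobnp_6m=_opt(row, "ntprobnp_6m"),
            ntprobnp_30d=_opt(row, "ntprobnp_30d"),
            nyha_pre=_opt(row, "nyha_pre", int),
            nyha_post=_opt(row, "nyha_post", int),
            kccq_pre=_opt(row, "kccq_pre"),
            kccq_post=_opt(row, "kccq_post"),
            death_time=_opt(row, "death_time"),
            death_cause=DeathCause(row.get("death_cause", "none")),
            eval_30d_available=bool(row.get("eval_30d_available", False)),
            hf_event_after_30d=bool(row.get("hf_event_after_30d", False)),
            low_gradient_flag=bool(row.get("low_gradient_flag", False)),
            survival_time=_opt(row, "survival_time"),
            survival_status=(
                "dead" if bool(row.get("survival_event", False)) else "alive"
            ),
        ))
    return records


def tabulate_outcomes(records: Sequence[PatientRecord]) -> dict:
    """Counts and percentages of improvement over the non-excluded cohort.

    Percentages use the non-excluded denominator for the objective endpoint
    and the non-missing denominator for the subjective one, rounded to one
    decimal.
    """
    if len(records) == 0:
        raise ValueError("empty cohort")
    labels = [classify_record(r) for r in records]
    n_improved = sum(l.objective is Objective.IMPROVED for l in labels)
    n_not = sum(l.objective is Objective.NOT_IMPROVED for l in labels)
    n_excluded = sum(l.objective is Objective.EXCLUDED for l in labels)
    n_subj_improved = sum(l.subjective is Subjective.IMPROVED for l in labels)
    n_subj_not = sum(l.subjective is Subjective.NOT_IMPROVED for l in labels)
    denom = n_improved + n_not
    subj_denom = n_subj_improved + n_subj_not
    return {
        "improved": n_improved,
        "not_improved": n_not,
        "excluded": n_excluded,
        "improved_pct": round(100.0 * n_improved / denom, 1) if denom else None,
        "subjective_improved": n_subj_improved,
        "subjective_improved_pct": (
            round(100.0 * n_subj_improved / subj_denom, 1) if subj_denom else None
        ),
    }
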