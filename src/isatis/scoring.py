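"""Score construction for inpatient satisfaction questionnaires.

Raw answer codes become valued item scores (codes 1..5 -> 0/25/50/75/100,
everything else missing), dimension scores (mean of valued items, defined
only when the dimension's minimum answered count is met), and a global
score (mean of *all* valued items over the 28 scored items, defined only
when every dimension score is defined).  Patients who did not return the
questionnaire, or completed fewer than 16 items, are nonresponders and
receive no scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .questionnaire import (
    NONRELEVANCY_CODES,
    ORDINAL_CODES,
    VALID_CODES,
    QuestionnaireSpec,
)

__all__ = [
    "ARMS",
    "PatientRecord",
    "ScoreSet",
    "recode_item",
    "classify_responder",
    "dimension_score",
    "global_score",
    "nonrelevancy_bucket",
    "score_cohort",
]

ARMS = ("internet", "telephone")

#: nonrelevancy + don't-know + refusal: answered but not valued
MISSING_VALUE_CODES = frozenset(VALID_CODES - ORDINAL_CODES)

CompletedDefinition = Literal["any", "valued"]


class ScoringError(ValueError):
    """Raised for invalid records or codes, identifying patient and item."""


@dataclass
class PatientRecord:
    """One enrolled patient: arm, baseline covariates, raw answer codes.

    ``responses`` maps item ID to the raw 0..10 answer code; items the
    patient left blank are simply absent.  ``delay_days`` is the delay
    between discharge and questionnaire completion and is only meaningful
    when the questionnaire was returned (``responses`` non-empty).
    """

    patient_id: str
    arm: str
    los_days: int
    sex: str = "male"
    age_years: float = 50.0
    relationship: str = "couple"
    education: str = "upper_secondary"
    activity: str = "employed"
    insurance: str = "private_complementary"
    delay_days: float | None = None
    responses: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ScoringError(f"patient {self.patient_id}: unknown arm {self.arm!r}")
        if self.los_days < 0:
            raise ScoringError(f"patient {self.patient_id}: negative LOS")
        for item, code in self.responses.items():
            if code not in VALID_CODES:
                raise ScoringError(
                    f"patient {self.patient_id}, item {item}: "
                    f"answer code {code} outside 0..10"
                )

    @property
    def returned(self) -> bool:
        return bool(self.responses)


@dataclass
class ScoreSet:
    """Per-patient scoring result; undefined scores are ``None``."""

    patient_id: str
    arm: str
    responder: bool
    dimension_scores: dict[str, float | None]
    global_score: float | None
    n_valued_items: int
    n_nonrelevancy: int


def recode_item(code: int) -> float | None:
    """Value a raw answer code: 1..5 -> 0/25/50/75/100, others -> None.

    Codes 0, 6, 7, 8 (item not relevant), 9 (don't know) and 10 (refusal)
    all count as missing in the analysis.
    """
    if code not in VALID_CODES:
        raise ScoringError(f"answer code {code} outside 0..10")
    if code in ORDINAL_CODES:
        return float((code - 1) * 25)
    return None


def _n_completed(
    rec: PatientRecord,
    spec: QuestionnaireSpec,
    definition: CompletedDefinition,
) -> int:
    if definition == "any":
        # any recorded 0..10 code counts, over all 32 items incl. excluded
        return sum(1 for item in rec.responses if item in set(spec.all_items))
    if definition == "valued":
        scored = set(spec.scored_items)
        return sum(
            1
            for item, code in rec.responses.items()
            if item in scored and code in ORDINAL_CODES
        )
    raise ScoringError(f"unknown completed definition {definition!r}")


def classify_responder(
    rec: PatientRecord,
    spec: QuestionnaireSpec,
    completed_definition: CompletedDefinition = "any",
) -> bool:
    """True iff the questionnaire was returned with >= 16 completed items.

    By default "completed" counts any recorded answer code (nonrelevancy
    and refusal are acts of completion) across all 32 items; with
    ``completed_definition="valued"`` only valued answers over the 28
    scored items count.
    """
    if not rec.returned:
        return False
    return _n_completed(rec, spec, completed_definition) >= spec.responder_min_items


def _valued(rec: PatientRecord, items: Iterable[str], spec: QuestionnaireSpec):
    out = []
    for item in items:
        code = rec.responses.get(item)
        if code is None:
            continue
        v = spec.recode_map.get(code)
        if v is None and code not in spec.recode_map:
            raise ScoringError(
                f"patient {rec.patient_id}, item {item}: code {code} outside 0..10"
            )
        if v is not None:
            out.append(float(v))
    return out


def dimension_score(
    rec: PatientRecord, dim: str, spec: QuestionnaireSpec
) -> float | None:
    """Mean of valued items of ``dim``; None below the minimum answered count."""
    items = spec.items_of(dim)
    values = _valued(rec, items, spec)
    if len(values) < spec.min_answered[dim]:
        return None
    return sum(values) / len(values)


def global_score(rec: PatientRecord, spec: QuestionnaireSpec) -> float | None:
    """Mean of all valued answers over the scored items.

    Defined only when every dimension score is defined.  Note this is the
    mean over items, not the mean of the six dimension scores.
    """
    for dim in spec.dimension_names:
        if dimension_score(rec, dim, spec) is None:
            return None
    values = _valued(rec, spec.scored_items, spec)
    return sum(values) / len(values)


_BUCKETS = ("0", "1-5", "6-10", ">10")


def nonrelevancy_bucket(rec: PatientRecord, spec: QuestionnaireSpec) -> str:
    """Bucket the count of nonrelevancy/don't-know/refusal answers.

    Counts answers over the 28 scored items whose code is in
    {0, 6, 7, 8, 9, 10} and maps the count to "0", "1-5", "6-10" or ">10".
    """
    n = sum(
        1
        for item in spec.scored_items
        if rec.responses.get(item) in MISSING_VALUE_CODES
    )
    if n == 0:
        return "0"
    if n <= 5:
        return "1-5"
    if n <= 10:
        return "6-10"
    return ">10"


def bucket_counts(
    records: Iterable[PatientRecord],
    spec: QuestionnaireSpec,
    completed_definition: CompletedDefinition = "any",
) -> dict[str, dict[str, int]]:
    """Per-arm counts of responders in each nonrelevancy bucket."""
    out = {arm: {b: 0 for b in _BUCKETS} for arm in ARMS}
    for rec in records:
        if classify_responder(rec, spec, completed_definition):
            out[rec.arm][nonrelevancy_bucket(rec, spec)] += 1
    return out


def score_patient(
    rec: PatientRecord,
    spec: QuestionnaireSpec,
    completed_definition: CompletedDefinition = "any",
) -> ScoreSet:
    responder = classify_responder(rec, spec, completed_definition)
    scored = spec.scored_items
    n_nonrel = sum(
        1 for item in scored if rec.responses.get(item) in MISSING_VALUE_CODES
    )
    n_valued = sum(
        1 for item in scored if rec.responses.get(item) in ORDINAL_CODES
    )
    if not responder:
        return ScoreSet(
            patient_id=rec.patient_id,
            arm=rec.arm,
            responder=False,
            dimension_scores={d: None for d in spec.dimension_names},
            global_score=None,
            n_valued_items=n_valued,
            n_nonrelevancy=n_nonrel,
        )
    dims = {d: dimension_score(rec, d, spec) for d in spec.dimension_names}
    if all(v is not None for v in dims.values()):
        values = _valued(rec, scored, spec)
        g = sum(values) / len(values)
    else:
        g = None
    return ScoreSet(
        patient_id=rec.patient_id,
        arm=rec.arm,
        responder=True,
        dimension_scores=dims,
        global_score=g,
        n_valued_items=n_valued,
        n_nonrelevancy=n_nonrel,
    )


def score_cohort(
    records: list[PatientRecord],
    spec: QuestionnaireSpec,
    *,
    los_filter: bool = True,
    min_los_nights: int = 2,
    completed_definition: CompletedDefinition = "any",
) -> tuple[list[ScoreSet], dict]:
    """Score a cohort and account for the participant flow.

    Applies the length-of-stay eligibility filter (stays of at least two
    nights by default) when ``los_filter`` is on, classifies responders,
    scores them, and returns per-arm flow counts: enrolled, LOS-eligible,
    responders with their rate, and score-eligible (global score defined).
    """
    seen: set[str] = set()
    for rec in records:
        if rec.patient_id in seen:
            raise ScoringError(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)

    flow = {
        arm: {
            "enrolled": 0,
            "los_excluded": 0,
            "los_eligible": 0,
            "responders": 0,
            "nonresponders": 0,
            "score_eligible": 0,
        }
        for arm in ARMS
    }
    scores: list[ScoreSet] = []
    for rec in records:
        f = flow[rec.arm]
        f["enrolled"] += 1
        if los_filter and rec.los_days < min_los_nights:
            f["los_excluded"] += 1
            continue
        f["los_eligible"] += 1
        ss = score_patient(rec, spec, completed_definition)
        scores.append(ss)
        if ss.responder:
            f["responders"] += 1
            if ss.global_score is not None:
                f["score_eligible"] += 1
        else:
            f["nonresponders"] += 1
    for f in flow.values():
        f["response_rate"] = (
            f["responders"] / f["los_eligible"] if f["los_eligible"] else math.nan
        )
    return scores, flow
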