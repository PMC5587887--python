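"""Questionnaire structure for the I-Satis inpatient satisfaction instrument.

The I-Satis questionnaire has 32 items (``Q1``..``Q32``); 28 of them are
scored across six dimensions, and 4 (``Q12``, ``Q19``, ``Q31``, ``Q32``)
are excluded from all score calculations.  Answer codes run from 0 to 10:

* codes 1-5 are increasing ordinal satisfaction answers, valued
  0/25/50/75/100 in the analysis;
* codes 0, 6, 7, 8 mean the item was not relevant for the patient;
* code 9 is "I don't know" and code 10 is "I don't wish to answer".

Nonrelevancy, don't-know and refusal codes are all treated as missing when
scores are computed.  The structure is held as data (:class:`QuestionnaireSpec`)
so the scoring engine is table-driven and other instruments with the same
code semantics can be configured from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "VALID_CODES",
    "ORDINAL_CODES",
    "NONRELEVANCY_CODES",
    "DONT_KNOW_CODE",
    "REFUSE_CODE",
    "DEFAULT_RECODE_MAP",
    "QuestionnaireSpec",
    "default_isatis_spec",
    "load_spec",
    "save_spec",
]

VALID_CODES = frozenset(range(11))
ORDINAL_CODES = frozenset({1, 2, 3, 4, 5})
NONRELEVANCY_CODES = frozenset({0, 6, 7, 8})
DONT_KNOW_CODE = 9
REFUSE_CODE = 10

#: codes 1..5 map to 0/25/50/75/100; every other valid code is missing (None)
DEFAULT_RECODE_MAP: dict[int, float | None] = {
    **{c: None for c in sorted(VALID_CODES - ORDINAL_CODES)},
    1: 0.0,
    2: 25.0,
    3: 50.0,
    4: 75.0,
    5: 100.0,
}


class SpecError(ValueError):
    """Raised when a questionnaire specification violates its invariants."""


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Dimension layout, recode map and score-eligibility thresholds.

    Parameters
    ----------
    dimensions
        Ordered mapping of dimension name to the tuple of item IDs it
        contains.  Order is the reporting order.
    recode_map
        Answer code -> valued score, or ``None`` for missing.
    min_answered
        Dimension name -> minimum number of valued items required for the
        dimension score to be defined.
    excluded_items
        Item IDs present on the form but excluded from all scores.
    responder_min_items
        Minimum number of completed items for a returned questionnaire to
        count as a response.
    """

    dimensions: dict[str, tuple[str, ...]]
    recode_map: dict[int, float | None] = field(
        default_factory=lambda: dict(DEFAULT_RECODE_MAP)
    )
    min_answered: dict[str, int] = field(default_factory=dict)
    excluded_items: tuple[str, ...] = ()
    responder_min_items: int = 16

    def __post_init__(self) -> None:
        self.validate()

    # -- derived views -------------------------------------------------
    @property
    def dimension_names(self) -> tuple[str, ...]:
        return tuple(self.dimensions)

    @property
    def scored_items(self) -> tuple[str, ...]:
        """All item IDs that enter a dimension, in dimension order."""
        return tuple(i for items in self.dimensions.values() for i in items)

    @property
    def all_items(self) -> tuple[str, ...]:
        """Scored plus excluded item IDs."""
        return self.scored_items + tuple(self.excluded_items)

    def items_of(self, dimension: str) -> tuple[str, ...]:
        try:
            return self.dimensions[dimension]
        except KeyError:
            raise SpecError(f"unknown dimension {dimension!r}") from None

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        if not self.dimensions:
            raise SpecError("spec must define at least one dimension")
        seen: dict[str, str] = {}
        for name, items in self.dimensions.items():
            if not items:
                raise SpecError(f"dimension {name!r} has no items")
            for item in items:
                if item in seen:
                    raise SpecError(
                        f"item {item!r} appears in both {seen[item]!r} and {name!r}"
                    )
                seen[item] = name
        for item in self.excluded_items:
            if item in seen:
                raise SpecError(
                    f"excluded item {item!r} also appears in dimension {seen[item]!r}"
                )
        if len(set(self.excluded_items)) != len(self.excluded_items):
            raise SpecError("duplicate IDs in excluded_items")
        if set(self.min_answered) != set(self.dimensions):
            raise SpecError("min_answered must cover exactly the dimensions")
        for name, k in self.min_answered.items():
            if not 1 <= k <= len(self.dimensions[name]):
                raise SpecError(
                    f"min_answered[{name!r}]={k} outside 1..{len(self.dimensions[name])}"
                )
        if self.responder_min_items < 1:
            raise SpecError("responder_min_items must be >= 1")
        bad = set(self.recode_map) - VALID_CODES
        if bad:
            raise SpecError(f"recode_map has out-of-range codes: {sorted(bad)}")
        if set(self.recode_map) != VALID_CODES:
            raise SpecError("recode_map must cover every code 0..10")


def default_isatis_spec() -> QuestionnaireSpec:
    """The standard I-Satis layout: 28 scored items in six dimensions.

    Dimension score eligibility requires at least 3/3/3/3/2/2 valued items
    respectively; a returned questionnaire with fewer than 16 completed
    items is treated as a nonresponse.
    """
    dimensions = {
        "global_care": ("Q1", "Q2", "Q4", "Q13", "Q14", "Q15"),
        "information": ("Q16", "Q18", "Q27", "Q28", "Q29", "Q30"),
        "communication": ("Q3", "Q5", "Q6", "Q17", "Q20"),
        "behavior": ("Q7", "Q8", "Q9", "Q10", "Q11"),
        "room_convenience": ("Q21", "Q22", "Q23", "Q24"),
        "catering": ("Q25", "Q26"),
    }
    min_answered = {
        "global_care": 3,
        "information": 3,
        "communication": 3,
        "behavior": 3,
        "room_convenience": 2,
        "catering": 2,
    }
    return QuestionnaireSpec(
        dimensions=dimensions,
        min_answered=min_answered,
        excluded_items=("Q12", "Q19", "Q31", "Q32"),
        responder_min_items=16,
    )


def save_spec(spec: QuestionnaireSpec, path: str | Path) -> None:
    """Serialize a spec to YAML (codes as integer keys, missing as null)."""
    doc = {
        "dimensions": {name: list(items) for name, items in spec.dimensions.items()},
        "recode_map": {int(k): v for k, v in spec.recode_map.items()},
        "min_answered": dict(spec.min_answered),
        "excluded_items": list(spec.excluded_items),
        "responder_min_items": int(spec.responder_min_items),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_spec(path: str | Path) -> QuestionnaireSpec:
    """Load a spec from YAML, validating all structural invariants.

    Raises
    ------
    SpecError
        If the document is malformed or violates an invariant (overlapping
        dimensions, a threshold larger than its dimension, ...).
    """
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise SpecError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise SpecError(f"{path}: expected a mapping at top level")
    try:
        return QuestionnaireSpec(
            dimensions={
                str(name): tuple(items)
                for name, items in doc["dimensions"].items()
            },
            recode_map={int(k): v for k, v in doc.get(
                "recode_map", DEFAULT_RECODE_MAP).items()},
            min_answered={str(k): int(v) for k, v in doc["min_answered"].items()},
            excluded_items=tuple(doc.get("excluded_items", ())),
            responder_min_items=int(doc.get("responder_min_items", 16)),
        )
    except (KeyError, TypeError, AttributeError) as exc:
        raise SpecError(f"{path}: missing or malformed field ({exc})") from exc
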