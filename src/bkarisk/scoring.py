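"""Additive risk score and Katz ADL score for below-knee amputation patients.

The risk index assigns integer points to four factor groups and sums them:

* age band: <65 years → 0, 65–79 → 1, ≥80 → 2
* preoperative comorbid systemic disease: 1 point per condition out of a
  closed set of six (COPD, hypertension, diabetes mellitus, prior myocardial
  infarction, prior stroke, prior lower-extremity infection)
* postoperative mobilization: early (within 24 h) → 0, late → 1,
  bedridden → 2
* early postoperative complications: 1 point each for hypoxia and for a
  clinically actionable metabolic disorder

yielding a total in [0, 12].  The Katz activities-of-daily-living score is
the count (0–6) of six activities the patient performs independently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import ValidationError

__all__ = [
    "AgeBand",
    "Comorbidity",
    "Mobilization",
    "KatzCategory",
    "KATZ_ACTIVITIES",
    "PatientRecord",
    "RiskScoreBreakdown",
    "KatzAssessment",
    "age_points",
    "age_band",
    "comorbidity_points",
    "mobilization_points",
    "complication_points",
    "total_score",
    "katz_score",
]

MIN_AGE = 18  # cohort inclusion criterion: adults at first amputation


class Comorbidity(str, enum.Enum):
    """The six preoperative systemic diseases that each score one point."""

    COPD = "copd"
    HYPERTENSION = "hypertension"
    DIABETES_MELLITUS = "diabetes_mellitus"
    PRIOR_MI = "prior_mi"
    PRIOR_STROKE = "prior_stroke"
    PRIOR_LIMB_INFECTION = "prior_limb_infection"

    @classmethod
    def coerce(cls, value: "Comorbidity | str") -> "Comorbidity":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unknown comorbidity {value!r}; allowed: "
                f"{[c.value for c in cls]}"
            ) from None


class Mobilization(str, enum.Enum):
    """Postoperative mobilization category (24-hour rule)."""

    EARLY = "early"  # ambulation with walking aid within 24 h of surgery
    LATE = "late"  # mobilized after 24 h
    BEDRIDDEN = "bedridden"  # never mobilized

    @classmethod
    def coerce(cls, value: "Mobilization | str") -> "Mobilization":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value))
        except ValueError:
            raise ValidationError(
                f"unrecognized category {value!r}; allowed: "
                f"{[m.value for m in cls]}"
            ) from None


class AgeBand(str, enum.Enum):
    """The three age strata of the score's age component."""

    UNDER_65 = "under_65"
    FROM_65_TO_79 = "65_to_79"
    OVER_79 = "over_79"


def age_band(age_years: int) -> AgeBand:
    """Age stratum for a validated adult age; bands match :func:`age_points`."""
    return (AgeBand.UNDER_65, AgeBand.FROM_65_TO_79, AgeBand.OVER_79)[
        age_points(age_years)
    ]


KATZ_ACTIVITIES = (
    "bathing",
    "dressing",
    "toileting",
    "transferring",
    "personal_care",
    "feeding",
)


class KatzCategory(str, enum.Enum):
    """Functional-independence category anchored at Katz scores 6, 4 and ≤2.

    Only those three anchors carry a clinical label; scores 3 and 5 are
    reported as ``intermediate`` rather than being assigned an invented label.
    """

    FULL_INDEPENDENCE = "full_independence"
    MODERATE = "moderate"
    SEVERE_IMPAIRMENT = "severe_impairment"
    INTERMEDIATE = "intermediate"


def age_points(age_years: int) -> int:
    """Points for the patient's age band: <65 → 0, 65–79 → 1, ≥80 → 2.

    Raises :class:`ValidationError` for ages below 18 (cohort inclusion
    criterion).  Ages are whole years; no sub-year resolution is defined.
    """
    if isinstance(age_years, bool) or not isinstance(age_years, int):
        raise ValidationError(f"age_years must be an integer, got {age_years!r}")
    if age_years < MIN_AGE:
        raise ValidationError(
            f"age_years={age_years} violates the adult inclusion criterion (>=18)"
        )
    if age_years < 65:
        return 0
    if age_years <= 79:
        return 1
    return 2


def comorbidity_points(comorbidities) -> int:
    """One point per distinct condition from the closed six-condition set."""
    conditions = {Comorbidity.coerce(c) for c in comorbidities}
    return len(conditions)


def mobilization_points(category: Mobilization | str) -> int:
    """early → 0, late → 1, bedridden → 2."""
    return {
        Mobilization.EARLY: 0,
        Mobilization.LATE: 1,
        Mobilization.BEDRIDDEN: 2,
    }[Mobilization.coerce(category)]


def complication_points(hypoxia: bool, metabolic_disorder: bool) -> int:
    """One point for each early complication present (hypoxia, metabolic)."""
    return int(bool(hypoxia)) + int(bool(metabolic_disorder))


@dataclass(frozen=True)
class RiskScoreBreakdown:
    """Per-factor points and their total (range 0–12)."""

    age_points: int
    comorbidity_points: int
    mobilization_points: int
    complication_points: int
    total: int

    def __post_init__(self) -> None:
        if self.age_points not in (0, 1, 2):
            raise ValidationError(f"age_points out of range: {self.age_points}")
        if not 0 <= self.comorbidity_points <= 6:
            raise ValidationError(
                f"comorbidity_points out of range: {self.comorbidity_points}"
            )
        if self.mobilization_points not in (0, 1, 2):
            raise ValidationError(
                f"mobilization_points out of range: {self.mobilization_points}"
            )
        if self.complication_points not in (0, 1, 2):
            raise ValidationError(
                f"complication_points out of range: {self.complication_points}"
            )
        expected = (
            self.age_points
            + self.comorbidity_points
            + self.mobilization_points
            + self.complication_points
        )
        if self.total != expected:
            raise ValidationError(
                f"total {self.total} != sum of components {expected}"
            )


@dataclass(frozen=True)
class KatzAssessment:
    """A Katz ADL component tuple with its score and category."""

    components: tuple
    score: int
    category: KatzCategory


@dataclass(frozen=True)
class PatientRecord:
    """One patient's risk-score inputs, outcomes and Katz components.

    ``katz_components`` is the 3-month assessment and is absent (None) for
    patients who were never assessed, e.g. those who died early.
    ``days_to_death`` is required iff ``died_within_1yr``.
    """

    patient_id: str
    age_years: int
    comorbidities: frozenset = field(default_factory=frozenset)
    mobilization: Mobilization = Mobilization.EARLY
    hypoxia: bool = False
    metabolic_disorder: bool = False
    died_within_1yr: bool = False
    days_to_death: int | None = None
    katz_components: tuple | None = None
    postop_comorbidity: bool = False
    prosthetic_usage: bool = False
    wound_complication: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.patient_id, str) or not self.patient_id:
            raise ValidationError("patient_id must be a non-empty string")
        # triggers the age inclusion check
        age_points(self.age_years)
        object.__setattr__(
            self,
            "comorbidities",
            frozenset(Comorbidity.coerce(c) for c in self.comorbidities),
        )
        object.__setattr__(
            self, "mobilization", Mobilization.coerce(self.mobilization)
        )
        for flag in (
            "hypoxia",
            "metabolic_disorder",
            "died_within_1yr",
            "postop_comorbidity",
            "prosthetic_usage",
            "wound_complication",
        ):
            object.__setattr__(self, flag, bool(getattr(self, flag)))
        if self.died_within_1yr:
            if self.days_to_death is None:
                raise ValidationError(
                    "days_to_death is required when died_within_1yr is true"
                )
            if not isinstance(self.days_to_death, int) or isinstance(
                self.days_to_death, bool
            ):
                raise ValidationError("days_to_death must be an integer")
            if self.days_to_death < 0:
                raise ValidationError("days_to_death must be >= 0")
        elif self.days_to_death is not None:
            raise ValidationError(
                "days_to_death must be absent for one-year survivors"
            )
        if self.katz_components is not None:
            comps = tuple(bool(c) for c in self.katz_components)
            if len(comps) != len(KATZ_ACTIVITIES):
                raise ValidationError(
                    f"katz_components needs exactly {len(KATZ_ACTIVITIES)} "
                    f"entries, got {len(comps)}"
                )
            object.__setattr__(self, "katz_components", comps)

    @property
    def katz(self) -> KatzAssessment | None:
        if self.katz_components is None:
            return None
        return katz_score(self.katz_components)


def total_score(record: PatientRecord) -> RiskScoreBreakdown:
    """Score a validated patient record; total is the sum of the four parts."""
    a = age_points(record.age_years)
    c = comorbidity_points(record.comorbidities)
    m = mobilization_points(record.mobilization)
    x = complication_points(record.hypoxia, record.metabolic_disorder)
    return RiskScoreBreakdown(a, c, m, x, a + c + m + x)


def katz_score(components) -> KatzAssessment:
    """Katz ADL score: the number of activities performed independently.

    Score 6 → full independence, 4 → moderate, ≤2 → severe impairment;
    scores 3 and 5 are categorised as intermediate.
    """
    comps = tuple(bool(c) for c in components)
    if len(comps) != len(KATZ_ACTIVITIES):
        raise ValidationError(
            f"expected {len(KATZ_ACTIVITIES)} Katz components, got {len(comps)}"
        )
    score = sum(comps)
    if score == 6:
        category = KatzCategory.FULL_INDEPENDENCE
    elif score == 4:
        category = KatzCategory.MODERATE
    elif score <= 2:
        category = KatzCategory.SEVERE_IMPAIRMENT
    else:
        category = KatzCategory.INTERMEDIATE
    return KatzAssessment(comps, score, category)
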