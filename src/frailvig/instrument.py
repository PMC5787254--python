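"""Scoring rules for the Frail-VIG frailty index.

The Frail-VIG index is a deficit-accumulation frailty index built for rapid
geriatric assessment: 22 questions covering 25 potential deficits across
eight domains (functional, nutritional, cognitive, emotional, social,
geriatric syndromes, severe symptoms, chronic diseases).  Scoring follows
the deficit-accumulation convention:

* each binary deficit present scores 1 point;
* dependency in basic activities of daily living (Barthel index, 0-100 in
  multiples of 5) scores 0-3 points by the standard dependency bands;
* cognitive impairment scores 0-2 (none / mild-moderate, GDS <= 5 /
  severe, GDS >= 6);
* each of six chronic diseases scores 0 (absent), 1 (present) or 2 when
  the disease meets advanced-illness severity/progression criteria
  (NECPAL); the advanced flag is an input, not computed here.

The index score is the accumulated points divided by the 25 potential
deficits, giving a 0-1 scale.  With advanced-disease double points the raw
sum can exceed 25 (theoretical maximum 31), so the score is capped at 1.0;
the denominator stays at 25 because the seven published category bands and
the frailty threshold assume the /25 lattice.  Frailty is a score strictly
above 0.25.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field, fields
from enum import Enum, IntEnum
from typing import Mapping, Optional

__all__ = [
    "ValidationError",
    "ScoringError",
    "CognitiveLevel",
    "DepressiveStatus",
    "DiseaseStatus",
    "AssessmentRecord",
    "FrailVigResult",
    "BAND_LABELS",
    "BAND_LOWER",
    "BAND_UPPER",
    "BAND_MIDPOINTS",
    "N_DEFICITS",
    "BINARY_ITEMS",
    "DISEASE_ITEMS",
    "DOMAINS",
    "ITEM_WEIGHTS",
    "map_barthel",
    "map_cognitive",
    "cognitive_from_gds",
    "score_assessment",
    "categorize",
    "is_frail",
]


class ValidationError(ValueError):
    """A raw input value violates the instrument's schema."""


class ScoringError(ValueError):
    """A record cannot be scored under the active missing-data policy."""


class CognitiveLevel(str, Enum):
    NONE = "none"
    MILD_MODERATE = "mild_moderate"
    SEVERE = "severe"


class DepressiveStatus(str, Enum):
    NO = "no"
    YES = "yes"
    NOT_EVALUABLE = "not_evaluable"


class DiseaseStatus(IntEnum):
    ABSENT = 0
    PRESENT = 1
    ADVANCED = 2


#: Single-point binary deficits (the depressive item is ternary and handled
#: separately; it still carries at most one point).
BINARY_ITEMS = (
    "iadl_money",
    "iadl_phone",
    "iadl_medication",
    "malnutrition",
    "insomnia_anxiety",
    "social_vulnerability",
    "delirium",
    "falls",
    "ulcers",
    "polypharmacy",
    "dysphagia",
    "pain",
    "dyspnea",
)

DISEASE_ITEMS = (
    "disease_cancer",
    "disease_respiratory",
    "disease_cardiac",
    "disease_neurological",
    "disease_digestive",
    "disease_renal",
)

ALL_ITEMS = BINARY_ITEMS + ("barthel", "cognitive", "depressive") + DISEASE_ITEMS

DOMAINS: Mapping[str, tuple] = {
    "functional": ("iadl_money", "iadl_phone", "iadl_medication", "barthel"),
    "nutritional": ("malnutrition",),
    "cognitive": ("cognitive",),
    "emotional": ("depressive", "insomnia_anxiety"),
    "social": ("social_vulnerability",),
    "geriatric_syndromes": ("delirium", "falls", "ulcers", "polypharmacy", "dysphagia"),
    "severe_symptoms": ("pain", "dyspnea"),
    "diseases": DISEASE_ITEMS,
}

#: Number of potential deficits each item contributes to the denominator.
#: The advanced-disease bonus point does not enlarge the denominator.
ITEM_WEIGHTS: Mapping[str, int] = {
    **{item: 1 for item in BINARY_ITEMS},
    "barthel": 3,
    "cognitive": 2,
    "depressive": 1,
    **{item: 1 for item in DISEASE_ITEMS},
}

N_DEFICITS = 25
assert sum(ITEM_WEIGHTS.values()) == N_DEFICITS

BAND_LABELS = (
    "0.1 (0–0.15)",
    "0.2 (0.16–0.25)",
    "0.3 (0.26–0.35)",
    "0.4 (0.36–0.45)",
    "0.5 (0.46–0.55)",
    "0.6 (0.56–0.65)",
    "0.7 (0.66–1)",
)
BAND_LOWER = (0.0, 0.16, 0.26, 0.36, 0.46, 0.56, 0.66)
BAND_UPPER = (0.15, 0.25, 0.35, 0.45, 0.55, 0.65, 1.0)
BAND_MIDPOINTS = tuple((lo + hi) / 2 for lo, hi in zip(BAND_LOWER, BAND_UPPER))

# Cuts at the midpoints of the printed interval gaps so every real score in
# [0, 1] maps to exactly one band; on the natural k/25 lattice these agree
# with the printed closed intervals.
_BAND_CUTS = (0.155, 0.255, 0.355, 0.455, 0.555, 0.655)

FRAILTY_THRESHOLD = 0.25


@dataclass
class AssessmentRecord:
    """One patient's 22 raw Frail-VIG answers at baseline.

    ``None`` marks an explicitly missing answer; how missing answers are
    handled is decided at scoring time (see :func:`score_assessment`).
    """

    patient_id: str = ""
    iadl_money: Optional[bool] = None
    iadl_phone: Optional[bool] = None
    iadl_medication: Optional[bool] = None
    barthel: Optional[int] = None
    malnutrition: Optional[bool] = None
    cognitive: Optional[CognitiveLevel] = None
    depressive: Optional[DepressiveStatus] = None
    insomnia_anxiety: Optional[bool] = None
    social_vulnerability: Optional[bool] = None
    delirium: Optional[bool] = None
    falls: Optional[bool] = None
    ulcers: Optional[bool] = None
    polypharmacy: Optional[bool] = None
    dysphagia: Optional[bool] = None
    pain: Optional[bool] = None
    dyspnea: Optional[bool] = None
    disease_cancer: Optional[DiseaseStatus] = None
    disease_respiratory: Optional[DiseaseStatus] = None
    disease_cardiac: Optional[DiseaseStatus] = None
    disease_neurological: Optional[DiseaseStatus] = None
    disease_digestive: Optional[DiseaseStatus] = None
    disease_renal: Optional[DiseaseStatus] = None

    def missing_items(self) -> list[str]:
        return [name for name in ALL_ITEMS if getattr(self, name) is None]

    @classmethod
    def field_names(cls) -> tuple:
        return tuple(f.name for f in fields(cls))


@dataclass
class FrailVigResult:
    """Scored Frail-VIG assessment for one patient."""

    patient_id: str
    item_points: dict
    domain_points: dict
    total_points: int
    score: float
    category: str
    frail: bool
    denominator: int = N_DEFICITS
    warnings: list = field(default_factory=list)


def map_barthel(barthel: int, *, round_to_five: bool = False, patient_id: str = "") -> int:
    """Map a Barthel index (0-100, multiples of 5) to 0-3 dependency points.

    95-100 -> 0 (no dependency), 65-90 -> 1 (mild-moderate), 25-60 -> 2
    (moderate-severe), 0-20 -> 3 (absolute dependency).  The published
    Barthel index only takes multiples of 5; other integers are rejected
    unless ``round_to_five`` asks for rounding to the nearest multiple.
    """
    ident = f" (patient_id={patient_id!r})" if patient_id else ""
    if isinstance(barthel, bool) or not float(barthel).is_integer():
        raise ValidationError(f"Barthel index must be an integer, got {barthel!r}{ident}")
    barthel = int(barthel)
    if not 0 <= barthel <= 100:
        raise ValidationError(f"Barthel index {barthel} outside 0-100{ident}")
    if barthel % 5 != 0:
        if not round_to_five:
            raise ValidationError(
                f"Barthel index {barthel} is not a multiple of 5{ident}"
            )
        barthel = int(round(barthel / 5.0)) * 5
    if barthel >= 95:
        return 0
    if barthel >= 65:
        return 1
    if barthel >= 25:
        return 2
    return 3


def map_cognitive(level: CognitiveLevel | str) -> int:
    """Map a cognitive-impairment level to 0-2 points."""
    try:
        level = CognitiveLevel(level)
    except ValueError:
        raise ValidationError(f"Unknown cognitive level {level!r}") from None
    return {
        CognitiveLevel.NONE: 0,
        CognitiveLevel.MILD_MODERATE: 1,
        CognitiveLevel.SEVERE: 2,
    }[level]


def cognitive_from_gds(gds: int) -> CognitiveLevel:
    """Convert a Reisberg GDS stage (1-7) to the instrument's three levels.

    GDS 1 (no cognitive decline) maps to *none*; stages 2-5 to
    *mild-moderate* (GDS <= 5); stages 6-7 to *severe* (GDS >= 6).
    """
    if not isinstance(gds, int) or isinstance(gds, bool) or not 1 <= gds <= 7:
        raise ValidationError(f"GDS stage must be an integer 1-7, got {gds!r}")
    if gds == 1:
        return CognitiveLevel.NONE
    if gds <= 5:
        return CognitiveLevel.MILD_MODERATE
    return CognitiveLevel.SEVERE


def categorize(score: float) -> str:
    """Return the published seven-band category label containing ``score``.

    Bands are cut at the midpoints of the printed interval gaps (0.155,
    0.255, ... 0.655) so categorisation is total on [0, 1]; every score a
    record can actually produce (a multiple of 1/25, a capped 1.0, or a
    rescaled k/m with m < 25) falls strictly inside a printed interval.
    """
    if not (0.0 <= score <= 1.0) or math.isnan(score):
        raise ValidationError(f"Score {score!r} outside [0, 1]")
    return BAND_LABELS[bisect_left(_BAND_CUTS, score)]


def is_frail(score: float) -> bool:
    """Frailty per the deficit-accumulation convention: score > 0.25."""
    if not (0.0 <= score <= 1.0) or math.isnan(score):
        raise ValidationError(f"Score {score!r} outside [0, 1]")
    return score > FRAILTY_THRESHOLD


def _coerce_bool(name: str, value, patient_id: str):
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    raise ValidationError(
        f"Item {name!r} must be boolean, got {value!r} (patient_id={patient_id!r})"
    )


def score_assessment(
    record: AssessmentRecord,
    *,
    missing_policy: str = "strict",
    not_evaluable_policy: str = "zero",
    advanced_mode: str = "per_disease",
    round_barthel: bool = False,
) -> FrailVigResult:
    """Apply the full Frail-VIG scoring table to one assessment record.

    Parameters
    ----------
    record
        The raw answers; ``None`` fields count as missing.
    missing_policy
        ``"strict"`` (default) refuses to score a record with any missing
        item.  ``"rescale"`` follows the general frailty-index convention
        of dividing by the number of assessable deficits instead of 25,
        but refuses when more than 5% of the potential deficits are
        unassessable.
    not_evaluable_policy
        Emotional status *not evaluable* scores 0 points with a warning by
        default (``"zero"``); ``"error"`` treats it as unscorable.
    advanced_mode
        ``"per_disease"`` (default): every advanced disease scores 2
        points.  ``"per_patient"``: advanced status adds a single bonus
        point per patient regardless of how many diseases qualify.
    round_barthel
        Accept Barthel values that are not multiples of 5 by rounding.
    """
    if missing_policy not in ("strict", "rescale"):
        raise ValueError(f"Unknown missing_policy {missing_policy!r}")
    if not_evaluable_policy not in ("zero", "error"):
        raise ValueError(f"Unknown not_evaluable_policy {not_evaluable_policy!r}")
    if advanced_mode not in ("per_disease", "per_patient"):
        raise ValueError(f"Unknown advanced_mode {advanced_mode!r}")

    pid = record.patient_id
    missing = record.missing_items()
    if missing and missing_policy == "strict":
        raise ScoringError(
            f"Record {pid!r} has missing items under strict policy: {missing}"
        )
    missing_weight = sum(ITEM_WEIGHTS[name] for name in missing)
    if missing_weight / N_DEFICITS > 0.05:
        raise ScoringError(
            f"Record {pid!r}: {missing_weight}/{N_DEFICITS} potential deficits "
            f"unassessable exceeds the 5% missing-data limit ({missing})"
        )

    warnings: list[str] = []
    item_points: dict[str, int] = {}

    for name in BINARY_ITEMS:
        value = getattr(record, name)
        if value is None:
            continue
        item_points[name] = int(_coerce_bool(name, value, pid))

    if record.barthel is not None:
        item_points["barthel"] = map_barthel(
            record.barthel, round_to_five=round_barthel, patient_id=pid
        )
    if record.cognitive is not None:
        item_points["cognitive"] = map_cognitive(record.cognitive)

    if record.depressive is not None:
        try:
            status = DepressiveStatus(record.depressive)
        except ValueError:
            raise ValidationError(
                f"Unknown depressive status {record.depressive!r} (patient_id={pid!r})"
            ) from None
        if status is DepressiveStatus.NOT_EVALUABLE:
            if not_evaluable_policy == "error":
                raise ScoringError(
                    f"Record {pid!r}: depressive status not evaluable under strict policy"
                )
            item_points["depressive"] = 0
            warnings.append("depressive status not evaluable; scored 0")
        else:
            item_points["depressive"] = int(status is DepressiveStatus.YES)

    any_advanced = False
    for name in DISEASE_ITEMS:
        value = getattr(record, name)
        if value is None:
            continue
        try:
            status = DiseaseStatus(value)
        except ValueError:
            raise ValidationError(
                f"Unknown disease status {value!r} for {name!r} (patient_id={pid!r})"
            ) from None
        if status is DiseaseStatus.ADVANCED:
            any_advanced = True
        if advanced_mode == "per_disease":
            item_points[name] = int(status)
        else:
            item_points[name] = int(status is not DiseaseStatus.ABSENT)
    patient_bonus = int(advanced_mode == "per_patient" and any_advanced)

    total_points = sum(item_points.values()) + patient_bonus
    denominator = N_DEFICITS - missing_weight
    score = min(total_points / denominator, 1.0)

    domain_points = {
        domain: sum(item_points.get(name, 0) for name in items)
        for domain, items in DOMAINS.items()
    }
    if patient_bonus:
        domain_points["diseases"] += patient_bonus

    return FrailVigResult(
        patient_id=pid,
        item_points=item_points,
        domain_points=domain_points,
        total_points=total_points,
        score=score,
        category=categorize(score),
        frail=is_frail(score),
        denominator=denominator,
        warnings=warnings,
    )
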