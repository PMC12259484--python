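"""Questionnaire data model: item bank, respondent records, interchange formats.

The instrument has two parts. Ten risk-estimation questions cover demographics,
work environment, self-isolation habits, distance keeping and hand washing; they
feed the risk engine. A separate bank of determinant-mapping items measures
Reasoned Action Approach (RAA) constructs — attitude, perceived norm, perceived
behavioural control — for three target behaviours. Respondents opt in to answer
between 0 and 20 of those items (in steps of 2) and are shown a random subset,
a planned-missingness design that keeps respondent burden low while the pooled
sample still covers every item.

Interchange formats are deliberately plain: the item bank is JSON, cohorts are
UTF-8 comma-separated CSV with multi-select cells joined by ";" and determinant
scores in wide columns named by item id (empty cell = item not presented).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from enum import StrEnum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import SchemaError, ValidationError


# --------------------------------------------------------------------------- #
# Enumerated answer domains
# --------------------------------------------------------------------------- #

class Behaviour(StrEnum):
    SOCIAL_DISTANCING = "social_distancing"
    SELF_ISOLATION = "self_isolation"
    HAND_WASHING = "hand_washing"


class Construct(StrEnum):
    """The three RAA determinant classes."""

    ATTITUDE = "attitude"
    PERCEIVED_NORM = "perceived_norm"
    PERCEIVED_BEHAVIOURAL_CONTROL = "perceived_behavioural_control"


class AgeBand(StrEnum):
    UNDER_20 = "under_20"
    AGE_20_29 = "20_29"
    AGE_30_39 = "30_39"
    AGE_40_49 = "40_49"
    AGE_50_59 = "50_59"
    AGE_60_69 = "60_69"
    AGE_70_PLUS = "70_plus"
    DECLINED = "declined"


class Gender(StrEnum):
    FEMALE = "female"
    MALE = "male"
    NONBINARY_OR_SELF_SPECIFIED = "nonbinary_or_self_specified"
    DECLINED = "declined"


class WorkContext(StrEnum):
    PATIENTS_VULNERABLE = "patients_vulnerable"
    CHILDREN = "children"
    COWORKERS = "coworkers"
    GENERAL_PUBLIC = "general_public"
    FROM_HOME = "from_home"
    NOT_WORKING = "not_working"


class IsolationBehaviour(StrEnum):
    """Reasons for currently leaving the house (multi-select)."""

    FOOD_MEDICINE_HEALTHCARE = "food_medicine_healthcare"
    OUTDOOR_EXERCISE = "outdoor_exercise"
    OTHER_SHOPS_SERVICES = "other_shops_services"
    MOSTLY_HOME = "mostly_home"
    VISIT_FAMILY = "visit_family"
    VISIT_FRIENDS = "visit_friends"


class IsolationTrigger(StrEnum):
    """Conditions under which the respondent would self-isolate more."""

    OWN_SYMPTOMS = "own_symptoms"
    CONTACT_WITH_SICK = "contact_with_sick"
    GOVERNMENT_RESTRICTIONS = "government_restrictions"
    NEVER = "never"
    OTHER = "other"


class StopBehaviour(StrEnum):
    """What 'self-isolating more' would mean: behaviours the respondent would stop."""

    FOOD_MEDICINE_HEALTHCARE = "food_medicine_healthcare"
    OUTDOOR_EXERCISE = "outdoor_exercise"
    OTHER_SHOPS_SERVICES = "other_shops_services"
    MOSTLY_HOME = "mostly_home"
    VISIT_FAMILY = "visit_family"
    VISIT_FRIENDS = "visit_friends"
    OTHER = "other"


class DistanceFrequency(StrEnum):
    """Ordinal frequency of keeping 1.5 m distance in public.

    ``NEVER_IN_PUBLIC`` is a special code: the respondent reports not being in
    public places at all, so a frequency rating is undefined.  It is stored
    verbatim but coded as missing wherever distance keeping serves as the
    behaviour measure (see :func:`distance_numeric`).
    """

    ALMOST_NEVER = "almost_never"
    RARELY = "rarely"
    SOMETIMES = "sometimes"
    OFTEN = "often"
    ALMOST_ALWAYS = "almost_always"
    NEVER_IN_PUBLIC = "never_in_public"


#: Ordinal coding of the five genuine frequency levels (1 = almost never).
DISTANCE_LEVELS: dict[DistanceFrequency, int] = {
    DistanceFrequency.ALMOST_NEVER: 1,
    DistanceFrequency.RARELY: 2,
    DistanceFrequency.SOMETIMES: 3,
    DistanceFrequency.OFTEN: 4,
    DistanceFrequency.ALMOST_ALWAYS: 5,
}


def distance_numeric(value: DistanceFrequency) -> float:
    """1–5 ordinal code for distance keeping; NaN for ``never_in_public``."""
    return float(DISTANCE_LEVELS.get(value, float("nan")))


class HandwashSituation(StrEnum):
    PUBLIC_SURFACES = "public_surfaces"
    ENTERING_BUILDING = "entering_building"
    BEFORE_FOOD = "before_food"
    AFTER_CONTACT = "after_contact"
    AFTER_SNEEZE_COUGH = "after_sneeze_cough"
    TOUCHING_FACE = "touching_face"
    NEVER_OR_OCCASIONALLY = "never_or_occasionally"


class HandwashThoroughness(StrEnum):
    SOAP_OR_SANITISER = "soap_or_sanitiser"
    TWENTY_SECONDS = "twenty_seconds"
    NAILS_AND_FINGERS = "nails_and_fingers"
    NONE_OF_ABOVE = "none_of_above"


# --------------------------------------------------------------------------- #
# Item bank
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ItemDefinition:
    """One determinant-mapping item.

    Each item operationalises one sub-determinant (an item-level facet of an
    RAA construct) for one target behaviour, answered on an integer scale
    ``[scale_min, scale_max]``.
    """

    item_id: str
    behaviour: Behaviour
    construct: Construct
    sub_determinant: str
    text: str
    scale_min: int = 1
    scale_max: int = 7

    def __post_init__(self) -> None:
        if not self.item_id:
            raise ValidationError("item_id must be non-empty")
        if self.scale_min >= self.scale_max:
            raise ValidationError(
                f"item {self.item_id!r}: scale_min ({self.scale_min}) must be "
                f"< scale_max ({self.scale_max})"
            )


@dataclass(frozen=True)
class ItemBank:
    items: tuple[ItemDefinition, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        if not self.items:
            raise ValidationError("bank must contain at least one item")
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ValidationError(f"duplicate item_id {item.item_id!r} in bank")
            seen.add(item.item_id)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> ItemDefinition:
        try:
            return self._by_id[item_id]
        except KeyError:
            raise KeyError(f"unknown item_id {item_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def _by_id(self) -> dict[str, ItemDefinition]:
        # cached lazily on the instance; frozen dataclass, so go via __dict__
        cache = self.__dict__.get("_by_id_cache")
        if cache is None:
            cache = {item.item_id: item for item in self.items}
            self.__dict__["_by_id_cache"] = cache
        return cache

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(item.item_id for item in self.items)


# Sub-determinant facet templates used to generate the default bank.  The
# crossings of 3 behaviours x 3 constructs x facets are sized so the bank holds
# exactly 276 items, matching the deployed instrument's item count; the texts
# are structural placeholders, not reconstructions of the original wording.
_FACETS: dict[Construct, tuple[str, ...]] = {
    Construct.ATTITUDE: (
        "expected_health_benefit",
        "expected_social_cost",
        "affective_evaluation",
        "perceived_effectiveness",
        "perceived_inconvenience",
        "perceived_personal_risk",
        "anticipated_regret",
        "outcome_for_others",
        "perceived_necessity",
        "enjoyment_loss",
        "moral_evaluation",
        "fatigue",
    ),
    Construct.PERCEIVED_NORM: (
        "injunctive_family",
        "injunctive_friends",
        "injunctive_government",
        "descriptive_neighbourhood",
        "descriptive_friends",
        "descriptive_country",
        "approval_of_noncompliance",
        "social_pressure_to_comply",
        "identification_with_compliers",
        "perceived_expectations",
    ),
    Construct.PERCEIVED_BEHAVIOURAL_CONTROL: (
        "self_efficacy_routine",
        "self_efficacy_social_situations",
        "self_efficacy_when_busy",
        "perceived_barriers_environment",
        "perceived_barriers_others",
        "skills_knowledge",
        "autonomy",
        "habit_strength",
        "capacity_to_plan",
        "resilience_to_lapses",
    ),
}

_BEHAVIOUR_ABBREV = {
    Behaviour.SOCIAL_DISTANCING: "sd",
    Behaviour.SELF_ISOLATION: "si",
    Behaviour.HAND_WASHING: "hw",
}
_CONSTRUCT_ABBREV = {
    Construct.ATTITUDE: "att",
    Construct.PERCEIVED_NORM: "norm",
    Construct.PERCEIVED_BEHAVIOURAL_CONTROL: "pbc",
}

def default_item_bank() -> ItemBank:
    """Generate the packaged default determinant item bank (276 items).

    Layout per behaviour (92 items each, 3 behaviours -> 276):

    * attitude: 12 facets x 3 phrasings = 36
    * perceived norm: 10 facets x 3 phrasings = 30
    * perceived behavioural control: 10 facets, first 6 x 3 phrasings and the
      remaining 4 x 2 phrasings = 26

    All items use a 1–7 bipolar response scale, the RAA convention.  Item ids
    encode behaviour, construct, facet and phrasing, e.g. ``sd_att_fatigue_2``.
    """
    items: list[ItemDefinition] = []
    for behaviour in Behaviour:
        for construct in Construct:
            facets = _FACETS[construct]
            for fi, facet in enumerate(facets):
                if construct is Construct.PERCEIVED_BEHAVIOURAL_CONTROL:
                    copies = 3 if fi < 6 else 2
                else:
                    copies = 3
                for phrasing in range(1, copies + 1):
                    iid = (
                        f"{_BEHAVIOUR_ABBREV[behaviour]}_"
                        f"{_CONSTRUCT_ABBREV[construct]}_{facet}_{phrasing}"
                    )
                    items.append(
                        ItemDefinition(
                            item_id=iid,
                            behaviour=behaviour,
                            construct=construct,
                            sub_determinant=facet,
                            text=(
                                f"[{behaviour.value}/{construct.value}] "
                                f"{facet.replace('_', ' ')} (phrasing {phrasing})"
                            ),
                            scale_min=1,
                            scale_max=7,
                        )
                    )
    return ItemBank(items=tuple(items), version="default-1")


def load_item_bank(path: str | Path) -> ItemBank:
    """Load and validate an item bank from its JSON interchange format."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SchemaError(f"item bank {path}: invalid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "items" not in payload:
        raise SchemaError(f"item bank {path}: top level must be {{version, items}}")
    raw_items = payload["items"]
    if not isinstance(raw_items, list) or not raw_items:
        raise SchemaError("bank must contain at least one item")
    items = []
    for i, raw in enumerate(raw_items):
        try:
            items.append(
                ItemDefinition(
                    item_id=str(raw["item_id"]),
                    behaviour=Behaviour(raw["behaviour"]),
                    construct=Construct(raw["construct"]),
                    sub_determinant=str(raw["sub_determinant"]),
                    text=str(raw.get("text", "")),
                    scale_min=int(raw["scale_min"]),
                    scale_max=int(raw["scale_max"]),
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            ident = raw.get("item_id", f"#{i}") if isinstance(raw, dict) else f"#{i}"
            raise SchemaError(f"item bank entry {ident!r}: {exc}") from exc
    try:
        return ItemBank(items=tuple(items), version=str(payload.get("version", "1")))
    except ValidationError as exc:
        raise SchemaError(str(exc)) from exc


def write_item_bank(bank: ItemBank, path: str | Path) -> None:
    payload = {
        "version": bank.version,
        "items": [
            {
                "item_id": it.item_id,
                "behaviour": it.behaviour.value,
                "construct": it.construct.value,
                "sub_determinant": it.sub_determinant,
                "text": it.text,
                "scale_min": it.scale_min,
                "scale_max": it.scale_max,
            }
            for it in bank.items
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


# --------------------------------------------------------------------------- #
# Respondent records
# --------------------------------------------------------------------------- #

VALID_OPT_IN = frozenset(range(0, 21, 2))


@dataclass
class ResponseRecord:
    """One respondent: risk-estimation answers plus sparse determinant scores."""

    respondent_id: str
    country: str
    age_band: AgeBand
    gender: Gender
    work_contexts: frozenset[WorkContext]
    isolation_behaviours: frozenset[IsolationBehaviour]
    isolation_triggers: frozenset[IsolationTrigger]
    behaviours_would_stop: frozenset[StopBehaviour]
    distance_frequency: DistanceFrequency
    handwash_situations: frozenset[HandwashSituation]
    handwash_thoroughness: frozenset[HandwashThoroughness]
    n_items_opted: int = 0
    determinant_scores: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_items_opted not in VALID_OPT_IN:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: n_items_opted "
                f"{self.n_items_opted!r} must be even in [0,20]"
            )
        if len(self.determinant_scores) > self.n_items_opted:
            raise ValidationError(
                f"respondent {self.respondent_id!r}: {len(self.determinant_scores)} "
                f"determinant scores exceed opt-in of {self.n_items_opted}"
            )

    def validate_against(self, bank: ItemBank) -> None:
        """Check every determinant score against its item's scale."""
        for item_id, score in self.determinant_scores.items():
            if item_id not in bank:
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: unknown item {item_id!r}"
                )
            item = bank[item_id]
            if not (item.scale_min <= score <= item.scale_max):
                raise ValidationError(
                    f"respondent {self.respondent_id!r}: score {score} for item "
                    f"{item_id!r} outside scale [{item.scale_min}, {item.scale_max}]"
                )


# --------------------------------------------------------------------------- #
# Cohort CSV interchange (comma-separated, UTF-8, header row, ';' multiselect)
# --------------------------------------------------------------------------- #

_FIXED_COLUMNS = (
    "respondent_id",
    "country",
    "age_band",
    "gender",
    "work_contexts",
    "isolation_behaviours",
    "isolation_triggers",
    "behaviours_would_stop",
    "distance_frequency",
    "handwash_situations",
    "handwash_thoroughness",
    "n_items_opted",
)

_MULTISELECT_DOMAINS = {
    "work_contexts": WorkContext,
    "isolation_behaviours": IsolationBehaviour,
    "isolation_triggers": IsolationTrigger,
    "behaviours_would_stop": StopBehaviour,
    "handwash_situations": HandwashSituation,
    "handwash_thoroughness": HandwashThoroughness,
}


def _join_multiselect(values: Iterable[StrEnum], domain: type[StrEnum]) -> str:
    order = {member: i for i, member in enumerate(domain)}
    return ";".join(v.value for v in sorted(values, key=order.__getitem__))


def _split_multiselect(cell: str, domain: type[StrEnum], where: str) -> frozenset:
    if not cell:
        return frozenset()
    out = []
    for token in cell.split(";"):
        try:
            out.append(domain(token.strip()))
        except ValueError:
            raise SchemaError(f"{where}: unknown {domain.__name__} code {token!r}")
    return frozenset(out)


def write_responses(records: Sequence[ResponseRecord], path: str | Path) -> None:
    """Write a cohort to CSV.

    Determinant-score columns are emitted only for items that at least one
    respondent answered, in sorted item-id order; an empty cell means the item
    was not presented to (or not answered by) that respondent.
    """
    answered: set[str] = set()
    for rec in records:
        answered.update(rec.determinant_scores)
    item_cols = sorted(answered)
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(list(_FIXED_COLUMNS) + item_cols)
        for rec in records:
            row = [
                rec.respondent_id,
                rec.country,
                rec.age_band.value,
                rec.gender.value,
                _join_multiselect(rec.work_contexts, WorkContext),
                _join_multiselect(rec.isolation_behaviours, IsolationBehaviour),
                _join_multiselect(rec.isolation_triggers, IsolationTrigger),
                _join_multiselect(rec.behaviours_would_stop, StopBehaviour),
                rec.distance_frequency.value,
                _join_multiselect(rec.handwash_situations, HandwashSituation),
                _join_multiselect(rec.handwash_thoroughness, HandwashThoroughness),
                str(rec.n_items_opted),
            ]
            for col in item_cols:
                score = rec.determinant_scores.get(col)
                row.append("" if score is None else str(score))
            writer.writerow(row)


def read_responses(path: str | Path, bank: ItemBank) -> list[ResponseRecord]:
    """Read and validate a cohort CSV against an item bank."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        missing = [c for c in _FIXED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
        item_cols = [c for c in header if c not in _FIXED_COLUMNS]
        for col in item_cols:
            if col not in bank:
                raise SchemaError(f"{path}: unknown item column {col!r}")
        idx = {c: header.index(c) for c in header}

        records: list[ResponseRecord] = []
        for rownum, row in enumerate(reader, start=2):
            where = f"{path} row {rownum}"
            if len(row) != len(header):
                raise SchemaError(f"{where}: expected {len(header)} cells, got {len(row)}")

            def cell(col: str) -> str:
                return row[idx[col]].strip()

            try:
                n_opted = int(cell("n_items_opted"))
            except ValueError:
                raise SchemaError(
                    f"{where}: n_items_opted {cell('n_items_opted')!r} must be "
                    "even in [0,20]"
                ) from None
            scores: dict[str, int] = {}
            for col in item_cols:
                raw = row[idx[col]].strip()
                if raw == "":
                    continue
                try:
                    scores[col] = int(raw)
                except ValueError:
                    raise SchemaError(
                        f"{where}: non-integer score {raw!r} for item {col!r}"
                    ) from None
            try:
                rec = ResponseRecord(
                    respondent_id=cell("respondent_id"),
                    country=cell("country"),
                    age_band=AgeBand(cell("age_band")),
                    gender=Gender(cell("gender")),
                    work_contexts=_split_multiselect(cell("work_contexts"), WorkContext, where),
                    isolation_behaviours=_split_multiselect(
                        cell("isolation_behaviours"), IsolationBehaviour, where
                    ),
                    isolation_triggers=_split_multiselect(
                        cell("isolation_triggers"), IsolationTrigger, where
                    ),
                    behaviours_would_stop=_split_multiselect(
                        cell("behaviours_would_stop"), StopBehaviour, where
                    ),
                    distance_frequency=DistanceFrequency(cell("distance_frequency")),
                    handwash_situations=_split_multiselect(
                        cell("handwash_situations"), HandwashSituation, where
                    ),
                    handwash_thoroughness=_split_multiselect(
                        cell("handwash_thoroughness"), HandwashThoroughness, where
                    ),
                    n_items_opted=n_opted,
                    determinant_scores=scores,
                )
                rec.validate_against(bank)
            except ValueError as exc:  # bad enum code
                raise SchemaError(f"{where}: {exc}") from exc
            except ValidationError as exc:
                raise ValidationError(f"{where}: {exc}") from exc
            records.append(rec)
    return records


# --------------------------------------------------------------------------- #
# Usage funnel
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class FunnelCounts:
    """Tool-usage funnel: opened, bounced, abandoned, completed."""

    total_opened: int
    opened_first_page_only: int
    started_not_completed: int
    completed: int

    def __post_init__(self) -> None:
        parts = (
            self.opened_first_page_only + self.started_not_completed + self.completed
        )
        if self.total_opened != parts:
            raise ValidationError(
                f"funnel counts must be additive: total_opened={self.total_opened} "
                f"!= {parts} (sum of strata)"
            )
        if min(
            self.total_opened,
            self.opened_first_page_only,
            self.started_not_completed,
            self.completed,
        ) < 0:
            raise ValidationError("funnel counts must be non-negative")


def funnel_stats(counts: FunnelCounts) -> float:
    """Drop-out percentage among users who got past the first page.

    Defined as ``100 * started_not_completed / (total_opened -
    opened_first_page_only)``: of everyone who actually began the assessment,
    the share who abandoned it before receiving results.
    """
    denom = counts.total_opened - counts.opened_first_page_only
    if denom <= 0:
        raise ValidationError("no users progressed past the first page")
    return 100.0 * counts.started_not_completed / denom


def load_funnel_counts(path: str | Path) -> FunnelCounts:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        return FunnelCounts(
            total_opened=int(payload["total_opened"]),
            opened_first_page_only=int(payload["opened_first_page_only"]),
            started_not_completed=int(payload["started_not_completed"]),
            completed=int(payload["completed"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"funnel counts {path}: {exc}") from exc
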