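"""Three-factor behavioural risk engine.

A respondent's risk is decomposed into three independent factors:

* **exposure risk** ("risk of getting the virus"): proximity and lack of
  self-isolation — work environment, reasons for leaving the house, distance
  keeping, and the conditions under which the respondent would isolate more;
* **hygiene risk** ("risk from not removing the virus"): lack of handwashing —
  situations in which the respondent does *not* wash and missing thoroughness
  practices;
* **uncontrollable risk**: demographic factors outside behavioural control.

Each factor is an additive aggregate of non-negative answer weights, normalised
to 0–100 against a configured scale maximum and clamped.  Protective answers
(working from home, staying mostly at home, each endorsed handwashing practice)
carry no weight of their own: they lower risk only by displacing risk-conferring
answers.  Willingness-to-isolate answers act as multiplicative discounts (<= 1)
on the exposure sum.  The weight values themselves are configuration — the
engine's contract is the aggregation, not any particular elicitation — and a
documented uniform-within-factor default ships for testing and simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import StrEnum
from pathlib import Path

from .errors import ConfigError
from .survey import (
    AgeBand,
    DistanceFrequency,
    Gender,
    HandwashSituation,
    HandwashThoroughness,
    IsolationBehaviour,
    IsolationTrigger,
    ResponseRecord,
    StopBehaviour,
    WorkContext,
)


class RiskCategory(StrEnum):
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


@dataclass(frozen=True)
class RiskWeights:
    """Answer-code weights for the three risk factors.

    ``hygiene_missed_*`` weights accrue when the protective practice is *not*
    endorsed; ``hygiene_risk_answers`` when the risk answer *is* endorsed.
    Multipliers apply once per endorsed code and must lie in (0, 1].
    """

    work_weights: dict[WorkContext, float]
    isolation_weights: dict[IsolationBehaviour, float]
    distance_weights: dict[DistanceFrequency, float]
    trigger_multipliers: dict[IsolationTrigger, float]
    would_stop_multipliers: dict[StopBehaviour, float]
    hygiene_missed_situations: dict[HandwashSituation, float]
    hygiene_missed_thoroughness: dict[HandwashThoroughness, float]
    hygiene_risk_answers: dict[str, float]
    age_weights: dict[AgeBand, float]
    gender_weights: dict[Gender, float]
    exposure_scale_max: float
    hygiene_scale_max: float
    uncontrollable_scale_max: float

    def __post_init__(self) -> None:
        for name, table in (
            ("work_weights", self.work_weights),
            ("isolation_weights", self.isolation_weights),
            ("distance_weights", self.distance_weights),
            ("hygiene_missed_situations", self.hygiene_missed_situations),
            ("hygiene_missed_thoroughness", self.hygiene_missed_thoroughness),
            ("hygiene_risk_answers", self.hygiene_risk_answers),
            ("age_weights", self.age_weights),
            ("gender_weights", self.gender_weights),
        ):
            for code, w in table.items():
                if w < 0:
                    raise ConfigError(f"{name}[{code}]: weight {w} must be >= 0")
        for name, table in (
            ("trigger_multipliers", self.trigger_multipliers),
            ("would_stop_multipliers", self.would_stop_multipliers),
        ):
            for code, m in table.items():
                if not (0 < m <= 1):
                    raise ConfigError(f"{name}[{code}]: multiplier {m} must be in (0, 1]")
        for name, s in (
            ("exposure_scale_max", self.exposure_scale_max),
            ("hygiene_scale_max", self.hygiene_scale_max),
            ("uncontrollable_scale_max", self.uncontrollable_scale_max),
        ):
            if s <= 0:
                raise ConfigError(f"{name} must be positive, got {s}")


def default_weights() -> RiskWeights:
    """Uniform-within-factor default weights.

    Risk-conferring answers weigh 1, protective answers 0; the distance item is
    graded linearly from 1 (almost never keeps distance) to 0 (almost always).
    Willingness-to-isolate triggers each discount exposure by 5%, and each
    behaviour the respondent would stop by 2% — small, because they describe
    conditional rather than current behaviour.  Age weights rise with decade to
    reflect steeply age-graded severity; the declined code gets the mid-range
    weight.  Scale maxima equal the largest attainable sum of each factor so
    the most risk-prone answer pattern scores 100.
    """
    work = {
        WorkContext.PATIENTS_VULNERABLE: 1.0,
        WorkContext.CHILDREN: 1.0,
        WorkContext.COWORKERS: 1.0,
        WorkContext.GENERAL_PUBLIC: 1.0,
        WorkContext.FROM_HOME: 0.0,
        WorkContext.NOT_WORKING: 0.0,
    }
    isolation = {
        IsolationBehaviour.FOOD_MEDICINE_HEALTHCARE: 1.0,
        IsolationBehaviour.OUTDOOR_EXERCISE: 1.0,
        IsolationBehaviour.OTHER_SHOPS_SERVICES: 1.0,
        IsolationBehaviour.MOSTLY_HOME: 0.0,
        IsolationBehaviour.VISIT_FAMILY: 1.0,
        IsolationBehaviour.VISIT_FRIENDS: 1.0,
    }
    distance = {
        DistanceFrequency.ALMOST_NEVER: 1.0,
        DistanceFrequency.RARELY: 0.75,
        DistanceFrequency.SOMETIMES: 0.5,
        DistanceFrequency.OFTEN: 0.25,
        DistanceFrequency.ALMOST_ALWAYS: 0.0,
        DistanceFrequency.NEVER_IN_PUBLIC: 0.0,
    }
    triggers = {
        IsolationTrigger.OWN_SYMPTOMS: 0.95,
        IsolationTrigger.CONTACT_WITH_SICK: 0.95,
        IsolationTrigger.GOVERNMENT_RESTRICTIONS: 0.95,
        IsolationTrigger.NEVER: 1.0,
        IsolationTrigger.OTHER: 1.0,
    }
    would_stop = {code: 0.98 if code is not StopBehaviour.OTHER else 1.0 for code in StopBehaviour}
    missed_situations = {
        HandwashSituation.PUBLIC_SURFACES: 1.0,
        HandwashSituation.ENTERING_BUILDING: 1.0,
        HandwashSituation.BEFORE_FOOD: 1.0,
        HandwashSituation.AFTER_CONTACT: 1.0,
        HandwashSituation.AFTER_SNEEZE_COUGH: 1.0,
        HandwashSituation.TOUCHING_FACE: 1.0,
    }
    missed_thoroughness = {
        HandwashThoroughness.SOAP_OR_SANITISER: 1.0,
        HandwashThoroughness.TWENTY_SECONDS: 1.0,
        HandwashThoroughness.NAILS_AND_FINGERS: 1.0,
    }
    risk_answers = {
        HandwashSituation.NEVER_OR_OCCASIONALLY.value: 2.0,
        HandwashThoroughness.NONE_OF_ABOVE.value: 1.0,
    }
    age = {
        AgeBand.UNDER_20: 0.0,
        AgeBand.AGE_20_29: 0.1,
        AgeBand.AGE_30_39: 0.2,
        AgeBand.AGE_40_49: 0.35,
        AgeBand.AGE_50_59: 0.5,
        AgeBand.AGE_60_69: 0.7,
        AgeBand.AGE_70_PLUS: 1.0,
        AgeBand.DECLINED: 0.35,
    }
    gender = {g: 0.0 for g in Gender}
    return RiskWeights(
        work_weights=work,
        isolation_weights=isolation,
        distance_weights=distance,
        trigger_multipliers=triggers,
        would_stop_multipliers=would_stop,
        hygiene_missed_situations=missed_situations,
        hygiene_missed_thoroughness=missed_thoroughness,
        hygiene_risk_answers=risk_answers,
        age_weights=age,
        gender_weights=gender,
        # exposure: 4 work + 5 isolation + 1 distance = 10
        exposure_scale_max=10.0,
        # hygiene: 6 situations + 3 thoroughness + 2 + 1 risk answers = 12
        hygiene_scale_max=12.0,
        uncontrollable_scale_max=1.0,
    )


@dataclass(frozen=True)
class RiskEstimate:
    exposure_risk: float
    hygiene_risk: float
    uncontrollable_risk: float
    exposure_category: RiskCategory
    hygiene_category: RiskCategory
    uncontrollable_category: RiskCategory

    def as_dict(self) -> dict:
        return {
            "exposure_risk": self.exposure_risk,
            "hygiene_risk": self.hygiene_risk,
            "uncontrollable_risk": self.uncontrollable_risk,
            "exposure_category": self.exposure_category.value,
            "hygiene_category": self.hygiene_category.value,
            "uncontrollable_category": self.uncontrollable_category.value,
        }


DEFAULT_CUTS: tuple[float, ...] = (33.0, 66.0)


def categorize(score: float, cuts: tuple[float, ...] = DEFAULT_CUTS) -> RiskCategory:
    """Map a 0–100 score to low/moderate/high via lower-inclusive cut points.

    ``score < cuts[0]`` is low; ``score >= cuts[-1]`` is high; anything between
    is moderate.  Cuts must be strictly increasing within (0, 100).
    """
    if not cuts or any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise ConfigError(f"cut points must be strictly increasing, got {cuts}")
    if cuts[0] <= 0 or cuts[-1] >= 100:
        raise ConfigError(f"cut points must lie within (0, 100), got {cuts}")
    if not (0 <= score <= 100):
        raise ConfigError(f"score {score} outside [0, 100]")
    if score < cuts[0]:
        return RiskCategory.LOW
    if score >= cuts[-1]:
        return RiskCategory.HIGH
    return RiskCategory.MODERATE


def _lookup(table: dict, code, table_name: str) -> float:
    try:
        return table[code]
    except KeyError:
        raise ConfigError(
            f"answer code {getattr(code, 'value', code)!r} missing from {table_name}"
        ) from None


def score_risk(
    response: ResponseRecord,
    weights: RiskWeights,
    cuts: tuple[float, ...] = DEFAULT_CUTS,
) -> RiskEstimate:
    """Score one respondent on the three risk factors.

    Factor separation holds by construction: handwashing answers touch only
    hygiene risk, isolation/distance/work/trigger answers only exposure risk,
    and demographics only uncontrollable risk.
    """
    # exposure: additive risk weights, then multiplicative isolation discounts
    exp_sum = 0.0
    for code in response.work_contexts:
        exp_sum += _lookup(weights.work_weights, code, "work_weights")
    for code in response.isolation_behaviours:
        exp_sum += _lookup(weights.isolation_weights, code, "isolation_weights")
    exp_sum += _lookup(weights.distance_weights, response.distance_frequency, "distance_weights")
    multiplier = 1.0
    for code in response.isolation_triggers:
        multiplier *= _lookup(weights.trigger_multipliers, code, "trigger_multipliers")
    for code in response.behaviours_would_stop:
        multiplier *= _lookup(
            weights.would_stop_multipliers, code, "would_stop_multipliers"
        )
    exposure = _clamp(100.0 * exp_sum * multiplier / weights.exposure_scale_max)

    # hygiene: weight accrues for each protective practice NOT endorsed plus
    # each endorsed risk answer
    hyg_sum = 0.0
    for code, w in weights.hygiene_missed_situations.items():
        if code not in response.handwash_situations:
            hyg_sum += w
    for code, w in weights.hygiene_missed_thoroughness.items():
        if code not in response.handwash_thoroughness:
            hyg_sum += w
    for code in response.handwash_situations:
        if code.value in weights.hygiene_risk_answers:
            hyg_sum += weights.hygiene_risk_answers[code.value]
    for code in response.handwash_thoroughness:
        if code.value in weights.hygiene_risk_answers:
            hyg_sum += weights.hygiene_risk_answers[code.value]
    hygiene = _clamp(100.0 * hyg_sum / weights.hygiene_scale_max)

    unc_sum = _lookup(weights.age_weights, response.age_band, "age_weights")
    unc_sum += _lookup(weights.gender_weights, response.gender, "gender_weights")
    uncontrollable = _clamp(100.0 * unc_sum / weights.uncontrollable_scale_max)

    return RiskEstimate(
        exposure_risk=exposure,
        hygiene_risk=hygiene,
        uncontrollable_risk=uncontrollable,
        exposure_category=categorize(exposure, cuts),
        hygiene_category=categorize(hygiene, cuts),
        uncontrollable_category=categorize(uncontrollable, cuts),
    )


def _clamp(x: float) -> float:
    return min(100.0, max(0.0, x))


# ----------------------------------------------------------------------- #
# Weights JSON interchange
# ----------------------------------------------------------------------- #

def load_weights(path: str | Path) -> RiskWeights:
    """Load a RiskWeights config from JSON (schema mirrors the dataclass)."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"weights file {path}: invalid JSON ({exc})") from exc

    def table(key: str, domain) -> dict:
        raw = payload.get(key)
        if not isinstance(raw, dict):
            raise ConfigError(f"weights file {path}: missing table {key!r}")
        try:
            return {domain(k): float(v) for k, v in raw.items()}
        except ValueError as exc:
            raise ConfigError(f"weights file {path}, table {key!r}: {exc}") from exc

    try:
        return RiskWeights(
            work_weights=table("work_weights", WorkContext),
            isolation_weights=table("isolation_weights", IsolationBehaviour),
            distance_weights=table("distance_weights", DistanceFrequency),
            trigger_multipliers=table("trigger_multipliers", IsolationTrigger),
            would_stop_multipliers=table("would_stop_multipliers", StopBehaviour),
            hygiene_missed_situations=table("hygiene_missed_situations", HandwashSituation),
            hygiene_missed_thoroughness=table(
                "hygiene_missed_thoroughness", HandwashThoroughness
            ),
            hygiene_risk_answers={
                str(k): float(v) for k, v in payload.get("hygiene_risk_answers", {}).items()
            },
            age_weights=table("age_weights", AgeBand),
            gender_weights=table("gender_weights", Gender),
            exposure_scale_max=float(payload["exposure_scale_max"]),
            hygiene_scale_max=float(payload["hygiene_scale_max"]),
            uncontrollable_scale_max=float(payload["uncontrollable_scale_max"]),
        )
    except KeyError as exc:
        raise ConfigError(f"weights file {path}: missing key {exc}") from exc


def write_weights(weights: RiskWeights, path: str | Path) -> None:
    def dump(table: dict) -> dict:
        return {getattr(k, "value", k): v for k, v in table.items()}

    payload = {
        "work_weights": dump(weights.work_weights),
        "isolation_weights": dump(weights.isolation_weights),
        "distance_weights": dump(weights.distance_weights),
        "trigger_multipliers": dump(weights.trigger_multipliers),
        "would_stop_multipliers": dump(weights.would_stop_multipliers),
        "hygiene_missed_situations": dump(weights.hygiene_missed_situations),
        "hygiene_missed_thoroughness": dump(weights.hygiene_missed_thoroughness),
        "hygiene_risk_answers": dict(weights.hygiene_risk_answers),
        "age_weights": dump(weights.age_weights),
        "gender_weights": dump(weights.gender_weights),
        "exposure_scale_max": weights.exposure_scale_max,
        "hygiene_scale_max": weights.hygiene_scale_max,
        "uncontrollable_scale_max": weights.uncontrollable_scale_max,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")
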