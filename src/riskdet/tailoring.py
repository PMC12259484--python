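"""ABCD-based tailored-message selection ("safety estimate").

An acyclic behaviour change diagram (ABCD) links each persuasive message (an
"application") to the behaviour change principle (BCP) it instantiates, the
conditions under which that principle is effective, and the sub-determinant and
RAA determinant it is assumed to change, for one target (sub-)behaviour.  The
message table is a flat TSV with one row per application, preserving that
column structure.

Selection is rule-driven: declarative tailoring rules (field / operator / value
predicates over the respondent's answers) decide which behaviours need
addressing; all ABCD entries for a firing behaviour become eligible, ordered by
rule priority, then by the respondent's factor risk for that behaviour
(highest first), then by stable table order.  Respondents for whom no rule
fires — already-protective answer patterns — receive the table's reinforcement
entries instead, so nobody leaves empty-handed.  Every emitted message carries
provenance: the ABCD entry and the rule that selected it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .errors import ConfigError, SchemaError, ValidationError
from .risk import RiskEstimate
from .survey import Behaviour, Construct, ResponseRecord

#: sub_determinant value marking fallback entries shown when no rule fires
REINFORCEMENT = "reinforcement"

ABCD_COLUMNS = (
    "behaviour",
    "sub_behaviour",
    "determinant",
    "sub_determinant",
    "bcp",
    "conditions_for_effectiveness",
    "application",
    "locale",
)


@dataclass(frozen=True)
class AbcdEntry:
    """One row of an acyclic behaviour change diagram table."""

    behaviour: Behaviour
    sub_behaviour: str
    determinant: Construct
    sub_determinant: str
    bcp: str
    conditions_for_effectiveness: str
    application: str
    locale: str = "en"

    def __post_init__(self) -> None:
        if not self.application:
            raise ValidationError(
                f"ABCD entry for {self.behaviour.value}/{self.sub_determinant}: "
                "application text must be non-empty"
            )


def load_abcd(path: str | Path) -> list[AbcdEntry]:
    """Load and validate an ABCD message table (TSV, 8 columns)."""
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        return _parse_abcd(csv.reader(fh, delimiter="\t"), str(path))


def _parse_abcd(reader, where: str) -> list[AbcdEntry]:
    try:
        header = next(reader)
    except StopIteration:
        raise SchemaError(f"{where}: empty ABCD table") from None
    missing = [c for c in ABCD_COLUMNS if c not in header]
    if missing:
        raise SchemaError(f"{where}: missing column(s) {', '.join(missing)}")
    idx = {c: header.index(c) for c in ABCD_COLUMNS}
    entries: list[AbcdEntry] = []
    seen: set[tuple] = set()
    for rownum, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            entry = AbcdEntry(
                behaviour=Behaviour(row[idx["behaviour"]].strip()),
                sub_behaviour=row[idx["sub_behaviour"]].strip(),
                determinant=Construct(row[idx["determinant"]].strip()),
                sub_determinant=row[idx["sub_determinant"]].strip(),
                bcp=row[idx["bcp"]].strip(),
                conditions_for_effectiveness=row[idx["conditions_for_effectiveness"]].strip(),
                application=row[idx["application"]].strip(),
                locale=row[idx["locale"]].strip() or "en",
            )
        except (ValueError, IndexError) as exc:
            raise SchemaError(f"{where} row {rownum}: {exc}") from exc
        except ValidationError as exc:
            raise ValidationError(f"{where} row {rownum}: {exc}") from exc
        key = (entry.behaviour, entry.sub_determinant, entry.application, entry.locale)
        if key in seen:
            raise ValidationError(
                f"{where} row {rownum}: duplicate (behaviour, sub_determinant, "
                f"application, locale) entry"
            )
        seen.add(key)
        entries.append(entry)
    if not entries:
        raise SchemaError(f"{where}: empty ABCD table")
    return entries


def write_abcd(entries: Sequence[AbcdEntry], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ABCD_COLUMNS)
        for e in entries:
            writer.writerow(
                [
                    e.behaviour.value,
                    e.sub_behaviour,
                    e.determinant.value,
                    e.sub_determinant,
                    e.bcp,
                    e.conditions_for_effectiveness,
                    e.application,
                    e.locale,
                ]
            )


def default_abcd() -> list[AbcdEntry]:
    """The packaged synthetic English ABCD fixture table."""
    text = resources.files("riskdet.data").joinpath("abcd_en_synthetic.tsv").read_text(
        encoding="utf-8"
    )
    return _parse_abcd(csv.reader(text.splitlines(), delimiter="\t"), "packaged abcd")


# --------------------------------------------------------------------------- #
# Tailoring rules
# --------------------------------------------------------------------------- #

_SCALAR_FIELDS = {"distance_frequency", "n_items_opted", "age_band", "gender", "country"}
_SET_FIELDS = {
    "work_contexts",
    "isolation_behaviours",
    "isolation_triggers",
    "behaviours_would_stop",
    "handwash_situations",
    "handwash_thoroughness",
}
_RULE_FIELDS = _SCALAR_FIELDS | _SET_FIELDS
_OPS = {"contains", "not_contains", "eq", "ne", "in"}


@dataclass(frozen=True)
class Trigger:
    """Declarative predicate: <field> <op> <value>.

    Ops: ``contains`` / ``not_contains`` (multi-select fields), ``eq`` / ``ne``
    (scalar fields), ``in`` (scalar field value among a list).
    """

    field: str
    op: str
    value: object

    def __post_init__(self) -> None:
        if self.field not in _RULE_FIELDS:
            raise ConfigError(f"trigger references unknown field {self.field!r}")
        if self.op not in _OPS:
            raise ConfigError(f"unknown trigger op {self.op!r}")
        if self.op in {"contains", "not_contains"} and self.field not in _SET_FIELDS:
            raise ConfigError(f"op {self.op!r} requires a multi-select field, got {self.field!r}")
        if self.op in {"eq", "ne", "in"} and self.field in _SET_FIELDS:
            raise ConfigError(f"op {self.op!r} requires a scalar field, got {self.field!r}")

    def evaluate(self, response: ResponseRecord) -> bool:
        raw = getattr(response, self.field)
        if self.field in _SET_FIELDS:
            codes = {getattr(v, "value", v) for v in raw}
            if self.op == "contains":
                return self.value in codes
            return self.value not in codes
        scalar = getattr(raw, "value", raw)
        if self.op == "eq":
            return scalar == self.value
        if self.op == "ne":
            return scalar != self.value
        return scalar in self.value  # "in"


@dataclass(frozen=True)
class TailoringRule:
    behaviour: Behaviour
    trigger: Trigger
    priority: int
    rule_id: str = ""

    def fires(self, response: ResponseRecord) -> bool:
        return self.trigger.evaluate(response)


def load_rules(path: str | Path) -> list[TailoringRule]:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"rules file {path}: invalid JSON ({exc})") from exc
    return _parse_rules(payload, str(path))


def _parse_rules(payload, where: str) -> list[TailoringRule]:
    if not isinstance(payload, list) or not payload:
        raise ConfigError(f"{where}: rules must be a non-empty JSON list")
    rules = []
    for i, raw in enumerate(payload):
        try:
            trig = raw["trigger"]
            rules.append(
                TailoringRule(
                    behaviour=Behaviour(raw["behaviour"]),
                    trigger=Trigger(
                        field=trig["field"], op=trig["op"], value=trig["value"]
                    ),
                    priority=int(raw["priority"]),
                    rule_id=str(raw.get("rule_id", f"rule_{i}")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{where} rule #{i}: {exc}") from exc
    return rules


def default_rules() -> list[TailoringRule]:
    """The packaged default tailoring ruleset."""
    text = resources.files("riskdet.data").joinpath("rules_default.json").read_text(
        encoding="utf-8"
    )
    return _parse_rules(json.loads(text), "packaged rules")


# --------------------------------------------------------------------------- #
# Message selection
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SelectedMessage:
    """One tailored message plus its selection provenance."""

    entry: AbcdEntry
    rule: TailoringRule | None  # None for default reinforcement messages

    def provenance(self) -> dict:
        return {
            "behaviour": self.entry.behaviour.value,
            "sub_determinant": self.entry.sub_determinant,
            "bcp": self.entry.bcp,
            "application": self.entry.application,
            "locale": self.entry.locale,
            "rule_id": self.rule.rule_id if self.rule else None,
            "rule_priority": self.rule.priority if self.rule else None,
            "reinforcement": self.rule is None,
        }


#: Fixed tie-break order among behaviours (most-upstream behaviour first).
_BEHAVIOUR_ORDER = (
    Behaviour.SELF_ISOLATION,
    Behaviour.SOCIAL_DISTANCING,
    Behaviour.HAND_WASHING,
)


def _factor_score(behaviour: Behaviour, risk: RiskEstimate) -> float:
    # distancing and isolation both belong to the exposure factor
    if behaviour is Behaviour.HAND_WASHING:
        return risk.hygiene_risk
    return risk.exposure_risk


def select_messages(
    response: ResponseRecord,
    risk: RiskEstimate,
    abcd: Sequence[AbcdEntry],
    rules: Sequence[TailoringRule],
    max_messages: int = 6,
) -> list[SelectedMessage]:
    """Select tailored messages for one respondent.

    Deterministic: entries for behaviours with at least one firing rule are
    ordered by the firing rule's priority (descending), then the behaviour's
    factor risk score (descending), then the fixed behaviour order, then stable
    table order, and truncated to ``max_messages``.  Reinforcement entries
    (``sub_determinant == "reinforcement"``) are never rule-selected; they are
    returned only when no rule fires at all.
    """
    if max_messages < 1:
        raise ConfigError(f"max_messages must be >= 1, got {max_messages}")
    fired = [rule for rule in rules if rule.fires(response)]
    if not fired:
        fallback = [e for e in abcd if e.sub_determinant == REINFORCEMENT]
        return [SelectedMessage(entry=e, rule=None) for e in fallback[:max_messages]]

    # for each behaviour, the highest-priority rule that fired
    best_rule: dict[Behaviour, TailoringRule] = {}
    for rule in fired:
        cur = best_rule.get(rule.behaviour)
        if cur is None or rule.priority > cur.priority:
            best_rule[rule.behaviour] = rule

    order = {b: i for i, b in enumerate(_BEHAVIOUR_ORDER)}
    candidates = [
        (e, i)
        for i, e in enumerate(abcd)
        if e.behaviour in best_rule and e.sub_determinant != REINFORCEMENT
    ]
    candidates.sort(
        key=lambda pair: (
            -best_rule[pair[0].behaviour].priority,
            -_factor_score(pair[0].behaviour, risk),
            order[pair[0].behaviour],
            pair[1],
        )
    )
    return [
        SelectedMessage(entry=e, rule=best_rule[e.behaviour])
        for e, _ in candidates[:max_messages]
    ]
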