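"""Score one respondent on the three risk factors and tailor messages.

The risk estimate splits into exposure risk (proximity / lack of isolation),
hygiene risk (lack of handwashing) and uncontrollable risk (demographics),
each 0-100 with a low/moderate/high category.  Messages come from the ABCD
table: rules over the reported answers decide which behaviours need
addressing, and each emitted message records the rule that selected it.
"""

from riskdet import (
    AgeBand,
    DistanceFrequency,
    Gender,
    HandwashSituation,
    HandwashThoroughness,
    IsolationBehaviour,
    IsolationTrigger,
    ResponseRecord,
    default_abcd,
    default_rules,
    default_weights,
    score_risk,
    select_messages,
)

respondent = ResponseRecord(
    respondent_id="demo",
    country="NL",
    age_band=AgeBand.AGE_60_69,
    gender=Gender.MALE,
    work_contexts=frozenset(),
    isolation_behaviours=frozenset(
        {IsolationBehaviour.VISIT_FRIENDS, IsolationBehaviour.OTHER_SHOPS_SERVICES}
    ),
    isolation_triggers=frozenset({IsolationTrigger.OWN_SYMPTOMS}),
    behaviours_would_stop=frozenset(),
    distance_frequency=DistanceFrequency.SOMETIMES,
    handwash_situations=frozenset({HandwashSituation.BEFORE_FOOD}),
    handwash_thoroughness=frozenset({HandwashThoroughness.SOAP_OR_SANITISER}),
)

estimate = score_risk(respondent, default_weights())
print("risk estimate (0-100 per factor):")
print(f"  exposure risk:       {estimate.exposure_risk:5.1f}  ({estimate.exposure_category.value})")
print(f"  hygiene risk:        {estimate.hygiene_risk:5.1f}  ({estimate.hygiene_category.value})")
print(f"  uncontrollable risk: {estimate.uncontrollable_risk:5.1f}  ({estimate.uncontrollable_category.value})")

messages = select_messages(respondent, estimate, default_abcd(), default_rules())
print(f"\ntailored messages ({len(messages)}, highest-need behaviour first):")
for m in messages:
    p = m.provenance()
    print(f"  [{p['behaviour']} / {p['sub_determinant']} via {p['rule_id']}]")
    print(f"    {p['application']}")
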