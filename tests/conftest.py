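import numpy as np
import pytest
from hypothesis import settings

from riskdet.survey import (
    AgeBand,
    IsolationTrigger,
    StopBehaviour,
    WorkContext,
    Behaviour,
    Construct,
    DistanceFrequency,
    Gender,
    HandwashSituation,
    HandwashThoroughness,
    IsolationBehaviour,
    ItemBank,
    ItemDefinition,
    ResponseRecord,
    default_item_bank,
)

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bank() -> ItemBank:
    return default_item_bank()


@pytest.fixture(scope="session")
def small_bank() -> ItemBank:
    """Five-item bank: convenient for planted-correlation simulations."""
    items = tuple(
        ItemDefinition(
            item_id=f"item_{i}",
            behaviour=Behaviour.SOCIAL_DISTANCING,
            construct=Construct.ATTITUDE,
            sub_determinant=f"facet_{i}",
            text=f"synthetic item {i}",
            scale_min=1,
            scale_max=7,
        )
        for i in range(5)
    )
    return ItemBank(items=items, version="test")


def make_response(
    respondent_id: str = "r0",
    distance: DistanceFrequency = DistanceFrequency.ALMOST_ALWAYS,
    work=frozenset(),
    isolation=frozenset({IsolationBehaviour.MOSTLY_HOME}),
    triggers=frozenset(),
    would_stop=frozenset(),
    situations=frozenset(
        {
            HandwashSituation.PUBLIC_SURFACES,
            HandwashSituation.ENTERING_BUILDING,
            HandwashSituation.BEFORE_FOOD,
            HandwashSituation.AFTER_CONTACT,
            HandwashSituation.AFTER_SNEEZE_COUGH,
            HandwashSituation.TOUCHING_FACE,
        }
    ),
    thoroughness=frozenset(
        {
            HandwashThoroughness.SOAP_OR_SANITISER,
            HandwashThoroughness.TWENTY_SECONDS,
            HandwashThoroughness.NAILS_AND_FINGERS,
        }
    ),
    n_items_opted: int = 0,
    scores: dict | None = None,
    age_band: AgeBand = AgeBand.AGE_30_39,
) -> ResponseRecord:
    """A maximally protective respondent unless overridden."""
    return ResponseRecord(
        respondent_id=respondent_id,
        country="NL",
        age_band=age_band,
        gender=Gender.FEMALE,
        work_contexts=frozenset(work),
        isolation_behaviours=frozenset(isolation),
        isolation_triggers=frozenset(triggers),
        behaviours_would_stop=frozenset(would_stop),
        distance_frequency=distance,
        handwash_situations=frozenset(situations),
        handwash_thoroughness=frozenset(thoroughness),
        n_items_opted=n_items_opted,
        determinant_scores=dict(scores or {}),
    )


def random_response(rng: np.random.Generator, respondent_id: str = "r0") -> ResponseRecord:
    """Uniformly random answers over every domain (no determinant scores)."""

    def subset(domain):
        return frozenset(m for m in domain if rng.random() < 0.5)

    return ResponseRecord(
        respondent_id=respondent_id,
        country="NL",
        age_band=rng.choice(list(AgeBand)),
        gender=rng.choice(list(Gender)),
        work_contexts=subset(list(WorkContext)),
        isolation_behaviours=subset(list(IsolationBehaviour)),
        isolation_triggers=subset(list(IsolationTrigger)),
        behaviours_would_stop=subset(list(StopBehaviour)),
        distance_frequency=rng.choice(list(DistanceFrequency)),
        handwash_situations=subset(list(HandwashSituation)),
        handwash_thoroughness=subset(list(HandwashThoroughness)),
        n_items_opted=int(rng.choice(range(0, 21, 2))),
    )
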