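"""Risk engine: aggregation oracle, categorisation, monotonicity, separation."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskdet.errors import ConfigError
from riskdet.risk import (
    RiskCategory,
    RiskWeights,
    categorize,
    default_weights,
    load_weights,
    score_risk,
    write_weights,
)
from riskdet.survey import (
    AgeBand,
    DistanceFrequency,
    HandwashSituation,
    HandwashThoroughness,
    IsolationBehaviour,
    IsolationTrigger,
    WorkContext,
)

from conftest import make_response, random_response


def uniform_toy_weights() -> RiskWeights:
    """Uniform weight 1 on a 4-answer exposure toy domain, no multipliers."""
    w = default_weights()
    return RiskWeights(
        work_weights={c: 0.0 for c in WorkContext},
        isolation_weights={
            IsolationBehaviour.FOOD_MEDICINE_HEALTHCARE: 1.0,
            IsolationBehaviour.OUTDOOR_EXERCISE: 1.0,
            IsolationBehaviour.VISIT_FAMILY: 1.0,
            IsolationBehaviour.VISIT_FRIENDS: 1.0,
            IsolationBehaviour.OTHER_SHOPS_SERVICES: 0.0,
            IsolationBehaviour.MOSTLY_HOME: 0.0,
        },
        distance_weights={d: 0.0 for d in DistanceFrequency},
        trigger_multipliers={t: 1.0 for t in IsolationTrigger},
        would_stop_multipliers={k: 1.0 for k in w.would_stop_multipliers},
        hygiene_missed_situations={},
        hygiene_missed_thoroughness={},
        hygiene_risk_answers={},
        age_weights=w.age_weights,
        gender_weights=w.gender_weights,
        exposure_scale_max=4.0,
        hygiene_scale_max=1.0,
        uncontrollable_scale_max=1.0,
    )


TOY_DOMAIN = (
    IsolationBehaviour.FOOD_MEDICINE_HEALTHCARE,
    IsolationBehaviour.OUTDOOR_EXERCISE,
    IsolationBehaviour.VISIT_FAMILY,
    IsolationBehaviour.VISIT_FRIENDS,
)


class TestScoreRisk:
    def test_uniform_weights_equal_fraction_of_risk_answers(self):
        """Exhaustive oracle over all 2^4 subsets of a 4-answer toy domain."""
        weights = uniform_toy_weights()
        for k in range(5):
            for subset in itertools.combinations(TOY_DOMAIN, k):
                rec = make_response(isolation=frozenset(subset))
                est = score_risk(rec, weights)
                assert est.exposure_risk == pytest.approx(100.0 * len(subset) / 4)

    def test_maximally_protective_respondent_scores_low(self):
        est = score_risk(make_response(age_band=AgeBand.UNDER_20), default_weights())
        assert est.exposure_risk == 0.0
        assert est.hygiene_risk == 0.0
        assert est.exposure_category is RiskCategory.LOW
        assert est.hygiene_category is RiskCategory.LOW

    def test_adding_visit_friends_never_decreases_exposure(self):
        base = make_response(isolation=frozenset({IsolationBehaviour.MOSTLY_HOME}))
        more = make_response(
            isolation=frozenset(
                {IsolationBehaviour.MOSTLY_HOME, IsolationBehaviour.VISIT_FRIENDS}
            )
        )
        weights = default_weights()
        assert (
            score_risk(more, weights).exposure_risk
            >= score_risk(base, weights).exposure_risk
        )

    def test_missing_weight_is_a_named_config_error(self):
        weights = uniform_toy_weights()
        del weights.isolation_weights[IsolationBehaviour.VISIT_FRIENDS]
        rec = make_response(isolation=frozenset({IsolationBehaviour.VISIT_FRIENDS}))
        with pytest.raises(ConfigError, match="visit_friends"):
            score_risk(rec, weights)

    @given(seed=st.integers(min_value=0, max_value=2**20))
    def test_monotonicity_under_any_added_risk_answer(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_response(rng)
        weights = default_weights()
        base = score_risk(rec, weights)
        # add one risk-conferring isolation answer
        for extra in (IsolationBehaviour.VISIT_FRIENDS, IsolationBehaviour.OTHER_SHOPS_SERVICES):
            if extra not in rec.isolation_behaviours:
                bumped = make_like(rec, isolation=rec.isolation_behaviours | {extra})
                assert score_risk(bumped, weights).exposure_risk >= base.exposure_risk
        # add one protective handwash answer
        for extra in (HandwashSituation.BEFORE_FOOD, HandwashSituation.PUBLIC_SURFACES):
            if extra not in rec.handwash_situations:
                bumped = make_like(rec, situations=rec.handwash_situations | {extra})
                assert score_risk(bumped, weights).hygiene_risk <= base.hygiene_risk
        # add one protective trigger (multiplier <= 1)
        if IsolationTrigger.OWN_SYMPTOMS not in rec.isolation_triggers:
            bumped = make_like(
                rec, triggers=rec.isolation_triggers | {IsolationTrigger.OWN_SYMPTOMS}
            )
            assert score_risk(bumped, weights).exposure_risk <= base.exposure_risk

    @given(seed=st.integers(min_value=0, max_value=2**20))
    def test_factor_separation(self, seed):
        """Handwashing only moves hygiene; isolation only exposure; age only uncontrollable."""
        rng = np.random.default_rng(seed)
        rec = random_response(rng)
        weights = default_weights()
        base = score_risk(rec, weights)

        flipped_wash = make_like(
            rec,
            situations=rec.handwash_situations ^ {HandwashSituation.AFTER_CONTACT},
            thoroughness=rec.handwash_thoroughness ^ {HandwashThoroughness.TWENTY_SECONDS},
        )
        est = score_risk(flipped_wash, weights)
        assert est.exposure_risk == base.exposure_risk
        assert est.uncontrollable_risk == base.uncontrollable_risk

        flipped_iso = make_like(
            rec,
            isolation=rec.isolation_behaviours ^ {IsolationBehaviour.VISIT_FAMILY},
            work=rec.work_contexts ^ {WorkContext.GENERAL_PUBLIC},
        )
        est = score_risk(flipped_iso, weights)
        assert est.hygiene_risk == base.hygiene_risk
        assert est.uncontrollable_risk == base.uncontrollable_risk

        older = make_like(rec, age_band=AgeBand.AGE_70_PLUS)
        est = score_risk(older, weights)
        assert est.exposure_risk == base.exposure_risk
        assert est.hygiene_risk == base.hygiene_risk

    def test_weights_roundtrip_through_json(self, tmp_path):
        weights = default_weights()
        path = tmp_path / "weights.json"
        write_weights(weights, path)
        assert load_weights(path) == weights


_FIELD_ALIASES = {
    "work": "work_contexts",
    "isolation": "isolation_behaviours",
    "triggers": "isolation_triggers",
    "would_stop": "behaviours_would_stop",
    "distance": "distance_frequency",
    "situations": "handwash_situations",
    "thoroughness": "handwash_thoroughness",
}


def make_like(rec, **overrides):
    """Copy a record with replaced answer fields (keeps the rest)."""
    import dataclasses

    kwargs = {_FIELD_ALIASES.get(k, k): v for k, v in overrides.items()}
    return dataclasses.replace(rec, **kwargs)


class TestCategorize:
    @pytest.mark.parametrize(
        "score,expected",
        [
            (0.0, RiskCategory.LOW),
            (32.999, RiskCategory.LOW),
            (33.0, RiskCategory.MODERATE),
            (65.999, RiskCategory.MODERATE),
            (66.0, RiskCategory.HIGH),
            (100.0, RiskCategory.HIGH),
        ],
    )
    def test_boundaries_lower_inclusive(self, score, expected):
        assert categorize(score, (33.0, 66.0)) is expected

    @given(
        score=st.floats(min_value=0, max_value=100, allow_nan=False),
        cuts=st.lists(
            st.floats(min_value=1, max_value=99), min_size=1, max_size=4, unique=True
        ),
    )
    def test_matches_linear_scan_oracle(self, score, cuts):
        cuts = tuple(sorted(cuts))
        # oracle: walk the cut list counting how many cuts the score reached
        reached = sum(score >= c for c in cuts)
        if reached == 0:
            expected = RiskCategory.LOW
        elif reached == len(cuts):
            expected = RiskCategory.HIGH
        else:
            expected = RiskCategory.MODERATE
        assert categorize(score, cuts) is expected

    def test_non_monotone_cuts_rejected(self):
        with pytest.raises(ConfigError):
            categorize(50.0, (66.0, 33.0))
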