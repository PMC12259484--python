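"""Synthetic respondent cohorts with known (planted) structure.

The generator realises the statistical structure the analysis modules assume,
so every pipeline stage is testable without any external download:

* A latent standard-normal "distance-keeping propensity" per respondent drives
  both the ordinal behaviour measure and the determinant items.  Each item's
  latent score is ``rho * z_behaviour + sqrt(1 - rho^2) * noise`` (a Gaussian
  copula), then shifted/scaled to the item's Likert scale and rounded — so the
  *planted* latent correlation ``rho`` appears in the data attenuated by
  discretisation.  The truth record therefore stores both the latent rho and
  the implied *manifest* correlation (estimated once by seeded Monte Carlo),
  which is the value recovery checks should cover.
* Planned missingness: each respondent opts in for an even number of items
  (0–20) and answers a uniformly random without-replacement subset of that
  size — missingness independent of scores, hence ignorable.
* Marginals default to the answer prevalences observed in the deployed tool's
  pooled sample (e.g. 61.5% keeping distance "(almost) always", 3.5% never in
  public, 91.1% using soap/sanitiser), and funnel strata default to the
  observed bounce/abandon/complete proportions.

What the simulator does *not* emulate: country-level heterogeneity, temporal
usage spikes, and dependence between the multi-select risk answers (drawn as
independent Bernoulli per option) or between those answers and the determinant
items.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats as _st

from .errors import ConfigError
from .survey import (
    AgeBand,
    DistanceFrequency,
    FunnelCounts,
    Gender,
    HandwashSituation,
    HandwashThoroughness,
    IsolationBehaviour,
    IsolationTrigger,
    ItemBank,
    ResponseRecord,
    StopBehaviour,
    WorkContext,
)

_PROB_TOL = 1e-9

# Pooled answer prevalences observed in the deployed tool (fractions).  The
# split of the jointly reported "working from home or not working" (63.1%) and
# of the pooled youngest/oldest age bands, and the co-worker-contact rate, are
# not reported separately and are fixed here once as plausible values.
DEFAULT_ANSWER_PREVALENCES: dict[str, dict[str, float]] = {
    "work_contexts": {
        WorkContext.PATIENTS_VULNERABLE.value: 0.067,
        WorkContext.CHILDREN.value: 0.061,
        WorkContext.COWORKERS.value: 0.25,
        WorkContext.GENERAL_PUBLIC.value: 0.282,
        WorkContext.FROM_HOME.value: 0.40,
        WorkContext.NOT_WORKING.value: 0.231,
    },
    "isolation_behaviours": {
        IsolationBehaviour.FOOD_MEDICINE_HEALTHCARE.value: 0.758,
        IsolationBehaviour.OUTDOOR_EXERCISE.value: 0.701,
        IsolationBehaviour.OTHER_SHOPS_SERVICES.value: 0.522,
        IsolationBehaviour.MOSTLY_HOME.value: 0.451,
        IsolationBehaviour.VISIT_FAMILY.value: 0.359,
        IsolationBehaviour.VISIT_FRIENDS.value: 0.271,
    },
    "isolation_triggers": {
        IsolationTrigger.OWN_SYMPTOMS.value: 0.854,
        IsolationTrigger.CONTACT_WITH_SICK.value: 0.733,
        IsolationTrigger.GOVERNMENT_RESTRICTIONS.value: 0.658,
        IsolationTrigger.NEVER.value: 0.044,
        IsolationTrigger.OTHER.value: 0.004,
    },
    "behaviours_would_stop": {
        StopBehaviour.OTHER_SHOPS_SERVICES.value: 0.434,
        StopBehaviour.FOOD_MEDICINE_HEALTHCARE.value: 0.406,
        StopBehaviour.OUTDOOR_EXERCISE.value: 0.346,
        StopBehaviour.VISIT_FAMILY.value: 0.319,
        StopBehaviour.VISIT_FRIENDS.value: 0.25,
        StopBehaviour.MOSTLY_HOME.value: 0.0,
        StopBehaviour.OTHER.value: 0.032,
    },
    "handwash_situations": {
        HandwashSituation.PUBLIC_SURFACES.value: 0.834,
        HandwashSituation.ENTERING_BUILDING.value: 0.774,
        HandwashSituation.BEFORE_FOOD.value: 0.766,
        HandwashSituation.AFTER_CONTACT.value: 0.652,
        HandwashSituation.AFTER_SNEEZE_COUGH.value: 0.41,
        HandwashSituation.TOUCHING_FACE.value: 0.289,
        HandwashSituation.NEVER_OR_OCCASIONALLY.value: 0.039,
    },
    "handwash_thoroughness": {
        HandwashThoroughness.SOAP_OR_SANITISER.value: 0.911,
        HandwashThoroughness.TWENTY_SECONDS.value: 0.698,
        HandwashThoroughness.NAILS_AND_FINGERS.value: 0.47,
        HandwashThoroughness.NONE_OF_ABOVE.value: 0.012,
    },
}

#: Distance-keeping marginal over the 5 ordinal levels plus never-in-public.
DEFAULT_BEHAVIOUR_MARGINAL: dict[str, float] = {
    DistanceFrequency.ALMOST_NEVER.value: 0.009,
    DistanceFrequency.RARELY.value: 0.019,
    DistanceFrequency.SOMETIMES.value: 0.087,
    DistanceFrequency.OFTEN.value: 0.236,
    DistanceFrequency.ALMOST_ALWAYS.value: 0.615,
    DistanceFrequency.NEVER_IN_PUBLIC.value: 0.035,
}

DEFAULT_AGE_MARGINAL: dict[str, float] = {
    AgeBand.UNDER_20.value: 0.0445,
    AgeBand.AGE_20_29.value: 0.176,
    AgeBand.AGE_30_39.value: 0.195,
    AgeBand.AGE_40_49.value: 0.201,
    AgeBand.AGE_50_59.value: 0.194,
    AgeBand.AGE_60_69.value: 0.143,
    AgeBand.AGE_70_PLUS.value: 0.0445,
    AgeBand.DECLINED.value: 0.001,
}

DEFAULT_GENDER_MARGINAL: dict[str, float] = {
    Gender.FEMALE.value: 0.541,
    Gender.MALE.value: 0.452,
    Gender.NONBINARY_OR_SELF_SPECIFIED.value: 0.0031,
    Gender.DECLINED.value: 0.0039,
}

# Completer counts by country in the deployed tool; remainder pooled under the
# ISO-3166 user-assigned code ZZ.
_COUNTRY_COMPLETERS: dict[str, int] = {
    "NL": 15376, "NZ": 14615, "BE": 7052, "GB": 6978, "RO": 6187, "US": 2998,
    "IT": 2240, "BR": 1415, "TR": 1137, "IE": 587, "AU": 523, "ID": 440,
    "DE": 385, "FR": 340, "CA": 323, "ES": 281, "IN": 251, "CY": 201,
    "PT": 117, "CH": 112, "MX": 109, "CN": 104, "PK": 101,
}
_TOTAL_COMPLETED = 63_850
DEFAULT_COUNTRY_MARGINAL: dict[str, float] = {
    **{c: n / _TOTAL_COMPLETED for c, n in _COUNTRY_COMPLETERS.items()},
    "ZZ": (_TOTAL_COMPLETED - sum(_COUNTRY_COMPLETERS.values())) / _TOTAL_COMPLETED,
}

#: Opt-in distribution over 0, 2, ..., 20 items (not reported; fixed choice:
#: a quarter decline, a visible mode at the maximum among the willing).
DEFAULT_OPT_IN: dict[int, float] = {
    0: 0.25, 2: 0.10, 4: 0.10, 6: 0.08, 8: 0.07,
    10: 0.10, 12: 0.05, 14: 0.05, 16: 0.05, 18: 0.05, 20: 0.10,
}

#: Funnel strata proportions observed in the deployed tool.
DEFAULT_DROPOUT: dict[str, float] = {
    "first_page_only": 27_424 / 102_909,
    "started_not_completed": 11_635 / 102_909,
    "completed": 63_850 / 102_909,
}


def _normalise(table: dict) -> dict:
    total = sum(table.values())
    return {k: v / total for k, v in table.items()}


# the published percentages carry rounding error (e.g. the distance marginal
# prints to 100.1%); renormalise so the probability invariant holds exactly
DEFAULT_BEHAVIOUR_MARGINAL = _normalise(DEFAULT_BEHAVIOUR_MARGINAL)
DEFAULT_AGE_MARGINAL = _normalise(DEFAULT_AGE_MARGINAL)
DEFAULT_GENDER_MARGINAL = _normalise(DEFAULT_GENDER_MARGINAL)
DEFAULT_COUNTRY_MARGINAL = _normalise(DEFAULT_COUNTRY_MARGINAL)
DEFAULT_OPT_IN = _normalise(DEFAULT_OPT_IN)
DEFAULT_DROPOUT = _normalise(DEFAULT_DROPOUT)

DEFAULT_ITEM_MEAN_SD = (4.5, 1.5)


def _check_probs(name: str, probs: dict) -> None:
    total = float(sum(probs.values()))
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigError(f"{name} probabilities must sum to 1, got {total!r}")
    if any(p < 0 for p in probs.values()):
        raise ConfigError(f"{name} probabilities must be non-negative")


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    ``n_respondents`` counts *completed* records (the ones generated); the two
    drop-out strata of the funnel are derived from ``dropout`` proportions.
    ``planted_r`` maps item ids to latent correlations with the behaviour
    propensity; unlisted items default to 0.  ``item_mean_sd`` gives the
    latent location/scale on each item's own response scale.
    """

    n_respondents: int = 1000
    seed: int = 0
    planted_r: dict[str, float] = field(default_factory=dict)
    item_mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    behaviour_marginal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOUR_MARGINAL)
    )
    opt_in_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OPT_IN)
    )
    answer_prevalences: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_ANSWER_PREVALENCES.items()}
    )
    age_marginal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AGE_MARGINAL)
    )
    gender_marginal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENDER_MARGINAL)
    )
    country_marginal: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_MARGINAL)
    )
    dropout: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))

    def __post_init__(self) -> None:
        if self.n_respondents < 0:
            raise ConfigError(f"n_respondents must be >= 0, got {self.n_respondents}")
        for iid, rho in self.planted_r.items():
            if not (-1 < rho < 1):
                raise ConfigError(f"planted_r[{iid!r}] = {rho} must be in (-1, 1)")
        _check_probs("behaviour_marginal", self.behaviour_marginal)
        _check_probs("opt_in_distribution", self.opt_in_distribution)
        _check_probs("age_marginal", self.age_marginal)
        _check_probs("gender_marginal", self.gender_marginal)
        _check_probs("country_marginal", self.country_marginal)
        _check_probs("dropout", self.dropout)
        for k in self.opt_in_distribution:
            if k not in range(0, 21, 2):
                raise ConfigError(f"opt_in_distribution key {k} must be even in [0,20]")
        for p in (prob for table in self.answer_prevalences.values() for prob in table.values()):
            if not (0 <= p <= 1):
                raise ConfigError(f"answer prevalence {p} outside [0,1]")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ConfigError(f"simulation config {path}: invalid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise ConfigError(f"simulation config {path}: top level must be an object")
    kwargs = {}
    simple = {
        "n_respondents", "seed", "planted_r", "behaviour_marginal",
        "answer_prevalences", "age_marginal", "gender_marginal",
        "country_marginal", "dropout",
    }
    try:
        for key, value in payload.items():
            if key in simple:
                kwargs[key] = value
            elif key == "opt_in_distribution":
                kwargs[key] = {int(k): float(v) for k, v in value.items()}
            elif key == "item_mean_sd":
                kwargs[key] = {k: (float(v[0]), float(v[1])) for k, v in value.items()}
            else:
                raise ConfigError(f"simulation config {path}: unknown key {key!r}")
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError, AttributeError) as exc:
        raise ConfigError(f"simulation config {path}: {exc}") from exc


# --------------------------------------------------------------------------- #
# Generation
# --------------------------------------------------------------------------- #

def _categorical(rng, codes: list, probs: list[float], size: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    return rng.choice(np.asarray(codes, dtype=object), size=size, p=p / p.sum())


def _distance_thresholds(marginal: dict[str, float]) -> tuple[float, np.ndarray]:
    """(P(never in public), z-thresholds for the 5 conditional levels)."""
    p_nip = marginal.get(DistanceFrequency.NEVER_IN_PUBLIC.value, 0.0)
    levels = [
        DistanceFrequency.ALMOST_NEVER, DistanceFrequency.RARELY,
        DistanceFrequency.SOMETIMES, DistanceFrequency.OFTEN,
        DistanceFrequency.ALMOST_ALWAYS,
    ]
    cond = np.array([marginal.get(l.value, 0.0) for l in levels], dtype=float)
    if cond.sum() <= 0:
        raise ConfigError("behaviour_marginal must give positive mass to the 5 levels")
    cond = cond / cond.sum()
    cum = np.cumsum(cond)[:-1]
    return p_nip, _st.norm.ppf(cum)


_DISTANCE_LEVELS = (
    DistanceFrequency.ALMOST_NEVER, DistanceFrequency.RARELY,
    DistanceFrequency.SOMETIMES, DistanceFrequency.OFTEN,
    DistanceFrequency.ALMOST_ALWAYS,
)


def simulate_cohort(
    config: SimulationConfig,
    bank: ItemBank,
    compute_manifest: bool = True,
) -> tuple[list[ResponseRecord], FunnelCounts, dict]:
    """Generate a cohort of completed respondents plus funnel counts and truth.

    Returns ``(records, funnel, truth)`` where ``truth`` holds every planted
    parameter, including the Monte Carlo estimate of each planted item's
    manifest (post-discretisation) correlation.  Identical config (including
    seed) reproduces the cohort bit-for-bit.
    """
    for iid in config.planted_r:
        if iid not in bank:
            raise ConfigError(f"planted_r references unknown item {iid!r}")
    for iid in config.item_mean_sd:
        if iid not in bank:
            raise ConfigError(f"item_mean_sd references unknown item {iid!r}")

    rng = np.random.default_rng(config.seed)
    n = config.n_respondents

    # --- behaviour: latent propensity -> ordinal distance answer
    z_b = rng.standard_normal(n)
    p_nip, thresholds = _distance_thresholds(config.behaviour_marginal)
    never_in_public = rng.random(n) < p_nip
    level_idx = np.searchsorted(thresholds, z_b)  # 0..4

    # --- demographics and multi-select answers (independent of z_b)
    ages = _categorical(rng, list(config.age_marginal), list(config.age_marginal.values()), n)
    genders = _categorical(
        rng, list(config.gender_marginal), list(config.gender_marginal.values()), n
    )
    countries = _categorical(
        rng, list(config.country_marginal), list(config.country_marginal.values()), n
    )
    multi_draws: dict[str, dict[str, np.ndarray]] = {}
    for fieldname, prevalences in config.answer_prevalences.items():
        multi_draws[fieldname] = {
            code: rng.random(n) < p for code, p in prevalences.items()
        }

    # --- planned missingness: opt-in sizes and random item subsets
    opt_sizes = _categorical(
        rng, list(config.opt_in_distribution),
        list(config.opt_in_distribution.values()), n,
    ).astype(int)
    item_ids = np.array(bank.item_ids, dtype=object)
    takers: dict[str, list[int]] = {}
    subset_of: list[np.ndarray] = []
    for i in range(n):
        k = min(int(opt_sizes[i]), len(item_ids))
        subset = rng.choice(item_ids, size=k, replace=False) if k else np.empty(0, object)
        subset_of.append(subset)
        for iid in subset:
            takers.setdefault(iid, []).append(i)

    # --- determinant scores: Gaussian copula against z_b, discretised
    scores_by_resp: list[dict[str, int]] = [dict() for _ in range(n)]
    for iid, resp_idx in takers.items():
        item = bank[iid]
        rho = config.planted_r.get(iid, 0.0)
        mean, sd = config.item_mean_sd.get(iid, DEFAULT_ITEM_MEAN_SD)
        idx = np.asarray(resp_idx)
        eps = rng.standard_normal(idx.size)
        latent = rho * z_b[idx] + np.sqrt(1.0 - rho * rho) * eps
        raw = np.rint(mean + sd * latent)
        vals = np.clip(raw, item.scale_min, item.scale_max).astype(int)
        for i, v in zip(idx, vals):
            scores_by_resp[i][iid] = int(v)

    # --- assemble records
    records: list[ResponseRecord] = []
    ms = multi_draws

    def picks(fieldname: str, domain, i: int) -> frozenset:
        table = ms.get(fieldname, {})
        return frozenset(domain(code) for code, mask in table.items() if mask[i])

    for i in range(n):
        distance = (
            DistanceFrequency.NEVER_IN_PUBLIC
            if never_in_public[i]
            else _DISTANCE_LEVELS[level_idx[i]]
        )
        records.append(
            ResponseRecord(
                respondent_id=f"r{i:06d}",
                country=str(countries[i]),
                age_band=AgeBand(ages[i]),
                gender=Gender(genders[i]),
                work_contexts=picks("work_contexts", WorkContext, i),
                isolation_behaviours=picks("isolation_behaviours", IsolationBehaviour, i),
                isolation_triggers=picks("isolation_triggers", IsolationTrigger, i),
                behaviours_would_stop=picks("behaviours_would_stop", StopBehaviour, i),
                distance_frequency=distance,
                handwash_situations=picks("handwash_situations", HandwashSituation, i),
                handwash_thoroughness=picks("handwash_thoroughness", HandwashThoroughness, i),
                n_items_opted=int(opt_sizes[i]),
                determinant_scores=scores_by_resp[i],
            )
        )

    funnel = _derive_funnel(n, config.dropout)
    truth = {
        "seed": config.seed,
        "n_respondents": n,
        "planted_r": dict(config.planted_r),
        "manifest_r": (
            _manifest_correlations(config, bank) if compute_manifest else None
        ),
        "item_mean_sd": {
            iid: list(config.item_mean_sd.get(iid, DEFAULT_ITEM_MEAN_SD))
            for iid in config.planted_r
        },
        "behaviour_marginal": dict(config.behaviour_marginal),
    }
    return records, funnel, truth


def _derive_funnel(n_completed: int, dropout: dict[str, float]) -> FunnelCounts:
    p_c = dropout.get("completed", 0.0)
    if n_completed > 0 and p_c <= 0:
        raise ConfigError("dropout['completed'] must be positive when n_respondents > 0")
    if n_completed == 0:
        return FunnelCounts(0, 0, 0, 0)
    fp = round(n_completed * dropout.get("first_page_only", 0.0) / p_c)
    snc = round(n_completed * dropout.get("started_not_completed", 0.0) / p_c)
    return FunnelCounts(
        total_opened=fp + snc + n_completed,
        opened_first_page_only=fp,
        started_not_completed=snc,
        completed=n_completed,
    )


def _manifest_correlations(
    config: SimulationConfig, bank: ItemBank, n_mc: int = 200_000
) -> dict[str, float]:
    """Monte Carlo estimate of each planted item's post-discretisation r.

    Uses a seed derived from the config seed, so the truth record is itself
    reproducible.  Items with rho = 0 are exactly 0 by symmetry.
    """
    out: dict[str, float] = {}
    _, thresholds = _distance_thresholds(config.behaviour_marginal)
    rng = np.random.default_rng([config.seed % (2**31), 9173])
    z = rng.standard_normal(n_mc)
    y = np.searchsorted(thresholds, z).astype(float) + 1.0
    for iid, rho in config.planted_r.items():
        if rho == 0.0:
            out[iid] = 0.0
            continue
        item = bank[iid]
        mean, sd = config.item_mean_sd.get(iid, DEFAULT_ITEM_MEAN_SD)
        eps = rng.standard_normal(n_mc)
        latent = rho * z + np.sqrt(1.0 - rho * rho) * eps
        x = np.clip(np.rint(mean + sd * latent), item.scale_min, item.scale_max)
        out[iid] = float(np.corrcoef(x, y)[0, 1])
    return out


# --------------------------------------------------------------------------- #
# Recoverability
# --------------------------------------------------------------------------- #

@dataclass
class RecoverabilityReport:
    """Planted vs estimated correlations plus PΔ2 rank agreement."""

    table: "pd.DataFrame"
    kendall_tau: float | None  # None when fewer than 2 comparable items


def recoverability_report(
    responses: list[ResponseRecord],
    truth: dict,
    bank: ItemBank,
    min_pairs: int = 10,
) -> RecoverabilityReport:
    """Compare planted parameters with what the analysis recovers.

    For every planted item: latent rho, manifest rho, the estimated r with its
    95% CI, and whether the CI covers the manifest value (the discretised data
    cannot be expected to recover the latent rho — attenuation is part of the
    generative model).  ``kendall_tau`` measures rank agreement between the
    planted latent correlations and the PΔ2 ranking.
    """
    import pandas as pd

    from .ciber import ciber_table

    results = ciber_table(responses, bank, min_pairs=min_pairs)
    est = results.summaries.set_index("item_id")
    manifest = truth.get("manifest_r") or {}
    rows = []
    for iid, rho in truth.get("planted_r", {}).items():
        if iid in est.index:
            row = est.loc[iid]
            target = manifest.get(iid, rho)
            rows.append(
                {
                    "item_id": iid,
                    "planted_r": rho,
                    "manifest_r": manifest.get(iid),
                    "estimated_r": float(row["r"]),
                    "r_ci_low": float(row["r_ci_low"]),
                    "r_ci_high": float(row["r_ci_high"]),
                    "n_pairs": int(row["n_pairs"]),
                    "ci_covers_truth": bool(
                        row["r_ci_low"] <= target <= row["r_ci_high"]
                    ),
                    "pdelta2": float(row["pdelta2"]),
                }
            )
        else:
            rows.append(
                {
                    "item_id": iid, "planted_r": rho,
                    "manifest_r": manifest.get(iid), "estimated_r": np.nan,
                    "r_ci_low": np.nan, "r_ci_high": np.nan, "n_pairs": 0,
                    "ci_covers_truth": False, "pdelta2": np.nan,
                }
            )
    table = pd.DataFrame(rows)
    usable = table.dropna(subset=["estimated_r"])
    if len(usable) >= 2 and usable["planted_r"].nunique() > 1:
        tau = float(
            _st.kendalltau(usable["planted_r"], usable["pdelta2"]).statistic
        )
    else:
        tau = None
    return RecoverabilityReport(table=table, kendall_tau=tau)
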