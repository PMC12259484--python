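"""Generate a synthetic respondent cohort and inspect the usage funnel.

The generator reproduces the answer-prevalence structure of the deployed
tool's pooled sample (distance-keeping marginal, handwashing rates, funnel
proportions) with planned missingness on the determinant items.
"""

from riskdet import SimulationConfig, default_item_bank, funnel_stats, simulate_cohort

bank = default_item_bank()
config = SimulationConfig(n_respondents=500, seed=42)
records, funnel, truth = simulate_cohort(config, bank)

print(f"item bank:            {len(bank)} determinant items")
print(f"completed respondents: {funnel.completed}")
print(f"bounced on first page: {funnel.opened_first_page_only}")
print(f"started, not finished: {funnel.started_not_completed}")
print(f"drop-out rate:         {funnel_stats(funnel):.1f}%  "
      "(abandoners among those who got past page 1)")

first = records[0]
print(f"\nexample respondent {first.respondent_id} ({first.country}):")
print(f"  distance keeping: {first.distance_frequency.value}")
print(f"  opted in for {first.n_items_opted} determinant items, "
      f"answered {len(first.determinant_scores)}")
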