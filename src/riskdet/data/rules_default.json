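[
  {
    "rule_id": "hw_never_washes",
    "behaviour": "hand_washing",
    "trigger": {"field": "handwash_situations", "op": "contains", "value": "never_or_occasionally"},
    "priority": 10
  },
  {
    "rule_id": "hw_no_thoroughness",
    "behaviour": "hand_washing",
    "trigger": {"field": "handwash_thoroughness", "op": "contains", "value": "none_of_above"},
    "priority": 9
  },
  {
    "rule_id": "hw_misses_before_food",
    "behaviour": "hand_washing",
    "trigger": {"field": "handwash_situations", "op": "not_contains", "value": "before_food"},
    "priority": 6
  },
  {
    "rule_id": "hw_misses_public_surfaces",
    "behaviour": "hand_washing",
    "trigger": {"field": "handwash_situations", "op": "not_contains", "value": "public_surfaces"},
    "priority": 5
  },
  {
    "rule_id": "sd_low_distance",
    "behaviour": "social_distancing",
    "trigger": {"field": "distance_frequency", "op": "in", "value": ["almost_never", "rarely", "sometimes"]},
    "priority": 10
  },
  {
    "rule_id": "sd_distance_often",
    "behaviour": "social_distancing",
    "trigger": {"field": "distance_frequency", "op": "eq", "value": "often"},
    "priority": 4
  },
  {
    "rule_id": "si_would_never_isolate",
    "behaviour": "self_isolation",
    "trigger": {"field": "isolation_triggers", "op": "contains", "value": "never"},
    "priority": 9
  },
  {
    "rule_id": "si_visits_friends",
    "behaviour": "self_isolation",
    "trigger": {"field": "isolation_behaviours", "op": "contains", "value": "visit_friends"},
    "priority": 7
  },
  {
    "rule_id": "si_visits_family",
    "behaviour": "self_isolation",
    "trigger": {"field": "isolation_behaviours", "op": "contains", "value": "visit_family"},
    "priority": 6
  },
  {
    "rule_id": "si_nonessential_shops",
    "behaviour": "self_isolation",
    "trigger": {"field": "isolation_behaviours", "op": "contains", "value": "other_shops_services"},
    "priority": 5
  }
]
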