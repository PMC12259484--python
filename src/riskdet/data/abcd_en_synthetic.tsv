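behaviour	sub_behaviour	determinant	sub_determinant	bcp	conditions_for_effectiveness	application	locale
social_distancing	keep_1_5m_distance	attitude	perceived_effectiveness	persuasive_communication	arguments are relevant and from a credible source	Keeping 1.5 metres of distance sharply reduces the chance that droplets from another person reach you. It is one of the most effective things you can do.	en
social_distancing	keep_1_5m_distance	attitude	perceived_personal_risk	risk_communication	risk information is personally relevant and paired with an efficacious action	Even people who feel healthy can carry and transmit the virus. Keeping your distance protects you and the people around you.	en
social_distancing	keep_1_5m_distance	perceived_norm	descriptive_neighbourhood	social_comparison	reference group is credible and similar to the person	Most people in your community are keeping their distance in shops and on the street. Joining them keeps everyone safer.	en
social_distancing	keep_1_5m_distance	perceived_norm	injunctive_family	mobilising_social_support	support is wanted and the supporters are valued	Your family and friends expect you to keep a safe distance so that you can keep visiting each other safely in the future.	en
social_distancing	keep_1_5m_distance	perceived_behavioural_control	self_efficacy_social_situations	guided_practice	practice opportunities are realistic and feedback is specific	Plan how you will step back politely when someone comes too close. Having a phrase ready makes it much easier to keep distance in conversations.	en
social_distancing	keep_1_5m_distance	perceived_behavioural_control	capacity_to_plan	planning_coping_responses	barriers are identified by the person themselves	Shop at quiet hours and choose wider streets where you can. Planning around crowds makes distance keeping almost automatic.	en
self_isolation	stay_at_home	attitude	outcome_for_others	anticipated_regret	outcomes are concrete and affectively charged	Every trip you skip removes a chance for the virus to reach someone vulnerable. Staying home is a gift to the people you never meet.	en
self_isolation	stay_at_home	attitude	perceived_necessity	persuasive_communication	arguments are relevant and from a credible source	Essential trips only: groceries, medicine, care. Each avoided errand measurably lowers your exposure.	en
self_isolation	reduce_visits	perceived_norm	injunctive_government	information_about_others_approval	the norm message is not contested by visible counter-examples	Current guidance asks everyone to limit visits to family and friends. Video calls keep you close without contact.	en
self_isolation	reduce_visits	perceived_norm	identification_with_compliers	modelling	model is similar to the person and reinforced for the behaviour	People like you are postponing visits and meeting outdoors at a distance instead. It works, and it keeps everyone out of risk.	en
self_isolation	stay_at_home	perceived_behavioural_control	habit_strength	counter_conditioning	alternative behaviour satisfies the same need	Replace the shopping trip with a delivery slot and the cafe visit with a walk-and-call. New routines form in a couple of weeks.	en
self_isolation	stay_at_home	perceived_behavioural_control	capacity_to_plan	goal_setting	goals are specific, proximal and self-chosen	Decide today which trips this week are truly necessary and cross out the rest. A written plan halves impulsive outings.	en
hand_washing	wash_hands_regularly	attitude	expected_health_benefit	persuasive_communication	arguments are relevant and from a credible source	Washing your hands removes the virus before it can reach your mouth, nose or eyes. Twenty seconds with soap breaks the virus apart.	en
hand_washing	wash_hands_regularly	attitude	perceived_inconvenience	reframing	the reframe is plausible to the person	Twenty seconds is shorter than it feels: hum a chorus you like. Make it a micro-break rather than a chore.	en
hand_washing	wash_hands_regularly	perceived_norm	descriptive_country	information_about_others_behaviour	the described norm is factually true	Nine out of ten people now use soap or sanitiser routinely. Washing your hands is simply what people do.	en
hand_washing	wash_hands_thoroughly	perceived_behavioural_control	skills_knowledge	instruction	instructions are clear and demonstrated	Wet, lather, scrub for 20 seconds including nails and between fingers, rinse, dry. Thoroughness is what removes the virus.	en
hand_washing	wash_hands_regularly	perceived_behavioural_control	habit_strength	cue_altering	the cue reliably precedes the behaviour	Link washing to fixed moments: entering home, before food, after public transport. A fixed cue builds the habit for you.	en
social_distancing	keep_1_5m_distance	attitude	reinforcement	positive_reinforcement	reinforcement follows the behaviour promptly	You already keep your distance nearly all the time. Well done - keep it up, it is protecting people around you.	en
self_isolation	stay_at_home	attitude	reinforcement	positive_reinforcement	reinforcement follows the behaviour promptly	You are already limiting your trips to what is essential. That discipline is exactly what slows the virus down.	en
hand_washing	wash_hands_regularly	attitude	reinforcement	positive_reinforcement	reinforcement follows the behaviour promptly	Your handwashing routine is already thorough. Keep washing at the key moments - it keeps working as long as you do.	en
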