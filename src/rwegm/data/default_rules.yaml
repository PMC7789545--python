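# Default rule configuration for seven-topic sentence classification.
# Words are in normalized (lowercase, lemmatized) form.  The shipped lexicon
# is seeded from high-PMI indicator words and is meant to be extended per
# corpus via a custom YAML file.
proximity_window: 5
negation_window: 3
priority_order: [VUS, Positive, Negative, Insurance, Order, Evaluation, Information]
indicator_words:
  Information: [guideline, panel, pathway, information, education, implication, brochure, inhibitor]
  Evaluation: [risk, family, history, hereditary, relative, carrier, carry, estimate, benefit, counsel]
  Insurance: [insurance, coverage, copay, authorization, denial]
  Order: [order, await, wait, pend, schedule, specimen]
conditional_indicators:
  Evaluation: [mother, sister, aunt, maternal, paternal]
  Information: [literature, pamphlet]
positivity_indicators: [positive, pathogenic, mutate, deleterious, actionable]
negativity_indicators: [negative, wildtype, unremarkable]
vus_indicators: [vus, "unknown significance", "uncertain significance"]
# "no" must be quoted: bare `no` is YAML-1.1 boolean False
negation_cues: ["no", "not", "without"]
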