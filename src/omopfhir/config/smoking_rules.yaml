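# Ordered first-match rule table collapsing concatenated smoking-survey
# responses onto one of six smoking-status categories.  Each rule lists the
# (question, answer) pairs that must all be present; the first matching rule
# wins.  Categories are translated to SNOMED codes through the
# "smoking-status" ConceptMap, whose element count is asserted to be 6 at
# pipeline start.
rules:
  - when: {TobaccoUse: "No"}
    category: never
  - when: {TobaccoUse: "Quit"}
    category: former
  - when: {TobaccoUse: "Yes", Cigarettes: "Yes"}
    category: current-every-day
  - when: {TobaccoUse: "Yes", Cigarettes: "Some days"}
    category: current-some-day
  - when: {TobaccoUse: "Yes"}
    category: current-status-unknown
  - when: {Cigarettes: "Yes"}
    category: current-every-day
  - when: {TobaccoUseInYears: "0"}
    category: never
default_category: unknown-if-ever
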