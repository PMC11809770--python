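# CLCF-SF (Challenge of Living with Cystic Fibrosis, short form) definition.
#
# RECONSTRUCTED FIXTURE: item wording below is a synthetic paraphrase, not the
# published questionnaire text.  The structural fields are as published:
# 15 items, five core (three expert-chosen challenge items plus the two
# perceived-support items in positions 6 and 7), thirteen 5-point and two
# 4-point response scales, all scored from 1, so totals span 15..73.
# ASSUMPTION: the two 4-point items are not identified in the available text;
# this fixture flags the two perceived-support items (sf06, sf07) as 4-point.
name: CLCF-SF
items:
  - id: sf01
    text: "How well do you feel you are juggling the demands of CF alongside the needs of the rest of your family?"
    domain: "Maintaining CF routines"
    n_categories: 5
    core: true
  - id: sf02
    text: "How well do you think your family as a whole copes with the challenges CF brings?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: true
  - id: sf03
    text: "How much does being responsible for a child with CF affect you personally?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: true
  - id: sf04
    text: "How much has CF limited what your family can do together?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: false
  - id: sf05
    text: "How much strain has CF placed on relationships within your family?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: false
  - id: sf06
    text: "How well supported do you feel by your local pharmacist?"
    domain: "Perceived support"
    n_categories: 4
    core: true
  - id: sf07
    text: "How well supported do you feel by the specialist CF team?"
    domain: "Perceived support"
    n_categories: 4
    core: true
  - id: sf08
    text: "How much emotional effort does keeping up with daily CF care take?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: false
  - id: sf09
    text: "How difficult is it to fit CF treatments into the family's day?"
    domain: "Maintaining CF routines"
    n_categories: 5
    core: false
  - id: sf10
    text: "How hard is it to keep your child's CF routines going when life is busy?"
    domain: "Maintaining CF routines"
    n_categories: 5
    core: false
  - id: sf11
    text: "How often does your child resist or refuse parts of the CF routine?"
    domain: "Child Challenge"
    n_categories: 5
    core: false
  - id: sf12
    text: "How demanding do you find your child's behaviour around treatments?"
    domain: "Child Challenge"
    n_categories: 5
    core: false
  - id: sf13
    text: "How much does your child's temperament add to the challenge of CF care?"
    domain: "Child Challenge"
    n_categories: 5
    core: false
  - id: sf14
    text: "How much do you worry about your child's current health?"
    domain: "Worries about Current Health"
    n_categories: 5
    core: false
  - id: sf15
    text: "How much practical day-to-day support does caring for CF demand from you?"
    domain: "Family Care-Giving Challenges"
    n_categories: 5
    core: false
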