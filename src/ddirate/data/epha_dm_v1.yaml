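# Default action-oriented decision model for rating drug-drug interaction
# severity (epha-dm-v1). Six question sets, asked in fixed order:
#   AIA  apparent interaction (OR of two sub-questions)
#   SAE  serious adverse event risk in the normal patient population
#   ACT  medical intervention needed beyond simple precautions
#   SUR  interaction risk difficult to assess in an outpatient setting
#   ATE  safer alternative exists AND credible dose-adjustment guidelines
#        are unavailable (two chained sub-questions)
#   RBR  risk outweighs the potential benefit
# Ratings: A no action / B precautionary measures / C clinical monitoring /
# D avoid / E contraindicated.
#
# The ACT..RBR subtree appears twice: once for SAE=no and once for SAE=yes,
# because an increased risk of a serious adverse event escalates the
# terminal severity (B->C on easy surveillance, C->D / D->E at the
# risk-benefit step). The duplicated nodes share question ids, so a rater
# answers each clinical question once. The model has 13 decision paths.
name: epha-dm-v1
version: "1"
root: AIA
leaves: [A, B, C, D, E]
nodes:
  AIA:
    text: "Apparent interaction: is there evidence that these drugs interact?"
    any_of:
      AIA_a: "Has this interaction been described in the scientific literature (e.g. credible clinical studies and credible case reports)?"
      AIA_b: "Can one postulate a plausible, hypothetical mechanism of pathogenic interaction?"
    "yes": SAE
    "no": "rating:A"
  SAE:
    text: "Is there an increased risk for the occurrence of a serious adverse event within the normal patient population?"
    "yes": ACT.sae
    "no": ACT.base
  ACT.base:
    question: ACT
    text: "Does the interaction outcome necessitate medical intervention, other than simple precautionary measures?"
    "yes": SUR.base
    "no": "rating:B"
  SUR.base:
    question: SUR
    text: "Is the interaction risk difficult to assess in an out-patient setting and within a short time-frame?"
    "yes": ATE_a.base
    "no": "rating:B"
  ATE_a.base:
    question: ATE_a
    text: "Does a suitable alternative exist (within the same ATC category), which carries a lower potential for interaction?"
    "yes": ATE_b.base
    "no": "rating:C"
  ATE_b.base:
    question: ATE_b
    text: "Are credible dose adjustment guidelines unavailable?"
    "yes": RBR.base
    "no": "rating:C"
  RBR.base:
    question: RBR
    text: "Does the risk outweigh the potential benefit?"
    "yes": "rating:D"
    "no": "rating:C"
  ACT.sae:
    question: ACT
    text: "Does the interaction outcome necessitate medical intervention, other than simple precautionary measures?"
    "yes": SUR.sae
    "no": "rating:B"
  SUR.sae:
    question: SUR
    text: "Is the interaction risk difficult to assess in an out-patient setting and within a short time-frame?"
    "yes": ATE_a.sae
    "no": "rating:C"
  ATE_a.sae:
    question: ATE_a
    text: "Does a suitable alternative exist (within the same ATC category), which carries a lower potential for interaction?"
    "yes": ATE_b.sae
    "no": "rating:C"
  ATE_b.sae:
    question: ATE_b
    text: "Are credible dose adjustment guidelines unavailable?"
    "yes": RBR.sae
    "no": "rating:C"
  RBR.sae:
    question: RBR
    text: "Does the risk outweigh the potential benefit?"
    "yes": "rating:E"
    "no": "rating:D"
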