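slice_id: buprenorphine_pills
kind: drug_quiz
provenance: published buprenorphine-pill quiz marginals, full set (arithmetically infeasible)
# Among 63 passers: 60 dose-correct, 58 image-correct, 53 both-correct.
# (60-53) + (58-53) + 53 = 65 > 63: no record-level table exists.  Shipped
# to exercise infeasibility detection; use buprenorphine_pills_marginal for
# a replayable table.
context: {drug: buprenorphine, formulation: pill}
fields:
  dose_correct: [true, false]
  image_correct: [true, false]
derived:
  passed: "dose_correct or image_correct"
constraints:
  - {name: quizzed, where: {}, count: 66}
  - {name: failed_both, where: {dose_correct: false, image_correct: false}, count: 3}
  - {name: passers_dose_correct, where: {dose_correct: true}, count: 60}
  - {name: passers_image_correct, where: {image_correct: true}, count: 58}
  - {name: passers_both_correct, where: {dose_correct: true, image_correct: true}, count: 53}
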