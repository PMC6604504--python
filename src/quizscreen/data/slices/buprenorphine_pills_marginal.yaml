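slice_id: buprenorphine_pills_marginal
kind: drug_quiz
provenance: published buprenorphine-pill quiz marginals (without the infeasible joint count)
context: {drug: buprenorphine, formulation: pill}
fields:
  dose_correct: [true, false]
  image_correct: [true, false]
derived:
  passed: "dose_correct or image_correct"
constraints:
  - {name: quizzed, where: {}, count: 66, provenance: "66 quizzed on buprenorphine pills"}
  - {name: failed_both, where: {dose_correct: false, image_correct: false}, count: 3,
     provenance: "3 failed both dose and image"}
  - {name: passers_dose_correct, where: {dose_correct: true}, count: 60,
     provenance: "60/63 (95%) dose correct among passers"}
  - {name: passers_image_correct, where: {image_correct: true}, count: 58,
     provenance: "58/63 (92%) image correct among passers"}
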