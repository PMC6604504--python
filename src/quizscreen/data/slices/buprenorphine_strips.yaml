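slice_id: buprenorphine_strips
kind: drug_quiz
provenance: published buprenorphine-strip quiz marginals
context: {drug: buprenorphine, formulation: strip}
fields:
  dose_correct: [true, false]
  image_correct: [true, false]
derived:
  passed: "dose_correct or image_correct"
constraints:
  - {name: quizzed, where: {}, count: 9}
  - {name: failed, where: {passed: false}, count: 0, provenance: "all strip users passed"}
  - {name: both_correct, where: {dose_correct: true, image_correct: true}, count: 8,
     provenance: "8/9 (89%) answered both dose and image correctly"}
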