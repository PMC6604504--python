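slice_id: methadone
kind: drug_quiz
provenance: published methadone quiz results
context: {drug: methadone}
fields:
  formulation: [pill, liquid]
  dose_correct: [true, false]
  image_correct: [true, false]
derived:
  passed: "dose_correct or image_correct"
constraints:
  - {name: quizzed, where: {}, count: 4}
  - {name: pills, where: {formulation: pill}, count: 3}
  - {name: liquid, where: {formulation: liquid}, count: 1}
  - {name: failed, where: {passed: false}, count: 0, provenance: "no participant failed"}
  - {name: dose_wrong, where: {dose_correct: false}, count: 1,
     provenance: "one incorrect answer, the pill dose question"}
  - {name: dose_wrong_pill, where: {formulation: pill, dose_correct: false}, count: 1}
  - {name: image_wrong, where: {image_correct: false}, count: 0}
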