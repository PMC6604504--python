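slice_id: heroin
kind: drug_quiz
provenance: published screening results, heroin drug quiz
context: {drug: heroin}
fields:
  cap_size_correct: [true, false]
  price_correct: [true, false]
  image_correct: [true, false]
derived:
  passed: "cap_size_correct or price_correct"
constraints:
  - {name: quizzed, where: {}, count: 172, provenance: "168 passers + 4 who failed both scored items"}
  - {name: failed_both_cap_price, where: {cap_size_correct: false, price_correct: false}, count: 4,
     provenance: "only 4 failed, by missing both cap size and street price"}
  - {name: passers_cap_correct, where: {passed: true, cap_size_correct: true}, count: 159,
     provenance: "159/168 (94.6%) cap size correct among passers"}
  - {name: passers_price_correct, where: {passed: true, price_correct: true}, count: 163,
     provenance: "163/168 (97.0%) street price correct among passers"}
  - {name: passers_both_correct, where: {cap_size_correct: true, price_correct: true}, count: 154,
     provenance: "154/168 (91.7%) both cap size and price correct"}
  - {name: passers_image_correct, where: {passed: true, image_correct: true}, count: 167,
     provenance: "167/168 (99.4%) recognized powdered heroin (unscored item)"}
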