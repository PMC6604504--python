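slice_id: drug_overall
kind: concat
provenance: all drug-quiz slices combined with the 3 auto-pass synthetic-opioid reporters
# 172 heroin + 40 prescription + 66 buprenorphine pills + 9 strips +
# 4 methadone + 3 synthetic = 294 quizzed, 285 passing (97.0%)
parts: [heroin, prescription, buprenorphine_pills_marginal, buprenorphine_strips, methadone]
extra:
  - count: 3
    record: {drug: synthetic_opioid}
constraints:
  - {name: opioid_reporters_quizzed, where: {}, count: 294,
     provenance: "294 recent-opioid reporters reached a scored or auto-pass quiz"}
  - {name: passed_drug_quiz, where: {passed: true}, count: 285,
     provenance: "285/294 (97.0%) passed the substance-use quiz"}
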