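slice_id: county
kind: county
provenance: published county-quiz score distribution among eligible-county reporters
# 387 reported an eligible county; 381 passed (98.4%), 347 of the passers
# scored 5/5 (91.1%), and 30 fours + 4 threes put the passer mean at 4.9.
fields:
  county_quiz_score: [5, 4, 3, 2]
constraints:
  - {name: eligible_county_reporters, where: {}, count: 387}
  - {name: passed, where: {county_quiz_score: [5, 4, 3]}, count: 381,
     provenance: "381/387 (98.4%) passed the county quiz"}
  - {name: score_5, where: {county_quiz_score: 5}, count: 347,
     provenance: "91.1% of passers answered all 5 correctly"}
  - {name: score_4, where: {county_quiz_score: 4}, count: 30}
  - {name: score_3, where: {county_quiz_score: 3}, count: 4}
  - {name: failed, where: {county_quiz_score: [2]}, count: 6}
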