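slice_id: funnel
kind: funnel
provenance: screening-funnel node counts
# 528 entries, 118 incomplete, 410 complete; 161 ineligible on reported
# criteria, 249 meeting them, 234 passing the quizzes (15 quiz failures).
fields:
  complete: [true, false]
  age_ok: [true, false]
  in_area: [true, false]
  opioid_reported: [true, false]
  county_quiz_pass: [true, false]
  drug_quiz_pass: [true, false]
derived:
  report_ok: "age_ok and in_area and opioid_reported"
  quiz_ok: "county_quiz_pass and drug_quiz_pass"
constraints:
  - {name: entries, where: {}, count: 528}
  - {name: incomplete, where: {complete: false}, count: 118, provenance: "118/528 (22.3%) incomplete"}
  - {name: complete, where: {complete: true}, count: 410}
  - {name: eligible, where: {complete: true, age_ok: true, in_area: true, opioid_reported: true,
                             county_quiz_pass: true, drug_quiz_pass: true}, count: 234,
     provenance: "234/410 (57.1%) deemed eligible"}
  - {name: report_ineligible, where: {complete: true, report_ok: false}, count: 161,
     provenance: "161/410 (39.3%) ineligible on reported age/residence/substance use"}
  - {name: no_substance, where: {complete: true, opioid_reported: false}, count: 116}
  - {name: age_out_of_range, where: {complete: true, age_ok: false}, count: 72}
  - {name: outside_area, where: {complete: true, in_area: false}, count: 23}
  - {name: quiz_failures, where: {complete: true, report_ok: true, quiz_ok: false}, count: 15,
     provenance: "249 met reported criteria, 234 passed the quizzes"}
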