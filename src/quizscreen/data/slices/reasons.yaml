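slice_id: reasons
kind: funnel
provenance: ineligibility-reason tallies over the 176 ineligible complete entries
# Reasons are non-exclusive (sum 116+72+23+5+7 = 223 over 176 people).
fields:
  age_ok: [true, false]
  in_area: [true, false]
  opioid_reported: [true, false]
  county_quiz_pass: [true, false]
  drug_quiz_pass: [true, false]
derived:
  quiz_fail: "(in_area and not county_quiz_pass) or (opioid_reported and not drug_quiz_pass)"
  any_reason: "(not age_ok) or (not in_area) or (not opioid_reported) or (in_area and not county_quiz_pass) or (opioid_reported and not drug_quiz_pass)"
constraints:
  - {name: ineligible_entries, where: {}, count: 176}
  - {name: none_eligible, where: {any_reason: false}, count: 0}
  - {name: no_substance, where: {opioid_reported: false}, count: 116,
     provenance: "116/176 (65.9%) reported no recent opioid use"}
  - {name: age_out_of_range, where: {age_ok: false}, count: 72,
     provenance: "72/176 (41%) outside the 18-35 range"}
  - {name: outside_area, where: {in_area: false}, count: 23,
     provenance: "23/176 (13.1%) living outside the study area"}
  - {name: county_quiz_fail, where: {in_area: true, county_quiz_pass: false}, count: 5,
     provenance: "failing the county quiz (n=5)"}
  - {name: drug_quiz_fail, where: {opioid_reported: true, drug_quiz_pass: false}, count: 7,
     provenance: "failing the drug quiz (n=7)"}
  - {name: quiz_fail_either, where: {quiz_fail: true}, count: 12,
     provenance: "12/176 (6.8%) ineligible for failing the county and/or drug quiz"}
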