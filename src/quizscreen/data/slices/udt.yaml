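slice_id: udt
kind: udt
provenance: 13-panel urine-drug-test results, 44 randomized / 34 completed within 3 days
fields: {}
derived:
  any_opioid: "panel_opiates or panel_methadone or panel_oxycodone or panel_propoxyphene or panel_buprenorphine"
  any_stimulant: "panel_methamphetamine or panel_amphetamine or panel_cocaine"
  any_drug: "panel_opiates or panel_methadone or panel_oxycodone or panel_propoxyphene or panel_buprenorphine or panel_methamphetamine or panel_amphetamine or panel_cocaine or panel_benzodiazepines or panel_phencyclidine or panel_barbiturates"
  any_panel: "any_drug or panel_marijuana or panel_tricyclic_antidepressants"
constraints:
  - {name: randomized, where: {}, count: 44}
  - {name: completed, where: {completed: true}, count: 34}
  - {name: marijuana, where: {completed: true, panel_marijuana: true}, count: 18}
  - {name: opiates, where: {completed: true, panel_opiates: true}, count: 9}
  - {name: methadone, where: {completed: true, panel_methadone: true}, count: 0}
  - {name: oxycodone, where: {completed: true, panel_oxycodone: true}, count: 1}
  - {name: propoxyphene, where: {completed: true, panel_propoxyphene: true}, count: 0}
  - {name: buprenorphine, where: {completed: true, panel_buprenorphine: true}, count: 17}
  - {name: any_opioid, where: {completed: true, any_opioid: true}, count: 25}
  - {name: methamphetamine, where: {completed: true, panel_methamphetamine: true}, count: 21}
  - {name: amphetamine, where: {completed: true, panel_amphetamine: true}, count: 21}
  - {name: cocaine, where: {completed: true, panel_cocaine: true}, count: 3}
  - {name: any_stimulant, where: {completed: true, any_stimulant: true}, count: 22}
  - {name: benzodiazepines, where: {completed: true, panel_benzodiazepines: true}, count: 2}
  - {name: phencyclidine, where: {completed: true, panel_phencyclidine: true}, count: 1}
  - {name: barbiturates, where: {completed: true, panel_barbiturates: true}, count: 0}
  - {name: any_drug_excl_marijuana_tca, where: {completed: true, any_drug: true}, count: 30}
  - {name: fully_negative, where: {completed: true, any_panel: false}, count: 2}
  - {name: heroin_reporters, where: {completed: true, reported_opioid_24h: heroin}, count: 21}
  - {name: heroin_matched, where: {completed: true, reported_opioid_24h: heroin, panel_opiates: true}, count: 8,
     provenance: "8/21 (38%) heroin reporters opiate-positive"}
  - {name: bup_reporters, where: {completed: true, reported_opioid_24h: buprenorphine}, count: 9}
  - {name: bup_matched, where: {completed: true, reported_opioid_24h: buprenorphine, panel_buprenorphine: true}, count: 8,
     provenance: "8/9 (89%) buprenorphine reporters panel-positive"}
  - {name: percocet_reporters, where: {completed: true, reported_opioid_24h: percocet}, count: 4}
  - {name: percocet_matched, where: {completed: true, reported_opioid_24h: percocet, panel_oxycodone: true}, count: 1,
     provenance: "1/4 (25%) percocet reporters oxycodone-positive"}
  - {name: heroin_days_mean, where: {completed: true, reported_opioid_24h: heroin}, mean: 0.22, of: days_elapsed, digits: 2}
  - {name: bup_days_mean, where: {completed: true, reported_opioid_24h: buprenorphine}, mean: 0.52, of: days_elapsed, digits: 2}
  - {name: percocet_days_mean, where: {completed: true, reported_opioid_24h: percocet}, mean: 0.75, of: days_elapsed, digits: 2}
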