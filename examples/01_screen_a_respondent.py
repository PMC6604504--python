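"""Run one respondent through the full screening flow.

A 25-year-old from an eligible county who reports heroin use and knows the
local purchase unit ("cap" = one-tenth of a gram) passes every gate; the
printed trace shows the 5-item county draw, the scored heroin components,
and the unscored image item.
"""
from quizscreen import ScriptedRespondent, default_config, run_session

config = default_config()
respondent = ScriptedRespondent(
    respondent_id="example",
    reported_county="ashford",
    reported_age=25,
    substances_30d=("heroin",),
)
transcript, result = run_session(respondent, config, seed=0)

print(f"eligible: {result.eligible}")
print(f"county quiz: {result.county_quiz_score}/5 (pass={result.county_quiz_pass})")
print(f"drug quiz components: {result.drug_quiz_components}")
for entry in transcript.entries:
    tag = "scored" if entry.scored else "unscored"
    print(f"  {entry.item_id:28s} correct={entry.correct}  [{tag}]")
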