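"""Self-report vs urine-drug-test concordance.

The shipped UDT fixture reproduces the published 13-panel table: 25/34
(74%) any-opioid positive, and per-drug match rates of 8/21 heroin, 8/9
buprenorphine, 1/4 percocet.  The simulator shows why heroin matches are
low: the opiate window tops out at 4 days, so use 5 days before the
specimen is already invisible.
"""
from quizscreen import (build_fixture, concordance_summary, shipped_slice,
                        simulate_udt)

fx = build_fixture(shipped_slice("udt"))
df = fx.to_frame()
done = df[df["completed"]]
reported = dict(zip(done["respondent_id"], done["reported_opioid_24h"]))
print(concordance_summary(done.to_dict("records"), reported).to_string(index=False))

rec = simulate_udt("demo", {"heroin": 5.0})
print("\nheroin used 5 days ago -> opiates panel positive:", rec.panels["opiates"])
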