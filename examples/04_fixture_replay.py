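"""Rebuild the published heroin-quiz table and re-score it with the engine.

The fixture stores only per-item correctness; replaying it through the real
scoring rules must reproduce every printed count (159/168 cap size, 163/168
price, 167/168 image, 4 failures).  The buprenorphine-pill slice shows the
other outcome: its printed joint marginals are arithmetically infeasible
and the builder reports the minimal conflicting subset.
"""
from quizscreen import (InfeasibleConstraints, build_fixture, default_config,
                        replay_fixture, shipped_slice, verify_fixture)

config = default_config()
sl = shipped_slice("heroin")
outcomes = replay_fixture(build_fixture(sl, seed=0), config)
print(verify_fixture(outcomes, sl).to_text())

try:
    build_fixture(shipped_slice("buprenorphine_pills"))
except InfeasibleConstraints as exc:
    print(f"\n{exc}")
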