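# quizscreen

Knowledge-quiz eligibility screening for web-based surveys of hidden
populations — built around the screening design used to enrol rural young
adults who use opioids, where neither residence nor recent drug use can be
verified in person.

Web surveys of people who use drugs (PWUD) face two verification problems:
IP-based geolocation is unreliable, and biological verification (urine
testing every applicant) would erase the advantages of online recruitment.
The design implemented here replaces both with *knowledge quizzes*:

* **Residence**: 5 questions drawn at random from a county-specific
  10-question bank of local knowledge (towns, smallest communities, jails,
  retail stores, landmarks, school mascots…); pass = ≥ 3 of 5 correct.
  Respondents naming a non-eligible county get an unscored generic quiz so
  the eligible counties stay masked.
* **Substance use**: short quizzes on the respondent's most-often-used
  opioid — purchase-unit ("cap") size and street price for heroin, dose and
  appearance for prescription opioids, buprenorphine and methadone — with
  pass = at least one scored component correct. Dose/image questions follow
  a 50/50 rule: exactly half of the options are correct. Non-opioid users
  get an unscored masking quiz; synthetic-opioid reporters auto-pass.

The package is aimed at survey methodologists and epidemiologists who want
to build, audit, or power such screens: it ships the screening engine, an
exact operating-characteristics oracle, a synthetic-respondent simulator,
constraint-based fixtures that reproduce the published screening results at
record level, and the urine-drug-test (UDT) concordance stage.

## The model at the core

The number of correct answers on a drawn county quiz is **Poisson-binomial**:
for per-item success probabilities *p₁,…,p₁₀* and a draw *D* of 5 items,

    P(pass) = E_D [ P( Σ_{i∈D} X_i ≥ 3 ) ],   X_i ~ Bernoulli(p_i),

computed exactly by dynamic-programming convolution averaged over all
C(10,5) = 252 equally likely draws. For a homogeneous four-option bank
(pᵢ = ¼) this reduces to the binomial tail Σ_{j≥3} C(5,j)(¼)ʲ(¾)^(5−j) =
**0.103515625** — a pure guesser's chance of passing the residence gate.
Drug quizzes pass on a disjunction of scored components, so under component
independence P(pass) = 1 − Π(1 − p_c); a heroin guesser passes with
1 − (¾)² = 0.4375. Sensitivity, specificity and PPV of the whole screen
follow by composing these terms through the flow's AND-logic over a persona
mix (Bayes' rule for PPV).

Because the study's microdata are not public, the `fixtures` module
synthesizes record-level tables from the *published marginal counts* by
integer programming over cross-classification cells, then replays them
through the real engine — every published percentage is recomputed from
re-scored transcripts, and arithmetically impossible marginal sets (the
buprenorphine-pill 60/58/53-of-63 joint counts) are detected and reported
with a minimal conflicting subset.

## Worked example

```python
from quizscreen import (build_fixture, county_pass_probability, default_config,
                        replay_fixture, shipped_slice, verify_fixture)

print(county_pass_probability([0.25] * 10))
# 0.103515625      <- guesser's chance of passing the 3-of-5 county quiz

config = default_config()
sl = shipped_slice("heroin")
outcomes = replay_fixture(build_fixture(sl, seed=0), config)
print(verify_fixture(outcomes, sl).to_text())
```

```
slice heroin: all constraints satisfied
           constraint  required  observed  satisfied
              quizzed       172       172       True
failed_both_cap_price         4         4       True
  passers_cap_correct       159       159       True
passers_price_correct       163       163       True
 passers_both_correct       154       154       True
passers_image_correct       167       167       True
```

The fixture stored only per-item responses; the 168 passers, the 4
failures, and the 159/163/167 component counts all *emerged* from re-scoring
the transcripts with the engine's pass rules (94.6%, 97.0% and 99.4% of
passers). The `examples/` directory has one short script per capability:
single-session screening, the guessing oracle, population simulation with
operating characteristics, fixture replay/infeasibility, and UDT
concordance. A thin CLI mirrors them (`quizscreen simulate | screen |
oracle | fixture | udt | report`).

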