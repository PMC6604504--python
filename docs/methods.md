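# Methods

## The screening flow

One session walks, in presentation order: age → reported county → county
quiz → past-30-day substance checklist → most-often-used opioid → drug
quiz. Eligibility requires age 18–35 inclusive, one of the 5 eligible
counties, at least one reported opioid, a county-quiz pass (≥ 3 of 5), and
a drug-quiz pass. Three design properties matter for correctness:

* **Masking.** The flow never terminates early on failure: an over-age
  respondent still takes the quizzes, a non-eligible county gets the
  unscored generic quiz, non-opioid users get a 3-question unscored masking
  quiz, so no respondent can infer which gate disqualified them.
* **Non-exclusive reasons.** Ineligibility reasons (`age`, `outside_area`,
  `county_quiz_fail`, `no_substance`, `drug_quiz_fail`) are all recorded;
  funnel reports carry both the non-exclusive tallies and an exclusive
  first-failure tally in flow order. Incomplete sessions are retained with
  partial transcripts and excluded from every eligibility denominator.
* **Branching on the dose question.** For dose-quizzed drugs, a wrong dose
  answer routes to the all-doses image question, so appearance alone can
  still carry the pass; the heroin image item is recorded but never scored
  (injectors may only ever see dissolved heroin).

A respondent who failed the county quiz continues into the substance
section. Whether the fielded instrument did this is not stated in the
source description; continuing preserves the masking intent and is the
package's assumption.

## Item construction

Dose and image questions follow the 50/50 rule: a drug manufactured in *m*
doses yields 2*m* options with the *m* true doses correct, and image sets
contain equally many authentic photographs and lookalikes. This pins every
structural guessing probability at ½ regardless of *m*, which is what makes
the guessing oracle's drug-quiz term drug-independent. Heroin keeps the
fielded four-option cap-size and price-bracket questions (1/10 gram and
US $10–$50 correct; bracket endpoints overlap as fielded) and the 10-image
question with 5 genuine powder-heroin options. Images are abstract labelled
options: scoring needs only the correct/incorrect label. Option order is
shuffled at construction under the caller's seed, so a session is fully
reproducible. Decoy doses default to continuing the true-dose grid past the
largest dose; any explicit decoy list must be disjoint from the true doses.

The shipped configuration (5 fictional counties, 10-item banks with the 6
cross-county parallel categories plus 4 county-specific ones, a generic
masking bank, and an opioid catalog with manufactured doses) is
illustrative: the real item wording is not public beyond topic categories.
Catalog note: transdermal fentanyl is carried as a quizzable prescription
product (doses in µg/h) distinct from the illicit synthetic-opioid entry,
which auto-passes because no stable scorable quiz exists for that market.

## Exact operating characteristics

`poisson_binomial_tail` computes P(#successes ≥ k) by O(n²) DP convolution
in double precision; the tail at k = 0 returns 1 exactly (no summation).
`county_pass_probability` averages the tail over all C(bank, draw) draws —
252 for the fielded 10-choose-5 — and reduces to the binomial tail for
homogeneous banks. Drug-quiz pass probability is 1 − Π(1 − p_c) over scored
components under independence, the only structure per-item accuracy
reporting supports; the simulator can impose correlation to probe
robustness, the closed forms cannot. Screen-level sensitivity/specificity/
PPV compose these terms per persona and apply Bayes' rule over the mix.
Test oracles re-derive the same quantities by exhaustive 2ⁿ enumeration in
exact rationals for n ≤ 12.

## The respondent simulator

A persona bundles an age distribution, a reported county, a distribution
over reported substance sets, a most-often-opioid preference, a
24-hour-use probability, a completion probability, and a knowledge model
mapping item categories to correctness probabilities (fallback = structural
guessing). Item responses are conditionally independent given the persona;
wrong answers are uniform over the incorrect options (only correctness is
ever scored). Six shipped personas span the error surface: knowledgeable
eligible residents (drug components at the reported item accuracies — cap
0.946, price 0.970 — county categories near the observed ~98% pass rate), a
recent mover with degraded school-linked categories (the pilot finding), an
out-of-area guesser falsely claiming an eligible county at pure guessing (a
lower bound, not an estimate of real outsider knowledge), an underage
respondent, a non-opioid user, and an abandoner (completion 0.25).
`coached_retake` answers previously seen items correctly with probability
max(base, carryover), quantifying how the random 5-of-10 draw resists
retakes: two independent draws share hypergeometric-mean 2.5 items.

Two equivalent sampling paths exist: the object-level path runs each
respondent through `run_session` (used wherever transcripts matter) and a
numpy-batched path computes pass rates at large n (used for the 10⁵
oracle-agreement checks); the test suite cross-checks them against each
other and against the closed forms.

What the simulator does *not* emulate: within-respondent correlation of
knowledge across items, response times, device effects, repeated fraudulent
entries, or any real covariate structure. Passing tests therefore certify
the engine's logic and the oracle's arithmetic, not behavioural realism.

## Record fixtures from printed marginals

No microdata are public, so published counts are re-expressed as constraint
slices: categorical allocation fields, derived boolean expressions, and
exact-count constraints (conjunctions of field-membership predicates).
Counts are allocated to cross-classification cells by integer programming
(HiGHS); under-determination is resolved deterministically by a cost that
prefers default field values with an index tie-break, and infeasibility is
reported with a minimal conflicting subset found by a deletion filter.
Fixtures store per-item correctness and replay through the real engine, so
every published fraction is recomputed from re-scored transcripts.

The published counts are mutually inconsistent in places, so slices are
shipped per result table rather than as one global set: the funnel slice
carries the 528/118/410/234 node counts with 161 report-ineligible and 15
implied quiz failures, while the reasons slice carries the /176
denominators with the stated 5 county + 7 drug quiz failures (the two
cannot coexist in one table). The buprenorphine-pill joint marginals
(60 dose, 58 image, 53 both among 63 passers) are arithmetically infeasible
— (60−53)+(58−53)+53 = 65 > 63 — and ship as the infeasibility
demonstration; a marginal-only variant replays the 95%/92% figures. The
prescription slice adds one norco passer to reconcile the drug list (sum
39) with the stated 38 passers + 2 failures. The overall 285/294 pass rate
is reproduced exactly as a fraction; its published rendering "97.0%" only
holds at integer precision (one-decimal half-up gives 96.9).

## Urine drug testing

The 13-panel cup is modelled at the positive/negative level; detection
windows (days) drive simulation and thresholds (ng/mL) are metadata. The
default detection model uses each window's upper bound deterministically
(reproducible; concordance is then non-increasing in specimen delay); a
uniform-in-window model is selectable for sensitivity analysis. The 2–5 h
urine-appearance delay is below day resolution and ignored. Hydrocodone
products map to the opiates panel via immunoassay cross-reactivity;
fentanyl, tramadol and illicit synthetics are explicitly outside the cup's
coverage and logged as such. Specimen delay is carried as a real-valued day
count: the published group means (0.22, 0.52, 0.75 days) are not all
attainable with whole-day values. The UDT fixture lays panel positives out
so every union count holds simultaneously (two opioid double-positives give
25 any-opioid from 9+17+1; one cocaine-only person gives 22 any-stimulant
from 21+3; the benzodiazepine/phencyclidine singletons land on
opioid-negative records so 30 are any-drug positive while exactly 2 are
negative on all panels). Randomization to UDT is a uniform draw from
completers reporting past-24-hour opioid use; the randomized fraction is an
input (44 randomized, 34 completed within the 3-day protocol window).

## Statistics and rounding

Kruskal–Wallis H is computed with midranks and the tie-correction divisor
1 − Σ(t³−t)/(N³−N) (H = 0 when all observations tie), df = groups − 1,
p-values from the χ² approximation; Spearman's ρ is the product-moment
correlation of midranks, undefined (raised) under zero rank variance. Both
are cross-checked against scipy and, for H, against direct rank-statistic
computation at small N; a vectorised null simulation confirms the nominal
0.05 type-I error at 5 groups of 10. Percentages round half-up at the
precision of the published rendering (integer or one decimal), with raw
fractions carried alongside; empty denominators yield an undefined value,
never zero.

## Problem sizes and numerical choices

Monte-Carlo checks run at n = 10⁵ per persona (3-SE agreement bands) via
the batched path and at n ≈ 10³–2·10⁴ for object-level cross-checks;
funnel-invariant sweeps use 10³ randomized populations of ≤ 8 sessions.
Enumeration oracles cap at bank size 12 (exact rationals). All randomness
flows through numpy Generators seeded explicitly; fixture construction is
seed-invariant by design (the MILP and record layout are deterministic).

## Known limitations

Knowledge quizzes cannot distinguish current from former users, and the
guesser persona is a stated lower bound on outsider knowledge, so the
reported specificity against real outsiders is optimistic. The published
Kruskal–Wallis (χ²₄ = 6.9) and Spearman (ρ = .03) results depend on the
non-public study data and are implemented as statistics only, not
reproduced. Detection-window modelling ignores dose, frequency of use,
metabolism and cross-reactivity beyond the hydrocodone mapping.
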