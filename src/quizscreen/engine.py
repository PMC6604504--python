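"""Execute one respondent's pass through the branching screening flow.

The flow, in presentation order: age -> reported county -> county quiz
(scored 5-of-10 draw for eligible counties, unscored generic masking quiz
otherwise) -> past-30-day substance checklist -> most-often-used opioid
(opioid-only list when nonopioids are co-reported) -> drug quiz (or the
unscored nonopioid masking quiz).  Ineligibility reasons are non-exclusive:
a 40-year-old who fails the county quiz carries both reasons.  Masking is
preserved by continuing the full flow regardless of earlier failures, so a
respondent can never infer which gate disqualified them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Protocol, Sequence, Union

import numpy as np

from .model import (
    CountyQuizSpec,
    DrugClass,
    DrugQuizSpec,
    GENERIC_BANK_ID,
    QuestionBank,
    QuizItem,
    ScreeningConfig,
    build_drug_quiz,
)

__all__ = [
    "REASONS",
    "SessionEntry",
    "SessionTranscript",
    "ScreeningResult",
    "FunnelReport",
    "AnswerSource",
    "ScriptedRespondent",
    "draw_county_quiz",
    "score_county_quiz",
    "score_drug_quiz",
    "run_session",
    "classify_funnel",
]

# Non-exclusive ineligibility reasons, in flow order (used for the exclusive
# first-failure tally as well).
REASONS = (
    "age",
    "outside_area",
    "county_quiz_fail",
    "no_substance",
    "drug_quiz_fail",
)

_DRUG_CATEGORIES = frozenset({"dose", "image", "cap_size", "price"})


@dataclass(frozen=True)
class SessionEntry:
    item_id: str
    component: str  # item category, or "price_text" for the free-text prompt
    chosen: tuple[str, ...]
    correct: Optional[bool]  # None when the item is unscorable
    scored: bool  # whether this entry enters a quiz score


@dataclass
class SessionTranscript:
    respondent_id: str
    reported_age: Optional[int] = None
    reported_county: Optional[str] = None
    reported_substances_30d: tuple[str, ...] = ()
    most_often_opioid: Optional[str] = None
    most_often_formulation: Optional[str] = None
    used_opioid_24h: bool = False
    complete: bool = True
    entries: list[SessionEntry] = field(default_factory=list)


@dataclass
class ScreeningResult:
    respondent_id: str
    complete: bool
    age_ok: Optional[bool] = None
    residence_reported_ok: Optional[bool] = None
    county_quiz_score: Optional[int] = None
    county_quiz_pass: Optional[bool] = None
    substance_reported_ok: Optional[bool] = None
    drug_quiz_components: dict[str, Optional[bool]] = field(default_factory=dict)
    drug_quiz_pass: Optional[bool] = None
    drug_quiz_auto: bool = False
    eligible: bool = False
    ineligibility_reasons: frozenset[str] = frozenset()


class AnswerSource(Protocol):
    """What the engine needs from a respondent (live form, simulator, or
    fixture replay)."""

    respondent_id: str
    reported_age: int
    reported_county: str
    substances_30d: Sequence[str]
    used_opioid_24h: bool
    completes: bool

    def choose_most_often(self, opioids: Sequence[str]) -> tuple[str, Optional[str]]:
        ...

    def answer(self, item: QuizItem, rng: np.random.Generator) -> str:
        ...


@dataclass
class ScriptedRespondent:
    """Deterministic answer source driven by per-category correctness flags.

    Used by the fixture replayer and tests: ``correct_by_category`` pins the
    drug-quiz components (``cap_size``/``price``/``dose``/``image``) and
    ``n_correct_county`` makes the respondent answer exactly that many of
    the presented county items correctly (in presentation order).  Item-level
    overrides win over category flags.  Unscorable masking items are answered
    with the first option.
    """

    respondent_id: str
    reported_county: str
    reported_age: int = 25
    substances_30d: tuple[str, ...] = ("heroin",)
    used_opioid_24h: bool = False
    completes: bool = True
    most_often: Optional[str] = None
    formulation: Optional[str] = None
    correct_by_category: Mapping[str, bool] = field(default_factory=dict)
    correct_by_item: Mapping[str, bool] = field(default_factory=dict)
    n_correct_county: Optional[int] = None
    default_correct: bool = True
    _county_answered: int = field(default=0, repr=False)

    def choose_most_often(self, opioids: Sequence[str]) -> tuple[str, Optional[str]]:
        drug = self.most_often if self.most_often in opioids else opioids[0]
        return drug, self.formulation

    def answer(self, item: QuizItem, rng: np.random.Generator) -> str:
        if not item.correct:
            return item.options[0]
        if item.item_id in self.correct_by_item:
            want = self.correct_by_item[item.item_id]
        elif item.category in _DRUG_CATEGORIES:
            want = self.correct_by_category.get(item.category, self.default_correct)
        elif self.n_correct_county is not None:
            want = self._county_answered < self.n_correct_county
            self._county_answered += 1
        else:
            want = self.correct_by_category.get(item.category, self.default_correct)
        pool = [o for o in item.options if (o in item.correct) == want]
        return pool[0]


# ---------------------------------------------------------------------------
# Quiz mechanics
# ---------------------------------------------------------------------------


def draw_county_quiz(
    bank: QuestionBank,
    spec: CountyQuizSpec,
    rng: Union[np.random.Generator, int, None] = None,
) -> list[QuizItem]:
    """Uniform without-replacement draw of ``spec.draw_size`` items; the
    returned order is the presentation order."""
    if len(bank) < spec.draw_size:
        raise ValueError(
            f"bank {bank.bank_id!r} has {len(bank)} items, cannot draw {spec.draw_size}"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    idx = gen.choice(len(bank), size=spec.draw_size, replace=False)
    return [bank.items[i] for i in idx]


def score_county_quiz(
    items: Sequence[QuizItem],
    responses: Sequence[str],
    spec: CountyQuizSpec = CountyQuizSpec(),
) -> tuple[int, bool]:
    """Score the drawn county quiz: count of correct answers and the
    3-of-5 pass flag."""
    if len(items) != spec.draw_size or len(responses) != spec.draw_size:
        raise ValueError(
            f"expected exactly {spec.draw_size} item/response pairs, "
            f"got {len(items)}/{len(responses)}"
        )
    score = 0
    for it, resp in zip(items, responses):
        ok = it.is_correct(resp)
        if ok is None:
            raise ValueError(f"item {it.item_id!r} is unscorable")
        score += int(ok)
    return score, score >= spec.pass_threshold


def score_drug_quiz(
    spec: DrugQuizSpec, responses: Mapping[str, Optional[bool]]
) -> tuple[dict[str, Optional[bool]], Optional[bool]]:
    """Apply the drug-quiz pass rule to per-component correctness flags.

    Pass = OR over the scored components (cap-size/price for heroin,
    dose/image for dose-quizzed drugs).  Synthetic-opioid quizzes auto-pass;
    the nonopioid masking quiz returns None (not applicable).  Unscored
    components are recorded but never enter the rule.
    """
    outcomes = dict(responses)
    if spec.auto_pass:
        return outcomes, True
    if not spec.applicable:
        return outcomes, None
    for comp in spec.scored_components:
        if responses.get(comp) is None:
            raise ValueError(f"missing response for scored component {comp!r}")
    return outcomes, any(responses[c] for c in spec.scored_components)


# ---------------------------------------------------------------------------
# Session driver
# ---------------------------------------------------------------------------


def _record(entries: list[SessionEntry], item: QuizItem, chosen: str, scored: bool) -> Optional[bool]:
    ok = item.is_correct(chosen)
    entries.append(
        SessionEntry(
            item_id=item.item_id,
            component=item.category,
            chosen=(chosen,),
            correct=ok,
            scored=scored and ok is not None,
        )
    )
    return ok


def _parse_dose(option: str) -> float:
    return float(option.split()[0])


def _administer_drug_quiz(
    quiz: DrugQuizSpec,
    respondent: AnswerSource,
    rng: np.random.Generator,
    entries: list[SessionEntry],
) -> tuple[dict[str, Optional[bool]], Optional[bool], bool]:
    components: dict[str, Optional[bool]] = {}
    if quiz.drug_class is DrugClass.heroin:
        components["cap_size"] = _record(entries, quiz.cap_item, respondent.answer(quiz.cap_item, rng), True)
        components["price"] = _record(entries, quiz.price_item, respondent.answer(quiz.price_item, rng), True)
        # image recognition recorded but excluded from the heroin score
        components["image"] = _record(entries, quiz.image_item, respondent.answer(quiz.image_item, rng), False)
    elif quiz.dose_item is not None:
        chosen = respondent.answer(quiz.dose_item, rng)
        dose_ok = _record(entries, quiz.dose_item, chosen, True)
        components["dose"] = dose_ok
        # incorrect dose branches to the all-doses image question
        if dose_ok:
            image_item = quiz.image_by_dose[_parse_dose(chosen)]
        else:
            image_item = quiz.image_all_item
        components["image"] = _record(entries, image_item, respondent.answer(image_item, rng), True)
        # open-ended street price, never scored
        entries.append(
            SessionEntry(
                item_id=f"{quiz.drug_id}-price-text",
                component="price_text",
                chosen=("",),
                correct=None,
                scored=False,
            )
        )
    else:  # synthetic-opioid or nonopioid masking quiz: unscored info items
        for it in quiz.info_items:
            _record(entries, it, respondent.answer(it, rng), False)
    outcomes, passed = score_drug_quiz(quiz, components)
    return outcomes, passed, quiz.auto_pass


def run_session(
    respondent: AnswerSource,
    config: ScreeningConfig,
    seed: Union[np.random.Generator, int, None] = None,
) -> tuple[SessionTranscript, ScreeningResult]:
    """Run one respondent through the full branching flow.

    Deterministic given (respondent answers, seed, config).  An abandoned
    session yields ``complete=False`` with a partial transcript and is
    excluded from eligibility denominators downstream.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flow, banks, catalog = config.flow, config.banks, config.catalog
    t = SessionTranscript(respondent_id=respondent.respondent_id)
    entries = t.entries

    t.reported_age = int(respondent.reported_age)
    age_ok = flow.age_ok(t.reported_age)
    t.reported_county = respondent.reported_county
    in_area = t.reported_county in flow.eligible_counties

    if not getattr(respondent, "completes", True):
        t.complete = False
        return t, ScreeningResult(
            respondent_id=t.respondent_id,
            complete=False,
            age_ok=age_ok,
            residence_reported_ok=in_area,
            eligible=False,
            ineligibility_reasons=frozenset({"incomplete"}),
        )

    # County quiz: scored bank for eligible counties, generic masking quiz
    # otherwise (stating an outside county already disqualifies).
    if in_area:
        bank, cspec = banks[t.reported_county], config.county_quiz
    else:
        bank, cspec = banks[GENERIC_BANK_ID], config.generic_quiz
    items = draw_county_quiz(bank, cspec, rng)
    choices = [respondent.answer(it, rng) for it in items]
    for it, ch in zip(items, choices):
        _record(entries, it, ch, cspec.scored)
    if cspec.scored:
        county_score, county_pass = score_county_quiz(items, choices, cspec)
    else:
        county_score, county_pass = None, None

    # Substance checklist and drug quiz
    t.reported_substances_30d = tuple(respondent.substances_30d)
    reported_any = bool(
        set(t.reported_substances_30d) - {"none_of_these", ""}
    )
    opioids = [s for s in t.reported_substances_30d if s in catalog and catalog.is_opioid(s)]
    substance_ok = bool(opioids)
    t.used_opioid_24h = bool(respondent.used_opioid_24h) and substance_ok

    components: dict[str, Optional[bool]] = {}
    drug_pass: Optional[bool] = None
    auto = False
    if not reported_any:
        pass  # no substances: skip all substance quizzes
    elif opioids:
        drug, formulation = respondent.choose_most_often(opioids)
        if drug not in opioids:
            raise ValueError(f"most-often drug {drug!r} was not among reported opioids")
        t.most_often_opioid = drug
        quiz = build_drug_quiz(catalog, drug, formulation, rng)
        t.most_often_formulation = quiz.formulation
        components, drug_pass, auto = _administer_drug_quiz(quiz, respondent, rng, entries)
    else:
        # nonopioid masking quiz on the first reported nonopioid
        known = [s for s in t.reported_substances_30d if s in catalog]
        masking_id = known[0] if known else "other"
        if masking_id in catalog:
            quiz = build_drug_quiz(catalog, masking_id, None, rng)
        else:
            quiz = build_drug_quiz(catalog, _first_nonopioid(catalog), None, rng)
        _administer_drug_quiz(quiz, respondent, rng, entries)

    reasons = set()
    if not age_ok:
        reasons.add("age")
    if not in_area:
        reasons.add("outside_area")
    if in_area and county_pass is False:
        reasons.add("county_quiz_fail")
    if not substance_ok:
        reasons.add("no_substance")
    if drug_pass is False:
        reasons.add("drug_quiz_fail")

    result = ScreeningResult(
        respondent_id=t.respondent_id,
        complete=True,
        age_ok=age_ok,
        residence_reported_ok=in_area,
        county_quiz_score=county_score,
        county_quiz_pass=county_pass,
        substance_reported_ok=substance_ok,
        drug_quiz_components=components,
        drug_quiz_pass=drug_pass,
        drug_quiz_auto=auto,
        eligible=not reasons,
        ineligibility_reasons=frozenset(reasons),
    )
    return t, result


def _first_nonopioid(catalog) -> str:
    for d, info in catalog.drugs.items():
        if info.drug_class is DrugClass.nonopioid:
            return d
    raise ValueError("catalog has no nonopioid drug for the masking quiz")


# ---------------------------------------------------------------------------
# Funnel aggregation
# ---------------------------------------------------------------------------


@dataclass
class FunnelReport:
    total: int
    incomplete: int
    complete: int
    eligible: int
    ineligible: int
    # non-exclusive reason tallies (a person may carry several)
    reasons: dict[str, int]
    # exclusive first-failure tallies, in flow order
    first_failure: dict[str, int]

    def to_text(self) -> str:
        lines = [
            "screening funnel",
            f"  entries            {self.total:>6}",
            f"  incomplete         {self.incomplete:>6}",
            f"  complete           {self.complete:>6}",
            f"  eligible           {self.eligible:>6}",
            f"  ineligible         {self.ineligible:>6}",
            "  ineligibility reasons (non-exclusive):",
        ]
        for r in REASONS:
            lines.append(f"    {r:<18} {self.reasons[r]:>6}")
        return "\n".join(lines)


def classify_funnel(results: Iterable[ScreeningResult]) -> FunnelReport:
    """Aggregate per-respondent results into funnel counts.

    Conservation: incomplete + complete = total and eligible + ineligible =
    complete.  Reason tallies are non-exclusive; the first-failure tally
    assigns each ineligible respondent to the earliest failed gate.
    """
    total = incomplete = eligible = ineligible = 0
    reasons = {r: 0 for r in REASONS}
    first = {r: 0 for r in REASONS}
    for res in results:
        total += 1
        if not res.complete:
            incomplete += 1
            continue
        if res.eligible:
            eligible += 1
            continue
        ineligible += 1
        for r in res.ineligibility_reasons:
            reasons[r] += 1
        for r in REASONS:
            if r in res.ineligibility_reasons:
                first[r] += 1
                break
    return FunnelReport(
        total=total,
        incomplete=incomplete,
        complete=total - incomplete,
        eligible=eligible,
        ineligible=ineligible,
        reasons=reasons,
        first_failure=first,
    )
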