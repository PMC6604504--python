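"""Exact pass probabilities and screen operating characteristics.

The number of correct answers on a drawn county quiz is Poisson-binomial:
independent Bernoulli trials with heterogeneous per-item success
probabilities.  With a 5-item draw from a 10-item bank and a 3-of-5 pass
rule, the pass probability is the mean, over all C(10,5)=252 equally likely
draws, of the Poisson-binomial upper tail at 3.  For a homogeneous bank the
draw is irrelevant and the value reduces to the binomial tail; a pure
guesser on four-option items passes with probability

    sum_{j>=3} C(5,j) 0.25^j 0.75^(5-j) = 0.103515625.

Drug quizzes pass on a disjunction of scored components, so under component
independence P(pass) = 1 - prod(1 - p_component).  These closed forms are
the brute-force oracle against which the Monte-Carlo simulator is checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence, TYPE_CHECKING

import numpy as np

from .model import (
    CountyQuizSpec,
    DrugClass,
    DrugQuizSpec,
    QuestionBank,
    QuizItem,
    ScreeningConfig,
    build_drug_quiz,
)

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import Persona

__all__ = [
    "ScreenOperatingPoint",
    "poisson_binomial_pmf",
    "poisson_binomial_tail",
    "item_success_profile",
    "county_pass_probability",
    "drug_pass_probability",
    "screen_pass_probability",
    "screen_operating_characteristics",
]


def _check_probs(probs: Sequence[float]) -> np.ndarray:
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one probability")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return p


def poisson_binomial_pmf(probs: Sequence[float]) -> np.ndarray:
    """Exact pmf of the number of successes among independent Bernoulli
    trials, by dynamic-programming convolution (O(n^2))."""
    p = _check_probs(probs)
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for i, pi in enumerate(p):
        pmf[1 : i + 2] = pmf[1 : i + 2] * (1 - pi) + pmf[: i + 1] * pi
        pmf[0] *= 1 - pi
    return pmf


def poisson_binomial_tail(probs: Sequence[float], k: int) -> float:
    """P(#successes >= k), exactly."""
    if k < 0:
        raise ValueError("k must be >= 0")
    pmf = poisson_binomial_pmf(probs)
    if k == 0:
        return 1.0  # complement rule holds exactly, no summation error
    if k > pmf.size - 1:
        return 0.0
    return float(pmf[k:].sum())


def item_success_profile(
    bank: QuestionBank, knowledge: Optional["KnowledgeLike"] = None
) -> list[float]:
    """Per-item success probabilities for a bank.

    With no knowledge model this is the pure-guesser profile
    |correct|/|options| per item; a knowledge model supplies per-category
    probabilities and may itself fall back to guessing.
    """
    if knowledge is None:
        return [it.guess_probability for it in bank.items]
    return [knowledge.item_prob(it) for it in bank.items]


class KnowledgeLike:  # typing aid only
    def item_prob(self, item: QuizItem) -> float:  # pragma: no cover
        raise NotImplementedError


def county_pass_probability(
    profile: Sequence[float],
    spec: CountyQuizSpec = CountyQuizSpec(),
) -> float:
    """Exact pass probability of the drawn county quiz: the mean over all
    equally likely without-replacement draws of the Poisson-binomial tail at
    the pass threshold.  Reduces to the binomial tail for homogeneous
    banks."""
    p = _check_probs(profile)
    n, k = p.size, spec.draw_size
    if n < k:
        raise ValueError(f"bank of {n} items cannot support a draw of {k}")
    total = 0.0
    count = 0
    for idx in combinations(range(n), k):
        total += poisson_binomial_tail(p[list(idx)], spec.pass_threshold)
        count += 1
    return total / count


def drug_pass_probability(
    spec: DrugQuizSpec, profile: Mapping[str, float]
) -> float:
    """P(pass) for a drug quiz under component independence:
    1 - prod(1 - p_c) over the scored components.  Auto-pass quizzes return
    1; the unscorable nonopioid masking quiz returns 0 (it can never confer
    eligibility)."""
    if spec.auto_pass:
        return 1.0
    if not spec.applicable:
        return 0.0
    miss = 1.0
    for comp in spec.scored_components:
        if comp not in profile:
            raise ValueError(f"profile lacks scored component {comp!r}")
        pc = profile[comp]
        if not 0.0 <= pc <= 1.0:
            raise ValueError(f"probability for {comp!r} outside [0, 1]")
        miss *= 1.0 - pc
    return 1.0 - miss


def _drug_component_profile(
    quiz: DrugQuizSpec, knowledge: Optional[KnowledgeLike]
) -> dict[str, float]:
    prof: dict[str, float] = {}
    if quiz.drug_class is DrugClass.heroin:
        items = {"cap_size": quiz.cap_item, "price": quiz.price_item}
    elif quiz.dose_item is not None:
        # both image branches (per-dose and all-doses) carry 50% correct
        # options, so a single image probability is exact
        items = {"dose": quiz.dose_item, "image": quiz.image_all_item}
    else:
        return prof
    for comp, item in items.items():
        prof[comp] = knowledge.item_prob(item) if knowledge else item.guess_probability
    return prof


def screen_pass_probability(persona: "Persona", config: ScreeningConfig) -> float:
    """Exact probability that a respondent of this persona is classified
    eligible, composing the flow's AND-logic: age in range, an eligible
    reported county, county-quiz pass, an opioid reported, and drug-quiz
    pass.  Conditional on a completed session (incompletes never enter
    eligibility denominators)."""
    flow = config.flow
    p_age = persona.prob_age_ok(flow)
    if p_age == 0.0:
        return 0.0
    if persona.county not in flow.eligible_counties:
        return 0.0
    profile = item_success_profile(config.banks[persona.county], persona.knowledge)
    p_county = county_pass_probability(profile, config.county_quiz)
    most = persona.most_often_distribution(config.catalog)
    p_opioid = persona.prob_opioid(config.catalog)
    p_drug = 0.0
    for drug, w in most.items():
        quiz = build_drug_quiz(config.catalog, drug, persona.formulation_for(drug))
        prof = _drug_component_profile(quiz, persona.knowledge)
        p_drug += w * drug_pass_probability(quiz, prof)
    return p_age * p_county * p_opioid * p_drug


@dataclass(frozen=True)
class ScreenOperatingPoint:
    """Operating characteristics of the screen against persona ground truth:
    sensitivity P(pass | eligible persona), specificity
    P(classified ineligible | ineligible persona), and the positive
    predictive value under the supplied persona mix (Bayes' rule)."""

    sensitivity: float
    specificity: float
    ppv: float


def screen_operating_characteristics(
    mix: Sequence[tuple["Persona", float]], config: ScreeningConfig
) -> ScreenOperatingPoint:
    weights = np.asarray([w for _, w in mix], dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mix weights must be nonnegative and not all zero")
    weights = weights / weights.sum()
    pass_probs = np.asarray(
        [screen_pass_probability(p, config) for p, _ in mix], dtype=float
    )
    truth = np.asarray([p.ground_truth_eligible for p, _ in mix], dtype=bool)
    w_elig = weights[truth].sum()
    w_inel = weights[~truth].sum()
    sens = float((weights[truth] * pass_probs[truth]).sum() / w_elig) if w_elig else float("nan")
    spec = (
        float((weights[~truth] * (1 - pass_probs[~truth])).sum() / w_inel)
        if w_inel
        else float("nan")
    )
    total_pass = float((weights * pass_probs).sum())
    ppv = float((weights[truth] * pass_probs[truth]).sum() / total_pass) if total_pass else float("nan")
    return ScreenOperatingPoint(sensitivity=sens, specificity=spec, ppv=ppv)
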