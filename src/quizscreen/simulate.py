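"""Synthetic respondents: persona-level knowledge models and populations.

A persona is a simulated respondent class: an age distribution, a reported
county (eligible or outside), a distribution over reported substance sets,
a most-often-opioid preference, and a knowledge model giving per-category
correctness probabilities.  Item-level responses are conditionally
independent given the persona — the simplest model consistent with per-item
accuracy reporting — and incorrect multiple-choice answers are uniform over
the incorrect options.  A knowledge model with no entry for a category falls
back to pure structural guessing (|correct|/|options|), which is how the
"out-of-area guesser" persona is built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .engine import SessionTranscript, run_session
from .model import (
    DrugClass,
    QuizItem,
    ScreeningConfig,
    ScreeningFlowSpec,
    build_drug_quiz,
)
from .oracle import item_success_profile

__all__ = [
    "KnowledgeModel",
    "Persona",
    "PopulationSpec",
    "SimulatedRespondent",
    "CoachedRespondent",
    "sample_population",
    "simulate_screening",
    "coached_retake",
    "default_personas",
    "pass_rate",
]


@dataclass(frozen=True)
class KnowledgeModel:
    """Per-category correctness probabilities.

    ``fallback`` applies to categories without an entry; ``None`` means
    structural guessing from the item itself (|correct|/|options|), so
    ``KnowledgeModel()`` is the pure guesser.
    """

    probs: Mapping[str, float] = field(default_factory=dict)
    fallback: Optional[float] = None

    def __post_init__(self) -> None:
        for cat, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"knowledge probability for {cat!r} outside [0, 1]")
        if self.fallback is not None and not 0.0 <= self.fallback <= 1.0:
            raise ValueError("fallback probability outside [0, 1]")

    def item_prob(self, item: QuizItem) -> float:
        p = self.probs.get(item.category, self.fallback)
        if p is None:
            return item.guess_probability
        return p


def _norm_weights(weights: Sequence[float], what: str) -> np.ndarray:
    w = np.asarray(list(weights), dtype=float)
    if w.size == 0 or np.any(w < 0) or w.sum() <= 0:
        raise ValueError(f"{what}: weights must be nonnegative with positive sum")
    return w / w.sum()


@dataclass(frozen=True)
class Persona:
    persona_id: str
    county: str
    ages: tuple[int, ...] = tuple(range(18, 36))
    age_weights: Optional[tuple[float, ...]] = None
    # distribution over reported substance sets (tuples of drug ids or
    # "none_of_these")
    substance_profiles: tuple[tuple[tuple[str, ...], float], ...] = ((("heroin",), 1.0),)
    most_often_weights: Mapping[str, float] = field(default_factory=dict)
    formulations: Mapping[str, str] = field(default_factory=dict)
    used_24h_prob: float = 0.0
    knowledge: KnowledgeModel = field(default_factory=KnowledgeModel)
    completion_prob: float = 1.0
    ground_truth_eligible: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.completion_prob <= 1.0:
            raise ValueError("completion_prob outside [0, 1]")
        if not 0.0 <= self.used_24h_prob <= 1.0:
            raise ValueError("used_24h_prob outside [0, 1]")
        _norm_weights([w for _, w in self.substance_profiles], self.persona_id)
        if self.age_weights is not None and len(self.age_weights) != len(self.ages):
            raise ValueError("age_weights length must match ages")

    # --- exact marginals consumed by the oracle ---

    def _age_dist(self) -> np.ndarray:
        if self.age_weights is None:
            return np.full(len(self.ages), 1.0 / len(self.ages))
        return _norm_weights(self.age_weights, self.persona_id)

    def prob_age_ok(self, flow: ScreeningFlowSpec) -> float:
        w = self._age_dist()
        return float(sum(wi for a, wi in zip(self.ages, w) if flow.age_ok(a)))

    def _profile_weights(self) -> np.ndarray:
        return _norm_weights([w for _, w in self.substance_profiles], self.persona_id)

    def prob_opioid(self, catalog) -> float:
        w = self._profile_weights()
        return float(
            sum(
                wi
                for (subs, _), wi in zip(self.substance_profiles, w)
                if any(s in catalog and catalog.is_opioid(s) for s in subs)
            )
        )

    def _most_often_given(self, opioids: Sequence[str]) -> dict[str, float]:
        """Preference over an offered opioid list: the persona's weights
        restricted and renormalised, uniform when none are registered."""
        base = {d: self.most_often_weights.get(d, 0.0) for d in opioids}
        tot = sum(base.values())
        if tot <= 0:
            return {d: 1.0 / len(opioids) for d in opioids}
        return {d: v / tot for d, v in base.items()}

    def most_often_distribution(self, catalog) -> dict[str, float]:
        """P(most-often opioid = drug | an opioid was reported)."""
        w = self._profile_weights()
        p_op = self.prob_opioid(catalog)
        out: dict[str, float] = {}
        if p_op == 0.0:
            return out
        for (subs, _), wi in zip(self.substance_profiles, w):
            opioids = [s for s in subs if s in catalog and catalog.is_opioid(s)]
            if not opioids:
                continue
            for d, pd in self._most_often_given(opioids).items():
                out[d] = out.get(d, 0.0) + wi * pd / p_op
        return out

    def formulation_for(self, drug: str) -> Optional[str]:
        return self.formulations.get(drug)


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of personas: integer counts, or mixing weights plus ``n``."""

    personas: tuple[tuple[Persona, float], ...]
    n: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.personas:
            raise ValueError("empty population spec")
        amounts = [a for _, a in self.personas]
        if any(a < 0 for a in amounts):
            raise ValueError("negative persona counts/weights")
        fractional = any(a != int(a) for a in amounts)
        if fractional or self.n is not None:
            if self.n is None or self.n <= 0:
                raise ValueError("mixing weights require a positive total n")
            if abs(sum(amounts) - 1.0) > 1e-9:
                raise ValueError("fractional mixing weights must sum to 1")
        elif sum(amounts) <= 0:
            raise ValueError("total population size must be positive")


class SimulatedRespondent:
    """One synthetic respondent: demographics drawn at construction, item
    answers drawn per presentation from the persona's knowledge model."""

    def __init__(self, persona: Persona, respondent_id: str, rng: np.random.Generator):
        self.persona = persona
        self.respondent_id = respondent_id
        self._rng = rng
        w = persona._age_dist()
        self.reported_age = int(rng.choice(np.asarray(persona.ages), p=w))
        self.reported_county = persona.county
        pw = persona._profile_weights()
        idx = int(rng.choice(len(pw), p=pw))
        self.substances_30d = tuple(persona.substance_profiles[idx][0])
        self.used_opioid_24h = bool(rng.random() < persona.used_24h_prob)
        self.completes = bool(rng.random() < persona.completion_prob)

    def choose_most_often(self, opioids: Sequence[str]) -> tuple[str, Optional[str]]:
        dist = self.persona._most_often_given(list(opioids))
        drugs = list(dist)
        drug = drugs[int(self._rng.choice(len(drugs), p=np.asarray(list(dist.values()))))]
        return drug, self.persona.formulation_for(drug)

    def _answer_with_prob(self, item: QuizItem, p: float, rng: np.random.Generator) -> str:
        if not item.correct:
            return str(rng.choice(np.asarray(item.options, dtype=object)))
        want = bool(rng.random() < p)
        pool = [o for o in item.options if (o in item.correct) == want]
        return str(rng.choice(np.asarray(pool, dtype=object)))

    def answer(self, item: QuizItem, rng: np.random.Generator) -> str:
        return self._answer_with_prob(item, self.persona.knowledge.item_prob(item), rng)


class CoachedRespondent(SimulatedRespondent):
    """A retaker (or coached peer): items already seen in prior transcripts
    are answered correctly with probability max(base, carryover); unseen
    items at base knowledge.  Quantifies how the random bank draw resists
    repeat attempts."""

    def __init__(
        self,
        inner: SimulatedRespondent,
        previous: Sequence[SessionTranscript],
        carryover: float,
    ):
        if not previous:
            raise ValueError("coached retake needs at least one prior transcript")
        if not 0.0 <= carryover <= 1.0:
            raise ValueError("carryover outside [0, 1]")
        self.__dict__.update(inner.__dict__)  # share the drawn demographics
        self.respondent_id = f"{inner.respondent_id}-retake"
        self.carryover = carryover
        self.seen = {e.item_id for t in previous for e in t.entries}

    def answer(self, item: QuizItem, rng: np.random.Generator) -> str:
        p = self.persona.knowledge.item_prob(item)
        if item.item_id in self.seen:
            p = max(p, self.carryover)
        return self._answer_with_prob(item, p, rng)


def coached_retake(
    respondent: SimulatedRespondent,
    previous: Sequence[SessionTranscript],
    carryover: float,
) -> CoachedRespondent:
    return CoachedRespondent(respondent, previous, carryover)


def sample_population(spec: PopulationSpec) -> list[SimulatedRespondent]:
    """Materialise a population: reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out: list[SimulatedRespondent] = []
    amounts = [a for _, a in spec.personas]
    if spec.n is None:
        assignment = [
            p for (p, a) in spec.personas for _ in range(int(a))
        ]
    else:
        w = _norm_weights(amounts, "population")
        idx = rng.choice(len(spec.personas), size=spec.n, p=w)
        assignment = [spec.personas[i][0] for i in idx]
    for i, persona in enumerate(assignment):
        out.append(SimulatedRespondent(persona, f"{persona.persona_id}-{i:06d}", rng))
    return out


def simulate_screening(
    spec: PopulationSpec, config: ScreeningConfig
) -> tuple[list[SessionTranscript], list]:
    """Sample a population and run every respondent through the engine;
    session randomness is derived from ``spec.seed``."""
    rng = np.random.default_rng((spec.seed, 1))
    transcripts, results = [], []
    for r in sample_population(spec):
        t, res = run_session(r, config, rng)
        transcripts.append(t)
        results.append(res)
    return transcripts, results


# ---------------------------------------------------------------------------
# Default persona library
# ---------------------------------------------------------------------------


def default_personas(config: ScreeningConfig) -> dict[str, Persona]:
    """Six shipped personas spanning the screen's error surface.

    The knowledgeable-eligible persona's drug-component probabilities use
    the reported per-item accuracies (cap size 0.946, price 0.970, image
    0.994 for heroin; dose 0.95 / image 0.82 for prescription pills); county
    categories sit near the observed ~98% county-quiz pass rate.  The
    recent-mover persona lowers the school-linked categories, reflecting the
    pilot finding that newer residents miss school mascots and colors.  The
    out-of-area guesser falsely claims an eligible county and answers every
    item at structural-guessing probability (a stated lower bound on real
    out-of-area knowledge, not an estimate).
    """
    county = sorted(config.flow.eligible_counties)[0]
    county_known = {
        "towns": 0.96,
        "smallest_communities": 0.88,
        "largest_town": 0.92,
        "jail": 0.95,
        "walmart": 0.97,
        "landmark": 0.94,
        "mascot": 0.97,
        "school_colors": 0.97,
        "festival": 0.96,
        "grocery": 0.98,
    }
    drug_known = {"cap_size": 0.946, "price": 0.970, "image": 0.95, "dose": 0.95}
    knowledgeable = KnowledgeModel({**county_known, **drug_known})
    mover = KnowledgeModel(
        {
            **county_known,
            **drug_known,
            "mascot": 0.55,
            "school_colors": 0.55,
            "smallest_communities": 0.70,
        }
    )
    substances = (
        (("heroin",), 0.55),
        (("percocet", "methamphetamine"), 0.20),
        (("buprenorphine",), 0.15),
        (("heroin", "buprenorphine"), 0.10),
    )
    return {
        "eligible_knowledgeable": Persona(
            persona_id="eligible_knowledgeable",
            county=county,
            substance_profiles=substances,
            most_often_weights={"heroin": 0.7, "buprenorphine": 0.2, "percocet": 0.1},
            used_24h_prob=0.25,
            knowledge=knowledgeable,
            completion_prob=1.0,
            ground_truth_eligible=True,
        ),
        "eligible_recent_mover": Persona(
            persona_id="eligible_recent_mover",
            county=county,
            substance_profiles=substances,
            most_often_weights={"heroin": 0.7, "buprenorphine": 0.2, "percocet": 0.1},
            used_24h_prob=0.25,
            knowledge=mover,
            completion_prob=1.0,
            ground_truth_eligible=True,
        ),
        "out_of_area_guesser": Persona(
            persona_id="out_of_area_guesser",
            county=county,  # falsely claims an eligible county
            substance_profiles=((("heroin",), 1.0),),
            knowledge=KnowledgeModel(),  # pure structural guessing
            ground_truth_eligible=False,
        ),
        "underage": Persona(
            persona_id="underage",
            county=county,
            ages=(16, 17),
            substance_profiles=((("heroin",), 1.0),),
            knowledge=knowledgeable,
            ground_truth_eligible=False,
        ),
        "nonopioid_user": Persona(
            persona_id="nonopioid_user",
            county=county,
            substance_profiles=((("methamphetamine",), 1.0),),
            knowledge=knowledgeable,
            ground_truth_eligible=False,
        ),
        "abandoner": Persona(
            persona_id="abandoner",
            county=county,
            substance_profiles=substances,
            most_often_weights={"heroin": 0.7, "buprenorphine": 0.2, "percocet": 0.1},
            knowledge=knowledgeable,
            completion_prob=0.25,
            ground_truth_eligible=True,
        ),
    }


# ---------------------------------------------------------------------------
# Vectorised pass-rate path (same stochastic model, numpy-batched)
# ---------------------------------------------------------------------------


def pass_rate(
    persona: Persona, config: ScreeningConfig, n: int, seed: int
) -> tuple[float, int]:
    """Monte-Carlo eligibility rate for one persona at sample size ``n``,
    conditional on completed sessions.  Implements the identical stochastic
    model as the object-level session path, batched in numpy; the two are
    cross-checked in the test suite.  Returns (rate, completed count)."""
    rng = np.random.default_rng(seed)
    flow, catalog = config.flow, config.catalog

    completes = rng.random(n) < persona.completion_prob
    ages = rng.choice(np.asarray(persona.ages), size=n, p=persona._age_dist())
    age_ok = (ages >= flow.age_min) & (ages <= flow.age_max)

    in_area = persona.county in flow.eligible_counties
    if in_area:
        profile = np.asarray(
            item_success_profile(config.banks[persona.county], persona.knowledge)
        )
        draw = np.argsort(rng.random((n, profile.size)), axis=1)[:, : config.county_quiz.draw_size]
        correct = rng.random(draw.shape) < profile[draw]
        county_pass = correct.sum(axis=1) >= config.county_quiz.pass_threshold
    else:
        county_pass = np.zeros(n, dtype=bool)

    pw = persona._profile_weights()
    prof_idx = rng.choice(len(pw), size=n, p=pw)
    opioid_lists = [
        [s for s in subs if s in catalog and catalog.is_opioid(s)]
        for subs, _ in persona.substance_profiles
    ]
    has_opioid = np.asarray([bool(o) for o in opioid_lists])[prof_idx]

    # drug quiz: component success probabilities per most-often candidate
    from .oracle import _drug_component_profile, drug_pass_probability  # local: avoid cycle at import time

    quiz_cache: dict[str, tuple[float, ...]] = {}

    def comp_probs(drug: str) -> tuple[float, ...]:
        if drug not in quiz_cache:
            quiz = build_drug_quiz(catalog, drug, persona.formulation_for(drug))
            if quiz.auto_pass:
                quiz_cache[drug] = ()
            else:
                prof = _drug_component_profile(quiz, persona.knowledge)
                quiz_cache[drug] = tuple(prof[c] for c in quiz.scored_components)
        return quiz_cache[drug]

    drug_pass = np.zeros(n, dtype=bool)
    for k, opioids in enumerate(opioid_lists):
        mask = (prof_idx == k) & has_opioid
        m = int(mask.sum())
        if m == 0:
            continue
        dist = persona._most_often_given(opioids)
        drugs = list(dist)
        pick = rng.choice(len(drugs), size=m, p=np.asarray(list(dist.values())))
        sub_pass = np.zeros(m, dtype=bool)
        for j, drug in enumerate(drugs):
            dm = pick == j
            if not dm.any():
                continue
            probs = comp_probs(drug)
            if not probs:  # auto-pass (synthetic opioid)
                sub_pass[dm] = True
                continue
            u = rng.random((int(dm.sum()), len(probs)))
            sub_pass[dm] = (u < np.asarray(probs)).any(axis=1)
        drug_pass[mask] = sub_pass

    eligible = age_ok & county_pass & has_opioid & drug_pass
    n_complete = int(completes.sum())
    if n_complete == 0:
        return float("nan"), 0
    return float(eligible[completes].mean()), n_complete
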