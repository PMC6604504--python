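"""Exact pass probabilities against independent brute-force oracles."""

from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quizscreen.model import CountyQuizSpec, build_drug_quiz
from quizscreen.oracle import (
    county_pass_probability,
    drug_pass_probability,
    item_success_profile,
    poisson_binomial_tail,
    screen_operating_characteristics,
    screen_pass_probability,
)
from quizscreen.simulate import KnowledgeModel, Persona


def enum_tail(probs, k):
    """Exact-rational enumeration over all 2^n outcome vectors."""
    fr = [Fraction.from_float(float(p)) for p in probs]
    total = Fraction(0)
    for outcome in product((0, 1), repeat=len(fr)):
        if sum(outcome) < k:
            continue
        term = Fraction(1)
        for o, p in zip(outcome, fr):
            term *= p if o else 1 - p
        total += term
    return total


class TestPoissonBinomialTail:
    def test_binomial_closed_form(self):
        # five 4-option items, 3-of-5 rule: sum_{j>=3} C(5,j) .25^j .75^(5-j)
        assert poisson_binomial_tail([0.25] * 5, 3) == pytest.approx(0.103515625, abs=1e-12)

    def test_certain_items(self):
        assert poisson_binomial_tail([1.0] * 4, 4) == pytest.approx(1.0, abs=1e-12)

    def test_two_coins(self):
        assert poisson_binomial_tail([0.5, 0.5], 1) == pytest.approx(0.75, abs=1e-12)

    def test_tail_at_zero_is_exactly_one(self):
        assert poisson_binomial_tail([0.123, 0.456, 0.789], 0) == 1.0

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_tail([0.5, 1.5], 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        probs=st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=12
        ),
        k=st.integers(min_value=0, max_value=12),
    )
    def test_dp_equals_exhaustive_enumeration(self, probs, k):
        dp = poisson_binomial_tail(probs, k)
        exact = float(enum_tail(probs, k))
        assert dp == pytest.approx(exact, abs=1e-10)


class TestCountyPassProbability:
    def test_homogeneous_bank_reduces_to_binomial(self):
        assert county_pass_probability([0.25] * 10) == pytest.approx(0.103515625, abs=1e-12)

    def test_certain_knowledge(self):
        assert county_pass_probability([1.0] * 10) == pytest.approx(1.0, abs=1e-12)

    def test_mixed_bank_matches_full_enumeration(self):
        """5 yes/no (p=.5) + 5 four-option (p=.25) items: average over all
        252 draws of the exact-rational outcome enumeration."""
        profile = [0.5] * 5 + [0.25] * 5
        total = Fraction(0)
        for idx in combinations(range(10), 5):
            total += enum_tail([profile[i] for i in idx], 3)
        expected = float(total / 252)
        assert county_pass_probability(profile) == pytest.approx(expected, abs=1e-12)

    def test_bank_smaller_than_draw_rejected(self):
        with pytest.raises(ValueError):
            county_pass_probability([0.5] * 4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        bump=st.integers(min_value=0, max_value=9),
        delta=st.floats(min_value=0.0, max_value=0.5),
    )
    def test_monotone_in_item_probability(self, bump, delta):
        base = [0.3] * 10
        raised = list(base)
        raised[bump] = min(1.0, base[bump] + delta)
        assert county_pass_probability(raised) >= county_pass_probability(base) - 1e-12


class TestDrugPassProbability:
    def test_heroin_guesser(self, config):
        quiz = build_drug_quiz(config.catalog, "heroin")
        assert drug_pass_probability(quiz, {"cap_size": 0.25, "price": 0.25}) == pytest.approx(
            0.4375, abs=1e-12
        )

    def test_roxicodone_guesser_half_half(self, config):
        quiz = build_drug_quiz(config.catalog, "roxicodone")
        assert drug_pass_probability(quiz, {"dose": 0.5, "image": 0.5}) == pytest.approx(
            0.75, abs=1e-12
        )

    def test_synthetic_auto_pass(self, config):
        quiz = build_drug_quiz(config.catalog, "synthetic_opioid")
        assert drug_pass_probability(quiz, {}) == 1.0

    def test_missing_component_rejected(self, config):
        quiz = build_drug_quiz(config.catalog, "heroin")
        with pytest.raises(ValueError, match="price"):
            drug_pass_probability(quiz, {"cap_size": 0.25})

    def test_guessing_profile_from_item_structure(self, config):
        """The 50/50 rule pins every dose/image guess at one half, whatever
        the number of manufactured doses."""
        for drug in ("roxicodone", "tylox", "oxycontin", "buprenorphine"):
            quiz = build_drug_quiz(config.catalog, drug)
            assert quiz.dose_item.guess_probability == 0.5
            assert quiz.image_all_item.guess_probability == 0.5


class TestOperatingCharacteristics:
    def test_perfect_knowledge_sensitivity_one(self, config):
        persona = Persona(
            persona_id="perfect",
            county=sorted(config.flow.eligible_counties)[0],
            knowledge=KnowledgeModel(fallback=1.0),
            ground_truth_eligible=True,
        )
        assert screen_pass_probability(persona, config) == pytest.approx(1.0, abs=1e-12)

    def test_truthful_outsider_specificity_one(self, config):
        persona = Persona(
            persona_id="outside",
            county="somewhere else",
            knowledge=KnowledgeModel(fallback=1.0),
            ground_truth_eligible=False,
        )
        assert screen_pass_probability(persona, config) == 0.0

    def test_false_claim_misclassification_composes(self, config):
        """A guessing outsider claiming an eligible county passes with
        county-tail x drug-OR probability exactly."""
        county = sorted(config.flow.eligible_counties)[0]
        persona = Persona(
            persona_id="imposter",
            county=county,
            substance_profiles=((("heroin",), 1.0),),
            knowledge=KnowledgeModel(),  # structural guessing
            ground_truth_eligible=False,
        )
        profile = item_success_profile(config.banks[county])
        expected = county_pass_probability(profile) * 0.4375
        assert screen_pass_probability(persona, config) == pytest.approx(expected, rel=1e-12)

    def test_operating_point_bayes_consistency(self, config, personas):
        mix = [(personas["eligible_knowledgeable"], 0.5),
               (personas["out_of_area_guesser"], 0.3),
               (personas["underage"], 0.2)]
        op = screen_operating_characteristics(mix, config)
        p_elig = screen_pass_probability(personas["eligible_knowledgeable"], config)
        p_guess = screen_pass_probability(personas["out_of_area_guesser"], config)
        ppv = 0.5 * p_elig / (0.5 * p_elig + 0.3 * p_guess)
        assert op.sensitivity == pytest.approx(p_elig)
        assert op.ppv == pytest.approx(ppv)
        assert 0 <= op.specificity <= 1
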