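"""Branching flow, scoring rules, and funnel aggregation."""

import numpy as np
import pytest

from quizscreen.engine import (
    ScriptedRespondent,
    classify_funnel,
    draw_county_quiz,
    run_session,
    score_county_quiz,
    score_drug_quiz,
)
from quizscreen.model import CountyQuizSpec, QuestionBank, build_drug_quiz


def _eligible(config, **kw):
    county = sorted(config.flow.eligible_counties)[0]
    defaults = dict(respondent_id="r", reported_county=county, substances_30d=("heroin",))
    defaults.update(kw)
    return ScriptedRespondent(**defaults)


class TestCountyQuiz:
    def test_draw_is_uniform_without_replacement(self, config):
        bank = config.banks["ashford"]
        spec = config.county_quiz
        counts = np.zeros(10)
        n = 20000
        rng = np.random.default_rng(11)
        ids = [it.item_id for it in bank.items]
        for _ in range(n):
            for it in draw_county_quiz(bank, spec, rng):
                counts[ids.index(it.item_id)] += 1
        freq = counts / n
        se = np.sqrt(0.5 * 0.5 / n)
        assert np.all(np.abs(freq - 0.5) < 3 * se)

    def test_draw_deterministic_under_seed(self, config):
        bank = config.banks["ashford"]
        a = draw_county_quiz(bank, config.county_quiz, 42)
        b = draw_county_quiz(bank, config.county_quiz, 42)
        assert [i.item_id for i in a] == [i.item_id for i in b]

    def test_small_bank_rejected(self, config):
        bank = QuestionBank(bank_id="tiny", items=config.banks["ashford"].items[:4])
        with pytest.raises(ValueError, match="draw"):
            draw_county_quiz(bank, config.county_quiz, 0)

    @pytest.mark.parametrize(
        "pattern, expected",
        [((1, 1, 1, 0, 0), (3, True)), ((1, 1, 0, 0, 0), (2, False)), ((1, 1, 1, 1, 1), (5, True))],
    )
    def test_three_of_five_rule(self, config, pattern, expected):
        items = draw_county_quiz(config.banks["ashford"], config.county_quiz, 3)
        responses = []
        for it, want in zip(items, pattern):
            pool = [o for o in it.options if (o in it.correct) == bool(want)]
            responses.append(pool[0])
        assert score_county_quiz(items, responses, config.county_quiz) == expected

    def test_wrong_response_count_rejected(self, config):
        items = draw_county_quiz(config.banks["ashford"], config.county_quiz, 3)
        with pytest.raises(ValueError):
            score_county_quiz(items, ["x"] * 4, config.county_quiz)


class TestDrugQuizScoring:
    def test_heroin_either_or_rule(self, config):
        quiz = build_drug_quiz(config.catalog, "heroin")
        # cap correct, price and image wrong -> pass
        _, ok = score_drug_quiz(quiz, {"cap_size": True, "price": False, "image": False})
        assert ok is True
        # only the unscored image correct -> fail
        _, ok = score_drug_quiz(quiz, {"cap_size": False, "price": False, "image": True})
        assert ok is False

    def test_prescription_dose_or_image_rule(self, config):
        quiz = build_drug_quiz(config.catalog, "roxicodone")
        _, ok = score_drug_quiz(quiz, {"dose": False, "image": True})
        assert ok is True
        _, ok = score_drug_quiz(quiz, {"dose": False, "image": False})
        assert ok is False

    def test_synthetic_opioid_auto_pass(self, config):
        quiz = build_drug_quiz(config.catalog, "synthetic_opioid")
        _, ok = score_drug_quiz(quiz, {})
        assert ok is True

    def test_nonopioid_not_applicable(self, config):
        quiz = build_drug_quiz(config.catalog, "methamphetamine")
        _, ok = score_drug_quiz(quiz, {})
        assert ok is None

    def test_missing_scored_component_rejected(self, config):
        quiz = build_drug_quiz(config.catalog, "heroin")
        with pytest.raises(ValueError, match="price"):
            score_drug_quiz(quiz, {"cap_size": True})


class TestSessionBranching:
    def test_fully_eligible_respondent(self, config):
        _, res = run_session(_eligible(config), config, 0)
        assert res.eligible
        assert res.ineligibility_reasons == frozenset()
        assert res.county_quiz_score == 5

    def test_age_out_of_range_flagged_but_flow_continues(self, config):
        t, res = run_session(_eligible(config, reported_age=36), config, 0)
        assert not res.eligible
        assert "age" in res.ineligibility_reasons
        # masking: quizzes were still administered
        assert res.county_quiz_score is not None
        assert res.drug_quiz_pass is True

    def test_outside_county_gets_generic_unscored_quiz(self, config):
        t, res = run_session(_eligible(config, reported_county="elsewhere"), config, 0)
        assert res.ineligibility_reasons == frozenset({"outside_area"})
        assert res.county_quiz_score is None
        county_entries = [e for e in t.entries if e.item_id.startswith("generic-")]
        assert len(county_entries) == 5
        assert all(e.correct is None and not e.scored for e in county_entries)

    def test_nonopioid_only_user_gets_masking_quiz(self, config):
        t, res = run_session(
            _eligible(config, substances_30d=("methamphetamine",)), config, 0
        )
        assert res.ineligibility_reasons == frozenset({"no_substance"})
        masked = [e for e in t.entries if e.item_id.startswith("methamphetamine-")]
        assert len(masked) == 3
        assert all(not e.scored for e in masked)

    def test_no_substance_skips_quizzes(self, config):
        t, res = run_session(
            _eligible(config, substances_30d=("none_of_these",)), config, 0
        )
        assert res.ineligibility_reasons == frozenset({"no_substance"})
        assert len(t.entries) == 5  # only the county quiz

    def test_most_often_restricted_to_opioids(self, config):
        t, res = run_session(
            _eligible(config, substances_30d=("methamphetamine", "heroin")), config, 0
        )
        assert t.most_often_opioid == "heroin"
        assert res.eligible

    def test_county_quiz_failure_continues_to_drug_quiz(self, config):
        t, res = run_session(_eligible(config, n_correct_county=2), config, 0)
        assert res.ineligibility_reasons == frozenset({"county_quiz_fail"})
        assert res.drug_quiz_pass is True  # still asked and passed

    def test_incomplete_session_excluded(self, config):
        t, res = run_session(_eligible(config, completes=False), config, 0)
        assert not t.complete
        assert res.ineligibility_reasons == frozenset({"incomplete"})

    def test_dose_miss_branches_to_all_doses_image(self, config):
        r = _eligible(
            config,
            substances_30d=("roxicodone",),
            correct_by_category={"dose": False, "image": True},
        )
        t, res = run_session(r, config, 0)
        image_entries = [e for e in t.entries if e.component == "image"]
        assert len(image_entries) == 1
        assert image_entries[0].item_id.endswith("image-all")
        assert res.drug_quiz_pass is True

    def test_engine_determinism(self, config):
        for seed in (0, 5):
            a = run_session(_eligible(config), config, seed)
            b = run_session(_eligible(config), config, seed)
            assert a[0] == b[0]
            assert a[1] == b[1]

    def test_brute_force_rescoring_matches_result(self, config):
        """Re-derive pass/fail by enumerating transcript entries directly."""
        cases = [
            _eligible(config),
            _eligible(config, n_correct_county=3),
            _eligible(config, correct_by_category={"cap_size": False, "price": True}),
            _eligible(config, substances_30d=("percocet",),
                      correct_by_category={"dose": True, "image": False}),
            _eligible(config, substances_30d=("percocet",),
                      correct_by_category={"dose": False, "image": False}),
        ]
        for r in cases:
            t, res = run_session(r, config, 1)
            county = [e for e in t.entries if e.scored and e.component not in
                      ("cap_size", "price", "dose", "image")]
            if county:
                score = sum(e.correct for e in county)
                assert score == res.county_quiz_score
                assert (score >= 3) == res.county_quiz_pass
            scored_drug = [e for e in t.entries if e.scored and e.component in
                           ("cap_size", "price", "dose", "image")]
            if scored_drug:
                assert any(e.correct for e in scored_drug) == res.drug_quiz_pass


class TestFunnel:
    def test_empty_input(self):
        rep = classify_funnel([])
        assert rep.total == rep.complete == rep.eligible == 0

    def test_all_eligible(self, config):
        results = [run_session(_eligible(config, respondent_id=f"r{i}"), config, i)[1]
                   for i in range(3)]
        rep = classify_funnel(results)
        assert rep.eligible == 3
        assert all(v == 0 for v in rep.reasons.values())

    def test_conservation_and_reason_bounds(self, config):
        rng = np.random.default_rng(2)
        results = []
        county = sorted(config.flow.eligible_counties)[0]
        for i in range(200):
            r = ScriptedRespondent(
                respondent_id=f"r{i}",
                reported_county=county if rng.random() < 0.8 else "far away",
                reported_age=int(rng.integers(15, 45)),
                substances_30d=("heroin",) if rng.random() < 0.7 else ("none_of_these",),
                completes=bool(rng.random() < 0.85),
                n_correct_county=int(rng.integers(0, 6)),
                correct_by_category={"cap_size": bool(rng.random() < 0.8),
                                     "price": bool(rng.random() < 0.8)},
            )
            results.append(run_session(r, config, rng)[1])
        rep = classify_funnel(results)
        assert rep.incomplete + rep.complete == rep.total
        assert rep.eligible + rep.ineligible == rep.complete
        assert all(v <= rep.ineligible for v in rep.reasons.values())
        assert sum(rep.first_failure.values()) == rep.ineligible
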