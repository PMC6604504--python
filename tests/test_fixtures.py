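"""Constraint allocation, infeasibility detection, and engine replay."""

from itertools import product

import pandas as pd
import pytest

from quizscreen.fixtures import (
    Constraint,
    FixtureSlice,
    InfeasibleConstraints,
    _matches,
    allocate_cells,
    build_fixture,
    replay_fixture,
    shipped_slice,
    shipped_slice_ids,
    verify_fixture,
)


def brute_force_feasible(slice_, constraints):
    """Exhaustive small-instance solver: enumerate all nonnegative integer
    cell-count vectors up to the stated total."""
    cells = [dict(zip(slice_.fields, combo)) for combo in product(*slice_.fields.values())]
    total = next(c.count for c in constraints if not c.where)
    masks = [
        [1 if _matches(cell, c.where, slice_.derived) else 0 for cell in cells]
        for c in constraints
    ]
    counts = [c.count for c in constraints]

    def rec(i, remaining, acc):
        if i == len(cells):
            if remaining:
                return False
            return all(
                sum(m * a for m, a in zip(mask, acc)) == want
                for mask, want in zip(masks, counts)
            )
        return any(rec(i + 1, remaining - k, acc + [k]) for k in range(remaining + 1))

    return rec(0, total, [])


def _toy_slice(constraints):
    return FixtureSlice(
        slice_id="toy",
        kind="drug_quiz",
        fields={"a": (True, False), "b": (True, False)},
        derived={"ok": "a or b"},
        constraints=tuple(constraints),
    )


class TestAllocation:
    def test_heroin_slice_integer_accounting(self):
        """154 both + 5 cap-only + 9 price-only + 4 neither = 172."""
        cells = dict()
        for cell, k in allocate_cells(shipped_slice("heroin")):
            cells[(cell["cap_size_correct"], cell["price_correct"])] = (
                cells.get((cell["cap_size_correct"], cell["price_correct"]), 0) + k
            )
        assert cells[(True, True)] == 154
        assert cells[(True, False)] == 5
        assert cells[(False, True)] == 9
        assert cells[(False, False)] == 4

    def test_buprenorphine_marginals_infeasible_with_minimal_subset(self):
        """(60-53) + (58-53) + 53 = 65 > 63 passers: every constraint in the
        reported subset is needed for the contradiction."""
        with pytest.raises(InfeasibleConstraints) as exc:
            build_fixture(shipped_slice("buprenorphine_pills"))
        conflict = set(exc.value.conflict)
        assert {"passers_dose_correct", "passers_image_correct",
                "passers_both_correct"} <= conflict
        # dropping any single member restores feasibility (minimality)
        sl = shipped_slice("buprenorphine_pills")
        for name in conflict:
            reduced = FixtureSlice(
                slice_id="reduced", kind=sl.kind, fields=sl.fields, derived=sl.derived,
                constraints=tuple(c for c in sl.constraints if c.name != name),
                context=sl.context,
            )
            allocate_cells(reduced)  # must not raise

    def test_empty_constraint_set_gives_default_records(self):
        sl = _toy_slice([Constraint(name="n", where={}, count=10)])
        fx = build_fixture(sl)
        assert len(fx.records) == 10
        assert all(r["a"] and r["b"] for r in fx.records)  # deterministic defaults

    def test_construction_deterministic(self):
        sl = shipped_slice("prescription")
        a = build_fixture(sl, seed=0).records
        b = build_fixture(sl, seed=0).records
        assert a == b

    @pytest.mark.parametrize(
        "constraints, feasible",
        [
            ([("n", {}, 6), ("a", {"a": True}, 4), ("b", {"b": True}, 3),
              ("ab", {"a": True, "b": True}, 1)], True),
            ([("n", {}, 3), ("a", {"a": True}, 3), ("b", {"b": True}, 3),
              ("ab", {"a": True, "b": True}, 1)], False),  # union 5 > 3
            ([("n", {}, 5), ("ok", {"ok": False}, 6)], False),
            # ok = a or b is a superset of a, so ok-count < a-count conflicts
            ([("n", {}, 5), ("a", {"a": True}, 3), ("ok", {"ok": True}, 2)], False),
        ],
    )
    def test_agrees_with_exhaustive_solver(self, constraints, feasible):
        cons = [Constraint(name=n, where=w, count=c) for n, w, c in constraints]
        sl = _toy_slice(cons)
        assert brute_force_feasible(sl, cons) is feasible
        if feasible:
            allocate_cells(sl)
        else:
            with pytest.raises(InfeasibleConstraints):
                allocate_cells(sl)


class TestVerification:
    def test_fresh_fixture_satisfies_all(self):
        sl = shipped_slice("heroin")
        assert verify_fixture(build_fixture(sl), sl).all_satisfied

    def test_single_flip_violates_exactly_touched_constraints(self):
        sl = shipped_slice("heroin")
        fx = build_fixture(sl)
        # flip one both-correct record's price flag
        rec = next(r for r in fx.records if r["cap_size_correct"] and r["price_correct"])
        rec["price_correct"] = False
        rep = verify_fixture(fx, sl)
        bad = set(rep.rows.loc[~rep.rows["satisfied"], "constraint"])
        assert bad == {"passers_price_correct", "passers_both_correct"}


class TestReplay:
    @pytest.mark.parametrize("slice_id", [s for s in
                             ["heroin", "prescription", "buprenorphine_pills_marginal",
                              "buprenorphine_strips", "methadone", "county", "funnel",
                              "reasons", "drug_overall", "udt"]])
    def test_replayed_outcomes_satisfy_every_constraint(self, config, slice_id):
        """Pass/fail must emerge from re-scoring the transcripts with the
        real engine, not from stored outcome flags."""
        sl = shipped_slice(slice_id)
        out = replay_fixture(build_fixture(sl, seed=0), config, seed=0)
        rep = verify_fixture(out, sl)
        assert rep.all_satisfied, rep.to_text()

    def test_funnel_slice_reproduces_headline_counts(self, config):
        from quizscreen.engine import ScreeningResult, classify_funnel

        out = replay_fixture(build_fixture(shipped_slice("funnel")), config)
        results = [
            ScreeningResult(respondent_id=str(r.respondent_id), complete=bool(r.complete),
                            eligible=bool(r.eligible),
                            ineligibility_reasons=frozenset(r.reasons))
            for r in out.itertuples()
        ]
        rep = classify_funnel(results)
        assert (rep.total, rep.incomplete, rep.complete) == (528, 118, 410)
        assert (rep.eligible, rep.ineligible) == (234, 176)
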