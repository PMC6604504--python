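"""Synthesize record-level tables that satisfy printed marginal counts.

The study deposited no microdata; what survives are marginal counts (funnel
nodes, per-item accuracies among quiz passers, UDT panel positives).  This
module rebuilds record-level tables consistent with those counts so that
every published percentage can be *recomputed* by running the real engine
over records: fixtures store per-item correctness, never outcomes, and
pass/fail flags must emerge from re-scoring.

Construction: a slice declares categorical allocation fields, derived
boolean expressions, and exact-count constraints (conjunctions of
field-membership terms).  Counts are allocated over the cross-classification
cells by integer programming (HiGHS via scipy); under-determined cells are
filled deterministically by a cost that prefers default field values, and
infeasible slices are reported with a minimal conflicting constraint subset
found by a deletion filter.

Printed counts are mutually inconsistent in places (two different
ineligible denominators, 15 implied vs 12 stated quiz failures, the
buprenorphine-pill 60/58/53-of-63 marginals), so the shipped constraint
files are organized per slice — each internally consistent and
independently replayable — rather than as one global set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import Bounds, LinearConstraint, milp

from .engine import ScriptedRespondent, run_session
from .model import ScreeningConfig, default_config

__all__ = [
    "Constraint",
    "FixtureSlice",
    "FixtureTable",
    "InfeasibleConstraints",
    "VerificationReport",
    "load_slice",
    "shipped_slice",
    "shipped_slice_ids",
    "allocate_cells",
    "build_fixture",
    "replay_fixture",
    "verify_fixture",
]


class InfeasibleConstraints(ValueError):
    """No record-level table can satisfy the constraints.

    ``conflict`` names a minimal subset of constraints that is already
    infeasible (removing any one of them restores feasibility).
    """

    def __init__(self, slice_id: str, conflict: Sequence[str]):
        self.slice_id = slice_id
        self.conflict = tuple(conflict)
        super().__init__(
            f"slice {slice_id!r} is infeasible; minimal conflicting constraints: "
            + ", ".join(self.conflict)
        )


@dataclass(frozen=True)
class Constraint:
    name: str
    where: Mapping[str, object] = field(default_factory=dict)
    count: Optional[int] = None
    mean: Optional[float] = None  # mean-of-field constraint (verify only)
    of: Optional[str] = None  # field the mean applies to
    digits: int = 2
    provenance: str = ""

    def __post_init__(self) -> None:
        if (self.count is None) == (self.mean is None):
            raise ValueError(f"constraint {self.name!r}: give exactly one of count/mean")
        if self.count is not None and self.count < 0:
            raise ValueError(f"constraint {self.name!r}: negative count")
        if self.mean is not None and self.of is None:
            raise ValueError(f"constraint {self.name!r}: mean needs a field ('of')")


@dataclass(frozen=True)
class FixtureSlice:
    slice_id: str
    kind: str  # drug_quiz | funnel | county | concat | udt
    provenance: str = ""
    fields: Mapping[str, tuple] = field(default_factory=dict)
    derived: Mapping[str, str] = field(default_factory=dict)
    constraints: tuple[Constraint, ...] = ()
    context: Mapping[str, object] = field(default_factory=dict)
    parts: tuple[str, ...] = ()  # for kind=concat
    extra: tuple[Mapping[str, object], ...] = ()  # for kind=concat


@dataclass
class FixtureTable:
    slice: FixtureSlice
    records: list[dict]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class VerificationReport:
    slice_id: str
    rows: pd.DataFrame  # constraint, required, observed, satisfied

    @property
    def all_satisfied(self) -> bool:
        return bool(self.rows["satisfied"].all())

    def to_text(self) -> str:
        head = f"slice {self.slice_id}: " + (
            "all constraints satisfied" if self.all_satisfied else "VIOLATIONS"
        )
        return head + "\n" + self.rows.to_string(index=False)


# ---------------------------------------------------------------------------
# Predicates
# ---------------------------------------------------------------------------


def _derived_values(record: Mapping, derived: Mapping[str, str]) -> dict:
    env = dict(record)
    for name, expr in derived.items():
        env[name] = eval(expr, {"__builtins__": {}}, env)  # noqa: S307 - shipped expressions
    return env


def _matches(record: Mapping, where: Mapping[str, object], derived: Mapping[str, str]) -> bool:
    env = _derived_values(record, derived)
    for fieldname, allowed in where.items():
        vals = allowed if isinstance(allowed, (list, tuple, set)) else [allowed]
        if fieldname not in env or env[fieldname] not in vals:
            return False
    return True


# ---------------------------------------------------------------------------
# Integer allocation over cross-classification cells
# ---------------------------------------------------------------------------


def _cells(slice_: FixtureSlice) -> list[dict]:
    names = list(slice_.fields)
    return [dict(zip(names, combo)) for combo in product(*slice_.fields.values())]


def _solve(slice_: FixtureSlice, constraints: Sequence[Constraint]) -> Optional[np.ndarray]:
    cells = _cells(slice_)
    ncell = len(cells)
    rows, rhs = [], []
    for c in constraints:
        rows.append([1.0 if _matches(cell, c.where, slice_.derived) else 0.0 for cell in cells])
        rhs.append(float(c.count))
    # deterministic fill of free cells: prefer default (first-listed) values
    names = list(slice_.fields)
    defaults = {n: slice_.fields[n][0] for n in names}
    cost = np.array(
        [
            sum(cell[n] != defaults[n] for n in names) + 1e-6 * i
            for i, cell in enumerate(cells)
        ]
    )
    a = np.array(rows)
    b = np.array(rhs)
    res = milp(
        c=cost,
        constraints=[LinearConstraint(a, b, b)],
        integrality=np.ones(ncell),
        bounds=Bounds(0, np.inf),
    )
    if not res.success:
        return None
    return np.round(res.x).astype(int)


def _minimal_conflict(slice_: FixtureSlice, constraints: list[Constraint]) -> list[str]:
    """Deletion filter: drop each constraint in turn; keep it only if the
    remainder becomes feasible without it."""
    core = list(constraints)
    i = 0
    while i < len(core):
        trial = core[:i] + core[i + 1 :]
        if trial and _solve(slice_, trial) is None:
            core = trial  # still infeasible without it: not needed
        else:
            i += 1
    return [c.name for c in core]


def allocate_cells(slice_: FixtureSlice) -> list[tuple[dict, int]]:
    """Allocate nonnegative integer counts to cross-classification cells so
    that every count constraint holds exactly."""
    count_constraints = [c for c in slice_.constraints if c.count is not None]
    if not count_constraints:
        raise ValueError(f"slice {slice_.slice_id!r} has no count constraints")
    x = _solve(slice_, count_constraints)
    if x is None:
        conflict = _minimal_conflict(slice_, count_constraints)
        raise InfeasibleConstraints(slice_.slice_id, conflict)
    return [(cell, int(k)) for cell, k in zip(_cells(slice_), x) if k > 0]


# ---------------------------------------------------------------------------
# Slice files
# ---------------------------------------------------------------------------


def _slice_from_doc(doc: Mapping) -> FixtureSlice:
    constraints = tuple(
        Constraint(
            name=c["name"],
            where=c.get("where", {}),
            count=c.get("count"),
            mean=c.get("mean"),
            of=c.get("of"),
            digits=c.get("digits", 2),
            provenance=c.get("provenance", ""),
        )
        for c in doc.get("constraints", [])
    )
    return FixtureSlice(
        slice_id=doc["slice_id"],
        kind=doc["kind"],
        provenance=doc.get("provenance", ""),
        fields={k: tuple(v) for k, v in doc.get("fields", {}).items()},
        derived=dict(doc.get("derived", {})),
        constraints=constraints,
        context=dict(doc.get("context", {})),
        parts=tuple(doc.get("parts", ())),
        extra=tuple(doc.get("extra", ())),
    )


def load_slice(path: Union[str, Path]) -> FixtureSlice:
    return _slice_from_doc(yaml.safe_load(Path(path).read_text()))


def shipped_slice(slice_id: str) -> FixtureSlice:
    text = resources.files("quizscreen.data.slices").joinpath(f"{slice_id}.yaml").read_text()
    return _slice_from_doc(yaml.safe_load(text))


def shipped_slice_ids() -> list[str]:
    root = resources.files("quizscreen.data.slices")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


# ---------------------------------------------------------------------------
# Building records
# ---------------------------------------------------------------------------


def build_fixture(slice_: FixtureSlice, seed: int = 0) -> FixtureTable:
    """Deterministic record-level table satisfying the slice constraints.

    Raises :class:`InfeasibleConstraints` (with the minimal conflicting
    subset) when no table exists.  Mean constraints are verification-only;
    the UDT slice is built by a dedicated constructor.
    """
    if slice_.kind == "udt":
        return build_udt_fixture(slice_)
    if slice_.kind == "concat":
        records: list[dict] = []
        for part in slice_.parts:
            records.extend(build_fixture(shipped_slice(part), seed).records)
        for spec in slice_.extra:
            for _ in range(int(spec.get("count", 1))):
                records.append(dict(spec["record"]))
        for i, r in enumerate(records):
            r["respondent_id"] = f"{slice_.slice_id}-{i:04d}"
        return FixtureTable(slice_, records)
    records = []
    i = 0
    for cell, k in allocate_cells(slice_):
        for _ in range(k):
            rec = {"respondent_id": f"{slice_.slice_id}-{i:04d}", **slice_.context, **cell}
            records.append(rec)
            i += 1
    return FixtureTable(slice_, records)


# --- UDT slice: record-level panel positivity solving the union counts ----

_H_DAYS = [1.0] * 4 + [0.62] + [0.0] * 16  # mean 0.22 over 21, range 0-1
_B_DAYS = [3.0, 1.0, 0.68] + [0.0] * 6  # mean 0.52 over 9, range 0-3
_P_DAYS = [1.0, 1.0, 1.0, 0.0]  # mean 0.75 over 4, range 0-1

from .udt import PANEL_IDS  # noqa: E402  (no cycle: udt does not import fixtures)


def build_udt_fixture(slice_: FixtureSlice) -> FixtureTable:
    """The 44-randomized / 34-completed UDT table.

    Panel positives are laid out so that every union count holds at once:
    9 opiate + 17 buprenorphine + 1 oxycodone positives with exactly two
    double-positives give 25 any-opioid; 21 methamphetamine+amphetamine and
    3 cocaine with one cocaine-only person give 22 any-stimulant; and the
    benzodiazepine/phencyclidine singletons land on otherwise
    opioid-negative records so that 30 test positive for any drug
    (marijuana and tricyclics excluded) while exactly 2 records are
    negative on all 13 panels.
    """

    def rec(rid: str, reported: str, days: Optional[float], completed: bool = True, **pos) -> dict:
        r = {
            "respondent_id": rid,
            "reported_opioid_24h": reported,
            "used_opioid_24h": True,
            "completed": completed,
            "days_elapsed": days,
        }
        for p in PANEL_IDS:
            r[f"panel_{p}"] = False
        for p, v in pos.items():
            r[f"panel_{p}"] = bool(v)
        return r

    records = []
    for i in range(21):  # heroin reporters h01..h21
        rid = f"udt-h{i + 1:02d}"
        pos = {}
        if i < 8:
            pos["opiates"] = True
        if i == 0 or 8 <= i < 16:
            pos["buprenorphine"] = True  # h01 is one of the two double-positives
        if i < 13 or i in (16, 17):
            pos["methamphetamine"] = pos["amphetamine"] = True
        if i in (0, 1, 18):
            pos["cocaine"] = True
        if i == 19:
            pos["benzodiazepines"] = True
        if i < 10 or i == 20:
            pos["marijuana"] = True
        records.append(rec(rid, "heroin", _H_DAYS[i], **pos))
    for i in range(9):  # buprenorphine reporters b1..b9
        rid = f"udt-b{i + 1}"
        pos = {}
        if i < 8:
            pos["buprenorphine"] = True
        if i == 0:
            pos["opiates"] = True  # the second double-positive
            pos["benzodiazepines"] = True
        if i < 6:
            pos["methamphetamine"] = pos["amphetamine"] = True
        if i == 8:
            pos["phencyclidine"] = True
        if i < 5:
            pos["marijuana"] = True
        records.append(rec(rid, "buprenorphine", _B_DAYS[i], **pos))
    for i in range(4):  # percocet reporters p1..p4
        rid = f"udt-p{i + 1}"
        pos = {}
        if i == 0:
            pos["oxycodone"] = True
            pos["marijuana"] = True
        if i == 1:
            pos["marijuana"] = True
        records.append(rec(rid, "percocet", _P_DAYS[i], **pos))
    for i in range(10):  # randomized but did not complete within 3 days
        records.append(rec(f"udt-n{i + 1:02d}", "heroin", None, completed=False))
    return FixtureTable(slice_, records)


# ---------------------------------------------------------------------------
# Replay through the real engine
# ---------------------------------------------------------------------------

_COMPONENT_FIELDS = ("cap_size_correct", "price_correct", "dose_correct", "image_correct")


def _respondent_from_record(rec: Mapping, config: ScreeningConfig) -> ScriptedRespondent:
    counties = sorted(config.flow.eligible_counties)
    drug = rec.get("drug", rec.get("drug_id"))
    in_area = rec.get("in_area", True)
    county = rec.get("county")
    if county is None:
        county = counties[0] if in_area else "out-of-area county"
    age_ok = rec.get("age_ok", True)
    opioid = rec.get("opioid_reported", True)
    if drug is None:
        drug = "heroin" if opioid else "none_of_these"
    substances = (drug,) if opioid or drug == "none_of_these" else (drug,)
    if not opioid and "opioid_reported" in rec:
        substances = ("none_of_these",)
    score = rec.get("county_quiz_score")
    if score is None:
        score = 5 if rec.get("county_quiz_pass", True) else 2
    comp = {
        f.removesuffix("_correct"): bool(rec[f]) for f in _COMPONENT_FIELDS if f in rec
    }
    if "drug_quiz_pass" in rec and not comp:
        ok = bool(rec["drug_quiz_pass"])
        comp = {"cap_size": ok, "price": ok, "image": ok, "dose": ok}
    return ScriptedRespondent(
        respondent_id=str(rec.get("respondent_id", "fixture")),
        reported_county=county,
        reported_age=25 if age_ok else 40,
        substances_30d=substances,
        used_opioid_24h=bool(rec.get("used_opioid_24h", False)),
        completes=bool(rec.get("complete", True)),
        most_often=drug if opioid and drug != "none_of_these" else None,
        formulation=rec.get("formulation"),
        correct_by_category=comp,
        n_correct_county=int(score),
    )


def _outcome_record(rec: Mapping, transcript, result) -> dict:
    out = {
        "respondent_id": result.respondent_id,
        "complete": result.complete,
        "age_ok": result.age_ok,
        "in_area": result.residence_reported_ok,
        "opioid_reported": result.substance_reported_ok,
        "county_quiz_score": result.county_quiz_score,
        "county_quiz_pass": result.county_quiz_pass,
        "drug_quiz_pass": result.drug_quiz_pass,
        "passed": result.drug_quiz_pass,
        "eligible": result.eligible,
        "drug": transcript.most_often_opioid,
        "formulation": transcript.most_often_formulation,
        "reasons": sorted(result.ineligibility_reasons),
    }
    for comp, ok in result.drug_quiz_components.items():
        out[f"{comp}_correct"] = ok
    return out


def replay_fixture(
    fixture: FixtureTable, config: Optional[ScreeningConfig] = None, seed: int = 0
) -> pd.DataFrame:
    """Run every fixture record through the real screening engine and return
    the re-scored outcome table.  Pass/fail columns here *emerge* from the
    engine's scoring rules; the fixture only encoded responses.  UDT
    fixtures are returned as-is (panel results are measurements, not
    quiz responses)."""
    if fixture.slice.kind == "udt":
        return fixture.to_frame()
    config = config or default_config()
    rng = np.random.default_rng(seed)
    counties = sorted(config.flow.eligible_counties)
    out = []
    for i, rec in enumerate(fixture.records):
        rec = dict(rec)
        if fixture.slice.kind == "county" and "county" not in rec:
            rec["county"] = counties[i % len(counties)]
        resp = _respondent_from_record(rec, config)
        t, res = run_session(resp, config, rng)
        out.append(_outcome_record(rec, t, res))
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Verification
# ---------------------------------------------------------------------------


def _round_half_up(x: float, digits: int) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def verify_fixture(
    records: Union[FixtureTable, pd.DataFrame, Sequence[Mapping]],
    slice_: FixtureSlice,
) -> VerificationReport:
    """Re-evaluate every constraint against a record table (fresh fixture or
    engine-replayed outcomes) and report observed vs required values."""
    if isinstance(records, FixtureTable):
        rows_in: Sequence[Mapping] = records.records
    elif isinstance(records, pd.DataFrame):
        rows_in = records.to_dict("records")
    else:
        rows_in = list(records)
    rows = []
    for c in slice_.constraints:
        matched = [r for r in rows_in if _matches(r, c.where, slice_.derived)]
        if c.count is not None:
            observed: float = len(matched)
            required: float = c.count
            ok = observed == required
        else:
            vals = [r[c.of] for r in matched if r.get(c.of) is not None]
            observed = _round_half_up(float(np.mean(vals)), c.digits) if vals else float("nan")
            required = c.mean
            ok = observed == required
        rows.append(
            {"constraint": c.name, "required": required, "observed": observed, "satisfied": ok}
        )
    return VerificationReport(slice_.slice_id, pd.DataFrame(rows))
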