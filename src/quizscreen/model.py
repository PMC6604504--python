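"""Domain types and configuration I/O for quiz-based eligibility screening.

The screening design verifies two things a web form cannot observe directly:

* **residence** in a small set of eligible counties, via 5 questions drawn at
  random from a county-specific 10-item bank of local-knowledge questions
  (pass = at least 3 of 5 correct), and
* **opioid use**, via short knowledge quizzes about the respondent's
  most-often-used opioid: purchase-unit ("cap") size and street price for
  heroin, manufactured dose and pill/strip appearance for prescription
  opioids, buprenorphine and methadone (pass = at least one scored component
  correct).

Dose and image questions follow a 50/50 construction rule: exactly half of
the presented options are correct, so a pure guesser succeeds with
probability one half regardless of how many doses a drug is manufactured in.
Images are modelled as abstract labelled options; scoring needs only the
correct/incorrect label, never pixel data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator, model_validator

__all__ = [
    "ConfigError",
    "ItemKind",
    "DrugClass",
    "QuizItem",
    "QuestionBank",
    "CountyQuizSpec",
    "DrugInfo",
    "DrugCatalog",
    "DrugQuizSpec",
    "ScreeningFlowSpec",
    "ScreeningConfig",
    "PARALLEL_CATEGORIES",
    "OPIOID_CLASSES",
    "GENERIC_BANK_ID",
    "HEROIN_CAP_OPTIONS",
    "HEROIN_CAP_CORRECT",
    "HEROIN_PRICE_OPTIONS",
    "HEROIN_PRICE_CORRECT",
    "build_dose_item",
    "build_image_item",
    "build_drug_quiz",
    "default_decoys",
    "load_config",
    "save_config",
    "default_config",
]


class ConfigError(ValueError):
    """A configuration file failed schema or invariant validation."""


# The six local-knowledge topics asked in every eligible county's bank; the
# remaining four bank items vary by county (schools, festivals, stores...).
PARALLEL_CATEGORIES = frozenset(
    {"towns", "smallest_communities", "largest_town", "jail", "walmart", "landmark"}
)

GENERIC_BANK_ID = "generic"

# Heroin purchase-unit and price questions as fielded: four options each,
# one correct.  Bracket endpoints overlap as printed on the instrument.
HEROIN_CAP_OPTIONS = ("one-tenth of a gram", "one gram", "five grams", "20 grams")
HEROIN_CAP_CORRECT = "one-tenth of a gram"
HEROIN_PRICE_OPTIONS = ("US $0-$10", "US $10-$50", "US $50-$75", "more than US $75")
HEROIN_PRICE_CORRECT = "US $10-$50"


class ItemKind(str, enum.Enum):
    yes_no = "yes_no"
    multiple_choice = "multiple_choice"


class DrugClass(str, enum.Enum):
    heroin = "heroin"
    prescription_opioid = "prescription_opioid"
    buprenorphine = "buprenorphine"
    methadone = "methadone"
    synthetic_opioid = "synthetic_opioid"
    nonopioid = "nonopioid"


OPIOID_CLASSES = frozenset(
    {
        DrugClass.heroin,
        DrugClass.prescription_opioid,
        DrugClass.buprenorphine,
        DrugClass.methadone,
        DrugClass.synthetic_opioid,
    }
)

# Dose-component classes: quizzes built from manufactured doses + images.
DOSE_QUIZ_CLASSES = frozenset(
    {DrugClass.prescription_opioid, DrugClass.buprenorphine, DrugClass.methadone}
)


class QuizItem(BaseModel):
    """One quiz question: ordered options, a labelled correct subset.

    ``correct`` may be empty only for unscorable masking items (the generic
    county bank and the synthetic-opioid / nonopioid information questions);
    scored items must carry a nonempty strict subset of the options.
    """

    model_config = ConfigDict(frozen=True)

    item_id: str
    kind: ItemKind
    category: str
    options: tuple[str, ...]
    correct: frozenset[str] = frozenset()

    @field_validator("options")
    @classmethod
    def _options_ok(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if len(v) < 2:
            raise ValueError("an item needs at least 2 options")
        if len(set(v)) != len(v):
            raise ValueError("duplicate options")
        return v

    @model_validator(mode="after")
    def _invariants(self) -> "QuizItem":
        if self.kind is ItemKind.yes_no and len(self.options) != 2:
            raise ValueError("yes/no items have exactly 2 options")
        if self.correct:
            if not self.correct < set(self.options):
                raise ValueError("correct must be a strict subset of options")
        return self

    @property
    def scorable(self) -> bool:
        return bool(self.correct)

    @property
    def guess_probability(self) -> float:
        """Success probability of a uniform single-choice guesser."""
        if not self.correct:
            return 0.0
        return len(self.correct) / len(self.options)

    def is_correct(self, chosen: str) -> Optional[bool]:
        """Score a single selected option; ``None`` for unscorable items."""
        if chosen not in self.options:
            raise ValueError(f"{chosen!r} is not an option of item {self.item_id!r}")
        if not self.correct:
            return None
        return chosen in self.correct


class QuestionBank(BaseModel):
    model_config = ConfigDict(frozen=True)

    bank_id: str
    items: tuple[QuizItem, ...]

    @model_validator(mode="after")
    def _unique_ids(self) -> "QuestionBank":
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"bank {self.bank_id!r} has duplicate item_ids")
        return self

    def __len__(self) -> int:
        return len(self.items)

    def validate_county_bank(self) -> None:
        """Enforce the eligible-county bank shape: 10 scorable items, of
        which exactly 6 carry the cross-county parallel categories."""
        if len(self.items) != 10:
            raise ConfigError(
                f"banks.{self.bank_id}: county bank must have 10 items, got {len(self.items)}"
            )
        parallel = [it for it in self.items if it.category in PARALLEL_CATEGORIES]
        if len(parallel) != 6 or len({it.category for it in parallel}) != 6:
            raise ConfigError(
                f"banks.{self.bank_id}: expected the 6 parallel categories exactly once each"
            )
        for it in self.items:
            if not it.scorable:
                raise ConfigError(
                    f"banks.{self.bank_id}.items[{it.item_id}]: county items must be scorable"
                )


class CountyQuizSpec(BaseModel):
    """Draw-and-threshold rule for the residence quiz (5 drawn, pass = >=3)."""

    model_config = ConfigDict(frozen=True)

    draw_size: int = 5
    pass_threshold: int = 3
    scored: bool = True

    @model_validator(mode="after")
    def _ordered(self) -> "CountyQuizSpec":
        if not (0 <= self.pass_threshold <= self.draw_size):
            raise ValueError("need 0 <= pass_threshold <= draw_size")
        return self


class DrugInfo(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug_id: str
    drug_class: DrugClass
    # formulation -> manufactured doses; unit is mg unless stated otherwise
    formulations: Mapping[str, tuple[float, ...]] = {}
    dose_unit: str = "mg"
    street_price_range_cents: Optional[tuple[int, int]] = None
    cap_size_answer: Optional[str] = None

    @model_validator(mode="after")
    def _invariants(self) -> "DrugInfo":
        if self.drug_class in DOSE_QUIZ_CLASSES:
            if not self.formulations or any(len(d) < 1 for d in self.formulations.values()):
                raise ValueError(
                    f"drugs.{self.drug_id}: dose-quizzed drugs need >=1 true dose per formulation"
                )
        if self.drug_class is DrugClass.heroin:
            if self.cap_size_answer != HEROIN_CAP_CORRECT:
                raise ValueError(
                    f"drugs.{self.drug_id}: heroin cap_size_answer must be {HEROIN_CAP_CORRECT!r}"
                )
            if self.street_price_range_cents != (1000, 5000):
                raise ValueError(
                    f"drugs.{self.drug_id}: heroin street price bracket must be US $10-$50"
                )
        return self

    def default_formulation(self) -> Optional[str]:
        if not self.formulations:
            return None
        return next(iter(self.formulations))


class DrugCatalog(BaseModel):
    model_config = ConfigDict(frozen=True)

    drugs: Mapping[str, DrugInfo]

    @model_validator(mode="after")
    def _ids_match(self) -> "DrugCatalog":
        for key, info in self.drugs.items():
            if key != info.drug_id:
                raise ValueError(f"drugs.{key}: key does not match drug_id {info.drug_id!r}")
        return self

    def __getitem__(self, drug_id: str) -> DrugInfo:
        try:
            return self.drugs[drug_id]
        except KeyError:
            raise KeyError(f"unknown drug {drug_id!r}") from None

    def __contains__(self, drug_id: str) -> bool:
        return drug_id in self.drugs

    def is_opioid(self, drug_id: str) -> bool:
        return self[drug_id].drug_class in OPIOID_CLASSES

    @property
    def opioid_ids(self) -> tuple[str, ...]:
        return tuple(d for d in self.drugs if self.is_opioid(d))


class ScreeningFlowSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    eligible_counties: frozenset[str]
    age_min: int = 18
    age_max: int = 35
    substance_checklist: tuple[str, ...] = ()
    use_window_days: int = 30
    udt_recall_hours: int = 24

    @model_validator(mode="after")
    def _invariants(self) -> "ScreeningFlowSpec":
        if len(self.eligible_counties) != 5:
            raise ValueError(
                f"flow.eligible_counties: expected exactly 5 counties, got {len(self.eligible_counties)}"
            )
        if self.age_min > self.age_max:
            raise ValueError("flow: age_min must not exceed age_max")
        return self

    def age_ok(self, age: int) -> bool:
        return self.age_min <= age <= self.age_max


class ScreeningConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    flow: ScreeningFlowSpec
    banks: Mapping[str, QuestionBank]
    catalog: DrugCatalog
    county_quiz: CountyQuizSpec = CountyQuizSpec()
    generic_quiz: CountyQuizSpec = CountyQuizSpec(scored=False)

    @model_validator(mode="after")
    def _cross_invariants(self) -> "ScreeningConfig":
        for county in sorted(self.flow.eligible_counties):
            if county not in self.banks:
                raise ValueError(f"banks: missing bank for eligible county {county!r}")
            self.banks[county].validate_county_bank()
        if GENERIC_BANK_ID not in self.banks:
            raise ValueError("banks: missing 'generic' masking bank")
        if len(self.banks[GENERIC_BANK_ID]) < self.county_quiz.draw_size:
            raise ValueError("banks.generic: smaller than the draw size")
        for bank_id, bank in self.banks.items():
            if bank.bank_id != bank_id:
                raise ValueError(f"banks.{bank_id}: key does not match bank_id")
        return self


# ---------------------------------------------------------------------------
# Item construction (the 50/50 dose/image rule)
# ---------------------------------------------------------------------------


def _as_rng(rng: Union[np.random.Generator, int, None]) -> Optional[np.random.Generator]:
    if rng is None or isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _fmt_dose(dose: float, unit: str) -> str:
    n = f"{dose:g}"
    return f"{n} {unit}"


def default_decoys(true_doses: Sequence[float]) -> list[float]:
    """Deterministic decoy doses disjoint from the true ones.

    Decoys continue past the largest true dose on an even grid, which keeps
    them plausible for single-dose drugs (50 -> 75) as well as multi-dose
    pill lines (5, 15, 30 -> 45, 60, 75).
    """
    if not true_doses:
        raise ValueError("need at least one true dose")
    uniq = sorted(set(true_doses))
    step = min((b - a for a, b in zip(uniq, uniq[1:])), default=uniq[0] or 1.0)
    step = step if step > 0 else 1.0
    decoys: list[float] = []
    cand = uniq[-1]
    while len(decoys) < len(true_doses):
        cand += step
        if cand not in uniq:
            decoys.append(cand)
    return decoys


def build_dose_item(
    drug_id: str,
    true_doses: Sequence[float],
    decoy_doses: Sequence[float],
    rng: Union[np.random.Generator, int, None] = None,
    *,
    unit: str = "mg",
    item_id: Optional[str] = None,
) -> QuizItem:
    """Build a dose question under the 50/50 rule: a drug manufactured in
    ``m`` doses gets ``2m`` options of which the ``m`` true doses are correct.
    Option order is shuffled under the caller's ``rng`` (left as listed when
    ``rng`` is None)."""
    m = len(true_doses)
    if m == 0:
        raise ValueError(f"{drug_id}: no true doses registered")
    if len(set(true_doses)) != m:
        raise ValueError(f"{drug_id}: duplicate true doses")
    if len(decoy_doses) < m:
        raise ValueError(
            f"{drug_id}: need at least {m} decoy doses, got {len(decoy_doses)}"
        )
    overlap = set(true_doses) & set(decoy_doses)
    if overlap:
        raise ValueError(f"{drug_id}: decoys overlap true doses: {sorted(overlap)}")
    options = [_fmt_dose(d, unit) for d in true_doses]
    correct = frozenset(options)
    options += [_fmt_dose(d, unit) for d in list(decoy_doses)[:m]]
    gen = _as_rng(rng)
    if gen is not None:
        options = [options[i] for i in gen.permutation(len(options))]
    return QuizItem(
        item_id=item_id or f"{drug_id}-dose",
        kind=ItemKind.multiple_choice,
        category="dose",
        options=tuple(options),
        correct=correct,
    )


_HEROIN_IMAGE_DECOYS = (
    "crushed drywall",
    "brown sugar",
    "instant coffee granules",
    "sidewalk chalk dust",
    "powdered cinnamon",
)


def build_image_item(
    drug: DrugInfo,
    dose_context: Union[float, str] = "all",
    rng: Union[np.random.Generator, int, None] = None,
    *,
    formulation: Optional[str] = None,
    item_id: Optional[str] = None,
) -> QuizItem:
    """Build an appearance-recognition question with 50% correct options.

    Heroin gets the fielded 10-image question (5 genuine powder-heroin
    photographs, 5 obviously-not-heroin textures).  Dose-quizzed drugs get
    one authentic photograph per dose in context plus as many lookalikes;
    ``dose_context="all"`` spans every manufactured dose and is used when a
    respondent missed the dose question (the branch still lets them pass on
    appearance alone).
    """
    gen = _as_rng(rng)
    if drug.drug_class is DrugClass.heroin:
        correct = tuple(f"powder heroin, shade {i}" for i in range(1, 6))
        options = list(correct) + list(_HEROIN_IMAGE_DECOYS)
        if gen is not None:
            options = [options[i] for i in gen.permutation(len(options))]
        return QuizItem(
            item_id=item_id or f"{drug.drug_id}-image",
            kind=ItemKind.multiple_choice,
            category="image",
            options=tuple(options),
            correct=frozenset(correct),
        )
    if drug.drug_class not in DOSE_QUIZ_CLASSES:
        raise ValueError(f"{drug.drug_id}: no registered images for class {drug.drug_class}")
    form = formulation or drug.default_formulation()
    if form is None or form not in drug.formulations:
        raise ValueError(f"{drug.drug_id}: no registered images (unknown formulation {form!r})")
    doses = drug.formulations[form]
    if dose_context == "all":
        context_doses = list(doses)
    else:
        if float(dose_context) not in doses:
            raise ValueError(
                f"{drug.drug_id}: {dose_context!r} is not a manufactured {form} dose"
            )
        context_doses = [float(dose_context)]
    unit = drug.dose_unit
    correct = tuple(
        f"{drug.drug_id} {_fmt_dose(d, unit)} {form} photo" for d in context_doses
    )
    decoys = [
        f"lookalike {form} ({_fmt_dose(d, unit)} imprint)" for d in context_doses
    ]
    options = list(correct) + decoys
    if gen is not None:
        options = [options[i] for i in gen.permutation(len(options))]
    suffix = "all" if dose_context == "all" else _fmt_dose(float(dose_context), unit)
    return QuizItem(
        item_id=item_id or f"{drug.drug_id}-{form}-image-{suffix}",
        kind=ItemKind.multiple_choice,
        category="image",
        options=tuple(options),
        correct=frozenset(correct),
    )


# ---------------------------------------------------------------------------
# Drug quiz assembly
# ---------------------------------------------------------------------------

# Info-only masking questions: never scored, no labelled correct answer.
_SYNTHETIC_INFO_ITEMS = (
    ("source", ("online", "gas station", "drug paraphernalia store", "other")),
    ("form", ("pills", "powder", "liquid", "other")),
    ("price", ("under US $10", "US $10-$25", "US $25-$50", "more than US $50")),
)
_NONOPIOID_INFO_ITEMS = (
    ("color", ("white", "off-white", "brown", "clear", "other")),
    ("texture", ("pill", "liquid", "powder", "rocks", "other")),
    ("size", ("under half a gram", "about a gram", "an eighth", "other")),
)


@dataclass(frozen=True)
class DrugQuizSpec:
    """A fully assembled drug quiz for one drug (and formulation).

    ``scored_components`` carries the pass rule: the quiz is passed when the
    disjunction over scored components is true.  The synthetic-opioid quiz
    has no scored components and auto-passes; the nonopioid masking quiz has
    none and is never scored.
    """

    drug_id: str
    drug_class: DrugClass
    formulation: Optional[str] = None
    cap_item: Optional[QuizItem] = None
    price_item: Optional[QuizItem] = None
    dose_item: Optional[QuizItem] = None
    image_item: Optional[QuizItem] = None  # heroin's single image question
    image_all_item: Optional[QuizItem] = None
    image_by_dose: Mapping[float, QuizItem] = field(default_factory=dict)
    info_items: tuple[QuizItem, ...] = ()

    @property
    def scored_components(self) -> tuple[str, ...]:
        if self.drug_class is DrugClass.heroin:
            return ("cap_size", "price")
        if self.drug_class in DOSE_QUIZ_CLASSES:
            return ("dose", "image")
        return ()

    @property
    def auto_pass(self) -> bool:
        return self.drug_class is DrugClass.synthetic_opioid

    @property
    def applicable(self) -> bool:
        """False for the nonopioid masking quiz, which is never scored."""
        return self.drug_class is not DrugClass.nonopioid


def _info_items(drug_id: str, spec_items) -> tuple[QuizItem, ...]:
    return tuple(
        QuizItem(
            item_id=f"{drug_id}-{name}",
            kind=ItemKind.multiple_choice,
            category=name,
            options=opts,
            correct=frozenset(),
        )
        for name, opts in spec_items
    )


def build_drug_quiz(
    catalog: DrugCatalog,
    drug_id: str,
    formulation: Optional[str] = None,
    rng: Union[np.random.Generator, int, None] = None,
) -> DrugQuizSpec:
    """Assemble the quiz for one drug.

    * heroin: cap-size and price (scored) plus the 10-image question
      (recorded, unscored);
    * prescription opioids / buprenorphine / methadone: dose and image
      (both scored; an incorrect dose branches to the all-doses image
      question) plus a free-text street-price prompt (unscored);
    * synthetic opioids: three unscored information questions, auto-pass;
    * nonopioids: the three-question masking quiz, never scored.
    """
    drug = catalog[drug_id]
    gen = _as_rng(rng)
    if drug.drug_class is DrugClass.heroin:
        return DrugQuizSpec(
            drug_id=drug_id,
            drug_class=drug.drug_class,
            cap_item=QuizItem(
                item_id=f"{drug_id}-cap-size",
                kind=ItemKind.multiple_choice,
                category="cap_size",
                options=HEROIN_CAP_OPTIONS,
                correct=frozenset({HEROIN_CAP_CORRECT}),
            ),
            price_item=QuizItem(
                item_id=f"{drug_id}-price",
                kind=ItemKind.multiple_choice,
                category="price",
                options=HEROIN_PRICE_OPTIONS,
                correct=frozenset({HEROIN_PRICE_CORRECT}),
            ),
            image_item=build_image_item(drug, rng=gen),
        )
    if drug.drug_class in DOSE_QUIZ_CLASSES:
        form = formulation or drug.default_formulation()
        if form not in drug.formulations:
            raise ValueError(f"{drug_id}: unknown formulation {form!r}")
        doses = drug.formulations[form]
        dose_item = build_dose_item(
            drug_id,
            doses,
            default_decoys(doses),
            gen,
            unit=drug.dose_unit,
            item_id=f"{drug_id}-{form}-dose",
        )
        return DrugQuizSpec(
            drug_id=drug_id,
            drug_class=drug.drug_class,
            formulation=form,
            dose_item=dose_item,
            image_all_item=build_image_item(drug, "all", gen, formulation=form),
            image_by_dose={
                d: build_image_item(drug, d, gen, formulation=form) for d in doses
            },
        )
    if drug.drug_class is DrugClass.synthetic_opioid:
        return DrugQuizSpec(
            drug_id=drug_id,
            drug_class=drug.drug_class,
            info_items=_info_items(drug_id, _SYNTHETIC_INFO_ITEMS),
        )
    return DrugQuizSpec(
        drug_id=drug_id,
        drug_class=drug.drug_class,
        info_items=_info_items(drug_id, _NONOPIOID_INFO_ITEMS),
    )


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------


def _config_from_mapping(doc: Mapping) -> ScreeningConfig:
    try:
        return ScreeningConfig.model_validate(doc)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            path = ".".join(str(p) for p in err["loc"])
            lines.append(f"{path}: {err['msg']}")
        raise ConfigError("invalid screening configuration:\n  " + "\n  ".join(lines)) from exc


def load_config(path: Union[str, Path]) -> ScreeningConfig:
    """Load and validate a screening configuration (YAML or JSON).

    Violations are reported with item-level paths, e.g.
    ``banks.ashford.items.3.correct: ...``.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: cannot parse: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return _config_from_mapping(doc)
    except ConfigError:
        raise
    except ValueError as exc:  # cross-invariant checks raised inside validators
        raise ConfigError(str(exc)) from exc


def _config_to_doc(config: ScreeningConfig) -> dict:
    def item_doc(it: QuizItem) -> dict:
        return {
            "item_id": it.item_id,
            "kind": it.kind.value,
            "category": it.category,
            "options": list(it.options),
            # stable order: as presented
            "correct": [o for o in it.options if o in it.correct],
        }

    return {
        "flow": {
            "eligible_counties": sorted(config.flow.eligible_counties),
            "age_min": config.flow.age_min,
            "age_max": config.flow.age_max,
            "substance_checklist": list(config.flow.substance_checklist),
            "use_window_days": config.flow.use_window_days,
            "udt_recall_hours": config.flow.udt_recall_hours,
        },
        "county_quiz": config.county_quiz.model_dump(),
        "generic_quiz": config.generic_quiz.model_dump(),
        "banks": {
            bank_id: {
                "bank_id": bank_id,
                "items": [item_doc(it) for it in bank.items],
            }
            for bank_id, bank in config.banks.items()
        },
        "catalog": {
            "drugs": {
                d: {
                    "drug_id": info.drug_id,
                    "drug_class": info.drug_class.value,
                    "formulations": {f: list(v) for f, v in info.formulations.items()},
                    "dose_unit": info.dose_unit,
                    "street_price_range_cents": list(info.street_price_range_cents)
                    if info.street_price_range_cents
                    else None,
                    "cap_size_answer": info.cap_size_answer,
                }
                for d, info in config.catalog.drugs.items()
            }
        },
    }


def save_config(config: ScreeningConfig, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(_config_to_doc(config), sort_keys=False))


def default_config() -> ScreeningConfig:
    """The shipped illustrative configuration: 5 fictional eligible counties
    with 10-item banks, a generic masking bank, and an opioid catalog."""
    text = resources.files("quizscreen.data").joinpath("config.yaml").read_text()
    return _config_from_mapping(yaml.safe_load(text))
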