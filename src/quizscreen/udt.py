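"""Urine-drug-test subsampling, panel simulation, and concordance.

Models the 13-panel point-of-care cup at the positive/negative level: each
panel carries a detection window (days) and a threshold (ng/mL, metadata
only — the cup reports binary results).  A panel turns positive when any
mapped drug was used recently enough that days-since-use plus the delay
between screening and specimen falls inside the window.  The default
detection model uses the window's upper bound deterministically; a
stochastic uniform-in-window model is available for sensitivity analysis.
Drugs the cup cannot see (fentanyl, tramadol, gabapentin, illicit
synthetics) are explicitly never-positive, with a logged notice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UDTPanelSpec",
    "UDTRecord",
    "PANELS",
    "PANEL_IDS",
    "DRUG_PANEL_MAP",
    "NOT_DETECTED",
    "OPIOID_PANELS",
    "STIMULANT_PANELS",
    "select_udt_subsample",
    "simulate_udt",
    "any_class_positive",
    "concordance_summary",
]


@dataclass(frozen=True)
class UDTPanelSpec:
    panel_id: str
    window_days: tuple[float, float]  # detection window, days after use
    threshold_ng_ml: float

    def __post_init__(self) -> None:
        lo, hi = self.window_days
        if lo > hi:
            raise ValueError(f"{self.panel_id}: window lower bound exceeds upper")
        if self.threshold_ng_ml <= 0:
            raise ValueError(f"{self.panel_id}: threshold must be positive")


# The 13 assay panels with manufacturer detection windows and thresholds.
# The tricyclic-antidepressant window/threshold is the usual point-of-care
# cup figure; it is excluded from the any-drug aggregate regardless.
PANELS: dict[str, UDTPanelSpec] = {
    p.panel_id: p
    for p in (
        UDTPanelSpec("marijuana", (15, 30), 50),
        UDTPanelSpec("opiates", (2, 4), 2000),
        UDTPanelSpec("methadone", (3, 5), 300),
        UDTPanelSpec("oxycodone", (2, 4), 100),
        UDTPanelSpec("propoxyphene", (1, 2), 300),
        UDTPanelSpec("buprenorphine", (2, 3), 10),
        UDTPanelSpec("methamphetamine", (3, 5), 1000),
        UDTPanelSpec("amphetamine", (2, 4), 1000),
        UDTPanelSpec("cocaine", (2, 4), 300),
        UDTPanelSpec("benzodiazepines", (3, 7), 300),
        UDTPanelSpec("phencyclidine", (7, 14), 25),
        UDTPanelSpec("barbiturates", (4, 7), 300),
        UDTPanelSpec("tricyclic_antidepressants", (2, 7), 1000),
    )
}
PANEL_IDS: tuple[str, ...] = tuple(PANELS)

NOT_DETECTED = "not_detected"

# Catalog drug -> panel (opiates covers heroin/morphine and, via
# immunoassay cross-reactivity, hydrocodone products); fentanyl, tramadol
# and illicit synthetics are outside the cup's coverage.
DRUG_PANEL_MAP: dict[str, str] = {
    "heroin": "opiates",
    "morphine": "opiates",
    "norco": "opiates",
    "lortab": "opiates",
    "percocet": "oxycodone",
    "percodan": "oxycodone",
    "roxicodone": "oxycodone",
    "oxycontin": "oxycodone",
    "tylox": "oxycodone",
    "opana": "oxycodone",
    "darvocet": "propoxyphene",
    "darvon": "propoxyphene",
    "buprenorphine": "buprenorphine",
    "methadone": "methadone",
    "fentanyl": NOT_DETECTED,
    "tramadol": NOT_DETECTED,
    "synthetic_opioid": NOT_DETECTED,
    "methamphetamine": "methamphetamine",
    "cocaine": "cocaine",
    "gabapentin": NOT_DETECTED,
}

OPIOID_PANELS = frozenset(
    {"opiates", "methadone", "oxycodone", "propoxyphene", "buprenorphine"}
)
STIMULANT_PANELS = frozenset({"methamphetamine", "amphetamine", "cocaine"})


@dataclass
class UDTRecord:
    respondent_id: str
    days_elapsed: float  # days between screening and specimen
    panels: dict[str, bool]
    completed: bool = True
    notices: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.completed and not 0 <= self.days_elapsed <= 3:
            raise ValueError(
                f"{self.respondent_id}: protocol requires the specimen within "
                f"3 days (got {self.days_elapsed})"
            )


def select_udt_subsample(
    candidates: Sequence,
    count: Optional[int] = None,
    fraction: Optional[float] = None,
    seed: Union[int, np.random.Generator, None] = None,
):
    """Uniform random subsample of qualifying candidates: those who
    completed screening and reported opioid use in the past 24 hours.
    Deterministic under ``seed``; each qualifier is selected with equal
    probability (exchangeability)."""
    pool = [
        c
        for c in candidates
        if getattr(c, "complete", getattr(c, "completed", False))
        and getattr(c, "used_opioid_24h", False)
    ]
    if count is None and fraction is None:
        raise ValueError("give a count or a fraction")
    if count is None:
        if not 0 <= fraction <= 1:
            raise ValueError("fraction outside [0, 1]")
        count = int(round(fraction * len(pool)))
    if count > len(pool):
        raise ValueError(f"requested {count} but only {len(pool)} candidates qualify")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[i] for i in sorted(idx)]


def simulate_udt(
    respondent_id: str,
    days_since_use: Mapping[str, float],
    days_elapsed: float = 0.0,
    panels: Mapping[str, UDTPanelSpec] = PANELS,
    panel_map: Mapping[str, str] = DRUG_PANEL_MAP,
    model: str = "upper",
    rng: Union[int, np.random.Generator, None] = None,
) -> UDTRecord:
    """Simulate one 13-panel result from true per-drug days-since-last-use
    (measured at screening; the specimen is collected ``days_elapsed`` days
    later).

    A panel is positive iff any mapped drug satisfies
    days_since_use + days_elapsed <= window length, where the window length
    is the upper bound of the panel's interval (``model="upper"``, the
    deterministic default) or drawn uniformly in the interval
    (``model="uniform"``).  The 2-5 hour urine-appearance delay is below
    day resolution and ignored.
    """
    if model not in ("upper", "uniform"):
        raise ValueError(f"unknown detection model {model!r}")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    notices = []
    positive = {p: False for p in panels}
    for drug, since in days_since_use.items():
        if since < 0:
            raise ValueError(f"{drug}: negative days-since-use")
        panel = panel_map.get(drug)
        if panel is None or panel == NOT_DETECTED:
            notices.append(f"{drug}: not detected by any panel")
            logger.info("udt: drug %r is not detected by any panel", drug)
            continue
        spec = panels[panel]
        lo, hi = spec.window_days
        window = hi if model == "upper" else float(gen.uniform(lo, hi))
        if since + days_elapsed <= window:
            positive[panel] = True
    return UDTRecord(
        respondent_id=respondent_id,
        days_elapsed=days_elapsed,
        panels=positive,
        notices=tuple(notices),
    )


def any_class_positive(
    record: Union[UDTRecord, Mapping[str, bool]], class_panels: Iterable[str]
) -> bool:
    """Union positivity over a panel class (e.g. any-opioid, any-stimulant)."""
    panels = record.panels if isinstance(record, UDTRecord) else record
    out = False
    for p in class_panels:
        if p not in PANELS:
            raise ValueError(f"unknown panel {p!r}")
        out = out or bool(panels.get(p, False))
    return out


def concordance_summary(
    udt_records: Sequence[Union[UDTRecord, Mapping]],
    reported: Mapping[str, str],
    panel_map: Mapping[str, str] = DRUG_PANEL_MAP,
) -> pd.DataFrame:
    """Self-report vs UDT concordance, per reported past-24-hour opioid.

    One row per reported drug: n, count and percentage with the mapped
    panel positive, and the mean and range of days between screening and
    specimen.  A final ``any_reported`` row counts respondents whose result
    matched their reported opioid.  Reporters of drugs outside the cup's
    coverage are excluded with a logged notice.
    """
    rows: dict[str, dict] = {}
    matched_total = 0
    n_total = 0
    for rec in udt_records:
        if isinstance(rec, UDTRecord):
            rid, days, panels = rec.respondent_id, rec.days_elapsed, rec.panels
        else:
            rid = rec["respondent_id"]
            days = rec.get("days_elapsed")
            panels = {p: rec.get(f"panel_{p}", rec.get(p, False)) for p in PANEL_IDS}
        drug = reported.get(rid)
        if drug is None:
            continue
        panel = panel_map.get(drug)
        if panel is None or panel == NOT_DETECTED:
            logger.info("concordance: reported drug %r has no panel; excluded", drug)
            continue
        row = rows.setdefault(
            drug, {"reported_drug": drug, "panel": panel, "n": 0, "positive": 0, "days": []}
        )
        row["n"] += 1
        n_total += 1
        pos = bool(panels.get(panel, False))
        row["positive"] += int(pos)
        matched_total += int(pos)
        if days is not None:
            row["days"].append(float(days))
    out = []
    for row in rows.values():
        days = row.pop("days")
        row["pct_positive"] = 100.0 * row["positive"] / row["n"] if row["n"] else float("nan")
        row["days_mean"] = float(np.mean(days)) if days else float("nan")
        row["days_min"] = min(days) if days else float("nan")
        row["days_max"] = max(days) if days else float("nan")
        out.append(row)
    out.sort(key=lambda r: -r["n"])
    out.append(
        {
            "reported_drug": "any_reported",
            "panel": "matched",
            "n": n_total,
            "positive": matched_total,
            "pct_positive": 100.0 * matched_total / n_total if n_total else float("nan"),
            "days_mean": float("nan"),
            "days_min": float("nan"),
            "days_max": float("nan"),
        }
    )
    return pd.DataFrame(out)
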