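"""Clinical outcome rules for injection cohorts with shoulder impingement.

Implements the rule set used to evaluate ultrasound-guided corticosteroid
injections in subacromial impingement syndrome:

* SPADI scoring (13 items, 0-10 each, converted to a 100-point scale);
* early treatment success: a strict >30% reduction at week 4 in any of the
  three VAS pain subdomains (rest, night, overhead activity);
* recurrence labeling with censoring for the survival analysis — a repeat
  injection within 365 days of the index injection counts as recurrence,
  documented symptom-free follow-up of at least 365 days (or a phone call
  confirming resolution) counts as no recurrence at day 365, a repeat
  injection after day 365 also counts as no recurrence, and responders whose
  follow-up stops short of 365 days without contact are censored at their
  last known contact day;
* static ultrasound thresholds: biceps tenosynovitis when the peritendinous
  effusion exceeds 1 mm, subdeltoid bursitis when the bursa exceeds 2 mm
  (both strict);
* greedy historical-control matching on age within a 5-year band.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VasTriple",
    "SpadiScore",
    "PatientRecord",
    "OutcomeLabel",
    "StaticFindings",
    "spadi_score",
    "classify_early_success",
    "label_recurrence",
    "classify_static_findings",
    "match_historical",
    "read_cohort_csv",
    "write_cohort_csv",
    "RECURRENCE_WINDOW_DAYS",
]

RECURRENCE_WINDOW_DAYS = 365
SUCCESS_REDUCTION = 0.30  # strict ">30%" rule

PhoneContact = Literal[
    "confirmed_resolved", "confirmed_injected_elsewhere", "no_response", "not_attempted"
]


@dataclass(frozen=True)
class VasTriple:
    """Visual-analog pain scores (0-10 cm) at rest, at night and overhead."""

    rest: float
    night: float
    overhead: float

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 10.0):
                raise ValueError(f"VAS {name} must be in [0, 10], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {"rest": self.rest, "night": self.night, "overhead": self.overhead}


@dataclass(frozen=True)
class SpadiScore:
    """Shoulder Pain and Disability Index on the 100-point scale."""

    pain_domain: float
    function_domain: float
    total: float


def spadi_score(
    pain_items: Sequence[float], function_items: Sequence[float]
) -> SpadiScore:
    """Score the SPADI from its 5 pain and 8 function items (each 0-10).

    Domain scores are the item mean times 10; the total is the mean of all
    13 items times 10, all on a 0-100 scale.
    """
    pain = np.asarray(pain_items, dtype=float)
    func = np.asarray(function_items, dtype=float)
    if pain.shape != (5,):
        raise ValueError(f"expected 5 pain items, got {pain.size}")
    if func.shape != (8,):
        raise ValueError(f"expected 8 function items, got {func.size}")
    items = np.concatenate([pain, func])
    if np.any((items < 0) | (items > 10)) or not np.all(np.isfinite(items)):
        raise ValueError("SPADI items must be finite and within [0, 10]")
    return SpadiScore(
        pain_domain=float(pain.mean() * 10),
        function_domain=float(func.mean() * 10),
        total=float(items.mean() * 10),
    )


def classify_early_success(baseline: VasTriple, week4: VasTriple) -> bool:
    """Early treatment success: >30% VAS reduction in any pain subdomain.

    A subdomain with baseline 0 cannot show a relative reduction and is
    ineligible; if all three baselines are 0 there is nothing to evaluate
    and a ``ValueError`` is raised.
    """
    base = baseline.as_dict()
    post = week4.as_dict()
    evaluable = [k for k, v in base.items() if v > 0]
    if not evaluable:
        raise ValueError("no evaluable pain subdomain (all baseline VAS are 0)")
    return any((base[k] - post[k]) / base[k] > SUCCESS_REDUCTION for k in evaluable)


@dataclass(frozen=True)
class StaticFindings:
    biceps_tenosynovitis: bool
    subdeltoid_bursitis: bool


def classify_static_findings(
    biceps_effusion_mm: float, bursa_thickness_mm: float
) -> StaticFindings:
    """Apply the static-ultrasound thresholds (strict > 1 mm and > 2 mm)."""
    if biceps_effusion_mm < 0 or bursa_thickness_mm < 0:
        raise ValueError("measurements must be non-negative")
    return StaticFindings(
        biceps_tenosynovitis=biceps_effusion_mm > 1.0,
        subdeltoid_bursitis=bursa_thickness_mm > 2.0,
    )


@dataclass
class PatientRecord:
    """One patient's demographics, scores, mVAHD vector and follow-up events."""

    id: str
    age: float
    sex: Literal["female", "male"] = "female"
    side: Literal["left", "right"] = "right"
    height_cm: float | None = None
    weight_kg: float | None = None
    bmi: float | None = None
    pain_duration_months: float | None = None
    baseline_vas: VasTriple | None = None
    week4_vas: VasTriple | None = None
    baseline_spadi: SpadiScore | None = None
    week4_spadi: SpadiScore | None = None
    mvahd: dict[str, float] = field(default_factory=dict)  # Fab/Fad/Eab/Ead -> cm
    static_findings: dict[str, bool] = field(default_factory=dict)
    injection_group: Literal["dual_target", "standard"] = "dual_target"
    injection_date: _dt.date | None = None
    repeat_injection_date: _dt.date | None = None
    last_visit_date: _dt.date | None = None
    phone_contact: PhoneContact = "not_attempted"

    def validate(self) -> None:
        if self.height_cm and self.weight_kg and self.bmi is not None:
            implied = self.weight_kg / (self.height_cm / 100.0) ** 2
            if abs(implied - self.bmi) > 0.5:
                raise ValueError(
                    f"patient {self.id}: bmi {self.bmi:.1f} inconsistent with "
                    f"height/weight (implied {implied:.1f})"
                )
        for key, v in self.mvahd.items():
            if not np.isfinite(v):
                raise ValueError(f"patient {self.id}: non-finite mVAHD {key}")
        if (
            self.injection_date
            and self.repeat_injection_date
            and self.repeat_injection_date < self.injection_date
        ):
            raise ValueError(
                f"patient {self.id}: repeat injection precedes index injection"
            )


@dataclass(frozen=True)
class OutcomeLabel:
    """Early-success flag plus recurrence status for the survival analysis."""

    early_success: bool
    recurrence_status: Literal[
        "recurrence", "no_recurrence", "censored", "not_applicable"
    ]
    time_days: int

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("time_days must be >= 0")
        if (self.recurrence_status == "not_applicable") != (not self.early_success):
            raise ValueError(
                "recurrence_status is not_applicable iff early_success is False"
            )


def label_recurrence(record: PatientRecord, early_success: bool) -> OutcomeLabel:
    """Label recurrence with censoring for an initial treatment responder.

    Non-responders are ``not_applicable``. For responders, in order:
    a repeat injection (in hospital or phone-confirmed elsewhere) within
    365 days is a recurrence at that day count; a repeat after 365 days is
    no recurrence at 365; documented follow-up coverage of >= 365 days, or a
    phone call confirming resolution, is no recurrence at 365; otherwise the
    patient is censored at the last known contact day.
    """
    if not early_success:
        return OutcomeLabel(False, "not_applicable", 0)
    if record.injection_date is None:
        raise ValueError(f"patient {record.id}: injection_date required")
    record.validate()
    if record.repeat_injection_date is not None:
        days = (record.repeat_injection_date - record.injection_date).days
        if days <= RECURRENCE_WINDOW_DAYS:
            return OutcomeLabel(True, "recurrence", days)
        return OutcomeLabel(True, "no_recurrence", RECURRENCE_WINDOW_DAYS)
    if record.phone_contact == "confirmed_injected_elsewhere":
        raise ValueError(
            f"patient {record.id}: injection elsewhere confirmed but "
            "repeat_injection_date missing"
        )
    coverage = 0
    if record.last_visit_date is not None:
        coverage = max(0, (record.last_visit_date - record.injection_date).days)
    if coverage >= RECURRENCE_WINDOW_DAYS or record.phone_contact == "confirmed_resolved":
        return OutcomeLabel(True, "no_recurrence", RECURRENCE_WINDOW_DAYS)
    return OutcomeLabel(True, "censored", coverage)


def match_historical(
    cases: Sequence[PatientRecord],
    pool: Sequence[PatientRecord],
    max_age_gap: float = 5.0,
) -> tuple[list[tuple[PatientRecord, PatientRecord]], list[PatientRecord]]:
    """Greedy nearest-age matching of cases to historical controls.

    Cases are processed in ascending id order; each is paired, without
    replacement, with the unused pool record of nearest age within
    ``max_age_gap`` years, ties broken by the earlier pool record. Cases with
    no eligible control are returned unmatched rather than raising.
    """
    pairs: list[tuple[PatientRecord, PatientRecord]] = []
    unmatched: list[PatientRecord] = []
    used: set[int] = set()
    for case in sorted(cases, key=lambda r: r.id):
        best: tuple[float, int] | None = None
        for j, ctrl in enumerate(pool):
            if j in used:
                continue
            gap = abs(ctrl.age - case.age)
            if gap > max_age_gap:
                continue
            if best is None or (gap, j) < best:
                best = (gap, j)
        if best is None:
            unmatched.append(case)
        else:
            used.add(best[1])
            pairs.append((case, pool[best[1]]))
    return pairs, unmatched


# ---------------------------------------------------------------------------
# Cohort CSV
#
# One row per patient. mVAHD columns are mvahd_fab_cm, mvahd_fad_cm,
# mvahd_eab_cm, mvahd_ead_cm; dates are ISO-8601; booleans 0/1.

MVAHD_COLUMNS = {
    "Fab": "mvahd_fab_cm",
    "Fad": "mvahd_fad_cm",
    "Eab": "mvahd_eab_cm",
    "Ead": "mvahd_ead_cm",
}
DATE_COLUMNS = ["injection_date", "repeat_injection_date", "last_visit_date"]
REQUIRED_COLUMNS = ["id", "age", "sex", "side"] + list(MVAHD_COLUMNS.values())


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table; raises with row-level error context."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in DATE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="coerce").dt.date
    errors: list[str] = []
    for i, row in df.iterrows():
        for col in MVAHD_COLUMNS.values():
            if not np.isfinite(row[col]):
                errors.append(f"row {i}: non-finite {col}")
        if {"height_cm", "weight_kg", "bmi"} <= set(df.columns):
            implied = row["weight_kg"] / (row["height_cm"] / 100.0) ** 2
            if np.isfinite(row["bmi"]) and abs(implied - row["bmi"]) > 0.5:
                errors.append(f"row {i}: bmi inconsistent with height/weight")
        inj = row.get("injection_date")
        rep = row.get("repeat_injection_date")
        if inj is not None and rep is not None and not pd.isna(rep) and rep < inj:
            errors.append(f"row {i}: repeat injection precedes index injection")
    if errors:
        raise ValueError("cohort validation failed:\n" + "\n".join(errors))
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def label_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the early-success and recurrence rules to every cohort row.

    Requires the six VAS columns (``vas_{rest,night,overhead}_{baseline,week4}``)
    and the event-date columns; adds ``early_success`` (0/1), the
    rule-derived ``early_success_rule``, ``recurrence_status``, ``time_days``
    and ``event`` (1 for recurrence, 0 otherwise). When the table already
    carries an ``early_success`` column (e.g. a group-conditional simulation
    where group membership defines the outcome) that column is kept as the
    outcome and the rule output is reported alongside it for comparison.
    """
    out = df.copy()
    has_truth = "early_success" in df.columns
    successes, statuses, times, events = [], [], [], []
    for _, row in df.iterrows():
        baseline = VasTriple(
            row["vas_rest_baseline"], row["vas_night_baseline"], row["vas_overhead_baseline"]
        )
        week4 = VasTriple(
            row["vas_rest_week4"], row["vas_night_week4"], row["vas_overhead_week4"]
        )
        rule_success = classify_early_success(baseline, week4)
        success = bool(row["early_success"]) if has_truth else rule_success
        rec = PatientRecord(
            id=str(row["id"]),
            age=float(row["age"]),
            sex=row["sex"],
            side=row["side"],
            injection_date=row.get("injection_date"),
            repeat_injection_date=_none_if_na(row.get("repeat_injection_date")),
            last_visit_date=_none_if_na(row.get("last_visit_date")),
            phone_contact=row.get("phone_contact", "not_attempted"),
        )
        label = label_recurrence(rec, success)
        successes.append(int(rule_success))
        statuses.append(label.recurrence_status)
        times.append(label.time_days)
        events.append(int(label.recurrence_status == "recurrence"))
    out["early_success_rule"] = successes
    if not has_truth:
        out["early_success"] = successes
    out["recurrence_status"] = statuses
    out["time_days"] = times
    out["event"] = events
    return out


def _none_if_na(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return value
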