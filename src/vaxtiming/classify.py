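"""Per-child classification: FIC status, timeliness and dose sequencing.

Definitions implemented here:

* **FIC** (fully immunized child): every dose in the schedule's FIC basis
  (default BCG, OPV1-3, pentavalent 1-3, MV) received by the cutoff age
  (default 365 days).  Children with all basis doses on the card but at
  least one after the cutoff are *FIC after 12 months* — not FIC, but not
  missing any vaccine either.
* **Timeliness**: a dose is *early* when given more than ``early_margin``
  days before its recommended age, *delayed* when more than ``delay_margin``
  days after, else *timely*; unrecorded doses are *missing*.  For measles an
  additional strict-early indicator flags doses more than 14 days before the
  recommended age.
* **Out-of-sequence (OS)**: (i) BCG given together with or after any other
  routine dose (the polio birth dose is exempt — it is co-administered with
  BCG by design); (ii) any pentavalent dose given together with or after
  measles; (iii) a pentavalent dose and its companion polio dose given on
  different days.  **FIC-OS** is an FIC child with any OS flag.

All age arithmetic is in whole calendar days; a dose given the same day as
another counts as "with" it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .cohort import ChildRecord, Cohort
from .schedule import DoseSpec, ScheduleSpec, timeliness_window

MV_STRICT_EARLY_MARGIN = 14  # days; secondary early rule for measles


@dataclass(frozen=True)
class FicResult:
    fic: bool
    missing_doses: frozenset[str]
    fic_after_cutoff: bool


@dataclass(frozen=True)
class DoseTimeliness:
    status: str  # early | timely | delayed | missing
    age_days: Optional[int]


@dataclass(frozen=True)
class TimelinessResult:
    per_dose: dict[str, DoseTimeliness]
    mv_early_strict: bool

    def status(self, label: str) -> str:
        return self.per_dose[label].status


@dataclass(frozen=True)
class SequenceFlags:
    late_bcg: bool
    penta_opv_split: bool
    penta_after_mv: bool

    @property
    def out_of_sequence(self) -> bool:
        return self.late_bcg or self.penta_opv_split or self.penta_after_mv


def age_at_dose(child: ChildRecord, dose: str) -> Optional[int]:
    """Age in whole days at the recorded dose, or None if not on the card."""
    date = child.event_date(dose)
    if date is None:
        return None
    return (date - child.dob).days


def classify_fic(child: ChildRecord, schedule: ScheduleSpec) -> FicResult:
    """FIC status at the schedule's cutoff age."""
    cutoff = schedule.fic_cutoff_days
    missing: set[str] = set()
    after_cutoff = False
    for label in schedule.fic_labels:
        age = age_at_dose(child, label)
        if age is None:
            missing.add(label)
        elif age > cutoff:
            after_cutoff = True
    fic = not missing and not after_cutoff
    return FicResult(
        fic=fic,
        missing_doses=frozenset(missing),
        fic_after_cutoff=(not missing) and after_cutoff,
    )


def _dose_status(age: Optional[int], spec: DoseSpec) -> str:
    if age is None:
        return "missing"
    earliest, latest = timeliness_window(spec)
    if age < earliest:
        return "early"
    if age > latest:
        return "delayed"
    return "timely"


def classify_timeliness(child: ChildRecord, schedule: ScheduleSpec) -> TimelinessResult:
    per_dose: dict[str, DoseTimeliness] = {}
    mv_early_strict = False
    for spec in schedule.doses:
        age = age_at_dose(child, spec.antigen)
        per_dose[spec.antigen] = DoseTimeliness(_dose_status(age, spec), age)
        if spec.series == "MV" and age is not None:
            mv_early_strict = (spec.recommended_age_days - age) > MV_STRICT_EARLY_MARGIN
    return TimelinessResult(per_dose=per_dose, mv_early_strict=mv_early_strict)


def flag_out_of_sequence(
    child: ChildRecord,
    schedule: ScheduleSpec,
    within_cutoff: bool = True,
    late_bcg_comparators: str = "all",
) -> SequenceFlags:
    """Evaluate the three out-of-sequence rules.

    Comparisons run over doses received by the FIC cutoff (``within_cutoff``,
    default) to match an "by 12 months of age" reading; set it False to use
    every card event.  ``late_bcg_comparators`` selects the comparator set
    for rule (i): ``"all"`` (every schedule dose except BCG and the polio
    birth dose) or ``"penta_mv"`` (pentavalent and measles only).
    Unrecorded doses never trigger a flag.
    """
    cutoff = schedule.fic_cutoff_days
    dates: dict[str, object] = {}
    for spec in schedule.doses:
        age = age_at_dose(child, spec.antigen)
        if age is None or (within_cutoff and age > cutoff):
            continue
        dates[spec.antigen] = child.event_date(spec.antigen)

    if late_bcg_comparators == "all":
        comparators = [lab for lab in dates if lab not in {"BCG", "OPV0"}]
    elif late_bcg_comparators == "penta_mv":
        comparators = [lab for lab in dates
                       if lab.startswith("PENTA") or schedule.dose(lab).series == "MV"]
    else:
        raise ValueError("late_bcg_comparators must be 'all' or 'penta_mv'")

    late_bcg = False
    if "BCG" in dates and comparators:
        late_bcg = dates["BCG"] >= min(dates[lab] for lab in comparators)

    penta_after_mv = False
    if "MV" in dates:
        penta_after_mv = any(
            dates[f"PENTA{k}"] >= dates["MV"]
            for k in (1, 2, 3) if f"PENTA{k}" in dates
        )

    penta_opv_split = any(
        f"PENTA{k}" in dates and f"OPV{k}" in dates
        and dates[f"PENTA{k}"] != dates[f"OPV{k}"]
        for k in (1, 2, 3)
    )

    return SequenceFlags(
        late_bcg=late_bcg,
        penta_opv_split=penta_opv_split,
        penta_after_mv=penta_after_mv,
    )


def classify_fic_os(fic: FicResult, flags: SequenceFlags) -> bool:
    """FIC-OS: fully immunized with at least one out-of-sequence dose."""
    return fic.fic and flags.out_of_sequence


def missing_profile(
    child: ChildRecord, schedule: ScheduleSpec
) -> tuple[int, frozenset[str], bool]:
    """Missing-vaccine profile of a non-FIC child.

    Returns (number of FIC-basis doses absent from the card, their labels,
    whether the child is instead "FIC after cutoff" — all doses on the card
    but at least one past the cutoff).  Doses received after the cutoff are
    not counted as missing.
    """
    res = classify_fic(child, schedule)
    if res.fic:
        raise ValueError(f"child {child.child_id} is FIC; no missing profile")
    return len(res.missing_doses), res.missing_doses, res.fic_after_cutoff


# -- cohort-level convenience --------------------------------------------------

def classify_child(child: ChildRecord, schedule: ScheduleSpec, **os_kwargs) -> dict:
    """One flat dict of every classification output for one child."""
    fic = classify_fic(child, schedule)
    tim = classify_timeliness(child, schedule)
    flags = flag_out_of_sequence(child, schedule, **os_kwargs)
    row: dict = {
        "child_id": child.child_id,
        "fic": fic.fic,
        "fic_after_cutoff": fic.fic_after_cutoff,
        "n_missing": len(fic.missing_doses),
        "missing_doses": ",".join(sorted(fic.missing_doses)),
        "late_bcg": flags.late_bcg,
        "penta_opv_split": flags.penta_opv_split,
        "penta_after_mv": flags.penta_after_mv,
        "out_of_sequence": flags.out_of_sequence,
        "fic_os": classify_fic_os(fic, flags),
        "mv_early_strict": tim.mv_early_strict,
        "year_of_visit": child.year_of_visit,
        "sex": child.sex,
    }
    for label in schedule.labels:
        dt_ = tim.per_dose[label]
        row[f"status_{label}"] = dt_.status
        row[f"age_{label}"] = dt_.age_days
    row.update(child.covariates)
    return row


def classify_cohort(cohort: Cohort, schedule: ScheduleSpec, **os_kwargs) -> pd.DataFrame:
    """Classify every child; one row per child, indexed by child_id order."""
    rows = [classify_child(c, schedule, **os_kwargs) for c in cohort]
    return pd.DataFrame(rows)
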