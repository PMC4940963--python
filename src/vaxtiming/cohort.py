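"""Vaccination-card cohorts: ingestion, serialization and inclusion rules.

A cohort is read from two delimited files: a long-format *records* file with
one row per vaccination event or follow-up visit, and a per-child
*covariates* file.  The inclusion rule mirrors a card-based audit of
children aged 12-23 months: a child enters the analysis iff it has at least
one follow-up visit, with the vaccination card seen, at an age inside the
``[min_age, max_age)`` window (default [365, 730) days); the earliest such
visit becomes the child's *analysis visit* and its calendar year the child's
``year_of_visit``.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .schedule import SERIES_FAMILIES, ScheduleSpec

RECORD_COLUMNS = ["child_id", "dob", "event_type", "antigen", "date", "card_seen"]
COVARIATE_COLUMNS = [
    "child_id", "sex", "postnatal_care", "mother_age_group", "education",
    "delivery_place", "parity", "ethnicity", "wealth", "site",
]


class CohortReadError(ValueError):
    """Raised when ingestion finds malformed rows; carries the row-level report."""

    def __init__(self, errors: list[dict]):
        self.errors = errors
        lines = "; ".join(f"row {e['row']}: {e['error']}" for e in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} malformed rows: {lines}{more}")


@dataclass(frozen=True)
class VaccinationEvent:
    antigen: str
    date: dt.date


@dataclass(frozen=True)
class Visit:
    date: dt.date
    card_seen: bool


@dataclass
class ChildRecord:
    """One child: identifiers, covariates, visit history and card events."""

    child_id: str
    dob: dt.date
    sex: Optional[str] = None
    covariates: dict[str, str] = field(default_factory=dict)
    visits: list[Visit] = field(default_factory=list)
    events: list[VaccinationEvent] = field(default_factory=list)
    analysis_visit: Optional[Visit] = None
    year_of_visit: Optional[int] = None

    def event_date(self, antigen: str) -> Optional[dt.date]:
        for ev in self.events:
            if ev.antigen == antigen:
                return ev.date
        return None


@dataclass
class Cohort:
    children: list[ChildRecord]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.children)

    def __iter__(self):
        return iter(self.children)


# -- ingestion ----------------------------------------------------------------

def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(str(value).strip())


def _truthy(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "y", "t"}


def assign_dose_indices(
    events: list[tuple[str, dt.date]], schedule: ScheduleSpec
) -> list[tuple[str, dt.date]]:
    """Resolve family-only antigen labels to explicit dose labels.

    Cards often record only the antigen family ("OPV", date) without a dose
    number; the only reproducible rule is chronological: that family's dated
    events are sorted and numbered 1..k.  Explicit labels pass through.
    """
    resolved: list[tuple[str, dt.date]] = []
    for fam in SERIES_FAMILIES:
        fam_events = sorted((d for a, d in events if a == fam))
        n_slots = sum(1 for ds in schedule.doses if ds.series == fam and ds.dose_index >= 1)
        if len(fam_events) > n_slots:
            raise ValueError(
                f"{len(fam_events)} undated-index {fam} events but schedule has "
                f"only {n_slots} numbered doses"
            )
        resolved.extend((f"{fam}{k}", d) for k, d in enumerate(fam_events, start=1))
    resolved.extend((a, d) for a, d in events if a not in SERIES_FAMILIES)
    return resolved


def read_cohort(
    records_path: str | Path,
    schedule: ScheduleSpec,
    covariates_path: str | Path | None = None,
    errors: str = "raise",
) -> Cohort:
    """Read a long-format records file (and optional covariates file).

    Malformed rows — unknown antigen label, unparseable date, event dated
    before the child's date of birth — are collected with their row numbers
    into an error report.  With ``errors="raise"`` (default) any malformed
    row aborts ingestion with :class:`CohortReadError`; with
    ``errors="collect"`` clean rows are kept and the report is attached to
    ``cohort.provenance["errors"]``.
    """
    if errors not in {"raise", "collect"}:
        raise ValueError("errors must be 'raise' or 'collect'")
    records_path = Path(records_path)
    sep = "\t" if records_path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(records_path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file lacks columns {missing}")

    known = set(schedule.labels) | set(SERIES_FAMILIES)
    report: list[dict] = []
    raw_children: dict[str, dict] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            cid = str(row.child_id)
            dob = _parse_date(row.dob)
            child = raw_children.setdefault(
                cid, {"dob": dob, "visits": [], "events": []}
            )
            if child["dob"] != dob:
                raise ValueError(f"inconsistent dob for child {cid}")
            kind = str(row.event_type).strip().lower()
            if kind == "visit":
                child["visits"].append(Visit(_parse_date(row.date), _truthy(row.card_seen)))
            elif kind == "vaccination":
                antigen = str(row.antigen).strip()
                if antigen not in known:
                    raise ValueError(f"unknown antigen label {antigen!r}")
                date = _parse_date(row.date)
                if date < dob:
                    raise ValueError(f"event date {date} before dob {dob}")
                child["events"].append((antigen, date))
            else:
                raise ValueError(f"unknown event_type {row.event_type!r}")
        except ValueError as exc:
            report.append({"row": i, "error": str(exc)})
    if report and errors == "raise":
        raise CohortReadError(report)

    covs: dict[str, dict] = {}
    if covariates_path is not None:
        cdf = pd.read_csv(Path(covariates_path), sep=sep, dtype=str, keep_default_na=False)
        for row in cdf.itertuples(index=False):
            d = row._asdict()
            covs[str(d.pop("child_id"))] = {k: v for k, v in d.items() if v != ""}

    children: list[ChildRecord] = []
    for cid, data in raw_children.items():
        try:
            resolved = assign_dose_indices(data["events"], schedule)
        except ValueError as exc:
            report.append({"row": None, "error": f"child {cid}: {exc}"})
            if errors == "raise":
                raise CohortReadError(report) from exc
            continue
        # dedup identical (antigen, date) pairs; keep earliest date per antigen
        events = sorted(set(resolved), key=lambda ad: (ad[1], ad[0]))
        cov = dict(covs.get(cid, {}))
        children.append(
            ChildRecord(
                child_id=cid,
                dob=data["dob"],
                sex=cov.pop("sex", None),
                covariates=cov,
                visits=sorted(data["visits"], key=lambda v: v.date),
                events=[VaccinationEvent(a, d) for a, d in events],
            )
        )
    children.sort(key=lambda c: c.child_id)
    return Cohort(
        children=children,
        provenance={"source": str(records_path), "errors": report},
    )


def write_cohort(
    cohort: Cohort,
    records_path: str | Path,
    covariates_path: str | Path | None = None,
) -> None:
    """Write a cohort back to the long-format records (+ covariates) files."""
    records_path = Path(records_path)
    sep = "\t" if records_path.suffix.lower() in {".tsv", ".tab"} else ","
    rows = []
    for c in cohort:
        for v in c.visits:
            rows.append([c.child_id, c.dob.isoformat(), "visit", "",
                         v.date.isoformat(), str(v.card_seen).lower()])
        for ev in c.events:
            rows.append([c.child_id, c.dob.isoformat(), "vaccination",
                         ev.antigen, ev.date.isoformat(), ""])
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(records_path, sep=sep, index=False)
    if covariates_path is not None:
        crows = []
        for c in cohort:
            d = {"child_id": c.child_id, "sex": c.sex or ""}
            d.update({k: c.covariates.get(k, "") for k in COVARIATE_COLUMNS[2:]})
            crows.append(d)
        pd.DataFrame(crows, columns=COVARIATE_COLUMNS).to_csv(
            Path(covariates_path), sep=sep, index=False
        )


# -- JSON round-trip (CLI chaining) -------------------------------------------

def cohort_to_json(cohort: Cohort, path: str | Path) -> None:
    data = {
        "provenance": cohort.provenance,
        "children": [
            {
                "child_id": c.child_id,
                "dob": c.dob.isoformat(),
                "sex": c.sex,
                "covariates": c.covariates,
                "visits": [[v.date.isoformat(), v.card_seen] for v in c.visits],
                "events": [[e.antigen, e.date.isoformat()] for e in c.events],
                "analysis_visit": (
                    [c.analysis_visit.date.isoformat(), c.analysis_visit.card_seen]
                    if c.analysis_visit else None
                ),
                "year_of_visit": c.year_of_visit,
            }
            for c in cohort
        ],
    }
    Path(path).write_text(json.dumps(data))


def cohort_from_json(path: str | Path) -> Cohort:
    data = json.loads(Path(path).read_text())
    children = []
    for d in data["children"]:
        av = d.get("analysis_visit")
        children.append(
            ChildRecord(
                child_id=d["child_id"],
                dob=dt.date.fromisoformat(d["dob"]),
                sex=d.get("sex"),
                covariates=d.get("covariates", {}),
                visits=[Visit(dt.date.fromisoformat(vd), cs) for vd, cs in d["visits"]],
                events=[VaccinationEvent(a, dt.date.fromisoformat(ed))
                        for a, ed in d["events"]],
                analysis_visit=Visit(dt.date.fromisoformat(av[0]), av[1]) if av else None,
                year_of_visit=d.get("year_of_visit"),
            )
        )
    return Cohort(children=children, provenance=data.get("provenance", {}))


# -- inclusion ----------------------------------------------------------------

def select_analysis_visit(
    child: ChildRecord, min_age: int = 365, max_age: int = 730
) -> Optional[Visit]:
    """Earliest card-seen visit at an age in [min_age, max_age) days, or None.

    The window is half-open: 12 months inclusive, 24 months exclusive —
    "children aged 12-23 months".  When several visits qualify the earliest
    is picked, so reported coverage reflects the card as close to the first
    birthday as the visit scheme allows.
    """
    for visit in sorted(child.visits, key=lambda v: v.date):
        age = (visit.date - child.dob).days
        if visit.card_seen and min_age <= age < max_age:
            return visit
    return None


def apply_inclusion(
    cohort: Cohort, min_age: int = 365, max_age: int = 730
) -> tuple[Cohort, dict]:
    """Keep exactly the children with a qualifying analysis visit.

    Returns the included cohort (children annotated with their analysis
    visit and its calendar year) and a log of counts by exclusion reason:
    children with no card-seen visit at all in the window are split from
    children with no visit in the window.
    """
    included: list[ChildRecord] = []
    n_no_window = 0
    n_no_card = 0
    for child in cohort:
        visit = select_analysis_visit(child, min_age, max_age)
        if visit is not None:
            child.analysis_visit = visit
            child.year_of_visit = visit.date.year
            included.append(child)
            continue
        in_window = any(
            min_age <= (v.date - child.dob).days < max_age for v in child.visits
        )
        if in_window:
            n_no_card += 1
        else:
            n_no_window += 1
    total = len(cohort)
    log = {
        "total": total,
        "included": len(included),
        "excluded_no_card": n_no_card,
        "excluded_no_window_visit": n_no_window,
        "included_fraction": (len(included) / total) if total else 0.0,
    }
    prov = dict(cohort.provenance)
    prov["inclusion"] = log
    return Cohort(children=included, provenance=prov), log
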