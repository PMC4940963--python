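"""Recommended immunization schedule: doses, ages and timeliness windows.

The default schedule is the WHO/EPI routine infant schedule as applied in
Kenya: BCG and a birth dose of oral polio vaccine (OPV0) at birth, three
doses each of OPV, pentavalent (DTP-HepB-Hib) and pneumococcal conjugate
vaccine (PCV) at 6, 10 and 14 weeks (days 42/70/98), and measles vaccine
(MV) at 9 months (day 274).  Eight doses — BCG, OPV1-3, pentavalent 1-3 and
MV — form the "fully immunized child" (FIC) basis; a child is FIC when all
eight are received by the 365-day cutoff.

A dose given more than ``early_margin`` days before its recommended age is
*early*; more than ``delay_margin`` days after, *delayed*.  The defaults are
4 days early for every dose, 14 days late for BCG/OPV/pentavalent/PCV and 30
days ("a month", taken as 30 fixed days so classification does not depend on
the calendar month of birth) for measles.
"""

from __future__ import annotations

import datetime as dt
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

#: Antigen families with multi-dose series.
SERIES_FAMILIES = ("OPV", "PENTA", "PCV")


class DoseSpec(BaseModel):
    """One scheduled dose and its timeliness window."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    antigen: str
    series: str
    dose_index: int
    recommended_age_days: int
    early_margin_days: int = 4
    delay_margin_days: int = 14
    in_fic: bool = True
    companion: Optional[str] = None

    @field_validator("recommended_age_days", "early_margin_days", "delay_margin_days")
    @classmethod
    def _non_negative(cls, v: int) -> int:
        if v < 0:
            raise ValueError("day counts must be non-negative")
        return v

    @field_validator("dose_index")
    @classmethod
    def _index_positive(cls, v: int) -> int:
        if v < 0:
            raise ValueError("dose_index must be >= 0")
        return v


class ScheduleSpec(BaseModel):
    """An ordered collection of doses plus the FIC cutoff and rollout dates."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    doses: tuple[DoseSpec, ...]
    fic_cutoff_days: int = 365
    rollout_dates: dict[str, dt.date] = {}

    @model_validator(mode="after")
    def _validate(self) -> "ScheduleSpec":
        labels = [d.antigen for d in self.doses]
        if len(labels) != len(set(labels)):
            dup = sorted({a for a in labels if labels.count(a) > 1})
            raise ValueError(f"duplicate dose labels: {dup}")
        if self.fic_cutoff_days <= 0:
            raise ValueError("fic_cutoff_days must be positive")
        by_label = {d.antigen: d for d in self.doses}
        # monotone recommended ages within a series
        for fam in {d.series for d in self.doses}:
            fam_doses = sorted(
                (d for d in self.doses if d.series == fam), key=lambda d: d.dose_index
            )
            for a, b in zip(fam_doses, fam_doses[1:]):
                if b.recommended_age_days <= a.recommended_age_days:
                    raise ValueError(
                        f"recommended age not increasing in series {fam}: "
                        f"{b.antigen} ({b.recommended_age_days} d) <= "
                        f"{a.antigen} ({a.recommended_age_days} d)"
                    )
        # companion symmetry
        for d in self.doses:
            if d.companion is None:
                continue
            other = by_label.get(d.companion)
            if other is None:
                raise ValueError(f"{d.antigen}: companion {d.companion} not in schedule")
            if other.companion != d.antigen:
                raise ValueError(
                    f"asymmetric companion: {d.antigen} -> {d.companion} "
                    f"but {other.antigen} -> {other.companion}"
                )
        for antigen in self.rollout_dates:
            if not any(d.antigen == antigen or d.series == antigen for d in self.doses):
                raise ValueError(f"rollout date for unknown antigen {antigen!r}")
        return self

    # -- convenience accessors -------------------------------------------------

    def dose(self, label: str) -> DoseSpec:
        for d in self.doses:
            if d.antigen == label:
                return d
        raise KeyError(f"no dose labelled {label!r} in schedule")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(d.antigen for d in self.doses)

    @property
    def fic_labels(self) -> tuple[str, ...]:
        """Dose labels forming the FIC basis, in schedule order."""
        return tuple(d.antigen for d in self.doses if d.in_fic)

    def rollout_date(self, dose: DoseSpec) -> Optional[dt.date]:
        return self.rollout_dates.get(dose.antigen) or self.rollout_dates.get(dose.series)


def timeliness_window(spec: DoseSpec) -> tuple[int, int]:
    """(earliest_timely, latest_timely) ages in days for a dose.

    A dose at age ``a`` is early iff ``a < earliest_timely`` (i.e. given more
    than ``early_margin_days`` before the recommended age), delayed iff
    ``a > latest_timely``.  The early bound is floored at 0: a birth dose can
    never be early.
    """
    earliest = max(0, spec.recommended_age_days - spec.early_margin_days)
    latest = spec.recommended_age_days + spec.delay_margin_days
    return earliest, latest


def default_epi_schedule() -> ScheduleSpec:
    """The study schedule: Kenyan routine infant immunization.

    BCG and OPV0 at birth; OPV/pentavalent/PCV doses 1-3 at days 42/70/98;
    MV at day 274.  Pentavalent dose k is companioned with OPV dose k (the
    two are recommended for same-day administration).  OPV0 and the PCV
    series are outside the 8-dose FIC basis; PCV carries a rollout date of
    2011-02-01, before which it was not offered.
    """
    doses: list[DoseSpec] = [
        DoseSpec(antigen="BCG", series="BCG", dose_index=1, recommended_age_days=0),
        DoseSpec(antigen="OPV0", series="OPV", dose_index=0,
                 recommended_age_days=0, in_fic=False),
    ]
    week_ages = {1: 42, 2: 70, 3: 98}
    for k, age in week_ages.items():
        doses.append(DoseSpec(antigen=f"OPV{k}", series="OPV", dose_index=k,
                              recommended_age_days=age, companion=f"PENTA{k}"))
        doses.append(DoseSpec(antigen=f"PENTA{k}", series="PENTA", dose_index=k,
                              recommended_age_days=age, companion=f"OPV{k}"))
        doses.append(DoseSpec(antigen=f"PCV{k}", series="PCV", dose_index=k,
                              recommended_age_days=age, in_fic=False))
    doses.append(DoseSpec(antigen="MV", series="MV", dose_index=1,
                          recommended_age_days=274, delay_margin_days=30))
    return ScheduleSpec(
        doses=tuple(doses),
        fic_cutoff_days=365,
        rollout_dates={"PCV": dt.date(2011, 2, 1)},
    )


# -- file IO ------------------------------------------------------------------

def _to_plain(spec: ScheduleSpec) -> dict:
    data = spec.model_dump(mode="json")
    data["doses"] = [
        {k: v for k, v in d.items() if v is not None} for d in data["doses"]
    ]
    return data


def save_schedule(spec: ScheduleSpec, path: str | Path) -> None:
    """Write a schedule as JSON or YAML (chosen by file extension)."""
    path = Path(path)
    data = _to_plain(spec)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_schedule(path: str | Path) -> ScheduleSpec:
    """Read and validate a schedule file (JSON or YAML).

    Unknown fields are rejected; every schedule invariant (unique labels,
    monotone series ages, companion symmetry) is enforced on load.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return ScheduleSpec.model_validate(raw)
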