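"""Cohort summary tables: coverage by year, FIC by covariates, OS, missing.

Every percentage cell is backed by its own numerator/denominator pair and
recomputed from them when a table is written — tables cannot drift from
their counts.  Percentages are rounded half-up to one decimal, the usual
convention of printed coverage tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .schedule import ScheduleSpec
from .stats import TestResult, chisq_independence

MISSING_STRATUM = "(missing)"


def percent(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageCell:
    numerator: int
    denominator: int

    def __post_init__(self):
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("need 0 <= numerator <= denominator")

    @property
    def percent(self) -> float:
        return percent(self.numerator, self.denominator)

    def __str__(self) -> str:
        return f"{self.percent} ({self.numerator})"


def _received_by_cutoff(classifications: pd.DataFrame, label: str, cutoff: int) -> pd.Series:
    ages = classifications[f"age_{label}"]
    return ages.notna() & (ages <= cutoff)


def antigen_coverage_table(
    classifications: pd.DataFrame,
    schedule: ScheduleSpec,
    by_year: bool = True,
) -> pd.DataFrame:
    """Per-antigen (and FIC) coverage at the cutoff age, by year of visit.

    Cells are :class:`CoverageCell`; the final column pools all years.
    Antigens with a rollout date (PCV) are tabulated only over children
    whose analysis-visit year is at or after the rollout year — before
    that the dose was not on offer, so the usual denominator would
    understate uptake.
    """
    cutoff = schedule.fic_cutoff_days
    years: list = sorted(y for y in classifications["year_of_visit"].dropna().unique()) \
        if by_year else []
    columns = [int(y) for y in years] + ["overall"]
    rows = {}
    for spec in schedule.doses:
        label = spec.antigen
        rollout = schedule.rollout_date(spec)
        eligible = pd.Series(True, index=classifications.index)
        if rollout is not None:
            eligible = classifications["year_of_visit"] >= rollout.year
        got = _received_by_cutoff(classifications, label, cutoff)
        cells = {}
        for col in columns:
            mask = eligible if col == "overall" \
                else eligible & (classifications["year_of_visit"] == col)
            denom = int(mask.sum())
            cells[col] = CoverageCell(int((got & mask).sum()), denom) if denom else None
        rows[label] = cells
    fic = classifications["fic"].astype(bool)
    rows["FIC"] = {}
    for col in columns:
        mask = slice(None) if col == "overall" \
            else (classifications["year_of_visit"] == col)
        sub = fic if col == "overall" else fic[mask]
        rows["FIC"][col] = CoverageCell(int(sub.sum()), int(len(sub))) if len(sub) else None
    return pd.DataFrame.from_dict(rows, orient="index")[columns]


def _strata(classifications: pd.DataFrame, covariate: str) -> pd.Series:
    col = classifications[covariate] if covariate in classifications else \
        pd.Series(pd.NA, index=classifications.index)
    return col.fillna(MISSING_STRATUM).replace("", MISSING_STRATUM).astype(str)


@dataclass
class StratifiedTable:
    """A per-stratum table plus the across-strata chi-square test.

    The "(missing)" stratum (children with the covariate unrecorded) is
    reported but excluded from the test.
    """

    outcome: str
    covariate: str
    table: pd.DataFrame
    test: Optional[TestResult]


def fic_by_covariate_table(
    classifications: pd.DataFrame, covariate: str
) -> StratifiedTable:
    """Sample composition and FIC coverage per stratum of one covariate."""
    strata = _strata(classifications, covariate)
    fic = classifications["fic"].astype(bool)
    rows = []
    for level, idx in strata.groupby(strata).groups.items():
        n = len(idx)
        n_fic = int(fic.loc[idx].sum())
        rows.append({
            "stratum": level,
            "n": n,
            "pct_of_sample": percent(n, len(classifications)),
            "fic_cell": CoverageCell(n_fic, n),
            "fic_pct": percent(n_fic, n),
        })
    table = pd.DataFrame(rows).set_index("stratum")
    test = _stratum_test(table, fic, strata)
    return StratifiedTable("FIC", covariate, table, test)


def _stratum_test(table: pd.DataFrame, outcome: pd.Series, strata: pd.Series,
                  ) -> Optional[TestResult]:
    levels = [s for s in table.index if s != MISSING_STRATUM]
    if len(levels) < 2:
        return None
    counts = []
    for level in levels:
        mask = strata == level
        counts.append([int((outcome & mask).sum()), int((~outcome & mask).sum())])
    try:
        return chisq_independence(counts)
    except ValueError:
        return None


def fic_os_table(
    classifications: pd.DataFrame, covariate: Optional[str] = None
) -> StratifiedTable:
    """Out-of-sequence rates among FIC children, overall or per stratum.

    Denominators are FIC children only; columns give the share with late
    BCG, pentavalent/OPV on different days, pentavalent with-or-after
    measles, and any of the three (FIC-OS).  The chi-square compares FIC-OS
    across strata.
    """
    fic_rows = classifications[classifications["fic"].astype(bool)]
    strata = _strata(fic_rows, covariate) if covariate else \
        pd.Series("overall", index=fic_rows.index)
    rows = []
    for level, idx in strata.groupby(strata).groups.items():
        sub = fic_rows.loc[idx]
        n = len(sub)
        row = {"stratum": level, "N": n}
        for col in ("late_bcg", "penta_opv_split", "penta_after_mv", "fic_os"):
            row[f"{col}_cell"] = CoverageCell(int(sub[col].sum()), n)
            row[f"{col}_pct"] = percent(int(sub[col].sum()), n)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("stratum")
    test = None
    if covariate:
        test = _stratum_test(table, classifications["fic_os"].astype(bool),
                             _strata(classifications, covariate))
    return StratifiedTable("FIC-OS", covariate or "overall", table, test)


def missing_vaccine_table(
    classifications: pd.DataFrame, schedule: ScheduleSpec
) -> pd.DataFrame:
    """Missing-vaccine profile of the non-FIC children.

    Rows "0".."8" give the distribution of the number of FIC-basis doses
    absent from the card ("0" = every dose on the card but at least one
    after the cutoff); per-antigen rows give the share of non-FIC children
    missing that dose (these can sum past 100: a child can miss several).
    """
    non_fic = classifications[~classifications["fic"].astype(bool)]
    n = len(non_fic)
    if n == 0:
        raise ValueError("no non-FIC children")
    rows = {}
    n_basis = len(schedule.fic_labels)
    for k in range(n_basis + 1):
        count = int((non_fic["n_missing"] == k).sum())
        rows[str(k)] = CoverageCell(count, n)
    for label in schedule.fic_labels:
        count = int(non_fic["missing_doses"].fillna("").str.split(",")
                    .apply(lambda ds: label in ds).sum())
        rows[label] = CoverageCell(count, n)
    df = pd.DataFrame({"cell": rows})
    df["pct"] = [c.percent for c in df["cell"]]
    df.attrs["N"] = n
    return df


# -- writers ------------------------------------------------------------------

def _audit(cell: CoverageCell) -> None:
    # self-consistency: the printed percent must recompute from the counts
    assert cell.percent == percent(cell.numerator, cell.denominator)


def write_coverage_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    for col in out.columns:
        out[col] = out[col].map(
            lambda c: (_audit(c), str(c))[1] if isinstance(c, CoverageCell) else ""
        )
    out.to_csv(Path(path), sep="\t")


def write_stratified_table(st: StratifiedTable, path: str | Path) -> None:
    out = st.table.copy()
    for col in list(out.columns):
        if col.endswith("_cell"):
            out[col.replace("_cell", "")] = out[col].map(
                lambda c: (_audit(c), str(c))[1]
            )
            out = out.drop(columns=[col])
    if st.test is not None:
        out.attrs["p_value"] = st.test.p_value
    out.to_csv(Path(path), sep="\t")
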