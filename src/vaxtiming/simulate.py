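"""Synthetic longitudinal vaccination-card cohorts.

The generator emulates a demographic-surveillance cohort of urban children
followed every four months, each visit recording whether a vaccination card
was seen and, if so, the dated doses on it.  The event process mirrors how
routine immunization is actually delivered:

* birth doses (BCG, OPV0) shortly after birth, with a small fraction of BCG
  deferred to the first 6-week contact;
* three penta/OPV/PCV contacts nominally at 42/70/98 days, reached through
  a per-series continuation chain (dose k only if dose k-1 was received)
  with non-decreasing cumulative delays, so inter-dose gaps never shrink
  below the 28-day schedule gap;
* OPV occasionally out of stock at a contact (dose-3 misses) or given on a
  different day than its companion pentavalent dose (splits);
* measles at 274 days plus a heavy-tailed delay, with a small early
  fraction and a rare contact swap that puts the last pentavalent dose on
  or after the measles date;
* PCV offered only once its calendar rollout date has passed.

Categorical covariates (site, education, wealth, postnatal care, parity,
ethnicity, maternal age, sex, delivery place) are drawn from configured
frequencies; centred log-odds effects shift series continuation, measles
uptake and the split probability, and one site shifts all delays by a fixed
number of days — enough heterogeneity to reproduce the direction of
observed coverage gradients.

Every latent draw is kept in a :class:`Truth` record whose labels (FIC,
split, late BCG, ...) are computed by independent straight-line code, so
the classifier can be audited against the generator.  A fixed seed gives a
bit-identical cohort.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.stats import gamma as _gamma
from scipy.stats import norm as _norm

from .classify import classify_cohort
from .cohort import ChildRecord, Cohort, VaccinationEvent, Visit
from .schedule import ScheduleSpec, default_epi_schedule

# ---------------------------------------------------------------------------
# discrete delay distributions (whole days — cards record dates)

def discretized_gamma_pmf(shape: float, scale: float, cap: int) -> np.ndarray:
    """Gamma density binned to whole days 0..cap and renormalized."""
    i = np.arange(cap + 1)
    hi = _gamma.cdf(i + 0.5, shape, scale=scale)
    lo = _gamma.cdf(np.maximum(i - 0.5, 0.0), shape, scale=scale)
    p = hi - lo
    p[0] = _gamma.cdf(0.5, shape, scale=scale)
    return p / p.sum()


def discretized_lognormal_pmf(median: float, sigma: float, cap: int) -> np.ndarray:
    """Log-normal (given median and log-sd) binned to whole days 0..cap."""
    mu = math.log(median)
    i = np.arange(cap + 1)
    cdf = _norm.cdf((np.log(i + 0.5) - mu) / sigma)
    p = np.diff(np.concatenate([[0.0], cdf]))
    return p / p.sum()


def zero_inflated_pmf(p0: float, body: np.ndarray) -> np.ndarray:
    """Point mass at 0 plus a body shifted to start at 1 day."""
    p = np.zeros(len(body) + 1)
    p[0] = p0
    p[1:] = (1.0 - p0) * body
    return p / p.sum()


def pmf_median(pmf: np.ndarray) -> int:
    return int(np.searchsorted(np.cumsum(pmf), 0.5))


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1.0 - 1e-12)
    return math.log(p / (1.0 - p))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# configuration

DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "sex": {"male": 0.505, "female": 0.495},
    "postnatal_care": {"yes": 0.924, "no": 0.076},
    "mother_age_group": {"11-20": 0.246, "21-24": 0.316, "25-29": 0.252, "30-55": 0.186},
    "education": {"<primary": 0.026, "primary": 0.700, "secondary+": 0.274},
    "delivery_place": {"facility": 0.834, "non-facility": 0.166},
    "parity": {"1": 0.324, "2": 0.308, "3+": 0.368},
    "ethnicity": {"Kikuyu": 0.258, "Luhya": 0.189, "Luo": 0.163,
                  "Kamba": 0.225, "Other": 0.165},
    "wealth": {"lower": 0.334, "middle": 0.332, "upper": 0.334},
    "site": {"Korogocho": 0.466, "Viwandani": 0.534},
}

# log-odds effects on third-contact continuation and measles uptake; the
# shared score models household "engagement" with services (direction of the
# observed coverage gradients, magnitudes are modelling choices)
DEFAULT_ENGAGEMENT_EFFECTS: dict[str, dict[str, float]] = {
    "site": {"Korogocho": 0.0, "Viwandani": 0.45},
    "education": {"<primary": -0.30, "primary": 0.0, "secondary+": 0.25},
    "wealth": {"lower": -0.25, "middle": 0.10, "upper": 0.10},
    "postnatal_care": {"no": -0.45, "yes": 0.0},
    "parity": {"1": 0.20, "2": 0.0, "3+": -0.20},
}


class SimConfig(BaseModel):
    """Parameters of the synthetic cohort generator (all ages in days)."""

    model_config = ConfigDict(extra="forbid")

    n_children: int = 1000
    seed: int = 0
    dob_start: dt.date = dt.date(2006, 9, 1)
    dob_end: dt.date = dt.date(2013, 12, 31)

    # follow-up
    visit_interval_days: int = 122          # ~4-monthly surveillance rounds
    first_visit_min_age: int = 30
    max_followup_age: int = 900
    card_seen_prob: float = 0.38            # per child: card available at visits

    # birth doses
    bcg_prob: float = 0.9715
    bcg_late_prob: float = 0.04             # deferred to the first 6-week contact
    bcg_delay_zero_frac: float = 0.30       # same-week BCG
    bcg_delay_median: float = 9.0
    bcg_delay_sigma: float = 0.80
    bcg_delay_cap: int = 35
    opv0_prob: float = 0.80

    # penta/OPV/PCV contact chain (nominal days 42/70/98)
    continuation_probs: tuple[float, float, float] = (0.990, 0.9758, 0.9027)
    opv_miss_probs: tuple[float, float, float] = (0.0, 0.0, 0.016)
    contact_delay_zero_frac: float = 0.35
    contact_delay_shape: float = 1.0
    contact_delay_scale: float = 4.5
    contact_delay_cap: int = 60
    early_first_contact_prob: float = 0.03  # contact 1 ahead of schedule
    early_first_contact_range: tuple[int, int] = (5, 12)
    min_dose_gap: int = 28

    # penta/OPV same-day administration
    split_prob: float = 0.0425              # baseline (reference site) per contact
    split_site_coef: float = 0.907          # log-odds increment, first site level
    split_offset_geom_p: float = 0.5
    split_offset_cap: int = 14

    # PCV
    pcv_uptake: float = 0.95
    pcv_rollout: dt.date = dt.date(2011, 2, 1)

    # measles
    mv_prob: float = 0.845
    mv_delay_median: float = 8.0
    mv_delay_sigma: float = 1.477
    mv_delay_cap: int = 200
    mv_early_prob: float = 0.09
    mv_early_range: tuple[int, int] = (5, 27)
    mv_before_penta_prob: float = 0.008     # last contact swapped past measles

    # covariates
    covariate_freqs: dict[str, dict[str, float]] = DEFAULT_COVARIATE_FREQS
    engagement_effects: dict[str, dict[str, float]] = DEFAULT_ENGAGEMENT_EFFECTS
    site_delay_shift_days: int = 2          # extra delay for the first site level

    fic_cutoff: int = 365

    @model_validator(mode="after")
    def _validate(self) -> "SimConfig":
        probs = {
            "card_seen_prob": self.card_seen_prob, "bcg_prob": self.bcg_prob,
            "bcg_late_prob": self.bcg_late_prob, "opv0_prob": self.opv0_prob,
            "split_prob": self.split_prob, "pcv_uptake": self.pcv_uptake,
            "mv_prob": self.mv_prob, "mv_early_prob": self.mv_early_prob,
            "mv_before_penta_prob": self.mv_before_penta_prob,
            "early_first_contact_prob": self.early_first_contact_prob,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("continuation_probs", "opv_miss_probs"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} entries must be in [0, 1]")
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if self.dob_end < self.dob_start:
            raise ValueError("dob_end before dob_start")
        for field, freqs in self.covariate_freqs.items():
            if abs(sum(freqs.values()) - 1.0) > 1e-6:
                raise ValueError(f"covariate_freqs[{field!r}] must sum to 1")
        return self

    # -- derived distributions (shared with the analytic oracles) ------------

    def contact_increment_pmf(self) -> np.ndarray:
        body = discretized_gamma_pmf(
            self.contact_delay_shape, self.contact_delay_scale,
            self.contact_delay_cap - 1,
        )
        return zero_inflated_pmf(self.contact_delay_zero_frac, body)

    def contact_cum_delay_pmf(self, k: int) -> np.ndarray:
        """Exact pmf of the cumulative delay at contact k (k = 1..3)."""
        inc = self.contact_increment_pmf()
        pmf = inc.copy()
        for _ in range(k - 1):
            pmf = np.convolve(pmf, inc)
        return pmf

    def pooled_contact_delay_median(self, k: int) -> int:
        """Median cumulative delay at contact k pooled over the site mix."""
        base = self.contact_cum_delay_pmf(k)
        shift = self.site_delay_shift_days
        n = len(base) + shift
        pooled = np.zeros(n)
        site_freqs = list(self.covariate_freqs["site"].items())
        first_site = site_freqs[0][1]           # shifted site share
        pooled[: len(base)] += (1.0 - first_site) * base
        pooled[shift: shift + len(base)] += first_site * base
        return pmf_median(pooled)

    def mv_delay_pmf(self) -> np.ndarray:
        return discretized_lognormal_pmf(
            self.mv_delay_median, self.mv_delay_sigma, self.mv_delay_cap
        )

    def bcg_delay_pmf(self) -> np.ndarray:
        body = discretized_lognormal_pmf(
            self.bcg_delay_median, self.bcg_delay_sigma, self.bcg_delay_cap - 1
        )
        pmf = np.zeros(self.bcg_delay_cap + 1)
        pmf[0] = self.bcg_delay_zero_frac / 3.0
        pmf[1] = self.bcg_delay_zero_frac / 3.0
        pmf[2] = self.bcg_delay_zero_frac / 3.0
        pmf[1:] += (1.0 - self.bcg_delay_zero_frac) * body
        return pmf / pmf.sum()


def default_study_like_config(n_children: int = 20000, seed: int = 0) -> SimConfig:
    """A config calibrated so large cohorts resemble a card-audit of an
    urban-poor surveillance population: ~38 % card-seen inclusion, third
    doses and measles driving incomplete immunization, roughly two-thirds
    of children fully immunized by 365 days and about one in five of those
    with a pentavalent/OPV dose split across days."""
    return SimConfig(n_children=n_children, seed=seed)


# ---------------------------------------------------------------------------
# truth container

@dataclass
class Truth:
    """Latent draws and generator-side labels for every generated child."""

    config: SimConfig
    children: list[dict]

    @property
    def df(self) -> pd.DataFrame:
        return pd.DataFrame(self.children)


# ---------------------------------------------------------------------------
# generation

CONTACT_AGES = (42, 70, 98)
MV_AGE = 274


def _draw_categorical(rng, freqs: dict[str, float], n: int) -> np.ndarray:
    levels = list(freqs)
    p = np.array([freqs[l] for l in levels], dtype=float)
    idx = rng.choice(len(levels), size=n, p=p / p.sum())
    return np.array(levels, dtype=object)[idx]


def _engagement_scores(config: SimConfig, covs: dict[str, np.ndarray]) -> np.ndarray:
    """Centred per-child log-odds score from the configured effects."""
    n = len(next(iter(covs.values())))
    score = np.zeros(n)
    for field, coefs in config.engagement_effects.items():
        freqs = config.covariate_freqs[field]
        mean = sum(freqs[l] * coefs.get(l, 0.0) for l in freqs)
        values = covs[field]
        score += np.array([coefs.get(v, 0.0) for v in values]) - mean
    return score


def _truth_labels(ages: dict[str, Optional[int]], cutoff: int) -> dict:
    """Generator-side labels, written as literal rule-by-rule conditionals."""
    within = {k: v for k, v in ages.items() if v is not None and v <= cutoff}

    fic = True
    for lab in ("BCG", "OPV1", "OPV2", "OPV3", "PENTA1", "PENTA2", "PENTA3", "MV"):
        if lab not in within:
            fic = False

    late_bcg = False
    if "BCG" in within:
        others = [v for k, v in within.items() if k not in ("BCG", "OPV0")]
        if others and within["BCG"] >= min(others):
            late_bcg = True

    split = False
    for k in (1, 2, 3):
        p, o = f"PENTA{k}", f"OPV{k}"
        if p in within and o in within and within[p] != within[o]:
            split = True

    penta_after_mv = False
    if "MV" in within:
        for k in (1, 2, 3):
            p = f"PENTA{k}"
            if p in within and within[p] >= within["MV"]:
                penta_after_mv = True

    os_flag = late_bcg or split or penta_after_mv
    return {
        "fic": fic, "late_bcg": late_bcg, "penta_opv_split": split,
        "penta_after_mv": penta_after_mv, "out_of_sequence": os_flag,
        "fic_os": fic and os_flag,
    }


def generate(config: SimConfig) -> tuple[Cohort, Truth]:
    """Generate a cohort (in the standard cohort schema) plus its Truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    cutoff = config.fic_cutoff

    n_days = (config.dob_end - config.dob_start).days + 1
    dob_offset = rng.integers(0, n_days, size=n)
    covs = {field: _draw_categorical(rng, freqs, n)
            for field, freqs in config.covariate_freqs.items()}
    score = _engagement_scores(config, covs)

    card = rng.random(n) < config.card_seen_prob
    first_visit = rng.integers(
        config.first_visit_min_age,
        config.first_visit_min_age + config.visit_interval_days, size=n,
    )

    bcg_pmf = config.bcg_delay_pmf()
    bcg_present = rng.random(n) < config.bcg_prob
    bcg_deferred = rng.random(n) < config.bcg_late_prob
    bcg_delay = rng.choice(len(bcg_pmf), size=n, p=bcg_pmf)

    opv0_present = rng.random(n) < config.opv0_prob
    opv0_delay = rng.integers(0, 4, size=n)

    c1, c2, c3 = config.continuation_probs
    u_att = rng.random((n, 3))
    p2 = _expit(_logit(c2) + 0.5 * score)
    p3 = _expit(_logit(c3) + score)
    attend1 = u_att[:, 0] < c1
    attend2 = attend1 & (u_att[:, 1] < p2)
    attend3 = attend2 & (u_att[:, 2] < p3)
    attend = np.column_stack([attend1, attend2, attend3])

    inc_pmf = config.contact_increment_pmf()
    inc = rng.choice(len(inc_pmf), size=(n, 3), p=inc_pmf)
    early1 = rng.random(n) < config.early_first_contact_prob
    lo, hi = config.early_first_contact_range
    early1_shift = rng.integers(lo, hi + 1, size=n)

    first_site = next(iter(config.covariate_freqs["site"]))
    delay_shift = np.where(covs["site"] == first_site,
                           config.site_delay_shift_days, 0)

    opv_miss = rng.random((n, 3)) < np.asarray(config.opv_miss_probs)
    split_logit = _logit(config.split_prob) + np.where(
        covs["site"] == first_site, config.split_site_coef, 0.0
    )
    split = rng.random((n, 3)) < _expit(split_logit)[:, None]
    split_off = np.minimum(
        rng.geometric(config.split_offset_geom_p, size=(n, 3)),
        config.split_offset_cap,
    )
    pcv_take = rng.random((n, 3)) < config.pcv_uptake

    mv_pmf = config.mv_delay_pmf()
    p_mv = _expit(_logit(config.mv_prob) + score)
    mv_present = rng.random(n) < p_mv
    mv_early = rng.random(n) < config.mv_early_prob
    mlo, mhi = config.mv_early_range
    mv_early_shift = rng.integers(mlo, mhi + 1, size=n)
    mv_delay = rng.choice(len(mv_pmf), size=n, p=mv_pmf)
    swap = rng.random(n) < config.mv_before_penta_prob
    swap_off = rng.integers(0, 4, size=n)

    children: list[ChildRecord] = []
    truth_rows: list[dict] = []
    for i in range(n):
        dob = config.dob_start + dt.timedelta(days=int(dob_offset[i]))
        ages: dict[str, Optional[int]] = {}

        # contact ages (cumulative delays keep gaps >= the schedule gap)
        cum = np.cumsum(inc[i]) + delay_shift[i]
        contact_age = [CONTACT_AGES[k] + int(cum[k]) for k in range(3)]
        if early1[i]:
            contact_age[0] = CONTACT_AGES[0] - int(early1_shift[i])

        # birth doses
        if bcg_present[i]:
            if bcg_deferred[i] and attend[i, 0]:
                ages["BCG"] = contact_age[0]
            else:
                ages["BCG"] = int(bcg_delay[i])
        if opv0_present[i]:
            if bcg_present[i] and not bcg_deferred[i] and ages["BCG"] <= 14:
                ages["OPV0"] = ages["BCG"]
            else:
                ages["OPV0"] = int(opv0_delay[i])

        # measles
        if mv_present[i]:
            if mv_early[i]:
                ages["MV"] = MV_AGE - int(mv_early_shift[i])
            else:
                ages["MV"] = MV_AGE + int(mv_delay[i]) + int(delay_shift[i])

        # routine contacts
        for k in range(3):
            if not attend[i, k]:
                continue
            age_k = contact_age[k]
            if k == 2 and swap[i] and mv_present[i]:
                age_k = ages["MV"] + int(swap_off[i])   # contact after measles
            ages[f"PENTA{k + 1}"] = age_k
            if not opv_miss[i, k]:
                ages[f"OPV{k + 1}"] = age_k + (int(split_off[i, k]) if split[i, k] else 0)
            if pcv_take[i, k] and dob + dt.timedelta(days=age_k) >= config.pcv_rollout:
                ages[f"PCV{k + 1}"] = age_k

        events = sorted(
            (VaccinationEvent(lab, dob + dt.timedelta(days=a))
             for lab, a in ages.items() if a is not None),
            key=lambda e: (e.date, e.antigen),
        )
        visits = []
        age = int(first_visit[i])
        while age < config.max_followup_age:
            visits.append(Visit(dob + dt.timedelta(days=age), bool(card[i])))
            age += config.visit_interval_days

        cid = f"C{i:06d}"
        child_covs = {field: str(covs[field][i]) for field in covs if field != "sex"}
        children.append(ChildRecord(
            child_id=cid, dob=dob, sex=str(covs["sex"][i]),
            covariates=child_covs, visits=visits, events=events,
        ))

        row = {
            "child_id": cid, "card": bool(card[i]), "score": float(score[i]),
            "attend1": bool(attend[i, 0]), "attend2": bool(attend[i, 1]),
            "attend3": bool(attend[i, 2]),
            "bcg_deferred": bool(bcg_deferred[i] and bcg_present[i]),
            "mv_present": bool(mv_present[i]),
            "p_attend3": float(c1 * p2[i] * p3[i]),
            "p_mv": float(p_mv[i]),
            "delay_shift": int(delay_shift[i]),
        }
        row.update({f"age_{lab}": ages.get(lab) for lab in
                    ("BCG", "OPV0", "OPV1", "OPV2", "OPV3",
                     "PENTA1", "PENTA2", "PENTA3", "PCV1", "PCV2", "PCV3", "MV")})
        row.update(_truth_labels(ages, cutoff))
        truth_rows.append(row)

    cohort = Cohort(children=children,
                    provenance={"source": "synthetic", "seed": config.seed})
    return cohort, Truth(config=config, children=truth_rows)


# ---------------------------------------------------------------------------
# analytic oracle and parameter recovery

def analytic_fic_probability(truth: Truth) -> float:
    """Closed-form P(FIC) averaged over the generated covariate draws.

    Per child: BCG present x full contact chain x OPV never missed x measles
    present and its delay inside the horizon (computed exactly on the
    discretized delay grid).  The rare measles/contact swap interaction is
    ignored (order 1e-4).
    """
    config = truth.config
    mv_cdf = np.cumsum(config.mv_delay_pmf())
    tail_budget = config.fic_cutoff - MV_AGE
    df = truth.df
    p_opv = float(np.prod(1.0 - np.asarray(config.opv_miss_probs)))
    p_mv_in = np.where(
        df["delay_shift"].to_numpy() > 0,
        mv_cdf[tail_budget - config.site_delay_shift_days],
        mv_cdf[tail_budget],
    )
    p_mv_by_cutoff = config.mv_early_prob + (1 - config.mv_early_prob) * p_mv_in
    p = (config.bcg_prob
         * df["p_attend3"].to_numpy()
         * p_opv
         * df["p_mv"].to_numpy() * p_mv_by_cutoff)
    return float(p.mean())


def recover_parameters(
    cohort: Cohort, truth: Truth, schedule: Optional[ScheduleSpec] = None
) -> pd.DataFrame:
    """Compare pipeline estimates against generator truth.

    Runs the classifier on the cohort and reports, per quantity: the
    pipeline estimate, the generator-truth value, a Monte-Carlo standard
    error and the z-score of their difference.
    """
    if schedule is None:
        schedule = default_epi_schedule()
    ids_c = [c.child_id for c in cohort]
    tdf = truth.df
    if list(tdf["child_id"]) != ids_c:
        raise ValueError("cohort and truth are not from the same generation")

    cls = classify_cohort(cohort, schedule)
    n = len(cls)
    rows = []

    def add(name, est, tru, se):
        se = max(se, 1e-12)
        rows.append({"quantity": name, "estimate": est, "truth": tru,
                     "se": se, "z": (est - tru) / se})

    def rate(name, est_mask, truth_mask):
        est = float(np.mean(est_mask))
        tru = float(np.mean(truth_mask))
        add(name, est, tru, math.sqrt(max(tru * (1 - tru), 1e-12) / n))

    cutoff = schedule.fic_cutoff_days
    rate("fic", cls["fic"], tdf["fic"])
    for lab in ("BCG", "OPV3", "PENTA3", "MV"):
        est = (cls[f"age_{lab}"].notna() & (cls[f"age_{lab}"] <= cutoff))
        tru = tdf[f"age_{lab}"].notna() & (tdf[f"age_{lab}"] <= cutoff)
        rate(f"coverage_{lab}", est, tru)

    fic_mask = cls["fic"].astype(bool).to_numpy()
    n_fic = max(int(fic_mask.sum()), 1)
    for flag in ("penta_opv_split", "late_bcg", "penta_after_mv", "fic_os"):
        est = float(cls.loc[fic_mask, flag].mean()) if n_fic else 0.0
        tru_rows = tdf[tdf["fic"]]
        tru = float(tru_rows[flag if flag != "fic_os" else "fic_os"].mean())
        add(f"{flag}_among_fic", est, tru,
            math.sqrt(max(tru * (1 - tru), 1e-12) / n_fic))

    # median ages: estimate vs the config's exact discrete-grid medians
    opv3 = cls["age_OPV3"].dropna()
    est_med = float(np.median(opv3)) if len(opv3) else float("nan")
    cfg_med = CONTACT_AGES[2] + truth.config.pooled_contact_delay_median(3)
    add("median_age_OPV3", est_med, float(cfg_med), 0.5)

    add("analytic_fic", float(cls["fic"].mean()), analytic_fic_probability(truth),
        math.sqrt(0.67 * 0.33 / n))
    return pd.DataFrame(rows)
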