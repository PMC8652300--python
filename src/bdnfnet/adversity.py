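"""Cumulative prenatal adversity score.

Ten indicators of the prenatal environment are each scored one point when
their rubric threshold is met, and summed.  Thresholds (absolute form):

    lack-of-money hassles > 9; depression (CES-D) > 22; pregnancy anxiety
    (STAI) > 1.95; domestic/sexual abuse present; marital strain < 2.9; any
    pregnancy health condition; smoking during pregnancy; gestational age
    <= 37 weeks; birth size percentile < 10 or > 90; household income below
    $30,000/year.

A missing field contributes 0 and is counted in ``n_missing``; an optional
within-cohort percentile mode replaces the psychometric-scale cut-offs by
the sample's 85th percentile (15th for marital strain, where lower is worse).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["PrenatalRecord", "AdversityScore", "compute_adversity",
           "score_cohort", "split_adversity_groups"]

HEALTH_CONDITIONS = ("diabetes", "hypertension", "asthma", "severe_vomiting",
                     "bleeding", "anemia_constipation", "infection_diarrhea")

INDICATORS = ("money", "depression", "anxiety", "abuse", "marital_strain",
              "health", "smoking", "gestational_age", "birth_size", "income")


@dataclasses.dataclass
class PrenatalRecord:
    """One mother/child's prenatal indicators; any field may be None."""

    money_hassles: float | None = None
    cesd: float | None = None
    stai: float | None = None
    abuse_present: bool | None = None
    marital_strain: float | None = None
    health_conditions: frozenset = frozenset()
    health_known: bool = True
    smoking: bool | None = None
    gestational_age: float | None = None
    birth_percentile: float | None = None
    income: float | None = None

    def __post_init__(self) -> None:
        if self.gestational_age is not None and not 20 < self.gestational_age < 45:
            raise ValueError(f"implausible gestational age {self.gestational_age}")
        if self.birth_percentile is not None and not 0 <= self.birth_percentile <= 100:
            raise ValueError(f"birth percentile {self.birth_percentile} outside [0, 100]")
        bad = set(self.health_conditions) - set(HEALTH_CONDITIONS)
        if bad:
            raise ValueError(f"unknown health conditions: {sorted(bad)}")


@dataclasses.dataclass(frozen=True)
class AdversityScore:
    total: int
    indicators: dict
    n_missing: int


def compute_adversity(
    rec: PrenatalRecord,
    money_cut: float = 9.0,
    cesd_cut: float = 22.0,
    stai_cut: float = 1.95,
    strain_cut: float = 2.9,
    ga_cut: float = 37.0,
    income_cut: float = 30_000.0,
) -> AdversityScore:
    """Score one record against the rubric.

    Boundary conventions follow the rubric text exactly: scale scores must be
    strictly *above* their cut-off (CES-D exactly 22 scores 0), marital
    strain strictly below 2.9, gestational age <= 37 inclusive, birth size
    strictly outside the 10th-90th percentile band.
    """
    ind: dict[str, int] = {}
    missing = 0

    def rule(name: str, value, met) -> None:
        nonlocal missing
        if value is None:
            ind[name] = 0
            missing += 1
        else:
            ind[name] = int(met(value))

    rule("money", rec.money_hassles, lambda v: v > money_cut)
    rule("depression", rec.cesd, lambda v: v > cesd_cut)
    rule("anxiety", rec.stai, lambda v: v > stai_cut)
    rule("abuse", rec.abuse_present, bool)
    rule("marital_strain", rec.marital_strain, lambda v: v < strain_cut)
    rule("health", rec.health_conditions if rec.health_known else None,
         lambda v: len(v) > 0)
    rule("smoking", rec.smoking, bool)
    rule("gestational_age", rec.gestational_age, lambda v: v <= ga_cut)
    rule("birth_size", rec.birth_percentile, lambda v: v < 10 or v > 90)
    rule("income", rec.income, lambda v: v < income_cut)

    if missing == len(INDICATORS):
        raise ValueError("uninformative record: all fields missing")
    return AdversityScore(total=sum(ind.values()), indicators=ind, n_missing=missing)


def _record_from_row(row: pd.Series) -> PrenatalRecord:
    def opt(name):
        v = row.get(name)
        return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

    conds = frozenset(c for c in HEALTH_CONDITIONS if bool(row.get(c, False)))
    ab, sm = opt("abuse_present"), opt("smoking")
    return PrenatalRecord(
        money_hassles=opt("money_hassles"), cesd=opt("cesd"), stai=opt("stai"),
        abuse_present=None if ab is None else bool(ab),
        marital_strain=opt("marital_strain"), health_conditions=conds,
        smoking=None if sm is None else bool(sm),
        gestational_age=opt("gestational_age"),
        birth_percentile=opt("birth_percentile"), income=opt("income"),
    )


def score_cohort(table: pd.DataFrame, percentile_mode: bool = False) -> pd.DataFrame:
    """Score every row of a cohort table (one row per mother/child).

    With ``percentile_mode`` the three psychometric-scale cut-offs are the
    within-sample 85th percentiles (15th for marital strain) instead of the
    absolute rubric values.
    """
    kwargs = {}
    if percentile_mode:
        kwargs["money_cut"] = float(np.nanpercentile(table["money_hassles"], 85))
        kwargs["cesd_cut"] = float(np.nanpercentile(table["cesd"], 85))
        kwargs["stai_cut"] = float(np.nanpercentile(table["stai"], 85))
        kwargs["strain_cut"] = float(np.nanpercentile(table["marital_strain"], 15))
    out = []
    for _, row in table.iterrows():
        s = compute_adversity(_record_from_row(row), **kwargs)
        rec = {"subject_id": row.get("subject_id", _), "adversity": s.total,
               "n_missing": s.n_missing}
        rec.update({f"ind_{k}": v for k, v in s.indicators.items()})
        out.append(rec)
    return pd.DataFrame(out)


def split_adversity_groups(scores) -> tuple[np.ndarray, dict]:
    """Median split into low (score <= median) and high (score > median).

    Returns (labels array of "low"/"high", report with group sizes).  All
    scores identical is a degenerate split and raises.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two subjects")
    med = float(np.median(scores))
    if np.all(scores == scores[0]):
        raise ValueError("degenerate split: all scores identical")
    labels = np.where(scores > med, "high", "low")
    report = {"median": med,
              "n_low": int((labels == "low").sum()),
              "n_high": int((labels == "high").sum())}
    return labels, report
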