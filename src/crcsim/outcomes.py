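"""Per-1000 outcome aggregation for screened versus unscreened cohorts.

All outcomes are reported per 1000 persons alive and free of diagnosed CRC
at exact age 40.  Life-years are undiscounted and counted from birth to
death; life-years gained (LYG) is the mean paired per-person difference
times 1000 (screened and unscreened runs share natural-history random
numbers, so the difference is a paired contrast).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .natural_history import Cohort
from .screening import ScreenedCohort

__all__ = ["BurdenWeights", "OutcomeTable", "tabulate", "patient_hours", "outcome_frame"]


@dataclass(frozen=True)
class BurdenWeights:
    """Patient hours per screening-process event."""

    hours_per_colonoscopy: float = 16.0
    hours_per_complication: float = 112.0
    hours_per_test: dict = field(
        default_factory=lambda: {"FIT": 1.0, "mt-sDNA": 1.0, "HSgFOBT": 2.0}
    )


def patient_hours(
    n_tests: float,
    modality: str,
    n_colonoscopies: float,
    n_complications: float,
    weights: BurdenWeights,
) -> float:
    """Linear patient-hour burden of the screening process."""
    if min(n_tests, n_colonoscopies, n_complications) < 0:
        raise ValueError("counts must be non-negative")
    return (
        n_tests * weights.hours_per_test[modality]
        + n_colonoscopies * weights.hours_per_colonoscopy
        + n_complications * weights.hours_per_complication
    )


@dataclass
class OutcomeTable:
    """One strategy x adherence scenario, per 1000 eligible persons."""

    strategy_label: str
    modality: str
    adherence_label: str
    cohort_size: int
    n_eligible: int
    lyg: float
    lyg_se: float
    crc_cases: float
    crc_deaths: float
    life_years_with_crc: float
    incidence_reduction_pct: float
    mortality_reduction_pct: float
    total_stool_tests: float
    total_colonoscopies: float
    complications: float
    patient_hours: float

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy_label,
            "modality": self.modality,
            "adherence": self.adherence_label,
            "cohort_size": self.cohort_size,
            "n_eligible": self.n_eligible,
            "LYG": round(self.lyg, 1),
            "LYG_SE": round(self.lyg_se, 2),
            "CRC_cases": round(self.crc_cases, 1),
            "CRC_deaths": round(self.crc_deaths, 1),
            "LY_with_CRC": round(self.life_years_with_crc, 1),
            "incidence_reduction_pct": round(self.incidence_reduction_pct, 1),
            "mortality_reduction_pct": round(self.mortality_reduction_pct, 1),
            "stool_tests": round(self.total_stool_tests),
            "colonoscopies": round(self.total_colonoscopies),
            "complications": round(self.complications, 1),
            "patient_hours": round(self.patient_hours, 1),
        }


def _per_person_metrics(dx_age, crc_death, death_age):
    diagnosed = np.isfinite(dx_age)
    crc_dead = np.isfinite(crc_death) & (crc_death <= death_age)
    ly_with_crc = np.where(diagnosed, death_age - np.where(diagnosed, dx_age, 0.0), 0.0)
    return diagnosed, crc_dead, ly_with_crc


def tabulate(
    screened: ScreenedCohort,
    cohort: Cohort,
    weights: BurdenWeights | None = None,
) -> OutcomeTable:
    """Aggregate a screened cohort against its paired unscreened baseline."""
    if weights is None:
        weights = BurdenWeights()
    if len(screened.death_age) != cohort.n:
        raise ValueError("screened and unscreened cohorts are not paired")
    m = cohort.eligible
    denom = int(m.sum())
    if denom == 0:
        raise ValueError("no eligible persons in cohort")
    per1000 = 1000.0 / denom

    diff = screened.death_age[m] - cohort.death_age[m]
    lyg = float(diff.mean()) * 1000.0
    lyg_se = float(diff.std(ddof=1)) / math.sqrt(denom) * 1000.0 if denom > 1 else 0.0

    s_dx, s_dead, s_lycrc = _per_person_metrics(
        screened.dx_age[m], screened.crc_death[m], screened.death_age[m]
    )
    u_dx, u_dead, u_lycrc = _per_person_metrics(
        cohort.dx_age[m], cohort.crc_death[m], cohort.death_age[m]
    )
    cases_s, cases_u = int(s_dx.sum()), int(u_dx.sum())
    deaths_s, deaths_u = int(s_dead.sum()), int(u_dead.sum())

    inc_red = 100.0 * (1.0 - cases_s / cases_u) if cases_u else math.nan
    mort_red = 100.0 * (1.0 - deaths_s / deaths_u) if deaths_u else math.nan

    tests = float(screened.n_tests[m].sum())
    colos = float(screened.n_colonoscopies[m].sum())
    compl = float(screened.n_complications[m].sum())

    return OutcomeTable(
        strategy_label=screened.strategy.label,
        modality=screened.strategy.modality,
        adherence_label=screened.adherence.label,
        cohort_size=cohort.n,
        n_eligible=denom,
        lyg=lyg,
        lyg_se=lyg_se,
        crc_cases=cases_s * per1000,
        crc_deaths=deaths_s * per1000,
        life_years_with_crc=float(s_lycrc.sum()) * per1000,
        incidence_reduction_pct=inc_red,
        mortality_reduction_pct=mort_red,
        total_stool_tests=tests * per1000,
        total_colonoscopies=colos * per1000,
        complications=compl * per1000,
        patient_hours=patient_hours(
            tests * per1000,
            screened.strategy.modality,
            colos * per1000,
            compl * per1000,
            weights,
        ),
    )


def outcome_frame(tables: list[OutcomeTable], metadata: dict | None = None) -> pd.DataFrame:
    """Stack outcome tables into one row-per-scenario frame; run metadata
    (seed, cohort size, fixture version) is attached as ``frame.attrs``."""
    frame = pd.DataFrame([t.to_dict() for t in tables])
    if metadata:
        frame.attrs.update(metadata)
    return frame
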