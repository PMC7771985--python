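"""Reproducible experiment suites over the screening microsimulation.

Three analyses are orchestrated here:

1. ``run_adherence_grid`` — every strategy crossed with a fixed annual
   likelihood to comply from 0% to 100% in 10% steps, plus the pairwise
   percent-LYG-difference matrix between two strategies and per-unit LYG
   sensitivity slopes.
2. ``run_differential_base_case`` — modality-specific imperfect adherence
   presets, efficient frontiers under both burden metrics and the resulting
   strategy recommendation per screening window.
3. ``run_assigned_counts`` — randomly assigned lifetime test counts, the
   LYG-versus-budget curve, and the smallest FIT budget matching the LYG of
   the full mt-sDNA budget.

Every run record carries (seed, cohort size, fixture version) so any table
can be replayed bit-for-bit.
"""

from __future__ import annotations

import math

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adherence as adh
from .fixtures import FIXTURE_VERSION, FixtureSet, load_fixtures
from .frontier import StrategyPoint, classify, recommend
from .natural_history import Cohort
from .outcomes import OutcomeTable, outcome_frame, tabulate
from .screening import ScreenedCohort, ScreeningStrategy, apply_screening_cohort

__all__ = [
    "ScenarioSuite",
    "build_cohort",
    "unscreened_result",
    "run_strategy",
    "lyg_slope",
    "run_adherence_grid",
    "run_differential_base_case",
    "run_assigned_counts",
    "smallest_matching_budget",
]


@dataclass
class ScenarioSuite:
    analysis: str  # adherence_grid | differential_base_case | assigned_counts
    master_seed: int = 1
    cohort_size: int = 200_000
    characteristics_mode: str = "granular"  # aggregate | granular
    mechanism: str = "annual_likelihood"  # annual_likelihood | fixed_split
    sex_fraction: float = 0.5
    fixtures: FixtureSet = field(default_factory=load_fixtures)

    def metadata(self) -> dict:
        return {
            "analysis": self.analysis,
            "seed": self.master_seed,
            "cohort_size": self.cohort_size,
            "characteristics_mode": self.characteristics_mode,
            "mechanism": self.mechanism,
            "fixture_version": self.fixtures.version,
        }

    def characteristics(self, modality: str):
        fx = self.fixtures
        if self.characteristics_mode == "granular" and modality == "HSgFOBT":
            # no granular HSgFOBT estimates exist; falls back to aggregate
            return fx.test_characteristics(modality, "aggregate")
        return fx.test_characteristics(modality, self.characteristics_mode)

    def adherence_for(self, modality: str, preset: str):
        model = self.fixtures.adherence_presets[preset][modality]
        if self.mechanism == "fixed_split" and model.variant == "annual_likelihood":
            model = adh.fixed_split(model.p)
        return model


def build_cohort(suite: ScenarioSuite) -> Cohort:
    fx = suite.fixtures
    return Cohort.generate(
        suite.cohort_size,
        fx.nh_params,
        fx.life_table,
        suite.master_seed,
        suite.sex_fraction,
    )


def unscreened_result(cohort: Cohort) -> ScreenedCohort:
    """The no-screening arm expressed as a screened-cohort record."""
    n = cohort.n
    return ScreenedCohort(
        strategy=ScreeningStrategy("FIT", 1, 50, 75, label="no screening"),
        adherence=adh.annual_likelihood(0.0),
        n_tests=np.zeros(n, dtype=np.int32),
        n_colonoscopies=np.zeros(n, dtype=np.int32),
        n_complications=np.zeros(n, dtype=np.int32),
        dx_age=cohort.dx_age.copy(),
        stage=cohort.stage.copy(),
        screen_detected=np.zeros(n, dtype=bool),
        crc_death=cohort.crc_death.copy(),
        death_age=cohort.death_age.copy(),
    )


def run_strategy(
    suite: ScenarioSuite,
    cohort: Cohort,
    strategy: ScreeningStrategy,
    adherence_model,
) -> OutcomeTable:
    screened = apply_screening_cohort(
        cohort,
        strategy,
        adherence_model,
        suite.characteristics(strategy.modality),
        suite.fixtures.colonoscopy,
    )
    return tabulate(screened, cohort, suite.fixtures.burden_weights)


def lyg_slope(lyg_hi: float, lyg_lo: float, pct_hi: float, pct_lo: float) -> float:
    """LYG change per unit (percentage point) change in adherence."""
    return (lyg_hi - lyg_lo) / (pct_hi - pct_lo)


def hsgfobt_rate(fit_rate: float, relative_factor: float = 1.16) -> float:
    """HSgFOBT adherence derived from the FIT rate.

    Meta-analytic completion of guaiac testing runs ~16% relatively below
    FIT, so each FIT preset maps to ``fit_rate / 1.16`` rounded to two
    decimals (0.40 -> 0.34, 0.50 -> 0.43, 0.60 -> 0.52).
    """
    if not 0.0 <= fit_rate <= 1.0:
        raise ValueError("fit_rate must lie in [0,1]")
    return round(fit_rate / relative_factor, 2)


# ---------------------------------------------------------------------------
# Analysis 1: spectrum of adherence
# ---------------------------------------------------------------------------


def run_adherence_grid(
    suite: ScenarioSuite,
    strategies: list[ScreeningStrategy] | None = None,
    levels: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1)),
    matrix_pair: tuple[str, str] | None = None,
) -> dict:
    """Outcomes for each strategy x adherence level, LYG-difference matrix
    for one strategy pair, and per-unit LYG sensitivity slopes."""
    if strategies is None:
        strategies = suite.fixtures.strategy_grid("adherence_grid")
    cohort = build_cohort(suite)
    tables: list[OutcomeTable] = []
    lyg: dict[tuple[str, float], float] = {}
    for strat in strategies:
        for p in levels:
            if p == 0.0:
                t = tabulate(unscreened_result(cohort), cohort, suite.fixtures.burden_weights)
                t.strategy_label = strat.label
                t.modality = strat.modality
                t.adherence_label = "likelihood 0%"
            else:
                model = (
                    adh.fixed_split(p)
                    if suite.mechanism == "fixed_split"
                    else adh.annual_likelihood(p)
                )
                t = run_strategy(suite, cohort, strat, model)
            tables.append(t)
            lyg[(strat.label, float(p))] = t.lyg

    slopes = {}
    for strat in strategies:
        hi, lo = lyg[(strat.label, 1.0)], lyg.get((strat.label, 0.1))
        if lo is not None:
            slopes[strat.label] = lyg_slope(hi, lo, 100.0, 10.0)

    matrix = None
    if matrix_pair is not None:
        a, b = matrix_pair
        nonzero = [p for p in levels if p > 0]
        matrix = pd.DataFrame(
            [
                [
                    100.0 * (lyg[(a, pa)] - lyg[(b, pb)]) / lyg[(b, pb)]
                    if lyg[(b, pb)] != 0.0
                    else math.nan
                    for pb in nonzero
                ]
                for pa in nonzero
            ],
            index=pd.Index(nonzero, name=f"{a} adherence"),
            columns=pd.Index(nonzero, name=f"{b} adherence"),
        )

    return {
        "outcomes": outcome_frame(tables, suite.metadata()),
        "lyg": lyg,
        "slopes": slopes,
        "difference_matrix_pct": matrix,
    }


# ---------------------------------------------------------------------------
# Analysis 2: differential base-case adherence and efficient frontiers
# ---------------------------------------------------------------------------


def _points(tables: list[OutcomeTable], burden_metric: str) -> list[StrategyPoint]:
    attr = "total_colonoscopies" if burden_metric == "colonoscopies" else "patient_hours"
    return [StrategyPoint(t.strategy_label, t.lyg, getattr(t, attr)) for t in tables]


def run_differential_base_case(
    suite: ScenarioSuite,
    preset: str = "base_case",
    strategies: list[ScreeningStrategy] | None = None,
    windows: tuple[tuple[int, int], ...] = ((50, 75), (45, 75)),
) -> dict:
    """Outcome tables, frontier classifications for both burden metrics and
    the per-window recommendation."""
    if strategies is None:
        strategies = suite.fixtures.strategy_grid("differential_base_case")
    cohort = build_cohort(suite)
    tables = [
        run_strategy(suite, cohort, s, suite.adherence_for(s.modality, preset))
        for s in strategies
    ]
    rule = suite.fixtures.recommendation_rule
    result: dict = {"outcomes": outcome_frame(tables, suite.metadata()), "frontiers": {}}
    for metric in ("colonoscopies", "hours"):
        frontier_reports = {}
        for start, stop in windows:
            window_tables = [
                t
                for t, s in zip(tables, strategies)
                if s.start_age == start and s.stop_age == stop
            ]
            if not window_tables:
                continue
            pts = _points(window_tables, metric)
            classified, frontier = classify(pts, rule)
            rec = recommend(pts, rule, metric)
            frontier_reports[f"{start}-{stop}"] = {
                "points": pd.DataFrame(
                    [
                        {
                            "strategy": p.label,
                            "LYG": p.lyg,
                            "burden": p.burden,
                            "class": p.classification,
                            "delta_LYG": p.delta_lyg,
                            "delta_burden": p.delta_burden,
                            "efficiency_ratio": p.efficiency_ratio,
                        }
                        for p in classified
                    ]
                ),
                "recommended": rec.label if rec else None,
            }
        result["frontiers"][metric] = frontier_reports
    return result


# ---------------------------------------------------------------------------
# Analysis 3: randomly assigned numbers of completed tests
# ---------------------------------------------------------------------------


def run_assigned_counts(
    suite: ScenarioSuite,
    budgets: dict[str, tuple[int, ...]] | None = None,
    start_age: int = 50,
    stop_age: int = 75,
    cohort: Cohort | None = None,
) -> dict:
    """Outcomes per assigned budget plus the FIT-tests-to-match report."""
    strategies = {
        "mt-sDNA": ScreeningStrategy("mt-sDNA", 3, start_age, stop_age),
        "FIT": ScreeningStrategy("FIT", 1, start_age, stop_age),
    }
    if budgets is None:
        n_mt = len(strategies["mt-sDNA"].scheduled_rounds())
        n_fit = len(strategies["FIT"].scheduled_rounds())
        budgets = {"mt-sDNA": (1, 5, n_mt), "FIT": (1, 5, 9, n_fit)}
    if cohort is None:
        cohort = build_cohort(suite)
    tables: list[OutcomeTable] = []
    lyg: dict[tuple[str, int], float] = {}
    for modality, strat in strategies.items():
        for budget in budgets[modality]:
            t = run_strategy(suite, cohort, strat, adh.assigned_count(budget))
            t.adherence_label = (
                f"up to {budget} ({budget}/{len(strat.scheduled_rounds())})"
            )
            tables.append(t)
            lyg[(modality, budget)] = t.lyg

    full_mt = len(strategies["mt-sDNA"].scheduled_rounds())
    target = lyg.get(("mt-sDNA", full_mt))
    matching = None
    if target is not None:
        matching = smallest_matching_budget(
            suite, cohort, strategies["FIT"], target, lyg
        )

    # matched-budget incremental ratios (mt-sDNA vs FIT at the same budget)
    ratios = {}
    by_key = {(t.modality, b): t for t, (m, b) in zip(tables, lyg.keys())}
    for b in budgets["mt-sDNA"]:
        if (("mt-sDNA", b) in lyg) and (("FIT", b) in lyg):
            t_mt, t_fit = by_key[("mt-sDNA", b)], by_key[("FIT", b)]
            dlyg = t_mt.lyg - t_fit.lyg
            if dlyg > 0:
                ratios[b] = (t_mt.total_colonoscopies - t_fit.total_colonoscopies) / dlyg

    return {
        "outcomes": outcome_frame(tables, suite.metadata()),
        "lyg": lyg,
        "fit_tests_to_match": matching,
        "matched_budget_ratios": ratios,
    }


def smallest_matching_budget(
    suite: ScenarioSuite,
    cohort: Cohort,
    strategy: ScreeningStrategy,
    target_lyg: float,
    cache: dict | None = None,
) -> int | None:
    """Smallest assigned-test budget whose LYG reaches ``target_lyg``.

    Binary search over budgets (LYG is non-decreasing in the budget in
    expectation)."""
    n_rounds = len(strategy.scheduled_rounds())
    cache = cache if cache is not None else {}

    def lyg_at(budget: int) -> float:
        key = (strategy.modality, budget)
        if key not in cache:
            t = run_strategy(suite, cohort, strategy, adh.assigned_count(budget))
            cache[key] = t.lyg
        return cache[key]

    if lyg_at(n_rounds) < target_lyg:
        return None
    lo, hi = 1, n_rounds
    while lo < hi:
        mid = (lo + hi) // 2
        if lyg_at(mid) >= target_lyg:
            hi = mid
        else:
            lo = mid + 1
    return lo
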