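"""Efficient frontier and strategy recommendation over outcome tables.

Strategies are points (burden, LYG) where burden is either colonoscopies or
patient hours per 1000.  Strongly dominated points (another point attains at
least the LYG for no more burden, with one inequality strict) are discarded;
the remaining points are reduced to the piecewise-linear efficient frontier
anchored at the no-screening origin (0, 0), along which incremental
efficiency ratios (dBurden/dLYG) are non-decreasing.  Non-frontier points
whose LYG reaches 98% of the frontier's interpolated LYG at their burden are
flagged near-efficient.  A recommendable strategy must be efficient or
near-efficient, have an incremental ratio at or below the acceptability
bound (65 colonoscopies or 8,766 patient hours per LYG), and offer the most
LYG among qualifying strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StrategyPoint",
    "RecommendationRule",
    "pairwise_ratio",
    "remove_strongly_dominated",
    "build_frontier",
    "flag_near_efficient",
    "classify",
    "recommend",
]


@dataclass
class StrategyPoint:
    label: str
    lyg: float
    burden: float
    classification: str = "unclassified"
    delta_lyg: float = math.nan
    delta_burden: float = math.nan
    efficiency_ratio: float = math.nan


@dataclass(frozen=True)
class RecommendationRule:
    ratio_bounds: tuple[float, float] = (39.0, 65.0)  # colonoscopy burden
    hours_bound: float = 8766.0  # patient-hour burden (365.25 d x 24 h)
    near_efficiency_threshold: float = 0.98

    def upper_bound(self, metric: str) -> float:
        if metric == "colonoscopies":
            return self.ratio_bounds[1]
        if metric == "hours":
            return self.hours_bound
        raise ValueError(f"unknown burden metric {metric!r}")


def pairwise_ratio(point: StrategyPoint, reference: StrategyPoint) -> float:
    """Incremental burden per incremental LYG of ``point`` versus
    ``reference`` (e.g. matched-budget comparisons across modalities)."""
    dlyg = point.lyg - reference.lyg
    if dlyg <= 0:
        return math.inf
    return (point.burden - reference.burden) / dlyg


def remove_strongly_dominated(points: list[StrategyPoint]) -> list[StrategyPoint]:
    """Discard points for which some other point has no more burden and no
    less LYG, with at least one strict inequality.  Exact ties are retained."""
    if not points:
        raise ValueError("need at least one strategy point")
    kept = []
    for p in points:
        dominated = any(
            (q.burden <= p.burden and q.lyg >= p.lyg)
            and (q.burden < p.burden or q.lyg > p.lyg)
            for q in points
        )
        if not dominated:
            kept.append(p)
    return kept


_ORIGIN = StrategyPoint("no screening", 0.0, 0.0, classification="origin")


def build_frontier(
    points: list[StrategyPoint], origin: StrategyPoint | None = None
) -> list[StrategyPoint]:
    """Efficient set with incremental ratios, anchored at the origin.

    Gift-wrapping from the origin: each step takes the candidate with the
    smallest incremental ratio (dBurden/dLYG) among those offering more LYG,
    which yields non-decreasing ratios along the frontier (the convex-hull
    property).  Colinear candidates are retained with equal ratios; a
    candidate adding burden but no LYG over the frontier end is discarded
    (the documented tie rule).
    """
    if origin is None:
        origin = _ORIGIN
    candidates = sorted(
        remove_strongly_dominated(points), key=lambda p: (p.burden, -p.lyg)
    )
    frontier: list[StrategyPoint] = []
    current = origin
    remaining = list(candidates)
    while True:
        best = None
        best_ratio = math.inf
        for p in remaining:
            if p.lyg <= current.lyg:
                continue
            ratio = (p.burden - current.burden) / (p.lyg - current.lyg)
            # ties: take the smaller step so colinear points all appear
            if ratio < best_ratio - 1e-12 or (
                abs(ratio - best_ratio) <= 1e-12
                and best is not None
                and p.lyg < best.lyg
            ):
                best, best_ratio = p, ratio
        if best is None:
            break
        annotated = replace(
            best,
            classification="efficient",
            delta_lyg=best.lyg - current.lyg,
            delta_burden=best.burden - current.burden,
            efficiency_ratio=best_ratio,
        )
        frontier.append(annotated)
        remaining = [p for p in remaining if p is not best]
        current = annotated
    return frontier


def frontier_lyg_at(
    frontier: list[StrategyPoint], burden: float, origin: StrategyPoint | None = None
) -> float:
    """LYG of the piecewise-linear frontier interpolated at ``burden``;
    outside the frontier span, the nearest endpoint's LYG."""
    if origin is None:
        origin = _ORIGIN
    xs = [origin.burden] + [p.burden for p in frontier]
    ys = [origin.lyg] + [p.lyg for p in frontier]
    return float(np.interp(burden, xs, ys))


def flag_near_efficient(
    points: list[StrategyPoint],
    frontier: list[StrategyPoint],
    threshold: float = 0.98,
    origin: StrategyPoint | None = None,
) -> list[StrategyPoint]:
    """Classify every point against the built frontier.

    A non-efficient point is near-efficient iff its LYG is at least
    ``threshold`` times the frontier's LYG at the same burden; otherwise it
    is weakly dominated (it survived strong-dominance removal) or strongly
    dominated (it did not).
    """
    efficient_labels = {id(p) for p in frontier}
    by_label = {p.label: p for p in frontier}
    survivors = {id(p) for p in remove_strongly_dominated(points)}
    out = []
    for p in points:
        if p.label in by_label and math.isclose(
            p.lyg, by_label[p.label].lyg
        ) and math.isclose(p.burden, by_label[p.label].burden):
            out.append(replace(by_label[p.label]))
            continue
        bar = frontier_lyg_at(frontier, p.burden, origin)
        if bar > 0 and p.lyg >= threshold * bar:
            cls = "near_efficient"
        elif id(p) in survivors:
            cls = "weakly_dominated"
        else:
            cls = "strongly_dominated"
        out.append(replace(p, classification=cls))
    return out


def classify(
    points: list[StrategyPoint],
    rule: RecommendationRule | None = None,
    origin: StrategyPoint | None = None,
) -> tuple[list[StrategyPoint], list[StrategyPoint]]:
    """Build the frontier and classify all points; returns
    ``(classified points, frontier)``."""
    if rule is None:
        rule = RecommendationRule()
    frontier = build_frontier(points, origin)
    classified = flag_near_efficient(
        points, frontier, rule.near_efficiency_threshold, origin
    )
    return classified, frontier


def _ratio_for_recommendation(
    p: StrategyPoint, frontier: list[StrategyPoint], origin: StrategyPoint
) -> float:
    """Chain ratio for efficient points; for near-efficient points, the
    incremental ratio versus the preceding efficient point (or origin)."""
    if p.classification == "efficient" and math.isfinite(p.efficiency_ratio):
        return p.efficiency_ratio
    prev = origin
    for q in frontier:
        if q.burden < p.burden and q.lyg < p.lyg:
            prev = q
        else:
            break
    return pairwise_ratio(p, prev)


def recommend(
    points: list[StrategyPoint],
    rule: RecommendationRule | None = None,
    metric: str = "colonoscopies",
    origin: StrategyPoint | None = None,
) -> StrategyPoint | None:
    """The qualifying strategy with the most LYG, or ``None``.

    Qualification: efficient or near-efficient, and incremental efficiency
    ratio at or below the bound for the burden metric.
    """
    if rule is None:
        rule = RecommendationRule()
    if origin is None:
        origin = _ORIGIN
    classified, frontier = classify(points, rule, origin)
    bound = rule.upper_bound(metric)
    eligible = [
        p
        for p in classified
        if p.classification in ("efficient", "near_efficient")
        and _ratio_for_recommendation(p, frontier, origin) <= bound
    ]
    if not eligible:
        return None
    # most LYG; ties broken by lower burden, then stable input order
    best = eligible[0]
    for p in eligible[1:]:
        if p.lyg > best.lyg or (p.lyg == best.lyg and p.burden < best.burden):
            best = p
    return best
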