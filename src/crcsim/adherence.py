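"""Stool-test attendance mechanisms.

Three imperfect-adherence mechanisms are supported besides perfect
adherence:

``annual_likelihood``
    An independent Bernoulli(p) draw at every *due* offer.  A declined offer
    leaves the person due again the following year, so the effective
    per-cycle completion probability exceeds *p* for multi-year intervals —
    this retry semantics drives the comparison between annual and triennial
    tests and is deliberate.

``fixed_split``
    Each person is permanently assigned at simulation start to be fully
    adherent (probability ``adherent_fraction``) or never adherent.  Cohort
    outcomes are then a weighted average of the perfect-adherence and
    no-screening outcomes.

``assigned_count``
    Each person receives a budget of ``max_tests`` rounds chosen uniformly
    without replacement from the strategy's scheduled round ages; they attend
    exactly those rounds (and may complete fewer if they die or leave the
    screening pathway after a positive test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AdherenceModel",
    "PersonAdherence",
    "perfect",
    "annual_likelihood",
    "fixed_split",
    "assigned_count",
    "init_person_adherence",
    "assign_round_budget",
    "attends",
]

VARIANTS = ("perfect", "annual_likelihood", "fixed_split", "assigned_count")


@dataclass(frozen=True)
class AdherenceModel:
    variant: str
    p: float = 1.0  # annual_likelihood
    adherent_fraction: float = 1.0  # fixed_split
    max_tests: int = 0  # assigned_count
    selection_rule: str = "uniform"  # assigned_count round selection

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown adherence variant {self.variant!r}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0,1]")
        if not 0.0 <= self.adherent_fraction <= 1.0:
            raise ValueError("adherent_fraction must lie in [0,1]")
        if self.max_tests < 0:
            raise ValueError("max_tests must be non-negative")
        if self.selection_rule != "uniform":
            raise ValueError(f"unknown selection rule {self.selection_rule!r}")

    @property
    def label(self) -> str:
        if self.variant == "perfect":
            return "perfect"
        if self.variant == "annual_likelihood":
            return f"likelihood {self.p:.0%}"
        if self.variant == "fixed_split":
            return f"fixed split {self.adherent_fraction:.0%}"
        return f"up to {self.max_tests} tests"


def perfect() -> AdherenceModel:
    return AdherenceModel("perfect")


def annual_likelihood(p: float) -> AdherenceModel:
    return AdherenceModel("annual_likelihood", p=p)


def fixed_split(adherent_fraction: float) -> AdherenceModel:
    return AdherenceModel("fixed_split", adherent_fraction=adherent_fraction)


def assigned_count(max_tests: int) -> AdherenceModel:
    return AdherenceModel("assigned_count", max_tests=max_tests)


@dataclass
class PersonAdherence:
    """Per-person adherence state resolved at simulation start."""

    adherent: bool = True  # fixed_split assignment
    allowed_ages: frozenset | None = None  # assigned_count round set


def assign_round_budget(
    model: AdherenceModel, strategy, rng: np.random.Generator
) -> frozenset:
    """Uniformly choose ``max_tests`` rounds (without replacement) from the
    strategy's scheduled round ages."""
    if model.variant != "assigned_count":
        raise ValueError("round budgets only apply to the assigned_count variant")
    rounds = strategy.scheduled_rounds()
    if model.max_tests > len(rounds):
        raise ValueError(
            f"max_tests={model.max_tests} exceeds the {len(rounds)} scheduled rounds"
        )
    chosen = rng.permutation(len(rounds))[: model.max_tests]
    return frozenset(rounds[k] for k in chosen)


def init_person_adherence(
    model: AdherenceModel, strategy, rng: np.random.Generator
) -> PersonAdherence:
    """Resolve start-of-simulation assignments (fixed-split arm membership,
    assigned-count round set) from the person's attendance stream."""
    state = PersonAdherence()
    if model.variant == "fixed_split":
        state.adherent = rng.random() < model.adherent_fraction
    elif model.variant == "assigned_count":
        rounds = strategy.scheduled_rounds()
        if model.max_tests >= len(rounds):
            # a full budget is 100% adherence: attend every due offer,
            # including make-up offers that drift off the round grid after
            # a post-colonoscopy pause (exact identity with `perfect`)
            if model.max_tests > len(rounds):
                raise ValueError(
                    f"max_tests={model.max_tests} exceeds the {len(rounds)} scheduled rounds"
                )
            state.allowed_ages = None
        else:
            state.allowed_ages = assign_round_budget(model, strategy, rng)
    return state


def attends(
    model: AdherenceModel,
    state: PersonAdherence,
    age: int,
    rng: np.random.Generator,
) -> bool:
    """Does the person complete the stool test offered (while due) at ``age``?"""
    if model.variant == "perfect":
        return True
    if model.variant == "annual_likelihood":
        return rng.random() < model.p
    if model.variant == "fixed_split":
        return state.adherent
    return state.allowed_ages is None or age in state.allowed_ages
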