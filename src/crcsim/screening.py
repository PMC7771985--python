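"""Stool-based screening applied on top of a natural-history cohort.

Screening offers are evaluated at integer ages.  A completed stool test that
is positive triggers a follow-up colonoscopy (perfect adherence to follow-up
and surveillance colonoscopy is assumed throughout); polypectomy removes
detected adenomas and cancels their future progression; detected preclinical
cancer becomes a screen diagnosis.  Findings place the person on a guideline
surveillance schedule (3 y high-risk, 5 y intermediate, 10 y low-risk); a
clean colonoscopy returns the person to routine stool screening after 10
years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import rng as _rng
from .adherence import AdherenceModel, attends, init_person_adherence
from .natural_history import NEVER, Cohort, EventTimeline, SEGMENT_REGION

__all__ = [
    "TestCharacteristics",
    "ScreeningStrategy",
    "ColonoscopyModel",
    "ScreeningHistory",
    "LesionSnapshot",
    "ScreenedCohort",
    "is_due",
    "stool_test_result",
    "perform_colonoscopy",
    "apply_screening",
    "apply_screening_cohort",
    "size_class",
]

MODALITIES = ("mt-sDNA", "FIT", "HSgFOBT")

# specificity age bands: <60, 60-64, 65-69, 70-74, 75+
SPECIFICITY_BAND_EDGES = (60, 65, 70, 75)


def specificity_band(age: float) -> int:
    return int(np.searchsorted(SPECIFICITY_BAND_EDGES, age, side="right"))


def size_class(diameter_mm: float) -> int:
    """0: 1-5 mm, 1: 6-9 mm, 2: >=10 mm."""
    if diameter_mm < 6.0:
        return 0
    if diameter_mm < 10.0:
        return 1
    return 2


@dataclass(frozen=True)
class TestCharacteristics:
    """Operating characteristics of one stool test.

    ``aggregate`` mode carries scalar per-size-class sensitivities and a
    single specificity (the convention of the published decision-analysis
    inputs, where advanced-adenoma sensitivity proxies >=10 mm and
    non-advanced proxies 1-9 mm).  ``granular`` mode carries a 3x3
    site-by-size sensitivity grid and age-band specificities.
    """

    modality: str
    mode: str  # "aggregate" | "granular"
    sensitivity_crc: float
    # aggregate mode
    sensitivity_by_size: tuple[float, float, float] | None = None
    specificity: float | None = None
    # granular mode: rows rectal/distal/proximal, columns <=5 / 6-9 / >=10 mm
    sensitivity_by_site_size: tuple[tuple[float, float, float], ...] | None = None
    specificity_by_age: tuple[float, float, float, float, float] | None = None
    patient_hours_per_test: float = 1.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.mode not in ("aggregate", "granular"):
            raise ValueError(f"unknown mode {self.mode!r}")
        probs = [self.sensitivity_crc]
        if self.mode == "aggregate":
            if self.sensitivity_by_size is None or self.specificity is None:
                raise ValueError("aggregate mode needs sensitivity_by_size and specificity")
            probs += list(self.sensitivity_by_size) + [self.specificity]
        else:
            if self.sensitivity_by_site_size is None or self.specificity_by_age is None:
                raise ValueError(
                    "granular mode needs sensitivity_by_site_size and specificity_by_age"
                )
            probs += [p for row in self.sensitivity_by_site_size for p in row]
            probs += list(self.specificity_by_age)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0,1]")
        if self.patient_hours_per_test <= 0:
            raise ValueError("patient hours per test must be positive")

    def lesion_sensitivity(self, region: int, size_cls: int) -> float:
        if self.mode == "granular":
            return self.sensitivity_by_site_size[region][size_cls]
        return self.sensitivity_by_size[size_cls]

    def specificity_at(self, age: float) -> float:
        if self.mode == "granular":
            return self.specificity_by_age[specificity_band(age)]
        return self.specificity


@dataclass(frozen=True)
class ScreeningStrategy:
    modality: str
    interval: int  # whole years between completed stool tests
    start_age: int
    stop_age: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.start_age >= self.stop_age:
            raise ValueError("start_age must precede stop_age")
        if self.interval < 1:
            raise ValueError("interval must be at least one year")
        if not self.label:
            object.__setattr__(
                self,
                "label",
                f"{self.modality} q{self.interval}y {self.start_age}-{self.stop_age}",
            )

    def scheduled_rounds(self) -> tuple[int, ...]:
        """Round ages under uninterrupted adherence (start, start+interval, ...)."""
        return tuple(range(self.start_age, self.stop_age + 1, self.interval))


@dataclass(frozen=True)
class ColonoscopyModel:
    """Per-lesion colonoscopy detection, complications and surveillance rules."""

    sensitivity_by_size: tuple[float, float, float] = (0.76, 0.85, 0.95)
    sensitivity_crc: float = 0.95
    complication_probability: float = 0.0025
    complication_mortality: float = 0.0  # off by default
    hours_per_colonoscopy: float = 16.0
    hours_per_complication: float = 112.0
    surveillance_interval_high: int = 3
    surveillance_interval_intermediate: int = 5
    surveillance_interval_low: int = 10
    resume_after_clean_years: int = 10
    max_surveillance_age: int = 85

    def __post_init__(self) -> None:
        for p in (*self.sensitivity_by_size, self.sensitivity_crc,
                  self.complication_probability, self.complication_mortality):
            if not 0.0 <= p <= 1.0:
                raise ValueError("colonoscopy probabilities must lie in [0,1]")
        if self.hours_per_colonoscopy <= 0 or self.hours_per_complication <= 0:
            raise ValueError("hour weights must be positive")


@dataclass
class ScreeningHistory:
    """Mutable per-person screening state consulted by :func:`is_due`."""

    last_completed_age: float = -math.inf
    blocked_until: float = -math.inf
    under_surveillance: bool = False
    next_colonoscopy_age: float = NEVER
    diagnosed: bool = False


@dataclass(frozen=True)
class LesionSnapshot:
    """A lesion as seen by a stool test at one age."""

    kind: str  # "adenoma" | "preclinical_crc"
    region: int  # 0 rectal, 1 distal, 2 proximal
    diameter_mm: float = 0.0


def is_due(strategy: ScreeningStrategy, history: ScreeningHistory, age: int) -> bool:
    """Is the person due a stool test offer at this integer age?

    Declined offers do not advance the clock: the person stays due every
    subsequent year until a test is completed.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    if history.diagnosed or history.under_surveillance:
        return False
    if not strategy.start_age <= age <= strategy.stop_age:
        return False
    if age < history.blocked_until:
        return False
    return age - history.last_completed_age >= strategy.interval


def stool_test_result(
    lesions: list[LesionSnapshot],
    chars: TestCharacteristics,
    age: float,
    rng: np.random.Generator,
) -> bool:
    """True for a positive stool test.

    Granular mode: each lesion is detected independently with its site-size
    (or cancer) sensitivity; if nothing is detected the test may still be
    positive with 1 - specificity(age band).  Aggregate mode: detection is
    governed by the most advanced lesion's class sensitivity; lesion-free
    persons test positive with 1 - specificity.
    """
    if chars.mode == "granular":
        for lesion in lesions:
            p = (
                chars.sensitivity_crc
                if lesion.kind == "preclinical_crc"
                else chars.lesion_sensitivity(lesion.region, size_class(lesion.diameter_mm))
            )
            if rng.random() < p:
                return True
        return rng.random() >= chars.specificity_at(age)
    # aggregate: rank lesions by advancement (cancer > large > medium > small)
    if lesions:
        best: float | None = None
        rank = -1
        for lesion in lesions:
            r = 3 if lesion.kind == "preclinical_crc" else size_class(lesion.diameter_mm)
            if r > rank:
                rank = r
                best = (
                    chars.sensitivity_crc
                    if r == 3
                    else chars.lesion_sensitivity(lesion.region, r)
                )
        return rng.random() < best
    return rng.random() >= chars.specificity_at(age)


# ---------------------------------------------------------------------------
# Per-person screening simulation
# ---------------------------------------------------------------------------


@dataclass
class _PersonLesions:
    """Mutable working copy of one person's lesions during screening."""

    init: np.ndarray
    region: np.ndarray
    growth: np.ndarray
    trans: np.ndarray
    clin: np.ndarray
    u_stage: np.ndarray
    u_survival: np.ndarray
    removed: np.ndarray  # bool
    d_init: float
    d_max: float

    def diameter(self, j: int, age: float) -> float:
        t = max(age - self.init[j], 0.0)
        return self.d_max - (self.d_max - self.d_init) * math.exp(-self.growth[j] * t)

    def snapshot(self, age: float) -> list[LesionSnapshot]:
        out = []
        for j in range(len(self.init)):
            if self.removed[j] or self.init[j] > age:
                continue
            if self.trans[j] <= age:
                if self.clin[j] > age:  # preclinical window
                    out.append(LesionSnapshot("preclinical_crc", int(self.region[j])))
                # clinical cancers are handled as symptomatic diagnoses
            else:
                out.append(
                    LesionSnapshot("adenoma", int(self.region[j]), self.diameter(j, age))
                )
        return out

    def next_clinical_age(self) -> float:
        ages = self.clin[~self.removed]
        return float(ages.min()) if len(ages) else NEVER


@dataclass
class ColonoscopyFindings:
    age: float
    reason: str
    adenomas_removed: int = 0
    largest_removed_mm: float = 0.0
    crc_detected_lesion: int = -1
    complication: bool = False
    next_surveillance_age: float = NEVER


@dataclass
class PersonScreenResult:
    n_tests: int = 0
    n_colonoscopies: int = 0
    n_complications: int = 0
    dx_age: float = NEVER
    stage: int = -1
    screen_detected: bool = False
    crc_death_age: float = NEVER
    death_age: float = NEVER

    @property
    def life_years(self) -> float:
        return self.death_age


def perform_colonoscopy(
    lesions: _PersonLesions,
    history: ScreeningHistory,
    reason: str,
    model: ColonoscopyModel,
    age: float,
    rng: np.random.Generator,
) -> ColonoscopyFindings:
    """Detect and remove lesions; schedule surveillance by findings.

    Raises if called on a diagnosed person (contract violation).  Detected
    adenomas are removed (future progression cancelled); a detected
    preclinical cancer is recorded for screen diagnosis by the caller.
    """
    if history.diagnosed:
        raise ValueError("colonoscopy on an already-diagnosed person")
    if reason not in ("follow_up", "surveillance"):
        raise ValueError(f"unknown colonoscopy reason {reason!r}")
    f = ColonoscopyFindings(age=age, reason=reason)
    for j in range(len(lesions.init)):
        if lesions.removed[j] or lesions.init[j] > age:
            continue
        if lesions.trans[j] <= age:
            if lesions.clin[j] > age and f.crc_detected_lesion < 0:
                if rng.random() < model.sensitivity_crc:
                    f.crc_detected_lesion = j
        else:
            d = lesions.diameter(j, age)
            if rng.random() < model.sensitivity_by_size[size_class(d)]:
                lesions.removed[j] = True
                f.adenomas_removed += 1
                f.largest_removed_mm = max(f.largest_removed_mm, d)
    f.complication = rng.random() < model.complication_probability

    if f.crc_detected_lesion < 0:
        # findings-based surveillance scheduling
        if f.adenomas_removed >= 3 or f.largest_removed_mm >= 10.0:
            interval = model.surveillance_interval_high
        elif f.adenomas_removed >= 1 and f.largest_removed_mm >= 6.0:
            interval = model.surveillance_interval_intermediate
        elif f.adenomas_removed >= 1:
            interval = model.surveillance_interval_low
        else:
            interval = None
        if interval is not None and age + interval <= model.max_surveillance_age:
            history.under_surveillance = True
            history.next_colonoscopy_age = age + interval
            f.next_surveillance_age = age + interval
        else:
            # clean exam (or surveillance aged out): back to routine stool
            # screening after the guideline gap
            history.under_surveillance = False
            history.next_colonoscopy_age = NEVER
            history.blocked_until = age + model.resume_after_clean_years
    return f


def _screen_person(
    lesions: _PersonLesions,
    oc_death: float,
    strategy: ScreeningStrategy,
    adherence_state,
    model: AdherenceModel,
    chars: TestCharacteristics,
    colo: ColonoscopyModel,
    params,
    rng_attend: np.random.Generator,
    rng_test: np.random.Generator,
    rng_colo: np.random.Generator,
) -> PersonScreenResult:
    res = PersonScreenResult()
    history = ScreeningHistory()
    survival = params.survival
    stage_dist_screen = params.stage.distribution("screen")

    last_age = max(strategy.start_age, int(colo.max_surveillance_age))
    for age in range(strategy.start_age, last_age + 1):
        if age >= oc_death:
            break
        # symptomatic diagnosis in the interval since the last action wins
        clin = lesions.next_clinical_age()
        if clin <= age:
            break
        did_colo = False
        if history.under_surveillance and history.next_colonoscopy_age <= age:
            findings = perform_colonoscopy(lesions, history, "surveillance", colo, age, rng_colo)
            did_colo = True
        elif is_due(strategy, history, age) and attends(
            model, adherence_state, age, rng_attend
        ):
            res.n_tests += 1
            history.last_completed_age = age
            positive = stool_test_result(lesions.snapshot(age), chars, age, rng_test)
            if positive:
                findings = perform_colonoscopy(lesions, history, "follow_up", colo, age, rng_colo)
                did_colo = True
        if did_colo:
            res.n_colonoscopies += 1
            if findings.complication:
                res.n_complications += 1
            j = findings.crc_detected_lesion
            if j >= 0:
                # screen diagnosis: shared pre-drawn uniforms couple the
                # screen stage to be no worse than the symptomatic one, and
                # cancer survival stays anchored at the would-be clinical
                # age, so earlier detection cannot hasten death (the benefit
                # channel is the stage shift)
                from .natural_history import _stage_from_uniform

                stage = _stage_from_uniform(stage_dist_screen, lesions.u_stage[j])
                delay = survival.death_delay(stage, lesions.u_survival[j])
                res.dx_age = float(age)
                res.stage = stage
                res.screen_detected = True
                res.crc_death_age = (
                    lesions.clin[j] + max(delay, 1e-9) if math.isfinite(delay) else NEVER
                )
                history.diagnosed = True
                break

    if not history.diagnosed:
        # remaining lesions may surface symptomatically
        clin = lesions.next_clinical_age()
        if clin < oc_death:
            j = int(np.argmin(np.where(lesions.removed, NEVER, lesions.clin)))
            from .natural_history import _stage_from_uniform

            stage = _stage_from_uniform(
                params.stage.distribution("symptomatic"), lesions.u_stage[j]
            )
            delay = survival.death_delay(stage, lesions.u_survival[j])
            res.dx_age = clin
            res.stage = stage
            res.crc_death_age = clin + max(delay, 1e-9) if math.isfinite(delay) else NEVER

    res.death_age = min(oc_death, res.crc_death_age)
    if res.dx_age >= res.death_age:  # died of other causes before symptoms
        res.dx_age = NEVER
        res.stage = -1
        res.crc_death_age = NEVER
        res.death_age = oc_death
    return res


def apply_screening(
    timeline: EventTimeline,
    strategy: ScreeningStrategy,
    adherence: AdherenceModel,
    chars: TestCharacteristics,
    colo: ColonoscopyModel,
    params,
) -> PersonScreenResult:
    """Screen one person against their unscreened timeline (same seeds)."""
    profile = timeline.profile
    carc = {c.parent_lesion: c for c in timeline.carcinomas}
    n = len(timeline.adenomas)
    lesions = _PersonLesions(
        init=np.array([a.init_age for a in timeline.adenomas]),
        region=np.array([SEGMENT_REGION[a.segment] for a in timeline.adenomas], dtype=np.int8),
        growth=np.array([a.growth_rate for a in timeline.adenomas]),
        trans=np.array([a.transition_age for a in timeline.adenomas]),
        clin=np.array(
            [carc[a.lesion_id].clinical_age if a.lesion_id in carc else NEVER
             for a in timeline.adenomas]
        ),
        u_stage=np.array(
            [carc[a.lesion_id].u_stage if a.lesion_id in carc else 0.0
             for a in timeline.adenomas]
        ),
        u_survival=np.array(
            [carc[a.lesion_id].u_survival if a.lesion_id in carc else 0.0
             for a in timeline.adenomas]
        ),
        removed=np.zeros(n, dtype=bool),
        d_init=params.growth.d_init,
        d_max=params.growth.d_max,
    )
    rng_attend = _rng.person_stream(profile.master_seed, profile.person_id, _rng.ATTEND)
    rng_test = _rng.person_stream(profile.master_seed, profile.person_id, _rng.TEST)
    rng_colo = _rng.person_stream(profile.master_seed, profile.person_id, _rng.COLO)
    state = init_person_adherence(adherence, strategy, rng_attend)
    return _screen_person(
        lesions,
        timeline.other_cause_death_age,
        strategy,
        state,
        adherence,
        chars,
        colo,
        params,
        rng_attend,
        rng_test,
        rng_colo,
    )


@dataclass
class ScreenedCohort:
    """Columnar per-person outcomes of one strategy applied to a cohort."""

    strategy: ScreeningStrategy
    adherence: AdherenceModel
    n_tests: np.ndarray
    n_colonoscopies: np.ndarray
    n_complications: np.ndarray
    dx_age: np.ndarray
    stage: np.ndarray
    screen_detected: np.ndarray
    crc_death: np.ndarray
    death_age: np.ndarray

    @property
    def life_years(self) -> np.ndarray:
        return self.death_age


def apply_screening_cohort(
    cohort: Cohort,
    strategy: ScreeningStrategy,
    adherence: AdherenceModel,
    chars: TestCharacteristics,
    colo: ColonoscopyModel,
) -> ScreenedCohort:
    """Apply one strategy to every person, reusing the cohort's natural
    history (common random numbers)."""
    n = cohort.n
    params = cohort.params
    region = np.asarray(SEGMENT_REGION, dtype=np.int8)[cohort.l_segment]
    out = ScreenedCohort(
        strategy=strategy,
        adherence=adherence,
        n_tests=np.zeros(n, dtype=np.int32),
        n_colonoscopies=np.zeros(n, dtype=np.int32),
        n_complications=np.zeros(n, dtype=np.int32),
        dx_age=np.full(n, NEVER),
        stage=np.full(n, -1, dtype=np.int8),
        screen_detected=np.zeros(n, dtype=bool),
        crc_death=np.full(n, NEVER),
        death_age=cohort.oc_death.copy(),
    )
    d_init, d_max = params.growth.d_init, params.growth.d_max
    for i in range(n):
        sl = cohort.lesions(i)
        if not cohort.eligible[i]:
            # simulated but excluded from reporting: keep unscreened outcome
            out.dx_age[i] = cohort.dx_age[i]
            out.stage[i] = cohort.stage[i]
            out.crc_death[i] = cohort.crc_death[i]
            out.death_age[i] = cohort.death_age[i]
            continue
        nles = sl.stop - sl.start
        if nles == 0:
            # still screened: false positives cost tests/colonoscopies
            lesions = _PersonLesions(
                init=np.empty(0), region=np.empty(0, dtype=np.int8),
                growth=np.empty(0), trans=np.empty(0), clin=np.empty(0),
                u_stage=np.empty(0), u_survival=np.empty(0),
                removed=np.empty(0, dtype=bool), d_init=d_init, d_max=d_max,
            )
        else:
            lesions = _PersonLesions(
                init=cohort.l_init[sl],
                region=region[sl],
                growth=cohort.l_growth[sl],
                trans=cohort.l_trans[sl],
                clin=cohort.l_clin[sl],
                u_stage=cohort.l_u_stage[sl],
                u_survival=cohort.l_u_survival[sl],
                removed=np.zeros(nles, dtype=bool),
                d_init=d_init,
                d_max=d_max,
            )
        rng_attend = _rng.person_stream(cohort.master_seed, i, _rng.ATTEND)
        rng_test = _rng.person_stream(cohort.master_seed, i, _rng.TEST)
        rng_colo = _rng.person_stream(cohort.master_seed, i, _rng.COLO)
        state = init_person_adherence(adherence, strategy, rng_attend)
        res = _screen_person(
            lesions, cohort.oc_death[i], strategy, state, adherence,
            chars, colo, params, rng_attend, rng_test, rng_colo,
        )
        out.n_tests[i] = res.n_tests
        out.n_colonoscopies[i] = res.n_colonoscopies
        out.n_complications[i] = res.n_complications
        out.dx_age[i] = res.dx_age
        out.stage[i] = res.stage
        out.screen_detected[i] = res.screen_detected
        out.crc_death[i] = res.crc_death_age
        out.death_age[i] = res.death_age
    return out
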