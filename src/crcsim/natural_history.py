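"""Natural history of colorectal neoplasia for an unscreened birth cohort.

The model follows the classical adenoma--carcinoma sequence used by the
CISNET-lineage colorectal microsimulations:

* adenomas initiate through a non-homogeneous Poisson process whose log rate
  combines a person-level frailty (``baseline_log_risk``), a sex effect and a
  piecewise-linear age effect;
* each adenoma grows along a deterministic saturating curve parameterised by
  a sampled time to reach 10 mm;
* an adenoma transitions to preclinical cancer when its diameter crosses a
  lognormally distributed size threshold (sex- and site-dependent);
* preclinical cancer becomes symptomatic after a lognormal sojourn time;
* stage at diagnosis is drawn from a detection-mode-dependent distribution
  and cancer survival from stage-specific mixture-cure curves;
* other-cause death comes from a packaged sex-specific cohort life table.

All event ages are continuous (real-valued years); screening offers are
evaluated at integer ages by the :mod:`crcsim.screening` layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtri  # inverse standard normal CDF

from . import rng as _rng

__all__ = [
    "SITE_SEGMENTS",
    "SEGMENT_REGION",
    "REGIONS",
    "STAGES",
    "PersonProfile",
    "Adenoma",
    "Carcinoma",
    "LifeTable",
    "NaturalHistoryParams",
    "EventTimeline",
    "Cohort",
    "sample_person",
    "simulate_adenoma_initiations",
    "adenoma_diameter",
    "sample_transition",
    "sample_sojourn",
    "stage_and_survival",
    "other_cause_death_age",
    "run_natural_history",
    "default_params",
]

# Six anatomical segments, collapsed to the three regions used by the
# stool-test operating characteristics (rectal / distal / proximal).
SITE_SEGMENTS = ("rectum", "sigmoid", "descending", "transverse", "ascending", "cecum")
SEGMENT_REGION = (0, 1, 1, 2, 2, 2)  # rectal=0, distal=1, proximal=2
REGIONS = ("rectal", "distal", "proximal")
STAGES = ("I", "II", "III", "IV")

NEVER = math.inf


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RiskParams:
    """Adenoma-initiation risk model.

    The instantaneous initiation rate for person *i* at age *a* is

    ``lambda_i(a) = exp(alpha_i + beta_female * female_i + g(a))``

    where ``alpha_i ~ Normal(mean_log_risk, sd_log_risk**2)`` and *g* is a
    piecewise-linear age effect with ``g(min_age) = 0``; the rate is zero
    before ``min_age``.
    """

    mean_log_risk: float
    sd_log_risk: float
    female_effect: float
    min_age: float
    age_knots: tuple[float, ...]  # ascending, first equals min_age
    age_slopes: tuple[float, ...]  # one slope per knot, last extends onward

    def __post_init__(self) -> None:
        if len(self.age_knots) != len(self.age_slopes):
            raise ValueError("age_knots and age_slopes must have equal length")
        if abs(self.age_knots[0] - self.min_age) > 1e-9:
            raise ValueError("first age knot must equal min_age")


@dataclass(frozen=True)
class GrowthParams:
    """Saturating adenoma growth, d(t) = d_max - (d_max - d_init) e^{-k t}.

    The growth constant *k* of each adenoma is set by its sampled time to
    reach 10 mm, drawn from a site-class-specific Frechet distribution
    (colon adenomas grow more slowly than rectal ones).
    """

    d_init: float = 1.0
    d_max: float = 50.0
    frechet_shape_colon: float = 2.0
    frechet_scale_colon: float = 22.0
    frechet_shape_rectum: float = 2.0
    frechet_scale_rectum: float = 14.0

    def growth_rate(self, t10: float) -> float:
        """Growth constant such that the diameter reaches 10 mm at t10."""
        return -math.log((self.d_max - 10.0) / (self.d_max - self.d_init)) / t10


@dataclass(frozen=True)
class TransitionParams:
    """Lognormal size threshold at which an adenoma turns malignant."""

    log_size_mu: float  # male, colon
    log_size_sigma: float
    female_offset: float = 0.0
    rectum_offset: float = 0.0

    def mu(self, female: bool, segment: int) -> float:
        mu = self.log_size_mu
        if female:
            mu += self.female_offset
        if segment == 0:  # rectum
            mu += self.rectum_offset
        return mu


@dataclass(frozen=True)
class SojournParams:
    """Lognormal preclinical sojourn time, site-specific."""

    log_mu_colon: float
    log_mu_rectum: float
    log_sigma: float

    def mu(self, segment: int) -> float:
        return self.log_mu_rectum if segment == 0 else self.log_mu_colon


@dataclass(frozen=True)
class StageParams:
    """Stage-at-diagnosis distributions (AJCC I-IV).

    Screen-detected preclinical cancers use a distinct, earlier-shifted
    distribution rather than the symptomatic one; surveillance detection
    uses the screen distribution.
    """

    symptomatic: tuple[float, float, float, float]
    screen: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for dist in (self.symptomatic, self.screen):
            if abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
                raise ValueError(f"stage distribution must be a probability vector: {dist}")

    def distribution(self, detection_mode: str) -> tuple[float, ...]:
        if detection_mode == "symptomatic":
            return self.symptomatic
        if detection_mode in ("screen", "surveillance"):
            return self.screen
        raise ValueError(f"unknown detection mode {detection_mode!r}")


@dataclass(frozen=True)
class SurvivalParams:
    """Mixture-cure cancer survival: S(t) = c_s + (1 - c_s) exp(-r_s t)."""

    cure: tuple[float, float, float, float]
    rate: tuple[float, float, float, float]

    def survival(self, stage: int, t: float) -> float:
        c, r = self.cure[stage], self.rate[stage]
        return c + (1.0 - c) * math.exp(-r * t)

    def death_delay(self, stage: int, u: float) -> float:
        """Inverse-CDF draw of years from diagnosis to cancer death.

        ``u`` uniform on (0,1); returns ``inf`` for cured individuals.  The
        cure mass sits in the upper tail (u >= 1 - cure), so that a shared
        uniform couples earlier-stage draws to never-shorter survival
        (stage-ordered survival curves are stochastically ordered).
        """
        c, r = self.cure[stage], self.rate[stage]
        if u >= 1.0 - c:
            return NEVER
        # T = F^{-1}(u) of the non-cured exponential component
        return -math.log1p(-u / (1.0 - c)) / r


@dataclass(frozen=True)
class NaturalHistoryParams:
    risk: RiskParams
    growth: GrowthParams
    transition: TransitionParams
    sojourn: SojournParams
    stage: StageParams
    survival: SurvivalParams
    segment_probs: tuple[float, ...] = (0.09, 0.24, 0.12, 0.24, 0.23, 0.08)
    max_age: float = 100.0
    # provenance tag per parameter block: supplement | crc_spin_publication
    # | fixture_default
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if abs(sum(self.segment_probs) - 1.0) > 1e-9:
            raise ValueError("segment probabilities must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalHistoryParams":
        return cls(
            risk=RiskParams(
                mean_log_risk=float(d["risk"]["mean_log_risk"]),
                sd_log_risk=float(d["risk"]["sd_log_risk"]),
                female_effect=float(d["risk"]["female_effect"]),
                min_age=float(d["risk"]["min_age"]),
                age_knots=tuple(float(x) for x in d["risk"]["age_knots"]),
                age_slopes=tuple(float(x) for x in d["risk"]["age_slopes"]),
            ),
            growth=GrowthParams(**{k: float(v) for k, v in d["growth"].items()}),
            transition=TransitionParams(**{k: float(v) for k, v in d["transition"].items()}),
            sojourn=SojournParams(**{k: float(v) for k, v in d["sojourn"].items()}),
            stage=StageParams(
                symptomatic=tuple(float(x) for x in d["stage"]["symptomatic"]),
                screen=tuple(float(x) for x in d["stage"]["screen"]),
            ),
            survival=SurvivalParams(
                cure=tuple(float(x) for x in d["survival"]["cure"]),
                rate=tuple(float(x) for x in d["survival"]["rate"]),
            ),
            segment_probs=tuple(float(x) for x in d["segment_probs"]),
            max_age=float(d.get("max_age", 100.0)),
            provenance=dict(d.get("provenance", {})),
        )


def default_params() -> NaturalHistoryParams:
    """The packaged default parameter set (see :mod:`crcsim.fixtures`)."""
    from .fixtures import load_fixtures

    return load_fixtures().nh_params


# ---------------------------------------------------------------------------
# Domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PersonProfile:
    person_id: int
    sex: str  # "female" | "male"
    baseline_log_risk: float
    master_seed: int
    birth_year: int = 1975

    @property
    def female(self) -> bool:
        return self.sex == "female"


@dataclass
class Adenoma:
    """One adenoma: initiation age, growth trajectory and (possible) fate."""

    lesion_id: int
    segment: int  # index into SITE_SEGMENTS
    init_age: float
    t10: float  # sampled years from initiation to 10 mm
    growth_rate: float
    transition_age: float = NEVER
    state: str = "adenoma"  # adenoma | preclinical_crc | clinical_crc | removed

    @property
    def site(self) -> str:
        """Three-level region used by the stool-test characteristics."""
        return REGIONS[SEGMENT_REGION[self.segment]]


@dataclass
class Carcinoma:
    parent_lesion: int
    segment: int
    onset_age: float
    sojourn: float = math.nan
    stage: int = -1  # 0..3 for I..IV, assigned exactly once at diagnosis
    crc_death_age: float | None = None
    # pre-drawn uniforms, shared between detection modes: a screen detection
    # reuses the symptomatic draws (through the stage CDF ordering this
    # couples the screen stage to be no worse than the symptomatic stage,
    # and cancer survival is anchored at the would-be clinical age, so
    # screening never hastens a cancer death)
    u_stage: float = math.nan
    u_survival: float = math.nan

    @property
    def clinical_age(self) -> float:
        return self.onset_age + self.sojourn


@dataclass
class EventTimeline:
    """Dated unscreened events for one person, birth to death."""

    profile: PersonProfile
    adenomas: list[Adenoma]
    carcinomas: list[Carcinoma]
    other_cause_death_age: float
    clinical_dx_age: float  # inf if never symptomatic before death
    stage: int  # -1 if undiagnosed
    crc_death_age: float  # inf if no cancer death
    death_age: float
    diagnosed_by_40: bool
    events: list[tuple[float, str]]

    @property
    def life_years(self) -> float:
        return self.death_age

    @property
    def eligible(self) -> bool:
        """Alive and free of diagnosed CRC at exact age 40 (the reporting
        denominator)."""
        return self.other_cause_death_age > 40.0 and not self.diagnosed_by_40


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------


class LifeTable:
    """Annual other-cause death probabilities per (sex, integer age)."""

    def __init__(self, q_male: Sequence[float], q_female: Sequence[float]):
        self.q = {
            "male": np.asarray(q_male, dtype=float),
            "female": np.asarray(q_female, dtype=float),
        }
        for sex, q in self.q.items():
            if q.ndim != 1 or len(q) < 2:
                raise ValueError("life table needs at least two ages")
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"{sex} probabilities outside [0,1]")
            if q[-1] != 1.0:
                raise ValueError("terminal age must be absorbing (probability 1)")

    @property
    def terminal_age(self) -> int:
        return len(self.q["male"]) - 1

    def annual_probabilities(self, sex: str) -> np.ndarray:
        return self.q[sex]

    def survival_to(self, sex: str, age: int) -> float:
        """Probability of surviving other causes to exact integer ``age``."""
        return float(np.prod(1.0 - self.q[sex][:age]))

    @classmethod
    def from_tsv(cls, path) -> "LifeTable":
        data = np.loadtxt(path, skiprows=1)
        ages = data[:, 0].astype(int)
        if not np.array_equal(ages, np.arange(len(ages))):
            raise ValueError("life table ages must be 0..terminal with step 1")
        return cls(q_male=data[:, 1], q_female=data[:, 2])


# ---------------------------------------------------------------------------
# Initiation-rate integral (closed form per piecewise-linear segment)
# ---------------------------------------------------------------------------


class _RateIntegral:
    """Cumulative integral of exp(g(t)) for the piecewise-linear age effect."""

    def __init__(self, risk: RiskParams, max_age: float):
        knots = list(risk.age_knots) + [max_age]
        self.t0 = np.array(knots[:-1])
        self.t1 = np.array(knots[1:])
        self.slope = np.array(risk.age_slopes)
        # g at segment starts
        g = [0.0]
        for k in range(len(self.slope) - 1):
            g.append(g[-1] + self.slope[k] * (self.t1[k] - self.t0[k]))
        self.g0 = np.array(g)
        self.seg_int = np.array(
            [
                self._segment_integral(k, self.t1[k])
                for k in range(len(self.slope))
            ]
        )
        self.cum = np.concatenate([[0.0], np.cumsum(self.seg_int)])

    def _segment_integral(self, k: int, upto: float) -> float:
        dt = upto - self.t0[k]
        if dt <= 0:
            return 0.0
        s = self.slope[k]
        if abs(s) < 1e-12:
            return math.exp(self.g0[k]) * dt
        return math.exp(self.g0[k]) * (math.exp(s * dt) - 1.0) / s

    @property
    def total(self) -> float:
        return float(self.cum[-1])

    def cumulative(self, age: float) -> float:
        """Integral of exp(g) from min_age to ``age``."""
        if age <= self.t0[0]:
            return 0.0
        k = int(np.searchsorted(self.t1, age, side="left"))
        k = min(k, len(self.slope) - 1)
        return float(self.cum[k] + self._segment_integral(k, min(age, self.t1[k])))

    def inverse(self, c: np.ndarray) -> np.ndarray:
        """Ages at which the cumulative integral equals ``c`` (vectorised)."""
        c = np.asarray(c, dtype=float)
        k = np.clip(np.searchsorted(self.cum, c, side="right") - 1, 0, len(self.slope) - 1)
        rem = c - self.cum[k]
        s = self.slope[k]
        g0 = self.g0[k]
        with np.errstate(divide="ignore", invalid="ignore"):
            dt = np.where(
                np.abs(s) < 1e-12,
                rem * np.exp(-g0),
                np.log1p(s * rem * np.exp(-g0)) / np.where(np.abs(s) < 1e-12, 1.0, s),
            )
        return self.t0[k] + dt


_INTEGRAL_CACHE: dict[tuple, _RateIntegral] = {}


def _rate_integral(params: NaturalHistoryParams) -> _RateIntegral:
    key = (params.risk, params.max_age)
    if key not in _INTEGRAL_CACHE:
        _INTEGRAL_CACHE[key] = _RateIntegral(params.risk, params.max_age)
    return _INTEGRAL_CACHE[key]


def expected_adenomas(
    params: NaturalHistoryParams, sex: str, age: float, marginal: bool = True
) -> float:
    """Expected cumulative adenoma count by ``age`` for a random (or, with
    ``marginal=False``, a mean-log-risk) person of the given sex.

    Used as the quadrature oracle for the initiation process.
    """
    r = params.risk
    log_mult = r.mean_log_risk + (r.female_effect if sex == "female" else 0.0)
    if marginal:
        log_mult += 0.5 * r.sd_log_risk**2  # lognormal frailty mean
    return math.exp(log_mult) * _rate_integral(params).cumulative(age)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def sample_person(
    sex_fraction: float, master_seed: int, person_id: int, params: NaturalHistoryParams
) -> PersonProfile:
    """Draw a person's sex (Bernoulli ``sex_fraction`` female) and frailty."""
    if not 0.0 <= sex_fraction <= 1.0:
        raise ValueError(f"sex_fraction must be in [0,1], got {sex_fraction}")
    g = _rng.person_stream(master_seed, person_id, _rng.PROFILE)
    u_sex, u_risk = g.random(2)
    sex = "female" if u_sex < sex_fraction else "male"
    alpha = params.risk.mean_log_risk + params.risk.sd_log_risk * float(ndtri(u_risk))
    return PersonProfile(
        person_id=person_id, sex=sex, baseline_log_risk=alpha, master_seed=master_seed
    )


def simulate_adenoma_initiations(
    profile: PersonProfile, params: NaturalHistoryParams, rng: np.random.Generator
) -> list[Adenoma]:
    """Sample a person's adenomas (ages sorted ascending) with site and
    growth trajectory."""
    integral = _rate_integral(params)
    log_mult = profile.baseline_log_risk + (
        params.risk.female_effect if profile.female else 0.0
    )
    mean_count = math.exp(log_mult) * integral.total if math.isfinite(log_mult) else 0.0
    n = int(rng.poisson(mean_count)) if mean_count > 0 else 0
    if n == 0:
        return []
    ages = np.sort(integral.inverse(rng.random(n) * integral.total))
    seg_cdf = np.cumsum(params.segment_probs)
    adenomas: list[Adenoma] = []
    gp = params.growth
    for j, a in enumerate(ages):
        seg = int(np.searchsorted(seg_cdf, rng.random(), side="right"))
        seg = min(seg, len(SITE_SEGMENTS) - 1)
        if seg == 0:
            shape, scale = gp.frechet_shape_rectum, gp.frechet_scale_rectum
        else:
            shape, scale = gp.frechet_shape_colon, gp.frechet_scale_colon
        u = rng.random()
        t10 = scale * (-math.log(u)) ** (-1.0 / shape)  # Frechet inverse CDF
        adenomas.append(
            Adenoma(
                lesion_id=j,
                segment=seg,
                init_age=float(a),
                t10=t10,
                growth_rate=gp.growth_rate(t10),
            )
        )
    return adenomas


def adenoma_diameter(adenoma: Adenoma, age: float, params: NaturalHistoryParams) -> float:
    """Diameter (mm) at ``age``; 1 mm at initiation, saturating at d_max."""
    if age < adenoma.init_age - 1e-12:
        raise ValueError("age precedes adenoma initiation")
    gp = params.growth
    t = max(age - adenoma.init_age, 0.0)
    return gp.d_max - (gp.d_max - gp.d_init) * math.exp(-adenoma.growth_rate * t)


def sample_transition(
    adenoma: Adenoma,
    profile: PersonProfile,
    params: NaturalHistoryParams,
    rng: np.random.Generator,
) -> float:
    """Age of malignant transition, or ``inf`` for never (within max age).

    The adenoma transitions when its diameter crosses a lognormal size
    threshold; the growth curve is inverted in closed form.
    """
    tp = params.transition
    gp = params.growth
    mu = tp.mu(profile.female, adenoma.segment)
    xi = math.exp(mu + tp.log_size_sigma * float(ndtri(rng.random())))
    if xi >= gp.d_max:
        return NEVER
    if xi <= gp.d_init:
        return adenoma.init_age
    t = -math.log((gp.d_max - xi) / (gp.d_max - gp.d_init)) / adenoma.growth_rate
    age = adenoma.init_age + t
    return age if age <= params.max_age else NEVER


def transition_probability(
    params: NaturalHistoryParams, female: bool, segment: int, diameter: float
) -> float:
    """Closed-form P(threshold <= diameter): the lifetime transition
    probability of an adenoma whose size path reaches ``diameter``."""
    from scipy.special import ndtr

    tp = params.transition
    mu = tp.mu(female, segment)
    if diameter <= 0:
        return 0.0
    return float(ndtr((math.log(diameter) - mu) / tp.log_size_sigma))


def sample_sojourn(
    carcinoma: Carcinoma, params: NaturalHistoryParams, rng: np.random.Generator
) -> float:
    """Strictly positive lognormal sojourn (preclinical onset to symptoms)."""
    sp = params.sojourn
    s = math.exp(sp.mu(carcinoma.segment) + sp.log_sigma * float(ndtri(rng.random())))
    return max(s, 1e-9)


def _stage_from_uniform(dist: Sequence[float], u: float) -> int:
    cdf = np.cumsum(dist)
    return int(min(np.searchsorted(cdf, u, side="right"), len(dist) - 1))


def stage_and_survival(
    carcinoma: Carcinoma,
    profile: PersonProfile,
    detection_mode: str,
    diagnosis_age: float,
    params: NaturalHistoryParams,
    rng: np.random.Generator | None = None,
    u_stage: float | None = None,
    u_survival: float | None = None,
) -> tuple[int, float | None]:
    """Assign stage at diagnosis and a cancer death age (or ``None`` if the
    person is cured of this cancer).

    Uniform draws may be supplied explicitly (the simulator pre-draws them so
    screen detection at any age reuses the same randomness); otherwise they
    come from ``rng``.
    """
    if u_stage is None:
        u_stage = rng.random()
    if u_survival is None:
        u_survival = rng.random()
    dist = params.stage.distribution(detection_mode)
    stage = _stage_from_uniform(dist, u_stage)
    delay = params.survival.death_delay(stage, u_survival)
    if not math.isfinite(delay):
        return stage, None
    return stage, diagnosis_age + max(delay, 1e-9)


def other_cause_death_age(
    profile: PersonProfile, table: LifeTable, rng: np.random.Generator
) -> float:
    """Sequential annual Bernoulli draw against the life table, uniform
    placement within the death year (vectorised; one uniform per age plus a
    placement uniform)."""
    q = table.annual_probabilities(profile.sex)
    u = rng.random(len(q))
    hits = u < q
    age = int(np.argmax(hits))  # terminal age has q = 1, so always a hit
    return age + float(rng.random())


def run_natural_history(
    profile: PersonProfile, params: NaturalHistoryParams, table: LifeTable
) -> EventTimeline:
    """Compose the unscreened lifetime for one person.

    Deterministic given ``(master_seed, person_id, params, table)``.  Per
    adenoma, draws are consumed in a fixed order regardless of the lesion's
    fate so that streams stay aligned across parameter variations.
    """
    rng_lesions = _rng.person_stream(profile.master_seed, profile.person_id, _rng.LESIONS)
    rng_death = _rng.person_stream(profile.master_seed, profile.person_id, _rng.OC_DEATH)

    adenomas = simulate_adenoma_initiations(profile, params, rng_lesions)
    # one stage/survival uniform pair per person, shared by every carcinoma:
    # whichever lesion is diagnosed (and in whichever mode), the stage-CDF
    # ordering then guarantees screening never draws a worse stage or a
    # shorter cancer survival than the unscreened counterfactual
    u_stage_person, u_survival_person = rng_lesions.random(2)
    carcinomas: list[Carcinoma] = []
    for ad in adenomas:
        ad.transition_age = sample_transition(ad, profile, params, rng_lesions)
        carc = Carcinoma(
            parent_lesion=ad.lesion_id,
            segment=ad.segment,
            onset_age=ad.transition_age,
            u_stage=u_stage_person,
            u_survival=u_survival_person,
        )
        # unconditional draw keeps the stream aligned whether or not the
        # adenoma ever transitions
        carc.sojourn = sample_sojourn(carc, params, rng_lesions)
        if math.isfinite(ad.transition_age):
            carcinomas.append(carc)

    oc_death = other_cause_death_age(profile, table, rng_death)

    # first symptomatic diagnosis before other-cause death
    dx_age = NEVER
    dx_carc: Carcinoma | None = None
    for carc in carcinomas:
        if carc.clinical_age < min(oc_death, dx_age):
            dx_age, dx_carc = carc.clinical_age, carc

    stage = -1
    crc_death = NEVER
    if dx_carc is not None:
        stage, death = stage_and_survival(
            dx_carc,
            profile,
            "symptomatic",
            dx_age,
            params,
            u_stage=dx_carc.u_stage,
            u_survival=dx_carc.u_survival,
        )
        dx_carc.stage = stage
        if death is not None:
            crc_death = death
        dx_carc.crc_death_age = None if crc_death is NEVER else crc_death

    death_age = min(oc_death, crc_death)

    events: list[tuple[float, str]] = []
    for ad in adenomas:
        if ad.init_age < death_age:
            events.append((ad.init_age, "adenoma_init"))
    for carc in carcinomas:
        if carc.onset_age < death_age:
            events.append((carc.onset_age, "preclinical_onset"))
    if dx_carc is not None and dx_age <= death_age:
        events.append((dx_age, "clinical_diagnosis"))
    if crc_death < oc_death:
        events.append((crc_death, "crc_death"))
    else:
        events.append((oc_death, "other_cause_death"))
    events.sort(key=lambda e: e[0])

    return EventTimeline(
        profile=profile,
        adenomas=adenomas,
        carcinomas=carcinomas,
        other_cause_death_age=oc_death,
        clinical_dx_age=dx_age,
        stage=stage,
        crc_death_age=crc_death,
        death_age=death_age,
        diagnosed_by_40=dx_age < 40.0,
        events=events,
    )


# ---------------------------------------------------------------------------
# Cohort container (columnar flattening of per-person timelines)
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Columnar natural-history arrays for a simulated cohort.

    Generated once per (seed, size, params) and shared by every screening
    scenario, so scenario contrasts are paired (common random numbers).
    """

    master_seed: int
    params: NaturalHistoryParams
    life_table: LifeTable
    sex_fraction: float
    # person-level
    female: np.ndarray  # bool
    oc_death: np.ndarray  # float
    dx_age: np.ndarray  # unscreened symptomatic diagnosis age (inf if none)
    stage: np.ndarray  # int8, -1 undiagnosed
    crc_death: np.ndarray  # float, inf if none
    death_age: np.ndarray
    eligible: np.ndarray  # alive and CRC-free at exact age 40
    # lesion-level (CSR layout: lesions of person i are
    # slice(lesion_ptr[i], lesion_ptr[i+1]))
    lesion_ptr: np.ndarray
    l_init: np.ndarray
    l_segment: np.ndarray
    l_growth: np.ndarray
    l_trans: np.ndarray  # inf if never
    l_clin: np.ndarray  # transition + sojourn (inf if never)
    l_u_stage: np.ndarray
    l_u_survival: np.ndarray

    @property
    def n(self) -> int:
        return len(self.oc_death)

    def lesions(self, i: int) -> slice:
        return slice(int(self.lesion_ptr[i]), int(self.lesion_ptr[i + 1]))

    @classmethod
    def generate(
        cls,
        n: int,
        params: NaturalHistoryParams,
        life_table: LifeTable,
        master_seed: int,
        sex_fraction: float = 0.5,
    ) -> "Cohort":
        female = np.zeros(n, dtype=bool)
        oc_death = np.zeros(n)
        dx_age = np.full(n, NEVER)
        stage = np.full(n, -1, dtype=np.int8)
        crc_death = np.full(n, NEVER)
        death_age = np.zeros(n)
        eligible = np.zeros(n, dtype=bool)

        ptr = np.zeros(n + 1, dtype=np.int64)
        cols: dict[str, list] = {
            k: []
            for k in ("init", "segment", "growth", "trans", "clin", "us", "uv")
        }

        for i in range(n):
            profile = sample_person(sex_fraction, master_seed, i, params)
            tl = run_natural_history(profile, params, life_table)
            female[i] = profile.female
            oc_death[i] = tl.other_cause_death_age
            dx_age[i] = tl.clinical_dx_age
            stage[i] = tl.stage
            crc_death[i] = tl.crc_death_age
            death_age[i] = tl.death_age
            eligible[i] = tl.eligible
            ptr[i + 1] = ptr[i] + len(tl.adenomas)
            carc_by_lesion = {c.parent_lesion: c for c in tl.carcinomas}
            for ad in tl.adenomas:
                carc = carc_by_lesion.get(ad.lesion_id)
                cols["init"].append(ad.init_age)
                cols["segment"].append(ad.segment)
                cols["growth"].append(ad.growth_rate)
                cols["trans"].append(ad.transition_age)
                if carc is not None:
                    cols["clin"].append(carc.clinical_age)
                    cols["us"].append(carc.u_stage)
                    cols["uv"].append(carc.u_survival)
                else:
                    cols["clin"].append(NEVER)
                    cols["us"].append(0.0)
                    cols["uv"].append(0.0)

        return cls(
            master_seed=master_seed,
            params=params,
            life_table=life_table,
            sex_fraction=sex_fraction,
            female=female,
            oc_death=oc_death,
            dx_age=dx_age,
            stage=stage,
            crc_death=crc_death,
            death_age=death_age,
            eligible=eligible,
            lesion_ptr=ptr,
            l_init=np.array(cols["init"]),
            l_segment=np.array(cols["segment"], dtype=np.int8),
            l_growth=np.array(cols["growth"]),
            l_trans=np.array(cols["trans"]),
            l_clin=np.array(cols["clin"]),
            l_u_stage=np.array(cols["us"]),
            l_u_survival=np.array(cols["uv"]),
        )
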