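"""Unit and oracle tests for the adenoma-carcinoma natural history."""

import math
from dataclasses import replace

import numpy as np
import pytest

from crcsim import rng as streams
from crcsim.natural_history import (
    Adenoma,
    Carcinoma,
    LifeTable,
    adenoma_diameter,
    expected_adenomas,
    other_cause_death_age,
    run_natural_history,
    sample_person,
    sample_sojourn,
    sample_transition,
    simulate_adenoma_initiations,
    stage_and_survival,
    transition_probability,
    _rate_integral,
)


# ---------------------------------------------------------------------------
# sample_person
# ---------------------------------------------------------------------------


class TestSamplePerson:
    def test_rejects_invalid_sex_fraction(self, params):
        with pytest.raises(ValueError, match="sex_fraction"):
            sample_person(1.5, 1, 0, params)

    def test_degenerate_fraction_gives_all_male(self, params):
        assert all(
            sample_person(0.0, seed, pid, params).sex == "male"
            for seed in (0, 99) for pid in range(20)
        )

    def test_deterministic_given_seed_and_id(self, params):
        a = sample_person(0.5, 42, 7, params)
        b = sample_person(0.5, 42, 7, params)
        assert a == b
        assert sample_person(0.5, 42, 8, params) != a

    def test_female_share_matches_binomial(self, params):
        n = 10_000
        share = np.mean(
            [sample_person(0.5, 5, pid, params).female for pid in range(n)]
        )
        sd = math.sqrt(0.25 / n)
        assert abs(share - 0.5) < 3 * sd


# ---------------------------------------------------------------------------
# adenoma initiation process
# ---------------------------------------------------------------------------


class TestInitiations:
    def test_zero_rate_gives_empty_list(self, params, rng):
        profile = sample_person(0.5, 1, 0, params)
        profile = replace(profile, baseline_log_risk=-math.inf)
        assert simulate_adenoma_initiations(profile, params, rng) == []

    def test_ages_sorted_and_within_bounds(self, params, rng):
        profile = replace(sample_person(0.5, 1, 0, params), baseline_log_risk=-3.0)
        ages = [a.init_age for a in simulate_adenoma_initiations(profile, params, rng)]
        assert ages == sorted(ages)
        assert all(params.risk.min_age <= a <= params.max_age for a in ages)

    def test_expected_count_matches_quadrature_oracle(self, params, rng):
        """Mean lesion count to age 65 vs numerical integration of the rate."""
        from scipy.integrate import quad

        alpha = -4.5
        profile = replace(sample_person(0.5, 1, 0, params), baseline_log_risk=alpha)
        integral = _rate_integral(params)

        def rate(t):
            # piecewise-linear log age effect, reconstructed independently
            g = 0.0
            knots, slopes = params.risk.age_knots, params.risk.age_slopes
            for k in range(len(slopes)):
                hi = knots[k + 1] if k + 1 < len(knots) else params.max_age
                g += slopes[k] * max(0.0, min(t, hi) - knots[k])
            return math.exp(alpha + g) if t >= params.risk.min_age else 0.0

        expected, _ = quad(rate, params.risk.min_age, 65.0)
        reps = 3000
        counts = [
            sum(a.init_age <= 65.0 for a in simulate_adenoma_initiations(profile, params, rng))
            for _ in range(reps)
        ]
        se = np.std(counts, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(counts) - expected) < 3.5 * se

    def test_cumulative_rate_monotone_in_age(self, params, rng):
        """Mean count by 70 dominates mean count by 50 under default risk."""
        profile = replace(sample_person(0.5, 1, 0, params), baseline_log_risk=-4.0)
        n50 = n70 = 0
        for _ in range(800):
            ads = simulate_adenoma_initiations(profile, params, rng)
            n50 += sum(a.init_age <= 50 for a in ads)
            n70 += sum(a.init_age <= 70 for a in ads)
        assert n70 >= n50
        assert expected_adenomas(params, "male", 70) >= expected_adenomas(params, "male", 50)


# ---------------------------------------------------------------------------
# growth, transition, sojourn
# ---------------------------------------------------------------------------


def _adenoma(params, init_age=50.0, t10=8.0, segment=1):
    return Adenoma(
        lesion_id=0,
        segment=segment,
        init_age=init_age,
        t10=t10,
        growth_rate=params.growth.growth_rate(t10),
    )


class TestGrowth:
    def test_initiation_diameter_is_one_mm(self, params):
        ad = _adenoma(params)
        assert adenoma_diameter(ad, ad.init_age, params) == pytest.approx(1.0)

    def test_reaches_ten_mm_at_sampled_time(self, params):
        """Growth-curve inversion: diameter hits 10 mm exactly at t10."""
        for t10 in (2.0, 8.0, 30.0):
            ad = _adenoma(params, t10=t10)
            assert adenoma_diameter(ad, ad.init_age + t10, params) == pytest.approx(10.0)

    def test_monotone_nondecreasing(self, params):
        ad = _adenoma(params)
        ages = np.linspace(ad.init_age, 100.0, 200)
        d = [adenoma_diameter(ad, a, params) for a in ages]
        assert all(d2 >= d1 for d1, d2 in zip(d, d[1:]))
        assert d[-1] <= params.growth.d_max

    def test_age_before_initiation_rejected(self, params):
        with pytest.raises(ValueError):
            adenoma_diameter(_adenoma(params), 49.0, params)


class TestTransition:
    def test_huge_threshold_never_transitions(self, params, rng):
        zero_params = replace(
            params, transition=replace(params.transition, log_size_mu=50.0)
        )
        profile = sample_person(0.5, 1, 0, params)
        ad = _adenoma(params)
        assert all(
            sample_transition(ad, profile, zero_params, rng) == math.inf
            for _ in range(200)
        )

    def test_transition_never_precedes_initiation(self, params, rng):
        profile = sample_person(0.5, 1, 0, params)
        ad = _adenoma(params, t10=2.0)
        for _ in range(5000):
            t = sample_transition(ad, profile, params, rng)
            assert t >= ad.init_age

    def test_transition_fraction_matches_closed_form(self, params, rng):
        """Empirical P(transition by the age the lesion reaches 15 mm) equals
        the lognormal threshold CDF at 15 mm, within a binomial CI."""
        profile = sample_person(0.0, 1, 0, params)  # male
        ad = _adenoma(params, t10=5.0, segment=1)
        gp = params.growth
        d_target = 15.0
        t_target = ad.init_age - math.log(
            (gp.d_max - d_target) / (gp.d_max - gp.d_init)
        ) / ad.growth_rate
        n = 20_000
        hits = sum(
            sample_transition(ad, profile, params, rng) <= t_target for _ in range(n)
        )
        p_expected = transition_probability(params, False, 1, d_target)
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hits / n - p_expected) < 3 * se


class TestSojourn:
    def test_degenerate_distribution(self, params, rng):
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        det = replace(params, sojourn=replace(params.sojourn, log_sigma=0.0,
                                              log_mu_colon=math.log(3.0)))
        assert all(
            sample_sojourn(carc, det, rng) == pytest.approx(3.0) for _ in range(50)
        )

    def test_positive_and_mean_matches_lognormal(self, params, rng):
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        n = 20_000
        draws = np.array([sample_sojourn(carc, params, rng) for _ in range(n)])
        assert np.all(draws > 0)
        sp = params.sojourn
        expected = math.exp(sp.log_mu_colon + sp.log_sigma**2 / 2)
        se = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - expected) < 3 * se


class TestStageAndSurvival:
    def test_forced_cure_gives_no_crc_death(self, params, rng):
        cured = replace(params, survival=replace(params.survival, cure=(1.0,) * 4))
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        profile = sample_person(0.5, 1, 0, params)
        for _ in range(50):
            stage, death = stage_and_survival(
                carc, profile, "symptomatic", 63.0, cured, rng
            )
            assert death is None

    def test_point_mass_stage_four(self, params, rng):
        p4 = replace(
            params,
            stage=replace(params.stage, symptomatic=(0.0, 0.0, 0.0, 1.0)),
        )
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        profile = sample_person(0.5, 1, 0, params)
        stages = {
            stage_and_survival(carc, profile, "symptomatic", 63.0, p4, rng)[0]
            for _ in range(100)
        }
        assert stages == {3}

    def test_death_after_diagnosis(self, params, rng):
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        profile = sample_person(0.5, 1, 0, params)
        for _ in range(2000):
            _, death = stage_and_survival(carc, profile, "screen", 63.0, params, rng)
            assert death is None or death > 63.0

    def test_five_year_survival_matches_curve(self, params, rng):
        """Empirical 5-y survival for a fixed stage vs the mixture-cure
        closed form, within a binomial CI."""
        carc = Carcinoma(parent_lesion=0, segment=1, onset_age=60.0)
        profile = sample_person(0.5, 1, 0, params)
        one_stage = replace(
            params, stage=replace(params.stage, symptomatic=(0.0, 0.0, 1.0, 0.0))
        )
        n = 20_000
        alive = 0
        for _ in range(n):
            _, death = stage_and_survival(
                carc, profile, "symptomatic", 63.0, one_stage, rng
            )
            alive += death is None or death > 68.0
        expected = params.survival.survival(2, 5.0)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(alive / n - expected) < 3 * se


# ---------------------------------------------------------------------------
# other-cause death
# ---------------------------------------------------------------------------


class TestLifeTable:
    def test_validates_probabilities_and_terminal(self):
        with pytest.raises(ValueError):
            LifeTable(q_male=[0.1, 0.5], q_female=[0.1, 0.9])  # no absorbing age
        with pytest.raises(ValueError):
            LifeTable(q_male=[1.2, 1.0], q_female=[0.1, 1.0])

    def test_certain_death_in_first_year(self, params, rng):
        table = LifeTable(q_male=[1.0, 1.0], q_female=[1.0, 1.0])
        profile = sample_person(0.5, 1, 0, params)
        for _ in range(20):
            assert other_cause_death_age(profile, table, rng) < 1.0

    def test_survival_to_terminal_when_probabilities_zero(self, params, rng):
        q = [0.0] * 10 + [1.0]
        table = LifeTable(q_male=q, q_female=q)
        profile = sample_person(0.5, 1, 0, params)
        for _ in range(20):
            age = other_cause_death_age(profile, table, rng)
            assert 10.0 <= age <= 11.0

    def test_empirical_survival_matches_product_oracle(self, params, life_table, rng):
        """Draws reproduce the life table's cumulative survival at each
        decade within 3 binomial SDs."""
        profile = sample_person(0.0, 1, 0, params)  # male
        n = 20_000
        draws = np.array(
            [other_cause_death_age(profile, life_table, rng) for _ in range(n)]
        )
        for decade in (40, 60, 80):
            expected = life_table.survival_to("male", decade)
            observed = np.mean(draws >= decade)
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se


# ---------------------------------------------------------------------------
# composed timelines
# ---------------------------------------------------------------------------


def _naive_rescan(timeline, params, step=1 / 64):
    """Independent straight-line re-computation of the first symptomatic
    diagnosis and death from the sampled lesion primitives."""
    carcs = [
        c for c in timeline.carcinomas if math.isfinite(c.onset_age)
    ]
    oc = timeline.other_cause_death_age
    dx, dx_c = math.inf, None
    age = 0.0
    while age <= params.max_age + 1:
        for c in carcs:
            if c.onset_age + c.sojourn <= age:
                cand = c.onset_age + c.sojourn
                if cand < dx and cand < oc:
                    dx, dx_c = cand, c
        if dx < math.inf:
            break
        age += step
    crc_death = math.inf
    if dx_c is not None:
        dist = params.stage.distribution("symptomatic")
        cdf = np.cumsum(dist)
        stage = int(np.searchsorted(cdf, dx_c.u_stage, side="right"))
        delay = params.survival.death_delay(stage, dx_c.u_survival)
        if math.isfinite(delay):
            crc_death = dx + delay
    return dx, min(oc, crc_death)


class TestRunNaturalHistory:
    def test_zero_rate_timeline_contains_only_death(self, params, life_table):
        profile = replace(
            sample_person(0.5, 1, 0, params), baseline_log_risk=-math.inf
        )
        tl = run_natural_history(profile, params, life_table)
        assert [kind for _, kind in tl.events] == ["other_cause_death"]
        assert tl.clinical_dx_age == math.inf

    def test_rerun_is_identical(self, params, life_table):
        profile = sample_person(0.5, 77, 3, params)
        a = run_natural_history(profile, params, life_table)
        b = run_natural_history(profile, params, life_table)
        assert a.events == b.events
        assert a.death_age == b.death_age

    def test_event_ordering_and_single_death(self, params, life_table):
        for pid in range(300):
            tl = run_natural_history(sample_person(0.5, 9, pid, params), params, life_table)
            ages = [age for age, _ in tl.events]
            assert ages == sorted(ages)
            deaths = [k for _, k in tl.events if k.endswith("death")]
            assert len(deaths) == 1
            assert tl.events[-1][1].endswith("death")
            for ad in tl.adenomas:
                assert ad.transition_age >= ad.init_age
            for c in tl.carcinomas:
                assert c.sojourn > 0
                assert c.clinical_age == pytest.approx(c.onset_age + c.sojourn)

    def test_matches_naive_rescan_oracle(self, params, life_table):
        """Event composition equals a per-step scan re-implementation."""
        step = 1 / 64
        for pid in range(1000):
            tl = run_natural_history(sample_person(0.5, 31, pid, params), params, life_table)
            dx, death = _naive_rescan(tl, params, step)
            if math.isfinite(dx):
                assert tl.clinical_dx_age == pytest.approx(dx, abs=step)
            else:
                assert tl.clinical_dx_age == math.inf
            assert tl.death_age == pytest.approx(death, abs=step)

    def test_cohort_conservation(self, small_cohort):
        c = small_cohort
        diagnosed = np.isfinite(c.dx_age)
        crc_deaths = np.isfinite(c.crc_death) & (c.crc_death <= c.oc_death)
        assert crc_deaths.sum() <= diagnosed.sum() <= c.n
        assert np.all(c.death_age <= c.oc_death + 1e-12)

    def test_cohort_matches_per_person_engine(self, params, life_table, small_cohort):
        """Columnar cohort arrays agree with directly composed timelines."""
        for pid in (0, 17, 123, 999):
            tl = run_natural_history(
                sample_person(0.5, small_cohort.master_seed, pid, params),
                params,
                life_table,
            )
            assert small_cohort.death_age[pid] == pytest.approx(tl.death_age)
            assert small_cohort.dx_age[pid] == tl.clinical_dx_age or (
                math.isinf(small_cohort.dx_age[pid]) and math.isinf(tl.clinical_dx_age)
            )
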