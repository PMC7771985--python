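# Model and methods

`crcsim` is a continuous-time microsimulation of colorectal cancer (CRC)
natural history in a single birth cohort, with stool-based screening
(mt-sDNA, FIT, HSgFOBT), follow-up and surveillance colonoscopy,
pluggable adherence mechanisms, per-1000 outcome accounting, and an
efficient-frontier strategy-selection layer. This note documents the model,
its parameters and defaults, the numerical choices, and what the synthetic
cohort does and does not capture.

## Natural history

Each simulated person carries a sex (Bernoulli, default half female) and a
lognormal adenoma-risk frailty. Events use real-valued ages; screening
decisions happen at integer ages.

**Adenoma initiation.** A non-homogeneous Poisson process with log rate

    ln λ_i(a) = α_i + β_f · female_i + g(a),   α_i ~ N(A, σ²),

where `g` is piecewise linear in age (knots at 20/50/60/70, zero before age
20). The cumulative rate has a closed form per segment, so lesion counts
are drawn as Poisson and placed by exact inverse-CDF sampling; a quadrature
oracle cross-checks the expectation in the test suite. Defaults:
`A = −5.65`, `σ = 1.1`, `β_f = −0.25`, slopes `0.045/0.030/0.015/0` per
decade band — calibrated as described below.

**Growth.** Diameter follows the saturating curve
`d(t) = d_max − (d_max − d_init)·e^(−kt)` with `d_init = 1 mm`,
`d_max = 50 mm`. The per-lesion growth constant is pinned by a sampled time
to reach 10 mm, Fréchet-distributed (shape 2; scale 22 y colon, 14 y
rectum): most adenomas grow slowly and never become large.

**Malignant transition.** Each adenoma owns a lognormal size threshold
(log-median `ln 30 mm` for male colon, σ = 0.72; rectal lesions transition
at ~18% smaller sizes, female at ~6% larger); the transition age inverts
the growth curve in closed form. Small, slow lesions effectively never
transition; the minority of fast growers drive cancer risk.

**Sojourn and diagnosis.** Preclinical cancer becomes symptomatic after a
lognormal sojourn (median ≈ 2.6 y colon, 2.2 y rectum, σ = 0.55). Stage at
diagnosis (AJCC I–IV) is drawn from a detection-mode distribution:
symptomatic `(0.16, 0.28, 0.32, 0.24)`, screen/surveillance-detected
`(0.44, 0.30, 0.18, 0.08)`. Cancer survival is a stage-specific mixture
cure model `S(t) = c + (1−c)·e^(−rt)` with cure fractions
`(0.88, 0.74, 0.52, 0.02)` and rates `(0.25, 0.30, 0.35, 0.45)` /year,
giving 5-year survival ≈ 92/80/62/9% by stage.

**Other-cause mortality.** A packaged synthetic sex-specific cohort life
table (`life_table_synthetic_us1975.tsv`): Gompertz–Makeham annual death
probabilities with an infant/child overlay, absorbing at 100. Remaining
life expectancy at 40 is 37.8 y (male) and 42.0 y (female), intended as an
approximation to a US 1975 birth cohort with secular mortality improvement.
The table is generated, not transcribed from a vital-statistics source —
replace the file to use an official table.

### Calibration

The functional forms above follow the published CRC-SPIN-lineage
methodology; coefficient values were calibrated once, jointly, to:

* adenoma prevalence ≈ 35% at age 60, ≈ 45% at 70;
* unscreened clinical incidence rising from ~120 (50s) to ~420 (80s) per
  100 000 person-years, mean diagnosis age ≈ 71;
* unscreened lifetime burden per 1000 persons CRC-free at 40: ≈ 78 cases,
  ≈ 33 CRC deaths;
* perfect-adherence life-years gained (LYG) for annual FIT and triennial
  mt-sDNA, ages 50–75, under the granular test characteristics, matching
  the published model family this package emulates (≈ 315 and ≈ 304 per
  1000, respectively).

After freezing, a three-seed 200 000-person replication gave mean LYG 312
(FIT) and 306 (mt-sDNA). Parameters are provenance-tagged in
`data/nh_params.yaml` and fully overridable.

## Screening layer

Persons are offered a stool test every integer year in `[start, stop]`.
They are **due** when not diagnosed, not under surveillance, not inside a
post-colonoscopy pause, and at least `interval` years past their last
*completed* test; declined offers leave them due again the next year (so
the effective per-cycle completion probability exceeds the per-offer
probability for multi-year intervals — this retry semantics is deliberate
and drives the annual-vs-triennial comparison).

**Test result.** Granular mode (packaged from the DeeP-C cross-sectional
study): each lesion is detected independently with its site (rectal /
distal / proximal) × size (≤5 / 6–9 / ≥10 mm) sensitivity, cancers with a
single cancer sensitivity; if nothing is detected the test is positive with
1 − specificity(age band: <60, 60–64, 65–69, 70–74, 75+). Aggregate mode
(the decision-analysis convention): the most advanced lesion's class
sensitivity governs, lesion-free persons test positive with
1 − specificity. No granular HSgFOBT estimates exist; HSgFOBT always runs
aggregate.

**Colonoscopy.** Follow-up of every positive stool test (adherence to
follow-up and surveillance colonoscopy is always 100%). Per-lesion
detection sensitivity by size class (0.76/0.85/0.95; cancer 0.95); detected
adenomas are removed and their future progression cancelled; a detected
preclinical cancer becomes a screen diagnosis. Complications occur with
probability 0.0025 per colonoscopy (burden only; complication mortality is
off by default). Findings-based surveillance: ≥3 adenomas or any ≥10 mm →
3 y; 1–2 with largest 6–9 mm → 5 y; 1–2 small → 10 y; a clean exam exits
the pathway and stool screening resumes after 10 y. Surveillance continues
to age 85. Stool testing is suspended while under surveillance.

**Screen-detection coupling.** Stage and survival uniforms are drawn once
per person and shared across lesions and detection modes, and the survival
clock of a screen-detected cancer is anchored at its would-be clinical age.
Because the screen stage distribution stochastically dominates the
symptomatic one and stage-ordered survival curves are stochastically
ordered, inverse-CDF sampling with the shared uniform guarantees that
screening never assigns a worse stage or an earlier cancer death than the
unscreened counterfactual — the benefit channel is the stage shift plus
removal, with no lead-time artifact. This also makes per-person life-years
under screening ≥ no screening whenever complications cannot kill, which
the test suite asserts exactly.

## Adherence mechanisms

* `perfect` — attend every due offer.
* `annual_likelihood(p)` — independent Bernoulli(p) per due offer.
* `fixed_split(f)` — permanent all-or-nothing assignment at simulation
  start; cohort outcomes are the f-weighted average of perfect-adherence
  and no-screening outcomes (the adherent arm is bitwise identical to the
  perfect run, person for person).
* `assigned_count(k)` — k round ages chosen uniformly without replacement
  from the strategy's scheduled grid (start, start+interval, …); persons
  attend exactly those ages (fewer if they die or leave the pathway), and
  missed rounds are not rescheduled. A **full** budget instead attends
  every due offer: after a post-colonoscopy pause, due ages can drift off
  the round grid, and a person granted every round has no reason to
  decline a make-up offer — this makes "full budget = 100% adherence" an
  exact identity with `perfect`.

Attendance draws use a dedicated random stream, so adherence scenarios are
compared on identical natural histories and identical test/colonoscopy
draws (`p = 1` is bitwise identical to `perfect`).

## Outcomes and frontier

All outcomes are per 1000 persons alive and CRC-free at exact age 40;
persons failing that condition are simulated (they consume random numbers)
but excluded from numerators and denominators. Life-years are undiscounted,
birth to death; LYG is the mean paired per-person difference × 1000, with
its Monte-Carlo SE reported. "Life-years with CRC" counts diagnosis to
death. Patient-hour burden: 1 h per FIT or mt-sDNA, 2 h per HSgFOBT, 16 h
per colonoscopy, 112 h per complication.

The frontier layer removes strongly dominated strategies (another point
attains ≥ LYG for ≤ burden, one strict), then gift-wraps from the
no-screening origin (0, 0), at each step taking the candidate with the
smallest incremental ratio ΔBurden/ΔLYG — yielding non-decreasing ratios
(convex-hull property; verified against an exhaustive-subset oracle).
Colinear points are retained with equal ratios; a candidate adding burden
but no LYG is discarded. Non-frontier points with LYG ≥ 98% of the
frontier's interpolated LYG at their burden are near-efficient (burden
outside the frontier span compares to the nearest endpoint). A
recommendable strategy must be efficient or near-efficient with an
incremental ratio at or below 65 colonoscopies (or 8766 patient hours —
one year of time — when burden is hours) per LYG, and offers the most LYG
among qualifiers; ties prefer lower burden, then input order.
Near-efficient points are excluded from ratio chains; for the
recommendation bound their ratio is computed against the preceding
efficient point.

## Randomness and reproducibility

Every draw comes from a counter-based Philox stream keyed by
`(master_seed, person_id, purpose)` with purposes {profile, lesions,
other-cause death, attendance, stool tests, colonoscopy}. Natural history
is therefore identical across screening scenarios (common random numbers),
which makes LYG a paired difference and stabilizes scenario contrasts at a
fraction of the published cohort sizes. Per adenoma, draws are consumed in
fixed order whether or not the lesion progresses, keeping streams aligned
across parameter variations. Replaying any suite with the same seed,
cohort size, and fixture version reproduces every table bit for bit.

## Problem sizes

Default scenario cohort size is 200 000 (the published analyses used
4 000 000); with common random numbers the paired-LYG SE at 200 000 is
≈ 6 per 1000, under 2% of the perfect-adherence LYG. The acceptance script
uses 150 000; test-suite invariants use 4 000; distributional oracles use
20 000 draws against 3-SD binomial bands. The integer
"FIT-tests-to-match" crossing moves by ±1 budget between seeds at these
sizes because adjacent budgets differ by only ~1.5 LYG per 1000.

## What the synthetic cohort does not capture

Serrated/sessile polyp pathways (a stated limitation of this model
family), race/ethnicity- or insurance-stratified risk and adherence,
secular incidence trends beyond the single 1975 cohort, endoscopist
variability in colonoscopy sensitivity, follow-up colonoscopy
non-adherence, costs and health-state utilities. The life table and the
aggregate ("primary analysis") test characteristics are best-effort
stand-ins rather than transcriptions of the original sources; conclusions
that hinge on their exact values (notably absolute incidence-reduction
levels under the aggregate characteristics) carry that uncertainty, while
paired contrasts, mechanism comparisons, and frontier geometry are robust
to it.
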