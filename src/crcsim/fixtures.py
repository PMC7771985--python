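"""Packaged constants and deterministic miniature cohorts.

The fixture set bundles everything a scenario run needs besides a seed: the
granular stool-test operating characteristics (site-by-size sensitivities
with their n/N provenance and age-band specificities), the aggregate
characteristics used by the primary decision-analysis convention, the
strategy grid, adherence presets, burden weights, recommendation-rule
constants, the sex-specific cohort life table and the natural-history
default parameters.  Loading is pure (no network) and checksummed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .adherence import AdherenceModel, annual_likelihood, fixed_split, perfect
from .frontier import RecommendationRule
from .natural_history import Cohort, LifeTable, NEVER, NaturalHistoryParams
from .outcomes import BurdenWeights
from .screening import ColonoscopyModel, ScreeningStrategy, TestCharacteristics

__all__ = ["FixtureSet", "load_fixtures", "make_toy_cohort", "FIXTURE_VERSION"]

FIXTURE_VERSION = "v1"

_DATA_FILES = (
    "test_characteristics.yaml",
    "nh_params.yaml",
    "strategies.tsv",
    "life_table_synthetic_us1975.tsv",
)


@dataclass(frozen=True)
class FixtureSet:
    version: str
    characteristics: dict  # (modality, mode) -> TestCharacteristics
    strategies: pd.DataFrame
    adherence_presets: dict
    burden_weights: BurdenWeights
    recommendation_rule: RecommendationRule
    colonoscopy: ColonoscopyModel
    life_table: LifeTable
    nh_params: NaturalHistoryParams
    checksums: dict

    def test_characteristics(self, modality: str, mode: str) -> TestCharacteristics:
        try:
            return self.characteristics[(modality, mode)]
        except KeyError:
            raise KeyError(
                f"no {mode} characteristics packaged for {modality}"
            ) from None

    def strategy_grid(self, analysis: str) -> list[ScreeningStrategy]:
        rows = self.strategies[self.strategies["analysis"] == analysis]
        if rows.empty:
            raise KeyError(f"unknown analysis {analysis!r}")
        return [
            ScreeningStrategy(
                modality=r.modality,
                interval=int(r.interval),
                start_age=int(r.start_age),
                stop_age=int(r.stop_age),
            )
            for r in rows.itertuples()
        ]


def _data_path(name: str):
    return resources.files("crcsim.data").joinpath(name)


def _sha256(name: str) -> str:
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def _build_characteristics(doc: dict) -> dict:
    out: dict = {}
    for modality, block in doc["granular"].items():
        sens = block["sensitivity"]
        out[(modality, "granular")] = TestCharacteristics(
            modality=modality,
            mode="granular",
            sensitivity_crc=float(block["sensitivity_crc"]["value"]),
            sensitivity_by_site_size=tuple(
                tuple(float(cell["value"]) for cell in sens[region])
                for region in ("rectal", "distal", "proximal")
            ),
            specificity_by_age=tuple(
                float(cell["value"]) for cell in block["specificity_by_age"]
            ),
            patient_hours_per_test=float(doc["patient_hours"][modality]),
        )
    for modality, block in doc["aggregate"].items():
        out[(modality, "aggregate")] = TestCharacteristics(
            modality=modality,
            mode="aggregate",
            sensitivity_crc=float(block["sensitivity_crc"]),
            sensitivity_by_size=tuple(float(x) for x in block["sensitivity_by_size"]),
            specificity=float(block["specificity"]),
            patient_hours_per_test=float(doc["patient_hours"][modality]),
        )
    return out


def load_fixtures(version: str = FIXTURE_VERSION) -> FixtureSet:
    """Load the packaged fixture set; checksum mismatch raises."""
    if version != FIXTURE_VERSION:
        raise KeyError(f"unknown fixture version {version!r}")
    recorded = yaml.safe_load(_data_path("checksums.yaml").read_text())
    for name in _DATA_FILES:
        actual = _sha256(name)
        if recorded[name] != actual:
            raise ValueError(f"fixture checksum mismatch for {name}")

    chars_doc = yaml.safe_load(_data_path("test_characteristics.yaml").read_text())
    nh_doc = yaml.safe_load(_data_path("nh_params.yaml").read_text())
    strategies = pd.read_csv(_data_path("strategies.tsv"), sep="\t", comment="#")
    with resources.as_file(_data_path("life_table_synthetic_us1975.tsv")) as p:
        life_table = LifeTable.from_tsv(p)

    adherence_presets = {
        "perfect": {m: perfect() for m in ("FIT", "HSgFOBT", "mt-sDNA")},
        # base-case imperfect first-round rates; the HSgFOBT rate derives
        # from FIT as 40% / 1.16 = 34%
        "base_case": {
            "FIT": annual_likelihood(0.40),
            "HSgFOBT": annual_likelihood(0.34),
            "mt-sDNA": annual_likelihood(0.70),
        },
        "sens_50": {
            "FIT": annual_likelihood(0.50),
            "HSgFOBT": annual_likelihood(0.43),
            "mt-sDNA": annual_likelihood(0.70),
        },
        "sens_60": {
            "FIT": annual_likelihood(0.60),
            "HSgFOBT": annual_likelihood(0.52),
            "mt-sDNA": annual_likelihood(0.70),
        },
        "base_case_split": {
            "FIT": fixed_split(0.40),
            "HSgFOBT": fixed_split(0.34),
            "mt-sDNA": fixed_split(0.70),
        },
    }

    return FixtureSet(
        version=version,
        characteristics=_build_characteristics(chars_doc),
        strategies=strategies,
        adherence_presets=adherence_presets,
        burden_weights=BurdenWeights(),
        recommendation_rule=RecommendationRule(),
        colonoscopy=ColonoscopyModel(),
        life_table=life_table,
        nh_params=NaturalHistoryParams.from_dict(nh_doc),
        checksums=dict(recorded),
    )


# ---------------------------------------------------------------------------
# Hand-built miniature cohorts for golden tests
# ---------------------------------------------------------------------------


def make_toy_cohort(
    people: list[dict],
    params: NaturalHistoryParams | None = None,
    life_table: LifeTable | None = None,
    master_seed: int = 0,
) -> Cohort:
    """Build a deterministic cohort from hand-placed lesions and death ages.

    Each entry: ``{"sex": "male", "oc_death": 82.0, "lesions": [{"init": 55,
    "segment": 1, "t10": 10, "trans": inf|age, "sojourn": 3, ...}]}``.
    Bypasses the stochastic natural history; used to test screening and
    outcome arithmetic on known inputs.
    """
    if params is None or life_table is None:
        fx = load_fixtures()
        params = params or fx.nh_params
        life_table = life_table or fx.life_table
    n = len(people)
    female = np.zeros(n, dtype=bool)
    oc_death = np.zeros(n)
    dx_age = np.full(n, NEVER)
    stage = np.full(n, -1, dtype=np.int8)
    crc_death = np.full(n, NEVER)
    death_age = np.zeros(n)
    eligible = np.zeros(n, dtype=bool)
    ptr = np.zeros(n + 1, dtype=np.int64)
    cols = {k: [] for k in ("init", "seg", "growth", "trans", "clin", "us", "uv")}

    for i, spec in enumerate(people):
        female[i] = spec.get("sex", "male") == "female"
        oc_death[i] = float(spec["oc_death"])
        us_default = float(spec.get("u_stage", 0.5))
        uv_default = float(spec.get("u_survival", 0.5))
        lesions = spec.get("lesions", [])
        first_clin = NEVER
        first = None
        for les in lesions:
            init = float(les["init"])
            if init >= oc_death[i]:
                raise ValueError(f"person {i}: lesion initiates after death")
            t10 = float(les.get("t10", 10.0))
            trans = float(les.get("trans", NEVER))
            if np.isfinite(trans) and trans < init:
                raise ValueError(f"person {i}: transition precedes initiation")
            sojourn = float(les.get("sojourn", 3.0))
            clin = trans + sojourn if np.isfinite(trans) else NEVER
            cols["init"].append(init)
            cols["seg"].append(int(les.get("segment", 1)))
            cols["growth"].append(params.growth.growth_rate(t10))
            cols["trans"].append(trans)
            cols["clin"].append(clin)
            cols["us"].append(float(les.get("u_stage", us_default)))
            cols["uv"].append(float(les.get("u_survival", uv_default)))
            if clin < first_clin:
                first_clin, first = clin, len(cols["init"]) - 1
        ptr[i + 1] = ptr[i] + len(lesions)
        if first is not None and first_clin < oc_death[i]:
            dx_age[i] = first_clin
            dist = params.stage.distribution("symptomatic")
            from .natural_history import _stage_from_uniform

            stage[i] = _stage_from_uniform(dist, cols["us"][first])
            delay = params.survival.death_delay(int(stage[i]), cols["uv"][first])
            crc_death[i] = first_clin + delay if np.isfinite(delay) else NEVER
        death_age[i] = min(oc_death[i], crc_death[i])
        eligible[i] = oc_death[i] > 40.0 and not dx_age[i] < 40.0

    return Cohort(
        master_seed=master_seed,
        params=params,
        life_table=life_table,
        sex_fraction=float(female.mean()) if n else 0.5,
        female=female,
        oc_death=oc_death,
        dx_age=dx_age,
        stage=stage,
        crc_death=crc_death,
        death_age=death_age,
        eligible=eligible,
        lesion_ptr=ptr,
        l_init=np.array(cols["init"]),
        l_segment=np.array(cols["seg"], dtype=np.int8),
        l_growth=np.array(cols["growth"]),
        l_trans=np.array(cols["trans"]),
        l_clin=np.array(cols["clin"]),
        l_u_stage=np.array(cols["us"]),
        l_u_survival=np.array(cols["uv"]),
    )
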