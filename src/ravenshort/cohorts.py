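"""Preset cohort descriptions for the two study populations.

Two age groups take the same 60-item test: a younger cohort (around 9–12
years, one source, n = 289, total score 37.17 ± 6.91, no recorded ages) and
an older cohort (around 13–16 years, three sources of 557/157/273 pooling to
n = 987, total score 43.83 ± 6.97). The first two items of set A serve as
practice items in the younger group only, so its administered set has 58
items. Older-cohort cleaning removes rows with missing responses (43),
duplicates (4) and under-age rows (37), i.e. 1,071 received rows → 987.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

from .simulate import (
    AgeModel,
    DefectSpec,
    GeneratorConfig,
    ItemBank,
    build_item_bank,
    calibrate_to_marginals,
)

#: minimum age (years) for membership in the older cohort
OLDER_MIN_AGE = 12.5
#: practice items administered but not scored in the younger group
PRACTICE_ITEMS = ("A1", "A2")


@dataclass(frozen=True)
class CohortSpec:
    """Target marginals and composition of one study cohort."""

    name: str
    n: int
    score_mean: float
    score_sd: float
    sources: Dict[str, int]
    age_models: Optional[Dict[str, AgeModel]] = None
    min_age: Optional[float] = None
    practice_items: Tuple[str, ...] = ()
    defects: DefectSpec = field(default_factory=DefectSpec)


YOUNGER = CohortSpec(
    name="younger",
    n=289,
    score_mean=37.17,
    score_sd=6.91,
    sources={"orwell": 289},
    age_models=None,  # exact ages were not recorded for this cohort
    min_age=None,
    practice_items=PRACTICE_ITEMS,
    defects=DefectSpec(n_missing_rows=11, n_duplicate_rows=0, n_underage_rows=0),
)

OLDER = CohortSpec(
    name="older",
    n=987,
    score_mean=43.83,
    score_sd=6.97,
    sources={"dataset1": 557, "dataset2": 157, "dataset3": 273},
    age_models={
        "dataset1": AgeModel(mean=13.14, sd=0.36, min_age=12.52, max_age=14.55),
        "dataset2": AgeModel(mean=13.99, sd=0.39, min_age=12.61, max_age=14.65),
        "dataset3": AgeModel(mean=14.75, sd=0.72, min_age=13.03, max_age=17.3),
    },
    min_age=OLDER_MIN_AGE,
    practice_items=(),
    defects=DefectSpec(n_missing_rows=43, n_duplicate_rows=4, n_underage_rows=37),
)

COHORTS = {c.name: c for c in (YOUNGER, OLDER)}


def cohort_config(
    cohort: CohortSpec,
    seed: int,
    item_bank: Optional[ItemBank] = None,
    calibrate: bool = True,
    bank_seed: int = 60,
) -> GeneratorConfig:
    """A generator configuration for a preset cohort.

    With ``calibrate=True`` (default) the ability distribution is adjusted so
    the analytic total-score moments match the cohort's score marginals; the
    shared default item bank is left untouched.
    """
    bank = item_bank if item_bank is not None else build_item_bank(seed=bank_seed)
    config = GeneratorConfig(
        n_persons=cohort.n,
        item_bank=bank,
        sources=dict(cohort.sources),
        age_models=dict(cohort.age_models) if cohort.age_models else None,
        seed=seed,
    )
    if calibrate:
        config = calibrate_to_marginals(config, cohort.score_mean, cohort.score_sd)
    return config
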