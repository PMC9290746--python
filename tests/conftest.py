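"""Shared fixtures: small hand-built matrices and session-scoped simulations.

Expensive artifacts (planted-signal cohorts, fitted 2PL models, calibrated
cohort pipelines) are session-scoped so every module can reuse them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ravenshort as rs
from ravenshort.items import ALL_ITEMS

#: fixed seed for all test randomness (chosen up front, used everywhere)
SEED = 2021

#: the five strongly discriminating items planted in the signal-recovery cohort;
#: their difficulties sit within the ability mass (|b| < 0.8) so the planted
#: signal is identifiable at θ ~ Normal(0, 1)
PLANTED_ITEMS = ["B10", "C3", "C6", "C9", "D3"]


def make_matrix(rows, items, ages=None, sources=None, ids=None):
    """Build an ItemResponseMatrix from a list of row value lists."""
    n = len(rows)
    ids = ids or [f"p{i+1}" for i in range(n)]
    ages = pd.Series(ages if ages is not None else [np.nan] * n, index=ids, dtype=float)
    sources = pd.Series(sources if sources is not None else ["sample"] * n, index=ids)
    return rs.ItemResponseMatrix(
        responses=pd.DataFrame(rows, index=ids, columns=items, dtype=float),
        ages=ages,
        sources=sources,
    )


@pytest.fixture(scope="session")
def default_bank():
    return rs.build_item_bank(seed=60)


@pytest.fixture(scope="session")
def planted_bank():
    """Difficulty grid as usual, but 5 items with a = 3 amid 55 with a = 0.3."""
    bank = rs.build_item_bank(seed=60)
    a = pd.Series(0.3, index=ALL_ITEMS)
    a[PLANTED_ITEMS] = 3.0
    return rs.ItemBank(a=a, b=bank.b)


@pytest.fixture(scope="session")
def planted_matrix(planted_bank):
    cfg = rs.GeneratorConfig(n_persons=2000, item_bank=planted_bank, seed=SEED)
    return rs.simulate_responses(cfg)


@pytest.fixture(scope="session")
def planted_split(planted_matrix):
    assignment = rs.make_splits(planted_matrix, seed=SEED)
    train, test, validation = rs.split_matrix(planted_matrix, assignment)
    return {"train": train, "test": test, "validation": validation, "matrix": planted_matrix}


@pytest.fixture(scope="session")
def planted_search(planted_split):
    return rs.grid_search(planted_split["train"], planted_split["test"])


@pytest.fixture(scope="session")
def recovery_model(default_bank):
    """2PL fit on a 2,000-person cohort generated from the known default bank."""
    cfg = rs.GeneratorConfig(n_persons=2000, item_bank=default_bank, seed=11)
    matrix = rs.simulate_responses(cfg)
    return {"bank": default_bank, "matrix": matrix, "model": rs.fit_2pl(matrix)}


def _cohort_pipeline(spec):
    config = rs.cohort_config(spec, seed=SEED)
    matrix = rs.simulate_responses(config)
    cleaned, report = rs.clean_responses(
        matrix, min_age=spec.min_age, practice_items=spec.practice_items
    )
    assignment = rs.make_splits(cleaned, seed=SEED)
    train, test, validation = rs.split_matrix(cleaned, assignment)
    search = rs.grid_search(train, test)
    r_val = rs.validate_form(search.chosen.items, validation, cleaned.administered_items)
    return {
        "spec": spec,
        "config": config,
        "raw": matrix,
        "matrix": cleaned,
        "cleaning": report,
        "assignment": assignment,
        "train": train,
        "test": test,
        "validation": validation,
        "search": search,
        "validation_correlation": r_val,
    }


@pytest.fixture(scope="session")
def younger_run():
    return _cohort_pipeline(rs.YOUNGER)


@pytest.fixture(scope="session")
def older_run():
    return _cohort_pipeline(rs.OLDER)
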