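"""Synthetic binary response cohorts from a two-parameter logistic item bank.

The generating model is the 2PL: a person with ability θ answers item *i*
correctly with probability ``P_i(θ) = 1 / (1 + exp(-a_i (θ - b_i)))`` where
``a_i > 0`` is the item's discrimination and ``b_i`` its difficulty on the
logit scale. Abilities are Normal(θ_mean, θ_sd²). Difficulties rise along the
canonical item order so that each set A→E is progressively harder, mirroring
the design of progressive-matrices tests. An optional guessing floor turns
the model into a 3PL; it is off by default.

The generator can be *calibrated*: given a target mean and SD of the 60-item
total score, :func:`calibrate_to_marginals` adjusts (θ_mean, θ_sd) — never
the item bank — so the analytic score moments match the targets. The same
bank thus serves cohorts of different ability (e.g. a younger and an older
age group taking one test).

:func:`inject_defects` decorates a clean matrix with missing cells, exact
duplicate rows and under-age rows on disjoint row sets, producing fixtures
for the cleaning rules.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .data import DEFAULT_SOURCE, ItemResponseMatrix
from .errors import ConfigurationError, ConvergenceError, DataError
from .items import ALL_ITEMS, ITEMS_PER_SET, SET_LETTERS, parse_item_label


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Item bank
# ---------------------------------------------------------------------------


@dataclass
class ItemBank:
    """Per-item 2PL parameters over the canonical 60 items.

    Invariants: all discriminations positive; difficulties non-decreasing
    within each set; set-mean difficulty non-decreasing A→E.
    """

    a: pd.Series  # discrimination, index = item labels
    b: pd.Series  # difficulty (logit scale)

    def __post_init__(self) -> None:
        labels = [parse_item_label(l) for l in self.a.index]
        self.a = pd.Series(self.a.to_numpy(dtype=float), index=labels)
        self.b = pd.Series(self.b.to_numpy(dtype=float), index=[parse_item_label(l) for l in self.b.index])
        self.b = self.b.reindex(labels)
        if self.a.isna().any() or self.b.isna().any():
            raise ConfigurationError("item bank has unmatched or missing parameters")
        if (self.a <= 0).any():
            bad = list(self.a.index[self.a <= 0])
            raise ConfigurationError(f"non-positive discriminations for items {bad[:5]}")
        for s in SET_LETTERS:
            bs = self.b[[l for l in labels if l.startswith(s)]].to_numpy()
            if len(bs) and np.any(np.diff(bs) < -1e-12):
                raise ConfigurationError(f"difficulties not non-decreasing within set {s}")
        means = self.set_mean_difficulties().to_numpy()
        if np.any(np.diff(means) < -1e-12):
            raise ConfigurationError("set-mean difficulties not non-decreasing A→E")

    @property
    def items(self):
        return list(self.a.index)

    def set_mean_difficulties(self) -> pd.Series:
        groups = [l[0] for l in self.b.index]
        return self.b.groupby(groups, sort=True).mean()

    def to_dict(self) -> dict:
        return {"a": self.a.to_dict(), "b": self.b.to_dict()}

    @classmethod
    def from_dict(cls, d: Mapping) -> "ItemBank":
        return cls(a=pd.Series(d["a"]), b=pd.Series(d["b"]))


def build_item_bank(
    difficulty_range: Tuple[float, float] = (-2.5, 2.5),
    discrimination_median: float = 1.0,
    discrimination_log_sd: float = 0.3,
    jitter: float = 0.0,
    seed: int = 0,
) -> ItemBank:
    """Construct a 60-item bank with progressively harder items.

    Difficulties are laid on an equally spaced grid from ``b_min`` to
    ``b_max`` in canonical order; an optional uniform jitter of half-width
    ``jitter`` is added and difficulties re-sorted within each set, which
    preserves both monotonicity invariants. Discriminations are log-normal
    with the given median and log-scale SD.
    """
    b_min, b_max = difficulty_range
    if not b_min < b_max:
        raise ConfigurationError(f"difficulty_range must satisfy b_min < b_max, got {difficulty_range}")
    if discrimination_median <= 0 or discrimination_log_sd < 0:
        raise ConfigurationError("discrimination law requires median > 0 and log-SD >= 0")
    if jitter < 0:
        raise ConfigurationError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(ALL_ITEMS)
    b = np.linspace(b_min, b_max, n)
    if jitter > 0:
        b = b + rng.uniform(-jitter, jitter, size=n)
        for s in range(len(SET_LETTERS)):  # re-sort within each set
            sl = slice(s * ITEMS_PER_SET, (s + 1) * ITEMS_PER_SET)
            b[sl] = np.sort(b[sl])
    a = np.exp(np.log(discrimination_median) + discrimination_log_sd * rng.standard_normal(n))
    return ItemBank(a=pd.Series(a, index=ALL_ITEMS), b=pd.Series(b, index=ALL_ITEMS))


# ---------------------------------------------------------------------------
# Generator configuration
# ---------------------------------------------------------------------------


@dataclass
class AgeModel:
    """Truncated-normal age distribution for one source dataset (years)."""

    mean: float
    sd: float
    min_age: float
    max_age: float

    def __post_init__(self) -> None:
        if self.sd <= 0 or not self.min_age < self.max_age:
            raise ConfigurationError(f"invalid age model {self}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GeneratorConfig:
    """Everything needed to simulate one cohort reproducibly.

    ``sources`` maps source-dataset name → number of examinees; when omitted a
    single source of ``n_persons`` is used. ``guessing`` adds a 3PL lower
    asymptote (0 = plain 2PL). The seed fully determines the output.
    """

    n_persons: int
    item_bank: ItemBank
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    sources: Optional[Dict[str, int]] = None
    age_models: Optional[Dict[str, AgeModel]] = None
    guessing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_sd <= 0:
            raise ConfigurationError("theta_sd must be positive")
        if self.n_persons < 1:
            raise ConfigurationError("n_persons must be >= 1")
        if not 0.0 <= self.guessing < 1.0:
            raise ConfigurationError("guessing must be in [0, 1)")
        if self.sources is not None:
            if any(n < 0 for n in self.sources.values()):
                raise ConfigurationError("source sizes must be non-negative")
            total = sum(self.sources.values())
            if total != self.n_persons:
                raise ConfigurationError(
                    f"source sizes sum to {total}, but n_persons = {self.n_persons}"
                )

    def source_sizes(self) -> Dict[str, int]:
        if self.sources is None:
            return {DEFAULT_SOURCE: self.n_persons}
        return dict(self.sources)

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "n_persons": self.n_persons,
            "theta_mean": self.theta_mean,
            "theta_sd": self.theta_sd,
            "item_bank": self.item_bank.to_dict(),
            "sources": dict(self.sources) if self.sources else None,
            "age_models": (
                {k: v.to_dict() for k, v in self.age_models.items()} if self.age_models else None
            ),
            "guessing": self.guessing,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        d["item_bank"] = ItemBank.from_dict(d["item_bank"])
        if d.get("age_models"):
            d["age_models"] = {k: AgeModel(**v) for k, v in d["age_models"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=max(size - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def response_probabilities(bank: ItemBank, theta: np.ndarray, guessing: float = 0.0) -> np.ndarray:
    """2PL/3PL correct-response probabilities, shape (n_persons, n_items)."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = bank.a.to_numpy() * (theta[:, None] - bank.b.to_numpy())
    p = _sigmoid(z)
    if guessing:
        p = guessing + (1.0 - guessing) * p
    return p


def simulate_responses(config: GeneratorConfig) -> ItemResponseMatrix:
    """Draw a cohort from the configured 2PL model; bit-reproducible per seed."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_persons
    theta = rng.normal(config.theta_mean, config.theta_sd, size=n)
    p = response_probabilities(config.item_bank, theta, config.guessing)
    resp = (rng.random(p.shape) < p).astype(float)

    sizes = config.source_sizes()
    sources = np.concatenate([[name] * k for name, k in sizes.items()]) if n else np.array([])
    ages = np.full(n, np.nan)
    if config.age_models:
        start = 0
        for name, k in sizes.items():
            model = config.age_models.get(name)
            if model is not None and k:
                ages[start : start + k] = _truncated_normal(
                    rng, model.mean, model.sd, model.min_age, model.max_age, k
                )
            start += k
    ids = [f"P{i+1:05d}" for i in range(n)]
    return ItemResponseMatrix(
        responses=pd.DataFrame(resp, index=ids, columns=config.item_bank.items),
        ages=pd.Series(ages, index=ids),
        sources=pd.Series(sources, index=ids),
    )


# ---------------------------------------------------------------------------
# Calibration to total-score marginals
# ---------------------------------------------------------------------------


def analytic_score_moments(
    bank: ItemBank,
    theta_mean: float,
    theta_sd: float,
    guessing: float = 0.0,
    n_quadrature: int = 61,
) -> Tuple[float, float]:
    """Mean and SD of the total score under the generating model.

    Integrates over θ ~ Normal(theta_mean, theta_sd²) with Gauss–Hermite
    quadrature. The variance decomposes into the between-person part
    Var_θ[T(θ)] plus the expected binomial part E_θ[Σ P_i(1-P_i)], where
    T(θ) = Σ_i P_i(θ).
    """
    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)
    theta = theta_mean + np.sqrt(2.0) * theta_sd * nodes
    w = weights / np.sqrt(np.pi)
    p = response_probabilities(bank, theta, guessing)  # (q, items)
    t = p.sum(axis=1)
    mean = float(w @ t)
    within = float(w @ (p * (1.0 - p)).sum(axis=1))
    between = float(w @ t**2) - mean**2
    return mean, float(np.sqrt(max(within + between, 0.0)))


def calibrate_to_marginals(
    config: GeneratorConfig,
    target_mean: float,
    target_sd: float,
    tol: float = 1e-4,
    max_iter: int = 200,
) -> GeneratorConfig:
    """Adjust (θ_mean, θ_sd) so analytic score moments hit the targets.

    The item bank is never modified. Deterministic; raises
    :class:`ConvergenceError` (carrying the best achieved moments) if no
    solution is found within ``max_iter`` function evaluations.
    """
    n_items = len(config.item_bank.items)
    if not 0.0 < target_mean < n_items:
        raise ConfigurationError(
            f"target_mean must lie strictly between 0 and {n_items}, got {target_mean}"
        )
    if target_sd <= 0:
        raise ConfigurationError("target_sd must be positive")

    def residual(x):
        mu, log_sigma = x
        m, s = analytic_score_moments(
            config.item_bank, mu, float(np.exp(log_sigma)), config.guessing
        )
        return [m - target_mean, s - target_sd]

    x0 = np.array([config.theta_mean, np.log(config.theta_sd)])
    sol = optimize.root(residual, x0, method="hybr", options={"maxfev": max_iter})
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    m, s = analytic_score_moments(config.item_bank, mu, sigma, config.guessing)
    if abs(m - target_mean) > tol or abs(s - target_sd) > tol:
        raise ConvergenceError(
            f"calibration did not reach tol={tol}: best moments mean={m:.4f}, sd={s:.4f} "
            f"for targets ({target_mean}, {target_sd})",
            best={"theta_mean": mu, "theta_sd": sigma, "mean": m, "sd": s},
        )
    return config.replace(theta_mean=mu, theta_sd=sigma)


# ---------------------------------------------------------------------------
# Defect injection
# ---------------------------------------------------------------------------


@dataclass
class DefectSpec:
    """How many rows get each defect; the affected row sets are pairwise disjoint."""

    n_missing_rows: int = 0
    n_duplicate_rows: int = 0
    n_underage_rows: int = 0

    def __post_init__(self) -> None:
        if min(self.n_missing_rows, self.n_duplicate_rows, self.n_underage_rows) < 0:
            raise ConfigurationError("defect counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_missing_rows + self.n_duplicate_rows + self.n_underage_rows


def inject_defects(
    matrix: ItemResponseMatrix, spec: DefectSpec, seed: int = 0
) -> ItemResponseMatrix:
    """Return a copy of ``matrix`` with the requested defects injected.

    Missing rows get one response cell blanked; duplicate rows are appended as
    exact copies (fresh person_id, identical responses and metadata) so the
    original matrix remains recoverable; under-age rows get an age drawn below
    12.5 years. The three row sets are disjoint, so each injected defect is
    removed by exactly one cleaning rule and the output of
    :func:`ravenshort.data.clean_responses` with ``min_age=12.5`` has
    ``n_input - spec.total`` rows (duplicates both add and remove one row).
    """
    n = matrix.n_persons
    if spec.total > n:
        raise ConfigurationError(
            f"defect spec needs {spec.total} distinct rows but matrix has {n}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    chosen = rng.choice(n, size=spec.total, replace=False)
    miss_rows = chosen[: spec.n_missing_rows]
    dup_rows = chosen[spec.n_missing_rows : spec.n_missing_rows + spec.n_duplicate_rows]
    under_rows = chosen[spec.n_missing_rows + spec.n_duplicate_rows :]

    resp = matrix.responses.copy()
    ages = matrix.ages.copy()
    sources = matrix.sources.copy()
    items = matrix.administered_items

    for r in miss_rows:
        col = items[rng.integers(len(items))]
        resp.iat[r, resp.columns.get_loc(col)] = np.nan
    for r in under_rows:
        ages.iloc[r] = float(rng.uniform(10.0, 12.45))

    if len(dup_rows):
        dup_ids = [f"{resp.index[r]}_dup" for r in dup_rows]
        dup_resp = resp.iloc[dup_rows].set_axis(dup_ids)
        resp = pd.concat([resp, dup_resp])
        ages = pd.concat([ages, ages.iloc[dup_rows].set_axis(dup_ids)])
        sources = pd.concat([sources, sources.iloc[dup_rows].set_axis(dup_ids)])

    return ItemResponseMatrix(resp, ages, sources)
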