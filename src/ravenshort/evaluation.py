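"""Validation apparatus for a selected short form.

Covers the held-out validation correlation, Monte Carlo cross-validation
stability of the selection, a random-subset baseline, Cronbach's alpha, and
floor/ceiling diagnostics of the score distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ItemResponseMatrix, ScoreVector, sum_score
from .errors import (
    ConfigurationError,
    DataError,
    NoSolutionError,
    UndefinedStatisticError,
)
from .pipeline import (
    GridConfig,
    evaluate_candidate,
    grid_search,
    split_development,
)


def validate_form(
    form: Sequence[str],
    validation_matrix: ItemResponseMatrix,
    full_items: Optional[Sequence[str]] = None,
) -> float:
    """Correlation between short-form and full-test sum scores on the untouched validation set."""
    return evaluate_candidate(form, validation_matrix, full_items)


# ---------------------------------------------------------------------------
# Monte Carlo cross-validation stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Per-item selection frequencies over repeated re-splits of the development set."""

    n_iterations: int
    selection_frequency: pd.Series  # item label → proportion of iterations selected
    chosen_forms: List[List[str]]
    n_failed: int = 0  # iterations where the grid produced no form within the cap

    def to_dict(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "selection_frequency": self.selection_frequency.to_dict(),
            "chosen_forms": [list(f) for f in self.chosen_forms],
            "n_failed": self.n_failed,
        }


def monte_carlo_stability(
    dev_matrix: ItemResponseMatrix,
    grid: Optional[GridConfig] = None,
    n_iterations: int = 100,
    master_seed: int = 0,
    max_length: int = 15,
    stratify_by_source: bool = True,
) -> StabilityResult:
    """Re-split the development set ``n_iterations`` times and rerun the grid search.

    The validation partition must already be excluded from ``dev_matrix``.
    Iteration *i* uses the derived seed ``master_seed + i`` so the whole run
    is reproducible from the master seed alone. Iterations whose grid search
    yields no candidate within the cap are counted in ``n_failed`` and
    contribute no selections.
    """
    if n_iterations < 1:
        raise ConfigurationError("n_iterations must be >= 1")
    items = dev_matrix.administered_items
    counts = pd.Series(0.0, index=items)
    forms: List[List[str]] = []
    n_failed = 0
    for i in range(n_iterations):
        train, test = split_development(
            dev_matrix, seed=(master_seed + i) % (2**31), stratify_by_source=stratify_by_source
        )
        try:
            result = grid_search(train, test, grid=grid, max_length=max_length)
        except NoSolutionError:
            n_failed += 1
            forms.append([])
            continue
        forms.append(list(result.chosen.items))
        counts.loc[result.chosen.items] += 1.0
    return StabilityResult(
        n_iterations=n_iterations,
        selection_frequency=counts / n_iterations,
        chosen_forms=forms,
        n_failed=n_failed,
    )


# ---------------------------------------------------------------------------
# Random-subset baseline
# ---------------------------------------------------------------------------


def percentile_outperformed(correlations: Sequence[float], reference: float) -> float:
    """Share of baseline draws strictly below ``reference`` (denominator = all draws)."""
    corr = np.asarray(correlations, dtype=float)
    if corr.size == 0:
        raise DataError("no baseline correlations")
    return float(np.mean(corr < reference))


@dataclass
class BaselineDistribution:
    """Correlations of random k-item subsets with the full test."""

    k: int
    n_draws: int
    correlations: np.ndarray
    subsets: List[List[str]] = field(default_factory=list)
    reference_correlation: Optional[float] = None
    n_redrawn: int = 0

    @property
    def summary(self) -> Dict[str, float]:
        return {
            "mean": float(np.mean(self.correlations)),
            "min": float(np.min(self.correlations)),
            "max": float(np.max(self.correlations)),
        }

    @property
    def percentile_outperformed(self) -> Optional[float]:
        if self.reference_correlation is None:
            return None
        return percentile_outperformed(self.correlations, self.reference_correlation)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_draws": self.n_draws,
            "correlations": [float(c) for c in self.correlations],
            "summary": self.summary,
            "reference_correlation": self.reference_correlation,
            "percentile_outperformed": self.percentile_outperformed,
            "n_redrawn": self.n_redrawn,
        }


def random_subset_baseline(
    eval_matrix: ItemResponseMatrix,
    full_items: Optional[Sequence[str]] = None,
    k: int = 15,
    n_draws: int = 100,
    seed: int = 0,
    reference_correlation: Optional[float] = None,
) -> BaselineDistribution:
    """Correlation distribution of ``n_draws`` uniformly random k-item subsets.

    Subsets are drawn from the administered items (items never administered
    cannot be scored). Draws whose short score has zero variance are redrawn
    and counted in ``n_redrawn``.
    """
    admin = eval_matrix.administered_items
    if k < 1 or k > len(admin):
        raise ConfigurationError(f"k must be in 1..{len(admin)}, got {k}")
    if n_draws < 1:
        raise ConfigurationError("n_draws must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    corrs = np.empty(n_draws)
    subsets: List[List[str]] = []
    n_redrawn = 0
    for d in range(n_draws):
        for _attempt in range(1000):
            pick = [admin[j] for j in rng.choice(len(admin), size=k, replace=False)]
            try:
                corrs[d] = evaluate_candidate(pick, eval_matrix, full_items)
            except UndefinedStatisticError:
                n_redrawn += 1
                continue
            subsets.append(pick)
            break
        else:
            raise UndefinedStatisticError(
                "could not draw a subset with positive score variance"
            )
    return BaselineDistribution(
        k=k,
        n_draws=n_draws,
        correlations=corrs,
        subsets=subsets,
        reference_correlation=reference_correlation,
        n_redrawn=n_redrawn,
    )


# ---------------------------------------------------------------------------
# Cronbach's alpha
# ---------------------------------------------------------------------------


@dataclass
class ReliabilityReport:
    """Cronbach's alpha: (k/(k-1)) * (1 - Σ item variances / total-score variance)."""

    cronbach_alpha: float
    k_items: int
    item_variances: pd.Series
    total_variance: float

    def to_dict(self) -> dict:
        return {
            "cronbach_alpha": self.cronbach_alpha,
            "k_items": self.k_items,
            "item_variances": self.item_variances.to_dict(),
            "total_variance": self.total_variance,
        }


def cronbach_alpha(
    matrix: ItemResponseMatrix, items: Optional[Sequence[str]] = None, ddof: int = 1
) -> ReliabilityReport:
    """Internal-consistency reliability of the sum score over ``items``.

    Variances use the ``ddof`` convention (default n-1) consistently for
    items and total. Requires at least 2 items and nonzero total variance.
    """
    labels = matrix._check_items(list(items) if items is not None else None)
    k = len(labels)
    if k < 2:
        raise DataError(f"Cronbach's alpha needs at least 2 items, got {k}")
    vals = matrix.complete_values(labels).astype(float)
    if len(vals) < 2:
        raise DataError("Cronbach's alpha needs at least 2 persons")
    item_var = vals.var(axis=0, ddof=ddof)
    total_var = vals.sum(axis=1).var(ddof=ddof)
    if total_var == 0.0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    alpha = (k / (k - 1)) * (1.0 - item_var.sum() / total_var)
    return ReliabilityReport(
        cronbach_alpha=float(alpha),
        k_items=k,
        item_variances=pd.Series(item_var, index=labels),
        total_variance=float(total_var),
    )


# ---------------------------------------------------------------------------
# Floor / ceiling diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CeilingReport:
    """Score-distribution diagnostics: histogram, skewness, top-decile mass.

    A strongly left-skewed (negative-skew) distribution with mass piled near
    the maximum indicates a ceiling effect: the test cannot separate
    above-average examinees. ``skewness`` is NaN when the scores are constant
    (fewer than two distinct values), in which case the histogram and decile
    mass are still reported.
    """

    histogram: pd.Series  # index 0..max_possible, probability mass
    skewness: float
    top_decile_mass: float
    max_possible: int
    n: int

    def to_dict(self) -> dict:
        return {
            "histogram": {int(k): float(v) for k, v in self.histogram.items()},
            "skewness": None if np.isnan(self.skewness) else float(self.skewness),
            "top_decile_mass": self.top_decile_mass,
            "max_possible": self.max_possible,
            "n": self.n,
        }


def ceiling_diagnostics(
    scores, max_possible: Optional[int] = None
) -> CeilingReport:
    """Histogram over 0..max_possible, adjusted Fisher–Pearson sample skewness,
    and the probability mass in the top 10% of the scale (score ≥ 0.9·max)."""
    if isinstance(scores, ScoreVector):
        vals = scores.to_numpy().astype(float)
        max_possible = scores.max_possible if max_possible is None else max_possible
    else:
        vals = np.asarray(scores, dtype=float)
        if max_possible is None:
            raise ConfigurationError("max_possible required when scores is a plain array")
    if vals.size == 0:
        raise DataError("no scores")
    if vals.min() < 0 or vals.max() > max_possible:
        raise DataError("scores outside 0..max_possible")
    counts = np.bincount(vals.astype(int), minlength=max_possible + 1)
    hist = pd.Series(counts / vals.size, index=np.arange(max_possible + 1))
    if np.unique(vals).size >= 2:
        skew = float(stats.skew(vals, bias=False))
    else:
        skew = float("nan")
    top = float(np.mean(vals >= 0.9 * max_possible))
    return CeilingReport(
        histogram=hist,
        skewness=skew,
        top_decile_mass=top,
        max_possible=int(max_possible),
        n=int(vals.size),
    )
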