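"""Short-form selection: data splitting, (λ, α) grid search, length sweep.

The procedure: split the cleaned cohort into a development set (80%) and an
untouched validation set (20%); halve the development set into train (40% of
the total) and test (40%). On the train set, regress the full-test sum score
on the item responses with the elastic net at every point of a (λ, α) grid
(defaults λ = 2.0–3.5, α = 0.5–1.0, step 0.05 for both). Each grid point's
surviving items form a candidate short version, scored by the Pearson
correlation between its sum score and the full-test sum score on the test
set. The chosen form is the candidate with the highest test correlation
among those with at most ``max_length`` items (default cap: 15), ties broken
by shorter length, then larger λ, then larger α.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import ItemResponseMatrix, sum_score
from .elasticnet import PenaltySpec, _coordinate_descent, soft_threshold
from .errors import ConfigurationError, DataError, NoSolutionError, UndefinedStatisticError
from .items import is_item_label, sort_items

PARTITIONS = ("train", "test", "validation")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    """person_id → partition label, with the seed and fractions that produced it."""

    labels: pd.Series  # values in {"train", "test", "validation"}
    seed: int
    fractions: Dict[str, float] = field(
        default_factory=lambda: {"train": 0.4, "test": 0.4, "validation": 0.2}
    )

    def ids(self, partition: str) -> List[str]:
        if partition not in PARTITIONS:
            raise ConfigurationError(f"unknown partition {partition!r}")
        return list(self.labels.index[self.labels == partition])

    def sizes(self) -> Dict[str, int]:
        return {p: int((self.labels == p).sum()) for p in PARTITIONS}


def _half_split(ids: List[str], rng: np.random.Generator) -> Tuple[List[str], List[str]]:
    """Shuffle and halve; the first (train) half gets the extra row when odd."""
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_train = (len(perm) + 1) // 2
    return perm[:n_train], perm[n_train:]


def make_splits(
    matrix: ItemResponseMatrix, seed: int, stratify_by_source: bool = True
) -> SplitAssignment:
    """Assign every person to train / test / validation.

    The validation set is drawn first: per source when stratified, with size
    ``ceil(0.2 * source size)`` (this ceiling convention reproduces validation
    sizes 58 from a 289-person cohort and 112+32+55 = 199 from sources of
    557/157/273). The remaining development rows are halved into train and
    test, train taking the extra row when odd. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels = pd.Series(index=matrix.responses.index, dtype=object)
    groups: List[List[str]]
    if stratify_by_source:
        srcs = matrix.sources
        groups = [list(srcs.index[srcs == s]) for s in sorted(srcs.unique())]
    else:
        groups = [matrix.person_ids]
    for ids in groups:
        perm = [ids[i] for i in rng.permutation(len(ids))]
        n_val = math.ceil(0.2 * len(perm))
        val, dev = perm[:n_val], perm[n_val:]
        n_train = (len(dev) + 1) // 2
        labels.loc[val] = "validation"
        labels.loc[dev[:n_train]] = "train"
        labels.loc[dev[n_train:]] = "test"
    assignment = SplitAssignment(labels=labels, seed=seed)
    sizes = assignment.sizes()
    empty = [p for p, n in sizes.items() if n == 0]
    if empty:
        raise DataError(f"partition(s) {empty} would be empty for n={matrix.n_persons}")
    return assignment


def split_matrix(
    matrix: ItemResponseMatrix, assignment: SplitAssignment
) -> Tuple[ItemResponseMatrix, ItemResponseMatrix, ItemResponseMatrix]:
    """Materialize (train, test, validation) sub-matrices."""
    return tuple(matrix.subset_persons(assignment.ids(p)) for p in PARTITIONS)


def split_development(
    dev_matrix: ItemResponseMatrix, seed: int, stratify_by_source: bool = True
) -> Tuple[ItemResponseMatrix, ItemResponseMatrix]:
    """Re-halve a development set into train/test (used by Monte Carlo stability)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if stratify_by_source:
        srcs = dev_matrix.sources
        groups = [list(srcs.index[srcs == s]) for s in sorted(srcs.unique())]
    else:
        groups = [dev_matrix.person_ids]
    train_ids: List[str] = []
    test_ids: List[str] = []
    for ids in groups:
        tr, te = _half_split(ids, rng)
        train_ids.extend(tr)
        test_ids.extend(te)
    if not train_ids or not test_ids:
        raise DataError("development set too small to halve")
    return dev_matrix.subset_persons(train_ids), dev_matrix.subset_persons(test_ids)


# ---------------------------------------------------------------------------
# Candidate scoring
# ---------------------------------------------------------------------------


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2:
        raise UndefinedStatisticError("correlation needs at least 2 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_candidate(
    items: Sequence[str],
    eval_matrix: ItemResponseMatrix,
    full_items: Optional[Sequence[str]] = None,
) -> float:
    """Pearson correlation between the candidate sum score and the full-test sum score."""
    if not items:
        raise DataError("candidate item set is empty")
    short = sum_score(eval_matrix, items).to_numpy().astype(float)
    full = sum_score(eval_matrix, full_items).to_numpy().astype(float)
    return _pearson(short, full)


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridConfig:
    """The (λ, α) grid: inclusive ranges with fixed steps (defaults mirror a
    λ 2.0–3.5 × α 0.5–1.0 sweep at step 0.05)."""

    lambda_min: float = 2.0
    lambda_max: float = 3.5
    lambda_step: float = 0.05
    alpha_min: float = 0.5
    alpha_max: float = 1.0
    alpha_step: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_min < 0 or self.lambda_max < self.lambda_min:
            raise ConfigurationError("invalid lambda range")
        if not (0 <= self.alpha_min <= self.alpha_max <= 1):
            raise ConfigurationError("invalid alpha range")
        if (self.lambda_step <= 0 and self.lambda_max > self.lambda_min) or (
            self.alpha_step <= 0 and self.alpha_max > self.alpha_min
        ):
            raise ConfigurationError("grid steps must be positive")

    @staticmethod
    def _axis(lo: float, hi: float, step: float) -> np.ndarray:
        if hi == lo:
            return np.array([lo])
        n = int(round((hi - lo) / step))
        vals = lo + step * np.arange(n + 1)
        return np.round(vals[vals <= hi + 1e-9], 10)

    @property
    def lambdas(self) -> np.ndarray:
        return self._axis(self.lambda_min, self.lambda_max, self.lambda_step)

    @property
    def alphas(self) -> np.ndarray:
        return self._axis(self.alpha_min, self.alpha_max, self.alpha_step)

    def to_dict(self) -> dict:
        return {
            "lambda_min": self.lambda_min,
            "lambda_max": self.lambda_max,
            "lambda_step": self.lambda_step,
            "alpha_min": self.alpha_min,
            "alpha_max": self.alpha_max,
            "alpha_step": self.alpha_step,
        }


@dataclass
class CandidateForm:
    """An item subset produced at one grid point, with its test-set correlation."""

    items: List[str]
    lambda_: float
    alpha: float
    test_correlation: float

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise DataError("candidate form contains duplicate items")
        if all(is_item_label(i) for i in self.items):
            self.items = sort_items(self.items)

    @property
    def length(self) -> int:
        return len(self.items)

    @property
    def penalty(self) -> PenaltySpec:
        return PenaltySpec(lambda_=self.lambda_, alpha=self.alpha)

    def to_dict(self) -> dict:
        return {
            "items": list(self.items),
            "length": self.length,
            "lambda": self.lambda_,
            "alpha": self.alpha,
            "test_correlation": self.test_correlation,
        }


@dataclass
class SearchResult:
    """Everything the grid sweep produced, plus the chosen short form."""

    all_candidates: List[CandidateForm]
    best_per_length: Dict[int, CandidateForm]
    chosen: CandidateForm
    max_length: int
    grid: GridConfig

    def to_dict(self) -> dict:
        return {
            "max_length": self.max_length,
            "grid": self.grid.to_dict(),
            "chosen": self.chosen.to_dict(),
            "best_per_length": {k: v.to_dict() for k, v in sorted(self.best_per_length.items())},
            "n_candidates": len(self.all_candidates),
        }


def _selection_key(c: CandidateForm):
    # highest test correlation; ties → shorter form, then larger λ, then larger α
    return (c.test_correlation, -c.length, c.lambda_, c.alpha)


def grid_search(
    train_matrix: ItemResponseMatrix,
    test_matrix: ItemResponseMatrix,
    grid: Optional[GridConfig] = None,
    max_length: int = 15,
) -> SearchResult:
    """Sweep the (λ, α) grid and pick the best short form within the length cap.

    For every grid point the elastic net is fitted on the train partition
    (outcome: full-test sum score), the nonzero-coefficient items become a
    candidate form, and the candidate is scored on the test partition.
    Fits are warm-started along descending λ within each α for speed; the
    result is deterministic given the inputs. Raises
    :class:`NoSolutionError` when no candidate has 1..max_length items.
    """
    grid = grid or GridConfig()
    items = train_matrix.administered_items
    if test_matrix.administered_items != items:
        raise DataError("train and test matrices administer different items")
    Xtr = train_matrix.complete_values().astype(float)
    ytr = Xtr.sum(axis=1)
    n, p = Xtr.shape
    if n < 2:
        raise DataError("train partition needs at least 2 persons")

    # standardized Gram quantities, computed once
    x_mean = Xtr.mean(axis=0)
    Xc = Xtr - x_mean
    yc = ytr - ytr.mean()
    sd = np.sqrt((Xc**2).mean(axis=0))
    nonzero = sd > 1e-12
    Xw = np.where(nonzero, Xc / np.where(nonzero, sd, 1.0), 0.0)
    G = Xw.T @ Xw / n
    c = Xw.T @ yc / n
    y_var = float(yc @ yc) / n

    Xte = test_matrix.complete_values().astype(float)
    full_te = Xte.sum(axis=1)
    te_ok = len(full_te) >= 2 and np.std(full_te) > 0

    candidates: List[CandidateForm] = []
    for alpha in grid.alphas:
        beta = None
        for lam in sorted(grid.lambdas, reverse=True):
            beta, _, _, _ = _coordinate_descent(
                G, c, y_var, float(lam), float(alpha), beta, 1e-7, 10_000
            )
            idx = np.flatnonzero(np.abs(beta) > 0)
            if idx.size == 0:
                continue
            short_te = Xte[:, idx].sum(axis=1)
            if te_ok and np.std(short_te) > 0:
                corr = float(np.corrcoef(short_te, full_te)[0, 1])
            else:
                corr = float("nan")
            candidates.append(
                CandidateForm(
                    items=[items[j] for j in idx],
                    lambda_=float(lam),
                    alpha=float(alpha),
                    test_correlation=corr,
                )
            )

    best_per_length: Dict[int, CandidateForm] = {}
    for cand in candidates:
        if math.isnan(cand.test_correlation):
            continue
        cur = best_per_length.get(cand.length)
        if cur is None or _selection_key(cand) > _selection_key(cur):
            best_per_length[cand.length] = cand

    eligible = [
        cand
        for cand in candidates
        if 1 <= cand.length <= max_length and not math.isnan(cand.test_correlation)
    ]
    if not eligible:
        raise NoSolutionError(
            f"no candidate form with 1..{max_length} items found on the grid "
            f"(λ {grid.lambda_min}–{grid.lambda_max}, α {grid.alpha_min}–{grid.alpha_max}); "
            "widen the grid or raise the cap"
        )
    chosen = max(eligible, key=_selection_key)
    return SearchResult(
        all_candidates=candidates,
        best_per_length=best_per_length,
        chosen=chosen,
        max_length=max_length,
        grid=grid,
    )


def length_sweep(
    search_result: SearchResult,
    lengths: Iterable[int] = range(11, 21),
    validation_matrix: Optional[ItemResponseMatrix] = None,
    full_items: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Best candidate per requested length, as a table.

    Columns: length, lambda, alpha, test_correlation and (when a validation
    matrix is supplied) validation_correlation. Lengths with no candidate are
    omitted.
    """
    rows = []
    for length in lengths:
        cand = search_result.best_per_length.get(int(length))
        if cand is None:
            continue
        row = {
            "length": cand.length,
            "lambda": cand.lambda_,
            "alpha": cand.alpha,
            "test_correlation": cand.test_correlation,
        }
        if validation_matrix is not None:
            row["validation_correlation"] = evaluate_candidate(
                cand.items, validation_matrix, full_items
            )
        rows.append(row)
    cols = ["length", "lambda", "alpha", "test_correlation"]
    if validation_matrix is not None:
        cols.append("validation_correlation")
    return pd.DataFrame(rows, columns=cols)
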