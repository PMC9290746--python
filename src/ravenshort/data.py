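"""Person × item response matrices: containers, delimited-text I/O, cleaning, scoring.

The universal currency of the pipeline is an :class:`ItemResponseMatrix`: a
rectangular table of binary (0/1) responses with per-person metadata (an
opaque unique id, an age in decimal years which may be missing, and a
source-dataset identifier). Responses may be explicitly missing before
cleaning; every downstream stage requires a complete matrix.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, ParseError
from .items import ALL_ITEMS, is_item_label, parse_item_label, sort_items

#: metadata columns recognized in delimited response tables
META_COLUMNS = ("person_id", "age", "source")
DEFAULT_SOURCE = "sample"
#: strings treated as a missing response / missing age on input
MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "N/A"}


@dataclass
class PersonRecord:
    """One examinee: identifier, metadata and their item responses.

    ``responses`` maps item label → 0.0, 1.0 or NaN (missing).
    """

    person_id: str
    age: float  # NaN when unknown
    source: str
    responses: Mapping[str, float]


@dataclass
class ItemResponseMatrix:
    """Rectangular persons × items response table with aligned metadata.

    ``responses`` is a float DataFrame indexed by unique person_id with one
    column per administered item (canonical order enforced), values in
    {0.0, 1.0, NaN}. ``ages`` and ``sources`` are Series aligned to the same
    index.
    """

    responses: pd.DataFrame
    ages: pd.Series
    sources: pd.Series

    def __post_init__(self) -> None:
        idx = self.responses.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate person_id values: {dupes[:5]}")
        cols = [parse_item_label(c) for c in self.responses.columns]
        if len(set(cols)) != len(cols):
            raise DataError("duplicate item columns in response matrix")
        ordered = sort_items(cols)
        self.responses = self.responses.set_axis(cols, axis=1)[ordered].astype(float)
        vals = self.responses.to_numpy()
        bad = ~(np.isnan(vals) | (vals == 0.0) | (vals == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataError(
                f"non-binary response {vals[i, j]!r} for person "
                f"{self.responses.index[i]!r}, item {ordered[j]!r}"
            )
        self.ages = pd.Series(self.ages, dtype=float).reindex(idx)
        self.sources = pd.Series(self.sources, dtype=object).reindex(idx).fillna(DEFAULT_SOURCE)

    # -- basic views ---------------------------------------------------------
    @property
    def administered_items(self) -> List[str]:
        return list(self.responses.columns)

    @property
    def n_persons(self) -> int:
        return len(self.responses)

    @property
    def person_ids(self) -> List[str]:
        return list(self.responses.index)

    def is_complete(self) -> bool:
        return not self.responses.isna().to_numpy().any()

    def complete_values(self, items: Optional[Sequence[str]] = None) -> np.ndarray:
        """Integer response array over ``items`` (default: all administered).

        Raises :class:`DataError` if any requested cell is missing.
        """
        items = self._check_items(items)
        block = self.responses[items]
        if block.isna().to_numpy().any():
            raise DataError("matrix contains missing responses; clean it first")
        return block.to_numpy(dtype=np.int64)

    def person(self, person_id: str) -> PersonRecord:
        if person_id not in self.responses.index:
            raise DataError(f"unknown person_id {person_id!r}")
        return PersonRecord(
            person_id=person_id,
            age=float(self.ages.loc[person_id]),
            source=str(self.sources.loc[person_id]),
            responses=self.responses.loc[person_id].to_dict(),
        )

    def _check_items(self, items: Optional[Sequence[str]]) -> List[str]:
        if items is None:
            return self.administered_items
        labels = [parse_item_label(i) for i in items]
        missing = [l for l in labels if l not in self.responses.columns]
        if missing:
            raise DataError(f"items not administered: {missing}")
        return labels

    # -- subsetting ----------------------------------------------------------
    def subset_persons(self, person_ids: Sequence[str]) -> "ItemResponseMatrix":
        ids = list(person_ids)
        unknown = [p for p in ids if p not in self.responses.index]
        if unknown:
            raise DataError(f"unknown person ids: {unknown[:5]}")
        return ItemResponseMatrix(
            self.responses.loc[ids].copy(), self.ages.loc[ids].copy(), self.sources.loc[ids].copy()
        )

    def drop_items(self, items: Sequence[str]) -> "ItemResponseMatrix":
        labels = [parse_item_label(i) for i in items]
        keep = [c for c in self.responses.columns if c not in labels]
        return ItemResponseMatrix(self.responses[keep].copy(), self.ages.copy(), self.sources.copy())

    def equals(self, other: "ItemResponseMatrix") -> bool:
        return (
            self.responses.equals(other.responses)
            and self.ages.equals(other.ages)
            and self.sources.equals(other.sources)
        )

    # -- tabular form --------------------------------------------------------
    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "person_id": self.responses.index,
                "age": self.ages.to_numpy(),
                "source": self.sources.to_numpy(),
            }
        )
        for c in self.responses.columns:
            df[c] = self.responses[c].to_numpy()
        return df


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") > header_line.count(",") else ","


def read_response_table(path, delimiter: Optional[str] = None) -> ItemResponseMatrix:
    """Read a delimited response table (comma default, tab accepted).

    Expected header: ``person_id`` plus item columns A1…E12 (any subset, any
    order), optionally ``age`` and ``source``. Missing cells are written as
    empty strings or ``NA``. Parse failures name the offending row/column.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    if not text.strip():
        raise ParseError(f"{path}: empty response table")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    header = next(reader)
    header = [h.strip() for h in header]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ParseError(f"duplicate header column(s): {dupes}")
    if "person_id" not in header:
        raise ParseError("header must contain a 'person_id' column")
    item_cols: List[Tuple[int, str]] = []
    for k, name in enumerate(header):
        if name in META_COLUMNS:
            continue
        if not is_item_label(name):
            raise ParseError(f"unknown column {name!r}: not metadata and not an item label A1–E12")
        item_cols.append((k, parse_item_label(name)))
    if not item_cols:
        raise ParseError("no item columns found in header")

    pid_k = header.index("person_id")
    age_k = header.index("age") if "age" in header else None
    src_k = header.index("source") if "source" in header else None

    ids, ages, sources, rows = [], [], [], []
    for lineno, row in enumerate(reader, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(f"line {lineno}: expected {len(header)} fields, got {len(row)}")
        pid = row[pid_k].strip()
        if not pid:
            raise ParseError(f"line {lineno}: empty person_id")
        age = np.nan
        if age_k is not None:
            cell = row[age_k].strip()
            if cell not in MISSING_TOKENS:
                try:
                    age = float(cell)
                except ValueError:
                    raise ParseError(f"line {lineno}: non-numeric age {cell!r}") from None
        source = row[src_k].strip() if src_k is not None else DEFAULT_SOURCE
        resp = np.full(len(item_cols), np.nan)
        for slot, (k, label) in enumerate(item_cols):
            cell = row[k].strip()
            if cell in MISSING_TOKENS:
                continue
            if cell in ("0", "1"):
                resp[slot] = float(cell)
            else:
                raise ParseError(
                    f"line {lineno}: non-binary value {cell!r} for person {pid!r}, item {label!r}"
                )
        ids.append(pid)
        ages.append(age)
        sources.append(source or DEFAULT_SOURCE)
        rows.append(resp)

    responses = pd.DataFrame(rows, index=ids, columns=[c for _, c in item_cols])
    try:
        return ItemResponseMatrix(
            responses, pd.Series(ages, index=ids, dtype=float), pd.Series(sources, index=ids)
        )
    except DataError as exc:
        raise ParseError(str(exc)) from exc


def write_response_table(matrix: ItemResponseMatrix, path, delimiter: str = ",") -> None:
    """Write ``matrix`` as UTF-8 delimited text; missing cells become empty strings."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        items = matrix.administered_items
        writer.writerow(["person_id", "age", "source", *items])
        resp = matrix.responses.to_numpy()
        ages = matrix.ages.to_numpy()
        srcs = matrix.sources.to_numpy()
        for i, pid in enumerate(matrix.person_ids):
            age = "" if np.isnan(ages[i]) else repr(float(ages[i]))
            cells = ["" if np.isnan(v) else str(int(v)) for v in resp[i]]
            writer.writerow([pid, age, srcs[i], *cells])


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------


@dataclass
class CleaningReport:
    """Bookkeeping of row/column removals, one rule per count.

    Rules are applied in a fixed order — practice columns, rows with missing
    responses, duplicate rows, under-age rows — so every removed row is
    attributed to exactly one rule and
    ``n_output = n_input - n_missing_removed - n_duplicates_removed - n_underage_removed``.
    """

    n_input: int
    n_missing_removed: int
    n_duplicates_removed: int
    n_underage_removed: int
    n_output: int
    practice_items_dropped: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.n_input,
            self.n_missing_removed,
            self.n_duplicates_removed,
            self.n_underage_removed,
            self.n_output,
        )
        if any(c < 0 for c in counts):
            raise DataError("cleaning counts must be non-negative")
        expected = (
            self.n_input
            - self.n_missing_removed
            - self.n_duplicates_removed
            - self.n_underage_removed
        )
        if self.n_output != expected:
            raise DataError(
                f"cleaning arithmetic violated: {self.n_output} != {expected}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CleaningReport":
        return cls(**json.loads(text))


def clean_responses(
    matrix: ItemResponseMatrix,
    min_age: Optional[float] = None,
    practice_items: Sequence[str] = (),
) -> Tuple[ItemResponseMatrix, CleaningReport]:
    """Apply the exclusion rules and return the surviving matrix plus a report.

    Rule order (fixed): (1) drop practice-item columns; (2) drop rows with any
    missing response; (3) drop duplicate rows — identical responses *and*
    metadata (age, source), keeping the first occurrence; (4) drop rows with
    ``age < min_age``. ``min_age=None`` disables the age filter; rows with an
    unknown age always pass it. Practice items already absent are ignored, so
    cleaning is idempotent.
    """
    practice = [parse_item_label(p) for p in practice_items]
    present = [p for p in practice if p in matrix.responses.columns]
    resp = matrix.responses.drop(columns=present)
    ages, sources = matrix.ages, matrix.sources
    n_input = len(resp)

    if min_age is not None and n_input > 0 and ages.isna().all():
        raise ConfigurationError(
            f"age filter min_age={min_age} requested but no ages are recorded"
        )

    keep = ~resp.isna().any(axis=1)
    n_missing = int((~keep).sum())
    resp, ages, sources = resp[keep], ages[keep], sources[keep]

    with_meta = resp.copy()
    with_meta["__age__"] = ages
    with_meta["__source__"] = sources
    keep = ~with_meta.duplicated(keep="first")
    n_dup = int((~keep).sum())
    resp, ages, sources = resp[keep], ages[keep], sources[keep]

    if min_age is not None:
        keep = ~(ages < min_age)  # NaN ages pass
        n_under = int((~keep).sum())
        resp, ages, sources = resp[keep], ages[keep], sources[keep]
    else:
        n_under = 0

    cleaned = ItemResponseMatrix(resp.copy(), ages.copy(), sources.copy())
    report = CleaningReport(
        n_input=n_input,
        n_missing_removed=n_missing,
        n_duplicates_removed=n_dup,
        n_underage_removed=n_under,
        n_output=cleaned.n_persons,
        practice_items_dropped=present,
    )
    return cleaned, report


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass
class ScoreVector:
    """Per-person integer sum scores over a named item subset."""

    scores: pd.Series  # index person_id, int
    max_possible: int

    def __post_init__(self) -> None:
        self.scores = pd.Series(self.scores).astype(int)
        if self.max_possible < 0:
            raise DataError("max_possible must be non-negative")
        if len(self.scores) and (
            self.scores.min() < 0 or self.scores.max() > self.max_possible
        ):
            raise DataError("scores out of range 0..max_possible")

    def to_numpy(self) -> np.ndarray:
        return self.scores.to_numpy()


def sum_score(matrix: ItemResponseMatrix, items: Optional[Iterable[str]] = None) -> ScoreVector:
    """Sum of responses over ``items`` (default: all administered) per person.

    Requires a complete matrix on the requested items (post-cleaning).
    """
    labels = matrix._check_items(list(items) if items is not None else None)
    vals = matrix.complete_values(labels)
    scores = pd.Series(vals.sum(axis=1), index=matrix.responses.index)
    return ScoreVector(scores=scores, max_possible=len(labels))
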