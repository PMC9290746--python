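"""Item labels for a 60-item progressive-matrices test.

The test has five sets A–E of 12 items each; the canonical ordering is
A1 … A12, B1 … B12, …, E12, which is also the order in which the items
are administered and the order in which all tables and reports list them.
"""

from __future__ import annotations

import re
from typing import Iterable, List

from .errors import ParseError

SET_LETTERS = "ABCDE"
ITEMS_PER_SET = 12

#: All 60 item labels in canonical (administration) order.
ALL_ITEMS: List[str] = [f"{s}{i}" for s in SET_LETTERS for i in range(1, ITEMS_PER_SET + 1)]

_ORDER = {label: k for k, label in enumerate(ALL_ITEMS)}
_LABEL_RE = re.compile(r"^([A-Ea-e])([1-9]|1[0-2])$")


def is_item_label(text: str) -> bool:
    """Return True if ``text`` is a valid item label (case-insensitive)."""
    return bool(_LABEL_RE.match(str(text).strip()))


def parse_item_label(text: str) -> str:
    """Normalize ``text`` to a canonical item label, e.g. ``'b7'`` → ``'B7'``.

    Raises :class:`ParseError` for anything outside A1–E12.
    """
    m = _LABEL_RE.match(str(text).strip())
    if not m:
        raise ParseError(f"invalid item label {text!r}: expected A1–E12")
    return f"{m.group(1).upper()}{int(m.group(2))}"


def set_letter(label: str) -> str:
    """The set (A–E) an item belongs to."""
    return parse_item_label(label)[0]


def item_index(label: str) -> int:
    """The 1-based position of an item within its set."""
    return int(parse_item_label(label)[1:])


def canonical_rank(label: str) -> int:
    """0-based position of ``label`` in the canonical A1…E12 ordering."""
    return _ORDER[parse_item_label(label)]


def sort_items(items: Iterable[str]) -> List[str]:
    """Return ``items`` sorted into canonical set order, validating each label."""
    return sorted((parse_item_label(i) for i in items), key=_ORDER.__getitem__)


def format_item_list(items: Iterable[str]) -> str:
    """Render an item subset in report style: ``"A12, B5, …, E1, and E5"``."""
    labels = sort_items(items)
    if not labels:
        return "(none)"
    if len(labels) == 1:
        return labels[0]
    if len(labels) == 2:
        return f"{labels[0]} and {labels[1]}"
    return ", ".join(labels[:-1]) + f", and {labels[-1]}"
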