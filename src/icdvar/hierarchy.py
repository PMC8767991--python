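"""ICD-10 code normalization and hierarchical grouping.

ICD-10 diagnostic codes are organized in three nested levels of aggregation:

* **chapters** (level 1), broad disease families such as
  ``Neoplasms (C00-D49)``;
* **blocks** (level 2), e.g. ``Hypertensive diseases (I10-I16)``;
* **3-character categories** (level 3), e.g. ``I10`` (essential
  hypertension).

The layout shipped here follows the ICD-10-CM chapter arrangement (separate
``C00-D49`` and ``D50-D89`` chapters) plus the special-purpose chapter
``U00-U85`` used for emergency codes such as ``U07`` (COVID-19).

Ordering of category stems is positional: the leading letter compares
lexicographically and each of the two remaining characters compares with
digits before letters (``'9' < 'A'``), so ``O9A`` sorts after ``O99`` and the
chapter range ``O00-O9A`` behaves as printed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "ICDCode",
    "CodeRange",
    "ICDHierarchy",
    "UNMAPPED",
    "normalize_code",
    "assign_group",
    "load_hierarchy",
    "category_sort_key",
]

#: Label of the catch-all bucket for categories outside every range.
UNMAPPED = "UNMAPPED"


class CodeValidationError(ValueError):
    """Raised for structurally invalid ICD-10 codes or hierarchy tables."""


def _char_value(char: str) -> int:
    """Positional value of a code character: digits 0-9, then letters 10-35."""
    if char.isdigit():
        return int(char)
    return 10 + ord(char) - ord("A")


def category_sort_key(stem: str) -> tuple[str, int, int]:
    """Sort key for a 3-character category stem (digits before letters)."""
    return (stem[0], _char_value(stem[1]), _char_value(stem[2]))


@dataclass(frozen=True)
class ICDCode:
    """A single ICD-10 diagnostic code.

    Attributes
    ----------
    raw:
        The code exactly as supplied (``"e11.9 "``).
    normalized:
        Uppercase alphanumeric form with dots and whitespace stripped
        (``"E119"``).
    category:
        The 3-character category stem (``"E11"``), the unit of level-3
        aggregation.
    """

    raw: str
    normalized: str
    category: str


def normalize_code(raw: str) -> ICDCode:
    """Normalize a raw ICD-10 code string.

    Uppercases, removes dots and whitespace, and validates the structural
    pattern: a leading letter followed by at least two alphanumerics.
    Idempotent: normalizing an already-normalized code returns an equal
    ``ICDCode`` (up to the ``raw`` field).

    Raises
    ------
    CodeValidationError
        If the input is empty, does not start with a letter, or has fewer
        than three leading code characters.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise CodeValidationError(f"empty ICD-10 code: {raw!r}")
    norm = raw.strip().upper().replace(".", "").replace(" ", "")
    if not norm[0].isalpha():
        raise CodeValidationError(f"ICD-10 code must start with a letter: {raw!r}")
    if len(norm) < 3 or not norm.isalnum():
        raise CodeValidationError(f"malformed ICD-10 code: {raw!r}")
    return ICDCode(raw=raw, normalized=norm, category=norm[:3])


@dataclass(frozen=True)
class CodeRange:
    """A contiguous, inclusive range of 3-character categories with a name."""

    start: str
    end: str
    name: str

    def __post_init__(self) -> None:
        for stem in (self.start, self.end):
            if len(stem) != 3 or not stem[0].isalpha() or not stem.isalnum():
                raise CodeValidationError(f"bad range endpoint: {stem!r}")
        if category_sort_key(self.start) > category_sort_key(self.end):
            raise CodeValidationError(f"range start after end: {self.start}-{self.end}")

    @property
    def key(self) -> str:
        """Compact range string used as grouping label, e.g. ``"I10-I16"``.

        Single-category ranges collapse to the bare stem (``"T14"``).
        """
        if self.start == self.end:
            return self.start
        return f"{self.start}-{self.end}"

    @property
    def label(self) -> str:
        """Human-readable name including the range string."""
        return f"{self.name} ({self.key})"

    def __contains__(self, category: str) -> bool:
        return (
            category_sort_key(self.start)
            <= category_sort_key(category)
            <= category_sort_key(self.end)
        )

    def categories(self) -> Iterator[str]:
        """Enumerate the plain letter+2-digit category stems in this range.

        Letter-suffixed stems such as ``O9A`` are not enumerated (they are
        still *contained* in the range); this is only used to pick concrete
        categories, e.g. when simulating cohorts.
        """
        for letter_ord in range(ord(self.start[0]), ord(self.end[0]) + 1):
            letter = chr(letter_ord)
            for num in range(100):
                stem = f"{letter}{num:02d}"
                if stem in self:
                    yield stem


def _check_disjoint(ranges: list[CodeRange], kind: str) -> None:
    ordered = sorted(ranges, key=lambda r: category_sort_key(r.start))
    for prev, cur in zip(ordered, ordered[1:]):
        if category_sort_key(cur.start) <= category_sort_key(prev.end):
            raise CodeValidationError(
                f"overlapping {kind} ranges: {prev.key} and {cur.key}"
            )


@dataclass(frozen=True)
class ICDHierarchy:
    """Validated chapter/block tables with category lookup at three levels."""

    chapters: tuple[CodeRange, ...]
    blocks: tuple[CodeRange, ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        _check_disjoint(list(self.chapters), "chapter")
        _check_disjoint(list(self.blocks), "block")
        for block in self.blocks:
            start_ch = self.chapter_of(block.start)
            end_ch = self.chapter_of(block.end)
            if start_ch is None or start_ch is not end_ch:
                raise CodeValidationError(
                    f"block {block.key} does not lie within a single chapter"
                )

    def chapter_of(self, category: str) -> CodeRange | None:
        """The chapter range containing ``category``, or None."""
        for chapter in self.chapters:
            if category in chapter:
                return chapter
        return None

    def block_of(self, category: str) -> CodeRange | None:
        """The block range containing ``category``, or None."""
        for block in self.blocks:
            if category in block:
                return block
        return None

    def group_key(self, category: str, level: int) -> str:
        """Grouping label for a category stem at a given aggregation level.

        Level 1 returns the chapter range key, level 2 the block range key,
        level 3 the category stem itself. Categories outside every range map
        to :data:`UNMAPPED`. Results are memoized; the lookup is pure.
        """
        if level not in (1, 2, 3):
            raise ValueError(f"aggregation level must be 1, 2 or 3, got {level!r}")
        if level == 3:
            return category
        cached = self._cache.get((category, level))
        if cached is not None:
            return cached
        rng = self.chapter_of(category) if level == 1 else self.block_of(category)
        key = rng.key if rng is not None else UNMAPPED
        self._cache[(category, level)] = key
        return key

    def name_of(self, group_key: str) -> str:
        """Human-readable name for a chapter/block key ('' if unknown)."""
        for rng in (*self.chapters, *self.blocks):
            if rng.key == group_key:
                return rng.name
        return ""

    def parent_key(self, group_key: str, level: int, parent_level: int) -> str:
        """Map a grouping key at ``level`` to its key at a coarser level."""
        if parent_level >= level:
            raise ValueError("parent_level must be coarser (smaller) than level")
        if group_key == UNMAPPED:
            return UNMAPPED
        stem = group_key.split("-")[0]
        return self.group_key(stem, parent_level)


def assign_group(code: ICDCode, level: int, hierarchy: ICDHierarchy) -> str:
    """Grouping label of ``code`` at aggregation level 1 (chapter),
    2 (block) or 3 (category)."""
    return hierarchy.group_key(code.category, level)


def _read_ranges(rows: Iterable[dict]) -> list[CodeRange]:
    return [
        CodeRange(start=r["start"].strip(), end=r["end"].strip(), name=r["label"].strip())
        for r in rows
    ]


def _load_packaged(name: str) -> list[CodeRange]:
    with resources.files("icdvar.data").joinpath(name).open(encoding="utf-8") as fh:
        return _read_ranges(csv.DictReader(fh))


def load_hierarchy(
    source: str | Path | None = None, *, include_special: bool = True
) -> ICDHierarchy:
    """Load the ICD-10 chapter/block hierarchy.

    Parameters
    ----------
    source:
        Optional CSV overriding the embedded tables, with header
        ``level,start,end,label`` where ``level`` is ``chapter`` or
        ``block``. The override must pass the same validation (disjoint
        chapters, blocks nested in chapters).
    include_special:
        Whether to keep the special-purpose chapter ``U00-U85`` (and its
        blocks). On by default because emergency codes like ``U07``
        (COVID-19) occur in pandemic-era visit data.
    """
    if source is None:
        chapters = _load_packaged("icd10_chapters.csv")
        blocks = _load_packaged("icd10_blocks.csv")
    else:
        with open(source, encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
        missing = {"level", "start", "end", "label"} - set(rows[0] if rows else {})
        if missing:
            raise CodeValidationError(f"hierarchy file missing columns: {sorted(missing)}")
        chapters = _read_ranges(r for r in rows if r["level"].strip() == "chapter")
        blocks = _read_ranges(r for r in rows if r["level"].strip() == "block")
    if not include_special:
        chapters = [c for c in chapters if c.start[0] != "U"]
        blocks = [b for b in blocks if b.start[0] != "U"]
    return ICDHierarchy(chapters=tuple(chapters), blocks=tuple(blocks))
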