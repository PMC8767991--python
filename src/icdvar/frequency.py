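"""Term-frequency matrices of diagnosis-code groups over date partitions.

The central object is the :class:`FrequencyMatrix`: rows are named date
partitions (typically the two study years), columns are code groupings at
one aggregation level, and each cell holds the absolute number of code
*occurrences* — a visit with k codes contributes k occurrences, not 1.
Matrices can be restricted to a stratum (modality, specialty, age group,
sex) before counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

from .hierarchy import ICDHierarchy, category_sort_key, UNMAPPED
from .visits import age_group_series, code_counts

__all__ = [
    "Partition",
    "PartitionSpec",
    "StratumFilter",
    "FrequencyMatrix",
    "build_matrix",
    "marginal_totals",
    "top_k",
    "rollup",
]


@dataclass(frozen=True)
class Partition:
    """A named closed-open date interval, e.g. Y2019 = [2019-01-01, 2020-01-01)."""

    name: str
    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not self.start < self.end:
            raise ValueError(f"partition {self.name}: start must precede end")


@dataclass(frozen=True)
class PartitionSpec:
    """An ordered set of pairwise-disjoint named date intervals."""

    partitions: tuple[Partition, ...]

    def __post_init__(self) -> None:
        parts = tuple(self.partitions)
        object.__setattr__(self, "partitions", parts)
        names = [p.name for p in parts]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate partition names: {names}")
        ordered = sorted(parts, key=lambda p: p.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"partitions {a.name} and {b.name} overlap")

    @classmethod
    def years(cls, *years: int) -> "PartitionSpec":
        """Calendar-year partitions named ``Y<year>``."""
        return cls(tuple(
            Partition(f"Y{y}", pd.Timestamp(y, 1, 1), pd.Timestamp(y + 1, 1, 1))
            for y in years
        ))

    def __iter__(self) -> Iterator[Partition]:
        return iter(self.partitions)

    def __len__(self) -> int:
        return len(self.partitions)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.partitions]

    def mask(self, dates: pd.Series, name: str) -> pd.Series:
        """Boolean mask of dates falling in the named partition."""
        part = next(p for p in self.partitions if p.name == name)
        dates = pd.to_datetime(dates)
        return (dates >= part.start) & (dates < part.end)

    def assign(self, dates: pd.Series) -> pd.Series:
        """Partition name per date (NaN for dates outside all partitions)."""
        dates = pd.to_datetime(dates)
        out = pd.Series(pd.NA, index=dates.index, dtype="object")
        for part in self.partitions:
            out[(dates >= part.start) & (dates < part.end)] = part.name
        return out


@dataclass(frozen=True)
class StratumFilter:
    """Optional equality constraints on visit attributes; empty = all visits."""

    modality: str | None = None
    specialty: str | None = None
    age_group: str | None = None
    sex: str | None = None

    def mask(self, visits: pd.DataFrame) -> pd.Series:
        m = pd.Series(True, index=visits.index)
        if self.modality is not None:
            m &= visits["modality"] == self.modality
        if self.specialty is not None:
            m &= visits["specialty"] == self.specialty
        if self.sex is not None:
            m &= visits["sex"] == self.sex
        if self.age_group is not None:
            m &= age_group_series(visits["age"]) == self.age_group
        return m

    @property
    def name(self) -> str:
        parts = [
            f"{k}={v}"
            for k, v in (("modality", self.modality), ("specialty", self.specialty),
                         ("age_group", self.age_group), ("sex", self.sex))
            if v is not None
        ]
        return ",".join(parts) or "all"


def _sorted_columns(columns: Sequence[str]) -> list[str]:
    regular = sorted((c for c in columns if c != UNMAPPED),
                     key=lambda c: category_sort_key(c[:3]))
    return regular + ([UNMAPPED] if UNMAPPED in columns else [])


@dataclass(frozen=True)
class FrequencyMatrix:
    """Partition-by-group table of diagnosis-code occurrence counts.

    Attributes
    ----------
    counts:
        DataFrame indexed by partition name, one column per grouping label.
    level:
        Aggregation level of the columns (1 chapter, 2 block, 3 category).
    stratum:
        The stratum the visits were restricted to before counting.
    n_outside:
        Code occurrences on visits dated outside every partition (excluded
        from the matrix, never silently absorbed).
    """

    counts: pd.DataFrame
    level: int
    stratum: StratumFilter = field(default_factory=StratumFilter)
    n_outside: int = 0

    @property
    def partitions(self) -> list[str]:
        return list(self.counts.index)

    @property
    def groups(self) -> list[str]:
        return list(self.counts.columns)

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def grand_total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def to_tsv(self, path: str | Path) -> None:
        """Serialize counts as TSV with a YAML metadata sidecar."""
        path = Path(path)
        out = self.counts.T
        out.index.name = "group"
        out["total"] = out.sum(axis=1)
        out.to_csv(path, sep="\t")
        meta = {
            "level": self.level,
            "stratum": self.stratum.name,
            "partitions": self.partitions,
            "n_outside": self.n_outside,
        }
        path.with_suffix(path.suffix + ".meta.yaml").write_text(
            yaml.safe_dump(meta, sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        level: int,
        stratum: StratumFilter | None = None,
        n_outside: int = 0,
    ) -> "FrequencyMatrix":
        counts = counts.loc[:, _sorted_columns(counts.columns)]
        return cls(counts=counts, level=level,
                   stratum=stratum or StratumFilter(), n_outside=n_outside)


def build_matrix(
    visits: pd.DataFrame,
    level: int,
    partitions: PartitionSpec,
    hierarchy: ICDHierarchy,
    stratum: StratumFilter | None = None,
    *,
    dedupe_per_visit: bool = False,
) -> FrequencyMatrix:
    """Count code occurrences by partition and grouping label.

    A visit contributes one occurrence per attached code (duplicate codes on
    one visit count separately unless ``dedupe_per_visit``). Visits dated
    outside all partitions are excluded and their occurrences tallied in the
    returned matrix's ``n_outside``.
    """
    stratum = stratum or StratumFilter()
    sub = visits.loc[stratum.mask(visits)]
    part = partitions.assign(sub["date"])
    code_field = sub["codes"].fillna("").astype(str)
    coded = code_field.str.len() > 0

    inside = part.notna() & coded
    n_outside = int(code_counts(sub.loc[part.isna() & coded]).sum())

    zeros = pd.DataFrame(
        0, index=pd.Index(partitions.names, name="partition"), columns=[], dtype=int
    )
    if not inside.any():
        return FrequencyMatrix.from_counts(zeros, level, stratum, n_outside)

    codes = code_field.loc[inside].str.split(";")
    if dedupe_per_visit:
        codes = codes.map(lambda cs: sorted(set(cs)))
    lengths = codes.str.len().to_numpy()
    flat = np.concatenate(codes.to_numpy()) if len(codes) else np.array([], dtype=object)
    part_rep = np.repeat(part.loc[inside].to_numpy(), lengths)

    cats = pd.Series(flat).str.slice(0, 3)
    labels = cats.map(lambda c: hierarchy.group_key(c, level))

    table = pd.crosstab(pd.Series(part_rep, name="partition"), labels)
    table = table.reindex(index=partitions.names, fill_value=0)
    table.index.name = "partition"
    table.columns.name = None
    return FrequencyMatrix.from_counts(table.astype(int), level, stratum, n_outside)


def marginal_totals(matrix: FrequencyMatrix) -> pd.DataFrame:
    """Per-group totals across partitions with percentage of the grand total."""
    totals = matrix.column_totals()
    grand = matrix.grand_total()
    share = 100.0 * totals / grand if grand else totals * np.nan
    return pd.DataFrame({"total": totals.astype(int), "share_pct": share})


def top_k(matrix: FrequencyMatrix, k: int) -> pd.DataFrame:
    """The k most frequent groups with cumulative share of the grand total.

    Sorted by total descending, ties broken lexicographically by group
    label; ``k`` larger than the number of groups returns all of them.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    marg = marginal_totals(matrix).rename_axis("group").reset_index()
    marg = marg.sort_values(["total", "group"], ascending=[False, True],
                            kind="mergesort")
    marg = marg.head(k).set_index("group")
    marg["cumulative_pct"] = marg["share_pct"].cumsum()
    return marg


def rollup(matrix: FrequencyMatrix, hierarchy: ICDHierarchy, to_level: int) -> FrequencyMatrix:
    """Aggregate a matrix to a coarser level through the hierarchy.

    Summing level-3 columns through the block/chapter tables reproduces the
    level-2/level-1 matrices exactly (conservation, UNMAPPED included).
    """
    if to_level >= matrix.level:
        raise ValueError("to_level must be coarser than the matrix level")
    mapping = {g: hierarchy.parent_key(g, matrix.level, to_level) for g in matrix.groups}
    rolled = matrix.counts.T.groupby(mapping).sum().T
    rolled.columns.name = None
    return FrequencyMatrix.from_counts(rolled, to_level, matrix.stratum, matrix.n_outside)
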