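"""Visit-level records: I/O, the coded-visit filter, age groups, and
cohort descriptor tables.

The in-memory container is a pandas DataFrame with one row per visit and
columns ``visit_id, patient_id, date, modality, specialty, sex, age, codes``,
where ``codes`` holds the (possibly empty) delimiter-joined list of ICD-10
codes attached to the visit. One visit can carry several codes and many
visits carry none — diagnostic coding is not mandatory in primary-care
records — so analyses first restrict to *coded* visits (>= 1 code).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hierarchy import CodeValidationError, normalize_code

__all__ = [
    "COLUMNS",
    "MODALITIES",
    "SPECIALTIES",
    "SEXES",
    "AGE_GROUPS",
    "ReadConfig",
    "read_visits",
    "write_visits",
    "filter_coded",
    "assign_age_group",
    "age_group_series",
    "code_counts",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

COLUMNS = ("visit_id", "patient_id", "date", "modality", "specialty", "sex", "age", "codes")

MODALITIES = ("face_to_face", "telemedicine")
SPECIALTIES = ("general_medicine", "nursing", "pediatrics", "other")
SEXES = ("male", "female", "unknown")

#: Age groups: name -> inclusive (low, high) bounds in whole years. The six
#: groups partition the non-negative integers: the nominally overlapping
#: printed definitions (adolescence to 18, youth from 14) are disambiguated
#: to disjoint bins 12-18 / 19-26, and age 60 goes to older_adult.
AGE_GROUPS: Mapping[str, tuple[int, int]] = {
    "early_childhood": (0, 5),
    "childhood": (6, 11),
    "adolescence": (12, 18),
    "youth": (19, 26),
    "adulthood": (27, 59),
    "older_adult": (60, 2**31),
}

_DEFAULT_VALUE_MAPS: dict[str, dict[str, str]] = {
    "modality": {"F2F": "face_to_face", "TM": "telemedicine", "TEL": "telemedicine"},
    "specialty": {"GP": "general_medicine", "GM": "general_medicine", "NUR": "nursing", "PED": "pediatrics"},
    "sex": {"M": "male", "F": "female", "U": "unknown"},
}


@dataclass(frozen=True)
class ReadConfig:
    """How to interpret a visit CSV.

    ``column_map`` renames file columns to the canonical names in
    :data:`COLUMNS`; ``value_maps`` translates categorical spellings
    (``"F2F"`` -> ``"face_to_face"``); ``code_delimiter`` splits the code
    list field; ``on_error`` is ``"raise"`` (fail fast) or ``"skip"``
    (drop invalid rows, counting them).
    """

    column_map: Mapping[str, str] | None = None
    value_maps: Mapping[str, Mapping[str, str]] | None = None
    code_delimiter: str = ";"
    on_error: str = "raise"


def _canonical_values(series: pd.Series, field_name: str, allowed: Sequence[str],
                      value_map: Mapping[str, str]) -> pd.Series:
    out = series.fillna("").astype(str).str.strip()
    out = out.map(lambda v: value_map.get(v, value_map.get(v.upper(), v)))
    out = out.str.lower().replace({"": "unknown" if "unknown" in allowed else ""})
    return out


def read_visits(path: str | Path, config: ReadConfig | None = None) -> pd.DataFrame:
    """Read visit-level records from CSV into the canonical frame.

    Every code in the ``codes`` field is normalized (uppercased, dots
    stripped) on read. Malformed rows (unparseable ISO date, negative age,
    unknown modality, invalid code, duplicate visit id) either abort the
    read or are dropped with a count, per ``config.on_error``. The returned
    frame carries a read report in ``df.attrs["read_report"]``.
    """
    config = config or ReadConfig()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if config.column_map:
        df = df.rename(columns=dict(config.column_map))
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"visit file {path} missing mandatory columns: {sorted(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()

    vmaps = {**_DEFAULT_VALUE_MAPS, **(dict(config.value_maps or {}))}
    df["modality"] = _canonical_values(df["modality"], "modality", MODALITIES, vmaps["modality"])
    df["specialty"] = _canonical_values(df["specialty"], "specialty", SPECIALTIES, vmaps["specialty"])
    df["sex"] = _canonical_values(df["sex"], "sex", SEXES, vmaps["sex"])

    bad = pd.Series(False, index=df.index)
    reasons: dict[str, int] = {}

    def _flag(mask: pd.Series, reason: str) -> None:
        nonlocal bad
        n = int((mask & ~bad).sum())
        if n:
            reasons[reason] = reasons.get(reason, 0) + n
        bad |= mask

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    _flag(dates.isna(), "unparseable date")
    ages = pd.to_numeric(df["age"], errors="coerce")
    _flag(ages.isna() | (ages < 0), "invalid age")
    _flag(~df["modality"].isin(MODALITIES), "unknown modality")
    _flag(~df["specialty"].isin(SPECIALTIES), "unknown specialty")
    _flag(~df["sex"].isin(SEXES), "unknown sex")
    _flag(df["visit_id"].duplicated(keep="first"), "duplicate visit_id")

    def _norm_codes(raw: str) -> str | None:
        raw = raw.strip()
        if not raw:
            return ""
        try:
            parts = [normalize_code(c).normalized for c in raw.split(config.code_delimiter)]
        except CodeValidationError:
            return None
        return ";".join(parts)

    codes = df["codes"].map(_norm_codes)
    _flag(codes.isna(), "invalid ICD-10 code")

    if bad.any():
        detail = ", ".join(f"{k}: {v}" for k, v in reasons.items())
        if config.on_error == "raise":
            raise ValueError(f"{int(bad.sum())} invalid rows in {path} ({detail})")
        logger.warning("skipping %d invalid rows in %s (%s)", int(bad.sum()), path, detail)

    df["date"] = dates
    df["age"] = ages
    df["codes"] = codes
    out = df.loc[~bad].copy()
    out["age"] = out["age"].astype(int)
    out.reset_index(drop=True, inplace=True)
    out.attrs["read_report"] = {
        "n_rows": int(len(df)),
        "n_kept": int(len(out)),
        "n_skipped": int(bad.sum()),
        "reasons": reasons,
    }
    return out


def write_visits(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical visit frame to CSV (ISO dates, ';'-joined codes)."""
    out = df.loc[:, list(COLUMNS)].copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def code_counts(df: pd.DataFrame) -> pd.Series:
    """Number of diagnostic codes attached to each visit."""
    codes = df["codes"].fillna("").astype(str)
    return codes.str.count(";").add(1).where(codes.str.len() > 0, 0).astype(int)


def filter_coded(df: pd.DataFrame, partitions=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to coded visits (>= 1 diagnosis).

    Returns ``(kept, report)`` where ``report`` has one row per partition
    (one ``all`` row when ``partitions`` is None) with the total visit
    count, uncoded count and missing-coding percentage. Idempotent.
    """
    has_code = code_counts(df) > 0
    kept = df.loc[has_code].copy()
    kept.reset_index(drop=True, inplace=True)

    if partitions is None:
        groups = {"all": pd.Series(True, index=df.index)}
    else:
        groups = {p.name: partitions.mask(df["date"], p.name) for p in partitions}
    rows = []
    for name, mask in groups.items():
        total = int(mask.sum())
        uncoded = int((mask & ~has_code).sum())
        rows.append({
            "partition": name,
            "n_visits": total,
            "n_uncoded": uncoded,
            "missing_pct": 100.0 * uncoded / total if total else float("nan"),
        })
    return kept, pd.DataFrame(rows).set_index("partition")


def assign_age_group(age: int) -> str:
    """Age-group name for an integer age in years (>= 0)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    for name, (low, high) in AGE_GROUPS.items():
        if low <= age <= high:
            return name
    raise AssertionError("age groups must cover all non-negative ages")


def age_group_series(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_age_group`."""
    bins = [low for low, _ in AGE_GROUPS.values()] + [np.inf]
    labels = list(AGE_GROUPS)
    return pd.cut(ages, bins=bins, labels=labels, right=False).astype(str)


def _summary_one(df: pd.DataFrame) -> dict[str, tuple[float, float | None]]:
    """Descriptor -> (value, within-family %) for one period's visits."""
    n = len(df)
    out: dict[str, tuple[float, float | None]] = {}
    nan = float("nan")

    def pct(k: float) -> float:
        return 100.0 * k / n if n else nan

    out["patients_total"] = (df["patient_id"].nunique() if n else nan, None)
    out["visits_total"] = (n if n else nan, None)
    for m in MODALITIES:
        k = int((df["modality"] == m).sum())
        out[f"visits_{m}"] = (k, pct(k))
    for s in SPECIALTIES:
        k = int((df["specialty"] == s).sum())
        if s == "other" and k == 0:
            continue
        out[f"visits_{s}"] = (k, pct(k))
    groups = age_group_series(df["age"]) if n else pd.Series(dtype=str)
    for g in AGE_GROUPS:
        k = int((groups == g).sum())
        out[f"visits_{g}"] = (k, pct(k))
    for s in ("male", "female", "unknown"):
        k = int((df["sex"] == s).sum())
        if s == "unknown" and k == 0:
            continue
        out[f"visits_{s}"] = (k, pct(k))
    counts = code_counts(df) if n else pd.Series(dtype=int)
    out["codes_total"] = (int(counts.sum()) if n else nan, None)
    out["codes_per_visit_mean"] = (counts.mean() if n else nan, None)
    out["codes_per_visit_sd"] = (counts.std(ddof=1) if n > 1 else nan, None)
    out["age_mean"] = (df["age"].mean() if n else nan, None)
    out["age_sd"] = (df["age"].std(ddof=1) if n > 1 else nan, None)
    return out


def cohort_summary(df: pd.DataFrame, partitions) -> pd.DataFrame:
    """Cohort descriptor table, one period per column pair.

    For each date partition: counts (or means), within-period percentages
    for the categorical families (modality, specialty, age group, sex), the
    diagnostic-code totals and the codes-per-visit and age moments. With
    exactly two partitions a ``difference_pct`` column reports the relative
    change ``100 * (late - early) / early`` of each descriptor. Empty
    partitions yield NaN descriptors rather than zeros.
    """
    pieces: dict[str, dict] = {}
    for part in partitions:
        sub = df.loc[partitions.mask(df["date"], part.name)]
        pieces[part.name] = _summary_one(sub)
    descriptors = list(next(iter(pieces.values())))
    data: dict[str, list] = {}
    for name, summ in pieces.items():
        data[f"{name}_n"] = [summ.get(d, (float("nan"), None))[0] for d in descriptors]
        data[f"{name}_pct"] = [summ.get(d, (None, None))[1] for d in descriptors]
    table = pd.DataFrame(data, index=pd.Index(descriptors, name="characteristic"))
    names = [p.name for p in partitions]
    if len(names) == 2:
        early, late = (table[f"{names[0]}_n"], table[f"{names[1]}_n"])
        with np.errstate(divide="ignore", invalid="ignore"):
            table["difference_pct"] = 100.0 * (late - early) / early
    return table
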