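"""Published reference tables from the Catalan primary-care study period
(2019 vs 2020) shipped as package data.

The underlying visit registry is not publicly deposited; what the study
printed — the cohort descriptor table, the 21 chapter-level counts per
year, and the stratified top-5 tables for face-to-face and telemedicine
visits — is shipped verbatim as CSV. These tables are the only
machine-checkable ground truth available and double as the calibration
source for the synthetic cohort generator.

Headline counts (visit totals, coded-visit counts) are exposed as module
constants. Note the study printed two slightly different coded-visit
counts in different places; both are kept, each tied to its own ratio.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .frequency import FrequencyMatrix, PartitionSpec, StratumFilter

__all__ = [
    "TOTAL_VISITS",
    "CODED_VISITS",
    "FINAL_CODED_VISITS",
    "TOTAL_CODES",
    "UNCODED_EARLY",
    "VISITS_EARLY",
    "UNCODED_LATE",
    "VISITS_LATE",
    "visit_summary",
    "chapter_counts",
    "face_to_face_top5",
    "telemedicine_top5",
    "chapter_matrix",
    "stratified_matrix",
]

#: Two-year visit total and how many of those carried >= 1 diagnosis.
TOTAL_VISITS = 3_555_799
CODED_VISITS = 2_824_371
#: The slightly smaller coded-visit count quoted for the final database.
FINAL_CODED_VISITS = 2_824_185
#: Diagnostic-code occurrences in the final database.
TOTAL_CODES = 3_921_974
#: Per-year visit totals and visits without any diagnosis.
VISITS_EARLY, UNCODED_EARLY = 1_421_779, 262_460
VISITS_LATE, UNCODED_LATE = 1_402_406, 315_541

EARLY, LATE = "Y2019", "Y2020"


def _read(name: str) -> pd.DataFrame:
    with resources.files("icdvar.data").joinpath(name).open(encoding="utf-8") as fh:
        return pd.read_csv(fh)


def visit_summary() -> pd.DataFrame:
    """Printed cohort descriptors (counts, shares, change %) per year."""
    return _read("catalonia_visit_summary.csv").set_index("characteristic")


def chapter_counts() -> pd.DataFrame:
    """Printed chapter-level (aggregation level 1) code counts per year."""
    return _read("catalonia_chapter_counts.csv").set_index("group")


def face_to_face_top5() -> pd.DataFrame:
    """Printed top-5 variation-index rows for face-to-face visits."""
    return _read("catalonia_face_to_face_top5.csv").set_index("group")


def telemedicine_top5() -> pd.DataFrame:
    """Printed top-5 variation-index rows for telemedicine visits."""
    return _read("catalonia_telemedicine_top5.csv").set_index("group")


def year_partitions() -> PartitionSpec:
    """The two study years as calendar partitions named Y2019/Y2020."""
    return PartitionSpec.years(2019, 2020)


def _matrix_from(table: pd.DataFrame, level: int, stratum: StratumFilter) -> FrequencyMatrix:
    counts = pd.DataFrame(
        {g: {EARLY: int(r["n_2019"]), LATE: int(r["n_2020"])} for g, r in table.iterrows()}
    ).loc[[EARLY, LATE]]
    counts.index.name = "partition"
    return FrequencyMatrix(counts=counts, level=level, stratum=stratum)


def chapter_matrix() -> FrequencyMatrix:
    """The printed 2 x 21 chapter count table as a FrequencyMatrix."""
    return _matrix_from(chapter_counts(), level=1, stratum=StratumFilter())


def stratified_matrix(modality: str) -> FrequencyMatrix:
    """The printed stratified top-5 counts as a (partial) FrequencyMatrix.

    Only the five groups the study printed are present, so variation
    indices recomputed from this matrix are normalized over those five
    groups, not the full table the study used.
    """
    if modality == "face_to_face":
        table = face_to_face_top5()
    elif modality == "telemedicine":
        table = telemedicine_top5()
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return _matrix_from(table, level=1, stratum=StratumFilter(modality=modality))
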