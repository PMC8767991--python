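"""Interannual variation percentages and the variation index.

Given a two-period frequency matrix with counts n(c, t0) and n(c, t1) per
code group c, this module computes:

* the **interannual variation** iav(c) = 100 * (n(c,t1) - n(c,t0)) / n(c,t0),
  the ordinary relative change of the group's count, undefined when the
  baseline is zero; and
* the **variation index** VI(c) = |Δc| / Σ_c' |Δc'| with Δc = n(c,t1) -
  n(c,t0), the relative weight of a group's variation over the total
  absolute interannual variation of all groups in the same table. The VI is
  always computed within the (level, stratum) table being reported and sums
  to 1 whenever any count changed.

Unlike the iav, the VI weights each group's disruption on a common linear
scale: a huge relative swing in a rare code can still carry a tiny index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .frequency import FrequencyMatrix
from .hierarchy import ICDHierarchy

__all__ = [
    "interannual_variation",
    "variation_index",
    "variation_table",
    "scatter_table",
]


def interannual_variation(n_early, n_late):
    """Relative change in percent, ``100 * (n_late - n_early) / n_early``.

    Accepts scalars or arrays. A zero baseline makes the change undefined
    and yields NaN (a sentinel, reported as ``NA`` in tables) rather than
    an error or an arbitrary 0.
    """
    n_early = np.asarray(n_early, dtype=float)
    n_late = np.asarray(n_late, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (n_late - n_early) / n_early
    out = np.where(n_early == 0, np.nan, out)
    return float(out) if out.ndim == 0 else out


def variation_index(deltas) -> np.ndarray:
    """Normalize absolute count changes to the variation index.

    ``VI_c = |Δ_c| / Σ |Δ_c'|`` over exactly the groups supplied. When every
    Δ is zero the index is undefined for all groups (NaN), never 0/0.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return deltas.copy()
    denom = np.abs(deltas).sum()
    if denom == 0:
        return np.full(deltas.shape, np.nan)
    return np.abs(deltas) / denom


def variation_table(
    matrix: FrequencyMatrix,
    sort: str = "by_total",
    hierarchy: ICDHierarchy | None = None,
) -> pd.DataFrame:
    """Per-group variation statistics from a two-partition matrix.

    Columns: the two period counts with their within-period shares, the
    pooled total and share, the absolute change, the interannual variation
    percentage and the variation index (normalized over this matrix's
    groups only). ``sort`` is ``by_total`` (pooled count descending) or
    ``by_index`` (variation index descending); ties break lexicographically
    by group label. Counts and shares are kept at full precision — rounding
    is a rendering concern.
    """
    if len(matrix.partitions) != 2:
        raise ValueError(
            f"variation_table needs exactly 2 partitions, got {matrix.partitions}"
        )
    if sort not in ("by_total", "by_index"):
        raise ValueError(f"unknown sort {sort!r}")
    early_name, late_name = matrix.partitions
    n_early = matrix.counts.loc[early_name]
    n_late = matrix.counts.loc[late_name]
    delta = n_late - n_early
    total = n_early + n_late
    grand = total.sum()

    def share(s: pd.Series) -> pd.Series:
        tot = s.sum()
        return 100.0 * s / tot if tot else s * np.nan

    table = pd.DataFrame({
        "group": matrix.groups,
        "label": [hierarchy.name_of(g) if hierarchy else "" for g in matrix.groups],
        "n_early": n_early.to_numpy(),
        "share_early_pct": share(n_early).to_numpy(),
        "n_late": n_late.to_numpy(),
        "share_late_pct": share(n_late).to_numpy(),
        "total": total.to_numpy(),
        "share_total_pct": (100.0 * total / grand if grand else total * np.nan).to_numpy(),
        "delta": delta.to_numpy(),
        "iav_pct": interannual_variation(n_early.to_numpy(), n_late.to_numpy()),
        "variation_index": variation_index(delta.to_numpy()),
    })
    key = "total" if sort == "by_total" else "variation_index"
    table = table.sort_values([key, "group"], ascending=[False, True],
                              kind="mergesort", na_position="last")
    table.attrs["level"] = matrix.level
    table.attrs["stratum"] = matrix.stratum.name
    table.attrs["partitions"] = matrix.partitions
    return table.reset_index(drop=True)


def scatter_table(matrix: FrequencyMatrix) -> pd.DataFrame:
    """Per-group (n_early, n_late, VI) triples for before-vs-during plots.

    One row per group; groups whose counts did not change lie on the
    identity diagonal of a log-log frequency plot. An empty matrix yields
    an empty table.
    """
    if len(matrix.partitions) != 2:
        raise ValueError("scatter_table needs exactly 2 partitions")
    early_name, late_name = matrix.partitions
    n_early = matrix.counts.loc[early_name]
    n_late = matrix.counts.loc[late_name]
    return pd.DataFrame({
        "group": matrix.groups,
        "n_early": n_early.to_numpy(),
        "n_late": n_late.to_numpy(),
        "variation_index": variation_index((n_late - n_early).to_numpy()),
    })
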