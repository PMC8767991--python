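"""End-to-end orchestration: simulate/load -> filter -> count -> variation
-> deterministic report bundle.

A :class:`RunConfig` (built in code or from YAML) names either an input
visit CSV or a simulate block, the date partitions, the aggregation levels
and strata to compute, and rendering options. :func:`run_pipeline` produces
an in-memory :class:`ReportBundle`; :func:`emit_tables` renders it to
TSV/CSV files whose bytes depend only on the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .frequency import Partition, PartitionSpec, StratumFilter, build_matrix, top_k
from .hierarchy import ICDHierarchy, load_hierarchy
from .synthetic import SyntheticConfig, default_config, generate
from .variation import scatter_table, variation_table
from .visits import cohort_summary, filter_coded, read_visits

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "emit_tables"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """What to analyze and how to report it.

    Exactly one of ``input_path`` / ``simulate`` must be set. ``simulate``
    is either a full :class:`SyntheticConfig` or a scale factor applied to
    the reference-calibrated default configuration.
    """

    input_path: str | None = None
    simulate: SyntheticConfig | None = None
    partitions: PartitionSpec = field(
        default_factory=lambda: PartitionSpec.years(2019, 2020))
    levels: tuple[int, ...] = (1, 2, 3)
    strata: tuple[StratumFilter, ...] = (StratumFilter(),)
    top_k: int = 21
    rounding: int = 2
    seed: int = 0
    hierarchy_path: str | None = None

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")
        if len(self.partitions) == 0:
            raise ValueError("at least one date partition is required")
        for level in self.levels:
            if level not in (1, 2, 3):
                raise ValueError(f"bad aggregation level {level!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        seed = int(raw.get("seed", 0))
        simulate = None
        if "simulate" in raw:
            block = raw["simulate"] or {}
            simulate = default_config(seed=seed, scale=float(block.get("scale", 1.0)))
        if "partitions" in raw:
            spec = PartitionSpec(tuple(
                Partition(p["name"], pd.Timestamp(p["start"]), pd.Timestamp(p["end"]))
                for p in raw["partitions"] or []
            ))
            if len(spec) == 0:
                raise ValueError("config declares an empty partition list")
        else:
            spec = PartitionSpec.years(2019, 2020)
        strata = tuple(
            StratumFilter(**s) for s in raw.get("strata", [{}])
        ) or (StratumFilter(),)
        config = cls(
            input_path=raw.get("input"),
            simulate=simulate,
            partitions=spec,
            levels=tuple(raw.get("levels", (1, 2, 3))),
            strata=strata,
            top_k=int(raw.get("top_k", 21)),
            rounding=int(raw.get("rounding", 2)),
            seed=seed,
            hierarchy_path=raw.get("hierarchy"),
        )
        config.validate()
        return config

    def config_hash(self) -> str:
        blob = repr(self).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All output tables of one run plus the reproducibility manifest."""

    cohort: pd.DataFrame
    coding_report: pd.DataFrame
    variation: dict[tuple[int, str], pd.DataFrame]
    top: dict[tuple[int, str], pd.DataFrame]
    scatter: dict[int, pd.DataFrame]
    manifest: dict


def run_pipeline(config: RunConfig, hierarchy: ICDHierarchy | None = None) -> ReportBundle:
    """Run the full analysis and return the report bundle.

    Stages: obtain visits (simulate or read), cohort descriptors on all
    visits, coded-visit filter, then per (level, stratum): frequency
    matrix, variation table and top-k view; scatter tables per level when
    there are exactly two partitions.
    """
    config.validate()
    hierarchy = hierarchy or load_hierarchy(config.hierarchy_path)

    if config.simulate is not None:
        logger.info("simulating cohort (seed=%d)", config.simulate.seed)
        visits = generate(config.simulate, hierarchy)
    else:
        logger.info("reading visits from %s", config.input_path)
        visits = read_visits(config.input_path)
    logger.info("stage visits: %d rows", len(visits))

    cohort = cohort_summary(visits, config.partitions)
    coded, coding_report = filter_coded(visits, config.partitions)
    logger.info("stage filter_coded: kept %d of %d visits", len(coded), len(visits))

    two_periods = len(config.partitions) == 2
    variation: dict[tuple[int, str], pd.DataFrame] = {}
    top: dict[tuple[int, str], pd.DataFrame] = {}
    scatter: dict[int, pd.DataFrame] = {}
    for level in config.levels:
        for stratum in config.strata:
            matrix = build_matrix(coded, level, config.partitions, hierarchy, stratum)
            top[(level, stratum.name)] = top_k(matrix, config.top_k)
            if two_periods:
                variation[(level, stratum.name)] = variation_table(
                    matrix, sort="by_index", hierarchy=hierarchy)
                if stratum.name == "all":
                    scatter[level] = scatter_table(matrix)
            logger.info("stage matrix level=%d stratum=%s: %d groups",
                        level, stratum.name, len(matrix.groups))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_visits": int(len(visits)),
        "n_coded_visits": int(len(coded)),
        "levels": list(config.levels),
        "strata": [s.name for s in config.strata],
        "partitions": config.partitions.names,
    }
    return ReportBundle(cohort=cohort, coding_report=coding_report,
                        variation=variation, top=top, scatter=scatter,
                        manifest=manifest)


def _render(df: pd.DataFrame, rounding: int) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else f"{v:.{rounding}f}")
    return out


def emit_tables(
    bundle: ReportBundle,
    outdir: str | Path,
    fmt: str = "tsv",
    rounding: int = 2,
) -> list[Path]:
    """Write the bundle to ``outdir`` as TSV or CSV plus a JSON manifest.

    Deterministic: fixed column order and row sort, fixed float rendering
    (``rounding`` decimals, ``NA`` for undefined values). On any error the
    partially written directory is removed.
    """
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def emit(name: str, df: pd.DataFrame, index: bool) -> None:
            path = outdir / f"{name}.{fmt}"
            _render(df, rounding).to_csv(path, sep=sep, index=index)
            written.append(path)

        emit("cohort_summary", bundle.cohort, index=True)
        emit("coding_report", bundle.coding_report, index=True)
        for (level, stratum), table in sorted(bundle.variation.items()):
            emit(f"variation_level{level}_{stratum.replace('=', '-')}", table, index=False)
        for (level, stratum), table in sorted(bundle.top.items()):
            emit(f"top{len(table)}_level{level}_{stratum.replace('=', '-')}", table, index=True)
        for level, table in sorted(bundle.scatter.items()):
            emit(f"scatter_level{level}", table, index=False)

        manifest_path = outdir / "manifest.json"
        manifest = dict(bundle.manifest)
        manifest["files"] = sorted(p.name for p in written)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                                 encoding="utf-8")
        written.append(manifest_path)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise
    return written
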