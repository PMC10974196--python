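"""End-to-end orchestration: compounds → clusters → engine → pKa → reports.

A run resolves, for every compound × functional, the four species of the
dissociation equilibrium (hydroxide and water trimer once per functional
— they are compound-independent), applies the true-minimum filter when
frequencies are available, assembles ΔG_dep and pKa, measures the
reaction-center geometry of the final acid/base structures, and renders
benchmark reports.  Per-species failures (engine errors, imaginary
frequencies, non-convergence) are recorded and the run continues; the
affected table cells stay empty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import paneldata
from .benchmark import BenchmarkTable, RegressionSummary, cost_summary, regression, render_benchmark
from .clusters import EMBED_SEED, ClusterSpec, build_species
from .compounds import Compound, builtin_compounds, load_compounds
from .engines import (
    Engine,
    EngineError,
    LogDirectoryEngine,
    QMResult,
    QMSettings,
    build_mock_engine,
    check_true_minimum,
    run_engine,
)
from .geometry import AnalysisError, ReactionCenterMetrics, reaction_center_metrics
from .pka import PkaRecord, delta_g_dep, records_to_csv
from .structures import write_xyz

__all__ = ["PipelineResult", "RunConfig", "ingest_log_directory", "run_pipeline"]

logger = logging.getLogger("pkadirect")


@dataclass(frozen=True)
class RunConfig:
    """Everything one benchmark run depends on, in one place."""

    compounds: Union[str, Sequence[Compound]] = "builtin"  # "builtin", CSV path, or objects
    functionals: tuple[str, ...] = paneldata.FUNCTIONALS
    engine: Union[str, Engine] = "mock"  # "mock", or an engine object
    basis: str = "6-311+G(d,p)"
    solvation: str = "SMD"
    temperature: float = 298.15
    reference_functional: str = "CAM-B3LYP"
    outdir: Optional[str] = None
    seed: int = EMBED_SEED
    report_formats: tuple[str, ...] = ("csv", "markdown", "json")

    def __post_init__(self) -> None:
        if not self.functionals:
            raise ValueError("functionals list must be non-empty")
        object.__setattr__(self, "functionals", tuple(self.functionals))
        object.__setattr__(self, "report_formats", tuple(self.report_formats))


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    table: BenchmarkTable
    records: list[PkaRecord]
    metrics: dict[str, dict[str, dict[str, ReactionCenterMetrics]]]  # functional -> compound -> kind
    statuses: list[dict]  # per species×functional status lines
    species_results: dict[tuple[str, str], QMResult]  # (label, functional) -> result


def ingest_log_directory(path: str | Path, manifest: Mapping) -> LogDirectoryEngine:
    """Engine serving parsed results from a directory of engine logs.

    ``manifest`` maps species label (``acid:<name>``, ``base:<name>``,
    ``hydroxide``, ``water``) to a log filename, or to a
    ``{functional: filename}`` map.
    """
    return LogDirectoryEngine(path, manifest)


def _resolve_compounds(source: Union[str, Sequence[Compound]]) -> list[Compound]:
    if isinstance(source, str):
        return builtin_compounds() if source == "builtin" else load_compounds(source)
    return list(source)


def _resolve_engine(engine: Union[str, Engine]) -> Engine:
    if isinstance(engine, str):
        if engine == "mock":
            return build_mock_engine(paneldata.CALCULATED_PKA)
        raise ValueError(f"unknown engine name {engine!r}; use 'mock' or pass an engine object")
    return engine


def _species_ok(result: QMResult, label: str, functional: str, statuses: list[dict]) -> bool:
    """Converged and (when frequencies are reported) a true minimum."""
    if not result.converged:
        statuses.append({"species": label, "functional": functional,
                         "status": "failed", "reason": "not converged"})
        return False
    if result.frequencies is not None and not check_true_minimum(result):
        statuses.append({"species": label, "functional": functional,
                         "status": "excluded", "reason": "imaginary frequency (not a true minimum)"})
        return False
    statuses.append({"species": label, "functional": functional, "status": "ok",
                     "reason": ""})
    return True


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full direct-approach benchmark described by ``config``."""
    compounds = _resolve_compounds(config.compounds)
    engine = _resolve_engine(config.engine)

    # initial clusters: compound species once each, shared across functionals
    clusters: dict[str, object] = {
        "hydroxide": build_species(ClusterSpec(kind="hydroxide"), config.seed),
        "water": build_species(ClusterSpec(kind="water"), config.seed),
    }
    for compound in compounds:
        for kind in ("acid", "base"):
            cluster = build_species(ClusterSpec(kind=kind, compound=compound), config.seed)
            clusters[cluster.label] = cluster

    statuses: list[dict] = []
    records: list[PkaRecord] = []
    species_results: dict[tuple[str, str], QMResult] = {}
    metrics: dict[str, dict[str, dict[str, ReactionCenterMetrics]]] = {}
    columns: dict[str, list] = {}
    times: dict[str, dict[str, float]] = {}
    n_failures = 0

    for functional in config.functionals:
        settings = QMSettings(
            functional=functional,
            basis=config.basis,
            solvation=config.solvation,
            temperature=config.temperature,
        )
        per_func_times: dict[str, float] = {}

        def _run(label: str) -> Optional[QMResult]:
            nonlocal n_failures
            try:
                result = run_engine(engine, clusters[label], settings)
            except EngineError as exc:
                statuses.append({"species": label, "functional": functional,
                                 "status": "failed", "reason": str(exc)})
                n_failures += 1
                logger.warning("%s / %s: %s", label, functional, exc)
                return None
            species_results[(label, functional)] = result
            per_func_times[label] = result.wall_time
            if not _species_ok(result, label, functional, statuses):
                n_failures += 1
                return None
            logger.info("%s / %s: G = %.6f Eh (%.1f min)",
                        label, functional, result.gibbs_free_energy, result.wall_time)
            return result

        hydroxide = _run("hydroxide")
        water = _run("water")
        metrics[functional] = {}
        column: list = []
        for compound in compounds:
            acid = _run(f"acid:{compound.name}")
            base = _run(f"base:{compound.name}")
            per_compound: dict[str, ReactionCenterMetrics] = {}
            for kind, result in (("acid", acid), ("base", base)):
                if result is not None:
                    try:
                        per_compound[kind] = reaction_center_metrics(result.structure)
                    except AnalysisError as exc:
                        logger.warning("geometry of %s:%s / %s: %s",
                                       kind, compound.name, functional, exc)
            if per_compound:
                metrics[functional][compound.name] = per_compound
            if None in (hydroxide, water, acid, base):
                column.append(None)
                continue
            dg = delta_g_dep(
                base.gibbs_free_energy,
                water.gibbs_free_energy,
                hydroxide.gibbs_free_energy,
                acid.gibbs_free_energy,
            )
            record = PkaRecord(
                compound=compound.name,
                functional=functional,
                delta_g_dep=dg,
                temperature=config.temperature,
            )
            records.append(record)
            column.append(record.pka)
        columns[functional] = column
        times[functional] = per_func_times

    if statuses and all(s["status"] != "ok" for s in statuses):
        raise EngineError("all species failed; no pKa could be assembled")

    regressions: dict[str, RegressionSummary] = {}
    refs = [c.pka_ref for c in compounds]
    for functional, column in columns.items():
        pairs = [(v, r) for v, r in zip(column, refs) if v is not None]
        if len(pairs) >= 3:
            regressions[functional] = regression([v for v, _ in pairs], [r for _, r in pairs])

    pairing = {
        f"acid:{c.name}": f"base:{c.name}"
        for c in compounds
        if all(
            f"{kind}:{c.name}" in times[f]
            for f in config.functionals
            for kind in ("acid", "base")
        )
    }
    cost = cost_summary(times, pairing) if pairing and all(times.values()) else {}

    table = BenchmarkTable(
        compounds=tuple(c.name for c in compounds),
        reference=tuple(refs),
        columns={f: tuple(col) for f, col in columns.items()},
        regression=regressions,
        cost=cost,
    )
    result = PipelineResult(
        table=table,
        records=records,
        metrics=metrics,
        statuses=statuses,
        species_results=species_results,
    )
    if config.outdir is not None:
        _write_outputs(config, result, clusters)
    return result


def _write_outputs(config: RunConfig, result: PipelineResult, clusters: Mapping) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = {"csv": "csv", "markdown": "md", "json": "json"}
    for fmt in config.report_formats:
        (outdir / f"benchmark.{ext[fmt]}").write_text(
            render_benchmark(result.table, fmt), encoding="utf-8"
        )
    (outdir / "pka_records.csv").write_text(records_to_csv(result.records), encoding="utf-8")

    geo_dir = outdir / "geometries"
    geo_dir.mkdir(exist_ok=True)
    for label, cluster in sorted(clusters.items()):
        fname = label.replace(":", "_").replace(" ", "_").replace(",", "") + ".xyz"
        write_xyz(cluster, geo_dir / fname)

    metric_rows = []
    for functional in sorted(result.metrics):
        for compound in sorted(result.metrics[functional]):
            for kind, m in sorted(result.metrics[functional][compound].items()):
                row = {"compound": compound, "functional": functional, "kind": kind,
                       "dihedral_deg": round(m.dihedral, 4)}
                row.update({k: round(v, 4) for k, v in sorted(m.lengths.items())})
                metric_rows.append(row)
    manifest = {
        "config": {
            "functionals": list(config.functionals),
            "engine": config.engine if isinstance(config.engine, str) else type(config.engine).__name__,
            "basis": config.basis,
            "solvation": config.solvation,
            "temperature": config.temperature,
            "reference_functional": config.reference_functional,
            "seed": config.seed,
        },
        "statuses": result.statuses,
        "geometry_metrics": metric_rows,
        "n_records": len(result.records),
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
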