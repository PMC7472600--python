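"""Stage orchestration: simulate -> quantify -> profile -> benchmark -> stats.

Each stage reads/writes plain CSV so runs are inspectable and restartable;
``run_pipeline`` chains them in order, logging per-stage sample counts,
coverage flags and the seed.  For fixed inputs and seed the artifact set is
byte-identical across reruns.
"""

from __future__ import annotations

import logging
import pathlib
from dataclasses import dataclass

from . import io as lio
from .benchmark import export_distributions, parameter_matrix, summarize_cohort
from .config import RunConfig
from .errors import LipidbenchError
from .indexes import full_panel
from .quantitation import fit_calibration, profile_from_peaks
from .stats import run_study
from .synthetic import generate

logger = logging.getLogger(__name__)


@dataclass
class PipelineArtifacts:
    out_dir: pathlib.Path
    profiles_csv: pathlib.Path
    panels_csv: pathlib.Path
    benchmark_csv: pathlib.Path
    benchmark_json: pathlib.Path
    comparisons_csv: pathlib.Path | None
    correlations_csv: pathlib.Path | None


def _stage(name: str):
    def wrap(exc: Exception) -> LipidbenchError:
        return LipidbenchError(f"{name}: {exc}")

    return wrap


def simulate_stage(config: RunConfig, out_dir, seed: int) -> dict[str, pathlib.Path]:
    """Write metadata, standards, peaks and ground-truth profile CSVs."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate(config.simulation, seed=seed, registry=config.registry)
    logger.info("simulate: n=%d cohort drawn with seed %d", len(cohort.metadata), seed)
    paths = {
        "metadata": out / "metadata.csv",
        "standards": out / "standards.csv",
        "peaks": out / "peaks.csv",
        "truth_profiles": out / "truth_profiles.csv",
    }
    lio.write_metadata_csv(cohort.metadata, paths["metadata"])
    assert cohort.tables is not None
    lio.write_standards_csv(cohort.tables.standards, paths["standards"])
    lio.write_peaks_csv(cohort.tables.peak_tables, paths["peaks"])
    lio.write_profiles_csv(cohort.compositions, paths["truth_profiles"], config.registry)
    return paths


def quantify_stage(config: RunConfig, standards_csv, peaks_csv, profiles_csv):
    """Fit per-FA calibrations and quantify every sample to a profile CSV."""
    try:
        standards = lio.read_standards_csv(standards_csv, config.registry)
        tables = lio.read_peaks_csv(peaks_csv, config.registry)
    except LipidbenchError as exc:
        raise _stage("quantify")(exc) from exc
    curves = {
        code: fit_calibration(pts, force_zero_intercept=config.force_zero_intercept)
        for code, pts in standards.items()
    }
    profiles = [
        profile_from_peaks(t, curves, config.registry, config.coverage_threshold)
        for t in tables
    ]
    flagged = sum(not p.coverage_pass for p in profiles)
    logger.info(
        "quantify: %d samples, %d curves, %d coverage-flagged",
        len(profiles),
        len(curves),
        flagged,
    )
    lio.write_profiles_csv(profiles, profiles_csv, config.registry)
    return profiles


def profile_stage(config: RunConfig, profiles, panels_csv):
    panels = [full_panel(p, config.registry) for p in profiles]
    logger.info("profile: %d panels computed", len(panels))
    lio.write_panels_csv(panels, panels_csv)
    return panels


def benchmark_stage(config: RunConfig, profiles, panels, out_dir, plots=False):
    out = pathlib.Path(out_dir)
    bench = summarize_cohort(profiles, panels, config.registry, config.percentile_min_n)
    lio.write_benchmark(bench, out / "benchmark.csv", "csv")
    lio.write_benchmark(bench, out / "benchmark.json", "json")
    matrix = parameter_matrix(profiles, panels, config.registry)
    export_distributions(
        bench, matrix, bins=config.bins, plots_dir=(out / "plots") if plots else None
    )
    logger.info("benchmark: %d interval rows", len(bench))
    return bench


def stats_stage(config: RunConfig, profiles, panels, metadata_csv, out_dir):
    out = pathlib.Path(out_dir)
    try:
        metadata = lio.read_metadata_csv(metadata_csv)
    except LipidbenchError as exc:
        raise _stage("stats")(exc) from exc
    study = run_study(
        profiles,
        panels,
        metadata,
        alpha=config.alpha,
        registry=config.registry,
        pooled_variance=config.pooled_variance,
        fdr=config.fdr,
    )
    lio.write_comparisons_csv(study.comparisons, out / "comparisons.csv")
    lio.write_correlations_csv(study.correlations, out / "correlations.csv")
    logger.info(
        "stats: %d comparisons, %d correlations",
        len(study.comparisons),
        len(study.correlations),
    )
    return study


def run_pipeline(
    config: RunConfig,
    out_dir,
    seed: int = 0,
    simulate: bool = True,
    standards_csv=None,
    peaks_csv=None,
    metadata_csv=None,
    plots: bool = False,
) -> PipelineArtifacts:
    """Execute all stages in order.

    With ``simulate=True`` the raw inputs are generated under ``out_dir``;
    otherwise ``standards_csv``/``peaks_csv`` (and optionally
    ``metadata_csv``) must point at existing files.  Any stage error aborts
    with the stage name and cause.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline: seed=%d out=%s", seed, out)
    if simulate:
        paths = simulate_stage(config, out, seed)
        standards_csv = paths["standards"]
        peaks_csv = paths["peaks"]
        metadata_csv = paths["metadata"]
    else:
        if standards_csv is None or not pathlib.Path(standards_csv).exists():
            raise LipidbenchError("quantify: missing standards")
        if peaks_csv is None or not pathlib.Path(peaks_csv).exists():
            raise LipidbenchError("quantify: missing peaks")
    profiles_csv = out / "profiles.csv"
    panels_csv = out / "panels.csv"
    profiles = quantify_stage(config, standards_csv, peaks_csv, profiles_csv)
    panels = profile_stage(config, profiles, panels_csv)
    benchmark_stage(config, profiles, panels, out, plots=plots)
    comparisons_csv = correlations_csv = None
    if metadata_csv is not None and pathlib.Path(metadata_csv).exists():
        stats_stage(config, profiles, panels, metadata_csv, out)
        comparisons_csv = out / "comparisons.csv"
        correlations_csv = out / "correlations.csv"
    return PipelineArtifacts(
        out_dir=out,
        profiles_csv=profiles_csv,
        panels_csv=panels_csv,
        benchmark_csv=out / "benchmark.csv",
        benchmark_json=out / "benchmark.json",
        comparisons_csv=comparisons_csv,
        correlations_csv=correlations_csv,
    )
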