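"""Healthy-cohort reference benchmark.

For each of the twenty profile parameters (ten fatty-acid percentages plus
ten derived indexes) the benchmark reports the raw minimum-maximum interval
and the median over the cohort — the veterinary "interval values" convention
— with optional nonparametric 2.5/97.5 percentiles when the cohort is large
enough (n >= 40), and per-parameter histogram summaries for distribution
plots.

Minima and maxima are raw order statistics, not robust reference-range
estimators: with raw per-animal data unpublished for comparable cohorts they
are the reproducible quantity, and clinical-chemistry style outlier handling
is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import registry as _registry
from .errors import InsufficientCohortError
from .indexes import PANEL_ORDER, LipidIndexPanel
from .quantitation import CompositionProfile
from .registry import FattyAcidDef

#: Cohort size from which 2.5/97.5 percentiles are added to an interval.
PERCENTILE_MIN_N = 40


@dataclass(frozen=True)
class ReferenceInterval:
    parameter: str
    n: int
    minimum: float
    maximum: float
    median: float
    p2_5: float | None = None
    p97_5: float | None = None


@dataclass(frozen=True)
class DistributionSummary:
    """Histogram plus the annotations drawn on a distribution plot."""

    parameter: str
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    minimum: float
    maximum: float
    median: float
    band_2_5: float
    band_97_5: float


def reference_interval(
    values: Sequence[float], parameter: str, percentile_min_n: int = PERCENTILE_MIN_N
) -> ReferenceInterval:
    """Min/max/median (and percentiles for n >= ``percentile_min_n``).

    NaN entries (e.g. undefined ratios) are dropped; ``n`` reports the
    non-missing count.  Median of an even count is the midpoint of the two
    central order statistics; percentiles use linear interpolation.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise InsufficientCohortError(
            f"insufficient cohort for {parameter}: need >= 2 values, got {arr.size}"
        )
    lo, hi = None, None
    if arr.size >= percentile_min_n:
        lo, hi = (float(v) for v in np.percentile(arr, [2.5, 97.5]))
    return ReferenceInterval(
        parameter=parameter,
        n=int(arr.size),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        median=float(np.median(arr)),
        p2_5=lo,
        p97_5=hi,
    )


def benchmark_parameter_names(
    registry: Sequence[FattyAcidDef] | None = None,
) -> list[str]:
    """Report row order: fatty acids in elution order, then the derived panel."""
    return _registry.cluster_codes(registry) + list(PANEL_ORDER)


def parameter_matrix(
    profiles: Sequence[CompositionProfile],
    panels: Sequence[LipidIndexPanel],
    registry: Sequence[FattyAcidDef] | None = None,
) -> dict[str, np.ndarray]:
    """Per-parameter value vectors over the cohort, in benchmark row order."""
    if len(profiles) != len(panels):
        raise InsufficientCohortError("profiles and panels must pair one-to-one")
    codes = _registry.cluster_codes(registry)
    out: dict[str, np.ndarray] = {}
    for code in codes:
        out[code] = np.array([p.percent[code] for p in profiles], dtype=float)
    for name in PANEL_ORDER:
        out[name] = np.array([getattr(pl, name) for pl in panels], dtype=float)
    return out


def summarize_cohort(
    profiles: Sequence[CompositionProfile],
    panels: Sequence[LipidIndexPanel],
    registry: Sequence[FattyAcidDef] | None = None,
    percentile_min_n: int = PERCENTILE_MIN_N,
) -> list[ReferenceInterval]:
    """One :class:`ReferenceInterval` per parameter, twenty rows in report order."""
    matrix = parameter_matrix(profiles, panels, registry)
    return [
        reference_interval(vals, name, percentile_min_n)
        for name, vals in matrix.items()
    ]


def _histogram(values: np.ndarray, bins: str | int = "fd") -> tuple[np.ndarray, np.ndarray]:
    if values.max() == values.min():
        v = values[0]
        edges = np.array([v - 0.5, v + 0.5])
        return np.array([values.size]), edges
    counts, edges = np.histogram(values, bins=bins)
    return counts, edges


def export_distributions(
    benchmark: Sequence[ReferenceInterval],
    values_by_parameter: Mapping[str, Sequence[float]],
    bins: str | int = "fd",
    plots_dir=None,
) -> dict[str, DistributionSummary]:
    """Histogram data (Freedman-Diaconis bins by default) per parameter.

    Annotates the raw extremes and median as on the benchmark plots, plus a
    nonparametric 2.5-97.5 percentile band (labelled as such; no parametric
    confidence construction is implied).  If ``plots_dir`` is given, one PNG
    per parameter is written as a side effect.
    """
    out: dict[str, DistributionSummary] = {}
    intervals = {ri.parameter: ri for ri in benchmark}
    for name, ri in intervals.items():
        vals = np.asarray(values_by_parameter[name], dtype=float)
        vals = vals[~np.isnan(vals)]
        counts, edges = _histogram(vals, bins)
        lo, hi = (float(v) for v in np.percentile(vals, [2.5, 97.5]))
        out[name] = DistributionSummary(
            parameter=name,
            bin_edges=tuple(float(e) for e in edges),
            counts=tuple(int(c) for c in counts),
            minimum=ri.minimum,
            maximum=ri.maximum,
            median=ri.median,
            band_2_5=lo,
            band_97_5=hi,
        )
    if plots_dir is not None:
        _write_plots(out, plots_dir)
    return out


def _write_plots(summaries: Mapping[str, DistributionSummary], plots_dir) -> None:
    import pathlib

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    directory = pathlib.Path(plots_dir)
    directory.mkdir(parents=True, exist_ok=True)
    for name, s in summaries.items():
        fig, ax = plt.subplots(figsize=(4, 3))
        widths = np.diff(s.bin_edges)
        ax.bar(s.bin_edges[:-1], s.counts, width=widths, align="edge",
               color="#9ecae1", edgecolor="white")
        ax.axvline(s.minimum, color="black", lw=1)
        ax.axvline(s.maximum, color="black", lw=1)
        ax.axvline(s.median, color="green", lw=1.5)
        ax.axvspan(s.band_2_5, s.band_97_5, color="green", alpha=0.08)
        ax.set_title(name)
        ax.set_ylabel("count")
        fig.tight_layout()
        safe = name.replace(":", "_").replace("/", "_")
        fig.savefig(directory / f"{safe}.png", dpi=100)
        plt.close(fig)
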