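"""Derived lipid parameters of the membrane profile.

From the ten closed cluster percentages, ten derived parameters are computed:

* family totals — Total SFA, Total MUFA, PUFA omega-3, PUFA omega-6, Total
  PUFA (sums of the member percentages);
* ratios — SFA/MUFA, omega-6/omega-3, and the PUFA balance
  ``100 * n-3 / total PUFA``;
* the unsaturation index ``UI = sum_i percent_i * ui_weight_i`` (double-bond
  weighted, weights 1-6) and the peroxidation index
  ``PI = sum_i percent_i * pi_weight_i`` (oxidizability weights 0.025-8).

UI and PI are linear in the percentages, so the index of a cohort-mean
composition equals the cohort mean of the per-sample index — the basis for
checking them against published per-sex mean columns.

All functions accept either a :class:`~lipidbench.quantitation.CompositionProfile`
or a plain ``{code: percent}`` mapping (useful for literature values printed
at 2 decimals, whose sum may be 100 +/- a last digit); values are computed at
full precision and rounded only at the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

from . import registry as _registry
from .errors import UndefinedRatioError
from .quantitation import CompositionProfile
from .registry import FattyAcidDef

#: Derived-parameter names in report order (follows the benchmark table).
PANEL_ORDER = (
    "total_sfa",
    "total_mufa",
    "pufa_n3",
    "pufa_n6",
    "total_pufa",
    "sfa_mufa_ratio",
    "n6_n3_ratio",
    "pufa_balance",
    "unsaturation_index",
    "peroxidation_index",
)

_RATIO_NAMES = {
    "sfa_mufa_ratio": "SFA/MUFA",
    "n6_n3_ratio": "omega-6/omega-3",
    "pufa_balance": "PUFA balance",
}


class FamilyTotals(NamedTuple):
    total_sfa: float
    total_mufa: float
    pufa_n3: float
    pufa_n6: float
    total_pufa: float


class Ratios(NamedTuple):
    sfa_mufa_ratio: float
    n6_n3_ratio: float
    pufa_balance: float


@dataclass(frozen=True)
class LipidIndexPanel:
    """The ten derived parameters for one sample.

    Undefined ratios (zero denominator) are carried as ``nan`` rather than
    raised, so cohort summaries can drop them per-parameter; ``missing``
    lists their field names.
    """

    sample_id: str
    total_sfa: float
    total_mufa: float
    pufa_n3: float
    pufa_n6: float
    total_pufa: float
    sfa_mufa_ratio: float
    n6_n3_ratio: float
    pufa_balance: float
    unsaturation_index: float
    peroxidation_index: float

    @property
    def missing(self) -> tuple[str, ...]:
        return tuple(
            name for name in PANEL_ORDER if math.isnan(getattr(self, name))
        )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PANEL_ORDER}


def _percent_map(profile: CompositionProfile | Mapping[str, float]) -> Mapping[str, float]:
    if isinstance(profile, CompositionProfile):
        return profile.percent
    return profile


def family_totals(
    profile: CompositionProfile | Mapping[str, float],
    registry: Sequence[FattyAcidDef] | None = None,
) -> FamilyTotals:
    """Sum member percentages per family (absent members count as zero)."""
    percent = _percent_map(profile)
    sums = {fam: 0.0 for fam in _registry.FAMILIES}
    for fa in registry if registry is not None else _registry.get_cluster():
        sums[fa.family] += percent.get(fa.code, 0.0)
    return FamilyTotals(
        total_sfa=sums["SFA"],
        total_mufa=sums["MUFA"],
        pufa_n3=sums["PUFA_n3"],
        pufa_n6=sums["PUFA_n6"],
        total_pufa=sums["PUFA_n3"] + sums["PUFA_n6"],
    )


def ratios(totals: FamilyTotals) -> Ratios:
    """Family ratios; a zero denominator raises :class:`UndefinedRatioError`."""
    if totals.total_mufa <= 0:
        raise UndefinedRatioError(_RATIO_NAMES["sfa_mufa_ratio"])
    if totals.pufa_n3 <= 0:
        raise UndefinedRatioError(_RATIO_NAMES["n6_n3_ratio"])
    if totals.total_pufa <= 0:
        raise UndefinedRatioError(_RATIO_NAMES["pufa_balance"])
    return Ratios(
        sfa_mufa_ratio=totals.total_sfa / totals.total_mufa,
        n6_n3_ratio=totals.pufa_n6 / totals.pufa_n3,
        pufa_balance=100.0 * totals.pufa_n3 / totals.total_pufa,
    )


def unsaturation_index(
    profile: CompositionProfile | Mapping[str, float],
    registry: Sequence[FattyAcidDef] | None = None,
) -> float:
    """Double-bond-weighted sum of the unsaturated percentages (SFA weigh 0)."""
    percent = _percent_map(profile)
    regs = registry if registry is not None else _registry.get_cluster()
    return math.fsum(percent.get(fa.code, 0.0) * fa.ui_weight for fa in regs)


def peroxidation_index(
    profile: CompositionProfile | Mapping[str, float],
    registry: Sequence[FattyAcidDef] | None = None,
) -> float:
    """Oxidizability-weighted sum of the unsaturated percentages."""
    percent = _percent_map(profile)
    regs = registry if registry is not None else _registry.get_cluster()
    return math.fsum(percent.get(fa.code, 0.0) * fa.pi_weight for fa in regs)


def full_panel(
    profile: CompositionProfile | Mapping[str, float],
    registry: Sequence[FattyAcidDef] | None = None,
    sample_id: str | None = None,
) -> LipidIndexPanel:
    """All ten derived parameters; undefined ratios become ``nan``."""
    totals = family_totals(profile, registry)
    try:
        r = ratios(totals)
    except UndefinedRatioError:
        # compute the definable subset; closure guarantees total_pufa and
        # total_mufa rarely vanish together, so resolve each independently
        sfa_mufa = (
            totals.total_sfa / totals.total_mufa if totals.total_mufa > 0 else math.nan
        )
        n6_n3 = totals.pufa_n6 / totals.pufa_n3 if totals.pufa_n3 > 0 else math.nan
        balance = (
            100.0 * totals.pufa_n3 / totals.total_pufa
            if totals.total_pufa > 0
            else math.nan
        )
        r = Ratios(sfa_mufa, n6_n3, balance)
    if sample_id is None:
        sample_id = (
            profile.sample_id if isinstance(profile, CompositionProfile) else ""
        )
    return LipidIndexPanel(
        sample_id=sample_id,
        total_sfa=totals.total_sfa,
        total_mufa=totals.total_mufa,
        pufa_n3=totals.pufa_n3,
        pufa_n6=totals.pufa_n6,
        total_pufa=totals.total_pufa,
        sfa_mufa_ratio=r.sfa_mufa_ratio,
        n6_n3_ratio=r.n6_n3_ratio,
        pufa_balance=r.pufa_balance,
        unsaturation_index=unsaturation_index(profile, registry),
        peroxidation_index=peroxidation_index(profile, registry),
    )
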