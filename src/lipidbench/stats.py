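"""Normality-gated cohort statistics.

Mirrors the descriptive workflow standard in clinical cohort reports: each
variable is screened with the D'Agostino-Pearson omnibus test (K^2 combining
skewness and kurtosis z-scores, chi-squared with 2 df under normality); a
male-vs-female comparison then uses the unpaired Welch t-test when both
groups look normal and the two-sided Mann-Whitney test otherwise, and
covariate relations use Pearson correlation when both vectors look normal
and Spearman otherwise.  Significance is judged at alpha = 0.05 per test
with no multiplicity correction (Benjamini-Hochberg is available as an
explicit opt-in).

The Mann-Whitney path is exact for small groups (both n <= 8): the two-sided
p-value is computed by full enumeration of the C(n_a + n_b, n_a) group
assignments, with midranks so ties are handled exactly.  Larger groups use
the tie-corrected normal approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .benchmark import benchmark_parameter_names, parameter_matrix
from .errors import (
    DegenerateCorrelationError,
    IncompleteMetadataError,
    InsufficientGroupError,
    SampleTooSmallError,
)
from .indexes import LipidIndexPanel
from .quantitation import CompositionProfile
from .registry import FattyAcidDef

ALPHA_DEFAULT = 0.05

#: Validity floor of the omnibus normality test.
NORMALITY_MIN_N = 20

#: Largest group sizes for which the Mann-Whitney p is computed exactly.
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class DogRecord:
    """Cohort metadata for one animal."""

    sample_id: str
    sex: Literal["M", "F"]
    neutered: bool
    age_months: float
    bodyweight_kg: float
    breed: str = "mixed"

    def __post_init__(self):
        if self.sex not in ("M", "F"):
            raise IncompleteMetadataError(f"{self.sample_id}: sex must be M or F")
        if self.age_months <= 0 or self.bodyweight_kg <= 0:
            raise IncompleteMetadataError(
                f"{self.sample_id}: age and bodyweight must be positive"
            )


class GroupSummary(NamedTuple):
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class NormalityResult:
    statistic: float  # K^2
    p_value: float
    is_normal: bool


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    group_a: GroupSummary
    group_b: GroupSummary
    test_used: Literal["unpaired_t", "mann_whitney"]
    statistic: float
    p_value: float
    significant: bool
    alpha: float = ALPHA_DEFAULT


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    covariate: str
    method: Literal["pearson", "spearman"]
    r: float
    p_value: float
    n: int
    significant: bool = False
    alpha: float = ALPHA_DEFAULT


@dataclass(frozen=True)
class StudyResult:
    comparisons: tuple[ComparisonResult, ...]
    correlations: tuple[CorrelationResult, ...]


def normality_test(values: Sequence[float], alpha: float = ALPHA_DEFAULT) -> NormalityResult:
    """D'Agostino-Pearson omnibus test; requires n >= 20."""
    arr = np.asarray(values, dtype=float)
    if arr.size < NORMALITY_MIN_N:
        raise SampleTooSmallError(
            f"sample too small for omnibus test: n = {arr.size} < {NORMALITY_MIN_N}"
        )
    k2, p = sps.normaltest(arr)
    return NormalityResult(float(k2), float(p), bool(p >= alpha))


def _is_normal(arr: np.ndarray, alpha: float) -> bool:
    """Gate helper: below the validity floor a variable counts as non-normal."""
    if arr.size < NORMALITY_MIN_N or np.std(arr) == 0:
        return False
    return normality_test(arr, alpha).is_normal


def mann_whitney_exact(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration (handles ties).

    Returns ``(U_a, p)`` where ``U_a`` is the U statistic of the first group
    and ``p`` counts assignments at least as extreme in either tail of the
    (symmetric) permutation distribution of U.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    offset = na * (na + 1) / 2.0
    u_obs = float(ranks[:na].sum() - offset)
    lo = min(u_obs, na * nb - u_obs)
    hi = na * nb - lo
    eps = 1e-9
    count = 0
    total = 0
    for idx in itertools.combinations(range(na + nb), na):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if u <= lo + eps or u >= hi - eps:
            count += 1
    return u_obs, min(1.0, count / total)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    parameter: str = "",
    pooled_variance: bool = False,
) -> ComparisonResult:
    """Normality-gated two-sided comparison of two independent groups.

    Both groups normal (testable and passing the omnibus gate) -> unpaired
    t-test, Welch by default (``pooled_variance=True`` for the classical
    equal-variance form).  Otherwise Mann-Whitney: exact enumeration when
    both groups have n <= 8, tie-corrected normal approximation above.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientGroupError(
            f"insufficient group: sizes {a.size}/{b.size}, need >= 3 each"
        )
    summary_a = GroupSummary(a.size, float(a.mean()), float(a.std(ddof=1)))
    summary_b = GroupSummary(b.size, float(b.mean()), float(b.std(ddof=1)))
    if _is_normal(a, alpha) and _is_normal(b, alpha):
        stat, p = sps.ttest_ind(a, b, equal_var=pooled_variance)
        test_used = "unpaired_t"
        stat, p = float(stat), float(p)
    else:
        test_used = "mann_whitney"
        if a.size <= EXACT_MW_MAX_N and b.size <= EXACT_MW_MAX_N:
            stat, p = mann_whitney_exact(a, b)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        parameter=parameter,
        group_a=summary_a,
        group_b=summary_b,
        test_used=test_used,
        statistic=stat,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
    )


def correlate(
    parameter_values: Sequence[float],
    covariate_values: Sequence[float],
    alpha: float = ALPHA_DEFAULT,
    parameter: str = "",
    covariate: str = "",
) -> CorrelationResult:
    """Normality-gated correlation: Pearson if both vectors pass, else Spearman.

    Always reports the *signed* coefficient; two-sided p via the
    t-approximation on r.
    """
    x = np.asarray(parameter_values, dtype=float)
    y = np.asarray(covariate_values, dtype=float)
    if x.size != y.size:
        raise DegenerateCorrelationError("degenerate correlation: unpaired vectors")
    if x.size < 5:
        raise DegenerateCorrelationError(
            f"degenerate correlation: n = {x.size} < 5"
        )
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateCorrelationError("degenerate correlation: constant input")
    if _is_normal(x, alpha) and _is_normal(y, alpha):
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(
        parameter=parameter,
        covariate=covariate,
        method=method,
        r=float(r),
        p_value=float(p),
        n=int(x.size),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up); opt-in extension only."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj


def run_study(
    profiles: Sequence[CompositionProfile],
    panels: Sequence[LipidIndexPanel],
    metadata: Sequence[DogRecord],
    alpha: float = ALPHA_DEFAULT,
    registry: Sequence[FattyAcidDef] | None = None,
    pooled_variance: bool = False,
    fdr: bool = False,
) -> StudyResult:
    """Full cohort sweep: per-parameter M-vs-F comparison and covariate correlations.

    Emits one :class:`ComparisonResult` per parameter (male group first) and
    one :class:`CorrelationResult` per parameter for each of age and
    bodyweight.  NaN parameter values (undefined ratios) are dropped pairwise.
    With ``fdr=True`` significance flags are recomputed on BH-adjusted
    p-values (not part of the reference procedure).
    """
    meta_by_id: Mapping[str, DogRecord] = {m.sample_id: m for m in metadata}
    missing = [p.sample_id for p in profiles if p.sample_id not in meta_by_id]
    if missing:
        raise IncompleteMetadataError(
            f"incomplete metadata: no record for samples {missing[:5]}"
        )
    matrix = parameter_matrix(profiles, panels, registry)
    records = [meta_by_id[p.sample_id] for p in profiles]
    is_male = np.array([m.sex == "M" for m in records])
    ages = np.array([m.age_months for m in records], dtype=float)
    weights = np.array([m.bodyweight_kg for m in records], dtype=float)

    comparisons = []
    correlations = []
    for name in benchmark_parameter_names(registry):
        vals = matrix[name]
        ok = ~np.isnan(vals)
        comparisons.append(
            compare_groups(
                vals[ok & is_male],
                vals[ok & ~is_male],
                alpha=alpha,
                parameter=name,
                pooled_variance=pooled_variance,
            )
        )
        for cov_name, cov in (("age_months", ages), ("bodyweight_kg", weights)):
            correlations.append(
                correlate(
                    vals[ok], cov[ok], alpha=alpha, parameter=name, covariate=cov_name
                )
            )
    if fdr:
        comp_adj = benjamini_hochberg([c.p_value for c in comparisons])
        corr_adj = benjamini_hochberg([c.p_value for c in correlations])
        comparisons = [
            replace(c, significant=bool(q < alpha))
            for c, q in zip(comparisons, comp_adj)
        ]
        correlations = [
            replace(c, significant=bool(q < alpha))
            for c, q in zip(correlations, corr_adj)
        ]
    return StudyResult(tuple(comparisons), tuple(correlations))
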