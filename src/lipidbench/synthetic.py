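"""Synthetic healthy-dog cohorts.

Generates cohorts with the statistical structure of a published healthy
reference population (n = 68; 30 males, 38 females; bodyweight 2.6-43 kg;
age 2-156 months, median ~41), so every pipeline stage is testable without
raw study data:

* covariates — sex counts exact; age and bodyweight drawn from truncated
  lognormals over the stated ranges;
* membrane compositions — an additive-logistic-normal model: a latent
  Gaussian on log abundances, closed to 100% by the softmax-style transform
  ``p_i = 100 * exp(y_i) / sum_j exp(y_j)``.  Positivity and closure hold by
  construction, and the full latent covariance admits injected covariate
  correlations, which a Dirichlet would not;
* raw data — per-FA linear detector responses generate five-level
  calibration standards and per-sample peak tables that round-trip through
  the quantitation stage (exactly, in the noise-free mode).

Latent means/scales and covariate slopes are calibrated numerically
(fixed-seed Monte-Carlo moment matching) so that per-sex closed means and
standard deviations approximate the published per-sex composition columns,
and injected covariate associations reproduce the published correlation
coefficients *as measured by the pipeline's distribution-gated correlation*
(rank correlation for these skewed covariates).  The published family-total
association with bodyweight is carried by an auxiliary stearic-acid slope
calibrated directly on the Total SFA target, since the member-level report
covers palmitic acid only.  Calibration is deterministic and cached per
spec, and is part of the model, not of the per-seed draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from . import registry as _registry
from .errors import InfeasibleSpecError, SchemaError
from .quantitation import CompositionProfile, PeakTable, StandardPoint
from .registry import FattyAcidDef
from .stats import DogRecord

logger = logging.getLogger(__name__)

#: Published per-sex composition columns (mean, sd) in percent of cluster.
#: Raw as printed (each mean column sums to 100.01; rescaled at load when
#: used as generator targets).
TABLE_MALE_MEAN_SD: Mapping[str, tuple[float, float]] = {
    "C16:0": (15.88, 3.52),
    "C16:1": (0.35, 0.27),
    "C18:0": (19.62, 2.45),
    "9c-C18:1": (10.07, 3.31),
    "11c-C18:1": (1.93, 0.35),
    "C18:2": (15.29, 2.65),
    "C20:3": (1.36, 0.35),
    "C20:4": (33.65, 7.06),
    "C20:5": (0.76, 0.39),
    "C22:6": (1.10, 0.61),
}
TABLE_FEMALE_MEAN_SD: Mapping[str, tuple[float, float]] = {
    "C16:0": (15.38, 3.53),
    "C16:1": (0.24, 0.10),
    "C18:0": (21.09, 2.23),
    "9c-C18:1": (9.62, 1.85),
    "11c-C18:1": (2.06, 0.33),
    "C18:2": (14.11, 1.84),
    "C20:3": (1.28, 0.39),
    "C20:4": (34.33, 5.25),
    "C20:5": (0.70, 0.32),
    "C22:6": (1.20, 0.67),
}

#: Published covariate correlations, signed (directions from the report
#: prose; magnitudes as printed).  Parameters are FA codes or family totals.
REPORTED_CORRELATIONS: tuple[tuple[str, str, float], ...] = (
    ("C20:5", "age_months", +0.396),
    ("C16:0", "bodyweight_kg", +0.385),
    ("total_sfa", "bodyweight_kg", +0.402),
    ("C16:1", "bodyweight_kg", +0.326),
    ("C20:4", "bodyweight_kg", -0.257),
    ("pufa_n6", "bodyweight_kg", -0.361),
    ("total_pufa", "bodyweight_kg", -0.347),
    ("unsaturation_index", "bodyweight_kg", -0.301),
    ("peroxidation_index", "bodyweight_kg", -0.256),
)


@dataclass(frozen=True)
class CorrelationTarget:
    """An association injected into the latent model.

    ``parameter`` is what the target is measured on (an FA code or a family
    total); ``inject_on`` is the FA whose latent mean carries the covariate
    slope.  They differ only for family-total targets.
    """

    parameter: str
    covariate: str  # "age_months" | "bodyweight_kg"
    r: float
    inject_on: str


DEFAULT_CORRELATION_TARGETS: tuple[CorrelationTarget, ...] = (
    CorrelationTarget("C20:5", "age_months", +0.396, "C20:5"),
    CorrelationTarget("C16:0", "bodyweight_kg", +0.385, "C16:0"),
    CorrelationTarget("total_sfa", "bodyweight_kg", +0.402, "C18:0"),
    CorrelationTarget("C16:1", "bodyweight_kg", +0.326, "C16:1"),
    CorrelationTarget("C20:4", "bodyweight_kg", -0.257, "C20:4"),
)

_FAMILY_PARAMS = {"total_sfa": "SFA", "total_mufa": "MUFA",
                  "pufa_n3": "PUFA_n3", "pufa_n6": "PUFA_n6"}

_BREEDS = (
    "Labrador Retriever", "German Shepherd", "Golden Retriever", "Beagle",
    "Border Collie", "Boxer", "English Setter", "Jack Russell Terrier",
    "Dachshund", "Maremma Sheepdog",
)


def _targets_tuple(table: Mapping[str, tuple[float, float]]):
    return tuple((code, float(m), float(s)) for code, (m, s) in table.items())


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generator parameters; defaults reproduce the reference study conditions."""

    n: int = 68
    n_female: int = 38
    age_range_months: tuple[float, float] = (2.0, 156.0)
    age_median_months: float = 41.0
    age_log_sigma: float = 0.75
    bodyweight_range_kg: tuple[float, float] = (2.6, 43.0)
    bodyweight_median_kg: float = 10.6  # geometric midpoint of the range
    bodyweight_log_sigma: float = 0.55
    neutered_rate_male: float = 6 / 30
    neutered_rate_female: float = 12 / 38
    mixed_breed_rate: float = 24 / 68
    male_mean_sd: tuple[tuple[str, float, float], ...] = field(
        default_factory=lambda: _targets_tuple(TABLE_MALE_MEAN_SD)
    )
    female_mean_sd: tuple[tuple[str, float, float], ...] = field(
        default_factory=lambda: _targets_tuple(TABLE_FEMALE_MEAN_SD)
    )
    correlation_targets: tuple[CorrelationTarget, ...] = DEFAULT_CORRELATION_TARGETS
    # raw-data (peak table) layer; standards span one decade centered on
    # each FA's typical sample concentration (trace analytes are calibrated
    # near their working range, as in practice)
    standards_levels: int = 5
    standards_rel_noise: float = 0.01
    area_rel_noise: float = 0.005
    coverage_range: tuple[float, float] = (0.975, 0.995)
    total_lipid_range_ug_ml: tuple[float, float] = (50.0, 500.0)

    def __post_init__(self):
        if not (0 <= self.n_female <= self.n):
            raise SchemaError("n_female must lie in [0, n]")
        for sex_targets in (self.male_mean_sd, self.female_mean_sd):
            total = sum(m for _, m, _ in sex_targets)
            if abs(total - 100.0) > 0.5:
                raise SchemaError(
                    f"per-sex mean vector sums to {total:.2f}, outside 100 +/- 0.5"
                )
            if any(m <= 0 or s <= 0 for _, m, s in sex_targets):
                raise SchemaError("target means and sds must be positive")

    def targets(self, sex: str) -> dict[str, tuple[float, float]]:
        """Per-sex (mean, sd) targets rescaled so means sum to exactly 100."""
        raw = self.male_mean_sd if sex == "M" else self.female_mean_sd
        scale = 100.0 / sum(m for _, m, _ in raw)
        return {code: (m * scale, s * scale) for code, m, s in raw}

    def noise_free(self) -> "SyntheticCohortSpec":
        """Copy with all raw-data noise removed (the oracle path)."""
        return replace(self, standards_rel_noise=0.0, area_rel_noise=0.0)

    def null_sex(self) -> "SyntheticCohortSpec":
        """Copy with sex effects zeroed (pooled targets for both sexes)."""
        wm = (self.n - self.n_female) / self.n
        pooled = tuple(
            (code, wm * mm + (1 - wm) * fm, wm * ms + (1 - wm) * fs)
            for (code, mm, ms), (_, fm, fs) in zip(
                self.male_mean_sd, self.female_mean_sd
            )
        )
        return replace(self, male_mean_sd=pooled, female_mean_sd=pooled)


@dataclass(frozen=True)
class SimulatedTables:
    """Raw-data layer: standards, true response lines, per-sample peak tables."""

    standards: Mapping[str, tuple[StandardPoint, ...]]
    true_curves: Mapping[str, tuple[float, float]]  # code -> (slope, intercept)
    peak_tables: tuple[PeakTable, ...]


@dataclass(frozen=True)
class SyntheticCohort:
    metadata: tuple[DogRecord, ...]
    compositions: tuple[CompositionProfile, ...]
    tables: SimulatedTables | None = None


# --------------------------------------------------------------------------
# calibration of the latent additive-logistic-normal model

@dataclass
class _Calibration:
    codes: tuple[str, ...]
    mu_log: dict[str, np.ndarray]      # sex -> (k,)
    sigma_log: dict[str, np.ndarray]   # sex -> (k,)
    beta: np.ndarray                   # (k, 2) slopes on (z_age, z_weight)
    achieved_r: dict[tuple[str, str], float]


_CAL_CACHE: dict[tuple, _Calibration] = {}

_CAL_SEED = 795934202   # fixed: calibration is part of the model definition
_CAL_N = 20000
_CAL_ITER = 40


def _param_values(p: np.ndarray, name: str, codes: Sequence[str],
                  registry: Sequence[FattyAcidDef]) -> np.ndarray:
    """Closed-scale values of an FA code or family-total parameter."""
    if name in codes:
        return p[:, codes.index(name)]
    if name in _FAMILY_PARAMS:
        fam = _FAMILY_PARAMS[name]
        cols = [i for i, fa in enumerate(registry) if fa.family == fam]
        return p[:, cols].sum(axis=1)
    if name == "total_pufa":
        cols = [i for i, fa in enumerate(registry)
                if fa.family in ("PUFA_n3", "PUFA_n6")]
        return p[:, cols].sum(axis=1)
    raise SchemaError(f"unknown correlation-target parameter: {name}")


def _rank_corr(za_rank: np.ndarray, vals: np.ndarray) -> float:
    vr = sps.rankdata(vals)
    return float(np.corrcoef(za_rank, vr)[0, 1])


def _calibrate(spec: SyntheticCohortSpec,
               registry: Sequence[FattyAcidDef]) -> _Calibration:
    codes = tuple(fa.code for fa in registry)
    key = (codes, spec.male_mean_sd, spec.female_mean_sd,
           spec.correlation_targets, spec.n, spec.n_female,
           spec.age_range_months, spec.age_median_months, spec.age_log_sigma,
           spec.bodyweight_range_kg, spec.bodyweight_median_kg,
           spec.bodyweight_log_sigma)
    cached = _CAL_CACHE.get(key)
    if cached is not None:
        return cached

    k = len(codes)
    rng = np.random.default_rng(_CAL_SEED)
    n = _CAL_N
    n_f = int(round(n * spec.n_female / spec.n))
    female = np.zeros(n, dtype=bool)
    female[:n_f] = True
    # covariates drawn exactly as in generation (truncated lognormal, then
    # standardized logs): the rank-correlation estimand depends on the
    # covariate's marginal shape, so calibration must match it
    za = _standardize_log(
        _truncated_lognormal(
            rng, n, spec.age_median_months, spec.age_log_sigma, *spec.age_range_months
        )
    )
    zw = _standardize_log(
        _truncated_lognormal(
            rng, n, spec.bodyweight_median_kg, spec.bodyweight_log_sigma,
            *spec.bodyweight_range_kg,
        )
    )
    eps = rng.standard_normal((n, k))
    za_rank = sps.rankdata(za)
    zw_rank = sps.rankdata(zw)

    targets = {s: spec.targets(s) for s in ("M", "F")}
    mu = {s: np.log([targets[s][c][0] for c in codes]) for s in ("M", "F")}
    sigma = {
        s: np.array([targets[s][c][1] / targets[s][c][0] for c in codes])
        for s in ("M", "F")
    }
    base_scale = 0.5 * (sigma["M"] + sigma["F"])
    beta = np.zeros((k, 2))
    cov_col = {"age_months": 0, "bodyweight_kg": 1}
    for t in spec.correlation_targets:
        j = codes.index(t.inject_on)
        beta[j, cov_col[t.covariate]] += t.r * base_scale[j]

    achieved: dict[tuple[str, str], float] = {}
    for it in range(_CAL_ITER):
        y = np.where(female[:, None], mu["F"], mu["M"]) + eps * np.where(
            female[:, None], sigma["F"], sigma["M"]
        )
        y = y + za[:, None] * beta[:, 0] + zw[:, None] * beta[:, 1]
        e = np.exp(y)
        p = 100.0 * e / e.sum(axis=1, keepdims=True)
        for s, mask in (("F", female), ("M", ~female)):
            m_hat = p[mask].mean(axis=0)
            s_hat = p[mask].std(axis=0, ddof=1)
            t_m = np.array([targets[s][c][0] for c in codes])
            t_s = np.array([targets[s][c][1] for c in codes])
            mu[s] = mu[s] + np.log(t_m / m_hat)
            sigma[s] = sigma[s] * np.clip(t_s / s_hat, 0.5, 2.0) ** 0.9
            if not (np.all(np.isfinite(sigma[s])) and np.all(sigma[s] > 1e-6)):
                raise InfeasibleSpecError(
                    "infeasible spec: latent scale collapsed during calibration"
                )
        for t in spec.correlation_targets:
            vals = _param_values(p, t.parameter, codes, registry)
            zr = za_rank if t.covariate == "age_months" else zw_rank
            r_hat = _rank_corr(zr, vals)
            achieved[(t.parameter, t.covariate)] = r_hat
            j = codes.index(t.inject_on)
            beta[j, cov_col[t.covariate]] += 0.8 * (t.r - r_hat) * base_scale[j]

    for t in spec.correlation_targets:
        r_hat = achieved[(t.parameter, t.covariate)]
        if abs(r_hat - t.r) > 0.05:
            raise InfeasibleSpecError(
                f"infeasible spec: target r={t.r:+.3f} for {t.parameter} vs "
                f"{t.covariate} calibrated only to {r_hat:+.3f}"
            )
    cal = _Calibration(codes, mu, sigma, beta, achieved)
    _CAL_CACHE[key] = cal
    return cal


# --------------------------------------------------------------------------
# generation

def _truncated_lognormal(rng: np.random.Generator, n: int, median: float,
                         log_sigma: float, lo: float, hi: float) -> np.ndarray:
    """Inverse-CDF sampling of a lognormal restricted to [lo, hi]."""
    mu = math.log(median)
    a = sps.norm.cdf((math.log(lo) - mu) / log_sigma)
    b = sps.norm.cdf((math.log(hi) - mu) / log_sigma)
    u = rng.uniform(a, b, size=n)
    return np.exp(mu + log_sigma * sps.norm.ppf(u))


def generate_covariates(
    spec: SyntheticCohortSpec, rng: np.random.Generator
) -> list[DogRecord]:
    """Sex (counts exact), neuter status, age, bodyweight and breed per animal."""
    n = spec.n
    sexes = np.array(["F"] * spec.n_female + ["M"] * (n - spec.n_female))
    rng.shuffle(sexes)
    ages = _truncated_lognormal(
        rng, n, spec.age_median_months, spec.age_log_sigma, *spec.age_range_months
    )
    weights = _truncated_lognormal(
        rng, n, spec.bodyweight_median_kg, spec.bodyweight_log_sigma,
        *spec.bodyweight_range_kg,
    )
    records = []
    for i in range(n):
        sex = str(sexes[i])
        p_neuter = (
            spec.neutered_rate_female if sex == "F" else spec.neutered_rate_male
        )
        neutered = bool(rng.random() < p_neuter)
        if rng.random() < spec.mixed_breed_rate:
            breed = "mixed"
        else:
            breed = str(_BREEDS[rng.integers(len(_BREEDS))])
        records.append(
            DogRecord(
                sample_id=f"dog{i + 1:03d}",
                sex=sex,  # type: ignore[arg-type]
                neutered=neutered,
                age_months=float(ages[i]),
                bodyweight_kg=float(weights[i]),
                breed=breed,
            )
        )
    return records


def _standardize_log(x: np.ndarray) -> np.ndarray:
    lx = np.log(x)
    sd = lx.std(ddof=0)
    if sd == 0:
        return np.zeros_like(lx)
    return (lx - lx.mean()) / sd


def generate_compositions(
    spec: SyntheticCohortSpec,
    covariates: Sequence[DogRecord],
    rng: np.random.Generator,
    registry: Sequence[FattyAcidDef] | None = None,
) -> list[CompositionProfile]:
    """Draw one closed 10-part composition per animal from the latent model.

    Ground-truth profiles carry percentages (closing to 100 within 1e-9
    relative) and nominal quantities equal to the percentages (a 100 ug/mL
    total); the raw-data layer rescales quantities per sample.
    """
    regs = registry if registry is not None else _registry.get_cluster()
    cal = _calibrate(spec, regs)
    codes = cal.codes
    k = len(codes)
    n = len(covariates)
    female = np.array([c.sex == "F" for c in covariates])
    za = _standardize_log(np.array([c.age_months for c in covariates]))
    zw = _standardize_log(np.array([c.bodyweight_kg for c in covariates]))
    eps = rng.standard_normal((n, k))
    y = np.where(female[:, None], cal.mu_log["F"], cal.mu_log["M"]) + eps * np.where(
        female[:, None], cal.sigma_log["F"], cal.sigma_log["M"]
    )
    y = y + za[:, None] * cal.beta[:, 0] + zw[:, None] * cal.beta[:, 1]
    e = np.exp(y)
    p = 100.0 * e / e.sum(axis=1, keepdims=True)
    profiles = []
    for i, rec in enumerate(covariates):
        percent = {c: float(p[i, j]) for j, c in enumerate(codes)}
        profiles.append(
            CompositionProfile(
                sample_id=rec.sample_id,
                quantity_ug_ml=dict(percent),
                percent=percent,
                coverage_fraction=1.0,
                coverage_pass=True,
            )
        )
    return profiles


def make_peak_tables(
    compositions: Sequence[CompositionProfile],
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    registry: Sequence[FattyAcidDef] | None = None,
) -> SimulatedTables:
    """Invert the quantitation stage: standards plus per-sample peak tables.

    Each FA gets a true linear response (slope, intercept drawn per seed) and
    ``standards_levels`` calibration points geometrically spanning the
    standards range, with multiplicative relative noise.  Sample areas apply
    the true line to the true ug/mL quantities (total lipid drawn per sample)
    with their own relative noise, plus a pooled 'other' area placing cluster
    coverage inside ``coverage_range``.  Zero noise makes the quantitation
    round-trip exact.
    """
    regs = registry if registry is not None else _registry.get_cluster()
    codes = [fa.code for fa in regs]
    # typical per-FA concentration: geometric-mean total lipid x cohort mean %
    lo_t, hi_t = spec.total_lipid_range_ug_ml
    typical_total = math.sqrt(lo_t * hi_t)
    wm = (spec.n - spec.n_female) / spec.n
    pooled_pct = {
        code: wm * mm + (1 - wm) * fm
        for (code, mm, _), (_, fm, _) in zip(spec.male_mean_sd, spec.female_mean_sd)
    }
    standards: dict[str, tuple[StandardPoint, ...]] = {}
    true_curves: dict[str, tuple[float, float]] = {}
    for code in codes:
        slope = float(rng.uniform(50.0, 200.0))
        intercept = float(rng.uniform(0.0, 5.0))
        true_curves[code] = (slope, intercept)
        c_typ = typical_total * pooled_pct.get(code, 1.0) / 100.0
        levels = np.geomspace(
            c_typ / math.sqrt(10.0), c_typ * math.sqrt(10.0), spec.standards_levels
        )
        pts = []
        for conc in levels:
            area = slope * conc + intercept
            if spec.standards_rel_noise > 0:
                area *= 1.0 + spec.standards_rel_noise * rng.standard_normal()
            pts.append(StandardPoint(code, float(conc), float(max(area, 1e-9))))
        standards[code] = tuple(pts)
    tables = []
    for prof in compositions:
        total = float(rng.uniform(*spec.total_lipid_range_ug_ml))
        rows = []
        cluster_area = 0.0
        for code in codes:
            q = total * prof.percent[code] / 100.0
            slope, intercept = true_curves[code]
            area = slope * q + intercept
            if spec.area_rel_noise > 0:
                area *= 1.0 + spec.area_rel_noise * rng.standard_normal()
            area = float(max(area, 0.0))
            cluster_area += area
            rows.append((code, area))
        coverage = float(rng.uniform(*spec.coverage_range))
        other = cluster_area * (1.0 / coverage - 1.0)
        rows.append(("other", other))
        tables.append(PeakTable(prof.sample_id, tuple(rows)))
    return SimulatedTables(standards, true_curves, tuple(tables))


def generate(
    spec: SyntheticCohortSpec | None = None,
    seed: int = 0,
    registry: Sequence[FattyAcidDef] | None = None,
    with_tables: bool = True,
) -> SyntheticCohort:
    """Full deterministic cohort draw: metadata, compositions, raw tables."""
    if spec is None:
        spec = SyntheticCohortSpec()
    rng = np.random.default_rng(seed)
    covariates = generate_covariates(spec, rng)
    compositions = generate_compositions(spec, covariates, rng, registry)
    tables = (
        make_peak_tables(compositions, spec, rng, registry) if with_tables else None
    )
    return SyntheticCohort(tuple(covariates), tuple(compositions), tables)
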