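import numpy as np
import pytest

from lipidbench.errors import InfeasibleSpecError
from lipidbench.indexes import family_totals
from lipidbench.quantitation import fit_calibration, profile_from_peaks
from lipidbench.stats import compare_groups, correlate
from lipidbench.synthetic import (
    CorrelationTarget,
    SyntheticCohortSpec,
    generate,
    generate_covariates,
)


class TestCovariates:
    def test_sex_counts_exact(self, default_spec):
        for seed in (0, 1, 99):
            rng = np.random.default_rng(seed)
            records = generate_covariates(default_spec, rng)
            sexes = [r.sex for r in records]
            assert sexes.count("F") == 38
            assert sexes.count("M") == 30

    def test_covariates_within_stated_ranges(self, cohort):
        for r in cohort.metadata:
            assert 2.0 <= r.age_months <= 156.0
            assert 2.6 <= r.bodyweight_kg <= 43.0

    def test_median_age_near_target(self, default_spec):
        medians = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            records = generate_covariates(default_spec, rng)
            medians.append(np.median([r.age_months for r in records]))
        assert np.mean(medians) == pytest.approx(41.0, abs=6.0)

    def test_determinism(self, default_spec):
        a = generate_covariates(default_spec, np.random.default_rng(5))
        b = generate_covariates(default_spec, np.random.default_rng(5))
        assert a == b


class TestCompositions:
    def test_closure_to_100(self, cohort):
        for p in cohort.compositions:
            assert sum(p.percent.values()) == pytest.approx(100.0, rel=1e-9)

    def test_bit_identical_for_same_seed(self, default_spec):
        c1 = generate(default_spec, seed=13, with_tables=False)
        c2 = generate(default_spec, seed=13, with_tables=False)
        assert c1.compositions == c2.compositions
        assert c1.metadata == c2.metadata

    def test_different_seeds_differ(self, default_spec):
        c1 = generate(default_spec, seed=13, with_tables=False)
        c2 = generate(default_spec, seed=14, with_tables=False)
        assert c1.compositions != c2.compositions

    def test_per_sex_means_recover_targets(self, default_spec):
        """Mean composition over many cohorts matches the per-sex targets
        within 2*sd/sqrt(n_sex) per fatty acid."""
        sums = {"M": None, "F": None}
        counts = {"M": 0, "F": 0}
        n_seeds = 100
        for seed in range(n_seeds):
            c = generate(default_spec, seed=seed, with_tables=False)
            for sex in ("M", "F"):
                vecs = [
                    p.percent_vector()
                    for p, m in zip(c.compositions, c.metadata)
                    if m.sex == sex
                ]
                block = np.sum(vecs, axis=0)
                sums[sex] = block if sums[sex] is None else sums[sex] + block
                counts[sex] += len(vecs)
        codes = [fa.code for fa in __import__("lipidbench.registry", fromlist=["get_cluster"]).get_cluster()]
        for sex, n_sex in (("M", 30), ("F", 38)):
            targets = default_spec.targets(sex)
            grand_mean = sums[sex] / counts[sex]
            for j, code in enumerate(codes):
                t_mean, t_sd = targets[code]
                tol = 2.0 * t_sd / np.sqrt(n_sex)
                assert grand_mean[j] == pytest.approx(t_mean, abs=tol), (sex, code)

    def test_infeasible_correlation_rejected(self, registry):
        bad = SyntheticCohortSpec(
            correlation_targets=(
                CorrelationTarget("C20:5", "age_months", 0.999, "C20:5"),
            )
        )
        with pytest.raises(InfeasibleSpecError, match="infeasible spec"):
            generate(bad, seed=0, with_tables=False)


class TestPeakTables:
    def test_noise_free_round_trip_exact(self, noise_free_cohort, quantified):
        for prof, truth in zip(quantified, noise_free_cohort.compositions):
            assert prof.coverage_pass
            for code, expected in truth.percent.items():
                assert prof.percent[code] == pytest.approx(expected, abs=1e-9)

    def test_default_noise_round_trip_error_small(self, default_spec):
        errs = []
        for seed in range(10):
            c = generate(default_spec, seed=300 + seed)
            curves = {
                code: fit_calibration(pts) for code, pts in c.tables.standards.items()
            }
            for table, truth in zip(c.tables.peak_tables, c.compositions):
                prof = profile_from_peaks(table, curves)
                errs.extend(
                    abs(prof.percent[k] - truth.percent[k]) for k in truth.percent
                )
        assert np.quantile(errs, 0.99) < 0.5

    def test_generated_coverage_always_passes(self, cohort):
        curves = {
            code: fit_calibration(pts) for code, pts in cohort.tables.standards.items()
        }
        for table in cohort.tables.peak_tables:
            prof = profile_from_peaks(table, curves)
            assert prof.coverage_pass
            assert 0.97 <= prof.coverage_fraction <= 1.0

    def test_standards_have_requested_levels(self, cohort):
        for code, pts in cohort.tables.standards.items():
            assert len(pts) == 5
            concs = [p.concentration_ug_ml for p in pts]
            assert max(concs) / min(concs) == pytest.approx(10.0, rel=1e-6)


class TestStatisticalStructure:
    def test_injected_correlations_recovered(self, default_spec):
        """Injected covariate associations are recovered by the gated
        correlation operation in the mean over cohorts (tolerance 0.08)."""
        rs_epa, rs_c16, rs_ara = [], [], []
        for seed in range(100):
            c = generate(default_spec, seed=seed, with_tables=False)
            ages = [m.age_months for m in c.metadata]
            wts = [m.bodyweight_kg for m in c.metadata]
            epa = [p.percent["C20:5"] for p in c.compositions]
            c16 = [p.percent["C16:0"] for p in c.compositions]
            ara = [p.percent["C20:4"] for p in c.compositions]
            rs_epa.append(correlate(epa, ages).r)
            rs_c16.append(correlate(c16, wts).r)
            rs_ara.append(correlate(ara, wts).r)
        assert np.mean(rs_epa) == pytest.approx(0.396, abs=0.08)
        assert np.mean(rs_c16) == pytest.approx(0.385, abs=0.08)
        assert np.mean(rs_ara) == pytest.approx(-0.257, abs=0.08)

    def test_null_sex_spec_rejects_at_alpha(self, default_spec):
        """With sex effects zeroed, the M-vs-F comparison rejects at ~5%
        per parameter (pooled over parameters and seeds)."""
        null_spec = default_spec.null_sex()
        rejections = 0
        total = 0
        for seed in range(150):
            c = generate(null_spec, seed=seed, with_tables=False)
            is_m = np.array([m.sex == "M" for m in c.metadata])
            mat = np.array([p.percent_vector() for p in c.compositions])
            totals = np.array(
                [family_totals(p) for p in c.compositions]
            )  # (n, 5) family sums
            values = np.hstack([mat, totals])
            for j in range(values.shape[1]):
                res = compare_groups(values[is_m, j], values[~is_m, j])
                rejections += res.significant
                total += 1
        rate = rejections / total
        assert 0.03 <= rate <= 0.07

    def test_sex_effect_present_by_default(self, default_spec):
        """The default spec separates the sexes on stearic acid (the largest
        injected sex difference) detectably more often than alpha."""
        hits = 0
        for seed in range(60):
            c = generate(default_spec, seed=1000 + seed, with_tables=False)
            is_m = np.array([m.sex == "M" for m in c.metadata])
            vals = np.array([p.percent["C18:0"] for p in c.compositions])
            hits += compare_groups(vals[is_m], vals[~is_m]).significant
        assert hits / 60 > 0.3
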