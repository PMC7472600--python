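import itertools

import numpy as np
import pytest
from scipy import stats as sps

from lipidbench.errors import (
    DegenerateCorrelationError,
    IncompleteMetadataError,
    InsufficientGroupError,
    SampleTooSmallError,
)
from lipidbench.indexes import full_panel
from lipidbench.stats import (
    DogRecord,
    benjamini_hochberg,
    compare_groups,
    correlate,
    mann_whitney_exact,
    normality_test,
    run_study,
)
from lipidbench.synthetic import generate


def oracle_mw_two_sided(a, b):
    """Independent enumeration oracle: fraction of group assignments whose U
    deviates from its null mean at least as much as observed."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    na, nb = len(a), len(b)
    center = na * nb / 2.0
    offset = na * (na + 1) / 2.0
    obs_dev = abs(ranks[: len(a)].sum() - offset - center)
    devs = [
        abs(ranks[list(idx)].sum() - offset - center)
        for idx in itertools.combinations(range(na + nb), na)
    ]
    return sum(d >= obs_dev - 1e-9 for d in devs) / len(devs)


class TestNormality:
    def test_small_sample_rejected(self):
        with pytest.raises(SampleTooSmallError, match="sample too small"):
            normality_test(list(range(10)))

    def test_type_i_error_on_normal_data(self):
        rng = np.random.default_rng(0)
        passes = sum(
            normality_test(rng.standard_normal(500)).is_normal for _ in range(200)
        )
        assert passes >= 0.95 * 200

    def test_power_on_exponential_data(self):
        rng = np.random.default_rng(1)
        rejects = sum(
            not normality_test(rng.exponential(size=500)).is_normal
            for _ in range(200)
        )
        assert rejects >= 0.99 * 200


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.test_used == "mann_whitney"
        assert res.p_value == 1.0
        assert not res.significant

    def test_fully_separated_small_groups(self):
        # 2 of the 20 equally likely assignments are this extreme
        res = compare_groups([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.p_value == pytest.approx(0.1)

    def test_small_group_is_error(self):
        with pytest.raises(InsufficientGroupError, match="insufficient group"):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("na,nb", [(3, 3), (3, 5), (4, 4), (5, 8), (8, 8)])
    def test_exact_path_equals_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 100 + nb)
        for trial in range(5):
            # mixed continuous and tied data
            if trial % 2:
                a = rng.integers(0, 4, size=na).astype(float)
                b = rng.integers(0, 4, size=nb).astype(float)
            else:
                a = rng.normal(size=na)
                b = rng.normal(0.5, size=nb)
            if np.ptp(np.concatenate([a, b])) == 0:
                continue
            _, p = mann_whitney_exact(a, b)
            assert p == pytest.approx(oracle_mw_two_sided(a, b), abs=1e-12)

    @pytest.mark.parametrize("na,nb", [(4, 6), (7, 7)])
    def test_exact_path_equals_scipy_on_tie_free_data(self, na, nb):
        rng = np.random.default_rng(42 + na)
        a, b = rng.normal(size=na), rng.normal(1.0, size=nb)
        _, p = mann_whitney_exact(a, b)
        expected = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(float(expected), abs=1e-12)

    def test_symmetry_under_group_swap(self):
        rng = np.random.default_rng(2)
        for sizes in [(5, 7), (30, 38)]:
            a, b = rng.normal(size=sizes[0]), rng.normal(0.3, size=sizes[1])
            r1 = compare_groups(a, b)
            r2 = compare_groups(b, a)
            assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)
            assert r1.test_used == r2.test_used

    def test_normal_groups_take_welch_path(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(0.2, 2.0, size=50)
        res = compare_groups(a, b)
        assert res.test_used == "unpaired_t"
        expected = sps.ttest_ind(a, b, equal_var=False)
        assert res.p_value == pytest.approx(float(expected.pvalue))
        pooled = compare_groups(a, b, pooled_variance=True)
        assert pooled.p_value == pytest.approx(
            float(sps.ttest_ind(a, b, equal_var=True).pvalue)
        )

    def test_skewed_groups_take_mann_whitney_path(self):
        rng = np.random.default_rng(4)
        a, b = rng.lognormal(size=30), rng.lognormal(size=38)
        res = compare_groups(a, b)
        assert res.test_used == "mann_whitney"


class TestCorrelate:
    def test_perfect_line_pearson(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=50)
        res = correlate(x, 2 * x + 1)
        assert res.method == "pearson"
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_monotone_transform_spearman_one(self):
        rng = np.random.default_rng(6)
        x = rng.exponential(size=60)  # skewed: fails the normality gate
        res = correlate(x, x**3)
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)

    def test_spearman_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(size=60)
        y = rng.exponential(size=60)
        base = correlate(x, y)
        for f in (np.log, np.sqrt, lambda v: v**3, np.exp):
            assert correlate(f(x), y).r == pytest.approx(base.r, rel=1e-9)

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateCorrelationError, match="constant"):
            correlate([1.0] * 30, list(range(30)))
        with pytest.raises(DegenerateCorrelationError):
            correlate([1.0, 2.0], [3.0, 4.0])

    def test_negative_association_keeps_sign(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=68)
        res = correlate(x, -x + 0.3 * rng.normal(size=68))
        assert res.r < -0.9


class TestRunStudy:
    def test_cardinality_and_schema(self, cohort):
        profiles = list(cohort.compositions)
        panels = [full_panel(p) for p in profiles]
        study = run_study(profiles, panels, list(cohort.metadata))
        assert len(study.comparisons) == 20
        assert len(study.correlations) == 40
        assert {c.covariate for c in study.correlations} == {
            "age_months",
            "bodyweight_kg",
        }
        for c in study.comparisons:
            assert 0.0 <= c.p_value <= 1.0
            assert c.significant == (c.p_value < 0.05)
            assert c.group_a.n + c.group_b.n == 68

    def test_missing_metadata_is_error(self, cohort):
        profiles = list(cohort.compositions)
        panels = [full_panel(p) for p in profiles]
        with pytest.raises(IncompleteMetadataError, match="incomplete metadata"):
            run_study(profiles, panels, list(cohort.metadata)[:-1])

    def test_fdr_flag_only_tightens(self, cohort):
        profiles = list(cohort.compositions)
        panels = [full_panel(p) for p in profiles]
        raw = run_study(profiles, panels, list(cohort.metadata))
        adj = run_study(profiles, panels, list(cohort.metadata), fdr=True)
        for r, a in zip(raw.comparisons, adj.comparisons):
            assert a.p_value == r.p_value  # p-values unchanged, flags tightened
            assert (not a.significant) or r.significant


def test_benjamini_hochberg_matches_direct_computation():
    p = np.array([0.01, 0.04, 0.03, 0.20])
    adj = benjamini_hochberg(p)
    # hand-computed step-up: sorted p*(m/k) with running minimum from the top
    assert adj == pytest.approx([0.04, 0.05333333, 0.05333333, 0.2])


def test_dog_record_validation():
    with pytest.raises(IncompleteMetadataError):
        DogRecord("s", "X", False, 10.0, 5.0)
    with pytest.raises(IncompleteMetadataError):
        DogRecord("s", "M", False, -1.0, 5.0)
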