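"""CV computation/categorization, variability summaries, and the test ladder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctradiomics.core import FeatureVector, MeasurementRecord
from ctradiomics.stats import (
    NOT_AVAILABLE,
    categorize_cv,
    coefficient_of_variation,
    compare_feature_across_algorithms,
    compare_variability_sources,
    rm_anova,
    variability_summary,
    variability_table,
)


def const_features(value=10.0, **overrides):
    from ctradiomics.core import FEATURE_NAMES

    vals = {name: value for name in FEATURE_NAMES}
    vals.update(overrides)
    return FeatureVector(**vals)


def make_records(n_lesions=5, readers=("R1", "R2"), value_fn=None):
    """Records for the full design: R1 twice, R2 once, three algorithms."""
    records = []
    for li in range(n_lesions):
        lesion = f"L{li:03d}"
        for reader, session in [("R1", 1), ("R1", 2), ("R2", 1)]:
            if reader not in readers:
                continue
            for algo in ("FBP", "S3", "S5"):
                v = 10.0 if value_fn is None else value_fn(li, reader, session, algo)
                records.append(
                    MeasurementRecord(lesion, reader, session, algo, const_features(v))
                )
    return records


class TestCoefficientOfVariation:
    def test_identical_pair_is_zero(self):
        assert coefficient_of_variation([100.0, 100.0]) == 0.0

    def test_two_point_arithmetic(self):
        # sample SD sqrt(200) over mean 100
        assert coefficient_of_variation([90.0, 110.0]) == pytest.approx(
            math.sqrt(200.0), abs=1e-9
        )

    def test_negative_mean_uses_absolute_value(self):
        cv = coefficient_of_variation([-90.0, -110.0])
        assert cv == pytest.approx(math.sqrt(200.0), abs=1e-9)

    def test_zero_mean_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero mean"):
            assert math.isnan(coefficient_of_variation([-1.0, 1.0]))

    @settings(deadline=None, max_examples=50)
    @given(k=st.floats(0.001, 1000), seed=st.integers(0, 2**16))
    def test_scale_invariance(self, k, seed):
        x = np.random.default_rng(seed).uniform(1, 10, size=12)
        assert coefficient_of_variation(k * x) == pytest.approx(
            coefficient_of_variation(x), rel=1e-9
        )


class TestCvCategories:
    @pytest.mark.parametrize("cv,category", [
        (4.6, "very_small"),
        (5.0, "very_small"),   # bounds closed as printed
        (5.001, "small"),
        (10.0, "small"),
        (10.001, "intermediate"),
        (20.0, "intermediate"),
        (20.001, "large"),
        (21.0, "large"),
        (131.3, "large"),
    ])
    def test_threshold_boundaries(self, cv, category):
        assert categorize_cv(cv) == category


class TestVariabilitySummary:
    def test_duplicated_records_give_zero_cv(self):
        records = make_records()
        for source in ("intra_reader", "inter_reader", "recon_FBP_S3"):
            s = variability_summary(records, source, "volume")
            assert np.all(s.per_lesion_cv == 0.0)
            assert s.summary_cv == 0.0
            assert s.category == "very_small"

    def test_missing_record_lists_lesions(self):
        records = make_records(n_lesions=3)
        records = [r for r in records if not (r.lesion_id == "L001" and r.session == 2)]
        with pytest.raises(ValueError, match="L001"):
            variability_summary(records, "intra_reader", "volume")

    def test_jittered_second_reader_raises_inter_cv(self, rng):
        def value_fn(li, reader, session, algo):
            base = 100.0 + 10.0 * li
            if reader == "R1" and session == 2:
                return base * (1 + rng.normal(0, 0.002))
            if reader == "R2":
                return base * (1 + rng.normal(0, 0.02))
            return base

        records = make_records(n_lesions=50, value_fn=value_fn)
        intra = variability_summary(records, "intra_reader", "volume")
        inter = variability_summary(records, "inter_reader", "volume")
        assert inter.summary_cv > intra.summary_cv

    def test_table_covers_all_sources(self):
        table = variability_table(make_records(), features=("volume", "sd"))
        assert len(table) == 2 * 5


class TestRmAnova:
    def test_matches_statsmodels_anova_rm(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        X = rng.normal(0, 1, (15, 3)) + rng.normal(0, 1, 15)[:, None]
        X += np.array([0.0, 0.3, 0.6])
        f_stat, p = rm_anova(X)
        df = pd.DataFrame({
            "subj": np.repeat(np.arange(15), 3),
            "cond": np.tile(np.arange(3), 15),
            "value": X.ravel(),
        })
        tbl = AnovaRM(df, "value", "subj", within=["cond"]).fit().anova_table
        assert f_stat == pytest.approx(float(tbl["F Value"].iloc[0]), rel=1e-9)
        assert p == pytest.approx(float(tbl["Pr > F"].iloc[0]), rel=1e-9)


class TestCompareAcrossAlgorithms:
    def test_identical_groups_give_na_sentinel(self, rng):
        x = rng.normal(size=20)
        omnibus, posthoc = compare_feature_across_algorithms(
            {"FBP": x, "S3": x.copy(), "S5": x.copy()}
        )
        assert omnibus.test_used == NOT_AVAILABLE
        assert math.isnan(omnibus.p_value)
        assert all(p.test_used == NOT_AVAILABLE for p in posthoc)

    def test_constant_shift_detected_in_posthoc(self, rng):
        base = rng.normal(100, 10, size=42)
        omnibus, posthoc = compare_feature_across_algorithms(
            {"FBP": base, "S3": base + rng.normal(0, 0.5, 42), "S5": base + 8.0}
        )
        assert omnibus.significant_after_correction
        pair = {p.grouping: p for p in posthoc}["S3 vs S5"]
        assert pair.significant_after_correction

    def test_nonnormal_data_routes_to_friedman(self, rng):
        base = rng.exponential(1.0, size=40) ** 3  # heavily skewed
        shifted = {"FBP": base, "S3": base * 1.01, "S5": base * 1.5}
        omnibus, posthoc = compare_feature_across_algorithms(shifted)
        assert omnibus.test_used == "friedman"
        assert all(
            p.test_used in ("wilcoxon_signed_rank", NOT_AVAILABLE) for p in posthoc
        )
        # Bonferroni over the three pairs
        assert posthoc[0].alpha_corrected == pytest.approx(0.05 / 3)

    def test_misaligned_groups_rejected(self, rng):
        with pytest.raises(ValueError, match="aligned"):
            compare_feature_across_algorithms(
                {"FBP": rng.normal(size=10), "S3": rng.normal(size=9),
                 "S5": rng.normal(size=10)}
            )


class TestCompareVariabilitySources:
    def test_identical_lists_na(self):
        cv = [1.0, 2.0, 3.0, 4.0]
        res = compare_variability_sources(cv, cv)
        assert res.test_used == NOT_AVAILABLE
        assert not res.significant_after_correction

    def test_uniformly_larger_source_significant(self, rng):
        a = rng.uniform(1, 5, size=30)
        b = a + rng.uniform(0.5, 1.5, size=30)  # b larger on every lesion
        res = compare_variability_sources(a, b, family_size=4)
        assert res.significant_after_correction
        assert res.alpha_corrected == pytest.approx(0.0125)

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(7)
        n_reject = 0
        n_rep = 1000
        for _ in range(n_rep):
            a = rng.uniform(0, 10, size=42)
            b = rng.uniform(0, 10, size=42)  # exchangeable with a
            res = compare_variability_sources(a, b, family_size=1)
            n_reject += res.significant_after_correction
        assert 0.03 <= n_reject / n_rep <= 0.07
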