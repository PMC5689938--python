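import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petrad.agreement_stats import (
    PairedDifferenceResult,
    classify_reproducibility,
    dice,
    icc2_single,
    icc_with_precision,
    inter_item_correlation,
    paired_differences,
    percentage_differences,
    precision_from_ci,
)
from petrad.volio import FeatureTable, ROIMask


def _mask(arr):
    return ROIMask(np.asarray(arr).reshape(-1, 1, 1), (1, 1, 1))


class TestDice:
    def test_identical_masks(self):
        m = _mask([1, 1, 0, 1])
        assert dice(m, m) == pytest.approx(1.0)

    def test_disjoint_masks(self):
        assert dice(_mask([1, 1, 0, 0]), _mask([0, 0, 1, 1])) == 0.0

    def test_half_overlap(self):
        a = _mask([1, 1, 1, 1, 0, 0])
        b = _mask([1, 1, 0, 0, 1, 1])
        assert dice(a, b) == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        with pytest.raises(ValueError, match="empty"):
            dice(_mask([0, 0]), _mask([0, 0]))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes"):
            dice(_mask([1, 0]), _mask([1, 0, 0]))


def _feature_table(values_by_variant, column="segmentation", feature="f"):
    rows = []
    for variant, values in values_by_variant.items():
        for i, v in enumerate(values):
            row = {
                "case_id": f"case{i}",
                "segmentation": "MTV1",
                "gray_level": 64,
                "recon": "OSEM",
                "feature_name": feature,
                "value": float(v),
            }
            row[column] = variant
            rows.append(row)
    return FeatureTable(pd.DataFrame(rows))


class TestPairedDifferences:
    def test_identical_values(self):
        t = _feature_table({"A": [1, 2, 3], "B": [1, 2, 3]})
        (res,) = paired_differences(t, ("A", "B"))
        assert res.d_mean_abs == 0.0
        assert res.sd == 0.0
        assert res.url == 0.0 and res.lrl == 0.0

    def test_single_case_arithmetic(self):
        # f_m = 3, f_n = 1: d = 2 / 2 * 100 = 100%
        t = _feature_table({"A": [3.0], "B": [1.0]})
        (res,) = paired_differences(t, ("A", "B"))
        assert res.d[0] == pytest.approx(100.0)

    def test_limits_hand_computed(self):
        # d values {-2, 0, 2}: mean 0, SD 2, URL 3.92, LRL -3.92
        d = np.array([-2.0, 0.0, 2.0])
        fn = np.array([100.0, 100.0, 100.0])
        fm = fn * (1 + d / 100.0 / (1 - d / 200.0))  # invert the pair-mean scale
        dd, _ = percentage_differences(fm, fn)
        np.testing.assert_allclose(dd, d, atol=1e-9)
        t = _feature_table({"A": fm, "B": fn})
        (res,) = paired_differences(t, ("A", "B"))
        assert res.d_mean_abs == pytest.approx(0.0, abs=1e-9)
        assert res.sd == pytest.approx(2.0)
        assert res.url == pytest.approx(3.92)
        assert res.lrl == pytest.approx(-3.92)

    def test_zero_denominator_cases_excluded(self):
        d, n_excluded = percentage_differences([1.0, 2.0, -3.0], [1.0, 2.0, 3.0])
        assert n_excluded == 1
        assert len(d) == 2

    def test_limit_width_identity(self):
        rng = np.random.default_rng(0)
        t = _feature_table({"A": rng.random(20) + 1, "B": rng.random(20) + 1})
        (res,) = paired_differences(t, ("A", "B"))
        assert res.url - res.lrl == pytest.approx(2 * 1.96 * res.sd)

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        t = _feature_table({"A": rng.random(15) + 0.5, "B": rng.random(15) + 0.5})
        (ab,) = paired_differences(t, ("A", "B"))
        (ba,) = paired_differences(t, ("B", "A"))
        np.testing.assert_allclose(ba.d, -ab.d)
        assert ba.d_mean_abs == pytest.approx(ab.d_mean_abs)
        assert ba.sd == pytest.approx(ab.sd)
        assert ba.url == pytest.approx(-ab.lrl)
        assert ba.lrl == pytest.approx(-ab.url)

    def test_coverage_of_limits(self):
        # ~95% of simulated normal differences fall inside [LRL, URL]
        rng = np.random.default_rng(42)
        d = rng.normal(0.0, 10.0, size=2000)
        mean, sd = d.mean(), d.std(ddof=1)
        lrl, url = mean - 1.96 * sd, mean + 1.96 * sd
        coverage = np.mean((d >= lrl) & (d <= url)) * 100
        assert coverage == pytest.approx(95.0, abs=3.0)


def _result(d_mean=0.0, sd=1.0, url=None, lrl=None):
    url = d_mean + 1.96 * sd if url is None else url
    lrl = d_mean - 1.96 * sd if lrl is None else lrl
    return PairedDifferenceResult(
        feature_name="f",
        pair_label="A-B",
        d=np.array([d_mean]),
        d_mean=d_mean,
        d_mean_abs=abs(d_mean),
        sd=sd,
        lrl=lrl,
        url=url,
        n_cases=10,
    )


class TestClassification:
    def test_high_band(self):
        cls = classify_reproducibility(_result(d_mean=5.0, sd=10.0, url=25.0, lrl=-20.0))
        assert cls.level == "High"
        assert cls.reproducible

    def test_intermediate_band(self):
        cls = classify_reproducibility(_result(d_mean=5.0, sd=15.0, url=44.0, lrl=-30.0))
        assert cls.level == "Intermediate"

    def test_nr_above_fifty(self):
        cls = classify_reproducibility(_result(d_mean=5.0, sd=20.0, url=55.0, lrl=-30.0))
        assert cls.level == "NR"

    def test_low_band(self):
        cls = classify_reproducibility(_result(d_mean=5.0, sd=20.0, url=48.0, lrl=-30.0))
        assert cls.level == "Low"

    def test_gate_failure_is_nr(self):
        cls = classify_reproducibility(_result(d_mean=30.0, sd=1.0, url=5.0, lrl=-5.0))
        assert cls.level == "NR"
        assert not cls.reproducible

    def test_near_zero_limits_high(self):
        cls = classify_reproducibility(_result(d_mean=0.0, sd=0.1))
        assert cls.level == "High"

    def test_inclusive_boundaries(self):
        assert classify_reproducibility(_result(0, 1, url=30.0, lrl=-10.0)).level == "High"
        assert classify_reproducibility(_result(0, 1, url=45.0, lrl=-10.0)).level == "Intermediate"
        assert classify_reproducibility(_result(0, 1, url=50.0, lrl=-10.0)).level == "Low"

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 30), st.floats(0, 40), st.floats(min_value=0.0, max_value=20))
    def test_monotone_in_sd(self, d_mean, sd, delta):
        order = {"High": 3, "Intermediate": 2, "Low": 1, "NR": 0}
        c_lo = classify_reproducibility(_result(d_mean=d_mean, sd=sd))
        c_hi = classify_reproducibility(_result(d_mean=d_mean, sd=sd + delta))
        assert order[c_hi.level] <= order[c_lo.level]


class TestICC:
    def test_precision_from_printed_bounds(self):
        assert precision_from_ci(0.84, 0.94) == pytest.approx(5.0)
        assert precision_from_ci(0.93, 0.98) == pytest.approx(2.5)

    def test_identical_raters_give_one(self):
        y = np.tile(np.arange(6, dtype=float)[:, None], (1, 3))
        icc, lb, ub = icc2_single(y)
        assert icc == 1.0 and lb == 1.0 and ub == 1.0

    def test_zero_between_case_variance_sentinel(self):
        y = np.ones((5, 3))
        with pytest.warns(UserWarning, match="between-case"):
            icc, lb, ub = icc2_single(y)
        assert np.isnan(icc)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="ICC needs"):
            icc2_single(np.ones((2, 2)))

    def test_matches_pingouin(self):
        # independent implementation check against a mature library
        import pingouin as pg

        rng = np.random.default_rng(5)
        for _ in range(5):
            y = rng.normal(size=(12, 3)) + 2 * rng.normal(size=(12, 1))
            icc, lb, ub = icc2_single(y)
            n, k = y.shape
            df = pd.DataFrame(
                {
                    "case": np.repeat(np.arange(n), k),
                    "rater": np.tile(np.arange(k), n),
                    "value": y.ravel(),
                }
            )
            res = pg.intraclass_corr(df, "case", "rater", "value").set_index("Type")
            row = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
            assert icc == pytest.approx(float(row["ICC"]), abs=1e-9)
            ci_col = "CI95" if "CI95" in res.columns else "CI95%"
            plb, pub = row[ci_col]
            assert lb == pytest.approx(float(plb), abs=0.006)
            assert ub == pytest.approx(float(pub), abs=0.006)

    def test_parameter_recovery(self):
        # y_ij = a_i + b_j + e_ij with known variance components
        # rater variance is kept small: with only 2 raters its 1-df estimate
        # dominates the estimator spread otherwise
        rng = np.random.default_rng(123)
        n, k = 500, 2
        va, vb, ve = 4.0, 0.05, 1.0
        y = (
            rng.normal(0, np.sqrt(va), size=(n, 1))
            + rng.normal(0, np.sqrt(vb), size=(1, k))
            + rng.normal(0, np.sqrt(ve), size=(n, k))
        )
        icc, lb, ub = icc2_single(y)
        expected = va / (va + vb + ve)
        assert icc == pytest.approx(expected, abs=0.05)
        assert lb <= icc <= ub

    def test_icc_with_precision_table(self):
        rng = np.random.default_rng(9)
        base = rng.random(8) * 5 + 1
        t = _feature_table(
            {
                "MTV1": base,
                "MTV2": base + rng.normal(0, 0.1, 8),
                "GBSV": base + rng.normal(0, 0.1, 8),
            }
        )
        (res,) = icc_with_precision(t, "SM")
        assert res.icc > 0.9
        assert res.ci_lb <= res.icc <= res.ci_ub
        assert res.precision == pytest.approx((res.ci_ub - res.ci_lb) / 2 * 100)

    def test_unknown_parameter(self):
        t = _feature_table({"MTV1": [1, 2, 3]})
        with pytest.raises(ValueError, match="unknown parameter"):
            icc_with_precision(t, "XX")


class TestIIC:
    def test_identical_gives_one(self):
        vals = np.arange(5, dtype=float) + 1
        t = _feature_table({64: vals, 128: vals}, column="gray_level")
        out = inter_item_correlation(t, 64, (128,))
        assert out.loc["f", 128] == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        vals = np.arange(5, dtype=float) + 1
        t = _feature_table({64: vals, 128: -vals}, column="gray_level")
        out = inter_item_correlation(t, 64, (128,))
        assert out.loc["f", 128] == pytest.approx(-1.0)

    def test_constant_vector_flagged_nan(self):
        t = _feature_table({64: [1.0] * 5, 128: np.arange(5.0)}, column="gray_level")
        out = inter_item_correlation(t, 64, (128,))
        assert np.isnan(out.loc["f", 128])
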