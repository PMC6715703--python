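"""Harrell-Davis estimation, GMD, ICC, and the boxplot outlier rule."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermolimits import (
    boxplot_outliers,
    gmd,
    hd_quantile,
    icc_consistency_avg,
    summarize_cohort,
    summarize_subject,
    threshold_change,
)

finite_floats = st.floats(-100, 100, allow_nan=False, allow_infinity=False)


def hd_oracle(values, q):
    """Independent HD evaluation: numeric integration of the Beta density."""
    from scipy.integrate import quad

    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    const = math.gamma(a + b) / (math.gamma(a) * math.gamma(b))
    pdf = lambda t: const * t ** (a - 1) * (1 - t) ** (b - 1)
    est = 0.0
    for i in range(n):
        w, _ = quad(pdf, i / n, (i + 1) / n, epsabs=1e-13, limit=200)
        est += w * x[i]
    return est


class TestHDQuantile:
    @pytest.mark.parametrize(
        "values, q, expected",
        [([5.0], 0.5, 5.0), ([0.0, 1.0], 0.5, 0.5)],
    )
    def test_tiny_samples(self, values, q, expected):
        assert hd_quantile(values, q).estimate == pytest.approx(expected)

    @pytest.mark.parametrize("q", [0.1, 0.25, 0.5, 0.75, 0.9])
    def test_matches_numeric_beta_integration(self, q, rng):
        for _ in range(5):
            vals = rng.lognormal(0.5, 0.7, size=rng.integers(3, 15))
            est = hd_quantile(vals, q).estimate
            assert est == pytest.approx(hd_oracle(vals, q), abs=1e-10)

    def test_weights_sum_to_one_and_estimate_bounded(self, rng):
        vals = rng.normal(size=10)
        res = hd_quantile(vals, 0.5)
        assert res.weights.sum() == pytest.approx(1.0)
        assert np.all(res.weights >= 0)
        assert vals.min() <= res.estimate <= vals.max()

    @given(
        vals=st.lists(finite_floats, min_size=2, max_size=20),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_equivariance(self, vals, a, b):
        v = np.asarray(vals)
        lhs = hd_quantile(a * v + b, 0.5).estimate
        rhs = a * hd_quantile(v, 0.5).estimate + b
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_symmetric_reflection(self, rng):
        v = rng.normal(size=11)
        lo = hd_quantile(v, 0.25).estimate
        hi = hd_quantile(-v, 0.75).estimate
        assert lo == pytest.approx(-hi)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            hd_quantile([], 0.5)
        with pytest.raises(ValueError):
            hd_quantile([1.0, np.nan], 0.5)
        with pytest.raises(ValueError):
            hd_quantile([1.0, 2.0], 1.0)


class TestGMD:
    @pytest.mark.parametrize(
        "values, expected",
        [([3, 3, 3, 3], 0.0), ([0, 1], 1.0), ([1, 2, 4], 2.0)],
    )
    def test_known_values(self, values, expected):
        assert gmd(values) == pytest.approx(expected)

    @given(vals=st.lists(finite_floats, min_size=2, max_size=50))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_pair_enumeration(self, vals):
        v = np.asarray(vals)
        brute = np.abs(v[:, None] - v[None, :]).sum() / (len(v) * (len(v) - 1))
        assert gmd(v) == pytest.approx(brute, rel=1e-12, abs=1e-12)

    @given(
        vals=st.lists(finite_floats, min_size=2, max_size=20),
        a=st.floats(-5, 5),
        b=st.floats(-50, 50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_equivariant_translation_invariant(self, vals, a, b):
        v = np.asarray(vals)
        assert gmd(a * v + b) == pytest.approx(
            abs(a) * gmd(v), rel=1e-9, abs=1e-9
        )

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            gmd([1.0])


class TestThresholdChange:
    @pytest.mark.parametrize(
        "temp, modality, expected",
        [(33.88, "warm", 1.88), (29.59, "cool", 2.41), (32.0, "warm", 0.0)],
    )
    def test_change_from_baseline(self, temp, modality, expected):
        assert threshold_change(temp, modality) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_change(55.0, "warm")


class TestBoxplotOutliers:
    def test_no_flags_for_regular_data(self):
        assert not boxplot_outliers(np.arange(1, 11)).any()
        assert not boxplot_outliers(np.full(6, 2.0)).any()

    def test_flags_extreme_value_only(self):
        vals = np.array([1, 2, 2, 3, 3, 3, 4, 100.0])
        flags = boxplot_outliers(vals)
        assert flags[-1]
        assert flags.sum() == 1


class TestICC:
    def test_identical_blocks(self, rng):
        b = rng.normal(size=20)
        assert icc_consistency_avg(b, b).icc == pytest.approx(1.0)

    def test_consistency_ignores_constant_shift(self, rng):
        b = rng.normal(size=20)
        assert icc_consistency_avg(b, b + 3.0).icc == pytest.approx(1.0)

    def test_independent_blocks_center_on_zero(self, rng):
        vals = [
            icc_consistency_avg(
                rng.normal(size=200), rng.normal(size=200)
            ).icc
            for _ in range(30)
        ]
        assert abs(np.mean(vals)) < 0.08
        res = icc_consistency_avg(rng.normal(size=200), rng.normal(size=200))
        assert res.ci_low < res.icc < res.ci_high

    def test_agrees_with_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=30)
        y = 0.8 * x + 0.3 * rng.normal(size=30)
        res = icc_consistency_avg(x, y)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(30), 2),
                "rater": np.tile(["b1", "b2"], 30),
                "score": np.column_stack([x, y]).ravel(),
            }
        )
        icc3k = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(C,k)"]
        assert res.icc == pytest.approx(icc3k["ICC"], abs=1e-6)
        assert res.ci_low == pytest.approx(icc3k["CI95"][0], abs=0.02)


class TestSummaries:
    def test_identical_trials(self):
        trials = pd.DataFrame(
            {
                "subject_id": ["a"] * 10,
                "modality": "warm",
                "block": [1] * 5 + [2] * 5,
                "trial": list(range(1, 6)) * 2,
                "temperature_c": 34.0,
            }
        )
        out = summarize_subject(trials)
        assert out["warm_threshold"] == pytest.approx(2.0)
        assert out["warm_gmd"] == pytest.approx(0.0)
        assert np.isnan(out["cool_threshold"])

    def test_pooled_median_uses_hd_estimator(self):
        temps = [33, 33, 34, 34, 35] * 2
        trials = pd.DataFrame(
            {
                "subject_id": ["a"] * 10,
                "modality": "warm",
                "block": [1] * 5 + [2] * 5,
                "trial": list(range(1, 6)) * 2,
                "temperature_c": temps,
            }
        )
        out = summarize_subject(trials)
        expected = hd_oracle(np.asarray(temps) - 32.0, 0.5)
        assert out["warm_threshold"] == pytest.approx(expected, abs=1e-10)

    def test_cohort_summary_schema_and_flags(self, small_study):
        _, subjects, trials = small_study
        summary = summarize_cohort(trials, subjects)
        assert len(summary) == len(subjects)
        for col in (
            "warm_threshold", "cool_threshold", "warm_gmd", "cool_gmd",
            "outlier_warm", "outlier_cool",
            "outlier_warm_gmd", "outlier_cool_gmd",
        ):
            assert col in summary.columns
        assert (summary["warm_gmd"].dropna() >= 0).all()
        assert (summary["warm_threshold"].dropna() >= 0).all()
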