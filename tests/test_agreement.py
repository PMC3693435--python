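import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammodensity import (
    AgreementUndefinedError,
    ParameterError,
    RaterReadings,
    bland_altman,
    categorize_boyd,
    lin_ccc,
    pairwise_agreement,
    per_category_summary,
    simulate_raters,
    weighted_kappa,
)
from oracles import ccc_brute_force, kappa_brute_force, kappa_from_table


class TestLinCcc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2.0, 3.0, 7.0])
        ccc, ci = lin_ccc(x, x)
        assert ccc == pytest.approx(1.0)
        assert ci == (1.0, 1.0)

    def test_pure_shift_closed_form(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 50, 200)
        c = 4.0
        ccc, _ = lin_ccc(x, x + c)
        s2 = x.var()
        assert ccc == pytest.approx(2 * s2 / (2 * s2 + c * c), abs=1e-9)
        # Pearson r is still 1: CCC penalizes the location shift.
        assert ccc < 1.0

    def test_small_fixed_vectors_match_oracle(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [1.0, 2.0, 3.0, 5.0]
        ccc, _ = lin_ccc(x, y)
        assert ccc == pytest.approx(ccc_brute_force(x, y), abs=1e-14)

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 31))
            x = rng.uniform(0, 100, n)
            y = rng.uniform(0, 100, n)
            ccc, _ = lin_ccc(x, y)
            assert ccc == pytest.approx(ccc_brute_force(list(x), list(y)), abs=1e-12)

    def test_both_series_constant_undefined(self):
        with pytest.raises(AgreementUndefinedError):
            lin_ccc([5.0, 5.0, 5.0], [7.0, 7.0, 7.0])

    def test_symmetric_in_arguments(self, rng):
        x = rng.uniform(0, 100, 40)
        y = rng.uniform(0, 100, 40)
        assert lin_ccc(x, y)[0] == pytest.approx(lin_ccc(y, x)[0], abs=1e-14)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2**32 - 1))
    def test_ccc_never_exceeds_pearson(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(10, 5, n)
        y = 0.5 * x + rng.normal(0, 3, n)
        if x.var() == 0 or y.var() == 0:
            return
        ccc, _ = lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 60, 300)
        y = x + rng.normal(0, 5, 300)
        ccc, (lo, hi) = lin_ccc(x, y)
        assert lo < ccc < hi
        assert -1 <= lo and hi <= 1


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 5.0, 9.0])
        s = bland_altman(x, x)
        assert s.mean_difference == 0.0
        assert s.p05_diff == 0.0 and s.p95_diff == 0.0

    def test_sign_convention_first_minus_second(self):
        x = np.linspace(0, 50, 20)
        s = bland_altman(x, x + 1.6)
        assert s.mean_difference == pytest.approx(-1.6)
        t = bland_altman(x + 1.6, x)
        assert t.mean_difference == pytest.approx(1.6)  # antisymmetric

    def test_normal_difference_percentiles(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0, 5, 100)
        s = bland_altman(d, np.zeros_like(d))
        # Normal quantiles at sd 5: +/- 8.22; allow Monte-Carlo error at n=100.
        assert s.p95_diff == pytest.approx(8.22, abs=2.5)
        assert s.p05_diff == pytest.approx(-8.22, abs=2.5)
        assert s.loa_high == pytest.approx(s.mean_difference + 1.96 * s.sd_diff)

    def test_pairwise_agreement_combines_ccc(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 60, 50)
        y = x + rng.normal(0, 2, 50)
        s = pairwise_agreement(x, y)
        assert s.ccc == pytest.approx(lin_ccc(x, y)[0])
        assert s.p05_diff <= s.p95_diff


class TestWeightedKappa:
    def test_perfect_agreement(self):
        a = np.array([0, 1, 2, 1, 0, 2, 2, 1])
        kappa, _ = weighted_kappa(a, a, 3)
        assert kappa == pytest.approx(1.0)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(7)
        a = rng.integers(0, 4, 20000)
        b = rng.integers(0, 4, 20000)
        kappa, _ = weighted_kappa(a, b, 4)
        assert kappa == pytest.approx(0.0, abs=0.02)

    def test_fixed_table_matches_oracle(self):
        table = [[5, 1, 0], [1, 6, 1], [0, 1, 5]]
        a, b = [], []
        for i in range(3):
            for j in range(3):
                a.extend([i] * table[i][j])
                b.extend([j] * table[i][j])
        kappa, _ = weighted_kappa(np.array(a), np.array(b), 3)
        assert kappa == pytest.approx(kappa_from_table(table), abs=1e-14)

    @settings(deadline=None, max_examples=60)
    @given(st.integers(2, 6), st.integers(0, 2**32 - 1))
    def test_matches_oracle_on_random_tables(self, k, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(k, 31))
        a = rng.integers(0, k, n)
        b = rng.integers(0, k, n)
        kappa, _ = weighted_kappa(a, b, k)
        expected = kappa_brute_force(list(a), list(b), k)
        if math.isnan(expected):
            assert math.isnan(kappa)
        else:
            assert kappa == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(20):
            k = int(rng.integers(2, 7))
            n = int(rng.integers(k + 5, 60))
            a = rng.integers(0, k, n)
            b = rng.integers(0, k, n)
            kappa, _ = weighted_kappa(a, b, k)
            ref = cohen_kappa_score(
                a, b, labels=list(range(k)), weights="quadratic"
            )
            if math.isnan(ref) or math.isnan(kappa):
                continue
            assert kappa == pytest.approx(ref, abs=1e-12)

    def test_constant_identical_raters_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            kappa, ci = weighted_kappa(np.ones(10, int), np.ones(10, int), 3)
        assert math.isnan(kappa)
        assert any("undefined" in r.message for r in caplog.records)

    def test_agreement_improves_as_noise_falls(self):
        """Under shared truth, both CCC and Boyd-binned quadratic kappa
        increase monotonically as rater noise decreases."""
        rng = np.random.default_rng(11)
        truth = rng.uniform(0, 80, 3000)
        cccs, kappas = [], []
        for sd in (12.0, 6.0, 2.0):
            rr = simulate_raters(truth, [0.0, 0.0], [sd, sd], seed=31)
            x, y = rr.pair("rater1", "rater2")
            cccs.append(lin_ccc(x, y)[0])
            a = np.array([int(categorize_boyd(v)) for v in x])
            b = np.array([int(categorize_boyd(v)) for v in y])
            kappas.append(weighted_kappa(a, b, 6)[0])
        assert cccs == sorted(cccs)
        assert kappas == sorted(kappas)


class TestPerCategorySummary:
    def test_single_constant_category(self):
        out = per_category_summary([10.0, 10.0, 10.0], ["a", "a", "a"])
        row = out.loc["a"]
        assert row["n"] == 3
        assert row["mean_pd"] == 10.0
        assert row["p05"] == 10.0 and row["p95"] == 10.0

    def test_partition_counts(self):
        out = per_category_summary([1, 2, 30, 40, 50], ["lo", "lo", "hi", "hi", "hi"])
        assert out.loc["lo", "n"] == 2
        assert out.loc["hi", "n"] == 3

    def test_empty_category_row(self):
        cats = pd.Categorical(["a", "a"], categories=["a", "b"])
        out = per_category_summary([5.0, 7.0], cats)
        assert out.loc["b", "n"] == 0
        assert math.isnan(out.loc["b", "mean_pd"])

    def test_ordered_construction_gives_increasing_means(self, rng):
        truth = rng.uniform(0, 100, 2000)
        cats = [int(categorize_boyd(v)) for v in truth]
        out = per_category_summary(truth, cats)
        means = out["mean_pd"].to_numpy()
        assert np.all(np.diff(means) > 0)


class TestRaterReadings:
    def test_pairwise_deletion_logged(self, caplog):
        rr = RaterReadings(
            image_ids=[1, 2, 3, 4],
            readings={
                "a": np.array([1.0, 2.0, np.nan, 4.0]),
                "b": np.array([1.0, np.nan, 3.0, 4.0]),
            },
        )
        with caplog.at_level("INFO"):
            x, y = rr.pair("a", "b")
        assert x.size == 2
        assert any("dropped 2" in r.message for r in caplog.records)

    def test_misaligned_readings_rejected(self):
        with pytest.raises(ParameterError):
            RaterReadings(image_ids=[1, 2], readings={"a": np.array([1.0])})
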