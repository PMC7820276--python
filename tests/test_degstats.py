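import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import gaussian_kde

from pahmsc import (
    ComparisonSpec,
    DegThresholds,
    ExpressionMatrix,
    IntegrativeDEModel,
    SimulationConfig,
    build_null,
    combine_stouffer,
    empirical_pvalue,
    generate_expression,
    log2_median_ratio,
    quantile_normalize,
    run_comparison,
    storey_qvalues,
    t_statistic,
)
from pahmsc.degstats import NullModel, _exhaustive_splits

MCT_VS_CON = ComparisonSpec("MCT/CON", "MCT", "CON")


class TestPerGeneStatistics:
    def test_t_hand_example(self):
        assert t_statistic([2, 4], [1, 3]) == pytest.approx(0.7071, abs=1e-4)

    def test_t_symmetry_and_degenerate_variance(self):
        assert t_statistic([1, 2, 3], [1, 2, 3]) == 0.0
        assert t_statistic([5, 5], [5, 5]) == 0.0  # floored, not NaN

    def test_t_requires_two_replicates(self):
        with pytest.raises(ValueError):
            t_statistic([1], [2, 3])

    @pytest.mark.parametrize(
        "a,b,expected",
        [([3, 5], [1, 3], 2.0), ([1, 2], [1, 2], 0.0),
         ([1, 2, 9], [0, 2, 4], 0.0)],
    )
    def test_lmr_examples(self, a, b, expected):
        assert log2_median_ratio(a, b) == pytest.approx(expected)

    def test_lmr_empty_side_rejected(self):
        with pytest.raises(ValueError):
            log2_median_ratio([], [1, 2])

    def test_label_exchange_antisymmetry(self):
        a, b = [2.0, 4.1], [1.2, 3.3]
        assert t_statistic(a, b) == pytest.approx(-t_statistic(b, a))
        assert log2_median_ratio(a, b) == pytest.approx(
            -log2_median_ratio(b, a))


class TestPermutationNull:
    def test_2v2_exhaustive_split_count(self):
        assert len(_exhaustive_splits(2, 2)) <= 3

    def test_pooled_null_shape(self):
        config = SimulationConfig(n_genes=100, seed=0)
        m, _ = generate_expression(config)
        null = build_null(m, MCT_VS_CON, "t", n_perm=3, seed=0)
        assert null.values.size == 300
        assert null.n_permutations == 3

    def test_null_symmetric_about_zero_on_null_data(self):
        pooled = []
        for seed in range(15):
            config = SimulationConfig(n_genes=80, effect_size=0.0, seed=seed)
            m, _ = generate_expression(config)
            pooled.append(build_null(m, MCT_VS_CON, "lmr").values)
        pooled = np.concatenate(pooled)
        se = pooled.std(ddof=1) / np.sqrt(pooled.size)
        assert abs(pooled.mean()) < 3 * se + 1e-12

    def test_too_few_samples_rejected(self):
        values = pd.DataFrame(np.ones((5, 3)), columns=["a1", "a2", "b1"])
        m = ExpressionMatrix(values, {"a1": "MCT", "a2": "MCT", "b1": "CON"})
        with pytest.raises(ValueError):
            build_null(m, MCT_VS_CON, "t")


class TestEmpiricalPvalue:
    def test_zero_statistic_has_full_tail_mass(self):
        null = NullModel("t", np.array([-1.0, 0.0, 1.0]), 0.5, 1)
        assert empirical_pvalue(0.0, null) == pytest.approx(1.0, abs=1e-9)

    def test_extreme_statistic_hits_clamp(self):
        null = NullModel("t", np.linspace(-1, 1, 99), 0.3, 1)
        assert empirical_pvalue(1e6, null) == pytest.approx(1 / 100)

    def test_closed_form_matches_numerical_integration(self):
        """Gaussian-mixture tail formula vs brute-force KDE integration."""
        rng = np.random.default_rng(0)
        sample = rng.normal(0, 1, 60)
        null = NullModel("t", sample, 0.4, 1)
        kde = gaussian_kde(sample, bw_method=0.4 / sample.std(ddof=1))
        clamp = 1.0 / (sample.size + 1)
        for stat in (0.5, 1.3, 2.2):
            left, _ = integrate.quad(lambda v: kde(v)[0], -np.inf, -stat)
            right, _ = integrate.quad(lambda v: kde(v)[0], stat, np.inf)
            assert empirical_pvalue(stat, null) == pytest.approx(
                max(left + right, clamp), abs=1e-6)

    def test_non_finite_statistic_rejected(self):
        null = NullModel("t", np.array([0.0, 1.0]), 0.5, 1)
        with pytest.raises(ValueError):
            empirical_pvalue(np.nan, null)


class TestStouffer:
    def test_uninformative_inputs(self):
        z, p = combine_stouffer(1.0, 1.0)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_equal_p_identity(self):
        from statistics import NormalDist
        nd = NormalDist()
        for p_in in (0.3, 0.05, 0.004):
            _, p = combine_stouffer(p_in, p_in)
            expected = 2 * (1 - nd.cdf(np.sqrt(2) * nd.inv_cdf(1 - p_in / 2)))
            assert p == pytest.approx(expected, abs=1e-12)

    def test_worked_example(self):
        _, p = combine_stouffer(0.05, 0.05)
        assert p == pytest.approx(0.00557, abs=5e-5)

    def test_sign_conflict_attenuates(self):
        _, same = combine_stouffer(0.05, 0.05, 1.0, 1.0)
        _, conflict = combine_stouffer(0.05, 0.05, 1.0, -1.0)
        assert conflict > same

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            combine_stouffer(0.0, 0.5)


class TestStoreyQvalues:
    def test_lambda_zero_reduces_to_bh(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(3)
        p = np.concatenate([rng.uniform(0, 1, 80), rng.uniform(0, 0.01, 20)])
        q, pi0 = storey_qvalues(p, lambda_=0.0)
        assert pi0 == 1.0
        _, bh, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, bh, atol=1e-12)

    def test_single_pvalue(self):
        q, _ = storey_qvalues([0.01], lambda_=0.0)
        assert q[0] == pytest.approx(0.01)

    def test_uniform_null_pi0_near_one(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0, 1, 10_000)
        _, pi0 = storey_qvalues(p, lambda_=0.5)
        assert pi0 == pytest.approx(1.0, abs=0.05)

    def test_degenerate_lambda_falls_back(self):
        with pytest.warns(RuntimeWarning):
            q, pi0 = storey_qvalues([0.1, 0.2, 0.3], lambda_=0.9)
        assert pi0 == 1.0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_and_bounded(self, p):
        q, pi0 = storey_qvalues(p, lambda_=0.5)
        assert (q <= 1.0 + 1e-12).all() and 0 < pi0 <= 1
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestRunComparison:
    def test_threshold_conjunction_defines_calls(self, fitted):
        for res in fitted.values():
            f = res.frame
            expected = (f["q"] <= 0.05) & (f["lmr"].abs() >= 0.58)
            assert (f["is_deg"] == expected).all()
            assert (f.loc[f["is_deg"], "direction"]
                    == np.where(f.loc[f["is_deg"], "lmr"] >= 0, "up", "down")
                    ).all()

    def test_small_fold_change_not_called(self, study):
        """Tiny q alone is not enough: |lmr| must clear the 1.5-fold bar."""
        matrix, _ = study
        strict = DegThresholds(fdr=0.05, lmr=5.0)
        res = run_comparison(matrix, MCT_VS_CON, thresholds=strict, seed=5)
        assert res.n_degs == 0

    def test_deterministic_given_seed(self, study):
        matrix, _ = study
        a = run_comparison(matrix, MCT_VS_CON, n_perm=5, seed=3).frame
        b = run_comparison(matrix, MCT_VS_CON, n_perm=5, seed=3).frame
        pd.testing.assert_frame_equal(a, b)

    def test_label_swap_negates_statistics_keeps_pvalues(self, study):
        matrix, _ = study
        fwd = run_comparison(matrix, MCT_VS_CON, seed=0).frame
        rev = run_comparison(
            matrix, ComparisonSpec("CON/MCT", "CON", "MCT"), seed=0).frame
        np.testing.assert_allclose(fwd["t"], -rev["t"], atol=1e-9)
        np.testing.assert_allclose(fwd["lmr"], -rev["lmr"], atol=1e-9)
        np.testing.assert_allclose(fwd["p_t"], rev["p_t"], atol=1e-9)
        np.testing.assert_allclose(fwd["p_lmr"], rev["p_lmr"], atol=1e-9)

    def test_summary_reports_counts(self, fitted):
        res = fitted["MCT/CON"]
        text = res.summary()
        assert "MCT/CON" in text and str(res.n_degs) in text

    def test_tsv_round_trip(self, fitted, tmp_path):
        res = fitted["MCT/CON"]
        path = tmp_path / "deg.tsv"
        res.to_tsv(path)
        back = type(res).frame_from_tsv(path)
        assert (back["is_deg"] == res.frame["is_deg"]).all()
        np.testing.assert_allclose(back["lmr"], res.frame["lmr"], atol=1e-5)

    def test_identical_conditions_rejected(self):
        with pytest.raises(ValueError):
            ComparisonSpec("x", "MCT", "MCT")

    def test_normal_combined_null_available(self, study):
        matrix, _ = study
        model = IntegrativeDEModel(matrix, MCT_VS_CON,
                                   combined_null="normal")
        res = model.fit(seed=0)
        # closed-form p must agree with direct Stouffer arithmetic
        f = res.frame
        _, p = combine_stouffer(f["p_t"].to_numpy(), f["p_lmr"].to_numpy(),
                                np.sign(f["t"]), np.sign(f["lmr"]))
        np.testing.assert_allclose(f["p"], p, atol=1e-12)
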