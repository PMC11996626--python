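"""Abundance normalisation, the lanthanide fraction, the quasi-binomial
logistic fit and correspondence analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st
from scipy import stats

import lanthascope as ls


def _table(counts, lengths, libsizes):
    genes = [f"g{i}" for i in range(len(counts))]
    samples = [f"s{j}" for j in range(len(counts[0]))]
    return ls.AbundanceTable(
        values=pd.DataFrame(counts, index=genes, columns=samples, dtype=float),
        gene_lengths=pd.Series(lengths, index=genes, dtype=float),
        library_sizes=pd.Series(libsizes, index=samples, dtype=float),
    )


class TestRpkm:
    def test_closed_formula(self):
        table = _table([[10]], [500], [1_000_000])
        rpkm = ls.compute_rpkm(table)
        assert rpkm.values.iloc[0, 0] == pytest.approx(20.0, abs=0)

    def test_zero_counts_zero_rpkm(self):
        rpkm = ls.compute_rpkm(_table([[0, 3]], [900], [1e6, 1e6]))
        assert rpkm.values.iloc[0, 0] == 0.0

    def test_doubling_library_halves_sample(self):
        r1 = ls.compute_rpkm(_table([[8], [4]], [300, 600], [1e6]))
        r2 = ls.compute_rpkm(_table([[8], [4]], [300, 600], [2e6]))
        assert np.allclose(r2.values, r1.values / 2)

    def test_zero_length_is_hard_error(self):
        with pytest.raises(ValueError):
            ls.compute_rpkm(_table([[1]], [0], [1e6]))

    def test_rpkm_table_rejected(self):
        rpkm = ls.compute_rpkm(_table([[1]], [100], [1e6]))
        with pytest.raises(ValueError):
            ls.compute_rpkm(rpkm)


class TestRelativeAbundance:
    def test_single_gene_is_hundred_percent(self):
        rpkm = ls.compute_rpkm(_table([[5, 0]], [100], [1e6, 1e6]))
        percent = ls.relative_abundance_percent(rpkm)
        assert percent.iloc[0, 0] == 100.0
        assert np.isnan(percent.iloc[0, 1])  # all-zero sample is missing

    def test_three_to_one_split(self):
        table = ls.AbundanceTable(
            values=pd.DataFrame({"s": [3.0, 1.0]}, index=["a", "b"]),
            gene_lengths=pd.Series([1.0, 1.0], index=["a", "b"]),
            library_sizes=pd.Series([1.0], index=["s"]),
            kind="rpkm",
        )
        percent = ls.relative_abundance_percent(table)
        assert list(percent["s"]) == [75.0, 25.0]

    def test_columns_sum_to_hundred(self):
        rng = np.random.default_rng(31)
        counts = rng.integers(0, 50, size=(6, 5))
        counts[:, 0] += 1  # keep every sample nonzero
        rpkm = ls.compute_rpkm(_table(counts.tolist(),
                                      rng.integers(100, 900, 6).tolist(),
                                      rng.integers(10**5, 10**6, 5).tolist()))
        sums = ls.relative_abundance_percent(rpkm).sum(axis=0)
        ok = sums[~sums.isna()]
        assert np.allclose(ok, 100.0, atol=1e-9)


class TestFln:
    def _rpkm(self, values, calls):
        genes = list(values)
        table = ls.AbundanceTable(
            values=pd.DataFrame({"s": list(values.values())}, index=genes),
            gene_lengths=pd.Series(1.0, index=genes),
            library_sizes=pd.Series([1.0], index=["s"]),
            kind="rpkm",
        )
        return table, calls

    def test_worked_example(self):
        # Ln 6, Ca 3, unknown 1 -> 6 / 10
        table, calls = self._rpkm(
            {"a": 6.0, "b": 3.0, "c": 1.0},
            {"a": "lanthanide", "b": "calcium", "c": "unknown"},
        )
        assert ls.compute_fln(table, calls).fln["s"] == pytest.approx(0.6, abs=0)

    def test_all_calcium_gives_zero(self):
        table, calls = self._rpkm({"a": 2.0, "b": 5.0},
                                  {"a": "calcium", "b": "calcium"})
        assert ls.compute_fln(table, calls).fln["s"] == 0.0

    def test_incomplete_excluded_entirely(self):
        table, calls = self._rpkm(
            {"a": 6.0, "b": 3.0, "c": 100.0},
            {"a": "lanthanide", "b": "calcium", "c": "incomplete"},
        )
        out = ls.compute_fln(table, calls)
        assert out.fln["s"] == pytest.approx(6.0 / 9.0)
        assert out.table.loc["s", "denominator"] == 9.0

    def test_unknown_excluded_on_request(self):
        table, calls = self._rpkm(
            {"a": 6.0, "b": 3.0, "c": 1.0},
            {"a": "lanthanide", "b": "calcium", "c": "unknown"},
        )
        out = ls.compute_fln(table, calls, include_unknown=False)
        assert out.fln["s"] == pytest.approx(6.0 / 9.0)

    def test_zero_denominator_is_missing(self):
        table, calls = self._rpkm({"a": 5.0}, {"a": "incomplete"})
        assert np.isnan(ls.compute_fln(table, calls).fln["s"])

    def test_count_based_mode_uses_presence(self):
        table, calls = self._rpkm(
            {"a": 6.0, "b": 0.0, "c": 1.0},
            {"a": "lanthanide", "b": "lanthanide", "c": "calcium"},
        )
        out = ls.compute_fln(table, calls, mode="count_based")
        assert out.fln["s"] == pytest.approx(0.5)

    def test_missing_call_rejected(self):
        table, _ = self._rpkm({"a": 1.0}, {})
        with pytest.raises(ValueError):
            ls.compute_fln(table, {})

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None,
              suppress_health_check=[HealthCheck.function_scoped_fixture])
    def test_scale_invariance(self, scale):
        table, calls = self._rpkm(
            {"a": 6.0, "b": 3.0, "c": 1.0},
            {"a": "lanthanide", "b": "calcium", "c": "unknown"},
        )
        scaled = ls.AbundanceTable(values=table.values * scale,
                                   gene_lengths=table.gene_lengths,
                                   library_sizes=table.library_sizes, kind="rpkm")
        assert ls.compute_fln(scaled, calls).fln["s"] == pytest.approx(
            ls.compute_fln(table, calls).fln["s"])


class TestLogisticFit:
    def test_constant_half_gives_zero_coefficients(self):
        x = np.linspace(0, 3, 12)
        fit = ls.fit_fractional_logistic(np.full(12, 0.5), x)
        assert fit.b0 == pytest.approx(0.0, abs=1e-10)
        assert fit.b1 == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_recovery(self):
        x = np.linspace(0, 3, 40)
        y = 1 / (1 + np.exp(-(1.5 - 2.0 * x)))
        fit = ls.fit_fractional_logistic(y, x)
        assert fit.converged
        assert fit.b0 == pytest.approx(1.5, abs=1e-6)
        assert fit.b1 == pytest.approx(-2.0, abs=1e-6)

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(41)
        n = 100
        x = rng.uniform(0, 2.5, n)
        mu = 1 / (1 + np.exp(-(2.0 - 2.0 * x)))
        y = rng.binomial(60, mu) / 60  # fractional responses with count noise
        fit = ls.fit_fractional_logistic(y, x)
        assert fit.b1 < 0
        assert abs(fit.b1 - (-2.0)) < 3 * fit.se_b1

    def test_agrees_with_statsmodels_quasibinomial(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.uniform(0, 2, 50)
        y = np.clip(1 / (1 + np.exp(-(1.0 - 1.5 * x)))
                    + rng.normal(0, 0.05, 50), 1e-4, 1 - 1e-4)
        ours = ls.fit_fractional_logistic(y, x)
        glm = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial())
        ref = glm.fit(scale="X2")
        assert ours.b0 == pytest.approx(ref.params[0], rel=1e-6)
        assert ours.b1 == pytest.approx(ref.params[1], rel=1e-6)
        assert ours.se_b1 == pytest.approx(ref.bse[1], rel=1e-4)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 2, 30)
        y = np.clip(rng.uniform(0.1, 0.9, 30), 0, 1)
        fit = ls.fit_fractional_logistic(y, x)
        perm = rng.permutation(30)
        fit_p = ls.fit_fractional_logistic(y[perm], x[perm])
        assert fit_p.b1 == pytest.approx(fit.b1, rel=1e-10)

    def test_centering_changes_intercept_not_slope(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 2, 30)
        y = np.clip(rng.uniform(0.1, 0.9, 30), 0, 1)
        fit = ls.fit_fractional_logistic(y, x)
        fit_c = ls.fit_fractional_logistic(y, x - x.mean())
        assert fit_c.b1 == pytest.approx(fit.b1, rel=1e-8)
        assert fit_c.b0 == pytest.approx(fit.b0 + fit.b1 * x.mean(), rel=1e-8)

    def test_no_variation_flagged_non_identifiable(self):
        fit = ls.fit_fractional_logistic([0.2, 0.4, 0.6], [1.0, 1.0, 1.0])
        assert not fit.identifiable and fit.p_b1 is None

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ls.fit_fractional_logistic([0.5, 0.5], [0.0, 1.0])


class TestCorrespondenceAnalysis:
    def test_diagonal_table_single_axis(self):
        ca = ls.correspondence_analysis(pd.DataFrame([[10.0, 0.0], [0.0, 10.0]]))
        assert ca.total_inertia == pytest.approx(1.0, abs=1e-12)
        assert len(ca.singular_values) == 1
        assert ca.inertia_fraction[0] == pytest.approx(1.0)

    def test_independence_table_zero_inertia(self):
        row = np.array([1.0, 2.0, 3.0])
        col = np.array([4.0, 1.0])
        ca = ls.correspondence_analysis(pd.DataFrame(np.outer(row, col)))
        assert ca.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert ca.singular_values.size == 0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_total_inertia_equals_chi2_over_n(self, seed):
        rng = np.random.default_rng(seed)
        shape = (int(rng.integers(2, 9)), int(rng.integers(2, 9)))
        table = rng.integers(1, 40, size=shape).astype(float)
        ca = ls.correspondence_analysis(pd.DataFrame(table))
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert ca.total_inertia == pytest.approx(chi2 / table.sum(), abs=1e-10)

    def test_axes_ordered_and_signs_fixed(self):
        rng = np.random.default_rng(77)
        table = pd.DataFrame(rng.integers(1, 30, size=(6, 5)).astype(float))
        ca = ls.correspondence_analysis(table)
        sv = ca.singular_values
        assert all(sv[i] >= sv[i + 1] for i in range(len(sv) - 1))
        for k in range(ca.col_scores.shape[1]):
            col = ca.col_scores.iloc[:, k].to_numpy()
            first_nonzero = col[np.abs(col) > 1e-12][0]
            assert first_nonzero > 0

    def test_env_arrows_drop_nitrate_and_bound_by_one(self):
        rng = np.random.default_rng(15)
        table = pd.DataFrame(rng.integers(1, 30, size=(8, 4)).astype(float),
                             index=[f"s{i}" for i in range(8)])
        env = pd.DataFrame(
            {"phosphate": rng.uniform(0, 2, 8),
             "temperature": rng.uniform(5, 25, 8),
             "nitrate": rng.uniform(0, 30, 8)},
            index=table.index,
        )
        ca = ls.correspondence_analysis(table, env=env)
        assert "nitrate" not in ca.env_arrows.index
        assert set(ca.env_arrows.index) == {"phosphate", "temperature"}
        assert (np.abs(ca.env_arrows.to_numpy()) <= 1 + 1e-9).all()

    def test_all_zero_row_dropped_with_warning(self):
        table = pd.DataFrame([[5.0, 1.0], [0.0, 0.0], [1.0, 4.0]])
        with pytest.warns(UserWarning):
            ca = ls.correspondence_analysis(table)
        assert ca.row_scores.shape[0] == 2

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ls.correspondence_analysis(pd.DataFrame([[1.0, -1.0]]))


class TestNearestGridJoin:
    def test_average_within_radius_and_missing_outside(self):
        grid = pd.DataFrame({
            "lat": [0.0, 0.5, 10.0], "lon": [0.0, 0.0, 10.0],
            "phosphate": [1.0, 3.0, 100.0],
        })
        points = pd.DataFrame({"lat": [0.1, 5.0], "lon": [0.0, 5.0]},
                              index=["near", "far"])
        joined = ls.nearest_grid_join(points, grid, ["phosphate"], radius=1.0)
        assert joined.loc["near", "phosphate"] == pytest.approx(2.0)
        assert np.isnan(joined.loc["far", "phosphate"])
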