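"""Linear/logarithmic fits, Pearson R, p-values, and the correlation table."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.integrate import quad

from laser_rfa import (
    CohortSpec,
    CorrelationStudy,
    SpecimenMeasurements,
    compare_fits,
    correlation_table,
    fit_linear,
    fit_logarithmic,
    generate_cohort,
)
from laser_rfa.validation import significance_marker


def data_with_exact_r(r, n, rng):
    """Construct (x, y) whose sample Pearson correlation is exactly r."""
    x = np.arange(n, dtype=float)
    xc = x - x.mean()
    xh = xc / np.linalg.norm(xc)
    z = rng.normal(size=n)
    z = z - z.mean()
    z = z - (z @ xh) * xh
    zh = z / np.linalg.norm(z)
    y = r * xh + math.sqrt(1 - r**2) * zh
    return x, y


def t_pvalue_by_quadrature(r, n):
    """Two-sided p for the correlation t-test, by numerical integration."""
    df = n - 2
    t = abs(r) * math.sqrt(df / (1 - r**2))
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    dens = lambda u: c * (1 + u**2 / df) ** (-(df + 1) / 2)
    tail, _ = quad(dens, t, np.inf)
    return 2 * tail


class TestFitLinear:
    def test_perfect_line_recovered(self):
        x = np.arange(5, dtype=float)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.model == "linear"
        assert fit.n == 5

    def test_independent_normals_are_uncorrelated(self, rng):
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        fit = fit_linear(x, y)
        assert abs(fit.pearson_r) < 0.1
        assert fit.p_value > 0.001

    @pytest.mark.parametrize("r,n", [(0.5, 3), (0.9, 3), (0.3, 10),
                                     (0.981, 30), (-0.7, 12)])
    def test_pvalue_matches_quadrature_of_t_density(self, r, n, rng):
        x, y = data_with_exact_r(r, n, rng)
        fit = fit_linear(x, y)
        assert fit.pearson_r == pytest.approx(r, abs=1e-12)
        assert fit.p_value == pytest.approx(t_pvalue_by_quadrature(r, n),
                                            abs=1e-6)

    def test_missing_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, np.nan, 10.0]
        assert fit_linear(x, y).n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 complete pairs"):
            fit_linear([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("x,y", [
        ([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0]),
        ([1.0, 2.0, 3.0, 4.0, 5.0], [2.0] * 5),
    ])
    def test_constant_series_rejected(self, x, y):
        with pytest.raises(ValueError, match="constant"):
            fit_linear(x, y)

    def test_pearson_r_invariant_under_affine_rescaling(self, rng):
        x, y = rng.normal(size=50), rng.normal(size=50)
        base = fit_linear(x, y).pearson_r
        for _ in range(10):
            a, b = rng.uniform(0.1, 5.0, 2)
            c, d = rng.normal(0, 10.0, 2)
            r = fit_linear(a * x + c, b * y + d).pearson_r
            assert r == pytest.approx(base, abs=1e-9)

    def test_pvalue_monotone_in_abs_r_and_n(self, rng):
        # grid check of the t-formula through the public fit
        ps = [fit_linear(*data_with_exact_r(r, 20, rng)).p_value
              for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ps_n = [fit_linear(*data_with_exact_r(0.5, n, rng)).p_value
                for n in (5, 10, 20, 40)]
        assert all(a > b for a, b in zip(ps_n, ps_n[1:]))


class TestFitLogarithmic:
    def test_exact_log_law_recovered(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        fit = fit_logarithmic(x, 3 * np.log(x) + 5)
        assert fit.slope == pytest.approx(3.0)
        assert fit.intercept == pytest.approx(5.0)
        assert fit.pearson_r == pytest.approx(1.0)
        assert fit.model == "logarithmic"

    def test_equals_linear_fit_on_log_x_field_by_field(self, rng):
        x = rng.uniform(0.1, 10.0, 40)
        y = rng.normal(size=40)
        log_fit = fit_logarithmic(x, y)
        lin_fit = fit_linear(np.log(x), y)
        assert dataclasses.replace(log_fit, model="linear") == lin_fit

    def test_nonpositive_x_rejected_naming_the_specimen(self):
        x = [1.0, 2.0, -0.5, 4.0]
        with pytest.raises(ValueError, match=r"\[2\].*-0\.5"):
            fit_logarithmic(x, [1.0, 2.0, 3.0, 4.0])

    def test_log_generated_cohort_favors_log_model(self):
        cohort = generate_cohort(CohortSpec(seed=2).noiseless())
        torque = [s.peak_torque for s in cohort]
        rf = [s.rf for s in cohort]
        log_fit = fit_logarithmic(torque, rf)
        lin_fit = fit_linear(torque, rf)
        assert abs(log_fit.pearson_r - 1.0) < 1e-9
        assert abs(lin_fit.pearson_r) < 1.0 - 1e-6


class TestCompareFits:
    def test_exact_log_data_prefers_logarithmic(self):
        x = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        _, _, preferred = compare_fits(x, 3 * np.log(x) + 5)
        assert preferred == "logarithmic"

    def test_exact_linear_data_prefers_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        _, _, preferred = compare_fits(x, 2 * x + 1)
        assert preferred == "linear"

    def test_exact_tie_breaks_to_linear(self):
        # with a duplicated x both fits are exactly perfect (r = 1.0 for x
        # and for ln x): the tie must go to the simpler linear model
        x = np.array([1.0, 1.0, 2.0])
        y = np.array([0.0, 0.0, 1.0])
        lin, log, preferred = compare_fits(x, y)
        assert abs(lin.pearson_r) == abs(log.pearson_r) == 1.0
        assert preferred == "linear"

    def test_noisy_log_cohorts_prefer_log_in_majority(self):
        # Monte-Carlo: preference for the true (log) model, strengthening as
        # noise shrinks
        def majority(noise_sd, seeds):
            wins = 0
            for s in seeds:
                cohort = generate_cohort(
                    CohortSpec(rf_noise_sd=noise_sd, isq_noise_sd=0.0,
                               pof_noise_sd=0.0, seed=s))
                _, _, preferred = compare_fits(
                    [c.peak_torque for c in cohort], [c.rf for c in cohort])
                wins += preferred == "logarithmic"
            return wins / len(seeds)

        seeds = range(100)
        frac_low = majority(40.0, seeds)
        frac_high = majority(400.0, seeds)
        assert frac_low > 0.5
        assert frac_low >= frac_high


def _noiseless_cohort(seed=0):
    return generate_cohort(CohortSpec(seed=seed).noiseless())


class TestCorrelationTable:
    def test_noiseless_cohort_all_cells_perfect_and_significant(self):
        matrix = correlation_table(_noiseless_cohort())
        assert len(matrix.cells) == 6
        for cell in matrix.cells.values():
            assert cell.available
            assert cell.pearson_r == pytest.approx(1.0, abs=1e-9)
            assert cell.marker == "p < .001"
            assert cell.n == 30
            assert cell.strength.label == "strong"

    def test_missing_measure_marks_cells_unavailable(self):
        cohort = [dataclasses.replace(s, isq=None) for s in _noiseless_cohort()]
        matrix = correlation_table(cohort)
        for a, b in [("rf", "isq"), ("isq", "peak_torque"), ("isq", "pullout")]:
            assert not matrix.cell(a, b).available
        assert matrix.cell("rf", "peak_torque").available

    def test_symmetric_pair_lookup(self):
        matrix = correlation_table(_noiseless_cohort())
        assert matrix.cell("rf", "peak_torque") is matrix.cell("peak_torque", "rf")
        with pytest.raises(KeyError, match="diagonal"):
            matrix.cell("rf", "rf")

    def test_invariant_to_specimen_permutation(self, rng):
        cohort = generate_cohort(CohortSpec(seed=8))
        perm = list(rng.permutation(len(cohort)))
        shuffled = [cohort[i] for i in perm]
        a = correlation_table(cohort).to_dict()
        b = correlation_table(shuffled).to_dict()
        assert a == b

    def test_weaker_pof_noise_ordering(self):
        # generator-controlled ordering: heavy POF noise pushes the RF~POF
        # cell below the RF~torque cell
        spec = dataclasses.replace(CohortSpec(seed=6).noiseless(),
                                   pof_noise_sd=400.0)
        matrix = correlation_table(generate_cohort(spec))
        r_pof = abs(matrix.cell("rf", "pullout").pearson_r)
        r_torque = abs(matrix.cell("rf", "peak_torque").pearson_r)
        assert r_pof < r_torque

    @pytest.mark.parametrize("p,marker", [
        (0.0005, "p < .001"), (0.005, "p < .01"), (0.03, "p < .05"),
        (0.05, "p < .05"), (0.2, "n.s."),
    ])
    def test_significance_marker_tiers(self, p, marker):
        assert significance_marker(p) == marker


class TestCorrelationStudy:
    def test_summary_lists_all_six_pairs(self):
        results = CorrelationStudy(_noiseless_cohort()).fit()
        text = results.summary()
        for pair in ("rf ~ isq", "rf ~ peak_torque", "peak_torque ~ pullout"):
            assert pair in text
        assert results.n_specimens == 30

    def test_from_dataframe_round_trip(self):
        from laser_rfa import cohort_to_frame

        cohort = _noiseless_cohort()
        study = CorrelationStudy.from_dataframe(cohort_to_frame(cohort))
        assert study.cohort == cohort

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            CorrelationStudy([SpecimenMeasurements("a"),
                              SpecimenMeasurements("b")])
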