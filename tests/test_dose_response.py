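"""Concentration-response fitting, LC50 intersection, covariate screen."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nematox.dose_response import (
    CurveFamily,
    DoseResponseFit,
    DoseResponsePoint,
    control_target,
    covariate_screen,
    estimate_lc50,
    fit_dose_response,
    lc50,
    lc50_range,
)
from nematox.endpoints import EndpointSummary
from nematox.models import Species, TreatmentSpec

from conftest import make_well

XS = np.array([59.7, 156.0, 369.0, 1040.0, 2680.0, 7660.0,
               500.0, 1500.0, 2000.0, 3000.0])


def points(x, y):
    return [DoseResponsePoint(concentration=float(a), response=float(b))
            for a, b in zip(x, y)]


def normal_equations(design, y):
    """Independent OLS oracle: explicit (X'X)^-1 X'y."""
    xtx = design.T @ design
    return np.linalg.solve(xtx, design.T @ y)


def grid_scan_root(f, upper, tol=1e-4):
    """Independent root oracle: sign-change scan on a fixed grid."""
    xs = np.arange(tol, upper, tol)
    vals = f(xs)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    return None if len(sign_change) == 0 else float(xs[sign_change[0]])


class TestFitting:
    def test_noiseless_quadratic_recovery(self):
        coef = (5e-7, -0.0049, 10.426)
        fit = fit_dose_response(points(XS, np.polyval(coef, XS)), "quadratic")
        assert fit.coefficients == pytest.approx(coef, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_trendline_aliases(self):
        assert CurveFamily.parse("Binomial") is CurveFamily.QUADRATIC
        assert CurveFamily.parse("trinomial") is CurveFamily.CUBIC
        assert CurveFamily.parse("exp") is CurveFamily.EXPONENTIAL_SHIFTED

    @pytest.mark.parametrize("family,design_fn", [
        (CurveFamily.QUADRATIC, lambda x: np.vander(x, 3)),
        (CurveFamily.CUBIC, lambda x: np.vander(x, 4)),
        (CurveFamily.LOGARITHMIC,
         lambda x: np.column_stack([np.log(x), np.ones_like(x)])),
    ])
    def test_noisy_fit_matches_normal_equations_oracle(self, family, design_fn):
        rng = np.random.default_rng(42)
        x = np.repeat(XS[:6], 5)
        y = np.clip(10 - 0.0012 * x + rng.normal(0, 1, x.size), 0, None)
        fit = fit_dose_response(points(x, y), family)
        beta = normal_equations(design_fn(x), y)
        assert fit.coefficients == pytest.approx(tuple(beta), rel=1e-9)

    def test_exponential_fit_matches_log_linear_oracle(self):
        rng = np.random.default_rng(43)
        x = np.repeat(XS[:6], 5)
        y = np.clip(9 * np.exp(-3e-4 * x) - 1 + rng.normal(0, 0.5, x.size),
                    0, None)
        fit = fit_dose_response(points(x, y), "exp")
        z = np.log(y + 1)
        slope, intercept = normal_equations(
            np.column_stack([x, np.ones_like(x)]), z)
        assert fit.coefficients[0] == pytest.approx(math.exp(intercept), rel=1e-12)
        assert fit.coefficients[1] == pytest.approx(slope, rel=1e-12)
        assert fit.r_squared_raw is not None

    def test_flat_response_cubic(self):
        fit = fit_dose_response(points(XS, np.full(XS.size, 7.0)), "cubic")
        assert fit.r_squared == 1.0
        assert fit.coefficients[:3] == pytest.approx((0, 0, 0), abs=1e-12)
        assert fit.coefficients[3] == pytest.approx(7.0)

    def test_too_few_distinct_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_dose_response(points([100, 100, 200, 200], [9, 8, 7, 6]),
                              "cubic")


class TestControlTarget:
    def test_half_of_full_recovery(self):
        wells = [make_well(live=10, well_id=f"w{i}") for i in range(6)]
        assert control_target(wells) == 5.0

    def test_rounding_half_away_from_zero(self):
        wells = ([make_well(live=8, well_id=f"w{i}") for i in range(9)]
                 + [make_well(live=7, well_id="x")])  # mean 7.9 -> 3.95 -> 4
        assert control_target(wells, rounding=True) == 4.0

    def test_unrounded_target(self):
        wells = [make_well(live=6, well_id="a"), make_well(live=6, well_id="b"),
                 make_well(live=7, well_id="c"), make_well(live=6, well_id="d"),
                 make_well(live=6, well_id="e")]  # mean 6.2
        assert control_target(wells) == pytest.approx(3.1)

    def test_no_surviving_controls_rejected(self):
        with pytest.raises(ValueError, match="without surviving controls"):
            control_target([make_well(live=0, well_id="w0")])


def _fit(family, coefs, x_max=7660.0):
    return DoseResponseFit(family=CurveFamily.parse(family),
                           coefficients=coefs, r_squared=1.0, x_max=x_max)


class TestLC50:
    def test_quadratic_closed_form_vs_grid_oracle(self):
        fit = _fit("quadratic", (5e-7, -0.0049, 10.426))
        value = lc50(fit, 5.0)
        assert value == pytest.approx(1272.60, abs=0.005)
        oracle = grid_scan_root(lambda x: np.polyval(fit.coefficients, x) - 5.0,
                                11490, tol=1e-3)
        assert value == pytest.approx(oracle, abs=2e-3)

    def test_cubic_vs_grid_scan_oracle(self):
        fit = _fit("cubic", (2e-10, -1e-6, -0.0014, 9.6338))
        value = lc50(fit, 5.0)
        assert value == pytest.approx(1813.16, abs=0.005)
        oracle = grid_scan_root(lambda x: np.polyval(fit.coefficients, x) - 5.0,
                                11490, tol=1e-3)
        assert value == pytest.approx(oracle, abs=2e-3)

    def test_exponential_uses_shifted_target(self):
        # intersection of A e^(kx) with target+1 = 6
        fit = _fit("exp", (8.8914, -3e-4))
        assert lc50(fit, 5.0) == pytest.approx(1311.08, abs=0.005)

    def test_logarithmic_closed_form(self):
        fit = _fit("log", (-2.314, 20.796))
        assert lc50(fit, 5.0) == pytest.approx(math.exp((5 - 20.796) / -2.314))

    def test_self_intersection_returns_smallest_dose(self):
        for fam, coefs in [("quadratic", (5e-7, -0.0049, 10.426)),
                           ("cubic", (2e-10, -1e-6, -0.0014, 9.6338)),
                           ("log", (-2.314, 20.796))]:
            fit = _fit(fam, coefs)
            y_at_min = fit.predict(59.7)
            assert lc50(fit, y_at_min) == pytest.approx(59.7, rel=1e-5)

    def test_complex_roots_not_attained(self):
        assert lc50(_fit("quadratic", (1e-6, 0.0, 10.0)), 5.0) is None

    def test_crossing_beyond_search_max_not_attained(self):
        fit = _fit("log", (-2.314, 20.796), x_max=100.0)  # crossing at ~922
        assert lc50(fit, 5.0) is None
        assert lc50(fit, 5.0, search_max=1000.0) is not None

    @given(st.floats(1.0, 8.0))
    def test_monotonicity_higher_target_means_lower_lc50(self, y_target):
        fit = _fit("quadratic", (5e-7, -0.0049, 10.426), x_max=3000.0)
        lo = lc50(fit, y_target)
        hi = lc50(fit, y_target + 0.5)
        assert lo is not None and hi is not None
        assert hi < lo

    @given(st.sampled_from(["quadratic", "cubic"]), st.floats(2.0, 6.0))
    def test_n_plus_one_shift_invariance(self, family, y_target):
        """Shifting responses and target by +1 moves only the intercept."""
        rng = np.random.default_rng(7)
        y = np.clip(10 - 0.0012 * XS + rng.normal(0, 0.8, XS.size), 0, None)
        base = fit_dose_response(points(XS, y), family)
        shifted = fit_dose_response(points(XS, y + 1.0), family)
        a = lc50(base, y_target)
        b = lc50(shifted, y_target + 1.0)
        assert (a is None) == (b is None)
        if a is not None:
            assert a == pytest.approx(b, rel=1e-6)


class TestLC50Range:
    def test_wb_polynomial_pair(self):
        fits = [
            estimate_lc50(_fit("quadratic", (5e-7, -0.0049, 10.426)), 5.0),
            estimate_lc50(_fit("cubic", (2e-10, -1e-6, -0.0014, 9.6338)), 5.0),
            estimate_lc50(_fit("log", (-2.314, 20.796)), 5.0),
            estimate_lc50(_fit("exp", (8.8914, -3e-4)), 5.0),
        ]
        low, high = lc50_range(fits)
        # log/exp fits excluded; range rounds to the reported 1273-1813
        assert round(low) == 1273 and round(high) == 1813

    def test_single_fit_degenerate_range(self):
        fit = estimate_lc50(_fit("quadratic", (5e-7, -0.0049, 10.426)), 5.0)
        low, high = lc50_range([fit])
        assert low == high == fit.lc50

    def test_min_max_matches_sort_oracle(self):
        values = [900.0, 400.0, 1600.0, 1100.0]
        fits = [DoseResponseFit(family=CurveFamily.QUADRATIC, coefficients=(),
                                r_squared=1, x_max=1, lc50=v) for v in values]
        assert lc50_range(fits) == (min(values), max(values))

    def test_no_polynomial_lc50_not_attained(self):
        fit = estimate_lc50(_fit("log", (-2.314, 20.796)), 5.0)
        assert lc50_range([fit]) is None


def _screen_inputs(recoveries, covs):
    summaries, specs = [], []
    for i, (rec, cv) in enumerate(zip(recoveries, covs)):
        tid = f"U-{i}"
        summaries.append(EndpointSummary(
            treatment_id=tid, species=Species.C_ELEGANS, n_wells=12,
            mean_p0_recovery=rec, mean_p0_fraction=rec / 10,
            mean_progeny=0.0))
        specs.append(TreatmentSpec(treatment_id=tid, sediment_id=tid,
                                   spike_level=0, tr_ni=10.0, **cv))
    return summaries, specs


class TestCovariateScreen:
    toc = [0.4, 1.9, 1.8, 1.2, 3.5, 8.1, 7.2, 10.4]
    cec = [5.5, 11.3, 19.0, 6.4, 14.5, 29.1, 29.3, 44.1]

    def test_planted_linear_signal_scores_one(self):
        recov = [2.0 + 0.8 * t for t in self.toc]
        summaries, specs = _screen_inputs(
            recov, [{"toc": t, "cec": c} for t, c in zip(self.toc, self.cec)])
        rows = covariate_screen(summaries, specs, max_factors=1)
        by_factors = {r.factors: r.r_squared for r in rows}
        assert by_factors[("toc",)] == pytest.approx(1.0, abs=1e-12)
        assert rows[0].factors == ("toc",)

    def test_single_factor_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        recov = list(rng.uniform(1, 10, 8))
        summaries, specs = _screen_inputs(recov, [{"cec": c} for c in self.cec])
        (row,) = covariate_screen(summaries, specs, max_factors=1)
        design = np.column_stack([np.ones(8), self.cec])
        beta = normal_equations(design, np.array(recov))
        resid = recov - design @ beta
        ss_tot = np.sum((np.array(recov) - np.mean(recov)) ** 2)
        assert row.r_squared == pytest.approx(1 - resid @ resid / ss_tot,
                                              rel=1e-9)

    def test_permuted_response_scores_below_planted_signal(self):
        recov = [2.0 + 0.8 * t for t in self.toc]
        covs = [{"toc": t, "cec": c} for t, c in zip(self.toc, self.cec)]
        planted, specs = _screen_inputs(recov, covs)
        rng = np.random.default_rng(11)
        permuted, _ = _screen_inputs(list(rng.permutation(recov)), covs)
        best_planted = covariate_screen(planted, specs, 1)[0].r_squared
        best_permuted = covariate_screen(permuted, specs, 1)[0].r_squared
        assert best_permuted < best_planted

    def test_collinear_subset_flagged_and_skipped(self):
        recov = [2.0 + 0.8 * t for t in self.toc]
        covs = [{"toc": t, "cec": 2 * t} for t in self.toc]  # cec = 2 toc
        summaries, specs = _screen_inputs(recov, covs)
        rows = covariate_screen(summaries, specs, max_factors=2)
        flagged = [r for r in rows if r.factors == ("toc", "cec")
                   or r.factors == ("cec", "toc")]
        assert flagged and flagged[0].collinear
        assert flagged[0].r_squared is None

    def test_too_few_treatments_rejected(self):
        recov = [1.0, 2.0, 3.0]
        summaries, specs = _screen_inputs(recov, [{"toc": t} for t in recov])
        with pytest.raises(ValueError, match="treatments"):
            covariate_screen(summaries, specs, max_factors=3)
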