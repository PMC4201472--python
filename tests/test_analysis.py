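"""Ratio arithmetic, grouping, one-site/linear fits, ANCOVA, classification."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from qbretsim.analysis import (
    ancova_equal_slopes,
    bret_ratio,
    classify_interaction,
    fit_linear,
    fit_one_site,
    group_by_luminescence,
    intensity_ratio,
    type1_analysis,
    type2_analysis,
)


def one_site(x, bmax, b50):
    return bmax * x / (b50 + x)


class TestRatios:
    def test_bret_ratio_arithmetic(self):
        assert bret_ratio(100.0, 100.0, 0.0) == 1.0
        assert bret_ratio(150.0, 100.0, 0.5) == pytest.approx(1.0)
        assert bret_ratio(50.0, 100.0, 0.5) == pytest.approx(0.0)

    def test_bret_ratio_rejects_nonpositive_denominator(self):
        with pytest.raises(ValueError):
            bret_ratio(1.0, 0.0)

    def test_intensity_ratio(self):
        assert intensity_ratio(200.0, 200.0) == 1.0
        assert intensity_ratio(0.0, 10.0) == 0.0
        assert intensity_ratio(20.0, 10.0) == 2 * intensity_ratio(10.0, 10.0)
        with pytest.raises(ValueError):
            intensity_ratio(1.0, 0.0)


class TestGrouping:
    def _records(self, lum):
        return pd.DataFrame(
            {"total_luminescence": lum,
             "fluorescence": np.ones(len(lum)),
             "bret_ratio": np.zeros(len(lum))}
        )

    def test_three_equal_groups_of_three(self):
        rec = self._records([5, 1, 9, 3, 7, 2, 8, 4, 6])
        out = group_by_luminescence(rec, 3)
        assert out["lum_group"].value_counts().tolist() == [3, 3, 3]
        # labels monotone in luminescence
        means = out.groupby("lum_group", observed=True)["total_luminescence"].mean()
        assert means["low"] < means["medium"] < means["high"]

    def test_partition_every_record_once(self):
        rec = self._records(np.arange(1, 11))
        out = group_by_luminescence(rec, 2)
        assert len(out) == 10 and out["lum_group"].notna().all()
        assert (out["lum_group"] == "low").sum() == 5

    def test_ties_split_by_stable_order(self):
        rec = self._records([3.0, 3.0, 3.0, 3.0])
        out = group_by_luminescence(rec, 2)
        assert out["lum_group"].tolist() == ["low", "low", "high", "high"]

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            group_by_luminescence(self._records([1.0]), 2)


class TestOneSiteFit:
    def test_recovers_noiseless_homodimer_parameters(self):
        """Typical homodimer titration: asymptote 0.457, half-saturation
        ratio 2.903 — recovered to 3 decimals from 20 noiseless points."""
        x = np.linspace(0.1, 12, 20)
        y = one_site(x, 0.457, 2.903)
        fit = fit_one_site(x, y)
        assert fit.converged
        assert fit.bret_max == pytest.approx(0.457, abs=1e-3)
        assert fit.bret_50 == pytest.approx(2.903, abs=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_flagged_not_raised(self):
        fit = fit_one_site(np.arange(1.0, 6.0), np.zeros(5))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_matches_grid_search_oracle_on_noisy_data(self):
        """Two-stage dense grid search over (Bmax, B50) minimizing SSE is the
        independent optimizer; agreement within 1e-3 relative."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            bmax, b50 = rng.uniform(0.1, 0.5), rng.uniform(0.5, 4.0)
            x = rng.uniform(0.05, 10, 30)
            y = one_site(x, bmax, b50) * (1 + 0.05 * rng.standard_normal(30))
            fit = fit_one_site(x, y)

            def sse(bm, bb):
                return np.sum((y - one_site(x, bm, bb)) ** 2)

            lo = np.array([1e-3, 1e-3])
            hi = np.array([2.0, 20.0])
            best = None
            for _ in range(6):  # successive grid refinement
                bms = np.linspace(lo[0], hi[0], 60)
                bbs = np.linspace(lo[1], hi[1], 60)
                vals = [(sse(bm, bb), bm, bb) for bm in bms for bb in bbs]
                _, bm, bb = min(vals)
                span = (hi - lo) / 10
                lo = np.maximum([bm, bb] - span, 1e-6)
                hi = np.array([bm, bb]) + span
                best = (bm, bb)
            assert fit.bret_max == pytest.approx(best[0], rel=1e-3)
            assert fit.bret_50 == pytest.approx(best[1], rel=1e-3)

    def test_parameter_recovery_under_noise(self):
        """Median relative error < 10% for both parameters over 100 noisy
        30-point datasets at 5% relative noise."""
        rng = np.random.default_rng(11)
        err_bmax, err_b50 = [], []
        for _ in range(100):
            bmax = rng.uniform(0.05, 0.5)
            b50 = rng.uniform(0.5, 5.0)
            x = rng.uniform(0.1, 15, 30)
            y = one_site(x, bmax, b50) * (1 + 0.05 * rng.standard_normal(30))
            fit = fit_one_site(x, y)
            assert fit.converged
            err_bmax.append(abs(fit.bret_max - bmax) / bmax)
            err_b50.append(abs(fit.bret_50 - b50) / b50)
        assert np.median(err_bmax) < 0.10
        assert np.median(err_b50) < 0.10

    def test_requires_three_points_and_nonnegative_x(self):
        with pytest.raises(ValueError):
            fit_one_site([1.0, 2.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            fit_one_site([-1.0, 1.0, 2.0], [0.1, 0.2, 0.3])


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        fit = fit_linear(np.arange(5.0), np.full(5, 3.0))
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.ones(5), np.arange(5.0))

    def test_matches_normal_equations_and_statsmodels(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 0.3 * x - 1.2 + rng.standard_normal(40)
        fit = fit_linear(x, y)
        # closed-form normal equations
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert fit.slope == pytest.approx(slope, rel=1e-12)
        assert fit.intercept == pytest.approx(intercept, rel=1e-12)
        # statsmodels as independent oracle for SEs and R^2
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.se_intercept == pytest.approx(ols.bse[0], rel=1e-10)
        assert fit.se_slope == pytest.approx(ols.bse[1], rel=1e-10)
        assert fit.r_squared == pytest.approx(ols.rsquared, rel=1e-12)


def permutation_p(xa, ya, xb, yb, n_perm=10_000, seed=0):
    """Permutation null for the slope difference: shuffle group labels,
    refit per-group OLS slopes, compare |slope difference|."""
    rng = np.random.default_rng(seed)
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    na = len(xa)

    def slope(xv, yv):
        xc = xv - xv.mean()
        return np.sum(xc * (yv - yv.mean())) / np.sum(xc**2)

    obs = abs(slope(xa, ya) - slope(xb, yb))
    hits = 0
    for _ in range(n_perm):
        idx = rng.permutation(len(x))
        d = abs(slope(x[idx[:na]], y[idx[:na]]) - slope(x[idx[na:]], y[idx[na:]]))
        hits += d >= obs
    return (hits + 1) / (n_perm + 1)


class TestAncova:
    def test_identical_lines_not_different(self, rng):
        x = np.linspace(0, 10, 30)
        y = 2 * x + 1
        cmp_ = ancova_equal_slopes((x, y), (x, y))
        assert cmp_.f_stat == pytest.approx(0.0, abs=1e-18)
        assert cmp_.p_value == pytest.approx(1.0)

    def test_clearly_different_slopes_rejected_and_permutation_agrees(self, rng):
        x = np.linspace(0, 5, 50)
        ya = 1.0 * x + 0.01 * rng.standard_normal(50)
        yb = 3.0 * x + 0.01 * rng.standard_normal(50)
        cmp_ = ancova_equal_slopes((x, ya), (x, yb))
        assert cmp_.p_value < 1e-3
        assert cmp_.slopes[0] == pytest.approx(1.0, abs=0.01)
        assert cmp_.slopes[1] == pytest.approx(3.0, abs=0.01)
        assert permutation_p(x, ya, x, yb) < 1e-3

    def test_matches_statsmodels_interaction_f_test(self, rng):
        xa = rng.uniform(0, 10, 25)
        xb = rng.uniform(0, 10, 35)
        ya = 0.5 * xa + 1 + rng.standard_normal(25)
        yb = 0.8 * xb - 1 + rng.standard_normal(35)
        cmp_ = ancova_equal_slopes((xa, ya), (xb, yb))
        g = np.r_[np.zeros(25), np.ones(35)]
        x = np.r_[xa, xb]
        y = np.r_[ya, yb]
        X_full = np.column_stack([np.ones(60), g, x, g * x])
        full = sm.OLS(y, X_full).fit()
        red = sm.OLS(y, X_full[:, :3]).fit()
        f, p, df = full.compare_f_test(red)
        assert cmp_.f_stat == pytest.approx(f, rel=1e-10)
        assert cmp_.p_value == pytest.approx(p, rel=1e-10)
        assert cmp_.df_num == int(df)
        assert cmp_.df_den == 60 - 4

    def test_agrees_with_permutation_null_across_datasets(self, rng):
        """F-test and permutation p-values track each other over 20 simulated
        datasets spanning null and alternative."""
        for k in range(20):
            delta = 0.0 if k % 2 == 0 else rng.uniform(0.1, 0.6)
            x = rng.uniform(0, 8, 30)
            xb = rng.uniform(0, 8, 30)
            ya = 0.5 * x + rng.standard_normal(30) * 0.3
            yb = (0.5 + delta) * xb + rng.standard_normal(30) * 0.3
            p_f = ancova_equal_slopes((x, ya), (xb, yb)).p_value
            p_perm = permutation_p(x, ya, xb, yb, n_perm=2000, seed=k)
            if p_f < 0.005:
                assert p_perm < 0.05
            elif p_f > 0.3:
                assert p_perm > 0.05
            else:  # borderline: require the same order of magnitude
                assert abs(np.log10(p_f) - np.log10(p_perm)) < 1.0

    def test_type_one_error_calibrated(self, rng):
        """Under equal slopes the 5% test rejects ~5% of the time."""
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = rng.uniform(0, 10, 20)
            xb = rng.uniform(0, 10, 20)
            ya = 1.0 * x + rng.standard_normal(20)
            yb = 1.0 * xb + rng.standard_normal(20)
            if ancova_equal_slopes((x, ya), (xb, yb)).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            ancova_equal_slopes(([1, 1, 1], [1, 2, 3]), ([1, 2, 3], [1, 2, 3]))


class TestPipelines:
    def _parametric(self, mode, n=120, noise=0.0, seed=0):
        from qbretsim.synthdata import NoiseSpec, SynthDatasetSpec
        from qbretsim.synthdata import generate_parametric_dataset

        spec = SynthDatasetSpec(
            mode=mode, n_points=n, seed=seed,
            noise=NoiseSpec(noise, noise, noise),
        )
        return generate_parametric_dataset(spec)

    def test_type1_non_specific_slopes_equal_background(self):
        df = self._parametric("non_specific", noise=0.0)
        rep = type1_analysis(df, n_groups=2)
        for fit in rep.group_fits.values():
            assert fit.slope == pytest.approx(1e-4, rel=1e-6)
        assert rep.comparison.p_value > 0.05

    def test_type1_specific_low_donor_slope_steeper(self):
        """With unsaturating acceptor levels each acceptor molecule finds
        more free donors in low-donor cells: steeper Type I slope. Within-
        group donor spread is the residual noise, so a few hundred wells
        (several pooled transfections) are needed for significance."""
        df = self._parametric("specific", n=400, noise=0.0)
        rep = type1_analysis(df, n_groups=2)
        assert rep.group_fits["low"].slope > rep.group_fits["high"].slope
        assert rep.comparison.p_value < 1e-3

    def test_type1_single_group(self):
        df = self._parametric("non_specific")
        rep = type1_analysis(df, n_groups=1)
        assert rep.comparison is None and len(rep.group_fits) == 1

    def test_type2_noiseless_hyperbola_perfect(self):
        df = self._parametric("specific", noise=0.0)
        df["bret_ratio"] -= 1e-4 * df["fluorescence"]  # strip background
        fit = type2_analysis(df)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert fit.bret_max == pytest.approx(0.457, rel=1e-4)
        assert fit.bret_50 == pytest.approx(2.903, rel=1e-4)


class TestClassification:
    def test_empty_input_indeterminate(self):
        out = classify_interaction(pd.DataFrame(
            columns=["fluorescence", "total_luminescence", "bret_ratio"]))
        assert out.verdict == "indeterminate"

    def test_parametric_datasets_classified_by_mode(self):
        from qbretsim.synthdata import SynthDatasetSpec
        from qbretsim.synthdata import generate_parametric_dataset

        from qbretsim.synthdata import NoiseSpec

        ns = generate_parametric_dataset(
            SynthDatasetSpec(mode="non_specific", n_points=100, seed=1))
        assert classify_interaction(ns).verdict == "non_specific"
        sp = generate_parametric_dataset(
            SynthDatasetSpec(mode="specific", n_points=400, seed=1,
                             noise=NoiseSpec(0.02, 0.02, 0.02)))
        out = classify_interaction(sp)
        assert out.verdict == "specific"
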