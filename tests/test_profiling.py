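"""Profile-likelihood tracing, confidence intervals and samples.

The stepper is exercised on closed-form surrogate objectives (where the
profile is known analytically) and on the bundled network fixture.
"""

import numpy as np
import pytest

from plsdesign.profiling import (
    ProfilingError,
    confidence_interval,
    delta_alpha,
    profile_objective,
    profile_samples,
)


def separable(th):
    return np.array([th[0] - 2.0, th[1] - 1.0])


def correlated(th):
    # chi2 = (t1 - t2)^2 + 0.01 t2^2  ->  chi2_PL(t1) = 0.01 t1^2 / 1.01
    return np.array([th[0] - th[1], 0.1 * th[1]])


class TestProfileObjective:
    def test_separable_quadratic_profile(self):
        curve = profile_objective(
            separable, ("t1", "t2"), np.array([2.0, 1.0]), 0.0, "t1"
        )
        assert np.max(np.abs(curve.chi2_pl - (curve.grid - 2.0) ** 2)) < 1e-8
        # nuisance is restored to its unconditional optimum everywhere
        assert np.max(np.abs(curve.nuisance[:, 1] - 1.0)) < 1e-6

    def test_correlated_quadratic_profile(self):
        curve = profile_objective(
            correlated, ("t1", "t2"), np.zeros(2), 0.0, "t1"
        )
        expected = 0.01 * curve.grid**2 / 1.01
        assert np.max(np.abs(curve.chi2_pl - expected)) < 1e-6

    def test_chi2_pl_never_below_minimum(self):
        curve = profile_objective(
            correlated, ("t1", "t2"), np.zeros(2), 0.0, "t1"
        )
        assert np.all(curve.chi2_pl >= -1e-9)
        j = np.argmin(np.abs(curve.grid))
        assert curve.chi2_pl[j] < 1e-3


class TestConfidenceInterval:
    def test_parabola_inverts_to_quantile(self):
        curve = profile_objective(
            separable, ("t1", "t2"), np.array([2.0, 1.0]), 0.0, "t1"
        )
        ci = confidence_interval(curve, alpha=0.05, df=1)
        half = np.sqrt(delta_alpha(0.05, 1))
        assert ci.lower == pytest.approx(2.0 - half, abs=1e-4)
        assert ci.upper == pytest.approx(2.0 + half, abs=1e-4)
        assert ci.identifiable

    def test_simultaneous_df_widens_interval(self):
        curve = profile_objective(
            separable, ("t1", "t2"), np.array([2.0, 1.0]), 0.0, "t1"
        )
        pointwise = confidence_interval(curve, alpha=0.05, df=1)
        simultaneous = confidence_interval(curve, alpha=0.05, df=2)
        assert simultaneous.upper > pointwise.upper
        assert simultaneous.lower < pointwise.lower

    def test_flat_profile_unbounded(self):
        flat = lambda th: np.array([th[1] - 1.0])  # t1 absent from objective
        curve = profile_objective(flat, ("t1", "t2"), np.array([0.0, 1.0]), 0.0, "t1")
        ci = confidence_interval(curve)
        assert ci.lower == -np.inf and ci.upper == np.inf
        assert ci.identifiability == "practically-non-identifiable"

    def test_insufficient_points_raise(self):
        curve = profile_objective(
            separable, ("t1", "t2"), np.array([2.0, 1.0]), 0.0, "t1"
        )
        curve.converged[:] = False
        curve.converged[0] = True
        with pytest.raises(ProfilingError):
            confidence_interval(curve)


class TestProfileSamples:
    def test_identifiable_samples_stay_inside_interval(self):
        curve = profile_objective(
            separable, ("t1", "t2"), np.array([2.0, 1.0]), 0.0, "t1"
        )
        ci = confidence_interval(curve)
        ss = profile_samples(curve)
        vals = [s["t1"] for s in ss.samples]
        assert min(vals) >= ci.lower - 1e-9 and max(vals) <= ci.upper + 1e-9
        assert not any(ss.extended)

    def test_flat_profile_spans_extension_range(self):
        flat = lambda th: np.array([th[1] - 1.0])
        curve = profile_objective(flat, ("t1", "t2"), np.array([0.0, 1.0]), 0.0, "t1")
        ss = profile_samples(curve, extension=3.0)
        vals = np.array([s["t1"] for s in ss.samples])
        assert vals.min() == pytest.approx(-3.0, abs=0.11)
        assert vals.max() == pytest.approx(3.0, abs=0.11)
        assert all(ss.extended[i] for i in range(len(ss)) if abs(vals[i]) > 0.01)
        # sampling density on unbounded branches: >= 10 points per decade
        assert len(ss) >= 60

    def test_sample_count_matches_brute_force_filter(self):
        curve = profile_objective(
            correlated, ("t1", "t2"), np.zeros(2), 0.0, "t1"
        )
        thr = delta_alpha(0.05, 1)
        expected = int(
            np.sum(curve.converged & (curve.chi2_pl < thr) & (np.abs(curve.grid) <= 3 + 1e-12))
        )
        assert len(profile_samples(curve)) == expected


class TestLinearGaussianOracle:
    """Profiles of a linear model y = X theta match closed-form projection."""

    def _problem(self, seed=5, n=30, k=3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, k))
        theta_true = rng.normal(size=k)
        y = X @ theta_true + rng.normal(0, 0.5, n)
        sigma = 0.5
        resid = lambda th: (X @ th - y) / sigma
        theta_hat, *_ = np.linalg.lstsq(X / sigma, y / sigma, rcond=None)
        chi2_min = float(np.sum(resid(theta_hat) ** 2))
        return X, y, sigma, resid, theta_hat, chi2_min

    @staticmethod
    def _closed_form_profile(X, y, sigma, i, values):
        """Conditional least squares: minimize over the other columns."""
        n, k = X.shape
        others = [j for j in range(k) if j != i]
        Xo, xi = X[:, others], X[:, i]
        out = []
        for v in values:
            r = y - v * xi
            beta, *_ = np.linalg.lstsq(Xo, r, rcond=None)
            out.append(np.sum((r - Xo @ beta) ** 2) / sigma**2)
        return np.array(out)

    def test_profile_curve_matches_conditional_ls(self):
        X, y, sigma, resid, theta_hat, chi2_min = self._problem()
        labels = ("b0", "b1", "b2")
        for i, lab in enumerate(labels):
            curve = profile_objective(resid, labels, theta_hat, chi2_min, lab)
            exact = self._closed_form_profile(X, y, sigma, i, curve.grid)
            assert np.max(np.abs(curve.chi2_pl - exact)) < 1e-4

    def test_interval_matches_analytic_crossing(self):
        from scipy.optimize import brentq

        X, y, sigma, resid, theta_hat, chi2_min = self._problem()
        labels = ("b0", "b1", "b2")
        thr = chi2_min + delta_alpha(0.05, 1)
        for i, lab in enumerate(labels):
            curve = profile_objective(resid, labels, theta_hat, chi2_min, lab)
            ci = confidence_interval(curve)
            f = lambda v: self._closed_form_profile(X, y, sigma, i, [v])[0] - thr
            lo = brentq(f, theta_hat[i] - 10, theta_hat[i])
            hi = brentq(f, theta_hat[i], theta_hat[i] + 10)
            assert ci.lower == pytest.approx(lo, abs=1e-4)
            assert ci.upper == pytest.approx(hi, abs=1e-4)


class TestBundledModelProfiles:
    def test_monotone_wings_outside_confidence_region(self, insilico_curves):
        # away from the MLE, chi2_PL may not decrease (slack for optimizer
        # noise); a violation would indicate re-optimization failure
        slack = 1e-2
        for curve in insilico_curves.values():
            g, c = curve.grid[curve.converged], curve.chi2_pl[curve.converged]
            thr = curve.chi2_min + delta_alpha(0.05, 1)
            right = c[g >= curve.theta_hat_value]
            left = c[g <= curve.theta_hat_value][::-1]
            for branch in (right, left):
                outside = branch[branch > thr]
                if outside.size > 1:
                    assert np.all(np.diff(outside) > -slack)

    def test_profile_minimum_consistent_with_fit(self, insilico_curves):
        for curve in insilico_curves.values():
            assert np.min(curve.chi2_pl) >= curve.chi2_min - 0.05
            j = np.argmin(np.abs(curve.grid - curve.theta_hat_value))
            assert curve.chi2_pl[j] <= curve.chi2_min + 1e-3
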