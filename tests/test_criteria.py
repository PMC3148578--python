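import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ippca import (
    CriterionError,
    decide_eigendev,
    decide_tw,
    eigendev,
    tw_test,
)
from ippca.spectral import EigenSpectrum, RankSelection, eigendecompose
from ippca.tracy_widom import TW1_MEAN, tw1_cdf, tw1_isf, tw1_sf


def spectrum_of(vals):
    return eigendecompose(np.diag(np.asarray(vals, dtype=float)))


def rank_of(p):
    return RankSelection(p=p, variance_fraction=0.9, achieved_fraction=1.0)


def fit_line_oracle(y):
    """Independent closed-form normal-equations solution for y ~ a*i + b."""
    p = len(y)
    i = np.arange(1, p + 1)
    n = p
    sx, sy, sxx, sxy = i.sum(), y.sum(), (i * i).sum(), (i * y).sum()
    a = (n * sxy - sx * sy) / (n * sxx - sx**2)
    b = (sy - a * sx) / n
    return a, b


class TestEigenDev:
    def test_zero_on_exact_geometric_decay(self):
        lam = 5.0 * 0.5 ** np.arange(1, 7)
        value, fit = eigendev(spectrum_of(lam), rank_of(6))
        assert value == pytest.approx(0.0, abs=1e-10)
        assert fit.p_used == 6

    def test_scaling_invariance(self):
        lam = np.array([9.0, 4.0, 2.5, 1.0])
        v1, _ = eigendev(spectrum_of(lam), rank_of(4))
        v2, _ = eigendev(spectrum_of(10.0 * lam), rank_of(4))
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_matches_normal_equations_oracle_941(self):
        """EigenDev(9,4,1) = root total squared residual about the best log line."""
        y = np.log([9.0, 4.0, 1.0])
        a, b = fit_line_oracle(y)
        resid = y - (a * np.arange(1, 4) + b)
        expected = np.sqrt(np.sum(resid**2))
        value, fit = eigendev(spectrum_of([9.0, 4.0, 1.0]), rank_of(3))
        assert value == pytest.approx(expected, rel=1e-12)
        assert fit.slope == pytest.approx(a)
        assert fit.intercept == pytest.approx(b)
        # cross-check: RMS-residual variant is the statistic divided by sqrt(p)
        assert value / np.sqrt(3) == pytest.approx(
            np.sqrt(np.mean(resid**2)), rel=1e-12
        )
        assert np.sum(fit.residuals) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=3, max_size=12),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_oracle_equality_and_scale_invariance_random(self, vals, scale):
        lam = np.sort(np.asarray(vals))[::-1]
        p = len(lam)
        y = np.log(lam)
        a, b = fit_line_oracle(y)
        expected = np.sqrt(max(np.sum((y - (a * np.arange(1, p + 1) + b)) ** 2), 0.0))
        v, _ = eigendev(spectrum_of(lam), rank_of(p))
        assert v == pytest.approx(expected, rel=1e-9, abs=1e-9)
        v_scaled, _ = eigendev(spectrum_of(scale * lam), rank_of(p))
        assert v_scaled == pytest.approx(v, rel=1e-8, abs=1e-8)

    def test_monotone_sensitivity_in_leading_eigenvalue(self):
        bulk = [4.0, 3.0, 2.0, 1.5, 1.0]
        values = []
        for lam1 in (8.0, 16.0, 32.0, 64.0):
            v, _ = eigendev(spectrum_of([lam1] + bulk), rank_of(6))
            values.append(v)
        assert np.all(np.diff(values) > 0)

    def test_too_few_positive_eigenvalues(self):
        with pytest.raises(CriterionError):
            eigendev(spectrum_of([1.0, 1e-15, 0.0]), rank_of(3))


class TestDecisions:
    @pytest.mark.parametrize(
        "value,verdict",
        [(0.30, "structured"), (0.10, "homogeneous"), (0.21, "homogeneous")],
    )
    def test_eigendev_threshold_rule(self, value, verdict):
        d = decide_eigendev(value, threshold=0.21)
        assert d.verdict == verdict
        assert d.criterion == "eigendev"
        assert d.statistic == value

    def test_tw_cutoff_rule(self):
        assert decide_tw(10.0, 1e-15).verdict == "structured"
        assert decide_tw(1.0, 0.05).verdict == "homogeneous"
        assert decide_tw(5.0, 1e-12).verdict == "homogeneous"  # strict inequality

    def test_non_finite_rejected(self):
        with pytest.raises(CriterionError):
            decide_eigendev(np.nan)


class TestTracyWidomLaw:
    def test_published_significance_points(self):
        """Upper-tail quantiles match the published TW1 table values."""
        assert tw1_isf(0.05) == pytest.approx(0.9793, abs=2e-3)
        assert tw1_isf(0.01) == pytest.approx(2.0234, abs=2e-3)
        assert tw1_isf(0.001) == pytest.approx(3.2724, abs=2e-3)

    def test_quantile_self_consistency(self):
        for p in (0.5, 0.05, 1e-3, 1e-8, 1e-12, 1e-15):
            assert tw1_sf(tw1_isf(p)) == pytest.approx(p, rel=1e-6)

    def test_cdf_monotone_and_bounded(self):
        x = np.linspace(-12, 16, 400)
        cdf = tw1_cdf(x)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[0] == pytest.approx(0.0, abs=1e-12)
        assert cdf[-1] == pytest.approx(1.0, abs=1e-12)
        assert tw1_cdf(TW1_MEAN) == pytest.approx(0.48, abs=0.05)


class TestTWTest:
    def _stat(self, X):
        X = X - X.mean(axis=0)
        q = X.std(axis=0)
        X = X / np.where(q > 0, q, 1.0)
        spec = eigendecompose(X @ X.T / X.shape[1])
        return tw_test(spec, X.shape[0], X.shape[1])

    def test_null_calibration_gaussian(self):
        """On iid Gaussian data the far tail is not inflated."""
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(100):
            stat, p = self._stat(rng.normal(size=(40, 400)))
            pvals.append(p)
        pvals = np.asarray(pvals)
        assert (pvals < 1e-6).sum() == 0
        assert (pvals < 0.05).mean() < 0.2
        assert np.median(pvals) > 0.1

    def test_inflated_leading_eigenvalue_is_significant(self):
        """Moderate two-group differentiation drives the leading eigenvalue
        far above the bulk and the TW p-value below the 1e-12 cutoff."""
        from ippca import SimulationConfig, simulate
        from ippca.criteria import tw_from_table

        t = simulate(
            SimulationConfig(subpop_sizes=(50, 50), n_markers=500, divergence=0.02, seed=9)
        )
        stat, p = tw_from_table(t)
        assert stat > 10
        assert p < 1e-12

    def test_small_m_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 50))
        with pytest.raises(CriterionError):
            self._stat(X)
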