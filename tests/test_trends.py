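"""Cross-clone trend analyses on constructed and simulated ensembles."""

import numpy as np
import pandas as pd
import pytest

from burstflow import trends
from burstflow.cytometry import default_bins, histogram
from burstflow.trends import (
    burst_correlation,
    mode_prediction,
    parameter_trend,
    scatter_statistics,
    trend_report,
    typical_shape,
    variance_mean_regression,
)


def _summaries(mu, sigma2, b=None, ka=None):
    n = len(mu)
    return pd.DataFrame({
        "clone_id": [f"c{i}" for i in range(n)],
        "mu": mu,
        "sigma2": sigma2,
        "b": b if b is not None else [np.nan] * n,
        "kappa_a": ka if ka is not None else [np.nan] * n,
    })


class TestPowerLaws:
    def test_poisson_like_set_gives_slope_one(self):
        mu = np.geomspace(5, 500, 12)
        fit = variance_mean_regression(_summaries(mu, mu))
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_scaling_set_gives_slope_two(self):
        mu = np.geomspace(5, 500, 12)
        fit = variance_mean_regression(_summaries(mu, 0.3 * mu**2))
        assert fit.alpha == pytest.approx(2.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_parameter_trend_recovers_construction(self):
        mu = np.geomspace(5, 500, 15)
        df = _summaries(mu, mu**1.7, b=0.5 * mu, ka=np.full(15, 0.4))
        assert parameter_trend(df, "b").alpha == pytest.approx(1.0, abs=1e-12)
        ka_fit = parameter_trend(df, "kappa_a")
        assert ka_fit.alpha == pytest.approx(0.0, abs=1e-12)

    def test_confidence_interval_shrinks_with_more_clones(self):
        rng = np.random.default_rng(0)

        def ci_width(n):
            mu = np.geomspace(5, 500, n)
            noise = rng.lognormal(0, 0.3, n)
            fit = variance_mean_regression(_summaries(mu, mu**1.7 * noise))
            return fit.alpha_ci[1] - fit.alpha_ci[0]

        assert ci_width(160) < ci_width(40) / 1.5

    def test_too_few_clones_errors(self):
        with pytest.raises(ValueError):
            variance_mean_regression(_summaries([10, 20], [10, 20]))
        with pytest.raises(ValueError):
            parameter_trend(_summaries([10.0], [10.0], b=[5.0], ka=[1.0]), "b")


class TestBurstCorrelation:
    def test_independent_draws_are_uncorrelated(self):
        rng = np.random.default_rng(1)
        hits = 0
        for k in range(20):
            b = rng.lognormal(2, 0.5, 31)
            ka = rng.lognormal(-0.5, 0.4, 31)
            out = burst_correlation(_summaries(np.full(31, 50.0), np.full(31, 100.0), b, ka))
            hits += abs(out["pearson_r"]) < 0.3
        assert hits >= 17  # ~95% of seeds at n=31

    def test_functional_dependence_gives_unit_correlation(self):
        ka = np.geomspace(0.2, 3, 20)
        out = burst_correlation(_summaries(np.full(20, 50.0), np.full(20, 100.0),
                                           5.0 * ka**2, ka))
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["slope"] == pytest.approx(2.0, abs=1e-10)

    def test_invariant_to_rescaling(self):
        rng = np.random.default_rng(2)
        b = rng.lognormal(2, 0.5, 20)
        ka = rng.lognormal(-0.5, 0.4, 20)
        base = burst_correlation(_summaries(np.full(20, 50.0), np.full(20, 1.0), b, ka))
        scaled = burst_correlation(_summaries(np.full(20, 50.0), np.full(20, 1.0),
                                              7.3 * b, 0.11 * ka))
        assert scaled["pearson_r"] == pytest.approx(base["pearson_r"])


class TestTypicalShape:
    @staticmethod
    def _clone_hist(mean, cv, seed):
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(cv**2))
        vals = rng.lognormal(np.log(mean) - sigma**2 / 2, sigma, 100_000)
        return histogram(np.clip(vals, 0.1, 1000), default_bins())

    def test_single_clone_at_target_mean_is_fixed_point(self):
        h = self._clone_hist(50.0, 0.5, 1)
        out = typical_shape([h], alpha=1.7, target_mean=h.mean)
        assert np.abs(out.mass - h.mass).sum() < 0.05

    def test_transformed_clones_share_the_target_mean(self):
        hists = [self._clone_hist(m, 0.5, i) for i, m in enumerate((20, 40, 80, 160))]
        mu0 = float(np.median([h.mean for h in hists]))
        out = typical_shape(hists, alpha=1.7)
        assert out.meta["mu0"] == pytest.approx(mu0)
        assert out.mean == pytest.approx(mu0, rel=0.1)

    def test_variance_follows_regression_prediction(self):
        # clones constructed exactly on sigma^2 = mu^1.7; after rescaling all
        # should have variance mu0^1.7 (up to binning error)
        means = np.array([20.0, 40.0, 80.0, 160.0])
        hists = [self._clone_hist(m, np.sqrt(m**1.7) / m, i)
                 for i, m in enumerate(means)]
        out = typical_shape(hists, alpha=1.7)
        mu0 = out.meta["mu0"]
        assert out.variance == pytest.approx(mu0**1.7, rel=0.2)


class TestModePredictions:
    def test_mode1_fraction_tracks_burst_size_at_shared_frequency(self):
        b = np.geomspace(2, 50, 10)
        df = _summaries(10 * b, np.full(10, 1.0), b, np.full(10, 0.5))
        out = mode_prediction(df, mode=1, fixed_value=1000.0)
        # small-f limit: f ~ kappa_a * b / kappa_t_plus, proportional to b
        ratio = out["f_pred"].to_numpy() / b
        assert np.allclose(ratio, ratio[0], rtol=0.05)

    def test_mode2_fraction_constant_at_shared_frequency_and_duration(self):
        df = _summaries(np.geomspace(10, 500, 8), np.full(8, 1.0),
                        np.geomspace(2, 50, 8), np.full(8, 0.5))
        out = mode_prediction(df, mode=2, fixed_value=0.02)
        assert np.allclose(out["f_pred"], out["f_pred"].iloc[0])

    def test_bound_clipping_flagged(self):
        df = _summaries([10.0] * 5, [1.0] * 5, [30.0] * 5, [2.0] * 5)
        df["f_max"] = 0.01
        out = mode_prediction(df, mode=2, fixed_value=1.0)
        assert out["f_exceeds_bound"].all()
        assert (out["f_pred_clipped"] <= 0.01 + 1e-12).all()

    def test_invalid_inputs(self):
        df = _summaries([10.0] * 5, [1.0] * 5, [5.0] * 5, [0.5] * 5)
        with pytest.raises(ValueError):
            mode_prediction(df, mode=3, fixed_value=1.0)
        with pytest.raises(ValueError):
            mode_prediction(df, mode=1, fixed_value=-1.0)


class TestReport:
    def test_bundles_all_statistics(self):
        rng = np.random.default_rng(3)
        mu = np.geomspace(10, 300, 12)
        df = _summaries(mu, mu**1.7, b=0.4 * mu**0.8, ka=rng.lognormal(-0.5, 0.3, 12))
        report = trend_report(df)
        d = report.to_dict()
        assert d["variance_mean"]["alpha"] == pytest.approx(1.7, abs=1e-9)
        assert d["b_trend"]["alpha"] == pytest.approx(0.8, abs=1e-9)
        assert "pearson_r" in d["correlation"]
        assert "sigma_over_mu" in d["scatter"]["b"]
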