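"""Cytometry processing: gating, histograms, smoothing, (de)convolution."""

import numpy as np
import pandas as pd
import pytest

from burstflow import cytometry
from burstflow.cytometry import (
    clone_included,
    convolve_autofluorescence,
    deconvolve_autofluorescence,
    default_bins,
    gate_events,
    histogram,
    masked_sq_deviation,
    model_to_rfu,
    optimize_gate,
    smooth,
)
from burstflow.moments import InsufficientSignalError
from burstflow.params import CalibrationConstants


def _events(gfp, fsc=None, ssc=None, rng=None):
    n = len(gfp)
    rng = rng or np.random.default_rng(0)
    return pd.DataFrame({
        "gfp": gfp,
        "fsc": rng.uniform(1, 1024, n) if fsc is None else fsc,
        "ssc": rng.uniform(1, 1024, n) if ssc is None else ssc,
    })


def _lognormal_hist(mean, cv, n=200_000, seed=0, bins=None):
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    vals = rng.lognormal(np.log(mean) - sigma**2 / 2, sigma, n)
    return histogram(np.clip(vals, 0.1, 1000.0), default_bins() if bins is None else bins)


class TestHistogram:
    def test_single_value_gives_delta(self):
        h = histogram(np.full(5000, 17.3))
        assert np.count_nonzero(h.mass) == 1
        assert h.mass.max() == pytest.approx(1.0)

    def test_mass_conservation(self):
        h = _lognormal_hist(30.0, 0.6)
        assert h.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_binned_mean_close_to_sample_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(np.log(40), 0.4, 100_000)
        h = histogram(vals)
        # half a log-bin width is a factor edge ratio^0.5
        ratio = (h.edges[1] / h.edges[0]) ** 0.5
        assert vals.mean() / ratio < h.mean < vals.mean() * ratio

    def test_out_of_range_values_clipped_and_reported(self):
        h = histogram(np.array([0.01, 0.5, 2000.0, 30.0] * 300))
        assert h.meta["clipped_fraction"] == pytest.approx(0.5)
        assert h.mass.sum() == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            histogram(np.array([]))


class TestGate:
    def test_full_gate_is_identity(self):
        ev = _events(np.full(2000, 10.0))
        assert len(gate_events(ev, gate_fraction=1.0)) == 2000

    def test_joint_quantile_box_on_independent_uniform(self):
        rng = np.random.default_rng(2)
        ev = _events(np.full(100_000, 10.0), rng=rng)
        frac = len(gate_events(ev, gate_fraction=0.6)) / 100_000
        assert frac == pytest.approx(0.36, abs=0.01)

    def test_narrow_gate_reduces_cv_when_gfp_tracks_size(self):
        rng = np.random.default_rng(3)
        s = rng.lognormal(0, 0.3, 50_000)
        ev = _events(gfp=20.0 * s, fsc=512 * s, ssc=512 * s)
        cv = lambda df: df["gfp"].std() / df["gfp"].mean()
        assert cv(gate_events(ev, 0.1)) < cv(gate_events(ev, 0.6)) < cv(ev)

    def test_too_few_survivors_errors(self):
        ev = _events(np.full(1000, 10.0))
        with pytest.raises(ValueError):
            gate_events(ev, gate_fraction=0.01)


class TestSmoothing:
    def test_above_nyquist_is_identity_with_warning(self):
        h = _lognormal_hist(30.0, 0.6, n=5000)
        with pytest.warns(UserWarning):
            out = smooth(h, 500)
        assert np.allclose(out.mass, h.mass)

    def test_conserves_mass(self):
        h = _lognormal_hist(30.0, 0.6, n=5000)
        assert smooth(h, 16).mass.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reduces_distance_to_true_curve(self):
        truth = _lognormal_hist(30.0, 0.5, n=2_000_000, seed=10)
        noisy = _lognormal_hist(30.0, 0.5, n=3000, seed=11)
        raw_err = np.linalg.norm(noisy.mass - truth.mass)
        smooth_err = np.linalg.norm(smooth(noisy, 16).mass - truth.mass)
        assert smooth_err < raw_err

    def test_bootstrap_cutoff_in_candidate_set(self):
        rng = np.random.default_rng(4)
        gfp = rng.lognormal(np.log(30), 0.5, 4000)
        cut = cytometry.optimize_smoothing(gfp, default_bins(), n_boot=20, seed=5)
        assert cut in (6, 8, 12, 16, 24, 32, 48)


class TestConvolution:
    @pytest.fixture(scope="class")
    def af(self):
        return _lognormal_hist(5.0, 0.5, n=500_000, seed=20)

    def test_near_zero_signal_returns_autofluorescence(self, af):
        tiny = histogram(np.full(5000, 0.100001))
        out = convolve_autofluorescence(tiny, af)
        assert out.mean == pytest.approx(af.mean + 0.1, rel=0.02)
        assert out.variance == pytest.approx(af.variance, rel=0.05)

    def test_means_and_variances_add(self, af):
        sig = _lognormal_hist(60.0, 0.5, n=500_000, seed=21)
        out = convolve_autofluorescence(sig, af)
        assert out.mean == pytest.approx(sig.mean + af.mean, rel=0.01)
        assert out.variance == pytest.approx(sig.variance + af.variance, rel=0.03)

    def test_wiener_round_trip(self, af):
        sig = _lognormal_hist(60.0, 0.5, n=500_000, seed=22)
        back = deconvolve_autofluorescence(convolve_autofluorescence(sig, af), af)
        assert np.abs(back.mass - sig.mass).sum() < 0.02
        assert back.mean == pytest.approx(sig.mean, rel=0.02)

    def test_self_deconvolution_concentrates_at_low_rfu(self, af):
        out = deconvolve_autofluorescence(af, af)
        assert out.mean < 0.3 * af.mean

    def test_strong_regularization_never_amplifies(self, af):
        data = convolve_autofluorescence(_lognormal_hist(60.0, 0.5, seed=23), af)
        out = deconvolve_autofluorescence(data, af, noise_level=1e6)
        assert out.variance <= data.variance * 1.01

    def test_insufficient_signal_errors(self, af):
        dim = _lognormal_hist(2.0, 0.5, n=50_000, seed=24)
        with pytest.raises(InsufficientSignalError):
            deconvolve_autofluorescence(dim, af)


class TestModelToRfu:
    @pytest.fixture(scope="class")
    def af(self):
        return _lognormal_hist(5.0, 0.5, n=500_000, seed=30)

    def test_predicted_mean_is_calibrated_sum(self, af):
        calib = CalibrationConstants()
        pmf = np.exp(-0.5 * ((np.arange(4000) - 2000) / 250) ** 2)
        out = model_to_rfu(pmf / pmf.sum(), calib, af)
        assert out.mean == pytest.approx(calib.nu * 2000 + af.mean, rel=0.02)

    def test_invariant_to_translation_rate_rescaling(self, af):
        # co-updating nu with kappa_p_plus leaves the RFU output unchanged up
        # to protein shot noise; here the same distribution is mapped at two
        # protein scalings
        calib1 = CalibrationConstants(kappa_p_plus=10.0)
        calib2 = CalibrationConstants(kappa_p_plus=5.0)
        k = np.arange(8000)
        pmf1 = np.exp(-0.5 * ((k - 4000) / 600) ** 2)
        out1 = model_to_rfu(pmf1 / pmf1.sum(), calib1, af)
        k2 = np.arange(4000)  # half the counts at twice the per-protein yield
        pmf2 = np.exp(-0.5 * ((k2 - 2000) / 300) ** 2)
        out2 = model_to_rfu(pmf2 / pmf2.sum(), calib2, af)
        assert np.abs(out1.mass - out2.mass).sum() < 0.01

    def test_deviation_requires_shared_binning(self, af):
        h1 = _lognormal_hist(30.0, 0.5, n=5000, seed=31)
        h2 = _lognormal_hist(30.0, 0.5, n=5000, seed=31, bins=np.geomspace(0.1, 1000, 129))
        with pytest.raises(ValueError):
            masked_sq_deviation(h1, h2)


class TestGateOptimization:
    def test_independent_gfp_prefers_widest_gate(self):
        rng = np.random.default_rng(40)
        ev = _events(rng.lognormal(np.log(30), 0.5, 20_000), rng=rng)
        best = optimize_gate(ev, candidate_fractions=(0.2, 0.6, 1.0), n_boot=15, seed=1)
        assert best == 1.0

    def test_strong_size_coupling_prefers_narrower_gate(self):
        rng = np.random.default_rng(41)
        s = rng.lognormal(0, 0.5, 20_000)
        gfp = 30.0 * s**2 * rng.lognormal(0, 0.2, 20_000)
        ev = _events(gfp=np.clip(gfp, 0.1, 1000), fsc=np.clip(512 * s, 1, 1024),
                     ssc=np.clip(512 * s, 1, 1024))
        best = optimize_gate(ev, candidate_fractions=(0.2, 0.6, 1.0), n_boot=15, seed=2)
        assert best < 1.0


class TestInclusionRule:
    def test_two_fold_mean_threshold(self):
        af = _lognormal_hist(5.0, 0.5, seed=50)
        bright = _lognormal_hist(40.0, 0.5, seed=51)
        dim = _lognormal_hist(7.0, 0.5, seed=52)
        assert clone_included(bright, af)
        assert not clone_included(dim, af)
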