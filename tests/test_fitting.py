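"""Per-clone fitting: deviation metric, bootstrap bound, recovery, intervals."""

from types import SimpleNamespace

import numpy as np
import pytest

from burstflow import cytometry, fitting
from burstflow.cytometry import RfuHistogram
from burstflow.fitting import (
    BurstModel,
    FitConfig,
    bootstrap_dev_bound,
    confidence_intervals,
    deviation,
)
from burstflow.params import BurstCoordinates


def _hist(mass, edges=None):
    mass = np.asarray(mass, dtype=float)
    if edges is None:
        edges = np.geomspace(1.0, 10.0 ** mass.size, mass.size + 1)
    return RfuHistogram(edges=edges, mass=mass / mass.sum())


class TestDeviation:
    def test_identical_histograms_give_zero(self):
        h = _hist([0.2, 0.3, 0.5])
        assert deviation(h, h) == 0.0

    def test_disjoint_unit_masses(self):
        a = _hist([1.0, 1e-12, 1e-12])
        b = _hist([1e-12, 1.0, 1e-12])
        assert deviation(a, b) == pytest.approx(2.0, rel=1e-6)

    def test_direct_arithmetic(self):
        a = _hist([0.5, 0.5])
        b = _hist([0.6, 0.4])
        assert deviation(a, b) == pytest.approx(0.02)

    def test_mask_excludes_bins_negligible_in_both(self):
        # a bin below 2% of the maximum in both distributions is ignored
        a = _hist([0.98, 0.02, 8e-3])
        b = _hist([0.98, 0.02, 2e-3])
        with_mask = deviation(a, b)
        without_mask = deviation(a, b, mask_fraction=0.0)
        assert with_mask < without_mask
        assert with_mask == pytest.approx(
            sum((a.mass[:2] - b.mass[:2]) ** 2), rel=1e-9
        )


class TestBootstrapBound:
    def test_seeded_determinism(self, bursting_clone):
        kwargs = dict(n_boot=200, smooth_cutoff=16)
        a = bootstrap_dev_bound(bursting_clone.events, seed=3, **kwargs)
        b = bootstrap_dev_bound(bursting_clone.events, seed=3, **kwargs)
        assert a == b

    def test_shrinks_roughly_inverse_in_events(self, bursting_clone):
        ev = bursting_clone.events
        big = bootstrap_dev_bound(ev, n_boot=200, smooth_cutoff=16, seed=4)
        small = bootstrap_dev_bound(ev.iloc[:2500], n_boot=200, smooth_cutoff=16, seed=4)
        ratio = small / big
        assert 2.0 < ratio < 8.0  # squared-error deviation scales ~ 1/n


class TestInverseCrime:
    def test_exact_self_generated_data_recovered(self, af_hist, calib):
        # identical forward map on both sides: the only question is whether
        # the optimizer finds the generating parameters
        truth = BurstCoordinates(b=15.0, kappa_a=0.8, tau=0.02)
        config = FitConfig(n_starts=1)
        surrogate_mean = calib.gamma * truth.kappa_a * truth.b + af_hist.mean
        rng = np.random.default_rng(0)
        surrogate = cytometry.histogram(
            np.clip(rng.lognormal(np.log(surrogate_mean), 0.5, 5000), 0.1, 1000),
            af_hist.edges,
        )
        scaffold = BurstModel(surrogate, af_hist, calib=calib, config=config)
        data = scaffold.predict(truth.b, truth.kappa_a, truth.tau)
        model = BurstModel(data, af_hist, calib=calib, config=config)
        model._fwd = scaffold._fwd  # share the map: a pure inverse problem
        fit = model.fit(tau=truth.tau)
        assert fit.b == pytest.approx(truth.b, rel=0.02)
        assert fit.kappa_a == pytest.approx(truth.kappa_a, rel=0.02)
        assert fit.dev_fit < 1e-7

    def test_sampled_data_recovery_within_tolerance(
        self, bursting_clone, bursting_truth, data_hist, af_hist, calib
    ):
        dev_data = bootstrap_dev_bound(bursting_clone.events, n_boot=200,
                                       smooth_cutoff=16, seed=5)
        model = BurstModel(data_hist, af_hist, calib=calib, dev_data=dev_data,
                           config=FitConfig(n_starts=1))
        fit = model.fit(tau=bursting_truth.tau)
        assert abs(np.log10(fit.b / bursting_truth.b)) < 0.1
        assert abs(np.log10(fit.kappa_a / bursting_truth.kappa_a)) < 0.15
        # the fit cannot beat measurement uncertainty meaningfully
        assert fit.dev_r < 2.0

    def test_moment_start_close_to_truth(self, data_hist, af_hist, calib, bursting_truth):
        model = BurstModel(data_hist, af_hist, calib=calib)
        start = model.moment_start()
        assert abs(np.log10(start.b / bursting_truth.b)) < 0.3
        assert abs(np.log10(start.kappa_a / bursting_truth.kappa_a)) < 0.3


class TestConfidenceIntervals:
    def test_quadratic_surface_matches_closed_form(self):
        # Dev_r = f0 + 0.5 * dx' H dx in log10 coordinates: the per-axis
        # extent of the {delta Dev_r = 1} ellipse is sqrt(2 (H^-1)_kk)
        H = np.array([[30.0, 10.0], [10.0, 20.0]])
        x0 = np.array([1.0, -0.3])

        def dev_at(b, ka, tau):
            dx = np.array([np.log10(b), np.log10(ka)]) - x0
            return 0.5 + 0.5 * dx @ H @ dx

        model = SimpleNamespace(deviation_at=dev_at)
        fit = SimpleNamespace(model=model, b=10.0 ** x0[0], kappa_a=10.0 ** x0[1],
                              tau=0.02, dev_fit=0.5, dev_data=1.0)
        ci = confidence_intervals(fit, step=0.02)
        expected = np.sqrt(2.0 * np.diag(np.linalg.inv(H)))
        assert ci.loc["b", "log10_halfwidth"] == pytest.approx(expected[0], rel=0.02)
        assert ci.loc["kappa_a", "log10_halfwidth"] == pytest.approx(expected[1], rel=0.02)
        assert (ci["lower"] < [fit.b, fit.kappa_a]).all()
        assert (ci["upper"] > [fit.b, fit.kappa_a]).all()

    def test_requires_deviation_bound(self, data_hist, af_hist, calib):
        model = BurstModel(data_hist, af_hist, calib=calib)
        fit = fitting.BurstFitResults(model=model, b=10, kappa_a=0.5, tau=0.02,
                                      dev_fit=1e-4, dev_data=None, converged=True, n_fev=1)
        with pytest.raises(ValueError):
            fit.conf_int()

    def test_intervals_shrink_with_more_events(
        self, bursting_clone, bursting_truth, af_hist, calib
    ):
        cfg = FitConfig(n_starts=1)
        widths = []
        for n_ev in (2500, 10_000):
            ev = bursting_clone.events.iloc[:n_ev]
            data = cytometry.process_clone(ev, gate=0.6, smooth_cutoff=16, seed=1)
            dev_data = bootstrap_dev_bound(ev, n_boot=200, smooth_cutoff=16, seed=6)
            model = BurstModel(data, af_hist, calib=calib, dev_data=dev_data, config=cfg)
            fit = model.fit(tau=bursting_truth.tau)
            widths.append(fit.conf_int().loc["b", "log10_halfwidth"])
        assert widths[1] < widths[0]


class TestResultsAPI:
    def test_summary_mentions_parameters(self, data_hist, af_hist, calib):
        model = BurstModel(data_hist, af_hist, calib=calib, dev_data=1e-4,
                           config=FitConfig(n_starts=1), clone_id="demo")
        fit = model.fit(tau=0.02)
        text = fit.summary()
        assert "burst size" in text and "kappa_a" in text and "Dev_r" in text

    def test_to_dict_round_trips_through_json(self, data_hist, af_hist, calib, tmp_path):
        import json

        model = BurstModel(data_hist, af_hist, calib=calib, dev_data=1e-4,
                           config=FitConfig(n_starts=1, tau_grid=(0.005, 0.02, 0.3)))
        prof = model.fit_profile()
        path = tmp_path / "fit.json"
        prof.save(path)
        back = json.loads(path.read_text())
        assert back["b_opt"] == pytest.approx(prof.b_opt)
        assert len(back["dev_r_profile"]) == 3

    def test_binning_mismatch_is_hard_error(self, data_hist, calib):
        other = cytometry.histogram(np.full(2000, 10.0), np.geomspace(0.1, 1000, 65))
        with pytest.raises(ValueError):
            BurstModel(data_hist, other, calib=calib)
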