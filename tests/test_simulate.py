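"""Synthetic-data generator: determinism, calibration, SSA cross-checks."""

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp, poisson

from burstflow import cme, simulate
from burstflow.moments import analytic_moments
from burstflow.params import BurstCoordinates, RateConstants
from burstflow.simulate import (
    ScenarioSpec,
    generate_autofluorescence,
    scenario_coordinates,
    simulate_clone,
    simulate_clone_ssa,
)

MILD = RateConstants(0.8, 4.0, 20.0, 1.0, 0.25)  # modest copy numbers, SSA-friendly


class TestDeterminism:
    def test_same_seed_is_bit_identical(self, calib):
        coords = BurstCoordinates(b=10.0, kappa_a=0.5, tau=0.02)
        a = simulate_clone(coords, calib=calib, n_events=1000, seed=5)
        b = simulate_clone(coords, calib=calib, n_events=1000, seed=5)
        assert a.events.equals(b.events)

    def test_different_seeds_differ(self, calib):
        coords = BurstCoordinates(b=10.0, kappa_a=0.5, tau=0.02)
        a = simulate_clone(coords, calib=calib, n_events=1000, seed=5)
        b = simulate_clone(coords, calib=calib, n_events=1000, seed=6)
        assert not a.events.equals(b.events)

    def test_ground_truth_recorded(self, bursting_clone, bursting_truth):
        gt = bursting_clone.ground_truth
        assert gt["b"] == bursting_truth.b
        assert gt["kappa_a"] == bursting_truth.kappa_a


class TestCalibration:
    def test_gfp_mean_matches_model_prediction_without_size_coupling(self, calib):
        coords = BurstCoordinates(b=12.0, kappa_a=0.6, tau=0.02)
        clone = simulate_clone(coords, calib=calib, n_events=10_000, seed=9,
                               size_coupling=0.0, autofluor_mean=5.0)
        mom = analytic_moments(clone.rates)
        nu = clone.calib.with_kappa_p_plus(simulate.SOLVER_KAPPA_P_PLUS).nu
        expected = nu * mom.protein_mean + 5.0
        gfp = clone.events["gfp"].to_numpy()
        se = gfp.std() / np.sqrt(gfp.size)
        assert abs(gfp.mean() - expected) < 3 * se + 0.05 * expected

    def test_size_coupling_creates_gfp_fsc_correlation(self, bursting_clone):
        ev = bursting_clone.events
        r = np.corrcoef(ev["gfp"], ev["fsc"])[0, 1]
        assert r > 0.05

    def test_channels_within_instrument_ranges(self, bursting_clone):
        ev = bursting_clone.events
        assert ev["gfp"].between(0.1, 1000.0).all()
        assert ev["fsc"].between(1, 1024).all()
        assert ev["ssc"].between(1, 1024).all()


class TestAutofluorescence:
    def test_configured_mean_and_cv(self):
        ev = generate_autofluorescence(n_events=20_000, mean=5.0, cv=0.5, seed=3)
        gfp = ev["gfp"].to_numpy()
        assert gfp.mean() == pytest.approx(5.0, rel=0.05)
        assert gfp.std() / gfp.mean() == pytest.approx(0.5, rel=0.1)

    def test_inclusion_rule_arithmetic(self):
        # a clone whose signal mean is below 1x the background mean fails the
        # 2x-total-mean inclusion filter once background is added
        from burstflow.cytometry import clone_included, histogram

        af = histogram(generate_autofluorescence(n_events=20_000, seed=4))
        rng = np.random.default_rng(5)
        signal = rng.exponential(3.0, 20_000)  # signal mean < autofluor mean (5)
        total = histogram(np.clip(signal + generate_autofluorescence(
            n_events=20_000, seed=6)["gfp"].to_numpy(), 0.1, 1000))
        assert not clone_included(total, af)


class TestScenarios:
    def test_frequency_only_ranges(self):
        spec = ScenarioSpec(scenario="frequency_only", n_clones=40, seed=1)
        coords = scenario_coordinates(spec, np.random.default_rng(1))
        ka = np.array([c.kappa_a for c in coords])
        assert np.all((ka >= 0.1) & (ka <= 3.0))
        assert all(c.b == 15.0 for c in coords)

    def test_combined_coupling_spans_b_range(self):
        spec = ScenarioSpec(scenario="combined", n_clones=200, seed=2)
        coords = scenario_coordinates(spec, np.random.default_rng(2))
        b = np.array([c.b for c in coords])
        ka = np.array([c.kappa_a for c in coords])
        assert b.min() >= 2.0 * 0.99 and b.max() <= 50.0 * 1.01
        # coupling b = c * kappa_a^2
        c_vals = b / ka**2
        assert np.allclose(c_vals, c_vals[0])

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario="sideways")

    def test_ensemble_moments_columns(self):
        df = simulate.ensemble_moments(ScenarioSpec(scenario="size_only", n_clones=6, seed=3))
        assert len(df) == 6
        assert {"rfu_mean", "rfu_variance", "b", "kappa_a"} <= set(df.columns)


class TestSSA:
    @pytest.fixture(scope="class")
    def ssa_samples(self):
        return simulate_clone_ssa(MILD, n_cells=20_000, seed=11)

    def test_constitutive_transcripts_are_poisson(self):
        rates = RateConstants(10.0, 1e-9, 5.0, 1.0, 0.25)
        out = simulate_clone_ssa(rates, n_cells=20_000, seed=12)
        m = out["transcript"]
        kmax = 14
        counts = np.bincount(np.minimum(m, kmax), minlength=kmax + 1)
        probs = poisson.pmf(np.arange(kmax + 1), 5.0)
        probs[-1] = 1 - probs[:-1].sum()
        stat = chisquare(counts, probs * counts.sum())
        assert stat.pvalue > 0.01

    def test_agrees_with_brute_force_oracle(self, ssa_samples):
        oracle = cme.brute_force_oracle(MILD, n_sd=10)
        pmf = cme.fine_pmf(oracle.marginal("protein"))
        n = ssa_samples["protein"]
        kmax = int(np.quantile(n, 0.999))
        counts = np.bincount(np.minimum(n, kmax), minlength=kmax + 1)
        probs = pmf[: kmax + 1].copy()
        probs[-1] = 1.0 - probs[:-1].sum()
        expected = probs * counts.sum()
        keep = expected > 5
        stat = chisquare(counts[keep], expected[keep] * counts[keep].sum() / expected[keep].sum())
        assert stat.pvalue > 0.01

    def test_stationarity_doubling_duration(self, ssa_samples):
        longer = simulate_clone_ssa(MILD, duration=2 * 12.0 / MILD.kappa_p_minus,
                                    n_cells=20_000, seed=13)
        stat = ks_2samp(ssa_samples["protein"], longer["protein"])
        assert stat.pvalue > 0.01

    def test_requires_stationary_duration(self):
        with pytest.raises(ValueError):
            simulate_clone_ssa(MILD, duration=1.0)

    def test_sampling_paths_indistinguishable(self, calib):
        # CME-marginal sampling vs exact stochastic simulation of the same
        # parameters must give statistically identical event tables
        coords = BurstCoordinates(b=5.0, kappa_a=0.8, tau=0.25)
        a = simulate_clone(coords, calib=calib, n_events=8000, seed=21, method="cme",
                           size_coupling=0.0)
        b = simulate_clone(coords, calib=calib, n_events=8000, seed=22, method="ssa",
                           size_coupling=0.0)
        stat = ks_2samp(a.events["gfp"], b.events["gfp"])
        assert stat.pvalue > 0.01


class TestEnsembleIO:
    def test_write_ensemble_round_trip(self, tmp_path, calib):
        spec = ScenarioSpec(scenario="size_only", n_clones=2, n_events=1000, seed=8,
                            calib=calib)
        clones = simulate.generate_ensemble(spec)
        simulate.write_ensemble(clones, tmp_path)
        import json

        manifest = json.loads((tmp_path / "ground_truth.json").read_text())
        assert len(manifest) == 2
        assert (tmp_path / manifest[0]["events"]).exists()
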