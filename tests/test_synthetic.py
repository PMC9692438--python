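"""Generators and the co-culture simulator.

Each generator must be a right inverse of its fitter in the noise-free
limit, be bit-reproducible under a fixed seed, and carry the noise
structure its analysis assumes.  The co-culture simulator must conserve
phage bookkeeping and produce regrowth if and only if resistance
mutations occur.
"""

import numpy as np
import pytest

from phagekit.adsorption import adsorption_model, fit_adsorption
from phagekit.errors import InputError
from phagekit.growth import extract_growth_parameters, fit_4pl, four_pl
from phagekit.inactivation import detect_regrowth, log_reduction
from phagekit.photometry import fit_extinction, fit_storage_decay
from phagekit.synthetic import (
    CocultureParams,
    SimulationConfig,
    gen_adsorption,
    gen_dilution_series,
    gen_genome,
    gen_osgc,
    gen_plate_counts,
    gen_storage,
    simulate_coculture,
)


class TestGeneratorFitterInverses:
    """fit(gen(theta, sd=0)) == theta to 1e-6 relative, for every pair."""

    def test_osgc(self):
        truth = (4.0, 6.025, 30.0, 8.0)
        fit = fit_4pl(gen_osgc(*truth, noise_sd=0.0, n_reps=1))
        np.testing.assert_allclose(fit.params, truth, rtol=1e-6)

    def test_adsorption(self):
        fit = fit_adsorption(gen_adsorption(1.904e-10, 5.664e-3, 1e8, noise_sd=0.0))
        assert fit.delta == pytest.approx(1.904e-10, rel=1e-6)
        assert fit.phi == pytest.approx(5.664e-3, rel=1e-6)

    def test_extinction(self):
        fit = fit_extinction(gen_dilution_series(2.7648e-10, noise_sd=0.0))
        assert fit.epsilon == pytest.approx(2.7648e-10, rel=1e-6)

    def test_storage(self):
        fit = fit_storage_decay(gen_storage(11.494, noise_sd=0.0))
        assert fit.tau_days == pytest.approx(11.494, rel=1e-6)


class TestNoiseStructure:
    def test_osgc_noise_free_lies_on_curve(self):
        curve = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.0, n_reps=3)
        truth = four_pl(curve.times_min, 4.0, 6.0, 30.0, 8.0)
        np.testing.assert_allclose(curve.log_titers, truth, rtol=1e-12)

    def test_osgc_replicate_sd_in_expected_range(self):
        curve = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.05, n_reps=3, rng=0)
        times = np.unique(curve.times_min)
        sds = [curve.log_titers[curve.times_min == t].std(ddof=1) for t in times]
        # pooled replicate sd concentrates near the generating value
        pooled = np.sqrt(np.mean(np.square(sds)))
        assert 0.02 <= pooled <= 0.10

    def test_adsorption_zero_delta_gives_unit_fractions(self):
        curve = gen_adsorption(0.0, 0.0, 1e8, noise_sd=0.0)
        np.testing.assert_allclose(curve.free_fraction, 1.0)

    def test_adsorption_reference_value_at_150(self):
        curve = gen_adsorption(1.904e-10, 5.664e-3, 1e8, noise_sd=0.0, n_reps=1)
        val = curve.free_fraction[curve.times_min == 150.0][0]
        assert val == pytest.approx(0.2482, abs=2e-4)

    def test_plate_counts_poisson_mean(self):
        counts = [
            np.mean(gen_plate_counts(4e8, rng=seed).counts) for seed in range(200)
        ]
        # Poisson(20), n=600 droplets total: mean within 5 sd of 20
        assert np.mean(counts) == pytest.approx(20.0, abs=1.0)

    def test_storage_day_zero_anchor_exact(self):
        series = gen_storage(11.494, noise_sd=0.2, rng=9)
        assert series.ratios[series.days == 0][0] == 1.0

    def test_determinism_under_seed(self):
        a = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.05, rng=42)
        b = gen_osgc(4.0, 6.0, 30.0, 8.0, noise_sd=0.05, rng=42)
        np.testing.assert_array_equal(a.log_titers, b.log_titers)
        ka, _ = simulate_coculture(rng=42, stochastic=True)
        kb, _ = simulate_coculture(rng=42, stochastic=True)
        np.testing.assert_array_equal(ka.bp_b, kb.bp_b)


class TestCoculture:
    def test_no_phage_no_mutation_is_pure_logistic(self):
        p = CocultureParams(delta_ml_per_cfu_min=0.0, mutation_prob=0.0, p0_per_ml=0.0)
        kc, _ = simulate_coculture(p, horizon_h=24.0)
        assert kc.bc[-1] == pytest.approx(p.carrying_capacity_per_ml, rel=0.01)
        np.testing.assert_allclose(kc.bc, kc.bp_b, rtol=1e-9)

    def test_phage_conservation_bookkeeping(self):
        _, book = simulate_coculture(CocultureParams(), horizon_h=24.0)
        expected = (
            book["p0_total"]
            - book["total_adsorbed"]
            + CocultureParams().burst_size * book["total_bursts"]
        )
        assert book["p_final"] == pytest.approx(expected, rel=1e-6)

    def test_high_moi_without_mutation_declines_without_regrowth(self):
        p = CocultureParams(mutation_prob=0.0, p0_per_ml=1e8)  # MOI 1000
        kc, _ = simulate_coculture(p, horizon_h=24.0)
        treated = np.log10(np.maximum(kc.bp_b, kc.detection_limit))
        assert kc.bp_b[-1] < kc.bp_b[0]
        assert not detect_regrowth(kc.times_h, treated).regrowth

    def test_mutation_free_runs_never_regrow_over_seeds(self):
        p = CocultureParams(mutation_prob=0.0)
        for seed in range(20):
            kc, _ = simulate_coculture(p, stochastic=True, rng=seed)
            treated = np.log10(np.maximum(kc.bp_b, kc.detection_limit))
            assert not detect_regrowth(kc.times_h, treated).regrowth

    def test_mutation_produces_regrowth_in_majority_of_seeds(self):
        p = CocultureParams(mutation_prob=1e-7)
        detected = 0
        for seed in range(20):
            kc, _ = simulate_coculture(p, stochastic=True, rng=seed)
            treated = np.log10(np.maximum(kc.bp_b, kc.detection_limit))
            if detect_regrowth(kc.times_h, treated).regrowth:
                detected += 1
        assert detected > 10

    def test_killing_curve_interface_compatibility(self):
        kc, _ = simulate_coculture(CocultureParams(mutation_prob=0.0))
        profile = log_reduction(kc)
        assert profile.max_reduction > 1.0  # phage visibly suppress bacteria

    def test_invalid_dt_rejected(self):
        with pytest.raises(InputError):
            simulate_coculture(CocultureParams(), dt_h=0.5)  # coarse vs 40-min latency


class TestSimulationConfig:
    def test_yaml_round_trip_and_digest(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("seed: 7\nosgc:\n  noise_sd: 0.02\n")
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.seed == 7
        assert cfg.osgc["noise_sd"] == 0.02
        assert cfg.osgc["a"] == 30.0  # defaults preserved under partial override
        assert cfg.digest() != SimulationConfig().digest()
        assert cfg.digest() == SimulationConfig.from_yaml(path).digest()

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("nonsense: 1\n")
        with pytest.raises(InputError):
            SimulationConfig.from_yaml(path)


def test_burst_size_truth_round_trip():
    # plateau-to-baseline ratio of 106 flows through fit and extraction
    curve = gen_osgc(4.0, 4.0 + np.log10(106), 30.0, 8.0, noise_sd=0.0, n_reps=1)
    gp = extract_growth_parameters(fit_4pl(curve))
    assert gp.burst_size == pytest.approx(106, abs=1e-6)


def test_adsorption_model_limits():
    delta, phi, x0 = 1.904e-10, 5.664e-3, 1e8
    assert adsorption_model(0.0, delta, phi, x0) == 1.0
    eq = phi / (delta * x0 + phi)
    assert adsorption_model(1e8, delta, phi, x0) == pytest.approx(eq, rel=1e-12)
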