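"""The synthetic-study generator: determinism, calibrated specialisation,
forward-simulation correctness and compatibility with the ingest path."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from metaoccu import io as mio
from metaoccu.network import d_prime, scores_frame
from metaoccu.occupancy import linpred_psi1
from metaoccu.simulate import (GeneratorConfig, generate_dataset,
                               generate_detections, generate_network,
                               generate_pollen, generate_truth, write_dataset)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = GeneratorConfig(n_species=6, n_sites=4, n_restored=2, seed=9)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        assert np.array_equal(a.detections.V, b.detections.V)
        assert np.array_equal(a.latent_z, b.latent_z)
        assert np.array_equal(a.network.counts, b.network.counts)
        assert a.pollen_pairs.equals(b.pollen_pairs)

    def test_species_count_does_not_shift_site_covariates(self):
        a = generate_truth(GeneratorConfig(n_species=5, n_sites=4,
                                           n_restored=2, seed=9))[1]
        b = generate_truth(GeneratorConfig(n_species=9, n_sites=4,
                                           n_restored=2, seed=9))[1]
        assert np.array_equal(a.woody_z, b.woody_z)
        assert np.array_equal(a.date_z, b.date_z)


class TestGenerateTruth:
    def test_dprime_moments_match_target(self):
        _, covs, _ = generate_truth(GeneratorConfig(seed=4))
        assert covs.d_prime.mean() == pytest.approx(0.29, abs=0.02)
        assert covs.d_prime.std() == pytest.approx(0.13, abs=0.02)

    def test_zero_hyper_sd_collapses_intercepts(self):
        params, _, _ = generate_truth(GeneratorConfig(
            n_species=7, n_sites=4, n_restored=2, seed=1,
            sd_psi1_0=1e-12, mu_psi1_0=-0.7))
        assert np.allclose(params.psi1_0, -0.7)

    def test_infeasible_beta_moments_rejected(self):
        with pytest.raises(ValueError, match="Beta"):
            generate_truth(GeneratorConfig(dprime_mean=0.5, dprime_sd=0.6))

    def test_covariates_are_standardised(self):
        _, covs, _ = generate_truth(GeneratorConfig(seed=4))
        assert covs.woody_z.mean() == pytest.approx(0.0, abs=1e-9)
        assert covs.woody_z.std() == pytest.approx(1.0, rel=1e-9)
        assert covs.date_z.mean() == pytest.approx(0.0, abs=1e-9)
        assert set(np.unique(covs.restored)) == {0, 1}


class TestGenerateDetections:
    def test_perfect_detection_reveals_latent_state(self):
        cfg = GeneratorConfig(n_species=6, n_sites=4, n_restored=2, seed=5)
        params, covs, _ = generate_truth(cfg)
        params.p_0 = np.full(6, 50.0)
        params.p_2 = np.zeros(6)
        params.p_3 = np.zeros(6)
        V, Z = generate_detections(params, covs, cfg)
        assert np.array_equal(V, np.repeat(Z[..., None], cfg.n_surveys, axis=3))

    def test_impossible_occupancy_gives_no_detections(self):
        cfg = GeneratorConfig(n_species=6, n_sites=4, n_restored=2, seed=5,
                              mu_psi1_0=-50.0, sd_psi1_0=1e-12,
                              mu_gamma_0=-50.0, sd_gamma_0=1e-12,
                              psi1_slopes=(0,) * 5, gamma_slopes=(0,) * 5)
        params, covs, _ = generate_truth(cfg)
        V, Z = generate_detections(params, covs, cfg)
        assert not V.any() and not Z.any()

    def test_first_year_occupancy_matches_binomial_oracle(self):
        # ~5000 species-site cells against the mean of psi1
        cfg = GeneratorConfig(n_species=500, n_sites=10, n_restored=5, seed=6)
        params, covs, _ = generate_truth(cfg)
        V, Z = generate_detections(params, covs, cfg)
        psi1 = linpred_psi1(params, covs)
        expect = psi1.mean()
        observed = Z[..., 0].mean()
        se = np.sqrt((psi1 * (1 - psi1)).mean() / psi1.size)
        assert abs(observed - expect) < 3 * se


class TestGenerateNetwork:
    def test_specialisation_gradient_tracks_weights(self):
        cfg = GeneratorConfig(seed=1)
        net, wf = generate_network(cfg)
        scores = scores_frame(d_prime(net))
        rho = spearmanr(wf["weight"], scores["d_prime"]).statistic
        assert rho > 0.8
        assert scores["d_prime"].mean() == pytest.approx(
            cfg.dprime_mean, abs=0.05)

    def test_extreme_weights_hit_extreme_dprime(self):
        cfg = GeneratorConfig(n_species=20, seed=2)
        weights = np.full(20, 0.01)
        weights[-1] = 1.0
        net, _ = generate_network(cfg, weights=weights)
        scores = scores_frame(d_prime(net))
        generalists = scores["d_prime"].iloc[:-1]
        assert generalists.mean() < 0.1
        assert scores["d_prime"].iloc[-1] > 0.9

    def test_too_few_genera_rejected(self):
        with pytest.raises(ValueError):
            generate_network(GeneratorConfig(n_genera=1))


class TestGeneratePollen:
    def test_theta_zero_means_no_limited_pairs(self):
        from metaoccu.pollen import score_pairs
        cfg = GeneratorConfig(seed=3, theta_control=0.0, theta_restored=0.0,
                              pollen_exclusion_rate=0.0)
        scored = score_pairs(generate_pollen(cfg).drop(columns=["restored"]))
        assert all(p.limited == 0 for p in scored)

    def test_planted_exclusion_rate(self):
        cfg = GeneratorConfig(seed=8, n_sites=40, n_restored=20,
                              pollen_n_restored=20, pollen_n_control=20,
                              pollen_pairs_per_site=50,
                              pollen_exclusion_rate=0.1)
        from metaoccu.pollen import score_pairs
        scored = score_pairs(generate_pollen(cfg).drop(columns=["restored"]))
        rate = np.mean([p.excluded for p in scored])
        n = len(scored)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(rate - 0.1) < 3 * se


class TestIngestCompatibility:
    def test_written_dataset_round_trips_through_ingest(self, tmp_path,
                                                        small_dataset):
        write_dataset(small_dataset, tmp_path)
        records = mio.read_survey_table(tmp_path / "surveys.csv")
        array = mio.build_detection_array(records)
        assert np.array_equal(array.V, small_dataset.detections.V)
        assert array.species_ids == small_dataset.detections.species_ids
        sites = mio.read_site_table(tmp_path / "sites.csv")
        assert sites.site_ids == small_dataset.site_table.site_ids
        pairs = pd.read_csv(tmp_path / "pollen_pairs.csv")
        assert {"site_id", "plant_id", "control_seeds",
                "supplemented_seeds"} <= set(pairs.columns)

    def test_detection_array_invariants(self, small_dataset):
        det = small_dataset.detections
        assert set(np.unique(det.V)) <= {0, 1}
        assert det.mask.all()
        # every retained species detected at least once
        assert det.V.reshape(det.n_species, -1).any(axis=1).all()
        # latent truth is consistent: detections only where occupied
        assert (det.V.max(axis=3) <= small_dataset.latent_z).all()
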