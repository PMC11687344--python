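"""The marginalised dynamic occupancy model: linear predictors, recursion,
likelihood (against exhaustive latent-state enumeration), gradients, the
posterior machinery, and the random-slopes variant."""

import itertools

import numpy as np
import pytest
from scipy.special import expit

from metaoccu.io import DetectionArray, Standardizer
from metaoccu.occupancy import (CommunityOccupancyModel, CovariateBundle,
                                OccupancyParams, PosteriorDraws,
                                RandomSlopesOccupancyModel, SamplerSettings,
                                detection_prob, fit, fit_random_slopes_variant,
                                linpred_gamma, linpred_phi, linpred_psi1,
                                marginal_loglik_site_species,
                                occupancy_recursion, occupancy_trajectory,
                                summarize, total_loglik)
from metaoccu.simulate import GeneratorConfig, generate_dataset


def brute_force_loglik(V, mask, psi1, gamma, phi, p):
    """Sum the joint probability over all 2^K latent occupancy sequences."""
    K, L = V.shape
    total = 0.0
    for zs in itertools.product([0, 1], repeat=K):
        pr = psi1 if zs[0] == 1 else 1 - psi1
        for t in range(1, K):
            if zs[t - 1] == 1:
                pr *= phi[t - 1] if zs[t] == 1 else 1 - phi[t - 1]
            else:
                pr *= gamma[t - 1] if zs[t] == 1 else 1 - gamma[t - 1]
        for k in range(K):
            for l in range(L):
                if not mask[k, l]:
                    continue
                pd = p[k, l] * zs[k]
                pr *= pd if V[k, l] == 1 else 1 - pd
        total += pr
    return np.log(total)


def _params(S, K, rng=None, **overrides):
    rng = rng or np.random.default_rng(0)
    base = dict(
        psi1_0=rng.normal(0, 1, S), psi1=rng.normal(0, 0.5, 5),
        gamma_0=rng.normal(-1, 1, S), gamma=rng.normal(0, 0.5, 5),
        gamma_year=np.r_[0.0, rng.normal(0, 0.3, K - 2)] if K > 1 else np.zeros(0),
        phi_0=rng.normal(0.5, 1, S), phi=rng.normal(0, 0.5, 5),
        phi_year=np.r_[0.0, rng.normal(0, 0.3, K - 2)] if K > 1 else np.zeros(0),
        p_0=rng.normal(0, 1, S), p_1=0.5, p_2=rng.normal(0, 0.5, S),
        p_3=rng.normal(-1, 0.3, S), p_4=0.3, p_year=np.r_[0.0, rng.normal(0, 0.3, K - 1)],
    )
    base.update(overrides)
    return OccupancyParams(**base)


def _covs(S, J, K, L, rng=None):
    rng = rng or np.random.default_rng(1)
    dp = rng.beta(2, 5, S)
    dp_z = (dp - dp.mean()) / dp.std() if S > 1 else np.zeros(S)
    return CovariateBundle(
        d_prime=dp, d_prime_z=dp_z,
        degree_z=rng.normal(0, 1, S),
        restored=(np.arange(J) < J // 2).astype(int),
        woody_z=rng.normal(0, 1, (J, K)),
        date_z=rng.normal(0, 1, (J, K, L)),
        survey_flowers_z=rng.normal(0, 1, (J, K, L)),
    )


class TestLinearPredictors:
    def test_all_zero_gives_half(self):
        S, J, K, L = 2, 2, 2, 2
        params = _params(S, K, psi1_0=np.zeros(S), psi1=np.zeros(5))
        covs = _covs(S, J, K, L)
        assert np.allclose(linpred_psi1(params, covs), 0.5)

    def test_restoration_effect_direction(self):
        # a positive restoration slope raises initial occurrence at restored sites
        S, J, K, L = 1, 2, 2, 2
        params = _params(S, K, psi1_0=np.zeros(S),
                         psi1=np.array([0, 2.26, 0, 0, 0.0]))
        covs = _covs(S, J, K, L)
        covs.restored = np.array([1, 0])
        psi = linpred_psi1(params, covs)
        assert psi[0, 0] == pytest.approx(expit(2.26))
        assert psi[0, 1] == pytest.approx(0.5)

    def test_opposite_slopes_cancel(self):
        S, J, K, L = 1, 1, 2, 2
        covs = _covs(S, J, K, L)
        covs.d_prime_z = np.array([1.0])
        covs.restored = np.array([1])
        params = _params(S, K, psi1_0=np.zeros(S),
                         psi1=np.array([1.0, -1.0, 0, 0, 0]))
        assert linpred_psi1(params, covs)[0, 0] == pytest.approx(0.5)

    def test_detection_peaks_at_standardised_date_zero(self):
        S, J, K, L = 1, 1, 1, 5
        params = _params(S, 1, p_0=np.zeros(S), p_1=0.0, p_2=np.zeros(S),
                         p_3=np.array([-1.5]), p_4=0.0, p_year=np.zeros(1))
        covs = _covs(S, J, K, L)
        covs.date_z = np.linspace(-2, 2, L).reshape(1, 1, L)
        covs.degree_z = np.zeros(S)
        covs.survey_flowers_z = np.zeros((J, K, L))
        p = detection_prob(params, covs)[0, 0, 0]
        assert p.argmax() == L // 2
        assert p[L // 2] == pytest.approx(0.5)

    def test_detection_monotone_in_flowers(self):
        S, J, K, L = 1, 1, 1, 3
        params = _params(S, 1, p_0=np.zeros(S), p_1=0.0, p_2=np.zeros(S),
                         p_3=np.zeros(S), p_4=0.41, p_year=np.zeros(1))
        covs = _covs(S, J, K, L)
        covs.date_z = np.zeros((1, 1, L))
        covs.survey_flowers_z = np.array([[-1.0, 0.0, 1.0]]).reshape(1, 1, L)
        p = detection_prob(params, covs)[0, 0, 0]
        assert p[0] < p[1] < p[2]


class TestOccupancyRecursion:
    def test_pure_persistence(self):
        assert occupancy_recursion(1.0, 0.8, 0.3) == pytest.approx(0.8)

    def test_fixed_point_when_rates_equal(self):
        for psi_prev in (0.0, 0.3, 1.0):
            assert occupancy_recursion(psi_prev, 0.6, 0.6) == pytest.approx(0.6)

    def test_direct_arithmetic(self):
        assert occupancy_recursion(0.4, 0.7, 0.2) == pytest.approx(0.40)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            occupancy_recursion(1.2, 0.5, 0.5)

    def test_memoryless_when_all_rates_equal(self):
        # psi1 = phi = gamma = c keeps marginal occupancy at c every year
        S, J, K, L = 3, 2, 4, 2
        c = 0.37
        logit_c = np.log(c / (1 - c))
        params = _params(S, K, psi1_0=np.full(S, logit_c), psi1=np.zeros(5),
                         gamma_0=np.full(S, logit_c), gamma=np.zeros(5),
                         gamma_year=np.zeros(K - 1),
                         phi_0=np.full(S, logit_c), phi=np.zeros(5),
                         phi_year=np.zeros(K - 1))
        covs = _covs(S, J, K, L)
        traj = occupancy_trajectory(params, covs, K)
        assert np.allclose(traj, c)


class TestMarginalLikelihood:
    def test_single_year_detection(self):
        # one year, one survey, V=1: psi * p = 0.25
        ll = marginal_loglik_site_species(
            np.array([[1]]), np.array([[True]]), 0.5, np.zeros(0), np.zeros(0),
            np.array([[0.5]]))
        assert ll == pytest.approx(np.log(0.25))

    def test_single_year_nondetection(self):
        # present-but-missed (0.5*0.5) plus absent (0.5) = 0.75
        ll = marginal_loglik_site_species(
            np.array([[0]]), np.array([[True]]), 0.5, np.zeros(0), np.zeros(0),
            np.array([[0.5]]))
        assert ll == pytest.approx(np.log(0.75))

    def test_matches_enumeration_small(self, rng):
        for _ in range(30):
            K, L = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            mask = rng.random((K, L)) < 0.8
            V = (rng.integers(0, 2, (K, L)) * mask).astype(int)
            psi1 = rng.uniform(0.05, 0.95)
            gamma = rng.uniform(0.05, 0.95, K - 1)
            phi = rng.uniform(0.05, 0.95, K - 1)
            p = rng.uniform(0.05, 0.95, (K, L))
            ll = marginal_loglik_site_species(V, mask, psi1, gamma, phi, p)
            assert ll == pytest.approx(
                brute_force_loglik(V, mask, psi1, gamma, phi, p), abs=1e-10)

    def test_survey_order_exchangeable(self, rng):
        K, L = 3, 5
        mask = np.ones((K, L), bool)
        V = rng.integers(0, 2, (K, L))
        psi1, gamma, phi = 0.4, np.array([0.3, 0.5]), np.array([0.7, 0.6])
        p = rng.uniform(0.1, 0.9, (K, L))
        ll = marginal_loglik_site_species(V, mask, psi1, gamma, phi, p)
        perm = rng.permutation(L)
        ll_perm = marginal_loglik_site_species(V[:, perm], mask, psi1, gamma,
                                               phi, p[:, perm])
        assert ll == pytest.approx(ll_perm, abs=1e-12)

    def test_perfect_detection_reduces_to_observed_chain(self):
        # with p = 1 and surveys consistent within years, the marginal
        # likelihood is the probability of the observed Z sequence
        V = np.array([[1, 1], [0, 0], [1, 1]])
        mask = np.ones((3, 2), bool)
        psi1, gamma, phi = 0.6, np.array([0.2, 0.3]), np.array([0.7, 0.8])
        p = np.full((3, 2), 1 - 1e-13)
        ll = marginal_loglik_site_species(V, mask, psi1, gamma, phi, p)
        # Z = (1, 0, 1): psi1 * (1-phi_1) * gamma_2
        assert ll == pytest.approx(np.log(0.6 * (1 - 0.7) * 0.3), abs=1e-6)


class TestTotalLoglik:
    def test_equals_per_cell_loop(self, medium_dataset):
        data, covs = medium_dataset.detections, medium_dataset.covariates
        params = medium_dataset.truth
        total = total_loglik(data, params, covs)
        psi1 = linpred_psi1(params, covs)
        gam = linpred_gamma(params, covs)
        phi = linpred_phi(params, covs)
        p = detection_prob(params, covs)
        loop = sum(
            marginal_loglik_site_species(data.V[i, j], data.mask[j],
                                         psi1[i, j], gam[i, j], phi[i, j],
                                         p[i, j])
            for i in range(data.n_species) for j in range(data.n_sites))
        assert total == pytest.approx(loop, rel=1e-10)

    def test_duplicating_a_site_doubles_contribution(self, small_dataset):
        data, covs, params = (small_dataset.detections,
                              small_dataset.covariates, small_dataset.truth)
        base = total_loglik(data, params, covs)
        V2 = np.concatenate([data.V, data.V[:, :1]], axis=1)
        mask2 = np.concatenate([data.mask, data.mask[:1]], axis=0)
        data2 = DetectionArray(
            V=V2, mask=mask2,
            date_z=np.concatenate([data.date_z, data.date_z[:1]], axis=0),
            survey_flowers_z=np.concatenate(
                [data.survey_flowers_z, data.survey_flowers_z[:1]], axis=0),
            species_ids=data.species_ids, site_ids=data.site_ids + ["dup"],
            date_standardizer=data.date_standardizer,
            flowers_standardizer=data.flowers_standardizer)
        covs2 = CovariateBundle(
            d_prime=covs.d_prime, d_prime_z=covs.d_prime_z,
            degree_z=covs.degree_z,
            restored=np.r_[covs.restored, covs.restored[:1]],
            woody_z=np.concatenate([covs.woody_z, covs.woody_z[:1]], axis=0),
            date_z=data2.date_z, survey_flowers_z=data2.survey_flowers_z)
        psi1 = linpred_psi1(params, covs)
        gam = linpred_gamma(params, covs)
        phi = linpred_phi(params, covs)
        p = detection_prob(params, covs)
        site0 = sum(
            marginal_loglik_site_species(data.V[i, 0], data.mask[0],
                                         psi1[i, 0], gam[i, 0], phi[i, 0],
                                         p[i, 0])
            for i in range(data.n_species))
        assert total_loglik(data2, params, covs2) == pytest.approx(
            base + site0, rel=1e-10)


class TestModelGradients:
    @pytest.mark.parametrize("cls", [CommunityOccupancyModel,
                                     RandomSlopesOccupancyModel])
    def test_gradient_matches_finite_differences(self, cls, small_dataset, rng):
        model = cls(small_dataset.detections, small_dataset.covariates)
        theta = model.initial_point() + rng.normal(0, 0.3, model.index.dim)
        lp, grad = model.log_posterior_and_grad(theta)
        for i in rng.choice(model.index.dim, size=20, replace=False):
            t2 = theta.copy()
            t2[i] += 1e-6
            lp2, _ = model.log_posterior_and_grad(t2)
            assert grad[i] == pytest.approx((lp2 - lp) / 1e-6, rel=2e-4, abs=2e-4)


def _empty_detection_array(S=4, J=3, K=2, L=2):
    std = Standardizer(mean=0.0, sd=1.0)
    return DetectionArray(
        V=np.zeros((S, J, K, L), dtype=np.uint8),
        mask=np.zeros((J, K, L), dtype=bool),
        date_z=np.zeros((J, K, L)), survey_flowers_z=np.zeros((J, K, L)),
        species_ids=[f"sp{i}" for i in range(S)],
        site_ids=[f"s{j}" for j in range(J)],
        date_standardizer=std, flowers_standardizer=std)


class TestFit:
    def test_prior_only_run_reproduces_priors(self):
        # no conducted surveys: the likelihood is flat, so draws follow the
        # priors (community slopes Normal(0,2); hyper-sds half-Normal(1.5))
        data = _empty_detection_array()
        covs = _covs(data.n_species, data.n_sites, data.n_years, data.n_surveys)
        draws, _ = fit(data, covs, settings=SamplerSettings(
            iterations=2400, warmup=800, chains=2, seed=5))
        slope = draws.flat("psi1")[:, 1]
        assert abs(slope.mean()) < 0.35
        assert slope.std() == pytest.approx(2.0, abs=0.45)
        sd_hyper = draws.flat("sd_psi1_0")
        assert sd_hyper.mean() == pytest.approx(1.5 * np.sqrt(2 / np.pi), abs=0.3)

    def test_smoke_fit_is_finite_and_reproducible(self):
        data = generate_dataset(GeneratorConfig(
            n_species=5, n_sites=4, n_restored=2, n_years=2, seed=11))
        settings = SamplerSettings(iterations=300, warmup=150, chains=2, seed=1)
        draws, report = fit(data.detections, data.covariates, settings=settings)
        assert all(np.isfinite(v).all() for v in draws.params.values())
        assert report.n_divergent >= 0
        draws2, _ = fit(data.detections, data.covariates, settings=settings)
        assert np.array_equal(draws.flat("psi1"), draws2.flat("psi1"))


class TestSummarize:
    def _draws(self, sample):
        sample = np.asarray(sample, dtype=float).reshape(1, -1)
        return PosteriorDraws(params={"x": sample}, n_divergent=0)

    def test_degenerate_draws_are_strong(self):
        mean, bci50, bci95, label = summarize(self._draws([2.0] * 50), "x")
        assert mean == 2.0 and bci50 == (2.0, 2.0) and bci95 == (2.0, 2.0)
        assert label == "strong"

    def test_symmetric_draws_have_no_certainty(self, rng):
        mean, _, _, label = summarize(self._draws(rng.normal(0, 1, 4000)), "x")
        assert label == "none"

    def test_marginal_label_between_intervals(self, rng):
        # mean 1.02 with spread wide enough that only the 50% interval
        # excludes zero
        sample = rng.normal(1.02, 0.9, 4000)
        _, bci50, bci95, label = summarize(self._draws(sample), "x")
        assert bci50[0] > 0 and bci95[0] < 0
        assert label == "marginal"

    def test_unknown_name_lists_available(self):
        with pytest.raises(KeyError, match="x"):
            summarize(self._draws([1.0]), "y")


class TestRandomSlopesVariant:
    def test_shrinkage_limit_collapses_to_community_mean(self):
        # as the hyper-sd goes to zero, species slopes equal the mean exactly
        data = _empty_detection_array(S=6)
        covs = _covs(6, 3, 2, 2)
        model = RandomSlopesOccupancyModel(data, covs)
        raw = np.zeros((1, 1, model.index.dim))
        raw[..., model.index.slices["mu_gamma_woody"]] = 1.3
        raw[..., model.index.slices["log_sd_gamma_woody"]] = -12.0
        raw[..., model.index.slices["z_gamma_woody"]] = 3.0
        named = model.named_draws(raw)
        assert np.allclose(named["gamma_woody"], 1.3, atol=1e-4)

    def test_recovers_dprime_colonisation_interaction(self):
        # the generator's d' x woody colonisation interaction should surface
        # as a positive correlation between d' and species woody slopes
        cfg = GeneratorConfig(n_species=25, n_sites=10, n_restored=5, seed=21)
        data = generate_dataset(cfg)
        _, _, corr = fit_random_slopes_variant(
            data.detections, data.covariates,
            settings=SamplerSettings(iterations=900, warmup=450, chains=2,
                                     seed=2))
        r = corr["gamma_woody"]
        assert r.mean() > 0.1
        assert (r > 0).mean() > 0.8

    def test_null_interaction_correlation_straddles_zero(self):
        cfg = GeneratorConfig(
            n_species=25, n_sites=10, n_restored=5, seed=22,
            psi1_slopes=(0.0, 2.26, -0.48, 0.0, 0.0),
            gamma_slopes=(0.0, 1.02, 1.60, 0.0, 0.0),
            phi_slopes=(0.0, -0.30, -0.61, 0.0, 0.0))
        data = generate_dataset(cfg)
        _, _, corr = fit_random_slopes_variant(
            data.detections, data.covariates,
            settings=SamplerSettings(iterations=900, warmup=450, chains=2,
                                     seed=3))
        r = corr["gamma_woody"]
        lo, hi = np.quantile(r, [0.025, 0.975])
        assert lo < 0 < hi
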