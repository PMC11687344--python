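"""Multi-species dynamic occupancy model with imperfect detection.

The model tracks a latent occurrence state Z[i,j,k] for species i at site j in
year k.  First-year occurrence follows an initial-occurrence probability psi1;
later years follow the metacommunity recursion

    Psi[k] = phi[k] * Psi[k-1] + gamma[k] * (1 - Psi[k-1]),

with persistence phi (occupied sites staying occupied) and colonisation gamma
(empty sites becoming occupied).  Detection on survey l is Bernoulli(Z * p).
All four probabilities carry logit-linear predictors:

    logit psi1 = psi1_0[i] + psi1 slopes . (d', restored, woody, d' x restored, d' x woody)
    logit gamma = gamma_0[i] + gamma slopes . (same, woody of the current year) + year offset
    logit phi   = phi_0[i]  + phi slopes . (same, woody lagged one year)       + year offset
    logit p     = p_0[i] + p_1 degree + p_2[i] date + p_3[i] date^2 + p_4 flowers + year offset

Species intercepts (and the phenology coefficients p_2, p_3) are drawn from
community-level normal distributions.  The latent Z is never sampled: the
likelihood marginalises it with a scaled forward recursion over the two-state
chain, per species-site, which keeps the posterior smooth for gradient-based
sampling.  Analytic gradients are propagated by a manual reverse pass through
the forward recursion, so the model can be fit with the package's Hamiltonian
Monte Carlo sampler.  Convergence gates follow common Stan practice: split
R-hat < 1.05, effective-sample-size ratio > 0.1, and no divergent transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
from scipy.special import expit, log_expit

from .hmc import HMCConfig, sample_hmc
from .io import DetectionArray

logger = logging.getLogger("metaoccu")

__all__ = [
    "OccupancyParams", "CovariateBundle", "PriorConfig", "PosteriorDraws",
    "FitReport", "linpred_psi1", "linpred_gamma", "linpred_phi",
    "detection_prob", "occupancy_recursion", "occupancy_trajectory",
    "marginal_loglik_site_species", "total_loglik", "fit",
    "fit_random_slopes_variant", "summarize", "SamplerSettings",
]

_PROB_EPS = 1e-12   # keeps marginalised probabilities strictly inside (0, 1)


# ---------------------------------------------------------------------------
# parameter and covariate containers
# ---------------------------------------------------------------------------

@dataclass
class OccupancyParams:
    """One realisation of every model parameter.

    Slope vectors are ordered (d', restored, woody, d' x restored, d' x woody).
    Year-offset vectors have their first entry pinned at zero for
    identifiability against the intercepts.
    """

    psi1_0: np.ndarray            # (S,)
    psi1: np.ndarray              # (5,)
    gamma_0: np.ndarray           # (S,)
    gamma: np.ndarray             # (5,)
    gamma_year: np.ndarray        # (K-1,) first entry 0
    phi_0: np.ndarray             # (S,)
    phi: np.ndarray               # (5,)
    phi_year: np.ndarray          # (K-1,) first entry 0
    p_0: np.ndarray               # (S,)
    p_1: float
    p_2: np.ndarray               # (S,) phenology linear
    p_3: np.ndarray               # (S,) phenology quadratic
    p_4: float
    p_year: np.ndarray            # (K,) first entry 0
    mu_psi1_0: float = 0.0
    sd_psi1_0: float = 1.0
    mu_gamma_0: float = 0.0
    sd_gamma_0: float = 1.0
    mu_phi_0: float = 0.0
    sd_phi_0: float = 1.0
    mu_p_0: float = 0.0
    sd_p_0: float = 1.0
    mu_p_2: float = 0.0
    sd_p_2: float = 1.0
    mu_p_3: float = -1.0
    sd_p_3: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sd_psi1_0", "sd_gamma_0", "sd_phi_0", "sd_p_0",
                     "sd_p_2", "sd_p_3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gamma_year", "phi_year", "p_year"):
            v = np.asarray(getattr(self, name))
            if v.size and abs(float(v[0])) > 1e-12:
                raise ValueError(f"{name}[0] must be pinned to 0")

    @property
    def n_species(self) -> int:
        return len(self.psi1_0)


@dataclass
class CovariateBundle:
    """Model covariates on the scales the linear predictors consume.

    ``d_prime_z`` and ``degree_z`` are z-scored (degree is log-transformed
    before standardising because it is right-skewed); ``restored`` stays
    binary; ``woody_z`` is the standardised per site-year log woody floral
    abundance, whose year index supports the one-year persistence lag.
    """

    d_prime: np.ndarray           # (S,) raw, in [0,1]; kept for reporting
    d_prime_z: np.ndarray         # (S,)
    degree_z: np.ndarray          # (S,)
    restored: np.ndarray          # (J,) binary
    woody_z: np.ndarray           # (J, K)
    date_z: np.ndarray            # (J, K, L)
    survey_flowers_z: np.ndarray  # (J, K, L)

    def validate(self, data: DetectionArray) -> None:
        S, J, K, L = data.V.shape
        if len(self.d_prime_z) != S or len(self.restored) != J:
            raise ValueError("covariate dimensions do not match detection array")
        if self.woody_z.shape != (J, K) or self.date_z.shape != (J, K, L):
            raise ValueError("covariate dimensions do not match detection array")


@dataclass(frozen=True)
class PriorConfig:
    """Weakly informative priors on the logit scale: they admit odds ratios
    across several orders of magnitude while discouraging the numerically
    degenerate tails."""

    slope_sd: float = 2.0
    hypermean_sd: float = 2.0
    hypersd_scale: float = 1.5
    year_sd: float = 2.0


@dataclass(frozen=True)
class SamplerSettings:
    iterations: int = 4000
    warmup: int = 2000
    chains: int = 4
    seed: int = 0
    target_accept: float = 0.85
    max_leapfrog: int = 24


@dataclass
class FitReport:
    converged: bool
    max_rhat: float
    min_ess_ratio: float
    n_divergent: int

    @classmethod
    def from_diagnostics(cls, max_rhat, min_ess_ratio, n_divergent) -> "FitReport":
        return cls(
            converged=bool(max_rhat < 1.05 and min_ess_ratio > 0.1
                           and n_divergent == 0),
            max_rhat=float(max_rhat),
            min_ess_ratio=float(min_ess_ratio),
            n_divergent=int(n_divergent),
        )


@dataclass
class PosteriorDraws:
    """Posterior draws keyed by parameter name.

    Arrays have shape (chains, draws) for scalars and (chains, draws, n) for
    vectors.  ``diagnostics`` maps each scalar element to (rhat, ess_ratio).
    """

    params: dict[str, np.ndarray]
    n_divergent: int
    diagnostics: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        first = next(iter(self.params.values()))
        return first.shape[0] * first.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws for one parameter with chains stacked: (draws, ...)."""
        if name not in self.params:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(self.params)}")
        a = self.params[name]
        return a.reshape(a.shape[0] * a.shape[1], *a.shape[2:])

    def param_set(self, d: int, n_years: int) -> OccupancyParams:
        """Materialise flattened draw ``d`` as an OccupancyParams realisation."""
        g = lambda n: self.flat(n)[d]
        K = n_years
        return OccupancyParams(
            psi1_0=g("psi1_0"), psi1=g("psi1"),
            gamma_0=g("gamma_0"), gamma=g("gamma"),
            gamma_year=_pin_first(g("gamma_year_free"), K - 1),
            phi_0=g("phi_0"), phi=g("phi"),
            phi_year=_pin_first(g("phi_year_free"), K - 1),
            p_0=g("p_0"), p_1=float(g("p_1")), p_2=g("p_2"), p_3=g("p_3"),
            p_4=float(g("p_4")), p_year=_pin_first(g("p_year_free"), K),
            mu_psi1_0=float(g("mu_psi1_0")), sd_psi1_0=float(g("sd_psi1_0")),
            mu_gamma_0=float(g("mu_gamma_0")), sd_gamma_0=float(g("sd_gamma_0")),
            mu_phi_0=float(g("mu_phi_0")), sd_phi_0=float(g("sd_phi_0")),
            mu_p_0=float(g("mu_p_0")), sd_p_0=float(g("sd_p_0")),
            mu_p_2=float(g("mu_p_2")), sd_p_2=float(g("sd_p_2")),
            mu_p_3=float(g("mu_p_3")), sd_p_3=float(g("sd_p_3")),
        )


def _pin_first(free: np.ndarray, size: int) -> np.ndarray:
    """Year-offset vector with the first level pinned at zero.  A scenario
    spanning fewer (or more) years than the fitted study uses the offsets
    that exist and zero elsewhere."""
    out = np.zeros(size)
    free = np.atleast_1d(np.asarray(free, dtype=float))
    n = min(size - 1, free.size)
    if n > 0:
        out[1:1 + n] = free[:n]
    return out


# ---------------------------------------------------------------------------
# linear predictors and the occupancy recursion
# ---------------------------------------------------------------------------

def _design_terms(dp, rest, woody):
    """The five slope covariate products: d', restored, woody, d'xrestored,
    d'xwoody — broadcast over (species, site[, year])."""
    return (dp, rest, woody, dp * rest, dp * woody)


def linpred_psi1(params: OccupancyParams, covs: CovariateBundle) -> np.ndarray:
    """Initial-occurrence probability psi1[i, j] (first study year)."""
    dp = covs.d_prime_z[:, None]
    rest = covs.restored[None, :]
    w1 = covs.woody_z[None, :, 0]
    lp = params.psi1_0[:, None]
    for s, t in zip(params.psi1, _design_terms(dp, rest, w1)):
        lp = lp + s * t
    return expit(lp)


def linpred_gamma(params: OccupancyParams, covs: CovariateBundle) -> np.ndarray:
    """Colonisation probability gamma[i, j, t] for the transition into year
    t+2 (1-based k = t+2), using the destination year's woody abundance."""
    dp = covs.d_prime_z[:, None, None]
    rest = covs.restored[None, :, None]
    w = covs.woody_z[None, :, 1:]
    lp = params.gamma_0[:, None, None] + params.gamma_year[None, None, :]
    for s, t in zip(params.gamma, _design_terms(dp, rest, w)):
        lp = lp + s * t
    return expit(lp)


def linpred_phi(params: OccupancyParams, covs: CovariateBundle) -> np.ndarray:
    """Persistence probability phi[i, j, t] for the transition into year t+2,
    using the *previous* year's woody abundance (resources in year k-1 drive
    persistence into year k)."""
    dp = covs.d_prime_z[:, None, None]
    rest = covs.restored[None, :, None]
    w = covs.woody_z[None, :, :-1]
    lp = params.phi_0[:, None, None] + params.phi_year[None, None, :]
    for s, t in zip(params.phi, _design_terms(dp, rest, w)):
        lp = lp + s * t
    return expit(lp)


def detection_logit(params: OccupancyParams, covs: CovariateBundle) -> np.ndarray:
    """Logit detection probability x[i, j, k, l]."""
    date = covs.date_z[None, :, :, :]
    lp = (
        params.p_0[:, None, None, None]
        + params.p_1 * covs.degree_z[:, None, None, None]
        + params.p_2[:, None, None, None] * date
        + params.p_3[:, None, None, None] * date ** 2
        + params.p_4 * covs.survey_flowers_z[None, :, :, :]
        + params.p_year[None, None, :, None]
    )
    return lp


def detection_prob(params: OccupancyParams, covs: CovariateBundle) -> np.ndarray:
    """Per-survey detection probability p[i, j, k, l]."""
    return expit(detection_logit(params, covs))


def occupancy_recursion(psi_prev, phi, gamma):
    """One step of the occupancy dynamics:
    psi_next = phi * psi_prev + gamma * (1 - psi_prev)."""
    psi_prev, phi, gamma = (np.asarray(a, dtype=float) for a in (psi_prev, phi, gamma))
    for name, a in (("psi_prev", psi_prev), ("phi", phi), ("gamma", gamma)):
        if np.any(a < 0) or np.any(a > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    return phi * psi_prev + gamma * (1 - psi_prev)


def occupancy_trajectory(params: OccupancyParams, covs: CovariateBundle,
                         n_years: int) -> np.ndarray:
    """Deterministic expected occupancy Psi[i, j, k] over the study years,
    obtained by iterating the recursion from psi1."""
    psi = np.empty((params.n_species, len(covs.restored), n_years))
    psi[..., 0] = linpred_psi1(params, covs)
    gam = linpred_gamma(params, covs)
    phi = linpred_phi(params, covs)
    for t in range(n_years - 1):
        psi[..., t + 1] = occupancy_recursion(psi[..., t], phi[..., t], gam[..., t])
    return psi


# ---------------------------------------------------------------------------
# marginalised likelihood: scaled forward recursion + manual reverse pass
# ---------------------------------------------------------------------------

def _emissions(x, V, mask):
    """Year-level log-emission under occupancy (loge1) and the no-detection
    indicator (emission under absence).  ``x`` is the detection logit."""
    M = mask[None, :, :, :]
    # Bernoulli log-lik per survey, stable via log-sigmoid
    ll = np.where(V > 0, log_expit(x), log_expit(-x))
    loge1 = np.sum(np.where(M, ll, 0.0), axis=3)
    nodet = (np.where(M, V, 0).sum(axis=3) == 0)
    return loge1, nodet


def _forward(psi1, gamma, phi, loge1, nodet):
    """Scaled forward pass over the 2-state chain.

    Emissions are rescaled per year so that the running state probabilities
    stay O(1): in years with a detection the absence emission is zero and the
    occupied emission is scaled to one (its log joins the normalising
    constant); in years without one, emissions are exp(loge1) and 1.

    Returns the per-(i,j) log-likelihood and the intermediates the reverse
    pass needs.
    """
    K = loge1.shape[2]
    e1 = np.where(nodet, np.exp(loge1), 1.0)
    e0 = nodet.astype(float)
    f1 = [None] * K
    f0 = [None] * K
    f1[0] = psi1 * e1[..., 0]
    f0[0] = (1.0 - psi1) * e0[..., 0]
    for t in range(1, K):
        f1[t] = (f1[t - 1] * phi[..., t - 1] + f0[t - 1] * gamma[..., t - 1]) * e1[..., t]
        f0[t] = (f1[t - 1] * (1.0 - phi[..., t - 1])
                 + f0[t - 1] * (1.0 - gamma[..., t - 1])) * e0[..., t]
    norm = np.sum(np.where(nodet, 0.0, loge1), axis=2)
    ll = np.log(f1[K - 1] + f0[K - 1]) + norm
    return ll, (e1, e0, f1, f0)


def forward_loglik(psi1, gamma, phi, loge1, nodet) -> np.ndarray:
    """Log of the marginal detection-history probability per (species, site),
    with the latent occupancy sequence summed out."""
    ll, _ = _forward(psi1, gamma, phi, loge1, nodet)
    return ll


def forward_loglik_grad(psi1, gamma, phi, loge1, nodet):
    """Marginal log-likelihood and its gradients with respect to psi1, gamma,
    phi (probability scale) and the year log-emissions.  A manual reverse-mode
    sweep of :func:`_forward`; validated against finite differences in tests."""
    K = loge1.shape[2]
    ll, (e1, e0, f1, f0) = _forward(psi1, gamma, phi, loge1, nodet)
    G = 1.0 / (f1[K - 1] + f0[K - 1])
    df1, df0 = G.copy(), G.copy()
    dgamma = np.zeros_like(gamma)
    dphi = np.zeros_like(phi)
    dloge1 = np.zeros_like(loge1)
    for t in range(K - 1, 0, -1):
        ph, ga = phi[..., t - 1], gamma[..., t - 1]
        s1 = f1[t - 1] * ph + f0[t - 1] * ga           # pre-emission mass, z=1
        dphi[..., t - 1] = f1[t - 1] * (df1 * e1[..., t] - df0 * e0[..., t])
        dgamma[..., t - 1] = f0[t - 1] * (df1 * e1[..., t] - df0 * e0[..., t])
        dloge1[..., t] = np.where(nodet[..., t], df1 * s1 * e1[..., t], 1.0)
        df1, df0 = (df1 * e1[..., t] * ph + df0 * e0[..., t] * (1.0 - ph),
                    df1 * e1[..., t] * ga + df0 * e0[..., t] * (1.0 - ga))
    dpsi1 = df1 * e1[..., 0] - df0 * e0[..., 0]
    dloge1[..., 0] = np.where(nodet[..., 0], df1 * psi1 * e1[..., 0], 1.0)
    return ll, dpsi1, dgamma, dphi, dloge1


def marginal_loglik_site_species(V_history, mask, psi1, gamma, phi, p) -> float:
    """Marginal log-likelihood of one species' detection history at one site.

    ``V_history`` and ``mask`` are (K, L); ``gamma``/``phi`` are the K-1
    transition probabilities; ``p`` the (K, L) per-survey detection
    probabilities.  Convenience scalar wrapper over the vectorised forward
    pass.
    """
    V = np.asarray(V_history)[None, None]
    M = np.asarray(mask, dtype=bool)[None]
    p = np.clip(np.asarray(p, dtype=float), _PROB_EPS, 1 - _PROB_EPS)
    ll_surv = np.where(V > 0, np.log(p)[None, None], np.log1p(-p)[None, None])
    loge1 = np.sum(np.where(M[None], ll_surv, 0.0), axis=3)
    nodet = (np.where(M[None], V, 0).sum(axis=3) == 0)
    psi1 = np.asarray([[psi1]], dtype=float)
    gam = np.asarray(gamma, dtype=float)[None, None]
    ph = np.asarray(phi, dtype=float)[None, None]
    return float(forward_loglik(psi1, gam, ph, loge1, nodet)[0, 0])


def total_loglik(data: DetectionArray, params: OccupancyParams,
                 covs: CovariateBundle) -> float:
    """Summed marginal log-likelihood over all species and sites."""
    covs.validate(data)
    psi1 = np.clip(linpred_psi1(params, covs), _PROB_EPS, 1 - _PROB_EPS)
    gam = np.clip(linpred_gamma(params, covs), _PROB_EPS, 1 - _PROB_EPS)
    phi = np.clip(linpred_phi(params, covs), _PROB_EPS, 1 - _PROB_EPS)
    x = detection_logit(params, covs)
    loge1, nodet = _emissions(x, data.V, data.mask)
    ll = forward_loglik(psi1, gam, phi, loge1, nodet)
    total = float(ll.sum())
    if not np.isfinite(total):
        raise FloatingPointError(
            "non-finite occupancy log-likelihood; parameter summary: "
            f"psi1 range=({psi1.min():.3g},{psi1.max():.3g}), "
            f"gamma range=({gam.min():.3g},{gam.max():.3g}), "
            f"phi range=({phi.min():.3g},{phi.max():.3g})")
    return total


# ---------------------------------------------------------------------------
# posterior: parameter packing, log density with gradient
# ---------------------------------------------------------------------------

class _ParamIndex:
    """Maps named blocks to slices of the flat HMC parameter vector."""

    def __init__(self, blocks: list[tuple[str, int]]):
        self.slices: dict[str, slice] = {}
        start = 0
        for name, n in blocks:
            self.slices[name] = slice(start, start + n)
            start += n
        self.dim = start

    def get(self, theta, name):
        return theta[self.slices[name]]

    def scalar(self, theta, name) -> float:
        return float(theta[self.slices[name]][0])

    def set(self, vec, name, value):
        vec[self.slices[name]] = value

    def add(self, vec, name, value):
        vec[self.slices[name]] += value


_HYPER_BLOCKS = ("psi1_0", "gamma_0", "phi_0", "p_0", "p_2", "p_3")


class CommunityOccupancyModel:
    """Log posterior (with gradient) for the community occupancy model, over an
    unconstrained parameter vector.

    Species-level intercepts and phenology coefficients use a non-centred
    parameterisation (theta_i = mu + sd * z_i with z standard normal), and
    hyper-standard-deviations are sampled on the log scale with the Jacobian
    term included — both choices keep hierarchical funnels tractable for HMC.
    """

    d_prime_effects = True     # community d' slopes present (main model)

    def __init__(self, data: DetectionArray, covs: CovariateBundle,
                 priors: PriorConfig = PriorConfig()):
        covs.validate(data)
        self.data = data
        self.covs = covs
        self.priors = priors
        S, J, K, L = data.V.shape
        self.S, self.J, self.K, self.L = S, J, K, L
        self.index = _ParamIndex(self._blocks())
        self._M = data.mask[None, :, :, :]
        self._Vf = data.V.astype(float)

    def _blocks(self) -> list[tuple[str, int]]:
        S, K = self.S, self.K
        blocks = [(f"mu_{n}", 1) for n in _HYPER_BLOCKS]
        blocks += [(f"log_sd_{n}", 1) for n in _HYPER_BLOCKS]
        blocks += [("psi1", 5), ("gamma", 5), ("phi", 5)]
        blocks += [("gamma_year_free", max(K - 2, 0)),
                   ("phi_year_free", max(K - 2, 0)),
                   ("p_year_free", K - 1)]
        blocks += [("p_1", 1), ("p_4", 1)]
        blocks += [(f"z_{n}", S) for n in _HYPER_BLOCKS]
        return blocks

    # -- packing ------------------------------------------------------------

    def initial_point(self) -> np.ndarray:
        theta = np.zeros(self.index.dim)
        for n in _HYPER_BLOCKS:
            self.index.set(theta, f"log_sd_{n}", np.log(0.5))
        return theta

    def _unpack(self, theta):
        ix = self.index
        mus = {n: ix.scalar(theta, f"mu_{n}") for n in _HYPER_BLOCKS}
        log_sds = {n: ix.scalar(theta, f"log_sd_{n}") for n in _HYPER_BLOCKS}
        sds = {n: np.exp(min(max(v, -30.0), 30.0)) for n, v in log_sds.items()}
        zs = {n: ix.get(theta, f"z_{n}") for n in _HYPER_BLOCKS}
        effects = {n: mus[n] + sds[n] * zs[n] for n in _HYPER_BLOCKS}
        return mus, log_sds, sds, zs, effects

    def params_from_theta(self, theta) -> OccupancyParams:
        ix = self.index
        mus, _, sds, _, effects = self._unpack(theta)
        K = self.K
        return OccupancyParams(
            psi1_0=effects["psi1_0"], psi1=ix.get(theta, "psi1").copy(),
            gamma_0=effects["gamma_0"], gamma=ix.get(theta, "gamma").copy(),
            gamma_year=_pin_first(ix.get(theta, "gamma_year_free"), K - 1),
            phi_0=effects["phi_0"], phi=ix.get(theta, "phi").copy(),
            phi_year=_pin_first(ix.get(theta, "phi_year_free"), K - 1),
            p_0=effects["p_0"], p_1=ix.scalar(theta, "p_1"),
            p_2=effects["p_2"], p_3=effects["p_3"],
            p_4=ix.scalar(theta, "p_4"),
            p_year=_pin_first(ix.get(theta, "p_year_free"), K),
            mu_psi1_0=mus["psi1_0"], sd_psi1_0=sds["psi1_0"],
            mu_gamma_0=mus["gamma_0"], sd_gamma_0=sds["gamma_0"],
            mu_phi_0=mus["phi_0"], sd_phi_0=sds["phi_0"],
            mu_p_0=mus["p_0"], sd_p_0=sds["p_0"],
            mu_p_2=mus["p_2"], sd_p_2=sds["p_2"],
            mu_p_3=mus["p_3"], sd_p_3=sds["p_3"],
        )

    # -- density ------------------------------------------------------------

    def log_posterior_and_grad(self, theta):
        ix = self.index
        pr = self.priors
        covs = self.covs
        S, J, K, L = self.S, self.J, self.K, self.L
        mus, log_sds, sds, zs, effects = self._unpack(theta)

        dp = covs.d_prime_z
        rest = covs.restored.astype(float)
        woody = covs.woody_z

        psi1_s = ix.get(theta, "psi1")
        gamma_s = ix.get(theta, "gamma")
        phi_s = ix.get(theta, "phi")
        gy = _pin_first(ix.get(theta, "gamma_year_free"), K - 1)
        fy = _pin_first(ix.get(theta, "phi_year_free"), K - 1)
        py = _pin_first(ix.get(theta, "p_year_free"), K)
        p1 = ix.scalar(theta, "p_1")
        p4 = ix.scalar(theta, "p_4")

        # --- linear predictors ---
        dp_i = dp[:, None]
        rest_j = rest[None, :]
        w1 = woody[None, :, 0]
        a = (effects["psi1_0"][:, None]
             + psi1_s[0] * dp_i + psi1_s[1] * rest_j + psi1_s[2] * w1
             + psi1_s[3] * dp_i * rest_j + psi1_s[4] * dp_i * w1)

        dp_ij = dp[:, None, None]
        rest_jt = rest[None, :, None]
        w_dest = woody[None, :, 1:]
        w_prev = woody[None, :, :-1]
        b = (effects["gamma_0"][:, None, None] + gy[None, None, :]
             + gamma_s[0] * dp_ij + gamma_s[1] * rest_jt + gamma_s[2] * w_dest
             + gamma_s[3] * dp_ij * rest_jt + gamma_s[4] * dp_ij * w_dest)
        c = (effects["phi_0"][:, None, None] + fy[None, None, :]
             + phi_s[0] * dp_ij + phi_s[1] * rest_jt + phi_s[2] * w_prev
             + phi_s[3] * dp_ij * rest_jt + phi_s[4] * dp_ij * w_prev)

        date = covs.date_z[None]
        x = (effects["p_0"][:, None, None, None]
             + p1 * covs.degree_z[:, None, None, None]
             + effects["p_2"][:, None, None, None] * date
             + effects["p_3"][:, None, None, None] * date ** 2
             + p4 * covs.survey_flowers_z[None]
             + py[None, None, :, None])

        psi1 = np.clip(expit(a), _PROB_EPS, 1 - _PROB_EPS)
        gam = np.clip(expit(b), _PROB_EPS, 1 - _PROB_EPS)
        phi = np.clip(expit(c), _PROB_EPS, 1 - _PROB_EPS)
        p = expit(x)

        V, M = self._Vf, self._M
        ll_surv = np.where(V > 0, log_expit(x), log_expit(-x))
        loge1 = np.sum(np.where(M, ll_surv, 0.0), axis=3)
        nodet = (np.where(M, V, 0.0).sum(axis=3) == 0)

        ll, dpsi1, dgam, dphi_p, dloge1 = forward_loglik_grad(
            psi1, gam, phi, loge1, nodet)
        loglik = float(ll.sum())

        # --- chain rule back to logits ---
        da = dpsi1 * psi1 * (1 - psi1)
        db = dgam * gam * (1 - gam)
        dc = dphi_p * phi * (1 - phi)
        dx = dloge1[..., None] * np.where(M, V - p, 0.0)

        grad = np.zeros_like(theta)

        # psi1 block
        d_psi10 = da.sum(axis=1)
        ix.set(grad, "psi1", [
            float((da * dp_i).sum()), float((da * rest_j).sum()),
            float((da * w1).sum()), float((da * dp_i * rest_j).sum()),
            float((da * dp_i * w1).sum())])
        # gamma block
        d_gamma0 = db.sum(axis=(1, 2))
        ix.set(grad, "gamma", [
            float((db * dp_ij).sum()), float((db * rest_jt).sum()),
            float((db * w_dest).sum()), float((db * dp_ij * rest_jt).sum()),
            float((db * dp_ij * w_dest).sum())])
        if K > 2:
            ix.set(grad, "gamma_year_free", db.sum(axis=(0, 1))[1:])
        # phi block
        d_phi0 = dc.sum(axis=(1, 2))
        ix.set(grad, "phi", [
            float((dc * dp_ij).sum()), float((dc * rest_jt).sum()),
            float((dc * w_prev).sum()), float((dc * dp_ij * rest_jt).sum()),
            float((dc * dp_ij * w_prev).sum())])
        if K > 2:
            ix.set(grad, "phi_year_free", dc.sum(axis=(0, 1))[1:])
        # detection block
        d_p0 = dx.sum(axis=(1, 2, 3))
        d_p2 = (dx * date).sum(axis=(1, 2, 3))
        d_p3 = (dx * date ** 2).sum(axis=(1, 2, 3))
        ix.set(grad, "p_1", float((dx * covs.degree_z[:, None, None, None]).sum()))
        ix.set(grad, "p_4", float((dx * covs.survey_flowers_z[None]).sum()))
        ix.set(grad, "p_year_free", dx.sum(axis=(0, 1, 3))[1:])

        # --- hierarchical chain + priors ---
        logp = loglik
        d_effects = {"psi1_0": d_psi10, "gamma_0": d_gamma0, "phi_0": d_phi0,
                     "p_0": d_p0, "p_2": d_p2, "p_3": d_p3}
        for n in _HYPER_BLOCKS:
            de, z, sd = d_effects[n], zs[n], sds[n]
            # non-centred chain
            ix.set(grad, f"mu_{n}", float(de.sum()))
            g_z = sd * de
            g_log_sd = sd * float((z * de).sum())
            # priors: z ~ N(0,1); mu ~ N(0, hm); sd ~ half-N(0, hs) + Jacobian
            logp += -0.5 * float((z * z).sum())
            g_z = g_z - z
            logp += -0.5 * (mus[n] / pr.hypermean_sd) ** 2
            ix.add(grad, f"mu_{n}", -mus[n] / pr.hypermean_sd ** 2)
            logp += -0.5 * (sd / pr.hypersd_scale) ** 2 + log_sds[n]
            g_log_sd += -(sd / pr.hypersd_scale) ** 2 * 1.0 + 1.0
            ix.set(grad, f"z_{n}", g_z)
            ix.set(grad, f"log_sd_{n}", g_log_sd)

        for name in ("psi1", "gamma", "phi"):
            v = ix.get(theta, name)
            logp += -0.5 * float((v / pr.slope_sd) @ (v / pr.slope_sd))
            grad[self.index.slices[name]] -= v / pr.slope_sd ** 2
        for name in ("p_1", "p_4"):
            v = ix.scalar(theta, name)
            logp += -0.5 * (v / pr.slope_sd) ** 2
            grad[self.index.slices[name]] -= v / pr.slope_sd ** 2
        for name in ("gamma_year_free", "phi_year_free", "p_year_free"):
            v = ix.get(theta, name)
            if v.size:
                logp += -0.5 * float((v / pr.year_sd) @ (v / pr.year_sd))
                grad[self.index.slices[name]] -= v / pr.year_sd ** 2

        return logp, grad

    # -- posterior assembly --------------------------------------------------

    def named_draws(self, raw: np.ndarray) -> dict[str, np.ndarray]:
        """Convert raw HMC draws (chains, draws, dim) to named natural-scale
        parameter draws."""
        C, D, _ = raw.shape
        out: dict[str, np.ndarray] = {}
        ix = self.index
        for n in _HYPER_BLOCKS:
            mu = raw[..., ix.slices[f"mu_{n}"]][..., 0]
            sd = np.exp(raw[..., ix.slices[f"log_sd_{n}"]][..., 0])
            z = raw[..., ix.slices[f"z_{n}"]]
            out[f"mu_{n}"] = mu
            out[f"sd_{n}"] = sd
            out[n] = mu[..., None] + sd[..., None] * z
        for name in ("psi1", "gamma", "phi", "gamma_year_free",
                     "phi_year_free", "p_year_free"):
            out[name] = raw[..., ix.slices[name]]
        for name in ("p_1", "p_4"):
            out[name] = raw[..., ix.slices[name]][..., 0]
        return out


def _diagnose(named: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    """Split R-hat and bulk-ESS ratio per scalar parameter element (arviz)."""
    diags: dict[str, tuple[float, float]] = {}
    for name, arr in named.items():
        C, D = arr.shape[:2]
        ds = az.convert_to_dataset(arr[..., None] if arr.ndim == 2 else arr)
        rhat = np.atleast_1d(az.rhat(ds)["x"].values)
        ess = np.atleast_1d(az.ess(ds)["x"].values)
        for i, (r, e) in enumerate(zip(rhat.ravel(), ess.ravel())):
            key = name if rhat.size == 1 else f"{name}[{i}]"
            diags[key] = (float(r), float(e) / (C * D))
    return diags


def _fit_model(model, settings: SamplerSettings):
    hmc_cfg = HMCConfig(
        iterations=settings.iterations, warmup=settings.warmup,
        chains=settings.chains, seed=settings.seed,
        target_accept=settings.target_accept,
        max_leapfrog=settings.max_leapfrog,
    )
    result = sample_hmc(model.log_posterior_and_grad, model.initial_point(), hmc_cfg)
    named = model.named_draws(result.draws)
    diags = _diagnose(named)
    max_rhat = max(r for r, _ in diags.values())
    min_ess = min(e for _, e in diags.values())
    report = FitReport.from_diagnostics(max_rhat, min_ess, result.n_divergent)
    if not report.converged:
        logger.warning(
            "sampler did not meet convergence gates: max R-hat %.3f, "
            "min ESS ratio %.3f, %d divergent transitions",
            report.max_rhat, report.min_ess_ratio, report.n_divergent)
    draws = PosteriorDraws(params=named, n_divergent=result.n_divergent,
                           diagnostics=diags)
    return draws, report


def fit(data: DetectionArray, covs: CovariateBundle,
        priors: PriorConfig = PriorConfig(),
        settings: SamplerSettings = SamplerSettings()) -> tuple[PosteriorDraws, FitReport]:
    """Fit the community occupancy model by HMC.

    Returns draws and a FitReport; a non-converged fit is still returned
    (with ``converged=False`` and a logged warning) so diagnostics can be
    inspected.
    """
    model = CommunityOccupancyModel(data, covs, priors)
    return _fit_model(model, settings)


def summarize(draws: PosteriorDraws, name: str):
    """Posterior mean, 50% and 95% central credible intervals and a certainty
    label for a scalar parameter: "strong" when the 95% interval excludes
    zero, "marginal" when only the 50% interval does, else "none".

    Vector parameters are addressed per element, e.g. ``"psi1[1]"`` for the
    restoration slope on initial occurrence.
    """
    if name.endswith("]") and "[" in name:
        base, idx = name[:-1].split("[")
        sample = draws.flat(base)[:, int(idx)]
    else:
        sample = draws.flat(name)
    if sample.ndim != 1:
        raise ValueError(f"{name!r} is a vector parameter; summarise elements"
                         f" such as {name!r}[0]")
    mean = float(sample.mean())
    l50, u50 = (float(q) for q in np.quantile(sample, [0.25, 0.75]))
    l95, u95 = (float(q) for q in np.quantile(sample, [0.025, 0.975]))
    if l95 > 0 or u95 < 0:
        label = "strong"
    elif l50 > 0 or u50 < 0:
        label = "marginal"
    else:
        label = "none"
    return mean, (l50, u50), (l95, u95), label


# ---------------------------------------------------------------------------
# a-posteriori variant: species-specific random slopes, correlated with d'
# ---------------------------------------------------------------------------

_RS_FAMILIES = ("psi1_rest", "psi1_woody", "gamma_rest", "gamma_woody",
                "phi_rest", "phi_woody")


class RandomSlopesOccupancyModel(CommunityOccupancyModel):
    """Variant model replacing the community d' effects with species-specific
    random slopes for restoration and woody abundance on initial occurrence,
    colonisation and persistence.  Specialisation enters only afterwards, as a
    posterior correlation between d' and the shrunken per-species slopes."""

    d_prime_effects = False

    def _blocks(self):
        S, K = self.S, self.K
        blocks = [(f"mu_{n}", 1) for n in _HYPER_BLOCKS]
        blocks += [(f"log_sd_{n}", 1) for n in _HYPER_BLOCKS]
        blocks += [(f"mu_{n}", 1) for n in _RS_FAMILIES]
        blocks += [(f"log_sd_{n}", 1) for n in _RS_FAMILIES]
        blocks += [("gamma_year_free", max(K - 2, 0)),
                   ("phi_year_free", max(K - 2, 0)),
                   ("p_year_free", K - 1)]
        blocks += [("p_1", 1), ("p_4", 1)]
        blocks += [(f"z_{n}", S) for n in _HYPER_BLOCKS]
        blocks += [(f"z_{n}", S) for n in _RS_FAMILIES]
        return blocks

    def initial_point(self):
        theta = np.zeros(self.index.dim)
        for n in _HYPER_BLOCKS + _RS_FAMILIES:
            self.index.set(theta, f"log_sd_{n}", np.log(0.5))
        return theta

    def _slope(self, theta, n):
        ix = self.index
        mu = ix.scalar(theta, f"mu_{n}")
        sd = float(np.exp(np.clip(ix.scalar(theta, f"log_sd_{n}"), -30.0, 30.0)))
        z = ix.get(theta, f"z_{n}")
        return mu, sd, z, mu + sd * z

    def log_posterior_and_grad(self, theta):
        ix = self.index
        pr = self.priors
        covs = self.covs
        S, J, K, L = self.S, self.J, self.K, self.L
        mus, log_sds, sds, zs, effects = self._unpack(theta)
        slopes = {n: self._slope(theta, n) for n in _RS_FAMILIES}

        rest = covs.restored.astype(float)
        woody = covs.woody_z
        gy = _pin_first(ix.get(theta, "gamma_year_free"), K - 1)
        fy = _pin_first(ix.get(theta, "phi_year_free"), K - 1)
        py = _pin_first(ix.get(theta, "p_year_free"), K)
        p1 = ix.scalar(theta, "p_1")
        p4 = ix.scalar(theta, "p_4")

        rest_j = rest[None, :]
        w1 = woody[None, :, 0]
        a = (effects["psi1_0"][:, None]
             + slopes["psi1_rest"][3][:, None] * rest_j
             + slopes["psi1_woody"][3][:, None] * w1)
        rest_jt = rest[None, :, None]
        w_dest = woody[None, :, 1:]
        w_prev = woody[None, :, :-1]
        b = (effects["gamma_0"][:, None, None] + gy[None, None, :]
             + slopes["gamma_rest"][3][:, None, None] * rest_jt
             + slopes["gamma_woody"][3][:, None, None] * w_dest)
        c = (effects["phi_0"][:, None, None] + fy[None, None, :]
             + slopes["phi_rest"][3][:, None, None] * rest_jt
             + slopes["phi_woody"][3][:, None, None] * w_prev)
        date = covs.date_z[None]
        x = (effects["p_0"][:, None, None, None]
             + p1 * covs.degree_z[:, None, None, None]
             + effects["p_2"][:, None, None, None] * date
             + effects["p_3"][:, None, None, None] * date ** 2
             + p4 * covs.survey_flowers_z[None]
             + py[None, None, :, None])

        psi1 = np.clip(expit(a), _PROB_EPS, 1 - _PROB_EPS)
        gam = np.clip(expit(b), _PROB_EPS, 1 - _PROB_EPS)
        phi = np.clip(expit(c), _PROB_EPS, 1 - _PROB_EPS)
        p = expit(x)
        V, M = self._Vf, self._M
        ll_surv = np.where(V > 0, log_expit(x), log_expit(-x))
        loge1 = np.sum(np.where(M, ll_surv, 0.0), axis=3)
        nodet = (np.where(M, V, 0.0).sum(axis=3) == 0)
        ll, dpsi1, dgam, dphi_p, dloge1 = forward_loglik_grad(
            psi1, gam, phi, loge1, nodet)
        loglik = float(ll.sum())

        da = dpsi1 * psi1 * (1 - psi1)
        db = dgam * gam * (1 - gam)
        dc = dphi_p * phi * (1 - phi)
        dx = dloge1[..., None] * np.where(M, V - p, 0.0)

        grad = np.zeros_like(theta)
        d_effects = {
            "psi1_0": da.sum(axis=1), "gamma_0": db.sum(axis=(1, 2)),
            "phi_0": dc.sum(axis=(1, 2)), "p_0": dx.sum(axis=(1, 2, 3)),
            "p_2": (dx * date).sum(axis=(1, 2, 3)),
            "p_3": (dx * date ** 2).sum(axis=(1, 2, 3)),
        }
        d_slopes = {
            "psi1_rest": (da * rest_j).sum(axis=1),
            "psi1_woody": (da * w1).sum(axis=1),
            "gamma_rest": (db * rest_jt).sum(axis=(1, 2)),
            "gamma_woody": (db * w_dest).sum(axis=(1, 2)),
            "phi_rest": (dc * rest_jt).sum(axis=(1, 2)),
            "phi_woody": (dc * w_prev).sum(axis=(1, 2)),
        }
        if K > 2:
            ix.set(grad, "gamma_year_free", db.sum(axis=(0, 1))[1:])
            ix.set(grad, "phi_year_free", dc.sum(axis=(0, 1))[1:])
        ix.set(grad, "p_year_free", dx.sum(axis=(0, 1, 3))[1:])
        ix.set(grad, "p_1", float((dx * covs.degree_z[:, None, None, None]).sum()))
        ix.set(grad, "p_4", float((dx * covs.survey_flowers_z[None]).sum()))

        logp = loglik
        for n in _HYPER_BLOCKS:
            de, z, sd, mu, lsd = d_effects[n], zs[n], sds[n], mus[n], log_sds[n]
            ix.set(grad, f"mu_{n}", float(de.sum()) - mu / pr.hypermean_sd ** 2)
            ix.set(grad, f"z_{n}", sd * de - z)
            ix.set(grad, f"log_sd_{n}",
                   sd * float((z * de).sum()) - (sd / pr.hypersd_scale) ** 2 + 1.0)
            logp += (-0.5 * float((z * z).sum())
                     - 0.5 * (mu / pr.hypermean_sd) ** 2
                     - 0.5 * (sd / pr.hypersd_scale) ** 2 + lsd)
        for n in _RS_FAMILIES:
            mu, sd, z, _ = slopes[n]
            de = d_slopes[n]
            ix.set(grad, f"mu_{n}", float(de.sum()) - mu / pr.hypermean_sd ** 2)
            ix.set(grad, f"z_{n}", sd * de - z)
            ix.set(grad, f"log_sd_{n}",
                   sd * float((z * de).sum()) - (sd / pr.hypersd_scale) ** 2 + 1.0)
            logp += (-0.5 * float((z * z).sum())
                     - 0.5 * (mu / pr.hypermean_sd) ** 2
                     - 0.5 * (sd / pr.hypersd_scale) ** 2 + np.log(sd))
        for name in ("p_1", "p_4"):
            v = ix.scalar(theta, name)
            logp += -0.5 * (v / pr.slope_sd) ** 2
            grad[self.index.slices[name]] -= v / pr.slope_sd ** 2
        for name in ("gamma_year_free", "phi_year_free", "p_year_free"):
            v = ix.get(theta, name)
            if v.size:
                logp += -0.5 * float((v / pr.year_sd) @ (v / pr.year_sd))
                grad[self.index.slices[name]] -= v / pr.year_sd ** 2
        return logp, grad

    def named_draws(self, raw):
        out: dict[str, np.ndarray] = {}
        ix = self.index
        for n in _HYPER_BLOCKS + _RS_FAMILIES:
            mu = raw[..., ix.slices[f"mu_{n}"]][..., 0]
            sd = np.exp(raw[..., ix.slices[f"log_sd_{n}"]][..., 0])
            z = raw[..., ix.slices[f"z_{n}"]]
            out[f"mu_{n}"] = mu
            out[f"sd_{n}"] = sd
            out[n] = mu[..., None] + sd[..., None] * z
        for name in ("gamma_year_free", "phi_year_free", "p_year_free"):
            out[name] = raw[..., ix.slices[name]]
        for name in ("p_1", "p_4"):
            out[name] = raw[..., ix.slices[name]][..., 0]
        return out


def fit_random_slopes_variant(data: DetectionArray, covs: CovariateBundle,
                              priors: PriorConfig = PriorConfig(),
                              settings: SamplerSettings = SamplerSettings()):
    """Fit the random-slopes variant and correlate the shrunken per-species
    slopes with specialisation.

    Returns ``(draws, report, correlations)`` where ``correlations`` maps each
    slope family (e.g. ``"gamma_woody"``) to the posterior draws of the
    Pearson correlation between d' and the species-specific slopes.
    """
    model = RandomSlopesOccupancyModel(data, covs, priors)
    draws, report = _fit_model(model, settings)
    dprime = covs.d_prime
    dpc = dprime - dprime.mean()
    denom_d = np.sqrt((dpc ** 2).sum())
    correlations: dict[str, np.ndarray] = {}
    for fam in _RS_FAMILIES:
        flat = draws.flat(fam)                      # (draws, S)
        sc = flat - flat.mean(axis=1, keepdims=True)
        denom_s = np.sqrt((sc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (sc @ dpc) / (denom_s * denom_d)
        correlations[fam] = np.nan_to_num(r, nan=0.0)
    return draws, report, correlations
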