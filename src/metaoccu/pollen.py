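"""Pollen-limitation scoring and the site-random-intercept logistic model.

Each experimental unit is a pair of flowers on the same plant: one received
supplemental hand pollination, the other was an open-pollinated control.  The
seed ratio control/supplemented measures pollination service.  Pairs are
excluded when the supplemented flower set no fruit (no denominator) or when
the control out-produced the supplemented flower more than two-fold (treatment
failure); a retained pair is "pollen limited" when the control produced less
than half the seeds of its supplemented partner.

The limitation indicator is then modelled as Bernoulli with a logit-linear
probability: a site-level random intercept (normal around a community mean)
plus a fixed effect of the site's herbaceous restoration treatment.  The fit
uses the package's HMC sampler with weakly informative priors, which also keep
estimates finite under complete separation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from .hmc import HMCConfig, sample_hmc
from .occupancy import FitReport, PosteriorDraws, _diagnose, summarize

__all__ = [
    "PollenPair", "PollenFit", "score_pair", "score_pairs",
    "fit_pollen_model", "limitation_probability",
]

EXCLUDE_NO_FRUIT = "no fruit"
EXCLUDE_RATIO = "control > 2x supplemented"


@dataclass(frozen=True)
class PollenPair:
    """One scored control/supplemented flower pair."""

    site_id: str
    plant_id: str
    control_seeds: int
    supplemented_seeds: int | None     # None: supplemented flower set no fruit
    ratio: float | None
    excluded: bool
    exclusion_reason: str | None
    limited: int | None                # 1 = pollen limited; None when excluded


def score_pair(site_id: str, plant_id: str, control_seeds: int,
               supplemented_seeds: int | None) -> PollenPair:
    """Score one pair: ratio, exclusion filters, limitation class.

    A supplemented flower with zero seeds leaves the ratio undefined and is
    excluded as fruitless.  A ratio of exactly 0.5 is classed not limited.
    """
    if control_seeds < 0 or (supplemented_seeds is not None and supplemented_seeds < 0):
        raise ValueError("seed counts must be non-negative")
    if supplemented_seeds is None or supplemented_seeds == 0:
        return PollenPair(site_id, plant_id, control_seeds, supplemented_seeds,
                          ratio=None, excluded=True,
                          exclusion_reason=EXCLUDE_NO_FRUIT, limited=None)
    ratio = control_seeds / supplemented_seeds
    if ratio > 2.0:
        return PollenPair(site_id, plant_id, control_seeds, supplemented_seeds,
                          ratio=ratio, excluded=True,
                          exclusion_reason=EXCLUDE_RATIO, limited=None)
    return PollenPair(site_id, plant_id, control_seeds, supplemented_seeds,
                      ratio=ratio, excluded=False, exclusion_reason=None,
                      limited=int(ratio < 0.5))


def score_pairs(table: pd.DataFrame) -> list[PollenPair]:
    """Score a pairs table (site_id, plant_id, control_seeds,
    supplemented_seeds; blank supplemented = no fruit)."""
    required = {"site_id", "plant_id", "control_seeds", "supplemented_seeds"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    out = []
    for r in table.itertuples(index=False):
        supp = None if pd.isna(r.supplemented_seeds) else int(r.supplemented_seeds)
        out.append(score_pair(str(r.site_id), str(r.plant_id),
                              int(r.control_seeds), supp))
    return out


def limitation_probability(beta0: float) -> float:
    """Probability of pollen limitation implied by a logit-scale intercept."""
    return float(expit(beta0))


@dataclass
class PollenFit:
    draws: PosteriorDraws
    report: FitReport
    site_ids: list[str]

    def summary(self, name: str):
        return summarize(self.draws, name)


class _PollenModel:
    """Log posterior of the logistic site-random-intercept model, non-centred:
    beta0_j = mu + sd * z_j, logit(theta_j) = beta0_j + beta1 * restored_j."""

    def __init__(self, y, site_index, restored, prior_sd=2.0, sigma_scale=1.0):
        self.y = np.asarray(y, dtype=float)
        self.site_index = np.asarray(site_index)
        self.restored = np.asarray(restored, dtype=float)
        self.n_sites = len(restored)
        self.prior_sd = prior_sd
        self.sigma_scale = sigma_scale
        self.dim = 3 + self.n_sites     # mu, log_sd, beta1, z[j]

    def initial_point(self):
        theta = np.zeros(self.dim)
        theta[1] = np.log(0.5)
        return theta

    def log_posterior_and_grad(self, theta):
        mu, log_sd, beta1 = theta[0], theta[1], theta[2]
        z = theta[3:]
        sd = np.exp(np.clip(log_sd, -30.0, 30.0))  # extreme proposals still get a finite density
        beta0 = mu + sd * z
        eta = beta0[self.site_index] + beta1 * self.restored[self.site_index]
        p = expit(eta)
        logp = float(np.sum(np.where(self.y > 0, log_expit(eta), log_expit(-eta))))
        resid = self.y - p
        d_beta0 = np.bincount(self.site_index, weights=resid,
                              minlength=self.n_sites)
        d_beta1 = float(np.sum(resid * self.restored[self.site_index]))
        grad = np.zeros_like(theta)
        grad[0] = d_beta0.sum() - mu / self.prior_sd ** 2
        grad[1] = sd * float((z * d_beta0).sum()) \
            - (sd / self.sigma_scale) ** 2 + 1.0
        grad[2] = d_beta1 - beta1 / self.prior_sd ** 2
        grad[3:] = sd * d_beta0 - z
        logp += (-0.5 * (mu / self.prior_sd) ** 2
                 - 0.5 * (beta1 / self.prior_sd) ** 2
                 - 0.5 * float(z @ z)
                 - 0.5 * (sd / self.sigma_scale) ** 2 + log_sd)
        return logp, grad

    def named_draws(self, raw):
        mu = raw[..., 0]
        sd = np.exp(raw[..., 1])
        z = raw[..., 3:]
        return {
            "mu_beta0": mu, "sd_beta0": sd, "beta1": raw[..., 2],
            "beta0": mu[..., None] + sd[..., None] * z,
        }


def fit_pollen_model(pairs: list[PollenPair], site_restored: dict[str, int],
                     iterations: int = 3000, warmup: int = 1500,
                     chains: int = 4, seed: int = 0) -> PollenFit:
    """Fit the pollen-limitation logistic model to the retained pairs.

    ``site_restored`` maps site ids to their binary restoration flag; sites
    with no retained pair drop out of the fit.
    """
    retained = [p for p in pairs if not p.excluded]
    if not retained:
        raise ValueError("all pairs excluded; nothing to fit")
    sites = sorted({p.site_id for p in retained})
    if len(sites) < 2:
        raise ValueError("need at least two sites with retained pairs")
    site_ix = {s: i for i, s in enumerate(sites)}
    y = np.array([p.limited for p in retained])
    idx = np.array([site_ix[p.site_id] for p in retained])
    restored = np.array([site_restored[s] for s in sites], dtype=float)

    model = _PollenModel(y, idx, restored)
    cfg = HMCConfig(iterations=iterations, warmup=warmup, chains=chains,
                    seed=seed, target_accept=0.9, max_leapfrog=16,
                    init_step_size=0.2)
    result = sample_hmc(model.log_posterior_and_grad, model.initial_point(), cfg)
    named = model.named_draws(result.draws)
    diags = _diagnose(named)
    report = FitReport.from_diagnostics(
        max(r for r, _ in diags.values()),
        min(e for _, e in diags.values()),
        result.n_divergent,
    )
    draws = PosteriorDraws(params=named, n_divergent=result.n_divergent,
                           diagnostics=diags)
    return PollenFit(draws=draws, report=report, site_ids=sites)
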