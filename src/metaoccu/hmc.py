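"""A small Hamiltonian Monte Carlo sampler.

Static-trajectory HMC with dual-averaging step-size adaptation toward a target
acceptance rate, a diagonal mass matrix estimated during warmup, jittered
leapfrog trajectory lengths (which breaks periodicity without a full NUTS tree)
and Stan-style divergence detection (a leapfrog energy error above a fixed
threshold).  The target density supplies the log posterior and its gradient;
everything here is model-agnostic.

Chains are run sequentially with independent RNG streams spawned from one seed,
so results are reproducible chain-by-chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HMCConfig", "HMCResult", "sample_hmc"]

DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergent trajectory


@dataclass
class HMCConfig:
    iterations: int = 4000       # total per chain, warmup included
    warmup: int = 2000           # discarded adaptation steps
    chains: int = 4
    seed: int = 0
    target_accept: float = 0.85
    max_leapfrog: int = 24       # trajectory length jittered in [1, max]
    init_step_size: float = 0.1
    init_jitter: float = 0.5     # uniform jitter half-width on the start point


@dataclass
class HMCResult:
    draws: np.ndarray            # (chains, kept, dim)
    n_divergent: int
    accept_rate: float
    step_sizes: list[float] = field(default_factory=list)


def _leapfrog(grad, theta, r, eps, n_steps, inv_mass):
    g = grad(theta)
    for _ in range(n_steps):
        r = r + 0.5 * eps * g
        theta = theta + eps * (inv_mass * r)
        g = grad(theta)
        if not np.all(np.isfinite(g)):
            return theta, r, g, False
        r = r + 0.5 * eps * g
    return theta, r, g, True


def sample_hmc(logp_and_grad, init, config: HMCConfig) -> HMCResult:
    """Sample from a density given ``logp_and_grad(theta) -> (logp, grad)``.

    ``init`` is the centre of the per-chain start distribution (dimension of
    the parameter vector).  Returns post-warmup draws stacked per chain.
    """
    init = np.asarray(init, dtype=float)
    dim = init.size
    rng_streams = np.random.SeedSequence(config.seed).spawn(config.chains)
    kept = config.iterations - config.warmup
    if kept < 1:
        raise ValueError("iterations must exceed warmup")
    all_draws = np.empty((config.chains, kept, dim))
    total_div = 0
    accepts = []
    step_sizes = []

    for c in range(config.chains):
        rng = np.random.default_rng(rng_streams[c])
        theta = init + rng.uniform(-config.init_jitter, config.init_jitter, dim)
        lp, _ = logp_and_grad(theta)
        if not np.isfinite(lp):
            theta = init.copy()
            lp, _ = logp_and_grad(theta)

        def grad_only(t):
            return logp_and_grad(t)[1]

        # dual averaging state (Hoffman & Gelman 2014 defaults)
        eps = config.init_step_size
        mu_da = np.log(10.0 * eps)
        log_eps_bar, h_bar = 0.0, 0.0
        gamma_da, t0, kappa = 0.05, 10.0, 0.75

        inv_mass = np.ones(dim)
        welford_n, welford_mean, welford_m2 = 0, np.zeros(dim), np.zeros(dim)
        mass_window = (config.warmup // 4, (3 * config.warmup) // 4)

        for it in range(config.iterations):
            r = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = lp - 0.5 * np.sum(inv_mass * r * r)
            n_steps = int(rng.integers(1, config.max_leapfrog + 1))
            theta_p, r_p, _, ok = _leapfrog(grad_only, theta, r, eps, n_steps, inv_mass)
            if ok:
                lp_p, _ = logp_and_grad(theta_p)
                h1 = lp_p - 0.5 * np.sum(inv_mass * r_p * r_p)
                delta_h = h1 - h0
            else:
                lp_p, delta_h = -np.inf, -np.inf
            divergent = (not np.isfinite(delta_h)) or (delta_h < -DIVERGENCE_THRESHOLD)
            alpha = 0.0 if divergent else min(1.0, float(np.exp(min(delta_h, 0.0))))
            if (not divergent) and rng.random() < alpha:
                theta, lp = theta_p, lp_p

            if it < config.warmup:
                # step-size adaptation
                frac = 1.0 / (it + 1 + t0)
                h_bar = (1 - frac) * h_bar + frac * (config.target_accept - alpha)
                log_eps = mu_da - np.sqrt(it + 1) / gamma_da * h_bar
                eta = (it + 1) ** -kappa
                log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
                eps = float(np.exp(log_eps))
                # accumulate posterior variance for the diagonal mass matrix
                if mass_window[0] <= it < mass_window[1]:
                    welford_n += 1
                    delta = theta - welford_mean
                    welford_mean += delta / welford_n
                    welford_m2 += delta * (theta - welford_mean)
                if it == mass_window[1] - 1 and welford_n > 10:
                    var = welford_m2 / (welford_n - 1)
                    var = np.clip(var, 1e-8, None)
                    inv_mass = var        # mass = 1/var
                    # restart step-size adaptation for the new metric
                    mu_da = np.log(10.0 * eps)
                    log_eps_bar, h_bar = 0.0, 0.0
                if it == config.warmup - 1:
                    eps = float(np.exp(log_eps_bar))
            else:
                if divergent:
                    total_div += 1
                accepts.append(alpha)
                all_draws[c, it - config.warmup] = theta
        step_sizes.append(eps)

    return HMCResult(
        draws=all_draws,
        n_divergent=total_div,
        accept_rate=float(np.mean(accepts)) if accepts else 0.0,
        step_sizes=step_sizes,
    )
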