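"""Synthetic study generator with known ground truth.

Emulates the study design end to end: 18 urban parks (half restored, half
mown controls) surveyed six times a year for three years, a ~108-species
pollinator community with annual population cycles, species-specific quadratic
detection phenology, covariate-driven initial occurrence / colonisation /
persistence, plant-genus interaction networks with a controllable
specialisation gradient, and paired pollen-supplementation outcomes.

Default effect sizes follow the directions and rough magnitudes the package's
occupancy model is meant to resolve (a strong positive restoration effect on
initial occurrence, positive woody effects on colonisation — stronger for
specialists — and a mild negative woody effect on persistence), and the
default specialisation distribution is a Beta with mean 0.29 and SD 0.13.
All are overridable through :class:`GeneratorConfig`.

Every sub-generator draws from its own named RNG stream spawned from the one
seed (PCG64 via numpy Generators), so e.g. adding species does not shift the
site covariates.  Generated tables pass the ingest validations unchanged, and
the latent truth is kept separate from the observable data so pipeline code
cannot accidentally consume it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .network import InteractionNetwork
from .occupancy import (CovariateBundle, OccupancyParams, linpred_gamma,
                        linpred_phi, linpred_psi1, detection_prob)

__all__ = [
    "GeneratorConfig", "SyntheticDataset", "generate_truth",
    "generate_detections", "generate_network", "generate_pollen",
    "generate_dataset", "write_dataset",
]

_STREAMS = ("params", "phenology", "dprime", "degree", "woody", "herb",
            "dates", "occupancy", "detection", "network", "pollen")


@dataclass
class GeneratorConfig:
    """Study-design knobs and true parameter values for the generator."""

    # design shape: 9 restored + 9 control parks, 3 years, 6 surveys/year
    n_species: int = 108
    n_sites: int = 18
    n_restored: int = 9
    n_years: int = 3
    n_surveys: int = 6

    # community hyper-parameters (logit scale)
    mu_psi1_0: float = -1.0
    sd_psi1_0: float = 1.0
    mu_gamma_0: float = -1.5
    sd_gamma_0: float = 1.0
    mu_phi_0: float = 0.5
    sd_phi_0: float = 1.0
    mu_p_0: float = 0.0        # logit detection at the phenological peak
    sd_p_0: float = 0.75

    # community slopes, ordered (d', restored, woody, d' x restored, d' x woody)
    psi1_slopes: tuple = (0.07, 2.26, -0.48, -0.21, -0.04)
    gamma_slopes: tuple = (-1.32, 1.02, 1.60, -0.11, 1.36)
    phi_slopes: tuple = (0.57, -0.30, -0.61, -0.42, -0.32)
    p_1: float = 0.98          # degree effect on detection
    p_4: float = 0.41          # survey-flower effect on detection

    # species-specific detection phenology: peak position on the standardised
    # date axis and (negative) curvature; widths leave a species detectable in
    # roughly 2-4 of 6 surveys
    peak_range: tuple = (-1.2, 1.2)
    curvature_range: tuple = (-2.5, -1.0)

    # specialisation distribution (Beta, rescaled moments)
    dprime_mean: float = 0.29
    dprime_sd: float = 0.13

    # site covariates: log woody floral abundance per site and survey counts
    woody_log_mean: float = 3.0
    woody_log_sd: float = 1.2
    woody_year_jitter: float = 0.3
    herb_log_mean: float = 2.0
    herb_restored_boost: float = 1.5

    # interaction network: shared community genera (each species also gets a
    # near-private genus); per-species interaction totals sized so the whole
    # network carries ~15k interactions, the volume of a pooled regional
    # dataset for a ~100-species community
    n_genera: int = 25
    interactions_log_mean: float = 4.5
    interactions_log_sd: float = 0.9
    genus_weight_sd: float = 1.2

    # pollen experiment: 11 sites (6 restored / 5 control), 16 pairs each
    pollen_n_restored: int = 6
    pollen_n_control: int = 5
    pollen_pairs_per_site: int = 16
    theta_control: float = 0.3
    theta_restored: float = 0.3
    pollen_site_sd: float = 0.5
    pollen_exclusion_rate: float = 0.1

    seed: int = 0

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(seq)
                for name, seq in zip(_STREAMS, children)}


@dataclass
class SyntheticDataset:
    """Observable tables plus (separately) the latent truth."""

    surveys: pd.DataFrame
    site_table: mio.SiteTable
    detections: mio.DetectionArray
    covariates: CovariateBundle
    truth: OccupancyParams          # aligned with detections.species_ids
    latent_z: np.ndarray            # (S_retained, J, K) true occurrence
    network: InteractionNetwork
    network_weights: pd.DataFrame   # species_id, specialisation weight
    pollen_pairs: pd.DataFrame
    config: GeneratorConfig



def _safe_z(x: np.ndarray) -> np.ndarray:
    """Z-score, or zeros when the values are constant (tiny communities can
    saturate e.g. the degree cap)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.zeros_like(x)
    return mio.standardize(x)[0]

def _beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    var = sd ** 2
    if var >= mean * (1 - mean):
        raise ValueError(
            f"infeasible Beta moments: mean={mean}, sd={sd} "
            f"(need sd^2 < mean*(1-mean))")
    nu = mean * (1 - mean) / var - 1
    return mean * nu, (1 - mean) * nu


def generate_truth(config: GeneratorConfig, streams=None):
    """Draw the true parameter set and the site/species covariates.

    Returns ``(params, covs, extras)`` where covariates are standardised
    exactly as the ingest path would standardise them (z-scores over the
    generated values) and ``extras`` carries the raw site tables needed to
    emit CSV files.
    """
    if streams is None:
        streams = config.streams()
    S, J, K, L = (config.n_species, config.n_sites, config.n_years,
                  config.n_surveys)
    if config.n_restored > J:
        raise ValueError("n_restored exceeds n_sites")

    rng_p = streams["params"]
    a, b = _beta_from_moments(config.dprime_mean, config.dprime_sd)
    dprime = streams["dprime"].beta(a, b, size=S)
    # generalists interact with more plant genera
    log_deg = 2.5 - 1.5 * dprime + streams["degree"].normal(0, 0.4, S)
    degree = np.clip(np.round(np.exp(log_deg)), 1, config.n_genera).astype(int)

    restored = np.zeros(J, dtype=int)
    restored[:config.n_restored] = 1

    # per-survey woody counts -> ingest-style site-year log summary
    rng_w = streams["woody"]
    site_woody = rng_w.normal(config.woody_log_mean, config.woody_log_sd, J)
    woody_counts = rng_w.poisson(
        np.exp(site_woody[:, None, None]
               + rng_w.normal(0, config.woody_year_jitter, (J, K))[..., None]),
        size=(J, K, L))
    woody_summary = np.log1p(woody_counts).mean(axis=2)          # (J, K)
    woody_z, woody_std = mio.standardize(woody_summary.ravel())
    woody_z = woody_z.reshape(J, K)

    # herbaceous flowers respond to restoration; survey-level total flowers
    rng_h = streams["herb"]
    herb_counts = rng_h.poisson(
        np.exp(config.herb_log_mean
               + config.herb_restored_boost * restored[:, None, None]
               + rng_h.normal(0, 0.4, (J, K, L))))
    flowers = np.log1p(herb_counts + woody_counts)
    flowers_z, _ = mio.standardize(flowers.ravel())
    flowers_z = flowers_z.reshape(J, K, L)

    # survey dates: the season window spread over L surveys, jittered
    rng_d = streams["dates"]
    base = np.linspace(121, 227, L)                              # May 1-Aug 15
    dates = np.clip(base[None, None, :]
                    + rng_d.integers(-6, 7, size=(J, K, L)), 1, 366)
    date_z, _ = mio.standardize(dates.ravel())
    date_z = date_z.reshape(J, K, L)

    dprime_z = _safe_z(dprime)
    degree_z = _safe_z(np.log(degree.astype(float)))

    # species intercepts and phenology
    rng_ph = streams["phenology"]
    peak = rng_ph.uniform(*config.peak_range, S)
    p_3 = rng_ph.uniform(*config.curvature_range, S)
    p_2 = -2.0 * p_3 * peak
    height = rng_p.normal(config.mu_p_0, config.sd_p_0, S)
    p_0 = height + p_3 * peak ** 2

    params = OccupancyParams(
        psi1_0=rng_p.normal(config.mu_psi1_0, config.sd_psi1_0, S),
        psi1=np.asarray(config.psi1_slopes, dtype=float),
        gamma_0=rng_p.normal(config.mu_gamma_0, config.sd_gamma_0, S),
        gamma=np.asarray(config.gamma_slopes, dtype=float),
        gamma_year=np.zeros(K - 1),
        phi_0=rng_p.normal(config.mu_phi_0, config.sd_phi_0, S),
        phi=np.asarray(config.phi_slopes, dtype=float),
        phi_year=np.zeros(K - 1),
        p_0=p_0, p_1=config.p_1, p_2=p_2, p_3=p_3, p_4=config.p_4,
        p_year=np.zeros(K),
        mu_psi1_0=config.mu_psi1_0, sd_psi1_0=config.sd_psi1_0,
        mu_gamma_0=config.mu_gamma_0, sd_gamma_0=config.sd_gamma_0,
        mu_phi_0=config.mu_phi_0, sd_phi_0=config.sd_phi_0,
        mu_p_0=config.mu_p_0, sd_p_0=config.sd_p_0,
    )
    covs = CovariateBundle(
        d_prime=dprime, d_prime_z=dprime_z, degree_z=degree_z,
        restored=restored, woody_z=woody_z, date_z=date_z,
        survey_flowers_z=flowers_z,
    )
    extras = {
        "woody_counts": woody_counts, "herb_counts": herb_counts,
        "dates": dates, "woody_summary": woody_summary, "degree": degree,
    }
    return params, covs, extras


def generate_detections(params: OccupancyParams, covs: CovariateBundle,
                        config: GeneratorConfig, streams=None):
    """Forward-simulate latent occurrence and binary detections.

    Returns ``(V, Z)``: the detection tensor (S, J, K, L) and the latent
    occurrence truth (S, J, K) — the latter is for tests and oracles only.
    """
    if streams is None:
        streams = config.streams()
    S = params.n_species
    J, K, L = config.n_sites, config.n_years, config.n_surveys
    rng_z = streams["occupancy"]
    rng_v = streams["detection"]

    psi1 = linpred_psi1(params, covs)
    gam = linpred_gamma(params, covs)
    phi = linpred_phi(params, covs)
    Z = np.zeros((S, J, K), dtype=np.int8)
    Z[..., 0] = rng_z.random((S, J)) < psi1
    for t in range(K - 1):
        stay = rng_z.random((S, J)) < phi[..., t]
        arrive = rng_z.random((S, J)) < gam[..., t]
        Z[..., t + 1] = np.where(Z[..., t] == 1, stay, arrive)

    p = detection_prob(params, covs)
    V = ((rng_v.random((S, J, K, L)) < p) & (Z[..., None] == 1)).astype(np.uint8)
    return V, Z


def generate_network(config: GeneratorConfig, streams=None,
                     weights: np.ndarray | None = None):
    """Interaction network with a controllable specialisation gradient.

    Each species splits its interactions between a near-private genus
    (receiving a share equal to its specialisation weight) and the shared
    community genera (in proportion to their availability); counts are
    multinomial.  A species with weight 0 visits in proportion to
    availability, so its standardised specialisation is near 0; a species with
    weight 1 is the sole visitor of its own genus, driving it toward 1 — the
    private-genus device is what lets the realised d' track the assigned
    weight, since the d' ceiling is exclusive use of a self-supplied genus.
    Returns ``(network, weights_frame)``.
    """
    if config.n_genera < 2:
        raise ValueError("need at least two plant genera")
    if streams is None:
        streams = config.streams()
    rng = streams["network"]
    S, G = config.n_species, config.n_genera
    if weights is None:
        a, b = _beta_from_moments(config.dprime_mean, config.dprime_sd)
        weights = rng.beta(a, b, size=S)
    avail = rng.lognormal(0.0, config.genus_weight_sd, G)
    avail = avail / avail.sum()
    totals = np.maximum(
        np.round(np.exp(rng.normal(config.interactions_log_mean,
                                   config.interactions_log_sd, S))), 3,
    ).astype(int)

    counts = np.zeros((S, G + S), dtype=np.int64)   # shared + private columns
    for i in range(S):
        probs = np.zeros(G + S)
        probs[:G] = (1 - weights[i]) * avail
        probs[G + i] = weights[i]
        counts[i] = rng.multinomial(totals[i], probs)
        if counts[i].sum() == 0:      # defensive; totals >= 3
            counts[i, G + i] = 1

    species = [f"sp_{i + 1:03d}" for i in range(S)]
    genera = ([f"genus_{g + 1:02d}" for g in range(G)]
              + [f"genus_pv_{i + 1:03d}" for i in range(S)])
    used = counts.sum(axis=0) > 0
    net = InteractionNetwork(
        counts=counts[:, used], pollinators=species,
        genera=[g for g, u in zip(genera, used) if u])
    wf = pd.DataFrame({"species_id": species, "weight": weights})
    return net, wf


def generate_pollen(config: GeneratorConfig, streams=None) -> pd.DataFrame:
    """Paired seed counts for the pollen-limitation experiment.

    Site intercepts are drawn around logit(theta) for each arm; each pair's
    limitation state is Bernoulli, and seed counts are constructed to realise
    the intended ratio class.  A fraction of pairs is planted as exclusion
    cases (fruitless supplemented flowers, or controls out-producing the
    supplemented flower more than two-fold).
    """
    for theta in (config.theta_control, config.theta_restored):
        if not 0.0 <= theta <= 1.0:
            raise ValueError("per-arm theta must lie in [0, 1]")
    if streams is None:
        streams = config.streams()
    rng = streams["pollen"]
    rows = []
    # pollen sites reuse the study parks (restored parks come first); a park
    # design smaller than the requested experiment clamps the site counts
    n_rest = min(config.pollen_n_restored, config.n_restored)
    n_ctrl = min(config.pollen_n_control, config.n_sites - config.n_restored)
    if n_rest + n_ctrl < 2:
        raise ValueError("pollen experiment needs at least two parks")
    for j in range(n_rest + n_ctrl):
        restored = int(j < n_rest)
        site_no = j + 1 if restored else config.n_restored + (j - n_rest) + 1
        theta = config.theta_restored if restored else config.theta_control
        if 0.0 < theta < 1.0:
            logit_site = (np.log(theta / (1 - theta))
                          + rng.normal(0, config.pollen_site_sd))
            theta_site = 1.0 / (1.0 + np.exp(-logit_site))
        else:
            theta_site = theta
        for n in range(config.pollen_pairs_per_site):
            plant = f"plant_{j + 1:02d}_{n + 1:02d}"
            site = f"site_{site_no:02d}"
            supplemented = int(rng.poisson(100)) + 1
            u = rng.random()
            if u < config.pollen_exclusion_rate / 2:
                rows.append((site, restored, plant, int(rng.poisson(40)), np.nan))
                continue
            if u < config.pollen_exclusion_rate:
                ratio = rng.uniform(2.05, 3.0)
                rows.append((site, restored, plant,
                             int(np.round(ratio * supplemented)), supplemented))
                continue
            limited = rng.random() < theta_site
            ratio = rng.uniform(0.05, 0.45) if limited else rng.uniform(0.55, 1.4)
            control = int(np.round(ratio * supplemented))
            rows.append((site, restored, plant, control, supplemented))
    return pd.DataFrame(
        rows, columns=["site_id", "restored", "plant_id",
                       "control_seeds", "supplemented_seeds"])


def _survey_frame(V, covs_extras, config: GeneratorConfig,
                  species_ids) -> pd.DataFrame:
    """Long-format survey table (full factorial) matching the ingest schema."""
    S, J, K, L = V.shape
    dates = covs_extras["dates"]
    herb = covs_extras["herb_counts"]
    woody = covs_extras["woody_counts"]
    i, j, k, l = np.meshgrid(np.arange(S), np.arange(J), np.arange(K),
                             np.arange(L), indexing="ij")
    return pd.DataFrame({
        "species_id": np.asarray(species_ids)[i.ravel()],
        "site_id": np.array([f"site_{x + 1:02d}" for x in range(J)])[j.ravel()],
        "year_index": k.ravel() + 1,
        "survey_index": l.ravel() + 1,
        "capture_count": V[i, j, k, l].ravel().astype(int),
        "survey_date": dates[j, k, l].ravel().astype(int),
        "herbaceous_floral_count": herb[j, k, l].ravel().astype(int),
        "woody_floral_count": woody[j, k, l].ravel().astype(int),
    })


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Run the full generator and push the result through the ingest path.

    The returned detection array and covariates are exactly what a user would
    obtain by writing the CSVs and re-reading them; the truth parameters and
    latent occupancy are subset to the species retained after the
    never-detected exclusion.
    """
    streams = config.streams()
    params, covs, extras = generate_truth(config, streams)
    V, Z = generate_detections(params, covs, config, streams)
    species_ids = [f"sp_{i + 1:03d}" for i in range(config.n_species)]
    surveys = _survey_frame(V, extras, config, species_ids)
    records = [
        mio.SurveyRecord(**{k: (str(v) if k in ("species_id", "site_id") else int(v))
                            for k, v in row.items()})
        for row in surveys.to_dict("records")
    ]
    array = mio.build_detection_array(records)

    keep = [species_ids.index(s) for s in array.species_ids]
    # re-standardise species covariates over the retained community, as the
    # ingest path would
    dprime = covs.d_prime[keep]
    degree = extras["degree"][keep]
    dprime_z = _safe_z(dprime)
    degree_z = _safe_z(np.log(degree.astype(float)))
    covs_fit = CovariateBundle(
        d_prime=dprime, d_prime_z=dprime_z, degree_z=degree_z,
        restored=covs.restored, woody_z=covs.woody_z,
        date_z=array.date_z, survey_flowers_z=array.survey_flowers_z,
    )
    truth = OccupancyParams(
        psi1_0=params.psi1_0[keep], psi1=params.psi1,
        gamma_0=params.gamma_0[keep], gamma=params.gamma,
        gamma_year=params.gamma_year,
        phi_0=params.phi_0[keep], phi=params.phi, phi_year=params.phi_year,
        p_0=params.p_0[keep], p_1=params.p_1, p_2=params.p_2[keep],
        p_3=params.p_3[keep], p_4=params.p_4, p_year=params.p_year,
        mu_psi1_0=params.mu_psi1_0, sd_psi1_0=params.sd_psi1_0,
        mu_gamma_0=params.mu_gamma_0, sd_gamma_0=params.sd_gamma_0,
        mu_phi_0=params.mu_phi_0, sd_phi_0=params.sd_phi_0,
        mu_p_0=params.mu_p_0, sd_p_0=params.sd_p_0,
    )
    site_table = mio.SiteTable(
        site_ids=array.site_ids, restored=covs.restored,
        woody_by_year=extras["woody_summary"],
    )
    net, weights = generate_network(config, streams)
    pollen = generate_pollen(config, streams)
    return SyntheticDataset(
        surveys=surveys, site_table=site_table, detections=array,
        covariates=covs_fit, truth=truth, latent_z=Z[keep],
        network=net, network_weights=weights, pollen_pairs=pollen,
        config=config,
    )


def write_dataset(data: SyntheticDataset, out_dir) -> None:
    """Write the observable CSVs plus the latent truth (separate file)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data.surveys.to_csv(out / "surveys.csv", index=False)
    mio.write_site_table(data.site_table, out / "sites.csv")
    counts = np.asarray(data.network.counts)
    edges = [
        (sp, gen, int(counts[i, g]), "synthetic")
        for i, sp in enumerate(data.network.pollinators)
        for g, gen in enumerate(data.network.genera)
        if counts[i, g] > 0
    ]
    pd.DataFrame(edges, columns=["pollinator_species", "plant_genus",
                                 "count", "source"]).to_csv(
        out / "interactions.csv", index=False)
    data.pollen_pairs.drop(columns=["restored"]).to_csv(
        out / "pollen_pairs.csv", index=False)
    truth = {
        "config": asdict(data.config),
        "species_ids": data.detections.species_ids,
        "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in data.truth.__dict__.items()},
        "latent_z": data.latent_z.tolist(),
    }
    (out / "truth.json").write_text(json.dumps(truth))
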