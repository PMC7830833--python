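"""Synthetic riverscape generator.

Emulates a two-species landscape-epigenetics design: sites on a river
network characterised by correlated environmental variables, and per
species three marker systems (diploid microsatellites, pooled-sequencing
SNP frequencies, MS-AFLP four-state epiloci) whose population structure
is driven by controllable couplings.

Generating model (all per site s, standardised gradients g1..g3):

* Environment — 14 variables are linear mixtures of three latent site
  gradients plus independent noise: a eutrophication axis (oxygen down;
  conductivity, nitrite, nitrate, BOD up; oxygen saturation down), an
  upstream-downstream axis (flow, width, pH, temperature up) and an
  altitude/nutrient axis (orthophosphate, slope, altitude, suspended
  matter up).  Riparian distances are leaf-to-leaf path lengths on a
  random bifurcating river tree.
* Genetics — a scalar neutral site factor z_s ~ N(0,1); the selection
  proxy a_s = z_s + gamma_env_gen * g1_s shifts SNP allele frequencies on
  the logit scale (an F-model: deviation scale set by f_gen, split
  between the shared site factor and per-locus noise), so SNP structure
  correlates with the eutrophication gradient when gamma_env_gen > 0.
  Microsatellites use z_s only (neutral markers carry no environmental
  signal).
* Epigenetics — site condition probabilities are logit-shifted by
  rho_epi_gen * a~_s + sqrt(1 - rho^2) * z'_s (a~_s is a_s standardised;
  z'_s an independent factor) plus beta_env * g1_s on per-locus loadings.
  rho_epi_gen = 1 with beta_env = 0 makes the epigenetic structure a
  deterministic function of the genetic site factors — the regime in
  which a marginal epigenetics~environment association is entirely
  spurious and disappears once genetic distance is controlled for.

Individuals are then drawn independently from their site's frequency or
condition-probability vectors; pooled SNP frequencies are exact site
frequencies by default (binomial read sampling is opt-in).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .diffstats import FrequencyTable, pool_frequencies
from .envspace import ENV_VARIABLES
from .msaflp import STATES, FourStateMatrix
from .seeding import named_rng

# variable -> (latent axis, loading); signs follow the gradient semantics above
_ENV_LOADINGS: dict[str, tuple[int, float]] = {
    "oxygen": (0, -0.90), "conductivity": (0, 0.85), "nitrite": (0, 0.80),
    "oxygen_saturation": (0, -0.75), "nitrate": (0, 0.70), "bod": (0, 0.45),
    "flow": (1, 0.90), "width": (1, 0.85), "ph": (1, 0.70), "temperature": (1, 0.45),
    "orthophosphate": (2, 0.85), "slope": (2, 0.80), "altitude": (2, 0.75),
    "sm": (2, 0.70),
}

# realistic units: (mean, sd) per variable for the final affine rescaling
_ENV_UNITS: dict[str, tuple[float, float]] = {
    "flow": (20.0, 8.0), "width": (25.0, 10.0), "slope": (1.2, 0.5),
    "altitude": (300.0, 120.0), "conductivity": (0.45, 0.15), "bod": (2.5, 0.8),
    "sm": (8.0, 3.0), "nitrate": (8.0, 3.0), "nitrite": (0.15, 0.06),
    "orthophosphate": (0.2, 0.08), "oxygen": (9.0, 1.2), "ph": (8.0, 0.3),
    "oxygen_saturation": (95.0, 8.0), "temperature": (19.8, 2.0),
}


@dataclass
class SimConfig:
    """Generator parameters; the defaults mirror the study design
    (13 sites, 24 individuals per species per site, ~260 epiloci,
    13-17 microsatellites, ~1,200-1,900 pooled SNPs)."""

    n_sites: int = 13
    n_individuals_per_site: int = 24
    n_microsat_loci: int = 15
    n_alleles_per_microsat: int = 8
    n_snps: int = 1500
    n_epiloci: int = 260
    f_gen: float = 0.10            # genetic differentiation intensity in [0, 1)
    epi_intensity: float = 0.20    # epigenetic differentiation intensity in [0, 1)
    rho_epi_gen: float = 0.7       # genetic -> epigenetic coupling in [0, 1]
    beta_env: float = 0.0          # direct environment -> epigenetic effect >= 0
    gamma_env_gen: float = 0.5     # environment -> genetic (selection proxy) >= 0
    env_noise_sd: float = 0.35     # per-variable noise around the latent mixture
    pool_read_depth: int | None = None  # binomial read sampling for SNP pools

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_individuals_per_site", "n_microsat_loci",
                     "n_alleles_per_microsat", "n_snps", "n_epiloci"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if not 0 <= self.f_gen < 1:
            raise ValueError("f_gen must be in [0, 1)")
        if not 0 <= self.epi_intensity < 1:
            raise ValueError("epi_intensity must be in [0, 1)")
        if not 0 <= self.rho_epi_gen <= 1:
            raise ValueError("rho_epi_gen must be in [0, 1]")
        if self.beta_env < 0 or self.gamma_env_gen < 0:
            raise ValueError("effect sizes must be >= 0")

    @property
    def sites(self) -> list[str]:
        return [f"s{k + 1:02d}" for k in range(self.n_sites)]


@dataclass
class SpeciesData:
    genotypes: pd.DataFrame
    snp_pool: FrequencyTable
    epi: FourStateMatrix
    site_factors: pd.DataFrame  # z, a, a_std, epi_factor per site


@dataclass
class SyntheticDataset:
    env: pd.DataFrame
    riparian: DistanceMatrix
    gradients: pd.DataFrame  # standardised g1..g3 per site
    species: dict[str, SpeciesData]
    config: SimConfig
    species_overrides: dict = field(default_factory=dict)


def _river_tree_distances(sites: list[str], rng: np.random.Generator) -> DistanceMatrix:
    """Leaf-to-leaf path lengths on a random bifurcating tree (km)."""
    # clusters: {leaf: depth to cluster root}
    clusters = [{s: 0.0} for s in sites]
    n = len(sites)
    d = np.zeros((n, n))
    idx = {s: i for i, s in enumerate(sites)}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        bi, bj = rng.uniform(5.0, 50.0, size=2)
        a, b = clusters[i], clusters[j]
        for la, da in a.items():
            for lb, db in b.items():
                dist = da + bi + db + bj
                d[idx[la], idx[lb]] = d[idx[lb], idx[la]] = dist
        merged = {la: da + bi for la, da in a.items()}
        merged.update({lb: db + bj for lb, db in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return DistanceMatrix(d, ids=sites)


def simulate_env(
    config: SimConfig, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, DistanceMatrix, pd.DataFrame]:
    """Environmental table, riparian distance matrix and latent gradients."""
    rng = rng if rng is not None else named_rng(seed, "simulate:env")
    sites = config.sites
    g = rng.standard_normal((config.n_sites, 3))
    g = g - g.mean(axis=0)
    g, _ = np.linalg.qr(g)  # mutually orthogonal latent gradients
    g = g / g.std(axis=0, ddof=0)  # standardised
    table = {}
    for var in ENV_VARIABLES:
        axis, loading = _ENV_LOADINGS[var]
        z = loading * g[:, axis] + config.env_noise_sd * rng.standard_normal(config.n_sites)
        mean, sd = _ENV_UNITS[var]
        table[var] = mean + sd * z
    env = pd.DataFrame(table, index=sites)
    riparian = _river_tree_distances(sites, rng)
    gradients = pd.DataFrame(g, index=sites, columns=["g1", "g2", "g3"])
    return env, riparian, gradients


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    m = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(m)
    return e / e.sum(axis=axis, keepdims=True)


def _deviation_scale(intensity: float) -> float:
    # logit-normal scale giving realised differentiation of roughly the
    # requested intensity at intermediate frequencies
    return 2.0 * np.sqrt(intensity / (1.0 - intensity))


def simulate_genetics(
    config: SimConfig,
    gradients: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, FrequencyTable, pd.DataFrame]:
    """Diploid microsatellite genotypes, pooled SNP frequencies and the
    per-site genetic factors (returned so the epigenetic layer can couple
    to them)."""
    rng = rng if rng is not None else named_rng(seed, "simulate:genetics")
    sites = config.sites
    S = config.n_sites
    g1 = gradients["g1"].to_numpy()
    z = rng.standard_normal(S)
    a = z + config.gamma_env_gen * g1
    a_std = a / np.sqrt(1.0 + config.gamma_env_gen**2)
    sigma = _deviation_scale(config.f_gen)
    w = np.sqrt(0.5)  # share of the deviation carried by the site factor

    # --- SNPs: biallelic, site frequencies on the logit scale
    p0 = rng.uniform(0.1, 0.9, size=config.n_snps)
    v = rng.standard_normal(config.n_snps)          # per-locus site-factor loading
    e = rng.standard_normal((S, config.n_snps))     # per-site-locus noise
    logit = np.log(p0 / (1 - p0))[None, :] + sigma * (
        w * a[:, None] * v[None, :] + np.sqrt(1 - w**2) * e
    )
    snp_freq = _logistic(logit)
    if config.pool_read_depth is not None:
        reads = rng.binomial(config.pool_read_depth, snp_freq)
        snp_freq = reads / config.pool_read_depth
    pool = pool_frequencies(
        pd.DataFrame(snp_freq, index=sites,
                     columns=[f"snp{j + 1:04d}" for j in range(config.n_snps)])
    )

    # --- microsatellites: multi-allelic, neutral (site factor z only)
    L, A = config.n_microsat_loci, config.n_alleles_per_microsat
    base = rng.dirichlet(np.full(A, 1.5), size=L)       # ancestral frequencies
    c = rng.standard_normal((L, A))                     # per-locus allele contrasts
    c -= c.mean(axis=1, keepdims=True)
    em = rng.standard_normal((S, L, A))
    logits = np.log(base)[None, :, :] + sigma * (
        w * z[:, None, None] * c[None, :, :] + np.sqrt(1 - w**2) * em
    )
    msat_freq = _softmax(logits)  # (sites, loci, alleles)

    n_ind = config.n_individuals_per_site
    cum = msat_freq.cumsum(axis=2)  # (S, L, A)
    u = rng.random((S, n_ind, L, 2))
    allele_idx = (u[:, :, :, :, None] > cum[:, None, :, None, :]).sum(axis=4)
    genotypes = pd.DataFrame({
        "individual": [f"{site}_i{j + 1:02d}" for site in sites for j in range(n_ind)],
        "population": [site for site in sites for _ in range(n_ind)],
    })
    flat = allele_idx.reshape(S * n_ind, L, 2)
    for lj in range(L):
        genotypes[f"ms{lj + 1:02d}_a1"] = [f"A{k + 1}" for k in flat[:, lj, 0]]
        genotypes[f"ms{lj + 1:02d}_a2"] = [f"A{k + 1}" for k in flat[:, lj, 1]]

    factors = pd.DataFrame({"z": z, "a": a, "a_std": a_std}, index=sites)
    return genotypes, pool, factors


def simulate_epigenetics(
    config: SimConfig,
    gradients: pd.DataFrame,
    genetic_factors: pd.DataFrame,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> FourStateMatrix:
    """Four-state epilocus matrix whose site structure couples to the
    genetic site factor (rho_epi_gen) and/or the eutrophication gradient
    (beta_env)."""
    rng = rng if rng is not None else named_rng(seed, "simulate:epigenetics")
    sites = config.sites
    S, L = config.n_sites, config.n_epiloci
    g1 = gradients["g1"].to_numpy()
    rho = config.rho_epi_gen
    z_indep = rng.standard_normal(S)
    f_site = rho * genetic_factors["a_std"].to_numpy() + np.sqrt(1 - rho**2) * z_indep

    # baseline condition probabilities: a small fraction of loci amplify
    # rarely (Condition IV dominant) and exercise the downstream filter
    rare = rng.random(L) < 0.08
    base = np.empty((L, 4))
    base[~rare] = rng.dirichlet([2.5, 1.5, 1.5, 1.5], size=(~rare).sum())
    if rare.any():
        base[rare] = rng.dirichlet([0.3, 0.3, 0.3, 12.0], size=rare.sum())

    sigma_e = _deviation_scale(config.epi_intensity)
    c = rng.standard_normal((L, 4))  # per-locus state contrasts for the site factor
    c -= c.mean(axis=1, keepdims=True)
    d = rng.standard_normal((L, 4))  # per-locus state loadings for the env effect
    d -= d.mean(axis=1, keepdims=True)
    logits = (
        np.log(base)[None, :, :]
        + sigma_e * f_site[:, None, None] * c[None, :, :]
        + config.beta_env * g1[:, None, None] * d[None, :, :]
    )
    probs = _softmax(logits)  # (sites, loci, states)

    n_ind = config.n_individuals_per_site
    u = rng.random((S, n_ind, L))
    cum = probs.cumsum(axis=2)  # (S, L, 4)
    states_idx = (u[:, :, :, None] > cum[:, None, :, :]).sum(axis=3)
    state_arr = np.array(STATES, dtype=object)[states_idx]

    index = [f"{site}_i{j + 1:02d}" for site in sites for j in range(n_ind)]
    pops = pd.Series([site for site in sites for _ in range(n_ind)], index=index)
    cols = [f"epi{j + 1:03d}" for j in range(L)]
    states = pd.DataFrame(
        state_arr.reshape(S * n_ind, L), index=index, columns=cols
    )
    return FourStateMatrix(states, pops)


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int | None = None,
    species_overrides: dict[str, dict] | None = None,
) -> SyntheticDataset:
    """Full two-species dataset sharing one environment and river network.

    The two species are independent draws with species-specific coupling
    parameters (``species_overrides`` maps species name to SimConfig
    field overrides), which supports comparative designs where one
    species' epigenetic structure is genetically coupled and the other's
    is not.
    """
    config = config or SimConfig()
    if species_overrides is None:
        species_overrides = {"gudgeon": {}, "minnow": {}}
    env, riparian, gradients = simulate_env(config, seed=seed)
    species = {}
    for name, over in species_overrides.items():
        cfg = replace(config, **over)
        grng = named_rng(seed, f"simulate:genetics:{name}")
        genotypes, pool, factors = simulate_genetics(cfg, gradients, rng=grng)
        erng = named_rng(seed, f"simulate:epigenetics:{name}")
        epi = simulate_epigenetics(cfg, gradients, factors, rng=erng)
        species[name] = SpeciesData(genotypes, pool, epi, factors)
    return SyntheticDataset(env, riparian, gradients, species, config,
                            species_overrides=species_overrides)


def config_echo(ds: SyntheticDataset) -> dict:
    """Plain-dict echo of the generating parameters (YAML-serialisable)."""
    return {
        "config": asdict(ds.config),
        "species_overrides": {k: dict(v) for k, v in ds.species_overrides.items()},
    }
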