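"""Synthetic data with the statistical structure the analysis assumes.

Three generators cover the pipeline's inputs:

* ``simulate_age_dataset`` — ages at death drawn from the adult standing age
  distribution implied by Gompertz survivorship, distorted (optionally) by
  population change, a windowed sampling bias, and rounded Gaussian
  age-estimation error, exactly mirroring the mortality model's own
  generative assumptions so that fits can be scored against recorded truth.
* ``simulate_corpora_dataset`` — ovarian corpora counts accumulated Poisson-wise
  with a linearly declining deposition rate.
* ``simulate_clade`` — a pure-birth chronogram (with bootstrap-style
  branch-length jitter replicates), species traits, and true demographic
  parameters in which lifespan scales allometrically with log length plus a
  lifespan offset for menopause species, while reproductive lifespan follows
  the same allometry in every species.

All generators are pure functions of their config (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .data_model import AgeDataset, Chronogram, CorporaDataset, GompertzParams, SpeciesTraits
from .mortality import gompertz_survivorship, ordinary_max_lifespan
from .reproduction import expected_corpora

__all__ = [
    "AgeSimConfig",
    "CorporaSimConfig",
    "CladeSimConfig",
    "simulate_age_dataset",
    "simulate_corpora_dataset",
    "simulate_clade",
    "CladeTruth",
]


@dataclass(frozen=True)
class AgeSimConfig:
    n: int = 1000
    alpha: float = 0.05          # baseline adult hazard (1/yr)
    beta: float = 0.1            # actuarial ageing rate (1/yr)
    maturity: float = 10.0
    r_true: float = 0.0          # total population change over the sampling period
    bias_window: tuple[float, float] | None = None
    bias_strength: float = 0.0   # s >= 0; bin weight is s+1 inside the window
    age_error: bool = False      # Normal(o, (o+B)/20) perturbation, rounded
    B: float = 0.0
    omega: float = 120.0         # age grid cap
    seed: int = 0
    species: str = "sim_species"
    sex: str = "female"
    dataset_id: str = "sim"
    population_id: str = "pop1"

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.bias_strength < 0:
            raise ValueError("bias strength must be >= 0")
        if self.beta < 0 or self.alpha <= 0:
            raise ValueError("need alpha > 0, beta >= 0")


def _adult_theta(cfg: AgeSimConfig) -> tuple[np.ndarray, np.ndarray, float]:
    """(bin ages, sampling probabilities, rho) for the true-age distribution."""
    ages = np.arange(np.floor(cfg.maturity), np.floor(cfg.omega) + 1.0)
    rel = ages - ages[0]
    params = GompertzParams(cfg.alpha, cfg.beta)
    L = gompertz_survivorship(rel, params)
    # per-year change implied by total change over half the observed span;
    # the grid cap stands in for the eventual maximum observed age
    rho = cfg.r_true / (0.5 * cfg.omega)
    R = (1.0 - rho) ** rel
    S = np.ones_like(ages)
    if cfg.bias_window is not None:
        lo, hi = cfg.bias_window
        S[(ages >= lo) & (ages <= hi)] = cfg.bias_strength + 1.0
    theta = L * R * S
    return ages, theta / theta.sum(), rho


def simulate_age_dataset(cfg: AgeSimConfig) -> tuple[AgeDataset, dict]:
    """Draw one age-at-death dataset; returns (dataset, truth record)."""
    rng = np.random.default_rng(cfg.seed)
    ages, theta, rho = _adult_theta(cfg)
    counts = rng.multinomial(cfg.n, theta)
    true_ages = np.repeat(ages, counts)
    if cfg.age_error:
        eps = (true_ages + cfg.B) / 20.0
        observed = np.rint(true_ages + eps * rng.standard_normal(len(true_ages)))
        observed = np.maximum(observed, 0.0)
    else:
        observed = true_ages
    vals, cnts = np.unique(observed, return_counts=True)
    max_obs = float(vals.max())
    window = cfg.bias_window
    if window is not None:
        window = (window[0], min(window[1], max_obs))
    ds = AgeDataset(
        dataset_id=cfg.dataset_id, species=cfg.species, sex=cfg.sex,
        population_id=cfg.population_id,
        records=[(float(a), int(c)) for a, c in zip(vals, cnts)],
        growth_prior=(cfg.r_true, 0.05),
        bias_window=window,
        age_bias_offset=cfg.B,
        source_type="simulated",
    )
    truth = {
        "dataset_id": cfg.dataset_id, "alpha": cfg.alpha, "beta": cfg.beta,
        "maturity": cfg.maturity, "r_true": cfg.r_true, "rho_true": rho,
        "bias_strength": cfg.bias_strength, "B": cfg.B, "seed": cfg.seed,
    }
    return ds, truth


@dataclass(frozen=True)
class CorporaSimConfig:
    n: int = 200
    deposition_alpha: float = 1.2    # initial corpora deposition rate (corpora/yr)
    decline_beta: float = 0.04       # linear per-year decline in deposition rate
    maturity: float = 10.0
    mortality_alpha: float = 0.05    # Gompertz params used to sample ages
    mortality_beta: float = 0.1
    omega: float = 120.0
    seed: int = 0
    species: str = "sim_species"
    dataset_id: str = "sim_corpora"

    def __post_init__(self):
        if self.deposition_alpha <= 0 or self.decline_beta <= 0:
            raise ValueError("deposition alpha and decline beta must be > 0")


def simulate_corpora_dataset(cfg: CorporaSimConfig) -> tuple[CorporaDataset, dict]:
    """Corpora counts from Poisson accumulation, ages from the adult standing
    age distribution of the configured mortality model."""
    rng = np.random.default_rng(cfg.seed)
    acfg = AgeSimConfig(n=cfg.n, alpha=cfg.mortality_alpha, beta=cfg.mortality_beta,
                        maturity=cfg.maturity, omega=cfg.omega, seed=cfg.seed)
    ages, theta, _ = _adult_theta(acfg)
    idx = rng.choice(len(ages), size=cfg.n, p=theta)
    adult_idx = (ages[idx] - ages[0]).astype(int)  # completed adult years: 0 = first
    lam = expected_corpora(adult_idx.astype(float), cfg.deposition_alpha, cfg.decline_beta)
    counts = rng.poisson(lam)
    ds = CorporaDataset(
        dataset_id=cfg.dataset_id, species=cfg.species,
        records=[(float(cfg.maturity + i), int(c)) for i, c in zip(adult_idx, counts)],
        age_at_maturity=cfg.maturity,
        max_lifespan_age=float(cfg.maturity + adult_idx.max()),
    )
    truth = {"dataset_id": cfg.dataset_id, "deposition_alpha": cfg.deposition_alpha,
             "decline_beta": cfg.decline_beta, "maturity": cfg.maturity,
             "cessation_age": 1.0 / cfg.decline_beta + cfg.maturity, "seed": cfg.seed}
    return ds, truth


# ---------------------------------------------------------------------------
# whole clades


@dataclass(frozen=True)
class CladeSimConfig:
    n_species: int = 32
    n_menopause: int = 5
    n_trees: int = 10
    birth_rate: float = 0.1              # pure-birth rate for the chronogram
    allometry_intercept: float = -10.0   # lifespan Z (yr) at log-length 0
    allometry_slope: float = 9.0         # yr per unit log-length (cm)
    menopause_offset: float = 40.0       # extra lifespan (yr) in menopause species
    log_length_mean: float = 5.8         # ~330 cm
    log_length_sd: float = 0.5
    phylo_noise_eta: float = 3.0         # OU amplitude of lifespan noise (yr)
    phylo_noise_rho: float = 0.3         # OU decay rate of lifespan noise
    obs_sd_lifespan: float = 2.0         # reported posterior sd of Z
    obs_sd_length: float = 0.05          # reported sd of log length
    maturity_base: float = 6.0           # maturity = base + slope * (logL - mean)
    maturity_slope: float = 3.0
    cessation_frac: float = 0.75         # cessation age as fraction of non-menopause Z
    tree_jitter_sd: float = 0.05         # lognormal depth jitter for bootstrap trees
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("need at least 3 species for an identifiable regression")
        if self.n_menopause > self.n_species:
            raise ValueError("n_menopause cannot exceed n_species")


@dataclass
class CladeTruth:
    table: pd.DataFrame   # per-species truth and observed summaries
    config: CladeSimConfig


def _pure_birth_newick(n_species: int, birth_rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Yule tree grown to n_species extant tips, then made ultrametric by
    extending tips to the present."""
    taxa = [f"sp{i:02d}" for i in range(n_species)]
    # grow: start with 2 lineages, split a uniformly chosen lineage at
    # exponential waiting times
    times = []
    t = 0.0
    k = 2
    while k < n_species:
        t += rng.exponential(1.0 / (birth_rate * k))
        times.append(t)
        k += 1
    total = t + rng.exponential(1.0 / (birth_rate * k))
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node.age_t = 0.0
    a = dendropy.Node()
    b = dendropy.Node()
    tree.seed_node.add_child(a)
    tree.seed_node.add_child(b)
    tips = [a, b]
    for bt in times:
        i = rng.integers(len(tips))
        node = tips.pop(i)
        node.split_t = bt
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        tips.extend([c1, c2])
    rng.shuffle(tips)
    for node, tx in zip(tips, taxa):
        node.taxon = tns.get_taxon(tx)
        node.split_t = total
    # assign edge lengths from split times
    tree.seed_node.split_t = 0.0

    def assign(node):
        for ch in node.child_nodes():
            ch.edge.length = ch.split_t - node.split_t if hasattr(ch, "split_t") else None
            assign(ch)

    # internal nodes that never got split_t are tips (handled); all internals have it
    for node in tree.preorder_node_iter():
        if not hasattr(node, "split_t"):
            node.split_t = total
    assign(tree.seed_node)
    return tree


def _tree_to_chronogram(tree: dendropy.Tree, index: int) -> Chronogram:
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    tx = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
    return Chronogram(taxa=taxa, distances=D, tree_index=index)


def simulate_clade(cfg: CladeSimConfig) -> tuple[list[Chronogram], list[SpeciesTraits], CladeTruth]:
    """Simulate chronogram bootstraps, traits, and per-species truth."""
    rng = np.random.default_rng(cfg.seed)
    tree = _pure_birth_newick(cfg.n_species, cfg.birth_rate, rng)
    base = _tree_to_chronogram(tree, 0)
    taxa = base.taxa
    n = cfg.n_species

    trees = []
    for k in range(cfg.n_trees):
        scale = float(np.exp(cfg.tree_jitter_sd * rng.standard_normal())) if k else 1.0
        trees.append(Chronogram(taxa=taxa, distances=base.distances * scale, tree_index=k))

    meno = np.zeros(n, dtype=int)
    meno[rng.choice(n, size=cfg.n_menopause, replace=False)] = 1

    log_len = cfg.log_length_mean + cfg.log_length_sd * rng.standard_normal(n)
    # phylogenetically correlated lifespan noise (OU kernel on the true tree)
    D = base.distances
    K = cfg.phylo_noise_eta ** 2 * np.exp(-cfg.phylo_noise_rho ** 2 * D)
    K += 1e-9 * np.eye(n)
    noise = rng.multivariate_normal(np.zeros(n), K, method="cholesky")
    z_nomeno = cfg.allometry_intercept + cfg.allometry_slope * log_len
    z_true = z_nomeno + cfg.menopause_offset * meno + noise
    z_obs = z_true + cfg.obs_sd_lifespan * rng.standard_normal(n)
    log_len_obs = log_len + cfg.obs_sd_length * rng.standard_normal(n)

    maturity = cfg.maturity_base + cfg.maturity_slope * (log_len - cfg.log_length_mean)
    maturity = np.maximum(maturity, 2.0)
    # reproductive lifespan follows the non-menopause allometry in ALL species
    cessation_true = maturity + cfg.cessation_frac * np.maximum(z_nomeno - maturity, 2.0)
    cessation_obs = cessation_true + cfg.obs_sd_lifespan * rng.standard_normal(n)

    traits = [
        SpeciesTraits(
            species=taxa[i], sex="female",
            length_mean=float(np.exp(log_len_obs[i])),
            length_sd=float(np.exp(log_len_obs[i]) * cfg.obs_sd_length),
            maturity_mean=float(maturity[i]), maturity_sd=0.5,
            menopause=int(meno[i]),
        )
        for i in range(n)
    ]
    truth = pd.DataFrame({
        "species": taxa, "menopause": meno,
        "log_length_true": log_len, "log_length_obs": log_len_obs,
        "log_length_obs_sd": cfg.obs_sd_length,
        "lifespan_true": z_true, "lifespan_nomenopause": z_nomeno,
        "lifespan_obs": z_obs, "lifespan_obs_sd": cfg.obs_sd_lifespan,
        "cessation_true": cessation_true, "cessation_obs": cessation_obs,
        "cessation_obs_sd": cfg.obs_sd_lifespan,
        "maturity": maturity,
    })
    return trees, traits, CladeTruth(table=truth, config=cfg)
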