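"""Bayesian Gompertz mortality estimation from age-at-death samples.

Published toothed-whale age-structure datasets are counts of dead whales per
age class. Treating them as a multinomial sample from the standing adult age
distribution, the per-bin probability is proportional to the product of

* ``L`` — Gompertz adult survivorship (parameters alpha, beta shared by all
  datasets of a species-sex),
* ``R`` — a population-change discount ``(1 - rho)^AGE`` where ``rho`` is the
  per-year change implied by the total change ``r`` over half the observed
  age span (datasets from one population share ``r``),
* ``S`` — a sampling-bias multiplier ``s + 1`` inside a dataset-specific age
  window, 1 outside,

renormalized over bins. Age-estimation error (sd ``(age + B) / 20``, observed
ages rounded to whole years) is marginalized by convolving the bin
probabilities with a row-stochastic error kernel.

From fitted hazards we derive the ordinary maximum lifespan Z — the age by
which 90% of adult person-years have been lived — plus survivorship and life
expectancy at any adult age, and, where juvenile sampling is good, a Siler
(bathtub) fit giving survival to maturity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._mcmc import run_ensemble
from .data_model import (
    AgeDataset,
    GompertzParams,
    MortalityPosterior,
    ValidationError,
    apply_inclusion_filters,
)

__all__ = [
    "gompertz_survivorship",
    "gompertz_hazard",
    "ExpectedAgeDistribution",
    "expected_age_distribution",
    "age_error_kernel",
    "fit_mortality",
    "ordinary_max_lifespan",
    "survival_and_expectancy_at_age",
    "siler_survivorship",
    "JuvenilePosterior",
    "fit_juvenile_survival",
    "predict_survival_to_maturity",
    "default_age_cap",
]

AGE_ERROR_SCALE = 1.0 / 20.0  # sd of age estimate = (age + B) / 20


def default_age_cap(max_observed_age: float) -> float:
    """Age grid cap: generous enough that survivorship mass beyond is nil."""
    return max(120.0, 3.0 * max_observed_age)


def gompertz_hazard(age: np.ndarray | float, params: GompertzParams,
                    from_age: float = 0.0) -> np.ndarray | float:
    return params.alpha * np.exp(params.beta * (np.asarray(age, float) - from_age))


def gompertz_survivorship(age, params: GompertzParams, from_age: float = 0.0):
    """P(alive at ``age`` | alive at ``from_age``) under Gompertz hazard.

    beta == 0 reduces to the exponential limit exp(-alpha * t).
    """
    t = np.asarray(age, dtype=float) - from_age
    if np.any(t < -1e-12):
        raise ValueError("age must be >= from_age")
    t = np.maximum(t, 0.0)
    if params.beta == 0.0:
        out = np.exp(-params.alpha * t)
    else:
        with np.errstate(over="ignore"):  # overflow -> survivorship 0
            out = np.exp(-(params.alpha / params.beta) * np.expm1(params.beta * t))
    return out if np.ndim(age) else float(out)


# ---------------------------------------------------------------------------
# expected age distribution (the multinomial cell probabilities)


@dataclass
class ExpectedAgeDistribution:
    ages: np.ndarray          # bin labels (years), 1-yr spacing, maturity..omega
    theta: np.ndarray         # cell probabilities after error marginalization
    L: np.ndarray             # normalized survivorship component
    R: np.ndarray             # population-change component
    S: np.ndarray             # sampling-bias component
    error_kernel: np.ndarray  # row-stochastic: true bin -> observed bin
    theta_true: np.ndarray    # cell probabilities before error marginalization


def age_error_kernel(ages: np.ndarray, B: float = 0.0,
                     enabled: bool = True) -> np.ndarray:
    """Row-stochastic matrix: P(observed bin j | true age in bin i).

    An estimated age is the true age plus Normal noise of sd (age + B)/20,
    rounded to the nearest whole year; mass falling off the grid is
    renormalized back onto it.
    """
    ages = np.asarray(ages, dtype=float)
    n = len(ages)
    if not enabled:
        return np.eye(n)
    eps = AGE_ERROR_SCALE * (ages + B)
    K = np.zeros((n, n))
    for i in range(n):
        if eps[i] <= 1e-12:
            K[i, i] = 1.0
            continue
        # P(round(N(age_i, eps)) = age_j) = Phi((a_j + .5 - a_i)/eps) - Phi((a_j - .5 - a_i)/eps)
        hi = special.ndtr((ages + 0.5 - ages[i]) / eps[i])
        lo = special.ndtr((ages - 0.5 - ages[i]) / eps[i])
        row = hi - lo
        K[i] = row / row.sum()
    return K


def expected_age_distribution(
    params: GompertzParams,
    maturity: float,
    omega: float,
    rho: float = 0.0,
    s: float = 0.0,
    bias_window: tuple[float, float] | None = None,
    B: float = 0.0,
    age_error: bool = True,
) -> ExpectedAgeDistribution:
    """Multinomial cell probabilities over 1-year adult age bins."""
    if rho >= 1.0:
        raise ValueError(f"per-year population change rho={rho} must be < 1")
    if s < 0:
        raise ValueError("bias strength s must be >= 0")
    if omega <= maturity:
        raise ValueError("age cap omega must exceed maturity")
    ages = np.arange(np.floor(maturity), np.floor(omega) + 1.0)
    rel = ages - ages[0]
    L = gompertz_survivorship(rel, params)
    L = L / L.sum()
    R = (1.0 - rho) ** rel
    S = np.ones_like(ages)
    if bias_window is not None:
        lo, hi = bias_window
        S[(ages >= lo) & (ages <= hi)] = s + 1.0
    theta_true = L * R * S
    theta_true = theta_true / theta_true.sum()
    K = age_error_kernel(ages, B=B, enabled=age_error)
    theta = theta_true @ K
    theta = theta / theta.sum()
    return ExpectedAgeDistribution(ages=ages, theta=theta, L=L, R=R, S=S,
                                   error_kernel=K, theta_true=theta_true)


# ---------------------------------------------------------------------------
# ordinary maximum lifespan and age-conditional summaries


def ordinary_max_lifespan(params: GompertzParams, maturity: float,
                          q: float = 0.9, omega: float | None = None) -> float:
    """Smallest age on the 1-year grid by which a fraction ``q`` of adult
    person-years have been lived."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if omega is None:
        omega = maturity + 150.0
    t = np.arange(0.0, np.ceil(omega - maturity) + 1.0)
    l = gompertz_survivorship(t, params)
    # cumulative person-years by trapezoid on the 1-yr grid
    seg = 0.5 * (l[:-1] + l[1:])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    frac = cum / cum[-1]
    k = int(np.searchsorted(frac, q))
    return float(maturity + t[min(k, len(t) - 1)])


def survival_and_expectancy_at_age(
    params: GompertzParams, M: float, maturity: float,
    omega: float | None = None,
) -> tuple[float, float]:
    """(probability of reaching age M from maturity, remaining life expectancy
    at M), by 1-year-grid quadrature."""
    if M < maturity:
        raise ValueError("M must be >= maturity")
    if omega is None:
        omega = M + 150.0
    l_M = float(gompertz_survivorship(M, params, from_age=maturity))
    t = np.arange(M - maturity, np.ceil(omega - maturity) + 1.0)
    l = gompertz_survivorship(t, params)
    e_M = float(np.trapezoid(l, t) / l[0])
    return l_M, e_M


# ---------------------------------------------------------------------------
# the fit


@dataclass
class _FitLayout:
    """Index bookkeeping for the parameter vector of one species-sex fit."""

    populations: list[str]
    windowed: list[str]  # dataset_ids with a bias window
    names: list[str]

    @classmethod
    def build(cls, datasets: list[AgeDataset]) -> "_FitLayout":
        pops = sorted({d.population_id for d in datasets})
        windowed = [d.dataset_id for d in datasets if d.bias_window is not None]
        names = ["log_alpha", "log_beta"]
        names += [f"r_{p}" for p in pops]
        names += [f"log_s_{d}" for d in windowed]
        return cls(populations=pops, windowed=windowed, names=names)


def fit_mortality(
    datasets: list[AgeDataset],
    maturity: float,
    seed: int = 0,
    n_steps: int = 1000,
    n_burn: int = 600,
    age_error: bool = True,
    check_filters: bool = True,
    omega: float | None = None,
    q: float = 0.9,
) -> MortalityPosterior:
    """Fit the shared Gompertz mortality model to all datasets of one
    species-sex and attach ordinary-maximum-lifespan draws.

    Datasets must be same species and sex; datasets sharing a population_id
    share the total-population-change parameter r, and every dataset with a
    declared bias window gets its own bias strength s_d.
    """
    if not datasets:
        raise ValueError("no datasets supplied")
    species = {d.species for d in datasets}
    sexes = {d.sex for d in datasets}
    if len(species) != 1 or len(sexes) != 1:
        raise ValueError("fit_mortality expects datasets of a single species-sex")
    if check_filters:
        included, excluded = apply_inclusion_filters(datasets, "lifespan", maturity)
        if excluded:
            raise ValidationError(
                "datasets fail the lifespan inclusion filter: "
                + ", ".join(f"{e.dataset_id} ({e.rule}={e.value:.3g})" for e in excluded)
            )

    if omega is None:
        omega = default_age_cap(max(d.max_observed_age for d in datasets))
    layout = _FitLayout.build(datasets)
    ages = np.arange(np.floor(maturity), np.floor(omega) + 1.0)
    rel = ages - ages[0]

    # precompute per-dataset fixed pieces
    counts, kernels, S_masks, half_span, pop_idx = [], [], [], [], []
    for d in datasets:
        counts.append(d.binned_counts(ages[0], np.floor(omega) + 1.0))
        kernels.append(age_error_kernel(ages, B=d.age_bias_offset, enabled=age_error))
        mask = np.zeros(len(ages))
        if d.bias_window is not None:
            lo, hi = d.bias_window
            mask[(ages >= lo) & (ages <= hi)] = 1.0
        S_masks.append(mask)
        half_span.append(0.5 * d.max_observed_age)
        pop_idx.append(layout.populations.index(d.population_id))
    windowed_idx = {did: k for k, did in enumerate(layout.windowed)}
    r_priors = {}
    for d in datasets:
        r_priors.setdefault(layout.populations.index(d.population_id), d.growth_prior)

    n_pop = len(layout.populations)

    def log_post(x: np.ndarray) -> float:
        log_a, log_b = x[0], x[1]
        if abs(log_a) > 20 or abs(log_b) > 20:
            return -np.inf
        alpha, beta = np.exp(log_a), np.exp(log_b)
        rs = x[2:2 + n_pop]
        log_ss = x[2 + n_pop:]
        # priors: alpha ~ HN(0.1), beta ~ HN(0.2) with log-jacobians;
        # r ~ Normal(source prior); s ~ Exponential(1) with log-jacobian
        lp = -0.5 * (alpha / 0.1) ** 2 + log_a
        lp += -0.5 * (beta / 0.2) ** 2 + log_b
        for p, (mu, sd) in r_priors.items():
            lp += -0.5 * ((rs[p] - mu) / sd) ** 2
        ss = np.exp(log_ss)
        if np.any(ss > 1e6):
            return -np.inf
        lp += np.sum(-ss + log_ss)
        with np.errstate(over="ignore"):  # underflow to 0 handled below
            L = np.exp(-(alpha / beta) * np.expm1(beta * rel)) if beta > 0 else np.exp(-alpha * rel)
        if not np.all(np.isfinite(L)) or L.sum() <= 0:
            return -np.inf
        for k, d in enumerate(datasets):
            rho = rs[pop_idx[k]] / half_span[k]
            if rho >= 1.0:
                return -np.inf
            R = (1.0 - rho) ** rel
            if d.dataset_id in windowed_idx:
                s_d = ss[windowed_idx[d.dataset_id]]
                S = 1.0 + s_d * S_masks[k]
            else:
                S = 1.0
            theta = L * R * S
            tot = theta.sum()
            if not np.isfinite(tot) or tot <= 0:
                return -np.inf
            theta = (theta / tot) @ kernels[k]
            c = counts[k]
            nz = c > 0
            if np.any(theta[nz] <= 0):
                return -np.inf
            lp += float(c[nz] @ np.log(theta[nz]))
        if not np.isfinite(lp):
            return -np.inf
        return lp

    # crude MAP start: coarse grid over (alpha, beta) to find a finite
    # region (a poor beta guess zeroes the likelihood for long-lived
    # species), then a local polish
    rest = np.concatenate([
        [r_priors[p][0] for p in range(n_pop)],
        np.full(len(layout.windowed), np.log(0.5)),
    ])
    grid = [
        np.concatenate([[la, lb], rest])
        for la in np.log([0.005, 0.02, 0.05, 0.1, 0.2])
        for lb in np.log([0.005, 0.02, 0.05, 0.1, 0.2, 0.4])
    ]
    x0 = max(grid, key=log_post)
    if not np.isfinite(log_post(x0)):
        raise RuntimeError("no finite starting point found for the mortality model")
    opt = optimize.minimize(lambda x: -log_post(x), x0, method="Nelder-Mead",
                            options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-4})
    if np.isfinite(opt.fun):
        x0 = opt.x

    res = run_ensemble(log_post, x0, layout.names, seed=seed,
                       n_steps=n_steps, n_burn=n_burn)
    draws = res.draws.copy()
    draws["alpha"] = np.exp(draws.pop("log_alpha"))
    draws["beta"] = np.exp(draws.pop("log_beta"))
    for did in layout.windowed:
        draws[f"s_{did}"] = np.exp(draws.pop(f"log_s_{did}"))
    # derived ordinary maximum lifespan per draw
    draws["Z"] = [
        ordinary_max_lifespan(GompertzParams(a, b), maturity, q=q, omega=omega)
        for a, b in zip(draws["alpha"], draws["beta"])
    ]
    return MortalityPosterior(
        species=next(iter(species)), sex=next(iter(sexes)), draws=draws,
        convergence=res.convergence, converged=res.converged, maturity=maturity,
    )


# ---------------------------------------------------------------------------
# juvenile (Siler / bathtub) mortality and survival to maturity


def siler_survivorship(age, a1: float, b1: float, a2: float,
                       a3: float, b3: float):
    """Whole-life survivorship under the bathtub hazard
    h(x) = a1*exp(-b1*x) + a2 + a3*exp(b3*x)."""
    x = np.asarray(age, dtype=float)
    H = (a1 / b1) * (1.0 - np.exp(-b1 * x)) + a2 * x + (a3 / b3) * np.expm1(b3 * x)
    out = np.exp(-H)
    return out if np.ndim(age) else float(out)


@dataclass
class JuvenilePosterior:
    """Per-dataset bathtub fits, species survival-to-maturity draws, and the
    across-species regression of logit survival on age at maturity."""

    dataset_draws: dict[str, pd.DataFrame]       # dataset_id -> Siler param draws
    survival_draws: dict[str, np.ndarray]        # species -> survival-to-maturity draws
    regression_draws: pd.DataFrame | None        # columns: intercept, slope, sigma
    convergence: dict[str, pd.DataFrame]
    converged: bool


_SILER_NAMES = ["log_a1", "log_b1", "log_a2", "log_a3", "log_b3"]


def _fit_siler_dataset(d: AgeDataset, maturity: float, omega: float,
                       seed: int, n_steps: int, n_burn: int) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    ages = np.arange(0.0, np.floor(omega) + 1.0)
    counts = d.binned_counts(0.0, np.floor(omega) + 1.0)

    def log_post(x):
        if np.any(np.abs(x) > 20):
            return -np.inf
        a1, b1, a2, a3, b3 = np.exp(x)
        # weakly informative half-Normal priors on the natural scale
        lp = (-0.5 * (a1 / 1.0) ** 2 - 0.5 * (b1 / 2.0) ** 2 - 0.5 * (a2 / 0.2) ** 2
              - 0.5 * (a3 / 0.1) ** 2 - 0.5 * (b3 / 0.2) ** 2 + np.sum(x))
        S = siler_survivorship(ages, a1, b1, a2, a3, b3)
        tot = S.sum()
        if not np.all(np.isfinite(S)) or tot <= 0:
            return -np.inf
        theta = S / tot
        nz = counts > 0
        if np.any(theta[nz] <= 0):
            return -np.inf
        return lp + float(counts[nz] @ np.log(theta[nz]))

    x0 = np.log([0.3, 0.5, 0.02, 0.02, 0.12])
    opt = optimize.minimize(lambda x: -log_post(x), x0, method="Nelder-Mead",
                            options={"maxiter": 3000})
    if np.isfinite(opt.fun):
        x0 = opt.x
    res = run_ensemble(log_post, x0, _SILER_NAMES, seed=seed,
                       n_steps=n_steps, n_burn=n_burn)
    draws = np.exp(res.draws.values)
    df = pd.DataFrame(draws, columns=["a1", "b1", "a2", "a3", "b3"])
    df["survival_to_maturity"] = siler_survivorship(
        np.full(len(df), maturity), df["a1"].values, df["b1"].values,
        df["a2"].values, df["a3"].values, df["b3"].values)
    return df, res.convergence, res.converged


def fit_juvenile_survival(
    datasets: list[AgeDataset],
    maturity: dict[str, float] | float,
    seed: int = 0,
    n_steps: int = 800,
    n_burn: int = 900,
    check_filters: bool = True,
) -> JuvenilePosterior:
    """Fit the bathtub model per well-sampled dataset and regress logit
    survival-to-maturity on age at maturity across species.

    The regression slope's sign is estimated, not assumed; callers should
    inspect the posterior before relying on a negative correlation.
    """
    if check_filters:
        included, excluded = apply_inclusion_filters(datasets, "juvenile", maturity)
        if excluded:
            raise ValidationError(
                "datasets fail the juvenile inclusion filter: "
                + ", ".join(e.dataset_id for e in excluded))

    def mat_for(sp):
        return maturity[sp] if isinstance(maturity, dict) else float(maturity)

    dataset_draws, conv, ok = {}, {}, True
    by_species: dict[str, list[np.ndarray]] = {}
    for k, d in enumerate(datasets):
        omega = default_age_cap(d.max_observed_age)
        df, cdf, c_ok = _fit_siler_dataset(d, mat_for(d.species), omega,
                                           seed=seed + 1000 + k,
                                           n_steps=n_steps, n_burn=n_burn)
        dataset_draws[d.dataset_id] = df
        conv[d.dataset_id] = cdf
        ok = ok and c_ok
        by_species.setdefault(d.species, []).append(df["survival_to_maturity"].values)
    survival_draws = {sp: np.concatenate(v) for sp, v in by_species.items()}

    regression_draws = None
    if len(survival_draws) >= 5:
        sps = sorted(survival_draws)
        y = np.array([special.logit(np.clip(np.mean(survival_draws[sp]), 1e-6, 1 - 1e-6))
                      for sp in sps])
        ysd = np.array([max(np.std(special.logit(np.clip(survival_draws[sp], 1e-6, 1 - 1e-6))), 1e-3)
                        for sp in sps])
        m = np.array([mat_for(sp) for sp in sps])

        def reg_post(x):
            a, b, log_sig = x
            if abs(log_sig) > 10:
                return -np.inf
            sig = np.exp(log_sig)
            var = sig ** 2 + ysd ** 2
            resid = y - (a + b * m)
            lp = -0.5 * (a / 10) ** 2 - 0.5 * (b / 10) ** 2 - 0.5 * (sig / 2) ** 2 + log_sig
            return lp - 0.5 * float(np.sum(resid ** 2 / var + np.log(var)))

        b0 = np.polyfit(m, y, 1)
        res = run_ensemble(reg_post, np.array([b0[1], b0[0], np.log(0.5)]),
                           ["intercept", "slope", "log_sigma"], seed=seed + 7,
                           n_steps=800, n_burn=500)
        regression_draws = res.draws.copy()
        regression_draws["sigma"] = np.exp(regression_draws.pop("log_sigma"))
        conv["regression"] = res.convergence
        ok = ok and res.converged

    return JuvenilePosterior(dataset_draws=dataset_draws, survival_draws=survival_draws,
                             regression_draws=regression_draws, convergence=conv,
                             converged=ok)


def predict_survival_to_maturity(posterior: JuvenilePosterior,
                                 maturity: float | np.ndarray,
                                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Posterior-predictive survival-to-maturity for a species with no direct
    juvenile fit, from the across-species regression on age at maturity."""
    if posterior.regression_draws is None:
        raise ValueError("no regression available (needs >= 5 species with direct fits)")
    if rng is None:
        rng = np.random.default_rng(0)
    reg = posterior.regression_draws
    mu = reg["intercept"].values + reg["slope"].values * np.asarray(maturity, float)
    draw = mu + reg["sigma"].values * rng.standard_normal(len(reg))
    return special.expit(draw)
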