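"""Ovarian-activity model: Poisson corpora accumulation with linear decline.

After each ovulation a persistent corpus remains in the ovary, so the corpora
count of a known-age female indexes her lifetime ovulations. The count at
adult age index ``i`` (i = 0 is the first adult year, at maturity) is modelled
Poisson with mean equal to the running sum of yearly deposition increments

    dk_j = max(0, alpha * (1 - beta * j)),

i.e. deposition starts at rate ``alpha`` and declines linearly, reaching zero
at ``1/beta`` years past maturity; the increment is clamped at zero beyond
that, so the mean plateaus. Reproductive lifespan (cessation age) is
``1/beta + age at maturity``. Datasets of one species share the decline rate
``beta`` but carry their own initial rate ``alpha_d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._mcmc import run_ensemble
from .data_model import CorporaDataset, ValidationError, apply_inclusion_filters

__all__ = [
    "expected_corpora",
    "CorporaPosterior",
    "fit_corpora",
    "reproductive_cessation_age",
    "relative_fecundity_schedule",
]


def expected_corpora(age_since_maturity, alpha: float, beta: float):
    """Mean cumulative corpora count at completed adult year(s)
    ``age_since_maturity`` (0 = the first adult year).

    Equals sum_{j=0..i} max(0, alpha*(1 - beta*j)); non-decreasing and concave
    in age, flat beyond the cessation point 1/beta.
    """
    i = np.floor(np.asarray(age_since_maturity, dtype=float)).astype(int)
    if np.any(i < 0):
        raise ValueError("age_since_maturity must be >= 0")
    kmax = int(i.max())
    incr = np.maximum(0.0, alpha * (1.0 - beta * np.arange(kmax + 1)))
    lam = np.cumsum(incr)[i]
    return lam if np.ndim(age_since_maturity) else float(lam)


def relative_fecundity_schedule(ages: np.ndarray, maturity: float, beta: float) -> np.ndarray:
    """phi(age): deposition rate at each whole-year age relative to its value
    at maturity — max(0, 1 - beta*(age - maturity)) for age >= maturity."""
    ages = np.asarray(ages, dtype=float)
    phi = np.where(ages >= maturity, np.maximum(0.0, 1.0 - beta * (ages - maturity)), 0.0)
    return phi


@dataclass
class CorporaPosterior:
    species: str
    draws: pd.DataFrame            # columns: alpha_<dataset_id>..., beta, cessation_age
    convergence: pd.DataFrame
    converged: bool
    maturity: float

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def fit_corpora(
    datasets: list[CorporaDataset],
    maturity: float | None = None,
    seed: int = 0,
    n_steps: int = 1000,
    n_burn: int = 500,
    check_filters: bool = True,
) -> CorporaPosterior:
    """Fit the shared-decline deposition model to all corpora datasets of one
    species; attaches cessation-age draws (1/beta + maturity)."""
    if not datasets:
        raise ValueError("no datasets supplied")
    species = {d.species for d in datasets}
    if len(species) != 1:
        raise ValueError("fit_corpora expects datasets of a single species")
    if maturity is None:
        maturity = datasets[0].age_at_maturity
    if check_filters:
        _, excluded = apply_inclusion_filters(datasets, "corpora")
        if excluded:
            raise ValidationError(
                "datasets fail the corpora inclusion filter: "
                + ", ".join(f"{e.dataset_id} ({e.rule}={e.value:.3g})" for e in excluded))
    if all(c == 0 for d in datasets for _, c in d.records):
        raise ValidationError("all corpora counts are zero; deposition rate unidentifiable")

    # adult age index per observation: completed whole years since maturity
    ages_i, counts, ds_idx = [], [], []
    for k, d in enumerate(datasets):
        for age, c in d.records:
            i = int(np.floor(max(age - maturity, 0.0)))
            ages_i.append(i)
            counts.append(c)
            ds_idx.append(k)
    ages_i = np.array(ages_i)
    counts = np.array(counts, dtype=float)
    ds_idx = np.array(ds_idx)
    imax = int(ages_i.max())
    j = np.arange(imax + 1)
    lgam = special.gammaln(counts + 1.0)

    n_ds = len(datasets)
    names = [f"log_alpha_{d.dataset_id}" for d in datasets] + ["log_beta"]

    def log_post(x):
        if np.any(np.abs(x) > 20):
            return -np.inf
        alphas = np.exp(x[:n_ds])
        beta = np.exp(x[n_ds])
        # priors: alpha_d ~ half-Normal(0,2), beta ~ half-Normal(0,0.1), log-jacobians
        lp = float(np.sum(-0.5 * (alphas / 2.0) ** 2 + x[:n_ds]))
        lp += -0.5 * (beta / 0.1) ** 2 + x[n_ds]
        incr = np.maximum(0.0, 1.0 - beta * j)
        cum = np.cumsum(incr)[ages_i]          # per-observation, unit alpha
        lam = alphas[ds_idx] * cum
        if np.any(lam <= 0):
            # a zero mean is only admissible for a zero count
            bad = (lam <= 0) & (counts > 0)
            if np.any(bad):
                return -np.inf
            lam = np.maximum(lam, 1e-12)
        return lp + float(np.sum(counts * np.log(lam) - lam - lgam))

    x0 = np.concatenate([np.full(n_ds, np.log(1.0)), [np.log(0.05)]])
    opt = optimize.minimize(lambda x: -log_post(x), x0, method="Nelder-Mead",
                            options={"maxiter": 2000})
    if np.isfinite(opt.fun):
        x0 = opt.x
    res = run_ensemble(log_post, x0, names, seed=seed, n_steps=n_steps, n_burn=n_burn)
    draws = res.draws.copy()
    for d in datasets:
        draws[f"alpha_{d.dataset_id}"] = np.exp(draws.pop(f"log_alpha_{d.dataset_id}"))
    draws["beta"] = np.exp(draws.pop("log_beta"))
    draws["cessation_age"] = reproductive_cessation_age(draws["beta"].values, maturity)
    return CorporaPosterior(species=next(iter(species)), draws=draws,
                            convergence=res.convergence, converged=res.converged,
                            maturity=maturity)


def reproductive_cessation_age(beta_draws, maturity: float):
    """Age at which the deposition rate reaches zero: 1/beta + maturity."""
    beta = np.asarray(beta_draws, dtype=float)
    if np.any(beta <= 0):
        raise ValueError("beta draws must be > 0")
    out = 1.0 / beta + maturity
    return out if np.ndim(beta_draws) else float(out)
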