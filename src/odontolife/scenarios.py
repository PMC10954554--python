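"""Counterfactual demographies for menopause species.

For each species with menopause, three demographic cases are compared:

* ``observed`` — the fitted demography as-is;
* ``ancestral`` — the inferred non-menopausal ancestor: lifespan reduced to
  the value predicted for the species' size by a regression *excluding* the
  menopause effect, with the reproductive schedule unchanged. The reduction
  rescales the Gompertz ageing rate beta (holding alpha) until the ordinary
  maximum lifespan hits the target, preserving the hazard's shape with one
  degree of freedom;
* ``slow`` — the slow-life-history alternative in which, instead of ceasing,
  females reproduce for their whole life: observed lifespan, fecundity
  decline stretched so the cessation age equals the lifespan.

Baseline fecundity is re-solved per case (stationarity), kinship metrics
recomputed per posterior draw, and cases contrasted by paired-draw tail
probabilities; draws are aligned across cases because they share the
upstream posterior draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import GompertzParams
from .kinship import (
    KinshipMetrics,
    LifeTable,
    build_life_table,
    kin_expectations,
    kinship_metrics,
    solve_baseline_fecundity,
)
from .mortality import ordinary_max_lifespan

__all__ = [
    "ScenarioInputs",
    "CASES",
    "rescale_beta_for_lifespan",
    "make_scenario",
    "scenario_metrics",
    "ScenarioContrast",
    "scenario_contrast",
]

CASES = ("observed", "ancestral", "slow")


@dataclass
class ScenarioInputs:
    """Aligned posterior draws feeding the counterfactuals for one species.

    ``cessation_draws`` is the observed reproductive lifespan (corpora
    cessation age or, for species without corpora data, the age of the
    oldest known reproductively active female). ``ancestral_Z_draws`` is the
    size-predicted non-menopause lifespan, required for the ancestral case.
    """

    species: str
    maturity: float
    alpha_draws: np.ndarray
    beta_draws: np.ndarray
    Z_draws: np.ndarray
    cessation_draws: np.ndarray
    survival_to_maturity: np.ndarray | float = 1.0
    ancestral_Z_draws: np.ndarray | None = None
    omega: int = 120

    def __post_init__(self):
        n = len(self.alpha_draws)
        for name in ("beta_draws", "Z_draws", "cessation_draws"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} not aligned with alpha_draws")

    @property
    def n_draws(self) -> int:
        return len(self.alpha_draws)

    def s2m(self, k: int) -> float:
        if np.ndim(self.survival_to_maturity):
            return float(self.survival_to_maturity[k])
        return float(self.survival_to_maturity)


def rescale_beta_for_lifespan(alpha: float, target_Z: float, maturity: float,
                              q: float = 0.9, omega: float | None = None) -> float:
    """Gompertz ageing rate giving ordinary maximum lifespan ``target_Z`` at
    fixed baseline hazard ``alpha``; Z is decreasing in beta, so the root is
    bracketed and bisected on log-beta."""
    if target_Z <= maturity + 1:
        raise ValueError("target lifespan must exceed maturity")

    def gap(log_b):
        return ordinary_max_lifespan(GompertzParams(alpha, float(np.exp(log_b))),
                                     maturity, q=q, omega=omega) - target_Z

    lo, hi = -12.0, 3.0
    if gap(lo) < 0:   # even tiny beta cannot reach so long a lifespan
        return float(np.exp(lo))
    if gap(hi) > 0:
        return float(np.exp(hi))
    # Z is computed on a 1-yr grid, so gap is a step function; bisect manually
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if gap(mid) >= 0:
            lo = mid
        else:
            hi = mid
    return float(np.exp(lo))


def _beta_corpora_from_cessation(cessation: float, maturity: float) -> float:
    span = max(cessation - maturity, 1.0)
    return 1.0 / span


def make_scenario(inputs: ScenarioInputs, case: str) -> list[LifeTable]:
    """Per-draw life tables (with solved baseline fecundity) for one case."""
    if case not in CASES:
        raise ValueError(f"unknown case {case!r}; expected one of {CASES}")
    tables = []
    for k in range(inputs.n_draws):
        alpha = float(inputs.alpha_draws[k])
        beta = float(inputs.beta_draws[k])
        Z = float(inputs.Z_draws[k])
        cess = float(inputs.cessation_draws[k])
        if case == "observed":
            bc = _beta_corpora_from_cessation(cess, inputs.maturity)
        elif case == "slow":
            bc = _beta_corpora_from_cessation(max(Z, cess), inputs.maturity)
        else:  # ancestral
            if inputs.ancestral_Z_draws is None:
                raise ValueError("ancestral case requires ancestral_Z_draws")
            target = float(inputs.ancestral_Z_draws[k])
            if abs(target - Z) > 1e-9:
                beta = rescale_beta_for_lifespan(alpha, target, inputs.maturity,
                                                 omega=float(inputs.omega))
            bc = _beta_corpora_from_cessation(cess, inputs.maturity)
        table = build_life_table(GompertzParams(alpha, beta), inputs.maturity, bc,
                                 survival_to_maturity=inputs.s2m(k), omega=inputs.omega)
        solve_baseline_fecundity(table)
        tables.append(table)
    return tables


def scenario_metrics(tables: list[LifeTable], currency: str = "both",
                     survival_weight_overlap: bool = False) -> pd.DataFrame:
    """Kinship metrics per draw for one case's life tables."""
    rows = []
    for k, t in enumerate(tables):
        traj = kin_expectations(t, currency=currency)
        m = kinship_metrics(traj, t, survival_weight_overlap=survival_weight_overlap)
        rows.append({
            "draw": k,
            "grandmother_years": m.grandmother_years,
            "relative_grandmother_years": m.relative_grandmother_years,
            "mother_years": m.mother_years,
            "relative_mother_years": m.relative_mother_years,
            "reproductive_overlap": m.reproductive_overlap,
            "baseline_fecundity": m.baseline_fecundity,
        })
    return pd.DataFrame(rows)


@dataclass
class ScenarioContrast:
    tail_probabilities: pd.DataFrame   # columns: case_a, case_b, p_a_greater_b
    zscored: pd.DataFrame              # columns: case, draw, value (pooled z-score)


def scenario_contrast(metric_draws: dict[str, np.ndarray]) -> ScenarioContrast:
    """Paired-draw comparisons between cases of one species' metric.

    Tail probabilities count ties as half; z-scores are computed over the
    draws of all cases pooled within the species, so the pooled draws have
    mean 0 and sd 1.
    """
    cases = list(metric_draws)
    lengths = {len(v) for v in metric_draws.values()}
    if len(lengths) != 1:
        raise ValueError(f"draw counts differ across cases: { {c: len(v) for c, v in metric_draws.items()} }")
    rows = []
    for i, ca in enumerate(cases):
        for cb in cases[i + 1:]:
            a, b = np.asarray(metric_draws[ca]), np.asarray(metric_draws[cb])
            p = float(np.mean(a > b) + 0.5 * np.mean(a == b))
            rows.append({"case_a": ca, "case_b": cb, "p_a_greater_b": p})
    pooled = np.concatenate([np.asarray(metric_draws[c], dtype=float) for c in cases])
    mu, sd = pooled.mean(), pooled.std()
    sd = sd if sd > 0 else 1.0
    zrows = []
    for c in cases:
        z = (np.asarray(metric_draws[c], dtype=float) - mu) / sd
        zrows.extend({"case": c, "draw": k, "value": v} for k, v in enumerate(z))
    return ScenarioContrast(
        tail_probabilities=pd.DataFrame(rows),
        zscored=pd.DataFrame(zrows, columns=["case", "draw", "value"]),
    )
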