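"""Leslie-matrix kinship demography: expected kin by focal age and the
help/harm overlap metrics.

A species' fitted demography is condensed into a one-year life table: yearly
survival probabilities (juvenile survival from the bathtub analysis, adult
survival from a Gompertz draw) and a relative fecundity schedule
``phi(age) = max(0, 1 - beta*(age - maturity))`` taken from the corpora
decline rate. The baseline fecundity ``f`` (daughters per female-year at
phi = 1) is solved so the implied Leslie matrix is stationary (dominant
eigenvalue 1, the Euler–Lotka condition), then deterministic kin recursions
give the expected number and age distribution of living offspring and
matrilineal grandoffspring of a focal female of each age. From these come:

* grandmother years — focal-survivorship-weighted expected sub-maturity
  grandoffspring, summed over focal ages (years spent alive with dependent
  grandoffspring);
* mother years — the same with offspring in place of grandoffspring;
* reproductive overlap — expected newborn grandoffspring at each focal age
  times the focal's remaining fraction of reproductive capacity, summed
  (mother–daughter co-reproduction).

"Relative" metrics divide by the age at maturity for cross-species
comparison. The sex ratio at birth is 0.5: "both sexes" counts are twice the
daughter-line expectations, with grandoffspring routed through daughters
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import GompertzParams
from .mortality import gompertz_survivorship, siler_survivorship
from .reproduction import relative_fecundity_schedule

__all__ = [
    "LifeTable",
    "KinTrajectories",
    "KinshipMetrics",
    "build_life_table",
    "solve_baseline_fecundity",
    "leslie_matrix",
    "dominant_eigenvalue",
    "kin_expectations",
    "kinship_metrics",
]


@dataclass
class LifeTable:
    """Discrete (1-year) survival and relative-fecundity schedules.

    ``survival[x]`` is P(alive at x+1 | alive at x) for integer ages
    0..omega-1; ``phi[x]`` the relative fecundity at age x; ``f`` the baseline
    daughter fecundity, populated by :func:`solve_baseline_fecundity`.
    """

    survival: np.ndarray
    phi: np.ndarray
    maturity: int
    f: float | None = None

    def __post_init__(self):
        self.survival = np.asarray(self.survival, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if len(self.phi) != len(self.survival) + 1:
            raise ValueError("phi must have one more entry than survival (ages 0..omega)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any((self.phi < 0) | (self.phi > 1 + 1e-12)):
            raise ValueError("phi must lie in [0, 1]")

    @property
    def omega(self) -> int:
        return len(self.phi) - 1

    @property
    def survivorship(self) -> np.ndarray:
        """l(x): probability of surviving from birth to age x; l(0) = 1."""
        return np.concatenate([[1.0], np.cumprod(self.survival)])

    def survivorship_from_maturity(self) -> np.ndarray:
        """l(x | maturity) for all ages (0 below maturity by convention)."""
        l = self.survivorship
        out = np.zeros_like(l)
        lm = l[self.maturity]
        if lm > 0:
            out[self.maturity:] = l[self.maturity:] / lm
        return out


def build_life_table(
    params: GompertzParams,
    maturity: float,
    beta_corpora: float,
    survival_to_maturity: float = 1.0,
    omega: int = 120,
    siler: tuple[float, float, float, float, float] | None = None,
) -> LifeTable:
    """Assemble a life table from fitted draws.

    Juvenile yearly survival is either the constant rate implied by
    ``survival_to_maturity`` or, if ``siler`` parameters are given, the yearly
    ratios of the bathtub survivorship. Adult survival follows the Gompertz
    draw; fecundity declines linearly at the corpora rate ``beta_corpora``.
    """
    m = int(round(maturity))
    if not 0 < m < omega:
        raise ValueError("maturity must lie strictly inside (0, omega)")
    ages = np.arange(omega + 1)
    p = np.empty(omega)
    if siler is not None:
        S = siler_survivorship(ages[: m + 1].astype(float), *siler)
        p[:m] = S[1:] / S[:-1]
    else:
        if not 0 < survival_to_maturity <= 1:
            raise ValueError("survival_to_maturity must be in (0, 1]")
        p[:m] = survival_to_maturity ** (1.0 / m)
    Sa = gompertz_survivorship(np.arange(omega - m + 1, dtype=float), params)
    # survivorship can underflow to 0 at extreme ages; survival past an
    # unreachable age is 0, not NaN
    p[m:] = np.divide(Sa[1:], Sa[:-1], out=np.zeros(omega - m), where=Sa[:-1] > 0)
    phi = relative_fecundity_schedule(ages.astype(float), m, beta_corpora)
    return LifeTable(survival=p, phi=phi, maturity=m)


def solve_baseline_fecundity(table: LifeTable) -> float:
    """Baseline daughter fecundity giving a stationary population.

    The Euler–Lotka condition at growth rate 1 is sum_x l(x) f phi(x) = 1,
    so f = 1 / sum_x l(x) phi(x); the assembled Leslie matrix then has
    dominant eigenvalue 1 (checked to 1e-6 by tests via power iteration).
    """
    denom = float(table.survivorship @ table.phi)
    if denom <= 0:
        raise ValueError("no reproductive age is reachable (sum l(x) phi(x) = 0)")
    f = 1.0 / denom
    table.f = f
    return f


def leslie_matrix(table: LifeTable) -> np.ndarray:
    """Leslie matrix over ages 0..omega: daughter fecundity f*phi(x) in the
    first row, yearly survival on the subdiagonal."""
    if table.f is None:
        raise ValueError("solve_baseline_fecundity must be called first")
    n = table.omega + 1
    A = np.zeros((n, n))
    A[0, :] = table.f * table.phi
    A[np.arange(1, n), np.arange(n - 1)] = table.survival
    return A


def dominant_eigenvalue(A: np.ndarray, n_iter: int = 2000, tol: float = 1e-12) -> float:
    """Power iteration; robust to the zero eigenvalues of a Leslie matrix."""
    v = np.ones(A.shape[0])
    v /= v.sum()
    lam = 0.0
    for _ in range(n_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return 0.0
        w /= norm
        lam_new = float(w @ A @ w) / float(w @ w)
        if abs(lam_new - lam) < tol:
            return lam_new
        lam, v = lam_new, w
    return lam


@dataclass
class KinTrajectories:
    """Expected living kin by kin age, per focal age, conditional on the
    focal female being alive at that age."""

    offspring: np.ndarray        # [focal age x, kin age a]
    grandoffspring: np.ndarray   # [focal age x, kin age b], matrilineal
    focal_survivorship: np.ndarray  # l(x | maturity), 0 below maturity
    currency: str                # 'both' (default) or 'daughters'
    maturity: int


def kin_expectations(table: LifeTable, currency: str = "both") -> KinTrajectories:
    """Deterministic kin recursion.

    A focal female of age x acquired offspring at rate f*phi(x-a) when she was
    age x-a; those kin survive to age a with probability l(a). Matrilineal
    grandoffspring accrue from her living daughters' fecundity. With
    currency='both', offspring and grandoffspring of both sexes are counted
    (twice the daughter-line numbers); daughters remain the only conduit to
    grandoffspring either way.
    """
    if table.f is None:
        raise ValueError("solve_baseline_fecundity must be called first")
    if currency not in ("both", "daughters"):
        raise ValueError("currency must be 'both' or 'daughters'")
    sex_mult = 2.0 if currency == "both" else 1.0
    n = table.omega + 1
    l = table.survivorship
    f = table.f
    phi = table.phi
    x_idx = np.arange(n)

    # daughters-only matrix: d[x, a] = f * phi(x - a) * l(a), a <= x
    d = np.zeros((n, n))
    for a in range(n):
        d[a:, a] = f * phi[: n - a] * l[a]

    # grandoffspring born when focal was age t, at rate sex_mult*f*sum_a d[t,a]*phi(a)
    g0 = sex_mult * f * (d @ phi)
    g = np.zeros((n, n))
    for b in range(n):
        g[b:, b] = g0[: n - b] * l[b]

    return KinTrajectories(
        offspring=sex_mult * d,
        grandoffspring=g,
        focal_survivorship=table.survivorship_from_maturity(),
        currency=currency,
        maturity=table.maturity,
    )


@dataclass
class KinshipMetrics:
    grandmother_years: float
    relative_grandmother_years: float
    mother_years: float
    relative_mother_years: float
    reproductive_overlap: float
    baseline_fecundity: float


def kinship_metrics(
    traj: KinTrajectories,
    table: LifeTable,
    survival_weight_overlap: bool = False,
) -> KinshipMetrics:
    """Help/harm summary metrics from kin trajectories.

    grandmother_years sums, over focal ages, the focal's survivorship from
    maturity times her expected grandoffspring below the age at maturity;
    mother_years does the same with offspring. reproductive_overlap sums the
    expected newborn grandoffspring at each focal age times the fraction of
    the fecundity schedule still ahead of the focal at that age (optionally
    survivorship-weighted via ``survival_weight_overlap``).
    """
    m = traj.maturity
    lw = traj.focal_survivorship
    young_g = traj.grandoffspring[:, :m].sum(axis=1)
    young_o = traj.offspring[:, :m].sum(axis=1)
    gy = float(lw @ young_g)
    my = float(lw @ young_o)

    phi = table.phi
    total_phi = phi.sum()
    remaining = np.cumsum(phi[::-1])[::-1] / total_phi if total_phi > 0 else np.zeros_like(phi)
    g0 = traj.grandoffspring[:, 0]
    w = lw if survival_weight_overlap else 1.0
    overlap = float(np.sum(w * g0 * remaining))

    if table.f is None:
        raise ValueError("life table has no solved baseline fecundity")
    return KinshipMetrics(
        grandmother_years=gy,
        relative_grandmother_years=gy / m,
        mother_years=my,
        relative_mother_years=my / m,
        reproductive_overlap=overlap,
        baseline_fecundity=table.f,
    )
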