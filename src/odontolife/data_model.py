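"""Domain types, table/Newick IO, and dataset inclusion filters.

The analysis consumes three kinds of evidence per species: age-structured
samples of dead whales (for mortality), ovarian corpora counts from known-age
females (for reproductive lifespan), and trait summaries (length, age at
maturity, menopause status) together with time-calibrated chronograms for
phylogenetic control. Each published age-at-death dataset carries metadata on
likely distortions — population growth during collection, an age window in
which sampling was biased, and a systematic ageing offset — that the mortality
model corrects for.

Ages are stored as real numbers and binned to 1-year half-open intervals
[a, a+1) at model time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "AgeDataset",
    "GompertzParams",
    "MortalityPosterior",
    "CorporaDataset",
    "SpeciesTraits",
    "Chronogram",
    "SchemaError",
    "ValidationError",
    "read_age_datasets",
    "write_age_datasets",
    "read_corpora_datasets",
    "write_corpora_datasets",
    "read_traits",
    "write_traits",
    "read_trees",
    "apply_inclusion_filters",
]


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """A row violates a precondition (negative age/count, bad interval...)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GompertzParams:
    """Adult hazard h(x) = alpha * exp(beta * x), x = years past maturity.

    ``beta == 0`` is allowed and treated as the exponential (constant-hazard)
    limit wherever survivorship is evaluated.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta < 0:
            raise ValidationError(
                f"Gompertz parameters must satisfy alpha > 0, beta >= 0; "
                f"got alpha={self.alpha}, beta={self.beta}"
            )


@dataclass
class AgeDataset:
    """One published sample of ages at death with bias metadata.

    records are (observed_age, count) pairs; ``growth_prior`` is the
    (mean, sd) of the total population change over the sampling period,
    ``bias_window`` an optional closed age interval in which sampling was
    over- or under-represented, and ``age_bias_offset`` the systematic
    ageing offset B entering the age-error sd (o + B) / 20.
    """

    dataset_id: str
    species: str
    sex: str
    population_id: str
    records: list[tuple[float, int]]
    growth_prior: tuple[float, float] = (0.0, 0.05)
    bias_window: tuple[float, float] | None = None
    age_bias_offset: float = 0.0
    source_type: str = ""

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be female/male, got {self.sex!r}")
        for i, (age, count) in enumerate(self.records):
            if age < 0:
                raise ValidationError(f"record {i}: negative age {age}")
            if count < 0 or int(count) != count:
                raise ValidationError(f"record {i}: count must be a non-negative integer, got {count}")
        if self.n_total == 0:
            raise ValidationError(f"dataset {self.dataset_id}: counts sum to 0")
        if self.bias_window is not None:
            lo, hi = self.bias_window
            if not (0 <= lo <= hi <= self.max_observed_age):
                raise ValidationError(
                    f"dataset {self.dataset_id}: bias window {self.bias_window} "
                    f"outside [0, {self.max_observed_age}]"
                )

    @property
    def n_total(self) -> int:
        return int(sum(c for _, c in self.records))

    @property
    def max_observed_age(self) -> float:
        return max(a for a, c in self.records if c > 0)

    def n_above(self, age: float) -> int:
        """Number of sampled whales strictly above ``age`` (adult samples)."""
        return int(sum(c for a, c in self.records if a > age))

    def n_below(self, age: float) -> int:
        return int(sum(c for a, c in self.records if a < age))

    def sampling_rate(self, maturity: float) -> float:
        """Adult samples per year of observed age span."""
        return self.n_above(maturity) / self.max_observed_age

    def binned_counts(self, lo: float, hi: float) -> np.ndarray:
        """Counts tallied into 1-year bins [a, a+1) for a = lo .. hi-1."""
        edges = np.arange(np.floor(lo), np.floor(hi) + 1.0)
        ages = np.array([a for a, _ in self.records], dtype=float)
        counts = np.array([c for _, c in self.records], dtype=float)
        idx = np.digitize(ages, edges) - 1
        out = np.zeros(len(edges) - 1)
        for i, c in zip(idx, counts):
            if 0 <= i < len(out):
                out[i] += c
        return out


@dataclass
class MortalityPosterior:
    """Posterior draws of Gompertz parameters with derived ordinary maximum
    lifespan Z (age by which 90% of adult person-years have been lived)."""

    species: str
    sex: str
    draws: pd.DataFrame  # columns: alpha, beta, Z, plus per-dataset nuisances
    convergence: pd.DataFrame  # columns: param, rhat, ess
    converged: bool
    maturity: float

    @property
    def n_draws(self) -> int:
        return len(self.draws)


@dataclass
class CorporaDataset:
    """Ovarian corpora counts from known-age females of one species."""

    dataset_id: str
    species: str
    records: list[tuple[float, int]]  # (age in years, corpora count)
    age_at_maturity: float
    max_lifespan_age: float | None = None  # max observed age from lifespan data

    def __post_init__(self) -> None:
        for i, (age, count) in enumerate(self.records):
            if age < 0:
                raise ValidationError(f"record {i}: negative age {age}")
            if count < 0 or int(count) != count:
                raise ValidationError(f"record {i}: corpora count must be a non-negative integer")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def sampling_rate(self) -> float:
        """Samples per year of maximum observed age from the lifespan data."""
        ref = self.max_lifespan_age
        if ref is None:
            ref = max(a for a, _ in self.records)
        return self.n / ref


@dataclass
class SpeciesTraits:
    species: str
    sex: str
    length_mean: float  # cm
    length_sd: float
    maturity_mean: float  # years
    maturity_sd: float
    menopause: int  # 0/1
    juvenile_sample_size: int = 0

    def __post_init__(self) -> None:
        if self.length_sd < 0 or self.maturity_sd < 0:
            raise ValidationError(f"{self.species}: trait sds must be >= 0")
        if self.menopause not in (0, 1):
            raise ValidationError(f"{self.species}: menopause must be 0 or 1")


@dataclass
class Chronogram:
    """A time-calibrated tree reduced to its patristic distance matrix."""

    taxa: list[str]
    distances: np.ndarray  # symmetric, zero diagonal, time units
    tree_index: int = 0
    ultrametric: bool = True

    def __post_init__(self) -> None:
        D = np.asarray(self.distances, dtype=float)
        if D.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("distance matrix shape does not match taxa")
        if not np.allclose(D, D.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        self.distances = D

    def submatrix(self, taxa: Sequence[str]) -> np.ndarray:
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise ValidationError(f"taxa missing from tree {self.tree_index}: {missing}")
        idx = [self.taxa.index(t) for t in taxa]
        return self.distances[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# readers / writers

_AGE_COLUMNS = ["dataset_id", "species", "sex", "population_id", "age", "count"]
_META_COLUMNS = ["dataset_id", "growth_prior_mean", "growth_prior_sd",
                 "bias_window_lo", "bias_window_hi", "age_bias_offset", "source_type"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_age_datasets(path: str | Path, meta_path: str | Path | None = None) -> list[AgeDataset]:
    """Read age-at-death datasets from a delimited table plus metadata sidecar.

    ``meta_path`` defaults to ``<path stem>.meta.csv`` next to ``path``; if the
    sidecar does not exist, every dataset gets the default metadata (growth
    prior (0, 0.05), no bias window, B = 0).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _AGE_COLUMNS, str(path))
    bad = df.index[(df["age"] < 0) | (df["count"] < 0)]
    if len(bad):
        raise ValidationError(f"{path}: negative age or count at row(s) {list(bad)}")

    if meta_path is None:
        cand = path.with_suffix(".meta.csv")
        meta_path = cand if cand.exists() else None
    meta: dict[str, dict] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path)
        _require_columns(mdf, ["dataset_id"], str(meta_path))
        for _, row in mdf.iterrows():
            meta[str(row["dataset_id"])] = row.to_dict()

    out: list[AgeDataset] = []
    for did, grp in df.groupby("dataset_id", sort=False):
        m = meta.get(str(did), {})

        def _get(key, default):
            v = m.get(key, default)
            return default if v is None or (isinstance(v, float) and np.isnan(v)) else v

        lo = _get("bias_window_lo", None)
        hi = _get("bias_window_hi", None)
        window = (float(lo), float(hi)) if lo is not None and hi is not None else None
        out.append(
            AgeDataset(
                dataset_id=str(did),
                species=str(grp["species"].iloc[0]),
                sex=str(grp["sex"].iloc[0]),
                population_id=str(grp["population_id"].iloc[0]),
                records=[(float(a), int(c)) for a, c in zip(grp["age"], grp["count"])],
                growth_prior=(float(_get("growth_prior_mean", 0.0)),
                              float(_get("growth_prior_sd", 0.05))),
                bias_window=window,
                age_bias_offset=float(_get("age_bias_offset", 0.0)),
                source_type=str(_get("source_type", "")),
            )
        )
    return out


def write_age_datasets(datasets: Sequence[AgeDataset], path: str | Path,
                       meta_path: str | Path | None = None) -> None:
    path = Path(path)
    rows = [
        {"dataset_id": d.dataset_id, "species": d.species, "sex": d.sex,
         "population_id": d.population_id, "age": a, "count": c}
        for d in datasets for a, c in d.records
    ]
    pd.DataFrame(rows, columns=_AGE_COLUMNS).to_csv(path, index=False)
    if meta_path is None:
        meta_path = path.with_suffix(".meta.csv")
    mrows = []
    for d in datasets:
        lo, hi = d.bias_window if d.bias_window is not None else (np.nan, np.nan)
        mrows.append({
            "dataset_id": d.dataset_id,
            "growth_prior_mean": d.growth_prior[0],
            "growth_prior_sd": d.growth_prior[1],
            "bias_window_lo": lo, "bias_window_hi": hi,
            "age_bias_offset": d.age_bias_offset, "source_type": d.source_type,
        })
    pd.DataFrame(mrows, columns=_META_COLUMNS).to_csv(meta_path, index=False)


def read_corpora_datasets(path: str | Path) -> list[CorporaDataset]:
    df = pd.read_csv(path)
    _require_columns(df, ["dataset_id", "species", "age", "corpora_count", "age_at_maturity"], str(path))
    bad = df.index[(df["age"] < 0) | (df["corpora_count"] < 0)]
    if len(bad):
        raise ValidationError(f"{path}: negative age or corpora_count at row(s) {list(bad)}")
    out = []
    for did, grp in df.groupby("dataset_id", sort=False):
        max_ls = None
        if "max_lifespan_age" in grp.columns and not pd.isna(grp["max_lifespan_age"].iloc[0]):
            max_ls = float(grp["max_lifespan_age"].iloc[0])
        out.append(CorporaDataset(
            dataset_id=str(did),
            species=str(grp["species"].iloc[0]),
            records=[(float(a), int(c)) for a, c in zip(grp["age"], grp["corpora_count"])],
            age_at_maturity=float(grp["age_at_maturity"].iloc[0]),
            max_lifespan_age=max_ls,
        ))
    return out


def write_corpora_datasets(datasets: Sequence[CorporaDataset], path: str | Path) -> None:
    rows = [
        {"dataset_id": d.dataset_id, "species": d.species, "age": a,
         "corpora_count": c, "age_at_maturity": d.age_at_maturity,
         "max_lifespan_age": d.max_lifespan_age}
        for d in datasets for a, c in d.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traits(path: str | Path) -> list[SpeciesTraits]:
    df = pd.read_csv(path)
    _require_columns(df, ["species", "sex", "length_mean", "maturity_mean", "menopause"], str(path))
    out = []
    for _, row in df.iterrows():
        sds = {}
        for col in ("length_sd", "maturity_sd"):
            if col not in df.columns or pd.isna(row.get(col)):
                warnings.warn(f"{row['species']}: {col} missing, defaulting to 0")
                sds[col] = 0.0
            else:
                sds[col] = float(row[col])
        out.append(SpeciesTraits(
            species=str(row["species"]), sex=str(row["sex"]),
            length_mean=float(row["length_mean"]), length_sd=sds["length_sd"],
            maturity_mean=float(row["maturity_mean"]), maturity_sd=sds["maturity_sd"],
            menopause=int(row["menopause"]),
            juvenile_sample_size=int(row.get("juvenile_sample_size", 0) or 0),
        ))
    return out


def write_traits(traits: Sequence[SpeciesTraits], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(t) for t in traits]).to_csv(path, index=False)


def read_trees(path: str | Path, required_taxa: Sequence[str] | None = None,
               ultrametric_tol: float = 1e-6) -> list[Chronogram]:
    """Read a multi-tree Newick file into patristic distance matrices.

    Trees whose tip depths differ by more than ``ultrametric_tol`` times tree
    depth are flagged (``ultrametric=False``) with a warning, not rejected.
    """
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ValidationError(f"{path}: could not parse Newick ({exc})") from exc
    if len(trees) == 0:
        raise ValidationError(f"{path}: no trees found")
    out = []
    for k, tree in enumerate(trees):
        taxa = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if required_taxa is not None:
            missing = sorted(set(required_taxa) - set(taxa))
            if missing:
                raise ValidationError(f"tree {k}: taxa absent: {missing}")
        pdm = tree.phylogenetic_distance_matrix()
        tx = {t.label: t for t in tree.taxon_namespace}
        n = len(taxa)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = pdm.patristic_distance(tx[taxa[i]], tx[taxa[j]])
        depths = np.array([lf.distance_from_root() for lf in tree.leaf_node_iter()])
        depth = depths.max() if len(depths) else 0.0
        ultra = bool(depth == 0 or (depths.max() - depths.min()) <= ultrametric_tol * depth)
        if not ultra:
            warnings.warn(f"tree {k} in {path} is not ultrametric within tolerance")
        out.append(Chronogram(taxa=taxa, distances=D, tree_index=k, ultrametric=ultra))
    return out


# ---------------------------------------------------------------------------
# inclusion filters

#: thresholds applied before each analysis stage
LIFESPAN_MIN_ADULT_SAMPLES = 10   # strictly more than this many above maturity
LIFESPAN_MIN_RATE = 0.5           # adult samples per year of max observed age
CORPORA_MIN_N = 20
CORPORA_MIN_RATE = 0.6
JUVENILE_MIN_N = 100              # strictly more than this many below maturity


@dataclass
class Exclusion:
    dataset_id: str
    rule: str
    value: float
    threshold: float


def apply_inclusion_filters(
    datasets: Sequence[AgeDataset | CorporaDataset],
    kind: str,
    maturity: float | dict[str, float] | None = None,
) -> tuple[list, list[Exclusion]]:
    """Partition datasets into (included, excluded-with-reason).

    kind='lifespan' needs >10 samples above maturity and an adult sampling
    rate above 0.5/yr; kind='corpora' needs n >= 20 and a rate above 0.6/yr
    relative to the species' maximum observed age in the lifespan data;
    kind='juvenile' needs >100 records below maturity. ``maturity`` may be a
    single value or a per-species mapping (required for lifespan/juvenile).
    """

    def mat_for(sp: str) -> float:
        if isinstance(maturity, dict):
            return maturity[sp]
        if maturity is None:
            raise ValueError(f"kind={kind!r} requires an age at maturity")
        return float(maturity)

    included, excluded = [], []
    if kind == "lifespan":
        for d in datasets:
            m = mat_for(d.species)
            n_adult = d.n_above(m)
            rate = d.sampling_rate(m)
            if n_adult <= LIFESPAN_MIN_ADULT_SAMPLES:
                excluded.append(Exclusion(d.dataset_id, "adult_samples", n_adult, LIFESPAN_MIN_ADULT_SAMPLES))
            elif rate <= LIFESPAN_MIN_RATE:
                excluded.append(Exclusion(d.dataset_id, "sampling_rate", rate, LIFESPAN_MIN_RATE))
            else:
                included.append(d)
    elif kind == "corpora":
        for d in datasets:
            if d.n < CORPORA_MIN_N:
                excluded.append(Exclusion(d.dataset_id, "sample_size", d.n, CORPORA_MIN_N))
            elif d.sampling_rate <= CORPORA_MIN_RATE:
                excluded.append(Exclusion(d.dataset_id, "sampling_rate", d.sampling_rate, CORPORA_MIN_RATE))
            else:
                included.append(d)
    elif kind == "juvenile":
        for d in datasets:
            m = mat_for(d.species)
            n_juv = d.n_below(m)
            if n_juv <= JUVENILE_MIN_N:
                excluded.append(Exclusion(d.dataset_id, "juvenile_samples", n_juv, JUVENILE_MIN_N))
            else:
                included.append(d)
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    return included, excluded


def exclusion_table(exclusions: Sequence[Exclusion]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"dataset_id": e.dataset_id, "rule": e.rule, "value": e.value, "threshold": e.threshold}
         for e in exclusions],
        columns=["dataset_id", "rule", "value", "threshold"],
    )
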