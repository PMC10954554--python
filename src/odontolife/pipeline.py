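"""End-to-end orchestration: simulate a clade, filter, fit, and compare.

The pipeline exercises the whole analysis on synthetic data from one
configuration: a simulated clade supplies chronograms, traits and true
demographic parameters per species; age-at-death and corpora datasets are
simulated per species from those truths; mortality and corpora models are
fitted; kinship metrics are computed from joint posterior draws; lifespan and
metric regressions are run over the bootstrap chronograms; and counterfactual
scenarios are contrasted for the menopause species. Each stage writes its
table under the output directory and a manifest records seeds, versions and
convergence, so reruns with the same config and seed reproduce every
stochastic output exactly.

A single global seed expands to fixed per-stage substreams, so toggling one
stage does not perturb another's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .comparative import ComparativeObservation, fit_phylo_regression, menopause_contrast
from .data_model import GompertzParams, exclusion_table, apply_inclusion_filters
from .kinship import build_life_table, kin_expectations, kinship_metrics, solve_baseline_fecundity
from .mortality import fit_mortality, ordinary_max_lifespan
from .reproduction import fit_corpora
from .scenarios import ScenarioInputs, make_scenario, scenario_contrast, scenario_metrics, rescale_beta_for_lifespan
from .synthetic import AgeSimConfig, CladeSimConfig, CorporaSimConfig, simulate_age_dataset, simulate_clade, simulate_corpora_dataset

logger = logging.getLogger("odontolife.pipeline")

_STAGES = ["simulate", "filter", "fit_mortality", "fit_corpora",
           "kinship", "regress", "scenarios"]


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(_STAGES))
    clade: dict = field(default_factory=dict)      # CladeSimConfig overrides
    n_age_samples: int = 600
    n_corpora_samples: int = 120
    mcmc_steps: int = 500
    mcmc_burn: int = 400
    n_kinship_draws: int = 100
    n_trees: int = 4
    omega: int = 120

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in _STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        order = [s for s in _STAGES if s in self.stages]
        need = {
            "filter": ["simulate"], "fit_mortality": ["filter"],
            "fit_corpora": ["filter"], "kinship": ["fit_mortality", "fit_corpora"],
            "regress": ["kinship"], "scenarios": ["regress"],
        }
        for s in order:
            for dep in need.get(s, []):
                if dep not in self.stages:
                    raise ValueError(f"stage {s!r} requires stage {dep!r}")

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=(int(self.seed), idx))
        return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages; returns the manifest dictionary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": dataclasses.asdict(config),
                      "stages": {}, "convergence": {}, "outputs": {}}
    state: dict = {}

    for stage in [s for s in _STAGES if s in config.stages]:
        logger.info("stage %s", stage)
        seed = config.stage_seed(stage)
        manifest["stages"][stage] = {"seed": seed}
        try:
            _RUNNERS[stage](config, state, out, seed, manifest)
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            raise RuntimeError(f"pipeline halted at stage {stage!r}: {exc}") from exc

    for f in sorted(out.glob("*.csv")):
        manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(config, state, out, seed, manifest):
    clade_cfg = CladeSimConfig(**{"seed": seed, "n_trees": config.n_trees, **config.clade})
    trees, traits, truth = simulate_clade(clade_cfg)
    state["trees"], state["traits"], state["truth"] = trees, traits, truth
    tt = truth.table
    # derive each species' true demographic parameters from its true lifespan
    rows, age_ds, corp_ds = [], {}, {}
    rng_seeds = np.random.SeedSequence(seed).generate_state(2 * len(tt)) % (2 ** 31)
    for i, row in tt.iterrows():
        maturity = float(row["maturity"])
        # pick a baseline hazard low enough that the species' true lifespan is
        # reachable (exponential-limit Z is maturity + ln(10)/alpha), then set
        # the ageing rate to hit it exactly
        alpha = min(0.05, np.log(10.0) / (2.0 * (float(row["lifespan_true"]) - maturity)))
        beta = rescale_beta_for_lifespan(alpha, float(row["lifespan_true"]), maturity,
                                         omega=float(config.omega))
        bc = 1.0 / max(float(row["cessation_true"]) - maturity, 1.0)
        acfg = AgeSimConfig(n=config.n_age_samples, alpha=alpha, beta=beta,
                            maturity=maturity, omega=float(config.omega),
                            seed=int(rng_seeds[2 * i]), species=row["species"],
                            dataset_id=f"{row['species']}_ages")
        ds, _ = simulate_age_dataset(acfg)
        age_ds[row["species"]] = ds
        ccfg = CorporaSimConfig(n=config.n_corpora_samples, deposition_alpha=1.2,
                                decline_beta=bc, maturity=maturity,
                                mortality_alpha=alpha, mortality_beta=beta,
                                omega=float(config.omega), seed=int(rng_seeds[2 * i + 1]),
                                species=row["species"],
                                dataset_id=f"{row['species']}_corpora")
        cds, _ = simulate_corpora_dataset(ccfg)
        corp_ds[row["species"]] = cds
        rows.append({"species": row["species"], "gompertz_alpha": alpha,
                     "gompertz_beta": beta, "corpora_beta": bc, "maturity": maturity})
    state["age_datasets"], state["corpora_datasets"] = age_ds, corp_ds
    pd.DataFrame(rows).to_csv(out / "true_parameters.csv", index=False)
    tt.to_csv(out / "clade_truth.csv", index=False)


def _stage_filter(config, state, out, seed, manifest):
    maturity = {r["species"]: r["maturity"] for _, r in state["truth"].table.iterrows()}
    inc_a, exc_a = apply_inclusion_filters(list(state["age_datasets"].values()),
                                           "lifespan", maturity)
    inc_c, exc_c = apply_inclusion_filters(list(state["corpora_datasets"].values()), "corpora")
    state["age_included"] = {d.species: d for d in inc_a}
    state["corpora_included"] = {d.species: d for d in inc_c}
    pd.concat([exclusion_table(exc_a), exclusion_table(exc_c)]).to_csv(
        out / "exclusions.csv", index=False)


def _stage_fit_mortality(config, state, out, seed, manifest):
    maturity = {r["species"]: r["maturity"] for _, r in state["truth"].table.iterrows()}
    fits, rows = {}, []
    for k, (sp, ds) in enumerate(sorted(state["age_included"].items())):
        post = fit_mortality([ds], maturity[sp], seed=seed + k,
                             n_steps=config.mcmc_steps, n_burn=config.mcmc_burn,
                             age_error=False, omega=float(config.omega))
        fits[sp] = post
        manifest["convergence"][f"mortality_{sp}"] = bool(post.converged)
        for d_i, r in post.draws.iterrows():
            rows.append({"species": sp, "sex": post.sex, "draw": d_i,
                         "alpha": r["alpha"], "beta": r["beta"], "Z": r["Z"]})
    state["mortality_fits"] = fits
    pd.DataFrame(rows).to_csv(out / "mortality_draws.csv", index=False)


def _stage_fit_corpora(config, state, out, seed, manifest):
    fits, rows = {}, []
    for k, (sp, ds) in enumerate(sorted(state["corpora_included"].items())):
        post = fit_corpora([ds], seed=seed + k, n_steps=config.mcmc_steps,
                           n_burn=config.mcmc_burn)
        fits[sp] = post
        manifest["convergence"][f"corpora_{sp}"] = bool(post.converged)
        for d_i, r in post.draws.iterrows():
            rows.append({"species": sp, "draw": d_i, "beta": r["beta"],
                         "cessation_age": r["cessation_age"]})
    state["corpora_fits"] = fits
    pd.DataFrame(rows).to_csv(out / "corpora_draws.csv", index=False)


def _joint_draws(config, state, sp, rng):
    """n_kinship_draws joint draws (mortality x corpora) for one species."""
    mdraws = state["mortality_fits"][sp].draws
    cdraws = state["corpora_fits"][sp].draws
    n = config.n_kinship_draws
    mi = rng.integers(len(mdraws), size=n)
    ci = rng.integers(len(cdraws), size=n)
    return mdraws.iloc[mi].reset_index(drop=True), cdraws.iloc[ci].reset_index(drop=True)


def _stage_kinship(config, state, out, seed, manifest):
    maturity = {r["species"]: r["maturity"] for _, r in state["truth"].table.iterrows()}
    rng = np.random.default_rng(seed)
    rows = []
    joint = {}
    shared = sorted(set(state["mortality_fits"]) & set(state["corpora_fits"]))
    for sp in shared:
        md, cd = _joint_draws(config, state, sp, rng)
        joint[sp] = (md, cd)
        for k in range(config.n_kinship_draws):
            params = GompertzParams(md["alpha"][k], md["beta"][k])
            bc = float(cd["beta"][k])
            table = build_life_table(params, maturity[sp], bc,
                                     survival_to_maturity=0.7, omega=config.omega)
            solve_baseline_fecundity(table)
            traj = kin_expectations(table)
            m = kinship_metrics(traj, table)
            rows.append({"species": sp, "draw": k,
                         "grandmother_years": m.grandmother_years,
                         "relative_grandmother_years": m.relative_grandmother_years,
                         "mother_years": m.mother_years,
                         "relative_mother_years": m.relative_mother_years,
                         "reproductive_overlap": m.reproductive_overlap,
                         "baseline_fecundity": m.baseline_fecundity})
    state["joint_draws"] = joint
    df = pd.DataFrame(rows)
    state["kinship_metrics"] = df
    df.to_csv(out / "kinship_metrics.csv", index=False)


def _stage_regress(config, state, out, seed, manifest):
    tt = state["truth"].table.set_index("species")
    obs = []
    for sp, post in sorted(state["mortality_fits"].items()):
        obs.append(ComparativeObservation(
            species=sp,
            response_mean=float(post.draws["Z"].mean()),
            response_sd=float(post.draws["Z"].std()),
            predictor_mean=float(tt.loc[sp, "log_length_obs"]),
            predictor_sd=float(tt.loc[sp, "log_length_obs_sd"]),
            menopause=int(tt.loc[sp, "menopause"]),
        ))
    trees = state["trees"]
    post = fit_phylo_regression(obs, trees, seed=seed, n_steps=config.mcmc_steps,
                                n_burn=config.mcmc_burn)
    state["lifespan_regression"] = post
    state["lifespan_obs"] = obs
    post.draws.to_csv(out / "lifespan_regression_draws.csv", index=False)
    post.summary().to_csv(out / "lifespan_regression_summary.csv", index=False)

    km = state["kinship_metrics"]
    flags = {sp: int(tt.loc[sp, "menopause"]) for sp in km["species"].unique()}
    contrasts = {}
    for metric in ("relative_grandmother_years", "reproductive_overlap"):
        md = {sp: g[metric].values for sp, g in km.groupby("species")}
        contrasts[metric] = menopause_contrast(md, flags, trees, seed=seed + 1,
                                               n_steps=config.mcmc_steps,
                                               n_burn=config.mcmc_burn)
        contrasts[metric].summary().to_csv(out / f"contrast_{metric}.csv", index=False)
    state["metric_contrasts"] = contrasts


def _stage_scenarios(config, state, out, seed, manifest):
    tt = state["truth"].table.set_index("species")
    reg = state["lifespan_regression"].draws
    rng = np.random.default_rng(seed)
    rows, tail_rows = [], []
    meno_sp = [sp for sp in state.get("joint_draws", {}) if int(tt.loc[sp, "menopause"]) == 1]
    for sp in meno_sp:
        md, cd = state["joint_draws"][sp]
        n = len(md)
        ri = rng.integers(len(reg), size=n)
        anc_Z = (reg["alpha"].values[ri]
                 + reg["beta_size"].values[ri] * float(tt.loc[sp, "log_length_obs"]))
        anc_Z = np.maximum(anc_Z, tt.loc[sp, "maturity"] + 5.0)
        inputs = ScenarioInputs(
            species=sp, maturity=float(tt.loc[sp, "maturity"]),
            alpha_draws=md["alpha"].values, beta_draws=md["beta"].values,
            Z_draws=md["Z"].values, cessation_draws=cd["cessation_age"].values,
            survival_to_maturity=0.7, ancestral_Z_draws=anc_Z, omega=config.omega)
        case_metrics = {}
        for case in ("observed", "ancestral", "slow"):
            tables = make_scenario(inputs, case)
            dfm = scenario_metrics(tables)
            dfm.insert(0, "case", case)
            dfm.insert(0, "species", sp)
            rows.append(dfm)
            case_metrics[case] = dfm
        for metric in ("relative_grandmother_years", "reproductive_overlap"):
            contrast = scenario_contrast({c: case_metrics[c][metric].values
                                          for c in case_metrics})
            t = contrast.tail_probabilities.copy()
            t.insert(0, "metric", metric)
            t.insert(0, "species", sp)
            tail_rows.append(t)
    if rows:
        pd.concat(rows, ignore_index=True).to_csv(out / "scenario_metrics.csv", index=False)
        pd.concat(tail_rows, ignore_index=True).to_csv(out / "scenario_contrasts.csv", index=False)


_RUNNERS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "fit_mortality": _stage_fit_mortality,
    "fit_corpora": _stage_fit_corpora,
    "kinship": _stage_kinship,
    "regress": _stage_regress,
    "scenarios": _stage_scenarios,
}
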