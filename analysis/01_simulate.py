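"""Simulate the study system: a clade of toothed-whale-like species.

Generates bootstrap chronograms, species traits, and — from each species'
true lifespan and reproductive lifespan — age-at-death and ovarian-corpora
datasets with the sampling structure the downstream models assume. Menopause
species carry a 40-year lifespan offset over the size allometry; their
reproductive lifespans follow the same allometry as everyone else's. Writes
the simulated datasets, the truth tables, and the inclusion-filter log.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import (CLADE, N_AGE_SAMPLES, N_CORPORA_SAMPLES, OMEGA, RESULTS,
                     save_trees, stage_seed)

from odontolife.data_model import apply_inclusion_filters, exclusion_table, write_age_datasets, write_corpora_datasets, write_traits
from odontolife.scenarios import rescale_beta_for_lifespan
from odontolife.synthetic import AgeSimConfig, CladeSimConfig, CorporaSimConfig, simulate_age_dataset, simulate_clade, simulate_corpora_dataset


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    seed = stage_seed("simulate")
    trees, traits, truth = simulate_clade(CladeSimConfig(seed=seed, **CLADE))
    tt = truth.table

    sub = np.random.SeedSequence(seed).generate_state(2 * len(tt)) % (2**31)
    age_ds, corp_ds, rows = [], [], []
    for i, r in tt.iterrows():
        mat = float(r["maturity"])
        alpha = min(0.05, np.log(10.0) / (2.0 * (r["lifespan_true"] - mat)))
        beta = rescale_beta_for_lifespan(alpha, float(r["lifespan_true"]), mat,
                                         omega=float(OMEGA))
        bc = 1.0 / max(float(r["cessation_true"]) - mat, 1.0)
        ds, _ = simulate_age_dataset(AgeSimConfig(
            n=N_AGE_SAMPLES, alpha=alpha, beta=beta, maturity=mat, omega=float(OMEGA),
            seed=int(sub[2 * i]), species=r["species"], dataset_id=f"{r['species']}_ages"))
        age_ds.append(ds)
        cds, _ = simulate_corpora_dataset(CorporaSimConfig(
            n=N_CORPORA_SAMPLES, deposition_alpha=1.2, decline_beta=bc, maturity=mat,
            mortality_alpha=alpha, mortality_beta=beta, omega=float(OMEGA),
            seed=int(sub[2 * i + 1]), species=r["species"],
            dataset_id=f"{r['species']}_corpora"))
        corp_ds.append(cds)
        rows.append({"species": r["species"], "gompertz_alpha": alpha,
                     "gompertz_beta": beta, "corpora_beta": bc, "maturity": mat})

    maturity = dict(zip(tt["species"], tt["maturity"]))
    inc_a, exc_a = apply_inclusion_filters(age_ds, "lifespan", maturity)
    inc_c, exc_c = apply_inclusion_filters(corp_ds, "corpora")

    write_age_datasets(inc_a, RESULTS / "age_datasets.csv")
    write_corpora_datasets(inc_c, RESULTS / "corpora_datasets.csv")
    write_traits(traits, RESULTS / "traits.csv")
    save_trees(trees, RESULTS / "trees.csv")
    tt.to_csv(RESULTS / "clade_truth.csv", index=False)
    pd.DataFrame(rows).to_csv(RESULTS / "true_parameters.csv", index=False)
    pd.concat([exclusion_table(exc_a), exclusion_table(exc_c)]).to_csv(
        RESULTS / "exclusions.csv", index=False)
    print(f"simulated {len(tt)} species ({int(tt['menopause'].sum())} with menopause); "
          f"{len(inc_a)}/{len(age_ds)} age datasets and {len(inc_c)}/{len(corp_ds)} "
          f"corpora datasets pass the inclusion filters")


if __name__ == "__main__":
    main()
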