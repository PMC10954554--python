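"""Fit the corpora-deposition model and derive reproductive cessation ages.

The Poisson accumulation model with linearly declining deposition rate is
refit per species; reproductive lifespan is 1/beta + age at maturity per
posterior draw. Writes the posterior draw table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import MCMC_BURN, MCMC_STEPS, RESULTS, stage_seed

from odontolife.data_model import read_corpora_datasets
from odontolife.reproduction import fit_corpora


def main() -> None:
    datasets = read_corpora_datasets(RESULTS / "corpora_datasets.csv")
    truth = pd.read_csv(RESULTS / "true_parameters.csv").set_index("species")
    seed = stage_seed("corpora")
    rows = []
    for k, ds in enumerate(sorted(datasets, key=lambda d: d.species)):
        post = fit_corpora([ds], seed=seed + k, n_steps=MCMC_STEPS, n_burn=MCMC_BURN,
                           check_filters=False)
        d = post.draws[["beta", "cessation_age"]].iloc[::5].reset_index(drop=True)
        d.insert(0, "species", ds.species)
        d.insert(1, "draw", range(len(d)))
        rows.append(d)
        tb = truth.loc[ds.species, "corpora_beta"]
        print(f"{ds.species}: decline beta {d['beta'].mean():.4f} (true {tb:.4f}), "
              f"cessation {d['cessation_age'].mean():.1f} yr")
    pd.concat(rows, ignore_index=True).to_csv(RESULTS / "corpora_draws.csv", index=False)


if __name__ == "__main__":
    main()
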