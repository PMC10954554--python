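"""Compute kinship-demography metrics from joint posterior draws.

For each species, mortality and corpora posterior draws are paired, a
stationary life table is built per draw (baseline fecundity solved by
Euler-Lotka), and the help/harm metrics computed: grandmother years, mother
years (both scaled by age at maturity), and mother-daughter reproductive
overlap. Writes the per-draw metrics table.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import N_KIN_DRAWS, OMEGA, RESULTS, stage_seed

from odontolife.data_model import GompertzParams
from odontolife.kinship import build_life_table, kin_expectations, kinship_metrics, solve_baseline_fecundity

SURVIVAL_TO_MATURITY = 0.7  # typical of well-sampled odontocete datasets


def main() -> None:
    mort = pd.read_csv(RESULTS / "mortality_draws.csv")
    corp = pd.read_csv(RESULTS / "corpora_draws.csv")
    truth = pd.read_csv(RESULTS / "true_parameters.csv").set_index("species")
    rng = np.random.default_rng(stage_seed("kinship"))
    rows = []
    for sp in sorted(set(mort["species"]) & set(corp["species"])):
        md = mort[mort["species"] == sp].reset_index(drop=True)
        cd = corp[corp["species"] == sp].reset_index(drop=True)
        mat = float(truth.loc[sp, "maturity"])
        mi = rng.integers(len(md), size=N_KIN_DRAWS)
        ci = rng.integers(len(cd), size=N_KIN_DRAWS)
        for k in range(N_KIN_DRAWS):
            params = GompertzParams(md["alpha"][mi[k]], md["beta"][mi[k]])
            t = build_life_table(params, mat, float(cd["beta"][ci[k]]),
                                 survival_to_maturity=SURVIVAL_TO_MATURITY, omega=OMEGA)
            solve_baseline_fecundity(t)
            m = kinship_metrics(kin_expectations(t), t)
            rows.append({"species": sp, "draw": k,
                         "grandmother_years": m.grandmother_years,
                         "relative_grandmother_years": m.relative_grandmother_years,
                         "mother_years": m.mother_years,
                         "relative_mother_years": m.relative_mother_years,
                         "reproductive_overlap": m.reproductive_overlap,
                         "baseline_fecundity": m.baseline_fecundity,
                         "alpha": md["alpha"][mi[k]], "beta": md["beta"][mi[k]],
                         "Z": md["Z"][mi[k]], "cessation_age": cd["cessation_age"][ci[k]]})
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "kinship_metrics.csv", index=False)
    summ = df.groupby("species")[["relative_grandmother_years", "reproductive_overlap",
                                  "baseline_fecundity"]].mean()
    print(summ.round(3).to_string())


if __name__ == "__main__":
    main()
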