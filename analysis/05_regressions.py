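"""Phylogenetically controlled comparative regressions.

Three questions: (1) do menopause species live longer than expected for
their size (lifespan ~ log length + menopause, OU kernel over the bootstrap
chronograms, measurement error in both variables)? (2) do they gain
grandmother years? (3) do they gain reproductive overlap? Model comparison
by leave-one-out expected log predictive density checks whether the
menopause term earns its keep. Writes pooled draws and summary tables.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import MCMC_BURN, MCMC_STEPS, RESULTS, load_trees, stage_seed

from odontolife.comparative import ComparativeObservation, compare_elpd, fit_phylo_regression, menopause_contrast


def main() -> None:
    mort = pd.read_csv(RESULTS / "mortality_draws.csv")
    truth = pd.read_csv(RESULTS / "clade_truth.csv").set_index("species")
    km = pd.read_csv(RESULTS / "kinship_metrics.csv")
    trees = load_trees(RESULTS / "trees.csv")
    seed = stage_seed("regress")

    z = mort.groupby("species")["Z"].agg(["mean", "std"])
    obs_w, obs_wo = [], []
    for sp, r in z.iterrows():
        base = dict(species=sp, response_mean=float(r["mean"]), response_sd=float(r["std"]),
                    predictor_mean=float(truth.loc[sp, "log_length_obs"]),
                    predictor_sd=float(truth.loc[sp, "log_length_obs_sd"]))
        obs_w.append(ComparativeObservation(menopause=int(truth.loc[sp, "menopause"]), **base))
        obs_wo.append(ComparativeObservation(menopause=0, **base))

    post = fit_phylo_regression(obs_w, trees, seed=seed, n_steps=MCMC_STEPS, n_burn=MCMC_BURN)
    post.draws.to_csv(RESULTS / "lifespan_regression_draws.csv", index=False)
    post.summary().to_csv(RESULTS / "lifespan_regression_summary.csv", index=False)
    b = post.draws["beta_pr"]
    print(f"lifespan ~ size + menopause: beta_pr {b.mean():.1f} yr "
          f"[{np.quantile(b, 0.025):.1f}, {np.quantile(b, 0.975):.1f}], "
          f"P(beta_pr > 0) = {post.tail_probability('beta_pr', 'greater'):.3f}")

    post_wo = fit_phylo_regression(obs_wo, trees, seed=seed, n_steps=MCMC_STEPS, n_burn=MCMC_BURN)
    d, se = compare_elpd(post, post_wo, obs_w, obs_wo, trees, seed=seed + 1)
    print(f"elpd difference (without - with menopause term): {d:.1f} +/- {se:.1f}")
    pd.DataFrame([{"elpd_diff_without_minus_with": d, "se": se}]).to_csv(
        RESULTS / "elpd_comparison.csv", index=False)

    flags = {sp: int(truth.loc[sp, "menopause"]) for sp in km["species"].unique()}
    for metric in ("relative_grandmother_years", "relative_mother_years",
                   "reproductive_overlap"):
        draws = {sp: g[metric].values for sp, g in km.groupby("species")}
        c = menopause_contrast(draws, flags, trees, seed=seed + 2,
                               n_steps=MCMC_STEPS, n_burn=MCMC_BURN)
        c.summary().to_csv(RESULTS / f"contrast_{metric}.csv", index=False)
        print(f"{metric}: P(menopause effect > 0) = "
              f"{c.tail_probability('beta_pr', 'greater'):.3f}")


if __name__ == "__main__":
    main()
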