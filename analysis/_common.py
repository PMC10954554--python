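"""Shared paths and IO helpers for the numbered analysis scripts.

Each script reads its inputs from, and writes its outputs to, ``results/``
so the sequence 01..06 can be run (or re-run) step by step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from odontolife.data_model import Chronogram

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 20240301  # global analysis seed; scripts derive per-stage streams

# study-scale settings, chosen once: a 16-species clade with 4 menopause
# species keeps every Bayesian refit inside a desktop run while leaving the
# contrasts well identified
CLADE = dict(n_species=16, n_menopause=4, n_trees=4, menopause_offset=40.0)
N_AGE_SAMPLES = 800
N_CORPORA_SAMPLES = 150
MCMC_STEPS = 600
MCMC_BURN = 500
N_KIN_DRAWS = 100
OMEGA = 120


def save_trees(trees: list[Chronogram], path: Path) -> None:
    rows = []
    for t in trees:
        n = len(t.taxa)
        for i in range(n):
            for j in range(n):
                rows.append({"tree": t.tree_index, "taxon_a": t.taxa[i],
                             "taxon_b": t.taxa[j], "distance": t.distances[i, j]})
    pd.DataFrame(rows).to_csv(path, index=False)


def load_trees(path: Path) -> list[Chronogram]:
    df = pd.read_csv(path)
    trees = []
    for k, g in df.groupby("tree"):
        taxa = sorted(g["taxon_a"].unique())
        idx = {t: i for i, t in enumerate(taxa)}
        D = np.zeros((len(taxa), len(taxa)))
        for r in g.itertuples():
            D[idx[r.taxon_a], idx[r.taxon_b]] = r.distance
        trees.append(Chronogram(taxa=taxa, distances=D, tree_index=int(k)))
    return trees


def stage_seed(name: str) -> int:
    names = ["simulate", "mortality", "corpora", "kinship", "regress", "scenarios"]
    ss = np.random.SeedSequence(entropy=(SEED, names.index(name)))
    return int(ss.generate_state(1)[0] % (2**31))
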