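"""Individual-based forward simulation oracle for the kinship recursions.

Independent of the matrix recursion in odontolife.kinship: kin are simulated
one lineage at a time with Poisson births at rate f*phi(age) and Bernoulli
survival, and counted directly. Used to check expected-kin trajectories and
the derived metrics by Monte-Carlo.
"""

from __future__ import annotations

import numpy as np

from odontolife.kinship import LifeTable


def simulate_kin_counts(table: LifeTable, focal_age: int, n_rep: int,
                        rng: np.random.Generator):
    """Monte-Carlo (mean, se) of living-daughter and per-age granddaughter
    counts at ``focal_age``, daughters-only currency, focal assumed alive.

    Returns (daughters_mean, daughters_se, grand_by_age_mean, grand_by_age_se)
    where grand_by_age arrays are indexed by granddaughter age.
    """
    f = table.f
    phi = table.phi
    p = table.survival
    omega = table.omega

    daughters_alive = np.zeros(n_rep)
    grand_by_age = np.zeros((n_rep, focal_age + 1))
    for rep in range(n_rep):
        # daughters: birth year, current age, alive flag
        d_birth_years = []
        for x in range(focal_age + 1):
            d_birth_years.extend([x] * rng.poisson(f * phi[x]))
        n_d = 0
        for by in d_birth_years:
            age_now = focal_age - by
            alive = True
            # track daughter's survival year by year; granddaughters born
            # while she is alive
            for a in range(age_now):
                # daughter of age a at focal year by + a bears granddaughters
                g = rng.poisson(f * phi[a])
                for _ in range(g):
                    g_birth = by + a
                    g_age = focal_age - g_birth
                    # granddaughter survives g_age years?
                    g_alive = True
                    for ga in range(g_age):
                        if rng.random() >= p[ga]:
                            g_alive = False
                            break
                    if g_alive and g_age <= focal_age:
                        grand_by_age[rep, g_age] += 1
                if a < omega and rng.random() >= p[a]:
                    alive = False
                    break
            if alive:
                # births in her final (current) year
                g = rng.poisson(f * phi[age_now]) if age_now <= omega else 0
                grand_by_age[rep, 0] += g
                n_d += 1
        daughters_alive[rep] = n_d

    d_mean = daughters_alive.mean()
    d_se = daughters_alive.std(ddof=1) / np.sqrt(n_rep)
    g_mean = grand_by_age.mean(axis=0)
    g_se = grand_by_age.std(axis=0, ddof=1) / np.sqrt(n_rep)
    return d_mean, d_se, g_mean, g_se
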