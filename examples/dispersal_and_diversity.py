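"""Dispersal and diversity partitioning in a heterogeneous landscape.

Starts from a hand-built metacommunity in which each of the three
patches is monodominated by a locally adapted species, then runs 2000
generations with and without dispersal and prints inverse-Simpson
alpha/gamma/beta diversity. Without dispersal, patches stay
monodominated (mean alpha = 1, gamma = 3). Dispersal mixes species
among patches: alpha rises toward gamma and beta (= mean alpha / gamma)
rises toward 1.
"""

import numpy as np

import evometa as em

for d in (0.0, 0.05):
    state, params = em.make_fixture("monomorphic", np.random.default_rng(0))
    params = params.replace(d=d, mu=1e-4)
    rng = np.random.default_rng(1)
    res = em.run_scenario(state, params, 2000, rng, thin=500, metrics_every=500)
    final = res.final_state
    alphas = [em.alpha_diversity(p) for p in final.patches]
    gamma = em.gamma_diversity(final)
    beta = em.beta_diversity(alphas, gamma)
    print(
        f"d={d}: alpha per patch {np.round(alphas, 3)}, "
        f"gamma {gamma:.3f}, beta {beta:.3f}"
    )

print(
    "\nbeta here is mean(alpha)/gamma: 1/3 when patches hold disjoint "
    "single species,\napproaching 1 as dispersal homogenizes composition."
)
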