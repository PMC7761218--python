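"""Evolutionary branching in a single patch.

Coevolves one monomorphic founder population under the desk-scale
burn-in (mu = 1e-4, 2e5 generations) at three niche widths and counts
the distinct phenotypic clusters that emerge. The narrower the
competition kernel relative to the resource distribution
(sigma_alpha / sigma_K), the more branches coexist: the expected modal
counts are 4, 2 and 1 for sigma_alpha = 0.68, 0.85, 1.5.

Runs in about half a minute.
"""

import numpy as np

import evometa as em

for sigma_alpha in (0.68, 0.85, 1.5):
    cfg = em.InitConfig.scaled(sigma_alpha=sigma_alpha)
    rng = np.random.default_rng(0)
    patch = em.coevolve_patch(cfg.x0_per_patch[0], cfg, rng)
    clusters = em.count_clusters(patch)
    big = patch.N > 0.01 * patch.N.sum()
    positions = np.round(np.sort(patch.x[big]), 2)
    print(
        f"sigma_alpha={sigma_alpha}: {clusters} cluster(s), "
        f"{len(patch)} lineages; major-lineage traits {positions}"
    )

print(
    "\nEach line shows the evolutionarily stable branch structure that a "
    "single founder splits into;\ncluster traits straddle the optimum "
    "(x_opt = 0), balancing carrying capacity against competition."
)
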