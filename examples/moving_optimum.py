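"""Adaptation and extinction under a moving environmental optimum.

A two-species community tracks (or fails to track) an optimum that
rises by Delta per generation. Under slow change both species persist
and the trait distribution follows the optimum with a lag; under fast
change the species with the lower trait value is driven extinct and
the survivor tracks the environment alone.
"""

import numpy as np

import evometa as em

for delta_env, label in ((1e-5, "slow"), (4e-4, "fast")):
    state, params = em.make_fixture(
        "two-species-per-patch", np.random.default_rng(0)
    )
    params = params.replace(delta_env=delta_env, mu=1e-4)
    rng = np.random.default_rng(2)
    res = em.run_scenario(state, params, 4000, rng, thin=1000, metrics_every=1000)
    patch = res.final_state.patches[1]
    n_species = len(np.unique(patch.species_id)) if len(patch) else 0
    mean_trait = float(np.average(patch.x, weights=patch.N)) if len(patch) else float("nan")
    print(
        f"{label} change (Delta={delta_env}): patch 2 ends with "
        f"{n_species} species, mean trait {mean_trait:.3f} "
        f"vs optimum {patch.x_opt:.3f}, SSD {em.ssd(patch):.1f}"
    )

print(
    "\nThe mean trait lags the optimum; fast change prunes the community "
    "to the highest-trait species\nwhile maladaptation (SSD) grows."
)
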