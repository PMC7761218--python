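"""Independent quadratic-time reference implementation of one generation.

Every quantity is computed with explicit Python loops and ``math``
scalar arithmetic, term by term, so that agreement with the vectorized
implementation verifies the model equations rather than the numpy code
path. Random draws follow the generator-call order that the package
documents as its reproducibility contract (per patch: one Poisson
vector for mutant counts, one Normal vector for mutation effects; per
patch one uniform vector for stochastic extinction; per patch the
Binomial emigrant counts and the sequential destination split), so a
shared seed yields comparable trajectories.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_K(x, x_opt, p):
    return p.K_max * math.exp(-((x_opt - x) ** 2) / (2.0 * p.sigma_K**2))


def oracle_alpha(xi, xj, p):
    return 1.0 / (1.0 + (xi - xj) ** 2 / (2.0 * p.sigma_alpha**2))


def oracle_C(x, residents, p):
    """residents: list of (trait, abundance) pairs."""
    return sum(Nj * oracle_alpha(x, xj, p) for xj, Nj in residents)


def oracle_step_patch(lineages, x_opt, p, rng, t, next_lid):
    """lineages: list of dicts with keys x, N, sid, lid, born."""
    if not lineages:
        return [], next_lid
    residents = [(q["x"], q["N"]) for q in lineages]
    births = [p.r * q["N"] for q in lineages]
    if p.mu > 0:
        n_mut = rng.poisson(np.array([p.mu * b for b in births]))
        n_mut = [min(int(m), int(math.floor(b))) for m, b in zip(n_mut, births)]
    else:
        n_mut = [0] * len(lineages)
    out = []
    for q, b, m in zip(lineages, births, n_mut):
        K = oracle_K(q["x"], x_opt, p)
        C = oracle_C(q["x"], residents, p)
        if K > 0:
            newN = q["N"] + (b - m) * (1.0 - C / K)
        else:
            newN = q["N"] + (b - m) * (1.0 - 2.0)
        out.append({**q, "N": max(newN, 0.0)})
    total = sum(n_mut)
    if total:
        parents = [i for i, m in enumerate(n_mut) for _ in range(m)]
        traits = rng.normal(
            np.array([lineages[i]["x"] for i in parents]), p.sigma_mu
        )
        for j, i in enumerate(parents):
            out.append(
                {
                    "x": float(traits[j]),
                    "N": 1.0,
                    "sid": lineages[i]["sid"],
                    "lid": next_lid + j,
                    "born": t,
                }
            )
        next_lid += total
    return out, next_lid


def oracle_extinction(lineages, p, rng):
    if not lineages:
        return []
    keep = [q["N"] >= 1.0 for q in lineages]
    at_risk = [k and q["N"] < p.theta for k, q in zip(keep, lineages)]
    if p.rho > 0 and any(at_risk):
        u = rng.random(len(lineages))
        keep = [
            k and not (ar and ui < p.rho)
            for k, ar, ui in zip(keep, at_risk, u)
        ]
    return [q for q, k in zip(lineages, keep) if k]


def oracle_disperse(patches, p, rng, t, next_lid):
    """patches: list of (x_opt, lineage-list); returns same structure."""
    k = len(patches)
    arrivals = [[] for _ in range(k)]
    for i, (_, lins) in enumerate(patches):
        if not lins:
            continue
        n_int = np.array([int(math.floor(q["N"])) for q in lins])
        em = rng.binomial(n_int, p.d)
        others = [j for j in range(k) if j != i]
        remaining = em.copy()
        for slot, j in enumerate(others):
            p_here = 1.0 / (len(others) - slot)
            take = (
                rng.binomial(remaining, p_here) if p_here < 1.0 else remaining.copy()
            )
            remaining = remaining - take
            for idx in np.nonzero(take)[0]:
                arrivals[j].append(
                    (lins[idx]["sid"], lins[idx]["x"], int(take[idx]))
                )
        for q, e in zip(lins, em):
            q["N"] -= float(e)
    for j, packets in enumerate(arrivals):
        _, lins = patches[j]
        for sid, x, cnt in packets:
            for q in lins:
                if q["sid"] == sid and q["x"] == x:
                    q["N"] += cnt
                    break
            else:
                lins.append({"x": x, "N": float(cnt), "sid": sid, "lid": next_lid, "born": t})
                next_lid += 1
    patches = [
        (x_opt, [q for q in lins if q["N"] > 0.0]) for x_opt, lins in patches
    ]
    return patches, next_lid


def assert_matches_oracle(state, p, seed, em, pytest):
    """Run one generation both ways from the same seed and compare every
    lineage field at 1e-12 relative tolerance."""
    import numpy as np

    got = em.step_generation(state, p, np.random.default_rng(seed))
    exp_patches, exp_t = oracle_step_generation(
        state, p, np.random.default_rng(seed)
    )
    assert got.t == exp_t
    for patch, (x_opt, lins) in zip(got.patches, exp_patches):
        assert patch.x_opt == pytest.approx(x_opt, rel=1e-14)
        assert len(patch) == len(lins)
        order = np.argsort(patch.lineage_id)
        exp_order = sorted(range(len(lins)), key=lambda j: lins[j]["lid"])
        for pos, j in zip(order, exp_order):
            assert patch.lineage_id[pos] == lins[j]["lid"]
            assert patch.species_id[pos] == lins[j]["sid"]
            assert patch.x[pos] == pytest.approx(lins[j]["x"], rel=1e-12)
            assert patch.N[pos] == pytest.approx(lins[j]["N"], rel=1e-12, abs=1e-12)


def oracle_step_generation(state, p, rng):
    """Full generation on a MetacommunityState; returns (patches, t).

    patches is a list of (x_opt, lineage-dict-list).
    """
    t = state.t
    next_lid = state.next_lineage_id
    patches = []
    for patch in state.patches:
        lins = [
            {"x": float(x), "N": float(N), "sid": int(s), "lid": int(l), "born": int(b)}
            for x, N, s, l, b in zip(
                patch.x, patch.N, patch.species_id, patch.lineage_id, patch.born
            )
        ]
        stepped, next_lid = oracle_step_patch(lins, patch.x_opt, p, rng, t, next_lid)
        patches.append((patch.x_opt, stepped))
    patches = [
        (x_opt, oracle_extinction(lins, p, rng)) for x_opt, lins in patches
    ]
    if p.d > 0:
        patches, next_lid = oracle_disperse(patches, p, rng, t, next_lid)
    if p.delta_env != 0:
        patches = [(x_opt + p.delta_env, lins) for x_opt, lins in patches]
    return patches, t + 1
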