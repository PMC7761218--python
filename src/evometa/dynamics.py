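"""The per-generation update rule of the eco-evolutionary model.

One generation applies, in order:

1. growth with mutation in every patch (discrete Lotka-Volterra dynamics
   with a trait-dependent carrying capacity and trait-distance-dependent
   competition; mutant lineages are founded with one individual),
2. extinction (deterministic below one individual, stochastic below the
   threshold ``theta``),
3. dispersal of individuals among patches,
4. the environmental increment (every patch optimum moves by
   ``delta_env``).

The two selection pressures are:

- carrying capacity ``K(x) = K_max * exp(-(x_opt - x)^2 / (2 sigma_K^2))``,
  a Gaussian resource distribution centred on the patch optimum, and
- competition ``alpha(x_i, x_j) = 1 / (1 + (x_i - x_j)^2 / (2 sigma_alpha^2))``,
  a symmetric kernel with heavier-than-Gaussian tails (which is what
  permits discrete coexisting phenotypic clusters rather than a
  continuum).

Growth of a lineage with trait ``x`` is ``G = r (1 - C(x)/K(x))`` with
``C(x) = sum_j N_j alpha(x, x_j)`` over all resident lineages of the
patch (all species pooled, the focal lineage included), and abundances
update as ``N_{t+1} = N_t (1 + G)``.

Randomness
----------
All stochastic draws consume a single ``numpy.random.Generator`` in a
fixed, documented order (per patch in index order: Poisson mutant
counts, then Normal mutation effects; then per patch one uniform vector
for stochastic extinction; then per patch Binomial emigrant counts and
the destination split), so a run is exactly reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
import numpy as np

from .params import ModelParams
from .state import MetacommunityState, PatchState, PopulationLineage

__all__ = [
    "carrying_capacity",
    "competition_coefficient",
    "competition_load",
    "growth_rate",
    "draw_mutants",
    "step_patch",
    "apply_extinction",
    "disperse",
    "advance_environment",
    "step_generation",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# kernels


def carrying_capacity(x, x_opt: float, params: ModelParams):
    """Trait-dependent carrying capacity K(x), individuals.

    Gaussian in the distance from the patch optimum, with maximum
    ``K_max`` attained exactly at ``x = x_opt``. Accepts scalars or
    arrays of trait values.
    """
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)) or not math.isfinite(x_opt):
        raise ValueError("non-finite trait value: corrupted state")
    dev = x_opt - x
    out = params.K_max * np.exp(-(dev * dev) / (2.0 * params.sigma_K**2))
    return float(out) if out.ndim == 0 else out


def competition_coefficient(x_i, x_j, params: ModelParams):
    """Per-capita competition alpha(x_i, x_j) in (0, 1].

    Symmetric, equal to 1 for identical traits, decaying with trait
    distance on the scale of the niche width ``sigma_alpha``. Heavier
    tails than the Gaussian carrying-capacity function.
    """
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if not (np.all(np.isfinite(x_i)) and np.all(np.isfinite(x_j))):
        raise ValueError("non-finite trait value: corrupted state")
    dx = x_i - x_j
    out = 1.0 / (1.0 + (dx * dx) / (2.0 * params.sigma_alpha**2))
    return float(out) if out.ndim == 0 else out


def _resident_arrays(residents) -> tuple[np.ndarray, np.ndarray]:
    """(traits, abundances) from a PatchState or lineage iterable."""
    if isinstance(residents, PatchState):
        return residents.x, residents.N
    lin = list(residents)
    return (
        np.array([p.x for p in lin], dtype=np.float64),
        np.array([p.N for p in lin], dtype=np.float64),
    )


def competition_load(x, residents, params: ModelParams):
    """Total competition C(x) felt by a phenotype x, individuals.

    ``C(x) = sum_j N_j alpha(x, x_j)`` over all resident lineages of one
    patch, all species pooled. When ``x`` equals a resident's trait the
    sum automatically includes the intraspecific term (alpha = 1).
    An empty resident set gives 0 (a lone invader before residents
    exist). ``x`` may be a scalar or an array (returns the curve).
    """
    xr, Nr = _resident_arrays(residents)
    if len(xr) == 0:
        x = np.asarray(x, dtype=np.float64)
        return 0.0 if x.ndim == 0 else np.zeros_like(x)
    x = np.asarray(x, dtype=np.float64)
    dx = np.atleast_1d(x)[:, None] - xr[None, :]
    alpha = 1.0 / (1.0 + (dx * dx) / (2.0 * params.sigma_alpha**2))
    load = alpha @ Nr
    return float(load[0]) if x.ndim == 0 else load


def growth_rate(x, N_self, residents, x_opt: float, params: ModelParams):
    """Per-generation growth rate G = r (1 - C(x)/K(x)).

    ``residents`` must already include the focal lineage (its own
    density contributes to C); ``N_self`` is informational. If K(x)
    underflows to zero the lineage is maximally maladapted and G is
    taken as ``-r`` (logged).
    """
    K = carrying_capacity(x, x_opt, params)
    C = competition_load(x, residents, params)
    K_arr = np.atleast_1d(np.asarray(K, dtype=np.float64))
    C_arr = np.atleast_1d(np.asarray(C, dtype=np.float64))
    if np.any(K_arr == 0.0):
        log.warning("K(x) underflowed to 0; treating growth as -r")
    ratio = np.where(K_arr > 0.0, C_arr / np.where(K_arr > 0.0, K_arr, 1.0), 2.0)
    G = params.r * (1.0 - ratio)
    return float(G[0]) if np.isscalar(x) or np.asarray(x).ndim == 0 else G


# ---------------------------------------------------------------------------
# mutation


def draw_mutants(
    lineage: PopulationLineage,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    t: int = 0,
    next_lineage_id: int | None = None,
    deterministic: bool = False,
) -> tuple[list[PopulationLineage], int]:
    """Draw the mutant lineages born to one parent this generation.

    The parent gives birth to ``r * N`` individuals, each carrying a
    mutation with probability ``mu``; the mutant count is drawn
    ``Poisson(mu * r * N)`` (capped at the birth count), each mutant
    founds a new lineage of size 1 with trait ``Normal(parent x,
    sigma_mu^2)`` and the parent's species identity. Returns
    ``(mutants, births_removed)``; the caller subtracts
    ``births_removed`` from the parent's births before density
    regulation. ``deterministic=True`` replaces the Poisson draw with
    the rounded expectation (a debugging mode).
    """
    births = params.r * lineage.N
    lam = params.mu * births
    if deterministic:
        n_mut = int(round(lam))
    else:
        n_mut = int(rng.poisson(lam)) if lam > 0 else 0
    n_mut = min(n_mut, int(math.floor(births)))
    if next_lineage_id is None:
        next_lineage_id = lineage.lineage_id + 1
    mutants = []
    if n_mut > 0:
        traits = rng.normal(lineage.x, params.sigma_mu, size=n_mut)
        mutants = [
            PopulationLineage(
                species_id=lineage.species_id,
                lineage_id=next_lineage_id + i,
                x=float(traits[i]),
                N=1.0,
                patch=lineage.patch,
                born=t,
            )
            for i in range(n_mut)
        ]
    return mutants, n_mut


# ---------------------------------------------------------------------------
# array-level inner update (shared by step_patch and the burn-in loop)


def _step_patch_arrays(x, N, sid, lid, born, x_opt, p: ModelParams, rng, t, next_lid):
    """One growth+mutation step on raw patch arrays; returns new arrays.

    C and K are computed from the pre-update residents; mutants are
    subtracted from the parent's births before density regulation and
    neither exert nor experience competition in their birth generation.
    """
    L = len(x)
    if L == 0:
        return x, N, sid, lid, born, next_lid
    dev = x_opt - x
    K = p.K_max * np.exp(-(dev * dev) / (2.0 * p.sigma_K**2))
    dx = x[:, None] - x[None, :]
    alpha = 1.0 / (1.0 + (dx * dx) / (2.0 * p.sigma_alpha**2))
    C = alpha @ N
    births = p.r * N

    if p.mu > 0.0:
        n_mut = rng.poisson(p.mu * births)
        np.minimum(n_mut, np.floor(births).astype(np.int64), out=n_mut)
        total_mut = int(n_mut.sum())
    else:
        n_mut = None
        total_mut = 0

    # K can underflow for extremely maladapted traits; treat as G = -r
    ok = K > 0.0
    ratio = np.where(ok, C / np.where(ok, K, 1.0), 2.0)
    removed = n_mut if total_mut else 0.0
    N_new = N + (births - removed) * (1.0 - ratio)
    np.maximum(N_new, 0.0, out=N_new)

    if total_mut:
        parent = np.repeat(np.arange(L), n_mut)
        traits = rng.normal(x[parent], p.sigma_mu)
        x = np.concatenate([x, traits])
        N = np.concatenate([N_new, np.ones(total_mut)])
        sid = np.concatenate([sid, sid[parent]])
        lid = np.concatenate(
            [lid, np.arange(next_lid, next_lid + total_mut, dtype=np.int64)]
        )
        born = np.concatenate([born, np.full(total_mut, t, dtype=np.int64)])
        next_lid += total_mut
        return x, N, sid, lid, born, next_lid
    return x, N_new, sid, lid, born, next_lid


def _extinction_arrays(x, N, sid, lid, born, p: ModelParams, rng):
    """Remove N < 1 deterministically; 1 <= N < theta with probability rho."""
    if len(x) == 0:
        return x, N, sid, lid, born
    keep = N >= 1.0
    if p.rho > 0.0:
        at_risk = keep & (N < p.theta)
        if at_risk.any():
            u = rng.random(len(N))
            keep &= ~(at_risk & (u < p.rho))
    if keep.all():
        return x, N, sid, lid, born
    return x[keep], N[keep], sid[keep], lid[keep], born[keep]


# ---------------------------------------------------------------------------
# public per-stage operations


def step_patch(
    patch: PatchState,
    params: ModelParams,
    rng: np.random.Generator,
    *,
    t: int = 0,
    next_lineage_id: int | None = None,
) -> PatchState:
    """Apply one generation of growth and mutation inside a patch.

    For each pre-existing lineage, C and K are computed from the
    pre-update resident state and ``N_{t+1} = N_t + (r N_t - N_m)(1 -
    C/K)`` where ``N_m`` is the lineage's mutant count; negative
    outcomes are clamped to 0 (removed at the next extinction pass).
    Mutant lineages are appended with N = 1.
    """
    if len(patch) and np.any(patch.N < 0.0):
        raise ValueError("negative lineage abundance: corrupted state")
    if next_lineage_id is None:
        next_lineage_id = int(patch.lineage_id.max()) + 1 if len(patch) else 0
    x, N, sid, lid, born, _ = _step_patch_arrays(
        patch.x, patch.N, patch.species_id, patch.lineage_id, patch.born,
        patch.x_opt, params, rng, t, next_lineage_id,
    )
    return PatchState(patch.x_opt, x, N, sid, lid, born, patch.index)


def apply_extinction(
    patch: PatchState, params: ModelParams, rng: np.random.Generator
) -> PatchState:
    """Extinction pass: N < 1 removed; 1 <= N < theta removed w.p. rho."""
    x, N, sid, lid, born = _extinction_arrays(
        patch.x, patch.N, patch.species_id, patch.lineage_id, patch.born,
        params, rng,
    )
    return PatchState(patch.x_opt, x, N, sid, lid, born, patch.index)


def disperse(
    state: MetacommunityState, params: ModelParams, rng: np.random.Generator
) -> MetacommunityState:
    """Move individuals among patches; total abundance conserved exactly.

    Per lineage, the emigrant count is ``Binomial(floor(N), d)`` (an
    individual-level Bernoulli; the fractional part of N never
    emigrates) and emigrants are split equally at random among the other
    ``k - 1`` patches. An emigrant packet merges with a destination
    lineage of identical species and trait, otherwise founds a new
    lineage there (born = current generation).
    """
    if params.d == 0.0:
        return state.copy()
    k = state.k
    if k < 2:
        raise ValueError("dispersal requires k >= 2 patches")
    new = state.copy()
    next_lid = new.next_lineage_id
    # arrivals[j] collects (species_id, trait, count, origin_lineage) packets
    arrivals: list[list[tuple[int, float, int]]] = [[] for _ in range(k)]
    for i, patch in enumerate(new.patches):
        L = len(patch)
        if L == 0:
            continue
        n_int = np.floor(patch.N).astype(np.int64)
        em = rng.binomial(n_int, params.d)
        others = [j for j in range(k) if j != i]
        remaining = em.copy()
        # sequential binomial thinning == multinomial over destinations
        for slot, j in enumerate(others):
            p_here = 1.0 / (len(others) - slot)
            take = (
                rng.binomial(remaining, p_here)
                if p_here < 1.0
                else remaining.copy()
            )
            remaining = remaining - take
            for idx in np.nonzero(take)[0]:
                arrivals[j].append(
                    (int(patch.species_id[idx]), float(patch.x[idx]), int(take[idx]))
                )
        patch.N = patch.N - em
    total_immigrants = 0
    for j, packets in enumerate(arrivals):
        if not packets:
            continue
        patch = new.patches[j]
        index = {
            (int(s), float(xv)): pos
            for pos, (s, xv) in enumerate(zip(patch.species_id, patch.x))
        }
        add_x, add_N, add_sid, add_lid, add_born = [], [], [], [], []
        for s, xv, cnt in packets:
            total_immigrants += cnt
            pos = index.get((s, xv))
            if pos is not None:
                patch.N[pos] += cnt
            else:
                key = (s, xv)
                # a packet may itself found a lineage later packets join
                found = None
                for a, (as_, ax) in enumerate(zip(add_sid, add_x)):
                    if as_ == s and ax == xv:
                        found = a
                        break
                if found is not None:
                    add_N[found] += cnt
                else:
                    add_x.append(xv)
                    add_N.append(float(cnt))
                    add_sid.append(s)
                    add_lid.append(next_lid)
                    add_born.append(new.t)
                    next_lid += 1
        if add_x:
            patch.x = np.concatenate([patch.x, add_x])
            patch.N = np.concatenate([patch.N, add_N])
            patch.species_id = np.concatenate(
                [patch.species_id, np.asarray(add_sid, dtype=np.int64)]
            )
            patch.lineage_id = np.concatenate(
                [patch.lineage_id, np.asarray(add_lid, dtype=np.int64)]
            )
            patch.born = np.concatenate(
                [patch.born, np.asarray(add_born, dtype=np.int64)]
            )
    # lineages fully emptied by emigration vanish immediately
    for patch in new.patches:
        if len(patch) and (patch.N == 0.0).any():
            keep = patch.N > 0.0
            patch.x = patch.x[keep]
            patch.N = patch.N[keep]
            patch.species_id = patch.species_id[keep]
            patch.lineage_id = patch.lineage_id[keep]
            patch.born = patch.born[keep]
    new.next_lineage_id = next_lid
    if log.isEnabledFor(logging.DEBUG):
        log.debug("generation %d: %d migrants", new.t, total_immigrants)
    return new


def advance_environment(
    state: MetacommunityState, params: ModelParams
) -> MetacommunityState:
    """Shift every patch optimum by the environmental change rate."""
    new = state.copy()
    for patch in new.patches:
        patch.x_opt += params.delta_env
    return new


def step_generation(
    state: MetacommunityState, params: ModelParams, rng: np.random.Generator
) -> MetacommunityState:
    """One full generation: growth+mutation, extinction, dispersal,
    environmental increment; the generation counter advances by one.

    Immigrants arrive after the extinction pass and therefore face
    competition only from the next generation onward.
    """
    patches = []
    next_lid = state.next_lineage_id
    for patch in state.patches:
        stepped = step_patch(
            patch, params, rng, t=state.t, next_lineage_id=next_lid
        )
        next_lid += len(stepped) - len(patch)
        patches.append(stepped)
    patches = [apply_extinction(p, params, rng) for p in patches]
    new = MetacommunityState(patches, t=state.t, next_lineage_id=next_lid)
    if params.d > 0.0:
        new = disperse(new, params, rng)
    if params.delta_env != 0.0:
        new = advance_environment(new, params)
    new.t = state.t + 1
    return new
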