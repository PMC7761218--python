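"""Diversity, stability and selection-landscape summaries.

Diversity is measured as the inverse Simpson index (the effective
number of equally abundant species), partitioned into patch-level
alpha, regional gamma (species abundances pooled across patches) and
beta = mean(alpha) / gamma. Maladaptation is summarised by the
abundance-weighted sum of squared trait deviations from the local
optimum (SSD), and stability by the coefficient of variation of total
patch abundance over time. The selection landscape juxtaposes the two
selection pressures — carrying capacity K(x) and competition load
C(x) — on a fine trait grid around the patch optimum; the region where
K > C is where rare mutants have positive growth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import carrying_capacity, competition_load
from .params import ModelParams
from .state import MetacommunityState, PatchState

__all__ = [
    "species_abundances",
    "inverse_simpson",
    "alpha_diversity",
    "gamma_diversity",
    "beta_diversity",
    "ssd",
    "cv_total_abundance",
    "SelectionLandscape",
    "selection_landscape",
    "time_averaged_landscape",
    "diversity_record",
]

#: half-width and step of the selection-landscape grid (trait units)
GRID_HALF_WIDTH = 3.0
GRID_STEP = 0.001


def species_abundances(patch: PatchState) -> dict[int, float]:
    """Pool lineage abundances by species within one patch."""
    out: dict[int, float] = {}
    for s, n in zip(patch.species_id, patch.N):
        out[int(s)] = out.get(int(s), 0.0) + float(n)
    return out


def inverse_simpson(abundances_by_species: Mapping[int, float]) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2), effective species.

    Equals S for S equally abundant species. An empty community is
    undefined and returns NaN.
    """
    vals = np.array([v for v in abundances_by_species.values()], dtype=float)
    total = vals.sum()
    if total <= 0:
        return float("nan")
    p = vals / total
    return float(1.0 / np.sum(p * p))


def alpha_diversity(patch: PatchState) -> float:
    """Patch-level inverse Simpson diversity (species pooled over
    their mutant subpopulations before computing shares)."""
    return inverse_simpson(species_abundances(patch))


def gamma_diversity(state: MetacommunityState) -> float:
    """Regional diversity: inverse Simpson on species abundances pooled
    across all patches (never a mean of patch values)."""
    pooled: dict[int, float] = {}
    for patch in state.patches:
        for s, n in species_abundances(patch).items():
            pooled[s] = pooled.get(s, 0.0) + n
    return inverse_simpson(pooled)


def beta_diversity(
    alpha_values: Sequence[float],
    gamma_value: float,
    convention: str = "alpha_over_gamma",
) -> float:
    """Beta diversity from patch alphas and the regional gamma.

    The default is mean(alpha) / gamma. The multiplicative-partition
    convention gamma / mean(alpha) — the reciprocal — is available with
    ``convention="gamma_over_alpha"``.
    """
    a = np.asarray(alpha_values, dtype=float)
    if np.isnan(gamma_value) or len(a) == 0 or np.any(np.isnan(a)):
        return float("nan")
    mean_alpha = float(a.mean())
    if convention == "alpha_over_gamma":
        return mean_alpha / gamma_value
    if convention == "gamma_over_alpha":
        return gamma_value / mean_alpha
    raise ValueError(f"unknown beta convention: {convention!r}")


def ssd(patch: PatchState, weighted: bool = True) -> float:
    """Sum of squared trait deviations from the local optimum.

    Computed over all individuals in the patch, i.e. abundance-weighted
    over lineages: sum_i N_i (x_i - x_opt)^2. ``weighted=False`` gives
    the per-lineage (unweighted) variant. Empty patch -> 0.
    """
    if len(patch) == 0:
        return 0.0
    dev = patch.x - patch.x_opt
    if weighted:
        return float(np.sum(patch.N * dev * dev))
    return float(np.sum(dev * dev))


def cv_total_abundance(series: Sequence[float]) -> float:
    """Coefficient of variation (sample sd / mean) of a per-generation
    total-abundance series. Zero mean -> NaN."""
    arr = np.asarray(series, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires a series of length >= 2")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


@dataclass
class SelectionLandscape:
    """Gridded selection pressures for one patch.

    ``grid`` spans x_opt +/- 3 in steps of 0.001 (6001 points);
    ``K_curve`` is the carrying capacity and ``C_curve`` the competition
    load at each grid point; ``fit_mask`` flags the positive-growth
    region x_fit where K > C.
    """

    x_opt: float
    grid: np.ndarray
    K_curve: np.ndarray
    C_curve: np.ndarray

    @property
    def fit_mask(self) -> np.ndarray:
        return self.K_curve > self.C_curve

    @property
    def x_fit(self) -> list[tuple[float, float]]:
        """Sub-intervals of the grid (as (lo, hi) pairs) where K > C."""
        m = self.fit_mask
        if not m.any():
            return []
        edges = np.diff(m.astype(np.int8))
        starts = list(np.nonzero(edges == 1)[0] + 1)
        ends = list(np.nonzero(edges == -1)[0])
        if m[0]:
            starts = [0] + starts
        if m[-1]:
            ends = ends + [len(m) - 1]
        return [(float(self.grid[a]), float(self.grid[b])) for a, b in zip(starts, ends)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.grid,
                "K": self.K_curve,
                "C": self.C_curve,
                "fit": self.fit_mask,
            }
        )


def _grid(x_opt: float) -> np.ndarray:
    n = int(round(GRID_HALF_WIDTH / GRID_STEP))
    return x_opt + GRID_STEP * np.arange(-n, n + 1)


def selection_landscape(
    patch: PatchState, params: ModelParams
) -> SelectionLandscape:
    """K(x) and C(x) on the standard grid around the patch optimum.

    At a grid point equal to a resident's trait, C includes the
    intraspecific term; everywhere else it is the total competition
    from residents with differing traits. An empty patch has C = 0
    everywhere (the whole grid is x_fit).
    """
    grid = _grid(patch.x_opt)
    K = carrying_capacity(grid, patch.x_opt, params)
    C = competition_load(grid, patch, params)
    C = np.zeros_like(grid) if np.isscalar(C) else C
    return SelectionLandscape(patch.x_opt, grid, K, np.asarray(C, dtype=float))


def time_averaged_landscape(
    states: Sequence[MetacommunityState],
    params: ModelParams,
    patch_index: int,
) -> SelectionLandscape:
    """Pointwise mean of K and C curves over sampled states for one patch.

    The standard sampling follows the figure protocol: 121 generations
    evenly spaced (every 250) from generation 20,000 to 50,000. When
    the environment moves, curves are averaged on the grid of offsets
    from each sample's current optimum and reported around the mean
    optimum.
    """
    if len(states) == 0:
        raise ValueError("need at least one sampled state")
    K_sum = C_sum = None
    opts = []
    for s in states:
        land = selection_landscape(s.patches[patch_index], params)
        opts.append(land.x_opt)
        K_sum = land.K_curve if K_sum is None else K_sum + land.K_curve
        C_sum = land.C_curve if C_sum is None else C_sum + land.C_curve
    n = len(states)
    mean_opt = float(np.mean(opts))
    return SelectionLandscape(mean_opt, _grid(mean_opt), K_sum / n, C_sum / n)


def diversity_record(state: MetacommunityState) -> dict:
    """Per-generation diversity snapshot: alpha per patch, gamma, beta."""
    alphas = [alpha_diversity(p) for p in state.patches]
    gamma = gamma_diversity(state)
    return {
        "generation": state.t,
        "D_alpha_per_patch": alphas,
        "D_gamma": gamma,
        "D_beta": beta_diversity(alphas, gamma),
    }
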