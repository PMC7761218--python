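"""State containers: lineages, patches, and the metacommunity.

A *lineage* (the elementary unit of the simulation) is an asexual
population with a single trait value. Internally a patch stores its
lineages as parallel numpy arrays so the per-generation update is
vectorized; :class:`PopulationLineage` is a lightweight record view used
for construction, inspection and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

__all__ = [
    "PopulationLineage",
    "PatchState",
    "MetacommunityState",
    "lineage_table",
    "state_from_table",
]


@dataclass(frozen=True)
class PopulationLineage:
    """One asexual lineage: a (trait, abundance) pair with identity labels.

    ``species_id`` is fixed at the start of the main simulation and
    inherited unchanged by all mutant descendants; ``lineage_id`` is
    unique across the whole metacommunity state.
    """

    species_id: int
    lineage_id: int
    x: float
    N: float
    patch: int = 0
    born: int = 0


class PatchState:
    """One habitat patch: its optimum trait value and resident lineages.

    Parallel arrays (same length L):

    - ``x``: trait values (float)
    - ``N``: abundances (float, individuals)
    - ``species_id``, ``lineage_id``, ``born``: integer labels
    """

    __slots__ = ("x_opt", "x", "N", "species_id", "lineage_id", "born", "index")

    def __init__(
        self,
        x_opt: float,
        x=(),
        N=(),
        species_id=(),
        lineage_id=(),
        born=(),
        index: int = 0,
    ):
        self.x_opt = float(x_opt)
        self.x = np.asarray(x, dtype=np.float64)
        self.N = np.asarray(N, dtype=np.float64)
        self.species_id = np.asarray(species_id, dtype=np.int64)
        self.lineage_id = np.asarray(lineage_id, dtype=np.int64)
        self.born = np.asarray(born, dtype=np.int64)
        self.index = int(index)
        n = len(self.x)
        for arr in (self.N, self.species_id, self.lineage_id, self.born):
            if len(arr) != n:
                raise ValueError("PatchState arrays must have equal length")

    @classmethod
    def from_lineages(
        cls, x_opt: float, lineages: Iterable[PopulationLineage], index: int = 0
    ) -> "PatchState":
        lin = list(lineages)
        for p in lin:
            if p.patch != index:
                raise ValueError(
                    f"lineage {p.lineage_id} has patch {p.patch}, expected {index}"
                )
        return cls(
            x_opt,
            x=[p.x for p in lin],
            N=[p.N for p in lin],
            species_id=[p.species_id for p in lin],
            lineage_id=[p.lineage_id for p in lin],
            born=[p.born for p in lin],
            index=index,
        )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def total_abundance(self) -> float:
        return float(self.N.sum())

    @property
    def lineages(self) -> tuple[PopulationLineage, ...]:
        return tuple(
            PopulationLineage(
                species_id=int(s),
                lineage_id=int(l),
                x=float(x),
                N=float(n),
                patch=self.index,
                born=int(b),
            )
            for s, l, x, n, b in zip(
                self.species_id, self.lineage_id, self.x, self.N, self.born
            )
        )

    def copy(self) -> "PatchState":
        return PatchState(
            self.x_opt,
            self.x.copy(),
            self.N.copy(),
            self.species_id.copy(),
            self.lineage_id.copy(),
            self.born.copy(),
            self.index,
        )

    def __repr__(self) -> str:
        return (
            f"PatchState(index={self.index}, x_opt={self.x_opt:.4g}, "
            f"lineages={len(self)}, total_N={self.total_abundance:.4g})"
        )


@dataclass
class MetacommunityState:
    """All patches plus the generation counter: the single evolving object.

    ``next_lineage_id`` is the metacommunity-wide counter used to mint
    unique lineage identifiers for mutants and newly founded immigrant
    lineages.
    """

    patches: list[PatchState]
    t: int = 0
    next_lineage_id: int = 0

    def __post_init__(self) -> None:
        for i, p in enumerate(self.patches):
            p.index = i
        ids = np.concatenate(
            [p.lineage_id for p in self.patches]
            or [np.empty(0, dtype=np.int64)]
        )
        if len(ids) and len(np.unique(ids)) != len(ids):
            raise ValueError("lineage_ids are not unique across the state")
        if len(ids):
            self.next_lineage_id = max(self.next_lineage_id, int(ids.max()) + 1)

    @property
    def k(self) -> int:
        return len(self.patches)

    @property
    def total_abundance(self) -> float:
        return float(sum(p.total_abundance for p in self.patches))

    def species_present(self) -> np.ndarray:
        """Sorted array of species ids with at least one lineage anywhere."""
        ids = [p.species_id[p.N > 0] for p in self.patches]
        if not ids:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(ids))

    def copy(self) -> "MetacommunityState":
        return MetacommunityState(
            [p.copy() for p in self.patches], self.t, self.next_lineage_id
        )

    def __iter__(self) -> Iterator[PatchState]:
        return iter(self.patches)


def lineage_table(state: MetacommunityState) -> pd.DataFrame:
    """Flatten a state into the canonical long table.

    Columns: generation, patch, species_id, lineage_id, trait, abundance.
    """
    frames = []
    for p in state.patches:
        frames.append(
            pd.DataFrame(
                {
                    "generation": np.full(len(p), state.t, dtype=np.int64),
                    "patch": np.full(len(p), p.index, dtype=np.int64),
                    "species_id": p.species_id,
                    "lineage_id": p.lineage_id,
                    "trait": p.x,
                    "abundance": p.N,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "generation",
                "patch",
                "species_id",
                "lineage_id",
                "trait",
                "abundance",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def state_from_table(
    df: pd.DataFrame, x_opts: Iterable[float], t: int | None = None
) -> MetacommunityState:
    """Rebuild a MetacommunityState from one generation of a lineage table."""
    if t is None:
        t = int(df["generation"].max())
    gen = df[df["generation"] == t]
    x_opts = list(x_opts)
    patches = []
    for i, x_opt in enumerate(x_opts):
        sub = gen[gen["patch"] == i]
        patches.append(
            PatchState(
                x_opt,
                x=sub["trait"].to_numpy(),
                N=sub["abundance"].to_numpy(),
                species_id=sub["species_id"].to_numpy(),
                lineage_id=sub["lineage_id"].to_numpy(),
                born=np.zeros(len(sub), dtype=np.int64),
                index=i,
            )
        )
    return MetacommunityState(patches, t=t)
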