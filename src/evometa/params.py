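"""Model parameter containers and validation.

All rates are per generation, all trait quantities are in units of the
(single) quantitative trait axis, and abundances are individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = ["ModelParams", "InitConfig", "DEFAULT_FOUNDER_TRAITS"]

#: Founder trait values used for the three patches at each niche-width level
#: (chosen uniformly in [-0.5, 0.5]; branch positions do not depend on them).
DEFAULT_FOUNDER_TRAITS: dict[float, tuple[float, float, float]] = {
    0.68: (0.1140, -0.4689, 0.3602),
    0.85: (0.3511, -0.4795, 0.1379),
    1.5: (0.4198, -0.3504, -0.4335),
}


@dataclass(frozen=True)
class ModelParams:
    """Every tunable of the eco-evolutionary model, validated on creation.

    Parameters
    ----------
    r : float
        Intrinsic rate of increase per generation. Must satisfy ``0 < r``;
        the discrete-logistic fixed point is stable for ``r < 2``.
    K_max : float
        Maximum carrying capacity (individuals), attained at the local
        optimum trait value.
    sigma_K : float
        Width (standard deviation) of the Gaussian carrying-capacity
        function, in trait units.
    sigma_alpha : float
        Niche width of the competition kernel, in trait units. Smaller
        values mean competition falls off faster with trait distance,
        permitting more coexisting phenotypic clusters.
    mu : float
        Mutation probability per birth.
    sigma_mu : float
        Standard deviation of mutation effects on the trait.
    theta : float
        Abundance threshold below which stochastic extinction applies.
    rho : float
        Per-generation removal probability for populations with
        ``1 <= N < theta``.
    d : float
        Per-individual dispersal probability per generation.
    delta_env : float
        Per-generation increase of every patch optimum (environmental
        change rate, trait units).
    delta_spacing : float
        Among-patch spacing of the optima (environmental heterogeneity,
        trait units).
    k : int
        Number of patches.
    seed : int or None
        RNG seed recorded for provenance (the simulator takes an explicit
        ``numpy.random.Generator``; this field documents the run).
    """

    r: float = 1.9
    K_max: float = 10_000.0
    sigma_K: float = 1.0
    sigma_alpha: float = 0.68
    mu: float = 1e-5
    sigma_mu: float = 0.05
    theta: float = 2.0
    rho: float = 0.025
    d: float = 0.0
    delta_env: float = 0.0
    delta_spacing: float = 0.5
    k: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if not self.K_max > 0:
            raise ValueError(f"K_max must be > 0, got {self.K_max}")
        if not self.sigma_K > 0:
            raise ValueError(f"sigma_K must be > 0, got {self.sigma_K}")
        if not self.sigma_alpha > 0:
            raise ValueError(f"sigma_alpha must be > 0, got {self.sigma_alpha}")
        if self.sigma_mu < 0:
            raise ValueError(f"sigma_mu must be >= 0, got {self.sigma_mu}")
        for name in ("mu", "d", "rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.d > 0 and self.k < 2:
            raise ValueError("dispersal (d > 0) requires k >= 2 patches")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class InitConfig:
    """Configuration of the single-patch coevolution (burn-in) protocol.

    The burn-in always runs with no dispersal and a constant environment
    (``d = 0``, ``delta_env = 0``); those fields of ``base`` are forced.

    Attributes
    ----------
    N0 : float
        Founder abundance (individuals).
    x0_per_patch : sequence of float
        Founder trait value for each of the ``k`` patches.
    generations : int
        Burn-in length. The full protocol is 10**6 generations at
        mu = 1e-5; the scaled protocol (default) uses mu = 1e-4 for
        2 * 10**5 generations, which reaches qualitatively the same
        branched configurations in desk-scale time.
    base : ModelParams
        Remaining model parameters.
    """

    base: ModelParams = field(default_factory=ModelParams)
    N0: float = 500.0
    x0_per_patch: Sequence[float] = DEFAULT_FOUNDER_TRAITS[0.68]
    generations: int = 200_000

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"N0 must be >= 1, got {self.N0}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if len(self.x0_per_patch) != self.base.k:
            raise ValueError(
                f"x0_per_patch has length {len(self.x0_per_patch)}, "
                f"expected k = {self.base.k}"
            )
        # burn-in contract: closed patches, constant environment
        object.__setattr__(
            self, "base", self.base.replace(d=0.0, delta_env=0.0)
        )

    @classmethod
    def scaled(cls, sigma_alpha: float = 0.68, **kwargs) -> "InitConfig":
        """Desk-scale burn-in: mu = 1e-4 for 2e5 generations."""
        x0 = DEFAULT_FOUNDER_TRAITS.get(sigma_alpha, (0.0,) * 3)
        base = ModelParams(sigma_alpha=sigma_alpha, mu=1e-4)
        kwargs.setdefault("x0_per_patch", x0)
        kwargs.setdefault("generations", 200_000)
        return cls(base=base, **kwargs)

    @classmethod
    def full(cls, sigma_alpha: float = 0.68, **kwargs) -> "InitConfig":
        """Full-protocol burn-in: mu = 1e-5 for 1e6 generations."""
        x0 = DEFAULT_FOUNDER_TRAITS.get(sigma_alpha, (0.0,) * 3)
        base = ModelParams(sigma_alpha=sigma_alpha, mu=1e-5)
        kwargs.setdefault("x0_per_patch", x0)
        kwargs.setdefault("generations", 1_000_000)
        return cls(base=base, **kwargs)
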