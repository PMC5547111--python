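"""Model definitions for cyclic competition games.

A model is a directed invasion tournament between ``n`` species together
with the three rate families that drive the dynamics: the interspecific
competition (invasion) rate ``sigma``, the reproduction rate ``mu`` and a
per-species vector ``p`` of intraspecific competition rates.  The same
:class:`InteractionModel` instance feeds the mean-field ODE layer, the
stochastic lattice simulation and the reaction-diffusion PDE solver, so the
invasion structure is defined exactly once.

Presets
-------
``rps``
    Three species on a single cycle, A -> B -> C -> A.
``erps``
    Extended RPS: five species on a single cycle, i -> i+1 (mod 5).
``rpsls``
    Rock-paper-scissors-lizard-Spock: five species on the regular pentagram
    tournament (each species invades two others and is invaded by two
    others), oriented so that species ``i`` invades ``i+1`` and ``i+3``
    (mod 5); its predators are ``i+2`` and ``i+4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "InteractionModel",
    "RunConfig",
    "make_model",
    "predators_of",
    "cyclic_shift",
    "SPECIES_LABELS",
]

SPECIES_LABELS = ("A", "B", "C", "D", "E")

_PRESET_SIZES = {"rps": 3, "erps": 5, "rpsls": 5}


@dataclass(frozen=True)
class InteractionModel:
    """A cyclic-competition game: who invades whom, and at what rates.

    Parameters
    ----------
    n_species
        Number of species.
    invades
        Set of ordered pairs ``(predator, prey)``; irreflexive.
    sigma
        Interspecific competition (invasion) rate, uniform across pairs.
    mu
        Reproduction rate.
    p
        Per-species intraspecific competition rates, ``p[i] >= 0``.
    labels
        Species display names; defaults to ``A..E``.
    """

    n_species: int
    invades: FrozenSet[Tuple[int, int]]
    sigma: float = 1.0
    mu: float = 1.0
    p: Tuple[float, ...] = ()
    labels: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if len(self.p) != self.n_species:
            raise ValueError(
                f"p has length {len(self.p)}, expected {self.n_species}"
            )
        if any(pi < 0 for pi in self.p):
            raise ValueError("intraspecific rates p must be nonnegative")
        if self.sigma < 0 or self.mu < 0:
            raise ValueError("sigma and mu must be nonnegative")
        for pred, prey in self.invades:
            if pred == prey:
                raise ValueError(f"reflexive invasion pair ({pred}, {prey})")
            if not (0 <= pred < self.n_species and 0 <= prey < self.n_species):
                raise ValueError(f"invasion pair ({pred}, {prey}) out of range")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(SPECIES_LABELS[: self.n_species])
            )

    def predators_of(self, i: int) -> FrozenSet[int]:
        """Species that invade (prey on) species ``i``."""
        if not 0 <= i < self.n_species:
            raise IndexError(f"species index {i} out of range")
        return frozenset(pred for pred, prey in self.invades if prey == i)

    def prey_of(self, i: int) -> FrozenSet[int]:
        """Species that species ``i`` invades."""
        if not 0 <= i < self.n_species:
            raise IndexError(f"species index {i} out of range")
        return frozenset(prey for pred, prey in self.invades if pred == i)

    @property
    def predator_matrix(self) -> np.ndarray:
        """Boolean matrix ``P[i, j] = True`` iff j preys on i."""
        mat = np.zeros((self.n_species, self.n_species), dtype=bool)
        for pred, prey in self.invades:
            mat[prey, pred] = True
        return mat

    @property
    def prey_matrix(self) -> np.ndarray:
        """Boolean matrix ``Q[i, j] = True`` iff i preys on j."""
        return self.predator_matrix.T

    def with_p(self, p: Sequence[float]) -> "InteractionModel":
        """Copy of this model with a new intraspecific rate vector."""
        return InteractionModel(
            n_species=self.n_species,
            invades=self.invades,
            sigma=self.sigma,
            mu=self.mu,
            p=tuple(float(x) for x in p),
            labels=self.labels,
        )


def _preset_invades(kind: str, n: int) -> FrozenSet[Tuple[int, int]]:
    if kind == "rps" or kind == "erps":
        return frozenset((i, (i + 1) % n) for i in range(n))
    if kind == "rpsls":
        return frozenset(
            (i, (i + k) % n) for i in range(n) for k in (1, 3)
        )
    raise ValueError(f"unknown preset kind {kind!r}")


def make_model(
    kind: str,
    p: Sequence[float],
    sigma: float = 1.0,
    mu: float = 1.0,
    custom_invades: Optional[Iterable[Tuple[int, int]]] = None,
    labels: Optional[Sequence[str]] = None,
) -> InteractionModel:
    """Build an :class:`InteractionModel` from a preset or a custom tournament.

    ``kind`` is one of ``rps``, ``erps``, ``rpsls`` or ``custom``.  For the
    presets the invasion structure is fixed (see module docstring) and the
    length of ``p`` must match the preset's species count.  For ``custom``,
    ``custom_invades`` is used verbatim after an irreflexivity check and the
    species count is ``len(p)``.
    """
    p = tuple(float(x) for x in p)
    if kind == "custom":
        if custom_invades is None:
            raise ValueError("custom model requires custom_invades")
        invades = frozenset(
            (int(a), int(b)) for a, b in custom_invades
        )
        n = len(p)
    else:
        if kind not in _PRESET_SIZES:
            raise ValueError(f"unknown model kind {kind!r}")
        n = _PRESET_SIZES[kind]
        if len(p) != n:
            raise ValueError(
                f"preset {kind!r} has {n} species but p has length {len(p)}"
            )
        invades = _preset_invades(kind, n)
    return InteractionModel(
        n_species=n,
        invades=invades,
        sigma=float(sigma),
        mu=float(mu),
        p=p,
        labels=tuple(labels) if labels is not None else (),
    )


def predators_of(model: InteractionModel, i: int) -> FrozenSet[int]:
    """Indices of species that invade species ``i`` in ``model``."""
    return model.predators_of(i)


def cyclic_shift(model: InteractionModel, k: int = 1) -> InteractionModel:
    """Relabel species by the cyclic shift ``i -> (i + k) mod n``.

    The presets are vertex-transitive under this shift, so the shifted model
    with a correspondingly permuted ``p`` vector is isomorphic to the
    original; all solvers should commute with the relabeling.
    """
    n = model.n_species
    k = k % n
    invades = frozenset(
        ((a + k) % n, (b + k) % n) for a, b in model.invades
    )
    p = tuple(model.p[(i - k) % n] for i in range(n))
    return InteractionModel(
        n_species=n,
        invades=invades,
        sigma=model.sigma,
        mu=model.mu,
        p=p,
        labels=model.labels,
    )


@dataclass(frozen=True)
class RunConfig:
    """Run parameters for lattice and PDE simulations.

    Mobility can be given either as the diffusion coefficient ``M``
    (sites^2 per generation on the unit square) or as the pair-exchange
    rate ``epsilon``; the two are tied by ``epsilon = 2 * M * N`` with
    ``N = L**2`` the number of lattice sites.
    """

    lattice_side: int
    t_max: float
    seed: int = 0
    mobility: Optional[float] = None
    epsilon: Optional[float] = None
    initial_densities: Tuple[float, ...] = ()
    snapshot_times: Tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.lattice_side < 4:
            raise ValueError("lattice side must be at least 4")
        if self.t_max <= 0:
            raise ValueError("t_max must be positive")
        n_sites = self.lattice_side ** 2
        if self.mobility is None and self.epsilon is None:
            raise ValueError("one of mobility or epsilon is required")
        if self.mobility is None:
            object.__setattr__(self, "mobility", self.epsilon / (2 * n_sites))
        elif self.epsilon is None:
            object.__setattr__(self, "epsilon", 2 * self.mobility * n_sites)
        elif abs(self.epsilon - 2 * self.mobility * n_sites) > 1e-9 * max(
            1.0, abs(self.epsilon)
        ):
            raise ValueError("epsilon and mobility are inconsistent (eps = 2MN)")
        dens = np.asarray(self.initial_densities, dtype=float)
        if dens.size:
            if np.any(dens < 0) or np.any(dens > 1):
                raise ValueError("initial densities must lie in [0, 1]")
            if dens.sum() > 1 + 1e-12:
                raise ValueError("initial densities must sum to at most 1")

    @property
    def n_sites(self) -> int:
        return self.lattice_side ** 2
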