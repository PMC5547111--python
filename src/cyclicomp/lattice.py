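"""Stochastic lattice realization of the cyclic game.

Individuals live on an L x L periodic square lattice, one per site, with
empty sites allowed.  Random sequential updating: each elementary attempt
draws an occupied site (empty draws are rejected and redrawn) and one of
its four von Neumann neighbors, then selects at most one of the reactions

    X Y  -> X 0   rate sigma   (Y is prey of X; interspecific kill)
    X 0  -> X X   rate mu      (reproduction into an empty neighbor)
    X X  -> X 0   rate p_X     (intraspecific kill; the neighbor dies)
    X Z  -> Z X   rate eps     (swap; Z is same species or empty)

with probability rate / Lambda, Lambda = sigma + mu + max_i p_i + eps,
else does nothing.  One Monte Carlo generation is round(Lambda * N)
attempts (N = L^2 sites), so that each reaction channel fires at its
stated rate per neighbor pair per generation: the lattice generation is
commensurate with the ODE/PDE time unit and with the mobility definition
eps = 2 M N (an individual performs ~eps exchange attempts per
generation).  The exchange rate is tied to the mobility by eps = 2 M N.

Every birth, interspecific death, intraspecific death and move is counted
per species per generation, so population bookkeeping is integer-exact:
count_i(t) = count_i(0) + sum(births_i) - sum(deaths_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .meanfield import DensityTrajectory
from .models import InteractionModel, RunConfig

__all__ = [
    "LatticeState",
    "EventLog",
    "init_lattice",
    "mc_generation",
    "run_lattice",
    "survival_probability",
]

EMPTY = -1


@dataclass
class LatticeState:
    """Grid of site occupancies (species index, or -1 for empty)."""

    grid: np.ndarray  # (L, L) int8
    generation: float = 0.0
    rng_seed: int = 0

    @property
    def side(self) -> int:
        return self.grid.shape[0]

    def counts(self, n_species: int) -> np.ndarray:
        return np.array(
            [(self.grid == s).sum() for s in range(n_species)], dtype=np.int64
        )


@dataclass
class EventLog:
    """Per-generation, per-species event counts (unscaled integers)."""

    births: np.ndarray  # (T, n)
    inter_deaths: np.ndarray  # (T, n): deaths of species i to a predator
    intra_deaths: np.ndarray  # (T, n): deaths of species i to its own kind
    moves: np.ndarray  # (T, n)
    n_sites: int

    @property
    def R(self) -> np.ndarray:
        """Reproduction rate series, scaled by lattice size."""
        return self.births / self.n_sites

    @property
    def C(self) -> np.ndarray:
        """Interspecific death rate series, scaled by lattice size."""
        return self.inter_deaths / self.n_sites

    @property
    def I(self) -> np.ndarray:
        """Intraspecific death rate series, scaled by lattice size."""
        return self.intra_deaths / self.n_sites


def init_lattice(
    L: int,
    initial_densities: Sequence[float],
    seed: int,
) -> LatticeState:
    """Random lattice: site -> species i w.p. density_i, else empty."""
    dens = np.asarray(initial_densities, dtype=float)
    if np.any(dens < 0) or np.any(dens > 1) or dens.sum() > 1 + 1e-12:
        raise ValueError("initial densities must be in [0,1] and sum to <= 1")
    rng = np.random.default_rng(seed)
    probs = np.append(dens, max(0.0, 1.0 - dens.sum()))
    vals = np.append(np.arange(len(dens)), EMPTY).astype(np.int8)
    grid = rng.choice(vals, size=(L, L), p=probs / probs.sum())
    return LatticeState(grid=grid, generation=0.0, rng_seed=seed)


@njit(cache=True)
def _mc_kernel(
    grid,
    nbr,
    prey_mat,
    p,
    sigma,
    mu,
    eps,
    lam,
    attempts_per_gen,
    n_gens,
    seed,
    births,
    inter_deaths,
    intra_deaths,
    moves,
    counts,
    densities,
    snap_gens,
    snaps,
    permissive_swap,
):  # pragma: no cover - exercised through run_lattice
    # xorshift64* stream seeded through splitmix64; much cheaper per draw
    # than the library generator and fully reproducible from `seed`
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    rng_state = z ^ (z >> np.uint64(31))
    if rng_state == np.uint64(0):
        rng_state = np.uint64(0x9E3779B97F4A7C15)
    inv53 = 1.0 / 9007199254740992.0  # 2**-53
    next_snap = 0
    n_sites = grid.shape[0]
    n_species = p.shape[0]
    occupied = 0
    for s in range(n_species):
        occupied += counts[s]
    four_n = 4.0 * n_sites
    for gen in range(n_gens):
        for _ in range(attempts_per_gen):
            if occupied == 0:
                break
            # Rejection-sample an occupied site; redraws consume no time.
            # One uniform draw supplies site, direction and (via its
            # remainder, independent under an ideal uniform) the event
            # variate u.
            while True:
                rng_state ^= rng_state >> np.uint64(12)
                rng_state ^= rng_state << np.uint64(25)
                rng_state ^= rng_state >> np.uint64(27)
                bits = rng_state * np.uint64(0x2545F4914F6CDD1D)
                f = (bits >> np.uint64(11)) * inv53 * four_n
                r = int(f)
                site = r >> 2
                sp = grid[site]
                if sp != EMPTY:
                    break
            nsite = nbr[site, r & 3]
            nb = grid[nsite]
            u = (f - r) * lam
            if nb == EMPTY:
                # reproduction [0, mu) then exchange [mu, mu+eps)
                if u < mu:
                    grid[nsite] = sp
                    births[gen, sp] += 1
                    counts[sp] += 1
                    occupied += 1
                elif u < mu + eps:
                    grid[nsite] = sp
                    grid[site] = EMPTY
                    moves[gen, sp] += 1
            elif nb == sp:
                # Intraspecific kill, then exchange.  The pair rate is
                # p_X, but a same-species pair can be drawn in either
                # order, so each ordered draw fires at p_X/2.
                if u < 0.5 * p[sp]:
                    grid[nsite] = EMPTY
                    intra_deaths[gen, sp] += 1
                    counts[sp] -= 1
                    occupied -= 1
                elif u < 0.5 * p[sp] + eps:
                    moves[gen, sp] += 1  # swap of identical occupants
            elif prey_mat[sp, nb]:
                if u < sigma:
                    grid[nsite] = EMPTY
                    inter_deaths[gen, nb] += 1
                    counts[nb] -= 1
                    occupied -= 1
                elif permissive_swap and u < sigma + eps:
                    grid[nsite] = sp
                    grid[site] = nb
                    moves[gen, sp] += 1
            elif permissive_swap:
                if u < eps:
                    grid[nsite] = sp
                    grid[site] = nb
                    moves[gen, sp] += 1
        inv_n = 1.0 / n_sites
        for s in range(n_species):
            densities[gen, s] = counts[s] * inv_n
        if next_snap < snap_gens.shape[0] and gen + 1 == snap_gens[next_snap]:
            snaps[next_snap] = grid.reshape(snaps.shape[1], snaps.shape[2])
            next_snap += 1


def _lambda(model: InteractionModel, eps: float) -> float:
    return model.sigma + model.mu + max(model.p) + eps


_NBR_CACHE: Dict[int, np.ndarray] = {}


def _neighbor_table(L: int) -> np.ndarray:
    """Flat-index von Neumann neighbors with periodic wrap, (N, 4)."""
    tab = _NBR_CACHE.get(L)
    if tab is None:
        idx = np.arange(L * L).reshape(L, L)
        tab = np.stack(
            [
                np.roll(idx, -1, axis=0),
                np.roll(idx, 1, axis=0),
                np.roll(idx, -1, axis=1),
                np.roll(idx, 1, axis=1),
            ],
            axis=-1,
        ).reshape(L * L, 4).astype(np.int32)
        _NBR_CACHE[L] = tab
    return tab


def _run_kernel(
    model: InteractionModel,
    state: LatticeState,
    eps: float,
    n_gens: int,
    seed: int,
    snap_gens: Optional[Sequence[int]] = None,
    permissive_swap: bool = False,
) -> Tuple[EventLog, np.ndarray, np.ndarray]:
    n = model.n_species
    L = state.side
    births = np.zeros((n_gens, n), dtype=np.int64)
    inter = np.zeros((n_gens, n), dtype=np.int64)
    intra = np.zeros((n_gens, n), dtype=np.int64)
    moves = np.zeros((n_gens, n), dtype=np.int64)
    densities = np.zeros((n_gens, n), dtype=np.float64)
    snap_arr = np.asarray(sorted(snap_gens or []), dtype=np.int64)
    snaps = np.zeros((len(snap_arr), L, L), dtype=np.int8)
    counts = state.counts(n)
    lam = _lambda(model, eps)
    flat = state.grid.reshape(-1)
    _mc_kernel(
        flat,
        _neighbor_table(L),
        np.ascontiguousarray(model.prey_matrix),
        np.asarray(model.p, dtype=np.float64),
        model.sigma,
        model.mu,
        eps,
        lam,
        int(round(lam * L * L)),
        n_gens,
        seed,
        births,
        inter,
        intra,
        moves,
        counts,
        densities,
        snap_arr,
        snaps,
        permissive_swap,
    )
    state.grid = flat.reshape(L, L)
    state.generation += n_gens
    log = EventLog(
        births=births,
        inter_deaths=inter,
        intra_deaths=intra,
        moves=moves,
        n_sites=L ** 2,
    )
    return log, densities, snaps


def mc_generation(
    model: InteractionModel,
    state: LatticeState,
    eps: float,
    seed: int,
    n_gens: int = 1,
    permissive_swap: bool = False,
) -> EventLog:
    """Advance ``state`` in place by ``n_gens`` Monte Carlo generations."""
    log, _, _ = _run_kernel(
        model, state, eps, n_gens, seed, permissive_swap=permissive_swap
    )
    return log


def run_lattice(
    model: InteractionModel,
    config: RunConfig,
    permissive_swap: bool = False,
) -> Tuple[DensityTrajectory, EventLog, Dict[int, np.ndarray]]:
    """Full lattice run: densities per generation, event log, snapshots.

    Randomness is fanned out from ``config.seed`` into independent init
    and dynamics streams.  Snapshots are grid copies taken at the
    requested (integer) generations; generation 0 is the initial state.
    """
    n = model.n_species
    dens0 = config.initial_densities or tuple([1.0 / n] * n)
    init_seed, dyn_seed = (
        int(s) for s in
        np.random.SeedSequence(config.seed).generate_state(2) % (2 ** 31)
    )
    state = init_lattice(config.lattice_side, dens0, init_seed)
    n_gens = int(round(config.t_max))
    snap_times = sorted({int(t) for t in config.snapshot_times if t <= n_gens})
    snapshots: Dict[int, np.ndarray] = {}
    if 0 in snap_times:
        snapshots[0] = state.grid.copy()
        snap_times.remove(0)
    dens0_row = state.counts(n) / config.n_sites
    log, dens, snaps = _run_kernel(
        model, state, config.epsilon, n_gens, dyn_seed,
        snap_gens=snap_times, permissive_swap=permissive_swap,
    )
    for t, snap in zip(snap_times, snaps):
        snapshots[t] = snap
    traj = DensityTrajectory(
        times=np.arange(n_gens + 1, dtype=float),
        densities=np.vstack([dens0_row, dens]),
    )
    return traj, log, snapshots


def survival_probability(
    model: InteractionModel,
    config: RunConfig,
    n_realizations: int,
) -> Dict[int, float]:
    """Fraction of independent runs ending with k surviving species.

    Seeds for the realizations are spawned from ``config.seed``; a species
    survives a lattice run iff at least one individual remains (extinction
    on the lattice is absorbing).
    """
    if n_realizations < 1:
        raise ValueError("need at least one realization")
    from dataclasses import replace

    freqs: Dict[int, float] = {k: 0.0 for k in range(model.n_species + 1)}
    seeds = np.random.SeedSequence(config.seed).generate_state(
        n_realizations
    ) % (2 ** 31)
    for s in seeds:
        cfg = replace(config, seed=int(s))
        traj, _, _ = run_lattice(model, cfg)
        k = int((traj.final > 0).sum())
        freqs[k] += 1.0 / n_realizations
    return freqs
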