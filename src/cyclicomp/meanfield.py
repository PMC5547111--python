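"""Mean-field (rate-equation) layer for cyclic competition games.

For species densities ``a_i`` the rate equations read

    da_i/dt = a_i [ mu (1 - rho) - sigma * sum_{j in predators(i)} a_j
                    - (p_i / 2) a_i ],        rho = sum_j a_j,

i.e. logistic growth into empty space at rate ``mu``, losses to each
predator at rate ``sigma``, and intraspecific competition at rate ``p_i``
(the factor 1/2 accounts for double counting of same-species pairs).

This module provides the right-hand side, trajectory integration, exact
fixed-point enumeration over all support subsets (the equilibrium
conditions are linear on a fixed support), analytic Jacobians, stability
classification, an attractiveness criterion for the boundary heteroclinic
cycle connecting the single-species saddles, one-parameter bifurcation
scans with bisection-refined thresholds, and sub-tournament analysis of
surviving species sets.

For the three-species game the closed forms of the single-species, pair
and interior fixed points (and the pair-point eigenvalues) are also
exposed; the generic linear-solve enumeration must reproduce them, which
the test suite checks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .models import InteractionModel

__all__ = [
    "FixedPoint",
    "DensityTrajectory",
    "BifurcationScan",
    "ode_rhs",
    "integrate",
    "find_fixed_points",
    "jacobian",
    "classify_stability",
    "heteroclinic_cycle_stable",
    "heteroclinic_product",
    "scan_bifurcation",
    "interior_fixed_point",
    "interior_leading_eigenvalue",
    "limit_fixed_point",
    "sub_tournament",
    "param_index",
    "rps_single_points",
    "rps_pair_points",
    "rps_interior_point",
    "rps_pair_eigenvalues",
]

#: default tolerance for calling an eigenvalue real part zero
STABILITY_TOL = 1e-9
#: a support density below this is treated as absent
SUPPORT_TOL = 1e-10


# --------------------------------------------------------------------------
# containers


@dataclass
class DensityTrajectory:
    """Time-indexed per-species densities from any of the three solvers."""

    times: np.ndarray  # (T,)
    densities: np.ndarray  # (T, n_species)

    @property
    def total_density(self) -> np.ndarray:
        return self.densities.sum(axis=1)

    @property
    def final(self) -> np.ndarray:
        return self.densities[-1]


@dataclass
class FixedPoint:
    """An equilibrium of the rate equations on a given support."""

    densities: np.ndarray
    support: frozenset
    eigenvalues: np.ndarray
    stability: str  # stable | unstable | saddle | marginal
    kind: str  # empty | single | pair | full | partial

    @property
    def support_size(self) -> int:
        return len(self.support)


@dataclass
class BifurcationScan:
    """Result of a one-parameter phase scan.

    ``phase[k]`` is the number of species in the attracting state at
    ``grid[k]``: the support size of the stable fixed point, ``0`` when no
    fixed point is stable (the attracting set is the boundary heteroclinic
    cycle and fluctuations drive the system to a single survivor), or
    ``-1`` when stable fixed points of different support sizes coexist.
    """

    param_name: str
    grid: np.ndarray
    phase: np.ndarray
    thresholds: List[float] = field(default_factory=list)
    phase_pairs: List[Tuple[int, int]] = field(default_factory=list)


# --------------------------------------------------------------------------
# right-hand side / Jacobian


def ode_rhs(model: InteractionModel, state: Sequence[float]) -> np.ndarray:
    """Time derivative of the density vector under the rate equations."""
    a = np.asarray(state, dtype=float)
    if a.shape != (model.n_species,):
        raise ValueError(
            f"state has shape {a.shape}, expected ({model.n_species},)"
        )
    if np.any(a < 0):
        raise ValueError("densities must be nonnegative")
    return _rhs(a, model.mu, model.sigma, np.asarray(model.p), model.predator_matrix)


def _rhs(a, mu, sigma, p, pred):
    rho = a.sum()
    growth = mu * (1.0 - rho) - sigma * (pred @ a) - 0.5 * p * a
    return a * growth


def jacobian(model: InteractionModel, point: Sequence[float]) -> np.ndarray:
    """Analytic Jacobian of :func:`ode_rhs` at ``point``."""
    a = np.asarray(point, dtype=float)
    n = model.n_species
    mu, sigma = model.mu, model.sigma
    p = np.asarray(model.p)
    pred = model.predator_matrix.astype(float)
    rho = a.sum()
    growth = mu * (1.0 - rho) - sigma * (pred @ a) - 0.5 * p * a
    jac = -a[:, None] * (mu + sigma * pred)
    jac[np.diag_indices(n)] += growth - 0.5 * p * a
    return jac


# --------------------------------------------------------------------------
# integration


def integrate(
    model: InteractionModel,
    init: Sequence[float],
    t_max: float,
    dt_out: float = 1.0,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> DensityTrajectory:
    """Integrate the rate equations from ``init`` up to ``t_max``.

    Uses adaptive LSODA (the pair-coexistence regime is mildly stiff for
    large ``p_i``) sampled every ``dt_out`` generations.  The simplex is
    forward invariant; integrator undershoots below zero at the tolerance
    scale are clamped in the returned trajectory.
    """
    a0 = np.asarray(init, dtype=float)
    if np.any(a0 < 0) or a0.sum() > 1 + 1e-12:
        raise ValueError("initial state must be in the density simplex")
    t_eval = np.arange(0.0, t_max + 0.5 * dt_out, dt_out)
    sol = solve_ivp(
        lambda t, y: _rhs(
            np.maximum(y, 0.0), model.mu, model.sigma,
            np.asarray(model.p), model.predator_matrix,
        ),
        (0.0, t_max),
        a0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed at t={sol.t[-1]}: {sol.message}")
    dens = sol.y.T.copy()
    dens[(dens < 0) & (dens > -10 * atol)] = 0.0
    return DensityTrajectory(times=sol.t, densities=dens)


# --------------------------------------------------------------------------
# fixed points


def classify_stability(eigenvalues: np.ndarray, tol: float = STABILITY_TOL) -> str:
    """Label a spectrum: stable / unstable / saddle / marginal."""
    re = np.real(np.asarray(eigenvalues))
    if np.any(np.abs(re) <= tol):
        return "marginal"
    if np.all(re < -tol):
        return "stable"
    if np.all(re > tol):
        return "unstable"
    return "saddle"


def _kind(support_size: int, n: int) -> str:
    if support_size == 0:
        return "empty"
    if support_size == 1:
        return "single"
    if support_size == 2:
        return "pair"
    if support_size == n:
        return "full"
    return "partial"


def find_fixed_points(
    model: InteractionModel,
    tol: float = STABILITY_TOL,
    support_tol: float = SUPPORT_TOL,
) -> List[FixedPoint]:
    """Enumerate equilibria over all ``2^n`` support subsets.

    On a fixed support the equilibrium conditions are linear:
    ``mu - sum_j [mu + sigma*1(j preys on i) + (p_i/2) delta_ij] a_j = 0``
    for each supported ``i``.  Each support contributes at most one
    candidate; it is kept when all supported densities are strictly
    positive.  Singular support systems are skipped.
    """
    n = model.n_species
    mu, sigma = model.mu, model.sigma
    p = np.asarray(model.p)
    pred = model.predator_matrix.astype(float)
    out: List[FixedPoint] = []
    for r in range(n + 1):
        for support in itertools.combinations(range(n), r):
            a = np.zeros(n)
            if r > 0:
                idx = np.array(support)
                mat = mu + sigma * pred[np.ix_(idx, idx)]
                mat[np.diag_indices(r)] += 0.5 * p[idx]
                try:
                    sol = np.linalg.solve(mat, np.full(r, mu))
                except np.linalg.LinAlgError:
                    continue
                if np.any(sol <= support_tol):
                    continue
                a[idx] = sol
            eig = np.linalg.eigvals(jacobian(model, a))
            out.append(
                FixedPoint(
                    densities=a,
                    support=frozenset(support),
                    eigenvalues=eig,
                    stability=classify_stability(eig, tol),
                    kind=_kind(r, n),
                )
            )
    return out


# --------------------------------------------------------------------------
# heteroclinic cycle


def _single_point_density(model: InteractionModel, i: int) -> float:
    # mu(1 - d) - (p_i/2) d = 0
    return 2 * model.mu / (2 * model.mu + model.p[i])


def heteroclinic_product(model: InteractionModel) -> float:
    """Product of saddle ratios over the boundary heteroclinic cycle.

    At the single-species equilibrium of species ``i`` the off-support
    (transverse) eigenvalues are ``mu(1 - d_i) - sigma d_i`` for the prey
    of ``i`` and ``mu(1 - d_i)`` for the rest, with ``d_i`` the resident
    density.  Each vertex contributes the saddle ratio
    ``nu_i = |most negative transverse| / (largest positive transverse)``;
    the cycle is asymptotically stable iff the product over its vertices
    exceeds one.  Vertices with no contracting transverse direction
    contribute ``nu_i = 0``.
    """
    nu_total = 1.0
    for i in range(model.n_species):
        d = _single_point_density(model, i)
        transverse = []
        for j in range(model.n_species):
            if j == i:
                continue
            lam = model.mu * (1.0 - d)
            if i in model.predators_of(j):
                lam -= model.sigma * d
            transverse.append(lam)
        expanding = max(transverse)
        if expanding <= 0:
            raise ValueError(
                f"single-species point of {model.labels[i]} is not a saddle; "
                "heteroclinic criterion inapplicable"
            )
        contracting = max(0.0, -min(transverse))
        nu_total *= contracting / expanding
    return nu_total


def heteroclinic_cycle_stable(model: InteractionModel) -> bool:
    """Whether the boundary heteroclinic cycle is attracting."""
    return heteroclinic_product(model) > 1.0


# --------------------------------------------------------------------------
# bifurcation scans

_PARAM_NAMES = {f"p_{c}": i for i, c in enumerate("abcde")}


def param_index(name) -> int:
    """Resolve a parameter name like ``'p_c'`` (or an index) to an index."""
    if isinstance(name, (int, np.integer)):
        return int(name)
    try:
        return _PARAM_NAMES[name]
    except KeyError:
        raise ValueError(f"unknown parameter name {name!r}") from None


def _phase_at(model_template: InteractionModel, idx: int, value: float) -> int:
    p = list(model_template.p)
    p[idx] = value
    model = model_template.with_p(p)
    stable = [
        fp for fp in find_fixed_points(model) if fp.stability == "stable"
    ]
    if not stable:
        return 0
    sizes = {fp.support_size for fp in stable}
    if len(sizes) > 1:
        return -1
    return sizes.pop()


def scan_bifurcation(
    model_template: InteractionModel,
    param_name,
    grid: Sequence[float],
    refine_tol: float = 1e-3,
) -> BifurcationScan:
    """Scan one intraspecific rate and label the attracting state.

    At each grid value the model is rebuilt, all fixed points are found
    and classified, and the phase label is the support size of the stable
    fixed point (0 when none is stable, i.e. the boundary heteroclinic
    cycle attracts).  Each phase change between adjacent grid values is
    refined by bisection to ``refine_tol``.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 10 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with >= 10 points")
    idx = param_index(param_name)
    phase = np.array([_phase_at(model_template, idx, g) for g in grid])
    thresholds: List[float] = []
    pairs: List[Tuple[int, int]] = []
    for k in range(len(grid) - 1):
        if phase[k] == phase[k + 1]:
            continue
        lo, hi = grid[k], grid[k + 1]
        ph_lo = phase[k]
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            if _phase_at(model_template, idx, mid) == ph_lo:
                lo = mid
            else:
                hi = mid
        thresholds.append(0.5 * (lo + hi))
        pairs.append((int(phase[k]), int(phase[k + 1])))
    # Exact transcritical points (e.g. an interior point exchanging
    # stability with a boundary point) leave both equilibria marginal at
    # the crossing, which a refined scan resolves as a zero-width phase-0
    # sliver bounded by two thresholds ~refine_tol apart.  Merge them.
    merged_t: List[float] = []
    merged_p: List[Tuple[int, int]] = []
    i = 0
    while i < len(thresholds):
        if (
            i + 1 < len(thresholds)
            and thresholds[i + 1] - thresholds[i] < 5 * refine_tol
        ):
            merged_t.append(0.5 * (thresholds[i] + thresholds[i + 1]))
            merged_p.append((pairs[i][0], pairs[i + 1][1]))
            i += 2
        else:
            merged_t.append(thresholds[i])
            merged_p.append(pairs[i])
            i += 1
    thresholds, pairs = merged_t, merged_p
    name = param_name if isinstance(param_name, str) else f"p_{'abcde'[idx]}"
    return BifurcationScan(
        param_name=name, grid=grid, phase=phase,
        thresholds=thresholds, phase_pairs=pairs,
    )


def limit_fixed_point(
    model_template: InteractionModel,
    param_name,
    value: float = 1e6,
) -> np.ndarray:
    """Stable pair fixed point evaluated at a large parameter value.

    As the intraspecific rate of a species grows without bound, the stable
    two-species point it belongs to approaches a single-survivor state
    (e.g. ``(0, 2/3, 0)`` for the three-species game with ``p_b = 1``).
    """
    idx = param_index(param_name)
    p = list(model_template.p)
    p[idx] = value
    model = model_template.with_p(p)
    stable_pairs = [
        fp for fp in find_fixed_points(model)
        if fp.kind == "pair" and fp.stability == "stable"
    ]
    if not stable_pairs:
        raise ValueError(
            f"no stable pair fixed point at {model.labels[idx]} rate {value}"
        )
    return stable_pairs[0].densities


def interior_fixed_point(model: InteractionModel) -> Optional[FixedPoint]:
    """The full-support equilibrium, or ``None`` if it does not exist."""
    for fp in find_fixed_points(model):
        if fp.kind == "full":
            return fp
    return None


def interior_leading_eigenvalue(model: InteractionModel) -> float:
    """Largest real part of the Jacobian spectrum at the interior point.

    Raises ``ValueError`` when the interior equilibrium does not exist
    (some closed-form coordinate is nonpositive).
    """
    fp = interior_fixed_point(model)
    if fp is None:
        raise ValueError("interior fixed point does not exist")
    return float(np.max(np.real(fp.eigenvalues)))


# --------------------------------------------------------------------------
# tournament structure


def sub_tournament(model: InteractionModel, support) -> str:
    """Classify the invasion structure restricted to ``support``.

    Returns ``'cyclic'`` if the restriction contains a directed cycle,
    ``'transitive'`` if it is a complete acyclic tournament (a total
    order), and ``'mixed'`` otherwise (some pair left unconnected).
    """
    import networkx as nx

    support = sorted(support)
    if len(support) < 2:
        raise ValueError("support must contain at least two species")
    g = nx.DiGraph()
    g.add_nodes_from(support)
    g.add_edges_from(
        (a, b) for a, b in model.invades if a in g and b in g
    )
    if not nx.is_directed_acyclic_graph(g):
        return "cyclic"
    n_pairs = len(support) * (len(support) - 1) // 2
    return "transitive" if g.number_of_edges() == n_pairs else "mixed"


# --------------------------------------------------------------------------
# closed forms for the three-species game


def rps_single_points(p: Sequence[float], mu: float = 1.0) -> List[np.ndarray]:
    """The three single-species equilibria ``2mu/(2mu + p_i)`` on each axis."""
    out = []
    for i in range(3):
        a = np.zeros(3)
        a[i] = 2 * mu / (2 * mu + p[i])
        out.append(a)
    return out


def rps_pair_points(p: Sequence[float]) -> dict:
    """Closed-form two-species equilibria of the three-species game.

    With ``sigma = mu = 1``:
    AB = w1 (p_b, p_a - 2, 0), AC = w2 (p_c - 2, 0, p_a),
    BC = w3 (0, p_c, p_b - 2), where e.g.
    ``w1 = 2 / (p_a p_b + 2(p_a + p_b) - 4)``.  Points are returned for all
    three pairs regardless of existence (coordinates may be negative).
    """
    pa, pb, pc = p
    w1 = 2.0 / (pa * pb + 2 * (pa + pb) - 4)
    w2 = 2.0 / (pa * pc + 2 * (pa + pc) - 4)
    w3 = 2.0 / (pb * pc + 2 * (pb + pc) - 4)
    return {
        "AB": w1 * np.array([pb, pa - 2, 0.0]),
        "AC": w2 * np.array([pc - 2, 0.0, pa]),
        "BC": w3 * np.array([0.0, pc, pb - 2]),
    }


def rps_interior_point(p: Sequence[float]) -> np.ndarray:
    """Closed-form interior equilibrium of the three-species game.

    ``(a*, b*, c*) = 2(p_b(p_c-2)+4, p_c(p_a-2)+4, p_a(p_b-2)+4) / Gamma``
    with ``Gamma = p_a p_b p_c + 8 + 2[p_a p_b + p_b p_c + p_c p_a
    - 2(p_a + p_b + p_c) + 12]`` (valid for ``sigma = mu = 1``).
    """
    pa, pb, pc = p
    gamma = (
        pa * pb * pc + 8
        + 2 * (pa * pb + pb * pc + pc * pa - 2 * (pa + pb + pc) + 12)
    )
    return (
        2.0
        * np.array([pb * (pc - 2) + 4, pc * (pa - 2) + 4, pa * (pb - 2) + 4])
        / gamma
    )


def rps_pair_eigenvalues(p: Sequence[float], pair: str = "AB") -> np.ndarray:
    """Closed-form Jacobian eigenvalues at a two-species equilibrium.

    For the AB point: ``{w1 (p_a(p_b-2)+4)/2, -w1 p_b(p_a-2)/2, -1}``; the
    AC and BC columns follow by the cyclic relabeling.  Stability therefore
    requires ``p_a(p_b-2)+4 < 0``, i.e. ``p_a > 4/(2-p_b)`` with
    ``p_b < 2``.
    """
    pa, pb, pc = p
    if pair == "AB":
        w = 2.0 / (pa * pb + 2 * (pa + pb) - 4)
        return np.array([w * (pa * (pb - 2) + 4) / 2, -w * pb * (pa - 2) / 2, -1.0])
    if pair == "AC":
        w = 2.0 / (pa * pc + 2 * (pa + pc) - 4)
        return np.array([w * (pc * (pa - 2) + 4) / 2, -w * pa * (pc - 2) / 2, -1.0])
    if pair == "BC":
        w = 2.0 / (pb * pc + 2 * (pb + pc) - 4)
        return np.array([w * (pb * (pc - 2) + 4) / 2, -w * pc * (pb - 2) / 2, -1.0])
    raise ValueError(f"unknown pair {pair!r}")
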