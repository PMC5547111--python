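"""Balance indicators and coexistence classification.

For each species the lattice event log yields, per generation and scaled
by the lattice size N, the reproduction gain R_i(t), the interspecific
loss C_i(t) and the intraspecific loss I_i(t).  Two balance indicators
summarize the competition budget:

    H_i(t) = R_i(t) - C_i(t)          (balance without intraspecific loss)
    S_i(t) = R_i(t) - C_i(t) - I_i(t) (net population change)

so H_i - S_i = I_i >= 0 identically, and the scaled population is the
running sum P_i(t) = P_i(0) + sum_{k<=t} S_i(k), integer-exact times N.
A species that persists must have S_i fluctuating about zero, in which
case the cumulative process behaves like an unbiased random walk: its
mean-squared displacement grows linearly in time (normal diffusion,
exponent 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Sequence, Tuple, Union

import numpy as np

from .lattice import EventLog
from .meanfield import DensityTrajectory

__all__ = [
    "BalanceSeries",
    "balance_from_log",
    "diffusion_exponent",
    "classify_coexistence",
]


@dataclass
class BalanceSeries:
    """Per-species balance indicators derived from an event log.

    The underlying counts are integers, so the identity
    ``H_counts - S_counts == I_counts`` and the population reconstruction
    are exact; the scaled series divide by the lattice size on access.
    """

    H_counts: np.ndarray  # (T, n) births minus interspecific deaths
    S_counts: np.ndarray  # (T, n) H_counts minus intraspecific deaths
    I_counts: np.ndarray  # (T, n) intraspecific deaths
    P_counts: np.ndarray  # (T+1, n) population, row 0 = initial
    n_sites: int

    @property
    def H(self) -> np.ndarray:
        return self.H_counts / self.n_sites

    @property
    def S(self) -> np.ndarray:
        return self.S_counts / self.n_sites

    @property
    def I(self) -> np.ndarray:
        return self.I_counts / self.n_sites

    @property
    def P(self) -> np.ndarray:
        return self.P_counts / self.n_sites


def balance_from_log(
    log: EventLog, initial_counts: Sequence[int]
) -> BalanceSeries:
    """Compute H_i, S_i and the reconstructed population P_i from a log."""
    counts0 = np.asarray(initial_counts, dtype=np.int64)
    if counts0.shape != (log.births.shape[1],):
        raise ValueError("initial_counts length does not match the log")
    H = log.births - log.inter_deaths
    S = H - log.intra_deaths
    P = np.vstack([counts0, counts0 + S.cumsum(axis=0)])
    return BalanceSeries(
        H_counts=H, S_counts=S, I_counts=log.intra_deaths.copy(),
        P_counts=P, n_sites=log.n_sites,
    )


def diffusion_exponent(
    series: np.ndarray,
    window: int = 50,
    fit_range: Tuple[int, int] = (1, 0),
) -> Tuple[float, float]:
    """Growth exponent of the mean-squared displacement of a cumulative sum.

    ``series`` holds per-step increments, either one realization ``(T,)``
    or an ensemble ``(n_realizations, T)``.  The squared displacement of
    the cumulative sum over a lag is averaged over all time origins (and
    over realizations, when given) for lags ``1..window``.  Returns the
    log-log least-squares slope and its standard error; an unbiased
    random walk gives 1, a constant drift gives 2.
    """
    arr = np.atleast_2d(np.asarray(series, dtype=float))
    T = arr.shape[-1]
    if T < 2 * window:
        raise ValueError("series too short for the requested window")
    if not np.any(arr != 0):
        raise ValueError("degenerate all-zero series")

    cum = np.concatenate(
        [np.zeros((arr.shape[0], 1)), np.cumsum(arr, axis=1)], axis=1
    )
    lags = np.arange(1, window + 1)
    msd = np.empty(window)
    for j, lag in enumerate(lags):
        disp = cum[:, lag:] - cum[:, :-lag]
        msd[j] = np.mean(disp ** 2)
    lo, hi = fit_range
    if hi <= 0:
        hi = len(lags)
    sel = slice(lo - 1, hi)
    x = np.log(lags[sel])
    y = np.log(np.maximum(msd[sel], 1e-300))
    A = np.vstack([x, np.ones_like(x)]).T
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = max(len(x) - 2, 1)
    resid = y - A @ coef
    s2 = (resid ** 2).sum() / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return float(coef[0]), float(np.sqrt(cov[0, 0]))


def classify_coexistence(
    traj: DensityTrajectory,
    extinct_tol: float = 1e-6,
    tail_fraction: float = 0.2,
) -> Tuple[FrozenSet[int], int]:
    """Surviving-species set: density above ``extinct_tol`` over the tail.

    A species counts as surviving iff its density exceeds the tolerance
    at every sample in the final ``tail_fraction`` of the run.  For
    lattice runs use ``extinct_tol=0`` (extinction is absorbing); for
    ODE/PDE means the default 1e-6 is far below one individual on any
    simulated lattice.
    """
    dens = traj.densities
    n_tail = max(1, int(np.ceil(tail_fraction * dens.shape[0])))
    tail = dens[-n_tail:]
    surv = frozenset(np.nonzero((tail > extinct_tol).all(axis=0))[0].tolist())
    return surv, len(surv)
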