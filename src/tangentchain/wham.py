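"""Weighted histogram analysis method (WHAM) for multi-temperature runs.

The square-well chain has discrete energies (integer multiples of -epsilon),
so histograms need no binning choices.  The self-consistent equations for
the density of states g(E) from K runs with N_k samples at inverse
temperatures beta_k,

    g(E) = sum_k H_k(E) / sum_k N_k exp(f_k - beta_k E),
    exp(-f_k) = sum_E g(E) exp(-beta_k E),

are iterated in log space until the free-energy shifts f_k change by less
than a tolerance.  The specific heat per bead then follows from the
canonical energy fluctuations, C_V / (N k_B) = (<E^2> - <E>^2) / (n T^2) in
reduced units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .mc import EnergyTrace


@dataclass
class HeatCapacityCurve:
    """Specific heat per bead C_V / (N k_B) on a reduced-temperature grid."""

    temperatures: np.ndarray
    cv: np.ndarray
    mean_energy: np.ndarray

    def peak_temperature(self) -> float:
        return float(self.temperatures[int(np.argmax(self.cv))])


@dataclass
class DensityOfStates:
    """log g(E) on the discrete energy levels observed in the traces."""

    energies: np.ndarray
    log_g: np.ndarray
    log_f: np.ndarray  # converged per-run dimensionless free energies f_k

    def moments(self, T: float) -> tuple[float, float]:
        """Canonical <E> and <E^2> at reduced temperature T."""
        logw = self.log_g - self.energies / T
        logZ = logsumexp(logw)
        w = np.exp(logw - logZ)
        e1 = float(np.sum(w * self.energies))
        e2 = float(np.sum(w * self.energies**2))
        return e1, e2


def estimate_dos(
    trace: EnergyTrace,
    tol: float = 1e-8,
    max_iter: int = 100000,
    burn_frac: float = 0.0,
) -> DensityOfStates:
    """Self-consistent WHAM estimate of the density of states.

    ``burn_frac`` discards the leading fraction of every energy series.
    Raises RuntimeError if the free-energy shifts have not converged to
    ``tol`` after ``max_iter`` iterations.
    """
    temps = np.asarray(trace.temperatures, dtype=np.float64)
    betas = 1.0 / temps
    E = np.asarray(trace.energies, dtype=np.float64)
    if E.ndim == 1:
        E = E[None, :]
    start = int(burn_frac * E.shape[1])
    E = E[:, start:]
    K, N = E.shape

    levels, counts = np.unique(E, return_counts=True)
    # per-run histograms on the common levels
    H = np.zeros((K, levels.size))
    for k in range(K):
        lv, ct = np.unique(E[k], return_counts=True)
        H[k, np.searchsorted(levels, lv)] = ct
    Ntot = H.sum(axis=0)  # = counts

    log_N = np.log(np.full(K, float(N)))
    log_f = np.zeros(K)
    bE = betas[:, None] * levels[None, :]  # (K, L)
    for it in range(max_iter):
        # log denominator: logsumexp_k [ log N_k + f_k - beta_k E ]
        log_den = logsumexp(log_N[:, None] + log_f[:, None] - bE, axis=0)
        log_g = np.log(Ntot) - log_den
        new_log_f = -logsumexp(log_g[None, :] - bE, axis=1)
        shift = new_log_f[0]
        new_log_f = new_log_f - shift  # fix the gauge
        resid = np.max(np.abs(new_log_f - log_f))
        log_f = new_log_f
        if resid < tol:
            break
    else:
        raise RuntimeError(f"WHAM did not converge: residual {resid:.3e} after {max_iter} iterations")
    return DensityOfStates(energies=levels, log_g=log_g, log_f=log_f)


def wham_specific_heat(
    trace: EnergyTrace,
    T_grid: np.ndarray,
    n_beads: int,
    tol: float = 1e-8,
    max_iter: int = 100000,
    burn_frac: float = 0.0,
) -> HeatCapacityCurve:
    """C_V / (N k_B) on a reduced-temperature grid by WHAM reweighting."""
    T_grid = np.asarray(T_grid, dtype=np.float64)
    dos = estimate_dos(trace, tol=tol, max_iter=max_iter, burn_frac=burn_frac)
    cv = np.empty_like(T_grid)
    me = np.empty_like(T_grid)
    for i, T in enumerate(T_grid):
        e1, e2 = dos.moments(T)
        cv[i] = (e2 - e1**2) / (n_beads * T**2)
        me[i] = e1
    return HeatCapacityCurve(temperatures=T_grid, cv=cv, mean_energy=me)


def fluctuation_specific_heat(energies: np.ndarray, T: float, n_beads: int) -> float:
    """Direct single-temperature estimator var(E) / (n T^2), the WHAM cross-check."""
    e = np.asarray(energies, dtype=np.float64)
    return float(np.var(e) / (n_beads * T**2))
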