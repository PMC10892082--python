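"""Canonical and replica-exchange Monte Carlo of the tangent-sphere chain.

The model is a chain of n hard spheres of diameter sigma whose bond length
is constrained to equal sigma (consecutive spheres touch), with a square-well
attraction of range R_att = 1.6 sigma and depth epsilon between all pairs of
non-adjacent monomers.  The total energy is -epsilon times the number of
pairs with |i - j| >= 2 within the well.

Sampling uses crankshaft, reptation (slithering snake), endpoint and pivot
moves, drawn with equal probabilities and accepted with the standard
Metropolis rule; hard-core violating candidates are always rejected, and at
infinite temperature every self-avoiding candidate is accepted.  Replica
exchange runs a ladder of temperatures in parallel and swaps neighbouring
replicas with probability min(1, exp(d_beta * dE)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .conformation import CA_BOND_LENGTH, Conformation

MOVE_TYPES = ("crankshaft", "reptation", "endpoint", "pivot")


@dataclass(frozen=True)
class SquareWellModel:
    """Tangent-sphere chain with square-well attraction.

    sigma is both the hard-sphere diameter and the bond length (Angstrom);
    the attraction range is fixed at 1.6 sigma and the well depth epsilon
    sets the energy unit.
    """

    sigma: float = CA_BOND_LENGTH
    epsilon: float = 1.0
    n: int = 80

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.n < 2:
            raise ValueError("need sigma > 0 and n >= 2")

    @property
    def r_att(self) -> float:
        return 1.6 * self.sigma

    @property
    def bond_length(self) -> float:
        return self.sigma

    def straight_chain(self) -> Conformation:
        """A fully extended chain along x (the all-zero-energy reference state)."""
        coords = np.zeros((self.n, 3))
        coords[:, 0] = np.arange(self.n) * self.sigma
        return Conformation(coords, bond_length=self.sigma)


def default_ladder_temperatures() -> np.ndarray:
    """The standard reduced-temperature meshes for the collapse study.

    Finer spacing where the specific heat varies fastest: 0.3-0.5 in steps
    of 0.02, 0.5-1.0 in steps of 0.05, 1.0-4.0 in steps of 0.2 (36 values).
    """
    return np.round(
        np.concatenate(
            [
                np.arange(0.30, 0.50, 0.02),
                np.arange(0.50, 1.00, 0.05),
                np.arange(1.00, 4.01, 0.20),
            ]
        ),
        10,
    )


@dataclass
class ReplicaLadder:
    """Ordered reduced temperatures and the sweep stride between swap attempts."""

    temperatures: np.ndarray = field(default_factory=default_ladder_temperatures)
    swap_stride: int = 100  # MC sweeps (steps per monomer) between swap attempts

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=np.float64)
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("ladder temperatures must be strictly increasing")
        if self.swap_stride < 1:
            raise ValueError("swap_stride must be >= 1")

    @property
    def n_replicas(self) -> int:
        return self.temperatures.size


@dataclass
class EnergyTrace:
    """Per-temperature energy series from a replica-exchange run.

    ``energies`` has shape (n_temperatures, n_records) in units of epsilon
    (non-positive integer multiples); ``stride`` is the number of sweeps
    between records.  ``swap_acceptance`` is the per-neighbour-pair swap
    acceptance fraction.
    """

    temperatures: np.ndarray
    energies: np.ndarray
    stride: int
    seed: int
    swap_acceptance: Optional[np.ndarray] = None
    move_acceptance: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# reference (pure NumPy) energy and moves: the oracle for the compiled kernels
# ---------------------------------------------------------------------------

def total_energy(conf: Conformation, model: SquareWellModel) -> float:
    """Total square-well energy in units of epsilon (a non-positive number).

    Counts pairs with |i - j| >= 2 within R_att; raises if the hard core is
    violated anywhere (relative tolerance 1e-9).
    """
    coords = conf.coords
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=2)
    dists = d[iu]
    if np.any(dists < model.sigma * (1.0 - 1e-9)):
        raise ValueError("hard-core overlap: infeasible conformation")
    return float(-model.epsilon * np.count_nonzero(dists <= model.r_att))


def _contact_count(conf: Conformation, model: SquareWellModel) -> int:
    return int(round(-total_energy(conf, model) / model.epsilon))


def has_overlap(conf: Conformation, sigma: float) -> bool:
    """True if any pair with |i - j| >= 2 is closer than sigma (1e-9 rel. tol.)."""
    return bool(_kernels.has_overlap(np.ascontiguousarray(conf.coords), sigma))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    q0, q1, q2, q3 = q
    return np.array(
        [
            [1 - 2 * (q2**2 + q3**2), 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
            [2 * (q1 * q2 + q0 * q3), 1 - 2 * (q1**2 + q3**2), 2 * (q2 * q3 - q0 * q1)],
            [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), 1 - 2 * (q1**2 + q2**2)],
        ]
    )


def propose_move(
    conf: Conformation, move_type: str, rng: np.random.Generator
) -> Conformation:
    """Candidate conformation from one trial move; bond lengths are preserved.

    Moves: ``crankshaft`` rotates one interior bead about the chord between
    its neighbours by a uniform angle; ``reptation`` removes a bead from one
    end and regrows it at the other in a uniform direction; ``endpoint``
    regrows an end bead in a uniform direction; ``pivot`` applies a uniform
    3D rotation to one side of a random interior bead.  Feasibility
    (self-avoidance) is not checked here; rejection happens in the
    acceptance step.
    """
    coords = conf.coords.copy()
    n, b = conf.n, conf.bond_length
    if move_type == "crankshaft":
        i = int(rng.integers(1, n - 1))
        axis = coords[i + 1] - coords[i - 1]
        norm = np.linalg.norm(axis)
        if norm < 1e-12:
            return Conformation(coords, b, conf.labels)
        axis /= norm
        ang = rng.uniform(-np.pi, np.pi)
        v = coords[i] - coords[i - 1]
        c, s = np.cos(ang), np.sin(ang)
        v_rot = v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)
        coords[i] = coords[i - 1] + v_rot
    elif move_type == "endpoint":
        end = n - 1 if rng.random() < 0.5 else 0
        nb = 1 if end == 0 else n - 2
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        coords[end] = coords[nb] + b * u
    elif move_type == "reptation":
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        if rng.random() < 0.5:
            coords = np.vstack([coords[1:], coords[-1] + b * u])
        else:
            coords = np.vstack([coords[0] + b * u, coords[:-1]])
    elif move_type == "pivot":
        i = int(rng.integers(1, n - 1))
        R = _random_rotation(rng)
        side = slice(0, i) if i <= n - 1 - i else slice(i + 1, n)
        coords[side] = (coords[side] - coords[i]) @ R.T + coords[i]
    else:
        raise ValueError(f"unknown move type {move_type!r}; choose from {MOVE_TYPES}")
    return Conformation(coords, b, conf.labels)


def metropolis_step(
    conf: Conformation,
    model: SquareWellModel,
    reduced_T: float,
    rng: np.random.Generator,
    move_type: Optional[str] = None,
) -> Tuple[Conformation, bool]:
    """One Metropolis move: propose, hard-core screen, accept/reject.

    ``reduced_T`` is k_B T / epsilon; ``np.inf`` accepts every self-avoiding
    candidate.  Returns the (possibly unchanged) conformation and a flag.
    """
    if not (reduced_T > 0):
        raise ValueError("reduced temperature must be positive (or inf)")
    if move_type is None:
        move_type = MOVE_TYPES[int(rng.integers(0, 4))]
    cand = propose_move(conf, move_type, rng)
    if has_overlap(cand, model.sigma):
        return conf, False
    if np.isinf(reduced_T):
        return cand, True
    dE = total_energy(cand, model) - total_energy(conf, model)
    if dE <= 0 or rng.random() < np.exp(-dE / (reduced_T * model.epsilon)):
        return cand, True
    return conf, False


# ---------------------------------------------------------------------------
# production drivers (compiled kernels)
# ---------------------------------------------------------------------------

def _run_batch(
    coords: np.ndarray,
    n_sweeps: int,
    beta_eps: float,
    model: SquareWellModel,
    seed: int,
    contacts0: int,
) -> Tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    energies = np.empty(n_sweeps, dtype=np.int64)
    acc = np.zeros(4, dtype=np.int64)
    att = np.zeros(4, dtype=np.int64)
    count = _kernels.run_sweeps(
        coords,
        n_sweeps,
        beta_eps,
        model.sigma,
        model.bond_length,
        model.r_att,
        seed,
        contacts0,
        energies,
        acc,
        att,
    )
    return int(count), energies, acc, att


def run_infinite_temperature(
    model: SquareWellModel,
    n_samples: int,
    seed: int,
    sample_stride: int = 20,
    burn_in: int = 2000,
) -> List[np.ndarray]:
    """Uniform sampling over self-avoiding tangent-chain conformations.

    Runs athermal Metropolis MC (every non-overlapping candidate accepted,
    pivot moves included for decorrelation) from a straight chain, discards
    ``burn_in`` sweeps, then records a snapshot every ``sample_stride``
    sweeps.  Returns a list of (n, 3) coordinate arrays.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 + n_samples)
    coords = np.ascontiguousarray(model.straight_chain().coords)
    _run_batch(coords, burn_in, 0.0, model, int(seeds[0] % 2**31), 0)
    samples = []
    for k in range(n_samples):
        _run_batch(coords, sample_stride, 0.0, model, int(seeds[k + 1] % 2**31), 0)
        samples.append(coords.copy())
    return samples


def run_replica_exchange(
    model: SquareWellModel,
    ladder: ReplicaLadder,
    n_sweeps: int,
    seed: int,
    burn_in: Optional[int] = None,
    snapshot_temperatures: Tuple[float, ...] = (),
    snapshot_stride: Optional[int] = None,
) -> Tuple[EnergyTrace, dict]:
    """Replica-exchange MC: per-temperature energy traces plus snapshots.

    Each replica runs ``ladder.swap_stride`` sweeps between neighbour-swap
    attempts (standard criterion min(1, exp(d_beta * dE)); even and odd
    neighbour pairs alternate).  Snapshots of the configurations at the
    requested temperatures are collected every ``snapshot_stride`` sweeps
    after ``burn_in`` (default: a quarter of the run).

    Returns the :class:`EnergyTrace` (one energy record per sweep per
    temperature, in epsilon units) and a dict mapping each snapshot
    temperature to a list of (n, 3) arrays.
    """
    if burn_in is None:
        burn_in = n_sweeps // 4
    if snapshot_stride is None:
        snapshot_stride = ladder.swap_stride
    M = ladder.n_replicas
    betas = 1.0 / ladder.temperatures
    rng = np.random.default_rng(seed)

    coords = np.stack([model.straight_chain().coords for _ in range(M)])
    coords = np.ascontiguousarray(coords)
    counts = np.zeros(M, dtype=np.int64)

    n_blocks = max(1, n_sweeps // ladder.swap_stride)
    energies = np.empty((M, n_blocks * ladder.swap_stride), dtype=np.float64)
    swap_att = np.zeros(M - 1, dtype=np.int64)
    swap_acc = np.zeros(M - 1, dtype=np.int64)
    move_acc = np.zeros(4, dtype=np.int64)
    move_att = np.zeros(4, dtype=np.int64)

    snap_idx = {float(T): int(np.argmin(np.abs(ladder.temperatures - T))) for T in snapshot_temperatures}
    snapshots: dict = {T: [] for T in snap_idx}

    sweep_done = 0
    for block in range(n_blocks):
        for m in range(M):
            kseed = int(rng.integers(0, 2**31 - 1))
            c, e, acc, att = _run_batch(
                coords[m], ladder.swap_stride, betas[m] * model.epsilon, model, kseed, int(counts[m])
            )
            counts[m] = c
            energies[m, sweep_done : sweep_done + ladder.swap_stride] = -model.epsilon * e
            move_acc += acc
            move_att += att
        sweep_done += ladder.swap_stride
        # alternate even / odd neighbour pairs
        for pair in range(block % 2, M - 1, 2):
            a, b_ = pair, pair + 1
            swap_att[pair] += 1
            d_beta = betas[a] - betas[b_]
            dE = -model.epsilon * (counts[a] - counts[b_])
            if d_beta * dE >= 0 or rng.random() < np.exp(d_beta * dE):
                coords[[a, b_]] = coords[[b_, a]]
                counts[[a, b_]] = counts[[b_, a]]
                swap_acc[pair] += 1
        if sweep_done > burn_in and sweep_done % snapshot_stride == 0:
            for T, m in snap_idx.items():
                snapshots[T].append(coords[m].copy())

    with np.errstate(invalid="ignore"):
        swap_frac = np.where(swap_att > 0, swap_acc / np.maximum(swap_att, 1), np.nan)
    if M > 1 and np.any(swap_frac[swap_att > 0] < 1e-3):
        warnings.warn(
            "some neighbour swap acceptances are ~0: energy histograms of "
            "adjacent replicas may not overlap; refine the ladder"
        )

    trace = EnergyTrace(
        temperatures=ladder.temperatures.copy(),
        energies=energies,
        stride=1,
        seed=seed,
        swap_acceptance=swap_frac,
        move_acceptance=np.where(move_att > 0, move_acc / np.maximum(move_att, 1), np.nan),
    )
    return trace, snapshots
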