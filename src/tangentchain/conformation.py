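"""Core data containers shared by the geometry, simulation and IO layers."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Mean distance between consecutive C-alpha atoms of a trans peptide (Angstrom).
CA_BOND_LENGTH = 3.81

VALID_LABELS = ("alpha", "beta", "loop", "none")


@dataclass
class Conformation:
    """An ordered chain of points in d-dimensional space.

    Parameters
    ----------
    coords : ndarray, shape (n, d)
        Monomer (or C-alpha) positions in Angstrom.  d is usually 3 but the
        random-walk generators can produce chains in any dimension >= 2.
    bond_length : float
        Nominal distance between consecutive points, in Angstrom.
    labels : sequence of str, optional
        Per-monomer structural class, each one of ``alpha``, ``beta``,
        ``loop`` or ``none``.
    fixed_bonds : bool
        When True the constructor asserts that every consecutive pair is at
        distance ``bond_length`` to within relative tolerance 1e-9.
    """

    coords: np.ndarray
    bond_length: float = CA_BOND_LENGTH
    labels: Optional[np.ndarray] = None
    fixed_bonds: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[0] < 2:
            raise ValueError("coords must be an (n, d) array with n >= 2")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.coords):
                raise ValueError(
                    f"labels length {len(self.labels)} != chain length {len(self.coords)}"
                )
            bad = set(self.labels) - set(VALID_LABELS)
            if bad:
                raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.fixed_bonds:
            lens = self.bond_lengths()
            rel = np.abs(lens - self.bond_length) / self.bond_length
            if rel.max() > 1e-9:
                raise ValueError(
                    f"bond length deviates by relative {rel.max():.3g} "
                    f"(> 1e-9) from {self.bond_length}"
                )

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def bond_lengths(self) -> np.ndarray:
        """Distances between consecutive points, shape (n-1,)."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)

    def with_labels(self, labels: Sequence[str]) -> "Conformation":
        return Conformation(self.coords.copy(), self.bond_length, np.asarray(labels, dtype=object))


@dataclass(frozen=True)
class AngleFrame:
    """A (bond-bending, dihedral) angle pair at one interior chain position.

    ``theta`` is the angle at a monomer between its two adjacent bonds in
    degrees; 180 means locally straight.  ``mu`` is the torsion of the four
    consecutive monomers starting one position earlier, signed, in
    (-180, 180]; NaN when the torsion is undefined (collinear triplet).
    """

    index: int
    theta: float
    mu: float


@dataclass(frozen=True)
class RadiusSample:
    """Radius of the circle (order 3) or sphere (order 4) through a point set.

    ``R`` is infinite for collinear triplets / coplanar quartets; ``X = 1/R``
    is then exactly 0.
    """

    R: float
    order: int

    @property
    def X(self) -> float:
        return 0.0 if np.isinf(self.R) else 1.0 / self.R

    @property
    def is_infinite(self) -> bool:
        return bool(np.isinf(self.R))


@dataclass(frozen=True)
class ContactRecord:
    """Nearest non-local partner of monomer ``i``.

    ``j`` minimises the Euclidean distance over all monomers with
    ``|i - j| >= min_sep`` (ties broken to the smallest j).  ``near_flag``
    marks contacts within the distance threshold (6 Angstrom by default,
    where the protein radial distribution function has a minimum).
    """

    i: int
    j: int
    distance: float
    near_flag: bool = False

    @property
    def separation(self) -> int:
        return abs(self.i - self.j)


@dataclass
class CdfTable:
    """Empirical cumulative distribution of inverse radii X = 1/R.

    ``x`` is sorted ascending and ``p`` holds P(1/r <= x) = i/n.  Samples
    with infinite R enter at X = 0.  ``bond_length`` is carried along so the
    dimensionless product Xb can be formed when fitting power laws.
    """

    x: np.ndarray
    p: np.ndarray
    n_samples: int
    bond_length: Optional[float] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.x.shape != self.p.shape:
            raise ValueError("x and p must have the same shape")
        if np.any(np.diff(self.p) < 0) or self.p[0] < 0 or self.p[-1] > 1 + 1e-12:
            raise ValueError("cumulative probabilities must be nondecreasing in [0, 1]")
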