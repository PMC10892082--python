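"""Generators for chain fixtures and random-walk ensembles.

Everything needed to exercise the geometry pipeline without external data:
d-dimensional fixed-bond random walks (plain, self-avoiding, and
plane-constrained), uniform points in a ball, and ideal secondary-structure
C-alpha traces (alpha helix, beta sheet, mixed chains) carrying ground-truth
class labels.

The helix defaults (1.5 A rise, 2.3 A radius, 100 deg twist per residue) are
the canonical alpha-helix C-alpha parameters; they imply a bond length of
about 3.83 A and a bending angle near 92 deg, matching the geometry of real
helical residues.  Sheet strands are planar zigzags with a 120 deg bending
angle; the default 4.8 A inter-strand spacing places cross-strand nearest
contacts in the hydrogen-bonded beta range, comfortably below the 6 A
contact threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .conformation import CA_BOND_LENGTH, Conformation
from .theory import WalkSpec


# ---------------------------------------------------------------------------
# random directions and walks
# ---------------------------------------------------------------------------

def _uniform_directions(n: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """n unit vectors uniform on the (d-1)-sphere (normalised Gaussians)."""
    v = rng.standard_normal((n, d))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_walk_batch(spec: WalkSpec, n_walks: int, rng: np.random.Generator) -> np.ndarray:
    """Stacked fixed-bond random walks, shape (n_walks, n_steps+1, d).

    Each step is an independent uniformly random direction of length b; no
    self-avoidance.  The first point is at the origin.
    """
    steps = spec.b * _uniform_directions(n_walks * spec.n_steps, spec.d, rng).reshape(
        n_walks, spec.n_steps, spec.d
    )
    pts = np.zeros((n_walks, spec.n_steps + 1, spec.d))
    pts[:, 1:, :] = np.cumsum(steps, axis=1)
    return pts


def random_walk(spec: WalkSpec, rng: np.random.Generator) -> Conformation:
    """A single fixed-bond random walk as a Conformation (coords in d dims)."""
    coords = random_walk_batch(spec, 1, rng)[0]
    return Conformation(coords, bond_length=spec.b)


def self_avoiding_segment_batch(
    spec: WalkSpec, sigma: float, n_walks: int, rng: np.random.Generator
) -> Tuple[np.ndarray, float]:
    """Short tangent-sphere walks with all pairwise distances >= sigma.

    Rejection sampling on top of :func:`random_walk_batch`; returns the
    accepted walks (exactly ``n_walks`` of them) and the acceptance fraction.
    """
    if abs(sigma - spec.b) > 1e-9 * spec.b:
        raise ValueError("tangent-sphere walks require sigma == bond length")
    accepted: List[np.ndarray] = []
    n_drawn = 0
    n_kept = 0
    while n_kept < n_walks:
        batch = random_walk_batch(spec, max(n_walks, 10000), rng)
        n_drawn += batch.shape[0]
        ok = np.ones(batch.shape[0], dtype=bool)
        npts = spec.n_steps + 1
        for i in range(npts):
            for j in range(i + 2, npts):
                dij = np.linalg.norm(batch[:, i] - batch[:, j], axis=1)
                ok &= dij >= sigma
        kept = batch[ok]
        accepted.append(kept)
        n_kept += kept.shape[0]
    out = np.concatenate(accepted)[:n_walks]
    return out, n_kept / n_drawn


def self_avoiding_segment(spec: WalkSpec, sigma: float, rng: np.random.Generator) -> Conformation:
    """A single short self-avoiding tangent-sphere walk."""
    coords, _ = self_avoiding_segment_batch(spec, sigma, 1, rng)
    return Conformation(coords[0], bond_length=spec.b)


def constrained_random_walk_batch(
    b: float, n_walks: int, rng: np.random.Generator
) -> np.ndarray:
    """Four-point walks whose first two steps are planar, shape (n_walks, 4, 3).

    The first two points lie along the x axis, the third is placed at a
    uniformly random in-plane angle in the x-y plane, and the final step is a
    uniformly random direction in full 3D.  The effective sampling dimension
    of the quartet then sits between 2 and 3, which flattens the power law of
    the inverse circumsphere-radius CDF relative to the plain 3D walk.
    """
    pts = np.zeros((n_walks, 4, 3))
    pts[:, 1, 0] = b
    phi = rng.uniform(0.0, 2.0 * np.pi, n_walks)
    pts[:, 2, 0] = b + b * np.cos(phi)
    pts[:, 2, 1] = b * np.sin(phi)
    pts[:, 3, :] = pts[:, 2, :] + b * _uniform_directions(n_walks, 3, rng)
    return pts


def constrained_random_walk(b: float, rng: np.random.Generator) -> Conformation:
    """A single 4-point constrained walk (first two steps planar)."""
    return Conformation(constrained_random_walk_batch(b, 1, rng)[0], bond_length=b)


def uniform_ball_points(
    n_points: int, radius: float, rng: np.random.Generator, d: int = 3
) -> np.ndarray:
    """Independent uniform points inside a d-ball, via the radial inverse CDF."""
    if n_points < 1:
        raise ValueError("need at least one point")
    dirs = _uniform_directions(n_points, d, rng)
    r = radius * rng.uniform(0.0, 1.0, n_points) ** (1.0 / d)
    return dirs * r[:, None]


# ---------------------------------------------------------------------------
# ideal secondary-structure traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixParams:
    """Regular helix of C-alpha positions: rise/residue, radius, twist/residue."""

    rise: float = 1.5  # Angstrom per residue
    radius: float = 2.3  # Angstrom
    twist: float = 100.0  # degrees per residue
    n: int = 30

    @property
    def bond_length(self) -> float:
        w = np.radians(self.twist)
        return float(np.sqrt(2.0 * self.radius**2 * (1.0 - np.cos(w)) + self.rise**2))


@dataclass(frozen=True)
class SheetParams:
    """Planar zigzag strands laid side by side with a bridging turn."""

    zigzag_angle: float = 120.0  # bending angle theta at strand interior, degrees
    spacing: float = 4.8  # inter-strand spacing, Angstrom
    topology: str = "antiparallel"  # or "parallel"
    strand_lengths: Tuple[int, ...] = (8, 8)
    bond_length: float = CA_BOND_LENGTH

    def __post_init__(self) -> None:
        if self.topology not in ("parallel", "antiparallel"):
            raise ValueError("topology must be 'parallel' or 'antiparallel'")
        if any(s < 3 for s in self.strand_lengths):
            raise ValueError("strands need at least 3 residues")


def ideal_alpha_helix(params: HelixParams = HelixParams()) -> Conformation:
    """Ideal alpha-helix C-alpha trace, all residues labelled ``alpha``.

    With the default parameters the implied bond length is ~3.83 A and the
    per-residue bending angle theta is ~91.8 deg.
    """
    k = np.arange(params.n)
    w = np.radians(params.twist)
    coords = np.column_stack(
        [params.radius * np.cos(k * w), params.radius * np.sin(k * w), params.rise * k]
    )
    labels = np.full(params.n, "alpha", dtype=object)
    return Conformation(coords, bond_length=params.bond_length, labels=labels)


def _zigzag_strand(n: int, b: float, theta_deg: float) -> np.ndarray:
    """Planar zigzag of n points in the x-y plane with bending angle theta."""
    half = np.radians(theta_deg) / 2.0
    s, c = b * np.sin(half), b * np.cos(half)
    k = np.arange(n)
    return np.column_stack([k * s, (k % 2) * c, np.zeros(n)])


def _bridge(p: np.ndarray, q: np.ndarray, b: float) -> np.ndarray:
    """Intermediate beads connecting p to q with every bond exactly b.

    Walks straight toward q in steps of b and finishes with a two-bond
    elbow: the last intermediate bead sits at distance b from both its
    predecessor and q (circle-intersection construction).
    """
    dist = float(np.linalg.norm(q - p))
    if dist <= 1e-9:
        raise ValueError("cannot bridge coincident points")
    m = max(2, int(np.ceil(dist / b)))  # bonds in the bridge; leaves a gap in (0, 2b]
    u = (q - p) / dist
    beads = [p + u * b * k for k in range(1, m - 1)]
    prev = beads[-1] if beads else p
    gap = float(np.linalg.norm(q - prev))
    if gap > 2.0 * b:
        raise ValueError("bridge construction failed (gap too large)")
    mid = 0.5 * (prev + q)
    h = np.sqrt(max(b**2 - (gap / 2.0) ** 2, 0.0))
    axis = (q - prev) / gap
    perp = np.cross(axis, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(perp) < 1e-9:
        perp = np.cross(axis, np.array([0.0, 1.0, 0.0]))
    perp /= np.linalg.norm(perp)
    beads.append(mid + h * perp)
    return np.array(beads)


def _turn_path(p: np.ndarray, q: np.ndarray, b: float) -> np.ndarray:
    """Turn beads from p to q; long turns detour through an out-of-plane waypoint.

    Short gaps (within two bonds) use the direct elbow.  Longer gaps -- the
    parallel-sheet return path -- would cut straight through the sheet, so
    the path detours through a waypoint displaced perpendicular to the sheet
    plane, keeping every bond exactly b.
    """
    dist = float(np.linalg.norm(q - p))
    if dist <= 2.0 * b:
        return _bridge(p, q, b)
    w = 0.5 * (p + q) + np.array([0.0, -2.5 * b, 0.0])
    return np.concatenate([_bridge(p, w, b), [w], _bridge(w, q, b)])


def ideal_beta_sheet(params: SheetParams = SheetParams()) -> Conformation:
    """Zigzag strands stacked at the given spacing, joined by loop-labelled turns.

    Antiparallel topology reverses every other strand so cross-strand nearest
    contacts run perpendicular to the contact-map diagonal (i + j roughly
    constant); parallel strands give contacts at roughly constant j - i >= 4.
    """
    b = params.bond_length
    coords_parts: List[np.ndarray] = []
    label_parts: List[np.ndarray] = []
    for s_idx, s_len in enumerate(params.strand_lengths):
        strand = _zigzag_strand(s_len, b, params.zigzag_angle)
        if params.topology == "antiparallel" and s_idx % 2 == 1:
            strand = strand[::-1].copy()
        strand[:, 2] += s_idx * params.spacing
        if coords_parts:
            prev_end = coords_parts[-1][-1]
            turn = _turn_path(prev_end, strand[0], b)
            coords_parts.append(turn)
            label_parts.append(np.full(len(turn), "loop", dtype=object))
        coords_parts.append(strand)
        label_parts.append(np.full(s_len, "beta", dtype=object))
    coords = np.concatenate(coords_parts)
    labels = np.concatenate(label_parts)
    return Conformation(coords, bond_length=b, labels=labels)


def compose_labeled_chain(
    segments: Sequence[Conformation],
    jitter_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> Conformation:
    """Concatenate labelled segments into one chain, optionally with jitter.

    Each subsequent segment is rigidly translated so that its first point
    continues the previous segment's final bond direction at distance b, so
    all internal and junction bonds stay at the nominal length.  Gaussian
    coordinate noise with standard deviation ``jitter_sd`` (A) is added last;
    jitter 0 reproduces the segment geometries exactly.
    """
    if not segments:
        raise ValueError("no segments")
    b = segments[0].bond_length
    coords = [segments[0].coords.copy()]
    labels = [
        segments[0].labels
        if segments[0].labels is not None
        else np.full(segments[0].n, "none", dtype=object)
    ]
    for seg in segments[1:]:
        # ideal-geometry segments may imply slightly different bond lengths
        # (e.g. the canonical helix gives 3.83 vs 3.81); tolerate up to 0.05 A
        if abs(seg.bond_length - b) > 0.05:
            raise ValueError("segments disagree on bond length")
        prev = coords[-1]
        direction = prev[-1] - prev[-2]
        direction = direction / np.linalg.norm(direction)
        anchor = prev[-1] + b * direction
        shifted = seg.coords - seg.coords[0] + anchor
        coords.append(shifted)
        labels.append(
            seg.labels if seg.labels is not None else np.full(seg.n, "none", dtype=object)
        )
    out = np.concatenate(coords)
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        out = out + rng.normal(0.0, jitter_sd, out.shape)
    return Conformation(out, bond_length=b, labels=np.concatenate(labels))
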