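"""Geometric kernels for chain analysis.

Bond-bending and dihedral angles, three-body (circumcircle) and four-body
(circumsphere) radii, inverse-radius cumulative distributions with power-law
slope fitting, nearest non-local contact maps and the characteristic
local/non-local length scales of a chain.

Conventions
-----------
* Angles are degrees externally, radians internally.  The bond-bending angle
  theta is measured at the middle point of a triplet, so a locally straight
  chain has theta = 180 deg.  Hard-sphere tangency forbids theta < 60 deg.
* The dihedral mu is signed, right-handed about the p2 -> p3 axis, in
  (-180, 180].  Coplanar quartets give 0 (cis) or +/-180 (trans).
* A triplet is flagged collinear (infinite circle radius, X = 0) when
  4A/(abc) < 1e-12 per Angstrom; a quartet is flagged coplanar when the
  equidistant-centre linear system is singular at the analogous relative
  threshold.
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .conformation import AngleFrame, CdfTable, Conformation, ContactRecord, RadiusSample

COLLINEARITY_TOL = 1e-12  # on 4A/(abc), units 1/Angstrom
_DEG = 180.0 / np.pi


# ---------------------------------------------------------------------------
# angles
# ---------------------------------------------------------------------------

def bond_bending_angle(p1, p2, p3) -> np.ndarray | float:
    """Bond-bending angle theta at vertex ``p2``, in degrees in (0, 180].

    Accepts single points or stacked arrays of shape (..., d).  Collinear
    extended triplets give exactly 180.
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident points: bond-bending angle undefined")
    cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang if ang.ndim else float(ang)


def dihedral_angle(p1, p2, p3, p4) -> np.ndarray | float:
    """Signed dihedral mu of four consecutive points, degrees in (-180, 180].

    Computed from the successive binormals b1 x b2 and b2 x b3 of the three
    bond vectors, with the sign taken right-handed about the p2 -> p3 axis.
    Raises if an interior triplet is collinear (undefined binormal).
    """
    mu = _dihedral_raw(p1, p2, p3, p4)
    if np.any(np.isnan(mu)):
        raise ValueError("collinear interior triplet: binormal undefined")
    return mu if np.ndim(mu) else float(mu)


def _dihedral_raw(p1, p2, p3, p4) -> np.ndarray:
    """Vectorised dihedral; NaN where a binormal vanishes."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    # atan2 formulation is stable near 0 and 180
    b2n = np.linalg.norm(b2, axis=-1)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", np.cross(n1, n2), b2) / np.where(b2n == 0, 1.0, b2n)
    mu = np.degrees(np.arctan2(y, x))
    scale = np.linalg.norm(b1, axis=-1) * b2n ** 2 * np.linalg.norm(b3, axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) <= 1e-12 * scale) | (
        np.linalg.norm(n2, axis=-1) <= 1e-12 * scale
    )
    mu = np.where(bad, np.nan, mu)
    # map -180 -> 180 so the range is (-180, 180]
    mu = np.where(mu <= -180.0 + 1e-12, 180.0, mu)
    return mu


# ---------------------------------------------------------------------------
# circumradius / circumsphere
# ---------------------------------------------------------------------------

def triplet_circumradii(p1, p2, p3) -> np.ndarray:
    """Circumcircle radii R = abc/(4A) for stacked triplets, any dimension.

    The area uses the Gram form A = sqrt(|u|^2 |v|^2 - (u.v)^2)/2, valid in
    any dimension.  Collinear triplets (4A/(abc) below tolerance) give inf.
    """
    p1, p2, p3 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3))
    a = np.linalg.norm(p2 - p3, axis=-1)
    b = np.linalg.norm(p1 - p3, axis=-1)
    c = np.linalg.norm(p1 - p2, axis=-1)
    if np.any(a == 0) or np.any(b == 0) or np.any(c == 0):
        raise ValueError("coincident points in triplet")
    u = p2 - p1
    v = p3 - p1
    gram = np.einsum("...i,...i->...", u, u) * np.einsum("...i,...i->...", v, v) - (
        np.einsum("...i,...i->...", u, v) ** 2
    )
    area4 = 2.0 * np.sqrt(np.maximum(gram, 0.0))  # = 4A
    abc = a * b * c
    with np.errstate(divide="ignore"):
        R = np.where(area4 / abc < COLLINEARITY_TOL, np.inf, abc / np.where(area4 == 0, 1.0, area4))
    return R


def circumradius_triplet(p1, p2, p3) -> RadiusSample:
    """Radius of the circle through three points as a :class:`RadiusSample`."""
    R = triplet_circumradii(p1, p2, p3)
    return RadiusSample(R=float(R), order=3)


def quartet_circumsphere_radii(
    p1, p2, p3, p4, return_centers: bool = False
) -> np.ndarray | Tuple[np.ndarray, np.ndarray]:
    """Circumsphere radii for stacked quartets of 3D points.

    The centre c is equidistant from all four points, hence solves the 3x3
    linear system 2(p_i - p_1) . c = |p_i|^2 - |p_1|^2 for i = 2, 3, 4
    (Cramer's rule, vectorised).  Coplanar quartets make the system singular
    and are flagged with R = inf.
    """
    p1, p2, p3, p4 = (np.atleast_2d(np.asarray(p, dtype=np.float64)) for p in (p1, p2, p3, p4))
    pts = np.stack([p1, p2, p3, p4], axis=-2)  # (..., 4, 3)
    diff = pts[..., 1:, :] - pts[..., :1, :]  # rows of A/2, (..., 3, 3)
    A = 2.0 * diff
    sq = np.einsum("...ij,...ij->...i", pts, pts)
    rhs = sq[..., 1:] - sq[..., :1]

    m = A
    det = (
        m[..., 0, 0] * (m[..., 1, 1] * m[..., 2, 2] - m[..., 1, 2] * m[..., 2, 1])
        - m[..., 0, 1] * (m[..., 1, 0] * m[..., 2, 2] - m[..., 1, 2] * m[..., 2, 0])
        + m[..., 0, 2] * (m[..., 1, 0] * m[..., 2, 1] - m[..., 1, 1] * m[..., 2, 0])
    )
    row_norm = np.linalg.norm(m, axis=-1)  # (..., 3)
    scale = np.prod(np.where(row_norm == 0, 1.0, row_norm), axis=-1)
    singular = np.abs(det) < COLLINEARITY_TOL * scale

    safe_det = np.where(singular, 1.0, det)
    center = np.empty(m.shape[:-2] + (3,))
    for k in range(3):
        mk = m.copy()
        mk[..., :, k] = rhs
        det_k = (
            mk[..., 0, 0] * (mk[..., 1, 1] * mk[..., 2, 2] - mk[..., 1, 2] * mk[..., 2, 1])
            - mk[..., 0, 1] * (mk[..., 1, 0] * mk[..., 2, 2] - mk[..., 1, 2] * mk[..., 2, 0])
            + mk[..., 0, 2] * (mk[..., 1, 0] * mk[..., 2, 1] - mk[..., 1, 1] * mk[..., 2, 0])
        )
        center[..., k] = det_k / safe_det
    R = np.linalg.norm(center - pts[..., 0, :], axis=-1)
    R = np.where(singular, np.inf, R)
    R = R[0] if R.shape == (1,) else R
    if return_centers:
        return R, center
    return R


def circumsphere_radius_quartet(p1, p2, p3, p4) -> RadiusSample:
    """Radius of the unique sphere through four 3D points."""
    for q, r in ((p1, p2), (p1, p3), (p1, p4), (p2, p3), (p2, p4), (p3, p4)):
        if np.allclose(q, r):
            raise ValueError("coincident points in quartet")
    R = quartet_circumsphere_radii(p1, p2, p3, p4)
    return RadiusSample(R=float(R), order=4)


def local_radius_from_theta(theta, b: float) -> np.ndarray | float:
    """Local radius of curvature R = b / (2 cos(theta/2)).

    ``theta`` in degrees in (0, 180]; a straight triplet (theta = 180) has
    infinite local radius.
    """
    theta = np.asarray(theta, dtype=np.float64)
    if b <= 0:
        raise ValueError("bond length must be positive")
    if np.any(theta <= 0) or np.any(theta > 180):
        raise ValueError("theta must lie in (0, 180] degrees")
    c = np.cos(np.radians(theta) / 2.0)
    straight = c < 1e-12  # cos(pi/2) is ~6e-17 in floating point, not 0
    with np.errstate(divide="ignore"):
        R = np.where(straight, np.inf, b / (2.0 * np.where(straight, 1.0, c)))
    return R if R.ndim else float(R)


# ---------------------------------------------------------------------------
# per-chain angle and radius series
# ---------------------------------------------------------------------------

def chain_thetas(coords: np.ndarray) -> np.ndarray:
    """Bond-bending angles at interior positions 1..n-2, degrees, shape (n-2,)."""
    coords = np.asarray(coords, dtype=np.float64)
    return np.atleast_1d(bond_bending_angle(coords[:-2], coords[1:-1], coords[2:]))


def chain_mus(coords: np.ndarray) -> np.ndarray:
    """Dihedrals of consecutive quartets, degrees, shape (n-3,); NaN where undefined."""
    coords = np.asarray(coords, dtype=np.float64)
    return np.atleast_1d(_dihedral_raw(coords[:-3], coords[1:-2], coords[2:-1], coords[3:]))


def theta_mu_map(conf: Conformation) -> List[AngleFrame]:
    """(theta, mu) pairs along a chain, one per interior position.

    Frame k (k = 0..n-4) pairs the bending angle at monomer k+1 with the
    torsion of the quartet (k, k+1, k+2, k+3); mu is NaN where the torsion
    is undefined (e.g. a perfectly straight stretch).
    """
    if conf.n < 4:
        raise ValueError("theta_mu_map needs a chain of at least 4 points")
    thetas = chain_thetas(conf.coords)[: conf.n - 3]
    mus = chain_mus(conf.coords)
    return [AngleFrame(index=k + 1, theta=float(t), mu=float(m)) for k, (t, m) in enumerate(zip(thetas, mus))]


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def nearest_nonlocal_distances(coords: np.ndarray, min_sep: int = 3) -> Tuple[np.ndarray, np.ndarray]:
    """Per-monomer nearest admissible partner: (j indices, distances).

    For each i, j minimises the Euclidean distance subject to |i - j| >=
    min_sep; ties go to the smallest j.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    D = cdist(coords, coords)
    idx = np.arange(n)
    D[np.abs(idx[:, None] - idx[None, :]) < min_sep] = np.inf
    j = np.argmin(D, axis=1)  # argmin returns the first (smallest) index on ties
    return j, D[idx, j]


def nearest_nonlocal_contact(conf: Conformation, min_sep: int = 3) -> List[ContactRecord]:
    """Nearest non-local contact of every monomer (|i - j| >= min_sep).

    Monomers of very short chains that admit no partner at all (possible
    only when n < 2 * min_sep) are omitted from the result.
    """
    if conf.n <= min_sep:
        warnings.warn(f"chain of length {conf.n} admits no pairs with |i-j| >= {min_sep}")
        return []
    j, d = nearest_nonlocal_distances(conf.coords, min_sep)
    return [
        ContactRecord(i=int(i), j=int(jj), distance=float(dd))
        for i, (jj, dd) in enumerate(zip(j, d))
        if np.isfinite(dd)
    ]


def contact_map(conf: Conformation, threshold: float = 6.0, min_sep: int = 3) -> List[ContactRecord]:
    """Nearest non-local contacts flagged near (<= threshold) or far."""
    return [
        ContactRecord(r.i, r.j, r.distance, near_flag=r.distance <= threshold)
        for r in nearest_nonlocal_contact(conf, min_sep)
    ]


# ---------------------------------------------------------------------------
# inverse-radius CDF and power-law slope
# ---------------------------------------------------------------------------

def inverse_radius_cdf(
    samples: Iterable[RadiusSample] | np.ndarray, bond_length: Optional[float] = None
) -> CdfTable:
    """Empirical CDF of X = 1/R.

    Accepts either RadiusSample objects or a plain array of radii (may
    contain inf); infinite radii enter at X = 0.
    """
    if isinstance(samples, np.ndarray):
        R = samples.astype(np.float64)
    else:
        samples = list(samples)
        if samples and isinstance(samples[0], RadiusSample):
            R = np.array([s.R for s in samples], dtype=np.float64)
        else:
            R = np.asarray(samples, dtype=np.float64)
    if R.size == 0:
        raise ValueError("no radius samples")
    with np.errstate(divide="ignore"):
        X = np.where(np.isinf(R), 0.0, 1.0 / R)
    X = np.sort(X)
    p = np.arange(1, X.size + 1, dtype=np.float64) / X.size
    return CdfTable(x=X, p=p, n_samples=X.size, bond_length=bond_length)


def fit_loglog_slope(
    cdf: CdfTable,
    fit_window: Optional[Tuple[float, float]] = None,
    xb_window: Tuple[float, float] = (0.05, 0.5),
) -> float:
    """Least-squares slope of log P versus log X over a window of X.

    ``fit_window`` is an explicit (X_lo, X_hi) range; when omitted the
    window is the asymptotic small-Xb regime Xb in [0.05, 0.5], which
    requires ``cdf.bond_length``.  At least 10 CDF points with X > 0 and
    P > 0 must fall inside the window.
    """
    if fit_window is None:
        if cdf.bond_length is None:
            raise ValueError("xb-based default window needs cdf.bond_length")
        fit_window = (xb_window[0] / cdf.bond_length, xb_window[1] / cdf.bond_length)
    lo, hi = fit_window
    mask = (cdf.x >= lo) & (cdf.x <= hi) & (cdf.x > 0) & (cdf.p > 0)
    if mask.sum() < 10:
        raise ValueError(f"only {int(mask.sum())} CDF points in the fit window; need >= 10")
    slope, _ = np.polyfit(np.log(cdf.x[mask]), np.log(cdf.p[mask]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# characteristic length scales
# ---------------------------------------------------------------------------

def histogram_mode(values: np.ndarray, bin_width: float, vmax: Optional[float] = None) -> float:
    """Mode of a histogram with fixed-width bins anchored at 0.

    Returns the centre of the most populated bin.  Infinite/NaN values and
    values beyond ``vmax`` (tail, irrelevant for the mode) are ignored.
    """
    v = np.asarray(values, dtype=np.float64)
    v = v[np.isfinite(v)]
    if vmax is not None:
        v = v[v <= vmax]
    if v.size == 0:
        raise ValueError("no finite values to histogram")
    lo = np.floor(v.min() / bin_width) * bin_width
    edges = np.arange(lo, v.max() + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, edges = np.histogram(v, bins=edges)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


def pure_triplet_mask(labels: np.ndarray, class_name: str) -> np.ndarray:
    """True at interior positions whose triplet has all three labels == class_name."""
    lab = np.asarray(labels, dtype=object)
    same = (lab[:-2] == class_name) & (lab[1:-1] == class_name) & (lab[2:] == class_name)
    return same


def collect_local_radii(
    confs: Sequence[Conformation], class_filter: Optional[str] = None
) -> np.ndarray:
    """Local radii b/(2 cos(theta/2)) over all interior triplets of many chains.

    With a class filter, only pure triplets -- all three monomers in the same
    structural class -- contribute.
    """
    out = []
    for conf in confs:
        thetas = chain_thetas(conf.coords)
        if class_filter is not None:
            if conf.labels is None:
                raise ValueError("class filter requested but conformation has no labels")
            thetas = thetas[pure_triplet_mask(conf.labels, class_filter)]
        if thetas.size:
            out.append(local_radius_from_theta(thetas, conf.bond_length))
    if not out:
        raise ValueError(f"no triplets for class {class_filter!r}")
    return np.concatenate([np.atleast_1d(o) for o in out])


def collect_nonlocal_distances(
    confs: Sequence[Conformation], class_filter: Optional[str] = None, min_sep: int = 3
) -> np.ndarray:
    """Nearest non-local contact distances over many chains (optionally one class)."""
    out = []
    for conf in confs:
        _, d = nearest_nonlocal_distances(conf.coords, min_sep)
        if class_filter is not None:
            if conf.labels is None:
                raise ValueError("class filter requested but conformation has no labels")
            d = d[np.asarray(conf.labels, dtype=object) == class_filter]
        if d.size:
            out.append(d[np.isfinite(d)])
    if not out:
        raise ValueError(f"no contacts for class {class_filter!r}")
    return np.concatenate(out)


def length_scale_modes(
    confs: Sequence[Conformation],
    class_filter: Optional[str] = None,
    local_bin: float = 0.02,
    nonlocal_bin: float = 0.04,
    min_sep: int = 3,
    local_max: float = 30.0,
) -> Tuple[float, float]:
    """Characteristic (local, non-local) length scales of an ensemble, Angstrom.

    The local scale is the histogram mode of the local radius of curvature
    over interior triplets (0.02 A bins); the non-local scale is the mode of
    the nearest non-local contact distance (0.04 A bins).  ``local_max``
    truncates the long near-straight tail, which cannot hold the mode.
    """
    radii = collect_local_radii(confs, class_filter)
    dists = collect_nonlocal_distances(confs, class_filter, min_sep)
    return (
        histogram_mode(radii, local_bin, vmax=local_max),
        histogram_mode(dists, nonlocal_bin),
    )


def scaled_profile(
    conf: Conformation,
    local_scales: dict | float,
    nonlocal_scales: dict | float,
    min_sep: int = 3,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-monomer local radius and nearest non-local distance, each scaled.

    Scales may be single numbers or per-class dicts (requires labels).
    Returns (scaled_local, scaled_nonlocal), both length n; the local series
    is NaN at the two chain ends (no interior triplet) and inf where the
    chain is locally straight.
    """
    n = conf.n
    local = np.full(n, np.nan)
    local[1:-1] = local_radius_from_theta(chain_thetas(conf.coords), conf.bond_length)
    _, nonlocal_d = nearest_nonlocal_distances(conf.coords, min_sep)

    def _scale_array(scales) -> np.ndarray:
        if np.isscalar(scales):
            return np.full(n, float(scales))
        if conf.labels is None:
            raise ValueError("per-class scales require labels")
        out = np.empty(n)
        for k, lab in enumerate(conf.labels):
            if lab not in scales:
                raise KeyError(f"no scale for observed class {lab!r}")
            out[k] = scales[lab]
        return out

    sl = _scale_array(local_scales)
    sn = _scale_array(nonlocal_scales)
    if np.any(sl <= 0) or np.any(sn <= 0):
        raise ValueError("scales must be positive")
    return local / sl, nonlocal_d / sn
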