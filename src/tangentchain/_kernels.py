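"""Numba inner loops for the tangent-sphere chain Monte Carlo.

The chain state is an (n, 3) float64 array of bead centres.  Energies are
tracked as non-negative contact counts (pairs with |i - j| >= 2 within the
square-well range); the physical energy is -epsilon times the count.  All
moves are rigid rotations or end re-grafts, so bond lengths are preserved to
machine precision; the hard-core test uses a 1e-9 relative tolerance to
absorb rotation round-off on exactly tangent pairs.

Move-local energy updates: single-bead moves (crankshaft, endpoint) and
reptation touch O(n) pairs; pivot touches only the moved-segment x fixed-
segment cross pairs, since a rigid rotation leaves intra-segment distances
unchanged.
"""

import numpy as np
from numba import njit

# move type codes
CRANKSHAFT = 0
REPTATION = 1
ENDPOINT = 2
PIVOT = 3

_HARD_CORE_REL_TOL = 1e-9


@njit(cache=True)
def seed_rng(seed):
    """Seed the compiled-code RNG stream (used by tests calling kernels directly)."""
    np.random.seed(seed)


@njit(cache=True)
def total_contacts(coords, r_att2):
    n = coords.shape[0]
    c = 0
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz <= r_att2:
                c += 1
    return c


@njit(cache=True)
def has_overlap(coords, sigma):
    n = coords.shape[0]
    s2 = sigma * sigma * (1.0 - 2.0 * _HARD_CORE_REL_TOL)
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz < s2:
                return True
    return False


@njit(cache=True)
def _bead_contacts(coords, i, px, py, pz, r_att2):
    """Contacts of a bead at (px,py,pz) playing the role of index i."""
    n = coords.shape[0]
    c = 0
    for j in range(n):
        dj = i - j
        if -2 < dj < 2:
            continue
        dx = px - coords[j, 0]
        dy = py - coords[j, 1]
        dz = pz - coords[j, 2]
        if dx * dx + dy * dy + dz * dz <= r_att2:
            c += 1
    return c


@njit(cache=True)
def _bead_overlaps(coords, i, px, py, pz, s2):
    n = coords.shape[0]
    for j in range(n):
        dj = i - j
        if -2 < dj < 2:
            continue
        dx = px - coords[j, 0]
        dy = py - coords[j, 1]
        dz = pz - coords[j, 2]
        if dx * dx + dy * dy + dz * dz < s2:
            return True
    return False


@njit(cache=True)
def _rand_unit():
    while True:
        x = np.random.normal()
        y = np.random.normal()
        z = np.random.normal()
        r2 = x * x + y * y + z * z
        if r2 > 1e-12:
            r = np.sqrt(r2)
            return x / r, y / r, z / r


@njit(cache=True)
def _rand_rotation(R):
    """Uniform SO(3) rotation matrix from a uniform unit quaternion."""
    while True:
        q0 = np.random.normal()
        q1 = np.random.normal()
        q2 = np.random.normal()
        q3 = np.random.normal()
        n2 = q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3
        if n2 > 1e-12:
            break
    s = 1.0 / np.sqrt(n2)
    q0 *= s
    q1 *= s
    q2 *= s
    q3 *= s
    R[0, 0] = 1.0 - 2.0 * (q2 * q2 + q3 * q3)
    R[0, 1] = 2.0 * (q1 * q2 - q0 * q3)
    R[0, 2] = 2.0 * (q1 * q3 + q0 * q2)
    R[1, 0] = 2.0 * (q1 * q2 + q0 * q3)
    R[1, 1] = 1.0 - 2.0 * (q1 * q1 + q3 * q3)
    R[1, 2] = 2.0 * (q2 * q3 - q0 * q1)
    R[2, 0] = 2.0 * (q1 * q3 - q0 * q2)
    R[2, 1] = 2.0 * (q2 * q3 + q0 * q1)
    R[2, 2] = 1.0 - 2.0 * (q1 * q1 + q2 * q2)


@njit(cache=True)
def _rotate_about_axis(vx, vy, vz, ax, ay, az, ang):
    """Rodrigues rotation of v about unit axis a by ang."""
    c = np.cos(ang)
    s = np.sin(ang)
    dot = ax * vx + ay * vy + az * vz
    cx = ay * vz - az * vy
    cy = az * vx - ax * vz
    cz = ax * vy - ay * vx
    rx = vx * c + cx * s + ax * dot * (1.0 - c)
    ry = vy * c + cy * s + ay * dot * (1.0 - c)
    rz = vz * c + cz * s + az * dot * (1.0 - c)
    return rx, ry, rz


@njit(cache=True)
def _accept(dc, beta_eps):
    """Metropolis acceptance for a contact-count change dc (dE = -eps*dc)."""
    if dc >= 0:
        return True
    return np.random.random() < np.exp(beta_eps * dc)


@njit(cache=True)
def _try_single_bead(coords, i, px, py, pz, sigma, r_att2, beta_eps):
    """Attempt to move bead i to p; returns contact-count change (0 if rejected)."""
    s2 = sigma * sigma * (1.0 - 2.0 * _HARD_CORE_REL_TOL)
    if _bead_overlaps(coords, i, px, py, pz, s2):
        return 0, False
    c_old = _bead_contacts(coords, i, coords[i, 0], coords[i, 1], coords[i, 2], r_att2)
    c_new = _bead_contacts(coords, i, px, py, pz, r_att2)
    dc = c_new - c_old
    if _accept(dc, beta_eps):
        coords[i, 0] = px
        coords[i, 1] = py
        coords[i, 2] = pz
        return dc, True
    return 0, False


@njit(cache=True)
def _move_crankshaft(coords, sigma, b, r_att2, beta_eps):
    n = coords.shape[0]
    i = np.random.randint(1, n - 1)
    ax = coords[i + 1, 0] - coords[i - 1, 0]
    ay = coords[i + 1, 1] - coords[i - 1, 1]
    az = coords[i + 1, 2] - coords[i - 1, 2]
    an = np.sqrt(ax * ax + ay * ay + az * az)
    if an < 1e-12:
        return 0, False
    ax /= an
    ay /= an
    az /= an
    ang = np.random.uniform(-np.pi, np.pi)
    vx = coords[i, 0] - coords[i - 1, 0]
    vy = coords[i, 1] - coords[i - 1, 1]
    vz = coords[i, 2] - coords[i - 1, 2]
    rx, ry, rz = _rotate_about_axis(vx, vy, vz, ax, ay, az, ang)
    px = coords[i - 1, 0] + rx
    py = coords[i - 1, 1] + ry
    pz = coords[i - 1, 2] + rz
    return _try_single_bead(coords, i, px, py, pz, sigma, r_att2, beta_eps)


@njit(cache=True)
def _move_endpoint(coords, sigma, b, r_att2, beta_eps):
    n = coords.shape[0]
    end = n - 1 if np.random.random() < 0.5 else 0
    nb = 1 if end == 0 else n - 2
    ux, uy, uz = _rand_unit()
    px = coords[nb, 0] + b * ux
    py = coords[nb, 1] + b * uy
    pz = coords[nb, 2] + b * uz
    return _try_single_bead(coords, end, px, py, pz, sigma, r_att2, beta_eps)


@njit(cache=True)
def _move_reptation(coords, sigma, b, r_att2, beta_eps):
    """Remove a bead from one end, regrow it at the other end."""
    n = coords.shape[0]
    s2 = sigma * sigma * (1.0 - 2.0 * _HARD_CORE_REL_TOL)
    head_to_tail = np.random.random() < 0.5
    ux, uy, uz = _rand_unit()
    if head_to_tail:
        # new bead appended after bead n-1; retained beads are 0..n-1 of the
        # shifted chain (old 1..n-1)
        px = coords[n - 1, 0] + b * ux
        py = coords[n - 1, 1] + b * uy
        pz = coords[n - 1, 2] + b * uz
        # new tail bead vs retained old beads 1..n-2 (all at new separation >= 2)
        c_new = 0
        for j in range(1, n - 1):
            dx = px - coords[j, 0]
            dy = py - coords[j, 1]
            dz = pz - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < s2:
                return 0, False
            if d2 <= r_att2:
                c_new += 1
        c_rm = _bead_contacts(coords, 0, coords[0, 0], coords[0, 1], coords[0, 2], r_att2)
        dc = c_new - c_rm
        if _accept(dc, beta_eps):
            for k in range(n - 1):
                coords[k, 0] = coords[k + 1, 0]
                coords[k, 1] = coords[k + 1, 1]
                coords[k, 2] = coords[k + 1, 2]
            coords[n - 1, 0] = px
            coords[n - 1, 1] = py
            coords[n - 1, 2] = pz
            return dc, True
        return 0, False
    else:
        px = coords[0, 0] + b * ux
        py = coords[0, 1] + b * uy
        pz = coords[0, 2] + b * uz
        # new head bead vs retained old beads 1..n-2 (all at new separation >= 2)
        c_new = 0
        for j in range(1, n - 1):
            dx = px - coords[j, 0]
            dy = py - coords[j, 1]
            dz = pz - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < s2:
                return 0, False
            if d2 <= r_att2:
                c_new += 1
        c_rm = _bead_contacts(
            coords, n - 1, coords[n - 1, 0], coords[n - 1, 1], coords[n - 1, 2], r_att2
        )
        dc = c_new - c_rm
        if _accept(dc, beta_eps):
            for k in range(n - 1, 0, -1):
                coords[k, 0] = coords[k - 1, 0]
                coords[k, 1] = coords[k - 1, 1]
                coords[k, 2] = coords[k - 1, 2]
            coords[0, 0] = px
            coords[0, 1] = py
            coords[0, 2] = pz
            return dc, True
        return 0, False


@njit(cache=True)
def _move_pivot(coords, sigma, r_att2, beta_eps, scratch, rotmat):
    """Rotate the shorter side of a random interior bead by a uniform rotation."""
    n = coords.shape[0]
    s2 = sigma * sigma * (1.0 - 2.0 * _HARD_CORE_REL_TOL)
    i = np.random.randint(1, n - 1)
    # moved segment: the shorter side, excluding the pivot bead itself
    if i <= n - 1 - i:
        lo, hi = 0, i  # beads lo..hi-1 move
    else:
        lo, hi = i + 1, n
    _rand_rotation(rotmat)
    cx = coords[i, 0]
    cy = coords[i, 1]
    cz = coords[i, 2]
    for k in range(lo, hi):
        vx = coords[k, 0] - cx
        vy = coords[k, 1] - cy
        vz = coords[k, 2] - cz
        scratch[k, 0] = cx + rotmat[0, 0] * vx + rotmat[0, 1] * vy + rotmat[0, 2] * vz
        scratch[k, 1] = cy + rotmat[1, 0] * vx + rotmat[1, 1] * vy + rotmat[1, 2] * vz
        scratch[k, 2] = cz + rotmat[2, 0] * vx + rotmat[2, 1] * vy + rotmat[2, 2] * vz
    # cross pairs moved x fixed: intra-segment distances are rotation-invariant
    c_old = 0
    c_new = 0
    for k in range(lo, hi):
        for j in range(0, lo):
            dj = k - j
            if -2 < dj < 2:
                continue
            dx = coords[k, 0] - coords[j, 0]
            dy = coords[k, 1] - coords[j, 1]
            dz = coords[k, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz <= r_att2:
                c_old += 1
            dx = scratch[k, 0] - coords[j, 0]
            dy = scratch[k, 1] - coords[j, 1]
            dz = scratch[k, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < s2:
                return 0, False
            if d2 <= r_att2:
                c_new += 1
        for j in range(hi, n):
            dj = k - j
            if -2 < dj < 2:
                continue
            dx = coords[k, 0] - coords[j, 0]
            dy = coords[k, 1] - coords[j, 1]
            dz = coords[k, 2] - coords[j, 2]
            if dx * dx + dy * dy + dz * dz <= r_att2:
                c_old += 1
            dx = scratch[k, 0] - coords[j, 0]
            dy = scratch[k, 1] - coords[j, 1]
            dz = scratch[k, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < s2:
                return 0, False
            if d2 <= r_att2:
                c_new += 1
    # note: distances from moved beads to the pivot bead itself are invariant
    # under the rotation, so pairs with the pivot (inside the fixed ranges)
    # contribute equally to c_old and c_new
    dc = c_new - c_old
    if _accept(dc, beta_eps):
        for k in range(lo, hi):
            coords[k, 0] = scratch[k, 0]
            coords[k, 1] = scratch[k, 1]
            coords[k, 2] = scratch[k, 2]
        return dc, True
    return 0, False


@njit(cache=True)
def run_sweeps(coords, n_sweeps, beta_eps, sigma, b, r_att, seed, contacts0, energies, acc, att):
    """Run n_sweeps Metropolis sweeps (n move attempts each) in place.

    energies[s] receives the contact count after sweep s.  acc/att are
    4-vectors of per-move-type accepted / attempted counts.  Returns the
    final contact count.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    r_att2 = r_att * r_att
    count = contacts0
    scratch = np.empty_like(coords)
    rotmat = np.empty((3, 3))
    for s in range(n_sweeps):
        for _ in range(n):
            m = np.random.randint(0, 4)
            att[m] += 1
            if m == CRANKSHAFT:
                dc, ok = _move_crankshaft(coords, sigma, b, r_att2, beta_eps)
            elif m == REPTATION:
                dc, ok = _move_reptation(coords, sigma, b, r_att2, beta_eps)
            elif m == ENDPOINT:
                dc, ok = _move_endpoint(coords, sigma, b, r_att2, beta_eps)
            else:
                dc, ok = _move_pivot(coords, sigma, r_att2, beta_eps, scratch, rotmat)
            if ok:
                acc[m] += 1
                count += dc
        energies[s] = count
    return count
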