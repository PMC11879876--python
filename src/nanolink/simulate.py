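"""Rigid-body Langevin dynamics of patchy Y-shaped nanostars.

Each nanostar is a rigid body of 7 purely repulsive core beads (WCA) and 3
attractive patch sites (Morse) that model sticky-end hybridization. Two
nanostar species A and B exist; A patches bind A patches and B binds B, but
A-B pairs never attract. Dynamics are Langevin (implicit solvent) in the
NVT ensemble with friction Gamma applied per core bead.

The integrator is velocity Verlet with an exact Ornstein-Uhlenbeck
thermostat sub-step (BAOAB splitting). Applying bead-wise friction
``-Gamma v_bead`` plus matched noise and reducing to the centre of mass
gives a total translational drag of ``7 Gamma`` and a rotational drag
tensor ``Gamma I_body`` — both relax at rate ``Gamma / m_bead``, so the
OU sub-step is exact and the sampled kinetic temperature is unbiased.
With ``Gamma = 0`` the scheme reduces to plain (NVE) velocity Verlet.

Units are LJ-style throughout: lengths in sigma, energies in epsilon,
times in tau_Br = k_B T / Gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import (
    N_CORE_BEADS,
    VALENCE,
    Configuration,
    NanostarGeometry,
    PeriodicBox,
    Trajectory,
    box_edge_for_density,
    quat_to_matrix,
)
from .rheology import StressSeries

SITES_PER_MOL = N_CORE_BEADS + VALENCE
WCA_CUT = 2.0 ** (1.0 / 6.0)

#: default bond-detection cutoff: patches within 0.2 sigma are hybridized
BOND_CUTOFF = 0.2


@dataclass(frozen=True)
class ForceField:
    """Pair interactions: WCA core repulsion + Morse patch attraction.

    The Morse well has its minimum at patch-patch contact (r = 0) so two
    bound patches sit essentially on top of each other, which together with
    the patch placement at the arm tips enforces one-to-one binding.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    morse_depth: float = 20.0  # D0, in epsilon
    morse_alpha: float = 8.0  # 1/sigma
    morse_cutoff: float = 0.5  # sigma

    def __post_init__(self) -> None:
        if self.morse_depth <= 0:
            raise ValueError("Morse depth D0 must be positive")
        if self.morse_cutoff < BOND_CUTOFF:
            raise ValueError(
                f"Morse cutoff {self.morse_cutoff} must cover the bond "
                f"criterion r <= {BOND_CUTOFF}"
            )


@dataclass(frozen=True)
class LangevinParams:
    """Langevin integration parameters (LJ units)."""

    dt: float = 0.01  # tau_Br
    friction: float = 1.0  # Gamma per bead
    temperature: float = 1.0  # epsilon / k_B
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.temperature <= 0:
            raise ValueError("dt and temperature must be positive")


@dataclass(frozen=True)
class SimulationProtocol:
    """Equilibration (attraction off) followed by production sampling."""

    equilibration: float = 100.0  # tau_Br
    production: float = 1000.0  # tau_Br
    frame_interval: float = 50.0  # tau_Br between stored frames
    stress_interval: float = 0.1  # tau_Br between stress samples

    def __post_init__(self) -> None:
        if self.equilibration < 0 or self.production < 0:
            raise ValueError("durations must be non-negative")


@dataclass
class TracerBead:
    """Large repulsive probe bead for simulated microrheology."""

    radius: float = 2.5  # sigma
    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    #: kept small so the probe is overdamped on all probed lags
    #: (inertial time mass / (Gamma * 2a) << 1 tau_Br)
    mass: float = 1.0

    def __post_init__(self) -> None:
        if self.radius <= 0.5:
            raise ValueError("tracer radius must exceed sigma/2")
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


class BondList(list):
    """Bonded patch pairs ((i, arm_k), (j, arm_l)); one bond per arm."""

    def __init__(self, bonds=()):
        super().__init__(bonds)
        used = set()
        for (i, k), (j, l) in self:
            if i == j:
                raise ValueError(f"self-bond within nanostar {i}")
            for end in ((i, k), (j, l)):
                if end in used:
                    raise ValueError(f"arm {end} appears in more than one bond")
                used.add(end)


def bonded_arm_fraction(bonds: BondList, n_nanostars: int) -> float:
    """Fraction of all arms engaged in a bond."""
    return 2 * len(bonds) / (VALENCE * n_nanostars)


# ---------------------------------------------------------------------------
# bond detection

def detect_bonds(config: Configuration, cutoff: float = BOND_CUTOFF) -> BondList:
    """Hybridized patch pairs: minimum-image distance <= cutoff, compatible
    types, one-to-one by greedy smallest-distance matching (ties broken by
    the lowest (i, arm, j, arm) index tuple). Deterministic and invariant
    under global translation/rotation of the configuration.
    """
    patches = config.patch_coords(wrap=True).reshape(-1, 3)
    n = config.n_nanostars
    mol = np.repeat(np.arange(n), VALENCE)
    arm = np.tile(np.arange(VALENCE), n)
    types = np.repeat(config.types, VALENCE)
    box = config.box
    from scipy.spatial import cKDTree

    tree = cKDTree(np.mod(patches, box.lengths), boxsize=box.lengths)
    candidates = []
    for a, b in tree.query_pairs(cutoff):
        if mol[a] == mol[b] or types[a] != types[b]:
            continue
        d = float(box.distance(patches[a], patches[b]))
        if d > cutoff:
            continue
        i, j = (a, b) if (mol[a], arm[a]) < (mol[b], arm[b]) else (b, a)
        candidates.append((d, int(mol[i]), int(arm[i]), int(mol[j]), int(arm[j])))
    candidates.sort()
    used: set[tuple[int, int]] = set()
    bonds = []
    for _, i, k, j, l in candidates:
        if (i, k) in used or (j, l) in used:
            continue
        used.add((i, k))
        used.add((j, l))
        bonds.append(((i, k), (j, l)))
    return BondList(bonds)


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _quat_mat(q, m):  # pragma: no cover - numba
    w, x, y, z = q[0], q[1], q[2], q[3]
    m[0, 0] = 1 - 2 * (y * y + z * z)
    m[0, 1] = 2 * (x * y - w * z)
    m[0, 2] = 2 * (x * z + w * y)
    m[1, 0] = 2 * (x * y + w * z)
    m[1, 1] = 1 - 2 * (x * x + z * z)
    m[1, 2] = 2 * (y * z - w * x)
    m[2, 0] = 2 * (x * z - w * y)
    m[2, 1] = 2 * (y * z + w * x)
    m[2, 2] = 1 - 2 * (x * x + y * y)


@njit(cache=True)
def _rotate_quat(q, axis_x, axis_y, axis_z, angle):  # pragma: no cover
    """q <- rot(axis, angle) * q, renormalized."""
    half = 0.5 * angle
    s = np.sin(half)
    rw, rx, ry, rz = np.cos(half), axis_x * s, axis_y * s, axis_z * s
    w, x, y, z = q[0], q[1], q[2], q[3]
    q[0] = rw * w - rx * x - ry * y - rz * z
    q[1] = rw * x + rx * w + ry * z - rz * y
    q[2] = rw * y - rx * z + ry * w + rz * x
    q[3] = rw * z + rx * y - ry * x + rz * w
    norm = np.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
    for k in range(4):
        q[k] /= norm


@njit(cache=True)
def _site_positions(com, quats, body, out):  # pragma: no cover
    n_mol = com.shape[0]
    m = np.empty((3, 3))
    for i in range(n_mol):
        _quat_mat(quats[i], m)
        for s in range(body.shape[0]):
            for d in range(3):
                out[i * body.shape[0] + s, d] = (
                    com[i, d]
                    + m[d, 0] * body[s, 0]
                    + m[d, 1] * body[s, 1]
                    + m[d, 2] * body[s, 2]
                )


@njit(cache=True)
def _build_pairs(pos, L, cutoff, mol_id, kind, mol_type, tracer_on,
                 pairs_buf):  # pragma: no cover
    """Candidate interacting site pairs within cutoff (+skin), cell-binned.

    Interaction rules: core-core always; patch-patch only for equal molecule
    types; tracer-core always; everything intra-molecular skipped.
    Returns the number of pairs, or -1 on buffer overflow.
    """
    n = pos.shape[0]
    ncx = max(1, int(L[0] / cutoff))
    ncy = max(1, int(L[1] / cutoff))
    ncz = max(1, int(L[2] / cutoff))
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cell_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        cx = int((pos[i, 0] / L[0] - np.floor(pos[i, 0] / L[0])) * ncx)
        cy = int((pos[i, 1] / L[1] - np.floor(pos[i, 1] / L[1])) * ncy)
        cz = int((pos[i, 2] / L[2] - np.floor(pos[i, 2] / L[2])) * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        nxt[i] = head[c]
        head[c] = i
    cut2 = cutoff * cutoff
    count = 0
    half = ncells > 26  # guard tiny boxes: fall back to all-pairs
    if not half:
        for i in range(n):
            for j in range(i + 1, n):
                ok = _pair_interacts(i, j, mol_id, kind, mol_type)
                if not ok:
                    continue
                d2 = _min_image_d2(pos, i, j, L)
                if d2 <= cut2:
                    if count >= pairs_buf.shape[0]:
                        return -1
                    pairs_buf[count, 0] = i
                    pairs_buf[count, 1] = j
                    count += 1
        return count
    for i in range(n):
        ci = cell_of[i]
        cz0 = ci % ncz
        cy0 = (ci // ncz) % ncy
        cx0 = ci // (ncy * ncz)
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    cx = (cx0 + ox) % ncx
                    cy = (cy0 + oy) % ncy
                    cz = (cz0 + oz) % ncz
                    c = (cx * ncy + cy) * ncz + cz
                    j = head[c]
                    while j >= 0:
                        if j > i and _pair_interacts(i, j, mol_id, kind, mol_type):
                            d2 = _min_image_d2(pos, i, j, L)
                            if d2 <= cut2:
                                if count >= pairs_buf.shape[0]:
                                    return -1
                                pairs_buf[count, 0] = i
                                pairs_buf[count, 1] = j
                                count += 1
                        j = nxt[j]
    return count


@njit(cache=True, inline="always")
def _pair_interacts(i, j, mol_id, kind, mol_type):  # pragma: no cover
    if mol_id[i] == mol_id[j]:
        return False
    ki, kj = kind[i], kind[j]
    if ki == 0 and kj == 0:
        return True
    if ki == 1 and kj == 1:
        return mol_type[i] == mol_type[j]
    if ki == 2 or kj == 2:
        return (ki == 0) or (kj == 0)  # tracer couples to cores only
    return False


@njit(cache=True, inline="always")
def _min_image_d2(pos, i, j, L):  # pragma: no cover
    d2 = 0.0
    for d in range(3):
        dd = pos[j, d] - pos[i, d]
        dd -= L[d] * np.rint(dd / L[d])
        d2 += dd * dd
    return d2


@njit(cache=True)
def _forces(pos, L, pairs, n_pairs, kind, attraction_on,
            eps, d0, alpha, r_morse_cut, tracer_contact,
            site_forces, virial):  # pragma: no cover
    """Pair forces on sites; returns (potential energy, ok_flag)."""
    for i in range(site_forces.shape[0]):
        for d in range(3):
            site_forces[i, d] = 0.0
    for a in range(3):
        for b in range(3):
            virial[a, b] = 0.0
    energy = 0.0
    wca_cut2 = WCA_CUT * WCA_CUT
    morse_shift = d0 * (
        np.exp(-2.0 * alpha * r_morse_cut) - 2.0 * np.exp(-alpha * r_morse_cut)
    )
    for p in range(n_pairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        dx = dy = dz = 0.0
        dd = pos[j, 0] - pos[i, 0]
        dx = dd - L[0] * np.rint(dd / L[0])
        dd = pos[j, 1] - pos[i, 1]
        dy = dd - L[1] * np.rint(dd / L[1])
        dd = pos[j, 2] - pos[i, 2]
        dz = dd - L[2] * np.rint(dd / L[2])
        r2 = dx * dx + dy * dy + dz * dz
        ki, kj = kind[i], kind[j]
        fmag_over_r = 0.0  # force on j along +d
        if ki == 0 and kj == 0:
            if r2 < wca_cut2:
                if r2 < 1e-12:
                    return 0.0, False
                inv2 = 1.0 / r2
                inv6 = inv2 * inv2 * inv2
                energy += 4.0 * eps * (inv6 * inv6 - inv6) + eps
                fmag_over_r = 24.0 * eps * (2.0 * inv6 * inv6 - inv6) * inv2
        elif ki == 1 and kj == 1:
            if attraction_on:
                r = np.sqrt(r2)
                if r < r_morse_cut:
                    e2 = np.exp(-2.0 * alpha * r)
                    e1 = np.exp(-alpha * r)
                    energy += d0 * (e2 - 2.0 * e1) - morse_shift
                    if r > 1e-12:
                        fmag_over_r = 2.0 * alpha * d0 * (e2 - e1) / r
        else:  # tracer-core WCA with contact distance a + sigma/2
            s = tracer_contact / WCA_CUT
            cut2 = tracer_contact * tracer_contact
            if r2 < cut2:
                if r2 < 1e-12:
                    return 0.0, False
                s2 = s * s / r2
                s6 = s2 * s2 * s2
                energy += 4.0 * eps * (s6 * s6 - s6) + eps
                fmag_over_r = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
        if fmag_over_r != 0.0:
            fx = fmag_over_r * dx
            fy = fmag_over_r * dy
            fz = fmag_over_r * dz
            site_forces[j, 0] += fx
            site_forces[j, 1] += fy
            site_forces[j, 2] += fz
            site_forces[i, 0] -= fx
            site_forces[i, 1] -= fy
            site_forces[i, 2] -= fz
            virial[0, 0] += dx * fx
            virial[0, 1] += dx * fy
            virial[0, 2] += dx * fz
            virial[1, 0] += dy * fx
            virial[1, 1] += dy * fy
            virial[1, 2] += dy * fz
            virial[2, 0] += dz * fx
            virial[2, 1] += dz * fy
            virial[2, 2] += dz * fz
    return energy, True


@njit(cache=True)
def _reduce_forces(site_forces, site_pos_world, com, n_mol, spm,
                   mol_forces, mol_torques):  # pragma: no cover
    for i in range(n_mol):
        for d in range(3):
            mol_forces[i, d] = 0.0
            mol_torques[i, d] = 0.0
        for s in range(spm):
            idx = i * spm + s
            rx = site_pos_world[idx, 0] - com[i, 0]
            ry = site_pos_world[idx, 1] - com[i, 1]
            rz = site_pos_world[idx, 2] - com[i, 2]
            fx = site_forces[idx, 0]
            fy = site_forces[idx, 1]
            fz = site_forces[idx, 2]
            mol_forces[i, 0] += fx
            mol_forces[i, 1] += fy
            mol_forces[i, 2] += fz
            mol_torques[i, 0] += ry * fz - rz * fy
            mol_torques[i, 1] += rz * fx - rx * fz
            mol_torques[i, 2] += rx * fy - ry * fx


@njit(cache=True, inline="always")
def _permute(k, v, out):  # pragma: no cover
    """P_k permutation operators on quaternion 4-vectors (w, x, y, z)."""
    if k == 1:
        out[0] = -v[1]
        out[1] = v[0]
        out[2] = v[3]
        out[3] = -v[2]
    elif k == 2:
        out[0] = -v[2]
        out[1] = -v[3]
        out[2] = v[0]
        out[3] = v[1]
    else:
        out[0] = -v[3]
        out[1] = v[2]
        out[2] = -v[1]
        out[3] = v[0]


@njit(cache=True)
def _nosquish_axis(k, q, p4, inertia, dt):  # pragma: no cover
    pk = np.empty(4)
    qk = np.empty(4)
    _permute(k, q, qk)
    _permute(k, p4, pk)
    phi = (p4[0] * qk[0] + p4[1] * qk[1] + p4[2] * qk[2] + p4[3] * qk[3]) / (
        4.0 * inertia[k - 1]
    )
    c = np.cos(dt * phi)
    s = np.sin(dt * phi)
    for d in range(4):
        p4[d] = c * p4[d] + s * pk[d]
    _permute(k, q, qk)  # q may not have changed yet, recompute for clarity
    for d in range(4):
        q[d] = c * q[d] + s * qk[d]


@njit(cache=True)
def _angular_step(quats, ang_mom, inertia, dt):  # pragma: no cover
    """Symplectic free-rotor drift (no-squish splitting).

    Propagates each quaternion for time dt under its world-frame angular
    momentum using the 3-2-1-2-3 axis splitting, which conserves energy
    and |q| to machine-level drift for free rigid bodies."""
    n = quats.shape[0]
    m = np.empty((3, 3))
    p4 = np.empty(4)
    pi_b = np.empty(3)
    for i in range(n):
        q = quats[i]
        _quat_mat(q, m)
        # body-frame angular momentum pi = R^T L
        for d in range(3):
            pi_b[d] = (
                m[0, d] * ang_mom[i, 0]
                + m[1, d] * ang_mom[i, 1]
                + m[2, d] * ang_mom[i, 2]
            )
        # conjugate quaternion momentum p4 = 2 (pi_1 P1 q + pi_2 P2 q + pi_3 P3 q)
        for d in range(4):
            p4[d] = 0.0
        tmp = np.empty(4)
        for k in range(1, 4):
            _permute(k, q, tmp)
            for d in range(4):
                p4[d] += 2.0 * pi_b[k - 1] * tmp[d]
        _nosquish_axis(3, q, p4, inertia, 0.5 * dt)
        _nosquish_axis(2, q, p4, inertia, 0.5 * dt)
        _nosquish_axis(1, q, p4, inertia, dt)
        _nosquish_axis(2, q, p4, inertia, 0.5 * dt)
        _nosquish_axis(3, q, p4, inertia, 0.5 * dt)
        norm = np.sqrt(q[0] ** 2 + q[1] ** 2 + q[2] ** 2 + q[3] ** 2)
        for d in range(4):
            q[d] /= norm
        # back out body momentum, then world angular momentum
        for k in range(1, 4):
            _permute(k, q, tmp)
            pi_b[k - 1] = 0.5 * (
                p4[0] * tmp[0] + p4[1] * tmp[1] + p4[2] * tmp[2] + p4[3] * tmp[3]
            )
        _quat_mat(q, m)
        for d in range(3):
            ang_mom[i, d] = (
                m[d, 0] * pi_b[0] + m[d, 1] * pi_b[1] + m[d, 2] * pi_b[2]
            )


@njit(cache=True)
def _ou_step(vel, ang_mom, quats, inertia, mass, c, kt,
             noise_v, noise_l):  # pragma: no cover
    """Exact OU thermostat on COM velocities and body-frame angular momenta."""
    n = vel.shape[0]
    amp_v = np.sqrt((1.0 - c * c) * kt / mass)
    m = np.empty((3, 3))
    for i in range(n):
        for d in range(3):
            vel[i, d] = c * vel[i, d] + amp_v * noise_v[i, d]
        _quat_mat(quats[i], m)
        lbx = m[0, 0] * ang_mom[i, 0] + m[1, 0] * ang_mom[i, 1] + m[2, 0] * ang_mom[i, 2]
        lby = m[0, 1] * ang_mom[i, 0] + m[1, 1] * ang_mom[i, 1] + m[2, 1] * ang_mom[i, 2]
        lbz = m[0, 2] * ang_mom[i, 0] + m[1, 2] * ang_mom[i, 1] + m[2, 2] * ang_mom[i, 2]
        lbx = c * lbx + np.sqrt((1.0 - c * c) * kt * inertia[0]) * noise_l[i, 0]
        lby = c * lby + np.sqrt((1.0 - c * c) * kt * inertia[1]) * noise_l[i, 1]
        lbz = c * lbz + np.sqrt((1.0 - c * c) * kt * inertia[2]) * noise_l[i, 2]
        ang_mom[i, 0] = m[0, 0] * lbx + m[0, 1] * lby + m[0, 2] * lbz
        ang_mom[i, 1] = m[1, 0] * lbx + m[1, 1] * lby + m[1, 2] * lbz
        ang_mom[i, 2] = m[2, 0] * lbx + m[2, 1] * lby + m[2, 2] * lbz


# ---------------------------------------------------------------------------
# principal-frame setup

def _principal_frame(geometry: NanostarGeometry):
    """Body sites in the centre-of-mass principal frame.

    Returns (body_sites (10,3), principal inertia (3,), R0, com_body) such
    that world_site = R_pose @ (R0 @ body_principal) + anchor, where the
    anchor is the central bead. Core beads carry unit mass; patches are
    massless interaction sites.
    """
    beads = geometry.bead_coords
    com = beads.mean(axis=0)
    centred_beads = beads - com
    inertia = np.zeros((3, 3))
    for b in centred_beads:
        inertia += np.eye(3) * (b @ b) - np.outer(b, b)
    vals, vecs = np.linalg.eigh(inertia)
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    sites = geometry.all_sites() - com
    body_principal = sites @ vecs  # coordinates in principal axes
    return body_principal, np.maximum(vals, 1e-10), vecs, com


# ---------------------------------------------------------------------------
# public operations

def init_configuration(
    n_nanostars: int,
    rho: float,
    geometry: NanostarGeometry | None = None,
    seed: int = 0,
    min_separation: float = 0.9,
    max_retries: int = 500,
    types: np.ndarray | None = None,
    exclude_sphere: tuple[np.ndarray, float] | None = None,
) -> Configuration:
    """Random non-overlapping initial configuration at volume fraction rho.

    Molecules are inserted one by one with uniform positions and uniform
    SO(3) orientations, rejecting placements whose core beads come closer
    than ``min_separation`` to any already-placed bead. An optional
    ``exclude_sphere`` (centre, radius) keeps beads out of a region, e.g.
    to embed a microrheology tracer from the start.
    """
    if n_nanostars < 1:
        raise ValueError("need at least one nanostar")
    if not 0 < rho < 0.3:
        raise ValueError("volume fraction must be in (0, 0.3)")
    geometry = geometry or NanostarGeometry.default()
    box = PeriodicBox.cubic(box_edge_for_density(n_nanostars, rho))
    rng = np.random.default_rng(seed)
    positions = np.zeros((n_nanostars, 3))
    quats = np.zeros((n_nanostars, 4))
    placed_beads: list[np.ndarray] = []
    for i in range(n_nanostars):
        for attempt in range(max_retries):
            pos = rng.uniform(0, 1, 3) * box.lengths
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            rot = quat_to_matrix(q)
            beads = geometry.bead_coords @ rot.T + pos
            ok = True
            if exclude_sphere is not None:
                delta = box.minimum_image(beads - exclude_sphere[0])
                if np.min(np.einsum("ij,ij->i", delta, delta)) < exclude_sphere[1] ** 2:
                    ok = False
            for other in placed_beads:
                if not ok:
                    break
                delta = box.minimum_image(beads[:, None, :] - other[None, :, :])
                if np.min(np.einsum("ijk,ijk->ij", delta, delta)) < min_separation**2:
                    ok = False
                    break
            if ok:
                positions[i] = pos
                quats[i] = q
                placed_beads.append(beads)
                break
        else:
            raise RuntimeError(
                f"could not place nanostar {i} after {max_retries} tries at "
                f"rho = {rho}; consider starting from a lattice"
            )
    return Configuration(
        positions=positions, quaternions=quats, box=box,
        geometry=geometry, types=types,
    )


def place_tracer(
    config: Configuration, radius: float = 2.5, seed: int = 0, mass: float = 20.0
) -> TracerBead:
    """Place a tracer bead in the largest void reachable from random probes.

    Tries a handful of random probe points, grows the largest empty sphere
    at each and puts the tracer at the best centre, so the initial
    configuration has no tracer-core overlap."""
    from .observables import largest_sphere_at

    rng = np.random.default_rng((seed, 0x7ACE))  # decorrelated from placement
    best = None
    for _ in range(8):
        probe = rng.uniform(0, 1, 3) * config.box.lengths
        xi, center = largest_sphere_at(config, probe)
        if best is None or xi > best[0]:
            best = (xi, center)
    if best[0] / 2 < radius + 0.5:
        raise RuntimeError(
            f"no void large enough for a tracer of radius {radius} "
            f"(largest clearance {best[0] / 2:.2f})"
        )
    return TracerBead(radius=radius, position=np.asarray(best[1]), mass=mass)


def _site_arrays(config: Configuration, tracer: TracerBead | None):
    n = config.n_nanostars
    kind = np.zeros(n * SITES_PER_MOL + (1 if tracer else 0), dtype=np.int64)
    mol_id = np.zeros_like(kind)
    mol_type = np.zeros_like(kind)
    for i in range(n):
        base = i * SITES_PER_MOL
        kind[base + N_CORE_BEADS : base + SITES_PER_MOL] = 1
        mol_id[base : base + SITES_PER_MOL] = i
        mol_type[base : base + SITES_PER_MOL] = config.types[i]
    if tracer:
        kind[-1] = 2
        mol_id[-1] = n
        mol_type[-1] = -1
    return kind, mol_id, mol_type


def compute_forces(
    config: Configuration,
    ff: ForceField | None = None,
    tracer: TracerBead | None = None,
    attraction_on: bool = True,
    velocities: np.ndarray | None = None,
):
    """Forces, torques, potential energy and instantaneous pressure tensor.

    Returns a dict with per-nanostar ``forces`` and ``torques`` (about the
    central bead), total ``energy``, the virial ``pressure`` tensor
    (kinetic part included when molecular COM ``velocities`` are given),
    per-site ``site_forces`` and the tracer force.
    """
    ff = ff or ForceField()
    n = config.n_nanostars
    sites = config.all_site_coords(wrap=False).reshape(-1, 3)
    if tracer is not None:
        sites = np.vstack([sites, tracer.position[None, :]])
    kind, mol_id, mol_type = _site_arrays(config, tracer)
    L = config.box.lengths
    tracer_contact = (tracer.radius + 0.5) if tracer else 1.0
    cutoff = max(WCA_CUT, ff.morse_cutoff, tracer_contact)
    pairs_buf = np.empty((max(64, len(sites) * 64), 2), dtype=np.int64)
    n_pairs = _build_pairs(sites, L, cutoff, mol_id, kind, mol_type,
                           tracer is not None, pairs_buf)
    if n_pairs < 0:
        pairs_buf = np.empty((len(sites) * 512, 2), dtype=np.int64)
        n_pairs = _build_pairs(sites, L, cutoff, mol_id, kind, mol_type,
                               tracer is not None, pairs_buf)
    site_forces = np.zeros_like(sites)
    virial = np.zeros((3, 3))
    energy, ok = _forces(
        sites, L, pairs_buf, n_pairs, kind, attraction_on,
        ff.epsilon, ff.morse_depth, ff.morse_alpha, ff.morse_cutoff,
        tracer_contact, site_forces, virial,
    )
    if not ok:
        raise FloatingPointError("overlapping sites closer than 1e-6 sigma")
    anchors = config.positions
    mol_forces = np.zeros((n, 3))
    mol_torques = np.zeros((n, 3))
    site_world = config.all_site_coords(wrap=False)
    for i in range(n):
        f = site_forces[i * SITES_PER_MOL : (i + 1) * SITES_PER_MOL]
        r = site_world[i] - anchors[i]
        mol_forces[i] = f.sum(axis=0)
        mol_torques[i] = np.cross(r, f).sum(axis=0)
    pressure = virial.copy()
    if velocities is not None:
        mass = float(N_CORE_BEADS)
        pressure += mass * velocities.T @ velocities
    pressure /= config.box.volume
    return {
        "forces": mol_forces,
        "torques": mol_torques,
        "energy": float(energy),
        "pressure": pressure,
        "site_forces": site_forces[: n * SITES_PER_MOL],
        "tracer_force": site_forces[-1] if tracer is not None else None,
    }


@dataclass
class SimulationResult:
    trajectory: Trajectory
    stress: StressSeries
    tracer_track: np.ndarray | None
    tracer_times: np.ndarray | None
    final_config: Configuration
    final_tracer: TracerBead | None
    energies: np.ndarray  # total (potential + kinetic) energy at frame times
    momenta: np.ndarray  # total linear momentum at frame times
    kinetic_temperature: float


def run_langevin(
    config: Configuration,
    ff: ForceField | None = None,
    params: LangevinParams | None = None,
    protocol: SimulationProtocol | None = None,
    tracer: TracerBead | None = None,
    velocities: np.ndarray | None = None,
    thermostat: bool = True,
) -> SimulationResult:
    """Integrate rigid-body Langevin dynamics through the given protocol.

    The equilibration phase runs with Morse attraction disabled; production
    turns it on and samples frames, off-diagonal stress components and the
    tracer track at the protocol's intervals. Seeded runs on one thread are
    bit-reproducible. With ``thermostat=False`` (and the friction ignored)
    the integrator is plain NVE velocity Verlet.
    """
    ff = ff or ForceField()
    params = params or LangevinParams()
    protocol = protocol or SimulationProtocol()
    geometry = config.geometry
    body_principal, inertia, r0, com_body = _principal_frame(geometry)
    n = config.n_nanostars
    mass = float(N_CORE_BEADS)
    rng = np.random.default_rng(params.seed)

    # pose conversion: kernel tracks COM + composed quaternion
    from scipy.spatial.transform import Rotation

    q_pose = config.quaternions
    rot_pose = quat_to_matrix(q_pose)
    com = config.positions + np.einsum("nij,j->ni", rot_pose, com_body)
    q0 = Rotation.from_matrix(r0).as_quat()  # (x,y,z,w)
    q0 = np.array([q0[3], q0[0], q0[1], q0[2]])
    quats = np.empty((n, 4))
    for i in range(n):
        quats[i] = _quat_multiply(q_pose[i], q0)
    vel = (
        velocities.copy()
        if velocities is not None
        else rng.normal(scale=np.sqrt(params.temperature / mass), size=(n, 3))
    )
    ang = np.zeros((n, 3))
    rot = quat_to_matrix(quats)
    lb = rng.normal(size=(n, 3)) * np.sqrt(params.temperature * inertia)
    ang = np.einsum("nij,nj->ni", rot, lb)

    kind, mol_id, mol_type = _site_arrays(config, tracer)
    L = config.box.lengths
    tracer_contact = (tracer.radius + 0.5) if tracer else 1.0
    dt = params.dt
    c = np.exp(-params.friction * dt) if thermostat else 1.0
    kt = params.temperature
    n_eq = int(round(protocol.equilibration / dt))
    n_prod = int(round(protocol.production / dt))
    frame_every = max(1, int(round(protocol.frame_interval / dt)))
    stress_every = max(1, int(round(protocol.stress_interval / dt)))

    n_sites = n * SITES_PER_MOL + (1 if tracer else 0)
    sites = np.empty((n_sites, 3))
    site_forces = np.zeros((n_sites, 3))
    virial = np.zeros((3, 3))
    mol_forces = np.zeros((n, 3))
    mol_torques = np.zeros((n, 3))
    pairs_buf = np.empty((max(1024, n_sites * 96), 2), dtype=np.int64)
    cutoff = max(WCA_CUT, ff.morse_cutoff, tracer_contact)
    skin = 0.4
    tr_pos = tracer.position.copy() if tracer else np.zeros(3)
    tr_vel = tracer.velocity.copy() if tracer else np.zeros(3)
    tr_mass = tracer.mass if tracer else 1.0
    tr_gamma_rate = (
        params.friction * (tracer.radius / 0.5) / tr_mass if tracer else 0.0
    )
    c_tr = np.exp(-tr_gamma_rate * dt) if thermostat else 1.0

    frames_pos, frames_quat, frame_times = [], [], []
    stress_samples, stress_times = [], []
    track, track_times = [], []
    energies, momenta = [], []
    ke_accum, ke_count = 0.0, 0

    def total_energy(pot: float) -> float:
        ke_trans = 0.5 * mass * float(np.sum(vel * vel))
        rot_m = quat_to_matrix(quats)
        l_body = np.einsum("nji,nj->ni", rot_m, ang)
        ke_rot = 0.5 * float(np.sum(l_body * l_body / inertia))
        extra = 0.5 * tr_mass * float(tr_vel @ tr_vel) if tracer is not None else 0.0
        return pot + ke_trans + ke_rot + extra

    def compute(attraction_on: bool):
        _site_positions(com, quats, body_principal, sites[: n * SITES_PER_MOL])
        if tracer is not None:
            sites[-1] = tr_pos
        n_pairs = _build_pairs(sites, L, cutoff + skin, mol_id, kind, mol_type,
                               tracer is not None, pairs_buf)
        if n_pairs < 0:
            raise RuntimeError("neighbor buffer overflow; box too dense")
        energy, ok = _forces(
            sites, L, pairs_buf, n_pairs, kind, attraction_on,
            ff.epsilon, ff.morse_depth, ff.morse_alpha, ff.morse_cutoff,
            tracer_contact, site_forces, virial,
        )
        if not ok or not np.isfinite(energy):
            raise FloatingPointError(
                "force divergence (overlap); reduce dt or check the initial "
                "configuration"
            )
        _reduce_forces(site_forces[: n * SITES_PER_MOL], sites, com, n,
                       SITES_PER_MOL, mol_forces, mol_torques)
        return energy

    energy = compute(False)
    phase_steps = [(n_eq, False), (n_prod, True)]
    step_global = 0
    for n_steps, attraction_on in phase_steps:
        if attraction_on:
            energy = compute(True)
        for step in range(n_steps):
            # B
            vel += (0.5 * dt / mass) * mol_forces
            ang += 0.5 * dt * mol_torques
            if tracer is not None:
                tr_vel += (0.5 * dt / tr_mass) * site_forces[-1]
            # A
            com += 0.5 * dt * vel
            _angular_step(quats, ang, inertia, 0.5 * dt)
            if tracer is not None:
                tr_pos += 0.5 * dt * tr_vel
            # O
            if thermostat:
                _ou_step(vel, ang, quats, inertia, mass, c, kt,
                         rng.normal(size=(n, 3)), rng.normal(size=(n, 3)))
                if tracer is not None:
                    tr_vel = c_tr * tr_vel + np.sqrt(
                        (1 - c_tr**2) * kt / tr_mass
                    ) * rng.normal(size=3)
            # A
            com += 0.5 * dt * vel
            _angular_step(quats, ang, inertia, 0.5 * dt)
            if tracer is not None:
                tr_pos += 0.5 * dt * tr_vel
            # B
            energy = compute(attraction_on)
            vel += (0.5 * dt / mass) * mol_forces
            ang += 0.5 * dt * mol_torques
            if tracer is not None:
                tr_vel += (0.5 * dt / tr_mass) * site_forces[-1]
            step_global += 1
            t_now = step_global * dt
            if attraction_on:
                if step % stress_every == 0:
                    p = virial.copy()
                    p += mass * vel.T @ vel
                    p /= np.prod(L)
                    stress_samples.append((p[0, 1], p[0, 2], p[1, 2]))
                    stress_times.append(t_now)
                    if tracer is not None:
                        track.append(tr_pos.copy())
                        track_times.append(t_now)
                    ke = 0.5 * mass * np.sum(vel * vel)
                    ke_accum += 2.0 * ke / (3.0 * n)
                    ke_count += 1
                if (step + 1) % frame_every == 0:
                    frames_pos.append(com.copy())
                    frames_quat.append(quats.copy())
                    frame_times.append(t_now)
                    energies.append(total_energy(energy))
                    momenta.append(mass * vel.sum(axis=0))

    # convert kernel poses back to anchor (central bead) + pose quaternion
    q0_conj = np.array([q0[0], -q0[1], -q0[2], -q0[3]])
    frames = []
    for pos_f, quat_f in zip(frames_pos, frames_quat):
        q_pose_f = np.array([_quat_multiply(q, q0_conj) for q in quat_f])
        rot_f = quat_to_matrix(q_pose_f)
        anchor = pos_f - np.einsum("nij,j->ni", rot_f, com_body)
        frames.append(
            Configuration(
                positions=config.box.wrap(anchor),
                quaternions=q_pose_f,
                box=config.box,
                geometry=geometry,
                types=config.types,
            )
        )
    if not frames:  # always provide at least the final state
        q_pose_f = np.array([_quat_multiply(q, q0_conj) for q in quats])
        rot_f = quat_to_matrix(q_pose_f)
        anchor = com - np.einsum("nij,j->ni", rot_f, com_body)
        frames = [
            Configuration(
                positions=config.box.wrap(anchor), quaternions=q_pose_f,
                box=config.box, geometry=geometry, types=config.types,
            )
        ]
        frame_times = [max(step_global, 1) * dt]
        energies = [total_energy(energy)]
        momenta = [mass * vel.sum(axis=0)]
    stress = StressSeries(
        times=np.array(stress_times) if stress_times else np.zeros(0),
        components=np.array(stress_samples).reshape(-1, 3),
        volume=float(np.prod(L)),
        temperature=params.temperature,
    )
    traj = Trajectory(
        frames=frames,
        times=np.array(frame_times),
        stress=stress,
        tracer_track=np.array(track) if track else None,
        tracer_times=np.array(track_times) if track_times else None,
    )
    final_tracer = None
    if tracer is not None:
        final_tracer = TracerBead(
            radius=tracer.radius, position=tr_pos, velocity=tr_vel,
            mass=tr_mass,
        )
    return SimulationResult(
        trajectory=traj,
        stress=stress,
        tracer_track=np.array(track) if track else None,
        tracer_times=np.array(track_times) if track_times else None,
        final_config=frames[-1],
        final_tracer=final_tracer,
        energies=np.array(energies),
        momenta=np.array(momenta).reshape(-1, 3),
        kinetic_temperature=ke_accum / ke_count if ke_count else float("nan"),
    )


def _quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def calibrate_bond_lifetime(
    ff: ForceField | None = None,
    temperature: float = 1.0,
    n_pairs: int = 8,
    max_time: float = 200.0,
    seed: int = 0,
) -> dict:
    """Mean bond lifetime tau_u for a given Morse depth.

    Simulates isolated pre-bonded nanostar pairs and records the first time
    each bond (patch distance <= 0.2 sigma) breaks; censored pairs (still
    bonded at ``max_time``) are reported separately, so the returned mean is
    a lower bound when censoring occurs.
    """
    ff = ff or ForceField()
    geometry = NanostarGeometry.default()
    lifetimes, censored = [], 0
    for rep in range(n_pairs):
        config = _bonded_pair_config(geometry, seed=seed + rep)
        params = LangevinParams(seed=seed + 1000 + rep, temperature=temperature)
        protocol = SimulationProtocol(
            equilibration=0.0, production=max_time,
            frame_interval=1.0, stress_interval=1.0,
        )
        result = run_langevin(config, ff, params, protocol)
        broke_at = None
        for frame, t in zip(result.trajectory.frames, result.trajectory.times):
            if len(detect_bonds(frame)) == 0:
                broke_at = t
                break
        if broke_at is None:
            censored += 1
        else:
            lifetimes.append(broke_at)
    mean = float(np.mean(lifetimes)) if lifetimes else float(max_time)
    return {
        "mean_lifetime": mean,
        "n_broken": len(lifetimes),
        "n_censored": censored,
        "max_time": max_time,
    }


def _bonded_pair_config(geometry: NanostarGeometry, seed: int = 0) -> Configuration:
    """Two nanostars facing each other with one patch pair in contact."""
    box = PeriodicBox.cubic(30.0)
    center = box.lengths / 2
    # arm 0 points along +y in the body frame; rotate the partner 180 deg
    # about z so its arm 0 points along -y, and place patches in contact
    d = 2 * 2.5 + 0.05  # centre-centre distance: patches 0.05 sigma apart
    q_id = np.array([1.0, 0.0, 0.0, 0.0])
    q_flip = np.array([0.0, 0.0, 0.0, 1.0])  # 180 deg about z
    positions = np.array([center - [0, d / 2, 0], center + [0, d / 2, 0]])
    return Configuration(
        positions=positions,
        quaternions=np.array([q_id, q_flip]),
        box=box,
        geometry=geometry,
    )
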