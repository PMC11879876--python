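"""Core domain types: periodic box, nanostar geometry, configurations, trajectories.

All lengths are in units of the bead diameter ``sigma`` (sigma = 2.5 nm for the
DNA-nanostar mapping); time is in Brownian times ``tau_Br = k_B T / Gamma`` and
energy in units of the characteristic interaction energy ``epsilon``.
Conversion to physical units happens only at I/O edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: bead diameter in nanometres for unit conversion at I/O edges
SIGMA_NM = 2.5

#: number of core beads per nanostar
N_CORE_BEADS = 7

#: nanostar valence (number of arms / sticky patches)
VALENCE = 3


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory input."""


@dataclass(frozen=True)
class PeriodicBox:
    """Orthorhombic periodic box with edge lengths in sigma units.

    Only orthorhombic (rectangular) boxes are supported; triclinic input is
    rejected at the I/O layer.
    """

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (3,):
            raise ValueError("box needs exactly three edge lengths")
        if not np.all(lengths > 0):
            raise ValueError(f"box edges must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @classmethod
    def cubic(cls, edge: float) -> "PeriodicBox":
        return cls(np.full(3, float(edge)))

    @property
    def volume(self) -> float:
        return float(np.prod(self.lengths))

    @property
    def min_edge(self) -> float:
        return float(self.lengths.min())

    def wrap(self, x: np.ndarray) -> np.ndarray:
        """Map coordinates into [0, L) per component."""
        x = np.asarray(x, dtype=float)
        return x - self.lengths * np.floor(x / self.lengths)

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Minimum-image displacement, each component in (-L/2, +L/2]."""
        d = np.asarray(d, dtype=float)
        return d - self.lengths * np.ceil(d / self.lengths - 0.5)

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Minimum-image Euclidean distance between points a and b."""
        delta = self.minimum_image(np.asarray(b) - np.asarray(a))
        return np.sqrt(np.sum(delta * delta, axis=-1))


def minimum_image(displacement: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Minimum-image convention applied to a displacement vector.

    Each returned component lies in ``(-L/2, +L/2]`` and differs from the
    input by an integer combination of box vectors.
    """
    return box.minimum_image(displacement)


def _default_body_frame() -> tuple[np.ndarray, np.ndarray]:
    """Planar Y geometry: 3 arms at 120 deg, 2 beads per arm + central bead.

    Beads sit at distances sigma and 2*sigma from the centre along each arm;
    the sticky patch site sits at 2.5*sigma, beyond the arm's last bead.
    """
    angles = np.deg2rad([90.0, 210.0, 330.0])
    arm_dirs = np.stack([np.cos(angles), np.sin(angles), np.zeros(3)], axis=1)
    beads = [np.zeros(3)]
    for d in arm_dirs:
        beads.append(1.0 * d)
        beads.append(2.0 * d)
    patches = [2.5 * d for d in arm_dirs]
    return np.array(beads), np.array(patches)


@dataclass(frozen=True)
class NanostarGeometry:
    """Rigid-body geometry of a Y-shaped nanostar.

    Seven core beads (diameter sigma) assembled into a rigid Y with three
    arms; three zero-volume patch sites model the sticky ends, each placed
    beyond its arm's last core bead so patch-patch contact happens before
    core-core overlap.
    """

    bead_coords: np.ndarray  # (7, 3) body frame
    patch_coords: np.ndarray  # (3, 3) body frame
    patch_diameter: float = 0.2  # fraction of sigma; bond-detection scale

    def __post_init__(self) -> None:
        beads = np.asarray(self.bead_coords, dtype=float)
        patches = np.asarray(self.patch_coords, dtype=float)
        if beads.shape != (N_CORE_BEADS, 3):
            raise ValueError(f"expected {N_CORE_BEADS} core beads, got {beads.shape}")
        if patches.shape != (VALENCE, 3):
            raise ValueError(f"expected {VALENCE} patch sites, got {patches.shape}")
        # each patch must lie further from the centre than any core bead
        if patches.shape[0] and np.linalg.norm(patches, axis=1).min() <= np.linalg.norm(
            beads, axis=1
        ).max() - 1e-9:
            raise ValueError("patch sites must lie beyond the arms' last core beads")
        object.__setattr__(self, "bead_coords", beads)
        object.__setattr__(self, "patch_coords", patches)

    @classmethod
    def default(cls, patch_diameter: float = 0.2) -> "NanostarGeometry":
        beads, patches = _default_body_frame()
        return cls(beads, patches, patch_diameter)

    @property
    def n_sites(self) -> int:
        return N_CORE_BEADS + VALENCE

    def all_sites(self) -> np.ndarray:
        """Core beads followed by patch sites, body frame, shape (10, 3)."""
        return np.concatenate([self.bead_coords, self.patch_coords], axis=0)


def _quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        raise ValueError("zero-norm quaternion")
    return q / norm


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrices from unit quaternions in (w, x, y, z) order.

    Vectorized over leading axes; quaternions must already be unit norm.
    """
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def volume_fraction(n_nanostars: int, box_volume: float) -> float:
    """rho = N * 7 * (pi sigma^3 / 6) / V — core beads only, sigma = 1."""
    return n_nanostars * N_CORE_BEADS * (np.pi / 6.0) / box_volume


def box_edge_for_density(n_nanostars: int, rho: float) -> float:
    """Cubic box edge that realizes volume fraction rho for N nanostars."""
    if not 0 < rho < 1:
        raise ValueError(f"volume fraction must be in (0, 1), got {rho}")
    volume = n_nanostars * N_CORE_BEADS * (np.pi / 6.0) / rho
    return float(volume ** (1.0 / 3.0))


@dataclass
class Configuration:
    """Poses of all nanostars in a periodic box, with derived world coordinates.

    positions : (N, 3) centre-of-geometry positions (central bead), sigma units
    quaternions : (N, 4) unit quaternions (w, x, y, z)
    types : (N,) int array, 0 = 'A', 1 = 'B'
    """

    positions: np.ndarray
    quaternions: np.ndarray
    box: PeriodicBox
    geometry: NanostarGeometry = field(default_factory=NanostarGeometry.default)
    types: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        self.quaternions = _quat_normalize(self.quaternions)
        if self.quaternions.shape != (self.n_nanostars, 4):
            raise ValueError("quaternions must have shape (N, 4)")
        if self.types is None:
            self.types = np.zeros(self.n_nanostars, dtype=np.int64)
        else:
            self.types = np.asarray(self.types, dtype=np.int64)
            if self.types.shape != (self.n_nanostars,):
                raise ValueError("types must have shape (N,)")

    @property
    def n_nanostars(self) -> int:
        return self.positions.shape[0]

    @property
    def rho(self) -> float:
        """Volume fraction from core-bead volume over box volume."""
        return volume_fraction(self.n_nanostars, self.box.volume)

    def _world(self, body_coords: np.ndarray, wrap: bool) -> np.ndarray:
        rot = quat_to_matrix(self.quaternions)  # (N, 3, 3)
        world = np.einsum("nij,kj->nki", rot, body_coords) + self.positions[:, None, :]
        if wrap:
            world = self.box.wrap(world)
        return world

    def bead_coords(self, wrap: bool = True) -> np.ndarray:
        """World-frame core-bead coordinates, shape (N, 7, 3)."""
        return self._world(self.geometry.bead_coords, wrap)

    def patch_coords(self, wrap: bool = True) -> np.ndarray:
        """World-frame patch-site coordinates, shape (N, 3, 3)."""
        return self._world(self.geometry.patch_coords, wrap)

    def all_site_coords(self, wrap: bool = True) -> np.ndarray:
        """Beads then patches per molecule, shape (N, 10, 3)."""
        return self._world(self.geometry.all_sites(), wrap)


def place_configuration(
    geometry: NanostarGeometry,
    poses: list[tuple[np.ndarray, np.ndarray, str]],
    box: PeriodicBox,
) -> Configuration:
    """Build a Configuration from explicit (position, quaternion, type) poses."""
    if not poses:
        raise ValueError("poses must be non-empty")
    positions = np.array([np.asarray(p[0], dtype=float) for p in poses])
    quats = np.array([np.asarray(p[1], dtype=float) for p in poses])
    types = np.array([0 if p[2] == "A" else 1 for p in poses], dtype=np.int64)
    return Configuration(
        positions=box.wrap(positions),
        quaternions=quats,
        box=box,
        geometry=geometry,
        types=types,
    )


@dataclass
class Trajectory:
    """Ordered configurations with timestamps in Brownian times.

    Optional side channels: off-diagonal stress samples and a tracer-bead
    track produced by the simulator.
    """

    frames: list[Configuration]
    times: np.ndarray
    stress: "object | None" = None  # StressSeries, kept loose to avoid cycle
    tracer_track: np.ndarray | None = None  # (n_samples, 3) unwrapped
    tracer_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise TrajectoryError("frame count and timestamp count differ")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("timestamps must be strictly increasing")
        boxes = {tuple(f.box.lengths) for f in self.frames}
        if len(boxes) > 1:
            raise TrajectoryError("time-varying boxes are not supported")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Configuration:
        return self.frames[i]

    @property
    def box(self) -> PeriodicBox:
        return self.frames[0].box
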