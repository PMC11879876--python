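"""Synthetic fixtures with machine-readable ground truth.

Every generator is a pure function of its parameters and seed, and each
fixture carries the quantity it was built to exhibit: torus-link curve
pairs of known linking number, interpenetrated diamond networks with known
girth and catenation, degree-capped random geometric networks, tracer MSDs
and stress traces with known viscoelastic ground truth, and two-channel
images of known colocalization.

The interpenetrated diamond fixture is the minimal analytically tractable
realization of a "network-within-network": two diamond sublattices offset
by half a unit cell (the ice-VII motif) have mutually catenated six-rings
and no cross-bonds. Valence is reduced from 4 to 3 by deleting all bonds
of one tetrahedral direction, which keeps the girth at 6 and the network
connected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .core import Configuration, NanostarGeometry, PeriodicBox
from .network import NetworkGraph
from .rheology import KB_T, MsdSeries, StressSeries
from .topology import ClosedPolygon


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request: kind, parameters, mandatory seed."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


def make_fixture(spec: FixtureSpec):
    makers = {
        "torus-link": make_torus_link,
        "diamond": make_diamond_network,
        "random-network": make_random_network,
        "trap-msd": make_trap_msd,
        "ou-stress": make_ou_stress,
        "two-channel-image": make_two_channel_image,
    }
    if spec.kind not in makers:
        raise ValueError(f"unknown fixture kind '{spec.kind}'")
    fn = makers[spec.kind]
    kwargs = dict(spec.params)
    if spec.kind not in ("torus-link",):
        kwargs.setdefault("seed", spec.seed)
    return fn(**kwargs)


# ---------------------------------------------------------------------------
# torus links

def make_torus_link(
    k: int,
    n_vertices: int = 64,
    major_radius: float = 4.0,
    minor_radius: float = 1.5,
) -> tuple[ClosedPolygon, ClosedPolygon]:
    """Two closed curves with linking number exactly k.

    For k >= 1 the curves are the two components of the (2, 2k) torus link:
    each winds once around the torus axis and k times around the tube, with
    a phase offset of pi (k = 1 is Hopf-equivalent). For k = 0 two circles
    are placed far apart (a split link).
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if n_vertices < 16:
        raise ValueError("need at least 16 vertices per curve")
    if minor_radius <= 0 or major_radius <= minor_radius:
        raise ValueError("need major_radius > minor_radius > 0")
    t = np.linspace(0.0, 1.0, n_vertices, endpoint=False)
    if k == 0:
        circle = np.stack(
            [
                major_radius * np.cos(2 * np.pi * t),
                major_radius * np.sin(2 * np.pi * t),
                np.zeros_like(t),
            ],
            axis=1,
        )
        far = circle + np.array([4 * major_radius, 0.0, 0.0])
        return ClosedPolygon(circle), ClosedPolygon(far)
    curves = []
    for phase in (0.0, np.pi):
        theta = 2 * np.pi * k * t + phase
        r = major_radius + minor_radius * np.cos(theta)
        curves.append(
            ClosedPolygon(
                np.stack(
                    [
                        r * np.cos(2 * np.pi * t),
                        r * np.sin(2 * np.pi * t),
                        minor_radius * np.sin(theta),
                    ],
                    axis=1,
                )
            )
        )
    return curves[0], curves[1]


def make_random_loop(
    rng: np.random.Generator,
    n_vertices: int = 24,
    scale: float = 3.0,
    n_modes: int = 3,
) -> ClosedPolygon:
    """Smooth random closed curve from a few random Fourier modes.

    Pairs of such curves land in assorted link types (mostly unlinked or
    Hopf-like) and exercise the linking kernels away from symmetric
    geometries."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    pts = np.zeros((n_vertices, 3))
    for m in range(1, n_modes + 1):
        amp = rng.normal(scale=scale / m, size=(3, 2))
        pts += amp[:, 0] * np.cos(m * t)[:, None] + amp[:, 1] * np.sin(m * t)[:, None]
    return ClosedPolygon(pts + rng.normal(scale=2.0, size=3))


# ---------------------------------------------------------------------------
# diamond networks

_DIAMOND_BASIS = np.array(
    [
        [0.00, 0.00, 0.00],
        [0.00, 0.50, 0.50],
        [0.50, 0.00, 0.50],
        [0.50, 0.50, 0.00],
        [0.25, 0.25, 0.25],
        [0.25, 0.75, 0.75],
        [0.75, 0.25, 0.75],
        [0.75, 0.75, 0.25],
    ]
)

#: the four tetrahedral bond directions (fractional, from the A sublattice)
_BOND_DIRECTIONS = np.array(
    [
        [0.25, 0.25, 0.25],
        [0.25, -0.25, -0.25],
        [-0.25, 0.25, -0.25],
        [-0.25, -0.25, 0.25],
    ]
)


def make_diamond_network(
    cells: tuple[int, int, int] = (3, 3, 3),
    sublattices: int = 1,
    noise: float = 0.0,
    dilution: float = 0.0,
    seed: int = 0,
    lattice_constant: float = 8.0,
    max_valence: int = 3,
) -> tuple[Configuration, NetworkGraph]:
    """Periodic diamond-lattice nanostar network, optionally interpenetrated.

    Nodes sit on diamond positions; bonds join tetrahedral nearest
    neighbours. By default valence is reduced from 4 to 3 by removing every
    bond of one tetrahedral direction (seed-selected), keeping girth 6 and
    connectivity; ``max_valence=4`` keeps the full diamond net (useful as a
    locally well-connected null fixture: the valence-3 net's ball-induced
    subgraphs fragment). With ``sublattices=2`` a second network (type B),
    offset by half a cell, interpenetrates the first with no cross-edges;
    its six-rings are catenated with those of the first by construction.
    Gaussian positional noise and extra random bond dilution are optional.
    """
    if max_valence not in (3, 4):
        raise ValueError("max_valence must be 3 or 4")
    cells = tuple(int(c) for c in cells)
    if min(cells) < 2:
        raise ValueError("need at least 2 cells per axis for periodic closure")
    if not 0 <= dilution < 0.3:
        raise ValueError("dilution must be in [0, 0.3)")
    if sublattices not in (1, 2):
        raise ValueError("sublattices must be 1 or 2")
    rng = np.random.default_rng(seed)
    a = lattice_constant
    box = PeriodicBox(np.array(cells, dtype=float) * a)
    if noise >= 0.25 * a * np.sqrt(3) / 4:
        raise ValueError("noise too large: would break minimum-image adjacency")

    frac_nodes = []
    node_type = []
    offsets = [np.zeros(3)] if sublattices == 1 else [np.zeros(3), np.full(3, 0.5)]
    for sub, offset in enumerate(offsets):
        for ix in range(cells[0]):
            for iy in range(cells[1]):
                for iz in range(cells[2]):
                    cell = np.array([ix, iy, iz], dtype=float)
                    for basis in _DIAMOND_BASIS:
                        frac_nodes.append(cell + basis + offset)
                        node_type.append(sub)
    frac = np.array(frac_nodes)  # units of one cell
    node_type = np.array(node_type)
    n = len(frac)
    positions = (frac * a) % (np.array(cells) * a)
    if noise > 0:
        positions = (positions + rng.normal(scale=noise, size=positions.shape)) % (
            np.array(cells) * a
        )

    # exact bond bookkeeping in fractional coordinates. Valence reduction
    # keeps only the hexagons avoiding the dropped direction; hexagons of
    # the two nets catenate only when their avoided directions differ AND
    # come from opposite direction families ({0,1} vs {2,3} for the
    # half-cell offset), so the sublattices drop cross-family directions.
    d_first = int(rng.integers(0, 4))
    d_second = 2 + int(rng.integers(0, 2)) if d_first < 2 else int(rng.integers(0, 2))
    drop_direction_of = {0: d_first, 1: d_second}
    if max_valence == 4:
        drop_direction_of = {0: -1, 1: -1}  # drop nothing
    index: dict[tuple, int] = {}
    for i, f in enumerate(frac):
        key = tuple(np.round((f % np.array(cells)) * 4).astype(int) % (np.array(cells) * 4))
        index[key] = i
    g = nx.MultiGraph()
    for i in range(n):
        g.add_node(i, pos=positions[i], type=int(node_type[i]))
    for i, f in enumerate(frac):
        # A-sublattice sites of the diamond basis emit the four bonds
        frac_local = (f * 4).round().astype(int) % 4
        if frac_local.sum() % 4 not in (0, 2):  # B-type basis site: skip, bonds
            continue  # are emitted by its A-type partners
        for d_idx, direction in enumerate(_BOND_DIRECTIONS):
            if d_idx == drop_direction_of[int(node_type[i])]:
                continue
            target = f + direction
            key = tuple(
                np.round((target % np.array(cells)) * 4).astype(int)
                % (np.array(cells) * 4)
            )
            j = index.get(key)
            if j is None or node_type[j] != node_type[i]:
                continue
            shift = np.floor(target / np.array(cells)).astype(np.int64)
            g.add_edge(i, j, arms=(d_idx, d_idx), shift=shift, u=i)
    if dilution > 0:
        edges = sorted(g.edges(keys=True))
        n_drop = int(round(dilution * len(edges)))
        drop = rng.choice(len(edges), size=n_drop, replace=False)
        for k in sorted(drop, reverse=True):
            g.remove_edge(*edges[k])

    quats = np.zeros((n, 4))
    quats[:, 0] = 1.0
    config = Configuration(
        positions=positions,
        quaternions=quats,
        box=box,
        geometry=NanostarGeometry.default(),
        types=node_type,
    )
    net = NetworkGraph(graph=g, box=box)
    if net.degrees().max() > max_valence:
        raise AssertionError(f"diamond fixture produced degree > {max_valence}")
    return config, net


# ---------------------------------------------------------------------------
# random geometric networks

def make_random_network(
    n_nanostars: int = 100,
    rho: float = 0.05,
    max_valence: int = 3,
    bond_range: float = 6.0,
    seed: int = 0,
) -> tuple[Configuration, NetworkGraph]:
    """Degree-capped random geometric network (null model).

    Centres are uniform in a box solving the volume-fraction definition;
    candidate edges (pairs within ``bond_range``) are added shortest-first
    subject to the valence cap.
    """
    from .core import box_edge_for_density

    rng = np.random.default_rng(seed)
    box = PeriodicBox.cubic(box_edge_for_density(n_nanostars, rho))
    positions = rng.uniform(0, 1, size=(n_nanostars, 3)) * box.lengths
    from scipy.spatial import cKDTree

    tree = cKDTree(positions % box.lengths, boxsize=box.lengths)
    pairs = sorted(
        (float(box.distance(positions[i], positions[j])), i, j)
        for i, j in tree.query_pairs(bond_range)
    )
    g = nx.MultiGraph()
    for i in range(n_nanostars):
        g.add_node(i, pos=positions[i], type=0)
    degree = np.zeros(n_nanostars, dtype=int)
    L = box.lengths
    for _, i, j in pairs:
        if degree[i] >= max_valence or degree[j] >= max_valence:
            continue
        raw = positions[j] - positions[i]
        d = box.minimum_image(raw)
        shift = np.rint((d - raw) / L).astype(np.int64)
        g.add_edge(i, j, arms=(degree[i], degree[j]), shift=shift, u=i)
        degree[i] += 1
        degree[j] += 1
    quats = np.zeros((n_nanostars, 4))
    quats[:, 0] = 1.0
    config = Configuration(
        positions=positions, quaternions=quats, box=box,
        geometry=NanostarGeometry.default(),
    )
    return config, NetworkGraph(graph=g, box=box)


# ---------------------------------------------------------------------------
# viscoelastic ground truth

def make_trap_msd(
    spring_constant: float = 1.0,
    tracer_radius: float = 2.5,
    noise: float = 0.0,
    seed: int = 0,
    viscosity: float = 1.0,
    n_lags: int = 80,
) -> MsdSeries:
    """Harmonic-trap tracer MSD with known GSER ground truth.

    MSD(t) = (6 k_B T / k) (1 - exp(-t / tau_k)) with tau_k = 6 pi eta a / k;
    the GSER plateau is G' = k / (6 pi a). ``noise`` applies seeded
    multiplicative lognormal scatter. The k -> 0 limit is pure diffusion
    with D = k_B T / (6 pi eta a).
    """
    a = tracer_radius
    rng = np.random.default_rng(seed)
    if spring_constant > 0:
        tau_k = 6 * np.pi * viscosity * a / spring_constant
        lags = np.geomspace(tau_k * 1e-3, tau_k * 50, n_lags)
        msd = (6 * KB_T / spring_constant) * (1 - np.exp(-lags / tau_k))
    else:
        diffusion = KB_T / (6 * np.pi * viscosity * a)
        lags = np.geomspace(1e-2, 1e3, n_lags)
        msd = 6 * diffusion * lags
    if noise > 0:
        msd = msd * np.exp(rng.normal(scale=noise, size=msd.shape))
    return MsdSeries(lags=lags, msd=msd, tracer_radius=a)


def make_ou_stress(
    amplitude: float = 0.01,
    tau_c: float = 5.0,
    n_samples: int = 100_000,
    dt: float = 0.1,
    seed: int = 0,
    volume: float = 1000.0,
) -> StressSeries:
    """Three independent OU traces with stationary ACF A * exp(-t / tau_c).

    Uses the exact discrete-time OU update, so the target autocorrelation
    holds at every lag regardless of dt. The Green-Kubo modulus of this
    series is G(t) = (V / k_B T) * A * exp(-t / tau_c).
    """
    rng = np.random.default_rng(seed)
    decay = np.exp(-dt / tau_c)
    innov = np.sqrt(amplitude * (1.0 - decay * decay))
    x = np.empty((n_samples, 3))
    x[0] = rng.normal(scale=np.sqrt(amplitude), size=3)
    noise = rng.normal(size=(n_samples - 1, 3))
    for i in range(1, n_samples):
        x[i] = decay * x[i - 1] + innov * noise[i - 1]
    return StressSeries(
        times=np.arange(n_samples) * dt, components=x, volume=volume,
    )


# ---------------------------------------------------------------------------
# two-channel colocalization images

def make_two_channel_image(
    size: tuple[int, int] = (256, 256),
    interpenetration_fraction: float = 0.5,
    droplet_scale: float = 12.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Synthetic red/green channel pair with known expected colocalization.

    A smooth random field partitions the image into a mixed region (area
    fraction phi, both channels bright) and a demixed remainder split into
    red-only and green-only droplet domains. The expected pixel-product
    mean is exactly phi (up to pixel-count rounding), returned as ground
    truth alongside the two [0, 1] channel images.
    """
    phi = float(interpenetration_fraction)
    if not 0.0 <= phi <= 1.0:
        raise ValueError("interpenetration fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = size
    f1 = ndimage.gaussian_filter(rng.normal(size=size), droplet_scale, mode="wrap")
    f2 = ndimage.gaussian_filter(rng.normal(size=size), droplet_scale, mode="wrap")
    mixed = f1 <= np.quantile(f1, phi)
    red = np.zeros(size)
    green = np.zeros(size)
    red[mixed] = 1.0
    green[mixed] = 1.0
    demixed = ~mixed
    red_only = demixed & (f2 <= np.median(f2[demixed]) if demixed.any() else False)
    red[red_only] = 1.0
    green[demixed & ~red_only] = 1.0
    expected = float(mixed.mean())
    return red, green, expected
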