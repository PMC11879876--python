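"""Minimum-loop census and Gauss linking analysis of bonded nanostar networks.

The topological state of the gel is characterized in three steps:

1. *Minimum loops*: for every nanostar we find the shortest simple cycle of
   bonds passing through it and keep one such loop; deduplicating over
   nanostars yields the loop set of the network (count ``N_minloop``, loop
   lengths ``l_min`` in nanostars).
2. *Gauss linking number* ``Lk`` between every pair of loops, evaluated
   exactly for polygonal curves by summing signed solid angles over segment
   pairs. An independent crossing-sign oracle (signed crossings in a generic
   planar projection) cross-checks the integral.
3. *Link census*: total linking ``L = sum_{i>j} |Lk(i, j)|``, the linking
   valence ``<Z> = L / N_minloop``, the fraction of loops linked at least
   once, and percolation of the loop-level link network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
from numba import njit

from .core import Configuration, PeriodicBox
from .network import NetworkGraph


# ---------------------------------------------------------------------------
# closed polygons

@dataclass
class ClosedPolygon:
    """Closed polygonal curve in unwrapped 3-D coordinates.

    The first vertex is not repeated at the end; closure is implied. The
    winding vector counts net box crossings: only curves with winding
    (0, 0, 0) are contractible in the periodic box and admit a well-defined
    linking number against other curves.
    """

    vertices: np.ndarray  # (n, 3)
    winding: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    nanostar_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.winding = np.asarray(self.winding, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def contractible(self) -> bool:
        return bool(np.all(self.winding == 0))

    @property
    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    @property
    def radius_of_gyration(self) -> float:
        rel = self.vertices - self.centroid
        return float(np.sqrt(np.mean(np.sum(rel * rel, axis=1))))

    @property
    def bounding_radius(self) -> float:
        rel = self.vertices - self.centroid
        return float(np.sqrt(np.max(np.sum(rel * rel, axis=1))))

    def translated(self, offset: np.ndarray) -> "ClosedPolygon":
        return ClosedPolygon(self.vertices + offset, self.winding, self.nanostar_ids)

    def refined(self, factor: int = 2) -> "ClosedPolygon":
        """Subdivide every edge into ``factor`` collinear pieces."""
        n = len(self.vertices)
        out = []
        for i in range(n):
            a = self.vertices[i]
            b = self.vertices[(i + 1) % n]
            for k in range(factor):
                out.append(a + (b - a) * (k / factor))
        return ClosedPolygon(np.array(out), self.winding, self.nanostar_ids)


@dataclass
class LoopSet:
    """Deduplicated minimum loops of a network."""

    loops: list[ClosedPolygon]

    def __len__(self) -> int:
        return len(self.loops)

    @property
    def n_minloop(self) -> int:
        return len(self.loops)

    @property
    def lengths(self) -> np.ndarray:
        """Loop lengths l_min, in nanostars."""
        return np.array([len(p.nanostar_ids) for p in self.loops], dtype=int)

    @property
    def radii_of_gyration(self) -> np.ndarray:
        return np.array([p.radius_of_gyration for p in self.loops])


# ---------------------------------------------------------------------------
# minimum-loop search

def _canonical_cycle(ids: tuple[int, ...]) -> tuple[int, ...]:
    """Lexicographically smallest representative over rotations/reflections."""
    n = len(ids)
    best = None
    for seq in (ids, ids[::-1]):
        for r in range(n):
            cand = seq[r:] + seq[:r]
            if best is None or cand < best:
                best = cand
    return best


def _min_cycles_through(
    graph: nx.MultiGraph, v: int, keep_all: bool
) -> list[tuple[int, ...]]:
    """Minimum simple cycle(s) through v as canonical node tuples.

    For each unordered pair of distinct neighbours of v, the shortest path
    between them avoiding v closes a cycle; the minimum over pairs is the
    minimum loop through v. With ``keep_all`` every co-minimal cycle is
    returned, otherwise only the lexicographically smallest canonical one.
    Parallel edges (2-cycles / double bonds) are excluded. Deterministic:
    neighbours scanned in sorted order and BFS ties resolved by node id.
    """
    nbrs = sorted(set(graph.neighbors(v)) - {v})
    if len(nbrs) < 2:
        return []
    sub = graph.copy()
    sub.remove_node(v)
    found: list[tuple[int, tuple[int, ...]]] = []
    for ai in range(len(nbrs)):
        for bi in range(ai + 1, len(nbrs)):
            a, b = nbrs[ai], nbrs[bi]
            if keep_all:
                try:
                    paths = list(nx.all_shortest_paths(sub, a, b))
                except nx.NetworkXNoPath:
                    continue
            else:
                try:
                    paths = [_deterministic_shortest_path(sub, a, b)]
                except nx.NetworkXNoPath:
                    continue
            for path in paths:
                cycle = (v, *path)
                found.append((len(cycle), _canonical_cycle(cycle)))
    if not found:
        return []
    min_len = min(f[0] for f in found)
    minimal = sorted({c for ln, c in found if ln == min_len})
    return minimal if keep_all else minimal[:1]


def _deterministic_shortest_path(graph: nx.Graph, source: int, target: int):
    """BFS shortest path with lowest-id tie-breaking (stable across runs)."""
    if source == target:
        return [source]
    parents = {source: None}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in sorted(graph.neighbors(u)):
                if w not in parents:
                    parents[w] = u
                    if w == target:
                        path = [w]
                        while parents[path[-1]] is not None:
                            path.append(parents[path[-1]])
                        return path[::-1]
                    nxt.append(w)
        frontier = nxt
    raise nx.NetworkXNoPath(f"no path between {source} and {target}")


def find_minimum_loops(net: NetworkGraph, keep_all_cominimal: bool = False) -> LoopSet:
    """Minimum-loop census: shortest cycle(s) per nanostar, deduplicated.

    For every node that lies on a cycle, the shortest simple cycle through it
    is found (ties broken by the lexicographically smallest canonical node
    sequence); loops are deduplicated by their nanostar-id set. With
    ``keep_all_cominimal`` every co-minimal cycle through each node is kept
    before deduplication (N_minloop depends on this choice). Double bonds
    (length-2 cycles) are excluded. A forest yields an empty LoopSet.
    """
    graph = net.graph
    seen: dict[frozenset, tuple[int, ...]] = {}
    for v in sorted(graph.nodes):
        for cycle in _min_cycles_through(graph, v, keep_all_cominimal):
            key = frozenset(cycle)
            if key not in seen:
                seen[key] = cycle
    loops = [unwrap_loop(seq, net) for seq in sorted(seen.values())]
    return LoopSet(loops=loops)


def unwrap_loop(node_sequence: tuple[int, ...], net: NetworkGraph) -> ClosedPolygon:
    """Unwrap a cycle's node positions into a continuous closed polygon.

    Vertices are accumulated by minimum-image steps from the first node; the
    winding vector counts the net box crossings of the cycle (nonzero
    winding marks a non-contractible cycle that percolates the box).
    """
    box = net.box
    verts = [net.position(node_sequence[0]).astype(float)]
    for prev, node in zip(node_sequence, node_sequence[1:]):
        step = box.minimum_image(net.position(node) - net.position(prev))
        verts.append(verts[-1] + step)
    closing = box.minimum_image(net.position(node_sequence[0]) - net.position(node_sequence[-1]))
    end = verts[-1] + closing
    gap = end - verts[0]
    winding = np.rint(gap / box.lengths).astype(np.int64)
    if np.abs(gap - winding * box.lengths).max() > 1e-9:
        raise ValueError("loop failed to close: nodes are not mutually adjacent")
    return ClosedPolygon(
        vertices=np.array(verts), winding=winding, nanostar_ids=tuple(node_sequence)
    )


# ---------------------------------------------------------------------------
# Gauss linking number (exact polygonal solid-angle sum)

@njit(cache=True)
def _gauss_kernel(a: np.ndarray, b: np.ndarray):  # pragma: no cover - numba
    """Sum of signed solid angles over all segment pairs, and the minimum
    vertex-to-segment separation between the two polygons."""
    na, nb = a.shape[0], b.shape[0]
    total = 0.0
    min_sep = 1e300
    for i in range(na):
        p1 = a[i]
        p2 = a[(i + 1) % na]
        for j in range(nb):
            p3 = b[j]
            p4 = b[(j + 1) % nb]
            r13 = p3 - p1
            r14 = p4 - p1
            r23 = p3 - p2
            r24 = p4 - p2
            # separation tracking: min distance of b's vertices to segment a
            seg = p2 - p1
            seg2 = seg[0] ** 2 + seg[1] ** 2 + seg[2] ** 2
            for q in (r13, r14):
                if seg2 > 0:
                    t = (q[0] * seg[0] + q[1] * seg[1] + q[2] * seg[2]) / seg2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                else:
                    t = 0.0
                dx = q[0] - t * seg[0]
                dy = q[1] - t * seg[1]
                dz = q[2] - t * seg[2]
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < min_sep:
                    min_sep = d2
            n1 = np.cross(r13, r14)
            n2 = np.cross(r14, r24)
            n3 = np.cross(r24, r23)
            n4 = np.cross(r23, r13)
            l1 = np.sqrt(n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2)
            l2 = np.sqrt(n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2)
            l3 = np.sqrt(n3[0] ** 2 + n3[1] ** 2 + n3[2] ** 2)
            l4 = np.sqrt(n4[0] ** 2 + n4[1] ** 2 + n4[2] ** 2)
            if l1 < 1e-14 or l2 < 1e-14 or l3 < 1e-14 or l4 < 1e-14:
                continue  # degenerate (coplanar touching) pair contributes 0
            n1 = n1 / l1
            n2 = n2 / l2
            n3 = n3 / l3
            n4 = n4 / l4
            def _clip(x):
                if x > 1.0:
                    return 1.0
                if x < -1.0:
                    return -1.0
                return x
            omega = (
                np.arcsin(_clip(n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]))
                + np.arcsin(_clip(n2[0] * n3[0] + n2[1] * n3[1] + n2[2] * n3[2]))
                + np.arcsin(_clip(n3[0] * n4[0] + n3[1] * n4[1] + n3[2] * n4[2]))
                + np.arcsin(_clip(n4[0] * n1[0] + n4[1] * n1[1] + n4[2] * n1[2]))
            )
            r12 = p2 - p1
            r34 = p4 - p3
            cr = np.cross(r34, r12)
            sgn = cr[0] * r13[0] + cr[1] * r13[1] + cr[2] * r13[2]
            if sgn > 0:
                total += omega
            elif sgn < 0:
                total -= omega
    return total / (4.0 * np.pi), np.sqrt(min_sep)


def gauss_linking_raw(a: ClosedPolygon, b: ClosedPolygon) -> tuple[float, float]:
    """Raw (unrounded) Gauss linking number and minimum curve separation."""
    return _gauss_kernel(
        np.ascontiguousarray(a.vertices), np.ascontiguousarray(b.vertices)
    )


def gauss_linking_number(
    a: ClosedPolygon,
    b: ClosedPolygon,
    tol: float = 0.05,
    min_separation: float = 1e-6,
) -> int:
    """Exact Gauss linking number of two disjoint closed polygons.

    Evaluates the double Gauss integral exactly for polygonal curves via
    per-segment-pair solid angles and rounds to the nearest integer. If the
    raw value strays more than ``tol`` from an integer, the pair is
    re-evaluated at doubled vertex resolution before failing.
    """
    if not (a.contractible and b.contractible):
        raise ValueError("linking number requires contractible (non-winding) curves")
    raw, sep = gauss_linking_raw(a, b)
    if sep <= min_separation:
        raise ValueError(
            f"curves touch or intersect (separation {sep:.2e}); Lk undefined"
        )
    lk = int(np.rint(raw))
    if abs(raw - lk) > tol:
        raw2, _ = gauss_linking_raw(a.refined(), b.refined())
        lk2 = int(np.rint(raw2))
        if abs(raw2 - lk2) > tol:
            raise ValueError(
                f"Gauss sum {raw:.4f} not close to an integer even after refinement"
            )
        return lk2
    return lk


# ---------------------------------------------------------------------------
# crossing-sign oracle

def crossing_sign_linking(
    a: ClosedPolygon,
    b: ClosedPolygon,
    n_projections: int = 3,
    seed: int = 0,
    max_retries: int = 50,
) -> int:
    """Linking number as half the sum of signed inter-curve crossings.

    Projects both curves along a random direction and counts signed
    crossings between strands of A and B (self-crossings are irrelevant to
    Lk). All ``n_projections`` generic directions must agree; degenerate
    projections (near-parallel segments or crossings at segment endpoints)
    are regenerated. This is an oracle independent of the Gauss-integral
    route and shares no code with it.
    """
    rng = np.random.default_rng(seed)
    values = []
    attempts = 0
    # Lattice-like curve pairs can be degenerate in *every* projection
    # (e.g. a vertex of one curve collinear with a segment line of the
    # other), so after the first failure curve B is jittered by a tiny
    # rigid offset, far below any inter-curve separation, which preserves
    # the link type while breaking the coincidence.
    jitter_scale = 0.0
    while len(values) < n_projections:
        if attempts >= max_retries:
            raise RuntimeError("persistent degenerate projections")
        attempts += 1
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        vb = b.vertices
        if jitter_scale > 0:
            vb = vb + rng.normal(scale=jitter_scale, size=3)
        value = _signed_crossings(a.vertices, vb, direction)
        if value is None:
            jitter_scale = 1e-7 * max(b.bounding_radius, 1.0)
            continue
        values.append(value)
    if len(set(values)) != 1:
        raise RuntimeError(f"projection-dependent crossing count: {values}")
    return values[0]


def _signed_crossings(va: np.ndarray, vb: np.ndarray, d: np.ndarray) -> int | None:
    """Half-sum of signed A-B crossings viewed along d; None if degenerate."""
    # orthonormal frame (u, v, d)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    frame = np.stack([u, v, d])
    pa = va @ frame.T
    pb = vb @ frame.T
    na, nb = len(pa), len(pb)
    total = 0
    eps = 1e-9
    for i in range(na):
        a1, a2 = pa[i], pa[(i + 1) % na]
        ta = a2 - a1
        for j in range(nb):
            b1, b2 = pb[j], pb[(j + 1) % nb]
            tb = b2 - b1
            denom = ta[0] * tb[1] - ta[1] * tb[0]
            if abs(denom) < eps:
                # parallel in projection: degenerate only if they overlap;
                # treat conservatively as degenerate if bounding boxes touch
                continue
            rx, ry = b1[0] - a1[0], b1[1] - a1[1]
            s = (rx * tb[1] - ry * tb[0]) / denom
            t = (rx * ta[1] - ry * ta[0]) / denom
            if -eps < s < eps or 1 - eps < s < 1 + eps:
                if -eps * 10 < s < eps * 10 or 1 - 10 * eps < s < 1 + 10 * eps:
                    return None  # crossing at a vertex: regenerate direction
            if eps < s < 1 - eps and eps < t < 1 - eps:
                za = a1[2] + s * (a2[2] - a1[2])
                zb = b1[2] + t * (b2[2] - b1[2])
                if abs(za - zb) < eps:
                    return None  # curves touch in 3-D along this sightline
                over, under = (ta, tb) if za > zb else (tb, ta)
                sign = np.sign(over[0] * under[1] - over[1] * under[0])
                total += int(sign)
    if total % 2 != 0:
        return None  # parity violation: grazing crossing missed, retry
    return total // 2


# ---------------------------------------------------------------------------
# link census

@dataclass
class LinkNetwork:
    """Pairwise linking records and network-level linking observables."""

    records: list[tuple[int, int, tuple[int, int, int], int]]
    n_loops: int
    n_excluded_noncontractible: int = 0

    @property
    def total_linking(self) -> int:
        """Total linking L = sum over loop pairs (and images) of |Lk|."""
        return int(sum(abs(r[3]) for r in self.records))

    @property
    def linking_valence(self) -> float:
        """Average linking valence <Z> = L / N_minloop."""
        if self.n_loops == 0:
            return 0.0
        return self.total_linking / self.n_loops

    @property
    def linked_fraction(self) -> float:
        """Fraction of loops with at least one nonzero linking partner."""
        if self.n_loops == 0:
            return 0.0
        linked = set()
        for i, j, _, lk in self.records:
            if lk != 0:
                linked.add(i)
                linked.add(j)
        return len(linked) / self.n_loops

    def loop_graph(self) -> nx.Graph:
        """Loops as nodes, edges where |Lk| >= 1 (the network of links)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_loops))
        for i, j, shift, lk in self.records:
            if lk != 0:
                g.add_edge(i, j, shift=shift, lk=lk)
        return g


def link_census(
    loops: LoopSet,
    box: PeriodicBox,
    image_cutoff: float | None = None,
) -> LinkNetwork:
    """Gauss linking number between all pairs of minimum loops.

    Every unordered loop pair is evaluated against every periodic image of
    the second loop whose centroid falls within ``image_cutoff`` of the
    first loop's centroid (default: half the box edge plus twice the largest
    loop bounding radius). Pairs whose bounding spheres cannot overlap are
    pruned without evaluating the O(m^2) kernel. Non-contractible
    (box-winding) loops are excluded and counted.
    """
    contractible = [p for p in loops.loops if p.contractible]
    n_excluded = len(loops.loops) - len(contractible)
    n = len(contractible)
    if image_cutoff is None:
        max_rad = max((p.bounding_radius for p in contractible), default=0.0)
        image_cutoff = box.min_edge / 2 + 2 * max_rad
    records: list[tuple[int, int, tuple[int, int, int], int]] = []
    centroids = np.array([p.centroid for p in contractible]).reshape(n, 3)
    radii = np.array([p.bounding_radius for p in contractible])
    max_shift = int(np.ceil(image_cutoff / box.min_edge)) + 1
    shifts = np.array(list(product(range(-max_shift, max_shift + 1), repeat=3)))
    id_sets = [set(p.nanostar_ids) for p in contractible]
    shift_offsets = shifts * box.lengths  # (S, 3)
    for i in range(n):
        # vectorized prune: centroid distance per (j, image)
        cj_all = centroids[None, :, :] + shift_offsets[:, None, :]  # (S, n, 3)
        d_all = np.linalg.norm(cj_all - centroids[i], axis=2)  # (S, n)
        close = d_all <= np.minimum(image_cutoff, radii[i] + radii[None, :])
        close[:, : i + 1] = False
        for s_idx, j in zip(*np.nonzero(close)):
            s = shifts[s_idx]
            try:
                lk = gauss_linking_number(
                    contractible[i], contractible[j].translated(s * box.lengths)
                )
            except ValueError:
                if id_sets[i] & id_sets[j]:
                    continue  # loops sharing a nanostar are joined, not linked
                raise
            records.append((i, j, (int(s[0]), int(s[1]), int(s[2])), lk))
    return LinkNetwork(
        records=records, n_loops=n, n_excluded_noncontractible=n_excluded
    )


def link_percolates(link_net: LinkNetwork, loops: LoopSet, box: PeriodicBox) -> bool:
    """Whether the network of linked loops wraps around the periodic box.

    Walks a spanning tree of each linked component assigning unwrapped loop
    centroids; any cross edge whose recorded image shift disagrees with the
    tree assignment closes a cycle that winds the box, i.e. the link network
    percolates.
    """
    contractible = [p for p in loops.loops if p.contractible]
    g = link_net.loop_graph()
    centroids = {i: p.centroid for i, p in enumerate(contractible)}
    for component in nx.connected_components(g):
        if len(component) < 2:
            continue
        root = min(component)
        assigned = {root: centroids[root]}
        stack = [root]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                data = g.edges[u, v]
                shift = np.array(data["shift"])
                # shift is recorded i -> j with i < j
                if u < v:
                    pos = assigned[u] + (centroids[v] + shift * box.lengths - centroids[u])
                else:
                    pos = assigned[u] + (centroids[v] - shift * box.lengths - centroids[u])
                if v not in assigned:
                    assigned[v] = pos
                    stack.append(v)
                else:
                    if np.abs(pos - assigned[v]).max() > 1e-6:
                        return True
    return False
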