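import itertools

import networkx as nx
import numpy as np
import pytest

from nanolink.core import PeriodicBox
from nanolink.network import NetworkGraph
from nanolink.synthetic import make_torus_link
from nanolink.topology import (
    ClosedPolygon,
    LoopSet,
    crossing_sign_linking,
    find_minimum_loops,
    gauss_linking_number,
    link_census,
    link_percolates,
    unwrap_loop,
)


def _simple_net(edges, positions, edge_len=10.0, shifts=None):
    """Small NetworkGraph fixture with explicit node positions."""
    box = PeriodicBox.cubic(edge_len)
    g = nx.MultiGraph()
    for i, p in enumerate(positions):
        g.add_node(i, pos=np.asarray(p, dtype=float), type=0)
    for k, (u, v) in enumerate(edges):
        shift = np.zeros(3, dtype=np.int64) if shifts is None else np.asarray(
            shifts[k], dtype=np.int64
        )
        g.add_edge(u, v, arms=(0, 0), shift=shift, u=u)
    return NetworkGraph(graph=g, box=box)


def _circle(n=64, radius=1.0, center=(0, 0, 0), plane="xy"):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    c = np.array(center, dtype=float)
    if plane == "xy":
        pts = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], axis=1)
    else:  # xz
        pts = np.stack([np.cos(t), np.zeros_like(t), np.sin(t)], axis=1)
    return ClosedPolygon(radius * pts + c)


from nanolink.synthetic import make_random_loop as _random_fourier_loop


class TestMinimumLoops:
    def test_six_cycle(self):
        hexagon = [(np.cos(a), np.sin(a), 0) for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        net = _simple_net([(i, (i + 1) % 6) for i in range(6)],
                          [(2 + x, 2 + y, 2 + z) for x, y, z in hexagon])
        loops = find_minimum_loops(net)
        assert loops.n_minloop == 1
        assert list(loops.lengths) == [6]

    def test_tree_has_no_loops(self):
        net = _simple_net([(0, 1), (1, 2), (1, 3)],
                          [(1, 1, 1), (2, 1, 1), (3, 1, 1), (2, 2, 1)])
        assert find_minimum_loops(net).n_minloop == 0

    def test_double_bond_excluded(self):
        net = _simple_net([(0, 1), (0, 1)], [(1, 1, 1), (2, 1, 1)])
        assert find_minimum_loops(net).n_minloop == 0

    def test_diamond_fixture_matches_brute_force_oracle(self, diamond_single):
        """Every minimum loop on the periodic diamond net is a hexagon and
        agrees node-by-node with an exhaustive shortest-cycle search."""
        config, net = diamond_single
        loops = find_minimum_loops(net)
        assert set(loops.lengths) == {6}
        # brute-force oracle: shortest cycle through each node by BFS over
        # neighbour pairs in the simple graph with v removed
        simple = nx.Graph(net.graph)
        loop_sets = {frozenset(p.nanostar_ids) for p in loops.loops}
        rng = np.random.default_rng(0)
        for v in rng.choice(net.n_nodes, size=30, replace=False):
            v = int(v)
            best = None
            sub = simple.copy()
            sub.remove_node(v)
            for a, b in itertools.combinations(simple.neighbors(v), 2):
                try:
                    path = nx.shortest_path(sub, a, b)
                except nx.NetworkXNoPath:
                    continue
                if best is None or len(path) + 1 < best:
                    best = len(path) + 1
            assert best == 6
            # the census contains a loop through v of that length
            assert any(v in s for s in loop_sets)

    def test_keep_all_cominimal_superset(self, diamond_single_v4):
        _, net = diamond_single_v4
        one = find_minimum_loops(net)
        all_ = find_minimum_loops(net, keep_all_cominimal=True)
        assert all_.n_minloop >= one.n_minloop
        one_sets = {frozenset(p.nanostar_ids) for p in one.loops}
        all_sets = {frozenset(p.nanostar_ids) for p in all_.loops}
        assert one_sets <= all_sets


class TestUnwrapLoop:
    def test_interior_loop_zero_winding(self):
        hexagon = [(2 + np.cos(a), 2 + np.sin(a), 2) for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        net = _simple_net([(i, (i + 1) % 6) for i in range(6)], hexagon)
        poly = unwrap_loop(tuple(range(6)), net)
        assert poly.contractible
        assert np.array_equal(poly.winding, [0, 0, 0])

    def test_boundary_crossing_loop_closes(self):
        """A hexagon straddling a periodic face still closes with zero
        winding and a sub-1e-9 closure gap."""
        base = [(9.5 + np.cos(a), 5 + np.sin(a), 5) for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        box = PeriodicBox.cubic(10.0)
        wrapped = [tuple(box.wrap(np.array(p))) for p in base]
        net = _simple_net([(i, (i + 1) % 6) for i in range(6)], wrapped)
        poly = unwrap_loop(tuple(range(6)), net)
        assert poly.contractible

    def test_box_winding_cycle_flagged(self):
        """A cycle passing once around the x axis gets winding (1,0,0) and
        is flagged non-contractible."""
        positions = [(2.5 * i, 5, 5) for i in range(4)]
        net = _simple_net(
            [(0, 1), (1, 2), (2, 3), (3, 0)], positions, edge_len=10.0
        )
        poly = unwrap_loop((0, 1, 2, 3), net)
        assert not poly.contractible
        assert abs(int(poly.winding[0])) == 1


class TestGaussLinking:
    def test_hopf_pair(self):
        a = _circle(plane="xy")
        b = _circle(center=(1, 0, 0), plane="xz")
        assert abs(gauss_linking_number(a, b)) == 1

    def test_split_pair_zero(self):
        a = _circle(plane="xy")
        b = _circle(center=(10, 0, 0), plane="xy")
        assert gauss_linking_number(a, b) == 0

    @pytest.mark.parametrize("k", range(6))
    def test_torus_links(self, k):
        a, b = make_torus_link(k)
        assert abs(gauss_linking_number(a, b)) == k

    def test_touching_curves_rejected(self):
        a = _circle(plane="xy")
        b = _circle(plane="xy")
        with pytest.raises(ValueError, match="touch"):
            gauss_linking_number(a, b)

    def test_noncontractible_rejected(self):
        a = _circle()
        b = ClosedPolygon(_circle().vertices, winding=np.array([1, 0, 0]))
        with pytest.raises(ValueError, match="contractible"):
            gauss_linking_number(a, b)

    def test_isotopy_invariance(self):
        """Lk is unchanged by rigid rotation + translation + uniform
        scaling of both curves, and by refining the polygons."""
        a, b = make_torus_link(2)
        lk = gauss_linking_number(a, b)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        move = lambda p: ClosedPolygon(2.7 * p.vertices @ rot.T + [5, -3, 11])
        assert gauss_linking_number(move(a), move(b)) == lk
        assert gauss_linking_number(a.refined(2), b.refined(2)) == lk

    def test_mirror_negates(self):
        a, b = make_torus_link(3)
        mirror = lambda p: ClosedPolygon(p.vertices * np.array([-1, 1, 1]))
        assert gauss_linking_number(mirror(a), mirror(b)) == -gauss_linking_number(a, b)


class TestCrossingOracle:
    def test_hopf_and_split(self):
        a = _circle(plane="xy")
        b = _circle(center=(1, 0, 0), plane="xz")
        assert abs(crossing_sign_linking(a, b, seed=1)) == 1
        c = _circle(center=(10, 0, 0))
        assert crossing_sign_linking(a, c, seed=1) == 0

    def test_agrees_with_gauss_on_random_pairs(self):
        """The projection-and-count oracle and the solid-angle integral give
        identical Lk (including sign) on hundreds of random curve pairs."""
        rng = np.random.default_rng(42)
        n_checked = 0
        trial = 0
        while n_checked < 500:
            trial += 1
            a = _random_fourier_loop(rng)
            b = _random_fourier_loop(rng)
            try:
                g = gauss_linking_number(a, b)
                c = crossing_sign_linking(a, b, seed=trial)
            except (ValueError, RuntimeError):
                continue
            assert c == g
            n_checked += 1


class TestLinkCensus:
    def test_single_loop_trivial(self):
        loops = LoopSet(loops=[_circle()])
        net = link_census(loops, PeriodicBox.cubic(20.0))
        assert net.total_linking == 0
        assert net.linking_valence == 0.0

    def test_totals_identity_and_relabel_invariance(self, diamond_double):
        config, netg = diamond_double
        loops = find_minimum_loops(netg)
        census = link_census(loops, config.box)
        assert census.linking_valence * census.n_loops == pytest.approx(
            census.total_linking
        )
        # reversing loop order relabels; totals are invariant
        reversed_loops = LoopSet(loops=list(reversed(loops.loops)))
        census_r = link_census(reversed_loops, config.box)
        assert census_r.total_linking == census.total_linking
        assert census_r.linked_fraction == census.linked_fraction

    def test_two_sublattice_fixture_fully_linked(self, diamond_double):
        """Interpenetrated valence-3 diamond nets: every hexagon of one net
        is catenated with hexagons of the other."""
        config, netg = diamond_double
        loops = find_minimum_loops(netg)
        census = link_census(loops, config.box)
        assert census.linked_fraction == 1.0
        assert census.linking_valence > 0.7

    def test_single_sublattice_unlinked(self, diamond_single):
        config, netg = diamond_single
        loops = find_minimum_loops(netg)
        census = link_census(loops, config.box)
        assert census.total_linking == 0

    def test_full_diamond_keepall_percolating_link_network(self, diamond_double_v4):
        """With all co-minimal hexagons of the full interpenetrated diamond,
        the link network is total (every loop linked, <Z> = 3) and
        percolates through the periodic box."""
        config, netg = diamond_double_v4
        loops = find_minimum_loops(netg, keep_all_cominimal=True)
        census = link_census(loops, config.box)
        assert census.linked_fraction == 1.0
        assert census.linking_valence >= 1.0
        assert link_percolates(census, loops, config.box)

    def test_oracle_confirms_fixture_links(self, diamond_double):
        """Crossing-sign oracle spot-checks nonzero census records."""
        config, netg = diamond_double
        loops = find_minimum_loops(netg)
        census = link_census(loops, config.box)
        contractible = [p for p in loops.loops if p.contractible]
        nonzero = [r for r in census.records if r[3] != 0][:10]
        assert nonzero
        for i, j, shift, lk in nonzero:
            moved = contractible[j].translated(np.array(shift) * config.box.lengths)
            assert crossing_sign_linking(contractible[i], moved, seed=7) == lk
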