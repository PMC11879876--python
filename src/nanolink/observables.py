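"""Structural observables: mesh size, loop statistics, branch paths, fractality.

The mesh size xi is the diameter of the largest sphere that contains a
random probe point while touching no core bead (random-insertion pore
size). Loop statistics summarize the minimum-loop census; branch-path
statistics measure chain lengths between degree-3 nanostars; the fractal
exponent nu relates the radius of gyration of graph-shortest paths to
their length in nanostars (d_f = 1 / nu).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from numba import njit
from scipy import optimize

from .core import Configuration
from .network import NetworkGraph
from .topology import LoopSet

BEAD_RADIUS = 0.5  # sigma/2: "not touching any bead" uses the bead surface


@dataclass
class MeshSamples:
    """Random-insertion mesh-size samples.

    xi : sphere diameters (sigma); capped entries equal the cap and are
    flagged (an unbounded void in a periodic box is a fixture artifact).
    """

    probes: np.ndarray
    centers: np.ndarray
    xi: np.ndarray
    capped: np.ndarray
    cap: float
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.xi)


@njit(cache=True)
def _surf_dist(c, beads, L):  # pragma: no cover - numba
    best = 1e300
    for i in range(beads.shape[0]):
        d2 = 0.0
        for d in range(3):
            dd = beads[i, d] - c[d]
            dd -= L[d] * np.rint(dd / L[d])
            d2 += dd * dd
        if d2 < best:
            best = d2
    return np.sqrt(best) - BEAD_RADIUS


@njit(cache=True)
def _nearest_dir(c, beads, L, out):  # pragma: no cover
    best = 1e300
    bx = by = bz = 0.0
    for i in range(beads.shape[0]):
        dx = c[0] - beads[i, 0]
        dx -= L[0] * np.rint(dx / L[0])
        dy = c[1] - beads[i, 1]
        dy -= L[1] * np.rint(dy / L[1])
        dz = c[2] - beads[i, 2]
        dz -= L[2] * np.rint(dz / L[2])
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < best:
            best = d2
            bx, by, bz = dx, dy, dz
    norm = np.sqrt(best)
    if norm < 1e-12:  # probe exactly on a bead centre: any direction works
        out[0] = 1.0
        out[1] = 0.0
        out[2] = 0.0
        return -BEAD_RADIUS
    out[0] = bx / norm
    out[1] = by / norm
    out[2] = bz / norm
    return norm - BEAD_RADIUS


@njit(cache=True)
def _grow_sphere(p, beads, L, cap_radius, tol):  # pragma: no cover
    """Constrained ascent: maximize clearance radius keeping p inside."""
    c = p.copy()
    u = np.empty(3)
    best_r = _nearest_dir(c, beads, L, u)
    lam = 0.25
    c_try = np.empty(3)
    for _ in range(400):
        if best_r >= cap_radius:
            return c, cap_radius
        for d in range(3):
            c_try[d] = c[d] + lam * u[d]
        r_try = _surf_dist(c_try, beads, L)
        # keep the probe inside: project the centre back toward p
        dpx = c_try[0] - p[0]
        dpx -= L[0] * np.rint(dpx / L[0])
        dpy = c_try[1] - p[1]
        dpy -= L[1] * np.rint(dpy / L[1])
        dpz = c_try[2] - p[2]
        dpz -= L[2] * np.rint(dpz / L[2])
        dist_p = np.sqrt(dpx * dpx + dpy * dpy + dpz * dpz)
        if dist_p > r_try and dist_p > 1e-12:
            scale = r_try / dist_p
            c_try[0] = p[0] + dpx * scale
            c_try[1] = p[1] + dpy * scale
            c_try[2] = p[2] + dpz * scale
            r_try = _surf_dist(c_try, beads, L)
        if r_try > best_r + 1e-12:
            improve = r_try - best_r
            for d in range(3):
                c[d] = c_try[d]
            best_r = _nearest_dir(c, beads, L, u)
            if improve < tol and lam < 2 * tol:
                break
            lam = min(lam * 1.3, 1.0)
        else:
            lam *= 0.5
            if lam < tol / 4:
                break
    return c, best_r


def sample_mesh_size(
    config: Configuration,
    n_samples: int = 1000,
    seed: int = 0,
    tol: float = 1e-4,
) -> MeshSamples:
    """Random-insertion mesh-size sampling.

    Probe points are uniform in the box; points landing inside a bead are
    rejected and resampled. For each kept probe the largest sphere that
    contains it and touches no bead is grown by constrained local ascent
    (centre climbs the distance-to-nearest-surface field, projected so the
    probe stays inside). xi = 2 * radius, capped at the smallest box edge.
    """
    beads = np.ascontiguousarray(
        config.bead_coords(wrap=True).reshape(-1, 3)
    )
    if len(beads) == 0:
        raise ValueError("degenerate configuration with no beads")
    L = config.box.lengths
    cap = config.box.min_edge
    cap_radius = cap / 2.0
    rng = np.random.default_rng(seed)
    probes = np.empty((n_samples, 3))
    centers = np.empty((n_samples, 3))
    xi = np.empty(n_samples)
    capped = np.zeros(n_samples, dtype=bool)
    n_rejected = 0
    for k in range(n_samples):
        while True:
            p = rng.uniform(0, 1, 3) * L
            if _surf_dist(p, beads, L) > 0:
                break
            n_rejected += 1
        c, r = _grow_sphere(p, beads, L, cap_radius, tol)
        assert _surf_dist(c, beads, L) >= r - 1e-6, "sphere overlaps a bead"
        probes[k] = p
        centers[k] = c
        xi[k] = 2.0 * min(r, cap_radius)
        capped[k] = r >= cap_radius
    return MeshSamples(
        probes=probes, centers=centers, xi=xi, capped=capped, cap=cap,
        n_rejected=n_rejected,
    )


def largest_sphere_at(config: Configuration, probe: np.ndarray, tol: float = 1e-4):
    """Diameter of the largest empty sphere containing one probe point."""
    beads = np.ascontiguousarray(config.bead_coords(wrap=True).reshape(-1, 3))
    L = config.box.lengths
    cap_radius = config.box.min_edge / 2.0
    c, r = _grow_sphere(np.asarray(probe, dtype=float), beads, L, cap_radius, tol)
    return 2.0 * min(r, cap_radius), c


def mesh_size_stats(samples: MeshSamples, n_bins: int = 40) -> dict:
    """Gaussian fit to the mesh-size histogram; mean xi and s.e.m.

    Capped samples are excluded from the fit. Poor Gaussian fits
    (R^2 < 0.9) set ``gaussian_ok = False``.
    """
    xi = samples.xi[~samples.capped]
    if len(xi) < 100:
        raise ValueError("need at least 100 uncapped samples")
    if np.ptp(xi) < 1e-12:
        raise ValueError("degenerate all-equal mesh samples")
    counts, edges = np.histogram(xi, bins=n_bins, density=True)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mu0, s0 = float(xi.mean()), float(xi.std())

    def gauss(x, amp, mu, s):
        return amp * np.exp(-0.5 * ((x - mu) / s) ** 2)

    try:
        popt, pcov = optimize.curve_fit(
            gauss, mids, counts, p0=(counts.max(), mu0, s0), maxfev=10000
        )
        resid = counts - gauss(mids, *popt)
        ss_tot = np.sum((counts - counts.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
        fit_mean = float(popt[1])
        fit_sigma = abs(float(popt[2]))
        fit_mean_err = float(np.sqrt(pcov[1, 1]))
        ok = r2 >= 0.9
    except RuntimeError:
        fit_mean, fit_sigma, fit_mean_err, r2, ok = mu0, s0, s0, 0.0, False
    return {
        "mean_xi": fit_mean if ok else mu0,
        "fit_mean": fit_mean,
        "fit_sigma": fit_sigma,
        "fit_mean_err": fit_mean_err,
        "sample_mean": mu0,
        "sample_sem": float(xi.std(ddof=1) / np.sqrt(len(xi))),
        "r_squared": float(r2),
        "gaussian_ok": bool(ok),
        "n_capped": int(samples.capped.sum()),
    }


# ---------------------------------------------------------------------------
# loop statistics

def loop_statistics(loops: LoopSet | list[LoopSet]) -> dict:
    """P(l_min), mean l_min (+ s.e.m. across frames when several are given),
    and the minimum-loop count N_minloop (mean over frames)."""
    loop_sets = loops if isinstance(loops, list) else [loops]
    all_lengths = np.concatenate([ls.lengths for ls in loop_sets]) if any(
        len(ls) for ls in loop_sets
    ) else np.zeros(0, dtype=int)
    if len(all_lengths) == 0:
        return {
            "distribution": {}, "mean_lmin": float("nan"), "sem_lmin": float("nan"),
            "n_minloop": 0.0,
        }
    values, counts = np.unique(all_lengths, return_counts=True)
    dist = {int(v): float(c) / len(all_lengths) for v, c in zip(values, counts)}
    frame_means = np.array(
        [ls.lengths.mean() for ls in loop_sets if len(ls) > 0]
    )
    sem = (
        float(frame_means.std(ddof=1) / np.sqrt(len(frame_means)))
        if len(frame_means) > 1
        else float(all_lengths.std(ddof=1) / np.sqrt(len(all_lengths)))
        if len(all_lengths) > 1
        else 0.0
    )
    return {
        "distribution": dist,
        "mean_lmin": float(all_lengths.mean()),
        "sem_lmin": sem,
        "n_minloop": float(np.mean([len(ls) for ls in loop_sets])),
    }


# ---------------------------------------------------------------------------
# branch paths

def branch_path_statistics(net: NetworkGraph) -> dict:
    """Shortest chains between branching points (degree-3 nanostars).

    lambda is counted in edges along the through-chain whose interior nodes
    all have degree <= 2; each chain is counted once. Returns the empty
    result when fewer than two branching points exist.
    """
    graph = net.graph
    degree = dict(graph.degree())
    branch = {v for v, d in degree.items() if d == 3}
    if len(branch) < 2:
        return {"lambdas": np.zeros(0, dtype=int), "mean_lambda": float("nan"),
                "n_chains": 0}
    lambdas = []
    visited_edges: set[tuple] = set()
    for start in sorted(branch):
        for _, nbr, key in graph.edges(start, keys=True):
            edge_id = (min(start, nbr), max(start, nbr), key)
            if edge_id in visited_edges:
                continue
            chain_edges = [edge_id]
            prev, node = start, nbr
            length = 1
            while node not in branch and degree[node] == 2:
                nxt = None
                for _, w, k in graph.edges(node, keys=True):
                    eid = (min(node, w), max(node, w), k)
                    if eid != chain_edges[-1]:
                        nxt = (w, eid)
                        break
                if nxt is None:
                    break
                node, eid = nxt
                chain_edges.append(eid)
                length += 1
                if length > graph.number_of_edges():
                    break
            if node in branch:
                visited_edges.update(chain_edges)
                lambdas.append(length)
    lambdas = np.array(lambdas, dtype=int)
    return {
        "lambdas": lambdas,
        "mean_lambda": float(lambdas.mean()) if len(lambdas) else float("nan"),
        "n_chains": int(len(lambdas)),
    }


# ---------------------------------------------------------------------------
# fractal dimension

def fractal_dimension(
    net: NetworkGraph,
    n_paths: int = 200,
    seed: int = 0,
    min_component: int = 20,
) -> dict:
    """Fractal exponent nu from graph-shortest paths: R_g ~ n^nu, d_f = 1/nu.

    Random node pairs are drawn in the largest connected component; each
    graph-shortest path's 3-D radius of gyration (from positions unwrapped
    by minimum-image steps along the path) is regressed against its length
    in nanostars on log-log axes.
    """
    graph = net.graph
    components = sorted(nx.connected_components(graph), key=len, reverse=True)
    if not components or len(components[0]) < min_component:
        raise ValueError(
            f"no connected component with >= {min_component} nodes"
        )
    giant = sorted(components[0])
    simple = nx.Graph(graph.subgraph(giant))
    rng = np.random.default_rng(seed)
    ns, rgs = [], []
    attempts = 0
    while len(ns) < n_paths and attempts < 20 * n_paths:
        attempts += 1
        a, b = rng.choice(len(giant), size=2, replace=False)
        try:
            path = nx.shortest_path(simple, giant[a], giant[b])
        except nx.NetworkXNoPath:  # pragma: no cover - component is connected
            continue
        if len(path) < 3:
            continue
        pts = [net.position(path[0]).astype(float)]
        for u, v in zip(path, path[1:]):
            step = net.box.minimum_image(net.position(v) - net.position(u))
            pts.append(pts[-1] + step)
        pts = np.array(pts)
        rel = pts - pts.mean(axis=0)
        rg = np.sqrt(np.mean(np.sum(rel * rel, axis=1)))
        if rg > 0:
            ns.append(len(path))
            rgs.append(rg)
    if len(ns) < 10:
        raise ValueError("too few usable paths for a fractal-dimension fit")
    from scipy import stats

    res = stats.linregress(np.log(ns), np.log(rgs))
    nu = float(res.slope)
    return {
        "nu": nu,
        "nu_stderr": float(res.stderr),
        "d_f": 1.0 / nu if nu > 0 else float("inf"),
        "n_paths": len(ns),
    }
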