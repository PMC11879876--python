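# nanolink

Simulation and topological analysis of limited-valence nanostar gels.

DNA nanostars — Y-shaped constructs with three sticky-ended arms — form
reversible physical networks whose high-frequency elasticity grows much
faster with concentration (`G'_p ~ rho^2.5`) than classical network
theories predict (phantom network: `G'_p ~ rho`). `nanolink` implements
the full computational chain needed to investigate why: above the overlap
volume fraction these networks interpenetrate, their minimum loops become
mutually catenated, and the density of topological links — not the mesh
size — sets the elastic plateau ("topological elasticity").

The package is a library for:

* **Simulation** — rigid-body Langevin dynamics of valence-3 patchy
  nanostars (7 WCA core beads + 3 Morse patch sites per star, two
  orthogonal binding species, optional microrheology tracer), with a
  symplectic no-squish rotational integrator and an exact OU thermostat.
* **Network structure** — sticky-end bond detection (`r <= 0.2 sigma`,
  one-to-one matching), bond graphs with periodic image shifts, branch
  statistics, interpenetration probes, mesh size by random insertion,
  branch-path and fractal-dimension analysis.
* **Topology** — minimum-loop census, exact Gauss linking numbers of
  polygonal loops with an independent crossing-count oracle, the link
  census (total linking `L`, linking valence `<Z> = L/N_minloop`, linked
  fraction, link-network percolation).
* **Rheology** — tracer-MSD microrheology via the generalized
  Stokes-Einstein relation, Green-Kubo stress-relaxation moduli
  `G(t) = V/(3 k_B T) sum <P_ab(0) P_ab(t)>`, stretched-exponential
  plateau fits `g(t) = a exp(-(t/tau)^b)`, and the elasticity-exponent
  algebra (`G'_p ~ N_minloop <Z>` vs `G'_p ~ N_minloop / xi^3`).
* **Imaging** — two-channel colocalization `I_y = I_r * I_g` for
  detecting interpenetrated binary networks.
* **Synthetic data** — seeded generators with machine-readable ground
  truth: torus links of known `Lk`, interpenetrated diamond lattices with
  catenated hexagons, degree-capped random networks, trap/diffusive MSDs,
  OU stress traces, and mixed/demixed channel images.

## Worked example

Catenation census of an interpenetrated diamond-lattice gel model
(`python examples/02_diamond_topology.py`):

```
nanostars: 432, bonds: 648
minimum loops: N_minloop = 173 (all hexagons, l_min = 6)
total linking L = 148
linking valence <Z> = L / N_minloop = 0.86
linked fraction = 1.00
link network percolates: False
probes seeing >= 2 disjoint subnetworks: 100%
```

Two diamond networks sharing a box without mutual bonds: every hexagonal
minimum loop is linked with rings of the other net (linked fraction 1),
while a single net gives `L = 0` — catenation is a pure interpenetration
effect. With the full 4-valent lattice and all co-minimal hexagons the
linking valence rises to `<Z> = 3` and the link network itself percolates,
the "network-within-network" state.

The other scripts in `examples/` each demonstrate one capability:
linking-number kernels (01), gel simulation and structure (03), GSER and
Green-Kubo rheology on closed-form ground truth (04), elasticity-exponent
predictions (05), and colocalization (06).

A thin CLI mirrors the pipeline for shell use:

```bash
nanolink simulate --n 100 --rho 0.06 --out gel.dump --stress stress.csv --seed 7
nanolink topology --traj gel.dump --frames last:3 --out topo/
nanolink observables --traj gel.dump --mesh-samples 5000 --out obs/
nanolink rheology --stress stress.csv --out moduli.json
```

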