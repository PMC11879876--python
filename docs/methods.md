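# Methods

`nanolink` studies how the high-frequency elasticity of limited-valence
physical gels emerges from their network structure and, above the overlap
concentration, from their topology — the catenation of loops. This note
records the models, algorithms, parameter choices and limitations.

## Units and the coarse-grained nanostar model

All internal quantities are in reduced (LJ-style) units: lengths in the
bead diameter `sigma` (2.5 nm in the DNA mapping, about 8 base pairs),
energies in the characteristic interaction energy `epsilon`, temperatures
in `epsilon/k_B`, and times in the Brownian time `tau_Br = k_B T / Gamma`
with the per-bead friction `Gamma = 1`. Conversion to nm happens only at
I/O edges.

A nanostar is a rigid Y of 7 core beads: a central bead plus three arms of
two beads each at distances `sigma` and `2 sigma`, arms 120 degrees apart
in a plane. Three massless patch sites sit at `2.5 sigma` along the arm
axes, beyond the outermost arm beads, and model the self-complementary
sticky ends. The default geometry is deliberately simple and three-fold
symmetric; arbitrary body-frame coordinates (e.g. inferred from a
finer-grained nucleotide model) can be supplied through the `[geometry]`
section of the run configuration, and everything downstream — the
integrator builds the inertia tensor and principal frame from whatever
beads it is given — adapts.

Two species A and B exist. A patches attract A patches and B attracts B;
A-B pairs never attract, which models orthogonal sticky-end designs used
to build binary interpenetrating networks.

## Interactions

* Core beads repel through a WCA potential (epsilon = 1, sigma = 1,
  cutoff `2^(1/6) sigma`, truncated and shifted at the minimum).
* Patches of compatible species attract through a Morse potential with
  its minimum at patch-patch contact (r = 0): depth `D0 = 20 epsilon`,
  width `alpha = 8 / sigma`, cutoff `0.5 sigma`, truncated-shifted.
  `D0 = 20` makes a bond effectively permanent on 10^3 tau_Br scales
  (the pre-bonded pair test holds for >= 10^3 tau_Br) while remaining a
  physical, reversible bond; `calibrate_bond_lifetime` measures the mean
  unbinding time for other depths.
* A bond is *detected* when two compatible patches sit within
  `0.2 sigma`. Bonds are made one-to-one by geometry (patches at arm
  tips, narrow Morse well) and additionally enforced in detection by
  greedy smallest-distance matching with lowest-index tie-breaks, so the
  analysis stays robust if a user supplies a geometry with crowded
  patches.
* The optional microrheology tracer is a large sphere (default radius
  `2.5 sigma`) coupling to core beads through a purely repulsive WCA with
  contact distance `a + sigma/2`; patches, being zero-volume sites, do
  not interact with it. Its mass is kept small (default 1) so the probe
  is overdamped on every probed lag — a heavy probe's inertial regime
  would contaminate the high-frequency end of the GSER spectrum. It is
  embedded either in the largest available void (`place_tracer`) or, at
  gel densities where no such void exists, by carving an exclusion sphere
  during initial placement (`init_configuration(exclude_sphere=...)`).

## Dynamics

Rigid-body Langevin dynamics in the NVT ensemble, `dt = 0.01 tau_Br`,
`T = 1`. The integrator is a BAOAB splitting:

* B — half kick of the centre-of-mass velocity and world-frame angular
  momentum from the reduced per-molecule force and torque;
* A — half drift; quaternions propagate under the symplectic no-squish
  free-rotor splitting (3-2-1-2-3 axis sequence), which conserves energy
  to ~1e-6 epsilon/tau_Br for free bodies at this time step;
* O — an exact Ornstein-Uhlenbeck update. Bead-wise friction
  `-Gamma v_bead` with matched noise, summed over the 7 unit-mass core
  beads of a rigid body, is exactly a total translational drag
  `7 Gamma` on the COM and a rotational drag tensor `Gamma I_body`; both
  relax at rate `Gamma / m_bead`, so the OU sub-step is exact and the
  sampled kinetic temperature is unbiased (the equipartition test passes
  at 2%). With the thermostat off the scheme reduces to plain velocity
  Verlet (NVE), conserving momentum to 1e-10 and, for non-interacting
  bodies, energy to ~1e-6 epsilon/tau_Br. During *collisions* the usual
  velocity-Verlet error applies: an interacting 20-star gas at
  rho = 0.02 drifts by ~1e-2 epsilon/tau_Br at dt = 0.01, which is normal
  for stiff WCA cores at this step and immaterial under the thermostat.

Equilibration runs with the Morse attraction disabled (a well-mixed
repulsive fluid), then production turns the attraction on. The
instantaneous pressure tensor is the bead-pairwise virial (inter-body
pairs only; rigid constraints contribute through them) plus the molecular
kinetic term. Initial placements are random sequential insertion with
core-core rejection below `0.9 sigma` and uniform SO(3) orientations.

The volume fraction is defined from core-bead volume only,
`rho = N * 7 * (pi sigma^3 / 6) / V`; patches are zero-volume binding
sites. This convention shifts the rho axis by a constant factor relative
to alternatives (e.g. a pervaded-sphere volume) and therefore cannot
affect any fitted exponent.

## Bonded network and interpenetration

The bond graph has one node per nanostar (positioned at its central
bead) and one arm-resolved edge per bond, each carrying the integer
periodic-image shift of the minimum-image bond vector; shifts summed
around a cycle give its winding vector. Branching points are degree-3
nodes; branch paths `lambda` are counted in edges along chains whose
interior nodes have degree <= 2. The fractal exponent `nu` is fitted from
graph-shortest paths between random node pairs in the giant component,
regressing log R_g (positions unwrapped along the path) on log length;
`d_f = 1/nu`. A single self-avoiding realization is not self-averaging,
so reliable estimates pool several configurations.

Interpenetration is probed as in two-colour experiments: spheres of a
given radius (default three mesh sizes) are dropped at random, the bond
subgraph induced on the enclosed nanostars is built, and connected
components below `min_component = 3` nodes are ignored; a probe seeing
two or more remaining components has found mutually non-bonded networks
sharing the same region. Probes retaining fewer than `2 * min_component`
nodes are excluded from the summary fraction as uninformative. The probe
is meaningful only when a *single* network's ball-induced subgraph is
connected; see the fixture caveat below.

## Minimum loops and the linking census

For every nanostar the shortest simple cycle of bonds through it is
found (BFS between each pair of its neighbours with the node removed;
ties broken by the lexicographically smallest canonical sequence), and
loops are deduplicated by nanostar set. Double bonds (2-cycles) are
excluded. A `keep_all_cominimal` flag keeps every co-minimal cycle per
node instead of one; `N_minloop` depends on this choice and the default
(one per node) follows the census definition used for gels, while the
keep-all mode enumerates all shortest cycles of a lattice.

Loop geometry is the closed polygon through the member nanostars'
central beads, unwrapped by minimum-image steps; winding cycles
(nonzero net box crossing) are non-contractible in the torus and are
excluded from linking — their count is reported, and it is the
practical signal that the box is too small for the loop census at that
density.

The Gauss linking number of two disjoint polygons is evaluated exactly
as a sum of signed solid angles over segment pairs, rounded to the
nearest integer (re-evaluated at doubled resolution if the raw sum
strays more than 0.05 from an integer; the kernel also tracks the
minimum inter-curve separation and refuses pairs closer than 1e-6).
An independent oracle computes Lk as half the sum of signed crossings
between the two curves in random planar projections, with degenerate
projections re-drawn; for lattice curves whose degeneracies are
direction-independent (vertices exactly collinear with the other
curve's segment lines), one curve is jittered by ~1e-7 of its radius,
far below any separation, before re-projection. The two routes agree,
including sign, on torus links up to |Lk| = 5 and on hundreds of random
smooth curve pairs.

The census evaluates every unordered loop pair against every periodic
image of the second loop whose centroid lies within an image cutoff
(default: half box edge plus twice the largest loop bounding radius),
after bounding-sphere pruning. Loop pairs that share a nanostar and
geometrically touch are joined, not linked, and are skipped. Totals:
`L = sum |Lk|` over records, linking valence `<Z> = L / N_minloop`,
linked fraction, and percolation of the loop-level link network
(detected by a spanning-tree walk over link records: a cross edge whose
image shift disagrees with the tree assignment closes a box-winding
cycle).

## Mesh size

The pore size `xi` at a random probe point is the diameter of the
largest sphere containing the point and clearing every core-bead surface
(bead radius sigma/2). The sphere is grown by constrained local ascent:
the centre climbs the distance-to-nearest-surface field with an adaptive
step, projected back so the probe stays inside, until the radius improves
by less than 1e-4 sigma. On the simple-cubic oracle (spacing 2 sigma,
probe at the body centre) the method is exact to 1e-3,
`xi = (2 sqrt 3 - 1) sigma`. Probes landing inside a bead are rejected
and resampled; spheres reaching half the smallest box edge are capped and
flagged, and capped samples are excluded from the Gaussian fit of P(xi)
from which `<xi>` and its s.e.m. are read (sample mean and s.e.m. are
reported alongside; fits with R^2 < 0.9 are flagged non-Gaussian).

## Rheology

*Microrheology.* The tracer MSD is time-origin-averaged via FFT on a
log-spaced lag grid. The generalized Stokes-Einstein relation is applied
in the local power-law form: `|G*(1/t)| = k_B T / (pi a MSD(t)
Gamma[1 + alpha(t)])` with `alpha = d ln MSD / d ln t` clipped to [0, 1]
(points with raw slope outside [-0.2, 1.2] are masked as noise), split
into `G' = |G*| cos(pi alpha/2)`, `G'' = |G*| sin(pi alpha/2)`. This
estimator is standard for particle tracking and is exact on power-law
MSDs; on a harmonic-trap MSD it returns the plateau `k / (6 pi a)` in
the plateau (low-frequency) region, and on diffusive MSDs the viscous
line `G'' = omega k_B T / (6 pi a D)`.

*Green-Kubo.* `G(t) = V / (3 k_B T) sum_c <P_c(0) P_c(t)>` over the three
distinct off-diagonal pressure components, each mean-subtracted, with
lags capped at 10% of the series length. Reading the sum as six ordered
pairs doubles the amplitude without changing the shape; the three-term
convention is the default and the alternative is a switch. The elastic
plateau is the `a` of a stretched-exponential fit
`g(t) = a exp(-(t/tau)^b)` (constrained least squares, initialized at
a = G(first lag), tau at the 1/e crossing, b = 1).

*Plateau and crossover.* `G'_p` is read at the largest frequency of the
spectrum (for trap-like spectra whose plateau sits at low frequency,
`storage_at` interpolates anywhere on the grid); the crossover
`omega_0` where `G' = G''` is found by log-linear interpolation of the
sign change and `tau_u = 1/omega_0` tracks the sticky-end unbinding
time.

*Scaling algebra.* Power-law fits are least squares on log-log axes,
optionally segmented at a fixed breakpoint (the overlap volume fraction
`rho* = 0.056` in the gel application). Predicted elasticity exponents
are pure functions of constituent slopes: mesh route
`n_minloop + 3 |s_xi|` (e.g. 1 + 3*0.84 = 3.52), linking route
`n_minloop + s_Z` (1 + 1.4 = 2.4), geometric overlap argument
`1 + 3 s_lmin` (1.3), with errors propagated in quadrature, next to the
phantom-network comparators `rho^1` (prefactor (f-2)/f) and `rho^(1/3)`.

## Colocalization

Channels are normalized to [0, 1] by the 99.9th-percentile reference by
default (robust to hot pixels; plain max is available), with no
background subtraction unless a flat offset is requested. The
colocalization map is the pixelwise product `I_y = I_r * I_g`; `<I_y>`
with the pixel s.d. is reported per image, and batch mode averages over
images with the s.d. across images.

## Synthetic fixtures and what they do (not) show

Every generator is a pure function of its parameters and seed and
carries its ground truth.

* *Torus links*: two curves on a common torus with Lk exactly k
  (k = 0 is a split pair) — oracle inputs for the linking kernels.
* *Interpenetrated diamond*: two diamond nets offset by half a cell
  (the ice-VII motif), girth 6, no cross-edges; hexagons of different
  nets are mutually catenated. Valence is reduced 4 -> 3 by removing all
  bonds of one tetrahedral direction per net; only hexagons avoiding the
  removed direction survive, and rings of the two nets link only when
  their avoided directions differ and come from opposite direction
  families, so the generator draws the two dropped directions from
  opposite families (seeded). Caveats established numerically: the
  valence-3 net's ball-induced subgraphs fragment even for a single
  connected net, so interpenetration probes are validated on the
  `max_valence=4` variant, whose single-net balls are connected; and
  under the one-loop-per-node census the valence-3 double net has
  `<Z> ~ 0.8-0.9` while the full double diamond with all co-minimal
  hexagons has every hexagon linked (`<Z> = 3`) and a percolating link
  network. Passing these fixture tests certifies the census machinery,
  not the statistics of disordered gels.
* *Random geometric network*: degree-capped shortest-first edges; the
  sparse regime is near-tree (loop-census null), the dense regime
  percolates.
* *Trap MSD / OU stress / two-channel images*: closed-form viscoelastic
  and colocalization ground truths, described above where they are used.

## Scaled-down gel runs

The full study protocol (5e5 tau_Br equilibration, 1e6 tau_Br
production, >= 25 configurations per state point, many state points)
is a cluster campaign. The package's own validation runs are desk-scale
by design: N = 60-200 nanostars, 10^2-10^3 tau_Br of production and a
handful of seeds, chosen so the whole test suite completes in minutes
on one CPU. At this scale the robust signals are gelation (bonded-arm
fraction > 0.6-0.8 with a spanning cluster at rho = 0.10), the strict
decrease of the mesh size with rho, and the growth of the loop count;
the topological observables (l_min, <Z>, linked fraction) are
transient and noisy because bonds at D0 = 20 barely rewire on these
timescales and because small boxes make many minimum loops box-winding
(non-contractible), shrinking the census. The trend checks therefore
pool loops over late frames and, where a trend is intrinsically a
steady-state property, the comparison is documented in the test
docstring. Printed-exponent reproduction is out of desk scope by
construction.

## Known limitations

* Orthorhombic boxes only; triclinic input is rejected.
* Hydrodynamic interactions are absent (free-draining Langevin).
* Linking ignores threading and links of second-order (non-minimum)
  loops; knots within single loops are not detected.
* The interpenetration probe's component count is only meaningful when
  a single network's ball-induced subgraph is connected (true for
  disordered gels and the 4-valent diamond; false for the direction-
  pruned valence-3 lattice).
* XYZ files never carry velocities or forces.
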