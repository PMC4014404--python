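# Methods

## Energy model

The package implements a native-centric, all-atom square-well potential.
Heavy atoms are hard spheres of unit mass; hydrogens are never
represented.  Two atoms in residues more than two positions apart along
the chain interact via a square well of depth −1 ε if they are in contact
in the native conformation (native distance within `(sigma, lambda*sigma]`)
and as pure hard spheres otherwise, with
`sigma = alpha*(r0_i + r0_j)` from united-atom van der Waals radii.
Defaults `alpha = 0.80`, `lambda = 1.6`.

The united-atom radius table (`gofold/data/uatom19.json`) assigns
aliphatic CHn carbons 1.84 Å, aromatic CH carbons 1.74 Å, bare carbons
1.70 Å, N 1.65 Å, O 1.52 Å, S 1.85 Å.  The aliphatic value is the
calibration anchor: `lambda*alpha*(2*1.84) = 4.71 Å`, i.e. a 4.7 Å
methyl–methyl cutoff.  Published contact totals for reference structures
depend on the (unpublished) radius table and NMR model choice of the
original parameterization; the package records its own counts and the
relative wild-type-versus-truncated differences when they deviate.

A disulfide bridge is treated through its native contacts like any other
pair; no dedicated bond term is added.

Local geometry is maintained by a bond network: covalent 1–2 bonds
(inferred from native geometry at a 1.9 Å cutoff, 2.3 Å for S–S, or taken
from an explicit bond list for toy structures whose pseudo-bonds are not
covalent-length) plus all 1–3 pairs, each held in an infinite square well
`[d0(1−δ), d0(1+δ)]` with δ = 0.02 around the native distance.  Non-bonded
pairs with chain separation ≤ 2 carry no interaction; their geometry is
controlled by the 1–2/1–3 network.  A consequence worth noting: 1–4 local
pairs are in principle free to approach, but the angle constraints make
that geometrically negligible for the structures generated here.

Static energies return +∞ when any interacting pair sits inside its hard
core, so analysis code cannot silently average over clashed conformations.

## Event-driven dynamics

Between discontinuities atoms fly ballistically, so the dynamics is exact:
the engine schedules, per interacting pair, the earliest crossing of a
hard core, well edge or bond wall (the positive root of
`|r + v t| = boundary`), and resolves it by an impulsive velocity update
along the pair axis.  Well entry adds ε to kinetic energy, escape subtracts
ε when the radial kinetic energy suffices and otherwise reflects; all other
walls reflect elastically.  Every event conserves linear momentum exactly
and total energy exactly (to float64 round-off, measured < 1e-9 ε drift
over 10^6 events).

Scheduling keeps one next-event time per pair; after an event only the
pairs touching the two affected atoms are recomputed, and all positions are
advanced to the event time at every event (O(N) per event).  This flat
per-pair table is the fastest structure at the target system sizes
(tens to a few hundred atoms); neighbour cell lists would only pay off far
beyond that, so they are not used.  The pair separation is snapped exactly
onto the discontinuity before the velocity update, which makes the
well-occupancy bookkeeping immune to round-off drift over arbitrarily long
runs.  The inner loop is numba-compiled.

Temperature (in ε/k_B; k_B = 1) is imposed by an Andersen thermostat:
Poisson-scheduled ghost collisions redraw one atom's velocity from the
Maxwell–Boltzmann distribution at rate `thermostat_rate` per atom per unit
time (default 0.1).  Ghost collisions count toward the event budget.
Initial velocities are Maxwell–Boltzmann with center-of-mass motion
removed.

## Replica exchange and grid calibration

Standard neighbour-swap replica exchange: after every `swap_interval`
events per replica, neighbour pairs of alternating parity attempt a swap,
accepted with probability `min(1, exp[(1/T_i − 1/T_j)(E_i − E_j)])`;
on acceptance configurations are exchanged and velocities rescaled by
`sqrt(T_new/T_old)`.  Samples and swap statistics from the first half of
rounds are discarded: replicas start from a common configuration, and the
early acceptance rate is not representative of equilibrium.

The temperature grid is geometric and grown (8, 12, 16, … up to 40 points)
until a pilot run meets the target acceptance (default 90%).  Because
pilot acceptances are binomial estimates, the stopping rule is
finite-sample aware: the pilot mean must exceed the target by two standard
errors (so the calibrated grid meets the target on independent production
runs, not merely on the pilot that selected it), and each pair must reach
the target minus a noise allowance `max(0.05, 2*sqrt(p(1−p)/n_attempts))`.
Replica round trips (bottom → top → bottom of the ladder) are tracked per
walker and reported in units of swap rounds.

## Thermodynamic analysis

Heat capacity is the energy-fluctuation estimator `Cv(T) = var(E)/T²`
per sampled temperature; T_f is its argmax refined by a parabola through
the three bracketing points (edge maxima are flagged).  WHAM iterates the
dimensionless free energies f_k on binned energy histograms (40 bins
default) in log space to an absolute tolerance of 1e-10 (at most 1e5
iterations; failure reports the histogram-overlap matrix).  Free-energy
surfaces along any recorded coordinate at any target temperature use
per-sample reweighting from the converged f_k; basin populations are
weighted sums over explicit rectangular predicates that must be disjoint.
Statistical error estimation is left to the caller (e.g. block averaging
over trajectory segments); the surfaces themselves carry no error model.

## Clustering and structural metrics

Conformational states are isolated with adaptive k-means under a cluster
radius cutoff: any conformation farther than the cutoff from every current
centroid seeds a new cluster, then assignment and centroid updates iterate
to a fixed point (cap 100 iterations).  The metric is Cα RMSD with
pairwise optimal superposition; centroids are coordinate means after
superposing members onto the current representative frame, re-iterated
twice to suppress reference-frame artifacts.  The representative is the
member closest to the centroid (ties to the lowest index).  A 9 Å cutoff
separates native from intermediate basins on toy trajectories that sample
both, matching the standard choice for this protein family; 5–6 Å suits
single-basin trajectories.

RMSD uses the proper-rotation (Kabsch) solution via
`scipy.spatial.transform.Rotation.align_vectors`; reflections are never
allowed.  Region-fit RMSD superposes on one region (e.g. the conserved
core) and measures another (e.g. a detached strand) without refitting.
SASA is numeric Shrake–Rupley with a deterministic golden-spiral point set
(960 points, probe 1.4 Å by default; both config-exposed since the
published analyses do not state them).  A per-residue fold-change ≥ 1.5
versus native flags "noticeably" exposed residues; the threshold is
config-exposed.

## Monte Carlo ensemble docking

Monomer conformations are rigid.  Two residues are in contact in a dimer
when any atom pair lies inside the attractive range of the intramolecular
potential (`sigma < d <= lambda*sigma`, same alpha/lambda); residue pairs
count once regardless of how many atom pairs realize them, while clashes
(`d < sigma`) count per atom pair.  The docking objective is the single
scalar `E = −n_contacts + 10·n_clashes`, optimized by Metropolis annealing
over rigid moves of monomer B: Gaussian translations along the docking
axis (σ = 1 Å), perpendicular translations (σ = 1 Å) and rotations about
B's center (random axis, σ = 5°), geometric cooling 0.8 → 0.02.  The move
budget is split over several independent annealing restarts from the
initial axis placement (default 4), followed by a short greedy polish with
fine moves; the best-ever pose across all phases is returned.  Restarts
are the robustness mechanism on rugged shape-complementarity landscapes
(a planted lock-and-key optimum is recovered reliably with
n_steps = 80 000 over 20 restarts).

The docking axis runs center-of-geometry to center-of-geometry, with B
placed beyond the maximum attractive range; when the two conformers share
a center (same-frame ensembles), a random axis is drawn instead, which
doubles as approach-direction sampling.  Ensemble docking draws conformer
pairs uniformly with replacement (distinct indices when possible) until
the running mean and SD of the contact count both change by < 1%
(relative) over a 250-pair window, or a 5000-pair cap.

Interface statistics: the density histogram of contact counts on integer
bins (unit-normalized; mode ties resolve to the lowest count), the
residue-pair contact probability map symmetrized over monomer exchange,
the top-k most frequent contacts (k = 50 default; ties by residue
numbers), the per-residue hot-spot profile (probability of joining any
top-k contact within a pose) and partner tables per hot spot.  Contacts
pairing {His, Arg, Lys} with {Phe, Tyr, Trp, His} are flagged as cation-π
candidates; when standard ring/charge-carrier atom names are present the
minimum ring-to-charge distance is annotated against the usual ~4.5 Å
criterion (the model's maximum contact distance, ~4.7 Å, means every such
contact is at or within a fraction of an Å of it).

## Protonation arithmetic

Henderson–Hasselbalch: `f = 1/(1 + 10^(pH − pKa))`, sites independent
(titration coupling between sites is out of scope).  Percent reporting
rounds half away from zero, so imidazole pKa 6.5 gives 17% protonated at
pH 7.2 and 67% at pH 6.2.  Stochastic His assignment draws independent
Bernoulli flags.  Note that published fold-increase ratios for specific
histidines derive from constant-pH MD sampled fractions, not from this
closed form; with a site pKa of 6.0 the closed form gives a 6.5-fold
increase from pH 7.2 to 6.2, and the package reports the closed-form
value.

## Synthetic data

The generators stand in for the upstream inputs a full study would take
from deposited structures and constant-pH MD, at desk scale:

* **Toy natives** — a two-strand anti-parallel hairpin (3.5 Å intra-strand
  spacing, 4.2 Å strand separation, so cross-strand pairs sit inside the
  1.84 Å-carbon square well) or a compact helix-like coil (radius 3.5 Å,
  80° twist, 1 Å rise; contacts between k and k+4/k+5), with 2–4
  pseudo-atoms per residue drawing from the shipped radius table, explicit
  bond lists, and a 0.01 Å seed-controlled jitter.  Feasibility is
  self-checked at build time: clash-free under the model's hard cores and
  at least one native contact per residue.  The 10-residue hairpin folds
  from a melted state to Q > 0.8 at T = 0.25 within 10^6 events.
* **Conformer ensembles** — random backbone torsions about every chain
  bond (these preserve all 1–2/1–3 constraints exactly, because every
  constrained pair crossing a torsion axis has an endpoint on it) with
  clash-free rejection sampling.  The torsion amplitude is calibrated in
  two stages (pilot batch, then batch-level refinement) so the realized
  ensemble-mean Cα RMSD lands within 15% of the target.
* **Detached-tail intermediates** — large random torsions at the
  tail/core junction bond on top of calibrated core noise; accepted
  members must have core-fit RMSD near target, tail RMSD at least 3× the
  core value, and pairwise-distinct tail placements in the core frame.
  This emulates a native-like core with a detached, disordered terminal
  strand.
* **Lock-and-key pairs** — a slab whose lattice spacing (7 Å) exceeds the
  maximum attractive range, so flat approaches earn at most one contact
  per key residue, with an asymmetric polyomino cavity whose rim atoms
  lean inward over the opening (contact-rich walls reachable only by
  insertion) and blocking atoms under the interstitial sites.  The key is
  the matching peg, pre-positioned so the center-to-center axis points
  into the cavity mouth.  The planted pose's contact list is ground truth,
  and a coarse exhaustive 6-DOF scan (24 axis-aligned rotations × 2 Å
  translation grid) certifies at build time that no other placement
  matches the planted contact count; failures regenerate with fresh
  jitter.

What the generators do **not** emulate: real side-chain chemistry and
packing heterogeneity, sequence-dependent energetics, titration-coupled
conformational response, or the conformational breadth of real constant-pH
MD ensembles.  Passing tests therefore demonstrate that the machinery
(model building, exact event dynamics, reweighting, clustering, docking
statistics) behaves correctly on controlled inputs with known answers —
not that any particular biological prediction is reproduced at desk scale.
Published large-scale results (basin populations near the folding
temperature, intermediate Rg expansion, density-histogram ratios between
species, specific hot-spot identities) required cluster-scale sampling
(~5×10^10 events per replica; thousands of docked pairs over constant-pH
MD ensembles) and are outside the test battery's scope.

## Problem sizes and determinism

Default test problem sizes: 10–16-residue toys (20–48 atoms), 10^5–10^6
events per run, 22–80 conformers per ensemble, 10–20 docked pairs per
statistic.  These sizes give stable statistics for every property under
test while keeping the suite fast.  All stochastic components
(dynamics, thermostats, swaps, generators, docking) are reproducible from
explicit integer seeds; the engine is bitwise deterministic given a seed.
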