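# Methods

`lidflex` analyses conformational ensembles of lid-gated alpha/beta-hydrolase
enzymes: how mutations redistribute the motions of the lid that gates the
active site, how residue-residue communication changes, and where a
stabilizing disulfide could be engineered without touching functional sites.
This note records the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## The synthetic ensemble generator

Real production trajectories for systems like this are rarely deposited, so
every statistic in the package is validated against ensembles with *known*
structure, drawn from an anisotropic elastic network model (ANM).

**Model.** C-alpha atoms are nodes; every pair closer than a cutoff
(default 10 Å) is joined by a harmonic spring of uniform stiffness
`gamma` (kcal·mol⁻¹·Å⁻²). The 3N×3N Hessian has six zero modes (rigid
translations/rotations) for a connected, genuinely three-dimensional node
set; the thermal covariance is

    Sigma = k_B T * pseudoinverse(H)    over the vibrational modes,

with k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹ and T = 300 K, matching the
kcal/mol/Å² unit system of the restraint operator. Frames are i.i.d.
Gaussian draws in mode space (no time correlation); all the equal-time
statistics the package computes are unaffected by this simplification, but
autocorrelation analyses would need a Langevin generator.

Planar node sets (e.g. a ring) have additional exactly floppy out-of-plane
modes because ANM springs only resist stretching along the bond axis; the
generator therefore drops *every* mode below 1e-8 of the largest eigenvalue
rather than assuming exactly six.

**Benchmark geometries.** Three deterministic node sets cover the regimes
the stages need:

* a 20-node ring (3.8 Å spacing) — a soft, low-effective-rank spectrum
  whose sampled covariance converges fast; used for covariance/RMSF/DCCM
  recovery;
* a 20-node compact cubic-lattice blob — stiff and isotropic; used when a
  planted mode must dominate a well-conditioned thermal background (PCA
  recovery) and for the six-rigid-mode invariant;
* a 161-residue spherical-spiral "fold" numbered 140–300, so the residue
  numbers of the studied esterase family resolve (catalytic Ser146,
  Glu240, His270, lid 182–199, lid-tracking subset 192–196, frame anchors
  Gln244/Asp284). The spiral is left-handed so that outward lid motion
  projects onto the +z axis of the lid coordinate frame.

**Stiffness.** `gamma` is chosen per benchmark so the closed-form C-alpha
RMSF lies in the sub-Å to ~2 Å range typical of folded proteins: 50 for
the soft ring and spiral, 1 for the stiff lattice. With unphysically soft
springs the per-frame superposition is no longer a small correction and
every fitted statistic acquires bias — visible in testing as RMSF errors
of tens of percent.

**Planted modes.** Two kinds of collective motion can be layered on the
thermal ensemble, with the ground truth recorded in a JSON sidecar:

* *two-state lid opening*: a unit vector supported only on the lid
  C-alphas, along the (protein-centroid → lid-centroid) outward axis, with
  amplitude 0 (closed) or scaled so the lid centroid moves exactly
  `displacement` Å (open), drawn per frame with stated occupancies. The
  drawn state of every frame is stored in `frame_metadata`, because at
  n = 600 the drawn occupancy itself fluctuates binomially (sd ≈ 0.019
  around 2/3) and recovery must be judged against the draw, not only the
  planted parameter.
* *Gaussian collective modes*: any unit 3N vector with Gaussian amplitude.
  For PCA recovery the vector is drawn inside the vibrational subspace —
  a rigid-body component would be silently removed by superposition and
  the planted direction could never be recovered.

Optional rigid-body frame noise (random rotation up to a maximal angle,
uniform translation) exercises the superposition contract: fitted
statistics must be invariant to it.

## Superposition statistics

RMSD uses least-squares (Kabsch) superposition with reflections excluded;
pairwise frame-frame RMSD matrices use the closed-form batched-SVD
identity. RMSF and all covariance statistics are referenced to the
*iteratively converged average structure*: fit all frames to the current
mean, recompute the mean, repeat until the mean moves < 1e-6 Å (max 10
passes). This removes the arbitrary bias of any single reference frame.
Clustering is hierarchical average linkage on the pairwise best-fit RMSD
matrix, cut to k clusters (default 2, the two dominant lid states);
medoids break ties toward the lowest frame index.

## Correlation, PCA, free-energy surfaces

The DCCM uses the scalar-product convention
C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩), giving the familiar [−1, 1]
maps. The superposition mask is configurable independently of the
analysis mask: when a mobile sub-structure (the lid) is the object of
study, fitting on the rigid core avoids smearing a compensating
counter-translation of the core into the leading mode — with an all-atom
fit the lid's share of the PC1 displacement magnitude drops from ~98% to
~50% by center-of-geometry bookkeeping alone.

PCA eigenvector signs are fixed (largest-magnitude coordinate positive)
for cross-platform determinism. Free-energy surfaces are
F = −kT ln(P/P_max) over a 2D histogram (default 60×60, T = 300 K);
empty bins are masked, not assigned a numeric energy. For validating the
Gaussian quadratic well, the radial profile averages occupied bins in
annuli before fitting — individual sparse outer bins carry log-Poisson
noise that says nothing about the estimator.

## Contacts and the dynamical network

A residue pair is in contact when its minimum heavy-atom (or C-alpha)
distance is ≤ 4.5 Å; persistence is the fraction of frames in contact.
The residue network places edges between non-covalent-neighbor pairs
persistent in ≥ 75% of frames — the conventional "default settings" of
molecular-viewer network analysis, written down and configurable. Edge
*length* is −log|C| (|C| clamped to [1e-6, 1−1e-6]), so strongly
correlated pairs are close and shortest paths trace communication routes.

Newman modularity needs a coupling *strength*, not a distance; using
−log|C| there would invert its meaning. Each edge therefore carries both
attributes: `weight` = −log|C| for paths and betweenness, `strength` =
|C| for modularity. Girvan–Newman removes the maximum-betweenness edge
(lexicographic tie-break) and returns the partition of maximal modularity
over the removal sequence, or the first partition with exactly k
communities when k is requested. Inter-community flow sums full-graph
edge betweenness over community-crossing edges (optionally normalized by
the total).

On spatially homogeneous chain-like folds the maximal-modularity
community *count* is degenerate — many partitions into arcs score nearly
equally, and sampling noise in the correlations picks among them. Stable
counts require genuinely modular coupling; the demo (below) plants it
explicitly.

## Lid frame, triad distances, restraints

The lid coordinate frame per conformer: origin at the C-alpha of the
catalytic serine (146), x toward C-alpha 244, y the Gram–Schmidt
orthogonalized direction toward C-alpha 284, z = x×y. Rebuilt per frame,
it cancels global rigid motion to machine precision; the lid-subset
(192–196) centroid's z tracks opening, x/y twist. The frame is recomputed
per frame rather than taken from the average structure precisely because
rigid-motion invariance demands it.

Triad side-chain distances follow the Ser–His–Glu charge-relay hydrogen
bonds: d1 = Ser146 Oγ···His270 Nε2, d2 = Glu240 carboxylate (min over
Oε1/Oε2)···His270 Nδ1; the atom pairs are configurable since C-alpha-only
synthetic models need C-alpha stand-ins. Coincident atoms give distance 0
and a `degenerate` flag rather than an error.

Distance restraints are flat-bottom, upper-side harmonic:
E = k·(d − bound)² for d > bound, else 0, defaults bound = 5.5 Å,
k = 32 kcal·mol⁻¹·Å⁻². Note the k·Δ² convention (AMBER restraint style),
*not* ½k·Δ² — energies differ by 2× between the conventions. The ligand
carbonyl carbon in the catalytic-state restraint triple must be named
explicitly; there is no sensible default. A frame is catalytic-state
compliant when all restraint energies are exactly zero.

## Disulfide screen

S-gamma atoms are modeled from backbone geometry alone: bond 1.81 Å,
Cα–Cβ–Sγ angle 114.6°, χ1 scanned on a 5° grid (resolution/cost balance);
the χ1×χ1′ grid point minimizing |Sγ–Sγ′ − 2.04 Å| is kept. Glycine gets
an ideal Cβ (1.53 Å, 110.5°, L-configuration). Screening windows are the
native-cystine statistics: χ3 within ±30° of −87° or +97° (circular
arithmetic) and both Cα–Cβ–Sγ angles within 114.6° ± 10°; screening-tool
reports sometimes label this angle "Cα-Cβ-Cγ", but cysteine has no Cγ —
the geometrically meaningful angle, implemented and recorded here, is to
Sγ. An S–S distance in [1.5, 2.5] Å must be reachable for a bond to be
formable; geometric impossibility is a recorded failure, not an error.
A Cβ–Cβ ≤ 8 Å pre-filter (generous for any disulfide) keeps the
all-pairs scan tractable.

Site filters reject candidates with any atom within 10 Å of a catalytic
triad residue or within 5 Å of another important region (lid, pocket) —
any-atom distances, configurable — or on a conserved-residue blacklist.
Every rejection records its reason; nothing is silently dropped.

## The demo benchmark

`lidflex demo` builds a two-role comparison on the 161-residue synthetic
fold (600 frames per role, one shared topology). Both roles are chains of
weakly coupled segments: springs crossing a segment seam are softened
20×, and each segment carries its own coherent Gaussian translation mode
(per-atom sd 3 Å). A uniform segment translation preserves intra-segment
geometry exactly, so contacts inside a segment stay fully persistent,
while cross-seam contact distances fluctuate and drop below the 75%
persistence threshold — weak coupling manifests as genuinely broken
contacts, which is the observable the residue network is built on. The
segment-mode directions lie in the plane perpendicular to the lid-frame
z axis (spaced 100° apart), so they shear seams strongly without
contaminating the lid-opening coordinate. The roles differ in coupling
and lid behaviour:

* **wildtype** — four seams (five segments); two-state lid with open
  occupancy 1/3 and 4 Å displacement;
* **mutant** — a single seam (broadly strengthened coupling); a more
  open, more mobile lid (open occupancy 2/3, 6 Å displacement).

The planted contrasts give the report's deltas their expected directions:
higher lid RMSF in the mutant, a positive mean lid-z shift (outward), and
fewer network communities. The community comparison is meaningful
*because* the coupling difference changes the persistent-contact topology
at segment scale; modularity over near-uniform correlation strengths on a
homogeneous fold cannot discriminate counts, and planted correlation-only
contrasts proved seed-unstable. The C-alpha demo uses a 10 Å
residue-contact cutoff for the network stage (appropriate for
C-alpha-only models; the 4.5 Å heavy-atom default applies to all-atom
inputs).

## What passing tests do and do not show

The generator produces i.i.d., harmonic, single-basin (plus planted
two-state) ensembles with exact superposition-removable rigid noise. Tests
against it validate the *estimators* — that DCCM, PCA, FES, RMSF,
clustering, the lid frame, network construction and the design screen
compute what they claim, at known convergence rates. They do not show that
real MD ensembles satisfy the assumptions (anharmonicity, time
correlation, solvent coupling, multi-basin landscapes), and reported
paper-scale quantities of any specific enzyme are out of reach without the
underlying trajectories.

## Problem sizes and determinism

Validation runs use n = 5000 frames for second-moment recovery (CLT-scaled
tolerances), n = 2000 for PCA mode recovery, n = 50,000 samples for the
FES well, n = 600 for two-state occupancy recovery (binomial sd 0.019),
and 600 frames per demo role. Every stochastic operation takes an explicit
seed; identical (seed, parameters) reproduce ensembles bit-exactly, and
the pipeline report is byte-identical on rerun.
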