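# lidflex

Conformational-ensemble analysis for lid-gated enzymes — how distal
mutations reshape the dynamics of an alpha/beta-hydrolase whose active
site is covered by a mobile lid, and where a stabilizing disulfide could
be engineered without harming function.

The package is aimed at computational structural biologists who have (or
simulate) conformational ensembles of esterase/lipase-like enzymes and
want the standard comparative battery as reusable, tested code rather
than one-off scripts:

* **Superposition statistics** — Kabsch superposition, RMSD time series,
  per-residue RMSF about the iteratively converged average structure,
  mass-weighted radius of gyration, average-linkage RMSD clustering with
  population fractions and medoid representatives.
* **Dynamic cross-correlation (DCCM)** — the normalized equal-time
  C-alpha displacement covariance
  `C_ij = <Δr_i·Δr_j> / sqrt(<Δr_i²><Δr_j²>)`, mapping correlated (+1)
  and anti-correlated (−1) motions.
* **PCA and free-energy surfaces** — eigenmodes of the coordinate
  covariance; `F = −kT ln(P/P_max)` over (PC1, PC2) or any pair of
  coordinates; per-residue mode-displacement maps written to B-factors.
* **Contacts and dynamical networks** — contact-persistence maps,
  pocket-residue detection (heavy atoms within 5 Å of a ligand), residue
  graphs with `w_ij = −log|C_ij|` edges on persistent contacts,
  Girvan–Newman communities, inter-community flow from edge betweenness.
* **Lid geometry** — an internal coordinate frame anchored on the
  catalytic region (origin Cα 146, x→Cα 244, y→Cα 284 by default) whose
  z coordinate of the lid centroid tracks opening/closing; catalytic
  triad side-chain distance series (Ser Oγ···His Nε2, Glu Oε···His Nδ1)
  and their 2D free-energy landscapes.
* **Restraint compliance** — flat-bottom upper-bound harmonic restraints
  `E = k(d − b)²` for `d > b` (defaults b = 5.5 Å,
  k = 32 kcal·mol⁻¹·Å⁻²) defining a catalytic-state geometry, and the
  fraction of frames satisfying all of them.
* **Disulfide design** — geometric cystine modeling from backbone
  coordinates with the native-rotamer windows (χ3 within ±30° of −87° or
  +97°, Cα–Cβ–Sγ angles 114.6° ± 10°), plus functional-site filters
  (10 Å triad exclusion, 5 Å lid/pocket exclusion, conservation
  blacklist).
* **A synthetic-ensemble generator** — a seeded anisotropic elastic
  network sampler with closed-form covariance, plantable two-state lid
  modes and rigid-body noise, so every stage above is validated by
  parameter recovery against known ground truth. See
  [docs/methods.md](docs/methods.md) for the model and its limits.

Inputs are PDB structures and multi-model PDB or DCD trajectories;
outputs are CSV/TSV tables and annotated PDBs consumable by standard
plotting tools and molecular viewers.

## Worked example

Build the self-contained synthetic benchmark — a 161-residue fold with a
two-state lid, a "wildtype" role (mostly closed lid, weak segmental
coupling) and a "mutant" role (more open, more mobile lid, strengthened
coupling) — and run the full pipeline on it:

```sh
lidflex demo --seed 5 --outdir demo --no-execute
lidflex run --config demo/config.yaml
```

The consolidated report (`demo/results/report.json`) ends with the
cross-role deltas, every one of them mutant minus wildtype:

```json
{
  "community_count_change": -3,
  "lid_z_shift_A": 0.7608675272934402,
  "rmsf_lid_mean_A": 0.26954846287527046,
  ...
}
```

Reading those numbers: the mutant's lid is more mobile (mean lid RMSF
3.16 Å vs 2.89 Å, a +0.27 Å change), its lid sits 0.76 Å further out
along the opening axis of the catalytic-frame z coordinate (11.83 Å vs
11.07 Å), and its residue network resolves into 3 fewer communities
(5 vs 8) — the strengthened coupling keeps more of the fold communicating
as one block. All three deltas point the way the planted construction
says they must, and the per-role truth sidecars
(`demo/wildtype.truth.json`, …) record the planted parameters so the
recovery can be audited: thresholding the wildtype lid-z trace recovers
an open-state occupancy of ≈ 1/3 and the mutant ≈ 2/3.

Individual stages are available both as CLI subcommands
(`lidflex rmsf`, `dccm`, `fes`, `communities`, `lid`, `triad`,
`restraint`, `ssdesign`, …) and as library functions
(`lidflex.superpose.rmsf_profile`, `lidflex.correlation.dccm`,
`lidflex.network.build_network`, `lidflex.ssdesign.scan_all_pairs`, …).

The selection mini-grammar used by `--mask` options and
`lidflex.io.select` supports `all`, `ca`, `heavy`, `backbone`, `ligand`,
`protein`, `name/resname/chain/element <values…>`,
`resid <n>` / `resid <lo>-<hi>`, boolean `and/or/not` with parentheses,
and `within <r> of <subexpression>`.

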