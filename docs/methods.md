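# Methods

## Constraint network and rigidity

Atoms are nodes; edges are typed distance constraints with a bar
multiplicity in the body-bar convention (every atom a 6-degree-of-freedom
body):

| constraint | detection | bars |
|---|---|---|
| rotatable covalent bond | residue topology templates (ALA/GLY/CYS/SER/HIS) + peptide C–N ≤ 2.0 Å; distance fallback (1.9 Å heavy–heavy, 2.2 Å with S) for residues without a template | 5 |
| torsion-locked bond | carbonyl C=O, peptide bond, disulfide S–S ≤ 2.5 Å, aromatic rings | 6 |
| hydrogen bond | heavy-atom donor(N, O_hydroxyl)–acceptor(O) distance ≤ 3.5 Å, antecedent–donor–acceptor angle ≥ 90°, donor and acceptor more than 3 covalent bonds apart | 5 |
| hydrophobic tether | side-chain C/S of apolar residues within 3.9 Å, at most 3 per atom, nearest first | 2 |

The hydrogen-bond criterion operates on heavy atoms only so no hydrogen
placement is required; the stringency is configurable, and
`rigidity_dilution` decomposes the structure over a ladder of cutoffs so a
user can bracket an uncertain stringency (cluster count is monotone along
the ladder).  Covalent edges never cross a recorded chain break: missing
residues are not modelled, and a numbering gap severs backbone
connectivity.

**Pebble game.**  The molecular decomposition uses the (6, 6) body-bar
pebble game: 6 pebbles per atom; a bar is independent iff 7 pebbles can be
gathered on its endpoints.  This game realises the body-bar rigidity
matroid exactly (Tay), so the result is independent of edge insertion
order; the implementation additionally fixes ascending vertex/edge
iteration so runs are bit-reproducible.  Internal floppy modes are
6N − (independent bars) − 6, clamped at zero for fragments too small to
carry six rigid-body motions.  Rigid clusters are grown over network edges
whose endpoints have zero relative freedom (no 7th pebble collectable),
which partitions the atoms; a 5-bar rotatable bond always leaves one
relative degree of freedom, so hinges never fuse clusters.

A second game handles *point* frameworks with pure distance constraints
(3 pebbles per site; an edge is independent iff 3+3 pebbles sit on the pair
and a 7th free pebble is reachable through the placed-bar digraph, which
enforces the count |E′| ≤ 3|V′| − 6 on the reach).  Generic 3-D bar-joint
rigidity has no exact counting characterisation (the double-banana class
defeats any sparsity rule), so this variant is documented as exact only
for sparsity-detectable dependencies; the test suite checks it against a
brute-force rigidity-matrix rank on structured cases (cliques, chains,
hinged and bridged bodies) and checks the body-bar game against a generic
body-bar rigidity matrix on random frameworks, where agreement is exact.

## Elastic network model

C-alpha nodes, springs of uniform unit stiffness between all pairs within
a 10 Å cutoff (configurable), unit masses: the standard anisotropic network
model.  The 3N×3N Hessian is diagonalised densely up to 200 nodes and by
sparse shift-invert (σ slightly negative, so the factorised matrix is
positive definite) above; both paths agree to 1e−8 on shared cases and are
covered by a test.  Eigenvector sign is fixed by making the first
non-negligible component positive.  A connected network has exactly six
numerically zero modes (< 1e−8 × largest eigenvalue); a disconnected one
raises rather than report a meaningless mode 7.  Mode overlap projects the
six rigid-body motions out of the probe displacement before taking the
cosine.

## Geometric simulation

Ghost template units are built from the decomposition: each rigid cluster
(≥ 3 atoms) is one unit with its input-structure geometry as template;
every atom not strictly interior to such a cluster also gets a bond-local
unit of itself plus its covalent neighbours (≤ 5 atoms).  Adjacent units
overlap on the two atoms of their shared bond: that fixes bond length and
angles while leaving the torsion free, which is exactly the freedom a
rotatable bond should keep.  (Requiring ≥ 3 shared atoms would weld every
dihedral and freeze the molecule.)

Each step of a trajectory (i) displaces every C-alpha target along the
chosen mode, scaled so the largest single C-alpha move is `step_size`
(default 0.05 Å), (ii) drags all atoms of a residue with its C-alpha, and
(iii) relaxes: alternately fit each unit to the current coordinates by
least squares (one batched SVD per unit size), move atoms to the average
of their units' template positions, and push apart non-bonded pairs closer
than `clash_scale` (0.85) × the sum of van der Waals radii, with a small
over-push margin (0.05 Å) so template pull-back does not immediately
re-enter contact.  Pairs within four covalent bonds are governed by the
templates, not steric exclusion, as in conventional nonbonded lists.
Convergence requires the worst template mismatch *and* the worst covalent
bond-length deviation below `tol` (0.125 Å) with residual overlap ≤ 0.05 Å;
this makes the conservation guarantees (bond lengths within tol + 0.01 Å
of their start, rigid-cluster internal RMSD < tol, no non-bonded pair more
than 0.05 Å inside the clash limit) hold at every recorded conformer by
construction.

Jamming is detected two ways: the relaxation itself failing within
`max_iter` (200), or the realised fraction of the intended step (its
projection on the bias) averaging below 0.2 over a 20-step window — a
blocked motion relaxes back onto valid geometry, so silent stalling rather
than divergence is the common failure mode.  A diagnostic relaxation with
steric pushes disabled then classifies the halt: if the step would succeed
without sterics the run is `jammed-steric` (domains in contact), otherwise
`jammed-no-convergence` (connectivity taut, e.g. a fully extended linker).

After every accepted step the bias direction is re-orthogonalised against
the current rigid-body motions and renormalised, so large excursions far
outside the harmonic regime remain meaningful; a frozen-eigenvector mode is
available via `reproject=False`.  Everything is deterministic — identical
inputs give bit-identical trajectories.

For structures supplied only at C-alpha resolution, `ca_subset` plus
`build_ghosts_from_domains` run the same machinery with one rigid unit per
annotated domain, chain-local units along linkers, successive-bead
pseudo-bonds, and a uniform bead radius (2.2 Å) standing in for side-chain
packing.  This coarse mode is what the scaled-down crystal-structure
flexibility checks use.

## Motion analytics

Superposition is the standard Kabsch SVD with the determinant correction
(always a proper rotation).  Tilt/twist at an interface (D1, D2): superpose
each conformer on the reference over D1's C-alphas, obtain the rotation
carrying the reference's D2 onto the conformer's, and decompose it by
swing–twist about the reference inter-centroid axis — twist is the signed
component about the axis in (−180°, 180°], tilt the remaining swing in
[0°, 180°]; both are zero at the reference by construction.  Absolute
angles depend on this axis convention, so cross-implementation comparisons
should use ranges and orderings, not absolute values; the published-number
checks do exactly that.  Interface mobility reports pooled tilt+twist
ranges over the analysed modes, ordered ascending, mirroring the stiff-knee
/ elbow / shoulder comparison for the b–b′, a–b and b′–a′ interfaces of
PDI.  Crystal-form proximity maps an external structure onto the
trajectory's atom ordering by (chain, residue, atom name), computes its
angles against the same reference, and reports the smallest Euclidean gap
in (tilt, twist) over the conformers.

Domain numbering conventions (mature vs translation-product, offset +17
for human PDI) are handled by a single integer shift on the annotation;
active sites are located by scanning for Cys-Gly-His-Cys on consecutively
numbered residues and taking the N-terminal (solvent-exposed, reactive)
cysteine of the first and last motifs, so no per-species residue table is
needed.

## Synthetic structures

The generator emulates multi-domain architecture, not protein chemistry:
poly-alanine chains built residue-by-residue from ideal internal
coordinates (NeRF, φ/ψ = −57°/−47° helical, β-region linkers).  A domain is
a helix–turn–helix bundle (two-residue turn frozen at (160°, −40°),
(−40°, 80°) after a scan for compact, clash-free antiparallel packing);
dense backbone hydrogen bonding makes bundles rigid under the default
network, while the 4-residue β-region linkers carry no hydrogen bonds and
stay flexible.  Dumbbell linker torsions kink the two bundles ~140° apart
so the softest mode is an in-plane hinge (|overlap| ≈ 0.87 with a
constructed hinge displacement); horseshoe linker torsions (found by a
seeded random search, then frozen) turn each successive domain so four
domains close into a planar C with ~17 Å adjacent spacing, and CGHC motifs
are planted near the outer-domain tips with glycine side chains removed.
A seeded 0.03 Å coordinate jitter breaks exact symmetry; output is
bit-identical for fixed spec and seed, and generation fails loudly if the
requested layout self-intersects.

What the toys do **not** emulate: side-chain diversity and packing, real
tertiary topology (trx folds), crystallographic disorder, and solvent.
Passing tests on them therefore validate the machinery — constraint
detection, counting, eigenanalysis, constraint-preserving motion,
angle decomposition — not biological realism; the crystal-structure checks
exist for the latter and require the real PDB entries.

## Problem sizes and defaults

Tests and the acceptance script run the dumbbell (220 atoms) and horseshoe
(~450 atoms) with ≤ 400 conformers per direction at `step_size` 0.05 Å and
`record_every` 1; coarse crystal-structure runs use ≤ 500 recorded
conformers per direction with `record_every` 4.  The full-scale published
runs index conformers to ±5000; absolute conformer indices are not
comparable across implementations (the step geometry behind them is not
recoverable), so only geometric observables are compared.

## Known limitations

- The hydrogen-bond and tether stringency behind the published PDI runs is
  not recoverable; defaults are conventional geometric criteria and the
  dilution ladder brackets them.
- The 3-D point-framework pebble game is heuristic for implied-hinge
  dependencies (double-banana class); the molecular body-bar game does not
  share this limitation.
- Tilt/twist absolute values are convention-dependent (whole-domain
  superposition, inter-centroid axis); only relative statements transfer.
- The geometric simulation has no energetics: jamming marks geometric
  impossibility, not a free-energy barrier, and conformer density along a
  trajectory has no Boltzmann meaning.
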