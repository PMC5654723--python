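# pdiflex

Rapid flexibility simulation for multi-domain proteins, built around the
three-stage geometric approach used to map the motion of protein disulfide
isomerase (PDI):

1. **Rigidity analysis** — the all-atom structure becomes a typed constraint
   network (covalent bonds, hydrogen bonds, hydrophobic tethers) that a
   body-bar pebble game decomposes into rigid clusters and flexible regions.
2. **Elastic-network normal modes** — a C-alpha anisotropic network model
   yields the low-frequency modes; modes 1–6 are rigid-body motions, so the
   softest internal motion is mode 7 (m7), typically the hinge-bending of the
   outer domains for a PDI-like a–b–b′–a′ "horseshoe".
3. **Geometric simulation** — the structure is stepped along a chosen mode
   while rigid "ghost" templates re-enforce local geometry and steric
   exclusion, producing all-atom conformer trajectories (indexed −N…0…+N,
   conformer 0 being the input structure) that run until the conformer budget
   or until the motion jams, e.g. by steric contact between closing domains.

On top of the trajectories the package computes the observables used to
characterise domain motion: active-site Cys Cα–Cα distances, domain-midpoint
distances, Kabsch superposition RMSDs, and per-interface **tilt** (hinge-bend)
and **twist** (axial rotation) angles via a swing–twist decomposition.

The method is purely geometric: it maps what motions the constraints permit,
not their energetics, populations or timescales.  It is intended for
structural biologists who want residue-resolution pictures of large-amplitude
domain motion at a cost of minutes, not MD-scale CPU-hours.

A synthetic-structure generator (poly-alanine helix bundles joined by
flexible linkers, in dumbbell or four-domain horseshoe layouts, with
optional planted CGHC active-site motifs) makes the entire pipeline testable
without any downloads.

## Worked example

```python
from pdiflex import (SyntheticSpec, make_structure, build_network, pebble_game,
                     build_enm, compute_modes, build_ghosts, run_trajectory,
                     domain_midpoint_distance)
from pdiflex.synth import default_annotation

spec = SyntheticSpec(geometry="dumbbell", seed=0)   # two helix bundles, short linker
protein = make_structure(spec)

network = build_network(protein)
clusters = pebble_game(network)
print(f"{clusters.n_clusters()} rigid clusters; "
      f"largest {len(clusters.largest_cluster())} of {len(protein.atoms)} atoms")

modes = compute_modes(build_enm(protein, cutoff=10.0), n_internal=5)
print(f"zero modes: {modes.n_zero}")

ghosts = build_ghosts(protein, clusters, network)
closing = run_trajectory(protein, modes.mode(7), "-", ghosts=ghosts,
                         max_conformers=400, mode_index=7)
mids = domain_midpoint_distance(closing, "D1", "D2", default_annotation(spec))
print(f"halt = {closing.halt_reason_neg}; "
      f"midpoint distance {mids.values[0]:.1f} A -> {mids.min():.1f} A")
```

prints

```
47 rigid clusters; largest 87 of 220 atoms
zero modes: 6
halt = jammed-steric; midpoint distance 24.0 A -> 14.6 A
```

The two helix-bundle domains are recovered as the two large rigid clusters
(87 and 83 atoms) separated by the flexible linker; the elastic network has
exactly the six rigid-body zero modes; and driving mode 7 in the closing
direction brings the domain midpoints from 24.0 Å to 14.6 Å before the
domains make steric contact and the simulation halts — the same behaviour
reported for the closing of oxidized human PDI at full scale.

## Command line

```bash
pdiflex synth --geometry horseshoe --active-sites --out hs.pdb
pdiflex rigidity hs.pdb --out rig/
pdiflex modes hs.pdb --cutoff 10 --n-internal 5
pdiflex all config.yaml        # full pipeline from a YAML RunConfig
```

`pdiflex all` writes, per mode and direction, a multi-model PDB trajectory
plus tidy CSVs of distances and tilt/twist angles, a summary JSON with halt
reasons and extrema, and a YAML manifest from which the run can be
reproduced bit-identically.

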