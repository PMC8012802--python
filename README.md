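# foldcompare

Comparative structural analysis of protein folds, built for the kind of
question that arises when a new crystal structure joins a family of distant
homologs — for example the NTF2-like (VirB8-like) domains of conjugative
type IV secretion systems, where sequence identity between members can drop
near 20% and only the fold itself carries the family signal.

The package chains four analyses behind one library surface and a small CLI:

1. **Sequence-independent pairwise alignment** — iterative TM-align-style
   search: seed correspondences (gapless threading, secondary-structure
   strings, short fragments) refined by alternating Kabsch superposition on
   the currently close residue pairs with dynamic programming on the score
   matrix `S(i,j) = 1/(1 + (d_ij/d0)²)`, where
   `d0 = 1.24·(L−15)^⅓ − 1.8 Å` (clamped at 0.5 Å) and
   `TM = (1/L_norm)·Σ_i 1/(1 + (d_i/d0)²)`.
2. **Progressive multiple structural alignment** — UPGMA guide tree on
   `1 − TM`, profile–profile DP on mean inter-profile Cα distances, one
   round of consensus refinement; yields a column table in one frame plus
   the per-position divergence statistic
   `rms(c) = sqrt( 2/(k(k−1)) · Σ_{i<j} ‖p_i − p_j‖² )`
   over the superposed member Cα positions of each column, binned into a
   violet→red palette, with identical/similar/variable conservation calls.
3. **Structure-based trees** — neighbor joining (Saitou–Nei) or UPGMA on
   all-against-all alignment distances, Robinson–Foulds comparison, and a
   region-deletion robustness experiment (delete a stated segment from
   every member, rebuild, compare topologies and class memberships).
4. **Interface analysis** — Shrake–Rupley solvent-accessible surface area,
   buried surface `BSA = SASA(A) + SASA(B) − SASA(AB)`, per-monomer buried
   fractions, geometric hydrogen-bond (N/O/S ≤ 3.5 Å) and salt-bridge
   (Lys/Arg/His vs Asp/Glu ≤ 4.0 Å) inventories, and enumeration of
   crystal-packing contacts from the unit cell and space-group operators.

A synthetic-structure module generates ideal helices/strands, compact α+β
templates, families diffused along a known tree with Gaussian noise and
indels, and toy assemblies with closed-form (sphere-cap) surface areas, so
every stage is testable without downloading anything.

## Worked example

```python
from foldcompare.synthetic import (FamilySpec, balanced_family_tree,
                                   evolve_family, make_fold_template)
from foldcompare import (align_structures, column_rms_divergence,
                         structure_distance_matrix, build_tree, robinson_foulds)
import numpy as np

template = make_fold_template(120, seed=7)            # 120-residue α+β trace
tree = balanced_family_tree(8, sigma=0.3)             # 0.3 Å noise per branch
traces, truth = evolve_family(FamilySpec(template=template, tree=tree, seed=42))

dm = structure_distance_matrix(traces)                # 1 − TM-score, all pairs
nj = build_tree(dm, "nj")
print("max distance:", round(dm.values.max(), 3))
print("RF to generating tree:", robinson_foulds(nj, truth))

msa = align_structures(traces[:5])
rms = column_rms_divergence(msa).rms
print("columns:", msa.n_columns,
      "median rms divergence (Å):", round(float(np.nanmedian(rms)), 2))
```

Output:

```
max distance: 0.035
RF to generating tree: 0
columns: 120 median rms divergence (Å): 0.63
```

The distance matrix is tight (these are 0.3 Å-noise siblings), neighbor
joining recovers the generating topology exactly (Robinson–Foulds 0), and
the per-column divergence sits near the injected noise level — the numbers
a violet-dominated divergence painting would summarize.

The same flow from a shell:

```bash
foldcompare simulate --n-leaves 8 --length 120 --sigma 0.3 -o fam
foldcompare compare fam/structures/*.pdb -o out        # MSA, profile, tree, bundle
foldcompare interface crystal.pdb --crystal -o contacts
```

Real structures are sliced with the `path:CHAIN:LO-HI` syntax (inclusive
author numbering), e.g. `3ub1.pdb:A:104-231` for a single NTF2-like domain
of a multi-domain chain; `foldcompare fetch` downloads PDB entries when a
network is available.

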