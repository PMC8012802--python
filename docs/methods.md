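# Methods

This note records the models, numerical choices and limitations behind
each stage of the pipeline, in the order data flows through it.

## Structure model and Cα traces

Structures are parsed with gemmi (PDB and mmCIF) into plain dataclasses:
all ATOM/HETATM records are kept, alternate locations retained with the
highest-occupancy conformer flagged primary (ties broken by the
lexicographically first alt-loc id — deterministic and the common
convention). Waters and heteroatoms stay in the model but are excluded
from Cα traces and surface-area computations by default.

Residue selection uses author numbering with insertion codes and
inclusive intervals on both ends, matching how domains are named in the
literature (e.g. a "104–231" central domain). A Cα trace records a chain
break wherever a residue lacks a Cα after alt-loc resolution or a
consecutive Cα–Cα distance falls outside (2.0, 4.5) Å; 4.5 Å is safely
above both trans (≈3.8 Å) and cis (≈2.9 Å) peptide spacing.

PDB output is written by the package's own fixed-width serializer (8.3f
coordinate fields, so round trips are exact to 10⁻³ Å); the unit cell and
space-group symbol go on CRYST1, which lets the gemmi-based reader recover
the symmetry operators on re-read. Coordinates that overflow the field are
refused rather than truncated.

### Crystallographic symmetry

Symmetry mates are generated from the space-group operators combined with
lattice translations in {−1, 0, 1}³, keeping mates with at least one atom
within the contact cutoff of the reference copy, deduplicated by their
Cartesian transform, identity excluded. The ±1 translation range is a
documented limitation: a molecule elongated beyond a full cell edge could
in principle touch a mate two cells away; none of the intended inputs
(compact globular domains in normal cells) approaches that regime.

### Secondary structure

Labels (H/E/C) come from Cα-only distance windows, in the spirit of
P-SEA: a window is helical when d(i,i+2) ∈ [5.0, 6.1], d(i,i+3) ∈
[4.5, 5.7] and d(i,i+4) ∈ [5.5, 7.1] Å, extended when d(i,i+2) ∈
[6.1, 7.4] and d(i,i+3) ∈ [8.5, 11.0] Å; runs shorter than 4 (H) / 3 (E)
are demoted to coil. The thresholds bracket both ideal geometry and the
spread seen in real folds. This assignment is used for reporting topology
and for seeding the alignment search — never as a hard constraint on the
alignment itself.

## Pairwise alignment

The alignment search is an iterative TM-align-style heuristic:

* **Seeds.** Gapless threading windows at sampled offsets plus their half
  windows (so an indel anywhere leaves at least one uncontaminated
  window), a secondary-structure string alignment, and — for traces of
  ≤ 24 residues — dense 4-residue fragment seeds at every register, which
  is what makes the search provably optimal on the small instances the
  brute-force oracle can enumerate.
* **Refinement.** Each seed alternates (i) a Kabsch fit on the currently
  close pairs with (ii) dynamic programming on
  S(i,j) = 1/(1+(d_ij/d0)²). The DP is affine with a gap-opening penalty
  of −0.6 score units and free extension (the TM-align convention), free
  end gaps on both sequences, and deterministic tie-breaking
  (diagonal ≻ up ≻ left). Iteration stops when the pair set repeats or
  after 30 rounds.
* **Scoring.** The converged pair set is re-superposed with the TM-score
  subset-refinement scheme (Kabsch fits on shrinking close-pair subsets,
  cutoff schedule 8 → 3 Å, keeping the frame with the best score sum) and
  the best final TM-score over all seeds wins. d0 follows the standard
  length calibration 1.24·(L−15)^⅓ − 1.8, clamped at 0.5 Å; the
  normalizing length defaults to the shorter chain so that a domain fully
  contained in a longer partner scores ≈ 1, which also makes the distance
  matrix symmetric.

`n_aligned` and `rmsd_aligned` are reported over matched pairs within
5 Å, the convention used when programs quote "r.m.s.d. over N aligned
residues". Everything is deterministic for fixed inputs and parameters.
Non-sequential (topology-independent) and flexible alignment are out of
scope.

## Multiple alignment and divergence profile

Traces are merged progressively along a UPGMA guide tree built on
1 − TM. At each merge the two profiles are first superposed via a
pairwise alignment of their consensus (column-mean) coordinates, then
aligned by DP on 1/(1+(d̄_ij/d0)²) with d̄ the mean Cα distance over all
cross-profile member pairs, iterating the frame correction three times.
After the final merge the frame is anchored on the member with the
highest mean TM-score to the others (deterministic, avoids privileging
the input order) and each member is re-superposed once on the consensus
of the others. One refinement round is the default; more can be
requested, with rapidly diminishing returns on the families tested.

Per column, the divergence statistic is the quadratic mean of all
pairwise distances between superposed member Cα positions,
rms = sqrt(2/(k(k−1)) · Σ_{i<j} d_ij²), computed through the centroid
identity Σ_{i<j} d² = k·Σ‖p_i − p̄‖² (the test suite checks it against the
explicit double loop). The arithmetic-mean variant is exposed as an
option. Columns with fewer than two members are undefined and rendered
grey; the default grey policy also greys any column missing at least one
member, with a `min_members` alternative behind a flag, since published
figures are ambiguous about which convention their grey marks encode.

Conservation calls use a configurable partition of the 20 amino acids;
the default is the standard physicochemical grouping {AVLIMC} {FWY} {KRH}
{DE} {STNQ} {G} {P}, recorded in output metadata because census counts
depend on it. "Identical" means one residue type across the scope,
"similar" means all types within one group, and identical ⇒ similar by
construction.

## Trees

Neighbor joining follows Saitou–Nei with Q-matrix selection; ties are
broken by the lexicographically smallest pair of cluster labels (a
cluster is labelled by its smallest leaf) and negative branch lengths are
clamped to zero with a warning. The final three clusters are resolved by
the closed-form three-point formulas, so additive matrices are recovered
exactly, branch lengths included. UPGMA tracks cluster heights and is
ultrametric by construction. Robinson–Foulds counts bipartitions present
in exactly one tree, in the unrooted convention (splits canonicalized to
the side not containing a fixed reference leaf). Trees serialize to
Newick and round-trip through dendropy; dendropy's own NJ and RF serve as
independent oracles in the test suite, never as the implementation.

The deletion experiment removes a stated author-numbered interval from
every trace, rebuilds the matrix and tree with identical parameters and
reports the RF distance plus, when a class map is given, which classes
changed separability (a class is separable when some bipartition isolates
exactly its members). Deleting more than half of any trace is refused as
a meaningless comparison.

## Surface areas and interfaces

SASA is Shrake–Rupley with a deterministic Fibonacci-spiral quadrature
(default 960 points — two-sphere benchmarks sit within 0.6% of the
closed-form cap areas, and refining to 4000 points moves totals by
< 0.2%), probe radius 1.4 Å, and Bondi van-der-Waals radii (C 1.70,
N 1.55, O 1.52, S 1.80 Å …) shipped as a versioned table. Radius-table
differences are the dominant source of percent-level discrepancies
between surface-area programs, which is why published areas are matched
only to ~10%.

An interface report computes SASA three times with identical parameters
(each partner alone, then the complex) and derives
BSA = SASA(A)+SASA(B)−SASA(AB); both the total BSA and its half (the
PISA-style "interface area") are reported because the literature quotes
either convention without always saying which. Hydrogen bonds are
heavy-atom donor/acceptor pairs (N/O/S, from a per-residue capability
dictionary) within 3.5 Å — crystal structures at typical resolution carry
no hydrogens, so no angular term is applied by default; salt bridges are
Lys NZ / Arg NE,NH1,NH2 / His ND1,NE2 against Asp OD1,OD2 / Glu OE1,OE2
within 4.0 Å. Selections that overlap are refused; a minimum cross
distance under 1.5 Å sets a clash flag on the report. Crystal-contact
mode runs one report per symmetry mate in contact and ranks them by
buried area. No solvation-energy or assembly-significance scoring is
attempted.

## Synthetic data

The generators define the conditions under which the pipeline is
verified:

* Ideal helix: Cα on a 2.3 Å-radius helix, 1.5 Å rise, 100° twist per
  residue (giving the textbook d(i,i+3) ≈ 5.1, d(i,i+4) ≈ 6.2 Å
  signature); ideal strand: 3.3 Å axial spacing with an alternating
  0.8 Å pleat.
* Fold templates: helical and extended segments joined by 3.8 Å steps
  and folded back toward their centroid — compact α+β-like geometry with
  protein-like Cα spacing, but no side chains, no hydrogen-bond lattice
  and no excluded-volume physics. Passing tests therefore demonstrate the
  correctness and robustness of the *algorithms* under controlled
  divergence, not performance on every pathology of real crystal
  structures (alternate conformations of whole segments, register errors,
  domain swaps).
* Families: a template diffused along a known tree, each branch adding
  isotropic Gaussian Cα noise (per-axis σ/√3 so the expected squared
  displacement equals σ²) and, optionally, Poisson-count deletions of
  geometric length. σ = 0.3 Å per branch — roughly coordinate-error
  magnitude per speciation step, totalling ~1 Å between distant leaves —
  is the default family condition; recipes whose expected cumulative
  deletions exceed half the template are refused. Sequences are inherited
  unchanged (no substitution model): conservation logic is tested on
  separately engineered alignments instead.
* Toy assemblies: explicit atom lists with closed-form expected areas
  from pairwise sphere-cap geometry; configurations with triple sphere
  overlaps have no closed form and are refused unless the analytic check
  is disabled. A P2₁-like toy cell places a molecule at the special
  position x = a/2, z = c/2 so its two screw mates (±b/2) are the only
  crystal contacts — exercising the same code path as a real tetragonal
  crystal's 2-fold pair.

All generators are pure functions of (spec, seed).

## Problem sizes

The verification harness uses 8-leaf families of 100–120-residue traces
(20 replicates for topology recovery), 100 random additive matrices of up
to 10 taxa, exhaustive alignment enumeration on 10–11-residue traces
(≈ 10⁵–10⁶ monotone matchings per instance, scored by batched Kabsch
fits), and 17-member engineered alignments for the conservation census.
These sizes keep a full from-scratch verification run in the
few-minutes range on one CPU while leaving every statistic far from its
decision boundary.

## Known limitations

* Sequential alignments only; circular permutations and domain swaps are
  invisible to the DP.
* The symmetry search spans one cell in each direction (see above).
* Secondary-structure assignment is Cα-geometric and coarse near breaks.
* H-bond detection is distance-only by design (no hydrogens available);
  an optional donor-angle criterion exists but is off by default.
* The mean-distance color profile and the census depend on the chosen
  similarity partition; both record their configuration in the output.
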