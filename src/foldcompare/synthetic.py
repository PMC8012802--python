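"""Synthetic structure generators.

Everything the test and acceptance harnesses need without touching the
network: ideal secondary-structure Cα geometry, Gaussian/indel perturbation
of traces, structure families diffused along a known tree (the stand-in for
a fold family retrieved from the PDB), and small all-atom toy assemblies
whose solvent-accessible areas and polar contacts are known in closed form
(sphere-cap geometry).

Every generator is a pure function of its arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SyntheticError
from .structio import (
    AtomRecord,
    CaTrace,
    Chain,
    Residue,
    RigidTransform,
    StructureModel,
)
from .structree import PhyloTree, TreeNode

__all__ = [
    "make_ideal_segment",
    "make_fold_template",
    "perturb",
    "FamilySpec",
    "balanced_family_tree",
    "evolve_family",
    "ToyAtom",
    "ToyAssemblySpec",
    "make_toy_assembly",
    "two_sphere_assembly",
    "hbond_contact_assembly",
    "crystal_contact_assembly",
    "sphere_sasa",
    "two_sphere_areas",
]

# ideal Cα geometry constants
HELIX_RADIUS = 2.3     # Å
HELIX_RISE = 1.5       # Å per residue
HELIX_TWIST = 100.0    # degrees per residue
STRAND_SPACING = 3.3   # Å axial translation per residue
STRAND_PLEAT = 0.8     # Å alternating offset


def make_ideal_segment(
    kind: str, n: int, sequence: str | None = None, structure_id: str = "ideal"
) -> CaTrace:
    """Cα trace of an ideal α-helix or extended β-strand of ``n`` residues."""
    if n < 4:
        raise SyntheticError(f"segment needs >= 4 residues, got {n}")
    if sequence is not None and len(sequence) != n:
        raise SyntheticError("sequence length must equal n")
    i = np.arange(n)
    if kind == "helix":
        theta = np.radians(HELIX_TWIST) * i
        coords = np.c_[
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        ]
    elif kind == "strand":
        coords = np.c_[
            STRAND_SPACING * i,
            STRAND_PLEAT * np.where(i % 2 == 0, 1.0, -1.0),
            np.zeros(n),
        ]
    else:
        raise SyntheticError(f"unknown segment kind {kind!r}")
    seq = sequence or "A" * n
    return CaTrace(
        structure_id=structure_id,
        chain_id="A",
        res_ids=[(int(k) + 1, "") for k in i],
        sequence=seq,
        coords=coords,
    )


def make_fold_template(
    n: int = 160, seed: int = 0, structure_id: str = "template"
) -> CaTrace:
    """A compact α+β-like template trace of ``n`` residues.

    Helical and extended segments joined by short connectors and folded
    back on themselves, emulating the overall geometry of a small α+β
    domain without claiming real protein physics.  Used as the ancestor of
    evolved families.
    """
    rng = np.random.default_rng(seed)
    segs = []
    remaining = n
    kind = "helix"
    direction = np.array([0.0, 0.0, 1.0])
    origin = np.zeros(3)
    coords: list[np.ndarray] = []
    while remaining > 0:
        ln = int(min(remaining, rng.integers(8, 16)))
        seg = make_ideal_segment(kind if ln >= 4 else "strand", max(ln, 4)).coords[:ln]
        # random rotation that keeps segments packed around the origin
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0.5, 2.5)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        seg = seg @ R.T
        if coords:
            start = coords[-1] + direction * 3.8
            seg = seg - seg[0] + start
        coords.extend(seg)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        # drift back toward the centroid to keep the trace compact
        centroid = np.mean(coords, axis=0)
        pull = centroid - coords[-1]
        if np.linalg.norm(pull) > 1e-6:
            direction = 0.5 * direction + 0.5 * pull / np.linalg.norm(pull)
            direction /= np.linalg.norm(direction)
        remaining -= ln
        kind = "strand" if kind == "helix" else "helix"
    arr = np.asarray(coords[:n])
    letters = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n)
    return CaTrace(
        structure_id=structure_id,
        chain_id="A",
        res_ids=[(k + 1, "") for k in range(n)],
        sequence="".join(letters),
        coords=arr,
    )


def perturb(
    trace: CaTrace,
    sigma: float,
    rigid: RigidTransform | None = None,
    indels: list[tuple[int, int]] | None = None,
    seed: int = 0,
    new_id: str | None = None,
) -> CaTrace:
    """Gaussian coordinate noise, optional rigid motion, then deletions.

    Noise is isotropic with per-axis standard deviation sigma/√3, so the
    expected squared displacement norm equals sigma².  ``indels`` are
    inclusive author-numbered deletion intervals.  Deterministic for a
    fixed seed.
    """
    if sigma < 0:
        raise SyntheticError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    coords = trace.coords.copy()
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma / math.sqrt(3.0), coords.shape)
    if rigid is not None:
        coords = rigid.apply(coords)
    out = CaTrace(
        structure_id=new_id or trace.structure_id,
        chain_id=trace.chain_id,
        res_ids=list(trace.res_ids),
        sequence=trace.sequence,
        coords=coords,
        selection=trace.selection,
    )
    if indels:
        lo_all = min(r for r, _ in trace.res_ids)
        hi_all = max(r for r, _ in trace.res_ids)
        for lo, hi in indels:
            if hi < lo or hi < lo_all or lo > hi_all:
                raise SyntheticError(f"indel {lo}-{hi} outside trace numbering")
            out = out.without_range(lo, hi)
    return out


# ---------------------------------------------------------------------------
# families evolved along a tree


@dataclass
class FamilySpec:
    """Recipe for a structure family diffused along a known tree.

    Branch lengths of ``tree`` are interpreted as per-branch Gaussian noise
    σ in Å; ``indel_rate`` is the expected number of deletions per branch,
    each with geometric length (parameter ``indel_length_p``).
    """

    template: CaTrace
    tree: PhyloTree
    indel_rate: float = 0.0
    indel_length_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.indel_rate < 0 or not 0 < self.indel_length_p <= 1:
            raise SyntheticError("invalid indel parameters")
        for node in self.tree.postorder():
            if node.length < 0:
                raise SyntheticError("negative branch length in family tree")


def balanced_family_tree(n_leaves: int, sigma: float, labels: list[str] | None = None) -> PhyloTree:
    """Balanced binary tree with equal per-branch noise ``sigma``."""
    if n_leaves < 2 or n_leaves & (n_leaves - 1):
        raise SyntheticError("n_leaves must be a power of two >= 2")
    labels = labels or [f"t{i+1}" for i in range(n_leaves)]
    nodes = [TreeNode(lab, sigma) for lab in labels]
    while len(nodes) > 1:
        nxt = []
        for a, b in zip(nodes[::2], nodes[1::2]):
            parent = TreeNode(None, sigma)
            parent.add(a)
            parent.add(b)
            nxt.append(parent)
        nodes = nxt
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root=root, rooted=True)


def evolve_family(spec: FamilySpec) -> tuple[list[CaTrace], PhyloTree]:
    """Diffuse the template along the tree; return leaf traces + true tree.

    Each branch adds Gaussian Cα noise of its length (Å) and, at rate
    ``indel_rate``, deletion events of geometric length.  Refuses recipes
    whose accumulated deletions could remove more than half the template.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template
    leaves: list[CaTrace] = []

    depth = _max_depth(spec.tree.root)
    exp_del = spec.indel_rate * depth / spec.indel_length_p
    if exp_del > 0.5 * len(template):
        raise SyntheticError(
            f"expected cumulative deletions ({exp_del:.0f}) exceed half the template"
        )

    def _walk(node: TreeNode, trace: CaTrace) -> None:
        indels: list[tuple[int, int]] = []
        if spec.indel_rate > 0:
            for _ in range(rng.poisson(spec.indel_rate)):
                length = int(rng.geometric(spec.indel_length_p))
                present = [r for r, _ in trace.res_ids]
                if len(present) - length < 0.5 * len(template):
                    continue
                start_idx = int(rng.integers(0, max(1, len(present) - length)))
                indels.append((present[start_idx], present[min(len(present) - 1, start_idx + length - 1)]))
        child_trace = perturb(
            trace,
            sigma=node.length,
            indels=indels or None,
            seed=int(rng.integers(0, 2**31 - 1)),
            new_id=node.label or trace.structure_id,
        )
        if node.is_leaf:
            child_trace.chain_id = ""  # leaf label == tree taxon label
            leaves.append(child_trace)
        else:
            for c in node.children:
                _walk(c, child_trace)

    root = spec.tree.root
    base = perturb(template, sigma=root.length, seed=int(rng.integers(0, 2**31 - 1)))
    for c in root.children:
        _walk(c, base)
    if not leaves:
        _walk(root, template)
    return leaves, spec.tree


def _max_depth(node: TreeNode) -> int:
    if node.is_leaf:
        return 1
    return 1 + max(_max_depth(c) for c in node.children)


# ---------------------------------------------------------------------------
# analytic SASA / contact toys


def sphere_sasa(radius: float, probe: float = 1.4) -> float:
    """Closed-form SASA of an isolated atom: 4π(r+probe)²."""
    return 4.0 * math.pi * (radius + probe) ** 2


def two_sphere_areas(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> tuple[float, float]:
    """Exposed areas of two intersecting solvent-expanded spheres.

    Spherical-cap geometry: each sphere of radius R_i = r_i + probe loses a
    cap of area 2πR_i·h_i where h_i = R_i − (d² + R_i² − R_j²)/(2d).
    """
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return sphere_sasa(r1, probe), sphere_sasa(r2, probe)
    if d <= abs(R1 - R2):
        if R1 < R2:
            return 0.0, sphere_sasa(r2, probe)
        return sphere_sasa(r1, probe), 0.0
    x1 = (d * d + R1 * R1 - R2 * R2) / (2 * d)
    x2 = d - x1
    h1 = R1 - x1
    h2 = R2 - x2
    return (
        4 * math.pi * R1 * R1 - 2 * math.pi * R1 * h1,
        4 * math.pi * R2 * R2 - 2 * math.pi * R2 * h2,
    )


@dataclass
class ToyAtom:
    element: str
    position: tuple[float, float, float]
    chain: str = "A"
    res_name: str = "GLY"
    res_seq: int = 1
    atom_name: str | None = None  # defaults to the element symbol


@dataclass
class ToyAssemblySpec:
    atoms: list[ToyAtom]
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    engineered_bonds: list[tuple[int, int, float]] = field(default_factory=list)
    analytic_check: bool = True
    probe: float = 1.4


def make_toy_assembly(
    spec: ToyAssemblySpec, radii: dict[str, float] | None = None
) -> tuple[StructureModel, dict]:
    """Build a toy all-atom model plus its closed-form SASA expectations.

    Returns the model and a truth dict with per-atom isolated and
    in-complex areas (pairwise sphere-cap geometry) and the engineered
    polar contacts.  Configurations with triple sphere overlaps have no
    closed form and are refused unless ``analytic_check`` is disabled.
    """
    from .chemdata import DEFAULT_VDW_RADIUS, VDW_RADII_BONDI

    radii = radii or VDW_RADII_BONDI
    pos = np.array([a.position for a in spec.atoms], float)
    if not np.all(np.isfinite(pos)):
        raise SyntheticError("non-finite toy atom position")
    rs = np.array([radii.get(a.element.upper(), DEFAULT_VDW_RADIUS) for a in spec.atoms])
    R = rs + spec.probe
    n = len(spec.atoms)
    isolated = np.array([sphere_sasa(r, spec.probe) for r in rs])
    complexed = isolated.copy()
    overlaps: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d < R[i] + R[j]:
                overlaps[i].append(j)
                overlaps[j].append(i)
                a_i, a_j = two_sphere_areas(rs[i], rs[j], d, spec.probe)
                complexed[i] -= isolated[i] - a_i
                complexed[j] -= isolated[j] - a_j
    if spec.analytic_check:
        _refuse_triple_overlaps(pos, R, overlaps)

    chains: dict[str, Chain] = {}
    for k, ta in enumerate(spec.atoms):
        ch = chains.setdefault(ta.chain, Chain(ta.chain))
        res = next(
            (r for r in ch.residues if r.res_seq == ta.res_seq and r.name == ta.res_name),
            None,
        )
        if res is None:
            res = Residue(ta.res_name, ta.res_seq, "")
            ch.residues.append(res)
        res.atoms.append(
            AtomRecord(
                serial=k + 1,
                atom_name=ta.atom_name or ta.element.upper(),
                element=ta.element.upper(),
                alt_loc="",
                res_name=ta.res_name,
                chain_id=ta.chain,
                res_seq=ta.res_seq,
                icode="",
                position=np.array(ta.position, float),
            )
        )
    model = StructureModel(
        id="toy",
        chains=list(chains.values()),
        unit_cell=spec.unit_cell,
        spacegroup=spec.spacegroup,
        sym_ops=[(np.asarray(r, float), np.asarray(t, float)) for r, t in spec.sym_ops],
    )
    truth = {
        "isolated_sasa": isolated,
        "complex_sasa": complexed,
        "total_isolated": float(isolated.sum()),
        "total_complex": float(complexed.sum()),
        "engineered_bonds": list(spec.engineered_bonds),
    }
    for i, j, target in spec.engineered_bonds:
        got = float(np.linalg.norm(pos[i] - pos[j]))
        if abs(got - target) > 1e-6:
            raise SyntheticError(
                f"engineered contact {i}-{j}: distance {got:.6f} != target {target:.6f}"
            )
    return model, truth


def _refuse_triple_overlaps(pos, R, overlaps) -> None:
    for i, neigh in overlaps.items():
        for a in range(len(neigh)):
            for b in range(a + 1, len(neigh)):
                j, k = neigh[a], neigh[b]
                tj = _cap_angle(pos, R, i, j)
                tk = _cap_angle(pos, R, i, k)
                uj = pos[j] - pos[i]
                uk = pos[k] - pos[i]
                ang = math.acos(
                    np.clip(
                        np.dot(uj, uk) / (np.linalg.norm(uj) * np.linalg.norm(uk)),
                        -1.0,
                        1.0,
                    )
                )
                if ang < tj + tk:
                    raise SyntheticError(
                        f"caps from atoms {j} and {k} overlap on atom {i}: "
                        "no closed-form SASA (disable analytic_check to force)"
                    )


def _cap_angle(pos, R, i, j) -> float:
    d = float(np.linalg.norm(pos[i] - pos[j]))
    x = (d * d + R[i] * R[i] - R[j] * R[j]) / (2 * d)
    return math.acos(np.clip(x / R[i], -1.0, 1.0))


# convenience toy constructors -----------------------------------------------


def two_sphere_assembly(
    d: float, elements: tuple[str, str] = ("C", "C")
) -> tuple[StructureModel, dict]:
    """Two atoms on the x axis at center distance ``d``, one per chain."""
    spec = ToyAssemblySpec(
        atoms=[
            ToyAtom(elements[0], (0.0, 0.0, 0.0), chain="A"),
            ToyAtom(elements[1], (d, 0.0, 0.0), chain="B"),
        ]
    )
    return make_toy_assembly(spec)


def hbond_contact_assembly(distance: float = 2.9) -> tuple[StructureModel, dict]:
    """Two-residue contact with one engineered backbone N···O hydrogen bond.

    Chain A carries a glycine whose carbonyl O faces the backbone N of the
    glycine in chain B at the target distance; every other cross-chain
    heavy-atom pair sits beyond the 3.5 Å criterion.
    """
    a_atoms = [
        ToyAtom("N", (-4.4, 1.2, 0.0), "A", "GLY", 1, "N"),
        ToyAtom("C", (-3.4, 0.4, 0.5), "A", "GLY", 1, "CA"),
        ToyAtom("C", (-2.1, 0.9, 0.0), "A", "GLY", 1, "C"),
        ToyAtom("O", (-1.0, 0.25, 0.0), "A", "GLY", 1, "O"),
    ]
    b_atoms = [
        ToyAtom("N", (distance - 1.0, 0.25, 0.0), "B", "GLY", 2, "N"),
        ToyAtom("C", (distance + 0.1, 1.1, 0.3), "B", "GLY", 2, "CA"),
        ToyAtom("C", (distance + 1.5, 0.6, 0.1), "B", "GLY", 2, "C"),
        ToyAtom("O", (distance + 2.6, 1.3, 0.2), "B", "GLY", 2, "O"),
    ]
    spec = ToyAssemblySpec(
        atoms=a_atoms + b_atoms,
        engineered_bonds=[(3, 4, distance)],
        analytic_check=False,  # bonded chains share overlaps; no closed form
    )
    return make_toy_assembly(spec)


def crystal_contact_assembly() -> tuple[StructureModel, dict]:
    """Toy molecule in a P2₁-like cell engineered so screw mates touch.

    The cell is 20×14×20 Å with operators x,y,z and −x,y+½,−z.  The
    molecule sits at (10, y, 10) so the screw mates displaced by ±7 Å in y
    are its only contacts within a 4 Å cutoff.
    """
    ops = [
        (np.eye(3), np.zeros(3)),
        (np.diag([-1.0, 1.0, -1.0]), np.array([0.0, 0.5, 0.0])),
    ]
    atoms = [
        ToyAtom("C", (10.0, 0.0, 10.0), "A", "GLY", 1, "CA"),
        ToyAtom("N", (10.0, 2.0, 10.0), "A", "GLY", 1, "N"),
        ToyAtom("O", (10.0, 4.0, 10.0), "A", "GLY", 1, "O"),
    ]
    spec = ToyAssemblySpec(
        atoms=atoms,
        unit_cell=(20.0, 14.0, 20.0, 90.0, 90.0, 90.0),
        spacegroup="P 1 21 1",
        sym_ops=ops,
        analytic_check=False,
    )
    return make_toy_assembly(spec)
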