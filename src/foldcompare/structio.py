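"""Structure reading/writing, Cα-trace extraction, crystallographic symmetry
expansion and coarse Cα-geometry secondary structure.

Parsing is delegated to :mod:`gemmi` (PDB and mmCIF, including unit cell and
space-group operators); the in-memory model is a small set of plain
dataclasses that the rest of the package consumes.  PDB output is written by
this module directly in the fixed-width format, so that write→read round
trips cross-check our serializer against gemmi's parser.
"""

from __future__ import annotations

import copy
import itertools
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .chemdata import three_to_one
from .errors import (
    ChainLookupError,
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    ParseError,
    SerializationError,
    TraceError,
    UnsupportedStructureError,
)

# Cα–Cα spacing bounds: consecutive distances outside (2.0, 4.5) Å flag a
# chain break (trans peptide ≈ 3.8 Å, cis ≈ 2.9 Å).
CA_CA_MIN = 2.0
CA_CA_MAX = 4.5


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t in Cartesian Å."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def is_proper(self, tol: float = 1e-8) -> bool:
        r = self.rotation
        return (
            np.allclose(r @ r.T, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) < tol
        )


@dataclass
class AtomRecord:
    serial: int
    atom_name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    het: bool = False
    is_primary: bool = True  # highest-occupancy alt-loc conformer

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ParseError(f"non-finite coordinates for atom {self.serial}")


@dataclass
class Residue:
    name: str
    res_seq: int
    icode: str
    atoms: list[AtomRecord] = field(default_factory=list)
    het: bool = False

    @property
    def key(self) -> tuple[int, str]:
        return (self.res_seq, self.icode)

    @property
    def is_water(self) -> bool:
        return self.name in ("HOH", "WAT", "DOD")

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    def atom(self, name: str, primary_only: bool = True) -> AtomRecord | None:
        for a in self.atoms:
            if a.atom_name == name and (a.is_primary or not primary_only):
                return a
        return None

    @property
    def ca(self) -> AtomRecord | None:
        return self.atom("CA")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """Parsed all-atom structure with optional unit cell and symmetry."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    spacegroup: str | None = None
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    assembly_ops: list[RigidTransform] | None = None
    source_format: str = "pdb"

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise ChainLookupError(f"chain {chain_id!r} not in structure {self.id!r}")

    def atoms(self) -> Iterator[AtomRecord]:
        for c in self.chains:
            for r in c.residues:
                yield from r.atoms

    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def protein_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            for r in c.residues:
                if not r.is_water and r.one_letter != "X":
                    yield r


@dataclass
class CaTrace:
    """Ordered Cα coordinates and residue identities for one chain slice.

    The currency of every structural comparison in the package.
    """

    structure_id: str
    chain_id: str
    res_ids: list[tuple[int, str]]
    sequence: str
    coords: np.ndarray
    selection: tuple[int, int] | None = None
    breaks: frozenset[int] = frozenset()  # index i: break between i and i+1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.res_ids) != len(self.coords) or len(self.sequence) != len(self.coords):
            raise TraceError("res_ids, sequence and coords must have equal length")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def label(self) -> str:
        if not self.chain_id:
            return self.structure_id
        return f"{self.structure_id}_{self.chain_id}"

    def subset(self, keep: Sequence[int]) -> "CaTrace":
        keep = list(keep)
        return CaTrace(
            self.structure_id,
            self.chain_id,
            [self.res_ids[i] for i in keep],
            "".join(self.sequence[i] for i in keep),
            self.coords[keep],
            self.selection,
        )

    def without_range(self, lo: int, hi: int) -> "CaTrace":
        """Drop residues with author number in [lo, hi] inclusive."""
        keep = [i for i, (seq, _ic) in enumerate(self.res_ids) if not lo <= seq <= hi]
        if not keep:
            raise EmptySelectionError(
                f"deleting {lo}-{hi} removes every residue of {self.label}"
            )
        return self.subset(keep)


# ---------------------------------------------------------------------------
# reading


def _looks_like_text(source) -> bool:
    return isinstance(source, str) and "\n" in source


def _detect_text_format(text: str) -> str:
    head = text.lstrip()[:4096]
    if head.startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _gemmi_read(source, fmt: str) -> gemmi.Structure:
    if _looks_like_text(source):
        if fmt == "auto":
            fmt = _detect_text_format(source)
        if fmt == "pdb":
            return gemmi.read_pdb_string(source)
        if fmt == "mmcif":
            block = gemmi.cif.read_string(source).sole_block()
            return gemmi.make_structure_from_block(block)
        raise FormatError(f"unknown format {fmt!r}")
    path = os.fspath(source)
    if fmt == "auto":
        return gemmi.read_structure(path)
    if fmt == "pdb":
        return gemmi.read_pdb(path)
    if fmt == "mmcif":
        block = gemmi.cif.read(path).sole_block()
        return gemmi.make_structure_from_block(block)
    raise FormatError(f"unknown format {fmt!r}")


def read_structure(source, format: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF structure into a :class:`StructureModel`.

    ``source`` may be a filesystem path or the raw file text.  All ATOM and
    HETATM records are captured, alternate locations retained (the highest
    occupancy conformer of each atom is flagged primary, ties broken by
    alt-loc id), and unit cell plus space-group symmetry operators are kept
    when present.
    """
    if format not in ("auto", "pdb", "mmcif"):
        raise FormatError(f"unknown format {format!r}")
    try:
        st = _gemmi_read(source, format)
    except (RuntimeError, ValueError) as exc:
        name = "<string>" if _looks_like_text(source) else str(source)
        raise ParseError(f"failed to parse {name}: {exc}") from exc

    src_fmt = format
    if src_fmt == "auto":
        src_fmt = (
            _detect_text_format(source)
            if _looks_like_text(source)
            else ("mmcif" if str(source).endswith((".cif", ".cif.gz", ".mmcif")) else "pdb")
        )

    model_id = st.name or "structure"
    cell = None
    if st.cell and st.cell.a > 1.0 and st.cell.volume > 2.0:
        cell = (st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
    sg_name = st.spacegroup_hm or None
    sym_ops: list[tuple[np.ndarray, np.ndarray]] = []
    if sg_name:
        sg = gemmi.find_spacegroup_by_name(sg_name)
        if sg is not None:
            for op in sg.operations():
                rot = np.array(op.rot, float) / op.DEN
                tran = np.array(op.tran, float) / op.DEN
                det = np.linalg.det(rot)
                if abs(abs(det) - 1.0) > 1e-6:
                    raise ParseError(f"symmetry operator with |det|={det:.6f} in {model_id}")
                sym_ops.append((rot, tran))

    assembly_ops: list[RigidTransform] | None = None
    if len(st.assemblies) > 0:
        ops = []
        for gen in st.assemblies[0].generators:
            for oper in gen.operators:
                tr = oper.transform
                ops.append(
                    RigidTransform(
                        np.array(tr.mat.tolist(), float), np.array(tr.vec.tolist(), float)
                    )
                )
        assembly_ops = ops or None

    if len(st) == 0:
        raise EmptyStructureError(f"{model_id}: no models")
    gmodel = st[0]
    chains: list[Chain] = []
    serial = 0
    for gchain in gmodel:
        chain = Chain(gchain.name)
        for gres in gchain:
            het = gres.het_flag == "H"
            res = Residue(gres.name, gres.seqid.num, (gres.seqid.icode or " ").strip(), het=het)
            for gatom in gres:
                serial += 1
                res.atoms.append(
                    AtomRecord(
                        serial=gatom.serial or serial,
                        atom_name=gatom.name,
                        element=gatom.element.name.upper(),
                        alt_loc=(gatom.altloc or "").strip(),
                        res_name=gres.name,
                        chain_id=gchain.name,
                        res_seq=gres.seqid.num,
                        icode=(gres.seqid.icode or " ").strip(),
                        position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=float(gatom.occ),
                        b_factor=float(gatom.b_iso),
                        het=het,
                    )
                )
            if res.atoms:
                chain.residues.append(res)
        if chain.residues:
            chains.append(chain)

    model = StructureModel(
        id=model_id,
        chains=chains,
        unit_cell=cell,
        spacegroup=sg_name,
        sym_ops=sym_ops,
        assembly_ops=assembly_ops,
        source_format=src_fmt,
    )
    if model.n_atoms() == 0:
        raise EmptyStructureError(f"{model_id}: no atoms")
    _flag_primary_altlocs(model)
    return model


def _flag_primary_altlocs(model: StructureModel) -> None:
    for chain in model.chains:
        for res in chain.residues:
            groups: dict[str, list[AtomRecord]] = {}
            for a in res.atoms:
                groups.setdefault(a.atom_name, []).append(a)
            for atoms in groups.values():
                # highest occupancy wins; tie → lexicographically first alt-loc
                best = min(atoms, key=lambda a: (-a.occupancy, a.alt_loc))
                for a in atoms:
                    a.is_primary = a is best


# ---------------------------------------------------------------------------
# selection helpers


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    res_range: tuple[int, int] | None = None,
    include_het: bool = False,
    include_water: bool = False,
    primary_only: bool = True,
) -> list[AtomRecord]:
    """Flat atom selection by chain and inclusive author residue range."""
    chains = [model.chain(chain)] if chain is not None else model.chains
    out: list[AtomRecord] = []
    for c in chains:
        for r in c.residues:
            if r.is_water and not include_water:
                continue
            if r.het and not r.is_water and not include_het:
                continue
            if res_range is not None and not res_range[0] <= r.res_seq <= res_range[1]:
                continue
            out.extend(a for a in r.atoms if a.is_primary or not primary_only)
    return out


def extract_ca_trace(
    model: StructureModel,
    chain: str,
    res_range: tuple[int, int] | None = None,
) -> CaTrace:
    """Slice a chain to its Cα trace over an inclusive author-numbered range.

    Residues without a Cα (after alt-loc resolution) are skipped and the gap
    flagged as a chain break, as is any consecutive-Cα distance outside
    (2.0, 4.5) Å.
    """
    ch = model.chain(chain)
    res_ids: list[tuple[int, str]] = []
    letters: list[str] = []
    coords: list[np.ndarray] = []
    breaks: set[int] = set()
    skipped_before_next = False
    for res in ch.residues:
        if res.het or res.is_water:
            continue
        if res_range is not None and not res_range[0] <= res.res_seq <= res_range[1]:
            continue
        ca = res.ca
        if ca is None:
            skipped_before_next = True
            continue
        if skipped_before_next and coords:
            breaks.add(len(coords) - 1)
        skipped_before_next = False
        res_ids.append(res.key)
        letters.append(res.one_letter)
        coords.append(ca.position)
    if not coords:
        raise EmptySelectionError(
            f"chain {chain!r} range {res_range} selects no Cα in {model.id!r}"
        )
    arr = np.asarray(coords)
    if len(arr) > 1:
        gaps = np.linalg.norm(np.diff(arr, axis=0), axis=1)
        for i, g in enumerate(gaps):
            if not CA_CA_MIN < g < CA_CA_MAX:
                breaks.add(i)
    return CaTrace(
        structure_id=model.id,
        chain_id=chain,
        res_ids=res_ids,
        sequence="".join(letters),
        coords=arr,
        selection=res_range,
        breaks=frozenset(breaks),
    )


# ---------------------------------------------------------------------------
# crystallographic symmetry


def _orth_matrix(cell: tuple[float, float, float, float, float, float]) -> np.ndarray:
    """Standard PDB orthogonalization matrix (a along x, b in xy plane)."""
    a, b, c, al, be, ga = cell
    al, be, ga = map(math.radians, (al, be, ga))
    cos_al, cos_be, cos_ga, sin_ga = math.cos(al), math.cos(be), math.cos(ga), math.sin(ga)
    v = math.sqrt(
        1 - cos_al**2 - cos_be**2 - cos_ga**2 + 2 * cos_al * cos_be * cos_ga
    )
    return np.array(
        [
            [a, b * cos_ga, c * cos_be],
            [0.0, b * sin_ga, c * (cos_al - cos_be * cos_ga) / sin_ga],
            [0.0, 0.0, c * v / sin_ga],
        ]
    )


def _transform_model(model: StructureModel, tr: RigidTransform, new_id: str) -> StructureModel:
    mate = copy.deepcopy(model)
    mate.id = new_id
    for atom in mate.atoms():
        atom.position = tr.apply(atom.position)
    return mate


def expand_symmetry(
    model: StructureModel, contact_cutoff: float = 5.0
) -> list[tuple[RigidTransform, StructureModel]]:
    """Enumerate crystallographic symmetry mates in contact with the model.

    Applies every space-group operator combined with lattice translations in
    {-1, 0, 1}³ and keeps the mates having at least one atom within
    ``contact_cutoff`` Å of the reference copy.  The identity is excluded and
    mates are deduplicated by their Cartesian transform.
    """
    if model.unit_cell is None or not model.sym_ops:
        raise UnsupportedStructureError(
            f"{model.id}: unit cell and symmetry operators required"
        )
    orth = _orth_matrix(model.unit_cell)
    frac = np.linalg.inv(orth)
    ref = np.array([a.position for a in model.atoms() if not _is_water_atom(a)])
    tree = cKDTree(ref)
    seen: set[tuple] = set()
    mates: list[tuple[RigidTransform, StructureModel]] = []
    for rot_f, tran_f in model.sym_ops:
        r_cart = orth @ rot_f @ frac
        for shift in itertools.product((-1, 0, 1), repeat=3):
            t_cart = orth @ (tran_f + np.array(shift, float))
            if np.allclose(r_cart, np.eye(3), atol=1e-9) and np.allclose(
                t_cart, 0.0, atol=1e-9
            ):
                continue
            key = tuple(np.round(np.concatenate([r_cart.ravel(), t_cart]), 6))
            if key in seen:
                continue
            moved = ref @ r_cart.T + t_cart
            dist, _ = tree.query(moved, k=1, distance_upper_bound=contact_cutoff)
            if not np.any(np.isfinite(dist)):
                continue
            seen.add(key)
            tr = RigidTransform(r_cart, t_cart)
            mates.append((tr, _transform_model(model, tr, f"{model.id}_sym{len(mates)+1}")))
    return mates


def _is_water_atom(atom: AtomRecord) -> bool:
    return atom.res_name in ("HOH", "WAT", "DOD")


# ---------------------------------------------------------------------------
# secondary structure from Cα geometry

#: Cα-distance windows for coarse secondary-structure assignment
#: (P-SEA-style criteria on d(i,i+2), d(i,i+3), d(i,i+4) in Å).
SS_THRESHOLDS = {
    "helix_d2": (5.0, 6.1),
    "helix_d3": (4.5, 5.7),
    "helix_d4": (5.5, 7.1),
    "strand_d2": (6.1, 7.4),
    "strand_d3": (8.5, 11.0),
    "min_run_E": 3,
    "min_run_H": 4,
}


def assign_secondary_structure(trace: CaTrace) -> str:
    """Per-residue H/E/C labels from Cα-only distance criteria.

    Helical and extended windows are detected from the d(i,i+2), d(i,i+3)
    and d(i,i+4) distance signature; runs shorter than 3 (E) or 4 (H)
    residues are demoted to coil.
    """
    n = len(trace)
    if n < 5:
        raise TraceError(f"secondary structure undefined for {n} residues (< 5)")
    x = trace.coords
    d = {k: np.linalg.norm(x[k:] - x[:-k], axis=1) for k in (2, 3, 4)}
    labels = np.full(n, "C", dtype="<U1")
    th = SS_THRESHOLDS

    def _within(v, key):
        lo, hi = th[key]
        return lo <= v <= hi

    for i in range(n - 4):
        if i in trace.breaks or (i + 1) in trace.breaks or (i + 2) in trace.breaks:
            continue
        if (
            _within(d[2][i], "helix_d2")
            and _within(d[3][i], "helix_d3")
            and _within(d[4][i], "helix_d4")
        ):
            labels[i : i + 5] = "H"
    for i in range(n - 3):
        if labels[i] == "H":
            continue
        if _within(d[2][i], "strand_d2") and _within(d[3][i], "strand_d3"):
            sl = labels[i : i + 4]
            sl[sl != "H"] = "E"
    _demote_short_runs(labels, "E", th["min_run_E"])
    _demote_short_runs(labels, "H", th["min_run_H"])
    return "".join(labels)


def _demote_short_runs(labels: np.ndarray, kind: str, min_len: int) -> None:
    n = len(labels)
    i = 0
    while i < n:
        if labels[i] == kind:
            j = i
            while j < n and labels[j] == kind:
                j += 1
            if j - i < min_len:
                labels[i:j] = "C"
            i = j
        else:
            i += 1


# ---------------------------------------------------------------------------
# writing


def _fmt_atom_line(a: AtomRecord, serial: int) -> str:
    for v in a.position:
        if not -999.999 <= v <= 9999.999:
            raise SerializationError(f"coordinate {v:.3f} overflows PDB field")
    record = "HETATM" if a.het else "ATOM  "
    name = a.atom_name
    if len(name) < 4:
        name = (" " + name) if len(a.element) == 1 else name
    return (
        f"{record}{serial:5d} {name:<4s}{(a.alt_loc or ' '):1s}{a.res_name:>3s} "
        f"{a.chain_id[:1]:1s}{a.res_seq:4d}{(a.icode or ' '):1s}   "
        f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
        f"{a.occupancy:6.2f}{a.b_factor:6.2f}          {a.element:>2s}"
    )


def _write_model_pdb(model: StructureModel, tr: RigidTransform | None, fh) -> None:
    if model.unit_cell is not None:
        a, b, c, al, be, ga = model.unit_cell
        sg = model.spacegroup or "P 1"
        fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} {sg:<11s}{1:4d}\n")
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                out = atom
                if tr is not None:
                    out = replace(atom, position=tr.apply(atom.position))
                fh.write(_fmt_atom_line(out, serial) + "\n")
        serial += 1
        fh.write(f"TER   {serial:5d}\n")
    fh.write("END\n")


def _trace_as_model(trace: CaTrace) -> StructureModel:
    one_to_three = {v: k for k, v in _ONE_TO_THREE_SOURCE.items()}
    chain = Chain(trace.chain_id or "A")
    for (seqnum, icode), letter, pos in zip(trace.res_ids, trace.sequence, trace.coords):
        name = one_to_three.get(letter, "UNK")
        res = Residue(name, seqnum, icode)
        res.atoms.append(
            AtomRecord(
                serial=len(chain.residues) + 1,
                atom_name="CA",
                element="C",
                alt_loc="",
                res_name=name,
                chain_id=chain.id,
                res_seq=seqnum,
                icode=icode,
                position=pos,
            )
        )
        chain.residues.append(res)
    return StructureModel(id=trace.structure_id, chains=[chain])


# one-letter → canonical three-letter (inverse of the parse-time map,
# restricted to the 20 standard residues)
_ONE_TO_THREE_SOURCE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def write_structure(
    obj,
    path,
    transforms=None,
    format: str = "pdb",
):
    """Write a model, a Cα trace, or a list of either as PDB.

    With a list, ``path`` is a directory and one file per entry is written
    (named after each entry's id); ``transforms`` optionally supplies one
    rigid transform per entry applied on output.  Returns the written path
    or list of paths.
    """
    if format != "pdb":
        raise FormatError(f"only PDB output is supported, not {format!r}")
    if isinstance(obj, (list, tuple)):
        outdir = Path(path)
        outdir.mkdir(parents=True, exist_ok=True)
        trs = transforms if transforms is not None else [None] * len(obj)
        if len(trs) != len(obj):
            raise SerializationError("one transform per entry required")
        paths = []
        used: set[str] = set()
        for entry, tr in zip(obj, trs):
            stem = entry.label if isinstance(entry, CaTrace) else entry.id
            name = stem
            k = 1
            while name in used:
                k += 1
                name = f"{stem}_{k}"
            used.add(name)
            paths.append(write_structure(entry, outdir / f"{name}.pdb", transforms=tr))
        return paths
    model = _trace_as_model(obj) if isinstance(obj, CaTrace) else obj
    p = Path(path)
    with open(p, "w") as fh:
        _write_model_pdb(model, transforms, fh)
    return p
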