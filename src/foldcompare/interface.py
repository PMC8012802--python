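"""Quantitative protein–protein interface analysis.

Shrake–Rupley numerical solvent-accessible surface area (deterministic
Fibonacci sphere points), buried-surface bookkeeping for a chain pair
(SASA of each partner alone and in complex), geometric hydrogen-bond and
salt-bridge inventories, and enumeration of crystal-packing contacts via
symmetry expansion.  Hydrogens are absent from typical crystal structures,
so polar contacts use heavy-atom distance criteria only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import (
    DEFAULT_VDW_RADIUS,
    SALT_BRIDGE_ACIDIC,
    SALT_BRIDGE_BASIC,
    VDW_RADII_BONDI,
    is_hbond_acceptor,
    is_hbond_donor,
)
from .errors import InterfaceError
from .structio import AtomRecord, RigidTransform, StructureModel, expand_symmetry, select_atoms

__all__ = [
    "SasaParams",
    "InterfaceReport",
    "sasa",
    "interface_report",
    "crystal_pair_report",
    "report_json",
    "report_tsv",
]


@dataclass(frozen=True)
class SasaParams:
    """Numerical SASA parameters.

    ``probe_radius`` is the solvent probe in Å (1.4 ≈ water);
    ``sphere_points`` sets the Shrake–Rupley quadrature density;
    ``radii_table`` maps element symbols to van-der-Waals radii (the Bondi
    set by default; differences against other radius tables are the main
    source of percent-level area differences between programs).
    """

    probe_radius: float = 1.4
    sphere_points: int = 960
    radii_table: dict = field(default_factory=lambda: dict(VDW_RADII_BONDI))
    radii_version: str = "bondi-1964"
    strict_elements: bool = False
    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    clash_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if self.probe_radius <= 0:
            raise InterfaceError("probe_radius must be positive")
        if self.sphere_points < 60:
            raise InterfaceError("sphere_points must be >= 60")

    def radius_of(self, element: str) -> float:
        r = self.radii_table.get(element.upper())
        if r is None:
            if self.strict_elements:
                raise InterfaceError(f"no van-der-Waals radius for element {element!r}")
            return DEFAULT_VDW_RADIUS
        return float(r)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit-sphere quadrature points."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


def sasa(
    atoms: list[AtomRecord], params: SasaParams | None = None
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley SASA: per-atom areas (Å²) and their total.

    Each atom's solvent-expanded sphere (r_vdW + probe) is sampled with
    ``sphere_points`` quadrature points; a point is buried if it falls
    inside any neighbor's expanded sphere.  Per-atom area equals the
    exposed-point fraction × 4π(r+probe)².
    """
    params = params or SasaParams()
    if not atoms:
        raise InterfaceError("SASA of an empty selection is undefined")
    pos = np.array([a.position for a in atoms])
    rad = np.array([params.radius_of(a.element) for a in atoms]) + params.probe_radius
    unit = _fibonacci_sphere(params.sphere_points)
    tree = cKDTree(pos)
    rmax = float(rad.max())
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = pos[i] + rad[i] * unit
        neigh = [j for j in tree.query_ball_point(pos[i], rad[i] + rmax) if j != i]
        exposed = np.ones(len(pts), bool)
        for j in neigh:
            d2 = np.sum((pts - pos[j]) ** 2, axis=1)
            exposed &= d2 >= rad[j] ** 2
        areas[i] = exposed.mean() * 4.0 * math.pi * rad[i] ** 2
    return areas, float(areas.sum())


def _atom_id(a: AtomRecord) -> str:
    ic = a.icode or ""
    return f"{a.chain_id}/{a.res_name} {a.res_seq}{ic}/{a.atom_name}"


@dataclass
class InterfaceReport:
    """Buried surface, polar contacts and interface residues of a pair.

    ``bsa_total`` = SASA(A) + SASA(B) − SASA(AB); ``interface_area`` is
    its half (the PISA convention); both are reported because published
    figures use either.  Buried fractions are each monomer's share of SAS
    hidden in the contact.
    """

    partner_a: str
    partner_b: str
    sasa_a: float
    sasa_b: float
    sasa_ab: float
    bsa_total: float
    interface_area: float
    buried_fraction_a: float
    buried_fraction_b: float
    hbonds: list[tuple[str, str, float]]
    salt_bridges: list[tuple[str, str, float]]
    interface_residues_a: list[str]
    interface_residues_b: list[str]
    clash: bool = False
    partner_transform: RigidTransform | None = None

    @property
    def n_polar_contacts(self) -> int:
        return len(self.hbonds) + len(self.salt_bridges)


def _resolve_selection(model: StructureModel | None, sel) -> list[AtomRecord]:
    if isinstance(sel, (list, tuple)) and (not sel or isinstance(sel[0], AtomRecord)):
        return list(sel)
    if isinstance(sel, dict):
        if model is None:
            raise InterfaceError("selection by chain/range needs a model")
        return select_atoms(model, **sel)
    raise InterfaceError(f"cannot interpret selection {sel!r}")


def interface_report(
    model: StructureModel | None,
    selection_a,
    selection_b,
    params: SasaParams | None = None,
    label_a: str = "A",
    label_b: str = "B",
    partner_transform: RigidTransform | None = None,
) -> InterfaceReport:
    """PISA-style quantitative report for a binary contact.

    SASA is computed three times with identical parameters (A alone, B
    alone, A+B); hydrogen bonds are donor/acceptor N,O,S heavy-atom pairs
    across the interface within 3.5 Å, salt bridges are Lys/Arg/His
    nitrogen vs Asp/Glu carboxylate oxygen pairs within 4.0 Å.
    """
    params = params or SasaParams()
    atoms_a = _resolve_selection(model, selection_a)
    atoms_b = _resolve_selection(model, selection_b)
    if not atoms_a or not atoms_b:
        raise InterfaceError("both selections must be non-empty")
    ids_a = {id(a) for a in atoms_a}
    if any(id(b) in ids_a for b in atoms_b):
        raise InterfaceError("selections overlap")

    per_a, tot_a = sasa(atoms_a, params)
    per_b, tot_b = sasa(atoms_b, params)
    per_ab, tot_ab = sasa(atoms_a + atoms_b, params)
    per_a_in = per_ab[: len(atoms_a)]
    per_b_in = per_ab[len(atoms_a):]
    bsa = tot_a + tot_b - tot_ab

    pos_a = np.array([a.position for a in atoms_a])
    pos_b = np.array([b.position for b in atoms_b])
    tree_b = cKDTree(pos_b)
    pairs = tree_b.query_ball_point(pos_a, max(params.hbond_cutoff, params.salt_bridge_cutoff))

    hbonds: list[tuple[str, str, float]] = []
    bridges: list[tuple[str, str, float]] = []
    seen_hb: set[tuple[str, str]] = set()
    min_cross = math.inf
    for i, js in enumerate(pairs):
        a = atoms_a[i]
        for j in js:
            b = atoms_b[j]
            d = float(np.linalg.norm(a.position - b.position))
            min_cross = min(min_cross, d)
            if d <= params.hbond_cutoff and a.element in ("N", "O", "S") and b.element in ("N", "O", "S"):
                da = is_hbond_donor(a.res_name, a.atom_name) and is_hbond_acceptor(b.res_name, b.atom_name)
                db = is_hbond_donor(b.res_name, b.atom_name) and is_hbond_acceptor(a.res_name, a.atom_name)
                if da or db:
                    donor, acc = (a, b) if da else (b, a)
                    key = tuple(sorted((_atom_id(a), _atom_id(b))))
                    if key not in seen_hb:
                        seen_hb.add(key)
                        hbonds.append((_atom_id(donor), _atom_id(acc), round(d, 3)))
            if d <= params.salt_bridge_cutoff and _is_salt_bridge(a, b):
                basic, acidic = (a, b) if _is_basic(a) else (b, a)
                bridges.append((_atom_id(basic), _atom_id(acidic), round(d, 3)))

    res_a = _buried_residues(atoms_a, per_a, per_a_in)
    res_b = _buried_residues(atoms_b, per_b, per_b_in)
    return InterfaceReport(
        partner_a=label_a,
        partner_b=label_b,
        sasa_a=tot_a,
        sasa_b=tot_b,
        sasa_ab=tot_ab,
        bsa_total=bsa,
        interface_area=bsa / 2.0,
        buried_fraction_a=max(0.0, (tot_a - float(per_a_in.sum())) / tot_a),
        buried_fraction_b=max(0.0, (tot_b - float(per_b_in.sum())) / tot_b),
        hbonds=sorted(hbonds),
        salt_bridges=sorted(bridges),
        interface_residues_a=res_a,
        interface_residues_b=res_b,
        clash=min_cross < params.clash_cutoff,
        partner_transform=partner_transform,
    )


def _is_basic(a: AtomRecord) -> bool:
    return a.atom_name in SALT_BRIDGE_BASIC.get(a.res_name, frozenset())


def _is_acidic(a: AtomRecord) -> bool:
    return a.atom_name in SALT_BRIDGE_ACIDIC.get(a.res_name, frozenset())


def _is_salt_bridge(a: AtomRecord, b: AtomRecord) -> bool:
    return (_is_basic(a) and _is_acidic(b)) or (_is_basic(b) and _is_acidic(a))


def _buried_residues(atoms, per_alone, per_complex) -> list[str]:
    lost: dict[tuple, float] = {}
    names: dict[tuple, str] = {}
    for a, s0, s1 in zip(atoms, per_alone, per_complex):
        key = (a.chain_id, a.res_seq, a.icode, a.res_name)
        lost[key] = lost.get(key, 0.0) + (s0 - s1)
        names[key] = f"{a.chain_id}/{a.res_name} {a.res_seq}{a.icode or ''}"
    return [names[k] for k in sorted(lost) if lost[k] > 1e-6]


def crystal_pair_report(
    model: StructureModel,
    params: SasaParams | None = None,
    contact_cutoff: float = 5.0,
) -> list[InterfaceReport]:
    """Interface reports for every distinct crystallographic contact.

    Symmetry mates within ``contact_cutoff`` of the reference copy are
    generated from the unit cell and space-group operators; one report per
    mate is returned, sorted by buried surface area (descending), with the
    reference copy as partner A.
    """
    params = params or SasaParams()
    ref_atoms = select_atoms(model)
    reports = []
    for tr, mate in expand_symmetry(model, contact_cutoff):
        mate_atoms = select_atoms(mate)
        rep = interface_report(
            None,
            ref_atoms,
            mate_atoms,
            params,
            label_a=model.id,
            label_b=mate.id,
            partner_transform=tr,
        )
        reports.append(rep)
    reports.sort(key=lambda r: (-r.bsa_total, r.partner_b))
    return reports


# ---------------------------------------------------------------------------
# export


def report_json(report: InterfaceReport) -> str:
    d = {
        "partner_a": report.partner_a,
        "partner_b": report.partner_b,
        "sasa_a_A2": round(report.sasa_a, 3),
        "sasa_b_A2": round(report.sasa_b, 3),
        "sasa_complex_A2": round(report.sasa_ab, 3),
        "bsa_total_A2": round(report.bsa_total, 3),
        "interface_area_A2": round(report.interface_area, 3),
        "buried_fraction_a": round(report.buried_fraction_a, 6),
        "buried_fraction_b": round(report.buried_fraction_b, 6),
        "n_hbonds": len(report.hbonds),
        "n_salt_bridges": len(report.salt_bridges),
        "hbonds": [list(h) for h in report.hbonds],
        "salt_bridges": [list(s) for s in report.salt_bridges],
        "interface_residues_a": report.interface_residues_a,
        "interface_residues_b": report.interface_residues_b,
        "clash": report.clash,
    }
    return json.dumps(d, indent=2, sort_keys=True) + "\n"


def report_tsv(reports: list[InterfaceReport]) -> str:
    lines = [
        "partner_a\tpartner_b\tbsa_total_A2\tinterface_area_A2\t"
        "buried_fraction_a\tburied_fraction_b\tn_hbonds\tn_salt_bridges\tclash"
    ]
    for r in reports:
        lines.append(
            f"{r.partner_a}\t{r.partner_b}\t{r.bsa_total:.6g}\t{r.interface_area:.6g}\t"
            f"{r.buried_fraction_a:.6g}\t{r.buried_fraction_b:.6g}\t"
            f"{len(r.hbonds)}\t{len(r.salt_bridges)}\t{int(r.clash)}"
        )
    return "\n".join(lines) + "\n"
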