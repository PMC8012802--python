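"""Structure I/O, trace slicing, symmetry expansion, secondary structure."""

import numpy as np
import pytest

from foldcompare.errors import (
    ChainLookupError,
    EmptySelectionError,
    FormatError,
    ParseError,
    SerializationError,
    TraceError,
)
from foldcompare.structio import (
    AtomRecord,
    CaTrace,
    Chain,
    Residue,
    RigidTransform,
    StructureModel,
    assign_secondary_structure,
    expand_symmetry,
    extract_ca_trace,
    read_structure,
    write_structure,
)
from foldcompare.synthetic import crystal_contact_assembly, make_ideal_segment

from conftest import random_rigid, trace_to_model


class TestReadStructure:
    def test_single_atom_record(self, minimal_pdb_text):
        model = read_structure(minimal_pdb_text, format="pdb")
        assert len(model.chains) == 1
        res = model.chains[0].residues
        assert len(res) == 1 and len(res[0].atoms) == 1
        a = res[0].atoms[0]
        assert a.atom_name == "CA" and a.res_name == "ALA" and a.res_seq == 1
        np.testing.assert_allclose(a.position, [11.104, 6.134, -6.504])

    def test_altloc_conformers_retained_primary_flagged(self, altloc_pdb_text):
        model = read_structure(altloc_pdb_text, format="pdb")
        og = [a for a in model.atoms() if a.atom_name == "OG"]
        assert len(og) == 2
        primary = {a.alt_loc: a.is_primary for a in og}
        assert primary == {"A": True, "B": False}  # 0.6 beats 0.4

    def test_altloc_occupancy_tie_breaks_lexicographically(self, altloc_pdb_text):
        text = altloc_pdb_text.replace("0.60", "0.40")
        model = read_structure(text, format="pdb")
        og = {a.alt_loc: a.is_primary for a in model.atoms() if a.atom_name == "OG"}
        assert og == {"A": True, "B": False}

    def test_empty_and_malformed_inputs(self):
        with pytest.raises((ParseError, Exception)):
            read_structure("not a structure\nat all\n", format="pdb")
        with pytest.raises(FormatError):
            read_structure("ATOM\n", format="xyz")


class TestRoundTrip:
    def test_write_read_preserves_fields_and_cell(self, tmp_path):
        model, _ = crystal_contact_assembly()
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert back.n_atoms() == model.n_atoms()
        assert back.unit_cell == pytest.approx(model.unit_cell)
        assert len(back.sym_ops) == 2  # P 1 21 1 recovered from CRYST1
        for a, b in zip(model.atoms(), back.atoms()):
            assert (a.atom_name, a.res_name, a.res_seq, a.chain_id) == (
                b.atom_name, b.res_name, b.res_seq, b.chain_id
            )
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_write_with_rotation_transform(self, tmp_path):
        model, _ = crystal_contact_assembly()
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        tr = RigidTransform(R, np.zeros(3))
        path = tmp_path / "rot.pdb"
        write_structure(model, path, transforms=tr)
        back = read_structure(path)
        orig = np.array([a.position for a in model.atoms()])
        got = np.array([a.position for a in back.atoms()])
        np.testing.assert_allclose(got, orig @ R.T, atol=1e-3)

    def test_trace_bundle_round_trip(self, tmp_path, template150):
        traces = [
            template150,
            make_ideal_segment("helix", 20, structure_id="h"),
        ]
        rng = np.random.default_rng(0)
        trs = [RigidTransform(*random_rigid(rng)) for _ in traces]
        paths = write_structure(traces, tmp_path / "bundle", transforms=trs)
        assert len(paths) == 2
        for trace, tr, p in zip(traces, trs, paths):
            back = read_structure(p)
            got = np.array([a.position for a in back.atoms()])
            np.testing.assert_allclose(got, tr.apply(trace.coords), atol=1e-3)

    def test_coordinate_overflow_refused(self, tmp_path):
        t = make_ideal_segment("strand", 4)
        t.coords[0, 0] = 123456.0
        with pytest.raises(SerializationError):
            write_structure(t, tmp_path / "x.pdb")


class TestCaTrace:
    def test_full_chain_identity_order(self, strand10):
        model = trace_to_model(strand10)
        trace = extract_ca_trace(model, "A")
        assert len(trace) == 10
        assert [r for r, _ in trace.res_ids] == list(range(1, 11))
        np.testing.assert_allclose(trace.coords, strand10.coords)

    def test_inclusive_author_range(self, template150):
        model = trace_to_model(template150)
        trace = extract_ca_trace(model, "A", (10, 20))
        assert len(trace) == 11
        assert trace.res_ids[0][0] == 10 and trace.res_ids[-1][0] == 20
        assert trace.selection == (10, 20)

    def test_missing_chain_and_empty_slice(self, template150):
        model = trace_to_model(template150)
        with pytest.raises(ChainLookupError):
            extract_ca_trace(model, "Z")
        with pytest.raises(EmptySelectionError):
            extract_ca_trace(model, "A", (900, 950))

    def test_residue_without_ca_flags_chain_break(self):
        chain = Chain("A")
        trace = make_ideal_segment("strand", 6)
        for i, pos in enumerate(trace.coords):
            res = Residue("ALA", i + 1, "")
            name = "CB" if i == 3 else "CA"  # residue 4 lacks a Cα
            res.atoms.append(
                AtomRecord(i + 1, name, "C", "", "ALA", "A", i + 1, "", pos)
            )
            chain.residues.append(res)
        model = StructureModel(id="frag", chains=[chain])
        got = extract_ca_trace(model, "A")
        assert [r for r, _ in got.res_ids] == [1, 2, 3, 5, 6]
        assert 2 in got.breaks  # break between indices 2 and 3 (res 3 -> 5)


class TestExpandSymmetry:
    def test_isolated_molecule_in_large_p1_cell(self):
        trace = make_ideal_segment("helix", 20)
        model = trace_to_model(trace)
        model.unit_cell = (200.0, 200.0, 200.0, 90.0, 90.0, 90.0)
        model.spacegroup = "P 1"
        model.sym_ops = [(np.eye(3), np.zeros(3))]
        assert expand_symmetry(model, 5.0) == []

    def test_toy_cell_matches_bruteforce_enumeration(self):
        """Exhaustive op × 27-translation oracle finds the same mates."""
        model, _ = crystal_contact_assembly()
        mates = expand_symmetry(model, 4.0)
        assert len(mates) == 2  # the two screw-related neighbors (±b/2)

        # independent enumeration in fractional space
        from foldcompare.structio import _orth_matrix
        import itertools

        orth = _orth_matrix(model.unit_cell)
        frac = np.linalg.inv(orth)
        ref = np.array([a.position for a in model.atoms()])
        found = set()
        for rot, tran in model.sym_ops:
            for shift in itertools.product((-1, 0, 1), repeat=3):
                R = orth @ rot @ frac
                t = orth @ (tran + np.array(shift, float))
                if np.allclose(R, np.eye(3)) and np.allclose(t, 0):
                    continue
                moved = ref @ R.T + t
                dmin = min(
                    np.linalg.norm(moved[i] - ref[j])
                    for i in range(len(ref))
                    for j in range(len(ref))
                )
                if dmin <= 4.0:
                    found.add(tuple(np.round(np.concatenate([R.ravel(), t]), 6)))
        got = {
            tuple(np.round(np.concatenate([tr.rotation.ravel(), tr.translation]), 6))
            for tr, _ in mates
        }
        assert got == found

    def test_mates_are_congruent_and_twofold(self):
        model, _ = crystal_contact_assembly()
        ref = np.array([a.position for a in model.atoms()])
        for tr, mate in expand_symmetry(model, 4.0):
            got = np.array([a.position for a in mate.atoms()])
            np.testing.assert_allclose(got, tr.apply(ref), atol=1e-6)
            # screw component of a 2-fold: rotation trace = -1
            assert np.trace(tr.rotation) == pytest.approx(-1.0)


class TestSecondaryStructure:
    def test_ideal_helix_is_helical(self, helix20):
        labels = assign_secondary_structure(helix20)
        assert labels.count("H") >= 16 and "E" not in labels

    def test_ideal_strand_is_extended(self, strand10):
        labels = assign_secondary_structure(strand10)
        assert labels.count("E") >= 7 and "H" not in labels

    def test_short_trace_refused(self):
        with pytest.raises(TraceError):
            assign_secondary_structure(make_ideal_segment("helix", 4))

    def test_short_runs_demoted_to_coil(self, helix20, strand10):
        # a helix broken by a large displacement cannot keep sub-minimal runs
        coords = np.vstack([helix20.coords[:6], helix20.coords[6:] + 50.0])
        t = CaTrace("b", "A", helix20.res_ids, helix20.sequence, coords)
        labels = assign_secondary_structure(t)
        for kind, min_run in (("H", 4), ("E", 3)):
            run = 0
            for c in labels + "C":
                if c == kind:
                    run += 1
                else:
                    assert run == 0 or run >= min_run
                    run = 0
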