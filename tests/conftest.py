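"""Shared fixtures: ideal geometry, an evolved synthetic family, toy
assemblies, and small hand-written PDB snippets.  Everything is generated
programmatically; nothing touches the network."""

from __future__ import annotations

import numpy as np
import pytest

from foldcompare.multalign import align_structures
from foldcompare.structree import PhyloTree
from foldcompare.synthetic import (
    FamilySpec,
    balanced_family_tree,
    evolve_family,
    make_fold_template,
    make_ideal_segment,
)

FAMILY_SIGMA = 0.3
FAMILY_LENGTH = 120
FAMILY_SEED = 42


@pytest.fixture(scope="session")
def helix20():
    return make_ideal_segment("helix", 20)


@pytest.fixture(scope="session")
def strand10():
    return make_ideal_segment("strand", 10)


@pytest.fixture(scope="session")
def template150():
    return make_fold_template(150, seed=3)


@pytest.fixture(scope="session")
def family8() -> tuple[list, PhyloTree]:
    """8 leaves diffused from one α+β template at σ = 0.3 Å per branch."""
    template = make_fold_template(FAMILY_LENGTH, seed=7)
    tree = balanced_family_tree(8, FAMILY_SIGMA)
    return evolve_family(FamilySpec(template=template, tree=tree, seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def family_msa(family8):
    traces, _ = family8
    return align_structures(traces[:5])


MINIMAL_PDB = (
    "ATOM      1  CA  ALA A   1      11.104   6.134  -6.504  1.00 10.00"
    "           C\n"
    "END\n"
)

ALTLOC_PDB = (
    "ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00"
    "           N\n"
    "ATOM      2  CA  SER A   1       1.458   0.000   0.000  1.00 10.00"
    "           C\n"
    "ATOM      3  OG ASER A   1       2.000   1.400   0.000  0.60 10.00"
    "           O\n"
    "ATOM      4  OG BSER A   1       2.000  -1.400   0.000  0.40 10.00"
    "           O\n"
    "END\n"
)


@pytest.fixture()
def minimal_pdb_text():
    return MINIMAL_PDB


@pytest.fixture()
def altloc_pdb_text():
    return ALTLOC_PDB


def trace_to_model(trace):
    """Cα-only StructureModel for a trace (via the PDB writer types)."""
    from foldcompare.structio import _trace_as_model

    return _trace_as_model(trace)


def random_rigid(rng) -> "tuple[np.ndarray, np.ndarray]":
    """Uniform-ish random proper rotation + translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20, 20, 3)
    return R, t
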