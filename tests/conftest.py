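"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from circuitop.contact_mapping import Contact, ContactMap


def oracle_classify(c1: Contact, c2: Contact) -> str:
    """Independent relation classifier via explicit residue-index sets.

    Materialise each contact's closed chain interval as a set of residue
    indices.  Overlap of at most one residue (tangent or disjoint) is series;
    subset containment is parallel; any other overlap is cross.
    """
    a = set(range(c1[0], c1[1] + 1))
    b = set(range(c2[0], c2[1] + 1))
    if len(a & b) <= 1:
        return "S"
    if a <= b or b <= a:
        return "P"
    return "X"


def oracle_census(contacts) -> tuple[int, int, int]:
    """Brute-force S/P/X counts over all unordered contact pairs."""
    n = {"S": 0, "P": 0, "X": 0}
    for a, b in itertools.combinations(sorted(contacts), 2):
        n[oracle_classify(a, b)] += 1
    return n["S"], n["P"], n["X"]


def random_contact_map(
    rng: np.random.Generator, N: int, m: int, exclusion: int = 3
) -> ContactMap:
    """A random contact map of up to m contacts obeying the band exclusion."""
    contacts: set[Contact] = set()
    while len(contacts) < m:
        i, j = sorted(rng.integers(1, N + 1, size=2))
        if j - i > exclusion:
            contacts.add((int(i), int(j)))
    return ContactMap(N=N, contacts=frozenset(contacts))


def pdb_atom_line(serial, name, resname, resid, x, y, z, record="ATOM", chain="A"):
    return (
        f"{record:<6}{serial:>5} {name:<4}{resname:>4} {chain}{resid:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def two_model_pdb(tmp_path):
    """A 2-model PDB of a 5-residue peptide, written as plain text."""
    lines = []
    for model in (1, 2):
        lines.append(f"MODEL     {model}")
        serial = 1
        for res in range(1, 6):
            for a in range(2):
                lines.append(
                    pdb_atom_line(
                        serial, f"C{a+1}", "ALA", res,
                        10.0 * res + model, 2.0 * a, 0.0,
                    )
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    path = tmp_path / "two_model.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_with_ions(tmp_path):
    """A single-structure PDB: 4 protein residues (3 atoms each) + ions/water."""
    lines = []
    serial = 1
    for res in range(1, 5):
        for a in range(3):
            lines.append(
                pdb_atom_line(serial, f"C{a+1}", "GLY", res, 8.0 * res, float(a), 0.0)
            )
            serial += 1
    lines.append(pdb_atom_line(serial, "NA", "NA", 5, 50.0, 0.0, 0.0, record="HETATM"))
    serial += 1
    lines.append(pdb_atom_line(serial, "O", "HOH", 6, 60.0, 0.0, 0.0, record="HETATM"))
    lines.append("END")
    path = tmp_path / "with_ions.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path
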