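"""Shared fixtures: hand-built PDB texts and random toy structures."""

import numpy as np
import pytest

from cpsite.structure import Atom, ResidueRecord, StructureTable
from cpsite.synthetic import SyntheticSpec, build_polypeptide, DEFAULT_BLOCKS


def _atom_line(serial, name, resname, chain, resnum, xyz, occ=1.0, b=10.0,
               element=None, altloc=" "):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:3s} {chain}{resnum:4d}"
        f"    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{occ:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


@pytest.fixture
def tripeptide_pdb():
    """Hand-built 3-residue chain with full backbone."""
    lines = []
    serial = 1
    coords = {
        1: {"N": (0.0, 0.0, 0.0), "CA": (1.458, 0.0, 0.0),
            "C": (2.009, 1.420, 0.0), "O": (1.251, 2.390, 0.0)},
        2: {"N": (3.332, 1.536, 0.0), "CA": (3.988, 2.840, 0.1),
            "C": (5.504, 2.700, 0.2), "O": (6.030, 1.590, 0.3)},
        3: {"N": (6.189, 3.840, 0.2), "CA": (7.640, 3.870, 0.3),
            "C": (8.200, 5.280, 0.4), "O": (7.470, 6.270, 0.5)},
    }
    names = {1: "ALA", 2: "GLY", 3: "LEU"}
    for resnum, atoms in coords.items():
        for name, xyz in atoms.items():
            lines.append(_atom_line(serial, name, names[resnum], "A",
                                    resnum, xyz, b=float(10 + resnum)))
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def ca_missing_pdb(tripeptide_pdb):
    """Same chain but residue 2 lacks its alpha carbon."""
    kept = [l for l in tripeptide_pdb.splitlines()
            if not ("CA" in l and " GLY " in l)]
    return "\n".join(kept) + "\n"


@pytest.fixture
def altloc_pdb():
    """One residue with an altloc pair: A at occupancy 0.6, B at 0.4."""
    lines = [
        _atom_line(1, "N", "ALA", "A", 1, (0, 0, 0)),
        _atom_line(2, "CA", "ALA", "A", 1, (1.0, 0.0, 0.0), occ=0.6,
                   altloc="A"),
        _atom_line(3, "CA", "ALA", "A", 1, (9.0, 9.0, 9.0), occ=0.4,
                   altloc="B"),
        _atom_line(4, "C", "ALA", "A", 1, (2.0, 1.0, 0.0)),
        _atom_line(5, "N", "GLY", "A", 2, (3.3, 1.2, 0.0)),
        _atom_line(6, "CA", "GLY", "A", 2, (4.4, 2.2, 0.0)),
        _atom_line(7, "C", "GLY", "A", 2, (5.9, 2.1, 0.0)),
        "END",
    ]
    return "\n".join(lines) + "\n"


def ca_only_structure(coords, aas=None, protein_id="toy"):
    """Build a StructureTable with one CA atom per residue."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    aas = aas or "A" * n
    residues = []
    for i in range(n):
        ca = Atom("CA", "C", coords[i], 1.0, 10.0)
        residues.append(
            ResidueRecord(
                chain_id="A", seq_position=i + 1, pdb_resnum=i + 1,
                icode="", aa=aas[i], ca_xyz=coords[i], atoms=[ca],
                b_factor_ca=10.0,
            )
        )
    return StructureTable(protein_id=protein_id, chain_id="A",
                          residues=residues)


def random_ca_structure(rng, n=30, scale=8.0, min_sep=1.5):
    """Random CA cloud with no coincident points."""
    while True:
        coords = rng.uniform(-scale, scale, size=(n, 3))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_sep:
            return ca_only_structure(coords)


def dssp_text(records):
    """Classic-dialect DSSP output for (resseq, chain, aa, ss) records."""
    lines = [
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI"
        "    X-CA   Y-CA   Z-CA",
    ]
    for i, (resseq, chain, aa, ss) in enumerate(records, start=1):
        buf = [" "] * 120
        buf[0:5] = f"{i:5d}"
        buf[5:10] = f"{resseq:5d}"
        buf[11] = chain
        buf[13] = aa
        buf[16] = ss if ss else " "
        buf[34:38] = f"{30:4d}"
        buf[38:45] = f"{0:7d}"
        buf[46:50] = f"{0.0:4.1f}"
        buf[50:56] = f"{0:6d}"
        buf[57:61] = f"{0.0:4.1f}"
        buf[61:67] = f"{0:6d}"
        buf[68:72] = f"{0.0:4.1f}"
        buf[72:78] = f"{0:6d}"
        buf[79:83] = f"{0.0:4.1f}"
        buf[103:109] = f"{-60.0:6.1f}"
        buf[109:115] = f"{-45.0:6.1f}"
        lines.append("".join(buf))
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_fold():
    """A 50-residue noisy helix/strand/loop chain with full backbone."""
    spec = SyntheticSpec(blocks=DEFAULT_BLOCKS, noise_sd=0.15, seed=7)
    return build_polypeptide(spec, protein_id="toyfold")
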