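"""Protein structure ingestion and per-residue bookkeeping.

A protein chain is represented as a :class:`StructureTable`: an ordered,
gap-free list of residues, each carrying its alpha carbon, heavy atoms,
B-factor and an 8-state secondary-structure code.  All downstream residue
measures and site positions refer to the internal 1-based ``seq_position``
numbering; the author (PDB) numbering is retained for reporting.
"""

from __future__ import annotations

import io
import logging
import math
import tempfile
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.DSSP import make_dssp_dict
from Bio.SeqUtils import seq1

logger = logging.getLogger("cpsite")

#: DSSP eight-state secondary structure alphabet ('-' = coil/none).
SSE8 = "HGIEBTS-"


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # Angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0


@dataclass
class ResidueRecord:
    chain_id: str
    seq_position: int          # 1-based, contiguous along the chain
    pdb_resnum: int            # author numbering
    icode: str                 # insertion code ('' if none)
    aa: str                    # one-letter code ('X' for unknown)
    ca_xyz: np.ndarray
    atoms: list = field(default_factory=list)
    b_factor_ca: float = 0.0
    sse8: str = "-"
    phi: Optional[float] = None  # degrees, None at termini / missing backbone
    psi: Optional[float] = None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureTable:
    protein_id: str
    chain_id: str
    residues: list  # of ResidueRecord
    source_path: Optional[str] = None

    def __len__(self) -> int:
        return len(self.residues)

    def __post_init__(self):
        if len(self.residues) < 2:
            raise ValueError("a StructureTable needs at least 2 residues")
        seen = set()
        for i, r in enumerate(self.residues, start=1):
            if r.seq_position != i:
                raise ValueError("seq_position must be contiguous from 1")
            key = (r.pdb_resnum, r.icode)
            if key in seen:
                raise ValueError(f"duplicate author residue number {key}")
            seen.add(key)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def sse_string(self) -> str:
        return "".join(r.sse8 for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.asarray([r.ca_xyz for r in self.residues], dtype=float)

    def numbering_table(self) -> pd.DataFrame:
        """Mapping between internal and author numbering."""
        return pd.DataFrame(
            {
                "seq_position": [r.seq_position for r in self.residues],
                "pdb_resnum": [r.pdb_resnum for r in self.residues],
                "icode": [r.icode for r in self.residues],
                "aa": [r.aa for r in self.residues],
            }
        )

    def to_fasta(self) -> str:
        return f">{self.protein_id}_{self.chain_id}\n{self.sequence}\n"


@dataclass
class CPSiteLabel:
    """A circular-permutation site with its experimental outcome.

    ``site_position`` is the 1-based position of the first residue of the
    permuted sequence; the cleavage point is the peptide bond between
    ``site_position - 1`` and ``site_position``.  A permutation at position 1
    is the identity and is rejected.
    """

    protein_id: str
    chain_id: str
    site_position: int
    viable: bool
    source: str = ""

    def __post_init__(self):
        if self.site_position <= 1:
            raise ValueError(
                "site_position must be > 1 (position 1 is the identity permutation)"
            )


# ---------------------------------------------------------------------------
# PDB ingestion
# ---------------------------------------------------------------------------

_HYDROGEN = {"H", "D"}


def _pick_altloc(bio_atom):
    """Resolve a possibly disordered atom to its highest-occupancy conformer."""
    if bio_atom.is_disordered():
        children = bio_atom.disordered_get_list()
        return max(children, key=lambda a: (a.get_occupancy() or 0.0))
    return bio_atom


def read_structure(
    pdb_text: str,
    chain_id: Optional[str] = None,
    model_index: int = 0,
    protein_id: str = "protein",
) -> StructureTable:
    """Parse one chain of a PDB-format text into a StructureTable.

    Waters, hetero ligands and hydrogens are excluded; altlocs resolve to the
    highest-occupancy conformer; residues without an alpha carbon are dropped
    with a warning.
    """
    parser = PDBParser(QUIET=True)
    bio = parser.get_structure(protein_id, io.StringIO(pdb_text))
    models = list(bio)
    if not models:
        raise ValueError("no models in PDB input")
    model = models[model_index]
    chains = {c.id: c for c in model}
    if chain_id is None:
        if len(chains) == 1:
            chain_id = next(iter(chains))
        else:
            raise ValueError(
                f"multiple chains present {sorted(chains)}; a chain must be selected"
            )
    if chain_id not in chains:
        raise ValueError(
            f"chain {chain_id!r} not found; available chains: {sorted(chains)}"
        )

    residues = []
    pos = 0
    for res in chains[chain_id]:
        hetflag, resnum, icode = res.id
        if hetflag.strip():  # water or hetero ligand
            continue
        atoms = []
        for bio_atom in res:
            a = _pick_altloc(bio_atom)
            element = (a.element or "").strip().upper()
            if element in _HYDROGEN:
                continue
            atoms.append(
                Atom(
                    name=a.get_name(),
                    element=element or a.get_name()[:1],
                    xyz=np.asarray(a.get_coord(), dtype=float),
                    occupancy=float(a.get_occupancy() or 1.0),
                    b_factor=float(a.get_bfactor() or 0.0),
                )
            )
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            logger.warning(
                "%s/%s residue %s%s has no CA atom; dropped",
                protein_id, chain_id, resnum, icode.strip(),
            )
            continue
        pos += 1
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_position=pos,
                pdb_resnum=int(resnum),
                icode=icode.strip(),
                aa=seq1(res.get_resname(), undef_code="X"),
                ca_xyz=ca.xyz,
                atoms=atoms,
                b_factor_ca=ca.b_factor,
            )
        )
    return StructureTable(protein_id=protein_id, chain_id=chain_id, residues=residues)


def write_pdb(structure: StructureTable) -> str:
    """Serialize a StructureTable back to minimal PDB ATOM records."""
    lines = []
    serial = 1
    for r in structure.residues:
        for a in r.atoms:
            lines.append(
                f"ATOM  {serial:5d} {a.name:^4s} {'GLY' if r.aa == 'X' else _three(r.aa):3s} "
                f"{r.chain_id:1s}{r.pdb_resnum:4d}{r.icode or ' ':1s}   "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
                f"{a.element:>2s}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _three(aa: str) -> str:
    return _AA3.get(aa, "GLY")


# ---------------------------------------------------------------------------
# Backbone dihedrals
# ---------------------------------------------------------------------------

def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def compute_dihedrals(structure: StructureTable) -> list:
    """Backbone (phi, psi) per residue; None at termini or missing backbone.

    Updates the residue records in place and returns the list of tuples.
    """
    out = []
    n = len(structure)
    for i, r in enumerate(structure.residues):
        phi = psi = None
        N, CA, C = r.atom("N"), r.atom("CA"), r.atom("C")
        if N is not None and CA is not None and C is not None:
            if i > 0:
                prev_c = structure.residues[i - 1].atom("C")
                if prev_c is not None:
                    phi = dihedral_angle(prev_c.xyz, N.xyz, CA.xyz, C.xyz)
            if i < n - 1:
                next_n = structure.residues[i + 1].atom("N")
                if next_n is not None:
                    psi = dihedral_angle(N.xyz, CA.xyz, C.xyz, next_n.xyz)
        r.phi, r.psi = phi, psi
        out.append((phi, psi))
    return out


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

def assign_sse(structure: StructureTable, dssp_text: Optional[str] = None) -> str:
    """Assign 8-state secondary structure codes to every residue.

    If a DSSP output text is supplied its summary column is ingested verbatim
    (blank -> '-').  Otherwise a coarse dihedral-window fallback assigns only
    {H, E, -}: phi in (-100, -30) and psi in (-80, -5) -> H; phi in
    (-180, -60) and psi in (60, 180) -> E; anything else (including undefined
    terminal dihedrals) -> '-'.  The fallback is an approximation and is
    overridden whenever DSSP text is available.
    """
    if dssp_text is not None:
        with tempfile.NamedTemporaryFile("w", suffix=".dssp", delete=False) as fh:
            fh.write(dssp_text)
            path = fh.name
        dssp_map, _ = make_dssp_dict(path)
        lookup = {}
        for (ch, res_id), row in dssp_map.items():
            if ch != structure.chain_id:
                continue
            _, resnum, icode = res_id
            lookup[(int(resnum), icode.strip())] = row[1]
        unmatched = [
            (r.pdb_resnum, r.icode)
            for r in structure.residues
            if (r.pdb_resnum, r.icode) not in lookup
        ]
        if unmatched:
            raise ValueError(f"DSSP/structure residue mismatch at {unmatched}")
        for r in structure.residues:
            code = lookup[(r.pdb_resnum, r.icode)]
            r.sse8 = code if code and code.strip() and code in SSE8 else "-"
    else:
        compute_dihedrals(structure)
        for r in structure.residues:
            if r.phi is not None and r.psi is not None:
                if -100 < r.phi < -30 and -80 < r.psi < -5:
                    r.sse8 = "H"
                    continue
                if -180 < r.phi < -60 and 60 < r.psi < 180:
                    r.sse8 = "E"
                    continue
            r.sse8 = "-"
    return structure.sse_string


# ---------------------------------------------------------------------------
# CP-site label tables
# ---------------------------------------------------------------------------

_VIABILITY = {"viable": True, "inviable": False}


def read_labels(
    tsv_text: str,
    structures: Optional[dict] = None,
) -> list:
    """Parse a CP-site label table (TSV with header).

    Required columns: ``protein_id``, ``chain``, ``position``, ``viability``
    (token ``viable`` or ``inviable``).  When ``structures`` maps protein ids
    to StructureTables, positions are validated against the chain length.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", comment="#")
    required = {"protein_id", "chain", "position", "viability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    labels = []
    for _, row in df.iterrows():
        token = str(row["viability"]).strip().lower()
        if token not in _VIABILITY:
            raise ValueError(f"unknown viability token {token!r}")
        pos = int(row["position"])
        pid = str(row["protein_id"])
        if structures is not None and pid in structures:
            if not (1 < pos <= len(structures[pid])):
                raise ValueError(
                    f"position {pos} out of range for {pid} "
                    f"(chain length {len(structures[pid])})"
                )
        labels.append(
            CPSiteLabel(
                protein_id=pid,
                chain_id=str(row["chain"]),
                site_position=pos,
                viable=_VIABILITY[token],
                source=str(row.get("source", "")),
            )
        )
    return labels
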