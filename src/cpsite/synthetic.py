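"""Synthetic toy structures, viability labels and sequence groups.

Everything downstream of structure ingestion is exercisable without real
data: backbones are built with ideal bond geometry from secondary-structure
block specifications (helix / strand / loop), viability labels are planted
through a stated logistic model on structure-derived features, and sequence
groups mimic the amino-acid enrichments seen at cleavage-point windows
(e.g. a ~32% proline excess over background).

Side chains are not built: descriptors run in backbone-only mode (N, CA,
C, O) on synthetic inputs, which is a documented test-mode limitation.
All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .structure import Atom, CPSiteLabel, ResidueRecord, StructureTable

logger = logging.getLogger("cpsite")

# Ideal trans-peptide backbone geometry (lengths in Angstrom, angles deg).
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8
_OMEGA = 180.0

#: (phi, psi) of the ideal secondary-structure blocks.
BLOCK_DIHEDRALS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}

#: Average amino-acid composition of a large curated protein sequence
#: collection (percent), used as the background distribution.
BACKGROUND_COMPOSITION = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91,
    "L": 9.65, "K": 5.80, "M": 2.41, "F": 3.86, "P": 4.74,
    "S": 6.64, "T": 5.35, "W": 1.10, "Y": 2.92, "V": 6.86,
}


@dataclass
class SyntheticSpec:
    """Specification of one toy polypeptide.

    ``blocks`` lists (sse_kind, length) runs; ``noise_sd`` adds isotropic
    Gaussian jitter to every atom; ``label_model`` holds the logistic
    intercept and per-feature coefficients used to plant viability labels.
    """

    blocks: List[Tuple[str, int]]
    noise_sd: float = 0.0
    label_model: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_MODEL)
    )
    enrichment_map: Dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for kind, length in self.blocks:
            if kind not in ("helix", "strand", "loop"):
                raise ValueError(f"unknown block kind {kind!r}")
            if length < 1:
                raise ValueError("block lengths must be >= 1")
        for v in self.enrichment_map.values():
            if v <= 0:
                raise ValueError("enrichment multipliers must be > 0")


#: Planted association: exposed/unpacked (low WCN) and loop residues viable.
DEFAULT_LABEL_MODEL = {"intercept": 0.0, "WCN": -2.0, "loop": 1.0}


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Next atom position from three predecessors (internal coordinates)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(ang),
            bond * math.cos(tor) * math.sin(ang),
            bond * math.sin(tor) * math.sin(ang),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def _sample_loop_dihedrals(rng: np.random.Generator) -> Tuple[float, float]:
    """Uniform draw from a permitted (generously coil-like) backbone region."""
    phi = rng.uniform(-160.0, -50.0)
    psi = rng.uniform(-60.0, 180.0)
    return phi, psi


def _draw_sequence(rng: np.random.Generator, n: int,
                   probs: Optional[np.ndarray] = None) -> str:
    aas = list(BACKGROUND_COMPOSITION)
    if probs is None:
        p = np.asarray([BACKGROUND_COMPOSITION[a] for a in aas], dtype=float)
        probs = p / p.sum()
    return "".join(rng.choice(aas, size=n, p=probs))


def build_polypeptide(
    spec: SyntheticSpec,
    protein_id: str = "synthetic",
    chain_id: str = "A",
    sequence: Optional[str] = None,
    max_retries: int = 50,
) -> StructureTable:
    """Construct an ideal-geometry backbone from secondary-structure blocks.

    Backbone atoms (N, CA, C, O) are placed sequentially with ideal bond
    lengths and angles; helix blocks use (phi, psi) = (-57, -47), strands
    (-120, +120), loops draw uniformly from the permitted region.  Chains
    with a steric self-clash (non-neighbor Cα pairs under 3.0 A) resample
    their loop dihedrals a bounded number of times.  Optional Gaussian noise
    perturbs every atom.  B-factors are synthesized as a noisy increasing
    function of the distance from the chain centroid, mimicking the higher
    mobility of surface residues.
    """
    rng = np.random.default_rng(spec.seed)
    n = sum(length for _, length in spec.blocks)
    if n < 2:
        raise ValueError("need at least 2 residues")
    kinds: List[str] = []
    for kind, length in spec.blocks:
        kinds.extend([kind] * length)
    if sequence is not None and len(sequence) != n:
        raise ValueError("sequence length must match the block total")
    seq = sequence or _draw_sequence(rng, n)

    for attempt in range(max_retries):
        dihedrals = []
        for kind in kinds:
            if kind == "loop":
                dihedrals.append(_sample_loop_dihedrals(rng))
            else:
                dihedrals.append(BLOCK_DIHEDRALS[kind])
        coords = _build_backbone(dihedrals)
        ca = coords["CA"]
        d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=2)
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        if np.all(d[sep >= 2] >= 3.0):
            break
        if not any(k == "loop" for k in kinds):
            raise RuntimeError("ideal-geometry chain self-clashes and has no "
                               "loop dihedrals to resample")
    else:
        raise RuntimeError(f"could not build a clash-free chain in "
                           f"{max_retries} attempts")

    if spec.noise_sd > 0:
        for key in coords:
            coords[key] = coords[key] + rng.normal(0.0, spec.noise_sd,
                                                   size=coords[key].shape)

    centroid = coords["CA"].mean(axis=0)
    cm = np.linalg.norm(coords["CA"] - centroid, axis=1)
    bfac = 10.0 + 2.0 * cm + rng.normal(0.0, 2.0, size=n)

    residues = []
    for i in range(n):
        atoms = [
            Atom("N", "N", coords["N"][i], 1.0, float(bfac[i])),
            Atom("CA", "C", coords["CA"][i], 1.0, float(bfac[i])),
            Atom("C", "C", coords["C"][i], 1.0, float(bfac[i])),
            Atom("O", "O", coords["O"][i], 1.0, float(bfac[i])),
        ]
        residues.append(
            ResidueRecord(
                chain_id=chain_id,
                seq_position=i + 1,
                pdb_resnum=i + 1,
                icode="",
                aa=seq[i],
                ca_xyz=coords["CA"][i],
                atoms=atoms,
                b_factor_ca=float(bfac[i]),
            )
        )
    return StructureTable(protein_id=protein_id, chain_id=chain_id,
                          residues=residues)


def _build_backbone(dihedrals: List[Tuple[float, float]]) -> Dict[str, np.ndarray]:
    n = len(dihedrals)
    N = np.empty((n, 3))
    CA = np.empty((n, 3))
    C = np.empty((n, 3))
    O = np.empty((n, 3))
    # seed the first three atoms in a plane
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_BOND_N_CA, 0.0, 0.0)
    ang = math.radians(_ANGLE_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    for i in range(1, n):
        psi_prev = dihedrals[i - 1][1]
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1],
                           _BOND_C_N, _ANGLE_CA_C_N, psi_prev)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i],
                            _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i],
                           _BOND_CA_C, _ANGLE_N_CA_C, dihedrals[i][0])
    for i in range(n):
        O[i] = _place_atom(N[i], CA[i], C[i],
                           _BOND_C_O, _ANGLE_CA_C_O, dihedrals[i][1] - 180.0)
    return {"N": N, "CA": CA, "C": C, "O": O}


def label_model_features(structure: StructureTable) -> Dict[str, np.ndarray]:
    """Feature values referenced by the planted logistic label model.

    ``WCN`` is the per-protein z-score of the weighted contact number
    (negative coefficient: unpacked residues viable); ``loop`` indicates a
    residue outside helix/strand conformation by the dihedral fallback.
    """
    from .descriptors import weighted_contact_number
    from .structure import assign_sse

    wcn = weighted_contact_number(structure)
    z = (wcn - wcn.mean()) / wcn.std()
    assign_sse(structure)
    loop = np.asarray([1.0 if r.sse8 == "-" else 0.0
                       for r in structure.residues])
    return {"WCN": z, "loop": loop}


def plant_viability_labels(
    structure: StructureTable,
    label_model: Optional[Dict[str, float]] = None,
    seed: int = 0,
    features: Optional[Dict[str, np.ndarray]] = None,
) -> List[CPSiteLabel]:
    """Bernoulli viability labels from a logistic model on residue features.

    P(viable at i) = logistic(b0 + sum_f beta_f * x_f(i)); position 1 is
    excluded (the identity permutation).  Coefficients address the features
    returned by :func:`label_model_features` unless ``features`` overrides
    them.
    """
    model = dict(DEFAULT_LABEL_MODEL if label_model is None else label_model)
    b0 = model.pop("intercept", 0.0)
    feats = features if features is not None else label_model_features(structure)
    rng = np.random.default_rng(seed)
    n = len(structure)
    logit = np.full(n, b0, dtype=float)
    for name, beta in model.items():
        if name not in feats:
            raise ValueError(f"label model references unknown feature {name!r}")
        logit += beta * np.asarray(feats[name], dtype=float)
    prob = 1.0 / (1.0 + np.exp(-logit))
    draws = rng.random(n) < prob
    return [
        CPSiteLabel(
            protein_id=structure.protein_id,
            chain_id=structure.chain_id,
            site_position=i + 1,
            viable=bool(draws[i]),
            source="synthetic",
        )
        for i in range(1, n)  # skip position 1
    ]


def enriched_composition(enrichment_map: Dict[str, float]) -> np.ndarray:
    """Background composition reweighted by per-amino-acid multipliers,
    renormalized to a probability vector."""
    aas = list(BACKGROUND_COMPOSITION)
    p = np.asarray([BACKGROUND_COMPOSITION[a] for a in aas], dtype=float)
    for aa, mult in enrichment_map.items():
        if aa not in BACKGROUND_COMPOSITION:
            raise ValueError(f"unknown amino acid {aa!r}")
        p[aas.index(aa)] *= mult
    return p / p.sum()


def generate_sequence_groups(
    enrichment_map: Dict[str, float],
    n_seqs: int = 1000,
    length: int = 6,
    seed: int = 0,
    background_length: int = 300,
) -> Tuple[List[str], List[str]]:
    """Background and site sequence groups with planted enrichments.

    The background group draws from the fixed baseline composition; the
    site group draws from the baseline reweighted by the enrichment map
    (e.g. {"P": 1.32} plants a 32% proline excess) and renormalized.

    Mirroring the real study design, site polypeptides are short cleavage
    windows (``length``, default 6) while background polypeptides are
    whole-chain-sized (``background_length``, default 300, a typical
    protein length); pass equal lengths for a fully exchangeable null.
    """
    rng = np.random.default_rng(seed)
    aas = list(BACKGROUND_COMPOSITION)
    base = enriched_composition({})
    site = enriched_composition(enrichment_map)
    background = ["".join(rng.choice(aas, size=background_length, p=base))
                  for _ in range(n_seqs)]
    sites = ["".join(rng.choice(aas, size=length, p=site))
             for _ in range(n_seqs)]
    return background, sites


def to_fasta(sequences: Sequence[str], prefix: str = "seq") -> str:
    return "".join(f">{prefix}_{i}\n{s}\n" for i, s in enumerate(sequences, 1))


# ---------------------------------------------------------------------------
# A ready-made labeled study for end-to-end exercises
# ---------------------------------------------------------------------------

#: Default fold template: helix-loop-strand-loop-helix, 50 residues.
DEFAULT_BLOCKS = [
    ("helix", 14), ("loop", 5), ("strand", 8), ("loop", 5),
    ("strand", 8), ("loop", 4), ("helix", 6),
]


#: Burial threshold (RSA %) used for synthetic backbone-only structures.
#: Without side chains, RSA is normalized by full-residue reference areas,
#: so even core residues rarely fall below the 10% used for real proteins;
#: 35% marks the relatively buried fraction of a backbone-only chain.
SYNTHETIC_BURIED_RSA = 35.0


def synthetic_descriptor_config():
    from .descriptors import DescriptorConfig

    return DescriptorConfig(buried_rsa_threshold=SYNTHETIC_BURIED_RSA)


def simulate_study(
    n_proteins: int = 16,
    blocks: Optional[List[Tuple[str, int]]] = None,
    label_model: Optional[Dict[str, float]] = None,
    noise_sd: float = 0.15,
    seed: int = 0,
    descriptor_config=None,
):
    """Generate a labeled multi-protein dataset with planted viability.

    Returns (feature_matrix, labels array, training row index, structures,
    label lists) where the feature matrix holds the full tertiary
    descriptor set for every residue and labels align with its rows
    (position-1 residues, which can never be CP sites, get label 0 and are
    excluded from the returned training row index).
    """
    from .descriptors import compute_feature_matrix, concat_matrices

    blocks = blocks or DEFAULT_BLOCKS
    descriptor_config = descriptor_config or synthetic_descriptor_config()
    rng = np.random.default_rng(seed)
    structures, matrices, all_labels = [], [], []
    for i in range(n_proteins):
        spec = SyntheticSpec(
            blocks=blocks,
            noise_sd=noise_sd,
            label_model=dict(label_model) if label_model else dict(DEFAULT_LABEL_MODEL),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        st = build_polypeptide(spec, protein_id=f"synth{i:03d}")
        structures.append(st)
        matrices.append(compute_feature_matrix(st, descriptor_config))
        all_labels.append(
            plant_viability_labels(
                st, spec.label_model, seed=int(rng.integers(0, 2**31 - 1))
            )
        )
    fm = concat_matrices(matrices)
    y = np.zeros(len(fm.data), dtype=int)
    rows = []
    offset = 0
    for st, labels in zip(structures, all_labels):
        for lab in labels:
            idx = offset + lab.site_position - 1
            y[idx] = int(lab.viable)
            rows.append(idx)
        offset += len(st)
    return fm, y, np.asarray(rows, dtype=int), structures, all_labels
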