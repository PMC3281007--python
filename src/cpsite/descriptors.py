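"""Tertiary-structure-derived per-residue measures.

Implements the descriptor family used to discriminate viable from inviable
circular-permutation sites: solvent exposure (RSA, residue depth, centroid
distance), local packing (contact number, weighted contact number, closeness
centrality, hydrogen-bond count), flexibility (crystallographic B-factor
passthrough and Gaussian-network-model fluctuations), and distances from the
buried/hydrophobic core (mean core distance and the weighted-harmonic
"farness" measure).

All measures locate a residue by its alpha carbon unless an atom-level
definition applies (contact number counts heavy atoms; SASA is atom-level).
Hydrogens are ignored throughout: the hydrogen-bond count uses a heavy-atom
donor/acceptor distance criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Optional, Set

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import StructureTable, assign_sse

logger = logging.getLogger("cpsite")


@dataclass
class DescriptorConfig:
    """Tunable parameters of the residue descriptors (distances in Angstrom)."""

    cn_radius: float = 6.4            # contact-number sphere radius
    wcn_exponent: int = 2             # inverse-power weight of WCN
    closeness_edge_cutoff: float = 8.0
    gnm_cutoff: float = 10.0
    sasa_probe: float = 1.4
    sasa_points: int = 960
    hbond_da_max: float = 3.5         # donor-acceptor heavy-atom distance
    buried_rsa_threshold: float = 10.0  # percent
    farness_weight_exponent: int = 2  # q; summand weight is d^-(q+1)

    def __post_init__(self):
        for name in ("cn_radius", "closeness_edge_cutoff", "gnm_cutoff",
                     "sasa_probe", "hbond_da_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.buried_rsa_threshold < 100:
            raise ValueError("buried_rsa_threshold must be in (0, 100)")


@dataclass
class CoreSet:
    """A working definition of the buried/hydrophobic core.

    kind: 'B' (buried, RSA below threshold), 'H' (hydrophobic amino acids),
    'B|H' (union) or 'B&H' (intersection).  Members are seq_positions.
    """

    kind: str
    members: Set[int]


@dataclass
class FeatureMatrix:
    """Residues x descriptors for one or more proteins.

    ``data`` carries ``protein_id`` and ``seq_position`` columns plus one
    column per feature; orientation/standardization state is tracked so the
    predictor cannot silently double-transform.
    """

    data: pd.DataFrame
    feature_names: list
    oriented: bool = False
    standardized: bool = False

    def values(self) -> np.ndarray:
        return self.data[self.feature_names].to_numpy(dtype=float)


# Van der Waals radii for heavy elements (Angstrom); unknown -> carbon.
_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}

# Maximum accessible surface areas (Angstrom^2) from the theoretical
# Gly-X-Gly tripeptide scale of Tien et al. (2013); used to normalize RSA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}

# Hydrophobic / hydrophilic / neutral residue classes (3-class scheme).
HYDROPHOBIC = set("ACFILMVW")
HYDROPHILIC = set("RNDQEK")
NEUTRAL = set("GHPSTY")


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _flat_atoms(structure: StructureTable):
    """All heavy atoms as (coords, radii, residue index 0-based)."""
    coords, radii, owner = [], [], []
    for i, r in enumerate(structure.residues):
        for a in r.atoms:
            coords.append(a.xyz)
            radii.append(_VDW.get(a.element.upper(), 1.70))
            owner.append(i)
    return np.asarray(coords, float), np.asarray(radii, float), np.asarray(owner, int)


def atom_sasa(structure: StructureTable, config: DescriptorConfig) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per heavy atom (A^2)."""
    coords, radii, _ = _flat_atoms(structure)
    probe = config.sasa_probe
    rr = radii + probe
    pts = _sphere_points(config.sasa_points)
    tree = cKDTree(coords)
    out = np.empty(len(coords))
    max_r = rr.max()
    for i in range(len(coords)):
        neighbors = tree.query_ball_point(coords[i], rr[i] + max_r)
        neighbors = [j for j in neighbors if j != i
                     and np.linalg.norm(coords[j] - coords[i]) < rr[i] + rr[j]]
        test = coords[i] + rr[i] * pts
        if neighbors:
            nb = np.asarray(neighbors, int)
            d2 = ((test[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (rr[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * np.pi * rr[i] ** 2
    return out


def sasa_rsa(
    structure: StructureTable,
    config: Optional[DescriptorConfig] = None,
    _atom_sasa: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Relative solvent accessibility per residue, in percent."""
    config = config or DescriptorConfig()
    sasa = atom_sasa(structure, config) if _atom_sasa is None else _atom_sasa
    _, _, owner = _flat_atoms(structure)
    rsa = np.empty(len(structure))
    for i, r in enumerate(structure.residues):
        res_sasa = sasa[owner == i].sum()
        if r.aa not in MAX_ASA:
            logger.warning("unknown residue type %r; using Gly MaxASA", r.aa)
        rsa[i] = 100.0 * res_sasa / MAX_ASA.get(r.aa, MAX_ASA["G"])
    return rsa


def residue_depth(
    structure: StructureTable,
    config: Optional[DescriptorConfig] = None,
    _atom_sasa: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Depth of each residue's alpha carbon below the accessible surface (A).

    Defined as the distance from the Cα to the nearest solvent-accessible
    heavy atom; zero when that nearest accessible atom belongs to the residue
    itself.
    """
    config = config or DescriptorConfig()
    sasa = atom_sasa(structure, config) if _atom_sasa is None else _atom_sasa
    coords, _, owner = _flat_atoms(structure)
    accessible = sasa > 0
    if not accessible.any():
        raise ValueError("no solvent-accessible atom in chain")
    acc_xyz = coords[accessible]
    acc_owner = owner[accessible]
    depth = np.empty(len(structure))
    for i, r in enumerate(structure.residues):
        d = np.linalg.norm(acc_xyz - r.ca_xyz, axis=1)
        j = int(np.argmin(d))
        depth[i] = 0.0 if acc_owner[j] == i else d[j]
    return depth


def centroid_distance(structure: StructureTable) -> np.ndarray:
    """Distance of each Cα from the unweighted Cα centroid (A)."""
    ca = structure.ca_coords()
    centroid = ca.mean(axis=0)
    return np.linalg.norm(ca - centroid, axis=1)


def contact_number(
    structure: StructureTable, config: Optional[DescriptorConfig] = None
) -> np.ndarray:
    """Heavy atoms of *other* residues within ``cn_radius`` of each Cα."""
    config = config or DescriptorConfig()
    coords, _, owner = _flat_atoms(structure)
    tree = cKDTree(coords)
    cn = np.empty(len(structure), dtype=float)
    for i, r in enumerate(structure.residues):
        idx = tree.query_ball_point(r.ca_xyz, config.cn_radius)
        cn[i] = sum(1 for j in idx if owner[j] != i)
    return cn


def weighted_contact_number(
    structure: StructureTable, exponent: int = 2
) -> np.ndarray:
    """Cα-level contact number with inverse-power distance weights, no cutoff."""
    ca = structure.ca_coords()
    diff = ca[:, None, :] - ca[None, :, :]
    d2 = (diff ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    if np.any(d2 <= 0):
        raise ValueError("coincident alpha carbons: degenerate geometry")
    if exponent == 2:
        w = 1.0 / d2
    else:
        w = d2 ** (-exponent / 2.0)
    return w.sum(axis=1)


def contact_graph(
    structure: StructureTable, cutoff: float
) -> nx.Graph:
    ca = structure.ca_coords()
    g = nx.Graph()
    g.add_nodes_from(range(len(ca)))
    tree = cKDTree(ca)
    for i, j in tree.query_pairs(cutoff):
        g.add_edge(i, j)
    return g


def closeness(
    structure: StructureTable, config: Optional[DescriptorConfig] = None
) -> np.ndarray:
    """Harmonic closeness centrality on the unit-hop Cα contact graph.

    closeness(i) = (1/(n-1)) * sum_j 1/sp(i, j); unreachable nodes
    contribute zero, so disconnected graphs are well defined.
    """
    config = config or DescriptorConfig()
    g = contact_graph(structure, config.closeness_edge_cutoff)
    n = len(structure)
    harm = nx.harmonic_centrality(g)
    return np.asarray([harm[i] / (n - 1) for i in range(n)])


def hydrogen_bond_count(
    structure: StructureTable, config: Optional[DescriptorConfig] = None
) -> np.ndarray:
    """Intra-molecular hydrogen bonds touching each residue (heavy-atom rule).

    A bond is counted between an N/O atom of one residue and an N/O atom of a
    different residue at donor-acceptor distance <= ``hbond_da_max``,
    excluding backbone N/O pairs of sequence-adjacent residues (the covalent
    peptide-bond neighborhood).
    """
    config = config or DescriptorConfig()
    coords, names, owner = [], [], []
    for i, r in enumerate(structure.residues):
        for a in r.atoms:
            if a.element.upper() in ("N", "O"):
                coords.append(a.xyz)
                names.append(a.name)
                owner.append(i)
    coords = np.asarray(coords, float)
    owner = np.asarray(owner, int)
    counts = np.zeros(len(structure))
    if len(coords) == 0:
        return counts
    tree = cKDTree(coords)
    backbone = {"N", "O", "OXT"}
    for ai, aj in tree.query_pairs(config.hbond_da_max):
        ri, rj = owner[ai], owner[aj]
        if ri == rj:
            continue
        if abs(ri - rj) == 1 and names[ai] in backbone and names[aj] in backbone:
            continue
        counts[ri] += 1
        counts[rj] += 1
    return counts


def kirchhoff_matrix(structure: StructureTable, cutoff: float) -> np.ndarray:
    ca = structure.ca_coords()
    diff = ca[:, None, :] - ca[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    gamma = -(d <= cutoff).astype(float)
    np.fill_diagonal(gamma, 0.0)
    np.fill_diagonal(gamma, -gamma.sum(axis=1))
    return gamma


def gnm_fluctuation(
    structure: StructureTable, config: Optional[DescriptorConfig] = None
) -> np.ndarray:
    """Gaussian-network-model mean-square fluctuation per residue.

    Diagonal of the pseudo-inverse of the Kirchhoff (connectivity) matrix on
    Cα nodes, discarding the single zero mode.  Unnormalized (no kT/gamma
    prefactor): only relative values matter downstream.
    """
    config = config or DescriptorConfig()
    if len(structure) < 3:
        raise ValueError("GNM needs at least 3 residues")
    gamma = kirchhoff_matrix(structure, config.gnm_cutoff)
    g = nx.from_numpy_array(gamma < 0)
    if not nx.is_connected(g):
        raise ValueError(
            f"contact network disconnected at cutoff {config.gnm_cutoff} A; "
            "increase gnm_cutoff"
        )
    w, v = np.linalg.eigh(gamma)
    # one zero mode for a connected network
    inv = np.zeros_like(w)
    inv[1:] = 1.0 / w[1:]
    return np.einsum("ik,k,ik->i", v, inv, v)


def core_set(
    structure: StructureTable,
    kind: str,
    rsa: Optional[np.ndarray] = None,
    config: Optional[DescriptorConfig] = None,
) -> CoreSet:
    """Working definition of the buried/hydrophobic core.

    B = residues with RSA below the buried threshold; H = hydrophobic
    residues; 'B|H' and 'B&H' by set algebra.  Seq positions are 1-based.
    """
    config = config or DescriptorConfig()
    kind = kind.replace("∪", "|").replace("∩", "&")
    if kind not in ("B", "H", "B|H", "B&H"):
        raise ValueError(f"unknown core kind {kind!r}")
    members: Set[int] = set()
    b: Set[int] = set()
    h: Set[int] = set()
    if "B" in kind:
        if rsa is None:
            raise ValueError("RSA values required for a buried core set")
        b = {
            r.seq_position
            for r, v in zip(structure.residues, rsa)
            if v < config.buried_rsa_threshold
        }
    if "H" in kind:
        h = {r.seq_position for r in structure.residues if r.aa in HYDROPHOBIC}
    if kind == "B":
        members = b
    elif kind == "H":
        members = h
    elif kind == "B|H":
        members = b | h
    else:
        members = b & h
    if not members:
        raise ValueError(f"core set {kind!r} is empty; farness is undefined")
    return CoreSet(kind=kind, members=members)


def mean_core_distance(structure: StructureTable, core: CoreSet) -> np.ndarray:
    """Arithmetic mean Cα distance from each residue to the core members (A).

    A residue that is itself the only core member gets NaN (undefined).
    """
    ca = structure.ca_coords()
    idx = np.asarray(sorted(core.members)) - 1
    out = np.empty(len(structure))
    for i in range(len(structure)):
        others = idx[idx != i]
        if len(others) == 0:
            out[i] = np.nan
            continue
        out[i] = np.linalg.norm(ca[others] - ca[i], axis=1).mean()
    return out


def farness(
    structure: StructureTable,
    core: CoreSet,
    q: int = 2,
) -> np.ndarray:
    """Weighted-harmonic distance of each residue from a core residue set.

    F(i, G) = [ sum_{j in G, j != i} d_ij^-(q+1) ]^-1 with the inverse-power
    weight W(j) = d_ij^-q applied to each reciprocal distance; q = 0 reduces
    to the unnormalized harmonic mean of the distances.  Large values mean
    far from the core.
    """
    ca = structure.ca_coords()
    idx = np.asarray(sorted(core.members)) - 1
    out = np.empty(len(structure))
    for i in range(len(structure)):
        others = idx[idx != i]
        if len(others) == 0:
            out[i] = np.nan
            continue
        d = np.linalg.norm(ca[others] - ca[i], axis=1)
        if np.any(d <= 0):
            raise ValueError(
                f"zero distance between residue {i + 1} and a core member"
            )
        out[i] = 1.0 / np.sum(d ** (-(q + 1)))
    return out


#: Canonical tertiary feature names in matrix column order.
TERTIARY_FEATURES = [
    "RSA", "depth", "CM", "hbonds", "closeness", "CN", "WCN",
    "bfactor", "gnmf", "DIS_b", "DIS_hpho",
    "F_b", "F_hpho", "F_bh_union", "F_bh_inter",
]


def compute_feature_matrix(
    structure: StructureTable,
    config: Optional[DescriptorConfig] = None,
    dssp_text: Optional[str] = None,
    score_tables: Optional[dict] = None,
    k: int = 3,
) -> FeatureMatrix:
    """Assemble all per-residue descriptors for one chain.

    Tertiary descriptors are always computed; sequence/secondary-structure
    propensity features (R_aa, R_aat3, R_aat5, R_sse) are appended when
    per-pattern score tables are supplied.  Secondary structure is taken from
    DSSP text when given, otherwise from the dihedral fallback.
    """
    config = config or DescriptorConfig()
    assign_sse(structure, dssp_text)
    sasa = atom_sasa(structure, config)
    rsa = sasa_rsa(structure, config, _atom_sasa=sasa)
    cores = {}
    for kind in ("B", "H", "B|H", "B&H"):
        cores[kind] = core_set(structure, kind, rsa=rsa, config=config)
    cols = {
        "RSA": rsa,
        "depth": residue_depth(structure, config, _atom_sasa=sasa),
        "CM": centroid_distance(structure),
        "hbonds": hydrogen_bond_count(structure, config),
        "closeness": closeness(structure, config),
        "CN": contact_number(structure, config),
        "WCN": weighted_contact_number(structure, config.wcn_exponent),
        "bfactor": np.asarray([r.b_factor_ca for r in structure.residues]),
        "gnmf": gnm_fluctuation(structure, config),
        "DIS_b": mean_core_distance(structure, cores["B"]),
        "DIS_hpho": mean_core_distance(structure, cores["H"]),
        "F_b": farness(structure, cores["B"], config.farness_weight_exponent),
        "F_hpho": farness(structure, cores["H"], config.farness_weight_exponent),
        "F_bh_union": farness(structure, cores["B|H"], config.farness_weight_exponent),
        "F_bh_inter": farness(structure, cores["B&H"], config.farness_weight_exponent),
    }
    names = list(TERTIARY_FEATURES)
    if score_tables is not None:
        from .propensity import residue_propensity_features

        prop = residue_propensity_features(structure, score_tables, k=k)
        for c in prop.columns:
            cols[c] = prop[c].to_numpy()
            names.append(c)
    df = pd.DataFrame(cols)
    df.insert(0, "seq_position", [r.seq_position for r in structure.residues])
    df.insert(0, "protein_id", structure.protein_id)
    return FeatureMatrix(data=df, feature_names=names)


def concat_matrices(matrices: Iterable[FeatureMatrix]) -> FeatureMatrix:
    mats = list(matrices)
    if not mats:
        raise ValueError("no matrices to concatenate")
    names = mats[0].feature_names
    for m in mats:
        if m.feature_names != names or m.oriented != mats[0].oriented \
                or m.standardized != mats[0].standardized:
            raise ValueError("feature matrices are not compatible")
    df = pd.concat([m.data for m in mats], ignore_index=True)
    return FeatureMatrix(
        data=df, feature_names=list(names),
        oriented=mats[0].oriented, standardized=mats[0].standardized,
    )
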