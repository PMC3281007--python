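"""Residue descriptors against independent brute-force oracles.

Every packing/graph/distance measure is checked exactly (or to 1e-8)
against a naive reimplementation on small random structures, plus the
closed-form and invariance properties (rigid motions, scaling laws,
monotone behavior under radial displacement).
"""

import numpy as np
import pytest

from cpsite.descriptors import (
    DescriptorConfig,
    CoreSet,
    atom_sasa,
    centroid_distance,
    closeness,
    compute_feature_matrix,
    contact_number,
    core_set,
    farness,
    gnm_fluctuation,
    hydrogen_bond_count,
    kirchhoff_matrix,
    mean_core_distance,
    residue_depth,
    sasa_rsa,
    weighted_contact_number,
    TERTIARY_FEATURES,
    _VDW,
)
from cpsite.synthetic import SyntheticSpec, build_polypeptide, DEFAULT_BLOCKS

from conftest import ca_only_structure, random_ca_structure


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementations under test)
# ---------------------------------------------------------------------------

def brute_cn(structure, radius):
    out = []
    for r in structure.residues:
        count = 0
        for other in structure.residues:
            if other is r:
                continue
            for a in other.atoms:
                if np.linalg.norm(a.xyz - r.ca_xyz) <= radius:
                    count += 1
        out.append(count)
    return np.asarray(out, dtype=float)


def brute_wcn(structure):
    ca = structure.ca_coords()
    n = len(ca)
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i] += np.linalg.norm(ca[i] - ca[j]) ** -2
    return out


def brute_closeness(structure, cutoff):
    """Breadth-first search harmonic centrality."""
    ca = structure.ca_coords()
    n = len(ca)
    adj = [
        [j for j in range(n)
         if j != i and np.linalg.norm(ca[i] - ca[j]) <= cutoff]
        for i in range(n)
    ]
    out = np.zeros(n)
    for s in range(n):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        out[s] = sum(1.0 / d for v, d in dist.items() if v != s) / (n - 1)
    return out


def brute_hbonds(structure, dmax):
    n = len(structure)
    counts = np.zeros(n)
    backbone = {"N", "O", "OXT"}
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = structure.residues[i], structure.residues[j]
            for a in ri.atoms:
                if a.element not in ("N", "O"):
                    continue
                for b in rj.atoms:
                    if b.element not in ("N", "O"):
                        continue
                    if np.linalg.norm(a.xyz - b.xyz) > dmax:
                        continue
                    if j - i == 1 and a.name in backbone and b.name in backbone:
                        continue
                    counts[i] += 1
                    counts[j] += 1
    return counts


def brute_gnm(structure, cutoff):
    """Dense eigendecomposition pseudo-inverse diagonal."""
    ca = structure.ca_coords()
    n = len(ca)
    gamma = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(ca[i] - ca[j]) <= cutoff:
                gamma[i, j] = -1.0
    for i in range(n):
        gamma[i, i] = -gamma[i].sum()
    w, v = np.linalg.eigh(gamma)
    out = np.zeros(n)
    for k in range(1, n):
        out += v[:, k] ** 2 / w[k]
    return out


def _ring_sphere_points(n, seed):
    """Equal-area latitude-ring quadrature points on the unit sphere;
    deterministic and constructed differently from the implementation's
    golden-spiral lattice."""
    rng = np.random.default_rng(seed)
    n_rings = int(round(np.sqrt(n)))
    cos_edges = np.linspace(1.0, -1.0, n_rings + 1)
    pts = []
    for k in range(n_rings):
        c = 0.5 * (cos_edges[k] + cos_edges[k + 1])
        s = np.sqrt(max(0.0, 1.0 - c * c))
        m = max(1, int(round(n / n_rings)))
        phi = 2 * np.pi * (np.arange(m) + rng.random()) / m
        ring = np.stack([s * np.cos(phi), s * np.sin(phi),
                         np.full(m, c)], axis=1)
        pts.append(ring)
    return np.concatenate(pts)


def brute_sasa(structure, probe, n_points, seed):
    """Sphere-point counting on an equal-area ring grid, independent of
    the lattice used by the implementation."""
    sphere = _ring_sphere_points(n_points, seed)
    atoms = [(a.xyz, _VDW.get(a.element.upper(), 1.70))
             for r in structure.residues for a in r.atoms]
    out = np.zeros(len(atoms))
    for i, (xyz, r) in enumerate(atoms):
        rr = r + probe
        pts = xyz + rr * sphere
        exposed = np.ones(len(pts), dtype=bool)
        for j, (oxyz, orad) in enumerate(atoms):
            if j == i:
                continue
            exposed &= np.linalg.norm(pts - oxyz, axis=1) >= orad + probe
        out[i] = exposed.mean() * 4 * np.pi * rr ** 2
    return out


# ---------------------------------------------------------------------------
# Closed-form cases
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_cm_two_residues(self):
        st = ca_only_structure([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(centroid_distance(st), [1.0, 1.0])

    def test_cm_equilateral_triangle(self):
        s = 4.0
        st = ca_only_structure(
            [[0, 0, 0], [s, 0, 0], [s / 2, s * np.sqrt(3) / 2, 0]]
        )
        np.testing.assert_allclose(
            centroid_distance(st), [s / np.sqrt(3)] * 3, rtol=1e-12
        )

    def test_cn_pair_within_and_outside_radius(self):
        st5 = ca_only_structure([[0, 0, 0], [5, 0, 0]])
        st7 = ca_only_structure([[0, 0, 0], [7, 0, 0]])
        np.testing.assert_array_equal(contact_number(st5), [1, 1])
        np.testing.assert_array_equal(contact_number(st7), [0, 0])

    def test_wcn_pair_closed_form(self):
        st = ca_only_structure([[0, 0, 0], [2, 0, 0]])
        np.testing.assert_allclose(weighted_contact_number(st), [0.25, 0.25])

    def test_wcn_scaling_homogeneity(self):
        rng = np.random.default_rng(0)
        st = random_ca_structure(rng, n=20)
        base = weighted_contact_number(st)
        st2 = ca_only_structure(st.ca_coords() * 2.0)
        np.testing.assert_allclose(weighted_contact_number(st2), base / 4.0)

    def test_wcn_coincident_error(self):
        st = ca_only_structure([[0, 0, 0], [0, 0, 0], [5, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            weighted_contact_number(st)

    def test_closeness_three_node_path(self):
        st = ca_only_structure([[0, 0, 0], [7, 0, 0], [14, 0, 0]])
        np.testing.assert_allclose(closeness(st), [0.75, 1.0, 0.75])

    def test_closeness_isolated_residue(self):
        st = ca_only_structure([[0, 0, 0], [7, 0, 0], [100, 0, 0]])
        assert closeness(st)[2] == 0.0

    def test_hbond_rule(self):
        # N-O at 2.9 A between non-adjacent residue pair -> one bond each;
        # at 4.0 A -> none.  (CA-only atoms are C, so craft N/O atoms.)
        from cpsite.structure import Atom

        def with_no(dist):
            st = ca_only_structure([[0, 0, 0], [20, 0, 0], [40, 0, 0]])
            st.residues[0].atoms.append(Atom("ND1", "N", np.array([0.0, 1.0, 0.0])))
            st.residues[2].atoms.append(
                Atom("OD1", "O", np.array([0.0, 1.0 + dist, 0.0]))
            )
            return st

        np.testing.assert_array_equal(
            hydrogen_bond_count(with_no(2.9)), [1, 0, 1]
        )
        np.testing.assert_array_equal(
            hydrogen_bond_count(with_no(4.0)), [0, 0, 0]
        )

    def test_farness_single_core_member(self):
        st = ca_only_structure([[0, 0, 0], [2, 0, 0]])
        core = CoreSet(kind="B", members={2})
        assert farness(st, core, q=2)[0] == pytest.approx(8.0)

    def test_farness_two_members_unit_distance(self):
        st = ca_only_structure([[0, 0, 0], [1, 0, 0], [-1, 0, 0]])
        core = CoreSet(kind="B", members={2, 3})
        assert farness(st, core, q=2)[0] == pytest.approx(0.5)

    def test_farness_scaling_power_law(self):
        rng = np.random.default_rng(1)
        st = random_ca_structure(rng, n=15)
        core = CoreSet(kind="B", members={3, 7, 11})
        q = 2
        base = farness(st, core, q=q)
        st2 = ca_only_structure(st.ca_coords() * 3.0)
        np.testing.assert_allclose(farness(st2, core, q=q), base * 3.0 ** (q + 1))

    def test_farness_q0_is_unnormalized_harmonic_form(self):
        rng = np.random.default_rng(2)
        st = random_ca_structure(rng, n=12)
        core = CoreSet(kind="B", members={2, 5, 9})
        ca = st.ca_coords()
        f0 = farness(st, core, q=0)
        for i in range(len(st)):
            inv_sum = sum(
                1.0 / np.linalg.norm(ca[i] - ca[j - 1])
                for j in core.members if j - 1 != i
            )
            assert f0[i] == pytest.approx(1.0 / inv_sum)

    def test_dis_simple_means(self):
        st = ca_only_structure([[0, 0, 0], [3, 0, 0], [1, 0, 0]])
        core_one = CoreSet(kind="B", members={2})
        assert mean_core_distance(st, core_one)[0] == pytest.approx(3.0)
        core_two = CoreSet(kind="B", members={2, 3})
        assert mean_core_distance(st, core_two)[0] == pytest.approx(2.0)

    def test_dis_singleton_core_is_nan_for_member(self):
        st = ca_only_structure([[0, 0, 0], [3, 0, 0]])
        core = CoreSet(kind="B", members={1})
        out = mean_core_distance(st, core)
        assert np.isnan(out[0]) and out[1] == pytest.approx(3.0)


class TestCoreSets:
    def test_buried_set_from_rsa(self):
        st = ca_only_structure(np.diag([4.0, 8.0, 12.0]) @ np.ones((3, 3)) / 3,
                               aas="LDG")
        st = ca_only_structure([[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]],
                               aas="LDGA")
        rsa = np.array([5.0, 50.0, 9.0, 12.0])
        assert core_set(st, "B", rsa=rsa).members == {1, 3}

    def test_hydrophobic_set_from_classes(self):
        st = ca_only_structure([[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]],
                               aas="LDGA")
        assert core_set(st, "H").members == {1, 4}

    def test_set_algebra(self):
        st = ca_only_structure([[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]],
                               aas="LDGA")
        rsa = np.array([5.0, 50.0, 9.0, 12.0])
        assert core_set(st, "B&H", rsa=rsa).members == {1}
        assert core_set(st, "B|H", rsa=rsa).members == {1, 3, 4}

    def test_empty_core_is_an_error(self):
        st = ca_only_structure([[0, 0, 0], [5, 0, 0]], aas="DD")
        with pytest.raises(ValueError, match="empty"):
            core_set(st, "H")


# ---------------------------------------------------------------------------
# Oracle equivalence on random structures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def random_structures():
    rng = np.random.default_rng(2024)
    return [random_ca_structure(rng, n=int(rng.integers(10, 51)))
            for _ in range(20)]


class TestOracles:
    def test_cn_exact(self, random_structures):
        cfg = DescriptorConfig()
        for st in random_structures:
            np.testing.assert_array_equal(
                contact_number(st, cfg), brute_cn(st, cfg.cn_radius)
            )

    def test_wcn_to_1e9(self, random_structures):
        for st in random_structures:
            np.testing.assert_allclose(
                weighted_contact_number(st), brute_wcn(st), rtol=1e-9
            )

    def test_closeness_exact(self, random_structures):
        cfg = DescriptorConfig()
        for st in random_structures:
            np.testing.assert_allclose(
                closeness(st, cfg),
                brute_closeness(st, cfg.closeness_edge_cutoff),
                rtol=1e-12,
            )

    def test_hbonds_exact(self, random_structures):
        from cpsite.structure import Atom

        cfg = DescriptorConfig()
        rng = np.random.default_rng(7)
        for st in random_structures[:10]:
            # sprinkle N/O atoms so the criterion has material to count
            for r in st.residues:
                r.atoms.append(Atom("N", "N", r.ca_xyz + rng.normal(0, 1, 3)))
                r.atoms.append(Atom("O", "O", r.ca_xyz + rng.normal(0, 1, 3)))
            np.testing.assert_array_equal(
                hydrogen_bond_count(st, cfg),
                brute_hbonds(st, cfg.hbond_da_max),
            )

    def test_dis_and_farness_exact(self, random_structures):
        rng = np.random.default_rng(11)
        for st in random_structures:
            n = len(st)
            members = set(rng.choice(np.arange(1, n + 1),
                                     size=max(2, n // 4), replace=False)
                          .tolist())
            core = CoreSet(kind="B", members=members)
            ca = st.ca_coords()
            dis = mean_core_distance(st, core)
            far = farness(st, core, q=2)
            for i in range(n):
                ds = [np.linalg.norm(ca[i] - ca[j - 1])
                      for j in members if j - 1 != i]
                assert dis[i] == pytest.approx(np.mean(ds))
                assert far[i] == pytest.approx(
                    1.0 / np.sum([d ** -3 for d in ds]), rel=1e-9
                )

    def test_gnm_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            st = random_ca_structure(rng, n=10, scale=5.0)
            try:
                got = gnm_fluctuation(st)
            except ValueError:
                continue  # disconnected at this cutoff; skip this draw
            np.testing.assert_allclose(got, brute_gnm(st, 10.0), atol=1e-8)

    def test_cm_matches_brute_force(self):
        rng = np.random.default_rng(17)
        st = random_ca_structure(rng, n=50)
        ca = st.ca_coords()
        centroid = ca.mean(axis=0)
        expect = np.array([np.linalg.norm(c - centroid) for c in ca])
        np.testing.assert_allclose(centroid_distance(st), expect, atol=1e-9)


# ---------------------------------------------------------------------------
# SASA, RSA and depth
# ---------------------------------------------------------------------------

class TestSasaDepth:
    def test_isolated_residue_fully_exposed(self):
        st = ca_only_structure([[0, 0, 0], [60, 0, 0]], aas="GG")
        rsa = sasa_rsa(st)
        assert rsa.min() >= 95.0

    def test_caged_residue_loses_accessibility(self):
        from cpsite.structure import Atom

        st_free = ca_only_structure([[0, 0, 0], [60, 0, 0]], aas="GG")
        st_caged = ca_only_structure([[0, 0, 0], [60, 0, 0]], aas="GG")
        # 26-point cage at 4 A around residue 1
        offsets = [
            np.array([i, j, k], dtype=float)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
        for m, off in enumerate(offsets):
            xyz = 4.0 * off / np.linalg.norm(off)
            st_caged.residues[1].atoms.append(Atom(f"C{m}", "C", xyz))
        free = sasa_rsa(st_free)[0]
        caged = sasa_rsa(st_caged)[0]
        assert caged < free

    def test_sasa_matches_high_resolution_random_oracle(self, toy_fold):
        cfg = DescriptorConfig(sasa_points=5000)
        got = atom_sasa(toy_fold, cfg)
        ref = brute_sasa(toy_fold, cfg.sasa_probe, 10_000, seed=5)
        # compare per residue at 2%, on the scale of the residue's area
        owner = np.concatenate([
            np.full(len(r.atoms), i) for i, r in enumerate(toy_fold.residues)
        ])
        for i in range(len(toy_fold)):
            a = got[owner == i].sum()
            b = ref[owner == i].sum()
            assert a == pytest.approx(b, rel=0.02, abs=1.0)

    def test_exposed_dipeptide_depth_zero(self):
        st = ca_only_structure([[0, 0, 0], [6, 0, 0]], aas="GG")
        np.testing.assert_array_equal(residue_depth(st), [0.0, 0.0])

    def test_central_bead_deeper_than_shell(self):
        # dense cube cluster: central residue buried below the surface
        pts = [np.array([i, j, k], dtype=float) * 3.0
               for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)]
        st = ca_only_structure(pts)
        depth = residue_depth(st)
        center = len(pts) // 2  # (0,0,0)
        corner = 0              # (-6,-6,-6)
        assert depth[center] > depth[corner]
        assert depth[center] > 0

    def test_depth_translation_invariant(self, toy_fold):
        base = residue_depth(toy_fold)
        shifted = ca_only_structure(np.zeros((2, 3)))  # placeholder
        for r in toy_fold.residues:
            r.ca_xyz = r.ca_xyz + np.array([100.0, -50.0, 25.0])
            for a in r.atoms:
                a.xyz = a.xyz + np.array([100.0, -50.0, 25.0])
        np.testing.assert_allclose(residue_depth(toy_fold), base, atol=1e-9)


# ---------------------------------------------------------------------------
# Structural invariances and monotonicity
# ---------------------------------------------------------------------------

class TestProperties:
    def test_rigid_motion_invariance_of_all_descriptors(self, toy_fold):
        cfg = DescriptorConfig(buried_rsa_threshold=35.0)
        ref = compute_feature_matrix(toy_fold, cfg)
        rng = np.random.default_rng(3)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        shift = np.array([7.0, -13.0, 5.0])
        for r in toy_fold.residues:
            r.ca_xyz = q @ r.ca_xyz + shift
            for a in r.atoms:
                a.xyz = q @ a.xyz + shift
        rot = compute_feature_matrix(toy_fold, cfg)
        for f in TERTIARY_FEATURES:
            if f == "RSA":  # lattice-direction sensitivity of sphere points
                np.testing.assert_allclose(
                    rot.data[f], ref.data[f], rtol=0.05, atol=1.0
                )
            elif f == "depth":
                np.testing.assert_allclose(
                    rot.data[f], ref.data[f], atol=0.3
                )
            else:
                np.testing.assert_allclose(
                    rot.data[f], ref.data[f], rtol=1e-6, atol=1e-8,
                    err_msg=f,
                )

    def test_radial_displacement_monotonicity(self):
        rng = np.random.default_rng(23)
        st = random_ca_structure(rng, n=20, scale=6.0)
        core = CoreSet(kind="B", members=set(range(2, 10)))
        i = 0
        ca = st.ca_coords()
        center = ca[sorted(j - 1 for j in core.members)].mean(axis=0)
        direction = ca[i] - center
        direction /= np.linalg.norm(direction)
        f_vals, d_vals, w_vals = [], [], []
        for step in (0.0, 3.0, 6.0, 12.0):
            coords = ca.copy()
            coords[i] = ca[i] + step * direction
            st2 = ca_only_structure(coords)
            f_vals.append(farness(st2, core)[i])
            d_vals.append(mean_core_distance(st2, core)[i])
            w_vals.append(weighted_contact_number(st2)[i])
        assert np.all(np.diff(f_vals) > 0)
        assert np.all(np.diff(d_vals) > 0)
        assert np.all(np.diff(w_vals) < 0)

    def test_kirchhoff_row_sums_zero(self, toy_fold):
        gamma = kirchhoff_matrix(toy_fold, 10.0)
        np.testing.assert_allclose(gamma.sum(axis=1), 0.0, atol=1e-12)

    def test_gnm_symmetric_three_bead_chain(self):
        st = ca_only_structure([[0, 0, 0], [6, 0, 0], [12, 0, 0]])
        f = gnm_fluctuation(st, DescriptorConfig(gnm_cutoff=7.0))
        assert f[0] == pytest.approx(f[2], rel=1e-9)
        assert f[0] > f[1]
        assert np.all(f >= 0)

    def test_gnm_disconnected_error(self):
        st = ca_only_structure([[0, 0, 0], [4, 0, 0], [100, 0, 0]])
        with pytest.raises(ValueError, match="cutoff"):
            gnm_fluctuation(st)


class TestFeatureMatrix:
    def test_toy_fold_matrix_complete(self, toy_fold):
        cfg = DescriptorConfig(buried_rsa_threshold=35.0)
        fm = compute_feature_matrix(toy_fold, cfg)
        assert fm.data.shape == (50, 2 + len(TERTIARY_FEATURES))
        assert not fm.data[fm.feature_names].isna().any().any()
        assert fm.feature_names == TERTIARY_FEATURES

    def test_recomputation_bit_identical(self, toy_fold):
        cfg = DescriptorConfig(buried_rsa_threshold=35.0)
        a = compute_feature_matrix(toy_fold, cfg)
        b = compute_feature_matrix(toy_fold, cfg)
        assert a.data.equals(b.data)

    def test_propensity_columns_appended_when_tables_given(self, toy_fold):
        cfg = DescriptorConfig(buried_rsa_threshold=35.0)
        tables = {
            "R_aa": {aa: 0.1 for aa in "ACDEFGHIKLMNPQRSTVWY"},
            "R_sse": {s: 0.2 for s in "HGIEBTS-"},
        }
        fm = compute_feature_matrix(toy_fold, cfg, score_tables=tables)
        assert "R_aa" in fm.feature_names and "R_sse" in fm.feature_names
        np.testing.assert_allclose(fm.data["R_aa"], 0.1)
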