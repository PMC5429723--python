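"""Unit cell reading, supercell replication, Wulff shape and carving."""

import itertools

import numpy as np
import pytest

from wulffgraft.crystal import (MillerFacet, UnitCell, carve, read_cif,
                                replicate, wulff_shape)
from wulffgraft.errors import FormatError, GeometryError

A_MAG = 8.3958  # angstrom, cubic lattice constant of the magnetite fixture


# ----------------------------------------------------------------- CIF

def test_magnetite_full_cell_composition(cell):
    """Symmetry expansion of the spinel Wyckoff sites (8a + 16d Fe, 32e O)
    must give 24 Fe + 32 O, the Fe3O4 stoichiometry at Z = 8."""
    assert cell.n_sites == 56
    comp = cell.composition()
    assert comp == {"Fe": 24, "O": 32}
    assert comp["Fe"] * 4 == comp["O"] * 3  # Fe:O = 3:4


def test_magnetite_cell_is_cubic(cell):
    assert cell.a == cell.b == cell.c == pytest.approx(A_MAG)
    assert (cell.alpha, cell.beta, cell.gamma) == (90.0, 90.0, 90.0)


def test_minimal_p1_cif(tmp_path):
    p = tmp_path / "p1.cif"
    p.write_text(
        "data_x\n_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n"
        "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
        "_symmetry_space_group_name_H-M 'P 1'\n"
        "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
        "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
        "C1 C 0 0 0\n")
    c = read_cif(p)
    assert c.n_sites == 1


def test_missing_cell_lengths_is_format_error(tmp_path):
    p = tmp_path / "bad.cif"
    p.write_text(
        "data_x\nloop_\n_atom_site_label\n_atom_site_type_symbol\n"
        "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
        "C1 C 0 0 0\n")
    with pytest.raises(FormatError, match="cell"):
        read_cif(p)


def test_missing_symmetry_requires_explicit_fallback(tmp_path):
    p = tmp_path / "nosym.cif"
    p.write_text(
        "data_x\n_cell_length_a 5\n_cell_length_b 5\n_cell_length_c 5\n"
        "_cell_angle_alpha 90\n_cell_angle_beta 90\n_cell_angle_gamma 90\n"
        "loop_\n_atom_site_label\n_atom_site_type_symbol\n"
        "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
        "C1 C 0 0 0\n")
    with pytest.raises(FormatError, match="symmetry"):
        read_cif(p)
    assert read_cif(p, allow_p1_fallback=True).n_sites == 1


# ----------------------------------------------------------- replicate

def test_replicate_counts_and_box(cell):
    sc = replicate(cell, 3, 3, 3)
    assert sc.n_atoms == 56 * 27 == 1512
    assert sc.box == pytest.approx([3 * A_MAG] * 3)
    assert sc.box[0] == pytest.approx(25.1874)


def test_replicate_identity(cell):
    one = replicate(cell, 1, 1, 1)
    assert one.n_atoms == cell.n_sites
    expected = np.array([cell.frac_to_cart @ f for _, f, _ in cell.sites])
    np.testing.assert_allclose(np.sort(one.positions, axis=0),
                               np.sort(expected, axis=0), atol=1e-9)


def test_replicate_rejects_nonpositive(cell):
    with pytest.raises(ValueError):
        replicate(cell, 0, 1, 1)


# ----------------------------------------------------------- Wulff

def test_cube_shape_analytic(cell):
    s = wulff_shape([MillerFacet((1, 0, 0), 1.0)], cell, 30.0)
    assert len(s.boundary_faces()) == 6
    assert s.volume() == pytest.approx(27000.0)
    assert s.surface_area() == pytest.approx(5400.0)


def test_octahedron_shape_analytic(cell):
    s = wulff_shape([MillerFacet((1, 1, 1), 1.0)], cell, 30.0)
    assert len(s.boundary_faces()) == 8
    assert len(s.vertices()) == 6
    # regular octahedron with inradius 15: edge a = r*sqrt(6), A = 2*sqrt(3)*a^2
    a = 15.0 * np.sqrt(6.0)
    assert s.surface_area() == pytest.approx(2 * np.sqrt(3) * a * a, rel=1e-9)


def brute_force_vertices(normals, dists, tol=1e-9):
    """Independent oracle: intersect all plane triples, keep feasible
    points, deduplicate."""
    pts = []
    for i, j, k in itertools.combinations(range(len(normals)), 3):
        m = np.array([normals[i], normals[j], normals[k]])
        if abs(np.linalg.det(m)) < 1e-10:
            continue
        v = np.linalg.solve(m, [dists[i], dists[j], dists[k]])
        if np.all(normals @ v <= dists + 1e-7):
            if not any(np.linalg.norm(v - w) < 1e-6 for w in pts):
                pts.append(v)
    return np.array(pts)


@pytest.mark.parametrize("facets", [
    [((1, 0, 0), 1.0)],
    [((1, 1, 1), 1.0)],
    [((1, 0, 0), 1.0), ((1, 1, 1), 1.15)],
    [((1, 0, 0), 1.0), ((1, 1, 1), 0.9)],
    [((1, 0, 0), 1.0), ((1, 1, 0), 1.05)],
])
def test_wulff_vertices_match_plane_triple_oracle(cell, facets):
    s = wulff_shape([MillerFacet(h, g) for h, g in facets], cell, 20.0)
    expected = brute_force_vertices(s.normals, s.distances)
    got = s.vertices()
    assert len(got) == len(expected)
    # match as sets within 1e-6
    for v in got:
        assert np.min(np.linalg.norm(expected - v, axis=1)) < 1e-6


def test_redundant_facet_contributes_no_face(cell):
    # a very high-energy {110} family is swallowed by the {100}+{111} envelope
    s = wulff_shape([MillerFacet((1, 0, 0), 1.0), MillerFacet((1, 1, 1), 1.15),
                     MillerFacet((1, 1, 0), 5.0)], cell, 30.0)
    faces = s.boundary_faces()
    assert len(s.normals) > 14          # redundant planes kept in the input
    assert len(faces) == 14             # but contribute no boundary face


def test_unbounded_facet_set_raises(cell):
    with pytest.raises(GeometryError, match="unbounded"):
        wulff_shape([MillerFacet((1, 0, 0), 1.0, expand_family=False)],
                    cell, 30.0)


def test_family_expansion_counts(cell):
    assert len(cell.expand_family((1, 0, 0))) == 6
    assert len(cell.expand_family((1, 1, 1))) == 8
    assert len(cell.expand_family((1, 1, 0))) == 12


# ----------------------------------------------------------- carve

def naive_carve_ids(bulk, shape, center):
    """Per-atom inequality filter, plain python."""
    ids = []
    for aid, pos in zip(bulk.ids, bulk.positions):
        r = pos - center
        if all(float(n @ r) <= d for n, d in zip(shape.normals,
                                                 shape.distances)):
            ids.append(int(aid))
    return set(ids)


def test_carve_equals_bruteforce_filter(cell, default_shape):
    bulk = replicate(cell, 5, 5, 5)
    center = np.asarray(bulk.box) / 2.0
    carved = carve(bulk, default_shape, center)
    assert set(carved.ids.tolist()) == naive_carve_ids(bulk, default_shape,
                                                       center)


def test_carved_atoms_satisfy_all_halfspaces(default_core, default_shape):
    slack = default_core.positions @ default_shape.normals.T \
        - default_shape.distances
    assert slack.max() <= 1e-6


def test_carve_degenerate_scale(cell, default_shape):
    bulk = replicate(cell, 4, 4, 4)
    center = np.asarray(bulk.box) / 2.0
    tiny = default_shape.scaled(1e-9)
    assert carve(bulk, tiny, center).n_atoms <= 1


def test_carve_count_monotone_in_diameter(cell):
    bulk = replicate(cell, 5, 5, 5)
    center = np.asarray(bulk.box) / 2.0
    counts = []
    for d in (8.0, 14.0, 20.0, 26.0, 32.0):
        s = wulff_shape([MillerFacet((1, 0, 0), 1.0),
                         MillerFacet((1, 1, 1), 1.15)], cell, d)
        counts.append(carve(bulk, s, center).n_atoms)
    assert all(a <= b for a, b in zip(counts, counts[1:]))


def test_cube_carve_bounding_box_matches_diameter(cell):
    """{100}-only carve: per-axis extent within one atomic-plane spacing
    (a/8 for the spinel lattice) of the target diameter."""
    bulk = replicate(cell, 5, 5, 5)
    s = wulff_shape([MillerFacet((1, 0, 0), 1.0)], cell, 30.0)
    carved = carve(bulk, s, np.asarray(bulk.box) / 2.0)
    spacing = cell.a / 8.0
    for ax in range(3):
        ext = carved.positions[:, ax].max() - carved.positions[:, ax].min()
        assert 30.0 - ext <= spacing + 1e-9


def test_carve_beyond_bulk_raises(cell, default_shape):
    bulk = replicate(cell, 2, 2, 2)
    with pytest.raises(GeometryError, match="replication"):
        carve(bulk, default_shape, np.asarray(bulk.box) / 2.0)


def test_unitcell_invariants_enforced():
    with pytest.raises(ValueError):
        UnitCell(a=-1, b=5, c=5, alpha=90, beta=90, gamma=90, sites=[])
    with pytest.raises(ValueError):
        UnitCell(a=5, b=5, c=5, alpha=190, beta=90, gamma=90, sites=[])
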