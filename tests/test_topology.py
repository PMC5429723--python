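"""Bond/angle/dihedral enumeration, charge assignment, file round-trips."""

import itertools
import random

import numpy as np
import pytest

from wulffgraft.errors import TopologyError
from wulffgraft.structure import AtomisticStructure
from wulffgraft.topology import (DEFAULT_SCHEME, assign_charges,
                                 enumerate_topology, read_topology_file,
                                 write_system)


def _structure(n, bonds):
    return AtomisticStructure(
        elements=["C"] * n,
        positions=np.random.default_rng(0).normal(size=(n, 3)) * 5,
        bonds=bonds)


def oracle_paths(n, bonds):
    """Exhaustive path enumeration: all simple paths of length 2 and 3,
    deduplicated by canonical orientation."""
    adj = {i: set() for i in range(n)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    angles = set()
    dihedrals = set()
    for a in range(n):
        for b in adj[a]:
            for c in adj[b] - {a}:
                angles.add((a, b, c) if a < c else (c, b, a))
                for d in adj[c] - {a, b}:
                    q = (a, b, c, d)
                    dihedrals.add(min(q, (d, c, b, a)))
    return angles, dihedrals


def test_bent_three_atom_molecule():
    topo = enumerate_topology(_structure(3, [(0, 1), (1, 2)]))
    assert topo.counts() == (2, 1, 0)
    assert topo.angles == [(0, 1, 2)]


def test_linear_four_atom_chain():
    topo = enumerate_topology(_structure(4, [(0, 1), (1, 2), (2, 3)]))
    assert topo.counts() == (3, 2, 1)
    assert topo.dihedrals == [(0, 1, 2, 3)]


def test_triangle_ring_deduplication():
    # 3-ring: each central bond traversed in both directions must not
    # produce duplicate dihedrals; a triangle has none with 4 distinct atoms
    topo = enumerate_topology(_structure(3, [(0, 1), (1, 2), (2, 0)]))
    assert topo.counts() == (3, 3, 0)


def test_square_ring():
    topo = enumerate_topology(_structure(4, [(0, 1), (1, 2), (2, 3), (3, 0)]))
    a, d = oracle_paths(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
    assert set(topo.angles) == a
    assert set(topo.dihedrals) == d


@pytest.mark.parametrize("seed", range(12))
def test_random_graphs_match_path_enumeration_oracle(seed):
    rng = random.Random(seed)
    n = rng.randint(4, 30)
    possible = list(itertools.combinations(range(n), 2))
    bonds = rng.sample(possible, min(len(possible), rng.randint(n - 1, 2 * n)))
    topo = enumerate_topology(_structure(n, bonds))
    a, d = oracle_paths(n, bonds)
    assert set(topo.angles) == a
    assert set(topo.dihedrals) == d
    # angle count identity: sum over vertices of C(deg, 2)
    deg = np.zeros(n, int)
    for x, y in bonds:
        deg[x] += 1
        deg[y] += 1
    assert len(topo.angles) == int(sum(k * (k - 1) // 2 for k in deg))


def test_shuffled_bond_list_gives_identical_topology():
    rng = random.Random(3)
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0), (1, 4)]
    st = _structure(5, bonds)
    ref = enumerate_topology(st)
    shuffled = [tuple(reversed(b)) if rng.random() < 0.5 else b
                for b in bonds]
    rng.shuffle(shuffled)
    got = enumerate_topology(st, shuffled)
    assert got.bonds == ref.bonds
    assert got.angles == ref.angles
    assert got.dihedrals == ref.dihedrals


def test_self_bond_and_dangling_id_raise():
    with pytest.raises(TopologyError, match="self-bond"):
        enumerate_topology(_structure(3, [(0, 0)]))
    with pytest.raises(TopologyError, match="unknown"):
        enumerate_topology(_structure(3, [(0, 7)]))


# ------------------------------------------------------------- charges

def test_neutral_galactose_template_charge():
    from wulffgraft.fixtures import monomer_template

    assert monomer_template("GAL").charge_sum() == pytest.approx(0.0,
                                                                 abs=1e-10)


def test_chain_with_ionized_glucuronate_net_charge():
    from wulffgraft.glycan import build_chain

    ch = build_chain(2.0, n_repeats=1)
    st = ch.structure
    topo = assign_charges(st, enumerate_topology(st), DEFAULT_SCHEME)
    # one ionized glucuronate (-1) plus the deprotonated root oxygen (-1)
    assert topo.net_charge == pytest.approx(-2.0, abs=1e-6)


def test_default_build_net_charge_is_sum_of_parts(default_build):
    """Summation oracle: net charge = core scheme charge + 64 x per-chain
    formal charge."""
    mag_ara = default_build["artifacts"]["mag_ara"]
    chain = default_build["artifacts"]["chain"]
    topo = assign_charges(mag_ara, enumerate_topology(mag_ara, []),
                          DEFAULT_SCHEME)
    comp = default_build["stages"]["core"]["composition"]
    core_q = comp["Fe"] * 1.2 + comp["O"] * -0.9
    chain_q = chain.structure.charges.sum()
    assert topo.net_charge == pytest.approx(core_q + 64 * chain_q, abs=1e-4)


def test_unmapped_atom_type_is_listed():
    st = AtomisticStructure(elements=["Xx"], positions=[[0, 0, 0]],
                            resnames=["UNK"])
    with pytest.raises(TopologyError, match="Xx"):
        assign_charges(st, enumerate_topology(st, []), DEFAULT_SCHEME)


def test_net_charge_invariant_under_reordering():
    from wulffgraft.glycan import build_chain

    st = build_chain(2.0, n_repeats=1).structure
    perm = np.random.default_rng(1).permutation(st.n_atoms)
    shuffled = st.select(perm)
    t1 = assign_charges(st, enumerate_topology(st, []), DEFAULT_SCHEME)
    t2 = assign_charges(shuffled, enumerate_topology(shuffled, []),
                        DEFAULT_SCHEME)
    assert t1.net_charge == pytest.approx(t2.net_charge, abs=1e-10)


# ------------------------------------------------------------- files

def test_write_system_round_trip(tmp_path):
    from wulffgraft.glycan import build_chain

    st = build_chain(2.0, n_repeats=1).structure
    topo = assign_charges(st, enumerate_topology(st), DEFAULT_SCHEME)
    paths = write_system(st, topo, tmp_path / "chain")
    back = read_topology_file(paths["top"])
    assert back.counts() == topo.counts()
    assert set(back.bonds) == set(topo.bonds)
    for aid, q in topo.charges.items():
        assert back.charges[aid] == pytest.approx(q, abs=1e-4)


def test_gro_round_trip_format_precision(tmp_path):
    from wulffgraft.structure import read_structure, write_structure

    st = _structure(10, [])
    write_structure(st, tmp_path / "x.gro")
    back = read_structure(tmp_path / "x.gro")
    # GRO stores nm to 3 decimals -> 0.001 nm = 0.01 angstrom
    np.testing.assert_allclose(back.positions, st.positions, atol=1e-2)


def test_pdb_round_trip(tmp_path):
    from wulffgraft.structure import read_structure, write_structure

    st = _structure(10, [])
    write_structure(st, tmp_path / "x.pdb")
    back = read_structure(tmp_path / "x.pdb")
    np.testing.assert_allclose(back.positions, st.positions, atol=1e-3)


def test_empty_structure_writes_valid_sections(tmp_path):
    st = AtomisticStructure(elements=[], positions=np.zeros((0, 3)))
    topo = enumerate_topology(st, [])
    paths = write_system(st, topo, tmp_path / "empty")
    back = read_topology_file(paths["top"])
    assert back.counts() == (0, 0, 0)
    assert paths["gro"].exists() and paths["pdb"].exists()


def test_mismatched_topology_structure_raises(tmp_path):
    st = _structure(3, [(0, 1)])
    topo = enumerate_topology(st)
    topo.charges = {99: 0.0}
    with pytest.raises(TopologyError, match="cover"):
        write_system(st, topo, tmp_path / "bad")
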