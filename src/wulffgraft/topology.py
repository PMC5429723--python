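"""Topology stage: bonds/angles/dihedrals enumeration, charges, MD files.

Given a structure and its bond list, the bonded topology follows purely
from the graph: angles are all simple paths of length two (central atom in
the middle), proper dihedrals all simple paths of length three with four
distinct atoms.  Both are stored in a canonical orientation — the
lexicographically smaller endpoint first — so re-enumeration of a shuffled
bond list reproduces an identical set.  Improper dihedrals are out of
scope.

Charges come from a scheme: template-carried values for ligand atoms and
per-type parameters for the magnetite core, water and lipids.  The shipped
magnetite values are simplified placeholders (bulk-neutral Fe +1.2 / O
−0.9); water uses TIP3P charges.

``write_system`` emits a PDB, a GRO and a GROMACS-flavoured plain-text
topology with [atoms]/[bonds]/[angles]/[dihedrals] sections; the column
layout is documented in docs/file_formats.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import TopologyError
from .structure import AtomisticStructure, write_structure

__all__ = [
    "TopologySet",
    "ChargeScheme",
    "DEFAULT_SCHEME",
    "enumerate_topology",
    "assign_charges",
    "write_system",
    "read_topology_file",
]


@dataclass
class TopologySet:
    """Enumerated bonded topology plus per-atom charges and type labels."""

    bonds: list                   # sorted (i, j) atom-id pairs, i < j
    angles: list                  # (i, j, k), j central, i < k
    dihedrals: list               # (a, b, c, d), (a,b,c,d) <= (d,c,b,a)
    charges: dict = field(default_factory=dict)   # atom id -> e
    type_labels: dict = field(default_factory=dict)

    @property
    def net_charge(self) -> float:
        return float(sum(self.charges.values()))

    def counts(self) -> tuple:
        return len(self.bonds), len(self.angles), len(self.dihedrals)


def enumerate_topology(structure: AtomisticStructure,
                       bonds=None) -> TopologySet:
    """Enumerate angles and dihedrals from the bond graph.

    Raises :class:`TopologyError` on self-bonds or bonds referencing
    unknown atom ids.
    """
    if bonds is None:
        bonds = structure.bonds
    ids = set(int(i) for i in structure.ids)
    adj: dict = {}
    canon_bonds = set()
    for a, b in bonds:
        a, b = int(a), int(b)
        if a == b:
            raise TopologyError(f"self-bond on atom {a}")
        if a not in ids or b not in ids:
            raise TopologyError(f"bond ({a},{b}) references unknown atom id")
        canon_bonds.add((min(a, b), max(a, b)))
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    angles = set()
    for j, nbrs in adj.items():
        ns = sorted(nbrs)
        for x in range(len(ns)):
            for y in range(x + 1, len(ns)):
                angles.add((ns[x], j, ns[y]))

    dihedrals = set()
    for b, c in canon_bonds:
        for a in adj[b] - {c}:
            for d in adj[c] - {b, a}:
                quad = (a, b, c, d)
                rev = (d, c, b, a)
                dihedrals.add(min(quad, rev))

    return TopologySet(
        bonds=sorted(canon_bonds),
        angles=sorted(angles),
        dihedrals=sorted(dihedrals),
    )


@dataclass
class ChargeScheme:
    """Per-type charge lookup.  Atoms whose type label is in
    ``template_types`` take the charge carried on the structure itself
    (monomer templates embed their own charges); everything else must
    resolve through ``by_type`` keyed on the atom's type label, or
    ``by_element_resname`` keyed on (element, resname)."""

    name: str
    by_type: dict = field(default_factory=dict)
    by_element_resname: dict = field(default_factory=dict)
    template_types: tuple = ("LIG",)


#: Simplified default scheme.  Magnetite values are placeholders scaled to
#: a bulk-neutral 3:4 lattice; water is TIP3P; DPPC is zwitterionic with
#: template-carried head charges.
DEFAULT_SCHEME = ChargeScheme(
    name="default",
    by_element_resname={
        ("Fe", "MAG"): 1.2,
        ("O", "MAG"): -0.9,
        ("O", "SOL"): -0.834,
        ("H", "SOL"): 0.417,
    },
    template_types=("LIG", "LIPID"),
)


def assign_charges(structure: AtomisticStructure, topology: TopologySet,
                   scheme: ChargeScheme = DEFAULT_SCHEME) -> TopologySet:
    """Fill per-atom charges from the scheme; unmapped atoms raise with an
    explicit listing."""
    charges = {}
    labels = {}
    unmapped = []
    for i in range(structure.n_atoms):
        aid = int(structure.ids[i])
        t = structure.types[i]
        if t in scheme.template_types:
            charges[aid] = float(structure.charges[i])
            labels[aid] = t
            continue
        if t in scheme.by_type:
            charges[aid] = scheme.by_type[t]
            labels[aid] = t
            continue
        key = (structure.elements[i], structure.resnames[i])
        if key in scheme.by_element_resname:
            charges[aid] = scheme.by_element_resname[key]
            labels[aid] = f"{key[0]}_{key[1]}"
            continue
        unmapped.append((aid, structure.elements[i], structure.resnames[i]))
    if unmapped:
        head = ", ".join(f"id {a} ({el} in {rn})" for a, el, rn in unmapped[:8])
        raise TopologyError(
            f"{len(unmapped)} atoms have no charge mapping in scheme "
            f"'{scheme.name}': {head}"
        )
    topology.charges = charges
    topology.type_labels = labels
    return topology


# ----------------------------------------------------------------------
# writers


def write_system(structure: AtomisticStructure, topology: TopologySet,
                 prefix) -> dict:
    """Write ``<prefix>.pdb``, ``<prefix>.gro`` and ``<prefix>.top``.

    The .top dialect has [atoms] (id, type, resid, resname, name, charge),
    [bonds], [angles] and [dihedrals] sections with whitespace-separated
    integer atom ids.
    """
    if topology.charges and set(topology.charges) != set(
            int(i) for i in structure.ids):
        raise TopologyError("topology charges do not cover the structure")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "pdb": prefix.with_suffix(".pdb"),
        "gro": prefix.with_suffix(".gro"),
        "top": prefix.with_suffix(".top"),
    }
    if structure.n_atoms:
        write_structure(structure, paths["pdb"])
        write_structure(structure, paths["gro"])
    else:  # valid empty coordinate files
        paths["pdb"].write_text("END\n")
        paths["gro"].write_text("empty system\n    0\n"
                                "   0.00000   0.00000   0.00000\n")

    with open(paths["top"], "w") as fh:
        fh.write("; wulffgraft topology\n[ atoms ]\n")
        fh.write("; id type resid resname name charge\n")
        for i in range(structure.n_atoms):
            aid = int(structure.ids[i])
            q = topology.charges.get(aid, 0.0)
            t = topology.type_labels.get(aid, structure.types[i] or
                                         structure.elements[i])
            fh.write(f"{aid:>8d} {t:>10s} {int(structure.resids[i]):>7d} "
                     f"{structure.resnames[i]:>6s} {structure.names[i]:>6s} "
                     f"{q:>10.4f}\n")
        fh.write("\n[ bonds ]\n")
        for a, b in topology.bonds:
            fh.write(f"{a:>8d} {b:>8d}\n")
        fh.write("\n[ angles ]\n")
        for a, b, c in topology.angles:
            fh.write(f"{a:>8d} {b:>8d} {c:>8d}\n")
        fh.write("\n[ dihedrals ]\n")
        for a, b, c, d in topology.dihedrals:
            fh.write(f"{a:>8d} {b:>8d} {c:>8d} {d:>8d}\n")
    return paths


def read_topology_file(path) -> TopologySet:
    """Re-read a ``.top`` written by :func:`write_system`."""
    section = None
    bonds, angles, dihedrals = [], [], []
    charges, labels = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("["):
                section = line.strip("[] ").lower()
                continue
            parts = line.split()
            if section == "atoms":
                aid = int(parts[0])
                labels[aid] = parts[1]
                charges[aid] = float(parts[5])
            elif section == "bonds":
                bonds.append((int(parts[0]), int(parts[1])))
            elif section == "angles":
                angles.append(tuple(int(x) for x in parts[:3]))
            elif section == "dihedrals":
                dihedrals.append(tuple(int(x) for x in parts[:4]))
    return TopologySet(bonds=bonds, angles=angles, dihedrals=dihedrals,
                       charges=charges, type_labels=labels)


def magnetite_bond_network(structure: AtomisticStructure,
                           cutoff: float = 2.35) -> list:
    """Fe–O bonds within the cutoff, for treating the carved core as a
    bonded network (a frozen/restrained core alternative simply skips
    this and leaves the core bond-free)."""
    from scipy.spatial import cKDTree

    fe = np.flatnonzero(structure.elements == "Fe")
    ox = np.flatnonzero(structure.elements == "O")
    if not len(fe) or not len(ox):
        return []
    tree = cKDTree(structure.positions[ox])
    bonds = []
    for i in fe:
        for j in tree.query_ball_point(structure.positions[i], cutoff):
            bonds.append((int(structure.ids[i]), int(structure.ids[ox[j]])))
    return bonds
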