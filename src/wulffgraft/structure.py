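"""Atomistic structure container and coordinate-file round-tripping.

The package passes a single flat container between build stages: element
symbols, atom names, Cartesian coordinates in angstrom, residue ids/names,
stable integer atom ids and an optional orthorhombic box.  Bonds are stored
as unordered pairs of *atom ids* (not array indices) so they survive
carving, merging and reordering.

Coordinate output goes through MDAnalysis writers (PDB in angstrom, GRO in
nm, both fixed-column).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AtomisticStructure", "read_structure", "write_structure"]


@dataclass
class AtomisticStructure:
    """A flat collection of atoms with stable ids.

    Parameters
    ----------
    elements : array of str
        Element symbols ("Fe", "O", "C", ...).
    positions : (n, 3) float array
        Cartesian coordinates in angstrom.
    ids : array of int
        Unique atom ids.  Preserved by carving and selection.
    resids : array of int
        Molecule/residue id per atom.
    resnames : array of str
        Residue name per atom ("MAG", "GAL", "DPPC", "SOL", ...).
    names : array of str
        Atom names; default to element symbols.
    box : (3,) float array or None
        Orthorhombic box lengths in angstrom.
    bonds : list of (id, id)
        Unordered bonded pairs, referencing atom ids.
    """

    elements: np.ndarray
    positions: np.ndarray
    ids: np.ndarray = None
    resids: np.ndarray = None
    resnames: np.ndarray = None
    names: np.ndarray = None
    box: np.ndarray | None = None
    bonds: list = field(default_factory=list)
    charges: np.ndarray = None
    types: np.ndarray = None

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if self.positions.shape[0] != n:
            raise ValueError("elements and positions length mismatch")
        if self.ids is None:
            self.ids = np.arange(n, dtype=int)
        self.ids = np.asarray(self.ids, dtype=int)
        if len(np.unique(self.ids)) != n:
            raise ValueError("atom ids must be unique")
        if self.resids is None:
            self.resids = np.zeros(n, dtype=int)
        self.resids = np.asarray(self.resids, dtype=int)
        if self.resnames is None:
            self.resnames = np.array(["UNK"] * n, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        if self.names is None:
            self.names = self.elements.copy()
        self.names = np.asarray(self.names, dtype=object)
        if self.charges is None:
            self.charges = np.zeros(n, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.types is None:
            self.types = np.array([""] * n, dtype=object)
        self.types = np.asarray(self.types, dtype=object)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.ids)

    def composition(self) -> Counter:
        """Element -> count."""
        return Counter(self.elements.tolist())

    def index_of(self, atom_ids) -> np.ndarray:
        """Array indices of the given atom ids (vectorised lookup)."""
        order = np.argsort(self.ids)
        pos = np.searchsorted(self.ids, atom_ids, sorter=order)
        idx = order[pos]
        if not np.array_equal(self.ids[idx], np.asarray(atom_ids)):
            raise KeyError("unknown atom id")
        return idx

    def select(self, mask) -> "AtomisticStructure":
        """Sub-structure of the atoms where ``mask`` is true; ids kept."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        keep = set(self.ids[idx].tolist())
        bonds = [(a, b) for a, b in self.bonds if a in keep and b in keep]
        return AtomisticStructure(
            elements=self.elements[idx].copy(),
            positions=self.positions[idx].copy(),
            ids=self.ids[idx].copy(),
            resids=self.resids[idx].copy(),
            resnames=self.resnames[idx].copy(),
            names=self.names[idx].copy(),
            box=None if self.box is None else self.box.copy(),
            bonds=bonds,
            charges=self.charges[idx].copy(),
            types=self.types[idx].copy(),
        )

    def translated(self, shift) -> "AtomisticStructure":
        out = self.copy()
        out.positions = out.positions + np.asarray(shift, dtype=float)
        return out

    def copy(self) -> "AtomisticStructure":
        return AtomisticStructure(
            elements=self.elements.copy(),
            positions=self.positions.copy(),
            ids=self.ids.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            names=self.names.copy(),
            box=None if self.box is None else np.asarray(self.box, float).copy(),
            bonds=list(self.bonds),
            charges=self.charges.copy(),
            types=self.types.copy(),
        )

    def merged_with(self, other: "AtomisticStructure") -> "AtomisticStructure":
        """Concatenate two structures, renumbering the second where its atom
        or residue ids collide with this one."""
        other = other.copy()
        if len(np.intersect1d(self.ids, other.ids)):
            offset = int(self.ids.max()) + 1 - int(other.ids.min())
            remap = {int(i): int(i) + offset for i in other.ids}
            other.ids = other.ids + offset
            other.bonds = [(remap[a], remap[b]) for a, b in other.bonds]
        if len(np.intersect1d(self.resids, other.resids)):
            other.resids = other.resids + int(self.resids.max()) + 1 - int(other.resids.min())
        return AtomisticStructure(
            elements=np.concatenate([self.elements, other.elements]),
            positions=np.vstack([self.positions, other.positions]),
            ids=np.concatenate([self.ids, other.ids]),
            resids=np.concatenate([self.resids, other.resids]),
            resnames=np.concatenate([self.resnames, other.resnames]),
            names=np.concatenate([self.names, other.names]),
            box=None if self.box is None else self.box.copy(),
            bonds=list(self.bonds) + list(other.bonds),
            charges=np.concatenate([self.charges, other.charges]),
            types=np.concatenate([self.types, other.types]),
        )

    def min_interatomic_distance(self) -> float:
        """Smallest pairwise distance (angstrom), via a KD-tree."""
        from scipy.spatial import cKDTree

        if self.n_atoms < 2:
            return np.inf
        tree = cKDTree(self.positions)
        d, _ = tree.query(self.positions, k=2)
        return float(d[:, 1].min())


# ----------------------------------------------------------------------
# File I/O via MDAnalysis


def _to_universe(structure: AtomisticStructure):
    import MDAnalysis as mda

    n = structure.n_atoms
    resid_vals, resindex = np.unique(structure.resids, return_inverse=True)
    u = mda.Universe.empty(
        n, n_residues=len(resid_vals), atom_resindex=resindex, trajectory=True
    )
    u.add_TopologyAttr("names", structure.names.astype(str))
    u.add_TopologyAttr("elements", structure.elements.astype(str))
    u.add_TopologyAttr("resids", resid_vals.astype(int))
    first = np.zeros(len(resid_vals), dtype=int)
    seen = {}
    for i, r in enumerate(resindex):
        if r not in seen:
            seen[r] = i
    for r, i in seen.items():
        first[r] = i
    u.add_TopologyAttr("resnames", structure.resnames[first].astype(str))
    u.atoms.positions = structure.positions.astype(np.float32)
    if structure.box is not None:
        u.dimensions = [*np.asarray(structure.box, float), 90.0, 90.0, 90.0]
    return u


def write_structure(structure: AtomisticStructure, path) -> None:
    """Write PDB (angstrom) or GRO (nm) depending on the file suffix."""
    path = Path(path)
    u = _to_universe(structure)
    if path.suffix.lower() not in {".pdb", ".gro"}:
        raise ValueError(f"unsupported coordinate format: {path.suffix}")
    with warnings_silenced():
        u.atoms.write(str(path))


def read_structure(path) -> AtomisticStructure:
    """Read a PDB or GRO file back into an :class:`AtomisticStructure`."""
    import MDAnalysis as mda

    path = Path(path)
    with warnings_silenced():
        u = mda.Universe(str(path))
    n = len(u.atoms)
    try:
        elements = np.array([e.capitalize() for e in u.atoms.elements], dtype=object)
    except Exception:
        elements = np.array(
            [_guess_element(nm) for nm in u.atoms.names], dtype=object
        )
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        box = np.asarray(u.dimensions[:3], dtype=float)
    return AtomisticStructure(
        elements=elements,
        positions=u.atoms.positions.astype(float),
        ids=np.arange(n),
        resids=u.atoms.resids.astype(int),
        resnames=np.array(u.atoms.resnames, dtype=object),
        names=np.array(u.atoms.names, dtype=object),
        box=box,
    )


def _guess_element(name: str) -> str:
    name = name.strip()
    if name[:2].capitalize() in {"Fe", "Cl", "Na", "Mg"}:
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


class warnings_silenced:
    """MDAnalysis emits benign missing-attribute warnings when writing
    structures assembled from scratch; keep build logs readable."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        warnings.simplefilter("ignore")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)
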