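"""Surface stage: Fe coordination classes, surface detection, graft sites.

Grafting targets *surface octahedral Fe*.  In the spinel lattice interior,
octahedral Fe has six O neighbours and tetrahedral Fe has four; carving
necessarily strips neighbours from surface atoms, so an undercoordinated
surface Fe inherits the bulk class of its crystallographic site label
(e.g. a 16d atom with 4 remaining O neighbours still counts as octahedral
for grafting purposes).

Site selection uses deterministic farthest-point sampling: after a
seed-designated first site, each subsequent site maximizes its minimum
distance to those already chosen, giving a near-uniform spread at any
requested count or density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .crystal import WulffShape
from .errors import CapacityError
from .structure import AtomisticStructure

__all__ = [
    "SiteClassification",
    "GraftSpec",
    "classify_fe_sites",
    "detect_surface_atoms",
    "select_graft_sites",
]

#: Default Fe–O neighbour cutoff (angstrom): between the Fe–O bond length
#: (~1.9–2.1 Å) and the next coordination shell.
FE_O_CUTOFF = 2.35

OCTAHEDRAL, TETRAHEDRAL = "octahedral", "tetrahedral"
UNDER = "undercoordinated-surface"
OTHER = "other"


@dataclass
class SiteClassification:
    atom_id: int
    coordination: int
    site_class: str                 # octahedral / tetrahedral / under / other
    bulk_class: str | None = None   # interior analog for surface atoms
    normal: np.ndarray | None = None

    @property
    def grafting_class(self) -> str | None:
        """The class used for grafting eligibility: explicit for interior
        atoms, the site-label bulk class for undercoordinated surface Fe."""
        if self.site_class in (OCTAHEDRAL, TETRAHEDRAL):
            return self.site_class
        return self.bulk_class


def classify_fe_sites(structure: AtomisticStructure,
                      neighbor_cutoff: float = FE_O_CUTOFF) -> list:
    """Label every Fe atom by its O coordination number.

    6 O neighbours → octahedral; 4 → tetrahedral; fewer →
    undercoordinated-surface, with the bulk class recovered from atoms
    sharing the same crystallographic site label (when available).
    """
    fe_mask = structure.elements == "Fe"
    o_mask = structure.elements == "O"
    if not o_mask.any():
        raise ValueError("structure contains no O atoms to coordinate Fe")
    if not fe_mask.any():
        raise ValueError("structure contains no Fe atoms")

    o_tree = cKDTree(structure.positions[o_mask])
    fe_pos = structure.positions[fe_mask]
    counts = np.array([len(x) for x in
                       o_tree.query_ball_point(fe_pos, neighbor_cutoff)])

    # interior consensus class per site label, for surface back-reference
    label_class: dict = {}
    fe_names = structure.names[fe_mask]
    for name in np.unique(fe_names):
        sub = counts[fe_names == name]
        if (sub == 6).any():
            label_class[name] = OCTAHEDRAL
        elif (sub == 4).any():
            label_class[name] = TETRAHEDRAL

    out = []
    for atom_id, name, c in zip(structure.ids[fe_mask], fe_names, counts):
        if c == 6:
            cls, bulk = OCTAHEDRAL, OCTAHEDRAL
        elif c == 4:
            cls, bulk = TETRAHEDRAL, TETRAHEDRAL
        elif c < 4 or c == 5:
            cls, bulk = UNDER, label_class.get(name)
        else:
            cls, bulk = OTHER, label_class.get(name)
        out.append(SiteClassification(int(atom_id), int(c), cls, bulk))
    return out


def detect_surface_atoms(structure: AtomisticStructure, shape: WulffShape,
                         skin: float = 1.5) -> dict:
    """Atoms within ``skin`` (angstrom) of any boundary facet plane.

    Assumes the structure was carved with ``shape`` centred at the origin.
    Returns {atom id: outward unit normal}; an atom near several planes
    (edge/corner) gets the normalized average of their face normals.
    """
    faces = shape.boundary_faces()
    normals = shape.normals[faces]
    dists = shape.distances[faces]
    gap = dists - structure.positions @ normals.T     # (n_atoms, n_faces)
    near = gap <= skin + 1e-9
    out = {}
    for i in np.flatnonzero(near.any(axis=1)):
        close = np.flatnonzero(near[i])
        tie = close[np.abs(gap[i, close] - gap[i, close].min()) < 1e-6]
        n = normals[tie].mean(axis=0)
        n = n / np.linalg.norm(n)
        out[int(structure.ids[i])] = n
    return out


@dataclass
class GraftSpec:
    """Grafting request: a chain count N, or a target density σ (chains
    per nm²) converted through the Wulff polyhedron surface area."""

    n_chains: int | None = None
    density_per_nm2: float | None = None
    surface_area_nm2: float | None = None
    selected_ids: list = field(default_factory=list)

    def resolve_count(self) -> int:
        if self.n_chains is not None:
            if self.n_chains < 0:
                raise ValueError("chain count must be >= 0")
            return int(self.n_chains)
        if self.density_per_nm2 is None or self.surface_area_nm2 is None:
            raise ValueError("need n_chains, or density plus surface area")
        return int(round(self.density_per_nm2 * self.surface_area_nm2))

    @property
    def realized_density(self) -> float | None:
        if self.surface_area_nm2:
            return len(self.selected_ids) / self.surface_area_nm2
        return None


def select_graft_sites(structure: AtomisticStructure, classifications,
                       surface_normals: dict, spec: GraftSpec,
                       seed: int = 0) -> GraftSpec:
    """Pick grafting sites among surface octahedral Fe by deterministic
    farthest-point sampling.

    The seed chooses the first site by index ordering (seed mod number of
    candidates); every later choice is the candidate maximizing the
    minimum distance to already-selected sites, ties broken by atom id.
    """
    by_id = {c.atom_id: c for c in classifications}
    cand_ids = sorted(
        i for i in surface_normals
        if i in by_id and by_id[i].grafting_class == OCTAHEDRAL
    )
    n = spec.resolve_count()
    if n > len(cand_ids):
        raise CapacityError(
            f"requested {n} graft sites but only {len(cand_ids)} surface "
            f"octahedral Fe candidates are available"
        )
    if n == 0:
        spec.selected_ids = []
        return spec

    pos = structure.positions[structure.index_of(cand_ids)]
    first = seed % len(cand_ids)
    chosen = [first]
    mind = np.linalg.norm(pos - pos[first], axis=1)
    for _ in range(n - 1):
        mind[chosen] = -1.0
        best = int(np.argmax(mind))  # argmax returns the first (lowest id) tie
        chosen.append(best)
        mind = np.minimum(mind, np.linalg.norm(pos - pos[best], axis=1))
    spec.selected_ids = [cand_ids[i] for i in chosen]
    return spec
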