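"""Membrane stage: DPPC bilayer, solvation and NP–membrane assembly.

The bilayer is laid out on a tetragonal (near-square) grid: each leaflet
holds exactly N lipids at an area per lipid of 0.63 nm² (fluid-phase DPPC
convention), tails facing inward, with the bilayer normal on z.  Solvation
tiles a rigid three-site (TIP3P-geometry) water lattice at bulk density
into the box and removes waters overlapping the solute or sitting inside
the hydrophobic slab.  Assembly places the nanoparticle in the upper water
phase at a prescribed minimum distance from the upper-leaflet phosphate
plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import GeometryError
from .structure import AtomisticStructure

__all__ = [
    "BilayerSpec",
    "SimSystem",
    "build_bilayer",
    "solvate",
    "assemble_system",
]

WATER_DENSITY_PER_NM3 = 33.4   # bulk water number density
TIP3P_OH = 0.9572              # angstrom
TIP3P_ANGLE = 104.52           # degrees
EXCLUSION_RADIUS = 2.4         # angstrom, solute heavy atom to water O


@dataclass
class BilayerSpec:
    """Bilayer build parameters."""

    lipids_per_leaflet: int = 489
    area_per_lipid_nm2: float = 0.63
    leaflet_separation_nm: float = 3.8   # phosphate-plane to phosphate-plane
    template: str = "DPPC"

    def __post_init__(self):
        if self.lipids_per_leaflet < 1:
            raise ValueError("lipids per leaflet must be >= 1")

    @property
    def leaflet_area_nm2(self) -> float:
        return self.lipids_per_leaflet * self.area_per_lipid_nm2


def _lipid_arrays(tpl: dict):
    names = [a[0] for a in tpl["atoms"]]
    elements = [a[1] for a in tpl["atoms"]]
    pos = np.array([a[2] for a in tpl["atoms"]], dtype=float)
    charges = np.array([a[3] for a in tpl["atoms"]], dtype=float)
    name_idx = {n: i for i, n in enumerate(names)}
    bonds = [(name_idx[a], name_idx[b]) for a, b in tpl["bonds"]]
    return names, elements, pos, charges, bonds, name_idx


def build_bilayer(spec: BilayerSpec) -> AtomisticStructure:
    """Two leaflets of exactly N lipids each on a tetragonal grid.

    The grid has ⌈√N⌉ columns and as many rows as needed; lipids sit at
    grid-cell centres.  The upper leaflet keeps the template orientation
    (head up); the lower leaflet is flipped through 180° about x.  The box
    is sized so the leaflet area equals N × area-per-lipid exactly.
    """
    from . import fixtures

    tpl = fixtures.dppc_template()
    names, elements, pos0, charges, bonds0, name_idx = _lipid_arrays(tpl)
    p_idx = name_idx[tpl["groups"]["head_reference"]]
    n_per = len(names)

    N = spec.lipids_per_leaflet
    lx = np.sqrt(spec.leaflet_area_nm2) * 10.0  # angstrom, square patch
    ncols = int(np.ceil(np.sqrt(N)))
    nrows = int(np.ceil(N / ncols))
    dx, dy = lx / ncols, lx / nrows
    half_sep = spec.leaflet_separation_nm * 10.0 / 2.0

    up = pos0 - pos0[p_idx]                 # phosphate at the origin
    flip = Rotation.from_euler("x", 180, degrees=True).as_matrix()
    down = up @ flip.T

    elements_all, names_all, pos_all, q_all = [], [], [], []
    resids, resnames, types = [], [], []
    bonds = []
    resid = 0
    for leaflet, base, zoff in (("upper", up, +half_sep),
                                ("lower", down, -half_sep)):
        placed = 0
        for r in range(nrows):
            for c in range(ncols):
                if placed >= N:
                    break
                centre = np.array([(c + 0.5) * dx, (r + 0.5) * dy, zoff])
                xyz = base + centre
                off = len(elements_all)
                elements_all += elements
                names_all += names
                pos_all.append(xyz)
                q_all.append(charges)
                resids += [resid] * n_per
                resnames += ["DPPC"] * n_per
                types += ["LIPID"] * n_per
                bonds += [(a + off, b + off) for a, b in bonds0]
                resid += 1
                placed += 1
    st = AtomisticStructure(
        elements=np.array(elements_all, dtype=object),
        positions=np.vstack(pos_all),
        names=np.array(names_all, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        charges=np.concatenate(q_all),
        types=np.array(types, dtype=object),
        box=np.array([lx, lx, 2 * half_sep + 40.0]),
        bonds=bonds,
    )
    return st


def leaflet_of(bilayer: AtomisticStructure, n_per_leaflet: int) -> np.ndarray:
    """Per-atom leaflet label array ('upper'/'lower') by residue index."""
    return np.where(bilayer.resids < n_per_leaflet, "upper", "lower")


def _water_template():
    th = np.radians(TIP3P_ANGLE)
    o = np.zeros(3)
    h1 = np.array([TIP3P_OH, 0.0, 0.0])
    h2 = np.array([TIP3P_OH * np.cos(th), TIP3P_OH * np.sin(th), 0.0])
    return np.array([o, h1, h2])


def _lattice_counts(box, density):
    """Per-axis water counts whose product best matches density × volume."""
    a = (1.0 / density) ** (1.0 / 3.0)
    target = density * np.prod(box)
    best, best_err = None, np.inf
    opts = [(int(np.floor(L / a)) or 1, int(np.ceil(L / a))) for L in box]
    for i in opts[0]:
        for j in opts[1]:
            for k in opts[2]:
                err = abs(i * j * k - target)
                if err < best_err:
                    best, best_err = (i, j, k), err
    return best


def solvate(structure: AtomisticStructure | None, box,
            exclusion_radius: float = EXCLUSION_RADIUS,
            seed: int = 0) -> AtomisticStructure:
    """Fill ``box`` (angstrom) with rigid three-site waters at bulk
    density, dropping any water whose O sits within ``exclusion_radius``
    of a solute heavy atom.  Water orientations are drawn deterministically
    from ``seed``; geometry (O–H length, H–O–H angle) is identical for
    every water.
    """
    box = np.asarray(box, dtype=float)
    if structure is not None and structure.n_atoms:
        ext = structure.positions.max(axis=0) - structure.positions.min(axis=0)
        if np.any(ext > box + 1e-6):
            raise GeometryError("box smaller than the solute extent")

    density = WATER_DENSITY_PER_NM3 / 1000.0  # per angstrom^3
    ni, nj, nk = _lattice_counts(box, density)
    grid = np.stack(np.meshgrid(
        (np.arange(ni) + 0.5) * box[0] / ni,
        (np.arange(nj) + 0.5) * box[1] / nj,
        (np.arange(nk) + 0.5) * box[2] / nk,
        indexing="ij"), axis=-1).reshape(-1, 3)

    if structure is not None and structure.n_atoms:
        heavy = structure.positions[structure.elements != "H"]
        tree = cKDTree(heavy)
        keep = tree.query(grid)[0] >= exclusion_radius
        grid = grid[keep]

    rng = np.random.default_rng(seed)
    base = _water_template()
    n_w = len(grid)
    rots = Rotation.random(n_w, random_state=rng).as_matrix() if n_w else []
    pos = np.empty((3 * n_w, 3))
    for w in range(n_w):
        pos[3 * w:3 * w + 3] = base @ rots[w].T + grid[w]

    start_resid = 0 if structure is None else int(structure.resids.max()) + 1
    waters = AtomisticStructure(
        elements=np.array(["O", "H", "H"] * n_w, dtype=object),
        positions=pos,
        names=np.array(["OW", "HW1", "HW2"] * n_w, dtype=object),
        resids=np.repeat(np.arange(n_w) + start_resid, 3),
        resnames=np.array(["SOL"] * (3 * n_w), dtype=object),
        types=np.array(["OW", "HW", "HW"] * n_w, dtype=object),
        charges=np.array([-0.834, 0.417, 0.417] * n_w),
        box=box,
        bonds=[(3 * w + a, 3 * w + a + 1) for w in range(n_w) for a in (0, 1)],
    )
    return waters


@dataclass
class SimSystem:
    """Assembled NP + bilayer + water system with a component index."""

    structure: AtomisticStructure
    components: dict              # name -> array of atom ids
    box: np.ndarray
    np_gap: float                 # realized NP-to-phosphate-plane gap, angstrom

    @property
    def total_atoms(self) -> int:
        return self.structure.n_atoms

    def component_sizes(self) -> dict:
        return {k: len(v) for k, v in self.components.items()}


def assemble_system(nanoparticle: AtomisticStructure,
                    bilayer: AtomisticStructure, gap: float = 5.0,
                    padding: float = 10.0, solvate_system: bool = True,
                    seed: int = 0) -> SimSystem:
    """Place the NP in the water phase above the bilayer and solvate.

    ``gap`` is the minimum distance (angstrom) from any NP atom to the
    upper-leaflet phosphorus plane (mean z of upper P atoms).  The box
    keeps ``padding`` of solvent headroom above the NP and below the
    bilayer.
    """
    if bilayer.box is None:
        raise ValueError("bilayer must carry box dimensions")
    lx, ly = float(bilayer.box[0]), float(bilayer.box[1])

    np_ext = nanoparticle.positions.max(axis=0) - nanoparticle.positions.min(axis=0)
    if np_ext[0] > lx or np_ext[1] > ly:
        raise GeometryError(
            "nanoparticle lateral extent exceeds the bilayer patch; "
            "increase lipids per leaflet"
        )

    upper_resids = np.unique(bilayer.resids)[:len(np.unique(bilayer.resids)) // 2]
    p_mask = (bilayer.names == "P") & np.isin(bilayer.resids, upper_resids)
    p_plane = float(bilayer.positions[p_mask, 2].mean())

    npart = nanoparticle.copy()
    centre_xy = np.array([lx / 2, ly / 2])
    np_centre = npart.positions[:, :2].mean(axis=0)
    npart.positions[:, :2] += centre_xy - np_centre
    npart.positions[:, 2] += (p_plane + gap) - npart.positions[:, 2].min()

    solute = bilayer.merged_with(npart)
    np_ids = solute.ids[-npart.n_atoms:]
    lipid_ids = solute.ids[:bilayer.n_atoms]

    zlo = bilayer.positions[:, 2].min() - padding
    zhi = npart.positions[:, 2].max() + padding
    shift = np.array([0.0, 0.0, -zlo])
    solute.positions = solute.positions + shift
    box = np.array([lx, ly, zhi - zlo])
    solute.box = box

    components = {"np": np.asarray(np_ids), "lipid": np.asarray(lipid_ids)}
    if solvate_system:
        waters = solvate(solute, box, seed=seed)
        # drop waters inside the hydrophobic slab (between phosphate planes)
        p_all = solute.positions[solute.names == "P", 2]
        slab_lo, slab_hi = p_all.min() + 1.0, p_all.max() - 1.0
        wz = waters.positions[waters.names == "OW", 2]
        bad_res = np.unique(waters.resids[np.repeat(
            (wz > slab_lo) & (wz < slab_hi), 3)])
        waters = waters.select(~np.isin(waters.resids, bad_res))
        full = solute.merged_with(waters)
        components["water"] = full.ids[solute.n_atoms:]
        solute = full

    p_plane_final = p_plane + shift[2]
    np_z = solute.positions[solute.index_of(components["np"]), 2]
    realized_gap = float(np_z.min() - p_plane_final)
    return SimSystem(structure=solute, components=components, box=box,
                     np_gap=realized_gap)
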