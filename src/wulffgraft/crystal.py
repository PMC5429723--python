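"""Crystal stage: unit cell, supercell, Wulff morphology and core carving.

The nanoparticle core is built in four steps:

1. :func:`read_cif` reads a crystallographic unit cell and expands its
   space-group symmetry to the full conventional cell (gemmi does the
   symmetry algebra).
2. :func:`replicate` tiles the cell into a Cartesian bulk supercell.
3. :func:`wulff_shape` derives the equilibrium crystal polyhedron: every
   facet family {hkl} contributes half-spaces whose distance from the
   origin is proportional to the facet's relative surface energy
   (the Wulff condition d_hkl ∝ γ_hkl).  The shape is scaled so that the
   face-to-face extent along the lowest-γ facet normal equals the target
   diameter.
4. :func:`carve` keeps exactly the bulk atoms inside every half-space.

All coordinates are Cartesian angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .errors import FormatError, GeometryError
from .structure import AtomisticStructure

__all__ = [
    "UnitCell",
    "MillerFacet",
    "WulffShape",
    "read_cif",
    "replicate",
    "wulff_shape",
    "carve",
]

#: Tolerance (angstrom) below which symmetry-equivalent positions are merged.
DEDUP_TOL = 1e-3


@dataclass
class UnitCell:
    """A conventional unit cell with symmetry fully expanded.

    ``sites`` holds one entry per atom of the *full* cell:
    (element symbol, fractional coordinates, site label).
    ``rotations`` are the point-group rotation matrices (fractional basis)
    used for Miller-family expansion.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float
    sites: list
    spacegroup: str = "P 1"
    rotations: list = field(default_factory=list)

    def __post_init__(self):
        for x in (self.a, self.b, self.c):
            if x <= 0:
                raise ValueError("lattice lengths must be positive")
        for x in (self.alpha, self.beta, self.gamma):
            if not 0 < x < 180:
                raise ValueError("lattice angles must lie in (0, 180)")
        if not self.rotations:
            self.rotations = [np.eye(3, dtype=int)]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def frac_to_cart(self) -> np.ndarray:
        """Column matrix M with r_cart = M @ r_frac (angstrom)."""
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        v = np.sqrt(
            1
            - np.cos(al) ** 2
            - np.cos(be) ** 2
            - np.cos(ga) ** 2
            + 2 * np.cos(al) * np.cos(be) * np.cos(ga)
        )
        return np.array(
            [
                [self.a, self.b * np.cos(ga), self.c * np.cos(be)],
                [0, self.b * np.sin(ga),
                 self.c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)],
                [0, 0, self.c * v / np.sin(ga)],
            ]
        )

    def composition(self) -> dict:
        out: dict = {}
        for el, _, _ in self.sites:
            out[el] = out.get(el, 0) + 1
        return out

    def hkl_normal(self, hkl) -> np.ndarray:
        """Unit Cartesian normal of the (hkl) lattice plane (via the
        reciprocal lattice)."""
        g = np.linalg.inv(self.frac_to_cart).T @ np.asarray(hkl, dtype=float)
        return g / np.linalg.norm(g)

    def expand_family(self, hkl) -> list:
        """All integer index triples symmetry-equivalent to ``hkl`` under
        the cell's point group."""
        h = np.asarray(hkl, dtype=int)
        seen = set()
        for rot in self.rotations:
            hp = tuple(int(x) for x in h @ np.asarray(rot))
            seen.add(hp)
        return sorted(seen)


def _rotations_from_spacegroup(sg: gemmi.SpaceGroup) -> list:
    rots = {}
    den = gemmi.Op.DEN
    for op in sg.operations():
        mat = (np.array(op.rot, dtype=float) / den).round().astype(int)
        rots[mat.tobytes()] = mat
    return list(rots.values())


def read_cif(path, allow_p1_fallback: bool = False) -> UnitCell:
    """Read a CIF file and return the symmetry-expanded full cell.

    Parameters
    ----------
    path : str or Path
        CIF file with cell parameters, an atom-site loop and either
        explicit symmetry operations or a space-group name.
    allow_p1_fallback : bool
        If true, a file without any symmetry information is treated as P1.
        Off by default: silent P1 on a symmetric structure corrupts the
        composition, so the missing tag is reported instead.
    """
    try:
        st = gemmi.read_small_structure(str(path))
    except Exception as exc:  # unparseable CIF
        raise FormatError(f"cannot parse CIF file {path}: {exc}") from exc
    cell = st.cell
    if cell.a == 0 or cell.b == 0 or cell.c == 0:
        raise FormatError(
            f"{path}: missing or zero cell parameters "
            "(_cell_length_a/_cell_length_b/_cell_length_c)"
        )
    if not st.sites:
        raise FormatError(f"{path}: no _atom_site loop found")

    sg = gemmi.find_spacegroup_by_name(st.spacegroup_hm) if st.spacegroup_hm else None
    if sg is None:
        if not allow_p1_fallback:
            raise FormatError(
                f"{path}: no usable symmetry "
                "(_symmetry_space_group_name_H-M or _symmetry_equiv_pos_as_xyz); "
                "pass allow_p1_fallback=True to treat the file as P1"
            )
        sg = gemmi.find_spacegroup_by_name("P 1")

    # Expand the asymmetric unit to the full cell, merging duplicates.
    ops = sg.operations()
    orth = np.array(cell.orth.mat.tolist(), dtype=float)
    sites: list = []
    occupied: list = []
    for site in st.sites:
        frac = np.array([site.fract.x, site.fract.y, site.fract.z], dtype=float)
        for op in ops:
            new = np.array(op.apply_to_xyz(list(frac)), dtype=float) % 1.0
            new[new > 1 - 1e-9] = 0.0
            dup = False
            for prev in occupied:
                d = np.abs(new - prev)
                d = np.minimum(d, 1 - d)  # periodic images
                if np.linalg.norm(orth @ d) < DEDUP_TOL:
                    dup = True
                    break
            if not dup:
                occupied.append(new)
                sites.append((site.element.name, new, site.label))

    return UnitCell(
        a=cell.a, b=cell.b, c=cell.c,
        alpha=cell.alpha, beta=cell.beta, gamma=cell.gamma,
        sites=sites,
        spacegroup=sg.hm,
        rotations=_rotations_from_spacegroup(sg),
    )


def replicate(cell: UnitCell, nx: int, ny: int, nz: int) -> AtomisticStructure:
    """Tile the full cell into an ``nx × ny × nz`` Cartesian supercell."""
    for n in (nx, ny, nz):
        if int(n) != n or n < 1:
            raise ValueError("replication factors must be integers >= 1")
    m = cell.frac_to_cart
    elements, positions, names = [], [], []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                shift = np.array([i, j, k], dtype=float)
                for el, frac, label in cell.sites:
                    elements.append(el)
                    names.append(label)
                    positions.append(m @ (frac + shift))
    box = np.array([nx * cell.a, ny * cell.b, nz * cell.c])
    return AtomisticStructure(
        elements=np.array(elements, dtype=object),
        positions=np.array(positions),
        names=np.array(names, dtype=object),
        box=box,
    )


@dataclass(frozen=True)
class MillerFacet:
    """One facet family: Miller index, relative surface energy γ and
    whether to expand to the full symmetry-equivalent {hkl} family."""

    hkl: tuple
    gamma: float
    expand_family: bool = True

    def __post_init__(self):
        if tuple(self.hkl) == (0, 0, 0):
            raise ValueError("Miller index must not be (0,0,0)")
        if self.gamma <= 0:
            raise ValueError("surface energy must be positive")


@dataclass
class WulffShape:
    """Bounded intersection of facet half-spaces n·r ≤ d with d ∝ γ."""

    normals: np.ndarray      # (F, 3) unit outward normals
    distances: np.ndarray    # (F,) plane distances, angstrom
    gammas: np.ndarray       # (F,) generating relative surface energies
    hkls: list               # (F,) generating Miller indices

    def __post_init__(self):
        self.normals = np.asarray(self.normals, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances <= 0):
            raise GeometryError("all plane distances must be positive")

    def scaled(self, factor: float) -> "WulffShape":
        return WulffShape(self.normals.copy(), self.distances * factor,
                          self.gammas.copy(), list(self.hkls))

    # -- geometry ------------------------------------------------------
    def vertices(self) -> np.ndarray:
        """Vertices of the polyhedron (unordered), via half-space
        intersection around the interior point at the origin."""
        hs = np.hstack([self.normals, -self.distances[:, None]])
        interior = np.zeros(3)
        inter = HalfspaceIntersection(hs, interior)
        # merge duplicate vertices produced by >3 planes meeting in a point
        verts = inter.intersections
        out: list = []
        for v in verts:
            if not any(np.linalg.norm(v - w) < 1e-7 for w in out):
                out.append(v)
        return np.array(out)

    def boundary_faces(self) -> np.ndarray:
        """Indices of input half-spaces that contribute an actual face
        (redundant facets are kept in the input but excluded here)."""
        verts = self.vertices()
        on_plane = np.abs(verts @ self.normals.T - self.distances) < 1e-7
        # a face needs >= 3 vertices on its plane
        return np.flatnonzero(on_plane.sum(axis=0) >= 3)

    def volume(self) -> float:
        return float(ConvexHull(self.vertices()).volume)

    def surface_area(self) -> float:
        return float(ConvexHull(self.vertices()).area)

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        """Boolean mask: point satisfies every half-space (boundary
        inclusive)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 3)
        return np.all(pts @ self.normals.T <= self.distances + tol, axis=1)

    def extent_along(self, direction) -> float:
        """Face-to-face extent of the polyhedron along a direction."""
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        proj = self.vertices() @ d
        return float(proj.max() - proj.min())


def _check_bounded(normals: np.ndarray) -> bool:
    """The intersection of n·r ≤ d (d > 0) is bounded iff no direction u
    has n·u ≤ 0 for all normals; check by LP in each axis direction."""
    for sign in (1.0, -1.0):
        for axis in range(3):
            c = np.zeros(3)
            c[axis] = -sign  # maximise sign * r_axis
            res = linprog(c, A_ub=normals, b_ub=np.ones(len(normals)),
                          bounds=[(None, None)] * 3, method="highs")
            if res.status == 3:  # unbounded
                return False
    return True


def wulff_shape(facets, cell: UnitCell, target_diameter: float) -> WulffShape:
    """Construct the Wulff polyhedron for a facet set.

    Each facet family contributes half-spaces at distance proportional to
    its γ; the result is scaled so the face-to-face extent along the
    lowest-γ facet normal equals ``target_diameter`` (angstrom).
    """
    if not facets:
        raise ValueError("at least one facet is required")
    if target_diameter <= 0:
        raise ValueError("target diameter must be positive")

    normals, dists, gammas, hkls = [], [], [], []
    for f in facets:
        members = cell.expand_family(f.hkl) if f.expand_family else [tuple(f.hkl)]
        for hkl in members:
            normals.append(cell.hkl_normal(hkl))
            dists.append(f.gamma)
            gammas.append(f.gamma)
            hkls.append(hkl)
    normals = np.array(normals)
    dists = np.array(dists)

    if not _check_bounded(normals):
        raise GeometryError(
            "facet set does not close the Wulff shape (unbounded intersection); "
            "add more facet families"
        )

    shape = WulffShape(normals, dists, np.array(gammas), hkls)
    gmin = shape.gammas.min()
    ref_normal = shape.normals[int(np.argmin(shape.gammas))]
    extent = shape.extent_along(ref_normal)
    shape = shape.scaled(target_diameter / extent)
    # face-to-face extent along the dominant (lowest-γ) normal now equals
    # the requested diameter by construction
    assert abs(shape.extent_along(ref_normal) - target_diameter) < 1e-6 * max(
        1.0, target_diameter
    )
    return shape


def carve(bulk: AtomisticStructure, shape: WulffShape, center) -> AtomisticStructure:
    """Keep exactly the bulk atoms inside the shape centred at ``center``.

    Atoms exactly on a facet plane are included (n·(r−c) ≤ d).  Atom ids
    are preserved from the bulk supercell.
    """
    center = np.asarray(center, dtype=float)
    if bulk.box is not None:
        radius = np.abs(shape.vertices()).max(axis=0)
        lo, hi = center - radius, center + radius
        if np.any(lo < -1e-6) or np.any(hi > np.asarray(bulk.box) + 1e-6):
            raise GeometryError(
                "Wulff shape extends beyond the bulk supercell; "
                "increase the replication factors"
            )
    mask = shape.contains(bulk.positions - center)
    carved = bulk.select(mask)
    carved.positions = carved.positions - center  # origin at carve centre
    carved.box = None  # a particle is not periodic
    return carved
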