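"""Glycan stage: branched polysaccharide chains and grafting to the core.

The coat polymer is a gum-arabic-like polysaccharide with monosaccharide
composition L-arabinose : D-galactose : L-rhamnose : D-glucuronic acid
= 3 : 3 : 1 : 1.  The documented default linkage topology realizes that
composition as a repeating 8-residue unit on a galactan backbone:

    ... → GAL → GAL → GAL → GCA → ...      (1→4-linked backbone)
          |      |      |      |
         ARA    ARA    ARA    RHA          (1→3-linked single branches)

Geometry is built in an extended conformation along a chain axis.  The
polymerization degree is chosen from the target contour length, and the
end-to-end length is then tuned exactly by a uniform zig-zag tilt of the
glycosidic segments (the builder's stand-in for glycosidic torsion
adjustment): tilting every backbone link by ±θ about the axis shortens
the chain smoothly, and θ is solved so the measured root-to-terminus
distance equals the target within machine precision.

Chains attach to selected surface octahedral Fe through the (deprotonated)
anomeric oxygen of the first residue at an Fe–O distance of 1.95 Å, chain
axis along the site's outward normal (or a caller-supplied axis).  Steric
clashes are resolved deterministically, in escalating order: a spin/tilt
scan of the rigid chain about the grafting axis, and — for the crowded
sites of a dense brush — re-spinning individual residues of the incoming
chain about their own glycosidic axes, which moves the branch arms
without touching the backbone trace or the chain length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import GeometryError, PlacementError
from .structure import AtomisticStructure
from .surface import SiteClassification
from .templates import _rotation_onto

__all__ = [
    "ResidueSpec",
    "GlycanChain",
    "compose_chain",
    "build_chain_geometry",
    "build_chain",
    "attach_chain",
]

GLYCOSIDIC_BOND = 1.43   # C1–O link bond length, angstrom
FE_O_BOND = 1.95         # Fe–O(root) link, angstrom
CLASH_TOL = 0.9          # minimum allowed interatomic distance, angstrom
RESIDUES_PER_REPEAT = 8


@dataclass(frozen=True)
class ResidueSpec:
    """One residue in a chain plan: type, parent residue index (None for
    the root) and the parent's link-oxygen name."""

    restype: str
    parent: int | None
    site: str | None
    role: str  # "backbone" | "branch"


def compose_chain(n_repeats: int) -> list:
    """Residue sequence with branch topology for ``n_repeats`` repeats.

    Returns 8·n_repeats residues per repeat: three galactoses and one
    glucuronate on the backbone, each carrying one single-residue branch
    (arabinose on the galactoses, rhamnose on the glucuronate), giving the
    exact 3:3:1:1 ara:gal:rha:glcA composition.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    seq: list = []
    prev_backbone = None
    for _ in range(n_repeats):
        for restype, branch in (("GAL", "ARA"), ("GAL", "ARA"),
                                ("GAL", "ARA"), ("GCA", "RHA")):
            idx = len(seq)
            seq.append(ResidueSpec(restype, prev_backbone,
                                   "O4" if prev_backbone is not None else None,
                                   "backbone"))
            seq.append(ResidueSpec(branch, idx, "O3", "branch"))
            prev_backbone = idx
    return seq


def composition_counts(sequence) -> dict:
    out: dict = {}
    for r in sequence:
        out[r.restype] = out.get(r.restype, 0) + 1
    return out


@dataclass
class GlycanChain:
    """A built chain: coordinates, bonds, tree topology and bookkeeping.

    ``build`` keeps the construction state (templates, tilt, resolved
    spins, spin increment) so grafting can re-spin individual residues
    against a crowded environment without moving the backbone trace.
    """

    structure: AtomisticStructure
    sequence: list
    root_atom_id: int
    tree_edges: list                  # (parent residue idx, child residue idx)
    end_to_end_nm: float
    composition: dict = field(default_factory=dict)
    build: dict | None = None

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def _load_templates(sequence, templates=None) -> dict:
    from . import fixtures

    needed = {r.restype for r in sequence}
    templates = dict(templates or {})
    for name in needed:
        if name not in templates:
            templates[name] = fixtures.monomer_template(name)
    return {k: v.canonical() for k, v in templates.items()}


def _spin(deg: float) -> np.ndarray:
    return Rotation.from_euler("z", deg, degrees=True).as_matrix()


def _place(sequence, tpls: dict, tilt: float, spins=None,
           spin_increment: float = 137.5):
    """Place every residue; returns per-residue (rotation, translation)
    world transforms plus world positions of link atoms."""
    spins = spins or {}
    xforms: dict = {}

    def world(idx, name):
        rot, tr = xforms[idx]
        tpl = tpls[sequence[idx].restype]
        return rot @ np.asarray(tpl.atom(name)[2], float) + tr

    kb = 0
    for idx, spec in enumerate(sequence):
        tpl = tpls[spec.restype]
        if spec.role == "backbone":
            u = np.array([np.sin(tilt) * (-1) ** kb, 0.0, np.cos(tilt)])
            # golden-angle default spin: branch arms trace a helix, which
            # keeps the chain envelope compact and interdigitation-friendly
            rot = _rotation_onto(np.array([0.0, 0.0, 1.0]), u) @ _spin(
                spins.get(idx, spin_increment * kb)
            )
            if spec.parent is None:
                c1 = np.zeros(3)
            else:
                c1 = world(spec.parent, spec.site) + GLYCOSIDIC_BOND * u
            kb += 1
        else:
            p3 = world(spec.parent, spec.site)
            pc1 = world(spec.parent, "C1")
            lat = p3 - pc1
            lat[2] = 0.0
            nl = np.linalg.norm(lat)
            lat = lat / nl if nl > 1e-8 else np.array([1.0, 0.0, 0.0])
            # tilt branches toward the distal end: smaller lateral radius
            v = 0.72 * lat + 0.69 * np.array([0.0, 0.0, 1.0])
            nv = np.linalg.norm(v)
            v = v / nv if nv > 1e-8 else np.array([1.0, 0.0, 0.0])
            rot = _rotation_onto(np.array([0.0, 0.0, 1.0]), v) @ _spin(
                spins.get(idx, 0.0)
            )
            c1 = p3 + GLYCOSIDIC_BOND * v
        xforms[idx] = (rot, c1)  # template frame has C1 at the origin
    return xforms


def _chain_structure(sequence, tpls, xforms) -> tuple:
    """Materialize placed residues into one structure, applying link
    chemistry (delete anomeric OH of children and the H of used parent
    link oxygens; deprotonate the root O1 for Fe binding)."""
    used_sites = {}
    for idx, spec in enumerate(sequence):
        if spec.parent is not None:
            used_sites.setdefault(spec.parent, []).append((spec.site, idx))

    elements, names, positions, charges, resids, resnames = [], [], [], [], [], []
    bonds = []
    atom_key: dict = {}   # (residue idx, atom name) -> global atom index
    root_atom = None

    for idx, spec in enumerate(sequence):
        tpl = tpls[spec.restype]
        rot, tr = xforms[idx]
        drop = set()
        if spec.parent is not None:
            drop.update(tpl.upstream_delete)
        else:
            drop.add("HO1")  # root anomeric O is deprotonated to bind Fe
        for site, _child in used_sites.get(idx, []):
            drop.add(tpl.downstream[site])  # the link oxygen loses its H
        for name, el, xyz, q in tpl.atoms:
            if name in drop:
                continue
            xyz_world = rot @ np.asarray(xyz, float) + tr
            if spec.parent is None and name == "O1":
                q = -1.0  # alkoxide; keeps the chain total at integer charge
                # put the root O on the chain axis below C1 so the grafted
                # chain stands perpendicular off its Fe site
                xyz_world = tr - GLYCOSIDIC_BOND * (rot @ np.array([0, 0, 1.0]))
            if any(name == s for s, _ in used_sites.get(idx, [])):
                q = 0.0   # bridging ether oxygen
            atom_key[(idx, name)] = len(elements)
            elements.append(el)
            names.append(name)
            positions.append(xyz_world)
            charges.append(q)
            resids.append(idx)
            resnames.append(spec.restype)
        for a, b in tpl.bonds:
            if a in drop or b in drop:
                continue
            bonds.append((atom_key[(idx, a)], atom_key[(idx, b)]))
        if spec.parent is not None:
            bonds.append((atom_key[(spec.parent, spec.site)],
                          atom_key[(idx, "C1")]))
        if spec.parent is None:
            root_atom = atom_key[(idx, "O1")]

    st = AtomisticStructure(
        elements=np.array(elements, dtype=object),
        positions=np.array(positions),
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        resnames=np.array(resnames, dtype=object),
        charges=np.array(charges),
        types=np.array(["LIG"] * len(elements), dtype=object),
        bonds=bonds,
    )
    return st, root_atom, atom_key


def _end_to_end(sequence, st: AtomisticStructure, root_atom: int) -> float:
    """Root-attachment-atom to most distal backbone atom, angstrom."""
    backbone = {i for i, r in enumerate(sequence) if r.role == "backbone"}
    mask = np.isin(st.resids, list(backbone))
    root = st.positions[root_atom]
    return float(np.linalg.norm(st.positions[mask] - root, axis=1).max())


def _resolve_clashes(sequence, tpls, xforms, tilt,
                     spin_increment: float = 137.5):
    """Deterministic 30°-step spin scan on residues involved in clashes.

    Backbone spins leave the C1→O4 anchors on the spin axis, so the
    backbone trace (and hence the solved chain length) is unchanged.
    """
    spins = {}
    for _ in range(4):
        st, root, _ = _chain_structure(sequence, tpls, xforms)
        tree = cKDTree(st.positions)
        pairs = tree.query_pairs(CLASH_TOL)
        bset = {tuple(sorted(b)) for b in st.bonds}
        pairs = [p for p in pairs if tuple(sorted(p)) not in bset]
        if not pairs:
            return xforms, st, root, spins
        offending = sorted({int(st.resids[i]) for p in pairs for i in p})
        changed = False
        for idx in offending:
            best, best_clear = None, -1.0
            others = st.positions[st.resids != idx]
            otree = cKDTree(others)
            kb = sum(1 for i in range(idx)
                     if sequence[i].role == "backbone")
            default = (spin_increment * kb
                       if sequence[idx].role == "backbone" else 0.0)
            for step in range(12):
                trial = dict(spins)
                trial[idx] = trial.get(idx, default) + 30.0 * step
                xf = _place(sequence, tpls, tilt, trial, spin_increment)
                tpl = tpls[sequence[idx].restype]
                rot, tr = xf[idx]
                mine = np.array([rot @ np.asarray(a[2], float) + tr
                                 for a in tpl.atoms])
                clear = float(otree.query(mine)[0].min())
                if clear > best_clear:
                    best, best_clear = trial.get(idx), clear
                if clear >= CLASH_TOL:
                    break
            if best is not None:
                spins[idx] = best
                changed = True
        xforms = _place(sequence, tpls, tilt, spins, spin_increment)
        if not changed:
            break
    st, root, _ = _chain_structure(sequence, tpls, xforms)
    return xforms, st, root, spins


def build_chain_geometry(sequence, target_length_nm: float,
                         templates=None,
                         spin_increment_deg: float = 137.5) -> GlycanChain:
    """Place a composed sequence in an extended conformation whose
    root-to-terminus length equals ``target_length_nm`` (within 2%;
    the tilt solve itself converges to machine precision).

    ``spin_increment_deg`` sets the helical pitch of the branch arms; it
    does not move the backbone trace or change the chain length, so
    different values give equal-length conformers with differently
    oriented arms (useful when packing a dense brush)."""
    tpls = _load_templates(sequence, templates)
    target = target_length_nm * 10.0  # nm -> angstrom

    def length_at(tilt):
        xf = _place(sequence, tpls, tilt, None, spin_increment_deg)
        st, root, _ = _chain_structure(sequence, tpls, xf)
        return _end_to_end(sequence, st, root)

    l0 = length_at(0.0)
    if len(sequence) == 1:
        tilt = 0.0
    else:
        if l0 < target:
            raise GeometryError(
                f"target length {target_length_nm} nm exceeds the extended "
                f"length {l0/10:.2f} nm of this sequence; increase n_repeats"
            )
        lmax_tilt = length_at(1.2)
        if target < lmax_tilt:
            raise GeometryError(
                f"target length {target_length_nm} nm is shorter than one "
                "extended repeat allows; reduce n_repeats"
            )
        tilt = brentq(lambda t: length_at(t) - target, 0.0, 1.2, xtol=1e-10)

    xforms = _place(sequence, tpls, tilt, None, spin_increment_deg)
    xforms, st, root, spins = _resolve_clashes(sequence, tpls, xforms, tilt,
                                               spin_increment_deg)
    edges = [(r.parent, i) for i, r in enumerate(sequence)
             if r.parent is not None]
    return GlycanChain(
        structure=st,
        sequence=list(sequence),
        root_atom_id=int(st.ids[root]),
        tree_edges=edges,
        end_to_end_nm=_end_to_end(sequence, st, root) / 10.0,
        composition=composition_counts(sequence),
        build={"templates": tpls, "tilt": tilt, "spins": spins,
               "spin_increment": spin_increment_deg, "root_index": root},
    )


def build_chain(target_length_nm: float, n_repeats: int | None = None,
                templates=None,
                spin_increment_deg: float = 137.5) -> GlycanChain:
    """Compose and build a chain.  When ``n_repeats`` is not given, the
    smallest repeat count whose fully extended length reaches the target
    is used (the polymerization degree follows from the length)."""
    if n_repeats is None:
        tpls0 = _load_templates(compose_chain(1), templates)
        n_repeats = 1
        while True:
            seq = compose_chain(n_repeats)
            xf = _place(seq, tpls0, 0.0)
            st, root, _ = _chain_structure(seq, tpls0, xf)
            if _end_to_end(seq, st, root) >= target_length_nm * 10.0:
                break
            n_repeats += 1
            if n_repeats > 200:
                raise GeometryError("cannot reach target length")
    return build_chain_geometry(compose_chain(n_repeats), target_length_nm,
                                templates, spin_increment_deg)


def _flex_refine(core, core_tree, chain, best_pos, anchor, fe_id, root_idx,
                 clash_tol, max_iter: int = 6):
    """Re-spin individual residues of an incoming chain against the
    grafted environment.

    Residue spins rotate each sugar (and the arm hanging off it) about
    its own glycosidic axis, so the backbone anchor trace — and hence the
    chain length — is untouched.  Returns refined positions or None.
    """
    bld = chain.build
    seq = chain.sequence
    tpls = bld["templates"]
    tilt = bld["tilt"]
    inc = bld["spin_increment"]
    cst = chain.structure

    # recover the rigid-body transform of the best orientation:
    # best_pos = R @ template_pos + t for some rotation R
    a = cst.positions - cst.positions.mean(axis=0)
    b = best_pos - best_pos.mean(axis=0)
    rot, _ = Rotation.align_vectors(b, a)
    rmat = rot.as_matrix()

    def rebuild(spins):
        xf = _place(seq, tpls, tilt, spins, inc)
        st, root, _ = _chain_structure(seq, tpls, xf)
        pos = st.positions @ rmat.T
        return pos - pos[root] + anchor, st

    def env_clearance(pos, mask=None):
        sel = np.arange(len(pos)) if mask is None else np.flatnonzero(mask)
        d, j = core_tree.query(pos[sel])
        for k, si in enumerate(sel):
            if si == root_idx and int(core.ids[j[k]]) == int(fe_id):
                d[k] = np.inf
        return float(d.min())

    defaults = {}
    kb = 0
    for idx, rspec in enumerate(seq):
        if rspec.role == "backbone":
            defaults[idx] = inc * kb
            kb += 1
        else:
            defaults[idx] = 0.0

    spins = dict(bld["spins"])
    bset = {tuple(sorted(p)) for p in cst.bonds}
    for _ in range(max_iter):
        pos, st = rebuild(spins)
        d, j = core_tree.query(pos)
        bad = set()
        for i in np.flatnonzero(d < clash_tol):
            if i == root_idx and int(core.ids[j[i]]) == int(fe_id):
                continue
            bad.add(int(st.resids[i]))
        self_pairs = cKDTree(pos).query_pairs(clash_tol)
        for pr in self_pairs:
            if tuple(sorted(pr)) not in bset:
                bad.update(int(st.resids[x]) for x in pr)
        if not bad:
            return pos
        for idx in sorted(bad):
            best_spin, best_c = None, -np.inf
            for step in range(12):
                trial = dict(spins)
                trial[idx] = spins.get(idx, defaults[idx]) + 30.0 * step
                p2, st2 = rebuild(trial)
                mask = st2.resids == idx
                ce = env_clearance(p2, mask)
                rest = p2[~mask]
                cs = float(cKDTree(rest).query(p2[mask])[0].min())
                c = min(ce, cs)
                if c > best_c:
                    best_spin, best_c = trial[idx], c
                if c >= clash_tol:
                    break
            if best_spin is not None:
                spins[idx] = best_spin
    pos, st = rebuild(spins)
    d, j = core_tree.query(pos)
    ok = env_clearance(pos) >= clash_tol
    if ok:
        self_pairs = cKDTree(pos).query_pairs(clash_tol)
        ok = all(tuple(sorted(p)) in bset for p in self_pairs)
    return pos if ok else None


def attach_chain(core: AtomisticStructure, site: SiteClassification,
                 chain: GlycanChain, bond_length: float = FE_O_BOND,
                 clash_tol: float = CLASH_TOL,
                 spin_offset_deg: float = 0.0,
                 axis=None) -> AtomisticStructure:
    """Bond a built chain to a grafting site.

    The chain axis (+z in the build frame) is aligned to ``axis`` (default
    the site's surface normal) and the root oxygen placed at
    ``bond_length`` from the Fe along the surface normal.  A deterministic
    spin/tilt scan about the grafting axis resolves clashes against
    everything already in ``core``; if no orientation clears
    ``clash_tol`` a :class:`PlacementError` is raised.
    """
    if site.normal is None:
        raise ValueError("graft site carries no surface normal")
    normal = np.asarray(site.normal, float)
    normal = normal / np.linalg.norm(normal)
    base_axis = normal if axis is None else np.asarray(axis, float)
    base_axis = base_axis / np.linalg.norm(base_axis)
    fe_pos = core.positions[core.index_of([site.atom_id])[0]]
    anchor = fe_pos + bond_length * normal

    cst = chain.structure
    root_idx = int(np.flatnonzero(cst.ids == chain.root_atom_id)[0])

    tree = cKDTree(core.positions)
    fe_id = site.atom_id
    best_pos, best_clear = None, -1.0

    # orthonormal frame around the grafting axis for tilt trials
    ref = np.array([1.0, 0.0, 0.0])
    if abs(base_axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(base_axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(base_axis, e1)

    trials = [(0.0, 0.0)]
    for tilt_deg in (6.0, 12.0, 18.0):
        for k in range(8):
            trials.append((tilt_deg, 45.0 * k))
    for tilt_deg, az in trials:
        t = np.radians(tilt_deg)
        a = np.radians(az)
        axis_t = (np.cos(t) * base_axis
                  + np.sin(t) * (np.cos(a) * e1 + np.sin(a) * e2))
        rot0 = _rotation_onto(np.array([0.0, 0.0, 1.0]), axis_t)
        for step in range(24):
            rot = Rotation.from_rotvec(
                np.radians(spin_offset_deg + 15.0 * step) * axis_t
            ).as_matrix() @ rot0
            pos = cst.positions @ rot.T
            pos = pos - pos[root_idx] + anchor
            d, j = tree.query(pos)
            # the root O is legitimately at bond_length from its Fe
            d_eff = d.copy()
            d_eff[root_idx] = (np.inf if core.ids[j[root_idx]] == fe_id
                               else d[root_idx])
            clear = float(d_eff.min())
            if clear > best_clear:
                best_pos, best_clear = pos, clear
            if clear >= clash_tol:
                break
        if best_clear >= clash_tol:
            break
    if best_clear < clash_tol and chain.build is not None:
        refined = _flex_refine(core, tree, chain, best_pos, anchor, fe_id,
                               root_idx, clash_tol)
        if refined is not None:
            best_pos, best_clear = refined, clash_tol
    if best_clear < clash_tol:
        raise PlacementError(
            f"chain at site {site.atom_id} clashes at {best_clear:.2f} A "
            f"for every spin/tilt; min allowed {clash_tol} A"
        )

    placed = cst.copy()
    placed.positions = best_pos
    # shift ids/resids explicitly so the new root id is known
    id_off = int(core.ids.max()) + 1
    rid_off = int(core.resids.max()) + 1
    placed.bonds = [(a + id_off, b + id_off) for a, b in placed.bonds]
    placed.ids = placed.ids + id_off
    placed.resids = placed.resids + rid_off
    merged = core.merged_with(placed)
    merged.bonds.append((int(fe_id), chain.root_atom_id + id_off))
    return merged
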