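"""Residue templates: idealized monosaccharides and the DPPC lipid.

The polysaccharide coat is assembled from four monosaccharide templates —
L-arabinose (furanose), D-galactose, L-rhamnose and D-glucuronic acid
(pyranoses) — with idealized ring geometry and literature-standard bond
lengths (C–C 1.52 Å, C–O 1.43 Å, O–H 0.96 Å, C–H 1.09 Å).  Templates carry
per-atom partial charges built from electroneutral chemical groups so that
every residue sums exactly to its formal charge (0, or −1 for ionized
glucuronate), and stay at integer totals through glycosidic-link formation.

Each template designates:

* ``upstream_link``  — the anomeric carbon C1 that bonds to the parent
  residue's link oxygen (glycosidic C1→O bond);
* ``upstream_delete`` — atoms lost when the residue becomes a child
  (its own anomeric hydroxyl O1/HO1);
* ``downstream``     — link oxygens able to accept a child residue
  (their hydroxyl H is deleted on linking).

Canonical template frame: C1 at the origin, the C1→ring-extension axis
along +z; builders rotate from there.

The DPPC template is an all-atom phosphatidylcholine with CHARMM-style
atom names (choline N/C1x, phosphate P/O1x, glycerol, two C16 acyl
tails) built head-up along +z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MonomerTemplate",
    "make_pyranose",
    "make_furanose",
    "make_dppc",
    "MONOMER_BUILDERS",
]

# bond lengths, angstrom
CC = 1.52
CO = 1.43
OH = 0.96
CH = 1.09

# group charges (e); placeholders chosen so every chemical group is neutral
Q_OHYD, Q_HHYD = -0.42, 0.42           # hydroxyl O/H
Q_CH = 0.09                            # H on carbon; carbon gets -0.09 per H
Q_ORING, Q_CRING = -0.30, 0.15         # ring O and its two flanking carbons
Q_OCARB = -0.50                        # each carboxylate oxygen (sum -1)


@dataclass
class MonomerTemplate:
    """One monosaccharide: atoms, bonds, charges and link bookkeeping."""

    resname: str
    atoms: list          # (name, element, xyz ndarray, charge)
    bonds: list          # (name_i, name_j)
    upstream_link: str   # atom bonding to the parent's link oxygen
    upstream_delete: list
    downstream: dict = field(default_factory=dict)  # link O -> its H name
    formal_charge: float = 0.0

    def atom(self, name):
        for a in self.atoms:
            if a[0] == name:
                return a
        raise KeyError(f"{self.resname}: no atom {name}")

    @property
    def names(self):
        return [a[0] for a in self.atoms]

    def positions(self) -> np.ndarray:
        return np.array([a[2] for a in self.atoms], dtype=float)

    def charge_sum(self) -> float:
        return float(sum(a[3] for a in self.atoms))

    def validate(self) -> None:
        import networkx as nx

        g = nx.Graph(self.bonds)
        g.add_nodes_from(self.names)
        assert nx.is_connected(g), f"{self.resname}: bond graph not connected"
        assert self.upstream_link in self.names
        for o, h in self.downstream.items():
            assert o in self.names and h in self.names
        assert abs(self.charge_sum() - self.formal_charge) < 1e-4

    def canonical(self) -> "MonomerTemplate":
        """Rotated/translated copy: C1 at origin, extension axis (C1 to the
        first downstream oxygen, else the ring oxygen) along +z."""
        pos = {a[0]: np.asarray(a[2], float) for a in self.atoms}
        origin = pos[self.upstream_link]
        if self.downstream:
            axis_to = pos[next(iter(self.downstream))]
        else:
            ring_o = "O5" if "O5" in pos else "O4"
            axis_to = pos[ring_o]
        v = axis_to - origin
        rot = _rotation_onto(v / np.linalg.norm(v), np.array([0.0, 0.0, 1.0]))
        atoms = [
            (n, el, rot @ (np.asarray(xyz, float) - origin), q)
            for n, el, xyz, q in self.atoms
        ]
        return MonomerTemplate(
            self.resname, atoms, list(self.bonds), self.upstream_link,
            list(self.upstream_delete), dict(self.downstream), self.formal_charge,
        )


def _rotation_onto(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector a onto unit vector b."""
    from scipy.spatial.transform import Rotation

    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(a @ b)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(np.pi * axis).as_matrix()
    axis = v / s
    angle = np.arctan2(s, c)
    return Rotation.from_rotvec(angle * axis).as_matrix()


# ----------------------------------------------------------------------
# ring construction helpers


def _ring_positions(n: int, bond: float, pucker: float) -> np.ndarray:
    """n-membered ring on a circle with alternating z-pucker; circle radius
    chosen so adjacent distances equal ``bond``."""
    chord_angle = np.pi / n
    dz = np.array([pucker * (-1) ** i for i in range(n)])
    # chord^2 = (2 r sin(pi/n))^2 + (dz_i - dz_{i+1})^2
    dz_step = 2 * pucker
    r = np.sqrt(max(bond**2 - dz_step**2, 0.1)) / (2 * np.sin(chord_angle))
    ang = 2 * np.pi * np.arange(n) / n
    return np.column_stack([r * np.cos(ang), r * np.sin(ang), dz])


def _sub_dirs(p: np.ndarray, axial_sign: float):
    """Outward 'equatorial-like' and 'axial-like' directions at ring atom p."""
    u = p.copy()
    u[2] = 0.0
    u /= np.linalg.norm(u)
    z = np.array([0.0, 0.0, 1.0])
    eq = u * 0.85 + axial_sign * 0.53 * z
    ax = u * 0.35 - axial_sign * 0.94 * z
    return eq / np.linalg.norm(eq), ax / np.linalg.norm(ax)


def _tangent(p: np.ndarray) -> np.ndarray:
    t = np.array([-p[1], p[0], 0.0])
    n = np.linalg.norm(t)
    return t / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def make_pyranose(resname: str, c6_kind: str) -> MonomerTemplate:
    """Six-membered (pyranose) sugar template.

    c6_kind: "CH2OH" (galactose), "CH3" (rhamnose, 6-deoxy) or
    "COO-" (glucuronate, ionized carboxylate).
    """
    ring_names = ["O5", "C1", "C2", "C3", "C4", "C5"]
    ring = _ring_positions(6, CC, 0.25)
    atoms: list = []
    bonds: list = []
    qextra: dict = {}

    for i, nm in enumerate(ring_names):
        el = "O" if nm == "O5" else "C"
        q = Q_ORING if nm == "O5" else 0.0
        atoms.append([nm, el, ring[i].copy(), q])
    for i in range(6):
        bonds.append((ring_names[i], ring_names[(i + 1) % 6]))
    qextra["C1"] = Q_CRING
    qextra["C5"] = Q_CRING

    # hydroxyls / link oxygens on C1..C4, ring H on C1..C5
    for i, cn in enumerate(["C1", "C2", "C3", "C4"]):
        p = ring[1 + i]
        axial_sign = 1.0 if p[2] > 0 else -1.0
        eq, ax = _sub_dirs(p, axial_sign)
        on, hn = f"O{i+1}", f"HO{i+1}"
        opos = p + CO * eq
        atoms.append([on, "O", opos, Q_OHYD])
        hdir = eq + 0.55 * _tangent(p)
        atoms.append([hn, "H", opos + OH * hdir / np.linalg.norm(hdir), Q_HHYD])
        bonds += [(cn, on), (on, hn)]
        atoms.append([f"H{i+1}", "H", p + CH * ax, Q_CH])
        bonds.append((cn, f"H{i+1}"))
        qextra[cn] = qextra.get(cn, 0.0) - Q_CH

    # C5: H plus the C6 substituent
    p5 = ring[5]
    s5 = 1.0 if p5[2] > 0 else -1.0
    eq5, ax5 = _sub_dirs(p5, s5)
    atoms.append(["H5", "H", p5 + CH * ax5, Q_CH])
    bonds.append(("C5", "H5"))
    qextra["C5"] = qextra.get("C5", 0.0) - Q_CH
    c6 = p5 + CC * eq5
    t5 = _tangent(p5)

    if c6_kind == "CH2OH":
        atoms.append(["C6", "C", c6, -2 * Q_CH])
        bonds.append(("C5", "C6"))
        for j, sgn in enumerate((1.0, -1.0)):
            d = 0.8 * t5 * sgn - 0.6 * s5 * np.array([0, 0, 1.0])
            atoms.append([f"H6{j+1}", "H", c6 + CH * d / np.linalg.norm(d), Q_CH])
            bonds.append(("C6", f"H6{j+1}"))
        o6 = c6 + CO * eq5
        atoms.append(["O6", "O", o6, Q_OHYD])
        h6d = eq5 + 0.55 * t5
        atoms.append(["HO6", "H", o6 + OH * h6d / np.linalg.norm(h6d), Q_HHYD])
        bonds += [("C6", "O6"), ("O6", "HO6")]
        formal = 0.0
    elif c6_kind == "CH3":
        atoms.append(["C6", "C", c6, -3 * Q_CH])
        bonds.append(("C5", "C6"))
        dirs = [
            eq5 + t5, eq5 - t5, eq5 + s5 * np.array([0, 0, 1.0]),
        ]
        for j, d in enumerate(dirs):
            atoms.append([f"H6{j+1}", "H", c6 + CH * d / np.linalg.norm(d), Q_CH])
            bonds.append(("C6", f"H6{j+1}"))
        formal = 0.0
    elif c6_kind == "COO-":
        atoms.append(["C6", "C", c6, 0.0])
        bonds.append(("C5", "C6"))
        for j, sgn in enumerate((1.0, -1.0)):
            d = eq5 + 0.9 * sgn * t5
            atoms.append([f"O6{'AB'[j]}", "O", c6 + 1.25 * d / np.linalg.norm(d),
                          Q_OCARB])
            bonds.append(("C6", f"O6{'AB'[j]}"))
        formal = -1.0
    else:  # pragma: no cover
        raise ValueError(c6_kind)

    for a in atoms:
        a[3] += qextra.pop(a[0], 0.0)

    tpl = MonomerTemplate(
        resname=resname,
        atoms=[tuple(a) for a in atoms],
        bonds=bonds,
        upstream_link="C1",
        upstream_delete=["O1", "HO1"],
        downstream={"O4": "HO4", "O3": "HO3", "O2": "HO2"},
        formal_charge=formal,
    )
    tpl.validate()
    return tpl


def make_furanose(resname: str = "ARA") -> MonomerTemplate:
    """Five-membered (furanose) arabinose template; terminal branch residue."""
    ring_names = ["O4", "C1", "C2", "C3", "C4"]
    ring = _ring_positions(5, CC, 0.15)
    atoms: list = []
    bonds: list = []
    qextra = {"C1": Q_CRING, "C4": Q_CRING}
    for i, nm in enumerate(ring_names):
        el = "O" if nm == "O4" else "C"
        q = Q_ORING if nm == "O4" else 0.0
        atoms.append([nm, el, ring[i].copy(), q])
    for i in range(5):
        bonds.append((ring_names[i], ring_names[(i + 1) % 5]))

    for i, cn in enumerate(["C1", "C2", "C3"]):
        p = ring[1 + i]
        s = 1.0 if p[2] >= 0 else -1.0
        eq, ax = _sub_dirs(p, s)
        on, hn = f"O{i+1}", f"HO{i+1}"
        opos = p + CO * eq
        atoms.append([on, "O", opos, Q_OHYD])
        hdir = eq + 0.55 * _tangent(p)
        atoms.append([hn, "H", opos + OH * hdir / np.linalg.norm(hdir), Q_HHYD])
        bonds += [(cn, on), (on, hn)]
        atoms.append([f"H{i+1}", "H", p + CH * ax, Q_CH])
        bonds.append((cn, f"H{i+1}"))
        qextra[cn] = qextra.get(cn, 0.0) - Q_CH

    # C4 exocyclic CH2OH (C5) and ring H
    p4 = ring[4]
    s4 = 1.0 if p4[2] >= 0 else -1.0
    eq4, ax4 = _sub_dirs(p4, s4)
    atoms.append(["H4", "H", p4 + CH * ax4, Q_CH])
    bonds.append(("C4", "H4"))
    qextra["C4"] = qextra.get("C4", 0.0) - Q_CH
    c5 = p4 + CC * eq4
    t4 = _tangent(p4)
    atoms.append(["C5", "C", c5, -2 * Q_CH])
    bonds.append(("C4", "C5"))
    for j, sgn in enumerate((1.0, -1.0)):
        d = 0.8 * sgn * t4 - 0.6 * s4 * np.array([0, 0, 1.0])
        atoms.append([f"H5{j+1}", "H", c5 + CH * d / np.linalg.norm(d), Q_CH])
        bonds.append(("C5", f"H5{j+1}"))
    o5 = c5 + CO * eq4
    atoms.append(["O5", "O", o5, Q_OHYD])
    h5d = eq4 + 0.55 * t4
    atoms.append(["HO5", "H", o5 + OH * h5d / np.linalg.norm(h5d), Q_HHYD])
    bonds += [("C5", "O5"), ("O5", "HO5")]

    for a in atoms:
        a[3] += qextra.pop(a[0], 0.0)

    tpl = MonomerTemplate(
        resname=resname,
        atoms=[tuple(a) for a in atoms],
        bonds=bonds,
        upstream_link="C1",
        upstream_delete=["O1", "HO1"],
        downstream={},
        formal_charge=0.0,
    )
    tpl.validate()
    return tpl


MONOMER_BUILDERS = {
    "ARA": lambda: make_furanose("ARA"),
    "GAL": lambda: make_pyranose("GAL", "CH2OH"),
    "RHA": lambda: make_pyranose("RHA", "CH3"),
    "GCA": lambda: make_pyranose("GCA", "COO-"),
}


# ----------------------------------------------------------------------
# DPPC


def make_dppc():
    """All-atom DPPC lipid template, head (choline) up along +z, two C16
    acyl tails descending.  Charges: zwitterionic head (choline +1,
    phosphate −1), zero net charge.

    Returns (atoms, bonds) in the same (name, element, xyz, charge)
    convention as the monomer templates; builders wrap it as needed.
    """
    atoms: list = []
    bonds: list = []

    def add(name, el, xyz, q=0.0):
        atoms.append((name, el, np.asarray(xyz, float), q))

    # choline: N(CH3)3 - C12H2 - C11H2 - O12
    zN = 22.0
    add("N", "N", [0, 0, zN], 1.0)
    for j, (dx, dy) in enumerate([(1.3, 0.6), (-1.3, 0.6), (0, -1.45)]):
        cn = f"C1{3+j}"
        add(cn, "C", [dx, dy, zN + 0.8])
        bonds.append(("N", cn))
        for k in range(3):
            ang = 2 * np.pi * k / 3
            add(f"H{3+j}{k+1}", "H",
                [dx + 0.9 * np.cos(ang), dy + 0.9 * np.sin(ang), zN + 1.6])
            bonds.append((cn, f"H{3+j}{k+1}"))
    add("C12", "C", [0.4, 0.4, zN - 1.4])
    bonds.append(("N", "C12"))
    add("H121", "H", [1.35, 0.7, zN - 1.5])
    add("H122", "H", [-0.3, 1.2, zN - 1.6])
    bonds += [("C12", "H121"), ("C12", "H122")]
    add("C11", "C", [0.1, -0.5, zN - 2.6])
    bonds.append(("C12", "C11"))
    add("H111", "H", [-0.9, -0.8, zN - 2.5])
    add("H112", "H", [0.8, -1.35, zN - 2.55])
    bonds += [("C11", "H111"), ("C11", "H112")]

    # phosphate
    zP = zN - 5.2
    add("P", "P", [0, 0, zP], 1.1)
    add("O12", "O", [0.05, -0.25, zP + 1.3], -0.35)  # ester to C11
    bonds += [("C11", "O12"), ("P", "O12")]
    add("O13", "O", [1.35, 0.45, zP - 0.3], -0.70)
    add("O14", "O", [-1.35, 0.45, zP - 0.3], -0.70)
    bonds += [("P", "O13"), ("P", "O14")]
    add("O11", "O", [0, -0.6, zP - 1.3], -0.35)      # ester to glycerol
    bonds.append(("P", "O11"))

    # glycerol backbone C1-C2-C3
    zG = zP - 2.6
    add("C1", "C", [0, 0, zG])
    bonds.append(("O11", "C1"))
    add("HA", "H", [0.95, 0.4, zG + 0.2])
    add("HB", "H", [-0.85, 0.6, zG + 0.15])
    bonds += [("C1", "HA"), ("C1", "HB")]
    add("C2", "C", [0.2, -0.7, zG - 1.3])
    bonds.append(("C1", "C2"))
    add("HS", "H", [1.25, -0.9, zG - 1.35])
    bonds.append(("C2", "HS"))
    add("C3", "C", [-0.6, -1.95, zG - 1.45])
    bonds.append(("C2", "C3"))
    add("HX", "H", [-1.6, -1.7, zG - 1.2])
    add("HY", "H", [-0.2, -2.75, zG - 1.9])
    bonds += [("C3", "HX"), ("C3", "HY")]

    # two palmitoyl tails (sn-2 on C2 via O21/C21, sn-1 analogue on C3 via
    # O31/C31); 16 carbons each including the carbonyl
    for tail, (anchor, x0) in enumerate([("C2", 2.0), ("C3", -2.0)]):
        t = tail + 2  # 2 / 3
        zE = zG - 3.0
        add(f"O{t}1", "O", [x0 * 0.5, -1.0 - tail, zE + 0.6])
        bonds.append((anchor, f"O{t}1"))
        add(f"C{t}1", "C", [x0 * 0.75, -0.8 - tail, zE - 0.6])
        bonds.append((f"O{t}1", f"C{t}1"))
        add(f"O{t}2", "O", [x0 * 0.75 + 1.25 * (1 if x0 > 0 else -1),
                            -0.1 - tail, zE - 0.3])
        bonds.append((f"C{t}1", f"O{t}2"))
        prev = f"C{t}1"
        for k in range(2, 17):  # C{t}2 .. C{t}16
            z = zE - 0.6 - 1.27 * (k - 1)
            x = x0 + 0.45 * ((-1) ** k)
            cn = f"C{t}{k}"
            add(cn, "C", [x, -0.8 - tail, z])
            bonds.append((prev, cn))
            nh = 3 if k == 16 else 2
            for m in range(nh):
                dy = 0.95 * (1 if m == 0 else -1)
                dz = 0.35 if m < 2 else -0.9
                add(f"H{t}{k}{'XYZ'[m]}", "H", [x, -0.8 - tail + dy, z + dz])
                bonds.append((cn, f"H{t}{k}{'XYZ'[m]}"))
            prev = cn

    total = sum(a[3] for a in atoms)
    assert abs(total) < 1e-10
    return atoms, bonds
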