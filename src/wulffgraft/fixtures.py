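"""Packaged reference data and synthetic generators.

Everything needed to exercise the pipeline offline ships with the package:

* a magnetite (Fe3O4) inverse-spinel unit cell in CIF format;
* the four monosaccharide templates and the DPPC lipid, stored as
  versioned JSON fixture files (coordinates, charges, bonds and link
  bookkeeping in one authoritative file each);
* generators for synthetic hydrogen-bond trajectories with planted ground
  truth, and for synthetic ROI images with known signal statistics.

``regenerate_fixture_files`` rebuilds the JSON fixtures from the idealized
geometry code in :mod:`wulffgraft.templates` and refreshes the checksum
manifest; the shipped files are the versioned artefacts of that code.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import templates as _tpl
from .crystal import UnitCell, read_cif
from .templates import MonomerTemplate

__all__ = [
    "magnetite_cif_path",
    "magnetite_cell",
    "monomer_template",
    "dppc_template",
    "fixture_manifest",
    "regenerate_fixture_files",
    "SynthHBondTrajectory",
    "synth_hbond_trajectory",
    "synth_roi_image",
]

MONOMER_NAMES = ("ARA", "GAL", "RHA", "GCA")


def _data_dir() -> Path:
    return Path(resources.files("wulffgraft") / "data")


def magnetite_cif_path() -> Path:
    """Path of the packaged magnetite unit-cell CIF."""
    return _data_dir() / "magnetite_fd3m.cif"


def magnetite_cell() -> UnitCell:
    """The magnetite conventional cell, symmetry-expanded (24 Fe + 32 O)."""
    return read_cif(magnetite_cif_path())


# ----------------------------------------------------------------------
# JSON template fixtures


def _template_to_dict(resname, atoms, bonds, upstream_link=None,
                      upstream_delete=(), downstream=None, formal=0.0):
    return {
        "resname": resname,
        "atoms": [
            {"name": n, "element": el, "xyz": [round(float(x), 6) for x in xyz],
             "charge": round(float(q), 6)}
            for n, el, xyz, q in atoms
        ],
        "bonds": [list(b) for b in bonds],
        "upstream_link": upstream_link,
        "upstream_delete": list(upstream_delete),
        "downstream": dict(downstream or {}),
        "formal_charge": formal,
        "version": 1,
    }


def _load_json(name: str) -> dict:
    path = _data_dir() / name
    with open(path) as fh:
        return json.load(fh)


def monomer_template(resname: str) -> MonomerTemplate:
    """Load a monosaccharide template fixture (ARA, GAL, RHA or GCA)."""
    if resname not in MONOMER_NAMES:
        raise KeyError(f"unknown monomer {resname!r}; have {MONOMER_NAMES}")
    d = _load_json(f"monomer_{resname}.json")
    tpl = MonomerTemplate(
        resname=d["resname"],
        atoms=[(a["name"], a["element"], np.array(a["xyz"]), a["charge"])
               for a in d["atoms"]],
        bonds=[tuple(b) for b in d["bonds"]],
        upstream_link=d["upstream_link"],
        upstream_delete=d["upstream_delete"],
        downstream=d["downstream"],
        formal_charge=d["formal_charge"],
    )
    tpl.validate()
    return tpl


def dppc_template() -> dict:
    """The DPPC lipid fixture: atoms/bonds plus headgroup atom-name
    manifest (phosphate and choline groups used by the analysis stage)."""
    d = _load_json("lipid_DPPC.json")
    d["atoms"] = [
        (a["name"], a["element"], np.array(a["xyz"]), a["charge"])
        for a in d["atoms"]
    ]
    d["bonds"] = [tuple(b) for b in d["bonds"]]
    return d


def fixture_manifest() -> dict:
    """Manifest of packaged fixture files with sha256 checksums."""
    return _load_json("manifest.json")


def verify_fixture_checksums() -> bool:
    man = fixture_manifest()
    for entry in man["files"]:
        p = _data_dir() / entry["file"]
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        if digest != entry["sha256"]:
            return False
    return True


def regenerate_fixture_files(out_dir=None) -> dict:
    """Rebuild the JSON fixtures from the geometry code and write a fresh
    checksum manifest.  Returns the manifest dict."""
    out = Path(out_dir) if out_dir else _data_dir()
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, builder in _tpl.MONOMER_BUILDERS.items():
        t = builder()
        d = _template_to_dict(t.resname, t.atoms, t.bonds, t.upstream_link,
                              t.upstream_delete, t.downstream, t.formal_charge)
        fn = f"monomer_{name}.json"
        (out / fn).write_text(json.dumps(d, indent=1) + "\n")
        written.append(fn)
    atoms, bonds = _tpl.make_dppc()
    d = _template_to_dict("DPPC", atoms, bonds)
    d["groups"] = {
        "phosphate": ["P", "O11", "O12", "O13", "O14"],
        "choline": ["N", "C11", "C12", "C13", "C14", "C15"],
        "head_reference": "P",
        "tail_reference": "C216",
    }
    (out / "lipid_DPPC.json").write_text(json.dumps(d, indent=1) + "\n")
    written.append("lipid_DPPC.json")
    written.append("magnetite_fd3m.cif")

    manifest = {
        "version": 1,
        "files": [
            {
                "file": f,
                "kind": ("unit-cell" if f.endswith(".cif")
                         else "lipid" if "DPPC" in f else "monomer"),
                "sha256": hashlib.sha256((out / f).read_bytes()).hexdigest(),
            }
            for f in sorted(written)
        ],
        "provenance": "idealized geometry generated by wulffgraft.templates",
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest


# ----------------------------------------------------------------------
# synthetic hydrogen-bond trajectories


@dataclass
class SynthHBondTrajectory:
    """A synthetic multi-frame system with planted hydrogen bonds.

    ``ground_truth`` maps (donor residue type, acceptor group) to the
    realized mean bond count per frame (exact, from the drawn on/off
    pattern); ``expected`` holds the requested count × fraction.
    """

    frames: list                 # list of (n, 3) arrays, angstrom
    elements: np.ndarray
    names: np.ndarray
    resids: np.ndarray
    restypes: dict               # donor resid -> residue type name
    bonds: list                  # (i, j) atom-index pairs
    donor_ids: np.ndarray
    acceptor_groups: dict        # group name -> atom-index array
    ground_truth: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def synth_hbond_trajectory(n_frames: int, planted, noise: float = 0.0,
                           seed: int = 0) -> SynthHBondTrajectory:
    """Generate frames in which specified donor–H···acceptor triplets meet
    the hydrogen-bond criteria in a given fraction of frames.

    Parameters
    ----------
    n_frames : int
        Number of frames (≥ 1).
    planted : list of dict
        Each with keys ``restype`` (donor residue type), ``group``
        (acceptor group name), ``n_bonds`` (int) and ``fraction``
        (probability per frame that the bond geometry is satisfied);
        optional ``donor_element`` ("O" default, or "C" for CH···O).
    noise : float
        Gaussian positional jitter (angstrom) added per frame; keep below
        ~0.2 so planted geometry stays inside the criteria margins.
    seed : int
        Seed for the on/off pattern and the jitter.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    for spec in planted:
        if not 0.0 <= spec["fraction"] <= 1.0:
            raise ValueError("planted fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    elements, names, resids = [], [], []
    base = []
    bonds = []
    donor_ids = []
    triplets = []  # (donor_idx, h_idx, acc_idx, spec_idx)
    groups: dict = {}
    restypes: dict = {}

    resid = 0
    origin = np.zeros(3)
    for si, spec in enumerate(planted):
        del_ = spec.get("donor_element", "O")
        restypes[resid] = spec["restype"]
        for b in range(int(spec["n_bonds"])):
            # one donor-H pair and one acceptor per planted bond, on a
            # well-separated grid so bonds never cross-talk
            d0 = origin + np.array([0.0, 12.0 * b, 18.0 * si])
            di = len(base)
            elements += [del_, "H", "O"]
            names += [f"D{si}_{b}", f"HD{si}_{b}", f"A{si}_{b}"]
            resids += [resid, resid, 9000 + si]
            base += [d0, d0 + [1.0, 0, 0], d0 + [2.8, 0, 0]]
            bonds.append((di, di + 1))
            donor_ids.append(di)
            triplets.append((di, di + 1, di + 2, si))
            groups.setdefault(spec["group"], []).append(di + 2)
        resid += 1

    base = np.array(base)
    on = np.zeros((n_frames, len(triplets)), dtype=bool)
    for t, (_, _, _, si) in enumerate(triplets):
        on[:, t] = rng.random(n_frames) < planted[si]["fraction"]

    frames = []
    for f in range(n_frames):
        pos = base.copy()
        for t, (di, hi, ai, si) in enumerate(triplets):
            if not on[f, t]:
                pos[ai] += np.array([6.0, 0.0, 0.0])  # break the geometry
        if noise > 0:
            pos = pos + rng.normal(0.0, noise, pos.shape)
        frames.append(pos)

    ground, expected = {}, {}
    for t, (di, hi, ai, si) in enumerate(triplets):
        key = (planted[si]["restype"], planted[si]["group"])
        ground[key] = ground.get(key, 0.0) + on[:, t].mean()
        expected[key] = expected.get(key, 0.0) + planted[si]["fraction"]

    return SynthHBondTrajectory(
        frames=frames,
        elements=np.array(elements, dtype=object),
        names=np.array(names, dtype=object),
        resids=np.array(resids),
        restypes=restypes,
        bonds=bonds,
        donor_ids=np.array(donor_ids, dtype=int),
        acceptor_groups={k: np.array(v, dtype=int) for k, v in groups.items()},
        ground_truth=ground,
        expected=expected,
    )


# ----------------------------------------------------------------------
# synthetic ROI images


def synth_roi_image(shape=(128, 128), tumor_mean: float = 100.0,
                    background_mean: float = 100.0, noise_sd: float = 0.0,
                    seed: int = 0, n_background: int = 3):
    """Synthetic grayscale image with a tumor ROI and disjoint background
    ROIs at specified mean intensities.

    Returns ``(image, tumor_mask, background_masks, truth_snr)`` where
    ``truth_snr = 0.655 * tumor_mean / background_mean``.
    """
    from skimage.draw import disk

    if tumor_mean <= 0 or background_mean <= 0:
        raise ValueError("ROI means must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    img = np.full(shape, background_mean * 0.5, dtype=float)

    tumor = np.zeros(shape, dtype=bool)
    rr, cc = disk((h // 2, w // 2), min(h, w) // 6, shape=shape)
    tumor[rr, cc] = True
    img[tumor] = tumor_mean

    centers = [(h // 5, w // 5), (h // 5, 4 * w // 5), (4 * h // 5, w // 5),
               (4 * h // 5, 4 * w // 5)][:n_background]
    bgs = []
    for cy, cx in centers:
        m = np.zeros(shape, dtype=bool)
        rr, cc = disk((cy, cx), min(h, w) // 10, shape=shape)
        m[rr, cc] = True
        if (m & tumor).any() or any((m & b).any() for b in bgs):
            raise ValueError("ROI masks overlap")
        img[m] = background_mean
        bgs.append(m)

    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, shape)
    truth = 0.655 * tumor_mean / background_mean
    return img, tumor, bgs, truth
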