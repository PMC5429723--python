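"""Analysis stage: hydrogen bonds, NP–membrane approach, imaging formulas.

Hydrogen bonds are detected geometrically per frame: a donor heavy atom D
with a covalently attached H and an acceptor A form a bond when the D–A
distance is below a class cutoff and the D–H···A angle (at the hydrogen)
exceeds a class minimum.  Two classes are supported: conventional OH···O
(D–A ≤ 3.5 Å, angle ≥ 150°) and the weaker, less directional CH···O
(D–A ≤ 3.8 Å, angle ≥ 130°); the looser CH···O criteria reflect its
reduced directionality.  Cutoffs are configurable.

Summaries are aggregated per (donor residue type, acceptor group) cell:
the time-averaged bond count per frame, a per-residue mean, and a
block-averaged standard error.

Imaging formulas follow radiological ROI conventions:
``SNR = 0.655 · ROI_tumor / averageROI_background`` and
``CNR = SNR_pre − SNR_post`` (the sign convention of the printed formula
is preserved; the magnitude is reported alongside).  Caliper tumor
volume is ``V = (length/2) · width²``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ConfigurationError

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "OHO_DEFAULT",
    "CHO_DEFAULT",
    "detect_hbonds",
    "hbond_summary",
    "np_membrane_distance",
    "ROIAnalysis",
    "snr",
    "cnr",
    "tumor_volume",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria for one hydrogen-bond class."""

    hbond_class: str            # "OH...O" or "CH...O"
    donor_element: str          # heavy donor element ("O" or "C")
    max_da_distance: float      # angstrom
    min_dha_angle: float        # degrees, at the hydrogen

    def __post_init__(self):
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("angle cutoff must lie in (0, 180]")


OHO_DEFAULT = HBondCriteria("OH...O", "O", 3.5, 150.0)
CHO_DEFAULT = HBondCriteria("CH...O", "C", 3.8, 130.0)


@dataclass(frozen=True)
class HBondRecord:
    frame: int
    donor: int
    hydrogen: int
    acceptor: int
    hbond_class: str
    donor_restype: str | None = None
    acceptor_group: str | None = None


def _donor_hydrogens(bonds, donor_ids, elements):
    """Map donor heavy-atom index -> list of attached H indices."""
    adj: dict = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out = {}
    missing = []
    for d in donor_ids:
        hs = [n for n in adj.get(int(d), []) if elements[n] == "H"]
        if not hs:
            missing.append(int(d))
        out[int(d)] = hs
    if missing:
        raise ConfigurationError(
            f"{len(missing)} selected donors have no attached hydrogen "
            f"(e.g. atom indices {missing[:6]})"
        )
    return out


def detect_hbonds(positions, bonds, donor_ids, acceptor_ids, criteria,
                  frame: int = 0, elements=None, restypes=None,
                  acceptor_group_of=None) -> list:
    """All (donor, H, acceptor) triplets satisfying any enabled criteria
    set at one frame.

    Parameters
    ----------
    positions : (n, 3) array, angstrom.
    bonds : iterable of (i, j) atom-index pairs (to locate donor H's).
    donor_ids, acceptor_ids : candidate heavy-donor / acceptor indices.
    criteria : iterable of :class:`HBondCriteria`; a class is only
        emitted when its criteria set is present.
    elements : per-atom element symbols (required to find hydrogens and
        partition donors by class).
    restypes, acceptor_group_of : optional dicts (atom index → donor
        residue type / acceptor group) used to annotate records.
    """
    positions = np.asarray(positions, dtype=float)
    if elements is None:
        raise ValueError("elements are required")
    elements = np.asarray(elements, dtype=object)
    donor_ids = np.asarray(donor_ids, dtype=int)
    acceptor_ids = np.asarray(acceptor_ids, dtype=int)
    if len(donor_ids) == 0 or len(acceptor_ids) == 0:
        raise ValueError("donor and acceptor selections must be non-empty")

    dh = _donor_hydrogens(bonds, donor_ids, elements)
    acc_tree = cKDTree(positions[acceptor_ids])
    records = []
    for crit in criteria:
        dsel = donor_ids[[elements[d] == crit.donor_element
                          for d in donor_ids]]
        for d in dsel:
            near = acc_tree.query_ball_point(positions[d],
                                             crit.max_da_distance)
            for ai in near:
                a = int(acceptor_ids[ai])
                if a == int(d):
                    continue
                for h in dh[int(d)]:
                    v1 = positions[d] - positions[h]
                    v2 = positions[a] - positions[h]
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom == 0:
                        continue
                    cosang = np.clip(v1 @ v2 / denom, -1.0, 1.0)
                    ang = np.degrees(np.arccos(cosang))
                    if ang >= crit.min_dha_angle:
                        records.append(HBondRecord(
                            frame=frame, donor=int(d), hydrogen=int(h),
                            acceptor=a, hbond_class=crit.hbond_class,
                            donor_restype=None if restypes is None
                            else restypes.get(int(d)),
                            acceptor_group=None if acceptor_group_of is None
                            else acceptor_group_of.get(a),
                        ))
    return records


def hbond_summary(frames, bonds, donor_ids, acceptor_groups, donor_restype,
                  criteria=(OHO_DEFAULT,), elements=None,
                  n_blocks: int = 5) -> pd.DataFrame:
    """Time-averaged hydrogen-bond counts per (donor residue type,
    acceptor group) cell.

    Parameters
    ----------
    frames : iterable of (n, 3) coordinate arrays (≥ 1 frame).
    acceptor_groups : dict group name -> atom-index array.
    donor_restype : dict donor atom index -> residue type name.
    n_blocks : number of blocks for the block-averaged standard error.

    Returns a DataFrame indexed by (restype, group) with columns
    ``mean`` (bonds per frame), ``se`` (block SE), ``mean_per_residue``
    and ``n_frames``.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("trajectory must contain at least one frame")
    group_of = {}
    acceptor_ids = []
    for g, ids in acceptor_groups.items():
        for i in ids:
            group_of[int(i)] = g
            acceptor_ids.append(int(i))

    # residues per donor type (for the per-residue average)
    residues_per_type: dict = {}
    donor_res: dict = {}
    for d, t in donor_restype.items():
        donor_res.setdefault(t, set()).add(d)
    for t, ds in donor_res.items():
        residues_per_type[t] = max(1, len(ds))

    cells = sorted({(t, g) for t in donor_res for g in acceptor_groups})
    per_frame = {c: np.zeros(len(frames)) for c in cells}
    for f, pos in enumerate(frames):
        recs = detect_hbonds(pos, bonds, list(donor_restype), acceptor_ids,
                             criteria, frame=f, elements=elements,
                             restypes=donor_restype,
                             acceptor_group_of=group_of)
        for r in recs:
            key = (r.donor_restype, r.acceptor_group)
            if key in per_frame:
                per_frame[key][f] += 1

    rows = []
    nb = max(1, min(n_blocks, len(frames)))
    for (t, g), series in per_frame.items():
        blocks = np.array_split(series, nb)
        bmeans = np.array([b.mean() for b in blocks])
        se = bmeans.std(ddof=1) / np.sqrt(nb) if nb > 1 else 0.0
        rows.append({
            "restype": t, "group": g,
            "mean": series.mean(), "se": float(se),
            "mean_per_residue": series.mean() / residues_per_type[t],
            "n_frames": len(frames),
        })
    return pd.DataFrame(rows).set_index(["restype", "group"]).sort_index()


def np_membrane_distance(frames, np_indices, phosphate_indices) -> np.ndarray:
    """Per-frame signed minimum distance (angstrom) from NP atoms to the
    phosphate plane (mean z of the phosphate selection).  Negative values
    mean the NP has penetrated below the plane."""
    np_indices = np.asarray(np_indices, dtype=int)
    phosphate_indices = np.asarray(phosphate_indices, dtype=int)
    if len(np_indices) == 0 or len(phosphate_indices) == 0:
        raise ValueError("selections must be non-empty")
    out = []
    for pos in frames:
        pos = np.asarray(pos, dtype=float)
        plane = pos[phosphate_indices, 2].mean()
        out.append(pos[np_indices, 2].min() - plane)
    return np.asarray(out)


# ----------------------------------------------------------------------
# imaging formulas


@dataclass
class ROIAnalysis:
    """ROI signal statistics for one image."""

    roi_tumor_mean: float
    background_roi_means: list
    snr: float

    @property
    def average_background(self) -> float:
        return float(np.mean(self.background_roi_means))


def snr(image, tumor_mask, background_masks) -> ROIAnalysis:
    """SNR = 0.655 × (tumor-ROI mean / mean of background-ROI means)."""
    image = np.asarray(image, dtype=float)
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if not tumor_mask.any():
        raise ValueError("tumor ROI mask is empty")
    if not background_masks:
        raise ValueError("at least one background ROI is required")
    bg_means = []
    for m in background_masks:
        m = np.asarray(m, dtype=bool)
        if not m.any():
            raise ValueError("empty background ROI mask")
        bg_means.append(float(image[m].mean()))
    avg_bg = float(np.mean(bg_means))
    if avg_bg <= 0:
        raise ValueError("average background intensity must be positive")
    tumor_mean = float(image[tumor_mask].mean())
    return ROIAnalysis(
        roi_tumor_mean=tumor_mean,
        background_roi_means=bg_means,
        snr=0.655 * tumor_mean / avg_bg,
    )


def cnr(snr_pre: float, snr_post: float) -> dict:
    """CNR = SNR_pre − SNR_post, sign preserved as printed; the magnitude
    is reported alongside."""
    if not (np.isfinite(snr_pre) and np.isfinite(snr_post)):
        raise ValueError("SNR values must be finite")
    value = float(snr_pre) - float(snr_post)
    return {"cnr": value, "magnitude": abs(value)}


def tumor_volume(length: float, width: float) -> float:
    """Caliper tumor volume V = (length/2) · width² (mm³ for mm inputs)."""
    if length < 0 or width < 0:
        raise ValueError("length and width must be non-negative")
    return (length / 2.0) * width ** 2
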