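"""Hydrogen-bond detection/summary, approach series, imaging formulas."""

import numpy as np
import pytest

from wulffgraft.analysis import (CHO_DEFAULT, OHO_DEFAULT, HBondCriteria,
                                 cnr, detect_hbonds, hbond_summary,
                                 np_membrane_distance, snr, tumor_volume)
from wulffgraft.errors import ConfigurationError
from wulffgraft.fixtures import synth_hbond_trajectory, synth_roi_image


# ------------------------------------------------------------- detection

def _collinear_frame(da=2.8):
    # O(donor) - H along +x, acceptor O at distance da from the donor
    return np.array([[0.0, 0, 0], [1.0, 0, 0], [da, 0, 0]])


def test_collinear_oh_o_detected():
    recs = detect_hbonds(_collinear_frame(), [(0, 1)], [0], [2],
                         [OHO_DEFAULT], elements=["O", "H", "O"])
    assert len(recs) == 1
    r = recs[0]
    assert (r.donor, r.hydrogen, r.acceptor) == (0, 1, 2)
    assert r.hbond_class == "OH...O"


def test_bent_geometry_below_angle_cutoff_rejected():
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]])  # ~90 deg at H
    recs = detect_hbonds(pos, [(0, 1)], [0], [2], [OHO_DEFAULT],
                         elements=["O", "H", "O"])
    assert recs == []


def test_ch_o_emitted_only_when_enabled():
    pos = _collinear_frame(3.6)
    els = ["C", "H", "O"]
    assert detect_hbonds(pos, [(0, 1)], [0], [2], [OHO_DEFAULT],
                         elements=els) == []
    recs = detect_hbonds(pos, [(0, 1)], [0], [2], [OHO_DEFAULT, CHO_DEFAULT],
                         elements=els)
    assert len(recs) == 1
    assert recs[0].hbond_class == "CH...O"


def test_donor_without_hydrogen_is_configuration_error():
    pos = _collinear_frame()
    with pytest.raises(ConfigurationError):
        detect_hbonds(pos, [], [0], [2], [OHO_DEFAULT],
                      elements=["O", "H", "O"])


def test_criteria_validation():
    with pytest.raises(ValueError):
        HBondCriteria("OH...O", "O", -1.0, 150.0)
    with pytest.raises(ValueError):
        HBondCriteria("OH...O", "O", 3.5, 181.0)


def brute_force_hbonds(pos, bonds, donors, acceptors, criteria, elements):
    """O(N^2) all-pairs oracle."""
    adj = {}
    for a, b in bonds:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    out = set()
    for crit in criteria:
        for d in donors:
            if elements[d] != crit.donor_element:
                continue
            for a in acceptors:
                if a == d:
                    continue
                if np.linalg.norm(pos[d] - pos[a]) > crit.max_da_distance:
                    continue
                for h in adj.get(d, []):
                    if elements[h] != "H":
                        continue
                    v1, v2 = pos[d] - pos[h], pos[a] - pos[h]
                    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(c, -1, 1)))
                    if ang >= crit.min_dha_angle:
                        out.add((d, h, a, crit.hbond_class))
    return out


@pytest.mark.parametrize("seed", range(5))
def test_detector_equals_all_pairs_oracle_on_random_frames(seed):
    rng = np.random.default_rng(seed)
    n = 200
    pos = rng.uniform(0, 25, (n, 3))
    elements = rng.choice(["O", "C", "H"], size=n, p=[0.4, 0.2, 0.4])
    heavies = np.flatnonzero(elements != "H")
    hydros = np.flatnonzero(elements == "H")
    bonds = [(int(rng.choice(heavies)), int(h)) for h in hydros]
    donors = sorted({a for a, _ in bonds})
    acceptors = [int(i) for i in np.flatnonzero(elements == "O")]
    crit = [OHO_DEFAULT, CHO_DEFAULT]
    recs = detect_hbonds(pos, bonds, donors, acceptors, crit,
                         elements=elements)
    got = {(r.donor, r.hydrogen, r.acceptor, r.hbond_class) for r in recs}
    assert got == brute_force_hbonds(pos, bonds, donors, acceptors, crit,
                                     elements)


# ------------------------------------------------------------- summary

def _summarize(tr, criteria=(OHO_DEFAULT,), n_blocks=5):
    donor_restype = {int(d): tr.restypes[int(tr.resids[d])]
                     for d in tr.donor_ids}
    return hbond_summary(tr.frames, tr.bonds, tr.donor_ids,
                         tr.acceptor_groups, donor_restype,
                         criteria=criteria, elements=tr.elements,
                         n_blocks=n_blocks)


def test_persistent_planted_bonds_give_exact_mean():
    tr = synth_hbond_trajectory(
        100, [{"restype": "GAL", "group": "phosphate", "n_bonds": 2,
               "fraction": 1.0}], seed=1)
    df = _summarize(tr)
    assert df.loc[("GAL", "phosphate"), "mean"] == pytest.approx(2.0)


def test_no_contacts_gives_all_zero_cells():
    tr = synth_hbond_trajectory(
        20, [{"restype": "GAL", "group": "phosphate", "n_bonds": 1,
              "fraction": 0.0}], seed=2)
    df = _summarize(tr)
    assert (df["mean"] == 0).all()


def test_intermittent_bond_recovered_within_blocks():
    tr = synth_hbond_trajectory(
        400, [{"restype": "ARA", "group": "choline", "n_bonds": 1,
               "fraction": 0.5}], seed=3)
    df = _summarize(tr)
    cell = df.loc[("ARA", "choline")]
    # exact agreement with the realized on/off pattern...
    assert cell["mean"] == pytest.approx(
        tr.ground_truth[("ARA", "choline")], abs=1e-12)
    # ...and within 3 block-SE of the requested fraction
    assert abs(cell["mean"] - 0.5) <= max(3 * cell["se"], 1e-12) + 0.08


def test_disabling_ch_o_never_increases_cells():
    tr = synth_hbond_trajectory(
        50,
        [{"restype": "GAL", "group": "phosphate", "n_bonds": 2,
          "fraction": 1.0},
         {"restype": "GAL", "group": "choline", "n_bonds": 1,
          "fraction": 1.0, "donor_element": "C"}],
        seed=4)
    with_ch = _summarize(tr, (OHO_DEFAULT, CHO_DEFAULT))
    without = _summarize(tr, (OHO_DEFAULT,))
    assert (without["mean"] <= with_ch["mean"] + 1e-12).all()
    assert with_ch.loc[("GAL", "choline"), "mean"] == pytest.approx(1.0)
    assert without.loc[("GAL", "choline"), "mean"] == 0.0


def test_empty_trajectory_raises():
    tr = synth_hbond_trajectory(1, [{"restype": "GAL", "group": "phosphate",
                                     "n_bonds": 1, "fraction": 1.0}])
    donor_restype = {int(d): "GAL" for d in tr.donor_ids}
    with pytest.raises(ValueError):
        hbond_summary([], tr.bonds, tr.donor_ids, tr.acceptor_groups,
                      donor_restype, elements=tr.elements)


# ------------------------------------------------------------- approach

def test_assembled_frame_distance_is_gap(default_build):
    from wulffgraft.membrane import BilayerSpec, assemble_system, build_bilayer
    from wulffgraft.structure import AtomisticStructure

    rng = np.random.default_rng(0)
    np_ = AtomisticStructure(elements=["Fe"] * 20,
                             positions=rng.uniform(-3, 3, (20, 3)))
    bil = build_bilayer(BilayerSpec(lipids_per_leaflet=16))
    sys_ = assemble_system(np_, bil, gap=5.0, solvate_system=False)
    st = sys_.structure
    np_idx = st.index_of(sys_.components["np"])
    upper_res = np.unique(bil.resids)[:8]
    p_idx = np.flatnonzero((st.names == "P")
                           & np.isin(st.resids, upper_res))
    d = np_membrane_distance([st.positions], np_idx, p_idx)
    assert d[0] == pytest.approx(5.0, abs=0.1)


def test_np_inside_membrane_gives_nonpositive_distance():
    pos = np.array([[0, 0, -2.0], [0, 0, 0.0], [1, 0, 0.0]])
    d = np_membrane_distance([pos], [0], [1, 2])
    assert d[0] <= 0


def test_monotone_approach_series():
    frames = []
    for z in np.linspace(20, 2, 10):
        frames.append(np.array([[0, 0, z], [0, 0, 0.0]]))
    d = np_membrane_distance(frames, [0], [1])
    assert (np.diff(d) < 0).all()


def test_empty_selection_raises():
    with pytest.raises(ValueError):
        np_membrane_distance([np.zeros((2, 3))], [], [1])


# ------------------------------------------------------------- imaging

def test_snr_uniform_image_is_formula_constant():
    img, tumor, bgs, truth = synth_roi_image(tumor_mean=100.0,
                                             background_mean=100.0)
    res = snr(img, tumor, bgs)
    assert res.snr == pytest.approx(0.655)
    assert truth == pytest.approx(0.655)


def test_snr_double_contrast():
    img, tumor, bgs, _ = synth_roi_image(tumor_mean=131.0,
                                         background_mean=65.5)
    assert snr(img, tumor, bgs).snr == pytest.approx(1.310)


def test_snr_scale_invariance():
    img, tumor, bgs, _ = synth_roi_image(tumor_mean=120.0,
                                         background_mean=80.0,
                                         noise_sd=2.0, seed=9)
    a = snr(img, tumor, bgs).snr
    b = snr(img * 7.3, tumor, bgs).snr
    assert a == pytest.approx(b, rel=1e-12)


def test_snr_empty_tumor_mask_raises():
    img, tumor, bgs, _ = synth_roi_image()
    with pytest.raises(ValueError, match="tumor"):
        snr(img, np.zeros_like(tumor), bgs)


@pytest.mark.parametrize("pre,post,expect", [(10.0, 3.0, 7.0),
                                             (5.0, 5.0, 0.0),
                                             (3.0, 10.0, -7.0)])
def test_cnr_sign_convention(pre, post, expect):
    res = cnr(pre, post)
    assert res["cnr"] == pytest.approx(expect)
    assert res["magnitude"] == pytest.approx(abs(expect))


@pytest.mark.parametrize("l,w,v", [(2.0, 1.0, 1.0), (5.0, 0.0, 0.0),
                                   (10.0, 4.0, 80.0)])
def test_tumor_volume_formula(l, w, v):
    assert tumor_volume(l, w) == pytest.approx(v)


def test_tumor_volume_rejects_negative():
    with pytest.raises(ValueError):
        tumor_volume(-1.0, 2.0)
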