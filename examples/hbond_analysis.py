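"""Hydrogen-bond analysis on a synthetic trajectory with known answers.

Plants persistent galactose–phosphate bonds (2 per frame), intermittent
arabinose–choline contacts (60% of frames) and a CH···O donor, then runs
the geometric detector and the per-cell summary.  The recovered means
should match the planted ground truth.
"""

from wulffgraft.analysis import CHO_DEFAULT, OHO_DEFAULT, hbond_summary
from wulffgraft.fixtures import synth_hbond_trajectory

planted = [
    {"restype": "GAL", "group": "phosphate", "n_bonds": 2, "fraction": 1.0},
    {"restype": "ARA", "group": "choline", "n_bonds": 1, "fraction": 0.6},
    {"restype": "GAL", "group": "choline", "n_bonds": 1, "fraction": 1.0,
     "donor_element": "C"},  # a CH...O hydrogen bond
]
tr = synth_hbond_trajectory(500, planted, noise=0.05, seed=3)

donor_restype = {int(d): tr.restypes[int(tr.resids[d])]
                 for d in tr.donor_ids}
df = hbond_summary(tr.frames, tr.bonds, tr.donor_ids, tr.acceptor_groups,
                   donor_restype, criteria=(OHO_DEFAULT, CHO_DEFAULT),
                   elements=tr.elements)

print(df.round(3).to_string())
print()
print("ground truth (realized planted means):")
for k, v in sorted(tr.ground_truth.items()):
    print(f"  {k[0]} -> {k[1]}: {v:.3f}")
print()
print("'mean' is hydrogen bonds per frame for each (donor residue type, "
      "lipid headgroup) cell; 'se' is the block-averaged standard error. "
      "The GAL-choline cell is carried entirely by the weaker CH...O "
      "class and vanishes if CHO_DEFAULT is removed from the criteria.")
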