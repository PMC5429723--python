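"""Build a DPPC bilayer and assemble a solvated NP–membrane system.

A small nanoparticle stand-in is placed 5 A above the upper-leaflet
phosphate plane of a 64-lipid-per-leaflet patch, then the box is filled
with rigid three-site waters at bulk density.  (The production-size
membrane uses 489 lipids per leaflet; this demo is scaled down to run in
seconds.)
"""

import numpy as np

from wulffgraft.membrane import BilayerSpec, assemble_system, build_bilayer
from wulffgraft.structure import AtomisticStructure

bilayer = build_bilayer(BilayerSpec(lipids_per_leaflet=64))
n_lipids = len(np.unique(bilayer.resids))
print(f"bilayer: {n_lipids} lipids ({n_lipids // 2} per leaflet), "
      f"{bilayer.n_atoms} atoms, patch {bilayer.box[0]/10:.2f} x "
      f"{bilayer.box[1]/10:.2f} nm")

rng = np.random.default_rng(0)
nano = AtomisticStructure(elements=["Fe"] * 60,
                          positions=rng.uniform(-6, 6, (60, 3)),
                          resnames=["MAG"] * 60)

system = assemble_system(nano, bilayer, gap=5.0, seed=0)
sizes = system.component_sizes()
print(f"assembled system: {system.total_atoms} atoms "
      f"(np {sizes['np']}, lipid {sizes['lipid']}, water {sizes['water']})")
print(f"realized NP-to-phosphate-plane gap: {system.np_gap:.2f} A "
      "(the requested initial separation before any dynamics)")
print(f"box: {system.box[0]/10:.2f} x {system.box[1]/10:.2f} x "
      f"{system.box[2]/10:.2f} nm")
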