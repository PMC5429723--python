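{
 "resname": "ARA",
 "atoms": [
  {
   "name": "O4",
   "element": "O",
   "xyz": [
    1.267555,
    0.0,
    0.15
   ],
   "charge": -0.3
  },
  {
   "name": "C1",
   "element": "C",
   "xyz": [
    0.391696,
    1.205517,
    -0.15
   ],
   "charge": 0.06
  },
  {
   "name": "C2",
   "element": "C",
   "xyz": [
    -1.025474,
    0.74505,
    0.15
   ],
   "charge": -0.09
  },
  {
   "name": "C3",
   "element": "C",
   "xyz": [
    -1.025474,
    -0.74505,
    -0.15
   ],
   "charge": -0.09
  },
  {
   "name": "C4",
   "element": "C",
   "xyz": [
    0.391696,
    -1.205517,
    0.15
   ],
   "charge": 0.06
  },
  {
   "name": "O1",
   "element": "O",
   "xyz": [
    0.766669,
    2.359566,
    -0.906615
   ],
   "charge": -0.42
  },
  {
   "name": "HO1",
   "element": "H",
   "xyz": [
    0.547241,
    3.181375,
    -1.351678
   ],
   "charge": 0.42
  },
  {
   "name": "H1",
   "element": "H",
   "xyz": [
    0.509228,
    1.567243,
    0.871489
   ],
   "charge": 0.09
  },
  {
   "name": "O2",
   "element": "O",
   "xyz": [
    -2.007167,
    1.458292,
    0.906615
   ],
   "charge": -0.42
  },
  {
   "name": "HO2",
   "element": "H",
   "xyz": [
    -2.856561,
    1.503556,
    1.351678
   ],
   "charge": 0.42
  },
  {
   "name": "H2",
   "element": "H",
   "xyz": [
    -1.333177,
    0.96861,
    -0.871489
   ],
   "charge": 0.09
  },
  {
   "name": "O3",
   "element": "O",
   "xyz": [
    -2.007167,
    -1.458292,
    -0.906615
   ],
   "charge": -0.42
  },
  {
   "name": "HO3",
   "element": "H",
   "xyz": [
    -2.312692,
    -2.252126,
    -1.351678
   ],
   "charge": 0.42
  },
  {
   "name": "H3",
   "element": "H",
   "xyz": [
    -1.333177,
    -0.96861,
    0.871489
   ],
   "charge": 0.09
  },
  {
   "name": "H4",
   "element": "H",
   "xyz": [
    0.509228,
    -1.567243,
    -0.871489
   ],
   "charge": 0.09
  },
  {
   "name": "C5",
   "element": "C",
   "xyz": [
    0.790269,
    -2.432198,
    0.954234
   ],
   "charge": -0.18
  },
  {
   "name": "H51",
   "element": "H",
   "xyz": [
    1.61959,
    -2.162735,
    0.300234
   ],
   "charge": 0.09
  },
  {
   "name": "H52",
   "element": "H",
   "xyz": [
    -0.039052,
    -2.701661,
    0.300234
   ],
   "charge": 0.09
  },
  {
   "name": "O5",
   "element": "O",
   "xyz": [
    1.165242,
    -3.586247,
    1.710849
   ],
   "charge": -0.42
  },
  {
   "name": "HO5",
   "element": "H",
   "xyz": [
    1.825811,
    -4.122128,
    2.155911
   ],
   "charge": 0.42
  }
 ],
 "bonds": [
  [
   "O4",
   "C1"
  ],
  [
   "C1",
   "C2"
  ],
  [
   "C2",
   "C3"
  ],
  [
   "C3",
   "C4"
  ],
  [
   "C4",
   "O4"
  ],
  [
   "C1",
   "O1"
  ],
  [
   "O1",
   "HO1"
  ],
  [
   "C1",
   "H1"
  ],
  [
   "C2",
   "O2"
  ],
  [
   "O2",
   "HO2"
  ],
  [
   "C2",
   "H2"
  ],
  [
   "C3",
   "O3"
  ],
  [
   "O3",
   "HO3"
  ],
  [
   "C3",
   "H3"
  ],
  [
   "C4",
   "H4"
  ],
  [
   "C4",
   "C5"
  ],
  [
   "C5",
   "H51"
  ],
  [
   "C5",
   "H52"
  ],
  [
   "C5",
   "O5"
  ],
  [
   "O5",
   "HO5"
  ]
 ],
 "upstream_link": "C1",
 "upstream_delete": [
  "O1",
  "HO1"
 ],
 "downstream": {},
 "formal_charge": 0.0,
 "version": 1
}
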