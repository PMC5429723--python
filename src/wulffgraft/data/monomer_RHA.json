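{
 "resname": "RHA",
 "atoms": [
  {
   "name": "O5",
   "element": "O",
   "xyz": [
    1.435409,
    0.0,
    0.25
   ],
   "charge": -0.3
  },
  {
   "name": "C1",
   "element": "C",
   "xyz": [
    0.717705,
    1.243101,
    -0.25
   ],
   "charge": 0.06
  },
  {
   "name": "C2",
   "element": "C",
   "xyz": [
    -0.717705,
    1.243101,
    0.25
   ],
   "charge": -0.09
  },
  {
   "name": "C3",
   "element": "C",
   "xyz": [
    -1.435409,
    0.0,
    -0.25
   ],
   "charge": -0.09
  },
  {
   "name": "C4",
   "element": "C",
   "xyz": [
    -0.717705,
    -1.243101,
    0.25
   ],
   "charge": -0.09
  },
  {
   "name": "C5",
   "element": "C",
   "xyz": [
    0.717705,
    -1.243101,
    -0.25
   ],
   "charge": 0.06
  },
  {
   "name": "O1",
   "element": "O",
   "xyz": [
    1.324424,
    2.29397,
    -1.006615
   ],
   "charge": -0.42
  },
  {
   "name": "HO1",
   "element": "H",
   "xyz": [
    1.280654,
    3.143442,
    -1.451678
   ],
   "charge": 0.42
  },
  {
   "name": "H1",
   "element": "H",
   "xyz": [
    0.907876,
    1.572487,
    0.771489
   ],
   "charge": 0.09
  },
  {
   "name": "O2",
   "element": "O",
   "xyz": [
    -1.324424,
    2.29397,
    1.006615
   ],
   "charge": -0.42
  },
  {
   "name": "HO2",
   "element": "H",
   "xyz": [
    -2.081974,
    2.6808,
    1.451678
   ],
   "charge": 0.42
  },
  {
   "name": "H2",
   "element": "H",
   "xyz": [
    -0.907876,
    1.572487,
    -0.771489
   ],
   "charge": 0.09
  },
  {
   "name": "O3",
   "element": "O",
   "xyz": [
    -2.648848,
    0.0,
    -1.006615
   ],
   "charge": -0.42
  },
  {
   "name": "HO3",
   "element": "H",
   "xyz": [
    -3.362628,
    -0.462642,
    -1.451678
   ],
   "charge": 0.42
  },
  {
   "name": "H3",
   "element": "H",
   "xyz": [
    -1.815751,
    0.0,
    0.771489
   ],
   "charge": 0.09
  },
  {
   "name": "O4",
   "element": "O",
   "xyz": [
    -1.324424,
    -2.29397,
    1.006615
   ],
   "charge": -0.42
  },
  {
   "name": "HO4",
   "element": "H",
   "xyz": [
    -1.280654,
    -3.143442,
    1.451678
   ],
   "charge": 0.42
  },
  {
   "name": "H4",
   "element": "H",
   "xyz": [
    -0.907876,
    -1.572487,
    -0.771489
   ],
   "charge": 0.09
  },
  {
   "name": "H5",
   "element": "H",
   "xyz": [
    0.907876,
    -1.572487,
    0.771489
   ],
   "charge": 0.09
  },
  {
   "name": "C6",
   "element": "C",
   "xyz": [
    1.362609,
    -2.360108,
    -1.054234
   ],
   "charge": -0.27
  },
  {
   "name": "H61",
   "element": "H",
   "xyz": [
    2.357107,
    -2.541136,
    -1.462037
   ],
   "charge": 0.09
  },
  {
   "name": "H62",
   "element": "H",
   "xyz": [
    1.022135,
    -3.311883,
    -1.462037
   ],
   "charge": 0.09
  },
  {
   "name": "H63",
   "element": "H",
   "xyz": [
    1.62706,
    -2.818151,
    -2.007315
   ],
   "charge": 0.09
  }
 ],
 "bonds": [
  [
   "O5",
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
   "C5"
  ],
  [
   "C5",
   "O5"
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
   "O4"
  ],
  [
   "O4",
   "HO4"
  ],
  [
   "C4",
   "H4"
  ],
  [
   "C5",
   "H5"
  ],
  [
   "C5",
   "C6"
  ],
  [
   "C6",
   "H61"
  ],
  [
   "C6",
   "H62"
  ],
  [
   "C6",
   "H63"
  ]
 ],
 "upstream_link": "C1",
 "upstream_delete": [
  "O1",
  "HO1"
 ],
 "downstream": {
  "O4": "HO4",
  "O3": "HO3",
  "O2": "HO2"
 },
 "formal_charge": 0.0,
 "version": 1
}
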