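{
 "atoms": [
  [
   "C1",
   "C"
  ],
  [
   "C2",
   "C"
  ],
  [
   "C3",
   "C"
  ],
  [
   "C4",
   "C"
  ],
  [
   "C5",
   "C"
  ],
  [
   "C6",
   "C"
  ],
  [
   "O1",
   "O"
  ],
  [
   "H7",
   "H"
  ],
  [
   "H2",
   "H"
  ],
  [
   "H3",
   "H"
  ],
  [
   "H4",
   "H"
  ],
  [
   "H5",
   "H"
  ],
  [
   "H6",
   "H"
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "C1C2": 1.3927,
    "C1C2C3": 119.65,
    "C1C6H6": 119.24,
    "C1O1": 1.3632,
    "C1O1H7": 109.43,
    "C2C1O1": 122.44,
    "C2C3": 1.391,
    "C2C3C4": 120.56,
    "C2H2": 1.0888,
    "C3C2H2": 120.38,
    "C3C4": 1.3902,
    "C3C4C5": 119.22,
    "C3H3": 1.087,
    "C4C3H3": 120.14,
    "C4C5": 1.3929,
    "C4C5C6": 120.83,
    "C4H4": 1.0859,
    "C5C4H4": 120.43,
    "C5C6": 1.3926,
    "C5H5": 1.087,
    "C6C5H5": 119.24,
    "C6H6": 1.0859,
    "O1H7": 0.96
   }
  },
  "SE": {
   "fixed_params": [
    "C1C2C3",
    "C2C3C4",
    "C3C4C5",
    "C4C5C6",
    "C2C1O1",
    "C5C4H4",
    "C1C6H6"
   ],
   "sigmas": {
    "C1C2": 0.00064,
    "C1O1": 0.00028,
    "C1O1H7": 0.019,
    "C2C3": 0.00043,
    "C2H2": 0.00033,
    "C3C2H2": 0.041,
    "C3C4": 0.00043,
    "C3H3": 0.00022,
    "C4C3H3": 0.024,
    "C4C5": 0.00043,
    "C4H4": 0.00016,
    "C5C6": 0.00037,
    "C5H5": 0.00023,
    "C6C5H5": 0.025,
    "C6H6": 0.0003,
    "O1H7": 0.0005
   },
   "values": {
    "C1C2": 1.39197,
    "C1C2C3": 119.68,
    "C1C6H6": 119.05,
    "C1O1": 1.36386,
    "C1O1H7": 108.907,
    "C2C1O1": 122.42,
    "C2C3": 1.3901,
    "C2C3C4": 120.5,
    "C2H2": 1.08363,
    "C3C2H2": 120.507,
    "C3C4": 1.39018,
    "C3C4C5": 119.3,
    "C3H3": 1.0809,
    "C4C3H3": 120.164,
    "C4C5": 1.3917,
    "C4C5C6": 120.79,
    "C4H4": 1.0796,
    "C5C4H4": 120.37,
    "C5C6": 1.38882,
    "C5H5": 1.08133,
    "C6C5H5": 119.286,
    "C6H6": 1.07972,
    "O1H7": 0.95939
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C1C2": 1.3941,
    "C1C2C3": 119.68,
    "C1C6H6": 119.04,
    "C1O1": 1.3681,
    "C1O1H7": 108.94,
    "C2C1O1": 122.45,
    "C2C3": 1.3937,
    "C2C3C4": 120.5,
    "C2H2": 1.0856,
    "C3C2H2": 120.31,
    "C3C4": 1.3921,
    "C3C4C5": 119.3,
    "C3H3": 1.0836,
    "C4C3H3": 120.17,
    "C4C5": 1.3951,
    "C4C5C6": 120.74,
    "C4H4": 1.0826,
    "C5C4H4": 120.37,
    "C5C6": 1.3943,
    "C5H5": 1.0836,
    "C6C5H5": 119.28,
    "C6H6": 1.0828,
    "O1H7": 0.9624
   }
  }
 },
 "description": "phenol, planar",
 "id": "phenol",
 "placements": [
  {
   "atom": "C2",
   "bond_param": "C1C2",
   "bond_ref": "C1"
  },
  {
   "angle_param": "C1C2C3",
   "angle_ref": "C1",
   "atom": "C3",
   "bond_param": "C2C3",
   "bond_ref": "C2"
  },
  {
   "angle_param": "C2C3C4",
   "angle_ref": "C2",
   "atom": "C4",
   "bond_param": "C3C4",
   "bond_ref": "C3",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C4",
    "C3",
    "C2",
    "C1"
   ],
   "torsion_name": "C4C3C2C1",
   "torsion_value": 0.0
  },
  {
   "angle_param": "C3C4C5",
   "angle_ref": "C3",
   "atom": "C5",
   "bond_param": "C4C5",
   "bond_ref": "C4",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C5",
    "C4",
    "C3",
    "C2"
   ],
   "torsion_name": "C5C4C3C2",
   "torsion_value": 0.0
  },
  {
   "angle_param": "C4C5C6",
   "angle_ref": "C4",
   "atom": "C6",
   "bond_param": "C5C6",
   "bond_ref": "C5",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C6",
    "C5",
    "C4",
    "C3"
   ],
   "torsion_name": "C6C5C4C3",
   "torsion_value": 0.0
  },
  {
   "angle_param": "C2C1O1",
   "angle_ref": "C2",
   "atom": "O1",
   "bond_param": "C1O1",
   "bond_ref": "C1",
   "note": "in-plane completion",
   "torsion_atoms": [
    "O1",
    "C1",
    "C2",
    "C3"
   ],
   "torsion_name": "O1C1C2C3",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C1O1H7",
   "angle_ref": "C1",
   "atom": "H7",
   "bond_param": "O1H7",
   "bond_ref": "O1",
   "note": "in-plane completion, OH towards C2",
   "torsion_atoms": [
    "H7",
    "O1",
    "C1",
    "C2"
   ],
   "torsion_name": "H7O1C1C2",
   "torsion_value": 0.0
  },
  {
   "angle_param": "C3C2H2",
   "angle_ref": "C3",
   "atom": "H2",
   "bond_param": "C2H2",
   "bond_ref": "C2",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H2",
    "C2",
    "C3",
    "C4"
   ],
   "torsion_name": "H2C2C3C4",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C4C3H3",
   "angle_ref": "C4",
   "atom": "H3",
   "bond_param": "C3H3",
   "bond_ref": "C3",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H3",
    "C3",
    "C4",
    "C5"
   ],
   "torsion_name": "H3C3C4C5",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C5C4H4",
   "angle_ref": "C5",
   "atom": "H4",
   "bond_param": "C4H4",
   "bond_ref": "C4",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H4",
    "C4",
    "C5",
    "C6"
   ],
   "torsion_name": "H4C4C5C6",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C6C5H5",
   "angle_ref": "C6",
   "atom": "H5",
   "bond_param": "C5H5",
   "bond_ref": "C5",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H5",
    "C5",
    "C6",
    "C1"
   ],
   "torsion_name": "H5C5C6C1",
   "torsion_value": 180.0
  },
  {
   "angle_param": "C1C6H6",
   "angle_ref": "C1",
   "atom": "H6",
   "bond_param": "C6H6",
   "bond_ref": "C6",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H6",
    "C6",
    "C1",
    "C2"
   ],
   "torsion_name": "H6C6C1C2",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
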