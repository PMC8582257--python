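{
 "atoms": [
  [
   "O1",
   "O"
  ],
  [
   "N2",
   "N"
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
  ]
 ],
 "columns": {
  "PW6B95": {
   "values": {
    "C3C4": 1.4191,
    "C3H3": 1.0831,
    "C4C5": 1.3564,
    "C4H4": 1.0795,
    "C5H5": 1.0813,
    "CCC": 102.79,
    "CCN": 112.16,
    "CNO": 105.48,
    "H7C4C3": 128.87,
    "H8C5C4": 133.62,
    "HCN": 118.78,
    "N2C3": 1.3064,
    "O1N2": 1.3802
   }
  },
  "SE": {
   "sigmas": {
    "C3C4": 0.00061,
    "C3H3": 0.0005,
    "C4C5": 0.001,
    "C4H4": 0.00054,
    "C5H5": 0.0009,
    "CCC": 0.054,
    "CCN": 0.057,
    "CNO": 0.042,
    "H7C4C3": 0.13,
    "H8C5C4": 0.24,
    "HCN": 0.13,
    "N2C3": 0.00085,
    "O1N2": 0.00057
   },
   "values": {
    "C3C4": 1.42101,
    "C3H3": 1.0759,
    "C4C5": 1.3515,
    "C4H4": 1.07311,
    "C5H5": 1.07556,
    "CCC": 102.986,
    "CCN": 112.159,
    "CNO": 105.518,
    "H7C4C3": 128.44,
    "H8C5C4": 133.52,
    "HCN": 118.5,
    "N2C3": 1.30706,
    "O1N2": 1.39274
   }
  },
  "rev-DSDPBEP86": {
   "values": {
    "C3C4": 1.4213,
    "C3H3": 1.0793,
    "C4C5": 1.3577,
    "C4H4": 1.0759,
    "C5H5": 1.0777,
    "CCC": 103.003,
    "CCN": 112.2,
    "CNO": 105.41,
    "H7C4C3": 128.77,
    "H8C5C4": 133.64,
    "HCN": 118.71,
    "N2C3": 1.3121,
    "O1N2": 1.393
   }
  }
 },
 "description": "1,2-isoxazole, planar",
 "id": "isoxazole",
 "misprints": [
  {
   "note": "printed H7/H8 labels refer to the figure numbering; they are the ring C4-H and C5-H hydrogens",
   "param": "H7C4C3",
   "printed_label": "H7C4C3"
  }
 ],
 "placements": [
  {
   "atom": "N2",
   "bond_param": "O1N2",
   "bond_ref": "O1"
  },
  {
   "angle_param": "CNO",
   "angle_ref": "O1",
   "atom": "C3",
   "bond_param": "N2C3",
   "bond_ref": "N2"
  },
  {
   "angle_param": "CCN",
   "angle_ref": "N2",
   "atom": "C4",
   "bond_param": "C3C4",
   "bond_ref": "C3",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C4",
    "C3",
    "N2",
    "O1"
   ],
   "torsion_name": "C4C3N2O1",
   "torsion_value": 0.0
  },
  {
   "angle_param": "CCC",
   "angle_ref": "C3",
   "atom": "C5",
   "bond_param": "C4C5",
   "bond_ref": "C4",
   "note": "ring planarity completion",
   "torsion_atoms": [
    "C5",
    "C4",
    "C3",
    "N2"
   ],
   "torsion_name": "C5C4C3N2",
   "torsion_value": 0.0
  },
  {
   "angle_param": "HCN",
   "angle_ref": "N2",
   "atom": "H3",
   "bond_param": "C3H3",
   "bond_ref": "C3",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H3",
    "C3",
    "N2",
    "O1"
   ],
   "torsion_name": "H3C3N2O1",
   "torsion_value": 180.0
  },
  {
   "angle_param": "H7C4C3",
   "angle_ref": "C3",
   "atom": "H4",
   "bond_param": "C4H4",
   "bond_ref": "C4",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H4",
    "C4",
    "C3",
    "N2"
   ],
   "torsion_name": "H4C4C3N2",
   "torsion_value": 180.0
  },
  {
   "angle_param": "H8C5C4",
   "angle_ref": "C4",
   "atom": "H5",
   "bond_param": "C5H5",
   "bond_ref": "C5",
   "note": "in-plane completion",
   "torsion_atoms": [
    "H5",
    "C5",
    "C4",
    "C3"
   ],
   "torsion_name": "H5C5C4C3",
   "torsion_value": 180.0
  }
 ],
 "printed_mad": {}
}
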